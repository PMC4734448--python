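"""Community-level multivariate statistics.

From-scratch implementations of the ordination and permutation-test
toolkit used to relate community composition to space, season and
environment: the Hellinger transform and distance, principal coordinates
analysis (PCoA), PERMANOVA with sequential sums of squares, indicator
species analysis (IndVal), (partial) redundancy analysis with AIC-based
stepwise model selection, Pearson correlation screening, and exploratory
factor analysis by iterated principal-axis factoring with varimax
rotation and parallel analysis.

All permutation tests use the (1 + exceedances) / (1 + n_perm) estimator
and a seedable NumPy generator, so p >= 1/(n_perm + 1) always and results
are reproducible under a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .transport import ConfigError

__all__ = [
    "DistanceMatrix",
    "OrdinationResult",
    "IndicatorResult",
    "FactorModel",
    "hellinger",
    "hellinger_and_distance",
    "pcoa",
    "permanova",
    "indval",
    "rda",
    "stepwise_aic_rda",
    "efa",
    "parallel_analysis",
    "pearson_matrix",
    "tucker_congruence",
]


# ---------------------------------------------------------------------------
# containers


@dataclass
class DistanceMatrix:
    """Symmetric non-negative sample-by-sample distances, zero diagonal."""

    ids: list[str]
    data: np.ndarray

    def __post_init__(self) -> None:
        d = np.asarray(self.data, dtype=float)
        if d.ndim != 2 or d.shape[0] != d.shape[1]:
            raise ConfigError("distance matrix must be square")
        if len(self.ids) != d.shape[0]:
            raise ConfigError("ids length does not match matrix size")
        if not np.allclose(d, d.T, atol=1e-12):
            raise ConfigError("distance matrix must be symmetric")
        if (np.diag(d) != 0).any():
            raise ConfigError("distance matrix diagonal must be zero")
        if (d < 0).any():
            raise ConfigError("distances must be non-negative")
        self.data = 0.5 * (d + d.T)

    @property
    def n(self) -> int:
        return self.data.shape[0]


@dataclass
class OrdinationResult:
    eigenvalues: np.ndarray
    proportion_explained: np.ndarray
    samples: pd.DataFrame  # sample scores, axes in columns
    variables: pd.DataFrame | None = None  # constraint/variable scores
    features: pd.DataFrame | None = None  # OTU/species loadings
    p_value: float | None = None
    extras: dict = field(default_factory=dict)


@dataclass
class IndicatorResult:
    """Per-OTU indicator statistics: best group, A (specificity),
    B (fidelity), IndVal = sqrt(A*B) and permutation p."""

    table: pd.DataFrame  # columns: best_group, A, B, indval, p

    def significant(self, alpha: float = 0.05) -> pd.DataFrame:
        t = self.table.dropna(subset=["indval"])
        return t[t["p"] <= alpha]


@dataclass
class FactorModel:
    loadings: pd.DataFrame  # variables x factors
    uniquenesses: pd.Series
    n_factors: int
    rotation: str
    scores: pd.DataFrame | None = None

    @property
    def communalities(self) -> pd.Series:
        return (self.loadings**2).sum(axis=1)

    def assignments(self) -> pd.Series:
        """Each variable's max-|loading| factor."""
        return self.loadings.abs().idxmax(axis=1)


# ---------------------------------------------------------------------------
# Hellinger transform and PCoA


def hellinger(table) -> pd.DataFrame:
    """Hellinger transform: sqrt of row-closed relative abundances."""
    X = pd.DataFrame(table).astype(float)
    totals = X.sum(axis=1)
    if (totals <= 0).any():
        raise ConfigError("all-zero row in abundance table")
    return np.sqrt(X.div(totals, axis=0))


def hellinger_and_distance(table) -> tuple[pd.DataFrame, DistanceMatrix]:
    """Hellinger-transformed table and Euclidean distances between its rows."""
    H = hellinger(table)
    V = H.to_numpy()
    sq = (V**2).sum(axis=1)
    d2 = sq[:, None] + sq[None, :] - 2.0 * V @ V.T
    np.clip(d2, 0.0, None, out=d2)
    D = np.sqrt(d2)
    np.fill_diagonal(D, 0.0)
    return H, DistanceMatrix(ids=[str(i) for i in H.index], data=D)


def _gower_center(D: np.ndarray) -> np.ndarray:
    A = -0.5 * D**2
    n = D.shape[0]
    J = np.eye(n) - np.ones((n, n)) / n
    return J @ A @ J


def pcoa(D: DistanceMatrix) -> OrdinationResult:
    """Classical metric scaling (principal coordinates analysis).

    Gower double-centring followed by eigendecomposition.  Negative
    eigenvalues are reported but excluded from the explained proportions;
    scores are eigenvectors scaled by sqrt(eigenvalue) for positive axes.
    """
    B = _gower_center(D.data)
    evals, evecs = np.linalg.eigh(B)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    tol = 1e-10 * max(1.0, abs(evals[0]))
    pos = evals > tol
    scores = evecs[:, pos] * np.sqrt(evals[pos])
    prop = evals[pos] / evals[pos].sum()
    cols = [f"PC{k + 1}" for k in range(int(pos.sum()))]
    return OrdinationResult(
        eigenvalues=evals,
        proportion_explained=prop,
        samples=pd.DataFrame(scores, index=D.ids, columns=cols),
    )


# ---------------------------------------------------------------------------
# PERMANOVA


def _design_columns(metadata: pd.DataFrame, term: str) -> np.ndarray:
    col = metadata[term]
    if col.isna().any():
        raise ConfigError(f"metadata term {term!r} has missing values")
    if col.dtype.kind in "OUSb" or isinstance(col.dtype, pd.CategoricalDtype):
        dummies = pd.get_dummies(col, drop_first=True).to_numpy(dtype=float)
        if dummies.shape[1] == 0:
            raise ConfigError(f"term {term!r} has a single level")
        return dummies - dummies.mean(axis=0)
    v = col.to_numpy(dtype=float)
    return (v - v.mean())[:, None]


def _hat(X: np.ndarray) -> np.ndarray:
    # projection onto the column space via pinv (tolerant of scaling)
    return X @ np.linalg.pinv(X)


def permanova(
    D: DistanceMatrix,
    metadata: pd.DataFrame,
    terms: list[str],
    n_perm: int = 999,
    seed: int | np.random.Generator | None = None,
) -> pd.DataFrame:
    """Permutational multivariate ANOVA on a distance matrix.

    Partitions the total sum of squares of the Gower-centred matrix G
    sequentially over model terms (order-dependent for multi-term
    models), computes pseudo-F per term against the residual, and
    estimates p by permuting sample rows (raw permutation; the same
    permutation is applied to rows and columns of G).

    Returns a DataFrame indexed by term (plus 'Residual' and 'Total')
    with columns df, SS, F, R2, p.
    """
    if n_perm < 99:
        raise ConfigError("n_perm must be >= 99")
    n = D.n
    if len(metadata) != n:
        raise ConfigError("metadata length does not match distance matrix")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    G = _gower_center(D.data)
    ss_total = float(np.trace(G))

    blocks, dfs = [], []
    X = np.empty((n, 0))
    rank_prev = 0
    hats = []
    for term in terms:
        cols = _design_columns(metadata, term)
        X = np.hstack([X, cols])
        rank = np.linalg.matrix_rank(X)
        df_term = rank - rank_prev
        if df_term < cols.shape[1]:
            raise ConfigError(f"term {term!r} is aliased with earlier terms (rank deficient)")
        rank_prev = rank
        dfs.append(df_term)
        hats.append(_hat(X))
    H_full = hats[-1]
    df_res = n - 1 - sum(dfs)
    if df_res <= 0:
        raise ConfigError("no residual degrees of freedom")

    # sequential projectors: H_j - H_{j-1}; residual projector I - H_full
    diffs = []
    prev = np.zeros((n, n))
    for H in hats:
        diffs.append(H - prev)
        prev = H
    R = np.eye(n) - H_full

    def term_stats(Gm: np.ndarray):
        ss_terms = np.array([float(np.sum(Pd * Gm)) for Pd in diffs])
        ss_res = float(np.sum(R * Gm))
        F = (ss_terms / np.array(dfs)) / (ss_res / df_res)
        return ss_terms, ss_res, F

    ss_terms, ss_res, F_obs = term_stats(G)

    exceed = np.zeros(len(terms))
    for _ in range(n_perm):
        p = rng.permutation(n)
        _, _, F_perm = term_stats(G[np.ix_(p, p)])
        exceed += F_perm >= F_obs
    pvals = (1.0 + exceed) / (1.0 + n_perm)

    rows = {
        t: {"df": dfs[k], "SS": ss_terms[k], "F": F_obs[k], "R2": ss_terms[k] / ss_total, "p": pvals[k]}
        for k, t in enumerate(terms)
    }
    rows["Residual"] = {"df": df_res, "SS": ss_res, "F": np.nan, "R2": ss_res / ss_total, "p": np.nan}
    rows["Total"] = {"df": n - 1, "SS": ss_total, "F": np.nan, "R2": 1.0, "p": np.nan}
    return pd.DataFrame(rows).T


# ---------------------------------------------------------------------------
# indicator species analysis


def indval(
    table,
    groups,
    n_perm: int = 999,
    seed: int | np.random.Generator | None = None,
) -> IndicatorResult:
    """Indicator-value analysis (group-mean-corrected IndVal).

    For OTU i and group g: A = mean abundance in g divided by the sum of
    group means (specificity), B = fraction of g's samples containing the
    OTU (fidelity), IndVal = sqrt(A * B).  The statistic is the maximum
    over groups; significance by permutation of group labels.  OTUs absent
    from every sample are flagged (NaN statistics, no test).
    """
    X = pd.DataFrame(table).astype(float)
    labels = pd.Series(list(groups), index=X.index)
    uniq = sorted(labels.unique())
    if len(uniq) < 2:
        raise ConfigError("at least two groups are required")
    counts = labels.value_counts()
    if (counts < 2).any():
        raise ConfigError("every group needs at least 2 samples")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    V = X.to_numpy()
    present = (V > 0).astype(float)
    member = np.stack([(labels == g).to_numpy(dtype=float) for g in uniq])  # g x n
    sizes = member.sum(axis=1)[:, None]

    def stat(Vm, Pm):
        means = (member @ Vm) / sizes  # g x p
        denom = means.sum(axis=0, keepdims=True)
        with np.errstate(invalid="ignore", divide="ignore"):
            A = np.where(denom > 0, means / denom, np.nan)
        B = (member @ Pm) / sizes
        iv = np.sqrt(A * B)
        return iv

    iv_obs = stat(V, present)
    best = np.nanargmax(np.where(np.isnan(iv_obs), -1.0, iv_obs), axis=0)
    obs = iv_obs[best, np.arange(V.shape[1])]

    exceed = np.zeros(V.shape[1])
    for _ in range(n_perm):
        p = rng.permutation(V.shape[0])
        iv_p = stat(V[p], present[p])
        stat_p = np.nanmax(np.where(np.isnan(iv_p), -np.inf, iv_p), axis=0)
        exceed += stat_p >= obs - 1e-12
    pvals = (1.0 + exceed) / (1.0 + n_perm)

    absent = V.sum(axis=0) == 0
    means = (member @ V) / sizes
    denom = means.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        A_all = np.where(denom > 0, means / denom, np.nan)
    B_all = (member @ present) / sizes
    sel = np.arange(V.shape[1])
    out = pd.DataFrame(
        {
            "best_group": [uniq[b] for b in best],
            "A": A_all[best, sel],
            "B": B_all[best, sel],
            "indval": obs,
            "p": pvals,
        },
        index=X.columns,
    )
    out.loc[absent, ["best_group"]] = None
    out.loc[absent, ["A", "B", "indval", "p"]] = np.nan
    return IndicatorResult(table=out)


# ---------------------------------------------------------------------------
# redundancy analysis


def _aliased_columns(X: np.ndarray, names: list[str], tol: float = 1e-10) -> list[str]:
    """Names of columns linearly dependent on earlier ones."""
    bad, kept = [], np.empty((X.shape[0], 0))
    for j, name in enumerate(names):
        cand = np.hstack([kept, X[:, [j]]])
        if np.linalg.matrix_rank(cand, tol=None) == kept.shape[1]:
            bad.append(name)
        else:
            kept = cand
    return bad


def rda(
    Y,
    X,
    condition=None,
    n_perm: int = 999,
    seed: int | np.random.Generator | None = None,
) -> OrdinationResult:
    """(Partial) redundancy analysis.

    Y (samples x features, typically Hellinger-transformed) and the
    constraint matrix X are centred; when ``condition`` is given both are
    first residualised on the conditioning block, so the analysis reflects
    variation not attributable to the covariates.  The constrained axes
    are the principal components of the fitted values of the regression
    of Y on X.  A permutation test compares the constrained variance
    against row permutations of the (residualised) response.
    """
    Yd = pd.DataFrame(Y).astype(float)
    Xd = pd.DataFrame(X).astype(float)
    if len(Yd) != len(Xd):
        raise ConfigError("Y and X must have the same number of samples")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    n = len(Yd)
    Yc = Yd.to_numpy() - Yd.to_numpy().mean(axis=0)
    Xc = Xd.to_numpy() - Xd.to_numpy().mean(axis=0)
    pz = 0
    names = list(Xd.columns)
    if condition is not None:
        Zd = pd.DataFrame(condition).astype(float)
        Zc = Zd.to_numpy() - Zd.to_numpy().mean(axis=0)
        Hz = _hat(Zc)
        Yc = Yc - Hz @ Yc
        norms_before = np.linalg.norm(Xc, axis=0)
        Xc = Xc - Hz @ Xc
        # constraints absorbed by the conditioning block carry no signal
        absorbed = np.linalg.norm(Xc, axis=0) <= 1e-10 * np.maximum(norms_before, 1e-300)
        Xc = Xc[:, ~absorbed]
        names = [nm for nm, a in zip(names, absorbed) if not a]
        pz = int(np.linalg.matrix_rank(Zc))

    if Xc.shape[1]:
        bad = _aliased_columns(Xc, names)
        if bad:
            raise ConfigError(f"collinear constraint columns: {bad}")
    q = Xc.shape[1]
    if q == 0:
        zero = np.zeros(0)
        return OrdinationResult(
            eigenvalues=zero,
            proportion_explained=zero,
            samples=pd.DataFrame(index=Yd.index),
            variables=pd.DataFrame(index=Xd.columns),
            features=pd.DataFrame(index=Yd.columns),
            p_value=None,
            extras={"constrained_proportion": 0.0, "ss_constrained": 0.0,
                    "ss_total": float((Yc**2).sum())},
        )

    H = _hat(Xc)
    Yhat = H @ Yc
    U, s, Vt = np.linalg.svd(Yhat, full_matrices=False)
    lam = s**2 / (n - 1)
    tol = 1e-12 * max(1.0, lam[0] if lam.size else 1.0)
    keep = lam > tol
    lam = lam[keep]
    total_var = float((Yc**2).sum()) / (n - 1)
    ss_fit = float((Yhat**2).sum())
    ss_tot = float((Yc**2).sum())
    ss_res = ss_tot - ss_fit

    axes = [f"RDA{k + 1}" for k in range(int(keep.sum()))]
    sample_scores = pd.DataFrame(U[:, keep] * s[keep], index=Yd.index, columns=axes)
    # biplot scores: correlations of constraints with the constrained axes
    with np.errstate(invalid="ignore"):
        var_scores = pd.DataFrame(
            np.array(
                [
                    [
                        _safe_corr(Xc[:, j], sample_scores.iloc[:, k].to_numpy())
                        for k in range(len(axes))
                    ]
                    for j in range(q)
                ]
            ),
            index=names,
            columns=axes,
        )
    feat_scores = pd.DataFrame(Vt[keep].T, index=Yd.columns, columns=axes)

    df_res = n - 1 - q - pz
    p_value = None
    if n_perm and df_res > 0 and ss_res > 1e-14 * ss_tot:
        F_obs = (ss_fit / q) / (ss_res / df_res)
        exceed = 0
        for _ in range(n_perm):
            Yp = Yc[rng.permutation(n)]
            fit_p = float(((H @ Yp) ** 2).sum())
            res_p = float((Yp**2).sum()) - fit_p
            F_p = (fit_p / q) / (res_p / df_res)
            exceed += F_p >= F_obs
        p_value = (1.0 + exceed) / (1.0 + n_perm)

    return OrdinationResult(
        eigenvalues=lam,
        proportion_explained=lam / total_var if total_var > 0 else lam * 0,
        samples=sample_scores,
        variables=var_scores,
        features=feat_scores,
        p_value=p_value,
        extras={
            "constrained_proportion": ss_fit / ss_tot if ss_tot > 0 else 0.0,
            "ss_constrained": ss_fit,
            "ss_total": ss_tot,
        },
    )


def _safe_corr(a: np.ndarray, b: np.ndarray) -> float:
    sa, sb = a.std(), b.std()
    if sa == 0 or sb == 0:
        return np.nan
    return float(np.corrcoef(a, b)[0, 1])


def stepwise_aic_rda(
    Y,
    candidates,
    direction: str = "forward",
    condition=None,
) -> dict:
    """Stepwise RDA model selection with an RSS-based AIC analogue.

    AIC = n * ln(RSS / n) + 2 * (k + 1), where RSS is the residual sum of
    squares of the constrained fit and k the number of selected constraint
    columns.  Forward steps add (backward steps remove) the term giving
    the largest AIC decrease; ties break toward the first-listed term.
    Aliased candidates (no rank gain) are never added.

    Returns {'terms': [...], 'aic': final AIC, 'trace': [(terms, aic), ...]}.
    """
    if direction not in ("forward", "backward"):
        raise ConfigError("direction must be 'forward' or 'backward'")
    Yd = pd.DataFrame(Y).astype(float)
    Xall = pd.DataFrame(candidates).astype(float)
    if Xall.shape[1] < 1:
        raise ConfigError("at least one candidate term is required")
    n = len(Yd)
    Yc = Yd.to_numpy() - Yd.to_numpy().mean(axis=0)
    Xc = Xall.to_numpy() - Xall.to_numpy().mean(axis=0)
    if condition is not None:
        Zc = pd.DataFrame(condition).astype(float).to_numpy()
        Zc = Zc - Zc.mean(axis=0)
        Hz = _hat(Zc)
        Yc = Yc - Hz @ Yc
        Xc = Xc - Hz @ Xc
    names = list(Xall.columns)
    ss_tot = float((Yc**2).sum())

    def aic_for(cols: list[str]) -> float:
        if not cols:
            rss = ss_tot
            k = 0
        else:
            Xs = Xc[:, [names.index(c) for c in cols]]
            if np.linalg.matrix_rank(Xs) < Xs.shape[1]:
                return np.inf
            rss = ss_tot - float(((_hat(Xs) @ Yc) ** 2).sum())
            k = Xs.shape[1]
        rss = max(rss, 1e-12 * max(ss_tot, 1.0))
        return n * np.log(rss / n) + 2.0 * (k + 1)

    current = [] if direction == "forward" else list(names)
    best_aic = aic_for(current)
    trace = [(list(current), best_aic)]
    improved = True
    while improved:
        improved = False
        if direction == "forward":
            moves = [current + [c] for c in names if c not in current]
        else:
            moves = [[c for c in current if c != r] for r in current]
        best_move, best_move_aic = None, best_aic
        for cand in moves:  # in listed order: strict '<' keeps the first-listed tie
            a = aic_for(cand)
            if a < best_move_aic - 1e-9:
                best_move, best_move_aic = cand, a
        if best_move is not None:
            current, best_aic = best_move, best_move_aic
            improved = True
            trace.append((list(current), best_aic))
    return {"terms": current, "aic": best_aic, "trace": trace}


# ---------------------------------------------------------------------------
# exploratory factor analysis


def parallel_analysis(
    X,
    n_reps: int = 100,
    quantile: float = 0.95,
    seed: int | np.random.Generator | None = None,
) -> int:
    """Number of factors to retain by Horn's parallel analysis.

    Observed correlation-matrix eigenvalues are compared with the given
    quantile of eigenvalues from column-wise permuted data; factors are
    retained while the observed eigenvalue exceeds the permutation
    threshold, stopping at the first failure.
    """
    Xd = pd.DataFrame(X).astype(float)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    V = Xd.to_numpy()
    n, p = V.shape
    if n < 3 or p < 2:
        raise ConfigError("parallel analysis needs at least 3 samples and 2 variables")
    obs = np.sort(np.linalg.eigvalsh(np.corrcoef(V, rowvar=False)))[::-1]
    perm_eigs = np.empty((n_reps, p))
    W = V.copy()
    for r in range(n_reps):
        for j in range(p):
            rng.shuffle(W[:, j])
        perm_eigs[r] = np.sort(np.linalg.eigvalsh(np.corrcoef(W, rowvar=False)))[::-1]
    thresh = np.quantile(perm_eigs, quantile, axis=0)
    k = 0
    while k < p and obs[k] > thresh[k]:
        k += 1
    return k


def _varimax(L: np.ndarray, max_iter: int = 500, tol: float = 1e-8) -> np.ndarray:
    """Orthogonal varimax rotation of a loading matrix."""
    p, k = L.shape
    if k < 2:
        return L
    R = np.eye(k)
    var_old = 0.0
    for _ in range(max_iter):
        B = L @ R
        U, s, Vt = np.linalg.svd(L.T @ (B**3 - B @ np.diag((B**2).sum(axis=0)) / p))
        R = U @ Vt
        var_new = s.sum()
        if var_new - var_old < tol:
            break
        var_old = var_new
    return L @ R


def efa(
    X,
    n_factors: int | str = "auto",
    rotation: str = "varimax",
    max_iter: int = 1000,
    tol: float = 1e-6,
    seed: int | np.random.Generator | None = None,
) -> FactorModel:
    """Exploratory factor analysis by iterated principal-axis factoring.

    Communalities are initialised at squared multiple correlations and
    iterated to convergence; ``n_factors='auto'`` chooses the count by
    parallel analysis.  Varimax (orthogonal) rotation by default;
    ``rotation=None`` returns the unrotated solution.  Factor scores by
    the regression (Thurstone) method.  Each variable is assigned to its
    max-|loading| factor via :meth:`FactorModel.assignments`.
    """
    Xd = pd.DataFrame(X).astype(float)
    if len(Xd) < 2:
        raise ConfigError("EFA needs at least 2 samples")
    stds = Xd.std(ddof=1)
    if (stds == 0).any():
        raise ConfigError(f"constant variables: {list(stds.index[stds == 0])}")
    Z = (Xd - Xd.mean()) / stds
    R = np.corrcoef(Z.to_numpy(), rowvar=False)
    p = R.shape[0]

    if n_factors == "auto":
        k = parallel_analysis(Xd, seed=seed)
        if k == 0:
            raise ConfigError("parallel analysis retained 0 factors")
    else:
        k = int(n_factors)
    if not (1 <= k < p):
        raise ConfigError(f"n_factors must be in [1, {p - 1}]")

    # initial communalities: squared multiple correlations (ridge-guarded)
    try:
        Rinv = np.linalg.inv(R)
        h2 = np.clip(1.0 - 1.0 / np.diag(Rinv), 0.0, 0.995)
    except np.linalg.LinAlgError:
        h2 = np.full(p, 0.5)

    L = None
    for it in range(max_iter):
        Rr = R.copy()
        np.fill_diagonal(Rr, h2)
        evals, evecs = np.linalg.eigh(Rr)
        order = np.argsort(evals)[::-1][:k]
        lam = np.clip(evals[order], 0.0, None)
        L = evecs[:, order] * np.sqrt(lam)
        h2_new = np.clip((L**2).sum(axis=1), 0.0, 0.995)
        if np.max(np.abs(h2_new - h2)) < tol:
            h2 = h2_new
            break
        h2 = h2_new
    else:
        raise ConfigError(f"communality iteration did not converge in {max_iter} iterations")

    if rotation == "varimax":
        L = _varimax(L)
    elif rotation not in (None, "none"):
        raise ConfigError(f"unknown rotation {rotation!r}")

    # orient each factor so its largest-|loading| entry is positive
    for j in range(L.shape[1]):
        i = np.argmax(np.abs(L[:, j]))
        if L[i, j] < 0:
            L[:, j] = -L[:, j]
    # order factors by explained variance (sum of squared loadings)
    order = np.argsort(-(L**2).sum(axis=0))
    L = L[:, order]

    cols = [f"MR{j + 1}" for j in range(k)]
    loadings = pd.DataFrame(L, index=Xd.columns, columns=cols)
    uniq = pd.Series(np.clip(1.0 - (L**2).sum(axis=1), 0.0, None), index=Xd.columns)
    scores = pd.DataFrame(
        Z.to_numpy() @ np.linalg.solve(R, L), index=Xd.index, columns=cols
    )
    return FactorModel(
        loadings=loadings,
        uniquenesses=uniq,
        n_factors=k,
        rotation=rotation or "none",
        scores=scores,
    )


def tucker_congruence(A, B) -> np.ndarray:
    """Tucker congruence coefficients between columns of two loading matrices."""
    A = np.asarray(A, dtype=float)
    B = np.asarray(B, dtype=float)
    num = A.T @ B
    den = np.sqrt(np.outer((A**2).sum(axis=0), (B**2).sum(axis=0)))
    return num / den


# ---------------------------------------------------------------------------
# Pearson screening


def pearson_matrix(X, threshold: float = 0.3, absolute: bool = True) -> dict:
    """Pairwise Pearson correlations with two-sided t-test p-values.

    Constant columns yield undefined correlations (NaN), flagged and
    excluded from the reported fraction of pairs whose correlation
    exceeds the threshold.
    """
    Xd = pd.DataFrame(X).astype(float)
    n, p = Xd.shape
    if n < 3:
        raise ConfigError("need at least 3 observations")
    V = Xd.to_numpy()
    stds = V.std(axis=0, ddof=1)
    constant = stds == 0
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.corrcoef(V, rowvar=False)
    r[constant, :] = np.nan
    r[:, constant] = np.nan
    np.fill_diagonal(r, np.where(constant, np.nan, 1.0))

    with np.errstate(invalid="ignore", divide="ignore"):
        t = r * np.sqrt((n - 2) / (1.0 - r**2))
    pmat = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
    np.fill_diagonal(pmat, 0.0)
    pmat[np.isnan(r)] = np.nan

    iu = np.triu_indices(p, k=1)
    pairs = r[iu]
    valid = ~np.isnan(pairs)
    vals = np.abs(pairs[valid]) if absolute else pairs[valid]
    frac = float((vals > threshold).mean()) if valid.any() else np.nan
    return {
        "r": pd.DataFrame(r, index=Xd.columns, columns=Xd.columns),
        "p": pd.DataFrame(pmat, index=Xd.columns, columns=Xd.columns),
        "fraction_above_threshold": frac,
        "constant_columns": list(Xd.columns[constant]),
    }
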