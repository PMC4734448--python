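"""Per-sample community processing and alpha-diversity statistics.

Covers the per-sample stages of an amplicon profiling workflow downstream
of OTU picking: rarefaction to a common depth, 16S gene-copy-number
correction, alpha diversity (richness, Shannon-Wiener index and evenness,
Chao1), the one-sided Mann-Whitney U test used to compare diversity
between sample groups, and the eukaryote-to-prokaryote read ratio (EPR).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .transport import ConfigError

__all__ = [
    "OtuTable",
    "DiversityRecord",
    "rarefy",
    "expected_richness",
    "rarefaction_curve",
    "copy_number_correct",
    "alpha_diversity",
    "alpha_diversity_table",
    "mann_whitney_one_sided",
    "eukaryote_prokaryote_ratio",
]


@dataclass
class OtuTable:
    """Samples x OTUs count table with per-OTU annotations.

    counts : DataFrame (rows = samples, columns = OTU ids), non-negative.
    taxonomy : Series mapping OTU id -> 7-rank taxonomy string.
    copy_number : Series mapping OTU id -> 16S gene copy number (> 0).
    domain : Series mapping OTU id -> 'prokaryote' | 'eukaryote'.
    """

    counts: pd.DataFrame
    taxonomy: pd.Series
    copy_number: pd.Series
    domain: pd.Series

    def __post_init__(self) -> None:
        if (self.counts.values < 0).any():
            raise ConfigError("negative counts in OTU table")
        missing = self.counts.columns.difference(self.taxonomy.index)
        if len(missing):
            raise ConfigError(f"taxonomy missing for OTUs: {list(missing)[:5]}")
        if (self.copy_number.reindex(self.counts.columns) <= 0).any():
            raise ConfigError("copy numbers must be positive for every OTU")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def otu_ids(self) -> list[str]:
        return list(self.counts.columns)

    def prokaryotes(self) -> "OtuTable":
        keep = self.counts.columns[self.domain.reindex(self.counts.columns) == "prokaryote"]
        return self.subset_otus(keep)

    def subset_otus(self, otus) -> "OtuTable":
        return OtuTable(
            counts=self.counts[list(otus)],
            taxonomy=self.taxonomy.reindex(otus),
            copy_number=self.copy_number.reindex(otus),
            domain=self.domain.reindex(otus),
        )

    def relative_abundance(self) -> pd.DataFrame:
        totals = self.counts.sum(axis=1)
        return self.counts.div(totals, axis=0)


@dataclass
class DiversityRecord:
    sample_id: str
    richness: int
    shannon: float
    evenness: float
    chao1: float


def rarefy(
    table: OtuTable,
    depth: int,
    mode: str = "draw",
    seed: int | np.random.Generator | None = None,
    subsample: str = "without",
) -> tuple[OtuTable, list[str]]:
    """Rarefy every sample to a common depth.

    mode='draw' takes one without-replacement subsample of size ``depth``
    per sample.  mode='expected' returns the expected (real-valued) count
    per OTU under repeated subsampling, which for both with-replacement
    (bootstrap) and without-replacement schemes equals depth * p_i; the
    two schemes differ in expected richness (see ``expected_richness``).
    Samples whose total is below ``depth`` are dropped and reported in the
    second return value.
    """
    if depth <= 0:
        raise ConfigError("rarefaction depth must be >= 1")
    if mode not in ("draw", "expected"):
        raise ConfigError(f"unknown rarefaction mode {mode!r}")
    if subsample not in ("with", "without"):
        raise ConfigError("subsample must be 'with' or 'without'")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed

    totals = table.counts.sum(axis=1)
    dropped = list(table.counts.index[totals < depth])
    kept = table.counts.loc[totals >= depth]

    if mode == "expected":
        new = kept.div(kept.sum(axis=1), axis=0) * depth
    else:
        rows = []
        for _, row in kept.iterrows():
            vals = row.to_numpy()
            if subsample == "without":
                rows.append(rng.multivariate_hypergeometric(vals.astype(np.int64), depth))
            else:
                rows.append(rng.multinomial(depth, vals / vals.sum()))
        new = pd.DataFrame(np.array(rows), index=kept.index, columns=kept.columns)

    out = OtuTable(
        counts=new,
        taxonomy=table.taxonomy,
        copy_number=table.copy_number,
        domain=table.domain,
    )
    return out, dropped


def expected_richness(counts, depth: int, mode: str = "bootstrap") -> float:
    """Expected number of OTUs observed in a subsample of size ``depth``.

    mode='bootstrap' (with replacement, the 'infinite bootstrap' reading):
        E[S] = sum_i 1 - (1 - p_i)^depth.
    mode='hypergeometric' (classical rarefaction, without replacement):
        E[S] = sum_i 1 - C(N - n_i, depth) / C(N, depth).
    """
    n = np.asarray(counts, dtype=float)
    n = n[n > 0]
    if n.size == 0:
        raise ConfigError("empty sample")
    N = n.sum()
    if mode == "bootstrap":
        return float((1.0 - (1.0 - n / N) ** depth).sum())
    if mode == "hypergeometric":
        if depth > N:
            raise ConfigError("depth exceeds sample total for hypergeometric rarefaction")
        # C(N-n_i, depth)/C(N, depth) via log-gammas for numerical safety
        from scipy.special import gammaln

        def logC(a, b):
            return gammaln(a + 1) - gammaln(b + 1) - gammaln(a - b + 1)

        keep = (N - n) >= depth
        prob_absent = np.zeros_like(n)
        prob_absent[keep] = np.exp(logC(N - n[keep], depth) - logC(N, depth))
        return float((1.0 - prob_absent).sum())
    raise ConfigError(f"unknown mode {mode!r}")


def rarefaction_curve(counts, depths, mode: str = "bootstrap") -> pd.DataFrame:
    """Expected richness at a ladder of depths (one sample)."""
    return pd.DataFrame(
        {"depth": list(depths), "expected_richness": [expected_richness(counts, d, mode) for d in depths]}
    )


def copy_number_correct(relabund, copy_number):
    """Divide relative abundances by 16S copy numbers and renormalise.

    Converts read fractions into cell-abundance estimates:
    out_i = (a_i / c_i) / sum_j (a_j / c_j).  Accepts a 1D vector or a
    samples x OTUs DataFrame (corrected row-wise).
    """
    c = np.asarray(copy_number, dtype=float)
    if (c <= 0).any():
        raise ConfigError("copy numbers must be positive")
    if isinstance(relabund, pd.DataFrame):
        w = relabund.div(pd.Series(c, index=relabund.columns), axis=1)
        return w.div(w.sum(axis=1), axis=0)
    a = np.asarray(relabund, dtype=float)
    w = a / c
    return w / w.sum()


def alpha_diversity(counts, sample_id: str = "", base: float | None = None) -> DiversityRecord:
    """Alpha diversity of one sample's counts.

    richness = number of OTUs present; Shannon H = -sum p ln p in nats by
    default (``base=2`` for bits); evenness = H / ln(richness) (0 when a
    single OTU is present); Chao1 = S + F1^2/(2 F2), with the
    bias-corrected form S + F1(F1-1)/(2(F2+1)) when no doubletons exist.
    """
    n = np.asarray(counts, dtype=float)
    n = n[n > 0]
    if n.size == 0:
        raise ConfigError("empty sample")
    total = n.sum()
    p = n / total
    log = np.log if base is None else (lambda x: np.log(x) / np.log(base))
    H = float(-(p * log(p)).sum())
    S = int(n.size)
    evenness = H / float(log(S)) if S > 1 else 0.0
    F1 = int((n == 1).sum())
    F2 = int((n == 2).sum())
    if F2 > 0:
        chao1 = S + F1 * F1 / (2.0 * F2)
    else:
        chao1 = S + F1 * (F1 - 1) / 2.0  # bias-corrected with F2 = 0
    return DiversityRecord(sample_id=sample_id, richness=S, shannon=H, evenness=evenness, chao1=chao1)


def alpha_diversity_table(table: OtuTable, base: float | None = None) -> pd.DataFrame:
    """Alpha diversity for every sample of a table."""
    recs = [alpha_diversity(row.to_numpy(), sid, base) for sid, row in table.counts.iterrows()]
    return pd.DataFrame(
        {
            "sample_id": [r.sample_id for r in recs],
            "richness": [r.richness for r in recs],
            "shannon": [r.shannon for r in recs],
            "evenness": [r.evenness for r in recs],
            "chao1": [r.chao1 for r in recs],
        }
    ).set_index("sample_id")


def mann_whitney_one_sided(x, y, alternative: str = "greater") -> dict:
    """One-sided (unilateral) Mann-Whitney U test.

    Exact p by enumeration when n_x + n_y <= 12 and there are no ties,
    otherwise the normal approximation with tie and continuity
    corrections.  Returns {'U': U statistic of x, 'p': p-value}.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 1 or y.size < 1:
        raise ConfigError("both groups must be non-empty")
    if alternative not in ("greater", "less"):
        raise ConfigError("alternative must be 'greater' or 'less'")
    no_ties = np.unique(np.concatenate([x, y])).size == x.size + y.size
    method = "exact" if (x.size + y.size <= 12 and no_ties) else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative=alternative, method=method)
    return {"U": float(res.statistic), "p": float(res.pvalue)}


def eukaryote_prokaryote_ratio(table: OtuTable) -> pd.Series:
    """Per-sample eukaryote/prokaryote read ratio on unrarefied counts.

    Samples with zero prokaryote reads are flagged undefined (NaN).
    """
    dom = table.domain.reindex(table.counts.columns)
    if dom.isna().any():
        raise ConfigError("domain labels missing for some OTUs")
    euk = table.counts.loc[:, dom == "eukaryote"].sum(axis=1)
    prok = table.counts.loc[:, dom == "prokaryote"].sum(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        epr = euk / prok
    return epr.where(prok > 0, np.nan)
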