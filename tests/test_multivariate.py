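"""Ordination, permutation tests and factor analysis against oracles.

scikit-bio provides the independent cross-checks for PCoA and PERMANOVA;
closed-form and brute-force oracles cover the rest.
"""

import numpy as np
import pandas as pd
import pytest

from reefplume.multivariate import (
    DistanceMatrix,
    efa,
    hellinger_and_distance,
    indval,
    parallel_analysis,
    pcoa,
    pearson_matrix,
    permanova,
    rda,
    stepwise_aic_rda,
    tucker_congruence,
)
from reefplume.transport import ConfigError


# ---------------------------------------------------------------------------
# Hellinger


class TestHellinger:
    def test_identical_rows_distance_zero(self):
        X = pd.DataFrame([[3, 1, 2], [6, 2, 4]])
        _, D = hellinger_and_distance(X)
        assert D.data[0, 1] == pytest.approx(0.0, abs=1e-12)

    def test_disjoint_compositions_reach_sqrt_two(self):
        X = pd.DataFrame([[1, 0], [0, 1]])
        _, D = hellinger_and_distance(X)
        assert D.data[0, 1] == pytest.approx(np.sqrt(2), abs=1e-12)

    def test_hand_evaluated_pair(self):
        X = pd.DataFrame([[1.0, 0.0], [0.25, 0.75]])
        _, D = hellinger_and_distance(X)
        expected = np.sqrt((1 - 0.5) ** 2 + (0 - np.sqrt(0.75)) ** 2)
        assert expected == pytest.approx(1.0, abs=1e-12)
        assert D.data[0, 1] == pytest.approx(expected, abs=1e-12)

    def test_all_zero_row_rejected(self):
        with pytest.raises(ConfigError):
            hellinger_and_distance(pd.DataFrame([[1, 1], [0, 0]]))


# ---------------------------------------------------------------------------
# PCoA


class TestPcoa:
    def test_recovers_euclidean_configuration(self):
        rng = np.random.default_rng(0)
        pts = rng.standard_normal((15, 4))
        from scipy.spatial.distance import cdist

        D = DistanceMatrix(ids=[str(i) for i in range(15)], data=cdist(pts, pts))
        res = pcoa(D)
        # pairwise distances of recovered scores reproduce the input
        rec = cdist(res.samples.to_numpy(), res.samples.to_numpy())
        np.testing.assert_allclose(rec, D.data, atol=1e-8)

    def test_matches_pca_of_hellinger_table(self):
        rng = np.random.default_rng(1)
        X = pd.DataFrame(rng.random((12, 20)))
        H, D = hellinger_and_distance(X)
        res = pcoa(D)
        Hc = H.to_numpy() - H.to_numpy().mean(axis=0)
        U, s, _ = np.linalg.svd(Hc, full_matrices=False)
        pca_scores = U * s
        m = res.samples.shape[1]
        for k in range(min(m, 8)):
            a = res.samples.to_numpy()[:, k]
            b = pca_scores[:, k]
            assert min(np.abs(a - b).max(), np.abs(a + b).max()) < 1e-8

    def test_equidistant_points_give_equal_eigenvalues(self):
        n = 7
        D = DistanceMatrix(ids=[str(i) for i in range(n)], data=np.ones((n, n)) - np.eye(n))
        res = pcoa(D)
        pos = res.eigenvalues[res.eigenvalues > 1e-10]
        assert len(pos) == n - 1
        assert np.ptp(pos) < 1e-10

    def test_cross_check_against_skbio(self):
        import skbio

        rng = np.random.default_rng(2)
        X = pd.DataFrame(rng.random((10, 15)))
        _, D = hellinger_and_distance(X)
        res = pcoa(D)
        sk = skbio.stats.ordination.pcoa(skbio.DistanceMatrix(D.data, ids=D.ids))
        np.testing.assert_allclose(
            res.eigenvalues[: len(res.proportion_explained)],
            sk.eigvals.values[: len(res.proportion_explained)],
            atol=1e-8,
        )


# ---------------------------------------------------------------------------
# PERMANOVA


def _classical_pseudo_f(D, labels):
    """Direct within/between-group oracle for a one-way design."""
    labels = np.asarray(labels)
    n = len(labels)
    ss_total = (D**2).sum() / (2 * n)
    ss_within = 0.0
    for g in np.unique(labels):
        idx = np.where(labels == g)[0]
        sub = D[np.ix_(idx, idx)]
        ss_within += (sub**2).sum() / (2 * len(idx))
    a = len(np.unique(labels))
    ss_among = ss_total - ss_within
    return (ss_among / (a - 1)) / (ss_within / (n - a))


class TestPermanova:
    def test_one_way_matches_classical_oracle(self):
        rng = np.random.default_rng(3)
        X = pd.DataFrame(rng.random((18, 25)))
        _, D = hellinger_and_distance(X)
        labels = ["a"] * 6 + ["b"] * 6 + ["c"] * 6
        meta = pd.DataFrame({"g": labels})
        res = permanova(D, meta, ["g"], n_perm=99, seed=0)
        assert res.loc["g", "F"] == pytest.approx(_classical_pseudo_f(D.data, labels), abs=1e-10)

    def test_cross_check_against_skbio(self):
        import skbio

        rng = np.random.default_rng(4)
        X = pd.DataFrame(rng.random((16, 30)))
        _, D = hellinger_and_distance(X)
        labels = ["a"] * 8 + ["b"] * 8
        res = permanova(D, pd.DataFrame({"g": labels}), ["g"], n_perm=99, seed=0)
        sk = skbio.stats.distance.permanova(
            skbio.DistanceMatrix(D.data, ids=D.ids), labels, permutations=99
        )
        assert res.loc["g", "F"] == pytest.approx(sk["test statistic"], abs=1e-9)

    def test_identical_groups_explain_nothing(self):
        rng = np.random.default_rng(5)
        block = rng.random((10, 12))
        X = pd.DataFrame(np.vstack([block, block]))  # two identical copies
        _, D = hellinger_and_distance(X)
        labels = ["a"] * 10 + ["b"] * 10
        res = permanova(D, pd.DataFrame({"g": labels}), ["g"], n_perm=199, seed=0)
        assert res.loc["g", "R2"] < 0.02
        assert res.loc["g", "p"] > 0.3

    def test_sequential_r2_partition_sums_to_one(self):
        rng = np.random.default_rng(6)
        X = pd.DataFrame(rng.random((20, 15)))
        _, D = hellinger_and_distance(X)
        meta = pd.DataFrame(
            {"g": ["a", "b"] * 10, "x": rng.standard_normal(20)}
        )
        res = permanova(D, meta, ["g", "x"], n_perm=99, seed=0)
        assert res.loc[["g", "x", "Residual"], "R2"].sum() == pytest.approx(1.0, abs=1e-10)

    def test_aliased_term_raises(self):
        rng = np.random.default_rng(7)
        X = pd.DataFrame(rng.random((10, 8)))
        _, D = hellinger_and_distance(X)
        v = rng.standard_normal(10)
        meta = pd.DataFrame({"x1": v, "x2": 2 * v})
        with pytest.raises(ConfigError, match="aliased"):
            permanova(D, meta, ["x1", "x2"], n_perm=99, seed=0)

    def test_pvalues_reproducible_and_bounded(self):
        rng = np.random.default_rng(8)
        X = pd.DataFrame(rng.random((12, 10)))
        _, D = hellinger_and_distance(X)
        meta = pd.DataFrame({"g": ["a", "b"] * 6})
        p1 = permanova(D, meta, ["g"], n_perm=199, seed=11).loc["g", "p"]
        p2 = permanova(D, meta, ["g"], n_perm=199, seed=11).loc["g", "p"]
        assert p1 == p2
        assert p1 >= 1 / 200


# ---------------------------------------------------------------------------
# IndVal


class TestIndval:
    def test_perfect_indicator(self):
        rng = np.random.default_rng(9)
        n = 12
        X = pd.DataFrame(rng.random((n, 5)) + 0.5)
        X["ind"] = 0.0
        X.loc[X.index[:6], "ind"] = 1.0  # present in every group-a sample only
        groups = ["a"] * 6 + ["b"] * 6
        res = indval(X, groups, n_perm=999, seed=0)
        row = res.table.loc["ind"]
        assert row["A"] == pytest.approx(1.0, abs=1e-12)
        assert row["B"] == pytest.approx(1.0, abs=1e-12)
        assert row["indval"] == pytest.approx(1.0, abs=1e-12)
        assert row["p"] <= 0.05

    def test_uniform_otu_closed_form(self):
        n, g = 12, 3
        X = pd.DataFrame({"u": np.ones(n), "noise": np.arange(n, dtype=float) + 1})
        groups = ["a"] * 4 + ["b"] * 4 + ["c"] * 4
        res = indval(X, groups, n_perm=99, seed=0)
        assert res.table.loc["u", "indval"] == pytest.approx(np.sqrt(1 / g), abs=1e-12)

    def test_absent_otu_flagged(self):
        X = pd.DataFrame({"zero": np.zeros(8), "ok": np.ones(8)})
        res = indval(X, ["a"] * 4 + ["b"] * 4, n_perm=99, seed=0)
        assert np.isnan(res.table.loc["zero", "indval"])
        assert res.table.loc["zero", "best_group"] is None

    def test_requires_two_groups_with_two_samples(self):
        X = pd.DataFrame({"x": np.ones(4)})
        with pytest.raises(ConfigError):
            indval(X, ["a"] * 4, n_perm=99)
        with pytest.raises(ConfigError):
            indval(X, ["a", "a", "a", "b"], n_perm=99)


# ---------------------------------------------------------------------------
# RDA


class TestRda:
    def test_orthogonal_constraint_explains_nothing(self):
        rng = np.random.default_rng(10)
        n = 40
        y_axis = rng.standard_normal(n)
        Y = pd.DataFrame({"f1": y_axis, "f2": 2 * y_axis})
        x = rng.standard_normal(n)
        x -= x.mean()
        # residualise x against Y's single axis -> exactly orthogonal constraint
        yc = y_axis - y_axis.mean()
        x = x - yc * (x @ yc) / (yc @ yc)
        fit = rda(Y, pd.DataFrame({"x": x}), n_perm=0)
        assert fit.extras["constrained_proportion"] < 1e-10

    def test_categorical_constraints_equal_group_mean_pca(self):
        rng = np.random.default_rng(11)
        n, p = 18, 12
        Y = pd.DataFrame(rng.random((n, p)))
        groups = np.repeat(["a", "b", "c"], 6)
        X = pd.get_dummies(pd.Series(groups), drop_first=True).astype(float)
        fit = rda(Y, X, n_perm=0)
        # oracle: PCA of per-sample group means of the centred response
        Yc = Y.to_numpy() - Y.to_numpy().mean(axis=0)
        M = np.vstack([Yc[groups == g].mean(axis=0) for g in groups])
        U, s, _ = np.linalg.svd(M, full_matrices=False)
        lam = (s**2) / (n - 1)
        lam = lam[lam > 1e-12]
        np.testing.assert_allclose(fit.eigenvalues, lam, atol=1e-8)
        scores = U[:, : len(lam)] * s[: len(lam)]
        for k in range(len(lam)):
            a, b = fit.samples.to_numpy()[:, k], scores[:, k]
            assert min(np.abs(a - b).max(), np.abs(a + b).max()) < 1e-8

    def test_conditioning_on_constraint_leaves_zero(self):
        rng = np.random.default_rng(12)
        Y = pd.DataFrame(rng.random((20, 8)))
        X = pd.DataFrame({"x": rng.standard_normal(20)})
        fit = rda(Y, X, condition=X, n_perm=0)
        assert fit.extras["constrained_proportion"] < 1e-10

    def test_constrained_plus_residual_totals_variance(self):
        rng = np.random.default_rng(13)
        Y = pd.DataFrame(rng.random((25, 10)))
        X = pd.DataFrame(rng.standard_normal((25, 3)), columns=list("abc"))
        fit = rda(Y, X, n_perm=0)
        assert fit.extras["ss_constrained"] <= fit.extras["ss_total"] + 1e-10
        Yc = Y.to_numpy() - Y.to_numpy().mean(axis=0)
        assert fit.extras["ss_total"] == pytest.approx(float((Yc**2).sum()), abs=1e-10)

    def test_collinear_constraints_named(self):
        rng = np.random.default_rng(14)
        Y = pd.DataFrame(rng.random((15, 6)))
        v = rng.standard_normal(15)
        X = pd.DataFrame({"a": v, "b": -3 * v})
        with pytest.raises(ConfigError, match="b"):
            rda(Y, X, n_perm=0)

    def test_true_covariate_association_detected(self):
        rng = np.random.default_rng(15)
        n = 30
        x = rng.standard_normal(n)
        Y = pd.DataFrame(np.outer(x, rng.random(8)) + 0.3 * rng.standard_normal((n, 8)))
        fit = rda(Y, pd.DataFrame({"x": x}), n_perm=199, seed=0)
        assert fit.p_value <= 0.05


class TestStepwiseAic:
    def test_signal_covariate_selected_noise_rejected(self):
        rng = np.random.default_rng(16)
        hits = 0
        for rep in range(25):
            n = 30
            x = rng.standard_normal(n)
            noise = rng.standard_normal((n, 3))
            Y = pd.DataFrame(np.outer(x, rng.random(6)) + 0.4 * rng.standard_normal((n, 6)))
            cand = pd.DataFrame(np.column_stack([x, noise]), columns=["sig", "n1", "n2", "n3"])
            sel = stepwise_aic_rda(Y, cand)["terms"]
            if "sig" in sel:
                hits += 1
        assert hits >= 23  # > 0.9 selection frequency

    def test_null_candidates_mostly_empty(self):
        rng = np.random.default_rng(17)
        empties = 0
        for rep in range(25):
            Y = pd.DataFrame(rng.standard_normal((30, 6)))
            cand = pd.DataFrame(rng.standard_normal((30, 3)), columns=["a", "b", "c"])
            if not stepwise_aic_rda(Y, cand)["terms"]:
                empties += 1
        assert empties >= 15

    def test_duplicated_covariate_never_selected_twice(self):
        rng = np.random.default_rng(18)
        n = 30
        x = rng.standard_normal(n)
        Y = pd.DataFrame(np.outer(x, rng.random(5)) + 0.2 * rng.standard_normal((n, 5)))
        cand = pd.DataFrame({"a": x, "a_copy": x.copy()})
        sel = stepwise_aic_rda(Y, cand)["terms"]
        assert len(sel) == 1


# ---------------------------------------------------------------------------
# EFA


class TestEfa:
    @staticmethod
    def _factor_data(rng, n=200, loading=0.8, noise=0.6):
        F = rng.standard_normal((n, 2))
        L = np.zeros((6, 2))
        L[:3, 0] = loading
        L[3:, 1] = loading
        X = F @ L.T + noise * rng.standard_normal((n, 6))
        return pd.DataFrame(X, columns=[f"v{i}" for i in range(6)]), L

    def test_recovers_planted_loadings(self):
        rng = np.random.default_rng(19)
        X, L = self._factor_data(rng)
        fm = efa(X, n_factors=2, seed=0)
        phi = np.abs(tucker_congruence(L, fm.loadings.to_numpy()))
        assert phi.max(axis=1).min() > 0.9

    def test_noise_free_single_factor_limit(self):
        rng = np.random.default_rng(20)
        F = rng.standard_normal(300)
        X = pd.DataFrame(np.outer(F, [0.8, 0.8, 0.8]) + 1e-6 * rng.standard_normal((300, 3)))
        fm = efa(X, n_factors=1, seed=0)
        assert (fm.loadings.abs() > 0.99).all().all()

    def test_parallel_analysis_on_pure_noise_retains_nothing(self):
        rng = np.random.default_rng(21)
        zero_count = 0
        for rep in range(20):
            X = pd.DataFrame(rng.standard_normal((100, 8)))
            if parallel_analysis(X, seed=rep) == 0:
                zero_count += 1
        assert zero_count >= 18  # > 90% of runs

    def test_communalities_bounded(self):
        rng = np.random.default_rng(22)
        X, _ = self._factor_data(rng)
        fm = efa(X, n_factors=2, seed=0)
        assert (fm.communalities <= 1.0 + 1e-9).all()
        assert (fm.uniquenesses >= -1e-9).all()

    def test_constant_variable_rejected(self):
        X = pd.DataFrame({"a": np.ones(50), "b": np.arange(50.0)})
        with pytest.raises(ConfigError, match="constant"):
            efa(X, n_factors=1)


# ---------------------------------------------------------------------------
# Pearson screening


class TestPearson:
    def test_self_and_anticorrelation(self):
        X = pd.DataFrame({"a": [1.0, 2, 3, 4], "b": [-1.0, -2, -3, -4]})
        out = pearson_matrix(X)
        assert out["r"].loc["a", "a"] == pytest.approx(1.0)
        assert out["r"].loc["a", "b"] == pytest.approx(-1.0)

    def test_hand_computed_pair(self):
        X = pd.DataFrame({"x": [1.0, 2, 3], "y": [2.0, 4, 7]})
        out = pearson_matrix(X)
        assert out["r"].loc["x", "y"] == pytest.approx(0.9934, abs=1e-4)

    def test_constant_column_flagged_and_excluded(self):
        rng = np.random.default_rng(23)
        X = pd.DataFrame({"a": rng.random(20), "b": rng.random(20), "c": np.ones(20)})
        out = pearson_matrix(X)
        assert out["constant_columns"] == ["c"]
        assert np.isnan(out["r"].loc["a", "c"])
        # fraction computed over the single valid pair
        valid_r = abs(out["r"].loc["a", "b"])
        assert out["fraction_above_threshold"] == float(valid_r > 0.3)
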