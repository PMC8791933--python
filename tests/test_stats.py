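import numpy as np
import pandas as pd
import pytest

import fshdsig as fs
from fshdsig.io import ValidationError

from .oracles import auc_rank_oracle, spearman_d2


class TestSelectAndRunTest:
    def test_normal_data_routes_to_welch(self):
        rng = np.random.default_rng(0)
        res = fs.select_and_run_test(
            {"CTRL": rng.normal(0, 1, 40), "FSHD": rng.normal(0.5, 1, 40)}, "continuous", "x"
        )
        assert res.test_used == "welch_t"
        assert "mean" in res.group_summaries["CTRL"]

    def test_skewed_data_routes_to_mann_whitney(self):
        rng = np.random.default_rng(0)
        res = fs.select_and_run_test(
            {"CTRL": rng.exponential(1, 60), "FSHD": rng.exponential(2, 60)}, "continuous", "x"
        )
        assert res.test_used == "mann_whitney_u"
        assert "median" in res.group_summaries["CTRL"]

    def test_ordinal_always_rank_based(self):
        rng = np.random.default_rng(1)
        res = fs.select_and_run_test(
            {"A": rng.normal(5, 1, 50).round(), "B": rng.normal(5, 1, 50).round()}, "ordinal"
        )
        assert res.test_used == "mann_whitney_u"

    def test_binary_never_selects_t(self):
        res = fs.select_and_run_test({"A": [1, 0, 1, 0, 1], "B": [0, 0, 1, 0, 0]}, "binary")
        assert res.test_used == "fisher_exact"

    def test_identical_balanced_binary_p_one(self):
        res = fs.select_and_run_test({"A": [1, 1, 0, 0], "B": [1, 1, 0, 0]}, "binary")
        assert res.p_value == pytest.approx(1.0)

    def test_tiny_group_rejected(self):
        with pytest.raises(ValidationError):
            fs.select_and_run_test({"A": [1.0], "B": [1.0, 2.0, 3.0]}, "continuous")


class TestRocAuc:
    def test_perfect_separation(self):
        res = fs.roc_auc([1, 2, 3, 10, 11, 12], [0, 0, 0, 1, 1, 1])
        assert res.auc == pytest.approx(1.0)

    def test_all_tied_scores(self):
        res = fs.roc_auc([5.0] * 8, [0, 1] * 4)
        assert res.auc == pytest.approx(0.5)

    def test_matches_rank_oracle_with_ties(self):
        rng = np.random.default_rng(2)
        for _ in range(20):
            scores = rng.integers(0, 6, size=30).astype(float)  # heavy ties
            labels = rng.integers(0, 2, size=30)
            if len(np.unique(labels)) < 2:
                continue
            assert fs.roc_auc(scores, labels).auc == pytest.approx(
                auc_rank_oracle(scores, labels), abs=1e-12
            )

    def test_complement_identity(self):
        rng = np.random.default_rng(3)
        scores = rng.normal(size=40)
        labels = rng.integers(0, 2, size=40)
        assert fs.roc_auc(scores, labels).auc + fs.roc_auc(-scores, labels).auc == pytest.approx(1.0)

    def test_single_class_rejected(self):
        with pytest.raises(ValidationError):
            fs.roc_auc([1.0, 2.0], [1, 1])


class TestCorrelationMatrix:
    def test_diagonal_and_symmetry(self):
        rng = np.random.default_rng(4)
        df = pd.DataFrame(rng.normal(size=(25, 4)), columns=list("wxyz"))
        res = fs.correlation_matrix(df)
        np.testing.assert_allclose(np.diag(res.pearson_r), 1.0)
        np.testing.assert_allclose(np.diag(res.spearman_rho), 1.0)
        np.testing.assert_allclose(res.pearson_r, res.pearson_r.T, atol=1e-12)
        np.testing.assert_allclose(res.spearman_rho, res.spearman_rho.T, atol=1e-12)

    def test_monotone_nonlinear_relationship(self):
        x = np.linspace(0, 3, 20)
        df = pd.DataFrame({"x": x, "y": np.exp(2 * x)})
        res = fs.correlation_matrix(df)
        assert res.spearman_rho.loc["x", "y"] == pytest.approx(1.0)
        assert res.pearson_r.loc["x", "y"] < 1.0

    def test_spearman_matches_rank_formula(self):
        df = pd.DataFrame({"x": [1, 2, 3, 4, 5], "y": [2, 1, 4, 3, 5]})
        res = fs.correlation_matrix(df)
        assert res.spearman_rho.loc["x", "y"] == pytest.approx(spearman_d2(df.x, df.y))
        assert res.spearman_rho.loc["x", "y"] == pytest.approx(0.8)

    def test_pairwise_complete_and_undefined_cells(self):
        df = pd.DataFrame(
            {
                "a": [1.0, 2.0, 3.0, 4.0, np.nan],
                "b": [2.0, 4.0, 6.0, np.nan, 10.0],
                "const": [1.0, 1.0, 1.0, 1.0, 1.0],
                "sparse": [1.0, np.nan, np.nan, np.nan, 2.0],
            }
        )
        res = fs.correlation_matrix(df)
        assert res.n_pairs.loc["a", "b"] == 3
        assert res.pearson_r.loc["a", "b"] == pytest.approx(1.0)
        assert np.isnan(res.pearson_r.loc["a", "const"])  # zero variance: grey cell
        assert np.isnan(res.pearson_r.loc["a", "sparse"])  # < 3 complete pairs

    def test_affine_and_monotone_invariances(self):
        rng = np.random.default_rng(5)
        x = rng.normal(size=30)
        y = rng.normal(size=30)
        base = fs.correlation_matrix(pd.DataFrame({"x": x, "y": y}))
        affine = fs.correlation_matrix(pd.DataFrame({"x": 3 * x + 7, "y": y}))
        assert affine.pearson_r.loc["x", "y"] == pytest.approx(base.pearson_r.loc["x", "y"])
        mono = fs.correlation_matrix(pd.DataFrame({"x": np.exp(x), "y": y}))
        assert mono.spearman_rho.loc["x", "y"] == pytest.approx(base.spearman_rho.loc["x", "y"])


class TestCohortSummary:
    def test_identical_groups_near_unit_p(self):
        rng = np.random.default_rng(6)
        vals = rng.normal(50, 5, size=12)
        meta = pd.DataFrame(
            {
                "participant_id": [f"P{i}" for i in range(24)],
                "group": ["CTRL"] * 12 + ["FSHD"] * 12,
                "age": np.concatenate([vals, vals]),
            },
            index=[f"B{i}" for i in range(24)],
        )
        (res,) = fs.cohort_summary(meta, variables=["age"])
        assert res.p_value > 0.9

    def test_all_samples_mode_changes_n_not_mean(self):
        rng = np.random.default_rng(7)
        base = pd.DataFrame(
            {
                "participant_id": [f"P{i}" for i in range(20)],
                "group": ["CTRL"] * 10 + ["FSHD"] * 10,
                "age": rng.normal(50, 5, size=20),
            },
            index=[f"B{i}" for i in range(20)],
        )
        doubled = pd.concat([base, base.set_index(base.index + "_dup")])
        (r1,) = fs.cohort_summary(base, variables=["age"])
        (r2,) = fs.cohort_summary(doubled, variables=["age"])

        ctrl_vals = base.loc[base.group == "CTRL", "age"].to_numpy()

        def check_central(summary):  # duplication may flip the normality route
            if "mean" in summary:
                assert summary["mean"] == pytest.approx(ctrl_vals.mean())
            else:
                assert summary["median"] == pytest.approx(np.median(ctrl_vals))

        assert r2.group_summaries["CTRL"]["n"] == 2 * r1.group_summaries["CTRL"]["n"]
        check_central(r1.group_summaries["CTRL"])
        check_central(r2.group_summaries["CTRL"])
        (r3,) = fs.cohort_summary(doubled, variables=["age"], participants_only=True)
        assert r3.group_summaries["CTRL"]["n"] == r1.group_summaries["CTRL"]["n"]

    def test_mrc_and_inflammation_binarized_to_fisher(self, scored_cohort):
        _, meta, _, scores = scored_cohort
        results = {r.variable_name: r for r in fs.cohort_summary(meta, scores[["dux4_log", "pax7_score"]])}
        assert results["mrc"].test_used == "fisher_exact"
        assert results["inflammation"].test_used == "fisher_exact"
        assert results["sex"].test_used == "fisher_exact"
        assert "dux4_log" in results and "pax7_score" in results

    def test_power_for_planted_group_shift(self):
        """A planted 5-SE group shift is detected at p < 0.01 in >= 95% of
        seeded replicates (normal-approximation power ~99%)."""
        rng = np.random.default_rng(9)
        hits = 0
        reps = 200
        n = 20
        shift = 5.0 * np.sqrt(2.0 / n)  # 5 standard errors of the difference
        for _ in range(reps):
            res = fs.select_and_run_test(
                {"CTRL": rng.normal(0, 1, n), "FSHD": rng.normal(shift, 1, n)}, "continuous"
            )
            hits += res.p_value < 0.01
        assert hits / reps >= 0.95

    def test_unknown_grouping_column(self):
        with pytest.raises(ValidationError):
            fs.cohort_summary(pd.DataFrame({"group": []}), group_col="cohort")


def test_benjamini_hochberg_matches_statsmodels():
    sm = pytest.importorskip("statsmodels.stats.multitest")
    p = np.array([0.001, 0.02, 0.04, 0.2, 0.5, 0.9])
    np.testing.assert_allclose(fs.benjamini_hochberg(p), sm.multipletests(p, method="fdr_bh")[1])
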