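import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

import fshdsig as fs
from fshdsig.io import ValidationError
from fshdsig.normalization import DegenerateInputError

from .oracles import welch_t


def _norm_cm(arr, genes=None, samples=None, scale="size_factor_normalized"):
    arr = np.asarray(arr, dtype=float)
    genes = genes or [f"G{i}" for i in range(arr.shape[0])]
    samples = samples or [f"S{j}" for j in range(arr.shape[1])]
    return fs.CountMatrix(values=pd.DataFrame(arr, index=genes, columns=samples), scale=scale)


class TestDux4Score:
    def test_all_zero_targets_score_zero(self):
        cm = _norm_cm(np.zeros((3, 2)), genes=["D1", "D2", "X"])
        assert (fs.dux4_score(cm, {"D1", "D2"}) == 0).all()

    def test_additivity(self):
        cm = _norm_cm([[5.0], [10.0], [7.0]], genes=["A", "B", "C"])
        assert fs.dux4_score(cm, {"A", "B"}).iloc[0] == pytest.approx(15.0)
        total = fs.dux4_score(cm, {"A", "B", "C"}).iloc[0]
        assert total == pytest.approx(
            fs.dux4_score(cm, {"A"}).iloc[0] + fs.dux4_score(cm, {"B", "C"}).iloc[0]
        )

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(arrays(np.float64, (60, 3), elements=st.floats(0, 100)))
    def test_brute_force_oracle_and_non_target_invariance(self, arr):
        genes = [f"T{i}" for i in range(57)] + ["X0", "X1", "X2"]
        cm = _norm_cm(arr, genes=genes)
        targets = {f"T{i}" for i in range(57)}
        score = fs.dux4_score(cm, targets)
        expected = np.array([sum(arr[i, j] for i in range(57)) for j in range(3)])
        np.testing.assert_allclose(score.to_numpy(), expected, rtol=1e-12)
        # perturbing non-target rows never changes the score
        arr2 = arr.copy()
        arr2[57:, :] += 1000
        np.testing.assert_allclose(
            fs.dux4_score(_norm_cm(arr2, genes=genes), targets).to_numpy(), expected, rtol=1e-12
        )

    def test_missing_targets_warn_and_contribute_zero(self):
        cm = _norm_cm([[5.0]], genes=["A"])
        with pytest.warns(UserWarning, match="absent"):
            score = fs.dux4_score(cm, {"A", "GONE"})
        assert score.iloc[0] == 5.0

    def test_empty_intersection_is_error(self):
        cm = _norm_cm([[5.0]], genes=["A"])
        with pytest.raises(ValidationError, match="undefined"):
            fs.dux4_score(cm, {"Z"})

    def test_requires_normalized_scale(self, tiny_counts):
        with pytest.raises(ValidationError, match="size-factor"):
            fs.dux4_score(tiny_counts, {"GA"})


class TestClassifyDux4:
    @pytest.mark.parametrize("score,label", [(20.0, "NEG"), (20.3, "POS"), (0.0, "NEG"), (807.8, "POS")])
    def test_strict_threshold_boundary(self, score, label):
        assert fs.classify_dux4(pd.Series([score])).iloc[0] == label

    def test_negative_score_rejected(self):
        with pytest.raises(ValidationError):
            fs.classify_dux4(pd.Series([-1.0]))

    def test_monotone_in_score(self):
        scores = pd.Series(np.linspace(0, 100, 51))
        labels = fs.classify_dux4(scores)
        pos = labels == "POS"
        # once positive, higher scores stay positive
        assert (pos.astype(int).diff().dropna() >= 0).all()


class TestPax7Score:
    def _qn(self, ind, rep):
        arr = np.array(ind + rep, dtype=float)[:, None]
        genes = [f"I{i}" for i in range(len(ind))] + [f"R{i}" for i in range(len(rep))]
        return _norm_cm(arr, genes=genes, scale="quantile_normalized"), set(genes[: len(ind)]), set(genes[len(ind):])

    def test_identical_multisets_give_zero(self):
        qn, ind, rep = self._qn([1.0, 2.0, 3.0], [3.0, 1.0, 2.0])
        assert fs.pax7_score(qn, ind, rep).iloc[0] == pytest.approx(0.0, abs=1e-12)

    def test_antisymmetry_under_list_swap(self):
        qn, ind, rep = self._qn([2.0, 3.5, 4.0], [1.0, 1.5, 0.5])
        t = fs.pax7_score(qn, ind, rep).iloc[0]
        assert fs.pax7_score(qn, rep, ind).iloc[0] == pytest.approx(-t, rel=1e-12)

    def test_welch_formula_oracle(self):
        ind = [2.0, 3.0, 4.0]
        rep = [1.001, 0.999, 1.0]
        qn, iset, rset = self._qn(ind, rep)
        t = fs.pax7_score(qn, iset, rset).iloc[0]
        assert t == pytest.approx(welch_t(ind, rep), abs=1e-9)

    def test_pooled_variant(self):
        ind = [2.0, 3.0, 4.0, 5.0]
        rep = [1.0, 1.5, 0.5]
        qn, iset, rset = self._qn(ind, rep)
        from scipy.stats import ttest_ind

        expected = ttest_ind(ind, rep, equal_var=True).statistic
        assert fs.pax7_score(qn, iset, rset, variance="pooled").iloc[0] == pytest.approx(expected)

    def test_shift_of_both_sets_leaves_t_unchanged(self):
        ind = [2.0, 3.0, 4.0]
        rep = [1.0, 0.5, 1.5]
        qn, iset, rset = self._qn(ind, rep)
        t = fs.pax7_score(qn, iset, rset).iloc[0]
        qn2, _, _ = self._qn([v + 7.0 for v in ind], [v + 7.0 for v in rep])
        assert fs.pax7_score(qn2, iset, rset).iloc[0] == pytest.approx(t, rel=1e-12)

    def test_constant_unequal_sets_degenerate(self):
        qn, iset, rset = self._qn([1.0, 1.0, 1.0], [2.0, 2.0, 2.0])
        with pytest.raises(DegenerateInputError):
            fs.pax7_score(qn, iset, rset)

    def test_too_few_genes_rejected(self):
        qn, iset, rset = self._qn([1.0, 2.0], [3.0, 4.0])
        with pytest.raises(ValidationError, match=">=2"):
            fs.pax7_score(qn, {"I0"}, rset)


class TestClassifyPax7:
    def test_exact_partition_at_2k(self):
        scores = pd.Series(np.arange(20.0), index=[f"B{i:02d}" for i in range(20)])
        labels = fs.classify_pax7(scores, k=10)
        assert (labels != "UNCLASSIFIED").all()
        assert labels.value_counts().to_dict() == {"HIGH": 10, "LOW": 10}

    def test_order_statistics_n39(self):
        ids = [f"B{i:02d}" for i in range(1, 40)]
        scores = pd.Series(np.arange(39.0), index=ids)
        labels = fs.classify_pax7(scores, k=10)
        assert (labels[ids[-10:]] == "HIGH").all()
        assert (labels[ids[:10]] == "LOW").all()
        assert (labels[ids[10:-10]] == "UNCLASSIFIED").all()

    def test_tie_break_deterministic_by_id(self):
        scores = pd.Series([3.0, 2.0, 2.0, 1.0], index=["B4", "B2", "B1", "B3"])
        for _ in range(3):
            labels = fs.classify_pax7(scores, k=1)
            assert labels["B4"] == "HIGH"
            assert labels["B3"] == "LOW"
            assert labels["B1"] == "UNCLASSIFIED" and labels["B2"] == "UNCLASSIFIED"
        # tie straddling rank k: smaller id takes the slot
        labels = fs.classify_pax7(scores, k=2)
        assert labels["B1"] == "HIGH" or labels["B1"] == "LOW"
        assert labels["B1"] != "UNCLASSIFIED"

    def test_small_cohort_reduces_k_with_warning(self):
        scores = pd.Series([1.0, 2.0, 3.0], index=["A", "B", "C"])
        with pytest.warns(UserWarning, match="reducing k"):
            labels = fs.classify_pax7(scores, k=10)
        assert (labels == ["LOW", "UNCLASSIFIED", "HIGH"]).all()

    def test_k_below_one_rejected(self):
        with pytest.raises(ValidationError):
            fs.classify_pax7(pd.Series([1.0]), k=0)


class TestFatCorrectionAndMarkers:
    def test_fat_zero_unchanged(self):
        assert fs.correct_for_fat(10.0, 0.0) == pytest.approx(10.0)

    def test_fat_fifty_doubles(self):
        assert fs.correct_for_fat(10.0, 50.0) == pytest.approx(20.0)

    def test_corrected_never_below_raw(self):
        fats = np.linspace(0, 99, 34)
        corrected = np.array([fs.correct_for_fat(7.0, f) for f in fats])
        assert (corrected >= 7.0 - 1e-12).all()
        assert (np.diff(corrected) > 0).all()

    def test_missing_and_domain(self):
        assert fs.correct_for_fat(10.0, None) is None
        with pytest.raises(ValueError):
            fs.correct_for_fat(10.0, 100.0)
        s = fs.correct_for_fat(pd.Series([10.0, 10.0]), pd.Series([50.0, np.nan]))
        assert s.iloc[0] == pytest.approx(20.0) and np.isnan(s.iloc[1])

    @pytest.mark.parametrize(
        "values,expected",
        [([[0.0], [0.0]], 0.0), ([[9.0]], 1.0), ([[9.0], [99.0]], 1.5)],
    )
    def test_marker_index_values(self, values, expected):
        genes = ["MYOD1", "MYOG"][: len(values)]
        cm = _norm_cm(values, genes=genes)
        assert fs.marker_content_index(cm, genes).iloc[0] == pytest.approx(expected)

    def test_no_marker_present_rejected(self):
        cm = _norm_cm([[1.0]], genes=["A"])
        with pytest.raises(ValidationError):
            fs.marker_content_index(cm, ["MYOD1"])
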