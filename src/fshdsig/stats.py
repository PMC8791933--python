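"""Group comparisons, ROC analysis and the clinical correlation matrix.

The test-selection rule mirrors common clinical-cohort practice: for a
continuous variable, Shapiro-Wilk normality is checked in each group and a
two-sided Welch t-test is used only when neither group rejects at p <= 0.05;
otherwise a two-sided Mann-Whitney U test (with tie correction) is used.
Ordinal variables go straight to Mann-Whitney; binary variables to a
two-sided Fisher's exact test.  Raw p-values are reported (no
multiple-testing correction by default; an optional Benjamini-Hochberg
helper is provided).

ROC analysis follows the rank definition: AUC equals the Mann-Whitney U
statistic over n_pos * n_neg with ties credited 0.5, computed via
scikit-learn's roc_curve.

The correlation matrix reports pairwise-complete Pearson r and Spearman rho
with p-values over all numeric (or 0/1-coded binary) variables; cells with
fewer than 3 complete pairs or zero variance are undefined, matching the
grey "no linear correlation" cells of clinical correlation heatmaps.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import auc as _sk_auc
from sklearn.metrics import roc_curve

from .io import ValidationError

__all__ = [
    "GroupComparisonResult",
    "CorrelationMatrixResult",
    "RocResult",
    "select_and_run_test",
    "roc_auc",
    "correlation_matrix",
    "cohort_summary",
    "benjamini_hochberg",
]

SHAPIRO_ALPHA = 0.05


@dataclass
class GroupComparisonResult:
    variable_name: str
    test_used: str  # welch_t | mann_whitney_u | fisher_exact
    statistic: float
    p_value: float
    group_summaries: dict = field(default_factory=dict)

    def as_dict(self) -> dict:
        return {
            "variable": self.variable_name,
            "test_used": self.test_used,
            "statistic": self.statistic,
            "p_value": self.p_value,
            "group_summaries": self.group_summaries,
        }


@dataclass
class RocResult:
    auc: float
    fpr: np.ndarray
    tpr: np.ndarray
    thresholds: np.ndarray


@dataclass
class CorrelationMatrixResult:
    variables: list[str]
    pearson_r: pd.DataFrame
    spearman_rho: pd.DataFrame
    pearson_p: pd.DataFrame
    spearman_p: pd.DataFrame
    n_pairs: pd.DataFrame


def _sem(x: np.ndarray) -> float:
    return float(np.std(x, ddof=1) / np.sqrt(len(x))) if len(x) > 1 else float("nan")


def _iqr(x: np.ndarray) -> float:
    return float(np.percentile(x, 75) - np.percentile(x, 25))


def _summaries(groups: Mapping[str, np.ndarray], family: str) -> dict:
    out = {}
    for name, vals in groups.items():
        vals = np.asarray(vals, dtype=float)
        if family == "parametric":
            out[name] = {"n": len(vals), "mean": float(np.mean(vals)), "sem": _sem(vals)}
        else:
            out[name] = {"n": len(vals), "median": float(np.median(vals)), "iqr": _iqr(vals)}
    return out


def select_and_run_test(
    values_by_group: Mapping[str, Sequence[float]],
    variable_kind: str = "continuous",
    variable_name: str = "",
) -> GroupComparisonResult:
    """Normality-gated two-group comparison.

    continuous: Shapiro-Wilk in each group; Welch t if both p > 0.05, else
    Mann-Whitney U.  ordinal: Mann-Whitney U.  binary (0/1 coded): Fisher's
    exact on the 2x2 count table.  All tests two-sided.
    """
    if variable_kind not in ("continuous", "ordinal", "binary"):
        raise ValidationError(f"unknown variable_kind {variable_kind!r}")
    if len(values_by_group) != 2:
        raise ValidationError("exactly two groups are required")
    (name_a, a), (name_b, b) = [(k, np.asarray(v, dtype=float)) for k, v in values_by_group.items()]
    a, b = a[~np.isnan(a)], b[~np.isnan(b)]

    if variable_kind == "binary":
        table = np.array(
            [[int((a == 1).sum()), int((a == 0).sum())], [int((b == 1).sum()), int((b == 0).sum())]]
        )
        odds, p = stats.fisher_exact(table, alternative="two-sided")
        summaries = {
            name_a: {"n": len(a), "positive": int((a == 1).sum())},
            name_b: {"n": len(b), "positive": int((b == 1).sum())},
        }
        return GroupComparisonResult(variable_name, "fisher_exact", float(odds), float(p), summaries)

    if len(a) < 2 or len(b) < 2:
        raise ValidationError(f"{variable_name or 'variable'}: each group needs >= 2 observations")

    route_parametric = False
    if variable_kind == "continuous" and len(a) >= 3 and len(b) >= 3:
        normal_a = np.ptp(a) > 0 and stats.shapiro(a).pvalue > SHAPIRO_ALPHA
        normal_b = np.ptp(b) > 0 and stats.shapiro(b).pvalue > SHAPIRO_ALPHA
        route_parametric = normal_a and normal_b
    if route_parametric:
        t, p = stats.ttest_ind(a, b, equal_var=False)
        return GroupComparisonResult(
            variable_name, "welch_t", float(t), float(p), _summaries({name_a: a, name_b: b}, "parametric")
        )
    u, p = stats.mannwhitneyu(a, b, alternative="two-sided")
    return GroupComparisonResult(
        variable_name, "mann_whitney_u", float(u), float(p), _summaries({name_a: a, name_b: b}, "rank")
    )


def roc_auc(scores: Sequence[float], labels: Sequence[int]) -> RocResult:
    """ROC curve and AUC for a score predicting a binary label.

    AUC equals the rank (Mann-Whitney) probability that a random positive
    outscores a random negative, with ties credited 0.5.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    if not np.isfinite(scores).all():
        raise ValidationError("scores must be finite")
    classes = np.unique(labels)
    if len(classes) != 2:
        raise ValidationError("labels must contain exactly two classes")
    y = (labels == classes.max()).astype(int)
    fpr, tpr, thresholds = roc_curve(y, scores)
    return RocResult(auc=float(_sk_auc(fpr, tpr)), fpr=fpr, tpr=tpr, thresholds=thresholds)


def correlation_matrix(
    data: pd.DataFrame,
    variables: Sequence[str] | None = None,
    min_pairs: int = 3,
) -> CorrelationMatrixResult:
    """All-pairs Pearson and Spearman correlations with p-values.

    Uses pairwise-complete observations.  A cell is undefined (NaN) when
    fewer than ``min_pairs`` complete pairs exist or either variable is
    constant over them.  Binary variables must already be coded 0/1;
    variables with more than two unordered categories should be excluded by
    the caller (see :func:`encode_for_correlation`).
    """
    variables = list(variables) if variables is not None else list(data.columns)
    df = data[variables].apply(pd.to_numeric, errors="coerce")
    k = len(variables)
    shape = (k, k)
    r = np.full(shape, np.nan)
    rho = np.full(shape, np.nan)
    pr = np.full(shape, np.nan)
    ps = np.full(shape, np.nan)
    npairs = np.zeros(shape, dtype=int)
    arr = df.to_numpy(dtype=float)
    for i in range(k):
        for j in range(i, k):
            mask = ~np.isnan(arr[:, i]) & ~np.isnan(arr[:, j])
            n = int(mask.sum())
            npairs[i, j] = npairs[j, i] = n
            if n < min_pairs:
                continue
            x, y = arr[mask, i], arr[mask, j]
            if np.ptp(x) == 0 or np.ptp(y) == 0:
                continue
            if i == j:
                r[i, i] = rho[i, i] = 1.0
                pr[i, i] = ps[i, i] = 0.0
                continue
            pres = stats.pearsonr(x, y)
            sres = stats.spearmanr(x, y)
            r[i, j] = r[j, i] = pres.statistic
            pr[i, j] = pr[j, i] = pres.pvalue
            rho[i, j] = rho[j, i] = sres.statistic
            ps[i, j] = ps[j, i] = sres.pvalue

    def _frame(m):
        return pd.DataFrame(m, index=variables, columns=variables)

    return CorrelationMatrixResult(
        variables=variables,
        pearson_r=_frame(r),
        spearman_rho=_frame(rho),
        pearson_p=_frame(pr),
        spearman_p=_frame(ps),
        n_pairs=_frame(npairs),
    )


def encode_for_correlation(metadata: pd.DataFrame, scores: pd.DataFrame | None = None) -> pd.DataFrame:
    """Numeric coding of the clinical table for the correlation matrix.

    group FSHD=1/CTRL=0, sex M=1/F=0, TIRM POS=1/NEG=0; numeric fields pass
    through; multi-category unordered fields (muscle aside, which is binary
    VL=0/TA=1) are dropped.
    """
    out = pd.DataFrame(index=metadata.index)
    mapping = {
        "group": {"FSHD": 1, "CTRL": 0},
        "sex": {"M": 1, "F": 0},
        "tirm": {"POS": 1, "NEG": 0},
        "muscle": {"TA": 1, "VL": 0},
    }
    for col in metadata.columns:
        if col in mapping:
            out[col] = metadata[col].map(mapping[col])
        else:
            coerced = pd.to_numeric(metadata[col], errors="coerce")
            if coerced.notna().any():
                out[col] = coerced
    if scores is not None:
        for col in scores.columns:
            coerced = pd.to_numeric(scores[col], errors="coerce")
            if coerced.notna().any():
                out[col] = coerced.reindex(out.index)
    return out


# Variable kinds and special comparison rules for the cohort summary.
_VARIABLE_KINDS = {
    "age": "continuous",
    "bmi": "continuous",
    "six_mwt": "continuous",
    "mfm": "continuous",
    "fat_fraction": "continuous",
    "dux4_log": "continuous",
    "pax7_score": "continuous",
    "css": "ordinal",
    "histology_sum": "ordinal",
    "d4z4_units": "ordinal",
    "sex": "binary",
    "tirm": "binary",
    # mrc and inflammation are binarized by study-specific rules below
    "mrc": "binary",
    "inflammation": "binary",
}


def _binarize(name: str, series: pd.Series) -> pd.Series:
    """Study-specific binary codings for the comparison table."""
    if name == "sex":
        return series.map({"M": 1, "F": 0})
    if name == "tirm":
        return series.map({"POS": 1, "NEG": 0})
    if name == "mrc":
        # normal strength (grade exactly 5.0) versus any reduction
        v = pd.to_numeric(series, errors="coerce")
        return (v == 5.0).astype(float).where(v.notna())
    if name == "inflammation":
        # any sign of inflammation (> 0) versus none
        v = pd.to_numeric(series, errors="coerce")
        return (v > 0).astype(float).where(v.notna())
    return pd.to_numeric(series, errors="coerce")


def cohort_summary(
    metadata: pd.DataFrame,
    scores: pd.DataFrame | None = None,
    group_col: str = "group",
    participants_only: bool = False,
    variables: Sequence[str] | None = None,
) -> list[GroupComparisonResult]:
    """Per-variable two-group comparison table (CTRL versus FSHD).

    With ``participants_only`` each participant contributes one record (the
    first by biopsy id); otherwise all biopsy samples enter, which double
    counts participants with two biopsies, mirroring per-sample cohort
    tables.
    """
    if group_col not in metadata.columns:
        raise ValidationError(f"unknown grouping column {group_col!r}")
    df = metadata.copy()
    if scores is not None:
        df = df.join(scores, how="left")
    if participants_only:
        df = df.sort_index().groupby("participant_id", sort=True).first()
    groups = df[group_col].dropna().unique()
    if len(groups) != 2:
        raise ValidationError(f"grouping column must have two levels, found {list(groups)}")
    groups = sorted(groups)
    use = variables if variables is not None else [v for v in _VARIABLE_KINDS if v in df.columns]
    results = []
    for var in use:
        kind = _VARIABLE_KINDS.get(var, "continuous")
        series = _binarize(var, df[var]) if kind == "binary" else pd.to_numeric(df[var], errors="coerce")
        by_group = {}
        for g in groups:
            vals = series[df[group_col] == g].dropna().to_numpy(dtype=float)
            by_group[g] = vals
        if any(len(v) < 2 for v in by_group.values()):
            continue  # not comparable in this cohort (e.g. CSS undefined in controls)
        results.append(select_and_run_test(by_group, kind, variable_name=var))
    return results


def benjamini_hochberg(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values (optional; off by default upstream)."""
    p = np.asarray(p_values, dtype=float)
    n = len(p)
    order = np.argsort(p)
    ranked = p[order] * n / (np.arange(n) + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(n)
    out[order] = np.minimum(ranked, 1.0)
    return out
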