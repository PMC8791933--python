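"""Imaging-biomarker classification and concordance with signature positivity.

Two MRI biomarkers are classified per biopsy: TIRM hyperintensity (POS/NEG,
marking edema/active disease) and quantitative fat fraction (POS when
strictly above 15%).  The combined biomarker is positive when either
component is.  Each biomarker is then evaluated as a predictor of DUX4
signature positivity through a 2x2 confusion table, with
sensitivity/specificity/PPV/NPV and a two-sided Fisher's exact p-value.

Sensitivity supports two denominators: the confusion-table positives (pairs
with both labels observed) or an externally supplied cohort-wide positive
total.  The latter matters when a signature-positive biopsy lacks biomarker
data — the study cohort counts it in the denominator — and is the default.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .io import ValidationError

__all__ = [
    "ConfusionTable2x2",
    "BiomarkerMetrics",
    "classify_fat",
    "combine_biomarkers",
    "confusion_table",
    "biomarker_metrics",
    "fisher_exact_2x2",
    "evaluate_predictors",
]


@dataclass
class ConfusionTable2x2:
    """Predictor-vs-outcome counts over complete (non-missing) pairs."""

    tp: int
    fp: int
    fn: int
    tn: int
    predictor_name: str = "predictor"
    outcome_name: str = "outcome"
    n_missing_excluded: int = 0

    def __post_init__(self) -> None:
        for name in ("tp", "fp", "fn", "tn", "n_missing_excluded"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be >= 0")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn

    def as_array(self) -> np.ndarray:
        return np.array([[self.tp, self.fn], [self.fp, self.tn]])


@dataclass
class BiomarkerMetrics:
    """Predictive-power metrics; ``None`` marks an undefined (0/0) metric."""

    sensitivity: float | None
    specificity: float | None
    ppv: float | None
    npv: float | None
    fisher_p: float
    odds_ratio: float

    def as_dict(self) -> dict:
        return {
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "ppv": self.ppv,
            "npv": self.npv,
            "fisher_p": self.fisher_p,
            "odds_ratio": None if np.isinf(self.odds_ratio) else self.odds_ratio,
        }


def classify_fat(fat_fraction, threshold: float = 15.0):
    """Fat-fraction positivity: POS iff fat fraction > threshold (strict).

    Exactly 15.0% is NEG (normal).  Missing stays missing.  Accepts a scalar
    or a Series (missing = NaN/None).
    """
    if isinstance(fat_fraction, pd.Series):
        f = pd.to_numeric(fat_fraction, errors="coerce")
        valid = f.dropna()
        if ((valid < 0) | (valid > 100)).any():
            raise ValidationError("fat_fraction outside [0, 100]")
        out = pd.Series([None] * len(f), index=f.index, dtype=object, name="fat_class")
        out[f > threshold] = "POS"
        out[f.notna() & (f <= threshold)] = "NEG"
        return out
    if fat_fraction is None or (isinstance(fat_fraction, float) and np.isnan(fat_fraction)):
        return None
    if not (0 <= fat_fraction <= 100):
        raise ValidationError(f"fat_fraction {fat_fraction} outside [0, 100]")
    return "POS" if fat_fraction > threshold else "NEG"


def _combine_one(tirm, fat):
    if tirm == "POS" or fat == "POS":
        return "POS"
    if tirm == "NEG" and fat == "NEG":
        return "NEG"
    return None  # at least one missing, no POS evidence


def combine_biomarkers(tirm, fat):
    """TIRM-and/or-fat combined biomarker.

    POS if either component is POS; NEG only if both are NEG; a pair with a
    missing member is POS if the observed member is POS and missing otherwise.
    Accepts scalars or aligned Series.
    """
    if isinstance(tirm, pd.Series) or isinstance(fat, pd.Series):
        tirm = pd.Series(tirm, dtype=object)
        fat = pd.Series(fat, dtype=object).reindex(tirm.index)
        out = pd.Series(
            [_combine_one(t if pd.notna(t) else None, f if pd.notna(f) else None) for t, f in zip(tirm, fat)],
            index=tirm.index,
            dtype=object,
            name="combined_class",
        )
        return out
    return _combine_one(tirm, fat)


def confusion_table(
    predictor: pd.Series,
    outcome: pd.Series,
    predictor_name: str = "predictor",
    outcome_name: str = "outcome",
) -> ConfusionTable2x2:
    """Build a 2x2 table from POS/NEG label Series aligned by biopsy id.

    Pairs with a missing member are excluded and counted in
    ``n_missing_excluded``.
    """
    predictor = pd.Series(predictor, dtype=object)
    outcome = pd.Series(outcome, dtype=object).reindex(predictor.index)
    p_obs = predictor.isin(["POS", "NEG"])
    o_obs = outcome.isin(["POS", "NEG"])
    complete = p_obs & o_obs
    n_missing = int((~complete).sum())
    if not complete.any():
        raise ValidationError("no complete predictor/outcome pairs")
    p = predictor[complete] == "POS"
    o = outcome[complete] == "POS"
    return ConfusionTable2x2(
        tp=int((p & o).sum()),
        fp=int((p & ~o).sum()),
        fn=int((~p & o).sum()),
        tn=int((~p & ~o).sum()),
        predictor_name=predictor_name,
        outcome_name=outcome_name,
        n_missing_excluded=n_missing,
    )


def _ratio(num: int, den: int) -> float | None:
    return num / den if den > 0 else None


def fisher_exact_2x2(t: ConfusionTable2x2) -> float:
    """Two-sided Fisher's exact p-value for the table.

    Two-sidedness by the standard rule: the total hypergeometric probability,
    at fixed margins, of all tables at most as probable as the observed one.
    """
    _, p = stats.fisher_exact(t.as_array(), alternative="two-sided")
    return float(p)


def biomarker_metrics(
    t: ConfusionTable2x2,
    sensitivity_denominator: str = "cohort_total_positives",
    cohort_positives: int | None = None,
) -> BiomarkerMetrics:
    """Sensitivity, specificity, PPV, NPV, Fisher p and odds ratio.

    With ``sensitivity_denominator='cohort_total_positives'`` (default) the
    sensitivity denominator is ``cohort_positives`` — the cohort-wide count
    of outcome-positive biopsies including any excluded for missing predictor
    data; it falls back to the table's tp+fn when not supplied.  With
    ``'table'`` the table's own positives are used.
    """
    if sensitivity_denominator not in ("table", "cohort_total_positives"):
        raise ValidationError("sensitivity_denominator must be 'table' or 'cohort_total_positives'")
    pos_total = t.tp + t.fn
    if sensitivity_denominator == "cohort_total_positives" and cohort_positives is not None:
        if cohort_positives < t.tp:
            raise ValidationError("cohort_positives smaller than observed true positives")
        pos_total = cohort_positives
    odds, _ = stats.fisher_exact(t.as_array())
    return BiomarkerMetrics(
        sensitivity=_ratio(t.tp, pos_total),
        specificity=_ratio(t.tn, t.fp + t.tn),
        ppv=_ratio(t.tp, t.tp + t.fp),
        npv=_ratio(t.tn, t.tn + t.fn),
        fisher_p=fisher_exact_2x2(t),
        odds_ratio=float(odds),
    )


def evaluate_predictors(
    metadata: pd.DataFrame,
    dux4_class: pd.Series,
    fat_threshold: float = 15.0,
    exclude_replicates: bool = False,
    sensitivity_denominator: str = "cohort_total_positives",
) -> dict[str, dict]:
    """Evaluate TIRM, fat and the combined biomarker against DUX4 positivity.

    Restricted to FSHD biopsies (the biomarkers are read out as predictors of
    signature positivity within the patient group).  Returns, per predictor,
    the confusion counts and metrics as plain dicts ready for a JSON report.
    The study uses the word "specificity" for the fraction of
    biomarker-positive biopsies that are signature-positive, which is
    formally the PPV; both are reported.
    """
    meta = metadata[metadata["group"] == "FSHD"]
    if exclude_replicates and "replicate_pair" in meta.columns:
        meta = meta[~meta["replicate_pair"].astype(bool)]
    outcome = pd.Series(dux4_class, dtype=object).reindex(meta.index)
    cohort_positives = int((outcome == "POS").sum())
    tirm = pd.Series(meta["tirm"], dtype=object)
    fat = classify_fat(pd.to_numeric(meta["fat_fraction"], errors="coerce"), threshold=fat_threshold)
    combined = combine_biomarkers(tirm, fat)
    results: dict[str, dict] = {}
    for name, pred in (("TIRM", tirm), ("Fat", fat), ("Combined", combined)):
        table = confusion_table(pred, outcome, predictor_name=name, outcome_name="DUX4")
        metrics = biomarker_metrics(
            table,
            sensitivity_denominator=sensitivity_denominator,
            cohort_positives=cohort_positives,
        )
        results[name] = {
            "counts": {
                "tp": table.tp,
                "fp": table.fp,
                "fn": table.fn,
                "tn": table.tn,
                "n_missing_excluded": table.n_missing_excluded,
            },
            "cohort_positives": cohort_positives,
            "metrics": metrics.as_dict(),
        }
    return results
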