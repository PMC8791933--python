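"""DUX4 and PAX7 signature scores and their class labels.

The DUX4 signature score of a biopsy is the cumulative size-factor-normalized
read count over a fixed list of (nominally 57) DUX4 target genes; a biopsy is
DUX4-positive when the score strictly exceeds 20 normalized reads.  Because
DUX4 bursts are sporadic and each target gene is lowly expressed, the
cumulative count over the whole list is what carries signal.

The PAX7 score of a biopsy is the two-sample t-statistic contrasting the
expression of PAX7-induced versus PAX7-repressed target genes within that
single sample, computed on log10(x+1), quantile-normalized data.  The score
is positive when induced targets exceed repressed targets; its reduction
marks FSHD pathology.  Within the FSHD group the k highest-scoring biopsies
are labeled PAX7-HIGH and the k lowest PAX7-LOW (k = 10 by default), with the
remainder unclassified.

A fat-fraction correction (score per unit non-fat tissue) and a myogenic
marker content index (mean log10(x+1) of MYOD1/MYOG or fiber-type markers)
support the downstream correlation analyses.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable

import numpy as np
import pandas as pd
from scipy import stats

from .io import CountMatrix, SignatureGeneSets, ValidationError
from .normalization import (
    DegenerateInputError,
    SizeFactors,
    compute_size_factors,
    log10_p1,
    normalize_counts,
    quantile_normalize,
)

__all__ = [
    "ScoreConfig",
    "dux4_score",
    "classify_dux4",
    "pax7_score",
    "classify_pax7",
    "correct_for_fat",
    "marker_content_index",
    "compute_signature_scores",
    "MYOGENIC_MARKERS",
]

#: General myogenic and regenerating-fiber marker genes used for the
#: muscle-content index.
MYOGENIC_MARKERS = ["MYOD1", "MYOG", "MYH3", "MYH8"]


@dataclass
class ScoreConfig:
    """Tunable scoring parameters.

    dux4_threshold: normalized-read-count cut-off for DUX4 positivity
    (strictly greater-than; default 20).  pax7_k: number of FSHD biopsies
    labeled HIGH and LOW at each extreme of the PAX7 score (default 10).
    pax7_variance: ``welch`` (unequal-variance, default) or ``pooled``
    t-statistic.  fat_correction: emit fat-corrected DUX4 scores as well.
    """

    dux4_threshold: float = 20.0
    pax7_k: int = 10
    pax7_variance: str = "welch"
    fat_correction: bool = False
    restrict_qn_to_targets: bool = False

    def __post_init__(self) -> None:
        if self.dux4_threshold <= 0:
            raise ValidationError("dux4_threshold must be > 0")
        if self.pax7_k < 1:
            raise ValidationError("pax7_k must be >= 1")
        if self.pax7_variance not in ("welch", "pooled"):
            raise ValidationError("pax7_variance must be 'welch' or 'pooled'")


def dux4_score(norm: CountMatrix, targets: Iterable[str]) -> pd.Series:
    """Cumulative normalized read count over the DUX4 target genes.

    Target genes absent from the matrix contribute 0 and are reported in a
    warning; an empty intersection is an error (the score is undefined).
    """
    if norm.scale != "size_factor_normalized":
        raise ValidationError(
            f"DUX4 score is defined on size-factor-normalized counts, got {norm.scale!r}"
        )
    targets = set(targets)
    if not targets:
        raise ValidationError("empty DUX4 target set")
    present = [g for g in norm.gene_ids if g in targets]
    missing = sorted(targets - set(present))
    if not present:
        raise ValidationError("no DUX4 target gene present in the matrix; score undefined")
    if missing:
        warnings.warn(f"{len(missing)} DUX4 target genes absent from matrix: {missing}", stacklevel=2)
    score = norm.values.loc[present].sum(axis=0)
    score.name = "dux4_score"
    return score


def classify_dux4(scores: pd.Series, threshold: float = 20.0) -> pd.Series:
    """POS/NEG labels: POS iff score > threshold (strict); boundary is NEG."""
    s = pd.Series(scores, dtype=float)
    if (s < 0).any():
        raise ValidationError("DUX4 scores must be non-negative")
    labels = pd.Series(np.where(s > threshold, "POS", "NEG"), index=s.index, name="dux4_class")
    return labels


def _single_sample_t(ind: np.ndarray, rep: np.ndarray, variance: str) -> float:
    ind_const = np.ptp(ind) == 0
    rep_const = np.ptp(rep) == 0
    if ind_const and rep_const:
        if ind[0] == rep[0]:
            return 0.0  # fully degenerate: no evidence either way
        raise DegenerateInputError(
            "both PAX7 target sets are constant with unequal means; t-statistic undefined"
        )
    t, _ = stats.ttest_ind(ind, rep, equal_var=(variance == "pooled"))
    return float(t)


def pax7_score(
    qn: CountMatrix,
    induced: Iterable[str],
    repressed: Iterable[str],
    variance: str = "welch",
) -> pd.Series:
    """Within-sample t-statistic of induced versus repressed PAX7 targets.

    Positive when induced targets exceed repressed targets.  Welch
    (unequal-variance) form by default; ``variance='pooled'`` gives the
    classical equal-variance statistic.
    """
    if qn.scale != "quantile_normalized":
        raise ValidationError(f"PAX7 score is defined on quantile-normalized data, got {qn.scale!r}")
    induced, repressed = set(induced), set(repressed)
    ind_present = [g for g in qn.gene_ids if g in induced]
    rep_present = [g for g in qn.gene_ids if g in repressed]
    if len(ind_present) < 2 or len(rep_present) < 2:
        raise ValidationError(
            f"need >=2 genes from each PAX7 set in the matrix; "
            f"found {len(ind_present)} induced, {len(rep_present)} repressed"
        )
    ind_vals = qn.values.loc[ind_present].to_numpy(dtype=float)
    rep_vals = qn.values.loc[rep_present].to_numpy(dtype=float)
    out = np.array(
        [_single_sample_t(ind_vals[:, j], rep_vals[:, j], variance) for j in range(qn.n_samples)]
    )
    return pd.Series(out, index=qn.values.columns, name="pax7_score")


def classify_pax7(scores: pd.Series, k: int = 10) -> pd.Series:
    """Label the k highest FSHD PAX7 scores HIGH, the k lowest LOW.

    ``scores`` must already be restricted to FSHD biopsies.  If fewer than 2k
    biopsies are available, k is reduced to floor(n/2) with a warning.  Ties
    at the k-th rank are broken by ascending biopsy id, so repeated runs give
    identical labels.
    """
    if k < 1:
        raise ValidationError("k must be >= 1")
    s = pd.Series(scores, dtype=float)
    n = len(s)
    if n < 2 * k:
        k = n // 2
        warnings.warn(f"fewer than 2k biopsies; reducing k to {k}", stacklevel=2)
    labels = pd.Series("UNCLASSIFIED", index=s.index, name="pax7_class", dtype=object)
    if k == 0:
        return labels
    order = pd.DataFrame({"score": s, "biopsy_id": s.index.astype(str)})
    high = order.sort_values(["score", "biopsy_id"], ascending=[False, True]).index[:k]
    # LOW drawn from the remainder so a tie spanning both boundaries cannot
    # place one biopsy in both groups (HIGH has priority, then id order)
    low = order.drop(high).sort_values(["score", "biopsy_id"], ascending=[True, True]).index[:k]
    labels.loc[high] = "HIGH"
    labels.loc[low] = "LOW"
    return labels


def correct_for_fat(score, fat_fraction):
    """Rescale a signature score to the non-fat tissue fraction.

    corrected = score / (1 - fat_fraction/100).  A missing fat fraction gives
    a missing corrected score; fat_fraction >= 100 is a domain error.
    Scalars and aligned Series are both accepted.
    """
    if isinstance(score, pd.Series) or isinstance(fat_fraction, pd.Series):
        score = pd.Series(score, dtype=float)
        fat = pd.Series(fat_fraction, dtype=float).reindex(score.index)
        if (fat.dropna() >= 100).any() or (fat.dropna() < 0).any():
            raise ValueError("fat_fraction must be in [0, 100)")
        return score / (1.0 - fat / 100.0)
    if fat_fraction is None or (isinstance(fat_fraction, float) and np.isnan(fat_fraction)):
        return None
    if not (0 <= fat_fraction < 100):
        raise ValueError(f"fat_fraction {fat_fraction} outside [0, 100)")
    return score / (1.0 - fat_fraction / 100.0)


def marker_content_index(norm: CountMatrix, markers: Iterable[str] = MYOGENIC_MARKERS) -> pd.Series:
    """Mean log10(normalized count + 1) over marker genes present in the matrix.

    Emitted for correlation analyses of muscle/myogenic content; it does not
    rescale the signature scores.
    """
    markers = list(markers)
    present = [g for g in norm.gene_ids if g in set(markers)]
    if not present:
        raise ValidationError(f"no marker gene present in the matrix (wanted {markers})")
    logged = log10_p1(norm.values.loc[present])
    idx = logged.mean(axis=0)
    idx.name = "marker_content_index"
    return idx


def compute_signature_scores(
    counts: CountMatrix,
    gene_sets: SignatureGeneSets,
    fshd_biopsies: Iterable[str] | None = None,
    config: ScoreConfig | None = None,
    size_factors: SizeFactors | None = None,
) -> pd.DataFrame:
    """End-to-end scoring of a raw count matrix.

    Normalizes depth (median of ratios), computes the DUX4 cumulative score
    with POS/NEG labels, and the PAX7 t-statistic on log10(x+1) +
    quantile-normalized data with HIGH/LOW labels over the FSHD biopsies.

    Returns a DataFrame indexed by biopsy id with columns dux4_score,
    dux4_log, dux4_class, pax7_score, pax7_class and marker_content_index.
    """
    config = config or ScoreConfig()
    sf = size_factors or compute_size_factors(counts)
    norm = normalize_counts(counts, sf)
    qn_genes = None
    if config.restrict_qn_to_targets:
        qn_genes = set(gene_sets.pax7_induced) | set(gene_sets.pax7_repressed)
    qn = quantile_normalize(log10_p1(norm), genes=qn_genes)

    d_score = dux4_score(norm, gene_sets.dux4_targets)
    d_class = classify_dux4(d_score, config.dux4_threshold)
    p_score = pax7_score(qn, gene_sets.pax7_induced, gene_sets.pax7_repressed, config.pax7_variance)

    table = pd.DataFrame(
        {
            "dux4_score": d_score,
            "dux4_log": log10_p1(d_score),
            "dux4_class": d_class,
            "pax7_score": p_score,
        }
    )
    table["pax7_class"] = pd.Series(pd.NA, index=table.index, dtype=object)
    if fshd_biopsies is not None:
        fshd = [b for b in table.index if b in set(fshd_biopsies)]
        if fshd:
            table.loc[fshd, "pax7_class"] = classify_pax7(p_score[fshd], config.pax7_k)
    try:
        table["marker_content_index"] = marker_content_index(norm)
    except ValidationError:
        table["marker_content_index"] = np.nan
    table.index.name = "biopsy_id"
    return table
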