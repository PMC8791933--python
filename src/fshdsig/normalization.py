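"""Depth normalization and the transforms the signature scores depend on.

Three transforms are provided:

* **median-of-ratios size factors** — the DESeq2-style depth correction: a
  per-gene reference is the geometric mean across samples (restricted to
  genes with no zero count in any sample), and each sample's size factor is
  the median ratio of its counts to that reference.
* **log10(x + 1)** — the variance-taming transform applied to signature
  scores and, for the PAX7 score, to the whole matrix.
* **quantile normalization** — forces every sample's value distribution onto
  a shared reference (the mean of within-sample order statistics); ties
  within a sample receive the mean of the reference values their ranks span,
  which keeps constant columns fixed and makes the transform idempotent.

The DUX4 cumulative score is computed on size-factor-normalized counts; the
log transform enters only afterwards, for statistics and ROC.  The PAX7
t-statistic is computed on log10(x+1), quantile-normalized values.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import numpy as np
import pandas as pd

from .io import CountMatrix, ValidationError

__all__ = ["SizeFactors", "compute_size_factors", "normalize_counts", "log10_p1", "quantile_normalize"]


class DegenerateInputError(ValueError):
    """The input is structurally valid but the operation is undefined on it."""


@dataclass
class SizeFactors:
    """Per-sample depth scaling factors from the median-of-ratios method."""

    factors: pd.Series  # sample_id -> s_j > 0
    n_reference_genes: int

    def __post_init__(self) -> None:
        if (self.factors <= 0).any():
            raise ValidationError("size factors must be strictly positive")
        if self.n_reference_genes < 1:
            raise ValidationError("need at least one reference gene")


def compute_size_factors(counts: CountMatrix) -> SizeFactors:
    """Median-of-ratios size factors on a raw count matrix.

    Genes with a zero count in any sample are excluded from the reference
    (the geometric mean is computed in log space, so a zero would send it to
    zero).  The median of an even-length ratio list is the mean of the two
    central values (numpy's convention).
    """
    if counts.scale != "raw":
        raise ValidationError(f"size factors are defined on raw counts, got scale {counts.scale!r}")
    if counts.n_samples < 2:
        raise DegenerateInputError("need at least 2 samples to compute size factors")
    arr = counts.values.to_numpy(dtype=float)
    all_positive = (arr > 0).all(axis=1)
    if not all_positive.any():
        raise DegenerateInputError("no gene has strictly positive counts in every sample")
    ref = arr[all_positive]
    log_geomean = np.log(ref).mean(axis=1)
    ratios = np.log(ref) - log_geomean[:, None]
    s = np.exp(np.median(ratios, axis=0))
    return SizeFactors(
        factors=pd.Series(s, index=counts.values.columns, name="size_factor"),
        n_reference_genes=int(all_positive.sum()),
    )


def normalize_counts(counts: CountMatrix, sf: SizeFactors) -> CountMatrix:
    """Divide each sample's counts by its size factor."""
    if counts.scale != "raw":
        raise ValidationError(f"expected raw counts, got scale {counts.scale!r}")
    missing = [s for s in counts.sample_ids if s not in sf.factors.index]
    if missing:
        raise ValidationError(f"samples without a size factor: {missing}")
    normed = counts.values.div(sf.factors[counts.values.columns], axis=1)
    return CountMatrix(values=normed, scale="size_factor_normalized")


def log10_p1(x):
    """Elementwise log10(x + 1); input must be non-negative.

    Accepts scalars, arrays, Series, DataFrames or a CountMatrix (whose scale
    tag is updated to ``log10p1``).
    """
    if isinstance(x, CountMatrix):
        return CountMatrix(values=log10_p1(x.values), scale="log10p1")
    arr = np.asarray(x, dtype=float) if np.isscalar(x) else x
    if np.nanmin(np.asarray(arr, dtype=float)) < 0:
        raise ValueError("log10_p1 requires non-negative input")
    out = np.log10(np.asarray(arr, dtype=float) + 1.0)
    if isinstance(x, pd.DataFrame):
        return pd.DataFrame(out, index=x.index, columns=x.columns)
    if isinstance(x, pd.Series):
        return pd.Series(out, index=x.index, name=x.name)
    if np.isscalar(x):
        return float(out)
    return out


def _qn_column(values: np.ndarray, reference: np.ndarray) -> np.ndarray:
    """Map one column onto the reference distribution, averaging over ties."""
    order = np.argsort(values, kind="stable")
    sorted_vals = values[order]
    # boundaries of tie groups in the sorted column
    starts = np.flatnonzero(np.r_[True, sorted_vals[1:] != sorted_vals[:-1]])
    counts = np.diff(np.r_[starts, len(sorted_vals)])
    group_means = np.add.reduceat(reference, starts) / counts
    out_sorted = np.repeat(group_means, counts)
    out = np.empty_like(out_sorted)
    out[order] = out_sorted
    return out


def quantile_normalize(m: CountMatrix, genes: Iterable[str] | None = None) -> CountMatrix:
    """Quantile-normalize a log10(x+1) matrix across samples.

    The reference distribution is the mean of within-sample order statistics.
    Tied values within a sample all receive the mean of the reference values
    over the ranks the tie occupies, so a constant column maps to itself and
    the transform is idempotent.

    Parameters
    ----------
    genes
        Optional restriction: normalize only these rows (e.g. the union of
        the signature target genes); other rows are dropped from the output.
    """
    if m.scale not in ("log10p1", "quantile_normalized"):
        raise ValidationError(f"quantile normalization expects log10p1 input, got scale {m.scale!r}")
    vals = m.values
    if genes is not None:
        keep = [g for g in m.gene_ids if g in set(genes)]
        if not keep:
            raise ValidationError("gene restriction leaves no rows")
        vals = vals.loc[keep]
    if vals.shape[1] < 2:
        raise DegenerateInputError("need at least 2 samples to quantile-normalize")
    arr = vals.to_numpy(dtype=float)
    if np.isnan(arr).any():
        raise ValidationError("quantile normalization requires a complete matrix")
    reference = np.sort(arr, axis=0).mean(axis=1)
    out = np.column_stack([_qn_column(arr[:, j], reference) for j in range(arr.shape[1])])
    return CountMatrix(
        values=pd.DataFrame(out, index=vals.index, columns=vals.columns),
        scale="quantile_normalized",
    )
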