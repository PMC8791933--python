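"""Imaging-biomarker contingency counts from the original clinical cohort.

The reference FSHD cohort (12 controls, 39 FSHD muscle biopsies after
replicate exclusion, 19 of them DUX4 signature-positive) reported, per
imaging biomarker, how biomarker status split the DUX4-positive and
DUX4-negative FSHD biopsies.  Those printed counts are bundled here as
:class:`~fshdsig.biomarkers.ConfusionTable2x2` inputs so the predictive-power
metrics can be recomputed without the controlled-access expression data.

Counts (FSHD biopsies only; outcome = DUX4 positivity):

* TIRM hyperintensity: 5/5 TIRM-positive biopsies were DUX4-positive and
  13/33 TIRM-negative biopsies were DUX4-positive; TIRM was not acquired for
  one (DUX4-positive) biopsy, so the table covers 38 biopsies while the
  cohort-wide positive total stays 19.
* Fat fraction (> 15%): 9/10 fat-positive biopsies were DUX4-positive; the
  remaining 10 DUX4-positive biopsies were fat-negative (all 39 biopsies had
  a fat fraction).
* Combined (TIRM and/or fat positive): 11/12 biomarker-positive biopsies
  were DUX4-positive; the biopsy lacking TIRM data was fat-negative, hence
  unclassifiable by the combined rule and excluded from its table.
"""

from __future__ import annotations

from .biomarkers import ConfusionTable2x2

__all__ = ["COHORT_DUX4_POSITIVES", "reference_cohort_tables"]

#: DUX4 signature-positive FSHD biopsies in the reference cohort, including
#: the one without TIRM data — the sensitivity denominator the cohort used.
COHORT_DUX4_POSITIVES = 19


def reference_cohort_tables() -> dict[str, ConfusionTable2x2]:
    """The reference cohort's predictor-vs-DUX4 confusion tables."""
    return {
        "TIRM": ConfusionTable2x2(
            tp=5, fp=0, fn=13, tn=20,
            predictor_name="TIRM", outcome_name="DUX4", n_missing_excluded=1,
        ),
        "Fat": ConfusionTable2x2(
            tp=9, fp=1, fn=10, tn=19,
            predictor_name="Fat", outcome_name="DUX4", n_missing_excluded=0,
        ),
        "Combined": ConfusionTable2x2(
            tp=11, fp=1, fn=7, tn=19,
            predictor_name="Combined", outcome_name="DUX4", n_missing_excluded=1,
        ),
    }
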