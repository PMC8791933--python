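"""Synthetic FSHD biopsy cohort generator with ground truth.

Emulates the statistical structure the signature analysis assumes, so every
pipeline stage is testable without access to the controlled-access patient
data:

* **Sporadic DUX4 bursts** — each FSHD biopsy is burst-active with a fixed
  probability (default 48.7%, the observed DUX4-positive fraction).  A burst
  deposits a log-uniform mass of normalized reads (default range 20.3-807.8)
  over a random ~half of the DUX4 target genes via symmetric Dirichlet
  weights, injected on the expected-count scale *before* negative-binomial
  sampling so depth normalization sees realistic overdispersion.  All
  biopsies, controls included, carry a small leakage signal calibrated so the
  expected control score matches the observed control mean (6.44).
* **A single latent pathology axis** u ~ Uniform(0,1) per FSHD biopsy (0 in
  controls) down-regulates PAX7-induced targets and up-regulates repressed
  targets (factor exp(∓pax7_effect*u)), raises fat fraction, histology and
  inflammation scores, and degrades participant-level strength/function
  measures (MRC, 6-MWT, MFM, CSS).  Burst state and u are drawn
  independently by default (the two signatures showed no clear correlation);
  a coupling knob exists.
* **Imaging** — fat fraction is group-wise Beta-distributed (control mean
  5.36%, FSHD mean 18.49%) shifted upward with u; TIRM positivity is sparse
  and concentrated in burst-active biopsies.

Gene symbols are synthetic placeholders (DUX4T_*, PAX7I_*, PAX7R_*, GENE_*)
except the four real myogenic marker genes MYOD1/MYOG/MYH3/MYH8, whose
expression is tied to u so that muscle-content correlations are exercised.

All randomness flows from a single seed with a documented draw order:
(1) per-sample depth factors, (2) baseline gene means, (3) burst indicators,
masses and allocations, (4) latent pathology u, (5) count sampling,
(6) clinical and imaging fields.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .io import (
    BiopsyMetadata,
    CountMatrix,
    SignatureGeneSets,
    ValidationError,
    write_counts,
    write_gene_sets,
    write_metadata,
)

__all__ = [
    "CohortConfig",
    "signature_gene_sets",
    "generate_cohort",
    "expected_scores",
    "write_fixtures",
]

N_DUX4_TARGETS = 57
N_PAX7_INDUCED = 30
N_PAX7_REPRESSED = 30
MARKER_GENES = ["MYOD1", "MYOG", "MYH3", "MYH8"]
_MARKER_BASE = {"MYOD1": 500.0, "MYOG": 400.0, "MYH3": 150.0, "MYH8": 300.0}


@dataclass
class CohortConfig:
    """Simulation parameters; defaults are the reference study conditions.

    burst_mass_range is on the normalized-score scale (cumulative normalized
    reads a burst adds); control_leak_mean is the expected DUX4 score of a
    burst-free biopsy.  mean_library_size defaults to a desk-scale 3e6 reads
    (the real cohort averaged ~3e7; the flag is a scale, not a behavior,
    choice).  nb_dispersion is the negative-binomial dispersion alpha in
    var = mu + alpha*mu^2.
    """

    seed: int = 0
    n_control: int = 12
    n_fshd: int = 38
    n_genes: int = 2000
    mean_library_size: float = 3e6
    nb_dispersion: float = 0.05
    burst_probability: float = 0.487
    burst_mass_range: tuple[float, float] = (20.3, 807.8)
    control_leak_mean: float = 6.44
    pax7_effect: float = 1.0
    fat_beta_ctrl: tuple[float, float] = (2.2, 38.8)
    fat_beta_fshd: tuple[float, float] = (1.5, 14.5)
    fat_u_shift: float = 18.23
    tirm_given_burst: float = 0.263
    tirm_given_no_burst: float = 0.02
    burst_pathology_coupling: float = 0.0
    depth_sigma: float = 0.12

    def __post_init__(self) -> None:
        for p in (self.burst_probability, self.tirm_given_burst, self.tirm_given_no_burst):
            if not (0 <= p <= 1):
                raise ValidationError("probabilities must lie in [0, 1]")
        if self.burst_mass_range[0] > self.burst_mass_range[1]:
            raise ValidationError("burst_mass_range must be (low, high) with low <= high")
        if self.control_leak_mean < 0:
            raise ValidationError("control_leak_mean must be >= 0")
        if self.nb_dispersion <= 0:
            raise ValidationError("nb_dispersion must be > 0")


def _gene_names(n_genes: int) -> tuple[list[str], SignatureGeneSets]:
    dux4 = [f"DUX4T_{i:02d}" for i in range(1, N_DUX4_TARGETS + 1)]
    induced = [f"PAX7I_{i:02d}" for i in range(1, N_PAX7_INDUCED + 1)]
    repressed = [f"PAX7R_{i:02d}" for i in range(1, N_PAX7_REPRESSED + 1)]
    n_named = len(dux4) + len(induced) + len(repressed) + len(MARKER_GENES)
    if n_genes < n_named:
        raise ValidationError(f"n_genes={n_genes} smaller than the {n_named} signature/marker genes")
    filler = [f"GENE_{i:05d}" for i in range(1, n_genes - n_named + 1)]
    names = dux4 + induced + repressed + MARKER_GENES + filler
    sets = SignatureGeneSets(
        dux4_targets=frozenset(dux4),
        pax7_induced=frozenset(induced),
        pax7_repressed=frozenset(repressed),
    )
    return names, sets


def signature_gene_sets(cfg: CohortConfig | None = None) -> SignatureGeneSets:
    """The gene sets matching the generator's gene naming (deterministic)."""
    n = cfg.n_genes if cfg is not None else 2000
    return _gene_names(n)[1]


def _biopsy_plan(cfg: CohortConfig) -> list[tuple[str, str, str]]:
    """(biopsy_id, participant_id, muscle) for the whole cohort.

    Controls donate one VL biopsy each; FSHD participants donate a VL biopsy
    and every third participant also a TA biopsy, until n_fshd is reached.
    """
    plan = [(f"CTRL-{i:02d}_VL", f"CTRL-{i:02d}", "VL") for i in range(1, cfg.n_control + 1)]
    n = 0
    p = 0
    fshd: list[tuple[str, str, str]] = []
    while n < cfg.n_fshd:
        p += 1
        pid = f"FSHD-{p:02d}"
        fshd.append((f"{pid}_VL", pid, "VL"))
        n += 1
        if n < cfg.n_fshd and p % 3 == 0:
            fshd.append((f"{pid}_TA", pid, "TA"))
            n += 1
    return plan + fshd


def generate_cohort(
    cfg: CohortConfig,
) -> tuple[CountMatrix, list[BiopsyMetadata], pd.DataFrame]:
    """Generate a raw count matrix, metadata records and a ground-truth table.

    The ground truth is a DataFrame indexed by biopsy id with columns
    burst_active, burst_mass (normalized-score scale), pathology_u, group and
    muscle.  Same seed, same output — bit for bit.
    """
    rng = np.random.default_rng(cfg.seed)
    genes, sets = _gene_names(cfg.n_genes)
    plan = _biopsy_plan(cfg)
    biopsy_ids = [b for b, _, _ in plan]
    groups = np.array(["CTRL" if b.startswith("CTRL") else "FSHD" for b in biopsy_ids])
    n_samples = len(biopsy_ids)
    is_fshd = groups == "FSHD"

    dux4_idx = np.arange(N_DUX4_TARGETS)
    ind_idx = np.arange(N_DUX4_TARGETS, N_DUX4_TARGETS + N_PAX7_INDUCED)
    rep_idx = np.arange(ind_idx[-1] + 1, ind_idx[-1] + 1 + N_PAX7_REPRESSED)
    marker_idx = np.arange(rep_idx[-1] + 1, rep_idx[-1] + 1 + len(MARKER_GENES))
    filler_idx = np.arange(marker_idx[-1] + 1, cfg.n_genes)

    # (1) per-sample depth factors, geometric mean 1
    depth = rng.lognormal(mean=0.0, sigma=cfg.depth_sigma, size=n_samples)
    depth /= np.exp(np.mean(np.log(depth)))

    # (2) baseline gene means, on the normalized-count scale
    base = np.zeros(cfg.n_genes)
    base[dux4_idx] = cfg.control_leak_mean / N_DUX4_TARGETS
    base[ind_idx] = 10 ** rng.normal(1.1, 0.45, size=N_PAX7_INDUCED)
    base[rep_idx] = 10 ** rng.normal(1.85, 0.50, size=N_PAX7_REPRESSED)
    base[marker_idx] = [_MARKER_BASE[g] for g in MARKER_GENES]
    filler = rng.lognormal(mean=np.log(200.0), sigma=1.3, size=len(filler_idx))
    budget = cfg.mean_library_size - base.sum()
    if budget <= 0:
        raise ValidationError("mean_library_size too small for the signature baseline")
    base[filler_idx] = filler * (budget / filler.sum())

    # (3) burst state per biopsy (controls never burst)
    burst_active = np.zeros(n_samples, dtype=bool)
    burst_active[is_fshd] = rng.random(is_fshd.sum()) < cfg.burst_probability
    lo, hi = cfg.burst_mass_range
    burst_mass = np.zeros(n_samples)
    n_burst = int(burst_active.sum())
    if n_burst and hi > 0:
        if lo <= 0:
            raise ValidationError("burst_mass_range low bound must be > 0 when bursts occur")
        burst_mass[burst_active] = np.exp(rng.uniform(np.log(lo), np.log(hi), size=n_burst))
    burst_alloc = np.zeros((N_DUX4_TARGETS, n_samples))
    for j in np.flatnonzero(burst_active):
        n_sel = max(2, int(rng.binomial(N_DUX4_TARGETS, 0.5)))
        sel = rng.choice(N_DUX4_TARGETS, size=n_sel, replace=False)
        w = rng.dirichlet(np.ones(n_sel))
        burst_alloc[sel, j] = burst_mass[j] * w

    # (4) latent pathology, optionally coupled to burst state
    u = np.zeros(n_samples)
    u[is_fshd] = rng.uniform(0.0, 1.0, size=is_fshd.sum())
    if cfg.burst_pathology_coupling:
        c = cfg.burst_pathology_coupling
        u[is_fshd] = np.clip(u[is_fshd] + c * (burst_active[is_fshd].astype(float) - 0.5), 0.0, 1.0)

    # expected counts: baseline modulated by pathology, plus burst injection
    mean_mat = np.tile(base[:, None], (1, n_samples))
    mean_mat[np.ix_(ind_idx, np.arange(n_samples))] *= np.exp(-cfg.pax7_effect * u)[None, :]
    mean_mat[np.ix_(rep_idx, np.arange(n_samples))] *= np.exp(+cfg.pax7_effect * u)[None, :]
    # myogenic markers track muscle content: regulatory factors fall with
    # pathology, regeneration myosins rise
    mean_mat[marker_idx[0], :] *= np.exp(-0.3 * u)
    mean_mat[marker_idx[1], :] *= np.exp(-0.3 * u)
    mean_mat[marker_idx[2], :] *= np.exp(+0.5 * u)
    mean_mat[marker_idx[3], :] *= np.exp(+0.5 * u)
    mean_mat[dux4_idx, :] += burst_alloc
    mean_mat *= depth[None, :]

    # (5) negative-binomial sampling, var = mu + alpha*mu^2
    alpha = cfg.nb_dispersion
    with np.errstate(divide="ignore", invalid="ignore"):
        p = 1.0 / (1.0 + alpha * mean_mat)
    counts = rng.negative_binomial(n=1.0 / alpha, p=p)
    values = pd.DataFrame(counts.astype(float), index=genes, columns=biopsy_ids)
    cm = CountMatrix(values=values, scale="raw")

    # (6) clinical and imaging fields
    participant_ids = [pid for _, pid, _ in plan]
    u_series = pd.Series(u, index=biopsy_ids)
    pid_series = pd.Series(participant_ids, index=biopsy_ids)
    u_part = u_series.groupby(pid_series).mean()

    part_fields: dict[str, dict] = {}
    for pid in dict.fromkeys(participant_ids):
        is_f = pid.startswith("FSHD")
        up = float(u_part[pid])
        age = float(np.clip(rng.normal(52.0, 10.0), 18, 85))
        sex = "M" if rng.random() < 0.5 else "F"
        bmi = float(np.clip(rng.normal(25.5, 4.0), 16, 45))
        if is_f:
            duration = float(max(1.0, rng.normal(20.0, 9.0)))
            reduction = round(2 * max(0.0, 1.5 * up + rng.normal(0.0, 0.3))) / 2
            mrc = float(max(0.0, 5.0 - min(reduction, 5.0)))
            css = int(np.clip(round(10 * up + rng.normal(0.0, 1.0)), 0, 10))
            six_mwt = float(max(50.0, rng.normal(513.5 - 130.0 * up, 45.0)))
            mfm = float(np.clip(rng.normal(1.0 - 0.15 * up, 0.02), 0.0, 1.0))
            d4z4 = int(rng.integers(3, 10))
            part_fields[pid] = dict(
                age=age, sex=sex, bmi=bmi, disease_duration=duration,
                age_at_onset=max(5.0, age - duration), mrc=mrc, css=css,
                six_mwt=six_mwt, mfm=mfm, d4z4_units=d4z4,
            )
        else:
            part_fields[pid] = dict(
                age=age, sex=sex, bmi=bmi, disease_duration=None, age_at_onset=None,
                mrc=5.0, css=None,
                six_mwt=float(rng.normal(513.5, 45.0)),
                mfm=float(np.clip(rng.normal(0.99, 0.01), 0.0, 1.0)),
                d4z4_units=None,
            )

    records: list[BiopsyMetadata] = []
    a_c, b_c = cfg.fat_beta_ctrl
    a_f, b_f = cfg.fat_beta_fshd
    for j, (bid, pid, muscle) in enumerate(plan):
        is_f = groups[j] == "FSHD"
        if is_f:
            fat = 100.0 * rng.beta(a_f, b_f) + cfg.fat_u_shift * u[j]
            tirm_p = cfg.tirm_given_burst if burst_active[j] else cfg.tirm_given_no_burst
            tirm = "POS" if rng.random() < tirm_p else "NEG"
            histology = int(np.clip(round(1.5 + 8.0 * u[j] + rng.normal(0.0, 1.0)), 0, 12))
            inflammation = int(rng.poisson(1.2 * u[j]))
        else:
            fat = 100.0 * rng.beta(a_c, b_c)
            tirm = "NEG"
            histology = int(np.clip(round(rng.normal(2.0, 1.0)), 0, 4))
            inflammation = int(rng.random() < 0.1)
        pf = part_fields[pid]
        records.append(
            BiopsyMetadata(
                biopsy_id=bid,
                participant_id=pid,
                group=groups[j],
                muscle=muscle,
                tirm=tirm,
                fat_fraction=float(np.clip(fat, 0.0, 100.0)),
                histology_sum=histology,
                inflammation=inflammation,
                **pf,
            )
        )

    gt = pd.DataFrame(
        {
            "burst_active": burst_active,
            "burst_mass": burst_mass,
            "pathology_u": u,
            "group": groups,
            "muscle": [m for _, _, m in plan],
        },
        index=pd.Index(biopsy_ids, name="biopsy_id"),
    )
    return cm, records, gt


def expected_scores(cfg: CohortConfig, gt: pd.DataFrame) -> pd.Series:
    """Analytic expectation of each biopsy's DUX4 score (normalized scale).

    leakage mean for burst-free biopsies; leakage mean + burst mass for
    burst-active ones.
    """
    exp = cfg.control_leak_mean + np.where(gt["burst_active"].to_numpy(), gt["burst_mass"].to_numpy(), 0.0)
    return pd.Series(exp, index=gt.index, name="expected_dux4_score")


def write_fixtures(
    counts: CountMatrix,
    metadata: list[BiopsyMetadata],
    gene_sets: SignatureGeneSets,
    ground_truth: pd.DataFrame,
    directory: str | Path,
) -> dict[str, Path]:
    """Write counts.tsv, metadata.tsv, genesets.gmt and ground_truth.tsv.

    The directory is a self-sufficient input for the whole pipeline.
    """
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    paths = {
        "counts": d / "counts.tsv",
        "metadata": d / "metadata.tsv",
        "gene_sets": d / "genesets.gmt",
        "ground_truth": d / "ground_truth.tsv",
    }
    write_counts(counts, paths["counts"])
    write_metadata(metadata, paths["metadata"])
    write_gene_sets(gene_sets, paths["gene_sets"])
    ground_truth.to_csv(paths["ground_truth"], sep="\t")
    return paths
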