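# fshdsig

Transcriptome signature scoring and imaging-biomarker concordance analysis
for facioscapulohumeral muscular dystrophy (FSHD) muscle biopsies.

FSHD is caused by sporadic mis-expression of the transcription factor DUX4 in
skeletal muscle. Because DUX4 bursts are rare and short-lived, single-gene
read-outs miss them; the field instead scores each biopsy by the **cumulative
size-factor-normalized read count over a fixed list of 57 DUX4 target
genes**, calling a biopsy DUX4-positive when that score exceeds 20 normalized
reads. A complementary **PAX7 score** — the two-sample t-statistic comparing
PAX7-induced versus PAX7-repressed target genes within one sample, on
log10(x+1), quantile-normalized data — tracks muscle pathology along an
independent axis. MRI biomarkers (TIRM hyperintensity and quantitative fat
fraction, abnormal above 15%) are then evaluated as practical predictors of
signature positivity.

This package implements that pipeline end to end for researchers working
with bulk RNA-seq of muscle biopsies:

* `fshdsig.io` — count-matrix / metadata / gene-set types and TSV/GMT readers
* `fshdsig.normalization` — median-of-ratios size factors, log10(x+1),
  quantile normalization
* `fshdsig.scoring` — DUX4 score + positivity call, PAX7 t-statistic +
  HIGH/LOW selection, fat-fraction correction, myogenic-content index
* `fshdsig.biomarkers` — TIRM/fat/combined classification, 2×2 confusion
  tables, sensitivity/specificity/PPV/NPV, two-sided Fisher's exact test
* `fshdsig.stats` — Shapiro–Wilk-gated Welch-t / Mann–Whitney group
  comparisons, ROC/AUC, pairwise-complete Pearson + Spearman correlation
  matrices
* `fshdsig.simulate` — a synthetic cohort generator with ground truth
  (sporadic DUX4 bursts, a latent pathology axis, correlated imaging and
  clinical fields), so the whole pipeline is testable without
  controlled-access patient data
* `fshdsig.pipeline` / `fshdsig.cli` — one-command orchestration

## Worked example

```python
import fshdsig as fs

cfg = fs.CohortConfig(seed=7)                      # 12 controls, 38 FSHD biopsies
counts, records, truth = fs.generate_cohort(cfg)   # raw counts + ground truth
meta = fs.metadata_frame(records)
scores = fs.compute_signature_scores(
    counts, fs.signature_gene_sets(cfg),
    fshd_biopsies=meta.index[meta.group == "FSHD"],
)
```

Running `python examples/02_signature_scores.py` (which does the above)
prints:

```
DUX4-positive FSHD biopsies: 23/38
control DUX4 scores: mean 7.33, max 10.92
PAX7 score means: CTRL -6.31, FSHD -9.58
positivity call vs ground-truth burst state: 100.0% agreement
```

Control biopsies carry only leakage-level DUX4 target expression (scores far
below the 20-read threshold), roughly half the FSHD biopsies are
burst-active and called positive, the positivity call recovers the simulated
burst state exactly, and PAX7 scores sit lower in FSHD. The other example
scripts cover cohort simulation (`01`), biomarker concordance (`03`) and the
statistical machinery (`04`).

The same pipeline runs from the shell:

```sh
fshdsig simulate --seed 7 --out fixtures/
fshdsig run-all --seed 7 --out results/
fshdsig reference-tables
```

`reference-tables` recomputes, from the bundled reference-cohort contingency
counts, the biomarker concordance numbers: TIRM alone flags DUX4-positive
biopsies with 100% PPV but only 26.3% sensitivity (5/19); fat fraction
reaches 47.4% sensitivity at 90% PPV (9/10); the combined biomarker attains
57.9% sensitivity (11/19) at 91.7% PPV (11/12).

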