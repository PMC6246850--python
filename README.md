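# connstim

Functional-connectome-based simulation of focal brain stimulation.

An observed region-by-region functional connectome (Fisher-z Pearson
correlations) is interpreted as the accumulation of direct plus indirect
interactions of an underlying direct network, `F = D + D² + D³ + …`.  Both
directions have closed forms in the shared eigenbasis: *network
deconvolution* maps eigenvalues through `λ → λ/(1+λ)` to recover `D`, and
*transitive closure* maps `η → η/(1−η)` to recover `F`.  A focal
stimulation event is a multiplicative operator `P` on `D` (strength `s` on
the target's rows/columns, 1 elsewhere; `s<1` down-regulates); the
post-stimulation connectome is `TC(ND(F) ⊙ P)`.  Candidate targets and
strengths are ranked by the percent change in Pearson similarity between a
patient connectome and a group-averaged healthy reference.

The package covers:

- `connstim.transforms` — the ND/TC eigen-transform pair and the pooled
  `α/β` spectral scaling that keeps them convergent.
- `connstim.connectome` — parcellations (a 92-region bilateral scheme ships
  as the default), time-series → connectome construction, group averaging,
  TSV/NIfTI I/O, and k-means subdivision of a parcellation into a
  high-resolution template.
- `connstim.stimulation` — perturbation operators, feasibility-guarded
  stimulation, and (target × strength) sweeps.
- `connstim.evaluation` — connectomic similarity, relative change, strength
  optimisation, target ranking, occurrence summaries, subsample and
  null-label cross-validation, rank–severity (Kendall) correlation, and
  similarity-based group discrimination (AUC).
- `connstim.topology` — edge-wise two-sample t-tests with Bonferroni
  correction and categorisation of stimulation-induced topological change
  (removed / new / unchanged abnormal connections).
- `connstim.synthetic` — seeded generators for healthy cohorts, patient
  cohorts with implanted lesions (and a ground-truth ledger), matching
  time series, and labelled atlas volumes, so the full pipeline runs
  without any external data.

## CLI

```sh
# generate a synthetic cohort with a known implanted lesion
connstim synth --n-regions 20 --n-healthy 10 --n-patients 10 \
    --lesion-pair 3 --lesion-strength 0.5 --seed 1 --out-dir cohort/

# build connectomes from region time-series TSVs
connstim build ts_subject1.tsv --out-dir connectomes/

# sweep all (target, strength) combinations for one subject
connstim simulate --connectome cohort/pd001.tsv --healthy-ref cohort/hc001.tsv \
    --parcellation cohort/parcellation.tsv --out sweep.tsv

# per-subject + group rankings, cross-validation, discrimination AUC
connstim rank --cohort cohort/cohort.tsv --parcellation cohort/parcellation.tsv --out-dir rank/
connstim crossval --cohort cohort/cohort.tsv --parcellation cohort/parcellation.tsv \
    --mode subsample --n-iter 100 --out-dir cv/
connstim auc --cohort cohort/cohort.tsv --parcellation cohort/parcellation.tsv --out auc.tsv
```

Cohort manifests are TSVs with columns `subject_id`, `group`
(`patient`/`healthy`), `connectome_path`, and optionally `score` (a
clinical severity value for `connstim correlate`).

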