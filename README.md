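# eegmst

Phase Lag Index (PLI) connectivity and minimum-spanning-tree (MST) topology
analysis for resting-state EEG cohorts, with nonparametric group statistics,
single-feature ROC discrimination, and a synthetic-cohort generator with
known band-specific phase-coupling structure.

## What it does

- **I/O + preprocessing** (`eegmst.io_preprocess`): EDF and BrainVision
  readers (pure-Python, no external EEG stack needed), EOG-channel removal,
  common-average re-referencing, zero-phase 0.5–48 Hz band-pass,
  downsampling to 250 Hz, 2-s epoching, and peak-to-peak amplitude epoch
  rejection with a minimum-epoch gate (default 40).
- **Connectivity** (`eegmst.connectivity`): analytic-signal phases per epoch
  and the PLI estimator |⟨sign sin Δφ⟩| per channel pair, per band
  (delta/theta/alpha/beta/gamma), with edge-sample exclusion and
  zero-variance handling. PLI is 0 for zero-lag (volume-conduction-like)
  pairs and 1 for a consistent nonzero lag.
- **MST topology** (`eegmst.mst_topology`): Kruskal's algorithm on 1 − PLI
  weights with deterministic tie-breaking, and the tree metric suite:
  max degree, normalized betweenness (BC), normalized eccentricity and
  diameter (hop counts / M), leaf fraction, tree hierarchy L/(2·M·BCmax),
  and kappa ⟨k²⟩/⟨k⟩.
- **Group statistics** (`eegmst.cohort_stats`): tie-corrected
  Kruskal-Wallis, Dunn's post-hoc z tests, Holm-Bonferroni adjustment
  (per-band or global families), Mann-Whitney U, and plain/partial Pearson
  correlations via covariate residualization.
- **Discrimination** (`eegmst.discrimination`): stratified 50/50 split,
  univariate logistic regression, test-half ROC with bootstrap CIs.
- **Synthetic cohorts** (`eegmst.synthetic_cohort`): deterministic
  multichannel recordings whose per-band coupling differs by group
  (theta up / beta down in the AD-like group), plus covariates, clinical
  scores and CSF values linked to the couplings, and an independent
  Monte-Carlo PLI oracle for estimator validation.

## CLI

```bash
eegmst simulate   --seed 1 --fast --out raw/          # synthetic cohort (EDF + subjects.csv)
eegmst preprocess --in raw/HC000.edf --format edf --out epochs/
eegmst connectivity --epochs epochs/ --out pli/
eegmst mst        --matrices pli/ --out mst/           # per-subject trees + metrics_long.csv
eegmst stats      --metrics mst/metrics_long.csv --subjects raw/subjects.csv --out stats/
eegmst correlate  --metrics mst/metrics_long.csv --subjects raw/subjects.csv --adjust --out corr/
eegmst roc        --metrics mst/metrics_long.csv --subjects raw/subjects.csv --seed 1 --out roc/
```

`simulate --spec spec.yaml` and `preprocess --config config.yaml` accept
YAML overrides (group sizes, bands, rejection limit, …); see
`eegmst.pipeline.PipelineConfig` and `eegmst.synthetic_cohort.CohortSpec`
for the full key lists.

## Library API sketch

```python
from eegmst import CohortSpec, PipelineConfig, generate_cohort_records, cohort_metrics_table

spec = CohortSpec.fast_preset(seed=1)
pairs = generate_cohort_records(spec)                   # [(SubjectRecord, Recording), ...]
table = cohort_metrics_table(((r.subject_id, rec) for r, rec in pairs),
                             PipelineConfig(reject_limit=250.0))
# table: long format (subject, band, metric, value) — input to cohort_stats / discrimination
```
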