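# emobio

EEG biomarker pipeline for mental imagery of facial expressions: synthetic
trial-structured cohorts, preprocessing, band-limited linear/non-linear
feature extraction, t-ranked feature selection, and SVM /
WiSARD-with-bleaching classification under repeated stratified holdout.

## What's inside

| Module | Purpose |
| --- | --- |
| `emobio.schedule` | Visual (2×120 trials, 1.5 s stimuli) and imagery (2×40 trials, 4 s imagery + neutral period) trial schedules |
| `emobio.montage` | 64-channel 10-10 montage and the right centro-parietal → occipital clusters C1/C2/C4/C5 (editable YAML in `emobio/data/`) |
| `emobio.synth` | Two-group synthetic EEG: 1/f background + band-limited oscillations + noise, with injectable (band × cluster × window) group effects |
| `emobio.preprocess` | Zero-phase band-pass (1–100 Hz) / notch (47.5–52.5 Hz), average reference, epoching, bad-epoch rejection, baseline correction, ERP averaging |
| `emobio.features` | 8 features per (trial, channel, band, window): envelope, Teager energy, power + SFI, largest Lyapunov exponent, correlation dimension, ApEn, SampEn on delay embeddings; baseline normalization |
| `emobio.wisard` | From-scratch weightless neural network: thermometer encoding, seeded tuple mapping, RAM discriminators, bleaching tie resolution |
| `emobio.pipeline` | Cluster averaging into the 160-column subject table, per-fold Welch-t ranking, repeated stratified 80/20 holdout over a feature-count grid, metrics, covariate correlations, reports |
| `emobio.workflow` | One-call cohort → (emotion, neutral) feature tables |
| `emobio.io` | Minimal BrainVision (.vhdr/.vmrk/.eeg) and EDF writers/readers, epoch tensor persistence |

## CLI

```bash
# write a cohort spec, simulate, preprocess, extract, classify, report
python - <<'PY'
from emobio.synth import CohortSpec
CohortSpec(n_per_group=2, sampling_rate_hz=125.0, seed=1).to_yaml("cohort.yaml")
PY
emobio simulate  --spec cohort.yaml --out raw/
emobio preprocess --in raw/sub-000.vhdr --out work/sub-000 --band 1 45
emobio features  --epochs work/sub-000 --out work/sub-000-features.csv --subject sub-000
emobio classify  --emotion emotion_table.csv --neutral neutral_table.csv --out eval/ --reps 50 --seed 0
emobio report    --in eval/ --out figs/
```

`classify` consumes per-subject feature tables (one row per subject, 160
`feature__band__cluster` columns plus a `group` column); build them from
per-subject feature CSVs with `emobio.pipeline.cluster_average`, or in one
call with `emobio.workflow.cohort_feature_tables`.

## Notes

- Classification figures mirror the usual presentation: accuracy vs number
  of features (mean ± SEM; emotion vs neutral runs) plus top-15 feature
  selection histograms by band and by cluster.
- ICA artifact removal is a pluggable no-op hook
  (`preprocess.apply_artifact_removal`); bad channels are excluded rather
  than interpolated.
- All randomness is seeded; identical seeds reproduce cohorts, splits and
  reports bit-identically.
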