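# cogload

A tested, reusable pipeline linking wearable physiological signals (PPG,
skin conductance, accelerometer, skin temperature at 51.2 Hz) to binary
cognitive-load classification and food-choice behaviour analysis:

* **synthgen** — synthetic subject-session generator (signals with known
  latent beat/SCR/artefact events, task label tracks, affect and workload
  questionnaires, food-weight tables) so every downstream stage is testable
  without access to restricted recordings.
* **ingest** — CSV readers with validation and NaN repair, accelerometer
  hand-tap clock synchronisation, and labelled segmentation.
* **preprocess** — zero-phase Butterworth band-passing, PPG beat detection
  with a sequential 10 % inter-beat-interval acceptance rule, and sparse
  convex decomposition of skin conductance into tonic / phasic / sudomotor
  driver components (ARMA-form bi-exponential kernel, solved by ADMM with a
  cached sparse factorisation; verified against an exact dense active-set
  oracle in the tests).
* **features** — 2-minute windows with 75 % overlap, three artefact rules
  (motion, heart-rate variability, implausibly low heart rate), and a frozen
  125-feature catalogue (46 pulse-shape + 4 spectral + 11 heart-rate +
  2 temperature + 43 conductance + 19 decomposition features).
* **modelsel** — hybrid selection (ANOVA filter to 40, then RFECV with a
  random forest) and nested leave-one-subject-out grid-search evaluation
  with per-subject macro metrics and no-leakage provenance records.
* **behaviour** — affect (PANAS) and workload (NASA-TLX) scoring,
  Shapiro–Wilk-routed paired tests, tie-corrected Friedman omnibus with
  pairwise post-hocs, and per-item food-consumption summaries with
  direction-of-change ratios.
* **aggregate** — per-subject fusion of accuracy / negative-affect labels
  with min-max-normalised consumption, plus agglomerative clustering of food
  items with Newick tree and heat-map matrix export.

## CLI

Each stage is a subcommand of `cogload`:

```bash
cogload synth --out cohort/ --seed 1 --n-subjects 12 --duration-scale 0.1
cogload ingest --signals cohort/S01_HL/signals.csv --events cohort/S01_HL/events.csv --out out/
cogload preprocess --in cohort/S01_HL/signals.csv --out out/
cogload featurize --in cohort/ --out features.csv
cogload train --features features.csv --model svm --reproduction-mode --seed 1 --out results/
cogload stats --panas panas.csv --nasatlx nasatlx.csv --food cohort/food.csv --out stats.json
cogload aggregate --metrics results/per_subject_metrics.csv --stats stats.json \
    --food cohort/food.csv --out aggregate/
```

`--reproduction-mode` performs feature selection once on all data before the
outer cross-validation loop (the published order of operations); the default
re-selects features inside each outer fold, which is leakage-safe.

## Notes

* Intervals are half-open `[start, end)` seconds; the task-label clock is
  authoritative and the sensor clock is shifted to it via the last of the
  three synchronisation taps.
* The decomposition solves
  `min ½‖y − tonic − phasic‖² + α‖driver‖₁ + γ‖spline‖²` with a nonnegative
  driver, at 12.8 Hz, then restores the input rate; the residual is defined
  as the exact remainder so `tonic + phasic + residual == input` always.
* The feature catalogue (name → group, definition) is exported by
  `cogload.features.feature_catalogue()` and as `feature_catalogue.json`
  next to any feature CSV the CLI writes.
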