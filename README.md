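# mossense

Smartphone behavioral-proxy sensing on fully simulated sensor streams:

- **sensor_model** — canonical event types (activity windows, GPS fixes,
  WiFi scans, calls/SMS, calendar, phone use, app sessions, biweekly PHQ-9)
  with lossless CSV / JSON persistence and strict validation.
- **synthetic_data** — a seeded cohort simulator whose behavior statistics
  (time at home, walking, calls, texts, mobility, phone use) track a latent
  depression-severity trajectory, with epoch-wise dropout and a ground-truth
  sidecar for oracle testing.
- **features** — base behavioral-proxy features per calendar day: the
  standard deviation of the gravity-corrected acceleration norm per 2-minute
  window, intensity-threshold walking classification (threshold 1.5),
  WiFi-fingerprint home detection from 3 consecutive nights, haversine GPS
  distances, log location variance, communication / calendar / phone-use
  counts, with explicit missing-data masks.
- **aggregation** — the 120-dimensional descriptor of the 14 days preceding
  each PHQ-9 score: 24 base day-features x {mean, sum, variance, min, max}.
- **recommender** — two-phase context-sensitive intervention scoring:
  range-scaled weighted basket scores over the trailing 24 h, personalized
  ranges (mean ± 2 sd of the last week) after two weeks, star-rating /
  cancellation-rate intervention ranking with a 5% chance bonus, rule-based
  eligibility, and rating-dependent block timers (36 x (6 − rating) hours).
- **detection** — leave-one-subject-out classification of PHQ-9 ≥ 11 with a
  450-tree random forest or an RBF SVM tuned by Nelder–Mead, leakage-free
  per-fold imputation and standardization.
- **evaluation** — adherence bands, session counting, paired Wilcoxon
  signed-rank progression tests (exact for small n) and the Spearman
  usage–symptom-change correlation.
- **cli** — one entry point wiring the stages together.

## CLI

```bash
# simulate a cohort (per-subject CSV streams + truth.json)
mossense simulate --config cohort.yaml --seed 1 --out out/cohort

# per-day features for one subject
mossense extract-features --in out/cohort/S000 --out out/days.csv

# 120-feature dataset, one row per (subject, post-baseline PHQ-9)
mossense build-dataset --in out/cohort --out out/dataset.csv

# leave-one-subject-out detection
mossense detect --dataset out/dataset.csv --model rf --seed 1 \
    --report out/report.json

# trial-style statistics
mossense evaluate --cohort out/cohort --out out/eval.json

# ranked intervention recommendation for a context snapshot
mossense recommend --context ctx.json --seed 1

# everything at once
mossense run-all --config cohort.yaml --seed 1 --out out/
```

`cohort.yaml` may set any `RunConfig` key (see `mossense/cli.py`), e.g.:

```yaml
n_subjects: 10
weeks: 4
noise_level: 0.5
n_trees: 450
walking_threshold: 1.5
```

All stages are deterministic under `--seed`; artifacts are stamped with a
hash of the effective configuration.

## Conventions worth knowing

- Timestamps are UTC epoch milliseconds; "per day" uses a per-subject
  timezone offset (default UTC). Day slots: morning [05–12), afternoon
  [12–18), evening otherwise.
- The exact roster of the 24 base features (18 measured + 6 derived totals)
  is this package's documented convention; see
  `mossense.aggregation.BASE_FEATURES`.
- Home detection: nightly BSSID fingerprints ([00:00–05:00), majority
  presence), first 3 consecutive nights with pairwise Jaccard ≥ 0.5; a day
  scan counts as at-home on any fingerprint intersection. All thresholds are
  configurable.
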