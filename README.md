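# lonewatch

Passive-sensing pipeline for predicting **maternal social loneliness** from
smartwatch data: PPG → HRV signal processing, sleep and activity feature
derivation, labeled 8-day sample construction with validity filtering and
within-sample imputation, and leave-one-participant-out (LOPO) evaluation of
decision-tree and gradient-boosting classifiers. A synthetic-cohort generator
with planted class effects stands in for the (non-deposited) study cohort, so
every stage is testable offline.

## Pipeline

1. **synthetic** — full participant bundles (PPG waveforms or, in
   `fast_mode`, interbeat-interval windows; nightly sleep summaries;
   10-minute activity records; 12-item loneliness questionnaire responses at
   two time points) with ground truth and configurable effect sizes: lonely
   participants get lower activity intensity (×0.6), a flatter hourly step
   profile, and lower resting SDNN (×0.8).
2. **ppg** — 5-minute windowing, one-class SVM reliability gate over
   morphological features, zero-phase 0.7–3.5 Hz Butterworth bandpass,
   moving-average adaptive-threshold peak detection, and IBI cleaning
   (absolute band 300–2000 ms, relative band ±30% around the iteratively
   re-estimated window mean, ≥10 retained intervals).
3. **hrv** — HR plus the six HRV parameters (AVNN, SDNN, RMSSD, LF, HF,
   LF/HF; Lomb spectrum of the uneven interval series) and nightly resting
   selection (lowest-HR sleep-period window).
4. **sleep** — TST, fragmentation, WASO, hand movement, quality indicator
   (WASO ≤ 20 min) and sufficient-sleep indicator (TST in 7–8.5 h).
5. **activity** — daily awake-time aggregates (steps, walking/running steps,
   distance, duration, intensity, sedentary minutes, steps > 7000 indicator)
   plus ten distribution statistics over hourly step counts and hourly
   activity duration.
6. **datasets** — one sample per questionnaire response (response day + 7
   preceding days); valid day = ≥10 h awake wear and valid sleep; samples
   with <4 valid days discarded; within-sample mean imputation; mean
   collapse over days (concatenation optional); label 1 iff the social
   factor scores ≥12; the seven feature-group combination datasets.
7. **modeling** — Gini decision tree and gradient boosting under LOPO with
   per-fold recursive feature elimination on activity features, pooled
   out-of-fold metrics (per-class precision/recall/F1, weighted F1,
   sensitivity, specificity, AUC) and averaged impurity importances.

## CLI

```bash
lonewatch simulate --config cohort.yaml --seed 1 --out cohort/     # write CSVs
lonewatch extract  --in cohort/ --out daily.csv                    # daily features
lonewatch build    --in cohort/ --out datasets/                    # 7 datasets
lonewatch evaluate --in datasets/ --out reports/ --model both      # LOPO eval
lonewatch report   --in reports/report.json --out summary.csv
```

`cohort.yaml` holds `CohortConfig` fields (`n_participants`,
`loneliness_prevalence`, `effect_multipliers`, `missing_day_rate`,
`fast_mode`, ...). All streams are plain CSV; the generator also writes a
`ground_truth.json` sidecar.

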