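# szforecast

Short-horizon seizure forecasting for neonatal EEG: from multichannel
recordings (EDF) through quantitative-EEG (QEEG) features and a
convolutional-LSTM preictal classifier to a seizure-alarm system evaluated
on the SPH/SOP framework, with probabilistic calibration metrics. A
synthetic neonatal-EEG cohort generator with a tunable planted preictal
signature makes the whole pipeline runnable and testable without clinical
data.

## The problem

Neonatal seizures are frequent in intensive care and mostly subclinical;
predicting an oncoming seizure minutes ahead would buy time for rapid
intervention and targeted monitoring. The pipeline frames this as
preictal-state classification: EEG is segmented into 20 s epochs labeled
**preictal** (6–1 min before a seizure onset), **interictal** (well away
from any seizure) or **ictal**, and a sequence model scores rolling 5-min
windows of QEEG features with a preictal probability updated every 20 s.

Alarms follow the standard two-parameter scheme: when the probability
crosses a threshold, a warning opens after the **seizure prediction
horizon** (SPH — guaranteed lead time for intervention) and lasts for the
**seizure occurrence period** (SOP — the window in which the seizure is
expected). An alarm is a true positive iff a seizure onsets inside its
occurrence period. Reported metrics include event-level sensitivity,
corrected time-in-warning (TIW), false detections per hour (FDR),
threshold-swept AUROC/AUPRC over SPH x SOP grids, and calibration
(reliability, expected calibration error, Brier skill score against the
climatology reference). See `docs/methods.md` for the full model
description and conventions.

## Worked example

Generate a 12-subject synthetic cohort (half with seizures, one hour
each, planted preictal signature strength 2), run subject-stratified
nested cross-validation with the ConvLSTM, and score the held-out traces:

```python
from szforecast import (SynthConfig, generate_cohort, prepare_cohort,
                        TrainConfig, make_fold_plan, run_nested_cv,
                        AlarmConfig, threshold_sweep)
from szforecast.forecaster import pooled_held_out_scores
from sklearn.metrics import roc_auc_score

cfg = SynthConfig(n_subjects=12, preictal_strength=2.0, seed=1)
subjects = prepare_cohort(generate_cohort(cfg))
plan = make_fold_plan([s.subject_id for s in subjects],
                      {s.subject_id: s.has_seizures for s in subjects},
                      k=6, seed=1)
result = run_nested_cv(subjects, TrainConfig(seed=1), plan)

probs, labels, _ = pooled_held_out_scores(result, subjects)
print(f"held-out epoch AUROC: {roc_auc_score(labels, probs):.3f}")

traces = [result.traces[s.subject_id] for s in subjects]
events = {s.subject_id: s.raw_events for s in subjects}
sweep = threshold_sweep(traces, AlarmConfig(sph_s=180, sop_s=420), events,
                        n_grid=201, include_observed=False)
print(f"alarm AUROC (SPH 3 min, SOP 7 min): {sweep.auroc:.3f}")
```

On this seed the run prints:

```
held-out epoch AUROC: 0.871
alarm AUROC (SPH 3 min, SOP 7 min): 0.658
```

The first number is preictal-vs-interictal discrimination of individual
epochs, pooled over all held-out subjects — the planted spectral/variance
drift is recovered well above chance (the same pipeline on a
strength-zero cohort gives an AUROC whose bootstrap interval includes
0.5). The second is the stricter alarm-level area: event sensitivity
against corrected time-in-warning across thresholds, where warning
timing, suppression and the 3-minute lead requirement all cost
performance relative to epoch-level discrimination.

The same stages are scriptable from the shell:

```bash
szforecast simulate --config cohort.yaml --out cohort/
szforecast featurize --edf cohort/ --out features/
szforecast cv --edf cohort/ --folds 6 --out run/
szforecast evaluate --traces run/ --events cohort/annotations.csv --sph 180 --sop 420
szforecast sweep --traces run/ --events cohort/annotations.csv \
    --sph 60:420:60 --sop 60:420:60 --out grid.csv
szforecast calibrate --traces run/ --events cohort/annotations.csv --sph 180 --sop 420
```

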