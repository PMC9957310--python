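# ergofield

Field-ergonomics analysis of full-shift physical workload: links **directly
measured** physiological load — percent heart-rate reserve (%HRR) from 1-Hz
heart rate, and trapezius-EMG median-power-frequency (MDF) fatigue slopes —
to **subjective** effort ratings (Borg RPE 6–20, Omni RPE 0–10, Borg CR10
0–10) collected at four timepoints over a work shift. It is written for
occupational-physiology and ergonomics researchers who run wearable-sensor
field studies (the built-in study design is a three-method apple-harvest
cohort: Ground, Ladder and Platform workers) and need the whole chain —
signal cleaning, derived metrics, artifact screening and the statistical
battery — to be reproducible and testable.

## The metrics

Metabolic load per survey period, from median-filtered 1-Hz heart rate:

```
HRmax  = 220 − age
HRrest = HRsit − 10          (HRsit: pre-shift quiet-sitting mean)
%HRR   = (HRwork − HRrest) / (HRmax − HRrest)
```

Localized muscle fatigue per subject and trapezius side, from 20–450 Hz
bandpassed EMG summarized in 10-min windows (Welch PSD, 1-s Hann segments)
with PCA-based artifact rejection, then

```
MPF = b0 + b_time · time     (OLS over non-break, non-anomalous windows)
```

where a negative `b_time` (Hz/min of spectral compression) indicates
accumulating fatigue. Subjective ratings are analyzed as changes from the
pre-shift baseline and related to %HRR and `b_time` through Pearson/Spearman
correlations, confounder-adjusted and stratified regressions, two-way ANOVA
with Tukey HSD, and Kruskal–Wallis with Dunn pairwise rank tests.

Because real field data are scarce, the package includes a synthetic-cohort
generator with known ground truth (programmable heart-rate gain, EMG
spectral-compression rate, and rating–exertion rank correlation) so every
estimator can be validated by parameter recovery.

## Worked example

Simulate a compressed-shift cohort (2 workers per harvesting method, 70-min
shift with one 10-min break) and run the full analysis:

```
ergofield simulate --seed 42 --n-per-group 2 --schedule-preset smoke -o demo/ds
ergofield analyze  --seed 42 -d demo/ds -o demo/out
ergofield recover  -d demo/ds -r demo/out
```

or equivalently from Python:

```python
from ergofield import RunConfig, run_simulate, run_analysis, run_recovery_report

cfg = RunConfig(n_per_group=2, seed=42, schedule_preset="smoke")
run_simulate(cfg, "demo/ds")
res = run_analysis(cfg, "demo/ds", "demo/out")
print(res["pooled"])                      # pooled fatigue model
print(res["hrr"].groupby("period").hrr.mean())
report = run_recovery_report(cfg, "demo/ds", "demo/out")
print(report["passed"])
```

This prints (numbers from the run above):

```
pooled: {'b_time': -0.0482, 'stderr': 0.0014, 'p_value': 0.0000,
         'n_windows': 72, 'n_subjects': 6, 'r_squared': 0.9985}
mean %HRR by period: {'T1': 0.248, 'T2': 0.167, 'T3': 0.278}
recovery: {'hr_work_bpm': True, 'hrr': True,
           'b_time_hz_per_min': True, 'rank_correlation': True}
```

Reading it: the pooled fixed-effects model (MDF ~ work-time + side + subject)
recovers a fatigue slope of −0.048 Hz per work minute — the generator
programmed −0.05 with per-subject jitter — with the side and subject level
shifts removed. Mean %HRR is lowest right after the break (T2) and highest
at the end of the shift (T3), following the programmed exertion profile. The
recovery report confirms that heart-rate work means, %HRR, the fatigue
slopes and the rating–exertion rank correlation all match the ground truth
within their documented sampling bands. `demo/out/` contains the tidy result
tables (`hrr.csv`, `emg_features.csv`, `fatigue_slopes.csv`,
`associations.csv`, …) plus a manifest with per-stage record counts and
SHA-256 checksums; rerunning with the same seed reproduces every file byte
for byte. `ergofield report -r demo/out --plots` renders summary figures.

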