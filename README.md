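# gradoffset

Forecasting the next value of longitudinal clinical biomarkers by weighted
gradient offsets, and classifying mild-cognitive-impairment (MCI) patients as
**progressors** (MCIp, converting to Alzheimer's dementia) or **stables**
(MCIs) from the completed trajectories.

## The problem

Short longitudinal panels — a handful of neuropsychological scores and MRI
morphometric measures recorded at two or three visits, six months or a year
apart — carry predictive information about whether an MCI patient will
convert to dementia. A patient seen at baseline and one follow-up has an
incomplete trajectory; completing it with a plausible third value lets a
trajectory classifier operate as if the extra follow-up had been observed.

`gradoffset` implements a piecewise-linear forecasting scheme for exactly
this setting, together with the nested cross-validated pipeline that turns
completed trajectories into progressor/stable predictions, and a synthetic
cohort generator with the statistical structure the method assumes (real
cohorts of this type are access-restricted and are not bundled).

## The method

All markers are first scaled by their maximum value so heterogeneous units
(test scores vs. mm³ volumes) become comparable, and markers are ranked by a
two-sample Student's *t*-test on baseline readings (MCIp vs. MCIs); nested
marker subsets grow one rank at a time.

For visits at *t*, *t*+Δ*t*, *t*+2Δ*t*:

* **Base gradient** δ<sub>m</sub><sup>c</sup> — the class-*c* mean of the
  per-year change (x<sub>m</sub>(t+Δt) − x<sub>m</sub>(t))/Δt of marker *m*.
* **Gradient offset** OS<sub>mi</sub> = δ<sub>m</sub><sup>c</sup> −
  δ<sub>mi</sub> — how much subject *i* deviates from typical class
  progression over the first interval.
* **Linear-prediction weights** μ — stacking all training subjects' offsets
  into A (n × N) and each marker's second-interval offsets into B<sub>m</sub>
  gives A μ = B<sub>m</sub>, solved per marker by least squares
  (μ = (AᵀA)⁻¹AᵀB<sub>m</sub> when AᵀA is invertible; minimum-norm otherwise)
  and averaged over leave-one-out folds of the training set.
* **Forecast** — a linear SVM on the two known visits suggests the test
  subject's base group, fixing α<sub>m</sub> = δ<sub>m</sub><sup>c</sup>; the
  subject's own offset vector OS<sub>y</sub> is mapped through the weights to
  the multimarker correction β<sub>m</sub> = μ[:,m]·OS<sub>y</sub>, and

  y<sub>m</sub>(t+2Δt) = y<sub>m</sub>(t+Δt) + (α<sub>m</sub> + β<sub>m</sub>)·Δt.

* **Classification** — a linear SVM trained on fully observed training-fold
  trajectories scores the forecast-completed test trajectories; AUC,
  accuracy, sensitivity (MCIp recall) and specificity (MCIs recall) are
  reported per subset size, alongside the mean absolute forecast error (MAE,
  percent of the normalized scale). A **ground-truth (GT) mode** classifies
  observed third visits instead, giving the benchmark ceiling.

The whole procedure runs inside a stratified 5-fold outer loop (the inner
leave-one-out loop averages the weights), repeated for every marker subset.

## Worked example

```
$ gradoffset simulate --n-progressor 49 --n-stable 70 --n-markers 8 \
      --dt 0.5 --seed 7 --out cohort.csv
wrote 119 subjects x 8 markers to cohort.csv

$ gradoffset rank --data cohort.csv --out ranked.csv
top marker: marker001 (p=0.111)

$ gradoffset run --data cohort.csv --max-subset 8 --seed 7 \
      --out report.csv --summary best.json
wrote 80 per-fold metric rows to report.csv
best forecast model: 2 markers — AUC 0.730, accuracy 0.588, MAE 1.72%
```

The simulated cohort mirrors a 6-month-interval follow-up study (49
progressors, 70 stables; markers decline ~5 %/year vs. ~1.5 %/year).
`report.csv` holds one row per (mode, subset size, fold) plus fold-averaged
rows; `best.json` records the subset size with the highest fold-averaged
forecast AUC. Here the two top-ranked markers give AUC 0.73 — the classes
overlap substantially at this noise level — while the forecast error stays
below 2 % of the normalized marker scale; the GT rows in `report.csv` show
what the same classifier achieves with observed third visits (AUC 0.86),
the gap being the price of forecasting.

The same pipeline is available as a library:

```python
from gradoffset import generate_cohort, mci_cohort_spec, run_nested_cv, RunConfig

ds = generate_cohort(mci_cohort_spec(seed=7))
report = run_nested_cv(ds, RunConfig(max_subset=8, seed=7))
print(report.aggregate)
```

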