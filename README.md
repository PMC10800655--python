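# emophysio

Multimodal physiological feature extraction and box-overlap feature
selection for four-class emotion recognition.

## The problem

Affective-computing studies elicit emotions with standardized images and
sounds while recording autonomic and central nervous system signals — ECG,
blood volume pulse (BVP), galvanic skin response (GSR), respiration, pupil
diameter, and EEG — and then ask which signals separate emotional states.
This package implements that analysis end to end for a three-phase protocol
(images, sounds, combined) in which four 90 s sessions of increasing arousal
each split into a low-valence and a high-valence half, yielding the four
quadrants of Russell's circumplex: A1-LV (sadness), A1-HV (relaxation),
A4-LV (fear/anger), A4-HV (happiness). A 22-subject cohort produces
264 labeled 45 s observations (12 per subject), each described by
57 features: 12 EEG + 9 HRV + 2 BVP + 17 GSR + 8 respiration/coupling +
9 pupil.

Since no public recording set exists for this protocol, the package includes
a seeded synthetic generator that plants known parameters (inverse-Gaussian
mean inter-beat interval, pulse arrival time, SCR rates and rise times,
pupil high-frequency power, EEG attention ratios, RSA coupling) which the
extractors are tested to recover.

## The methods at its core

- **Point-process HRV.** Heartbeats are a stochastic point process with
  inverse-Gaussian inter-beat density; the IG mean is an order-p
  autoregression on previous intervals, fitted by exponentially weighted
  maximum likelihood, giving stable mu_RR, sigma^2 and VLF/LF/HF spectral
  indices from 45 s windows — far shorter than the 5 min classical HRV
  needs.
- **The Square Method (SM).** For every feature pair, each class is an
  axis-aligned box centered on the class means with 95%-CI half-widths. The
  12 ordered intersection-over-own-area ratios average into a pair score A;
  pairs with A above a threshold are dropped, features are weighted by
  surviving-pair membership, correlated features (|r| > 0.8) lose the
  lower-weight member, and features with above-mean weight are selected.
- **Subject-stratified benchmarking.** Seven model families (KNN, DT, LR,
  SVM, LDA, RF, AdaBoost) under 10-fold cross-validation whose folds
  partition subjects, with grid search, fold-local imputation and scaling,
  and a held-out 7-subject test set for the all-phases condition.

## Worked example

```python
from emophysio.synthetic import Rates, make_fixture_suite
from emophysio.features import assemble
from emophysio.square import select_features
from emophysio.classify import BenchmarkConfig, run_cv

# 4 simulated subjects x 3 phases at reduced rates, shortened rest
recs, truth = make_fixture_suite(4, seed=1, rates=Rates.fast(),
                                 rest_pre_phase=60.0)
table = assemble(recs)
print(f"{len(table)} observations x {table.shape[1]} columns")

sm = select_features(table, threshold=30.0, seed=1)
print("selected:", sm.selected[:5])

cfg = BenchmarkConfig(seed=1, models=("KNN", "LDA"), cv_folds=4,
                      grids={"KNN": {"clf__n_neighbors": [3, 5]}, "LDA": {}})
for name, res in run_cv(table, sm.selected, cfg).items():
    print(f"{name}: {res.mean_accuracy:.2f} +/- {res.sd_accuracy:.2f}")
```

prints

```
48 observations x 63 columns
selected: ['eeg_parietal_theta', 'gsr_mean_abs_diff2_z', 'gsr_peaks_rise_time', 'gsr_phasic_mean', 'gsr_scr_amp_mean']
KNN: 1.00 +/- 0.00
LDA: 1.00 +/- 0.00
```

The 48 rows are 4 subjects x 3 phases x 4 quadrants; the 63 columns are the
57-feature registry plus metadata. At a 30% overlap threshold the SM keeps
features whose class boxes barely intersect — here EEG band power and
several electrodermal features, including the SCR rise time that separates
the valence dimension by construction. On this small, cleanly planted cohort
the subject-held-out folds classify perfectly; chance would be 0.25. Planted
effect sizes are generator settings, so accuracies on synthetic data say
nothing about human recordings.

A thin CLI wraps the same pipeline:

```sh
emophysio simulate out/ --n-subjects 4 --seed 1 --fast
emophysio extract out/ --n-subjects 4 --seed 1 --fast --out-csv features.csv
emophysio select features.csv --threshold 30 --seed 1
emophysio benchmark features.csv --seed 1
```

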