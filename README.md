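# emgstress

Detecting driver stress from a single surface-EMG channel with simple
time-domain statistics and a kernel SVM.

Muscle tension is one of the body's fastest stress responses: trapezius EMG
amplitude variability rises when a driver moves from rest into city or
highway traffic. This package implements that detection pipeline end to
end — rest-baseline normalization, 17 statistical time features (STFs),
Kruskal–Wallis feature ranking, and multi-kernel SVM classification with a
window-length study — together with a seedable synthetic EMG cohort
generator, so every stage runs and is testable without any data download.
An optional reader for the Physionet "Stress Recognition in Automobile
Drivers" waveform records is included for users who have the `wfdb` package
and the accession.

## Method

Each subject's recording (15.5 Hz effective sampling) covers one ~15-min
**rest** period and two **city** + two **highway** driving periods. One
5-min window is cut from the start of each period; rest windows are the
no-stress condition (NSC), driving windows the stress condition (SC).
Because raw EMG amplitude depends on electrode placement and skin
impedance, every window of a subject is z-scored with that subject's rest
statistics,

    x̃ = (x − μ_rest) / σ_rest ,

with μ, σ the rest-window mean and population standard deviation. From each
normalized window, 17 STFs are computed: grouped mode, mean, range,
variance, standard deviation, impulse factor, square mean root (SMR), shape
factor w/ SMR, RMS, shape factor w/ RMS, crest factor, latitude factor,
skewness, kurtosis, 5th and 6th central moments (RMS-normalized), and
median. A Kruskal–Wallis test per feature ranks NSC-vs-SC discriminability
by p-value; the top features below α = 0.01 (variance and standard
deviation, with median and SMR excluded as overlap-vetoed) feed a
soft-margin SVM. Six kernels are compared — linear, quadratic, cubic
`(1 + u·v)^d`, and Gaussian `exp(−‖u−v‖²/s²)` at fine/medium/coarse
bandwidths `s = √P/4, √P, 4√P` for `P` predictors — under stratified
10-fold cross-validation (accuracy, sensitivity on SC, specificity on NSC,
AUC), across window lengths of 1–5 min, plus a 2-10-2 tanh MLP comparator
trained by Levenberg–Marquardt least squares.

## Worked example

The numbered scripts under `analysis/` run the study on a synthetic
10-subject cohort (seed 42) and write their tables under `results/`:

```sh
python analysis/01_simulate_cohort.py     # scratch/cohort/: 10 recordings
python analysis/02_extract_features.py    # results/features_{1..5}min.csv
python analysis/03_rank_features.py       # results/pvalues.csv, selection.json
python analysis/04_window_kernel_study.py # results/accuracy_matrix.csv
python analysis/05_compare_classifiers.py # results/comparison.csv
```

`03_rank_features.py` prints the Kruskal–Wallis ranking (top rows):

```
 feature       H  p_value
variance    23.7 1.12e-06
     std    23.7 1.12e-06
     rms    23.7 1.12e-06
   range    23.5 1.23e-06
     smr    23.5 1.23e-06
    mode    1.91    0.167
```

The spread statistics separate rest from driving completely — 1.12e-06 is
the smallest p a tie-corrected rank test can produce with 10 NSC vs 40 SC
windows — while shape ratios (crest/impulse/latitude factors, skewness,
kurtosis) carry no signal, as expected for a variance-scaling stress model.
RMS ties variance/std exactly: on zero-mean normalized windows it is a
monotone transform of the standard deviation. Selection keeps
`variance, std`.

`04` and `05` then report 10-fold CV performance on those two features:

```
                 1min  2min  3min  4min  5min
linear          100.0 100.0 100.0 100.0 100.0
cubic           100.0 100.0 100.0 100.0 100.0
...
 classifier  accuracy   auc
SVM (cubic)   100.000 1.000
        MLP   100.000 1.000
```

All kernels reach ceiling accuracy here because the default synthetic
stress effect (variance multipliers 2 and 3 vs rest) is large relative to
the estimator noise of even a 1-min window — see `docs/methods.md` for what
this does and does not demonstrate about real EMG.

The same pipeline is scriptable stage by stage via the `emgstress` CLI
(`generate`, `extract`, `select`, `train`, `report`); `emgstress --help`
lists the options.

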