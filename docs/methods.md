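# Methods

## Signal model and the synthetic cohort generator

The generator (`emgstress.synthetic`) emulates the statistical structure the
analysis relies on, not motor-unit physiology. One subject's recording is

    x(t) = offset + env(t) · n(t),      n(t) ~ N(0, scale² · m(scenario)),

where `scale` and `offset` are per-subject amplitude idiosyncrasies
(electrode placement, skin impedance), `m` is the scenario variance
multiplier (rest 1, city 2, highway 3 by default), and `env(t)` is a
multiplicative burst envelope: Poisson-timed raised-cosine bumps of 0.5–2 s
whose peak multiplies the local amplitude by the burst gain (default 2,
default rate 0.5/min). Samples are drawn per scenario interval at 15.5 Hz.

Parameter defaults and why:

| parameter | default | rationale |
|---|---|---|
| subjects | 10 | cohort size of the driving study being emulated |
| protocol | rest 15, city 13, highway 8, city 13, highway 8 min | one baseline + two city + two highway periods, inside the protocol's stated duration ranges |
| sampling rate | 15.5 Hz | effective EMG rate of the drivedb records |
| subject scale | log-normal, median 50 a.u., σ_log 0.5 | multiplicative inter-subject spread; guarantees raw (un-normalized) features are incomparable across subjects, which is what motivates the baseline normalization |
| subject offset | N(0, 5 a.u.) | small DC electrode offset |
| variance multipliers | city 2, highway 3 | free parameters; monotone with the low/medium/high stress levels the protocol targets |
| burst rate / gain | 0.5 min⁻¹ / 2 | gives non-Gaussian tails so higher-moment features are non-degenerate; unit tests asserting exact moments set the rate to 0 |

All randomness flows through `numpy.random.SeedSequence`: identical seeds
give bitwise-identical cohorts.

What the generator does **not** emulate: EMG autocorrelation/band structure
(samples are white), scenario-dependent mean shifts, motion artifacts,
electrode drift, or inter-period non-stationarity. Two consequences matter
for interpreting results. First, since windows are zero-mean after
normalization, RMS is a monotone transform of the standard deviation and
receives an identical Kruskal–Wallis rank profile — on real data the two
separate (stress also shifts mean amplitude). Second, the default stress
effect (variance ×2–3) is far larger than the variance-estimator noise of
even a 930-sample window, so all kernels sit at ceiling accuracy and the
window-length curve is flat at 100%; passing these checks demonstrates the
pipeline's correctness and its qualitative behaviour (accuracy never
degrades with longer windows; chance-level AUC under permuted labels), not
a realistic error rate for road data.

## Segmentation and normalization

Five scenario intervals per recording (exactly 1 rest + 2 city + 2 highway)
are required; one window is cut from the **start** of each interval (the
within-interval placement is a convention; starts are deterministic and
reproducible). Window sample counts are round-half-up of `minutes·60·fs`
(4650 samples at 5 min, 930 at 1 min). Rest ⇔ NSC, city/highway ⇔ SC, so
the label balance is always 1:4. Time coordinates are 0-based seconds with
half-open `[start, end)` intervals.

Normalization is `x̃ = (x − μ)/σ` with μ, σ taken from the subject's
**rest** window (population 1/N convention for σ). Per-window
self-normalization is also implemented (`normalization: self`) but it
forces unit variance on every window and thereby erases the variance/std
contrast the classifier uses; rest-baseline is the default because it
preserves exactly that contrast while removing per-subject gain and offset
(features are invariant to `x → a·x + b`, `a > 0`). In the window-length
study the baseline is recomputed from the rest window truncated to the same
length, so the rest window has exactly unit variance at every length.

## The 17 statistical time features

Conventions, chosen once and applied everywhere (the oracle tests pin them):

- every averaged quantity uses the population 1/N convention;
- **range** is `max − min` (non-negative);
- the **peak** entering the crest, impulse and latitude factors is `max |x|`
  (normalized windows have negative samples);
- **SMR** averages `√|x|` before squaring, the standard square-mean-root of
  the vibration-features literature, again because of signed samples;
- **median** of an even-length window is the mean of the two central order
  statistics;
- the order-3..6 central moments (**skewness**, **kurtosis**, 5th, 6th) are
  normalized by powers of the **RMS**, not the standard deviation. This
  non-standard scaling is kept deliberately; the conventional values are
  recoverable via `skew_conv = skew · (rms/std)³` etc., an identity the
  tests verify. On zero-mean data rms ≈ std and the two conventions agree;
- the **grouped mode** histograms the window into `⌈1 + log₂N⌉` (Sturges)
  equal-width classes over `[min, max]` (configurable), takes the leftmost
  maximal class, and interpolates `L + c·d⁻/(d⁻+d⁺)` with `d⁻`, `d⁺` the
  absolute count differences to the left/right neighbours (a missing
  neighbour counts 0; if `d⁻+d⁺ = 0` the class midpoint is returned; a
  constant window returns the constant).

An all-zero window has RMS = SMR = 0, leaving the ratio features undefined;
this is raised as `FeatureError` rather than silently propagating NaNs.

## Feature ranking and selection

Each feature column is tested with the tie-corrected Kruskal–Wallis H
(via `scipy.stats.kruskal`; the all-identical degenerate case is defined as
H = 0, p = 1), with p from the χ² upper tail on `groups − 1` degrees of
freedom — adequate at these group sizes, and a rank test is used instead of
ANOVA because physiological features are generally non-Gaussian. Grouping
is binary NSC-vs-SC by default; the three-scenario grouping is available.

One numerical choice deserves emphasis: observations are treated as tied
when equal to 12 significant digits (`tie_sig_digits`, disableable). Rest
windows have variance exactly 1 by construction, but last-bit floating-point
noise would otherwise make those ten values "distinct" and let the tie
correction reorder columns that are all completely separated. Rank tests on
measured data should not be sensitive to 1-ulp differences.

Selection keeps the `top_k = 2` smallest-p features with `p < α = 0.01`.
Exact p ties are broken by feature-table column order, which is documented
and fixed (variance and std precede rms). An explicit exclusion list
(default `median, smr`) reproduces the overlap-based veto of the original
study; that veto is a judgement call with no quantitative rule, so it is
configuration, not inference. No multiple-testing correction is applied
across the 17 tests, matching the procedure being implemented.

## Classifiers

**SVM.** Soft-margin SVC with Gram matrices from `make_kernel`: linear
`u·v`, inhomogeneous polynomials `(1 + u·v)^d` for d = 2, 3 (the study
never writes its polynomial kernel; the inhomogeneous form is the common
default), and Gaussian `exp(−‖u−v‖²/s²)`. The fine/medium/coarse bandwidth
presets are `s = √P/4, √P, 4√P` for P predictors — the kernel-scale
convention of the classification-learner GUIs these kernel families come
from; a literal `P/4, P, 4P` convention is available
(`kernel_grid(..., convention="literal")`). Features are standardized to
the training fold's statistics before kernel evaluation (variance and std
live on different scales); box constraint C = 1. The dual is solved by
scikit-learn's SMO at tolerance 1e-6 — the contract is a KKT-satisfying
solution (free support vectors sit on the ±1 margin to 1e-4; tested), not
a particular solver trajectory. Two classes occupying identical point sets
raise `DegenerateDataError`.

**MLP comparator.** P–10–2 network, tanh (bipolar-sigmoid) hidden units,
linear outputs fit to ±1 one-hot targets by damped Gauss–Newton
(Levenberg–Marquardt): exact Jacobian (52 parameters at P = 2), damping
λ₀ = 1e-3 with ×10 / ÷10 on rejected/accepted steps, at most 200 epochs,
seeded Gaussian init (σ = 0.5). Prediction is the output argmax; the
decision value for AUC is `out_SC − out_NSC`. Training is deterministic
given the seed.

**Cross-validation.** Stratified 10-fold with seeded shuffling; every
sample is validated exactly once and fold class proportions are within one
sample of global. Reported accuracy is the mean of per-fold accuracies
(with equal fold sizes this equals pooled accuracy); sensitivity (on SC,
the positive class) and specificity (on NSC) come from the pooled confusion
counts; AUC is the rank/trapezoidal area under the ROC of the pooled
decision values.

## Study orchestration and problem sizes

`run_study` generates (or loads) the cohort, builds one feature table per
window length (1–5 min), selects features once on the longest window, runs
the 6-kernel × 5-length CV grid, and compares the best kernel against the
MLP, persisting every intermediate artifact (cohort CSVs, per-length
feature tables, selection JSON, p-value/accuracy/comparison tables) when an
output directory is given. Everything is deterministic given the config
seed.

Default problem sizes: 10 subjects × 57 min at 15.5 Hz (~53 k samples per
recording), 50 windows, 850 feature values; the repeated-cohort checks in
the test suite and the acceptance script use 20–50 regenerated cohorts.
These sizes keep any single check within seconds while leaving the moment
and type-I-error simulations enough samples for their stated tolerances
(variance recovery within 5% needs ≥10⁴ samples; the χ² approximation's
type-I error at α = 0.05 is verified to ±0.02 over 1000 replicates).

## Known limitations

- The synthetic cohort is far cleaner than road EMG; ceiling accuracies on
  it say nothing about real-world error rates (see above).
- The grouped mode depends on an arbitrary binning; Sturges is a
  convention, and mode values are therefore only comparable within one
  binning policy.
- The Kruskal–Wallis χ² p-value is approximate for small groups; with 10
  vs 40 samples the attainable p floor is ~1e-6, so completely separated
  features tie there and their ordering is decided by the documented
  tie-break, not by evidence.
- Binary classification only (stress vs no-stress); the three-level
  scenario distinction appears only in the feature-ranking grouping.
- The drivedb reader is a thin optional hook (`io.read_wfdb_recording`)
  and requires the third-party `wfdb` package; results on the real
  accession are not part of the test surface.
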