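# Methods

## The temporal generalization method

Multivariate decoding of epoched MEG/EEG asks, at each time sample t,
whether the spatial pattern of sensor amplitudes discriminates two trial
classes. Temporal generalization extends this by asking whether the decoder
trained at t also discriminates the classes at every other sample t'. The
result is a train-time x test-time matrix of decoding performance whose
shape diagnoses the underlying dynamics:

- a **diagonal** matrix (decoders only work near their training time)
  indicates a serial chain of short-lived neural codes;
- a **square** matrix (every decoder works at every informative time)
  indicates a single sustained code;
- **below-chance** cells (AUC < 0.5) indicate that the discriminative
  pattern has reversed sign between t and t'.

Because sensor time series are auto-correlated, generalization must be
assessed on held-out trials: `tgdecode` fixes a stratified k-fold split
before any training, and a trial contributes to the AUC of cell (t, t')
only from the fold in which it was held out. Probabilities are pooled
across folds and a single AUC is computed per cell (rather than averaging
per-fold AUCs): each trial is then predicted exactly once per cell and the
estimate has lower variance at small fold sizes.

## Decoder

At one time sample the decoder is a linear support vector machine on the
z-scored channel amplitudes:

- **Normalization.** Per-channel mean and SD are estimated on the training
  fold only and applied to both folds. A channel whose training SD is zero
  (up to rounding) is mapped to zeros (SD replaced by 1), so degenerate
  simulated inputs cannot raise division errors.
- **Classifier.** Hinge-loss maximum margin with the regularization
  constant fixed at C = 1 (no hyperparameter search, no dimensionality
  reduction or feature selection). Per-trial sample weights equalize the
  total contribution of the four design subclasses (LSGS, LDGS, LSGD,
  LDGD): a trial in subclass s has weight proportional to 1/count(s). The
  weights enter only the fit, not the evaluation.
- **Calibration.** Platt's sigmoid P(deviant | f) = 1/(1 + exp(A f + B)) is
  fit on the training-fold decision values by penalized maximum likelihood
  (smoothed targets (N+ + 1)/(N+ + 2) and 1/(N- + 2); damped Newton with
  backtracking). The fit is direct, on the same training fold, with no
  inner calibration split — the procedure is deterministic, and since AUC
  is rank-based, residual calibration bias does not affect the performance
  metric, only the interpretability of the probabilities.
- **Scoring.** AUC with ties counted 1/2 (midrank convention), so
  AUC · n1 · n2 equals the Mann-Whitney U of the same scores exactly.
  Deviant is +1 throughout, which makes below-chance AUC a meaningful,
  signed statement rather than an artifact of class ordering.

## Statistics

- **Within subject** (trials as the random variable): Mann-Whitney U on the
  calibrated probabilities, two-sided. A vectorized per-cell p-map
  (`within_subject_pmap`) uses the tie-corrected normal approximation,
  adequate at the per-subject trial counts involved.
- **Across subjects**: Wilcoxon signed-rank on per-subject AUCs against
  chance 0.5 (or on paired differences against 0). For n ≤ 25 the sign-flip
  null is enumerated exactly; when absolute differences tie (common when
  simulated AUCs saturate at exactly 1.0) the enumeration conditions on the
  observed midranks — a dynamic program over doubled ranks — so the exact
  p-floor 2/2^n survives ties. Zero differences are dropped; an all-zero
  vector returns p = 1 with a warning. Two-sided is the default because
  below-chance effects are hypotheses here, not noise.
- **Multiple comparisons**: Benjamini-Hochberg step-up over all t x t'
  cells of a map as a single family, returning the data-dependent rejection
  threshold. The exact small-n Wilcoxon floor matters: with 10 subjects and
  6400 cells, a true effect present in every subject attains p = 2/1024 and
  the step-up can recover hundreds of such cells; an approximate p of
  ~0.006 for the same configuration cannot clear the line.
- **Anti-generalization**: to ask whether a below-chance cell reflects a
  full polarity reversal of one pattern, AUC(t, t) is compared with
  1 − AUC(t, t') per subject (paired Wilcoxon). Exact mirror values give a
  zero difference (full reversal, p = 1 by construction); a significant
  positive difference indicates the reversal is partial.

## Generalization duration

For each training time the duration is the number of FDR-significant test
samples times 1000/sample_rate ms. By default the counting window is the
data-driven set of samples whose *diagonal* cell is significant — the
analogue of restricting to the span where diagonal decoding performs above
chance — and the summary mean is over training times in that set; a fixed
(t_start, t_end) window can be supplied instead. The duration can be
computed from the group-level mask or from per-subject within-subject
masks; see the caveat below.

## Synthetic data

The simulator generates the two regimes the method is designed to
dissociate. Each generator g projects onto the n_channels sensors with
coefficients C_g drawn fresh per subject from N(0, 1), and is active with
unit amplitude over a contiguous sample window A_g (optionally carrying a
per-sample class-coupling sign s_g). A trial of class y ∈ {−1, +1} is

    S(c, t) = y · Σ_g A_g(t) · s_g(t) · C_g(c) + ε,
    ε ~ N(0, σ²) i.i.d. over trials, channels and samples.

The noise scale is set by σ = RMS / snr where RMS is the root-mean-square
of the noiseless signal over informative entries (active samples, all
channels) — a scale-invariant definition chosen because "signal-to-noise
ratio" otherwise underdetermines σ. Defaults are 50 trials (balanced), 20
channels, 80 samples, SNR 0.5, and groups of 10 subjects; the sequential
scenario uses ten abutting 6-sample generators, the sustained scenario one
60-sample generator, and the reversal scenario one generator whose class
coupling flips sign mid-window (its two segments share one projection, so
decoders trained before the flip generalize below chance after it). A
zero-duration scenario yields pure N(0, 1) noise for null calibration.
Simulated epochs carry a nominal 256 Hz sampling rate (the rate of the
down-sampled recordings the method targets).

What the simulator does **not** emulate: realistic forward models (sensor
covariance is diagonal; real MEG noise is spatially correlated), induced
(non-phase-locked) activity — a linear amplitude decoder cannot capture it
either — trial-to-trial latency jitter, and amplitude dynamics within a
generator's window. Passing the simulation-based tests therefore shows the
pipeline recovers the dynamics it models, not that real recordings will be
as clean.

One simulator-specific caveat: two independent N(0,1) projections in 20
channels have |correlation| ~ 1/√20 ≈ 0.22, so a decoder for one generator
partially discriminates during another generator's window, with a sign that
is random per generator pair. Within a subject this cross-generalization is
genuinely significant and inflates per-subject duration estimates; across
subjects the random signs cancel, so group-level maps (and the group
durations reported by the acceptance script) recover the generator
lifetime. With 306 real sensors the overlap would be ~1/√306 and the effect
correspondingly smaller.

## Session label sequences

The local-global design crosses a within-trial (local) and an across-trial
(global) oddball. `localglobal_sequence` builds blocks of a habituation
run-in (global standards, excluded) followed by main trials with
round(p · n) global deviants placed so every run of consecutive global
standards — before the first, between, and after the last deviant — has
length within [min_gap, max_gap]; the trial after each global deviant is
excluded from analysis. Block types alternate the mapping between
local and global classes, which makes the local and the global contrast
select the same analyzed trials (only the class assignment differs) and
keeps both free of block-composition artifacts.
`reference_session_labels()` instantiates 12 blocks x 80 main trials with
15 deviants each, yielding exactly 390/390 analyzed local-standard/deviant
trials and 600/180 global ones.

## Numerical and design choices

- All randomness flows through `numpy.random.SeedSequence`; a subject's
  stream derives from (config seed, subject index), so groups are
  reproducible element-wise and subjects are independent.
- The SVM dual solver and the Platt Newton iteration are deterministic, so
  identical inputs give bit-identical models; the diagonal-decoding path
  issues the same training and prediction calls as the matrix diagonal and
  the two agree bit-for-bit under shared folds (asserted in tests).
- Fold assignment uses stratification on the four subclasses, not the
  binary class, so rare subclasses are represented in every fold; a
  subclass smaller than k raises an error naming it.
- Baseline correction subtracts a per-trial per-channel constant (mean over
  a half-open [t_start, t_end) window); it is idempotent and linear.
- Containers round-trip bit-exactly (little-endian float64 array + JSON
  sidecar) and are readable from any npy/JSON-capable environment.

## Problem sizes used in the shipped analyses

The test suite and `scripts/acceptance.py` run the reference conditions in
full (80 x 80 matrices, 10 subjects, 10 folds). Null calibration uses a
20 x 20 grid — pure noise has no temporal structure for the extra samples
to reveal — with 100 repetitions in the test suite and 20 in the
acceptance script. The generator-lifetime recovery analysis uses lifetimes
of 4, 8 and 16 samples with enough generators to span 60 active samples.

## Known limitations

- Platt probabilities fit without an inner split are slightly optimistic
  on their own training fold; this biases probabilities, not the rank-based
  AUC or the U statistics.
- The within-subject per-cell p-map uses the asymptotic Mann-Whitney
  approximation; for very small trial counts (< ~15 per class) an exact
  variant would be preferable.
- `generalization_duration` counts significant samples, so a
  non-contiguous significance mask contributes all its samples, not the
  longest run.
- The CLI's `decode` stores per-subject matrices as CSV only; the trial ×
  cell probability cubes are available programmatically
  (`run_tgm(..., store_probabilities=True)`) but are not serialized.
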