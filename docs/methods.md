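# Methods

This note documents the models, numerical choices and open design decisions
behind `emgsnail`, in the spirit of the methods documentation of simulation
and statistics packages.

## Problem setting

Seven-class hand-gesture decoding (fist, pinch, wrist flexion/extension,
palm opening, thumb, rest) from five bipolar surface-EMG channels — two over
forearm flexors, two over extensors, one on the thenar eminence — sampled at
1000 Hz. The target population is hemiplegic (post-stroke) patients, whose
paretic signals have reduced amplitude, distorted spectra, crosstalk and
high inter-subject variability; the operational question is which of the
many hand-crafted EMG features, alone or concatenated, generalize across
subjects.

## Synthetic-EMG generator

Clinical hemiplegic recordings cannot be redistributed, so all tests and
demonstrations run on a generative stand-in. The model is the standard
surface-EMG surrogate: zero-mean Gaussian noise band-limited to 20–300 Hz
(matching the preprocessing band), multiplied by a smooth burst envelope
(Tukey ramp × a slow 1.5–4 Hz random modulation). Design choices:

* **Gesture structure.** Each class has a fixed per-channel amplitude
  profile (e.g. wrist flexion loads the flexor channels, thumb loads the
  thenar channel). One recording per subject contains `reps_per_gesture`
  bursts per gesture (default 10) in random order, 200–400 ms long,
  separated by 250–600 ms of rest-level activity. Rest is the same noise
  process at 5 % of the gesture scale — the seventh class is sampled from
  these gaps.
* **Subject effects.** A per-subject log-normal gain (SD 0.2 by default)
  models electrode placement and tissue differences; a symmetric mixing
  matrix with `1 − crosstalk` on the diagonal models inter-channel
  crosstalk (default 0.05).
* **Severity** ∈ [0, 1] linearly shrinks each gesture profile toward the
  rest profile: severity 1 is fully expressed gesture activity, severity 0
  removes all class information (useful as a chance-level control). This is
  a one-knob abstraction of paresis grade.
* **Artifacts.** Optional spike artifacts (12 × local RMS, Poisson arrivals
  at `artifact_rate` per second) exercise the Hampel filter.
* **Determinism.** All randomness flows from one `numpy` `Generator` seeded
  by `SynthConfig.seed`; identical configs give bit-identical datasets.
  Class profiles use a separate hard-coded design RNG so they are part of
  the model, not of the run.

What the generator does **not** emulate: motor-unit action potentials and
firing statistics, spasticity-induced co-contraction patterns, electrode
lift-off, power-line interference, or any real patient's waveform. Passing
tests on this surrogate therefore demonstrates correctness and sane
statistical behaviour of the algorithms, not clinical performance; CCR
values on synthetic data are not comparable to values on patient data.

`planted_feature_matrix` bypasses signal generation entirely and emits a
feature matrix with a known set of informative columns (class-specific
means, per-subject offsets, unit noise) among pure-noise columns. It is the
ground truth for search-recovery tests: a correct search must find the
planted columns.

## Preprocessing

Fixed order: band-pass → Hampel → RMS normalization → window detection.

* Band-pass: Butterworth order 4 (as a band-pass prototype), 20–300 Hz,
  applied forward–backward (`sosfiltfilt`) so that the phase response is
  zero and burst peak timing is preserved for the short analysis windows.
  The acquisition hardware's 5–500 Hz cutoff is treated as a property of
  the recording, not re-applied.
* Hampel: centred window of 100 samples (rounded up to odd), scale
  estimated as 1.4826 × MAD, replacement threshold 2 estimated SDs. The
  first and last half-windows are passed through untouched — with padded
  windows the MAD degenerates there and legitimate samples would be
  clipped. On clean signals the filter is the identity; on spiked signals
  it modifies at most the spiked samples.
* RMS normalization scales each channel to unit RMS (target configurable);
  an all-zero channel is a hard error naming the channel.
* Window detection: per-sample moving-RMS envelope (100 ms) summed over
  channels; peaks above `median + max(3 × 1.4826 × MAD, 0.2 × median)`
  (the relative floor keeps a burst-free envelope from producing spurious
  detections) with a 200 ms minimum separation become anchors. Each window
  is 30–60 ms long with 1/3 of its span before the peak and 2/3 after;
  overlaps are resolved in favour of the higher peak. On synthetic ground
  truth at severity 1 the detector's burst recall and precision both exceed
  0.95.

## Feature bank

127 registered features: 80 time-domain, 19 frequency-domain, 12
time–frequency, 10 fractal/complexity, 6 spatial. Channel features are
extracted per channel and concatenated in registry × channel order; spatial
features (flexor/extensor/thenar power and MAV ratios, ε-guarded
denominators) are computed once per segment. A JSON manifest mirrors the
registry and is the contract tested against (127 entries, exactly 80 TD).

Numerical conventions:

* Thresholded counts (ZC, SSC, WAMP, MYOP, TURNS) default to thresholds
  proportional to the segment RMS (1 % for the step thresholds, 100 % for
  the myopulse rate), so they are invariant to amplitude scaling and
  survive RMS normalization.
* AR coefficients (orders 2–6) use Burg's method — stable on the short
  30–60 ms windows — via `statsmodels`; cepstral coefficients (CC-R) follow
  the standard recursion from the order-4 AR fit.
* Wavelet features use db4 with 3 levels (log band energies); segments
  shorter than 64 samples are padded symmetrically; the stationary
  transform additionally pads to a multiple of 8.
* The empirical-wavelet features (EWT-k energy, EWP-k relative power) index
  bands of one fixed 10-band log-spaced partition of (0, Nyquist] (first
  inner edge at Nyquist/50), so EWT-4/6/8/10 are four views of the same
  decomposition and the ten relative powers sum to 1.
* The Hilbert–Huang feature is the amplitude-weighted mean frequency of the
  Hilbert marginal spectrum over empirical modes obtained by cubic-spline
  sifting (up to 3 modes, SD stopping criterion 0.2); segments with too few
  extrema fall back to the raw analytic signal.
* Fractal features: Higuchi dimension with kmax = 8 (FR4 is the same slope
  restricted to lags 1–4), DFA over log-spaced scales 4..n/4 with linear
  box detrending, approximate entropy with m = 2, r = 0.2 SD.
* Logarithmic variants compute sign(v)·ln(1 + |v|) of the base feature
  (LMAV, LSSI, LVAR, LWL, LRMS, LIEMG, LCARD, MLASP), preserving sign and
  monotonicity.
* Several acronyms from the myoelectric literature have no single canonical
  formula (FR4, PERC2, FDD, ROG, ASM, RSD1/RSD2, NSV, ER, CRD, MMAV5); this
  package fixes explicit definitions — FR4 as the short-lag Higuchi slope,
  PERC2 as the 2nd-percentile frequency of the cumulative spectrum, FDD as
  spectral flatness, ROG as the gradient-to-signal RMS ratio, ASM as the
  mean absolute second difference, RSD1/RSD2 as root-squared first/second
  difference moments, NSV as the accumulated negative slope, ER as the
  first-half energy ratio, CARD/CRD as quantized-amplitude cardinalities
  (quantum 1 % of RMS), MMAV5 as a quintile-weighted MAV — and keeps them
  behind the manifest so alternative definitions are swappable.
* Extraction refuses to emit non-finite values: every failure names the
  segment and feature.

## Evaluator

The ranking score everywhere is the mean CCR over repeated random
subject-wise holdout: `test_fraction` (default 0.1) of the participants —
max(1, round(n × fraction)), i.e. 2 of 19 — are held out entirely per
iteration, ×`n_iterations` (default 100). Holding out whole subjects is the
leak-free protocol for subject-independent claims. Columns are standardized
with training-fold statistics only; the classifier is a soft-margin SVM
(linear kernel, C = 1, one-vs-one) — linear because the search issues up to
~10⁷ fits and the kernel is configurable. Iterations whose training fold
misses a class are redrawn (bounded at 50). Split seeds derive from
(protocol seed, iteration, redraw) only — never from the candidate — so all
candidates are scored on identical partitions and rankings are paired.
Constant columns pass through centred rather than erroring. A `split_hook`
exposes per-iteration fold membership and scaler statistics for leakage
instrumentation in tests.

## Brute-force search

Streaming enumeration of all C(n, r) sorted-name tuples, r = 1..4; ranking
key is (mean CCR desc, SD asc, lexicographic name tuple) — a total order,
required for reproducible quintiles. Scored candidates can be checkpointed
to JSONL per level; a resumed run rescores nothing and reproduces the pools
byte for byte. Desk-scale defaults cap the feature count at 25 in the CLI
(`--allow-large` lifts the cap); the full 127-feature tetra level is ~10⁷
SVM fits and is a cluster-scale undertaking. The top-quintile cutoff is
exactly ⌈0.2K⌉; the domain-distribution report classifies candidates by
the set of domains they span; the lineage trace connects top-k sets of
consecutive sizes by strict set inclusion.

## SNAiL spiral search

Design decisions where the concept left room:

* **Seeding.** The spiral pool starts as the union of the top quintiles of
  the sourced brute-force pools (`source_depth` ∈ 1..4); seed scores are
  inherited through the shared cache, never recomputed.
* **Growth.** One feature per stage: stage targeting size s takes the top
  max(2, round(|pool|/φ)) sets of size s−1 as parents, and proposes every
  parent ∪ {f} for f in the extension alphabet (features of the seed pool
  plus features of the parents), deduplicated, capped at ⌈φ·|pool|⌉ in
  parent-rank order. Seeds smaller than s−1 contribute to the alphabet but
  do not parent — this keeps every stage pool at one uniform size.
* **Truncation.** After evaluation the pool keeps the top
  ⌈candidates/φ⌉ — the golden-ratio contraction that gives the search its
  spiral shape. With φ → ∞ the pool contracts to a single set and the
  procedure degenerates to greedy forward selection from the top parent
  (asserted against a hand-rolled greedy oracle).
* **Stopping.** "Deferred overfitting" is operationalized as: stop when the
  best mean CCR has not improved for `patience` (default 2) consecutive
  stages, armed only once `min_size` (5) is reached, hard stop at
  `max_size` (20). The kept-best winner is monotone non-decreasing across
  stages by construction.
* An exhausted extension alphabet raises a distinct `SearchExhausted`
  signal rather than silently stopping.

## Statistical comparison

Eight canonical baselines (MFS1–8) are pinned as name lists and resolved
through the registry (punctuation-tolerant, so AR-4 ≡ AR4). All sets —
spiral winner first — are evaluated under one shared protocol/seed, and
each row is tested against the winner with a one-tailed unpaired
pooled-variance t-test (H₁: winner's mean CCR is higher), DF = n₁ + n₂ − 2.
Pooled rather than Welch variance matches the equal-n design (two
100-iteration runs ⇒ DF = 198). Shared splits make the iterations paired in
fact, but the test remains the unpaired one by design; it is therefore
conservative. Zero pooled variance degenerates to t = 0, p = 0.5 at equal
means, and to the 0/1 p-limit otherwise. Stars are assigned at
p < 0.05/0.01/0.001/0.0001. No multiple-testing correction is applied.

## Problem sizes for tests and the acceptance run

The test suite and `scripts/acceptance.py` use scaled-down study
conditions chosen once: 6–12 synthetic subjects, 2–4 repetitions per
gesture, the 25-feature capped bank, 10–20 evaluation iterations, search
depth 2 (mono + binary sourcing), and 10 seeds for stochastic recovery
claims. These sizes keep a full run in the minutes range on one CPU while
leaving the statistical contracts (chance level ≈ 100/7 %, recovery of ≥ 4
of 5 planted features, monotone winners, exact ⌈0.2K⌉ and ⌈k/φ⌉ counts)
testable. The combination counts (8 001 / 333 375 / 10 334 625) are exact
properties of the 127-entry manifest and are verified by full enumeration.

## Known limitations

* The synthetic generator's envelope model makes amplitude features
  unrealistically informative relative to clinical data; spectral and
  fractal features differ between classes only through amplitude/bandwidth
  interactions.
* Burg AR fits on 30–60 sample windows are high-variance; the registry
  keeps them because short-window behaviour is part of the method under
  study.
* The empirical-wavelet partition is fixed rather than spectrum-adaptive;
  adaptive boundary detection on 30–60 ms windows was judged too unstable.
* The evaluator fits ~|candidates| × iterations SVMs; the full tetra-level
  brute force at 127 features is supported by the API (checkpointed,
  resumable, trivially parallel over candidates) but is not a desk-scale
  computation.
* EDF input requires the optional `mne` dependency; the delimited CSV
  format is the primary interchange.
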