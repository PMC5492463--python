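# Methods

## Signal model of the synthetic generator

Each epoch of each channel is

    x_c(t) = n_c(t) + e_c(t) · s_c(t)

* `n_c` — white Gaussian baseline noise with rms `baseline_rms`
  (default 1.25e-3 mV = 1.25 μV, the noise floor of wireless sEMG front
  ends). The package's signal unit is the **millivolt**: posture-transition
  bursts in lower-limb sEMG reach a few mV, and the conventional Willison
  amplitude threshold (0.05, in signal units) then falls naturally inside the
  burst dynamic range.
* `s_c` — the carrier: zero-mean Gaussian noise band-limited to 20–450 Hz by
  a zero-phase 4th-order Butterworth filter and normalised to unit rms. This
  is the standard interference-pattern surrogate for surface EMG, which at
  normal contraction levels is well modelled as amplitude-modulated
  band-limited Gaussian noise.
* `e_c` — a trapezoidal burst envelope (25% rise, 50% plateau, 25% fall)
  with activity- and channel-specific onset fraction, duration fraction and
  peak amplitude. The default envelope matrix encodes which muscle dominates
  which movement (e.g. rectus femoris in stand-to-squat, channel 1 in
  stand-to-sit); the trip-fall is the shortest-onset, highest-amplitude burst
  on all four channels, reflecting that falls produce an abrupt change in
  most channels. Peaks span 0.5–6 mV.

Sampling is 1024 Hz with 1.5 s epochs (1536 samples), 4 channels, 8 activity
classes of which trip-fall is flagged as the fall class, ≥30 epochs per class
per subject and 3 subjects by default.

Two scalars control the dataset difficulty:

* `separation` pulls every per-class envelope descriptor toward (0) or away
  from (>1) the across-class mean: at 0 all classes are statistically
  identical, at 1 the configured contrasts are reproduced. It is the knob
  used by tests that need a known ordering of class separability.
* `subject_jitter` (default 0.05) multiplies each subject's envelope peaks by
  N(1, 0.05²) factors. It is deliberately small: per-subject feature rankings
  are expected to agree strongly across subjects, and a 5% amplitude jitter
  preserves that while still making subjects distinguishable.

Randomness uses one seed sequence per dataset, split deterministically into a
jitter stream and one child stream per epoch, so datasets are bit-identical
for equal seeds regardless of how epochs are iterated.

### What the generator does not model

Motor-unit physiology (recruitment, firing statistics, MUAP shapes),
electrode lift-off, motion artifacts, sweat/impedance drift, inter-day
electrode placement variability, and signal-dependent spectral changes
(fatigue). Consequently, passing tests demonstrate the *pipeline* —
extractors, scoring, classifiers, cross-validation — is correct and behaves
directionally as expected when classes differ by burst amplitude and timing;
they do not certify accuracy figures on real recordings, where
class-conditional differences are subtler and noise is structured.

## Feature conventions

All counting features use a strict unit step, u(z)=1 iff z>0: touching zero
is not a crossing, a flat pair of samples is not a turn. Per-channel outputs
are concatenated in channel order (scalar features → dimension 4 on the
default montage).

* **VAR** divides the raw sum of squares by N−1 *without* mean subtraction —
  the conventional EMG "variance" treats the signal as zero-mean. A
  `centered` option restores the textbook estimator.
* **MA** is the summed absolute consecutive difference (the waveform-length
  statistic); no division by N.
* **WAMP** counts strict exceedances |xᵢ₊₁−xᵢ| > T, default T = 0.05 signal
  units.
* **MF** weights one-sided periodogram power (squared spectral magnitude,
  DC excluded) by frequency; an all-zero signal is an error rather than 0/0.
* **HIST** uses 21 equal bins on [−5, 5]; out-of-range samples are clipped
  into the edge bins so counts always sum to N.
* **AR** uses Yule–Walker on the biased autocovariance (delegated to
  statsmodels, `demean=False`), order P = 4, sign convention
  xᵢ ≈ Σ aₖ xᵢ₋ₖ. All four coefficients per channel are kept (dimension 16
  over 4 channels); the registry flags this as deviating from the commonly
  tabulated 12, which would require dropping an unspecified coefficient.
* **ARCU** estimates the same AR(4) polynomial from the diagonal slice of the
  biased third-order cumulant, c₃(τ) = (1/N)Σ xₙ xₙ₊τ². For a causal AR
  process driven by iid skewed innovations, c₃(−τ) = Σₖ aₖ c₃(k−τ) holds
  exactly for τ ≥ 1 (the innovation is independent of earlier samples, so
  the driving term vanishes only on the negative-lag side). The coefficients
  solve this recursion in least squares over τ = 1..2P with a small-`rcond`
  pseudo-inverse; with symmetric (zero-skew) innovations the system is nearly
  singular and the regularised solution is returned rather than an error,
  since finite output per epoch is more useful than aborting a batch run.
* **EWT / EWP / ZCWT** use the db8 wavelet with **periodized** boundary
  handling, which keeps the transform orthogonal so sub-band energies
  partition the signal energy exactly (Parseval to machine precision) — the
  property the test suite asserts. Symmetric padding was considered and
  rejected because its redundant boundary coefficients break energy
  conservation. EWT/ZCWT use the five detail layers of a level-5
  decomposition (approximation excluded, 5 values/channel); EWP uses the
  full packet tree at depth 3 (8 terminal nodes/channel), giving the
  conventional dimensions 20 and 32 on four channels.
* **FE** (fuzzy entropy): ln φ_m − ln φ_{m+1} with φ the mean exponential
  similarity exp(−(d/r)²) of mean-removed m-templates under Chebyshev
  distance; defaults m = 2, r = 0.2·sd. A constant signal (sd 0) uses an
  absolute floor r = 1e-12 and returns 0.
* **PE** (permutation entropy): ordinal patterns of n = 4 consecutive
  samples, delay 1, natural log, unnormalised; ties rank by order of
  occurrence (stable argsort), so constant signals give a single motif and
  entropy 0.

## Separability and the trade-off index

S_B sums (mᵢ − m̄)(mᵢ − m̄)ᵀ over classes with m̄ the unweighted mean of class
means; S_W sums the population-normalised within-class covariances over
classes. Summing (rather than averaging) S_W makes the two-class 1-D index
equal μ²/σ² for class means ±μ; the alternative only rescales J by the class
count and changes no comparison. J = tr(S_B)/tr(S_W) is invariant to uniform
scaling, translation and orthogonal rotation of feature space, which the
suite verifies. No standardisation is applied before J: the index is computed
on raw feature values, and its scale invariance makes per-feature-type
comparisons meaningful without it.

The trade-off index normalises the best separability and the fastest
extraction to 100 (a = 100·J/max J; t = 100·min time/time, the
"respective proportions" reading of inverse-normalised time) and scores
(1−w)·a + w·t for w = 0..0.5 step 0.05; separability always keeps the
majority weight. Extraction times feed the index but are host-dependent and
are never asserted against reference values.

## Classifiers

All classifiers share fit/predict and a lossless JSON round-trip. Feature
standardisation is learned on training folds only: z-scoring for FDA,
GK-FDA, GK-SVM and FCM; min–max to [0,1] for FMMNN (whose membership
geometry lives in the unit cube).

* **FDA** solves the generalised eigenproblem S_B v = λ S_W v with a ridge
  of 1e-6·tr(S_W)/d on S_W, projects onto ≤ k−1 directions and assigns the
  nearest projected class mean.
* **GK-FDA** is the same criterion kernelised with
  k(x,z) = exp(−‖x−z‖²/2σ²): between/within matrices built from kernel class
  means, ridge 1e-6 on the within matrix, nearest projected class mean. At
  large σ it reproduces linear FDA (asserted against sklearn's LDA as an
  independent cross-check).
* **GK-SVM** wraps sklearn's SVC (RBF, gamma = 1/2σ², one-vs-one). Only σ is
  grid-searched; the cost defaults to C = 1 with the grid extension left to
  the caller, since the width is the parameter that materially changes the
  decision geometry here.
* **FMMNN** implements single-pass hyperbox learning: expand the
  highest-membership same-class box whose every edge stays ≤ θ (the
  per-edge cap is the invariant the suite checks), else seed a point box;
  then remove any strict all-dimension overlap with other-class boxes by
  contracting along the minimum-overlap dimension (the classical four-case
  rule), rescanning until clean. Membership decays linearly outside a box
  with sensitivity γ = 4. Prediction ties break toward the smallest class
  index. Order dependence is inherent and documented: over training-order
  shuffles the easy-set accuracy varies ≤ 10%.
* **FCM** runs fuzzifier-2 alternating optimisation (tolerance 1e-6, ≤ 300
  iterations) with centers initialised at random data points; five seeded
  restarts are run and the lowest final objective kept, because with eight
  clusters a single run can land in a poor local optimum. Clusters map to
  their majority hard-assigned training label; empty clusters inherit the
  label of the nearest non-empty centroid.

Hyperparameter search maximises mean stratified 3-fold inner-CV accuracy on
the training folds only — never on test data — with ties to the smallest grid
value. Grids: σ ∈ {0.5, 0.6, …, 5.0}; θ ∈ {0.05, …, 0.5}.

## Evaluation protocol

Stratified five-fold cross-validation, deterministic per seed; per-class fold
sizes differ by at most one. The default protocol trains each subject
separately and averages cells across subjects (pooled mode via
`per_subject=False`). Fall detection relabels the seven ADLs as one class and
trip-fall as the other, then reports sensitivity TP/(TP+FN) over fall epochs
and specificity TN/(TN+FP) over ADL epochs from the pooled five-fold
confusion matrix. Wall-clock extraction/prediction times are reported per
epoch for context only.

## Problem sizes used in tests and the acceptance script

Test datasets use one subject with 6–10 epochs per class (48–80 epochs),
which already exhibits every property being asserted; oracle-equivalence
checks use 100 random vectors per extractor (length 80 for fuzzy entropy,
256–512 otherwise); parameter recovery uses N = 4096 (AR) and N = 8192
(cumulant AR); asymptotic entropy and separability closed forms use 1e5
samples. These sizes were chosen as the smallest at which the asserted
properties are stable across seeds.

## Known limitations

* Synthetic classes differ mainly in burst amplitude/timing, so
  amplitude-driven features (WAMP, MA, IAV) dominate by construction;
  the benchmark validates directional behaviour, not real-data rankings.
* The cumulant-AR estimator needs skewed innovations; on symmetric noise it
  returns regularised (noise-dominated) coefficients by design.
* FMMNN accuracy depends on presentation order; results are reported for the
  dataset order produced by the generator.
* Timing columns measure this host and are not comparable across machines.
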