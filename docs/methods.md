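# Methods

## The model

A subject's state at beat k is the vector x(k) of N = 12 beat-sampled
haemodynamic channels. Within a moving window of the last w = 100 beats the
interdependency structure is summarised by two symmetric N×N matrices:

* **S** (adjacency): S_ij = 1 iff channels i and j are *structured* —
  interdependent in the generalised-correlation sense below; diag(S) = 0 by
  default.
* **E** (entropy): E_ij = plug-in mutual information of the pair, in bits.

The window's complexity is C = ‖S∘E‖₂, the spectral norm of the Hadamard
product. S∘E is symmetric non-negative, so C equals its largest eigenvalue;
it is 0 exactly when no pair is both structured and informative, and by
Perron–Frobenius monotonicity it can only grow when couplings are added or
strengthened. Stamping each value with the time of the window's *last* beat
makes C(t) a causal statistic: "information available at time t".

Sampling is beat-to-beat — one observation per cardiac cycle, inter-beat
interval 60/HR of the preceding beat — so a 100-beat window nominally spans
100 s at HR 60 bpm and shrinks as the heart accelerates. The window length
is an empirical convention of this analysis type and is exposed as
configuration, not tuned here.

## Generalised correlation by image entropy

For a pair (x, y) of window vectors, each axis is **rank-binned** into
B = 10 classes of near-equal occupancy (ties broken by stable order of
occurrence), and the joint counts form a B×B image. Its Shannon entropy
H(X,Y) satisfies log₂B ≤ H ≤ 2·log₂B for balanced margins: a perfectly
dependent monotone pair fills one cell per row (H = log₂B), an independent
pair spreads mass near-uniformly (H ≈ 2·log₂B). Rank binning makes the
image — and every downstream quantity — invariant under strictly
increasing transforms of either channel and insensitive to outliers and
units.

**Decision rule.** The pair is structured when H_obs falls at or below the
empirical α-quantile (α = 0.05) of the entropies of `n_null = 200` random
re-pairings of y against x. A permutation null was chosen because the
underlying channel distributions are arbitrary; the test is distribution-
free given the margins. Two supplementary quantities are reported:
`strength` rescales the entropy deficit between the null median and the
perfect-dependence floor onto [0, 1], and `mi = H(X) + H(Y) − H(X,Y)` ≥ 0
is the pair's information content in bits (the E entry). With quantile
binning H(X) ≈ H(Y) ≈ log₂B, so mi ∈ [0, log₂B] up to ties.

**Shared permutation null.** Under rank binning the null distribution of
H(X,Y) depends on the data only through the marginal bin occupancy vectors.
The sliding analysis therefore draws one seeded Monte-Carlo null sample per
distinct (n, B, margins) signature and reuses its quantile/median across
all windows and pairs sharing it — a ~100-fold saving with no change in the
test's distribution. `null_mode="fresh"` restores an independent seeded
null per (window, pair); `structure_test` (the public single-pair API)
always draws a fresh null from its own seed.

**Degenerate inputs.** A constant channel carries no rank information; its
pairs are reported unstructured with mi = 0 (zero row/column in S and E),
with a warning rather than an error.

## The synthetic cohort

The generator emulates the study conditions the analysis assumes — it is
the test bed, not a physiological model:

* **Protocol clock**: 300 s supine, 900 s passive tilt, 900 s provocation
  (nitroglycerine at 1200 s). Non-fainters complete the 2100 s protocol;
  fainters terminate uniformly in [900, 2100] s, so some faint before and
  some after drug administration — which is what makes control HR (all
  drug-exposed, +8 bpm) *higher* than fainter HR at fixed offsets before
  termination, reproducing the direction of the published group means.
* **Channels**: per group, each channel = configured mean + subject-level
  normal offset (between-subject SD) + phase offsets + AR(1) beat noise
  (lag-1 coefficient 0.3 — short-range autocorrelation without long-memory
  machinery). DBP and PP are generated; SBP = DBP + PP exactly. Group means
  and between-SDs default to values near the published upright-phase group
  statistics (fainters HR 74 bpm passive / 82 provoked vs controls
  80.9/88.9 ± 16.2; MAP ≈ 103 vs 99 mmHg); remaining channels use textbook
  resting values (PEP 100 ms, LVET 280 ms, SV 80 mL, CO 6 L/min, SVR
  1200 dyn·s/cm⁵, TAC 1.5 mL/mmHg, TFC 28/kΩ) with plausible spreads, since
  no per-channel tables exist to calibrate against.
* **Pre-syncope coupling**: in fainters' final 150 s a single shared latent
  AR(1) factor is added to *all* channels, scaled per channel to
  w(t)·g·σ_c with w ramping linearly 0 → coupling_max = 0.8 and injection
  gain g = 2.5. One latent factor is the simplest mechanism that guarantees
  a rising dependency network across every pair; the gain is set so that
  the shared-signal-to-noise ratio at full ramp (≈ 2:1 per channel) makes
  coupling detectable by a 100-sample window test, i.e. so that the
  generator actually produces the phenomenon whose detection is under test.
  The last 30 s add a linear HR/BP fall (25 bpm, 15 mmHg DBP, 10 mmHg PP) —
  the vasovagal collapse.
* **Determinism**: cohorts are pure functions of the spec; per-subject
  seeds are spawned from the master seed via NumPy seed sequences.

**What the generator does not emulate** — and hence what passing tests do
*not* establish about real data: baroreflex dynamics, respiratory and very-
low-frequency rhythms, measurement artefacts, demographic covariates, any
physiologically realistic partial-coupling structure between specific
channel pairs, and realistic between-channel correlations at baseline
(channels other than the SBP/DBP/PP triple are independent by
construction). Results on synthetic cohorts demonstrate the *pipeline's*
correctness and calibration, not clinical performance.

One structural caveat: PP = SBP − DBP makes that triple algebraically
dependent, so in control windows those pairs are genuinely (and correctly)
detected as structured; a fully independent-looking control cohort is
impossible under the channel definitions. Calibration checks of the
dependency test's false-positive rate therefore use pure independent-noise
windows.

## Statistical evaluation

* **Time points**: {300, 270, 240, 210, 180, 150, 120, 90, 60, 30} s before
  termination; values by linear interpolation between bracketing samples.
  (270 s is included: the reported group tables use it even where the
  listed grid omits it.)
* **Normality gate**: Lilliefors-corrected Kolmogorov–Smirnov (parameters
  estimated from the sample; the uncorrected KS would be anticonservative),
  p > 0.05 for both groups → pooled-variance Student t; otherwise
  Mann–Whitney U. The U test is exact by full enumeration of group
  assignments (midranks, hence valid under ties) when C(n₁+n₂, n₁) ≤ 2·10⁵,
  exact by the no-ties recurrence when n₁·n₂ ≤ 400, else the tie-corrected
  normal approximation.
* **ROC**: empirical curve over all thresholds; ties count 1/2; AUC by
  trapezoid. The orientation is fixed a priori (higher value → syncope), so
  an anti-predictive variable shows AUC < 0.5 instead of being silently
  flipped — this is why HR, confounded by control-only tachycardia, sits
  below 0.5 here. 95% CIs and the paired complexity-vs-HR/MAP comparisons
  use the DeLong variance/covariance estimator, the standard for correlated
  empirical AUCs. No multiple-testing correction across time points
  (per-time-point reporting at the 5% level).
* **Cutoffs**: candidate thresholds are midpoints between consecutive
  distinct values ("value ≥ threshold" → positive). "Optimal" maximises
  Youden's J (ties → lowest threshold); the constrained cutoffs are the
  highest threshold keeping sensitivity > 80% and the lowest keeping
  specificity > 80%, each reported with its complementary rate, with an
  explicit not-attainable marker.

## Numerical and scoping choices

* Spectral norm by `eigvalsh` (max |eigenvalue|) — exact for the symmetric
  matrices produced here; validation rejects asymmetry rather than falling
  back to SVD silently.
* Incomplete beats (any non-finite channel) are dropped before windowing,
  never interpolated: interpolation would inject artificial cross-channel
  structure and inflate C.
* No normalisation of C by N or window size is applied.
* Complexity magnitudes are implementation-scale: bounded by
  (N−1)·log₂B ≈ 36.5 bits here, versus hundreds of bits in published
  clinical tables produced with an undisclosed (proprietary) image
  criterion and resolution. Comparisons are therefore directional (AUC,
  trends, calibration), never absolute bit values.
* `run_study` computes the sliding window only over the last `tail_s`
  (default 480 s) before each subject's termination: windows are mutually
  independent and causal, so values at the analysed 300…30 s offsets are
  identical to a full-record run; the default simply avoids computing
  windows no time point uses. Set `tail_s: null` for full trajectories.
* Reported study runs use stride 5 beats (one complexity value per ~4 s);
  stride 1 is the default for single-subject trajectories.
* Floats are serialised with shortest round-trip formatting and fixed row
  order, so every writer is byte-deterministic under a fixed seed.

## Known limitations

* The structured/chaotic criterion (permutation quantile on image entropy)
  is a principled stand-in for an undisclosed proprietary rule; no claim of
  numerical equivalence is made, and whether the original rule demands a
  minimum dependency intensity beyond significance is unknown.
* Plug-in MI on a 10×10 image at n = 100 is biased upward under
  independence (≈ 0.6 bits); the bias is common to both groups and absorbed
  by the permutation null, but E should not be read as an unbiased MI
  estimate.
* The between-time-point trajectory of the generator (uniform termination
  times, piecewise-constant phase offsets) is a modelling choice; only
  group-level statistics at fixed offsets are calibrated.
* DeLong p-values for AUC differences need not match values obtained with
  other (unstated) methods on the original data.
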