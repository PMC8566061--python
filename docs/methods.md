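# Methods

This note records the models, algorithms, parameter choices and known
limitations behind `fixmodal`, in the order the pipeline applies them.

## 1. Data model

Recordings are monocular gaze time series at exactly 1 kHz: timestamps in
ms with unit spacing, horizontal/vertical gaze and target positions in
degrees of visual angle. NaN is the single missing-data representation for
eye position (blinks and removed events); target position is never
missing. Sample indexing is 0-based and half-open internally; the analysis
window specified as 1-based inclusive samples 192–691 of a trial epoch
(500 samples) converts to the half-open range [191, 691) at the API
boundary. On-disk column names are configurable (a "dialect" map), since
recording exports differ between laboratories.

## 2. Fixation cleanup

Six steps, applied in order, each only ever growing the set of NaN
samples (monotonicity is asserted in the test suite):

1. **Latency alignment.** The target signal is delayed by the shift
   s ∈ [0, 500] samples minimising the mean absolute eye–target
   discrepancy summed over both axes (NaN excluded), ties to the smaller
   shift. Delaying the *target* rather than advancing the eye keeps the
   eye signal and its artifacts untouched; epoch boundaries derived from
   the shifted target then align with the eye's response.
2. **Window choice.** Samples 192–691 (1-based) of each aligned epoch.
3. **Blink-saccade removal.** Blinks leave NaN gaps flanked by
   high-velocity lid artifacts. From the last good sample before a gap we
   march backward until three contiguous samples fall below the
   per-recording fixation velocity threshold FixVelT; the run's sample
   nearest the gap ends the preceding fixation, and everything between it
   and the gap is masked (symmetrically after the gap). FixVelT is
   `median + 5 × 1.4826 × MAD` of radial velocity over samples below a
   coarse 55 deg/s cap — a robust upper bound on fixation velocity noise.
   The constant 5 and the cap are configuration; this construction is this
   package's own (the formulation used on the original recordings was not
   restated with the rest of the procedure and lives in companion work).
4. **Velocity-based saccade removal.** Maximal runs of radial velocity
   above 55 deg/s mark saccade peaks; each saccade extends to the nearest
   local velocity minima below 30 deg/s on either side, and the whole
   interval is masked. Velocity is the central difference of position
   (deg/s at 1 kHz); the differentiator is unstated in the source
   procedure, so central difference with optional Savitzky–Golay
   pre-smoothing (off by default) is used. Applying the detector to its
   own output is a fixed point.
5. **Parabolic-fragment removal.** In every NaN-free 27-sample window
   (sliding by one sample, each axis separately) position is regressed on
   the sample index with a second-order polynomial; windows with R² > 0.6
   and |quadratic coefficient| > 0.00055 deg/sample² are masked. The
   coefficient threshold is only meaningful for a fixed predictor scale,
   so the predictor is defined as the raw sample index. Constant windows
   (R² undefined) are never flagged. This step catches small or slow
   saccades — including most microsaccade transients — that the velocity
   criterion misses.
6. **Anticipatory-saccade removal.** In a perfectly periodic task
   subjects sometimes saccade to the upcoming target early; the saccade
   itself is caught by steps 4–5, but the following fixation level sits
   far from the current target. A contiguous valid segment is masked when
   its median offset from the current target exceeds 2.0° (the task's
   minimum target step) *and* the move brings it ≥ 50% closer to the next
   target. Both thresholds are configuration; this operationalization of
   "elevated fixation levels" is this package's own. The last trial has no
   next target and is never touched.

A trial survives only if its analysis window retains exactly 500
contiguous valid samples. Boundary searches that hit a recording edge are
clipped and logged, not fatal.

## 3. Multimodality test

### Model and priors

Each 500-sample axis distribution y is modelled as a finite mixture of
K ∈ {1..5} univariate normals with weights w ~ Dirichlet(1,…,1), means
μ_j ~ N(ξ, κ⁻¹) and precisions σ_j⁻² ~ Gamma(α, β), with the hierarchical
rate β ~ Gamma(g, h). K is a priori uniform on {1..5}. Hyperparameters
adapt to the data range R: ξ = midrange, κ = 1/R², α = 2, g = 0.2,
h = 10/R² — the standard weakly informative choice for this sampler,
exposed as configuration (`MixturePrior`). The fitting engine used on the
original recordings delegated these choices to a package; they are
explicit here.

### Sampler

A Richardson–Green reversible-jump MCMC chain. Each sweep performs:

* Gibbs updates of w | z, μ | …, σ² | …, β | σ², and allocations z;
  means are kept in ascending order (each μ_j is proposed from its
  unconstrained full conditional and rejected if it would break the
  order — a valid Metropolis step whose acceptance ratio is the order
  indicator);
* one split/combine attempt (moment-matched split with u₁, u₂ ~ Beta(2,2),
  u₃ ~ Uniform; combine merges an adjacent-in-mean pair). The acceptance
  ratio was re-derived by hand; the selection probabilities cancel because
  a split chooses among k components while the reverse combine chooses
  among the k adjacent pairs of the (k+1)-component state;
* one birth/death attempt on empty components (birth weight ~ Beta(1, k),
  remaining weights rescaled; the Jacobian (1−w*)^{k−1} and the proposal
  density k(1−w*)^{k−1} leave a net 1/k factor beside the ordering factor
  k+1).

Weights summing to one and positive variances are asserted on every
sweep. The chain runs 500 burn-in plus 2000 kept sweeps (whether the
"2000 iterations" of the original analysis included burn-in is unknowable
from its description; kept-after-burn-in is the conservative reading),
single chain, seed mandatory. Non-convergence is *not* detected; the
posterior over K is read off the kept K draws.

### Bayes factor and categories

a = P(K>1)/P(K=1) under the prior (4.0 for the uniform prior, available in
closed form; a Monte-Carlo estimate is kept as a cross-check and for
priors only available as samplers). b is the same odds under the kept
draws; BF = b/a, log natural (the 1/3/5 thresholds correspond to the
standard evidence scale on the natural log). If no kept draw has K = 1,
BF is flagged +inf; if none has K > 1, BF = 0. Sanitization is
deliberately cohort-level, never per fixation: BF = 0 → 0.003 before
logging, infinite log BF → the cohort's maximum finite log BF (or a
documented cap of 2×10⁴ for an all-infinite cohort); categories are
recomputed from the sanitized values.

Component summaries (mean, SD, weight per component) condition on the
modal K: kept sweeps with K = modal K are averaged after ascending-mean
relabelling (the ordering constraint makes this the identity). The modal
K ties break toward smaller K.

## 4. Precision metrics

* ClassicPrecision: sample SD with the n−1 denominator (the denominator
  must be fixed for exactness even though it is negligible at n = 500).
* MaxCompSD: SD of the maximum-weight component; weight ties break toward
  the smaller SD (conservative; ties are measure-zero but the rule must be
  deterministic).
* RMS-S2S: √mean(Δy²) over successive samples.
* MAD: median (default) or mean absolute deviation, unscaled.
* BCEA = 2kπ σ_x σ_y √(1−ρ²), k = −ln(1−P), default P = 0.68. Included
  for comparison only; it assumes a unimodal Gaussian joint distribution.
* sd_coverage: empirical fraction within mean ± n·SD, with the analytic
  normal reference 2Φ(n)−1; zero-SD input covers 1.0 by convention,
  degenerate BCEA variance returns 0 with a warning.

All location metrics are offset-invariant and scale linearly under
positive scaling (property-tested).

## 5. Synthetic generator

The generator emulates the random-saccade task: 100 one-second trials at
1 kHz; targets uniform over ±15° × ±9° with ≥ 2° steps (rejection
sampling); per-trial latency truncated-normal(237, 17) on [192, 316] ms
(the reported empirical mean/SD/range, used here as a generative law);
raised-cosine saccades with duration 2.2·amplitude + 21 ms (a simple
main-sequence-style rule — any smooth profile exceeding the 55 deg/s
detector threshold for ≥ 2° steps suffices, and every generated saccade
is verified in the suite to exceed it).

**Fixation noise** is a sum of (i) a smooth band-limited wander — white
noise convolved with a Gaussian kernel of SD 15 ms, rescaled analytically
to a marginal SD of 0.04° — standing in for the low-frequency oculomotor
drift/tremor that dominates fixational movement, and (ii) white sensor
noise of SD 0.01°. The split matters: a non-differentiable process (e.g.
AR(1)) at this amplitude shows spurious curvature at exactly the
27-sample scale of the parabolic detector and spurious velocity spikes,
neither of which real, low-pass-filtered tracker output exhibits. The
resulting RMS-S2S ≈ 0.014° and window SD ≈ 0.04° sit in the realistic
range for a 1 kHz video tracker. The 0.04° overall noise scale lies
between the reported cohort medians of within-mode and total spread.

Per-trial fixation regimes (defaults 50/25/25%): pure noise (unimodal
truth), linear drift of 0.5 deg/s centred on the target (a mid-range
drift speed; smears the window distribution over ≈ 0.25° per 500 ms), or
a microsaccade-induced level shift of 0.3° (below the 0.5° microsaccade
convention) at the fixation midpoint. Blinks (10% of trials) are NaN gaps
of 50–150 ms flanked by 15 ms, 3° linear ramps so blink-saccade removal
has something to find.

**What passing tests do and do not show.** The generator produces
piecewise-stationary fixations with exactly one event type per trial and
noise that is Gaussian by construction; it contains no post-saccadic
oscillations, no RIONEPS, no pupil dynamics, no session-level drift of
calibration, and its microsaccades are single clean level shifts. Ground
truth therefore measures detector behaviour under idealised, known
conditions; it does not certify performance on real recordings. Notably,
the parabolic step catches the generator's microsaccade transients (as it
is designed to catch small saccades), so trials of the level-shift regime
are generally excluded by the completeness filter and the surviving
synthetic cohort derives its multimodality mostly from drift and
correlated noise.

## 6. Pipeline, determinism and problem sizes

Per-fixation sampler seeds derive from
SeedSequence(master, recording, trial, axis), making every output file
byte-reproducible under a fixed configuration (asserted in the suite).
BF sanitization happens once, cohort-wide, in the pipeline.

The validation suites use fifty seeded datasets of n = 500 each: power on
0.5·N(−0.15, 0.03²) + 0.5·N(+0.15, 0.03²) (mode separation 10 within-mode
SDs), specificity on N(0, 0.05²), parameter recovery on the
modal-K-correct power runs; the prior-odds cross-check uses 10⁶ draws;
the preprocessing comparison uses one 100-trial session. These sizes give
binomial standard errors of a few percent on the rates while keeping the
full suite to a few minutes of CPU.

## 7. Known limitations

* Single-chain rjMCMC without convergence diagnostics; pathological
  inputs could yield an unconverged posterior over K undetected.
* Specificity of the Bayes-factor test is calibrated against the chosen
  data-adaptive hyperpriors; markedly different priors shift the
  K-posterior and hence the category rates.
* The anticipatory-saccade rule and FixVelT formula are this package's
  constructions (configurable), not re-implementations of a published
  formula.
* Only monocular, already-calibrated data in degrees are supported; no
  EDF parsing, no screen-to-degree conversion, no binocular handling.
* Joint horizontal×vertical (bivariate) mixtures are out of scope; axes
  are tested independently.
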