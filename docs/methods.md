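# Methods

## The problem

In delayed orientation discrimination, an observer remembers a grating
orientation θ_n, then judges whether a probe rotated by a small offset δθ is
clockwise or counterclockwise of it. Reports are systematically attracted
toward the previous trial's orientation θ_{n−1} (serial dependence), while
orientation representations decoded from early visual cortex are *repelled*
from it (adaptation). This package implements the measurement tools for both
effects and a two-stage encoder–decoder model that reconciles them: gain
adaptation at encoding produces the neural repulsion; a readout that
accounts (or over-accounts) for that adaptation produces the behavioral
attraction.

All orientation arithmetic is 180°-periodic. Internally every cosine / von
Mises argument and every circular statistic uses the doubled-angle
convention (orientation × 2 mapped to the full circle, results halved back).
Differences Δθ = θ_{n−1} − θ_n are wrapped to (−90°, +90°].

## Behavioral response model

A trial's report is modeled as
`P(CW) = g/2 + (1 − g)·Φ((δθ − μ)/σ)` with a fixed guess rate g = 0.25,
which floors every response likelihood at g/2 and keeps the NLL finite for
any parameters. Holding g fixed (rather than free) keeps σ comparable
across observers. μ and σ are fit by bounded L-BFGS-B from multiple σ
starts (2°, 5°, 10°); ties break by lower NLL, then smaller σ. Trials
without a response are dropped (and counted).

Serial dependence is parameterized by letting μ follow a derivative of
Gaussian of Δθ:

    dog(x) = x · A · w · c · exp(−(w x)²),   c = √(2e),

so the curve's extremum equals A (at x = 1/(w√2)); A > 0 means attraction.
FWHM is computed numerically by root-finding at half peak. The three-
parameter behavioral fit (A, w, σ) maximizes response likelihood; fits to
neural decoding errors minimize RSS instead (the errors are continuous).
In the least-squares variant the width is bounded to w ≥ 0.005/°, below
which the curve is near-linear over ±90° and A trades off freely against w.

Precision as a function of history: trials with Δθ < 0 are "folded"
(probe offset and response sign-flipped) so bias points one way, the data
are split at |Δθ| = 30°, and the larger bin is subsampled to the smaller's
size 31 times, reporting the median σ. Sliding bias curves use a 32° wide
half-open window stepped at 1°.

## Encoder–decoder model

Encoding: N = 100 units with von Mises tuning evenly tiling [0, 180°),
κ = 1.0, peak unadapted rate R (R = 5 for all non-Bayesian readouts; it
does not affect their noiseless bias). Expected rates:

    Resp_N(θ_n) = R · γ_N · exp(κ(cos(Φ − θ_n) − 1)),      γ_N = 1
    γ_A(Φ)      = γ_N − rect(γ_m · cos³(γ_s(Φ − θ_{n−1})))
    Resp_A      = R · γ_A · exp(κ(cos(Φ − θ_n) − 1))

(cosines in doubled angles; γ_s scales width in the doubled space, so at
γ_s = 1 the gain dip spans ±45° of orientation). γ_m ∈ [0, 1] is the dip
depth; gains lie in [1 − γ_m, 1].

Decoding: Poisson likelihood of the observed rates over a 1° orientation
grid, under different assumed expected rates:

- **unaware**: assumes Resp_N — repelled from θ_{n−1} (this is what a
  history-blind multivariate decoder applied to adapted cortex measures);
- **aware**: assumes the true Resp_A — exactly unbiased on noiseless input
  (observed and expected rates align at θ_n, which maximizes each Poisson
  term simultaneously);
- **overaware**: assumes a deeper/wider dip (γ_m2, γ_s2) — net attraction
  when the assumed adaptation exceeds the true one;
- **bayes-unaware / bayes-aware**: the respective likelihood multiplied by
  a temporal-contiguity prior, a mixture of a circular Gaussian of width ψ
  centred on θ_{n−1} (weight P_SAME = 0.64) and a uniform density.

Numerical choices: the likelihood grid is 1° with circular parabolic peak
interpolation (ties break to the first grid argmax); expected rates are
floored at 1e−12 inside logs; noiseless "responses" enter the Poisson log
pmf through the continuous extension k·log λ − λ − lnΓ(k+1). No
Bayes-overaware variant is provided, keeping all readouts at two free
parameters.

## Inverted encoding model

Eight channels with basis `max(0, cos(θ − ω_i))⁵` on the half circle
(value 1 at the channel center, 0 at the orthogonal orientation; the summed
activation is constant to <1%). Training solves Ŵ = pinv(C)·B (SVD
pseudo-inverse, relative tolerance 1e−10); decoding computes Ĉ = B·pinv(Ŵ)
and reads the population vector Ĉ·e^{i2ω}: its angle (halved) is θ̂, its
modulus R̂ a certainty proxy. Zero-resultant trials are NaN-flagged and
excluded from circular summaries. Cross-validation is leave-one-fold-out
over consecutive folds of 4 blocks × trials-per-block (68 trials at the
scanner's 17-trial blocks); unbalanced training folds warn but proceed.

Circular statistics (doubled space): μ_circ is the resultant angle,
σ_circ = √(−2 ln|R̄|) (unitless), and circular correlation uses the
pairwise Fisher–Lee form Σ_{i<j} sin(a_i − a_j) sin(b_i − b_j) /
√(Σ sin²·Σ sin²) — the mean-centered form is degenerate when a marginal is
uniform, which the balanced task design guarantees.

Voxel selection is a deterministic two-stage filter on localizer data: keep
the top half of voxels by two-sample t (stimulus vs control location), then
the top half of those by one-way F across 10° orientation bins (≈25%
retained). Dimensionality: split trials at |Δθ| < 30° vs > 60°, subsample
to equal n, mean-center, eigendecompose the voxel covariance, and report
components-to-90%-variance and the AUC of the cumulative-variance curve.

## HRF estimation and trial-wise responses

The FIR design has one 0/1 column per tap (30 taps = 24 s at TR 0.8 s) per
event type (stimulus, probe) plus per-block constants; kernels come from
ordinary least squares (pseudo-inverse with a warning if rank deficient).
Each voxel's kernel is then parameterized by a 6-parameter double gamma —
difference of two gamma densities with free mode and dispersion per lobe,
undershoot ratio, and amplitude; bounds keep both modes positive — fit by
multi-start least squares. A fit explaining < 50% of kernel variance is
flagged non-converged for exclusion, mirroring the usual practice of
dropping unparameterizable voxels rather than silently keeping them.
Trial-wise amplitudes come from a GLM whose design holds one
kernel-convolved delta per stimulus and probe event plus block constants;
solving it by least squares removes linear carry-over from previous events.
On noiseless data both identities are exact to numerical precision (the
test suite asserts < 1e−6).

## Two-stage fitting

Stage 1 (encoding): (γ_m, γ_s) minimize the RSS between observed decoding
errors and the unaware readout's noiseless bias curve interpolated at each
trial's Δθ. Stage 2 (decoding): with encoding fixed per fold, the readout's
two free parameters — (R, ψ) for Bayesian decoders, (γ_m2, γ_s2) for
overaware — maximize the binary-response likelihood, with a per-participant
σ estimated first (free constant bias) and held fixed. Both stages share
the neural decoder's folds, search a 30 × 30 grid (γ ranges [0, 0.8] ×
[0.25, 4]; ψ ∈ [2°, 60°]; R log-spaced in [0.5, 50] — ranges chosen to
bracket no/strong adaptation, narrow/broad dips, and weak/dominant priors),
then refine by Nelder–Mead from the best grid point; the refined objective
is never allowed to be worse than the grid optimum, and flat objectives are
flagged. Model comparison pools out-of-fold log-likelihood (no information
criterion; equal parameter counts by construction). Variance evaluation
simulates 1,000 Poisson trials per fitted fold, pools errors, and compares
distributions by Jensen–Shannon divergence (nats, ∈ [0, ln 2]) on a common
±90° binning with ε-smoothing of empty bins.

A caution on identifiability: at realistic neural noise the encoding-stage
objective has a strong γ_m–γ_s trade-off (correlation ≈ 0.8 between the
estimates). With a 4° peak bias against ~15° circular noise and 800 trials,
parameter estimates carry ~15–20% median relative error; recovery tightens
quickly at lower noise or larger γ_m. Curve-level recovery (the quantity
the readout stage consumes) is much better conditioned than the individual
parameters.

## Synthetic data

The generator mirrors the scanner task: blocks of 17 trials (configurable),
uniform mode drawing each block's orientations as a permuted linearly
spaced grid over 180° with a random phase offset, or binned mode jittering
±5° (uniform — magnitude is our choice, undocumented in the source
protocol) around 22.5°-spaced centers offset by 11.25°, alternating
near-oblique → near-cardinal. Timing: 1 s stimulus, delays ∈ {5, 7, 9} s,
ITI uniform 5–9 s. Probe offsets are ±4.5° by default, or per-block
magnitudes drawn from a range to emulate the difficulty titration.

Observers invert the response model: P(CW) from the DoG or any supplied
bias curve, σ, and the 25% guess rate, with seeded sampling — so
psychometric fits have exact generating-parameter oracles.

The voxel simulator drives 32 von Mises-tuned voxels (κ = 2) with
stimulus- and probe-evoked amplitudes convolved with a double-gamma HRF on
the TR grid (onsets snapped to TRs; the snapped onsets are what the dataset
reports, keeping GLM identities exact). Adaptation attenuates each trial's
stimulus amplitude by 40% of the previous trial's realized (post-
attenuation) amplitude, per voxel, within block. The probe (a thin line)
drives half the grating's response (probe_gain = 0.5). Gaussian noise of
SD 2.0 response units yields time-course decoding r_circ ≈ 0.4, matching
the scale of real early-visual decoding; these are the package's standard
simulation conditions. With attenuation on, IEM errors show a robust
negative (repulsive) DoG amplitude for both time-course and trial-beta
decoding; with it off the sign is at chance — the simulator's design does
not itself manufacture repulsion, though HRF-overlap artifacts (attractive
from positive-lobe overlap, repulsive from the undershoot) are present and
timing-dependent at low noise.

What the simulator does *not* emulate: physiological/scanner noise
structure (temporal autocorrelation, drift), voxel-to-voxel noise
correlations, heterogeneous tuning widths and HRFs across voxels,
attention and eye movements, and the live staircase. Passing tests
therefore certify the analysis machinery and its internal consistency on
data with the assumed statistical structure, not the empirical effect
sizes of any particular cohort.

## Problem sizes

Defaults were chosen to run the whole suite on one CPU in a few minutes:
behavioral simulations use ~425–1,020 trials; study-scale fitting checks
use 800 trials and 20 seeds; voxel simulations use 8 blocks × 17 trials ×
32 voxels (~2,600 TRs); variance simulations 1,000 trials per parameter
set. All sizes are arguments, so cohort-scale runs only change constants.

## Known limitations

- The encoding-stage parameters are weakly identified at high noise (see
  above); report curve-level summaries when noise is large.
- The DoG amplitude from least squares is heavy-tailed on near-zero-signal
  data (narrow-width spike fits); its *sign* is robust and is what the
  qualitative analyses use.
- FIR kernels are average evoked responses; when event amplitudes covary
  across overlapping events the per-voxel kernel shape absorbs some of
  that covariation (the voxel-averaged kernel does not).
- The aware decoder's exactness holds at the grid resolution; parabolic
  interpolation can move a peak by a fraction of the grid step.
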