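"""Adaptation-aware encoder-decoder model of orientation coding.

Encoding: a bank of N von Mises tuned units evenly tiling the 180-deg
orientation space.  The gain of each unit is attenuated as a function of its
tuning distance from the previous stimulus (a rectified cos^3 dip), modelling
short-term sensory adaptation.  Poisson spiking is assumed.

Decoding: maximum-likelihood readouts of the adapted population that assume

* no adaptation          (``unaware``   -> repulsive bias),
* the true adaptation    (``aware``     -> unbiased),
* exaggerated adaptation (``overaware`` -> attractive bias),

plus a Bayesian stage in which the likelihood is multiplied by a
temporal-contiguity prior (mixture of a circular Gaussian centred on the
previous stimulus and a uniform), yielding ``bayes-unaware`` and
``bayes-aware`` readouts.

All angular arguments of cos/von Mises terms use the doubled-angle convention
(orientations are 180-deg periodic).
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy.special import gammaln

from .circular import wrap_ori

__all__ = [
    "PopulationModel",
    "AdaptationParams",
    "PriorParams",
    "LikelihoodProfile",
    "DECODERS",
    "gain_profile",
    "population_response",
    "likelihood_unaware",
    "likelihood_aware",
    "likelihood_overaware",
    "apply_prior",
    "bias_curve",
    "simulate_decoder_variance",
]

#: names of the five readout schemes
DECODERS = ("unaware", "aware", "overaware", "bayes-unaware", "bayes-aware")

#: rate floor inside log Poisson terms (guards rectified-to-zero rates)
RATE_FLOOR = 1e-12


@dataclasses.dataclass(frozen=True)
class PopulationModel:
    """Unadapted von Mises population code.

    Parameters
    ----------
    n_units : number of tuned units tiling [0, 180).
    kappa : von Mises concentration of the tuning curves (doubled space).
    rate_scale : peak expected Poisson rate R of an unadapted unit at its
        preferred orientation.
    grid_step : resolution (deg) of the likelihood grid used by the decoders.
    """

    n_units: int = 100
    kappa: float = 1.0
    rate_scale: float = 5.0
    grid_step: float = 1.0

    def __post_init__(self):
        if self.n_units < 2:
            raise ValueError("n_units must be >= 2")
        if self.kappa <= 0 or self.rate_scale <= 0 or self.grid_step <= 0:
            raise ValueError("kappa, rate_scale and grid_step must be positive")

    @property
    def centers(self) -> np.ndarray:
        """Tuning-curve centers Phi (deg), evenly tiling [0, 180)."""
        return np.arange(self.n_units) * (180.0 / self.n_units)

    @property
    def grid(self) -> np.ndarray:
        """Orientation grid (deg) over which likelihood profiles are evaluated."""
        return np.arange(0.0, 180.0, self.grid_step)

    def tuning(self, theta) -> np.ndarray:
        """Unadapted peak-1 tuning profile exp(kappa*(cos(2*(Phi-theta))-1)).

        ``theta`` may be scalar or an array; output shape is
        ``np.shape(theta) + (n_units,)``.
        """
        theta = np.asarray(theta, dtype=float)
        d = np.deg2rad(2.0 * (theta[..., None] - self.centers))
        return np.exp(self.kappa * (np.cos(d) - 1.0))


@dataclasses.dataclass(frozen=True)
class AdaptationParams:
    """Gain-dip parameters: magnitude gamma_m in [0, 1], width scale gamma_s > 0."""

    gamma_m: float
    gamma_s: float

    def __post_init__(self):
        if not 0.0 <= self.gamma_m <= 1.0:
            raise ValueError(f"gamma_m must lie in [0, 1], got {self.gamma_m}")
        if self.gamma_s <= 0:
            raise ValueError(f"gamma_s must be positive, got {self.gamma_s}")


@dataclasses.dataclass(frozen=True)
class PriorParams:
    """Temporal-contiguity prior: mixture weight P_SAME and width psi (deg)."""

    p_same: float = 0.64
    psi: float = 20.0

    def __post_init__(self):
        if not 0.0 <= self.p_same <= 1.0:
            raise ValueError("p_same must lie in [0, 1]")
        if self.psi <= 0:
            raise ValueError("psi must be positive")


@dataclasses.dataclass
class LikelihoodProfile:
    """Log-likelihood (or log-posterior) of orientation for one trial."""

    grid: np.ndarray  # orientations, deg
    log_likelihood: np.ndarray
    map_orientation: float  # deg, parabolic-interpolated peak

    @property
    def posterior(self) -> np.ndarray:
        """Normalized probability over the grid (sums to 1)."""
        p = np.exp(self.log_likelihood - self.log_likelihood.max())
        return p / p.sum()


# ---------------------------------------------------------------------------
# Encoding
# ---------------------------------------------------------------------------

def gain_profile(theta_prev, gamma_m, gamma_s, centers) -> np.ndarray:
    """Adapted gain gamma(Phi) = 1 - rect(gamma_m * cos^3(gamma_s*(Phi - theta_prev))).

    Evaluated in doubled-angle space; values lie in [1 - gamma_m, 1], with
    gain exactly 1 wherever the rectified lobe is zero.
    """
    AdaptationParams(gamma_m, gamma_s)  # validate
    centers = np.asarray(centers, dtype=float)
    d = np.deg2rad(2.0 * (centers - theta_prev))
    lobe = gamma_m * np.cos(gamma_s * d) ** 3
    return 1.0 - np.maximum(0.0, lobe)


def population_response(theta_n, theta_prev=None, model: PopulationModel = None,
                        adapt: AdaptationParams | None = None) -> np.ndarray:
    """Expected Poisson rates of the population for one presented orientation.

    rate_i = R * gamma_i * exp(kappa * (cos(2*(Phi_i - theta_n)) - 1)); the
    peak unadapted rate equals R.  With ``theta_prev is None`` or
    ``adapt is None`` the unadapted profile is returned.
    """
    if model is None:
        model = PopulationModel()
    rates = model.rate_scale * model.tuning(theta_n)
    if adapt is not None and theta_prev is not None:
        rates = rates * gain_profile(theta_prev, adapt.gamma_m, adapt.gamma_s,
                                     model.centers)
    return rates


# ---------------------------------------------------------------------------
# Decoding
# ---------------------------------------------------------------------------

def _poisson_loglik(resp, expected) -> np.ndarray:
    """Sum_i log Poisson(resp_i; expected_i) along the last axis.

    ``resp`` may be non-integer (the noiseless expected rates are used as
    pseudo-counts when fitting): the continuous extension
    k log lam - lam - lnGamma(k+1) is used.  Expected rates are floored to
    avoid -inf where rectification gives zero rate.
    """
    resp = np.asarray(resp, dtype=float)
    lam = np.maximum(np.asarray(expected, dtype=float), RATE_FLOOR)
    return (resp * np.log(lam) - lam - gammaln(resp + 1.0)).sum(axis=-1)


def _map_from_profile(grid, logp) -> float:
    """Peak of a log profile with circular parabolic interpolation."""
    i = int(np.argmax(logp))
    n = len(grid)
    l0, l1, l2 = logp[(i - 1) % n], logp[i], logp[(i + 1) % n]
    denom = l0 - 2.0 * l1 + l2
    delta = 0.0 if denom >= -1e-300 else 0.5 * (l0 - l2) / denom
    delta = float(np.clip(delta, -0.5, 0.5))
    step = grid[1] - grid[0] if n > 1 else 1.0
    return float((grid[i] + delta * step) % 180.0)


def _profile(resp, model, expected_matrix) -> LikelihoodProfile:
    resp = np.asarray(resp, dtype=float)
    if np.any(resp < 0):
        raise ValueError("response vector must be nonnegative")
    logp = _poisson_loglik(resp, expected_matrix)
    return LikelihoodProfile(model.grid, logp, _map_from_profile(model.grid, logp))


def likelihood_unaware(resp, model: PopulationModel) -> LikelihoodProfile:
    """ML readout assuming the *unadapted* expected rates for every theta."""
    expected = model.rate_scale * model.tuning(model.grid)
    return _profile(resp, model, expected)


def likelihood_aware(resp, model: PopulationModel, theta_prev,
                     adapt: AdaptationParams) -> LikelihoodProfile:
    """ML readout assuming the *true* adapted expected rates.

    On noiseless adapted input the observed and expected rates align exactly
    at theta_n, so the MAP equals the presented orientation (unbiased).
    """
    gain = gain_profile(theta_prev, adapt.gamma_m, adapt.gamma_s, model.centers)
    expected = model.rate_scale * model.tuning(model.grid) * gain
    return _profile(resp, model, expected)


def likelihood_overaware(resp, model: PopulationModel, theta_prev,
                         assumed: AdaptationParams) -> LikelihoodProfile:
    """ML readout assuming an *exaggerated* adaptation (gamma_m2, gamma_s2).

    With assumed adaptation deeper than the true one the MAP is attracted
    toward the previous stimulus at intermediate Delta-theta.
    """
    return likelihood_aware(resp, model, theta_prev, assumed)


def prior_density(grid, theta_prev, prior: PriorParams) -> np.ndarray:
    """Temporal-contiguity prior P(theta | theta_prev) on the grid (per deg).

    Mixture of a circular Gaussian of width psi centred on theta_prev
    (normalized to integrate to 1 over 180 deg) and a uniform density 1/180,
    with weight p_same on the Gaussian component.
    """
    grid = np.asarray(grid, dtype=float)
    step = grid[1] - grid[0] if len(grid) > 1 else 1.0
    d = wrap_ori(grid - theta_prev)
    pt = np.exp(-(d**2) / (2.0 * prior.psi**2))
    pt = pt / (pt.sum() * step)
    return prior.p_same * pt + (1.0 - prior.p_same) / 180.0


def apply_prior(profile: LikelihoodProfile, theta_prev,
                prior: PriorParams) -> LikelihoodProfile:
    """Multiply a likelihood profile by the contiguity prior -> posterior."""
    dens = prior_density(profile.grid, theta_prev, prior)
    logpost = profile.log_likelihood + np.log(dens)
    return LikelihoodProfile(profile.grid, logpost,
                             _map_from_profile(profile.grid, logpost))


def _decode_one(resp, decoder, model, theta_prev, adapt, assumed, prior):
    if decoder == "unaware":
        return likelihood_unaware(resp, model)
    if decoder == "aware":
        return likelihood_aware(resp, model, theta_prev, adapt)
    if decoder == "overaware":
        return likelihood_overaware(resp, model, theta_prev, assumed)
    if decoder == "bayes-unaware":
        return apply_prior(likelihood_unaware(resp, model), theta_prev, prior)
    if decoder == "bayes-aware":
        return apply_prior(likelihood_aware(resp, model, theta_prev, adapt),
                           theta_prev, prior)
    raise ValueError(f"unknown decoder {decoder!r}; expected one of {DECODERS}")


def decode(resp, decoder, model: PopulationModel, theta_prev=None,
           adapt: AdaptationParams | None = None,
           assumed: AdaptationParams | None = None,
           prior: PriorParams | None = None) -> LikelihoodProfile:
    """Decode one response vector with any of the five readout schemes."""
    return _decode_one(resp, decoder, model, theta_prev, adapt, assumed, prior)


# ---------------------------------------------------------------------------
# Model curves and simulation
# ---------------------------------------------------------------------------

def bias_curve(decoder, model: PopulationModel, adapt: AdaptationParams,
               delta_grid=None, assumed: AdaptationParams | None = None,
               prior: PriorParams | None = None, theta_n: float = 90.0
               ) -> np.ndarray:
    """Noiseless decoded bias (deg) as a function of Delta-theta.

    For each Delta-theta the population is adapted by
    theta_prev = theta_n + Delta-theta, its noiseless expected rates are
    decoded, and the signed wrapped error of the MAP relative to theta_n is
    returned.  Positive bias = attraction toward the previous stimulus for
    positive Delta-theta.
    """
    if decoder not in DECODERS:
        raise ValueError(f"unknown decoder {decoder!r}; expected one of {DECODERS}")
    if delta_grid is None:
        delta_grid = np.arange(-90.0, 90.1, 1.0)
    delta_grid = np.asarray(delta_grid, dtype=float)
    out = np.empty(len(delta_grid))
    for j, d in enumerate(delta_grid):
        theta_prev = (theta_n + d) % 180.0
        resp = population_response(theta_n, theta_prev, model, adapt)
        prof = _decode_one(resp, decoder, model, theta_prev, adapt, assumed, prior)
        out[j] = wrap_ori(prof.map_orientation - theta_n)
    return out


def simulate_decoder_variance(decoder, model: PopulationModel,
                              adapt: AdaptationParams, n_trials: int = 1000,
                              seed: int | None = None,
                              assumed: AdaptationParams | None = None,
                              prior: PriorParams | None = None):
    """Poisson-sampled decoding errors for variance summaries.

    Draws ``n_trials`` (theta_n, theta_prev) pairs uniformly, samples Poisson
    spike counts from the adapted expected rates, decodes each trial, and
    returns ``(errors, delta)`` arrays (deg): ``errors`` are wrapped decoder
    errors, ``delta = wrap(theta_prev - theta_n)``.
    """
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    rng = np.random.default_rng(seed)
    theta_n = rng.uniform(0.0, 180.0, n_trials)
    theta_prev = rng.uniform(0.0, 180.0, n_trials)
    errors = np.empty(n_trials)
    for t in range(n_trials):
        rates = population_response(theta_n[t], theta_prev[t], model, adapt)
        counts = rng.poisson(rates)
        prof = _decode_one(counts, decoder, model, theta_prev[t], adapt,
                           assumed, prior)
        errors[t] = wrap_ori(prof.map_orientation - theta_n[t])
    return errors, wrap_ori(theta_prev - theta_n)
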