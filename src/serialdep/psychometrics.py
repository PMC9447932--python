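"""Psychometric models for binary CW/CCW discrimination responses.

The response model treats encoding as a Gaussian process with bias mu and
standard deviation sigma (degrees): the probability of a clockwise response to
a probe offset delta-theta-probe is

    P(CW) = g/2 + (1 - g) * Phi((probe_offset - mu) / sigma)

with a fixed guess rate g = 0.25, so every response has likelihood >= g/2 and
the negative log-likelihood is always finite.  Serial dependence is
parameterized by letting mu follow a derivative-of-Gaussian (DoG) function of
the orientation difference Delta-theta between consecutive stimuli.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy.optimize import brentq, minimize
from scipy.stats import norm

from .circular import circ_mean_ori, circ_sd

__all__ = [
    "GUESS_RATE",
    "DOG_NORMALIZATION",
    "ResponseModelFit",
    "DoGFit",
    "dog",
    "dog_fwhm",
    "response_probability",
    "fit_response_model",
    "fit_dog_behavior",
    "sliding_bias_curve",
    "close_far_precision",
]

GUESS_RATE = 0.25

#: sqrt(2e): scales x*A*w*exp(-(w x)^2) so that its peak value equals A
DOG_NORMALIZATION = float(np.sqrt(2.0 * np.e))


@dataclasses.dataclass
class ResponseModelFit:
    mu: float  # bias, deg
    sigma: float  # encoding SD, deg
    guess_rate: float
    nll: float  # negative log-likelihood, nats
    n_trials: int
    boundary: bool = False  # True if the optimum sits on a parameter bound


@dataclasses.dataclass
class DoGFit:
    amplitude: float  # peak bias A, deg (positive = attraction)
    width: float  # w, 1/deg
    fwhm: float  # deg, computed numerically from the fitted curve
    sigma: float | None = None  # behavioral fits only
    nll: float | None = None  # likelihood fits
    rss: float | None = None  # least-squares fits
    n_trials: int = 0


def dog(x, amplitude, width):
    """Derivative-of-Gaussian bias curve x*A*w*c*exp(-(w*x)^2), c = sqrt(2e).

    Odd in x; its extremum over x equals ``amplitude`` (attained at
    x = 1/(w*sqrt(2))).
    """
    if width <= 0:
        raise ValueError(f"width must be positive, got {width}")
    x = np.asarray(x, dtype=float)
    return x * amplitude * width * DOG_NORMALIZATION * np.exp(-((width * x) ** 2))


def dog_fwhm(amplitude, width):
    """Full width at half maximum of the DoG curve, by numeric root-finding."""
    if amplitude == 0:
        return np.nan
    xpk = 1.0 / (width * np.sqrt(2.0))
    half = abs(amplitude) / 2.0

    def f(x):
        return abs(dog(x, amplitude, width)) - half

    lo = brentq(f, 1e-9, xpk)
    # |dog| decays to 0 as x grows; bracket the outer crossing
    hi_end = xpk
    while abs(dog(hi_end * 2, amplitude, width)) > half:
        hi_end *= 2
    hi = brentq(f, xpk, hi_end * 2)
    return hi - lo


def response_probability(probe_offset, mu, sigma, guess_rate=GUESS_RATE):
    """P(respond CW) under the Gaussian response model with a fixed guess rate.

    Bounded in [guess_rate/2, 1 - guess_rate/2]; nondecreasing in the probe
    offset for fixed (mu, sigma).
    """
    if np.any(np.asarray(sigma) <= 0):
        raise ValueError("sigma must be positive")
    z = (np.asarray(probe_offset, dtype=float) - mu) / sigma
    return guess_rate / 2.0 + (1.0 - guess_rate) * norm.cdf(z)


def _as_cw(responses) -> np.ndarray:
    """Coerce responses to a boolean CW array; NaN / 'none' are invalid here."""
    r = np.asarray(responses)
    if r.dtype.kind in "biu":
        return r.astype(bool)
    if r.dtype.kind == "f":
        if np.any(np.isnan(r)):
            raise ValueError("responses contain missing values; drop them first")
        return r.astype(bool)
    return np.char.lower(r.astype(str)) == "cw"


def _binary_nll(cw, p):
    p = np.clip(p, 1e-12, 1 - 1e-12)
    return float(-(np.log(p[cw]).sum() + np.log1p(-p[~cw]).sum()))


_SIGMA_BOUNDS = (0.1, 80.0)
_MU_BOUNDS = (-45.0, 45.0)
_SIGMA_STARTS = (2.0, 5.0, 10.0)


def fit_response_model(probe_offsets, responses, mu=None,
                       guess_rate=GUESS_RATE) -> ResponseModelFit:
    """Maximum-likelihood fit of (mu, sigma) to binary responses.

    ``mu=None`` fits the bias as a free constant; passing a number holds it
    fixed and fits sigma only.  The guess rate is held fixed (never
    estimated).  Optimization is bounded L-BFGS-B from multiple sigma starts;
    ties are broken by lowest NLL then smallest sigma.  If all responses are
    one class the optimum sits on a bound and the fit is flagged.
    """
    x = np.asarray(probe_offsets, dtype=float)
    cw = _as_cw(responses)
    if len(np.unique(x)) < 2:
        raise ValueError("need >= 2 distinct probe offsets to fit the model")

    fit_mu = mu is None

    def nll(params):
        m = params[0] if fit_mu else mu
        s = params[-1]
        return _binary_nll(cw, response_probability(x, m, s, guess_rate))

    best = None
    for s0 in _SIGMA_STARTS:
        x0 = [0.0, s0] if fit_mu else [s0]
        bounds = [_MU_BOUNDS, _SIGMA_BOUNDS] if fit_mu else [_SIGMA_BOUNDS]
        res = minimize(nll, x0, method="L-BFGS-B", bounds=bounds)
        key = (res.fun, res.x[-1])
        if best is None or key < (best.fun, best.x[-1]):
            best = res
    m_hat = float(best.x[0]) if fit_mu else float(mu)
    s_hat = float(best.x[-1])
    on_bound = (np.isclose(s_hat, _SIGMA_BOUNDS, atol=1e-6).any()
                or (fit_mu and np.isclose(m_hat, _MU_BOUNDS, atol=1e-6).any())
                or cw.all() or (~cw).all())
    return ResponseModelFit(mu=m_hat, sigma=s_hat, guess_rate=guess_rate,
                            nll=float(best.fun), n_trials=len(x),
                            boundary=bool(on_bound))


def fit_dog_behavior(delta, probe_offsets, responses,
                     guess_rate=GUESS_RATE) -> DoGFit:
    """ML fit of serial dependence: mu(Delta-theta) = dog(Delta-theta; A, w).

    Three free parameters (A, w, sigma) maximize the likelihood of the binary
    responses.  Trials with missing Delta-theta (e.g. the first of a block)
    are dropped.  Raises if the Delta-theta support is degenerate.
    """
    delta = np.asarray(delta, dtype=float)
    x = np.asarray(probe_offsets, dtype=float)
    cw = _as_cw(responses)
    ok = ~np.isnan(delta)
    delta, x, cw = delta[ok], x[ok], cw[ok]
    if len(np.unique(delta)) < 3:
        raise ValueError("Delta-theta support is degenerate; cannot fit a DoG")

    def nll(params):
        a, w, s = params
        p = response_probability(x, dog(delta, a, w), s, guess_rate)
        return _binary_nll(cw, p)

    bounds = [(-60.0, 60.0), (0.005, 0.3), _SIGMA_BOUNDS]
    best = None
    for a0 in (-5.0, 0.0, 5.0):
        for w0 in (0.02, 0.05):
            for s0 in _SIGMA_STARTS:
                res = minimize(nll, [a0, w0, s0], method="L-BFGS-B",
                               bounds=bounds)
                if best is None or res.fun < best.fun:
                    best = res
    a, w, s = (float(v) for v in best.x)
    return DoGFit(amplitude=a, width=w, fwhm=dog_fwhm(a, w), sigma=s,
                  nll=float(best.fun), n_trials=int(len(x)))


def sliding_bias_curve(delta, values, estimator="response_model",
                       window=32.0, step=1.0, centers=None,
                       probe_offsets=None, guess_rate=GUESS_RATE):
    """Windowed summaries of bias (and precision) as a function of Delta-theta.

    For each window center c the estimator is applied to trials whose
    Delta-theta falls in the half-open window [c - window/2, c + window/2)
    (wrapped distance).  Estimators:

    * ``"response_model"`` -- ``values`` are binary responses and
      ``probe_offsets`` must be given; returns per-window (mu, sigma) from
      :func:`fit_response_model`.
    * ``"circular_mean"`` -- ``values`` are orientation errors (deg); returns
      per-window circular mean and circular SD.

    Empty windows yield NaN (flagged missing, never zero).  Returns a dict
    with ``centers``, ``bias``, ``spread``, ``n``.
    """
    delta = np.asarray(delta, dtype=float)
    if centers is None:
        centers = np.arange(-90.0, 90.0 + step / 2, step)
    centers = np.asarray(centers, dtype=float)
    half = window / 2.0
    bias = np.full(len(centers), np.nan)
    spread = np.full(len(centers), np.nan)
    n = np.zeros(len(centers), dtype=int)
    for j, c in enumerate(centers):
        d = (delta - (c - half)) % 180.0  # in [0, 180)
        mask = (d >= 0) & (d < window) & ~np.isnan(delta)
        n[j] = int(mask.sum())
        if n[j] == 0:
            continue
        if estimator == "circular_mean":
            errs = np.asarray(values, dtype=float)[mask]
            bias[j] = circ_mean_ori(errs)
            spread[j] = circ_sd(errs)
        elif estimator == "response_model":
            if probe_offsets is None:
                raise ValueError("probe_offsets required for the response-model "
                                 "estimator")
            xo = np.asarray(probe_offsets, dtype=float)[mask]
            if len(np.unique(xo)) < 2:
                continue
            fit = fit_response_model(xo, np.asarray(values)[mask],
                                     guess_rate=guess_rate)
            bias[j], spread[j] = fit.mu, fit.sigma
        else:
            raise ValueError(f"unknown estimator {estimator!r}")
    return {"centers": centers, "bias": bias, "spread": spread, "n": n}


def close_far_precision(delta, probe_offsets, responses, threshold=30.0,
                        n_resample=31, seed=0, guess_rate=GUESS_RATE):
    """Precision (sigma) for trials following close vs far stimuli.

    Trials with Delta-theta < 0 are "folded" (probe offset and response sign
    flipped) so that serial-dependence bias points the same way in both
    groups and does not inflate the variance estimate.  Trials are split at
    ``|Delta-theta| = threshold``; the larger bin is subsampled without
    replacement to the smaller bin's size ``n_resample`` times and the median
    sigma of those fits is reported for that bin.

    Returns ``(sigma_close, sigma_far, resamples)`` where ``resamples`` maps
    the subsampled bin name to its per-resample sigma values.
    """
    if not 0.0 < threshold < 90.0:
        raise ValueError(f"threshold must lie in (0, 90) deg, got {threshold}")
    delta = np.asarray(delta, dtype=float)
    x = np.asarray(probe_offsets, dtype=float).copy()
    cw = _as_cw(responses).copy()
    ok = ~np.isnan(delta)
    delta, x, cw = delta[ok], x[ok], cw[ok]

    flip = delta < 0
    x[flip] = -x[flip]
    cw[flip] = ~cw[flip]

    close = np.abs(delta) < threshold
    groups = {"close": close, "far": ~close}
    sizes = {k: int(v.sum()) for k, v in groups.items()}
    if min(sizes.values()) == 0:
        raise ValueError("both close and far bins must be non-empty")
    small = min(sizes, key=sizes.get)
    large = max(sizes, key=sizes.get)
    if small == large:  # equal sizes: keep deterministic naming
        small, large = "close", "far"

    sigma = {small: fit_response_model(x[groups[small]], cw[groups[small]],
                                       guess_rate=guess_rate).sigma}
    rng = np.random.default_rng(seed)
    idx_large = np.flatnonzero(groups[large])
    draws = []
    for _ in range(n_resample):
        sub = rng.choice(idx_large, size=sizes[small], replace=False)
        draws.append(fit_response_model(x[sub], cw[sub],
                                        guess_rate=guess_rate).sigma)
    sigma[large] = float(np.median(draws))
    return sigma["close"], sigma["far"], {large: np.asarray(draws)}
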