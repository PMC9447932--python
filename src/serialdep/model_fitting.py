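"""Two-stage fitting of the encoder-decoder model, and model evaluation.

Stage 1 (encoding): the gain-dip parameters (gamma_m, gamma_s) are fit by
minimizing the residual sum of squares between observed neural decoding
errors and the noiseless bias curve of the unaware readout.

Stage 2 (decoding): with the encoding stage fixed, each candidate readout's
two free parameters -- (R, psi) for the Bayesian decoders, (gamma_m2,
gamma_s2) for the overaware decoder -- are fit by maximizing the likelihood
of binary CW/CCW responses, with the bias mu(Delta-theta) given by the
decoder's noiseless bias curve, a per-participant sigma estimated first and
held fixed, and the fixed 25% guess rate.

Both stages use the neural decoder's cross-validation folds, a 30 x 30 grid
search over each parameter pair followed by Nelder-Mead refinement around the
best grid point (the refined objective is never allowed to be worse than the
grid optimum).  Model comparison pools out-of-fold log-likelihoods; variance
evaluation simulates Poisson-sampled decoding per fitted fold and compares
pooled error distributions by Jensen-Shannon divergence.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
from scipy.optimize import minimize
from scipy.spatial.distance import jensenshannon

from .circular import circ_sd, wrap_ori
from .population_model import (AdaptationParams, PopulationModel, PriorParams,
                               gain_profile, simulate_decoder_variance)
from .psychometrics import (GUESS_RATE, fit_response_model,
                            response_probability)

__all__ = [
    "FitResult",
    "ModelComparison",
    "GRID_RANGES",
    "make_cv_folds",
    "fit_encoding_stage",
    "fit_decoding_stage",
    "compare_models",
    "evaluate_variance",
]

GRID_N = 30  # values per parameter (900 grid locations per pair)

#: parameter search ranges; chosen to bracket all qualitative regimes
GRID_RANGES = {
    "gamma_m": (0.0, 0.8),
    "gamma_s": (0.25, 4.0),
    "gamma_m2": (0.0, 0.8),
    "gamma_s2": (0.25, 4.0),
    "psi": (2.0, 60.0),
    "rate": (0.5, 50.0),  # log-spaced
}


@dataclasses.dataclass
class FitResult:
    stage: str  # "encoding" | "decoding"
    decoder: str
    params: list  # one dict per CV fold
    objective: list  # RSS or NLL per fold (refined)
    fold_ids: list
    grid: dict  # parameter names -> sampled values
    sigma: float | None = None  # per-participant sigma (decoding stage)
    flags: list = dataclasses.field(default_factory=list)


@dataclasses.dataclass
class ModelComparison:
    log_likelihood: dict  # model -> pooled out-of-fold LL (behavioral)
    js_divergence: dict = dataclasses.field(default_factory=dict)
    sigma_close: dict = dataclasses.field(default_factory=dict)
    sigma_far: dict = dataclasses.field(default_factory=dict)


def make_cv_folds(n_trials, fold_size):
    """Consecutive-trial fold labels, reused identically across both stages.

    A trailing partial fold keeps its own label and triggers a warning.
    """
    labels = np.arange(n_trials) // fold_size
    if n_trials % fold_size:
        warnings.warn(f"{n_trials} trials leave a partial trailing fold of "
                      f"{n_trials % fold_size}", RuntimeWarning, stacklevel=2)
    return labels


class _CurveEngine:
    """Vectorized noiseless bias curves over a Delta-theta grid.

    Precomputes the peak-1 tuning matrix over the likelihood grid so that
    each candidate parameter set costs only a couple of matrix products.
    All decoders share theta_n = 90 deg; curves are functions of
    Delta = theta_prev - theta_n only (verified odd-symmetric in tests).
    """

    def __init__(self, model: PopulationModel, delta_step=2.0):
        self.model = model
        self.delta = np.arange(-90.0, 90.0 + delta_step / 2, delta_step)
        self.theta_n = 90.0
        self.theta_prev = self.theta_n + self.delta
        self.grid = model.grid
        self.step = model.grid_step
        self.T = model.tuning(self.grid)  # (G, N) peak-1
        self.logT = np.log(self.T)
        self.sumT = self.T.sum(axis=1)  # (G,)
        self.t_n = model.tuning(self.theta_n)  # (N,) response tuning
        # prior distance |grid - theta_prev| wrapped, for Bayesian decoders
        self.prior_d2 = wrap_ori(self.grid[None, :]
                                 - self.theta_prev[:, None]) ** 2

    def _gains(self, gm, gs):
        return np.stack([gain_profile(tp, gm, gs, self.model.centers)
                         for tp in self.theta_prev])  # (D, N)

    def _map(self, L):
        """Row-wise argmax with circular parabolic interpolation -> bias deg."""
        idx = np.argmax(L, axis=1)
        n = L.shape[1]
        rows = np.arange(L.shape[0])
        l0 = L[rows, (idx - 1) % n]
        l1 = L[rows, idx]
        l2 = L[rows, (idx + 1) % n]
        denom = l0 - 2.0 * l1 + l2
        with np.errstate(divide="ignore", invalid="ignore"):
            delta = np.where(denom < -1e-300, 0.5 * (l0 - l2) / denom, 0.0)
        theta = (self.grid[idx] + np.clip(delta, -0.5, 0.5) * self.step) % 180.0
        return wrap_ori(theta - self.theta_n)

    def _resp(self, gm, gs):
        """Observed (noiseless, peak-1) adapted population profiles (D, N)."""
        return self.t_n[None, :] * self._gains(gm, gs)

    def unaware(self, gm, gs):
        a = self._resp(gm, gs)
        return self._map(a @ self.logT.T - self.sumT[None, :])

    def overaware(self, gm, gs, gm2, gs2):
        a = self._resp(gm, gs)
        g2 = self._gains(gm2, gs2)
        # log expected = log g2 + logT; theta-constant terms dropped
        return self._map(a @ self.logT.T - g2 @ self.T.T)

    def bayes(self, gm, gs, rate, psi, aware):
        a = self._resp(gm, gs)
        if aware:
            g = self._gains(gm, gs)
            loglik = a @ self.logT.T - g @ self.T.T
        else:
            loglik = a @ self.logT.T - self.sumT[None, :]
        prior = PriorParams(psi=psi)
        pt = np.exp(-self.prior_d2 / (2.0 * psi**2))
        pt = pt / (pt.sum(axis=1, keepdims=True) * self.step)
        dens = prior.p_same * pt + (1.0 - prior.p_same) / 180.0
        return self._map(rate * loglik + np.log(dens))

    def curve(self, decoder, encoding: AdaptationParams, params):
        gm, gs = encoding.gamma_m, encoding.gamma_s
        if decoder == "unaware":
            return self.unaware(gm, gs)
        if decoder == "aware":
            return np.zeros_like(self.delta)
        if decoder == "overaware":
            return self.overaware(gm, gs, params["gamma_m2"],
                                  params["gamma_s2"])
        if decoder in ("bayes-unaware", "bayes-aware"):
            return self.bayes(gm, gs, params["rate"], params["psi"],
                              aware=decoder == "bayes-aware")
        raise ValueError(f"unknown decoder {decoder!r}")


def _grid_values(name):
    lo, hi = GRID_RANGES[name]
    if name == "rate":
        return np.geomspace(lo, hi, GRID_N)
    return np.linspace(lo, hi, GRID_N)


def _grid_then_refine(objective, names, flags):
    """30 x 30 grid search + Nelder-Mead; never worse than the grid optimum."""
    vals = [_grid_values(n) for n in names]
    best_obj, best_p = np.inf, None
    for v0 in vals[0]:
        for v1 in vals[1]:
            o = objective((v0, v1))
            if o < best_obj:
                best_obj, best_p = o, (v0, v1)
    lo = np.array([GRID_RANGES[n][0] for n in names])
    hi = np.array([GRID_RANGES[n][1] for n in names])

    def clipped(p):
        return objective(tuple(np.clip(p, lo, hi)))

    res = minimize(clipped, np.asarray(best_p), method="Nelder-Mead",
                   options={"xatol": 1e-4, "fatol": 1e-8, "maxiter": 400})
    if res.fun <= best_obj:
        refined = tuple(np.clip(res.x, lo, hi))
        obj = float(res.fun)
    else:  # refinement must never lose to the grid
        refined, obj = best_p, float(best_obj)
        flags.append("refinement-no-improvement")
    if np.isclose(obj, objective((vals[0][0], vals[1][0]))) and \
       np.isclose(obj, objective((vals[0][-1], vals[1][-1]))):
        flags.append("flat-objective")
    return dict(zip(names, (float(v) for v in refined))), obj, \
        dict(zip(names, vals))


def fit_encoding_stage(errors, delta, model: PopulationModel | None = None,
                       fold_labels=None) -> FitResult:
    """Fit (gamma_m, gamma_s) to neural decoding errors by RSS.

    For each fold, parameters minimize the RSS between the unaware decoder's
    noiseless bias curve (interpolated at each training trial's Delta-theta)
    and that trial's observed error; trials in the fold itself are held out.
    With ``fold_labels=None`` a single fit on all trials is returned.
    """
    model = model or PopulationModel()
    errors = np.asarray(errors, dtype=float)
    delta = np.asarray(delta, dtype=float)
    ok = ~(np.isnan(errors) | np.isnan(delta))
    engine = _CurveEngine(model)
    if fold_labels is None:
        fold_labels = np.zeros(len(errors), dtype=int)
        fold_iter = [(0, np.ones(len(errors), dtype=bool))]
    else:
        fold_labels = np.asarray(fold_labels)
        uniq = np.unique(fold_labels)
        many = len(uniq) > 1
        fold_iter = [(f, (fold_labels != f) if many else np.ones(len(errors),
                                                                 dtype=bool))
                     for f in uniq]
    params, objs, fold_ids, flags = [], [], [], []
    for f, train in fold_iter:
        m = train & ok
        e_t, d_t = errors[m], delta[m]

        def rss(p):
            curve = engine.unaware(*p)
            pred = np.interp(d_t, engine.delta, curve)
            return float(((pred - e_t) ** 2).sum())

        fl = []
        p_hat, obj, grid = _grid_then_refine(rss, ("gamma_m", "gamma_s"), fl)
        params.append(p_hat)
        objs.append(obj)
        fold_ids.append(int(f))
        flags.append(fl)
    return FitResult(stage="encoding", decoder="unaware", params=params,
                     objective=objs, fold_ids=fold_ids, grid=grid,
                     flags=flags)


def _fold_params(encoding_fit: FitResult, fold_id) -> AdaptationParams:
    i = encoding_fit.fold_ids.index(int(fold_id))
    p = encoding_fit.params[i]
    return AdaptationParams(p["gamma_m"], p["gamma_s"])


_DECODER_PARAM_NAMES = {
    "overaware": ("gamma_m2", "gamma_s2"),
    "bayes-unaware": ("rate", "psi"),
    "bayes-aware": ("rate", "psi"),
}


def _response_nll(delta, probe_offsets, cw, curve_delta, curve, sigma,
                  guess_rate):
    mu = np.interp(delta, curve_delta, curve)
    p = response_probability(probe_offsets, mu, sigma, guess_rate)
    p = np.clip(p, 1e-12, 1 - 1e-12)
    return float(-(np.log(p[cw]).sum() + np.log1p(-p[~cw]).sum()))


def fit_decoding_stage(delta, probe_offsets, responses,
                       encoding_fit: FitResult, decoder,
                       model: PopulationModel | None = None,
                       fold_labels=None, sigma=None,
                       guess_rate=GUESS_RATE) -> FitResult:
    """Fit a readout's 2 free parameters to binary responses by ML.

    ``decoder`` is one of ``overaware`` (gamma_m2, gamma_s2; R fixed at the
    model's rate scale), ``bayes-unaware`` or ``bayes-aware`` (R, psi).  The
    per-participant sigma is estimated first (response model with a free
    constant bias) and held fixed unless passed explicitly.  Fold labels
    must match the encoding fit's folds.
    """
    if decoder not in _DECODER_PARAM_NAMES:
        raise ValueError(f"decoder must be one of "
                         f"{sorted(_DECODER_PARAM_NAMES)}, got {decoder!r}")
    model = model or PopulationModel()
    delta = np.asarray(delta, dtype=float)
    x = np.asarray(probe_offsets, dtype=float)
    from .psychometrics import _as_cw
    cw = _as_cw(responses)
    ok = ~np.isnan(delta)
    if sigma is None:
        sigma = fit_response_model(x[ok], cw[ok], guess_rate=guess_rate).sigma
    engine = _CurveEngine(model)
    names = _DECODER_PARAM_NAMES[decoder]

    if fold_labels is None:
        fold_labels = np.zeros(len(delta), dtype=int)
    fold_labels = np.asarray(fold_labels)
    if sorted(np.unique(fold_labels).tolist()) != sorted(encoding_fit.fold_ids):
        raise ValueError("fold labels do not match the encoding fit's folds")
    uniq = np.unique(fold_labels)
    many = len(uniq) > 1
    params, objs, fold_ids, flags = [], [], [], []
    for f in uniq:
        train = (fold_labels != f) if many else np.ones(len(delta), bool)
        m = train & ok
        d_t, x_t, cw_t = delta[m], x[m], cw[m]
        adapt = _fold_params(encoding_fit, f)

        def nll(p):
            curve = engine.curve(decoder, adapt, dict(zip(names, p)))
            return _response_nll(d_t, x_t, cw_t, engine.delta, curve, sigma,
                                 guess_rate)

        fl = []
        p_hat, obj, grid = _grid_then_refine(nll, names, fl)
        params.append(p_hat)
        objs.append(obj)
        fold_ids.append(int(f))
        flags.append(fl)
    return FitResult(stage="decoding", decoder=decoder, params=params,
                     objective=objs, fold_ids=fold_ids, grid=grid,
                     sigma=float(sigma), flags=flags)


def model_bias_curve(fit: FitResult, encoding_fit: FitResult,
                     model: PopulationModel | None = None, fold_id=None,
                     delta_step=2.0):
    """Noiseless bias curve of a fitted decoder (averaged over folds).

    Returns ``(delta_grid, bias)``; with ``fold_id`` given, only that fold's
    parameters are used.
    """
    model = model or PopulationModel()
    engine = _CurveEngine(model, delta_step)
    folds = [fold_id] if fold_id is not None else fit.fold_ids
    curves = []
    for f in folds:
        i = fit.fold_ids.index(int(f))
        adapt = _fold_params(encoding_fit, f)
        curves.append(engine.curve(fit.decoder, adapt, fit.params[i]))
    return engine.delta, np.mean(curves, axis=0)


def compare_models(fits, delta, probe_offsets, responses, fold_labels,
                   encoding_fit: FitResult,
                   model: PopulationModel | None = None,
                   guess_rate=GUESS_RATE) -> ModelComparison:
    """Pooled out-of-fold behavioral log-likelihood per fitted decoder.

    Each fold's held-out trials are scored with the parameters fit without
    that fold.  All fits must share identical folds; no information
    criterion is applied (equal parameter counts by design).
    """
    model = model or PopulationModel()
    delta = np.asarray(delta, dtype=float)
    x = np.asarray(probe_offsets, dtype=float)
    from .psychometrics import _as_cw
    cw = _as_cw(responses)
    fold_labels = np.asarray(fold_labels)
    ok = ~np.isnan(delta)
    engine = _CurveEngine(model)
    lls = {}
    for name, fit in fits.items():
        if sorted(fit.fold_ids) != sorted(encoding_fit.fold_ids):
            raise ValueError(f"fit {name!r} used different folds")
        ll = 0.0
        for f in fit.fold_ids:
            test = (fold_labels == f) & ok
            i = fit.fold_ids.index(int(f))
            adapt = _fold_params(encoding_fit, f)
            curve = engine.curve(fit.decoder, adapt, fit.params[i])
            ll -= _response_nll(delta[test], x[test], cw[test], engine.delta,
                                curve, fit.sigma, guess_rate)
        lls[name] = float(ll)
    return ModelComparison(log_likelihood=lls)


def evaluate_variance(fit: FitResult, encoding_fit: FitResult,
                      reference_errors, model: PopulationModel | None = None,
                      n_sim=1000, seed=0, close_thresh=30.0, n_bins=36):
    """Poisson-simulated error distribution of a fitted decoder.

    Simulates ``n_sim`` trials per fold's parameter set (Poisson rates at the
    encoding stage), pools the decoded errors, and returns a dict with the
    Jensen-Shannon divergence (nats, in [0, ln 2]) between the pooled error
    histogram and the reference error distribution on a common binning
    (empty bins epsilon-smoothed), plus sigma_circ for close/far trials.
    """
    model = model or PopulationModel()
    rng = np.random.default_rng(seed)
    errors, deltas = [], []
    for f in fit.fold_ids:
        i = fit.fold_ids.index(int(f))
        adapt = _fold_params(encoding_fit, f)
        p = fit.params[i]
        kwargs = {}
        sim_model = model
        if fit.decoder == "overaware":
            kwargs["assumed"] = AdaptationParams(p["gamma_m2"], p["gamma_s2"])
        else:
            kwargs["prior"] = PriorParams(psi=p["psi"])
            sim_model = dataclasses.replace(model, rate_scale=p["rate"])
        e, d = simulate_decoder_variance(fit.decoder, sim_model, adapt,
                                         n_trials=n_sim,
                                         seed=int(rng.integers(2**31)),
                                         **kwargs)
        errors.append(e)
        deltas.append(d)
    errors = np.concatenate(errors)
    deltas = np.concatenate(deltas)

    bins = np.linspace(-90.0, 90.0, n_bins + 1)
    p_sim, _ = np.histogram(errors, bins=bins)
    p_ref, _ = np.histogram(np.asarray(reference_errors, dtype=float),
                            bins=bins)
    eps = 1e-9
    p_sim = p_sim + eps
    p_ref = p_ref + eps
    js = float(jensenshannon(p_sim / p_sim.sum(), p_ref / p_ref.sum()) ** 2)

    close = np.abs(deltas) < close_thresh
    return {"js_divergence": js,
            "sigma_close": circ_sd(errors[close]),
            "sigma_far": circ_sd(errors[~close]),
            "errors": errors, "delta": deltas}
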