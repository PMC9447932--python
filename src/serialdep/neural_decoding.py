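"""Inverted encoding model (IEM) decoding of orientation from voxel patterns.

A linear encoding model expresses each voxel as a weighted sum of 8
hypothetical orientation channels with half-wave-rectified cos^5 tuning.
Training estimates the channel-to-voxel weights by pseudo-inverse; inverting
the weights on held-out trials reconstructs channel responses, whose
population vector (doubled-angle space) gives the decoded orientation and a
vector-length certainty proxy.  Also here: circular error summaries, DoG fits
to raw decoding errors, the two-stage localizer-based voxel filter, and the
close/far PCA dimensionality comparison.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
from scipy import stats

from .circular import circ_corr_ori, circ_mean_ori, circ_sd, wrap_ori
from .psychometrics import dog

__all__ = [
    "IEMModel",
    "DecodedTrials",
    "channel_basis",
    "train_iem",
    "decode_trials",
    "crossval_decode",
    "circ_bias",
    "circ_sd_errors",
    "circ_corr",
    "dog_fit_errors",
    "select_voxels",
    "pca_dimensionality",
]

DEFAULT_CHANNELS = np.arange(8) * 22.5
BASIS_EXPONENT = 5
_PINV_RTOL = 1e-10


def channel_basis(theta, centers=DEFAULT_CHANNELS):
    """Channel activations max(0, cos(theta - omega))^5 (orientation space).

    The cosine is taken of the wrapped orientation difference expressed on
    the half circle, so a channel responds 1 at its center and 0 at the
    orthogonal orientation (90 deg away).  Output shape: (..., n_channels).
    """
    theta = np.asarray(theta, dtype=float)
    d = wrap_ori(theta[..., None] - np.asarray(centers, dtype=float))
    return np.maximum(0.0, np.cos(np.deg2rad(d))) ** BASIS_EXPONENT


@dataclasses.dataclass
class IEMModel:
    channels: np.ndarray  # centers omega, deg
    weights: np.ndarray  # channel x voxel

    @property
    def n_voxels(self):
        return self.weights.shape[1]


@dataclasses.dataclass
class DecodedTrials:
    """Per-trial decoder output; undefined estimates are NaN-flagged."""

    theta_hat: np.ndarray  # deg in [0, 180); NaN if resultant is zero
    certainty: np.ndarray  # vector length R_hat >= 0
    theta_true: np.ndarray | None = None
    fold: np.ndarray | None = None

    @property
    def errors(self):
        """Signed decoding errors wrap(theta_hat - theta_true), deg."""
        if self.theta_true is None:
            raise ValueError("no stimulus labels attached")
        return wrap_ori(self.theta_hat - self.theta_true)


def train_iem(B_train, theta_train, centers=DEFAULT_CHANNELS) -> IEMModel:
    """Estimate channel weights W = pinv(C) B from a training set.

    Requires at least as many trials as channels and a design whose channel
    matrix has full column rank (orientations spanning the space).
    """
    B_train = np.asarray(B_train, dtype=float)
    centers = np.asarray(centers, dtype=float)
    if B_train.shape[0] < len(centers):
        raise ValueError(f"need >= {len(centers)} training trials, got "
                         f"{B_train.shape[0]}")
    C = channel_basis(np.asarray(theta_train, dtype=float), centers)
    if np.linalg.matrix_rank(C) < len(centers):
        raise ValueError("channel design is rank deficient: training "
                         "orientations do not span the space")
    W = np.linalg.pinv(C, rcond=_PINV_RTOL) @ B_train
    return IEMModel(channels=centers, weights=W)


def decode_trials(model: IEMModel, B_test, theta_true=None) -> DecodedTrials:
    """Invert the trained model: Chat = B pinv(W); population-vector readout.

    theta_hat is the angle (halved back to orientation degrees) and R_hat the
    modulus of Chat . exp(i * 2*omega).  A zero resultant leaves theta_hat
    NaN (excluded from circular summaries).
    """
    B_test = np.atleast_2d(np.asarray(B_test, dtype=float))
    if B_test.shape[1] != model.n_voxels:
        raise ValueError("voxel count mismatch between model and test data")
    C_hat = B_test @ np.linalg.pinv(model.weights, rcond=_PINV_RTOL)
    z = C_hat @ np.exp(1j * np.deg2rad(2.0 * model.channels))
    r = np.abs(z)
    theta = np.where(r > 1e-12,
                     (np.rad2deg(np.angle(z)) / 2.0) % 180.0, np.nan)
    tt = None if theta_true is None else np.asarray(theta_true, dtype=float)
    return DecodedTrials(theta_hat=theta, certainty=r, theta_true=tt)


def crossval_decode(B, theta, fold_size=68, fold_labels=None,
                    centers=DEFAULT_CHANNELS) -> DecodedTrials:
    """Leave-one-fold-out decoding: every trial decoded exactly once.

    Folds are consecutive runs of ``fold_size`` trials (the task's 4 blocks
    of 17) unless explicit ``fold_labels`` are given.  An unbalanced training
    fold (an empty 22.5-deg orientation bin) triggers a warning but decoding
    proceeds.
    """
    B = np.asarray(B, dtype=float)
    theta = np.asarray(theta, dtype=float)
    n = len(theta)
    if fold_labels is None:
        if n % fold_size:
            raise ValueError(f"{n} trials not divisible into folds of "
                             f"{fold_size}")
        fold_labels = np.arange(n) // fold_size
    fold_labels = np.asarray(fold_labels)
    theta_hat = np.empty(n)
    certainty = np.empty(n)
    for f in np.unique(fold_labels):
        test = fold_labels == f
        train = ~test
        hist, _ = np.histogram(theta[train] % 180.0, bins=8, range=(0, 180))
        if np.any(hist == 0):
            warnings.warn(f"training set for fold {f} is unbalanced (empty "
                          "orientation bin)", RuntimeWarning, stacklevel=2)
        model = train_iem(B[train], theta[train], centers)
        out = decode_trials(model, B[test])
        theta_hat[test] = out.theta_hat
        certainty[test] = out.certainty
    return DecodedTrials(theta_hat=theta_hat, certainty=certainty,
                         theta_true=theta, fold=fold_labels)


# -- circular summaries (doubled-angle convention) --------------------------

def circ_bias(errors):
    """Circular mean of decoding errors, deg in (-90, +90]."""
    return circ_mean_ori(errors)


def circ_sd_errors(errors):
    """Circular SD sqrt(-2 ln|R|) of decoding errors (unitless)."""
    return circ_sd(errors)


def circ_corr(theta_hat, theta):
    """Circular correlation between decoded and presented orientations."""
    return circ_corr_ori(theta_hat, theta)


def dog_fit_errors(errors, delta, n_starts=8):
    """Least-squares DoG fit to raw decoding errors as a function of Delta.

    Positive amplitude = attraction toward the previous stimulus, negative =
    repulsion.  Multi-start Gauss-Newton over width; raises if no start
    converges.  Returns a :class:`serialdep.psychometrics.DoGFit`.
    """
    from scipy.optimize import least_squares

    from .psychometrics import DoGFit, dog_fwhm

    errors = np.asarray(errors, dtype=float)
    delta = np.asarray(delta, dtype=float)
    ok = ~(np.isnan(errors) | np.isnan(delta))
    errors, delta = errors[ok], delta[ok]

    def resid(p):
        return dog(delta, p[0], p[1]) - errors

    best = None
    widths = np.geomspace(0.008, 0.15, n_starts)
    for w0 in widths:
        for a0 in (-10.0, 10.0):
            try:
                # w floor keeps the amplitude identified: below it the DoG is
                # near-linear over +-90 deg and A trades off freely against w
                res = least_squares(resid, [a0, w0],
                                    bounds=([-90.0, 5e-3], [90.0, 0.5]))
            except Exception:
                continue
            if best is None or res.cost < best.cost:
                best = res
    if best is None:
        raise RuntimeError("DoG fit failed to converge from every start")
    a, w = (float(v) for v in best.x)
    fwhm = dog_fwhm(a, w) if a != 0 else np.nan
    return DoGFit(amplitude=a, width=w, fwhm=fwhm, rss=float(2 * best.cost),
                  n_trials=int(len(errors)))


def select_voxels(loc_resp, spatial_label, orientations, bin_width=10.0):
    """Two-stage localizer voxel filter; keeps ~25% of the input pool.

    Stage 1 keeps the half of the voxels with the largest two-sample t
    statistic for (target-location vs control-location) responses; stage 2
    keeps the half of those with the largest one-way F statistic across
    ``bin_width``-deg orientation bins (target-location trials only).
    Returns sorted voxel indices.  Deterministic.
    """
    loc_resp = np.asarray(loc_resp, dtype=float)
    spatial_label = np.asarray(spatial_label, dtype=bool)
    orientations = np.asarray(orientations, dtype=float)
    n_vox = loc_resp.shape[1]
    if n_vox < 4:
        raise ValueError("need at least 4 voxels for the two-stage filter")

    tstat, _ = stats.ttest_ind(loc_resp[spatial_label],
                               loc_resp[~spatial_label], axis=0)
    stage1 = np.argsort(-tstat)[:max(1, n_vox // 2)]

    ori = orientations[spatial_label] % 180.0
    bins = np.digitize(ori, np.arange(bin_width, 180.0, bin_width))
    resp = loc_resp[spatial_label][:, stage1]
    groups = [resp[bins == b] for b in np.unique(bins)]
    fstat, _ = stats.f_oneway(*groups, axis=0)
    stage2 = stage1[np.argsort(-fstat)[:max(1, len(stage1) // 2)]]
    return np.sort(stage2)


def pca_dimensionality(B, delta, close_thresh=30.0, far_thresh=60.0,
                       var_target=0.90, seed=0):
    """Dimensionality of activity patterns after close vs far stimuli.

    Trials are subset into |Delta| < close_thresh and |Delta| > far_thresh,
    the larger subset subsampled (without replacement) to the smaller's size,
    and each subset mean-centered and eigendecomposed.  Returns a dict with
    ``n90`` (components to reach ``var_target`` of the variance) and ``auc``
    (mean of the cumulative-variance curve; higher = lower-dimensional) for
    both subsets.
    """
    if far_thresh < close_thresh:
        raise ValueError("far_thresh must be >= close_thresh")
    B = np.asarray(B, dtype=float)
    delta = np.asarray(delta, dtype=float)
    rng = np.random.default_rng(seed)
    masks = {"close": np.abs(delta) < close_thresh,
             "far": np.abs(delta) > far_thresh}
    sizes = {k: int(v.sum()) for k, v in masks.items()}
    if min(sizes.values()) == 0:
        raise ValueError("both close and far subsets must be non-empty")
    n_keep = min(sizes.values())
    out = {}
    for name, mask in masks.items():
        idx = np.flatnonzero(mask)
        if len(idx) > n_keep:
            idx = rng.choice(idx, size=n_keep, replace=False)
        X = B[idx] - B[idx].mean(axis=0)
        evals = np.linalg.eigvalsh(np.cov(X, rowvar=False))[::-1]
        evals = np.maximum(evals, 0.0)
        cum = np.cumsum(evals) / evals.sum()
        out[f"n90_{name}"] = int(np.searchsorted(cum, var_target) + 1)
        out[f"auc_{name}"] = float(cum.mean())
    return out
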