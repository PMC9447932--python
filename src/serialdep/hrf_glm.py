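"""FIR deconvolution and voxel-wise hemodynamic modelling.

The front end of kernel-based decoding: estimate each voxel's average evoked
response to the stimulus and the probe with a finite-impulse-response (FIR)
deconvolution (30 taps = 24 s at TR 0.8 s), parameterize the estimated kernel
with a 6-parameter double-gamma function, and use the voxel-specific kernel
in a trial-wise GLM that simultaneously estimates the response amplitude of
every stimulus and probe event, removing linear carry-over from previous
trials.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
from scipy.optimize import least_squares
from scipy.stats import gamma as gamma_dist

__all__ = [
    "DoubleGammaParams",
    "double_gamma",
    "build_fir_design",
    "deconvolve",
    "fit_double_gamma",
    "trialwise_betas",
]

N_TAPS_DEFAULT = 30


@dataclasses.dataclass(frozen=True)
class DoubleGammaParams:
    """Difference-of-gammas HRF: 6 parameters.

    ``peak_delay`` / ``under_delay`` are the modes (s) of the positive lobe
    and the undershoot; ``peak_disp`` / ``under_disp`` their dispersions (s);
    ``ratio`` the undershoot-to-peak ratio; ``amplitude`` an overall scale.
    """

    peak_delay: float = 6.0
    peak_disp: float = 0.9
    under_delay: float = 16.0
    under_disp: float = 0.9
    ratio: float = 1.0 / 6.0
    amplitude: float = 1.0
    converged: bool = True  # False for voxels whose fit failed

    def as_array(self):
        return np.array([self.peak_delay, self.peak_disp, self.under_delay,
                         self.under_disp, self.ratio, self.amplitude])


def double_gamma(t, params: DoubleGammaParams | None = None):
    """Evaluate the double-gamma kernel at times ``t`` (s).

    Each lobe is a gamma density with mode ``delay`` and scale ``disp``
    (shape = 1 + delay/disp), so the kernel peaks near ``peak_delay``.
    """
    if params is None:
        params = DoubleGammaParams()
    t = np.asarray(t, dtype=float)
    pos = gamma_dist.pdf(t, 1.0 + params.peak_delay / params.peak_disp,
                         scale=params.peak_disp)
    neg = gamma_dist.pdf(t, 1.0 + params.under_delay / params.under_disp,
                         scale=params.under_disp)
    return params.amplitude * (pos - params.ratio * neg)


def canonical_hrf(tr=0.8, n_taps=N_TAPS_DEFAULT,
                  params: DoubleGammaParams | None = None):
    """Double-gamma kernel sampled on the TR grid, peak-normalized to 1."""
    h = double_gamma(np.arange(n_taps) * tr, params)
    return h / np.abs(h).max()


def build_fir_design(onsets_stim, onsets_probe, n_trs, block_bounds,
                     n_taps=N_TAPS_DEFAULT):
    """FIR design matrix: [stim taps | probe taps | per-block constants].

    ``onsets_stim`` / ``onsets_probe`` are TR indices; ``block_bounds`` is a
    sequence of (start, stop) TR index pairs (half-open).  Tap column k is the
    onset-indicator vector shifted forward by k TRs; entries are 0/1 and the
    column count is 2*n_taps + n_blocks.  Duplicate onsets within an event
    type are rejected.
    """
    onsets_stim = np.asarray(onsets_stim, dtype=int)
    onsets_probe = np.asarray(onsets_probe, dtype=int)
    for name, ons in (("stimulus", onsets_stim), ("probe", onsets_probe)):
        if len(np.unique(ons)) != len(ons):
            raise ValueError(f"duplicate {name} onsets produce identical "
                             "design columns")
        if np.any(ons < 0) or np.any(ons >= n_trs):
            raise ValueError(f"{name} onset outside the time series")
    n_blocks = len(block_bounds)
    X = np.zeros((n_trs, 2 * n_taps + n_blocks))
    for k in range(n_taps):
        rows = onsets_stim + k
        X[rows[rows < n_trs], k] = 1.0
        rows = onsets_probe + k
        X[rows[rows < n_trs], n_taps + k] = 1.0
    for b, (lo, hi) in enumerate(block_bounds):
        X[lo:hi, 2 * n_taps + b] = 1.0
    return X


def deconvolve(X, Y, n_taps=N_TAPS_DEFAULT):
    """Least-squares FIR estimate h = (X'X)^(-1) X'Y.

    Returns ``(h_stim, h_probe, constants)`` with tap-by-voxel kernels for
    the stimulus and probe event types.  A rank-deficient design falls back
    to the pseudo-inverse solution with a warning.
    """
    X = np.asarray(X, dtype=float)
    Y = np.atleast_2d(np.asarray(Y, dtype=float).T).T
    h, _, rank, _ = np.linalg.lstsq(X, Y, rcond=None)
    if rank < X.shape[1]:
        warnings.warn("FIR design is rank deficient; using the minimum-norm "
                      "least-squares solution", RuntimeWarning, stacklevel=2)
    return h[:n_taps], h[n_taps:2 * n_taps], h[2 * n_taps:]


_DG_BOUNDS = (np.array([1.0, 0.2, 4.0, 0.2, 0.0, -np.inf]),
              np.array([12.0, 3.0, 30.0, 5.0, 2.0, np.inf]))
_DG_STARTS = [
    np.array([6.0, 0.9, 16.0, 0.9, 1.0 / 6.0, 1.0]),
    np.array([4.5, 0.8, 11.0, 1.3, 0.35, 1.0]),
    np.array([7.5, 1.2, 20.0, 1.0, 0.1, 1.0]),
]


def fit_double_gamma(kernel, tr, r2_threshold=0.5) -> DoubleGammaParams:
    """Least-squares double-gamma parameterization of an FIR kernel.

    Runs from multiple starts (amplitude initialized from the kernel scale)
    and keeps the lowest-residual solution.  The fit is flagged
    ``converged=False`` -- for exclusion, never silent use -- if the best
    solution explains less than ``r2_threshold`` of the kernel variance.
    """
    kernel = np.asarray(kernel, dtype=float)
    if kernel.size < 6:
        raise ValueError("kernel must have at least 6 taps")
    t = np.arange(kernel.size) * tr
    scale = np.abs(kernel).max()
    if scale == 0:
        return DoubleGammaParams(amplitude=0.0, converged=False)

    def resid(p):
        return double_gamma(t, DoubleGammaParams(*p)) - kernel

    best = None
    for start in _DG_STARTS:
        x0 = start.copy()
        x0[5] = scale * np.sign(kernel[np.abs(kernel).argmax()])
        try:
            res = least_squares(resid, x0, bounds=_DG_BOUNDS)
        except Exception:
            continue
        if best is None or res.cost < best.cost:
            best = res
    if best is None:
        return DoubleGammaParams(converged=False)
    ss_res = 2.0 * best.cost
    ss_tot = ((kernel - kernel.mean()) ** 2).sum()
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 0.0
    return DoubleGammaParams(*best.x, converged=bool(best.success
                                                     and r2 >= r2_threshold))


def _event_design(onsets, n_trs, kernel_col):
    """Columns: one per event, the kernel placed at each onset (truncated)."""
    n_taps = kernel_col.size
    X = np.zeros((n_trs, len(onsets)))
    for j, o in enumerate(onsets):
        seg = min(n_taps, n_trs - o)
        X[o:o + seg, j] = kernel_col[:seg]
    return X


def trialwise_betas(Y, onsets_stim, onsets_probe, kernel, block_bounds):
    """Simultaneous per-trial stimulus and probe amplitudes via a GLM.

    ``Y`` is TR x voxel (or a single TR series); ``kernel`` is either one tap
    series shared by all voxels or a tap x voxel array of voxel-specific
    kernels.  The design holds one kernel-convolved delta column per stimulus
    and per probe event plus per-block constants; solving it by least squares
    removes linear contributions of previous stimulus/probe presentations.

    Returns ``(betas_stim, betas_probe)`` as trial x voxel arrays.
    """
    Y = np.asarray(Y, dtype=float)
    if Y.ndim == 1:
        Y = Y[:, None]
    n_trs, n_vox = Y.shape
    onsets_stim = np.asarray(onsets_stim, dtype=int)
    onsets_probe = np.asarray(onsets_probe, dtype=int)
    kernel = np.asarray(kernel, dtype=float)
    n_blocks = len(block_bounds)
    const = np.zeros((n_trs, n_blocks))
    for b, (lo, hi) in enumerate(block_bounds):
        const[lo:hi, b] = 1.0

    def solve(k, y):
        X = np.hstack([_event_design(onsets_stim, n_trs, k),
                       _event_design(onsets_probe, n_trs, k), const])
        beta, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
        if rank < X.shape[1]:
            warnings.warn("trial-wise design is rank deficient; minimum-norm "
                          "solution used", RuntimeWarning, stacklevel=3)
        return beta

    if kernel.ndim == 1:
        beta = solve(kernel, Y)
    else:
        beta = np.column_stack([solve(kernel[:, v], Y[:, v])
                                for v in range(n_vox)])
    n_tr = len(onsets_stim)
    return beta[:n_tr], beta[n_tr:n_tr + len(onsets_probe)]
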