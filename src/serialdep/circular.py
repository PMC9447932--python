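"""Circular helpers for 180-degree-periodic orientation data.

Orientation is periodic with period 180 deg, so all circular arithmetic uses
the doubled-angle convention: orientations are mapped onto the full circle by
doubling (deg -> 2*deg in radians), statistics are computed there, and angular
results are halved back to orientation degrees.  Spread measures (circular SD)
are left in doubled-radian units, matching the convention of reporting a
unitless sigma_circ in [0, inf).
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "wrap_ori",
    "ori_to_rad2",
    "rad2_to_ori",
    "circ_resultant",
    "circ_mean_ori",
    "circ_sd",
    "circ_corr_ori",
]


def wrap_ori(x):
    """Wrap an orientation difference (degrees) to the interval (-90, +90].

    180-degree periodic: wrap_ori(x + 180) == wrap_ori(x).
    """
    x = np.asarray(x, dtype=float)
    w = (x + 90.0) % 180.0 - 90.0
    w = np.where(w == -90.0, 90.0, w)
    return w if w.ndim else float(w)


def ori_to_rad2(deg):
    """Map orientation degrees to doubled-angle radians (full circle)."""
    return np.deg2rad(2.0 * np.asarray(deg, dtype=float))


def rad2_to_ori(rad2):
    """Map doubled-angle radians back to orientation degrees in [0, 180)."""
    return (np.rad2deg(np.asarray(rad2, dtype=float)) / 2.0) % 180.0


def _resultant_vector(deg):
    a = ori_to_rad2(np.asarray(deg, dtype=float))
    a = a[~np.isnan(a)]
    if a.size == 0:
        return np.nan + 0j, 0
    return np.exp(1j * a).mean(), a.size


def circ_resultant(deg):
    """Length |R| of the mean resultant vector of orientations (doubled space)."""
    z, n = _resultant_vector(deg)
    return float(np.abs(z)) if n else np.nan


def circ_mean_ori(deg):
    """Circular mean of orientation values/errors, in degrees in (-90, +90].

    NaN entries are ignored; an empty input or zero-length resultant gives NaN.
    """
    z, n = _resultant_vector(deg)
    if n == 0 or np.abs(z) < 1e-15:
        return np.nan
    return float(wrap_ori(np.rad2deg(np.angle(z)) / 2.0))


def circ_sd(deg):
    """Circular standard deviation sqrt(-2 ln|R|), unitless (doubled-radian).

    0 iff all values identical; grows without bound as the distribution
    approaches uniformity on the (doubled) circle.
    """
    r = circ_resultant(deg)
    if not np.isfinite(r):
        return np.nan
    r = min(max(r, 1e-300), 1.0)
    return float(np.sqrt(-2.0 * np.log(r)))


def circ_corr_ori(a, b):
    """Fisher-Lee circular correlation between two orientation samples.

    Both inputs are in orientation degrees; the statistic is computed on the
    doubled angles using the pairwise form

        r = sum_{i<j} sin(a_i - a_j) sin(b_i - b_j)
            / sqrt(sum_{i<j} sin^2(a_i - a_j) * sum_{i<j} sin^2(b_i - b_j)),

    which (unlike the mean-centered variant) remains well defined when a
    marginal is uniform on the circle -- the relevant case here, since the
    task presents orientations balanced across the space.  Pairs with a NaN
    in either input are dropped; requires at least 2 valid pairs.
    """
    a = ori_to_rad2(np.asarray(a, dtype=float))
    b = ori_to_rad2(np.asarray(b, dtype=float))
    ok = ~(np.isnan(a) | np.isnan(b))
    a, b = a[ok], b[ok]
    if a.size < 2:
        return np.nan
    sa = np.sin(a[:, None] - a[None, :])
    sb = np.sin(b[:, None] - b[None, :])
    denom = np.sqrt((sa**2).sum() * (sb**2).sum())
    if denom == 0:
        return np.nan
    return float((sa * sb).sum() / denom)
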