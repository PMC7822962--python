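"""Arithmetic and densities on the 180°-periodic orientation circle.

Orientation is a half-circular quantity: a grating rotated by 180° is
indistinguishable from the original, so orientations live on a circle of
period 180°. All circular computation here uses the standard angle-doubling
convention (multiply by 2, work on the full circle, map back), which makes
the report-noise distribution a true von Mises.

Conventions
-----------
* Orientations are degrees in ``(0, 180]``.
* Signed errors (response − target, flanker − target) are degrees in
  ``(−90, +90]``; the boundary value −90 is mapped to +90.
* The noise width ``sigma`` is the circular standard deviation of the
  doubled-angle distribution mapped back to orientation degrees
  (factor 90/π), so a fitted sigma is directly comparable to the
  ~10–20° widths typical of peripheral orientation reports.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq
from scipy.special import i0e, i1e

__all__ = [
    "PERIOD",
    "wrap_error",
    "wrap_orientation",
    "circ_diff",
    "sigma_to_kappa",
    "kappa_to_sigma",
    "vm_density",
    "sample_vm_noise",
    "CircularMoments",
    "circ_moments",
]

#: Period of the orientation space, in degrees.
PERIOD = 180.0

#: Degrees of orientation per radian of doubled angle.
_DEG_PER_RAD = 90.0 / np.pi


def _check_finite(x: np.ndarray, name: str) -> None:
    if not np.all(np.isfinite(x)):
        raise ValueError(f"{name} must be finite")


def wrap_error(raw_difference):
    """Wrap a raw angular difference to the signed-error range ``(−90, +90]``.

    Parameters
    ----------
    raw_difference : float or array-like
        Difference of two orientations, degrees; any finite value.

    Returns
    -------
    float or ndarray
        ``((x + 90) mod 180) − 90`` with the −90 boundary mapped to +90.
    """
    x = np.asarray(raw_difference, dtype=float)
    _check_finite(x, "raw_difference")
    wrapped = np.mod(x + 90.0, PERIOD) - 90.0
    wrapped = np.where(wrapped == -90.0, 90.0, wrapped)
    if np.isscalar(raw_difference) or x.ndim == 0:
        return float(wrapped)
    return wrapped


def wrap_orientation(value):
    """Wrap an angle in degrees to the orientation range ``(0, 180]``."""
    x = np.asarray(value, dtype=float)
    _check_finite(x, "value")
    wrapped = np.mod(x, PERIOD)
    wrapped = np.where(wrapped == 0.0, PERIOD, wrapped)
    if np.isscalar(value) or x.ndim == 0:
        return float(wrapped)
    return wrapped


def circ_diff(a, b):
    """Signed circular difference ``a − b`` on the orientation circle.

    Zero means the two orientations coincide; positive values mean ``a``
    is counter-clockwise of ``b`` by less than a quarter turn of the
    doubled circle.
    """
    return wrap_error(np.asarray(a, dtype=float) - np.asarray(b, dtype=float))


def kappa_to_sigma(kappa: float) -> float:
    """Circular SD (orientation degrees) of a von Mises with concentration kappa.

    Computed on the doubled-angle circle and mapped back:
    ``sigma = (90/π)·sqrt(−2·ln(I1(κ)/I0(κ)))``. ``kappa = 0`` gives the
    uniform distribution, whose circular SD is unbounded (returns ``inf``).
    """
    if kappa < 0:
        raise ValueError("kappa must be >= 0")
    if kappa == 0:
        return float("inf")
    # i1e/i0e is the mean resultant length R; exponential scaling cancels.
    r = i1e(kappa) / i0e(kappa)
    return float(_DEG_PER_RAD * np.sqrt(-2.0 * np.log(r)))


def sigma_to_kappa(sigma: float) -> float:
    """Numerically invert :func:`kappa_to_sigma` to better than 1e−8 degrees."""
    if not np.isfinite(sigma) or sigma <= 0:
        raise ValueError("sigma must be a positive finite number of degrees")
    # Target mean resultant length on the doubled circle.
    r_target = np.exp(-0.5 * (sigma / _DEG_PER_RAD) ** 2)
    if r_target < 5e-13:
        # numerically uniform regime: small-kappa expansion R ~ kappa/2
        return float(2.0 * r_target)

    def f(kappa):
        return i1e(kappa) / i0e(kappa) - r_target

    lo, hi = 1e-12, 10.0
    while f(hi) < 0:
        hi *= 10.0
        if hi > 1e12:  # pragma: no cover - sigma ~ 0 would be rejected above
            raise ValueError(f"sigma={sigma} is too small to invert")
    return float(brentq(f, lo, hi, xtol=1e-14, rtol=8.9e-16, maxiter=200))


def vm_density(error, sigma):
    """Von Mises density of a signed orientation error, per degree.

    ``f(θ) = exp(κ(σ)·cos(πθ/90)) / (180·I0(κ(σ)))`` — a zero-mean von
    Mises on the doubled-angle circle expressed per degree of orientation,
    so the integral over any 180° span is 1. Uses exponentially scaled
    Bessel evaluation so small sigma (large kappa) does not overflow.
    """
    if not np.isfinite(sigma) or sigma <= 0:
        raise ValueError("sigma must be a positive finite number of degrees")
    kappa = sigma_to_kappa(sigma)
    theta = np.asarray(error, dtype=float)
    dens = np.exp(kappa * (np.cos(theta / _DEG_PER_RAD) - 1.0)) / (PERIOD * i0e(kappa))
    if np.isscalar(error) or theta.ndim == 0:
        return float(dens)
    return dens


def vm_density_kappa(error, kappa):
    """Like :func:`vm_density` but parameterized directly by concentration."""
    theta = np.asarray(error, dtype=float)
    return np.exp(kappa * (np.cos(theta / _DEG_PER_RAD) - 1.0)) / (PERIOD * i0e(kappa))


def sample_vm_noise(rng: np.random.Generator, sigma: float, size=None):
    """Draw signed orientation errors from the zero-mean von Mises noise.

    Samples on the doubled-angle circle and maps back to orientation
    degrees in ``(−90, +90]``.
    """
    kappa = sigma_to_kappa(sigma)
    doubled = rng.vonmises(0.0, kappa, size=size)
    return wrap_error(doubled * _DEG_PER_RAD)


@dataclass(frozen=True)
class CircularMoments:
    """First and second moments of a sample of signed orientation errors.

    ``mean``/``sd``/``variance`` are the circular moments on the
    doubled-angle circle mapped back to orientation degrees; the
    ``linear_*`` fields are the ordinary sample moments of the signed
    errors, which practically coincide with the circular ones when the
    errors are concentrated well inside (−90, 90].
    """

    mean: float
    sd: float
    variance: float
    linear_mean: float
    linear_sd: float
    linear_variance: float
    n: int


def circ_moments(errors) -> CircularMoments:
    """Circular and linear moments of a list of signed errors (degrees)."""
    x = np.asarray(errors, dtype=float)
    _check_finite(x, "errors")
    if x.size < 2:
        raise ValueError("need at least 2 errors to compute moments")
    doubled = x / _DEG_PER_RAD
    z = np.mean(np.exp(1j * doubled))
    r = np.abs(z)
    circ_mean = wrap_error(np.angle(z) * _DEG_PER_RAD)
    if r >= 1.0:  # degenerate all-equal sample
        circ_sd = 0.0
    else:
        circ_sd = float(_DEG_PER_RAD * np.sqrt(-2.0 * np.log(r)))
    lin_var = float(np.var(x, ddof=1))
    return CircularMoments(
        mean=float(circ_mean),
        sd=circ_sd,
        variance=circ_sd**2,
        linear_mean=float(np.mean(x)),
        linear_sd=float(np.sqrt(lin_var)),
        linear_variance=lin_var,
        n=int(x.size),
    )
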