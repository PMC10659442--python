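"""Intensity model for the 1D birth-death-diffusion snapshot process.

A particle population is produced at a point source ``z`` inside an interval
``[0, L]`` at nondimensional rate ``lam``, diffuses with unit diffusivity,
degrades at rate ``mu``, and is absorbed (exported) at both interval ends.
The positions of particles alive at the observation instant form a spatial
Poisson point process whose intensity ``u`` solves the boundary-value problem

    0 = u''(x) + lam * delta(x - z) - mu * u(x),   u(0) = u(L) = 0.

This module provides the closed-form solution (the Dirichlet Green's function
of the 1D modified Helmholtz operator), its integral (the expected particle
count), analytic parameter derivatives, and a second-order finite-difference
solver used as an independent numerical oracle.

All rates are nondimensional: physical rates ``kappa`` are scaled by
``L0**2 / D`` (reference length squared over diffusivity), lengths by ``1/L0``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.linalg import solve_banded

__all__ = [
    "NondimParams",
    "DimensionalParams",
    "CellGeometry",
    "IntensityProfile",
    "nondimensionalize",
    "intensity",
    "intensity_shape",
    "expected_count",
    "integrated_shape",
    "cumulative_intensity",
    "dintensity_dmu",
    "solve_intensity_numeric",
]

# Below this, mu is treated as exactly zero and the Brownian-exit limit
# u = lam * min(x,z) * (L - max(x,z)) / L is used (the printed form is 0/0).
_MU_TINY = 1e-10

_LOG2 = float(np.log(2.0))


@dataclass(frozen=True)
class NondimParams:
    """Nondimensional birth rate ``lam`` and death rate ``mu``, the inference target."""

    lam: float
    mu: float

    def __post_init__(self) -> None:
        if not (np.isfinite(self.lam) and np.isfinite(self.mu)):
            raise ValueError("rates must be finite")
        if self.lam < 0 or self.mu < 0:
            raise ValueError("rates must be nonnegative")


@dataclass(frozen=True)
class DimensionalParams:
    """Physical birth/death rates (1/time), diffusivity (length^2/time), reference length."""

    kappa_plus: float
    kappa_minus: float
    D: float
    L0: float

    def __post_init__(self) -> None:
        if self.kappa_plus < 0 or self.kappa_minus < 0:
            raise ValueError("rates must be nonnegative")
        if not self.D > 0:
            raise ValueError("diffusivity D must be positive")
        if not self.L0 > 0:
            raise ValueError("reference length L0 must be positive")


@dataclass(frozen=True)
class CellGeometry:
    """Per-cell domain length ``L`` and source position ``z`` with 0 < z < L."""

    L: float
    z: float

    def __post_init__(self) -> None:
        if not self.L > 0:
            raise ValueError("domain length L must be positive")
        if not 0 < self.z < self.L:
            raise ValueError("source z must lie strictly inside (0, L)")


@dataclass(frozen=True)
class IntensityProfile:
    """Intensity values on an ordered grid spanning [0, L]."""

    grid: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        grid = np.asarray(self.grid, dtype=float)
        values = np.asarray(self.values, dtype=float)
        if grid.ndim != 1 or grid.shape != values.shape:
            raise ValueError("grid and values must be 1D arrays of equal length")
        if np.any(np.diff(grid) <= 0):
            raise ValueError("grid must be strictly increasing")
        object.__setattr__(self, "grid", grid)
        object.__setattr__(self, "values", values)


def nondimensionalize(p: DimensionalParams) -> NondimParams:
    """Rescale physical rates to nondimensional ones: ``rate * L0**2 / D``.

    The corresponding length rescaling (positions and domain lengths are
    multiplied by ``1 / L0``) is exposed as :func:`length_rescaling`.
    """
    scale = p.L0**2 / p.D
    return NondimParams(lam=p.kappa_plus * scale, mu=p.kappa_minus * scale)


def length_rescaling(p: DimensionalParams) -> float:
    """Factor converting physical lengths to nondimensional ones (``1 / L0``)."""
    return 1.0 / p.L0


def _log_sinh(y: np.ndarray) -> np.ndarray:
    """log(sinh(y)) for y > 0, overflow-safe: y + log1p(-exp(-2y)) - log 2."""
    y = np.asarray(y, dtype=float)
    with np.errstate(divide="ignore"):
        return y + np.log1p(-np.exp(-2.0 * y)) - _LOG2


def _log_cosh(y: np.ndarray) -> np.ndarray:
    """log(cosh(y)), overflow-safe."""
    y = np.abs(np.asarray(y, dtype=float))
    return y + np.log1p(np.exp(-2.0 * y)) - _LOG2


def _coth(y: np.ndarray) -> np.ndarray:
    """coth(y) for y > 0; tanh never overflows so this is stable everywhere."""
    return 1.0 / np.tanh(y)


def _check_position(x: np.ndarray, L: float) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    if np.any(x < 0) or np.any(x > L):
        raise ValueError("position outside the domain [0, L]")
    return x


def intensity_shape(x, mu: float, geom: CellGeometry):
    """Shape function ``v(x; mu)`` with ``u = lam * v`` (intensity per unit birth rate).

    For mu > 0 this is the Green's function
    ``sinh(s a) sinh(s b) / (s sinh(s L))`` with ``s = sqrt(mu)``,
    ``a = min(x, z)``, ``b = L - max(x, z)``; for mu ~ 0 the limit
    ``a b / L``.  Evaluated in log space so arguments up to ``s L ~ 700``
    stay finite.
    """
    L, z = geom.L, geom.z
    x = _check_position(x, L)
    a = np.minimum(x, z)
    b = L - np.maximum(x, z)
    if mu < _MU_TINY:
        return a * b / L
    s = np.sqrt(mu)
    with np.errstate(divide="ignore"):
        logv = _log_sinh(s * a) + _log_sinh(s * b) - _log_sinh(s * L) - np.log(s)
    return np.exp(logv)


def intensity(x, theta: NondimParams, geom: CellGeometry):
    """Point-process intensity ``u(x)`` (expected particles per unit length).

    Vanishes at both absorbing ends, is linear in ``lam``, continuous in ``x``
    with a derivative kink at the source ``z``.
    """
    return theta.lam * intensity_shape(x, theta.mu, geom)


def integrated_shape(mu: float, geom: CellGeometry) -> float:
    """``int_0^L v(x; mu) dx``, the expected count per unit birth rate.

    Equals ``(1/mu) * [1 - sech(s L/2) cosh(s (L - 2 z)/2)]`` for
    ``s = sqrt(mu) > 0`` and ``z (L - z) / 2`` in the mu -> 0 limit
    (birth rate times the mean Brownian exit time from the source).
    """
    L, z = geom.L, geom.z
    if mu < _MU_TINY:
        return z * (L - z) / 2.0
    s = np.sqrt(mu)
    # sech(sL/2) cosh(s(L-2z)/2) in log space
    log_geo = _log_cosh(s * (L - 2.0 * z) / 2.0) - _log_cosh(s * L / 2.0)
    return float(-np.expm1(log_geo)) / mu


def expected_count(theta: NondimParams, geom: CellGeometry) -> float:
    """Expected number of observed particles, ``E[N] = int_0^L u dx``."""
    return theta.lam * integrated_shape(theta.mu, geom)


def cumulative_intensity(x, theta: NondimParams, geom: CellGeometry):
    """``U(x) = int_0^x u(t) dt``; bin masses are differences of this function."""
    L, z = geom.L, geom.z
    x = _check_position(x, L)
    lam, mu = theta.lam, theta.mu
    if mu < _MU_TINY:
        total = lam * z * (L - z) / 2.0
        left = lam * (L - z) * np.square(np.minimum(x, z)) / (2.0 * L)
        right = total - lam * z * np.square(L - np.maximum(x, z)) / (2.0 * L)
        return np.where(x <= z, left, right)
    s = np.sqrt(mu)
    total = expected_count(theta, geom)
    with np.errstate(divide="ignore"):
        # int_0^x u = (lam/mu) * 2 sinh^2(s x/2) sinh(s (L-z)) / sinh(s L),  x <= z
        log_left = (
            _LOG2
            + 2.0 * _log_sinh(s * np.minimum(x, z) / 2.0)
            + _log_sinh(s * (L - z))
            - _log_sinh(s * L)
        )
        # int_x^L u = (lam/mu) * 2 sinh^2(s (L-x)/2) sinh(s z) / sinh(s L),  x >= z
        log_right = (
            _LOG2
            + 2.0 * _log_sinh(s * (L - np.maximum(x, z)) / 2.0)
            + _log_sinh(s * z)
            - _log_sinh(s * L)
        )
    left = lam / mu * np.exp(log_left)
    right = total - lam / mu * np.exp(log_right)
    return np.where(x <= z, left, right)


def dintensity_dmu(x, theta: NondimParams, geom: CellGeometry):
    """Analytic ``du/dmu``, from differentiating the log-space form of ``u``.

    With ``s = sqrt(mu)``:
    ``du/dmu = u/(2 s) * (a coth(s a) + b coth(s b) - L coth(s L) - 1/s)``.
    Finite differences are used only as a test oracle; near-singular
    information integrands amplify FD noise.
    """
    L, z = geom.L, geom.z
    x = _check_position(x, L)
    mu = theta.mu
    if mu < _MU_TINY:
        # Series limit: u = lam*a*b/L * (1 - mu*(a^2 + b^2 + ... )/6); use a
        # small central difference at a safe scale instead of the long series.
        h = 1e-6
        up = intensity(x, NondimParams(theta.lam, mu + h), geom)
        lo = intensity(x, NondimParams(theta.lam, max(mu - h, 0.0)), geom)
        return (up - lo) / (h + min(h, mu))
    s = np.sqrt(mu)
    a = np.minimum(x, z)
    b = L - np.maximum(x, z)
    u = intensity(x, theta, geom)
    with np.errstate(invalid="ignore"):
        factor = np.where(a > 0, a * _coth(s * np.maximum(a, 1e-300)), 0.0)
        factor = factor + np.where(b > 0, b * _coth(s * np.maximum(b, 1e-300)), 0.0)
    factor = factor - L * _coth(s * L) - 1.0 / s
    return u * factor / (2.0 * s)


def solve_intensity_numeric(
    theta: NondimParams, geom: CellGeometry, n_grid: int = 1024
) -> IntensityProfile:
    """Second-order finite-difference solution of the intensity BVP.

    Centered differences on a uniform grid with homogeneous Dirichlet ends;
    the point source is deposited on the two nodes bracketing ``z`` by linear
    ("hat-function") weights scaled by ``1/h``, which preserves O(h^2)
    convergence for off-grid sources.  Serves as the independent oracle for
    the closed form.
    """
    if n_grid < 16:
        raise ValueError("n_grid must be at least 16")
    L, z = geom.L, geom.z
    h = L / n_grid
    grid = np.linspace(0.0, L, n_grid + 1)
    n_int = n_grid - 1  # interior unknowns

    # Tridiagonal system: (u_{i-1} - 2 u_i + u_{i+1})/h^2 - mu u_i = -lam d_h(z)
    ab = np.zeros((3, n_int))
    ab[0, 1:] = 1.0 / h**2
    ab[1, :] = -2.0 / h**2 - theta.mu
    ab[2, :-1] = 1.0 / h**2

    rhs = np.zeros(n_int)
    j = min(int(z / h), n_grid - 1)
    w_right = z / h - j  # fraction of the mass on node j+1
    # interior node indices are 1..n_grid-1 -> unknown index i-1
    if 1 <= j <= n_grid - 1:
        rhs[j - 1] -= theta.lam * (1.0 - w_right) / h
    if 1 <= j + 1 <= n_grid - 1:
        rhs[j] -= theta.lam * w_right / h

    interior = solve_banded((1, 1), ab, rhs)
    values = np.zeros(n_grid + 1)
    values[1:-1] = interior
    return IntensityProfile(grid=grid, values=values)
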