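"""Fisher information of the snapshot point process and D-optimal design.

For a Poisson point process, the Campbell formula turns the expected negative
Hessian of the log-likelihood into a quadrature over the domain:

    I_ij = int_0^L (d_i u)(d_j u) / u dx,   d_i = d/d theta_i,  theta = (lam, mu).

Because u is linear in lam, ``d_lam u = u / lam`` and the (lam, lam) entry has
the closed form ``E[N] / lam^2``; the mu-derivative is analytic (see
:func:`poissnap.model.dintensity_dmu`).  The determinant of the 2x2 matrix is
the D-optimality score used to compare experimental geometries, and the
information for a heterogeneous cell population is the expectation of the
matrix over the geometry distribution (law of total expectation), computed by
tensorized Gaussian quadrature over the Beta law of z/L and the Gamma law of L.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import TYPE_CHECKING

import numpy as np
from scipy.integrate import quad
from scipy.special import roots_genlaguerre, roots_jacobi

from .likelihood import Partition
from .model import (
    CellGeometry,
    NondimParams,
    cumulative_intensity,
    dintensity_dmu,
    expected_count,
    intensity,
)

if TYPE_CHECKING:
    from .heterogeneity import HeterogeneityModel

__all__ = [
    "InfoMatrix",
    "fisher_information",
    "det_information",
    "heterogeneous_information",
    "binned_information",
    "information_lambda_closed_form",
]

# Adaptive quadrature tolerances; the kink at x = z is handled by splitting
# the panel there, so the integrands seen by quad are smooth.
_QUAD_KW = dict(epsabs=1e-12, epsrel=1e-11, limit=200)


@dataclass(frozen=True)
class InfoMatrix:
    """Symmetric positive-semidefinite 2x2 Fisher information over (lam, mu)."""

    I_ll: float
    I_lm: float
    I_mm: float

    def as_array(self) -> np.ndarray:
        return np.array([[self.I_ll, self.I_lm], [self.I_lm, self.I_mm]])

    @property
    def det(self) -> float:
        return self.I_ll * self.I_mm - self.I_lm**2

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.as_array())):
            raise ValueError("information entries must be finite")


def information_lambda_closed_form(theta: NondimParams, geom: CellGeometry) -> float:
    """Closed form of the (lam, lam) entry: ``E[N] / lam^2``.

    Equivalently ``(lam mu)^{-1} [1 - sech(s L/2) cosh(s (L - 2z)/2)]``.
    """
    return expected_count(theta, geom) / theta.lam**2


def _split_quad(f, z: float, L: float) -> float:
    left = quad(f, 0.0, z, **_QUAD_KW)[0]
    right = quad(f, z, L, **_QUAD_KW)[0]
    return left + right


def fisher_information(theta: NondimParams, geom: CellGeometry) -> InfoMatrix:
    """Single-cell information matrix by adaptive quadrature split at the source.

    Uses ``d_lam u = u / lam`` exactly; ``d_mu u`` analytically.  The
    (lam, lam) entry is returned from its closed form (the quadrature route is
    exercised in tests).
    """
    if not theta.lam > 0 or not theta.mu > 0:
        raise ValueError("information requires lam > 0 and mu > 0")
    lam = theta.lam
    z, L = geom.z, geom.L

    def du_dmu(x):
        return dintensity_dmu(x, theta, geom)

    I_ll = information_lambda_closed_form(theta, geom)
    # I_lm = int (u/lam) du_dmu / u = (1/lam) int du_dmu
    I_lm = _split_quad(lambda x: du_dmu(x), z, L) / lam
    I_mm = _split_quad(lambda x: du_dmu(x) ** 2 / intensity(x, theta, geom), z, L)
    return InfoMatrix(I_ll=I_ll, I_lm=I_lm, I_mm=I_mm)


def det_information(theta: NondimParams, geom: CellGeometry) -> float:
    """D-optimality score: determinant of the single-cell information matrix."""
    return fisher_information(theta, geom).det


def optimal_source_location(
    theta: NondimParams, L: float = 1.0, n_grid: int = 201
) -> float:
    """Source location maximizing det I on an ``n_grid``-point grid over (0, L).

    Ties break toward smaller z (deterministic).  For fast degradation the
    optimum is the domain center; for slow degradation it bifurcates to two
    symmetric off-center locations (the smaller is returned).
    """
    zs = np.linspace(0.0, L, n_grid + 2)[1:-1]
    dets = np.array([det_information(theta, CellGeometry(L=L, z=z)) for z in zs])
    return float(zs[int(np.argmax(dets))])


def _geometry_quadrature(het: "HeterogeneityModel", n_z: int, n_L: int):
    """Nodes (geometries) and normalized weights for E over the geometry law.

    z/L | L ~ Beta(1/sigma_z, 1/sigma_z) -> Gauss-Jacobi with exponents
    1/sigma_z - 1; L ~ Gamma(shape 1/sigma_L^2, scale sigma_L^2) ->
    generalized Gauss-Laguerre with alpha = shape - 1.  Degenerate spreads
    collapse to point masses at z = L/2 and L = 1.
    """
    if het.sigma_L > 0:
        shape = 1.0 / het.sigma_L**2
        nodes_L, w_L = roots_genlaguerre(n_L, shape - 1.0)
        L_vals = nodes_L * het.sigma_L**2
        w_L = w_L / w_L.sum()
    else:
        L_vals, w_L = np.array([1.0]), np.array([1.0])
    if het.sigma_z > 0:
        p = 1.0 / het.sigma_z
        nodes_t, w_t = roots_jacobi(n_z, p - 1.0, p - 1.0)
        t_vals = (nodes_t + 1.0) / 2.0  # z/L in (0, 1)
        w_t = w_t / w_t.sum()
    else:
        t_vals, w_t = np.array([0.5]), np.array([1.0])
    return L_vals, w_L, t_vals, w_t


def heterogeneous_information(
    theta: NondimParams,
    het: "HeterogeneityModel",
    n_z: int = 32,
    n_L: int = 32,
) -> InfoMatrix:
    """Population-averaged information ``E_geom[I(theta; z, L)]``.

    Tensorized Gaussian quadrature over the Beta law of the relative source
    location and the Gamma law of the domain length; spectral accuracy since
    the entries are smooth in (z, L).  Reduces to :func:`fisher_information`
    at zero spreads.
    """
    L_vals, w_L, t_vals, w_t = _geometry_quadrature(het, n_z, n_L)
    acc = np.zeros(3)
    for Lv, wl in zip(L_vals, w_L):
        for tv, wt in zip(t_vals, w_t):
            I = fisher_information(theta, CellGeometry(L=Lv, z=tv * Lv))
            acc += wl * wt * np.array([I.I_ll, I.I_lm, I.I_mm])
    return InfoMatrix(I_ll=acc[0], I_lm=acc[1], I_mm=acc[2])


def heterogeneous_information_mc(
    theta: NondimParams,
    het: "HeterogeneityModel",
    n_samples: int = 2000,
    seed: int | None = None,
) -> InfoMatrix:
    """Monte Carlo fallback for the geometry average (diagnostic cross-check)."""
    from .heterogeneity import sample_geometries

    geoms = sample_geometries(n_samples, het, seed=seed)
    acc = np.zeros(3)
    for g in geoms:
        I = fisher_information(theta, g)
        acc += np.array([I.I_ll, I.I_lm, I.I_mm])
    acc /= n_samples
    return InfoMatrix(I_ll=acc[0], I_lm=acc[1], I_mm=acc[2])


def binned_information(
    theta: NondimParams,
    part: Partition,
    geom: CellGeometry,
    which_param: str = "mu",
) -> float:
    """Scalar Fisher information of the binned (counts-per-bin) observation.

    ``I_bin = sum_j (int_{A_j} d_theta u)^2 / int_{A_j} u``.  By the
    Cauchy-Schwarz inequality this never exceeds the unbinned information,
    with exact equality for the scale parameter lam (``d_lam u`` proportional
    to u makes binning lossless for it).
    """
    if which_param not in ("lam", "mu"):
        raise ValueError("which_param must be 'lam' or 'mu'")
    masses = np.diff(cumulative_intensity(part.edges, theta, geom))
    if np.any(masses <= 0):
        raise ValueError("partition contains a bin with zero intensity mass")
    if which_param == "lam":
        d_masses = masses / theta.lam
    else:
        z = geom.z
        d_masses = np.empty(part.K)
        for j in range(part.K):
            lo, hi = part.edges[j], part.edges[j + 1]
            f = lambda x: dintensity_dmu(x, theta, geom)
            if lo < z < hi:
                d_masses[j] = quad(f, lo, z, **_QUAD_KW)[0] + quad(f, z, hi, **_QUAD_KW)[0]
            else:
                d_masses[j] = quad(f, lo, hi, **_QUAD_KW)[0]
    return float(np.sum(d_masses**2 / masses))


def unbinned_information(theta: NondimParams, geom: CellGeometry, which_param: str = "mu") -> float:
    """Scalar unbinned information for one parameter (diagonal of the matrix)."""
    I = fisher_information(theta, geom)
    return I.I_ll if which_param == "lam" else I.I_mm
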