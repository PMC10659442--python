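"""Where should the source sit for the most informative experiment?

Scans the D-optimality score det I (determinant of the Fisher information in
the birth and death rates) over source locations for slow and fast
degradation, and shows how geometric heterogeneity across cells shifts the
information budget.
"""

from poissnap import (
    HeterogeneityModel,
    NondimParams,
    heterogeneous_information,
    optimal_source_location,
)

for mu in (1.0, 100.0):
    theta = NondimParams(lam=500.0, mu=mu)
    z_star = optimal_source_location(theta, L=1.0)
    print(f"mu={mu:>5}: optimal source location z* = {z_star:.3f}")
# Fast degradation (mu=100) favors a centered source; slow degradation (mu=1)
# bifurcates to an off-center optimum (its mirror image is equally good).

print()
for mu in (1.0, 100.0):
    theta = NondimParams(lam=500.0, mu=mu)
    d_fixed = heterogeneous_information(theta, HeterogeneityModel(0.0, 0.0)).det
    d_spread = heterogeneous_information(theta, HeterogeneityModel(0.75, 0.0)).det
    verdict = "raises" if d_spread > d_fixed else "lowers"
    print(
        f"mu={mu:>5}: det E[I] fixed={d_fixed:.3e}  spread(sigma_z=0.75)={d_spread:.3e}"
        f"  -> source heterogeneity {verdict} information"
    )
# Cell-to-cell variation in source location *increases* the expected
# information when particles are long-lived (mu small) and decreases it when
# they are short-lived.
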