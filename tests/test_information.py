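"""Fisher information: quadrature vs closed form, Monte Carlo oracle, binning
inequality, and D-optimal design behavior."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.integrate import quad

from poissnap import (
    CellGeometry,
    HeterogeneityModel,
    NondimParams,
    Partition,
    binned_information,
    det_information,
    dintensity_dmu,
    expected_count,
    fisher_information,
    heterogeneous_information,
    heterogeneous_information_mc,
    information_lambda_closed_form,
    intensity,
    integrated_shape,
    optimal_source_location,
    sample_snapshot_direct,
    unbinned_information,
)

SWEEP = [
    (lam, mu, zfrac, L)
    for lam in (10.0, 500.0)
    for mu in (0.1, 1.0, 10.0, 100.0)
    for zfrac in (0.1, 0.3, 0.5, 0.7, 0.9)
    for L in (1.0,)
]


class TestFisherMatrix:
    @pytest.mark.parametrize("lam,mu,zfrac,L", SWEEP)
    def test_lambda_entry_quadrature_matches_closed_form(self, lam, mu, zfrac, L):
        """Quadrature of (d_lam u)^2 / u = u / lam^2 agrees with the closed
        form (lam mu)^-1 [1 - sech(sL/2) cosh(s(L-2z)/2)] to 1e-8 relative."""
        th = NondimParams(lam, mu)
        g = CellGeometry(L=L, z=zfrac * L)
        kw = dict(epsabs=1e-13, epsrel=1e-12)
        numeric = (
            quad(lambda x: intensity(x, th, g) / lam**2, 0, g.z, **kw)[0]
            + quad(lambda x: intensity(x, th, g) / lam**2, g.z, L, **kw)[0]
        )
        closed = information_lambda_closed_form(th, g)
        assert numeric == pytest.approx(closed, rel=1e-8)
        # and the identity I_ll = E[N] / lam^2
        assert closed == pytest.approx(expected_count(th, g) / lam**2, rel=1e-12)

    @pytest.mark.parametrize("lam,mu,zfrac,L", SWEEP)
    def test_entries_finite_positive_and_psd(self, lam, mu, zfrac, L):
        I = fisher_information(NondimParams(lam, mu), CellGeometry(L=L, z=zfrac * L))
        assert np.all(np.isfinite(I.as_array()))
        assert I.I_ll > 0 and I.I_mm > 0
        assert I.det >= -1e-12 * I.I_ll * I.I_mm

    def test_matches_monte_carlo_score_covariance(self, bench_theta, unit_geom):
        """The information equals the covariance of the score over snapshots;
        estimate it from 5000 direct draws and compare entrywise within 3 SE."""
        th, g = bench_theta, unit_geom
        rng = np.random.default_rng(12)
        dmu_E = (
            quad(lambda x: dintensity_dmu(x, th, g), 0, g.z)[0]
            + quad(lambda x: dintensity_dmu(x, th, g), g.z, g.L)[0]
        )
        V = integrated_shape(th.mu, g)
        scores = np.empty((5000, 2))
        for r in range(5000):
            s = sample_snapshot_direct(th, g, seed=rng)
            x = s.positions
            score_lam = s.count / th.lam - V
            score_mu = np.sum(dintensity_dmu(x, th, g) / intensity(x, th, g)) - dmu_E
            scores[r] = (score_lam, score_mu)
        I = fisher_information(th, g)
        prods = {
            (0, 0): scores[:, 0] ** 2,
            (0, 1): scores[:, 0] * scores[:, 1],
            (1, 1): scores[:, 1] ** 2,
        }
        target = {(0, 0): I.I_ll, (0, 1): I.I_lm, (1, 1): I.I_mm}
        for ij, p in prods.items():
            se = p.std() / np.sqrt(p.size)
            assert abs(p.mean() - target[ij]) < 3 * se, ij


class TestBinnedInformation:
    @pytest.mark.parametrize("K", [2, 4, 8, 16])
    def test_lambda_insensitive_to_binning(self, bench_theta, unit_geom, K):
        part = Partition.uniform(unit_geom.L, K)
        binned = binned_information(bench_theta, part, unit_geom, "lam")
        assert binned == pytest.approx(
            unbinned_information(bench_theta, unit_geom, "lam"), rel=1e-9
        )

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(data=st.data(), K=st.sampled_from([2, 4, 8, 16]))
    def test_binning_never_gains_information(self, data, K):
        """Cauchy-Schwarz: binned information <= unbinned, for random edges and
        both parameters."""
        theta = NondimParams(500.0, 10.0)
        geom = CellGeometry(1.0, 0.5)
        interior = sorted(
            data.draw(
                st.lists(
                    st.floats(0.02, 0.98), min_size=K - 1, max_size=K - 1, unique=True
                )
            )
        )
        part = Partition(np.array([0.0, *interior, 1.0]))
        for param in ("lam", "mu"):
            binned = binned_information(theta, part, geom, param)
            assert binned <= unbinned_information(theta, geom, param) + 1e-10

    def test_two_equal_bins_strictly_lose_mu_information(self, bench_theta, unit_geom):
        part = Partition.uniform(unit_geom.L, 2)
        binned = binned_information(bench_theta, part, unit_geom, "mu")
        assert binned < unbinned_information(bench_theta, unit_geom, "mu")

    def test_uniform_refinement_converges_to_unbinned(self, bench_theta, unit_geom):
        unbinned = unbinned_information(bench_theta, unit_geom, "mu")
        vals = [
            binned_information(bench_theta, Partition.uniform(1.0, K), unit_geom, "mu")
            for K in (2, 4, 8, 16, 32, 64)
        ]
        assert all(a < b for a, b in zip(vals, vals[1:]))  # monotone in nesting
        assert vals[-1] == pytest.approx(unbinned, rel=1e-3)


class TestDesign:
    def test_fast_degradation_favors_centered_source(self):
        th = NondimParams(500.0, 100.0)
        assert optimal_source_location(th, L=1.0) == pytest.approx(0.5, abs=0.01)

    def test_slow_degradation_bifurcates_to_off_center_optima(self):
        th = NondimParams(500.0, 1.0)
        zs = np.linspace(0.0, 1.0, 203)[1:-1]
        dets = np.array([det_information(th, CellGeometry(1.0, z)) for z in zs])
        z_star = zs[np.argmax(dets)]
        center = dets[np.argmin(np.abs(zs - 0.5))]
        assert z_star < 0.45  # clearly off-center
        assert dets.max() > center
        # the mirrored location is an equally good optimum
        mirror = dets[np.argmin(np.abs(zs - (1 - z_star)))]
        assert mirror == pytest.approx(dets.max(), rel=1e-6)

    def test_information_saturates_in_domain_length_at_large_mu(self):
        th = NondimParams(500.0, 100.0)
        d8 = det_information(th, CellGeometry(8.0, 4.0))
        d16 = det_information(th, CellGeometry(16.0, 8.0))
        assert abs(d16 - d8) / d8 < 0.01


class TestHeterogeneousInformation:
    def test_degenerate_spreads_recover_fixed_geometry(self, bench_theta, unit_geom):
        fixed = fisher_information(bench_theta, unit_geom)
        avg = heterogeneous_information(bench_theta, HeterogeneityModel(0.0, 0.0))
        np.testing.assert_allclose(avg.as_array(), fixed.as_array(), rtol=1e-6)

    def test_source_spread_raises_information_at_slow_degradation(self):
        th = NondimParams(500.0, 1.0)
        d0 = heterogeneous_information(th, HeterogeneityModel(0.0, 0.0)).det
        d75 = heterogeneous_information(th, HeterogeneityModel(0.75, 0.0)).det
        assert d75 > d0

    def test_source_spread_lowers_information_at_fast_degradation(self):
        th = NondimParams(500.0, 100.0)
        dets = [
            heterogeneous_information(th, HeterogeneityModel(sz, 0.0)).det
            for sz in (0.0, 0.25, 0.5, 0.75, 1.0)
        ]
        assert all(a > b for a, b in zip(dets, dets[1:]))

    def test_quadrature_agrees_with_monte_carlo_average(self):
        th = NondimParams(500.0, 1.0)
        het = HeterogeneityModel(0.75, 0.25)
        gq = heterogeneous_information(th, het)
        mc = heterogeneous_information_mc(th, het, n_samples=3000, seed=9)
        np.testing.assert_allclose(mc.as_array(), gq.as_array(), rtol=0.1)


def test_information_requires_positive_rates(unit_geom):
    with pytest.raises(ValueError):
        fisher_information(NondimParams(0.0, 1.0), unit_geom)
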