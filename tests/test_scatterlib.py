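"""Mie and infinite-cylinder single-scattering physics."""

import numpy as np
import pytest
from scipy import stats

from dermapol import polcore, scatterlib as sl
from .oracles import mie_qext_direct, rayleigh_qsca

M_REL = 1.4 / 1.33  # scatterer index relative to the interstitial medium
X_CYL = np.pi * 1.5 / (0.632 / 1.33)  # 1.5 um cylinder at 632 nm in tissue


class TestMie:
    def test_rayleigh_limit(self):
        _, qsca = sl.mie_efficiencies(0.01, M_REL)
        assert qsca == pytest.approx(rayleigh_qsca(0.01, M_REL), rel=0.01)

    def test_matches_independent_series(self):
        """Downward log-derivative recurrence vs direct upward evaluation."""
        qext, _ = sl.mie_efficiencies(10.0, 1.5)
        assert qext == pytest.approx(mie_qext_direct(10.0, 1.5, 40), abs=1e-8)

    def test_energy_conservation_real_index(self):
        for x in (0.5, 1.3, 5.0):
            qext, qsca = sl.mie_efficiencies(x, M_REL)
            assert qext >= qsca - 1e-12
            assert qext == pytest.approx(qsca, abs=1e-10)

    def test_coefficients_vanish_at_small_x(self):
        a, b = sl.mie_coefficients(1e-4, M_REL)
        assert np.max(np.abs(a)) < 1e-10
        assert np.max(np.abs(b)) < 1e-10

    def test_mueller_block_structure_and_physicality(self):
        th = np.linspace(0.0, 180.0, 91)
        M = sl.mie_mueller(1.32, M_REL, th)
        assert np.argmax(M[:, 0, 0]) == 0  # forward peak
        assert np.all(np.abs(M[:, 0, 1]) <= M[:, 0, 0] + 1e-12)
        np.testing.assert_allclose(M[:, 0, 1], M[:, 1, 0])
        np.testing.assert_allclose(M[:, 2, 2], M[:, 3, 3])
        np.testing.assert_allclose(M[:, 2, 3], -M[:, 3, 2])

    def test_rayleigh_polarization_at_90deg(self):
        M = sl.mie_mueller(0.01, M_REL, np.array([90.0]))[0]
        assert -M[0, 1] / M[0, 0] == pytest.approx(1.0, abs=1e-6)

    def test_scattering_matrices_map_physical_to_physical(self, rng):
        th = rng.uniform(0, 180, 20)
        for M in sl.mie_mueller(1.32, M_REL, th):
            assert polcore.validate_physical(M, tol=1e-9).ok


class TestCylinder:
    def test_cross_polarization_vanishes_at_normal_incidence(self):
        J = sl.cylinder_amplitudes(X_CYL, M_REL, 90.0, np.linspace(0, 359, 360))
        assert np.max(np.abs(J[:, 1, 0])) < 1e-12
        assert np.max(np.abs(J[:, 0, 1])) < 1e-12

    @pytest.mark.parametrize("zeta", [90.0, 60.0, 35.0])
    def test_optical_theorem(self, zeta):
        """Extinction from the forward amplitude equals the series extinction."""
        eff = sl.cylinder_efficiencies(X_CYL, M_REL, zeta)
        J0 = sl.cylinder_amplitudes(X_CYL, M_REL, zeta, np.array([0.0]))[0]
        assert (2.0 / X_CYL) * J0[0, 0].real == pytest.approx(
            eff["Qext_I"], rel=1e-6
        )
        assert (2.0 / X_CYL) * J0[1, 1].real == pytest.approx(
            eff["Qext_II"], rel=1e-6
        )
        # non-absorbing: Qext == Qsca
        assert eff["Qext_I"] == pytest.approx(eff["Qsca_I"], rel=1e-10)
        assert eff["Qext_II"] == pytest.approx(eff["Qsca_II"], rel=1e-10)

    @pytest.mark.parametrize("zeta", [90.0, 45.0])
    def test_energy_closure_by_quadrature(self, zeta):
        """Integrated differential cross-section equals the series total."""
        Th = np.linspace(0, 2 * np.pi, 4096, endpoint=False)
        J = sl.cylinder_amplitudes(X_CYL, M_REL, zeta, np.degrees(Th))
        eff = sl.cylinder_efficiencies(X_CYL, M_REL, zeta)
        qI = (2 / X_CYL) * np.mean(np.abs(J[:, 0, 0]) ** 2 + np.abs(J[:, 1, 0]) ** 2)
        qII = (2 / X_CYL) * np.mean(np.abs(J[:, 1, 1]) ** 2 + np.abs(J[:, 0, 1]) ** 2)
        assert qI == pytest.approx(eff["Qsca_I"], rel=1e-6)
        assert qII == pytest.approx(eff["Qsca_II"], rel=1e-6)

    def test_invalid_tilt_rejected(self):
        with pytest.raises(ValueError):
            sl.cylinder_coefficients(X_CYL, M_REL, 0.0)


class TestAmplitudeToMueller:
    def test_identity_and_quarter_wave(self):
        np.testing.assert_allclose(
            sl.amplitude_to_mueller(np.eye(2, dtype=complex)), np.eye(4), atol=1e-12
        )
        M = sl.amplitude_to_mueller(np.diag([1.0, 1j]))
        np.testing.assert_allclose(M, polcore.linear_retarder(90.0), atol=1e-12)


@pytest.fixture(scope="module")
def lookup():
    return sl.build_lookup(
        sl.SpherePopulation(), sl.CylinderPopulation(), n_theta=1800,
        n_zeta=180, n_Theta=720,
    )


class TestLookup:
    def test_cdfs_monotone_and_normalized(self, lookup):
        assert np.all(np.diff(lookup.sph_cdf) >= 0)
        assert lookup.sph_cdf[0] == 0.0 and lookup.sph_cdf[-1] == pytest.approx(1.0)
        assert np.all(np.diff(lookup.cyl_cdf, axis=1) >= 0)
        np.testing.assert_allclose(lookup.cyl_cdf[:, -1], 1.0)
        assert np.all(lookup.cyl_m11 >= 0)

    def test_deterministic_and_cached(self):
        a = sl.build_lookup(sl.SpherePopulation(), sl.CylinderPopulation())
        b = sl.build_lookup(sl.SpherePopulation(), sl.CylinderPopulation())
        assert a is b  # cache hit for identical configuration

    def test_sphere_sampling_reproduces_phase_function(self, lookup, rng):
        """Inverse-CDF samples agree with the tabulated phase function."""
        n = 1_000_000
        th = lookup.sample_sphere_theta(rng.random(n))
        edges = np.linspace(0, np.pi, 61)
        counts, _ = np.histogram(th, bins=edges)
        w = lookup.sph_mm[:, 0] * np.sin(lookup.sph_theta_rad)
        centers_idx = np.searchsorted(lookup.sph_theta_rad, 0.5 * (edges[:-1] + edges[1:]))
        # expected bin mass from the tabulated CDF itself
        cdf_at = np.interp(edges, lookup.sph_theta_rad, lookup.sph_cdf)
        expected = np.diff(cdf_at) * n
        keep = expected > 20
        chi2 = np.sum((counts[keep] - expected[keep]) ** 2 / expected[keep])
        p = stats.chi2.sf(chi2, np.sum(keep) - 1)
        assert p > 0.01, (chi2, p, w[centers_idx].sum())

    def test_mean_sphere_cos_matches_asymmetry_parameter(self, lookup, rng):
        th = lookup.sample_sphere_theta(rng.random(1_000_000))
        # weight by phase function is already in the CDF; plain mean applies
        assert np.mean(np.cos(th)) == pytest.approx(lookup.sph_g, abs=0.01)
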