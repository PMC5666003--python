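"""Sphere-cylinder-birefringence Monte Carlo engine.

Unit-scale checks (launch geometry, free paths, budget, reproducibility,
detection-cone nesting) run at small photon counts; the statistically heavy
isotropy-null and damage-trend checks live in the acceptance suite.
"""

import numpy as np
import pytest

from dermapol import polcore, scbm
from dermapol.scatterlib import CylinderPopulation, SpherePopulation


def small_config(**kw):
    defaults = dict(n_photons=20_000, seed=7)
    defaults.update(kw)
    return scbm.SimulationConfig(**defaults)


class TestLaunch:
    def test_normal_incidence_direction(self):
        np.testing.assert_allclose(scbm.launch_direction(0.0, 1.33), [0, 0, 1])

    def test_oblique_snell_refraction(self):
        u = scbm.launch_direction(15.0, 1.33)
        assert u[0] == pytest.approx(np.sin(np.deg2rad(15.0)) / 1.33)
        assert np.linalg.norm(u) == pytest.approx(1.0)
        assert u[2] == pytest.approx(np.cos(np.arcsin(np.sin(np.deg2rad(15)) / 1.33)))


class TestStepSampling:
    def test_free_path_mean(self, rng):
        paths = scbm.sample_free_paths(200.0, 1_000_000, rng)
        assert np.mean(paths) == pytest.approx(1.0 / 200.0, rel=0.01)

    def test_event_type_shares(self):
        cfg = small_config()
        assert cfg.p_sphere == pytest.approx(20.0 / 200.0)

    def test_shares_must_sum_to_total(self):
        with pytest.raises(ValueError, match="sum"):
            scbm.SimulationConfig(
                sphere=SpherePopulation(mus_share=50.0),
                cylinder=CylinderPopulation(mus_share=100.0),
            )


class TestBirefringence:
    def test_quarter_wave_accumulation(self):
        """Propagation ⊥ optic axis over λ/(4Δn) accumulates 90° retardance."""
        from dermapol import _kernels

        dn, lam_cm = 1e-4, 632e-7
        seg = lam_cm / (4 * dn)
        P = np.eye(4)
        u = np.array([0.0, 0.0, 1.0])
        m = np.array([1.0, 0.0, 0.0])
        n = np.array([0.0, 1.0, 0.0])
        _kernels._apply_birefringence(P, u, m, n, seg, dn, 1.0, 0.0, 0.0, lam_cm)
        np.testing.assert_allclose(P, polcore.linear_retarder(90.0), atol=1e-12)

    def test_propagation_parallel_to_axis_is_identity(self):
        from dermapol import _kernels

        P = np.eye(4)
        u = np.array([1.0, 0.0, 0.0])
        m = np.array([0.0, 0.0, 1.0])
        n = np.cross(u, m)
        _kernels._apply_birefringence(P, u, m, n, 1.0, 1e-4, 1.0, 0.0, 0.0, 632e-7)
        np.testing.assert_allclose(P, np.eye(4))

    def test_zero_birefringence_is_identity(self):
        from dermapol import _kernels

        P = np.eye(4)
        u = np.array([0.0, 0.0, 1.0])
        _kernels._apply_birefringence(
            P, u, np.array([1.0, 0, 0]), np.array([0.0, 1, 0]), 1.0, 0.0,
            1.0, 0.0, 0.0, 632e-7,
        )
        np.testing.assert_allclose(P, np.eye(4))


class TestRun:
    def test_photon_budget_identity(self):
        res = scbm.run(small_config())
        assert sum(res.budget.values()) == res.n_launched

    def test_budget_identity_matrix_estimator(self):
        res = scbm.run(small_config(estimator="matrix"))
        assert sum(res.budget.values()) == res.n_launched == 20_000

    def test_bit_reproducible(self):
        r1 = scbm.run(small_config())
        r2 = scbm.run(small_config())
        np.testing.assert_array_equal(r1.matrix, r2.matrix)
        assert r1.budget == r2.budget

    def test_different_seeds_differ(self):
        r1 = scbm.run(small_config(seed=1))
        r2 = scbm.run(small_config(seed=2))
        assert np.any(r1.matrix != r2.matrix)

    def test_no_cylinder_events_when_share_zero(self):
        # sphere-only run must be insensitive to the cylinder orientation
        base = dict(
            medium=scbm.Medium(birefringence=0.0),
            sphere=SpherePopulation(mus_share=200.0),
            n_photons=5_000,
        )
        r1 = scbm.run(small_config(
            cylinder=CylinderPopulation(mus_share=0.0, mean_axis_deg=0.0), **base
        ))
        r2 = scbm.run(small_config(
            cylinder=CylinderPopulation(mus_share=0.0, mean_axis_deg=60.0), **base
        ))
        np.testing.assert_array_equal(r1.matrix, r2.matrix)

    def test_acceptance_nested_in_cone_angle(self):
        """Smaller detection cones accept strictly fewer photons."""
        detected = []
        for cone in (90.0, 30.0, 10.0):
            cfg = small_config(beam=scbm.BeamGeometry(detection_cone_deg=cone))
            detected.append(scbm.run(cfg).n_detected)
        assert detected[0] > detected[1] > detected[2] > 0

    def test_zero_detections_raise(self):
        cfg = small_config(
            n_photons=4,
            beam=scbm.BeamGeometry(detection_cone_deg=0.5),
        )
        with pytest.raises(scbm.EmptyResultError, match="budget"):
            scbm.run(cfg)

    def test_normalized_output_and_A_range(self):
        res = scbm.run(small_config())
        assert res.matrix[0, 0] == 1.0
        assert 0.0 <= res.A <= 1.0


class TestOrientation:
    def test_alpha_tracks_fibre_axis(self):
        """α ≈ 4·(mean fibre axis), the MMT orientation relation, and A is
        insensitive to the axis (normal incidence for exact covariance)."""
        results = {}
        for axis in (0.0, 10.0, -20.0):
            cfg = scbm.SimulationConfig(
                beam=scbm.BeamGeometry(incidence_angle_deg=0.0),
                cylinder=CylinderPopulation(
                    mus_share=180.0, mean_axis_deg=axis, angular_std_deg=10.0
                ),
                n_photons=60_000,
                seed=13,
            )
            results[axis] = scbm.run(cfg)
        for axis, res in results.items():
            expected = polcore.wrap_alpha(4.0 * axis)
            diff = polcore.wrap_alpha(res.alpha_deg - expected)
            assert min(abs(diff), abs(abs(diff) - 180.0)) < 8.0
        A_vals = [r.A for r in results.values()]
        se = max(r.A_se for r in results.values())
        assert max(A_vals) - min(A_vals) < 6.0 * se + 0.02


class TestEstimatorCrossCheck:
    def test_matrix_and_stokes_agree(self):
        """The two independent transport estimators agree on the aggregate
        matrix within combined Monte Carlo uncertainty."""
        kw = dict(n_photons=60_000, seed=3)
        rs = scbm.run(scbm.SimulationConfig(estimator="stokes", **kw))
        rm = scbm.run(scbm.SimulationConfig(estimator="matrix", **kw))
        # block elements that carry the anisotropy signal
        for (i, j) in [(1, 1), (2, 2), (3, 3), (1, 0), (0, 1)]:
            assert rs.matrix[i, j] == pytest.approx(rm.matrix[i, j], abs=0.04), (i, j)
        assert rs.A == pytest.approx(rm.A, abs=3 * (rs.A_se + rm.A_se) + 0.01)


class TestDamageSweep:
    def test_preset_parameter_tables(self):
        assert scbm.PRESETS["no_sunscreen"][0] == (20.0, 180.0, 10.0)
        assert scbm.PRESETS["no_sunscreen"][3] == (50.0, 150.0, 22.0)
        assert scbm.PRESETS["sunscreen"][3] == (35.0, 165.0, 16.0)

    def test_unknown_preset_rejected(self):
        with pytest.raises(ValueError, match="unknown preset"):
            scbm.stage_configs("uv_proof")

    def test_stage_configs_fix_study_conditions(self):
        cfgs = scbm.stage_configs("sunscreen", n_photons=1000, seed=5)
        assert len(cfgs) == 4
        for cfg in cfgs:
            assert cfg.medium.birefringence == 1e-4
            assert cfg.medium.thickness_cm == 0.05
            assert cfg.medium.total_mus == 200.0
            assert cfg.sphere.diameter_um == 0.2
            assert cfg.cylinder.diameter_um == 1.5
            assert cfg.sphere.mus_share + cfg.cylinder.mus_share == 200.0
        assert [c.cylinder.angular_std_deg for c in cfgs] == [10.0, 12.0, 14.0, 16.0]

    def test_matched_seeds_across_presets(self):
        a = scbm.stage_configs("no_sunscreen", seed=9)
        b = scbm.stage_configs("sunscreen", seed=9)
        assert [c.seed for c in a] == [c.seed for c in b]

    def test_sweep_rows_structure(self):
        rows = scbm.damage_sweep("no_sunscreen", n_photons=8_000, seed=2)
        assert len(rows) == 4
        assert rows[0]["ratio"] == "20:180"
        assert rows[3]["sigma_deg"] == 22.0
        assert all(np.isfinite(r["A"]) for r in rows)
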