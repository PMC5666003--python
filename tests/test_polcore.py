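"""Stokes-Mueller algebra and the MMT anisotropy/orientation parameters."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from dermapol import polcore
from .conftest import random_physical_mueller


class TestNormalize:
    def test_scaling_removed_and_idempotent(self):
        M = 3.0 * np.eye(4)
        out = polcore.normalize_by_m11(M)
        np.testing.assert_allclose(out, np.eye(4))
        M2 = np.eye(4)
        M2[0, 0], M2[1, 1] = 2.0, 1.0
        out2 = polcore.normalize_by_m11(M2)
        assert out2[1, 1] == pytest.approx(0.5)
        np.testing.assert_allclose(
            polcore.normalize_by_m11(out2), out2, atol=1e-15
        )

    def test_nonpositive_m11_rejected(self):
        M = np.eye(4)
        M[0, 0] = 0.0
        with pytest.raises(polcore.DegenerateMatrixError):
            polcore.normalize_by_m11(M)


class TestMMTParameters:
    def test_identity_is_isotropic(self):
        assert polcore.mmt_A(np.eye(4)) == 0.0

    def test_quarter_wave_retarder_is_fully_anisotropic(self):
        # m22 = 1, m33 = 0 -> b = t = 0.5
        assert polcore.mmt_A(polcore.linear_retarder(90.0)) == pytest.approx(1.0)

    @pytest.mark.parametrize("delta", [10.0, 30.0, 45.0, 90.0, 120.0, 179.0])
    @pytest.mark.parametrize("theta", [-40.0, 0.0, 10.0, 30.0, 45.0])
    def test_retarder_closed_forms(self, delta, theta):
        """A and α of a pure linear retarder match b=(1+cosδ)/2, t=(1−cosδ)/2, α=4θ."""
        M = polcore.linear_retarder(delta, theta)
        b = (1.0 + np.cos(np.deg2rad(delta))) / 2.0
        t = (1.0 - np.cos(np.deg2rad(delta))) / 2.0
        A_expected = 2.0 * b * t / (b * b + t * t)
        assert polcore.mmt_A(M) == pytest.approx(A_expected, abs=1e-9)
        alpha_expected = polcore.wrap_alpha(4.0 * theta)
        assert polcore.mmt_alpha(M) == pytest.approx(alpha_expected, abs=1e-6)

    def test_retarder_30deg_value(self):
        # frozen from the closed form above: A(δ=30°) = 1/7
        assert polcore.mmt_A(polcore.linear_retarder(30.0, 22.0)) == pytest.approx(
            1.0 / 7.0, abs=1e-9
        )

    def test_alpha_examples(self):
        assert polcore.mmt_alpha(polcore.linear_retarder(60, 0)) == pytest.approx(0.0)
        assert polcore.mmt_alpha(polcore.linear_retarder(60, 10)) == pytest.approx(40.0)
        assert polcore.mmt_alpha(polcore.linear_retarder(60, 30)) == pytest.approx(-60.0)

    def test_degenerate_pixel_gives_nan_alpha_and_zero_A(self):
        M = polcore.isotropic_depolarizer(1.0)  # diag(1,0,0,0)
        assert polcore.mmt_A(M) == 0.0
        assert np.isnan(polcore.mmt_alpha(M))

    def test_vectorized_matches_scalar(self, physical_matrices):
        stack = physical_matrices(16)
        stack = polcore.normalize_by_m11(stack)
        A_vec = polcore.mmt_A(stack)
        a_vec = polcore.mmt_alpha(stack)
        for k in range(16):
            assert A_vec[k] == pytest.approx(polcore.mmt_A(stack[k]))
            av = polcore.mmt_alpha(stack[k])
            if np.isnan(av):
                assert np.isnan(a_vec[k])
            else:
                assert a_vec[k] == pytest.approx(av)


class TestRotation:
    def test_zero_rotation_and_identity(self, rng):
        M = random_physical_mueller(rng)
        np.testing.assert_allclose(polcore.rotate_sample_frame(M, 0.0), M)
        np.testing.assert_allclose(
            polcore.rotate_sample_frame(np.eye(4), 33.0), np.eye(4), atol=1e-15
        )

    @pytest.mark.parametrize("theta,phi", [(0.0, 17.0), (10.0, 45.0), (-30.0, 123.0)])
    def test_rotated_retarder_equals_directly_built(self, theta, phi):
        direct = polcore.linear_retarder(77.0, theta + phi)
        rotated = polcore.rotate_sample_frame(polcore.linear_retarder(77.0, theta), phi)
        np.testing.assert_allclose(rotated, direct, atol=1e-12)

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(
        phi=st.floats(-180, 180),
        seed=st.integers(0, 2**31 - 1),
    )
    def test_A_rotation_invariant_alpha_equivariant(self, phi, seed):
        """A is orientation-insensitive; α shifts by 4φ under sample rotation."""
        M = random_physical_mueller(np.random.default_rng(seed))
        M = polcore.normalize_by_m11(M)
        R = polcore.rotate_sample_frame(M, phi)
        assert polcore.mmt_A(R) == pytest.approx(polcore.mmt_A(M), abs=1e-9)
        a0, a1 = polcore.mmt_alpha(M), polcore.mmt_alpha(R)
        if not (np.isnan(a0) or np.isnan(a1)):
            expected = polcore.wrap_alpha(a0 + 4.0 * phi)
            diff = polcore.wrap_alpha(a1 - expected)
            # wrap-aware comparison (±90 is the same orientation point)
            assert min(abs(diff), abs(abs(diff) - 180.0)) < 1e-6


class TestBuildElement:
    def test_retarder_sign_convention(self):
        """Convention anchor: retarder(90°, 0°) maps (1,0,0,1) to (1,0,−1,0)."""
        out = polcore.linear_retarder(90.0, 0.0) @ np.array([1.0, 0.0, 0.0, 1.0])
        np.testing.assert_allclose(out, [1.0, 0.0, -1.0, 0.0], atol=1e-12)

    def test_zero_retardance_is_identity(self):
        np.testing.assert_allclose(
            polcore.build_element("linear_retarder", retardance_deg=0.0), np.eye(4)
        )

    def test_full_depolarizer(self):
        np.testing.assert_allclose(
            polcore.build_element("isotropic_depolarizer", depolarization=1.0),
            np.diag([1.0, 0.0, 0.0, 0.0]),
        )

    def test_ideal_polarizer(self):
        P = polcore.linear_diattenuator(1.0, 0.0)
        out = P @ np.array([1.0, 0.0, 0.0, 0.0])
        np.testing.assert_allclose(out, [1.0, 1.0, 0.0, 0.0])

    @pytest.mark.parametrize(
        "kind,params",
        [
            ("linear_diattenuator", {"diattenuation": 1.5}),
            ("isotropic_depolarizer", {"depolarization": -0.1}),
            ("no_such_element", {}),
        ],
    )
    def test_invalid_parameters_rejected(self, kind, params):
        with pytest.raises(ValueError):
            polcore.build_element(kind, **params)


class TestValidatePhysical:
    def test_identity_passes(self):
        assert polcore.validate_physical(np.eye(4)).ok

    def test_overpolarizing_matrix_fails(self):
        M = np.eye(4)
        M[1, 1] = 2.0
        report = polcore.validate_physical(M)
        assert not report.ok
        assert report.messages

    def test_every_built_element_passes(self, physical_matrices):
        for M in physical_matrices(50):
            assert polcore.validate_physical(M, tol=1e-9).ok
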