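import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from chinpaint import (
    PhaseField,
    build_fidelity,
    convex_split,
    convex_split_derivatives,
    discrete_free_energy,
    double_well,
    double_well_prime,
    laplacian_noflux,
)
from chinpaint.phasefield import ConfigError, ShapeError


class TestDoubleWell:
    @pytest.mark.parametrize(
        "phi, expected",
        [(1.0, 0.0), (-1.0, 0.0), (0.0, 0.25), (3.0, 16.0)],
    )
    def test_known_values(self, phi, expected):
        assert double_well(phi) == pytest.approx(expected)

    def test_nonnegative_with_minima_at_pure_phases(self, rng):
        phi = rng.uniform(-3, 3, 1000)
        h = double_well(phi)
        assert np.all(h >= 0)
        assert double_well(np.array([-1.0, 1.0])) == pytest.approx([0.0, 0.0])

    def test_rejects_non_finite(self):
        with pytest.raises(ValueError):
            double_well(np.nan)
        with pytest.raises(ValueError):
            convex_split_derivatives(np.inf)


class TestConvexSplit:
    @pytest.mark.parametrize(
        "phi, expected",
        [(1.0, (1.0, 1.0)), (0.0, (0.0, 0.0)), (-2.0, (-8.0, -2.0))],
    )
    def test_derivative_values(self, phi, expected):
        assert convex_split_derivatives(phi) == pytest.approx(expected)

    @given(st.floats(-3, 3))
    @settings(max_examples=200)
    def test_split_identity(self, phi):
        """H_c' - H_e' reconstructs H' = phi^3 - phi exactly."""
        hc_p, he_p = convex_split_derivatives(phi)
        assert hc_p - he_p == pytest.approx(double_well_prime(phi), abs=1e-12)

    def test_split_reconstructs_potential(self, rng):
        phi = rng.uniform(-3, 3, 10_000)
        hc, he = convex_split(phi)
        np.testing.assert_allclose(hc - he, double_well(phi), atol=1e-12)
        hc_p, he_p = convex_split_derivatives(phi)
        np.testing.assert_allclose(hc_p - he_p, double_well_prime(phi), atol=1e-12)


class TestLaplacian:
    def test_constant_grid_maps_to_zero(self):
        out = laplacian_noflux(np.full((7, 5), 3.2))
        np.testing.assert_allclose(out, 0.0, atol=1e-14)

    def test_center_impulse_stencil(self):
        g = np.zeros((3, 3))
        g[1, 1] = 1.0
        out = laplacian_noflux(g, 1.0, 1.0)
        expected = np.array([[0.0, 1.0, 0.0], [1.0, -4.0, 1.0], [0.0, 1.0, 0.0]])
        np.testing.assert_allclose(out, expected)

    @pytest.mark.parametrize("shape", [(1, 1), (1, 8), (8, 1), (16, 16), (64, 64)])
    def test_conservativity(self, rng, shape):
        """No-flux ghosts make the discrete Laplacian sum to zero."""
        g = rng.normal(size=shape)
        total = laplacian_noflux(g).sum()
        assert abs(total) <= 1e-10 * max(1.0, np.abs(g).sum())

    def test_transpose_symmetry(self, rng):
        g = rng.normal(size=(12, 12))
        np.testing.assert_allclose(laplacian_noflux(g).T, laplacian_noflux(g.T), atol=1e-13)

    def test_anisotropic_cell_sizes(self):
        g = np.zeros((1, 3))
        g[0, 1] = 1.0
        out = laplacian_noflux(g, dx=0.5, dy=1.0)
        np.testing.assert_allclose(out, [[4.0, -8.0, 4.0]])

    def test_rejects_bad_cell_size(self):
        with pytest.raises(ConfigError):
            laplacian_noflux(np.zeros((3, 3)), dx=0.0)


class TestFreeEnergy:
    @pytest.mark.parametrize("value", [-1.0, 1.0])
    def test_zero_on_pure_phases(self, value):
        fld = PhaseField(np.full((10, 10), value))
        assert discrete_free_energy(fld, 1.5) == 0.0

    def test_uniform_zero_field(self):
        fld = PhaseField(np.zeros((6, 8)))
        assert discrete_free_energy(fld, 2.0) == pytest.approx(0.25 * 48)

    def test_two_cell_interface(self):
        # bulk 0 + 0.5 * eps^2 * (jump/dx)^2 * area = 0.5 * 4 = 2
        fld = PhaseField(np.array([[-1.0, 1.0]]))
        assert discrete_free_energy(fld, 1.0) == pytest.approx(2.0)

    def test_nonnegative_and_transpose_invariant(self, rng):
        vals = rng.uniform(-2, 2, (9, 9))
        e = discrete_free_energy(PhaseField(vals), 1.0)
        assert e >= 0
        assert discrete_free_energy(PhaseField(vals.T), 1.0) == pytest.approx(e)

    def test_rejects_bad_eps(self):
        with pytest.raises(ConfigError):
            discrete_free_energy(PhaseField(np.zeros((2, 2))), 0.0)


class TestFidelity:
    def test_uniform_when_no_damage(self):
        fid = build_fidelity(np.zeros((4, 4), bool), 1000.0)
        np.testing.assert_array_equal(fid.lam, np.full((4, 4), 1000.0))

    def test_zero_when_all_damaged(self):
        fid = build_fidelity(np.ones((4, 4), bool), 123.0)
        np.testing.assert_array_equal(fid.lam, np.zeros((4, 4)))

    def test_checkerboard_pattern(self):
        mask = np.array([[True, False], [False, True]])
        fid = build_fidelity(mask, 9000.0)
        np.testing.assert_array_equal(fid.lam, [[0.0, 9000.0], [9000.0, 0.0]])

    def test_lam_zero_exactly_on_mask(self, rng):
        mask = rng.random((15, 11)) < 0.3
        fid = build_fidelity(mask, 77.0)
        assert np.all(fid.lam[mask] == 0.0)
        assert np.all(fid.lam[~mask] == 77.0)

    def test_shape_and_sign_errors(self):
        with pytest.raises(ShapeError):
            build_fidelity(np.zeros((2, 3), bool), 1.0, shape=(3, 2))
        with pytest.raises(ConfigError):
            build_fidelity(np.zeros((2, 2), bool), -1.0)


class TestPhaseFieldType:
    def test_rejects_non_finite_and_bad_sizes(self):
        with pytest.raises(ValueError):
            PhaseField(np.array([[np.nan, 1.0]]))
        with pytest.raises(ConfigError):
            PhaseField(np.zeros((2, 2)), dx=-1.0)

    def test_shape_properties(self):
        fld = PhaseField(np.zeros((3, 5)), dx=0.5, dy=2.0)
        assert (fld.ny, fld.nx) == (3, 5)
        assert fld.cell_area == pytest.approx(1.0)
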