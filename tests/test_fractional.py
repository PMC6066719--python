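"""Spectral operator tests: symbol, eigenmodes, propagator, stability."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fracatrial.fractional import (DEALIAS_FRAC, FractionalOrder, SpectralGrid,
                                   StabilityError, apply_H,
                                   diffusion_propagator, max_stable_beta,
                                   spectral_symbol)

SHEET_DX = 0.03215        # cm, reference sheet spacing


@pytest.mark.parametrize("alpha,beta", [(2.0, 0.0), (1.5, 0.2), (1.1, 0.28)])
def test_symbol_is_minus_one_at_unit_wavenumber(alpha, beta):
    # ln 1 = 0, so the log-periodic factor drops out at k = 1 rad/cm
    s = spectral_symbol(np.array([1.0]), FractionalOrder(alpha, beta))
    assert s[0] == pytest.approx(-1.0)


def test_symbol_classical_limit():
    s = spectral_symbol(np.array([0.0, 2.0]), FractionalOrder(2.0, 0.0))
    assert s[0] == 0.0
    assert s[1] == pytest.approx(-4.0)


@settings(max_examples=50, deadline=None)
@given(k=st.floats(1e-3, 1e3), alpha=st.floats(1.01, 2.0))
def test_symbol_pure_power_law_at_zero_beta(k, alpha):
    s = spectral_symbol(np.array([k]), FractionalOrder(alpha, 0.0))
    assert s[0] == pytest.approx(-k ** alpha, rel=1e-12)


class TestApplyH:
    def test_constant_field_annihilated(self):
        grid = SpectralGrid(N=64, dx=0.02)
        out = apply_H(np.full(64, 3.7), grid, FractionalOrder(1.6, 0.2))
        assert np.abs(out).max() < 1e-10

    @pytest.mark.parametrize("alpha,beta", [(2.0, 0.0), (1.4, 0.25)])
    def test_periodic_sine_eigenfunction(self, alpha, beta):
        """sin(k0 x) is an exact eigenfunction with eigenvalue s(k0)."""
        grid = SpectralGrid(N=128, dx=2.0 / 128)
        x = np.arange(128) * grid.dx
        k0 = 2.0 * np.pi * 3 / grid.L
        order = FractionalOrder(alpha, beta)
        out = apply_H(np.sin(k0 * x), grid, order, boundary="periodic")
        lam = spectral_symbol(np.array([k0]), order)[0]
        assert np.allclose(out, lam * np.sin(k0 * x), rtol=1e-8, atol=1e-8)

    def test_neumann_cosine_eigenfunction(self):
        """DCT modes cos(k_m (x + dx/2)) are eigenfunctions of the mirror
        extension operator."""
        grid = SpectralGrid(N=64, dx=0.03)
        x = (np.arange(64) + 0.5) * grid.dx
        k0 = grid.wavenumbers()[5]
        order = FractionalOrder(1.7, 0.1)
        f = np.cos(k0 * x)
        out = apply_H(f, grid, order)
        lam = spectral_symbol(np.array([k0]), order)[0]
        assert np.allclose(out, lam * f, rtol=1e-8, atol=1e-8)

    def test_matches_finite_difference_laplacian(self):
        """At gamma = 2 + j0 the operator is the classical Laplacian."""
        def error(N):
            grid = SpectralGrid(N=N, dx=2.0 / N)
            x = (np.arange(N) + 0.5) * grid.dx
            f = np.exp(-((x - 1.0) / 0.25) ** 2)
            out = apply_H(f, grid, FractionalOrder(2.0, 0.0))
            fd = np.empty_like(f)
            fd[1:-1] = (f[2:] - 2 * f[1:-1] + f[:-2]) / grid.dx ** 2
            fd[0] = (f[1] - f[0]) / grid.dx ** 2       # zero-flux edges
            fd[-1] = (f[-2] - f[-1]) / grid.dx ** 2
            return np.abs(out - fd)[2:-2].max()

        e1, e2 = error(128), error(256)
        assert e1 < 0.5                    # small absolute error
        assert e1 / e2 == pytest.approx(4.0, rel=0.5)   # O(dx^2) refinement

    def test_output_is_real_array(self):
        grid = SpectralGrid(N=32, dx=0.05)
        out = apply_H(np.sin(np.arange(32)), grid, FractionalOrder(1.5, 0.2))
        assert out.dtype.kind == "f"

    def test_2d_separable_sum(self):
        grid = SpectralGrid(N=32, dx=0.05, ndim=2)
        x = (np.arange(32) + 0.5) * grid.dx
        kx = grid.wavenumbers()[3]
        f = np.outer(np.ones(32), np.cos(kx * x))   # varies along x only
        order = FractionalOrder(1.8, 0.1)
        out = apply_H(f, grid, order)
        lam = spectral_symbol(np.array([kx]), order)[0]
        assert np.allclose(out, lam * f, rtol=1e-8, atol=1e-8)

    def test_shape_mismatch_rejected(self):
        grid = SpectralGrid(N=32, dx=0.05)
        with pytest.raises(ValueError):
            apply_H(np.zeros(16), grid, FractionalOrder())


class TestPropagator:
    def test_zero_kappa_is_identity(self):
        grid = SpectralGrid(N=64, dx=0.02)
        prop = diffusion_propagator(grid, FractionalOrder(1.5, 0.2), 0.0, 0.01)
        f = np.sin(np.linspace(0, 5, 64))
        assert np.array_equal(prop(f), f)

    def test_semigroup_property(self):
        grid = SpectralGrid(N=64, dx=0.02)
        order = FractionalOrder(1.6, 0.15)
        p1 = diffusion_propagator(grid, order, 1.0, 0.7)
        p2 = diffusion_propagator(grid, order, 1.0, 0.3)
        p12 = diffusion_propagator(grid, order, 1.0, 1.0)
        f = np.exp(-((np.arange(64) - 30.0) / 6.0) ** 2)
        assert np.allclose(p2(p1(f)), p12(f), rtol=1e-12, atol=1e-12)

    def test_sine_mode_decay_closed_form(self):
        grid = SpectralGrid(N=128, dx=0.02)
        order = FractionalOrder(1.8, 0.1)
        kappa, t = 0.8, 40.0              # cm^2/s, ms
        x = (np.arange(128) + 0.5) * grid.dx
        k0 = grid.wavenumbers()[7]
        f = np.cos(k0 * x)
        prop = diffusion_propagator(grid, order, kappa, t)
        lam = spectral_symbol(np.array([k0]), order)[0]
        assert np.allclose(prop(f), np.exp(kappa * 1e-3 * lam * t) * f,
                           rtol=1e-10, atol=1e-10)

    def test_mean_conservation(self):
        grid = SpectralGrid(N=64, dx=0.03, ndim=2)
        prop = diffusion_propagator(grid, FractionalOrder(1.3, 0.2), 2.0, 5.0)
        rng = np.random.default_rng(7)
        f = rng.normal(size=(64, 64))
        assert prop(f).mean() == pytest.approx(f.mean(), rel=1e-10)

    def test_contraction(self):
        grid = SpectralGrid(N=64, dx=0.03)
        prop = diffusion_propagator(grid, FractionalOrder(1.5, 0.25), 1.0, 1.0)
        assert np.all(prop.factor <= 1.0 + 1e-15)
        f = np.sin(np.linspace(0, 20, 64))
        assert np.linalg.norm(prop(f)) <= np.linalg.norm(f) + 1e-12

    def test_unstable_beta_refused(self):
        grid = SpectralGrid(N=128, dx=0.0156)
        with pytest.raises(StabilityError, match="beta"):
            diffusion_propagator(grid, FractionalOrder(1.5, 0.5), 1.0, 0.01)


class TestStabilityBound:
    def test_reference_grid_bound(self):
        """beta_max ~ 0.34 at the 321.5-um sheet spacing (rad/cm modes)."""
        grid = SpectralGrid(N=128, dx=SHEET_DX, ndim=2)
        bmax = max_stable_beta(grid)
        assert bmax == pytest.approx(0.343, abs=0.005)
        assert bmax > 0.28

    def test_beta_zero_always_stable(self):
        for dx in (0.001, 0.03, 1.0):
            grid = SpectralGrid(N=64, dx=dx)
            diffusion_propagator(grid, FractionalOrder(1.2, 0.0), 1.0, 0.01)

    def test_coarser_grid_admits_larger_beta(self):
        b_fine = max_stable_beta(SpectralGrid(N=128, dx=0.01))
        b_coarse = max_stable_beta(SpectralGrid(N=128, dx=0.03))
        assert b_coarse > b_fine

    def test_tissue_scheme_bound_admits_published_beta(self):
        """Under the tissue convention (k-unit scale 2, 2/3 low-pass) the
        156.25-um strand admits beta = 0.28 with almost no margin."""
        grid = SpectralGrid(N=128, dx=2.0 / 128)
        bmax = max_stable_beta(grid, k_scale=2.0, lowpass_frac=DEALIAS_FRAC)
        assert 0.28 < bmax < 0.285


def test_fractional_order_validation():
    with pytest.raises(ValueError):
        FractionalOrder(alpha=0.9)
    with pytest.raises(ValueError):
        FractionalOrder(alpha=2.5)
    with pytest.raises(ValueError):
        FractionalOrder(alpha=1.5, beta=-0.1)
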