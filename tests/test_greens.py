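"""Green-function module: continued fraction, Laplace and Fourier
inversions, validated against closed forms and limits."""

import math

import numpy as np
import pytest

from wlcbuckle.greens import (FractionParams, GreensError, continued_fraction,
                              default_r_grid, find_poles, greens_K_N,
                              greens_r_N, mean_square_r, radial_green,
                              stiff_eta_density, _theta_series)


class TestContinuedFraction:
    @pytest.mark.parametrize("p", [0.5, 2.5, 1 + 2j])
    def test_zero_wavevector_is_pure_pole(self, p):
        assert continued_fraction(FractionParams(K=0.0, p=p)) == pytest.approx(1.0 / p)

    def test_hand_evaluated_truncation(self):
        # 1/(1 + (1/3)/(3 + (4/15)/7)) with a1^2 = 1/3, a2^2 = 4/15
        val = continued_fraction(FractionParams(K=1.0, p=1.0, l_max=2))
        assert val == pytest.approx(319.0 / 354.0, rel=1e-15)

    def test_large_p_leading_behavior(self):
        p = 1e8
        val = continued_fraction(FractionParams(K=3.0, p=p, l_max=80))
        assert val == pytest.approx(1.0 / p, rel=1e-6)

    def test_truncation_converged(self):
        a = continued_fraction(FractionParams(K=7.0, p=2.0, l_max=60))
        b = continued_fraction(FractionParams(K=7.0, p=2.0, l_max=65))
        assert abs(a - b) <= 1e-12 * abs(b)

    def test_validation(self):
        with pytest.raises(ValueError):
            FractionParams(K=-1.0, p=1.0)
        with pytest.raises(ValueError):
            FractionParams(K=1.0, p=1.0, l_max=0)


class TestPoles:
    def test_zero_wavevector_poles(self):
        pe = find_poles(0.0, n_poles=3)
        assert np.allclose(pe.poles.real, [0.0, -2.0, -6.0], atol=1e-10)
        assert np.allclose(pe.poles.imag, 0.0, atol=1e-10)
        assert pe.residues[0] == pytest.approx(1.0, abs=1e-12)
        assert abs(pe.residues[1]) < 1e-12

    def test_leading_pole_is_a_pole(self):
        pe = find_poles(0.5, n_poles=3)
        p0 = complex(pe.poles[0]) + 1e-6
        val = continued_fraction(FractionParams(K=0.5, p=p0, l_max=200))
        assert abs(val) > 1e4

    def test_residue_sum_reproduces_rigid_rod(self):
        # at N -> 0 the expansion must rebuild j0(K N)
        K, N = 2.0, 1e-3
        pe = find_poles(K, n_poles=80)
        val = complex(np.sum(pe.residues * np.exp(pe.poles * N)))
        assert val.real == pytest.approx(np.sinc(K * N / np.pi), abs=1e-4)

    def test_input_validation(self):
        with pytest.raises(ValueError):
            find_poles(-1.0)
        with pytest.raises(ValueError):
            find_poles(1.0, n_poles=0)


class TestGreensKN:
    def test_K_zero_is_one(self):
        assert greens_K_N(0.0, 0.7) == 1.0

    @pytest.mark.parametrize("K", [0.5, 2.0, 5.0])
    def test_rigid_rod_limit(self, K):
        N = 1e-3
        assert greens_K_N(K, N) == pytest.approx(np.sinc(K * N / np.pi), abs=1e-4)

    def test_small_K_expansion_gives_second_moment(self):
        K = 1e-3
        m2 = (1.0 - greens_K_N(K, 1.0)) * 6.0 / K ** 2
        assert m2 == pytest.approx(mean_square_r(1.0), rel=1e-4)

    @pytest.mark.parametrize("K,N", [(2.0, 0.5), (20.0, 0.25), (50.0, 1.0)])
    def test_residue_contour_cross_check(self, K, N):
        a = greens_K_N(K, N, method="residue")
        b = greens_K_N(K, N, method="contour")
        assert a == pytest.approx(b, rel=1e-8)

    def test_unknown_method(self):
        with pytest.raises(ValueError):
            greens_K_N(1.0, 1.0, method="nope")


class TestMeanSquareR:
    def test_closed_form_values(self):
        assert mean_square_r(1.0) == pytest.approx(0.5676676416183064, rel=1e-12)
        assert mean_square_r(0.25) == pytest.approx(0.25 - (1 - math.exp(-0.5)) / 2,
                                                    rel=1e-12)

    def test_rod_limit(self):
        for N in (1e-4, 1e-3):
            assert mean_square_r(N) == pytest.approx(N * N, rel=5e-3)


class TestRadialDistribution:
    @pytest.mark.parametrize("N", [0.25, 1.0, 2.0])
    def test_normalization(self, N, rg_by_N):
        rg = rg_by_N(N)
        assert abs(rg.norm_check - 1.0) < 1e-3

    @pytest.mark.parametrize("N", [0.25, 1.0, 2.0])
    def test_second_moment_matches_closed_form(self, N, rg_by_N):
        rg = rg_by_N(N)
        assert rg.second_moment == pytest.approx(mean_square_r(N), rel=1e-3)

    def test_gaussian_limit_shape(self, rg_by_N):
        # flexible chains approach the Gaussian with matching <r^2>;
        # the sup-norm deviation decays like 1/N (measured: 0.23 of the
        # peak at N=4, below 0.1 by N=8)
        def dev(N):
            rg = rg_by_N(N)
            m2 = mean_square_r(N)
            r = rg.r_grid
            gauss = 4 * np.pi * r ** 2 * (3 / (2 * np.pi * m2)) ** 1.5 \
                * np.exp(-3 * r ** 2 / (2 * m2))
            return np.max(np.abs(rg.density - gauss)) / np.max(rg.density)

        d4, d8 = dev(4.0), dev(8.0)
        assert d8 < d4 < 0.3
        assert d8 < 0.1

    def test_support_contract(self, rg025):
        # the radial density vanishes toward full extension
        tail = rg025.density[rg025.r_grid > 0.999 * 0.25]
        assert np.all(tail < 1e-3 * np.max(rg025.density))

    def test_density_nonnegative(self, rg025, rg1):
        for rg in (rg025, rg1):
            assert np.min(rg.density) >= 0.0

    def test_F0_infinite_outside_credible(self, rg025):
        F0 = rg025.F0()
        assert np.all(np.isfinite(F0[rg025.credible]))

    def test_grid_validation(self):
        with pytest.raises(ValueError):
            greens_r_N(1.0, r_grid=np.array([0.0, 0.5]))
        with pytest.raises(ValueError):
            greens_r_N(-1.0)

    def test_default_grid_interior_and_stretched(self):
        g = default_r_grid(2.0, 100)
        assert g[0] > 0 and g[-1] < 2.0
        # square-root stretch: spacing shrinks toward r = N
        d = np.diff(g)
        assert d[-1] < d[0]


class TestStiffLimit:
    def test_theta_series_branches_agree(self):
        x = np.array([0.55, 0.6, 0.65])
        direct = np.array([sum((-1) ** (k + 1) * k * k * math.exp(-k * k * xx)
                               for k in range(1, 60)) for xx in x])
        assert np.allclose(_theta_series(x), direct, rtol=1e-12)

    def test_stiff_density_normalized_and_peaked(self):
        N = 0.01
        rg = radial_green(N, r_points=800)
        assert rg.method == "stiff"
        assert abs(rg.norm_check - 1.0) < 1e-3
        # mean retraction <eta> = N^2/3 in 2 lp units
        eta = N - rg.r_grid
        mean_eta = np.trapezoid(eta * rg.density, rg.r_grid) / \
            np.trapezoid(rg.density, rg.r_grid)
        assert mean_eta == pytest.approx(N ** 2 / 3.0, rel=5e-2)

    def test_stiff_matches_exact_at_threshold_scale(self, rg025):
        # At N = 0.25 the weakly-bending form is an O(N) approximation of
        # the exact density: same peak location to a few percent.
        N = 0.25
        dens_stiff = stiff_eta_density(N, N - rg025.r_grid)
        r_pk_exact = rg025.r_grid[np.argmax(rg025.density)]
        r_pk_stiff = rg025.r_grid[np.argmax(dens_stiff)]
        assert r_pk_stiff == pytest.approx(r_pk_exact, rel=0.05)
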