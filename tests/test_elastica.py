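"""Euler elastica reference: printed formula, elliptic solution, and the
brute-force discrete-segment oracle."""

import math

import numpy as np
import pytest

from wlcbuckle.chain import ChainSpec
from wlcbuckle.elastica import (discrete_elastica_fixed_R,
                                discrete_elastica_fixed_f,
                                elastica_extension, euler_force,
                                euler_force_dimensionless,
                                min_bend_energy_at_R)


class TestEulerForce:
    def test_L_equals_lp(self):
        ch = ChainSpec(L=1.0, lp=1.0, kBT=1.0)
        assert euler_force(ch) == pytest.approx(math.pi ** 2)

    def test_dimensionless_form(self):
        assert euler_force_dimensionless(1.0) == pytest.approx(math.pi ** 2 / 2.0,
                                                               rel=1e-15)

    def test_inverse_square_scaling(self):
        ch1 = ChainSpec(L=1.0, lp=3.0)
        ch2 = ChainSpec(L=2.0, lp=3.0)
        assert euler_force(ch1) == pytest.approx(4.0 * euler_force(ch2), rel=1e-15)


class TestExtension:
    def test_straight_below_threshold(self):
        ch = ChainSpec.from_dimensionless(0.5)
        fE = euler_force_dimensionless(0.5)
        for fr in (-1.0, 0.0, 0.5, 1.0):
            assert elastica_extension(ch, fr * fE) == 1.0

    def test_continuous_at_threshold(self):
        ch = ChainSpec.from_dimensionless(0.5)
        fE = euler_force_dimensionless(0.5)
        assert elastica_extension(ch, fE * (1 + 1e-9)) == pytest.approx(1.0, abs=1e-4)

    def test_slope_discontinuity_second_order(self):
        # slope ~ 0 below fE, finite above: the transition is second order
        ch = ChainSpec.from_dimensionless(0.5)
        fE = euler_force_dimensionless(0.5)
        eps = 0.01 * fE
        below = (elastica_extension(ch, fE - eps) - elastica_extension(ch, fE - 2 * eps)) / eps
        above = (elastica_extension(ch, fE + 2 * eps) - elastica_extension(ch, fE + eps)) / eps
        assert below == 0.0
        assert above < -0.1 / fE

    @pytest.mark.parametrize("fr", [1.5, 2.0])
    def test_matches_discrete_minimizer(self, fr):
        ch = ChainSpec.from_dimensionless(0.25)
        fE = euler_force_dimensionless(0.25)
        ext = elastica_extension(ch, fr * fE)
        d = discrete_elastica_fixed_f(0.25, fr * fE)
        assert d["extension"] == pytest.approx(ext, rel=1e-3)


class TestConstrainedEnergy:
    def test_straight_rod_zero_energy(self):
        ch = ChainSpec.from_dimensionless(0.25)
        sol = min_bend_energy_at_R(ch, 0.25)
        assert sol.bend_energy == 0.0
        assert np.all(sol.theta == 0.0)

    def test_discrete_oracle_agreement(self):
        ch = ChainSpec.from_dimensionless(0.25)
        sol = min_bend_energy_at_R(ch, 0.9 * 0.25)
        d = discrete_elastica_fixed_R(0.25, 0.9 * 0.25)
        assert d["bend_energy"] == pytest.approx(sol.bend_energy, rel=1e-3)

    def test_small_retraction_linear_in_euler_force(self):
        # EB ~ fE (L - R) near full extension (second-order energetics)
        N = 0.4
        ch = ChainSpec.from_dimensionless(N)
        fE = euler_force_dimensionless(N)
        sol = min_bend_energy_at_R(ch, 0.99 * N)
        assert sol.bend_energy == pytest.approx(fE * 0.01 * N, rel=2e-2)

    def test_monotone_energy_growth(self):
        ch = ChainSpec.from_dimensionless(0.5)
        rl = np.linspace(0.3, 0.999, 30)
        eb = np.array([min_bend_energy_at_R(ch, x * 0.5).bend_energy for x in rl])
        assert np.all(np.diff(eb) < 0)  # energy falls as extension grows

    def test_extension_quadrature_consistency(self):
        ch = ChainSpec.from_dimensionless(0.5)
        sol = min_bend_energy_at_R(ch, 0.7 * 0.5, n_s=4001)
        assert sol.verify_extension() == pytest.approx(sol.extension, abs=1e-6)

    def test_invalid_R(self):
        ch = ChainSpec.from_dimensionless(0.5)
        with pytest.raises(ValueError):
            min_bend_energy_at_R(ch, -0.1)
        with pytest.raises(ValueError):
            min_bend_energy_at_R(ch, 0.6)

    def test_legendre_pair_consistency(self):
        # d(EB)/d(L-R) equals the constraint force returned by the
        # parametric solution (conjugate-variable check)
        N = 0.5
        ch = ChainSpec.from_dimensionless(N)
        rl = np.linspace(0.55, 0.95, 20)
        eb = np.array([min_bend_energy_at_R(ch, x * N).bend_energy for x in rl])
        fpar = np.array([min_bend_energy_at_R(ch, x * N).f for x in rl])
        dEdRet = -np.gradient(eb, rl * N)
        interior = slice(2, -2)
        assert np.allclose(dEdRet[interior], fpar[interior], rtol=1e-2)
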