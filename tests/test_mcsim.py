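"""Discretized-chain Monte Carlo: geometry, energies, ensembles,
analytic free-chain oracles and reproducibility."""

import math

import numpy as np
import pytest
from scipy import stats

from wlcbuckle._mckernels import mc_sweeps
from wlcbuckle.greens import mean_square_r
from wlcbuckle.mcsim import (DiscreteChain, MCConfig, bending_energy,
                             build_chain, empirical_green,
                             empirical_reference_energy,
                             entropy_decomposition, free_chain_energy,
                             freely_rotating_r2, joint_angle_cdf,
                             joint_cos_mean, mc_fixed_R, mc_fixed_f,
                             reference_energy)

FAST = MCConfig(n_equil=4000, n_sweeps=40_000, sample_stride=10, seed=12345)


class TestGeometry:
    def test_straight_chain(self):
        ch = build_chain(0.25, 51, 0.25)
        assert ch.end_distance() == pytest.approx(0.25, abs=1e-14)
        assert bending_energy(ch) == pytest.approx(0.0, abs=1e-9)

    def test_arc_chord_exact(self):
        ch = build_chain(0.25, 51, 0.125)
        assert ch.end_distance() == pytest.approx(0.125, abs=1e-12)
        np.testing.assert_allclose(ch.bond_lengths(), ch.ds, rtol=1e-14)

    def test_segment_parameters(self):
        ch = build_chain(0.25, 51, 0.25)
        assert ch.ds == pytest.approx(0.005)
        assert ch.k_bend == pytest.approx(100.0)

    def test_inextensibility_guard(self):
        with pytest.raises(ValueError):
            build_chain(0.25, 51, 0.3)
        with pytest.raises(ValueError):
            build_chain(0.25, 4, 0.2)

    def test_single_joint_energy(self):
        # one bent joint contributes k (1 - cos theta)
        ch = build_chain(1.0, 5, 1.0)
        theta = 0.3
        pos = ch.positions.copy()
        ds = ch.ds
        # bend the last bond by theta in-plane
        pos[-1] = pos[-2] + ds * np.array([math.cos(theta), math.sin(theta), 0.0])
        bent = DiscreteChain(1.0, 5, pos)
        assert bending_energy(bent) == pytest.approx(
            bent.k_bend * (1 - math.cos(theta)), rel=1e-12)

    def test_semicircle_continuum_energy(self):
        # polygon with every joint turned by pi/(Nb-2) versus the
        # continuum arc of the matching length
        Nb, N = 51, 0.25
        ds = N / (Nb - 1)
        beta = math.pi / (Nb - 2)
        ang = (np.arange(Nb - 1) - (Nb - 2) / 2) * beta
        pos = np.vstack([[0, 0, 0], np.cumsum(
            ds * np.column_stack([np.cos(ang), np.sin(ang), np.zeros(Nb - 1)]),
            axis=0)])
        ch = DiscreteChain(N, Nb, pos)
        e = bending_energy(ch)
        kappa = 0.5
        arc_len = (Nb - 2) * ds
        e_cont = kappa * math.pi ** 2 / (2 * arc_len)
        assert e == pytest.approx(e_cont, rel=1e-2)


class TestEnsembles:
    def test_fixed_R_constraint_and_acceptance(self):
        ch = build_chain(0.25, 31, 0.2)
        run = mc_fixed_R(ch, 0.2, FAST)
        assert 0.0 < run.acceptance_rate < 1.0
        assert run.ensemble == "fixed_R"

    def test_fixed_R_validation(self):
        ch = build_chain(0.25, 31, 0.2)
        with pytest.raises(ValueError):
            mc_fixed_R(ch, 0.15, FAST)          # mismatched start
        ch2 = build_chain(0.25, 31, 0.25 * (1 - 1e-8))
        with pytest.raises(ValueError):
            mc_fixed_R(ch2, 0.25 * (1 - 1e-8), FAST)  # non-ergodic corner

    def test_seed_reproducibility(self):
        r1 = mc_fixed_f(build_chain(0.5, 11, 0.5), 1.0, FAST)
        r2 = mc_fixed_f(build_chain(0.5, 11, 0.5), 1.0, FAST)
        assert np.array_equal(r1.Epoly_samples, r2.Epoly_samples)
        assert np.array_equal(r1.R_samples, r2.R_samples)

    def test_free_chain_energy_oracle(self):
        chain = build_chain(1.0, 21, 1.0)
        run = mc_fixed_f(chain, 0.0, FAST)
        exact = free_chain_energy(21, chain.k_bend)
        assert abs(run.Epoly_mean - exact) < 3 * run.Epoly_sem

    def test_free_chain_r2_oracle(self):
        chain = build_chain(1.0, 21, 1.0)
        run = mc_fixed_f(chain, 0.0, FAST)
        r2, sem = run.R2_stats()
        exact = freely_rotating_r2(21, chain.k_bend, chain.ds)
        assert abs(r2 - exact) < 3 * sem
        # discrete closed form sits within O(ds) of the continuum value
        assert exact == pytest.approx(mean_square_r(1.0), abs=2 * chain.ds)

    def test_compression_retracts_post_buckling(self):
        # N = 0.25: f/fE = 2 retracts far more than f/fE = 0.67
        from wlcbuckle.elastica import euler_force_dimensionless
        fE = euler_force_dimensionless(0.25)
        cfg = MCConfig(n_equil=6000, n_sweeps=60_000, seed=7)
        r_lo, _ = mc_fixed_f(build_chain(0.25, 31, 0.25), 0.67 * fE, cfg).R_stats()
        r_hi, _ = mc_fixed_f(build_chain(0.25, 31, 0.25), 2.0 * fE, cfg).R_stats()
        assert r_hi < r_lo - 0.1 * 0.25

    def test_freely_jointed_crankshaft_vs_rejection(self):
        # k = 0, fixed ends: crankshaft sampling must reproduce the
        # freely jointed fixed-end ensemble (rejection-sampling oracle)
        Nb, N = 7, 1.0
        R = 0.4 * N
        ds = N / (Nb - 1)
        ch = build_chain(N, Nb, R)
        ch = DiscreteChain(N, Nb, ch.positions, k_bend_override=0.0)
        cfg = MCConfig(n_equil=2000, n_sweeps=60_000, sample_stride=5, seed=21)
        pos = ch.positions
        scratch = np.empty_like(pos)
        mids = []
        n_samples = cfg.n_sweeps // cfg.sample_stride
        for s in range(n_samples):
            mc_sweeps(pos, 0.0, ds, 0.0, False, 2.5, cfg.sample_stride,
                      (cfg.seed + s) % 2 ** 31, scratch)
            mids.append(np.linalg.norm(pos[3] - pos[0]))
        mids = np.asarray(mids)
        # rejection oracle: free chains conditioned on the end distance
        rng = np.random.default_rng(99)
        keep = []
        for _ in range(200):
            v = rng.normal(size=(4000, Nb - 1, 3))
            v /= np.linalg.norm(v, axis=2, keepdims=True)
            pos_f = np.cumsum(v * ds, axis=1)
            ends = np.linalg.norm(pos_f[:, -1], axis=1)
            sel = np.abs(ends - R) < 0.02 * N
            keep.append(np.linalg.norm(pos_f[sel, 2], axis=1))
            if sum(len(kk) for kk in keep) > 4000:
                break
        oracle = np.concatenate(keep)
        # compare means and spreads with generous combined error bars
        sem_mc = np.std(mids) / math.sqrt(len(mids) / 20.0)
        sem_or = np.std(oracle) / math.sqrt(len(oracle))
        assert abs(np.mean(mids) - np.mean(oracle)) < 4 * (sem_mc + sem_or)
        assert np.std(mids) == pytest.approx(np.std(oracle), rel=0.15)


class TestJointDistribution:
    def test_detailed_balance_single_joint(self):
        # joint bend angle of a short free chain follows
        # p(theta) ~ sin(theta) exp(-k (1 - cos theta))
        Nb, N = 5, 0.5
        ch = build_chain(N, Nb, N)
        k = ch.k_bend
        ds = ch.ds
        pos = ch.positions
        scratch = np.empty_like(pos)
        angles = []
        # stride chosen long enough that successive joint samples are
        # decorrelated (KS requires independent draws)
        for s in range(20_000):
            mc_sweeps(pos, k, ds, 0.0, True, 1.2, 10, (77 + s) % 2 ** 31, scratch)
            u = np.diff(pos, axis=0) / ds
            cosang = float(np.dot(u[1], u[2]))
            angles.append(math.acos(max(-1.0, min(1.0, cosang))))
        angles = np.asarray(angles)
        stat = stats.kstest(angles, lambda t: joint_angle_cdf(t, k)).statistic
        assert stat < 1.63 / math.sqrt(len(angles))


class TestReferenceEnergy:
    def test_printed_convention(self):
        assert reference_energy(51) == pytest.approx(117.5)
        assert reference_energy(4) == 0.0

    def test_empirical_mode_needs_three_counts(self):
        with pytest.raises(ValueError):
            empirical_reference_energy(0.25, 0.2, [11, 31])

    def test_empirical_slope_near_one_per_bead(self):
        # rigid-bond chains carry ~1 kBT per bead of equipartition
        # energy; the fit exposes the difference from the (5/2)-slope
        # convention instead of hiding it
        fit = empirical_reference_energy(
            0.25, 0.8 * 0.25, [11, 31, 51],
            MCConfig(n_equil=5000, n_sweeps=60_000, seed=31))
        assert fit.slope == pytest.approx(1.0, abs=0.1)
        assert abs(fit.slope - 2.5) > 1.0
        assert fit(4) == 0.0


class TestThermoPieces:
    def test_entropy_identity(self):
        d = entropy_decomposition(10.0, 4.0, 2.5)
        assert d.S_times_T == pytest.approx(3.5)
        assert d.identity_residual() == pytest.approx(0.0, abs=1e-14)
        d0 = entropy_decomposition(6.5, 4.0, 2.5)
        assert d0.S_times_T == pytest.approx(0.0)

    def test_closed_form_consistency(self):
        # <E_joint> = k(1 + 1/k - coth k) and <cos> = coth k - 1/k agree
        for k in (2.0, 10.0, 100.0):
            e = free_chain_energy(3, k)
            assert e == pytest.approx(k * (1 - joint_cos_mean(k)), rel=1e-10)


class TestEmpiricalGreen:
    def test_normalized_histogram(self):
        rng = np.random.default_rng(0)
        samples = rng.uniform(0.1, 0.9, 50_000)
        eg = empirical_green(samples, 20, 1.0)
        width = eg.bin_centers[1] - eg.bin_centers[0]
        assert np.sum(eg.density) * width == pytest.approx(1.0, rel=1e-12)
        assert eg.warning == ""

    def test_small_sample_warning(self):
        eg = empirical_green(np.ones(100) * 0.5, 10, 1.0)
        assert "samples" in eg.warning
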