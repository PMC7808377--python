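"""Monte Carlo engine tests: move proposals, Metropolis rule, sweep
bookkeeping, determinism, pinning protocol, and Boltzmann fidelity against
analytic references."""
import numpy as np
import pytest
from scipy import integrate, stats

import laminachain as lc
from laminachain.engine import _ball_draws, run_replicate

from conftest import short_schedule


class TestProposeMove:
    def test_within_move_radius(self, params, rng):
        st = lc.initialize_chain(params)
        for _ in range(200):
            new = lc.propose_move(st, 5, rng, params)
            assert np.linalg.norm(new - st.coords[5]) <= params.move_radius

    def test_mean_displacement_of_uniform_ball(self, rng):
        # mean |u| of uniform sampling in a ball of radius R is 3R/4
        draws = _ball_draws(rng, 100_000, 3.0)
        mean = np.linalg.norm(draws, axis=1).mean()
        assert mean == pytest.approx(2.25, abs=0.01)

    def test_pinned_bead_rejected(self, params, rng):
        st = lc.initialize_chain(params)
        with pytest.raises(ValueError, match="pinned"):
            lc.propose_move(st, 0, rng, params)

    def test_deterministic_given_seed(self, params):
        st = lc.initialize_chain(params)
        a = [lc.propose_move(st, 3, np.random.default_rng(5), params)
             for _ in range(1)]
        b = [lc.propose_move(st, 3, np.random.default_rng(5), params)
             for _ in range(1)]
        assert np.array_equal(a, b)


class TestMetropolis:
    def test_always_accept_downhill_and_flat(self, rng):
        assert all(lc.metropolis_accept(-1.0, rng) for _ in range(100))
        assert all(lc.metropolis_accept(0.0, rng) for _ in range(100))

    def test_acceptance_probability_at_unit_barrier(self):
        rng = np.random.default_rng(42)
        n = 1_000_000
        acc = sum(lc.metropolis_accept(1.0, rng) for _ in range(n))
        assert acc / n == pytest.approx(np.exp(-1.0), abs=0.002)

    def test_nan_raises(self, rng):
        with pytest.raises(ValueError):
            lc.metropolis_accept(float("nan"), rng)


class TestSweepAndSchedule:
    def test_sample_count_follows_schedule(self):
        p = lc.ModelParams(schedule=short_schedule(50_000, 5_000, 1_000),
                           n_replicates=1)
        res = lc.run_simulation(p)
        assert len(res.replicates[0].samples) == (50_000 - 5_000) // 1_000
        idx = [s.sweep_index for s in res.replicates[0].samples]
        assert idx[0] == 6_000 and idx[-1] == 50_000
        assert all(i > p.schedule.pre_equilibration_sweeps for i in idx)

    def test_run_sweep_mutates_free_beads_only(self, params, rng):
        st = lc.initialize_chain(params)
        before = st.coords.copy()
        lc.run_sweep(st, params, rng)
        assert np.array_equal(st.coords[0], before[0])
        assert not np.array_equal(st.coords[1:], before[1:])

    def test_determinism_same_seed_bitwise(self):
        p = lc.ModelParams(schedule=short_schedule(30_000, 2_000), seed=9,
                           n_replicates=2)
        r1 = lc.run_simulation(p)
        r2 = lc.run_simulation(p)
        for a, b in zip(r1.replicates, r2.replicates):
            assert a.seed == b.seed
            for sa, sb in zip(a.samples, b.samples):
                assert np.array_equal(sa.coords, sb.coords)

    def test_replicates_differ(self):
        p = lc.ModelParams(schedule=short_schedule(30_000, 2_000), seed=9,
                           n_replicates=2)
        r = lc.run_simulation(p)
        assert not np.array_equal(r.replicates[0].samples[-1].coords,
                                  r.replicates[1].samples[-1].coords)

    def test_acceptance_decreases_with_stiffness(self):
        rates = []
        for lp in (5.0, 50.0, 200.0):
            p = lc.ModelParams(persistence_length=lp,
                               schedule=short_schedule(100_000, 5_000, 10_000),
                               n_replicates=1, seed=2)
            rates.append(lc.run_simulation(p).replicates[0].acceptance_rate)
        assert rates[0] > rates[1] > rates[2]

    def test_stiff_limit_freezes_bending_moves(self):
        p = lc.ModelParams(persistence_length=1e6,
                           schedule=short_schedule(100_000, 5_000, 10_000),
                           n_replicates=1, seed=2)
        rate = lc.run_simulation(p).replicates[0].acceptance_rate
        assert rate < 0.001


class TestPinning:
    def test_pins_exactly_on_site(self):
        p = lc.ModelParams(n_anchors=2, anchor_separation=50.0,
                           persistence_length=5.0,
                           schedule=short_schedule(), seed=1, n_replicates=1)
        st = lc.initialize_chain(p)
        st2, sweeps = lc.pin_second_anchor(st, p, np.random.default_rng(1))
        assert st2.pinned[-1]
        assert np.array_equal(st2.coords[-1], st2.anchor_sites[1])
        assert 0 < sweeps < p.schedule.pre_equilibration_sweeps

    def test_stretched_chain_pins_and_stays_connected(self):
        p = lc.ModelParams(n_anchors=2, anchor_separation=300.0,
                           persistence_length=50.0,
                           schedule=short_schedule(200_000, 50_000, 10_000),
                           seed=3, n_replicates=1)
        res = lc.run_simulation(p)
        rep = res.replicates[0]
        assert rep.pinning_sweeps > 0
        bonds = np.linalg.norm(np.diff(rep.final_state.coords, axis=0), axis=1)
        # taut on average, with thermal bond fluctuations (sd ~ 5.8 nm)
        sigma_bond = np.sqrt(1.0 / (2.0 * p.stretching_k))
        assert bonds.max() < p.bond_length + 4.0 * sigma_bond
        assert 25.0 < bonds.mean() < 40.0

    def test_unreachable_separation_rejected(self):
        with pytest.raises(ValueError):
            lc.ModelParams(n_anchors=2, anchor_separation=400.0)

    def test_pinned_beads_never_move(self):
        p = lc.ModelParams(n_anchors=2, anchor_separation=100.0,
                           schedule=short_schedule(50_000, 10_000, 5_000),
                           seed=4, n_replicates=1)
        res = lc.run_simulation(p)
        sites = res.replicates[0].final_state.anchor_sites
        for s in res.replicates[0].samples:
            assert np.array_equal(s.coords[0], sites[0])
            assert np.array_equal(s.coords[-1], sites[1])


class TestBoltzmannFidelity:
    def test_free_chain_joint_angle_langevin(self):
        """For a free chain the joint-angle distribution is
        p(θ) ∝ exp(−k(1−cos θ)) sin θ, so ⟨cos θ⟩ = coth(k) − 1/k with
        k = L_P/(2 r_bead); checked within 3 s.e. over replicate means."""
        k = 50.0 / 30.0
        exact = 1.0 / np.tanh(k) - 1.0 / k
        p = lc.ModelParams(persistence_length=50.0, excluded_volume=False,
                           wall=False,
                           schedule=short_schedule(200_000, 20_000, 100),
                           n_replicates=3, seed=7)
        res = lc.run_simulation(p)
        rep_means = []
        for rep in res.replicates:
            vals = []
            for s in rep.samples:
                b = np.diff(s.coords, axis=0)
                b /= np.linalg.norm(b, axis=1, keepdims=True)
                vals.append(np.einsum("ij,ij->i", b[:-1], b[1:]).mean())
            rep_means.append(np.mean(vals))
        mean = np.mean(rep_means)
        sem = np.std(rep_means, ddof=1) / np.sqrt(len(rep_means))
        assert abs(mean - exact) < 3.0 * sem + 1e-12

    def test_dimer_bond_length_distribution(self):
        """Sampled dimer bond lengths follow r² exp(−U_stretch(r)):
        KS distance against the quadrature CDF below 0.02."""
        p = lc.ModelParams(n_beads=2, persistence_length=50.0,
                           excluded_volume=False, wall=False,
                           schedule=short_schedule(2_000_000, 10_000, 50),
                           n_replicates=1, seed=3)
        res = lc.run_simulation(p)
        r = np.array([np.linalg.norm(s.coords[1] - s.coords[0])
                      for s in res.replicates[0].samples])
        grid = np.linspace(1e-3, 120.0, 4000)
        pdf = grid**2 * np.exp(-p.stretching_k * (grid - p.bond_length) ** 2)
        cdf = integrate.cumulative_trapezoid(pdf, grid, initial=0.0)
        cdf /= cdf[-1]
        ks = stats.ks_1samp(r, lambda x: np.interp(x, grid, cdf))
        assert ks.statistic < 0.02

    def test_strong_adsorption_keeps_chain_at_surface(self):
        p = lc.ModelParams(eps_ads=1.0, persistence_length=50.0,
                           schedule=short_schedule(1_000_000, 100_000, 1_000),
                           n_replicates=1, seed=1)
        res = lc.run_simulation(p)
        heights = np.concatenate([s.heights for s in res.replicates[0].samples])
        assert np.mean(heights <= 30.0) >= 0.95
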