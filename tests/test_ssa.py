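"""Exact SSA engine: statistical exactness, determinism, conservation,
transition times and the coupled reference model."""

import numpy as np
import pytest
from scipy import stats
from scipy.linalg import expm

from epigrn import er_model
from epigrn.ssa import (
    Network, coupled_full_model, coupled_initial_state, er_network,
    estimate_transition_times, first_dwell_time, gillespie_run,
    measure_differentiation_time, sample_trajectory, spawn_seeds,
)


def simple_network(species, channels):
    """channels: list of (rate, factor names, {species: delta})."""
    idx = {s: i for i, s in enumerate(species)}
    C = len(channels)
    stoich = np.zeros((C, len(species)), dtype=np.int64)
    factors = -np.ones((C, 3), dtype=np.int64)
    c = np.zeros(C)
    for k, (rate, facs, deltas) in enumerate(channels):
        c[k] = rate
        for j, f in enumerate(facs):
            factors[k, j] = idx[f]
        for s, d in deltas.items():
            stoich[k, idx[s]] = d
    return Network(species=tuple(species), stoich=stoich, factors=factors, c=c)


class TestGillespieCore:
    def test_pure_death_fires_exactly_five_events(self):
        net = simple_network(["X"], [(1.0, ["X"], {"X": -1})])
        traj = gillespie_run(net, np.array([5.0]), t_max=1e9, seed=1)
        assert traj.times.size == 5
        assert traj.state_final[0] == 0

    def test_immigration_death_stationary_mean(self):
        lam, mu = 8.0, 0.5
        net = simple_network(["X"], [(lam, [], {"X": 1}), (mu, ["X"], {"X": -1})])
        grid = np.linspace(50, 2050, 2001)  # post-burn-in samples
        vals = []
        for s in spawn_seeds(7, 4):
            states, _, _ = sample_trajectory(net, np.array([0.0]), grid, int(s))
            vals.append(states[:, 0])
        mean = np.concatenate(vals).mean()
        # autocorrelated samples: conservative SE from per-run means
        per_run = [v.mean() for v in vals]
        se = np.std(per_run, ddof=1) / np.sqrt(len(per_run))
        assert abs(mean - lam / mu) < 3 * max(se, 0.05)

    def test_same_seed_identical_trajectories(self):
        net = simple_network(["X"], [(2.0, [], {"X": 1}), (0.1, ["X"], {"X": -1})])
        t1 = gillespie_run(net, np.array([3.0]), 50.0, seed=42)
        t2 = gillespie_run(net, np.array([3.0]), 50.0, seed=42)
        assert np.array_equal(t1.times, t2.times)
        assert np.array_equal(t1.states, t2.states)

    def test_three_state_chain_matches_master_equation(self):
        # linear chain 0 <-> 1 <-> 2; occupancy at t = 1.5 from 10^4 runs
        k01, k10, k12, k21 = 1.0, 0.6, 0.8, 1.2
        net = simple_network(
            ["S0", "S1", "S2"],
            [
                (k01, ["S0"], {"S0": -1, "S1": 1}),
                (k10, ["S1"], {"S1": -1, "S0": 1}),
                (k12, ["S1"], {"S1": -1, "S2": 1}),
                (k21, ["S2"], {"S2": -1, "S1": 1}),
            ],
        )
        Q = np.array([
            [-k01, k01, 0.0],
            [k10, -(k10 + k12), k12],
            [0.0, k21, -k21],
        ])
        p_exact = (expm(Q * 1.5))[0]
        grid = np.array([1.5])
        counts = np.zeros(3)
        n = 10_000
        for s in spawn_seeds(3, n):
            states, _, _ = sample_trajectory(net, np.array([1.0, 0.0, 0.0]), grid, int(s))
            counts[np.argmax(states[0])] += 1
        p_hat = counts / n
        se = np.sqrt(p_exact * (1 - p_exact) / n)
        assert np.all(np.abs(p_hat - p_exact) < 3 * se + 1e-3)

    def test_absorbing_state_ends_run_early(self):
        net = simple_network(["X"], [(1.0, ["X"], {"X": -1})])
        traj = gillespie_run(net, np.array([2.0]), t_max=1e6, seed=0)
        assert traj.state_final[0] == 0
        assert traj.times[-1] < 1e6


class TestERConservation:
    def test_conservation_holds_on_every_snapshot(self, ders1):
        net = er_network(ders1)
        traj = gillespie_run(net, er_model.closed_state(ders1), 50.0, seed=5)
        net.check_conservation(traj.states)  # raises on violation

    def test_tampered_state_detected(self, ders1):
        net = er_network(ders1)
        bad = er_model.closed_state(ders1).astype(float)
        bad[er_model.M] += 1
        with pytest.raises(er_model.InvalidStateError):
            net.check_conservation(bad)


class TestTransitionTimes:
    @pytest.fixture(scope="class")
    def ders1_times(self, ders1):
        return estimate_transition_times(ders1, n_events=30, seed=21, t_max_per_passage=1e5)

    def test_sample_means_are_the_estimates(self, ders1_times):
        tt = ders1_times
        assert tt.tau_open == pytest.approx(tt.samples_open.mean())
        assert tt.tau_close == pytest.approx(tt.samples_close.mean())
        assert tt.n_open >= 30 and tt.n_close >= 30

    def test_red_like_geometry(self, ders1_times):
        assert ders1_times.tau_open < ders1_times.tau_close

    def test_waiting_times_exponential(self, ders1_times):
        # escape from a metastable state: KS against Exp(mean) at alpha = 0.01
        s = ders1_times.samples_open
        res = stats.kstest(s, "expon", args=(0, s.mean()))
        assert res.pvalue > 0.01

    def test_monostable_open_flags_rare_closing(self):
        c = np.zeros(16)
        c[14] = 0.5
        c[0:6] = [0.1, 1.0, 0.5, 0.1, 1.0, 0.5]
        c[8:11] = [0.02, 1.0, 0.02]  # feeble deacetylation: closing possible but rare
        p = er_model.ERParams(c=c, n_sites=15, e_hdm=5, e_hdac=5)
        tt = estimate_transition_times(p, n_events=3, seed=1, t_max_per_passage=200.0)
        assert tt.n_open >= 1          # opening happens
        assert tt.rare_close            # closing never observed
        assert tt.lower_bound_close > 0
        assert np.isnan(tt.tau_close)


class TestCoupledModel:
    def test_channel_bookkeeping(self, ders1, pers2, grn):
        model = coupled_full_model([ders1, pers2], grn)
        n = grn.n_genes
        assert model.network.n_channels == 16 * n + 3 * n + 2 * n * n

    def test_frozen_open_er_reduces_to_gated_grn(self, ders1, pers2, grn):
        # zero all ER channels, both genes fully acetylated: binding gates all open,
        # marginal GRN propensities must match grn_propensities with eta = 1
        from epigrn.grn_model import GRNState, grn_propensities

        frozen = [er_model.ERParams(c=np.zeros(16), n_sites=15, e_hdm=5, e_hdac=5)] * 2
        model = coupled_full_model(frozen, grn)
        x = coupled_initial_state(model, [np.array([0.0, 1.0])] * 2, np.array([30.0, 50.0]))
        a = model.network.propensities(x)
        expected = grn_propensities(
            GRNState(x=np.array([30, 50]), bound=np.zeros((2, 2))), grn, np.ones(2)
        )
        assert a[32:] == pytest.approx(expected)

    def test_silenced_ders_open_pers_settles_near_pss(self, pers2, grn):
        # DERS frozen shut, PERS frozen open: the GRN must relax to the
        # pluripotency state predicted by the reduced model at pfrac (0, 1)
        from epigrn.grn_model import find_steady_states

        frozen_closed = er_model.ERParams(c=np.zeros(16), n_sites=15, e_hdm=5, e_hdac=5)
        model = coupled_full_model([frozen_closed, frozen_closed], grn)
        x0 = coupled_initial_state(
            model, [np.array([1.0, 0.0]), np.array([0.0, 1.0])], np.array([0.0, 0.0])
        )
        grid = np.linspace(150, 400, 50)
        states, _, _ = sample_trajectory(model.network, x0, grid, 17)
        x2 = states[:, model.x_index[1]].mean() / grn.S
        pss = [s for s in find_steady_states(grn, np.array([0.0, 1.0]))
               if s.stable and s.label == "PSS"][0]
        assert x2 == pytest.approx(pss.q[1], rel=0.1)


class TestMeanFieldConsistency:
    def test_large_system_tracks_meanfield_fixed_point(self):
        # monostable-open system at Y = 500: the SSA time-averaged acetylation
        # fraction must sit within 5% of the mean-field fixed point
        from epigrn.er_model import find_er_attractors
        from epigrn.map_action import er_params_at_size
        from epigrn.ssa import er_initial_state

        c = np.zeros(16)
        c[14] = 0.3                                   # acetylation
        c[6] = 0.05                                   # weak methylation
        c[0:6] = [0.1, 1.0, 0.5, 0.05, 1.0, 0.5]      # demethylation machinery
        c[8:14] = [0.02, 1.0, 0.3, 0.01, 1.0, 0.3]    # deacetylation machinery
        base = er_model.ERParams(c=c, n_sites=15, e_hdm=5, e_hdac=5)
        big = er_params_at_size(base, 500)
        att = find_er_attractors(big)
        assert att.shape[0] == 1
        net = er_network(big)
        x0 = er_initial_state(big, att[0])
        grid = np.linspace(20, 220, 400)
        states, _, _ = sample_trajectory(net, x0.astype(float), grid, 23)
        a_frac = (states[:, er_model.A] + states[:, er_model.C_HDAC]).mean() / big.n_sites
        assert a_frac == pytest.approx(att[0, 1], rel=0.05)

    def test_grn_means_track_reduced_flow_at_large_s(self, grn):
        # frozen-open gates, S = 1000: the averaged monomer trajectory follows
        # the reduced ODE within Monte-Carlo error
        from dataclasses import replace as dreplace

        from epigrn.grn_model import reduced_rhs

        big = dreplace(grn, S=1000.0)
        frozen = [er_model.ERParams(c=np.zeros(16), n_sites=15, e_hdm=5, e_hdac=5)] * 2
        model = coupled_full_model(frozen, big)
        q0 = np.array([0.3, 0.6])
        grid = np.array([2.0, 5.0])
        runs = []
        for s in spawn_seeds(2, 15):
            x0 = coupled_initial_state(model, [np.array([0.0, 1.0])] * 2, big.S * q0)
            states, _, _ = sample_trajectory(model.network, x0, grid, int(s))
            runs.append(states[:, model.x_index] / big.S)
        mean_traj = np.mean(runs, axis=0)
        # reference: RK4 of the reduced flow at full accessibility
        q = q0.copy()
        dt = 0.001
        ref = []
        t = 0.0
        for target in grid:
            while t < target - 1e-9:
                k1 = reduced_rhs(q, big, np.ones(2))
                k2 = reduced_rhs(q + 0.5 * dt * k1, big, np.ones(2))
                k3 = reduced_rhs(q + 0.5 * dt * k2, big, np.ones(2))
                k4 = reduced_rhs(q + dt * k3, big, np.ones(2))
                q = q + dt / 6 * (k1 + 2 * k2 + 2 * k3 + k4)
                t += dt
            ref.append(q.copy())
        ref = np.array(ref)
        assert np.abs(mean_traj - ref).max() < 0.15


class TestDifferentiationTime:
    def test_criterion_true_at_start_gives_zero(self):
        times = np.arange(0.0, 20.0, 0.5)
        ok = np.ones_like(times, dtype=bool)
        assert first_dwell_time(times, ok, dwell=5.0) == 0.0

    def test_dwell_requires_sustained_condition(self):
        times = np.arange(0.0, 30.0, 1.0)
        ok = np.zeros_like(times, dtype=bool)
        ok[5:9] = True    # 4 units: too short
        ok[12:20] = True  # 8 units: long enough
        assert first_dwell_time(times, ok, dwell=5.0) == 12.0

    def test_censored_run_reported_not_averaged(self, ders2, pers1, grn):
        # blue-cluster DERS opens far too slowly for this horizon
        model = coupled_full_model([ders2, pers1], grn)
        tau, censored, _ = measure_differentiation_time(model, seed=3, t_max=60.0)
        assert censored
        assert tau == pytest.approx(60.0, abs=1.0)
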