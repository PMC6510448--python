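"""Multiscale hybrid simulator: QSSA samplers, PDMP integration, interventions."""

import numpy as np
import pytest
from dataclasses import replace
from scipy import stats

from epigrn import er_model
from epigrn.hybrid import (
    hybrid_run, promoter_occupancy_pmf, qssa_sample_complexes,
    qssa_sample_promoters, reprogram_strategy,
)
from epigrn.ssa import er_network, sample_trajectory


class TestPromoterSampler:
    def test_no_monomers_means_empty_promoters(self, grn):
        occ = qssa_sample_promoters(np.zeros(2), grn, np.ones(2), seed=0)
        assert np.all(occ == 0)

    def test_closed_promoter_surely_empty(self, grn):
        occ = qssa_sample_promoters(np.array([2.0, 2.0]), grn, np.array([0.0, 1.0]), seed=1)
        assert np.all(occ[0] == 0)

    def test_single_site_single_gene_detailed_balance(self):
        from epigrn.grn_model import GRNParams

        p = GRNParams(R=np.array([0.1]), omega1=np.array([2.0]), omega2=np.array([1.0]),
                      beta=np.array([[3.0]]), delta=np.array([[2.0]]), S=100.0, E=1)
        x = np.array([0.8])
        states, w = promoter_occupancy_pmf(x, p, np.ones(1), 0)
        rho = 1.5 * 0.8**2
        expected = rho / (1 + rho)
        bound = dict(zip(states, w))[(1,)]
        assert bound == pytest.approx(expected, rel=1e-12)

    def test_sampler_matches_long_ssa_occupancy(self, grn):
        # fixed monomer counts: promoter-only network vs the product-form law
        from epigrn.ssa import Network

        x = np.array([1.2, 0.9])
        X = np.round(x * grn.S)
        e = int(grn.e[0])
        # two binding + two unbinding channels on promoter 1, monomers clamped
        species = ("F", "B1", "B2")
        stoich = np.array([
            [-1, 1, 0], [-1, 0, 1], [1, -1, 0], [1, 0, -1],
        ], dtype=np.int64)
        factors = -np.ones((4, 3), dtype=np.int64)
        factors[0, 0] = 0
        factors[1, 0] = 0
        factors[2, 0] = 1
        factors[3, 0] = 2
        c = np.array([
            grn.b[0, 0] * X[0] * (X[0] - 1), grn.b[0, 1] * X[1] * (X[1] - 1),
            grn.d[0, 0], grn.d[0, 1],
        ])
        net = Network(species=species, stoich=stoich, factors=factors, c=c)
        grid = np.linspace(5, 3000, 7001)
        st, _, _ = sample_trajectory(net, np.array([e, 0, 0], dtype=float), grid, 31)
        counts = np.zeros((e + 1, e + 1))
        for b1, b2 in st[:, 1:].astype(int):
            counts[b1, b2] += 1
        emp = counts / counts.sum()
        # product-form prediction with the same dimer abundances
        rho = np.array([grn.b[0, 0] * X[0] * (X[0] - 1) / grn.d[0, 0],
                        grn.b[0, 1] * X[1] * (X[1] - 1) / grn.d[0, 1]])
        import math

        pred = np.zeros_like(emp)
        for n1 in range(e + 1):
            for n2 in range(e + 1 - n1):
                coef = math.factorial(e) / (
                    math.factorial(n1) * math.factorial(n2) * math.factorial(e - n1 - n2))
                pred[n1, n2] = coef * rho[0] ** n1 * rho[1] ** n2
        pred /= pred.sum()
        sel = pred > 1e-4
        n_eff = counts.sum()
        chi2 = float((((emp - pred) ** 2 / pred)[sel]).sum() * n_eff)
        dof = int(sel.sum()) - 1
        # autocorrelated samples: generous threshold at alpha = 0.01 scaled x5
        assert chi2 < 5 * stats.chi2.ppf(0.99, dof)


class TestComplexSampler:
    def test_no_substrate_no_complexes(self, ders1):
        y5, y7 = qssa_sample_complexes(np.array([0, 15, 0]), ders1, seed=0)
        assert y5 == 0 and y7 == 0

    def test_support_respected(self, ders1):
        rng = np.random.default_rng(5)
        for _ in range(300):
            m = rng.integers(0, 16)
            a = rng.integers(0, 16 - m)
            y5, y7 = qssa_sample_complexes(np.array([m, a]), ders1, rng)
            assert 0 <= y5 <= min(ders1.e_hdm, m)
            assert 0 <= y7 <= min(ders1.e_hdac, a)

    def test_briggs_haldane_mean_at_large_substrate_excess(self, ders1):
        # with substrate >> enzymes the depletion-corrected law approaches the
        # binomial with per-enzyme occupancy g/(g + r)
        p = replace(ders1, n_sites=2000, e_hdm=20, e_hdac=20)
        M, A = 1200, 300
        c = p.c
        g = (c[0] + c[3] * A) * M
        r = c[1] + c[2] + c[4] + c[5]
        expected = p.e_hdm * g / (g + r)
        rng = np.random.default_rng(0)
        draws = np.array([qssa_sample_complexes(np.array([M, A]), p, rng)[0] for _ in range(1500)])
        assert draws.mean() == pytest.approx(expected, rel=0.05)

    def test_pmf_matches_frozen_totals_ssa(self, pers2):
        # binding/unbinding only (slow channels and catalysis off): the exact
        # stationary complex laws against a long full-model run
        c = pers2.c.copy()
        c[[2, 5, 6, 7, 10, 13, 14, 15]] = 0.0
        p = replace(pers2, c=c)
        M, A = 7, 7
        x0 = np.array([M, 15 - M - A, A, 5, 0, 5, 0], dtype=float)
        grid = np.linspace(20, 1500, 3000)
        st, _, _ = sample_trajectory(er_network(p), x0, grid, 17)
        rng = np.random.default_rng(2)
        smp = np.array([qssa_sample_complexes((M, A), p, rng) for _ in range(4000)])
        assert smp[:, 0].mean() == pytest.approx(st[:, er_model.C_HDM].mean(), abs=0.15)
        assert smp[:, 1].mean() == pytest.approx(st[:, er_model.C_HDAC].mean(), abs=0.15)


class TestHybridRun:
    def test_same_seed_identical(self, ders1, pers2, grn):
        a = hybrid_run([ders1, pers2], grn, 100.0, seed=8)
        b = hybrid_run([ders1, pers2], grn, 100.0, seed=8)
        assert np.array_equal(a.x, b.x)
        assert np.array_equal(a.acetyl, b.acetyl)

    def test_frozen_er_matches_pure_ode(self, grn):
        # all ER rates zero, both genes open: the PDMP with its occupancy noise
        # time-averages to the reduced deterministic flow
        frozen = [er_model.ERParams(c=np.zeros(16), n_sites=15, e_hdm=5, e_hdac=5)] * 2
        res = hybrid_run(
            frozen, grn, 400.0, seed=4,
            er_init=[np.array([0.0, 1.0])] * 2, x_init=np.array([0.5, 0.5]),
        )
        from epigrn.grn_model import find_steady_states

        states = [s for s in find_steady_states(grn, np.ones(2)) if s.stable]
        tail = res.x[-200:]
        dists = [np.linalg.norm(tail.mean(axis=0) - s.q) for s in states]
        assert min(dists) < 0.25

    def test_eta_tracks_acetylation_threshold(self, ders1, pers2, grn):
        res = hybrid_run([ders1, pers2], grn, 300.0, seed=12)
        thr = np.array([p.y0 * p.n_sites for p in (ders1, pers2)])
        assert np.array_equal(res.eta, (res.acetyl >= thr).astype(float))

    def test_scale_violation_warns(self, ders1, pers2):
        from epigrn.grn_model import GRNParams

        tiny = GRNParams(R=np.array([0.02, 0.02]), omega1=np.array([4.0, 4.0]),
                         omega2=np.ones(2), beta=np.full((2, 2), 1.0),
                         delta=np.ones((2, 2)), S=2.0, E=3)
        with pytest.warns(UserWarning, match="S >> E"):
            hybrid_run([ders1, pers2], tiny, 5.0, seed=0)


class TestReprogramming:
    def test_identity_factor_changes_nothing(self, ders2):
        out = reprogram_strategy(ders2, "two_step", factor=1.0)
        assert np.array_equal(out["params"].c, ders2.c)

    def test_two_step_touches_the_declared_channels_only(self, ders2):
        out = reprogram_strategy(ders2, "two_step", factor=4.0)
        changed = np.nonzero(out["params"].c != ders2.c)[0] + 1
        assert set(changed) == {3, 11}
        assert out["params"].c[2] == pytest.approx(ders2.c[2] * 4.0)
        assert out["params"].c[10] == pytest.approx(ders2.c[10] / 4.0)

    def test_one_step_touches_demethylation_only(self, ders2):
        out = reprogram_strategy(ders2, "one_step", factor=4.0)
        changed = np.nonzero(out["params"].c != ders2.c)[0] + 1
        assert set(changed) == {3}

    def test_non_blue_cluster_warned(self, ders1):
        with pytest.warns(UserWarning, match="blue"):
            reprogram_strategy(ders1, "one_step", factor=2.0, cluster="red")

    def test_lost_bistability_flagged(self, ders2):
        out = reprogram_strategy(ders2, "two_step", factor=50.0)
        assert not out["bistable"]
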