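"""ABC ensembles, clustering and KS sensitivity analysis."""

import numpy as np
import pytest

from epigrn.ensemble import (
    EnsembleRecord, abc_rejection, default_prior_ranges, empirical_cdf,
    generate_raw_data, kmeans_clusters, ks_compare, sensitivity_report,
    summary_stats,
)
from epigrn.ssa import TransitionTimes


@pytest.fixture(scope="module")
def raw_ders(reference_er):
    return generate_raw_data(reference_er, "ders", seed=11)


class TestRawData:
    def test_shape_is_protocol(self, raw_ders):
        assert raw_ders.levels.shape == (10, 25)

    def test_ders_stays_near_open_attractor(self, raw_ders, reference_er):
        assert raw_ders.levels[:, -1].mean() > 0.8 * reference_er.n_sites

    def test_pers_stays_near_closed_attractor(self, reference_er):
        raw = generate_raw_data(reference_er, "pers", seed=11)
        assert raw.levels[:, -1].mean() < 0.2 * reference_er.n_sites

    def test_same_seed_reproducible(self, reference_er, raw_ders):
        again = generate_raw_data(reference_er, "ders", seed=11)
        assert np.array_equal(again.levels, raw_ders.levels)

    def test_non_bistable_reference_refused(self, reference_er):
        from dataclasses import replace

        c = reference_er.c.copy()
        c[[6, 7]] = 0.0
        c[0] = 1.0  # no methylation, strong demethylation: monostable open
        with pytest.raises(ValueError, match="bistable"):
            generate_raw_data(replace(reference_er, c=c), "ders", seed=0)

    def test_summary_statistics_definition(self, raw_ders):
        ss = summary_stats(raw_ders)
        assert ss.mean == pytest.approx(raw_ders.levels.mean(axis=0))
        assert ss.sd == pytest.approx(raw_ders.levels.std(axis=0))
        assert np.all(ss.sd >= 0)


class TestABCRejection:
    def test_infinite_tolerance_accepts_everything(self, raw_ders, reference_er):
        prior = default_prior_ranges(reference_er.c, spread=2.0)
        records, prov = abc_rejection(
            raw_ders, prior, n_accept=10, seed=5, eps_mean=1e9, eps_sd=1e9
        )
        assert len(records) == 10
        assert prov["acceptance_rate"] == 1.0

    def test_accepted_sets_pass_their_own_tolerance_on_resimulation(self, raw_ders, reference_er):
        from dataclasses import replace

        from epigrn.ensemble import _simulate_protocol
        from epigrn.er_model import find_er_attractors
        from epigrn.ssa import er_initial_state

        prior = default_prior_ranges(reference_er.c, spread=2.0)
        eps_mean, eps_sd = 0.15 * 15, 0.2 * 15
        records, _ = abc_rejection(raw_ders, prior, n_accept=30, seed=6,
                                   eps_mean=eps_mean, eps_sd=eps_sd)
        target = summary_stats(raw_ders)
        x0 = er_initial_state(reference_er, find_er_attractors(reference_er)[-1]).astype(float)
        n_pass = 0
        for i, rec in enumerate(records):
            levels = _simulate_protocol(replace(reference_er, c=rec.c), x0, 1000 + i,
                                        10, raw_ders.times)
            ss = summary_stats(levels)
            ok = (np.max(np.abs(ss.mean - target.mean)) <= 1.5 * eps_mean
                  and np.max(np.abs(ss.sd - target.sd)) <= 1.5 * eps_sd)
            n_pass += ok
        # acceptance is stochastic: an accepted set re-simulated with new noise
        # must stay within (slightly relaxed) tolerance almost always
        assert n_pass >= 0.9 * len(records)

    def test_hopeless_tolerance_aborts_with_advice(self, raw_ders, reference_er):
        prior = default_prior_ranges(reference_er.c, spread=100.0)
        with pytest.raises(RuntimeError, match="acceptance rate|widen"):
            abc_rejection(raw_ders, prior, n_accept=5, seed=7,
                          eps_mean=1e-6, eps_sd=1e-6, probe=200, max_candidates=400)

    def test_invalid_prior_rejected(self, raw_ders):
        with pytest.raises(ValueError, match="prior"):
            abc_rejection(raw_ders, np.zeros((16, 2)), n_accept=1, seed=0)


def _record(tau_open, tau_close, cluster="none"):
    tt = TransitionTimes(
        tau_open=tau_open, tau_close=tau_close,
        samples_open=np.array([tau_open]), samples_close=np.array([tau_close]),
        se_open=np.nan, se_close=np.nan,
    )
    return EnsembleRecord(c=np.ones(16), role="ders", regime="bistable", times=tt)


class TestClustering:
    def test_separable_blobs_recovered_with_canonical_names(self):
        rng = np.random.default_rng(0)
        recs = []
        truth = []
        for _ in range(20):  # red: fast opening, slow closing
            recs.append(_record(10 ** rng.normal(1.0, 0.1), 10 ** rng.normal(4.0, 0.1)))
            truth.append("red")
        for _ in range(20):  # blue: slow opening, fast closing
            recs.append(_record(10 ** rng.normal(4.0, 0.1), 10 ** rng.normal(1.0, 0.1)))
            truth.append("blue")
        for _ in range(20):  # green: slow both
            recs.append(_record(10 ** rng.normal(4.0, 0.1), 10 ** rng.normal(4.0, 0.1)))
            truth.append("green")
        kmeans_clusters(recs, seed=1)
        assert [r.cluster for r in recs] == truth

    def test_labels_invariant_to_record_order(self):
        rng = np.random.default_rng(3)
        recs = [
            _record(10 ** rng.normal(mu1, 0.2), 10 ** rng.normal(mu2, 0.2))
            for mu1, mu2 in [(1, 4)] * 10 + [(4, 1)] * 10 + [(4, 4)] * 10
        ]
        kmeans_clusters(recs, seed=7)
        labels = [r.cluster for r in recs]
        perm = np.random.default_rng(5).permutation(len(recs))
        shuffled = [recs[i] for i in perm]
        kmeans_clusters(shuffled, seed=7)
        assert [shuffled[list(perm).index(i)].cluster for i in range(len(recs))] == labels

    def test_red_opens_faster_than_blue_by_naming(self):
        rng = np.random.default_rng(4)
        recs = [
            _record(10 ** rng.normal(mu1, 0.3), 10 ** rng.normal(mu2, 0.3))
            for mu1, mu2 in [(1, 3.5)] * 15 + [(3.5, 1)] * 15 + [(3.5, 3.5)] * 15
        ]
        kmeans_clusters(recs, seed=2)
        red = np.mean([r.times.tau_open for r in recs if r.cluster == "red"])
        blue = np.mean([r.times.tau_open for r in recs if r.cluster == "blue"])
        assert red < blue

    def test_too_few_records_rejected(self):
        with pytest.raises(ValueError, match="exceeds"):
            kmeans_clusters([_record(1, 1), _record(2, 2)], k=3)


class TestKSCompare:
    def test_identical_samples_give_zero(self):
        x = np.array([1.0, 2.0, 3.0])
        D, p = ks_compare(x, x.copy())
        assert D == 0.0 and p == 1.0

    def test_known_power_case(self):
        rng = np.random.default_rng(8)
        a = rng.uniform(0, 1, 100)
        b = rng.uniform(0.5, 1.5, 100)
        D, p = ks_compare(a, b)
        assert p < 1e-3

    def test_matches_bruteforce_sup_over_pooled_points(self):
        rng = np.random.default_rng(9)
        for _ in range(200):
            a = rng.normal(size=rng.integers(5, 40))
            b = rng.normal(loc=rng.normal(), size=rng.integers(5, 40))
            D, _ = ks_compare(a, b)
            pooled = np.concatenate([a, b])
            cdf_a = np.searchsorted(np.sort(a), pooled, side="right") / a.size
            cdf_b = np.searchsorted(np.sort(b), pooled, side="right") / b.size
            assert D == pytest.approx(np.abs(cdf_a - cdf_b).max(), abs=1e-12)

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            ks_compare(np.array([]), np.array([1.0]))


class TestSensitivityReport:
    def test_planted_signal_flagged_with_direction(self):
        rng = np.random.default_rng(10)
        c_a = rng.lognormal(0.0, 0.3, (40, 16))
        c_b = rng.lognormal(0.0, 0.3, (40, 16))
        c_a[:, 0] *= 3.0  # c1 shifted up in group red
        c = np.vstack([c_a, c_b])
        groups = np.array(["red"] * 40 + ["blue"] * 40)
        rep = sensitivity_report(c, groups)
        row = rep[(rep.parameter == "c1")].iloc[0]
        assert row.significant and row.bias_a == "larger"
        assert len(rep) == 16

    def test_null_partition_false_positive_rate(self):
        # random halves of one ensemble: expected significant count ~ alpha * 16
        rng = np.random.default_rng(12)
        c = rng.lognormal(0.0, 0.5, (60, 16))
        fp = 0
        n_shuffles = 200
        for s in range(n_shuffles):
            perm = np.random.default_rng(s).permutation(60)
            groups = np.empty(60, dtype=object)
            groups[perm[:30]] = "A"
            groups[perm[30:]] = "B"
            rep = sensitivity_report(c, groups)
            fp += int(rep.significant.sum())
        rate = fp / (n_shuffles * 16)
        assert 0.01 < rate < 0.12  # nominal 0.05 with Monte-Carlo slack

    def test_benjamini_hochberg_column_optional(self):
        rng = np.random.default_rng(13)
        c = rng.lognormal(0.0, 0.5, (30, 16))
        groups = np.array(["A"] * 15 + ["B"] * 15)
        plain = sensitivity_report(c, groups)
        adj = sensitivity_report(c, groups, benjamini_hochberg=True)
        assert "p_bh" not in plain.columns
        assert (adj.p_bh >= adj.p_value - 1e-12).all()

    def test_cdf_export_is_a_distribution(self):
        x, y = empirical_cdf(np.array([3.0, 1.0, 2.0]))
        assert np.array_equal(x, [1.0, 2.0, 3.0])
        assert np.array_equal(y, [1 / 3, 2 / 3, 1.0])
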