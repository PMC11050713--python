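"""Dysregulation calls, reproducibility, Jaccard, log-rank screen, ARI."""

import numpy as np
import pandas as pd
import pytest

import riepath as rp
from riepath.analysis import AnalysisError, jaccard_matrix


def make_activation(scores, pathways, samples):
    return rp.ActivationMatrix(
        scores=pd.DataFrame(scores, index=pathways, columns=samples)
    )


def labels_for(samples, n_normal):
    vals = ["normal"] * n_normal + ["tumor"] * (len(samples) - n_normal)
    return pd.Series(vals, index=samples)


class TestClassifyDysregulation:
    def setup_method(self):
        # normal scores {0.9, 1.0, 1.1}: mean 1.0, sd 0.1 -> cutoff 1.2 at k=2
        self.samples = ["n1", "n2", "n3", "t1", "t2"]
        self.labels = labels_for(self.samples, 3)

    def _calls(self, t1, t2, k=2.0):
        act = make_activation([[0.9, 1.0, 1.1, t1, t2]], ["p"], self.samples)
        return rp.classify_dysregulation(act, self.labels, k=k)

    def test_above_threshold_is_dysregulated(self):
        calls = self._calls(1.5, 1.1)
        assert calls.calls.loc["p", "t1"] == 1
        assert calls.calls.loc["p", "t2"] == 0

    def test_thresholds_reproduce_calls_exactly(self):
        calls = self._calls(1.5, 1.1)
        thr = calls.thresholds.loc["p"]
        cutoff = thr["mean"] + thr["k"] * thr["sd"]
        assert (1.5 > cutoff) == bool(calls.calls.loc["p", "t1"])
        assert (1.1 > cutoff) == bool(calls.calls.loc["p", "t2"])
        assert thr["mean"] == pytest.approx(1.0)
        assert thr["sd"] == pytest.approx(0.1)

    def test_tied_normals_use_sd_floor_and_strict_inequality(self):
        act = make_activation([[1.0, 1.0, 1.0, 1.0, 2.0]], ["p"], self.samples)
        calls = rp.classify_dysregulation(act, self.labels, k=2.0)
        # tumor exactly at the mean stays near-normal; a clearly higher one flips
        assert calls.calls.loc["p", "t1"] == 0
        assert calls.calls.loc["p", "t2"] == 1


class TestSummaries:
    def test_counts_and_fractions(self):
        calls = rp.DysregulationCalls(
            calls=pd.DataFrame(
                [[1, 0], [0, 1], [1, 1]], index=["a", "b", "c"], columns=["t1", "t2"]
            ),
            thresholds=pd.DataFrame(
                {"mean": [0, 0, 0], "sd": [1, 1, 1], "k": [2, 2, 2]},
                index=["a", "b", "c"],
            ),
        )
        s = rp.dysregulation_summaries(calls)
        assert s["n_pathways_dysregulated_in_all"] == 1
        assert s["per_pathway_fraction"]["a"] == pytest.approx(0.5)
        assert list(s["per_sample_fraction"]) == pytest.approx([2 / 3, 2 / 3])


class TestReproducibilityScore:
    @staticmethod
    def _two_sample_frame(cos):
        """Two unit columns in the plane with the requested cosine."""
        return pd.DataFrame(
            np.array([[1.0, cos], [0.0, np.sqrt(1 - cos**2)]]), columns=["a", "b"]
        )

    def test_hand_case_equals_fifty(self):
        X = self._two_sample_frame(0.9)
        A = self._two_sample_frame(0.7)
        # denominator = 2 * (0.9 - 0.7)^2 = 0.08, RS = 4 / 0.08 = 50
        assert rp.reproducibility_score(X, A) == pytest.approx(50.0, rel=1e-9)

    def test_cosine_scale_invariance(self):
        rng = np.random.default_rng(0)
        X = pd.DataFrame(rng.normal(size=(5, 4)), columns=list("abcd"))
        A = pd.DataFrame(rng.normal(size=(3, 4)), columns=list("abcd"))
        base = rp.reproducibility_score(X, A)
        assert rp.reproducibility_score(X * 2.0, A) == pytest.approx(base, rel=1e-12)
        assert rp.reproducibility_score(X, A * 0.5) == pytest.approx(base, rel=1e-12)

    def test_identical_similarity_structure_gives_inf(self):
        rng = np.random.default_rng(1)
        X = pd.DataFrame(rng.normal(size=(4, 3)), columns=list("abc"))
        assert rp.reproducibility_score(X, X.copy()) == np.inf

    def test_degrading_structure_decreases_rs(self):
        rng = np.random.default_rng(2)
        X = pd.DataFrame(rng.normal(size=(20, 8)))
        A = X + rng.normal(scale=0.1, size=X.shape)
        B = X + rng.normal(scale=1.0, size=X.shape)
        assert rp.reproducibility_score(X, A) > rp.reproducibility_score(X, B)

    def test_zero_norm_column_is_error(self):
        X = pd.DataFrame([[0.0, 1.0], [0.0, 1.0]], columns=["a", "b"])
        with pytest.raises(AnalysisError):
            rp.reproducibility_score(X, X)


class TestJaccard:
    @pytest.mark.parametrize(
        "u, v, expected",
        [
            ({"a", "b"}, {"b", "c"}, 1 / 3),
            ({"a"}, {"b"}, 0.0),
            ({"a", "b"}, {"a", "b"}, 1.0),
            (set(), set(), 0.0),
        ],
    )
    def test_set_formula(self, u, v, expected):
        assert rp.jaccard_similarity(u, v) == pytest.approx(expected)

    def test_symmetric_and_bounded(self):
        rng = np.random.default_rng(3)
        universe = list("abcdefgh")
        for _ in range(20):
            u = set(rng.choice(universe, rng.integers(0, 8), replace=False))
            v = set(rng.choice(universe, rng.integers(0, 8), replace=False))
            j = rp.jaccard_similarity(u, v)
            assert 0.0 <= j <= 1.0
            assert j == rp.jaccard_similarity(v, u)
            if j == 1.0:
                assert u == v and u

    def test_matrix_zeroes_diagonal_for_display(self):
        m = jaccard_matrix({"x": {"a"}, "y": {"a", "b"}})
        assert m.loc["x", "x"] == 0.0
        assert m.loc["x", "y"] == pytest.approx(0.5)


def oracle_logrank_statistic(times_a, times_b, events_a, events_b):
    """Brute-force log-rank chi-square from the risk-set O-E table."""
    times = np.concatenate([times_a, times_b])
    events = np.concatenate([events_a, events_b])
    group = np.concatenate([np.zeros(len(times_a)), np.ones(len(times_b))])
    o_minus_e, var = 0.0, 0.0
    for t in np.unique(times[events == 1]):
        at_risk = times >= t
        n = at_risk.sum()
        n_a = (at_risk & (group == 0)).sum()
        d = ((times == t) & (events == 1)).sum()
        d_a = ((times == t) & (events == 1) & (group == 0)).sum()
        o_minus_e += d_a - d * n_a / n
        if n > 1:
            var += d * (n_a / n) * (1 - n_a / n) * (n - d) / (n - 1)
    return o_minus_e**2 / var


class TestLogrankScreen:
    @staticmethod
    def _screen(times_d, times_n, events_d=None, events_n=None, alpha=0.05):
        nd, nn = len(times_d), len(times_n)
        samples = [f"d{i}" for i in range(nd)] + [f"n{i}" for i in range(nn)]
        calls = rp.DysregulationCalls(
            calls=pd.DataFrame([[1] * nd + [0] * nn], index=["p"], columns=samples),
            thresholds=pd.DataFrame({"mean": [0.0], "sd": [1.0], "k": [2.0]}, index=["p"]),
        )
        surv = rp.SurvivalTable(
            data=pd.DataFrame(
                {
                    "time": list(times_d) + list(times_n),
                    "event": list(events_d or [1] * nd) + list(events_n or [1] * nn),
                },
                index=pd.Index(samples),
            )
        )
        return rp.logrank_screen(calls, surv, alpha=alpha)

    def test_identical_groups_give_statistic_zero(self):
        res = self._screen([5.0, 8.0, 9.0], [5.0, 8.0, 9.0])
        assert res.loc["p", "statistic"] == pytest.approx(0.0, abs=1e-12)
        assert res.loc["p", "p"] == pytest.approx(1.0)

    def test_toy_table_matches_risk_set_oracle(self):
        td, tn = [1.0, 2.0, 3.0], [10.0, 11.0, 12.0]
        res = self._screen(td, tn)
        expected = oracle_logrank_statistic(
            np.array(td), np.array(tn), np.ones(3), np.ones(3)
        )
        assert res.loc["p", "statistic"] == pytest.approx(expected, abs=1e-8)
        assert res.loc["p", "significant"] == (res.loc["p", "p"] < 0.05)

    def test_random_tables_match_oracle(self):
        rng = np.random.default_rng(9)
        for _ in range(5):
            td = rng.exponential(100, 12).round(1)
            tn = rng.exponential(150, 15).round(1)
            ed = rng.integers(0, 2, 12)
            en = rng.integers(0, 2, 15)
            if ed.sum() + en.sum() == 0:
                continue
            res = self._screen(td, tn, list(ed), list(en))
            expected = oracle_logrank_statistic(td, tn, ed, en)
            assert res.loc["p", "statistic"] == pytest.approx(expected, abs=1e-8)

    def test_empty_group_excluded_not_crash(self):
        samples = ["a", "b", "c"]
        calls = rp.DysregulationCalls(
            calls=pd.DataFrame([[1, 1, 1]], index=["p"], columns=samples),
            thresholds=pd.DataFrame({"mean": [0.0], "sd": [1.0], "k": [2.0]}, index=["p"]),
        )
        surv = rp.SurvivalTable(
            data=pd.DataFrame({"time": [1.0, 2.0, 3.0], "event": [1, 1, 1]}, index=pd.Index(samples))
        )
        res = rp.logrank_screen(calls, surv)
        assert len(res) == 0

    def test_hazard_doubling_detected(self):
        rng = np.random.default_rng(10)
        td = rng.exponential(500.0, 100)
        tn = rng.exponential(1000.0, 100)
        res = self._screen(list(td), list(tn))
        assert bool(res.loc["p", "significant"])


class TestARIBenchmark:
    def test_perfect_and_swapped_labelings(self):
        from sklearn.metrics import adjusted_rand_score

        truth = [0, 0, 1, 1, 0, 1]
        assert adjusted_rand_score(truth, truth) == 1.0
        assert adjusted_rand_score(truth, [1 - t for t in truth]) == 1.0

    def test_random_partition_ari_near_zero(self):
        from sklearn.metrics import adjusted_rand_score

        rng = np.random.default_rng(11)
        truth = np.repeat([0, 1], 50)
        aris = [
            adjusted_rand_score(truth, rng.permutation(truth)) for _ in range(50)
        ]
        assert abs(np.median(aris)) < 0.1

    def test_benchmark_recovers_labels_on_synthetic_cohort(self):
        spec = rp.SimulationSpec(
            n_genes=200, n_pathways=20, genes_per_pathway=(10, 10),
            n_normal=60, n_tumor=60, perturbed_pathway_fraction=0.25,
            mean_shift=1.5, cov_inflation=2.0, seed=1,
        )
        expr, sets, _, _ = rp.simulate_cohort(spec)
        cfg = rp.RunConfig(
            benchmark_repeats=5, benchmark_n_tumor=30, benchmark_n_normal=30, seed=1
        )
        aris = rp.ari_benchmark(expr, sets, cfg)
        assert len(aris) == 5
        assert np.median(aris) >= 0.8

    def test_insufficient_samples_is_error(self, fixture_cohort):
        expr, sets, _, _ = fixture_cohort
        cfg = rp.RunConfig(benchmark_repeats=2)  # needs 50+50, fixture has 30+30
        with pytest.raises(AnalysisError):
            rp.ari_benchmark(expr, sets, cfg)
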