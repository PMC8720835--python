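import itertools
import math

import numpy as np
import pytest
from scipy import stats as sps

import mothsim as ms
from mothsim.stats import (dunn_test, enumerate_fisher_exact,
                           fisher_exact_2x2, fisher_exact_rxc,
                           g2_goodness_of_fit, holm_bonferroni,
                           pairwise_fisher, scheirer_ray_hare)


class TestG2:
    def test_zero_when_observed_equals_expected(self):
        rep = g2_goodness_of_fit([25, 25, 25, 25])
        assert rep.statistic == pytest.approx(0.0, abs=1e-12)
        assert rep.p_value == pytest.approx(1.0)
        assert rep.df == 3

    def test_direct_evaluation_against_closed_form(self):
        obs = [10, 20, 30, 40]
        rep = g2_goodness_of_fit(obs, [25, 25, 25, 25])
        manual = 2.0 * sum(o * math.log(o / 25.0) for o in obs)
        assert rep.statistic == pytest.approx(manual)
        assert rep.statistic == pytest.approx(21.29, abs=0.01)

    def test_total_concentration_in_one_cell(self):
        rep = g2_goodness_of_fit([100, 0, 0, 0])
        assert rep.statistic == pytest.approx(2.0 * 100.0 * math.log(4.0))

    def test_matches_scipy_log_likelihood_ratio(self, rng):
        for _ in range(20):
            obs = rng.integers(1, 60, size=5)
            rep = g2_goodness_of_fit(obs)
            stat, p = sps.power_divergence(obs, lambda_="log-likelihood")
            assert rep.statistic == pytest.approx(stat)
            assert rep.p_value == pytest.approx(p)

    def test_invariant_to_cell_ordering(self):
        a = g2_goodness_of_fit([5, 10, 30], [15, 15, 15])
        b = g2_goodness_of_fit([30, 5, 10], [15, 15, 15])
        assert a.statistic == pytest.approx(b.statistic)

    def test_rejects_zero_expected_and_mismatched_totals(self):
        with pytest.raises(ValueError):
            g2_goodness_of_fit([1, 2], [0, 3])
        with pytest.raises(ValueError):
            g2_goodness_of_fit([10, 10], [5, 5])


class TestFisher:
    def test_perfectly_separated_2x2(self):
        # enumerate margins (5,5)/(5,5): only the two extreme tables are as
        # improbable as the observed one -> p = 2/252
        rep = fisher_exact_2x2([[5, 0], [0, 5]])
        assert rep.p_value == pytest.approx(2.0 / 252.0)

    def test_homogeneous_2x2_has_p_one(self):
        assert fisher_exact_2x2([[3, 3], [3, 3]]).p_value == pytest.approx(1.0)

    def test_degenerate_margins_flagged(self):
        rep = fisher_exact_rxc([[0, 0], [3, 4]])
        assert rep.p_value == 1.0
        assert "degenerate margins" in rep.labels

    def test_matches_scipy_on_random_2x2(self, rng):
        for _ in range(25):
            t = rng.integers(0, 8, size=(2, 2))
            if t.sum(axis=0).min() == 0 or t.sum(axis=1).min() == 0:
                continue
            ours = fisher_exact_2x2(t).p_value
            _, ref = sps.fisher_exact(t, alternative="two-sided")
            assert ours == pytest.approx(ref, rel=1e-9)

    def test_enumeration_matches_exact_on_2x2(self, rng):
        for _ in range(10):
            t = rng.integers(0, 6, size=(2, 2)) + 1
            assert enumerate_fisher_exact(t) == pytest.approx(
                fisher_exact_2x2(t).p_value, rel=1e-9)

    @pytest.mark.parametrize("table", [
        [[3, 1, 2], [1, 4, 2]],
        [[2, 0, 3], [1, 3, 1], [2, 1, 2]],
        [[4, 1], [0, 3], [2, 2], [1, 3]],
    ])
    def test_monte_carlo_converges_to_enumeration(self, table):
        """MC estimate within 3 SE of the brute-force exact p (N <= 20)."""
        exact = enumerate_fisher_exact(table)
        rep = fisher_exact_rxc(table, n_mc=40_000,
                               rng=np.random.default_rng(11))
        assert abs(rep.p_value - exact) < 3.0 * rep.stderr + 1e-4

    def test_rxc_df_counts_cells(self):
        rep = fisher_exact_rxc([[4, 1], [0, 3], [2, 2], [1, 3]], n_mc=1000,
                               rng=np.random.default_rng(0))
        assert rep.df == 3


class TestHolm:
    def test_single_p_unchanged(self):
        assert holm_bonferroni([0.04]) == [pytest.approx(0.04)]

    def test_hand_computed_step_down(self):
        # sorted: 0.01, 0.02, 0.04 -> 3*0.01, max(.03, 2*0.02), max(.04, .04)
        assert holm_bonferroni([0.01, 0.02, 0.04]) == [
            pytest.approx(0.03), pytest.approx(0.04), pytest.approx(0.04)]

    def test_capped_monotone_and_dominates_raw(self, rng):
        for _ in range(20):
            p = rng.uniform(0, 1, size=rng.integers(2, 8))
            adj = np.array(holm_bonferroni(p))
            assert (adj <= 1.0 + 1e-12).all()
            assert (adj >= p - 1e-12).all()
            order = np.argsort(p)
            assert (np.diff(adj[order]) >= -1e-12).all()
            bonf = np.minimum(1.0, p * p.size)
            assert (adj <= bonf + 1e-12).all()

    def test_matches_statsmodels(self, rng):
        from statsmodels.stats.multitest import multipletests
        for _ in range(10):
            p = rng.uniform(0, 1, size=6)
            _, ref, _, _ = multipletests(p, method="holm")
            np.testing.assert_allclose(holm_bonferroni(p), ref, atol=1e-12)

    def test_pairwise_fisher_adjusts(self):
        tables = {("a", "b"): np.array([[8, 2], [2, 8]]),
                  ("a", "c"): np.array([[8, 2], [7, 3]]),
                  ("b", "c"): np.array([[2, 8], [7, 3]])}
        reports = pairwise_fisher(tables)
        for r in reports:
            assert r.adjusted_p >= r.p_value


class TestSRH:
    def test_identical_values_give_zero_h(self):
        rep = scheirer_ray_hare([1.0] * 12, ["a", "b"] * 6,
                                ["x", "x", "y", "y"] * 3)
        assert rep["A"].statistic == pytest.approx(0.0)
        assert rep["B"].statistic == pytest.approx(0.0)

    def test_one_factor_limit_equals_kruskal_wallis(self, rng):
        """With a single-level second factor, SRH reduces to KW (with ties)."""
        for _ in range(10):
            groups = [rng.integers(0, 8, size=rng.integers(5, 12)) / 2.0
                      for _ in range(3)]
            values = np.concatenate(groups)
            fa = np.concatenate([[i] * len(g) for i, g in enumerate(groups)])
            fb = np.zeros_like(fa)
            rep = scheirer_ray_hare(values, fa, fb)
            h_ref, p_ref = sps.kruskal(*groups)
            assert rep["A"].statistic == pytest.approx(h_ref, rel=1e-9)
            assert rep["A"].p_value == pytest.approx(p_ref, rel=1e-9)
            assert math.isnan(rep["B"].statistic)

    def test_detects_planted_factor_a_shift_only(self, rng):
        n = 50
        values, fa, fb = [], [], []
        for a in (0, 1):
            for b in (0, 1):
                vals = rng.normal(loc=2.0 * a, size=n)
                values.extend(vals)
                fa.extend([a] * n)
                fb.extend([b] * n)
        rep = scheirer_ray_hare(values, fa, fb)
        assert rep["A"].p_value < 0.01
        assert rep["B"].p_value > 0.1

    def test_interaction_undefined_for_single_observation_cells(self):
        rep = scheirer_ray_hare([1.0, 2.0, 3.0, 4.0], [0, 0, 1, 1],
                                [0, 1, 0, 1])
        assert math.isnan(rep["interaction"].statistic)


class TestDunn:
    def test_identical_groups_give_zero_z(self):
        reports = dunn_test([np.arange(6.0), np.arange(6.0)])
        assert reports[0].statistic == pytest.approx(0.0)
        assert reports[0].p_value == pytest.approx(1.0)

    def test_two_group_z_squared_equals_kruskal_h(self, rng):
        """Untied two-group case: Dunn's z^2 is the KW H statistic."""
        for _ in range(10):
            x = rng.permutation(40)[:15].astype(float)
            y = np.setdiff1d(np.arange(40.0), x)[:12]
            z = dunn_test([x, y])[0].statistic
            h, _ = sps.kruskal(x, y)
            assert z ** 2 == pytest.approx(h, rel=1e-9)

    def test_shifted_group_has_smallest_pairwise_p(self, rng):
        a = rng.normal(size=40)
        b = rng.normal(size=40)
        c = rng.normal(loc=3.0, size=40)
        reports = dunn_test([a, b, c], labels=["a", "b", "c"], adjust=False)
        by_pair = {r.labels: r.p_value for r in reports}
        assert by_pair[("a", "c")] < by_pair[("a", "b")]
        assert by_pair[("b", "c")] < by_pair[("a", "b")]

    def test_tie_correction_applied(self):
        # heavy ties shrink the rank variance; z grows relative to untied
        a = np.array([1.0, 1.0, 1.0, 2.0])
        b = np.array([2.0, 2.0, 3.0, 3.0])
        rep = dunn_test([a, b], adjust=False)[0]
        assert rep.p_value < 1.0
        n = 8
        untied_var = n * (n + 1) / 12.0
        _, counts = np.unique(np.concatenate([a, b]), return_counts=True)
        tie_term = np.sum(counts ** 3 - counts) / (12.0 * (n - 1))
        assert tie_term > 0  # the data really are tied


class TestReportContainers:
    def test_contingency_table_validation(self):
        with pytest.raises(ValueError):
            ms.ContingencyTable(np.array([[1, -1], [0, 2]]))
        with pytest.raises(ValueError):
            ms.ContingencyTable(np.array([1, 2, 3]))

    def test_p_value_range_enforced(self):
        with pytest.raises(ValueError):
            ms.TestReport("x", 0.0, 1, 1.5)


class TestBenchmarkReport:
    def test_report_sections_on_small_campaign(self):
        spec = ms.TreatmentSpec("meander_amplitude", (0.05, 0.15),
                                n_per_model=20, seed=9)
        res = ms.run_treatment(spec, ms.WindParams(), ms.PlumeParams(),
                               ms.SensorParams())
        rep = ms.benchmark_report(res, n_mc=2000,
                                  rng=np.random.default_rng(0))
        assert set(rep) >= {"fisher_overall", "fisher_pairwise",
                            "g2_per_level"}
        assert len(rep["fisher_pairwise"]) == 6
        for entry in rep["fisher_pairwise"]:
            assert entry["adjusted_p"] >= entry["p_value"]
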