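"""Distribution comparisons, colony inheritance statistics, phenotype correlation."""

import numpy as np
import pytest

from ephascore import popstats
from ephascore.popstats import (
    ColonySeries,
    ScoreDistribution,
    bootstrap_subset_test,
    colony_divergence_fraction,
    convergence_summary,
    ks_compare,
    kw_dunn,
    pairwise_ks_matrix,
    pearson_with_split,
)


def brute_force_ks_d(a, b):
    """Oracle: max ECDF difference swept over every observed value."""
    a, b = np.sort(a), np.sort(b)
    grid = np.concatenate([a, b])
    d = 0.0
    for x in grid:
        fa = np.searchsorted(a, x, side="right") / a.size
        fb = np.searchsorted(b, x, side="right") / b.size
        d = max(d, abs(fa - fb))
    return d


def dist(name, scores):
    return ScoreDistribution(name, np.asarray(scores, dtype=float))


class TestKS:
    def test_identical_distributions(self):
        a = dist("a", [0.1, 0.5, 0.9, 1.2, 1.4])
        d, p = ks_compare(a, dist("b", a.scores))
        assert d == 0.0 and p == 1.0

    def test_disjoint_supports(self):
        d, p = ks_compare(dist("a", [1, 2, 3, 4, 5]), dist("b", [10, 11, 12, 13, 14]))
        assert d == 1.0 and p < 0.05

    def test_interleaved_quartets(self):
        d, _ = ks_compare(
            dist("a", [1, 2, 3, 4]), dist("b", [1.5, 2.5, 3.5, 4.5]), min_n=4
        )
        assert d == pytest.approx(0.25)
        assert brute_force_ks_d(np.array([1, 2, 3, 4.0]),
                                np.array([1.5, 2.5, 3.5, 4.5])) == pytest.approx(0.25)

    def test_matches_brute_force_on_small_samples(self):
        rng = np.random.default_rng(3)
        for _ in range(200):
            na, nb = rng.integers(5, 21, 2)
            a = np.round(rng.normal(0, 1, na), 1)  # rounding forces ties
            b = np.round(rng.normal(0.3, 1.2, nb), 1)
            d, _ = ks_compare(dist("a", a), dist("b", b))
            assert d == pytest.approx(brute_force_ks_d(a, b), abs=1e-12)

    def test_undersized_rejected(self):
        with pytest.raises(ValueError):
            ks_compare(dist("a", [1, 2, 3]), dist("b", [1, 2, 3, 4, 5]))


class TestPairwiseKS:
    def test_identical_triplet_no_significance(self):
        base = np.linspace(0, 1, 50)
        dists = [dist(f"p{i}", base) for i in range(3)]
        pmat, frac = pairwise_ks_matrix(dists)
        assert frac == 0.0
        assert np.allclose(pmat.to_numpy(), 1.0)

    def test_matrix_symmetric_unit_diagonal(self):
        rng = np.random.default_rng(4)
        dists = [dist(f"p{i}", rng.normal(i * 0.3, 0.2, 40)) for i in range(4)]
        pmat, _ = pairwise_ks_matrix(dists)
        arr = pmat.to_numpy()
        assert np.allclose(arr, arr.T)
        assert np.allclose(np.diag(arr), 1.0)

    def test_twelve_distinct_lines_mostly_distinguished(self):
        """12 lines with distinct (mean, spread) profiles separate in >=90% of pairs."""
        rng = np.random.default_rng(5)
        dists = []
        for i in range(12):
            mean = 0.25 + 0.13 * i
            sd = 0.10 + 0.012 * i
            dists.append(dist(f"line{i}", np.clip(rng.normal(mean, sd, 200), 0, None)))
        _, frac = pairwise_ks_matrix(dists, alpha=0.05, correction="bonferroni")
        assert frac >= 0.9


class TestKWDunn:
    def test_hand_computed_example(self):
        """Three small groups; ranks and Dunn variance worked by hand."""
        groups = [np.array([1, 2, 3, 4, 5.0]), np.array([2, 3, 4, 5, 6.0]),
                  np.array([10, 11, 12, 13, 14.0])]
        omnibus_p, padj, sig = kw_dunn(groups)
        assert omnibus_p == pytest.approx(0.007261, abs=1e-5)  # matches R kruskal.test
        # mean ranks 4.6 / 6.4 / 13, pooled variance 7.942857 with tie correction
        assert padj[0, 1] == pytest.approx(1.0)
        assert padj[0, 2] == pytest.approx(0.008633, abs=1e-5)
        assert padj[1, 2] == pytest.approx(0.057568, abs=1e-5)
        assert sig == {(0, 2)}

    def test_identical_groups_nothing_significant(self):
        g = np.linspace(0, 1, 30)
        _, _, sig = kw_dunn([g, g, g])
        assert sig == set()

    def test_single_shifted_group_detected(self):
        rng = np.random.default_rng(6)
        groups = [rng.normal(0, 1, 50), rng.normal(0, 1, 50), rng.normal(2, 1, 50)]
        omnibus_p, _, sig = kw_dunn(groups)
        assert omnibus_p < 1e-6
        assert sig == {(0, 2), (1, 2)}

    def test_all_tied_warns_p_one(self):
        with pytest.warns(UserWarning):
            p, _, sig = kw_dunn([np.ones(10), np.ones(10)])
        assert p == 1.0 and sig == set()

    def test_omnibus_type_i_error(self):
        rng = np.random.default_rng(7)
        n_rep, rejections = 1000, 0
        for _ in range(n_rep):
            groups = [rng.normal(0, 1, 25) for _ in range(3)]
            p, _, _ = kw_dunn(groups)
            rejections += p < 0.05
        assert abs(rejections / n_rep - 0.05) < 3 * np.sqrt(0.05 * 0.95 / n_rep)


class TestBootstrapSubset:
    def test_colony_equal_to_baseline_gives_p_one(self, baseline_scores):
        p = bootstrap_subset_test(baseline_scores, baseline_scores, n_iter=1000, seed=0)
        assert p == 1.0

    def test_top_decile_colony_extreme(self, baseline_scores):
        colony = np.sort(baseline_scores)[-40:]
        p = bootstrap_subset_test(colony, baseline_scores, n_iter=2000, seed=1)
        assert p == pytest.approx(1 / 2001)

    def test_oversized_colony_rejected(self, baseline_scores):
        with pytest.raises(ValueError):
            bootstrap_subset_test(np.ones(500), baseline_scores)

    def test_reproducible_under_seed(self, baseline_scores):
        colony = baseline_scores[:30] + 0.05
        p1 = bootstrap_subset_test(colony, baseline_scores, n_iter=1000, seed=9)
        p2 = bootstrap_subset_test(colony, baseline_scores, n_iter=1000, seed=9)
        assert p1 == p2

    def test_ks_statistic_variant(self, baseline_scores):
        colony = np.sort(baseline_scores)[-40:]
        p = bootstrap_subset_test(colony, baseline_scores, n_iter=1000, seed=2,
                                  statistic="ks")
        assert p == pytest.approx(1 / 1001)

    def test_null_p_values_uniform(self, baseline_scores):
        """True random subsets give calibrated (uniform) p-values."""
        from scipy import stats as sps

        rng = np.random.default_rng(10)
        pvals = []
        for _ in range(300):
            colony = rng.choice(baseline_scores, size=30, replace=False)
            pvals.append(
                bootstrap_subset_test(colony, baseline_scores, n_iter=1999,
                                      seed=int(rng.integers(2**31 - 1)))
            )
        _, p = sps.kstest(pvals, "uniform")
        assert p > 0.01

    def test_power_monotone_in_offset(self, baseline_scores):
        """Shifting the colony further from the baseline mean shrinks p."""
        subset = baseline_scores[:40]
        centered = subset - subset.mean() + baseline_scores.mean()
        pvals = []
        for offset in (0.0, 0.04, 0.12):
            pvals.append(bootstrap_subset_test(centered + offset, baseline_scores,
                                               n_iter=4999, seed=3))
        assert pvals[0] > pvals[1] > pvals[2]


def _colonies(baseline_scores, w, seed=0, n=9):
    from ephascore.synthetic import ColonySynthParams, generate_colony_series

    founders = np.quantile(baseline_scores, np.linspace(0.05, 0.95, n))
    return generate_colony_series(ColonySynthParams(
        population_scores=baseline_scores, n_colonies=n, founders=founders,
        intra_colony_sd_day10=0.05, convergence_weight_day20=w,
        cells_per_colony_per_day=40, seed=seed,
    ))


class TestColonyStats:
    def test_null_divergence_fraction_near_zero(self, baseline_scores):
        rng = np.random.default_rng(11)
        colonies = [
            ColonySeries(
                colony_id=f"c{i}",
                day10=dist(f"c{i}_10", rng.choice(baseline_scores, 40)),
                day20=dist(f"c{i}_20", rng.choice(baseline_scores, 40)),
                baseline=dist("base", baseline_scores),
            )
            for i in range(6)
        ]
        assert colony_divergence_fraction(colonies, day=10) <= 0.05 + 1e-9

    def test_spread_founders_fully_divergent(self, baseline_scores):
        """Widely spaced founders with tight day-10 spreads: ~every pair differs."""
        from ephascore.synthetic import ColonySynthParams, generate_colony_series

        colonies = generate_colony_series(ColonySynthParams(
            population_scores=baseline_scores, n_colonies=5,
            founders=np.linspace(0.1, 1.1, 5), intra_colony_sd_day10=0.02,
            cells_per_colony_per_day=40, seed=1,
        ))
        assert colony_divergence_fraction(colonies, day=10) >= 0.9

    def test_divergence_drops_with_convergence(self, baseline_scores):
        colonies = _colonies(baseline_scores, w=1.0, seed=2)
        f10 = colony_divergence_fraction(colonies, day=10)
        f20 = colony_divergence_fraction(colonies, day=20)
        assert f20 < f10

    def test_order_invariance(self, baseline_scores):
        colonies = _colonies(baseline_scores, w=0.5, seed=3)
        frac = colony_divergence_fraction(colonies, day=10)
        assert colony_divergence_fraction(colonies[::-1], day=10) == frac

    def test_convergence_summary_shape_and_w0_cv_ratio(self, baseline_scores):
        colonies = _colonies(baseline_scores, w=0.0, seed=4)
        summary = convergence_summary(colonies)
        assert len(summary.table) == 9
        assert 0.5 < summary.cv_ratio_min and summary.cv_ratio_max < 2.0

    def test_full_convergence_pulls_means_to_baseline(self, baseline_scores):
        colonies = _colonies(baseline_scores, w=1.0, seed=5)
        summary = convergence_summary(colonies)
        closer = (summary.table["abs_dev20"] < summary.table["abs_dev10"]).sum()
        assert closer >= 8


class TestPearsonWithSplit:
    def test_exact_linear(self):
        x = {f"p{i}": 0.1 * i for i in range(6)}
        y = {k: 2 * v + 1 for k, v in x.items()}
        report = pearson_with_split(x, y)
        assert report.overall_r == pytest.approx(1.0)

    def test_independent_mean_r_near_zero(self):
        rng = np.random.default_rng(12)
        rs = []
        for _ in range(500):
            x = {f"p{i}": v for i, v in enumerate(rng.normal(0.4, 0.2, 11))}
            y = {f"p{i}": v for i, v in enumerate(rng.normal(0, 1, 11))}
            rs.append(pearson_with_split(x, y).overall_r)
        assert abs(np.mean(rs)) < 0.05

    def test_piecewise_relation_split_beats_overall(self):
        """Different slopes on either side of the threshold: group r > overall r."""
        rng = np.random.default_rng(13)
        x_vals = np.concatenate([rng.uniform(0.05, 0.35, 6), rng.uniform(0.45, 1.0, 6)])
        y_vals = np.where(x_vals < 0.4, 5 * x_vals, -2 * x_vals + 4)
        y_vals = y_vals + rng.normal(0, 0.05, x_vals.size)
        x = {f"p{i}": v for i, v in enumerate(x_vals)}
        y = {f"p{i}": v for i, v in enumerate(y_vals)}
        report = pearson_with_split(x, y, threshold=0.4)
        assert len(report.low_members) == 6 and len(report.high_members) == 6
        assert abs(report.group_low_r) > abs(report.overall_r)
        assert abs(report.group_high_r) > abs(report.overall_r)

    def test_zero_variance_flagged(self):
        x = {"a": 0.5, "b": 0.5, "c": 0.5}
        y = {"a": 1.0, "b": 2.0, "c": 3.0}
        with pytest.raises(ValueError, match="zero-variance"):
            pearson_with_split(x, y)

    def test_small_group_gets_no_group_r(self):
        x = {"a": 0.1, "b": 0.2, "c": 0.6, "d": 0.7, "e": 0.8}
        y = {k: i * 1.0 for i, k in enumerate(x)}
        report = pearson_with_split(x, y)
        assert report.group_low_r is None
        assert report.group_high_r is not None
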