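import numpy as np
import pandas as pd
import pytest

import panemt
from panemt.stats import PURITY_INTERCEPT, PURITY_SLOPE, _breslow_loglik


def grid_search_cox_beta(time, event, covariate, lo=-3.0, hi=3.0, n=24001):
    """Independent maximizer: evaluate the Breslow partial likelihood on a grid."""
    grid = np.linspace(lo, hi, n)
    t = np.asarray(time, dtype=float)
    e = np.asarray(event, dtype=float)
    x = np.asarray(covariate, dtype=float)
    x = x - x.mean()
    lls = [_grid_ll(b, t, e, x) for b in grid]
    return grid[int(np.argmax(lls))]


def _grid_ll(beta, t, e, x):
    """Breslow partial log-likelihood by direct per-event summation."""
    ll = 0.0
    for i in range(len(t)):
        if e[i] == 1:
            risk = t >= t[i]
            ll += beta * x[i] - np.log(np.exp(beta * x[risk]).sum())
    return ll


class TestCoxUnivariate:
    def test_matches_grid_search_oracle_on_small_instances(self):
        rng = np.random.default_rng(0)
        for trial in range(5):
            n = 40
            x = rng.normal(size=n)
            t = rng.exponential(1.0 / (0.05 * np.exp(0.7 * x)))
            e = (rng.random(n) > 0.25).astype(int)
            if e.sum() == 0:
                continue
            res = panemt.cox_univariate(t, e, x)
            beta_grid = grid_search_cox_beta(t, e, x)
            assert res.beta == pytest.approx(beta_grid, abs=1e-3)

    def test_handles_ties_with_breslow_convention(self):
        t = np.array([1.0, 1.0, 2.0, 2.0, 3.0, 4.0])
        e = np.array([1, 1, 1, 0, 1, 1])
        x = np.array([0.5, -0.2, 1.0, 0.0, -1.0, 0.3])
        res = panemt.cox_univariate(t, e, x)
        beta_grid = grid_search_cox_beta(t, e, x)
        assert res.beta == pytest.approx(beta_grid, abs=1e-3)

    def test_true_hazard_ratio_recovered(self):
        rng = np.random.default_rng(1)
        n = 1000
        group = rng.integers(0, 2, size=n).astype(float)
        t = rng.exponential(1.0 / (0.02 * np.exp(np.log(2.0) * group)))
        e = np.ones(n, dtype=int)
        res = panemt.cox_univariate(t, e, group)
        assert 1.8 <= res.hr <= 2.2

    def test_null_covariate_calibration(self):
        """beta = 0: the Wald interval covers zero in >= 93/100 replicates."""
        rng = np.random.default_rng(2)
        covered = 0
        for _ in range(100):
            n = 500
            x = rng.normal(size=n)
            t = rng.exponential(10.0, size=n)
            e = (rng.random(n) > 0.3).astype(int)
            res = panemt.cox_univariate(t, e, x)
            if abs(res.beta) < 2 * res.se:
                covered += 1
        assert covered >= 93

    def test_degenerate_inputs_raise(self):
        with pytest.raises(ValueError, match="no events"):
            panemt.cox_univariate([1, 2, 3], [0, 0, 0], [1.0, 2.0, 3.0])
        with pytest.raises(ValueError, match="constant"):
            panemt.cox_univariate([1, 2, 3], [1, 1, 0], [1.0, 1.0, 1.0])

    def test_loglik_derivatives_consistent(self):
        rng = np.random.default_rng(3)
        t = rng.exponential(5, 20)
        e = (rng.random(20) > 0.3).astype(float)
        x = rng.normal(size=20)
        eps = 1e-6
        for beta in (-0.5, 0.0, 1.2):
            _, d1, d2 = _breslow_loglik(beta, t, e, x)
            llp, d1p, _ = _breslow_loglik(beta + eps, t, e, x)
            llm, d1m, _ = _breslow_loglik(beta - eps, t, e, x)
            assert d1 == pytest.approx((llp - llm) / (2 * eps), abs=1e-4)
            assert d2 == pytest.approx((d1p - d1m) / (2 * eps), abs=1e-4)


class TestKaplanMeier:
    def test_uncensored_median(self):
        t = np.arange(1.0, 11.0)
        km = panemt.km_summary(t, np.ones(10), ["all"] * 10)
        assert km.table.iloc[0]["median"] == pytest.approx(5.0)

    def test_all_censored_group_median_not_reached(self):
        t = [1.0, 2.0, 3.0, 1.0, 2.0, 3.0]
        e = [0, 0, 0, 1, 1, 1]
        g = ["cens"] * 3 + ["obs"] * 3
        km = panemt.km_summary(t, e, g)
        row = km.table.set_index("group")
        assert np.isnan(row.loc["cens", "median"])
        assert row.loc["obs", "median"] == pytest.approx(2.0)

    def test_km_equals_empirical_survival_without_censoring(self):
        rng = np.random.default_rng(0)
        t = rng.exponential(5, 50)
        km = panemt.km_summary(t, np.ones(50), ["g"] * 50)
        curve = km.curves["g"]
        for _, row in curve.iloc[1:].iterrows():
            emp = (t > row["time"]).mean()
            assert row["survival"] == pytest.approx(emp, abs=1e-12)

    def test_separated_groups_give_small_logrank_p(self):
        t = np.concatenate([np.full(30, 2.0) + np.arange(30) * 0.01,
                            np.full(30, 20.0) + np.arange(30) * 0.01])
        e = np.ones(60)
        g = ["short"] * 30 + ["long"] * 30
        km = panemt.km_summary(t, e, g)
        assert km.logrank_p < 1e-6

    def test_median_split_helper(self):
        scores = pd.Series([1.0, 2.0, 3.0, 4.0], index=list("abcd"))
        groups = panemt.median_split_groups(scores)
        assert groups.tolist() == ["low", "low", "high", "high"]


class TestPurity:
    def test_zero_score(self):
        out = panemt.estimate_purity([0.0])
        assert out["purity"].iloc[0] == pytest.approx(np.cos(0.6049872018), abs=1e-10)
        assert out["purity"].iloc[0] == pytest.approx(0.82251, abs=1e-4)

    def test_score_at_half_pi_argument(self):
        s = (np.pi / 2 - PURITY_INTERCEPT) / PURITY_SLOPE
        out = panemt.estimate_purity([s])
        assert out["purity"].iloc[0] == pytest.approx(0.0, abs=1e-10)
        assert s == pytest.approx(6579.6, abs=0.1)

    def test_monotone_decreasing_within_range(self):
        scores = np.linspace(0, (np.pi - PURITY_INTERCEPT) / PURITY_SLOPE, 50)
        out = panemt.estimate_purity(scores)
        assert out["in_range"].all()
        assert (np.diff(out["purity"]) < 0).all()

    def test_out_of_range_flagged_not_rejected(self):
        out = panemt.estimate_purity([-1e6])
        assert not out["in_range"].iloc[0]


class TestCategoryNormalization:
    def test_hand_example(self):
        counts = pd.DataFrame({"c1": [50], "c2": [150]}, index=["BRCA"])
        out = panemt.normalize_category_counts(counts, target=100)
        assert out.loc["BRCA"].tolist() == [25.0, 75.0]

    def test_already_normalized_unchanged(self):
        counts = pd.DataFrame({"c1": [40, 70], "c2": [60, 30]}, index=["A", "B"])
        out = panemt.normalize_category_counts(counts, target=100)
        pd.testing.assert_frame_equal(out, counts.astype(float))

    def test_proportions_preserved_and_composition_sums_to_100(self):
        rng = np.random.default_rng(0)
        counts = pd.DataFrame(rng.integers(1, 500, size=(6, 4)),
                              index=[f"T{i}" for i in range(6)],
                              columns=[f"c{i}" for i in range(4)])
        out = panemt.normalize_category_counts(counts)
        ratio = out.div(counts)
        for _, row in ratio.iterrows():
            assert np.allclose(row, row.iloc[0])
        comp = panemt.category_composition(out)
        assert comp.sum() == pytest.approx(100.0)

    def test_zero_total_row_dropped(self):
        counts = pd.DataFrame({"c1": [10, 0], "c2": [10, 0]}, index=["ok", "empty"])
        out = panemt.normalize_category_counts(counts)
        assert list(out.index) == ["ok"]


class TestBalancedSampling:
    @staticmethod
    def _cohort(shift, n_cancers=6, n_per_cluster=12, seed=0):
        rng = np.random.default_rng(seed)
        rows = []
        for ci in range(n_cancers):
            for cl in (1, 2, 3, 4):
                for j in range(n_per_cluster):
                    mu = shift if cl in (3, 4) else 0.0
                    rows.append({
                        "sample": f"c{ci}_k{cl}_{j}",
                        "cancer": f"T{ci}",
                        "cluster": cl,
                        "score": rng.normal(mu, 1.0),
                    })
        df = pd.DataFrame(rows).set_index("sample")
        return df["score"], df["cluster"], df["cancer"]

    def test_planted_shift_consistent_every_iteration(self):
        scores, clusters, cancers = self._cohort(shift=2.0)
        comparison = panemt.score_enhanced_in([3, 4], [1, 2])
        report = panemt.balanced_sampling_validation(
            scores, clusters, cancers, comparison, n_per=10, iterations=100, seed=1)
        assert report.n_consistent == 100
        assert report.fraction_consistent == 1.0

    def test_null_shift_rarely_consistent(self):
        scores, clusters, cancers = self._cohort(shift=0.0, seed=5)
        comparison = panemt.score_enhanced_in([3, 4], [1, 2])
        report = panemt.balanced_sampling_validation(
            scores, clusters, cancers, comparison, n_per=10, iterations=100, seed=2)
        # four one-sided tests must all pass at alpha=0.05 under the null
        assert report.n_consistent < 20

    def test_reproducible_and_order_invariant(self):
        scores, clusters, cancers = self._cohort(shift=0.3, seed=3)
        comparison = panemt.score_enhanced_in([3, 4], [1, 2])
        a = panemt.balanced_sampling_validation(scores, clusters, cancers,
                                                comparison, iterations=20, seed=9)
        perm = np.random.default_rng(0).permutation(len(scores))
        b = panemt.balanced_sampling_validation(scores.iloc[perm], clusters, cancers,
                                                comparison, iterations=20, seed=9)
        assert a.verdicts == b.verdicts

    def test_small_cells_take_all_available(self):
        scores, clusters, cancers = self._cohort(shift=2.0, n_per_cluster=4)
        comparison = panemt.score_enhanced_in([3, 4], [1, 2])
        report = panemt.balanced_sampling_validation(
            scores, clusters, cancers, comparison, n_per=10, iterations=10, seed=0)
        assert report.n_iterations == 10

    def test_shortest_median_survival_verdict(self):
        rng = np.random.default_rng(4)
        rows = []
        for ci in range(4):
            for cl in (1, 2, 3):
                scale = 2.0 if cl == 3 else 10.0
                for j in range(25):
                    rows.append({
                        "sample": f"c{ci}_k{cl}_{j}",
                        "cancer": f"T{ci}",
                        "cluster": cl,
                        "survival_time": rng.exponential(scale),
                        "event": 1,
                    })
        df = pd.DataFrame(rows).set_index("sample")
        comparison = panemt.shortest_median_survival(3)
        report = panemt.balanced_sampling_validation(
            df[["survival_time", "event"]], df["cluster"], df["cancer"],
            comparison, n_per=10, iterations=20, seed=0)
        assert report.fraction_consistent >= 0.9
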