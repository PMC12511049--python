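import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from eegmst.cohort_stats import (
    correlation_table,
    dunn_posthoc,
    holm_adjust,
    kruskal_wallis,
    mann_whitney,
    pearson,
    results_to_frame,
    run_group_analysis,
)
from eegmst.exceptions import DesignError, ParameterError


class TestKruskalWallis:
    def test_non_overlapping_groups(self):
        h, df, p = kruskal_wallis([[1, 2, 3], [4, 5, 6], [7, 8, 9]])
        assert h == pytest.approx(7.2)
        assert df == 2
        assert p == pytest.approx(float(sps.chi2.sf(7.2, 2)))

    def test_identical_groups(self):
        h, df, p = kruskal_wallis([[5, 5, 5], [5, 5, 5]])
        assert h == 0.0
        assert p == 1.0

    def test_matches_scipy_with_ties(self, rng):
        for _ in range(20):
            groups = [rng.integers(0, 8, size=rng.integers(4, 12)).astype(float) for _ in range(3)]
            h, df, p = kruskal_wallis(groups)
            ref = sps.kruskal(*groups)
            assert h == pytest.approx(ref.statistic)
            assert p == pytest.approx(ref.pvalue)

    def test_two_group_rank_sum_relation(self, rng):
        # with 2 groups and no ties, H equals z² of the rank-sum statistic
        a, b = rng.permutation(40)[:18].astype(float), rng.permutation(100)[50:72].astype(float) + 0.5
        h, df, p = kruskal_wallis([a, b])
        assert df == 1
        ref = sps.kruskal(a, b)
        assert h == pytest.approx(ref.statistic)

    def test_monotone_transform_invariance(self, rng):
        groups = [rng.normal(size=10), rng.normal(1, 1, size=12), rng.normal(size=9)]
        h1, _, _ = kruskal_wallis(groups)
        h2, _, _ = kruskal_wallis([np.exp(2 * g) for g in groups])
        assert h1 == pytest.approx(h2)

    def test_preconditions(self):
        with pytest.raises(ParameterError):
            kruskal_wallis([[1.0, 2.0]])
        with pytest.raises(ParameterError):
            kruskal_wallis([[1.0], []])


class TestDunn:
    def test_separated_groups(self, rng):
        samples = [
            rng.normal(0, 1, 25),
            rng.normal(4, 1, 25),
            rng.normal(8, 1, 25),
        ]
        pvals = dunn_posthoc(samples, ["a", "b", "c"])
        assert all(p < 0.01 for p in pvals.values())

    def test_identical_pair(self):
        data = [1.0, 2.0, 3.0, 4.0, 5.0]
        pvals = dunn_posthoc([data, list(data)], ["a", "b"])
        assert pvals[("a", "b")] > 0.95

    def test_against_permutation_oracle(self, rng):
        # two-sided Dunn p for one pair vs. label-permutation distribution of
        # the mean-rank difference (10⁴ shuffles)
        a = rng.normal(0.0, 1.0, 20)
        b = rng.normal(0.8, 1.0, 22)
        c = rng.normal(0.4, 1.0, 18)
        p_normal = dunn_posthoc([a, b, c], ["a", "b", "c"])[("a", "b")]

        pooled = np.concatenate([a, b, c])
        ranks = sps.rankdata(pooled)
        ra, rb = ranks[:20], ranks[20:42]
        observed = abs(ra.mean() - rb.mean())
        count = 0
        n_shuffles = 10_000
        for _ in range(n_shuffles):
            perm = rng.permutation(ranks)
            if abs(perm[:20].mean() - perm[20:42].mean()) >= observed - 1e-12:
                count += 1
        p_perm = count / n_shuffles
        assert p_normal == pytest.approx(p_perm, abs=0.03)

    def test_null_calibration(self, rng):
        # identically distributed pair: rejection rate at α=0.05 in [0.03, 0.07]
        n_reps, rejections = 1000, 0
        for _ in range(n_reps):
            a = rng.normal(size=50)
            b = rng.normal(size=50)
            if dunn_posthoc([a, b], ["a", "b"])[("a", "b")] < 0.05:
                rejections += 1
        assert 0.03 <= rejections / n_reps <= 0.07

    def test_empty_group(self):
        with pytest.raises(ParameterError):
            dunn_posthoc([[1.0], []], ["a", "b"])


class TestHolm:
    def test_worked_example(self):
        assert holm_adjust([0.01, 0.04, 0.03]) == pytest.approx([0.03, 0.06, 0.06])

    def test_single_p_unchanged(self):
        assert holm_adjust([0.2]) == [0.2]

    def test_cap_and_step_down(self):
        assert holm_adjust([0.5, 0.9]) == pytest.approx([1.0, 1.0])

    def test_matches_statsmodels(self, rng):
        from statsmodels.stats.multitest import multipletests

        for _ in range(10):
            p = rng.uniform(size=7)
            ours = holm_adjust(p.tolist())
            theirs = multipletests(p, method="holm")[1]
            np.testing.assert_allclose(ours, theirs, atol=1e-12)

    def test_order_invariance(self, rng):
        p = rng.uniform(size=9)
        perm = rng.permutation(9)
        direct = np.asarray(holm_adjust(p.tolist()))
        permuted = np.asarray(holm_adjust(p[perm].tolist()))
        np.testing.assert_allclose(direct[perm], permuted)

    def test_adjusted_at_least_raw(self, rng):
        p = rng.uniform(size=12)
        adj = holm_adjust(p.tolist())
        assert all(a >= r for a, r in zip(adj, p))

    def test_invalid_p(self):
        with pytest.raises(ParameterError):
            holm_adjust([0.5, 1.2])


class TestMannWhitney:
    def test_complete_separation(self):
        u, p = mann_whitney([4, 5, 6], [1, 2, 3])
        assert u == 9.0  # all b < all a: U for a is n_a*n_b
        u_rev, _ = mann_whitney([1, 2, 3], [4, 5, 6])
        assert u_rev == 0.0

    def test_identical_samples(self):
        u, p = mann_whitney([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert p > 0.9

    def test_against_permutation(self, rng):
        a = rng.normal(0, 1, 12)
        b = rng.normal(0.7, 1, 14)
        _, p = mann_whitney(a, b)
        ref = sps.permutation_test(
            (a, b),
            lambda x, y: sps.rankdata(np.concatenate([x, y]))[: len(x)].sum(),
            permutation_type="independent",
            alternative="two-sided",
            n_resamples=10_000,
            random_state=0,
        )
        assert p == pytest.approx(ref.pvalue, abs=0.03)


class TestPearson:
    def test_perfect_linear(self):
        x = np.arange(10.0)
        res = pearson(x, 2 * x + 1)
        assert res.r == pytest.approx(1.0)
        res_neg = pearson(x, -x)
        assert res_neg.r == pytest.approx(-1.0)

    def test_matches_scipy(self, rng):
        x, y = rng.normal(size=30), rng.normal(size=30)
        res = pearson(x, y)
        ref_r, ref_p = sps.pearsonr(x, y)
        assert res.r == pytest.approx(ref_r)
        assert res.p == pytest.approx(ref_p)

    def test_partial_removes_confound(self, rng):
        n = 200
        z = rng.normal(size=n)
        x = z + 0.5 * rng.normal(size=n)
        y = z + 0.5 * rng.normal(size=n)
        plain = pearson(x, y)
        adjusted = pearson(x, y, covariates=z)
        assert plain.r > 0.5
        assert abs(adjusted.r) < 0.15

    def test_partial_matches_pingouin(self, rng):
        import pingouin as pg

        n = 60
        covs = rng.normal(size=(n, 2))
        x = covs @ [0.5, -0.3] + rng.normal(size=n)
        y = covs @ [0.2, 0.4] + rng.normal(size=n)
        res = pearson(x, y, covariates=covs)
        df = pd.DataFrame({"x": x, "y": y, "c1": covs[:, 0], "c2": covs[:, 1]})
        ref = pg.partial_corr(df, x="x", y="y", covar=["c1", "c2"])
        assert res.r == pytest.approx(float(ref["r"].iloc[0]), abs=1e-10)
        assert res.p == pytest.approx(float(ref["p_val"].iloc[0]), abs=1e-10)

    def test_empty_covariates_equal_plain(self, rng):
        x, y = rng.normal(size=25), rng.normal(size=25)
        assert pearson(x, y).r == pearson(x, y, covariates=np.empty((25, 0))).r

    def test_zero_variance(self):
        with pytest.raises(ParameterError):
            pearson([1.0, 1.0, 1.0, 1.0], [1.0, 2.0, 3.0, 4.0])


def _metrics_table(rng, effect_band=None, effect_metric=None, shift=0.0, n_per_group=(12, 12, 12)):
    bands = ["theta", "beta"]
    metrics = ["mean_pli", "leaf_fraction"]
    rows, labels = [], {}
    groups = ["HC", "MCI-AD", "AD"]
    sid = 0
    for g, n in zip(groups, n_per_group):
        for _ in range(n):
            subject = f"s{sid:03d}"
            labels[subject] = g
            sid += 1
            for band in bands:
                for metric in metrics:
                    value = rng.normal()
                    if g == "AD" and band == effect_band and metric == effect_metric:
                        value += shift
                    rows.append(
                        {"subject": subject, "band": band, "metric": metric, "value": value}
                    )
    return pd.DataFrame(rows), pd.Series(labels)


class TestRunGroupAnalysis:
    def test_injected_effect_flagged(self, rng):
        table, groups = _metrics_table(rng, "theta", "mean_pli", shift=3.0)
        results = run_group_analysis(table, groups)
        flagged = {r.metric for r in results if r.p_adjusted < 0.05}
        assert ("theta", "mean_pli") in flagged
        hit = next(r for r in results if r.metric == ("theta", "mean_pli"))
        assert hit.pairwise  # post-hoc ran
        assert hit.pairwise[("HC", "AD")] < 0.05

    def test_null_cells_mostly_clean(self, rng):
        rejections = 0
        cells = 0
        for _ in range(30):
            table, groups = _metrics_table(rng)
            for r in run_group_analysis(table, groups):
                cells += 1
                if r.p_adjusted < 0.05:
                    rejections += 1
        assert rejections / cells < 0.05

    def test_single_group_design_error(self, rng):
        table, groups = _metrics_table(rng, n_per_group=(10, 0, 0))
        table = table[table.subject.map(groups) == "HC"]
        with pytest.raises(DesignError):
            run_group_analysis(table, groups)

    def test_missing_group_label(self, rng):
        table, groups = _metrics_table(rng)
        with pytest.raises(DesignError):
            run_group_analysis(table, groups.drop("s000"))

    def test_family_rules(self, rng):
        table, groups = _metrics_table(rng, "theta", "mean_pli", shift=3.0)
        per_band = run_group_analysis(table, groups, family_rule="per_band")
        global_ = run_group_analysis(table, groups, family_rule="global")
        target = ("theta", "mean_pli")
        p_band = next(r for r in per_band if r.metric == target).p_adjusted
        p_glob = next(r for r in global_ if r.metric == target).p_adjusted
        assert p_glob >= p_band  # global family is at least as conservative

    def test_results_frame(self, rng):
        table, groups = _metrics_table(rng)
        frame = results_to_frame(run_group_analysis(table, groups))
        assert {"band", "metric", "chi2", "p", "p_holm"}.issubset(frame.columns)
        assert len(frame) == 4


class TestCorrelationTable:
    def test_all_pairs_and_partial(self, rng):
        n = 50
        idx = [f"s{i}" for i in range(n)]
        z = rng.normal(size=n)
        features = pd.DataFrame(
            {"theta:mean_pli": z + 0.3 * rng.normal(size=n), "beta:kappa": rng.normal(size=n)},
            index=idx,
        )
        targets = pd.DataFrame({"MMSE": -z + 0.3 * rng.normal(size=n)}, index=idx)
        plain = correlation_table(features, targets)
        assert len(plain) == 2
        hit = plain[plain.x == "theta:mean_pli"].iloc[0]
        assert hit.r < -0.5 and hit.p < 0.01

        covs = pd.DataFrame({"z": z}, index=idx)
        adjusted = correlation_table(features, targets, covariates=covs)
        adj = adjusted[adjusted.x == "theta:mean_pli"].iloc[0]
        assert abs(adj.r) < abs(hit.r)  # confound explains the association

    def test_missing_values_dropped_pairwise(self, rng):
        idx = [f"s{i}" for i in range(10)]
        features = pd.DataFrame({"f": rng.normal(size=10)}, index=idx)
        targets = pd.DataFrame({"t": rng.normal(size=10)}, index=idx)
        targets.iloc[:3, 0] = np.nan
        out = correlation_table(features, targets)
        assert out.iloc[0].n == 7
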