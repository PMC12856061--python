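"""Statistical battery and the study-table reproduction driver."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest

from osseoquant import stats
from osseoquant.synthetic import generate_cohort


def table(**groups):
    rows = [{"group": g, "value": v} for g, vals in groups.items() for v in vals]
    return pd.DataFrame(rows)


class TestShapiroWilk:
    def test_n3_matches_closed_form(self):
        """For n = 3 the W statistic has the closed form
        ((x(3) - x(1)) / sqrt(2))^2 / sum((x - xbar)^2)."""
        x = np.array([7514.0, 7586.0, 7763.0])
        res = stats.shapiro_wilk(x)
        hand = ((x.max() - x.min()) / math.sqrt(2)) ** 2 / ((x - x.mean()) ** 2).sum()
        assert res.statistic == pytest.approx(hand, abs=1e-6)

    def test_constant_sample_flagged(self):
        with pytest.warns(UserWarning):
            res = stats.shapiro_wilk([5.0, 5.0, 5.0])
        assert np.isnan(res.p)

    def test_sample_size_bounds(self):
        with pytest.raises(ValueError):
            stats.shapiro_wilk([1.0, 2.0])

    def test_type_one_error_calibrated(self):
        """Under normality the test rejects at about the nominal level."""
        rng = np.random.default_rng(11)
        rejections = sum(stats.shapiro_wilk(rng.normal(size=10)).p < 0.05 for _ in range(5000))
        assert rejections / 5000 == pytest.approx(0.05, abs=0.01)


class TestAnova:
    def test_volume_table_p_value(self):
        t = table(NS=[5793, 6289, 6961], BMP=[7514, 7586, 7763], DIPY=[5936, 6325, 7137])
        res = stats.one_way_anova(t)
        assert res.p == pytest.approx(0.036362, abs=1e-5)
        assert res.df == (2, 6)

    def test_identical_groups_give_zero_f(self):
        res = stats.one_way_anova(table(a=[3, 3], b=[3, 3]))
        assert res.statistic == 0.0 and res.p == 1.0

    def test_separated_constant_groups_give_zero_p(self):
        res = stats.one_way_anova(table(a=[1, 1], b=[2, 2]))
        assert math.isinf(res.statistic) and res.p == 0.0

    def test_unbalanced_design_drops_missing(self):
        t = table(NS=[55, 54, 86], BMP=[100, 100], DIPY=[85, 68, 79])
        res = stats.one_way_anova(t)
        assert res.df == (2, 5)
        assert res.p == pytest.approx(0.0749, abs=1e-3)

    def test_two_group_anova_equals_squared_t(self):
        rng = np.random.default_rng(4)
        a, b = rng.normal(size=6), rng.normal(loc=0.5, size=8)
        f = stats.one_way_anova(table(a=a, b=b))
        t = stats.pooled_t_test(a, b)
        assert f.statistic == pytest.approx(t.statistic**2, rel=1e-10)
        assert f.p == pytest.approx(t.p, rel=1e-10)

    def test_permutation_oracle_small_groups(self):
        """ANOVA p agrees with the full permutation distribution of F for
        n = 3 per group on well-behaved data."""
        from scipy.stats import f_oneway

        values = np.array([1.2, 2.1, 0.4, 1.8, 0.9, 1.5, 2.4, 0.2, 1.1])
        observed = f_oneway(values[:3], values[3:6], values[6:]).statistic
        count = total = 0
        all_idx = set(range(9))
        for ga in itertools.combinations(range(9), 3):
            rest = sorted(all_idx - set(ga))
            for gb in itertools.combinations(rest, 3):
                gc = sorted(set(rest) - set(gb))
                f = f_oneway(values[list(ga)], values[list(gb)], values[gc]).statistic
                count += f >= observed - 1e-12
                total += 1
        perm_p = count / total
        res = stats.one_way_anova(
            pd.DataFrame({"group": ["a"] * 3 + ["b"] * 3 + ["c"] * 3, "value": values})
        )
        # the F reference distribution is only an approximation at n=3;
        # agreement to ~0.05 in p is the realistic expectation
        assert res.p == pytest.approx(perm_p, abs=0.05)


class TestTukey:
    def test_identical_groups_p_one(self):
        out = stats.tukey_hsd(table(a=[2, 2, 2], b=[2, 2, 2]))
        assert out[("a", "b")].p == 1.0

    def test_large_separation_significant(self):
        rng = np.random.default_rng(0)
        t = table(a=rng.normal(0, 1, 5), b=rng.normal(0, 1, 5), c=rng.normal(10, 1, 5))
        out = stats.tukey_hsd(t)
        assert out[("a", "c")].p < 0.001
        assert out[("b", "c")].p < 0.001

    def test_matches_statsmodels_reference(self):
        """Independent cross-check on a random 3x5 table."""
        sm = pytest.importorskip("statsmodels.stats.multicomp")
        rng = np.random.default_rng(7)
        t = table(a=rng.normal(0, 1, 5), b=rng.normal(1, 1, 5), c=rng.normal(2, 1, 5))
        ours = stats.tukey_hsd(t)
        ref = sm.pairwise_tukeyhsd(t["value"], t["group"])
        pairs = [(row[0], row[1]) for row in ref._results_table.data[1:]]
        for (g1, g2), padj in zip(pairs, ref.pvalues):
            assert ours[(g1, g2)].p == pytest.approx(float(padj), abs=1e-6)


class TestTTests:
    def test_volume_pairwise_round_to_printed_values(self):
        bmp = [7514, 7586, 7763]
        assert round(stats.pooled_t_test(bmp, [5793, 6289, 6961]).p, 2) == 0.02
        assert round(stats.pooled_t_test(bmp, [5936, 6325, 7137]).p, 2) == 0.03

    def test_identical_samples(self):
        res = stats.pooled_t_test([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.statistic == 0.0 and res.p == 1.0

    def test_zero_variance_equal_means(self):
        res = stats.pooled_t_test([2.0, 2.0], [2.0, 2.0])
        assert res.p == 1.0

    def test_bonferroni_never_decreases(self):
        res = stats.pooled_t_test([1.0, 2.0, 3.0], [2.0, 3.0, 5.0])
        adj = stats.bonferroni(res, 3)
        assert adj.p >= res.p
        assert adj.adjusted
        assert stats.bonferroni(res, 100).p == 1.0


class TestRankTests:
    def test_disjoint_n3_exact_p_matches_enumeration(self):
        """p = 0.1 for fully separated samples of 3 vs 3, verified by
        enumerating all 20 group assignments."""
        a, b = [1.0, 2.0, 3.0], [10.0, 11.0, 12.0]
        res = stats.mann_whitney(a, b)
        assert res.statistic == 0.0
        pooled = a + b
        observed_u = 0
        extreme = total = 0
        for combo in itertools.combinations(range(6), 3):
            ga = [pooled[i] for i in combo]
            gb = [pooled[i] for i in range(6) if i not in combo]
            u = sum(1 for x in ga for y in gb if x > y)
            # two-sided: as or more extreme in either tail
            extreme += min(u, 9 - u) <= min(observed_u, 9 - observed_u)
            total += 1
        assert res.p == pytest.approx(extreme / total)
        assert res.p == pytest.approx(0.1)

    def test_all_tied_gives_p_one(self):
        assert stats.mann_whitney([5.0], [5.0]).p == 1.0
        t = table(a=[5.0, 5.0], b=[5.0, 5.0])
        assert stats.kruskal_wallis(t).p == 1.0
        dunn = stats.dunn_posthoc(t)
        assert dunn[("a", "b")].p == 1.0

    def test_null_rejection_rate_calibrated(self):
        """Mann–Whitney at alpha = 0.05 rejects at about 5% under the null."""
        rng = np.random.default_rng(21)
        rejections = 0
        n_sims = 2000
        for _ in range(n_sims):
            a, b = rng.normal(size=20), rng.normal(size=20)
            rejections += stats.mann_whitney(a, b).p < 0.05
        assert rejections / n_sims == pytest.approx(0.05, abs=0.02)

    def test_dunn_matches_hand_ranks(self):
        """Dunn z for a toy table against an explicitly hand-ranked formula."""
        t = table(a=[1.0, 2.0, 3.0], b=[4.0, 5.0, 6.0], c=[7.0, 8.0, 9.0])
        out = stats.dunn_posthoc(t, adjust="none")
        # ranks are 1..9 with no ties: mean ranks 2, 5, 8; var base N(N+1)/12
        se = math.sqrt(9 * 10 / 12 * (1 / 3 + 1 / 3))
        z_ac = (2 - 8) / se
        from scipy.stats import norm

        assert out[("a", "c")].statistic == pytest.approx(z_ac)
        assert out[("a", "c")].p == pytest.approx(2 * norm.sf(abs(z_ac)))

    def test_dunn_separation_property(self):
        rng = np.random.default_rng(2)
        t = table(a=rng.normal(0, 1, 8), b=rng.normal(0, 1, 8), c=rng.normal(10, 1, 8))
        out = stats.dunn_posthoc(t)
        assert out[("a", "c")].p < 0.01
        assert out[("a", "b")].p > 0.1


@pytest.fixture(scope="module")
def report():
    return stats.reproduce_tables()


class TestReproduceTables:

    def test_group_means_match_printed(self, report):
        for qty in ("microct_bridging_pct", "volume_mm3", "histology_interior_pct"):
            for g, cell in report["group_means"][qty].items():
                assert cell["match"], (qty, g, cell)

    def test_key_p_values_match_printed(self, report):
        assert report["anova"]["volume"]["match"]
        assert report["anova"]["microct_bridging"]["match"]
        assert report["ttests"]["BMP_vs_NS"]["match"]
        assert report["ttests"]["BMP_vs_DIPY"]["match"]

    def test_interior_anova_discrepancy_is_flagged_not_forced(self, report):
        """The printed interior ANOVA p (0.226) is not recoverable from the
        printed per-subject values (computation gives 0.230); the driver
        reports the computed value and flags the mismatch."""
        cell = report["anova"]["histology_interior"]
        assert cell["computed"] == pytest.approx(0.2299, abs=1e-3)
        assert not cell["match"]

    def test_printed_sds_flagged(self, report):
        """Printed +/- values do not equal the sample SDs of the printed
        per-subject volumes; both are reported, mismatches flagged."""
        sds = report["sd"]["volume_mm3"]
        assert sds["BMP"]["computed"] == pytest.approx(128.1, abs=0.1)
        assert not sds["BMP"]["match"]

    def test_markdown_rendering(self, report):
        text = stats.report_to_markdown(report)
        assert "volume_mm3" in text and "| BMP |" in text

    def test_missing_fixture_dir_raises(self, tmp_path):
        with pytest.raises(FileNotFoundError):
            stats.reproduce_tables(tmp_path)


class TestCohortNullCalibration:
    def test_pooled_t_type_one_error(self):
        """Pooled t on simulated two-group null cohorts rejects at ~5%.

        Uses a vectorized simulation of 10 000 cohorts (n = 5 per group).
        """
        from scipy.stats import ttest_ind

        rng = np.random.default_rng(101)
        a = rng.normal(size=(10_000, 5))
        b = rng.normal(size=(10_000, 5))
        p = ttest_ind(a, b, axis=1, equal_var=True).pvalue
        # sanity: vectorized scipy agrees with our wrapper on one cohort
        assert stats.pooled_t_test(a[0], b[0]).p == pytest.approx(p[0], rel=1e-12)
        assert (p < 0.05).mean() == pytest.approx(0.05, abs=0.01)
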