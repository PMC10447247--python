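"""Genotype F-test methods and frequency-curve aggregation."""

import numpy as np
import pandas as pd
import pytest

from septamorph import (
    distance_map,
    generate_stripe_mask,
    genotype_f_test,
    genotype_frequency_curves,
    thickness_histogram,
)

from conftest import make_cohort_table


def sequential_anova_oracle(table: pd.DataFrame) -> tuple[float, int, int]:
    """Closed-form sums-of-squares computation of the sequential F.

    SS(genotype | intercept) from genotype means; residual SS from the
    full cell-mean fit (each mouse its own mean, since mouse is the finest
    term of the nested design).
    """
    y = table["mean_thickness_um"].to_numpy(float)
    n = y.size
    grand = y.mean()
    ss_cond = 0.0
    for g in table["genotype"].unique():
        sub = y[(table["genotype"] == g).to_numpy()]
        ss_cond += sub.size * (sub.mean() - grand) ** 2
    sse_full = 0.0
    for m in table["mouse_id"].unique():
        sub = y[(table["mouse_id"] == m).to_numpy()]
        sse_full += ((sub - sub.mean()) ** 2).sum()
    n_mice = table["mouse_id"].nunique()
    df_den = n - n_mice  # rank of intercept+genotype+mouse = number of mice
    F = (ss_cond / 1.0) / (sse_full / df_den)
    return F, 1, df_den


@pytest.fixture
def balanced_table():
    """2 genotypes x 2 mice x 3 images with mouse and image variation."""
    return make_cohort_table(
        {
            "c1": ("control", [3.0, 3.2, 3.1]),
            "c2": ("control", [2.8, 3.0, 2.9]),
            "k1": ("cKO", [4.1, 4.3, 4.2]),
            "k2": ("cKO", [4.4, 4.6, 4.5]),
        }
    )


class TestSequentialAnova:
    def test_matches_closed_form_sums_of_squares(self, balanced_table):
        res = genotype_f_test(balanced_table, "sequential_anova")
        F, df_num, df_den = sequential_anova_oracle(balanced_table)
        assert res.df_num == df_num and res.df_den == df_den
        assert abs(res.F_statistic - F) / F < 1e-10

    def test_pure_shift_gives_infinite_f_and_tiny_p(self):
        table = make_cohort_table(
            {
                "c1": ("control", [3.0, 3.0, 3.0]),
                "c2": ("control", [3.0, 3.0, 3.0]),
                "k1": ("cKO", [4.0, 4.0, 4.0]),
                "k2": ("cKO", [4.0, 4.0, 4.0]),
            }
        )
        res = genotype_f_test(table, "sequential_anova")
        assert res.p_value < 1e-6
        # residual SS is zero up to float cancellation, so F blows up
        assert np.isinf(res.F_statistic) or res.F_statistic > 1e12

    def test_row_order_invariance(self, balanced_table, rng):
        res = genotype_f_test(balanced_table, "sequential_anova")
        shuffled = balanced_table.sample(frac=1.0, random_state=4).reset_index(drop=True)
        res2 = genotype_f_test(shuffled, "sequential_anova")
        assert np.isclose(res.F_statistic, res2.F_statistic)
        assert np.isclose(res.p_value, res2.p_value)

    def test_mouse_relabeling_invariance(self, balanced_table):
        relabeled = balanced_table.assign(
            mouse_id=balanced_table["mouse_id"].map(
                {"c1": "zz9", "c2": "aa1", "k1": "mm5", "k2": "qq7"}
            )
        )
        res = genotype_f_test(balanced_table)
        res2 = genotype_f_test(relabeled)
        assert np.isclose(res.F_statistic, res2.F_statistic)

    def test_genotype_coefficient_reported(self, balanced_table):
        res = genotype_f_test(balanced_table, "sequential_anova")
        assert "condition[cKO]" in res.coefficients


class TestMouseLevelMethods:
    def test_stratum_equals_anova_on_mouse_means(self, balanced_table):
        res = genotype_f_test(balanced_table, "mouse_stratum")
        means = balanced_table.groupby("mouse_id")["mean_thickness_um"].mean()
        a = means[["c1", "c2"]].to_numpy()
        b = means[["k1", "k2"]].to_numpy()
        grand = np.concatenate([a, b]).mean()
        ssb = 2 * (a.mean() - grand) ** 2 + 2 * (b.mean() - grand) ** 2
        ssw = ((a - a.mean()) ** 2).sum() + ((b - b.mean()) ** 2).sum()
        F = ssb / (ssw / 2)
        assert np.isclose(res.F_statistic, F)
        assert (res.df_num, res.df_den) == (1, 2)

    def test_aggregated_t_squared_equals_stratum_f(self, balanced_table):
        stratum = genotype_f_test(balanced_table, "mouse_stratum")
        agg = genotype_f_test(balanced_table, "mouse_aggregated")
        assert np.isclose(stratum.F_statistic, agg.F_statistic)
        assert np.isclose(stratum.p_value, agg.p_value)

    def test_single_mouse_per_genotype_rejected(self):
        table = make_cohort_table(
            {"c1": ("control", [3.0, 3.1]), "k1": ("cKO", [4.0, 4.1])}
        )
        with pytest.raises(ValueError, match="2 mice"):
            genotype_f_test(table, "mouse_stratum")


class TestTableValidation:
    def test_all_identical_values_rejected(self, balanced_table):
        table = balanced_table.assign(mean_thickness_um=3.0)
        with pytest.raises(ValueError, match="identical"):
            genotype_f_test(table)

    def test_mouse_with_two_genotypes_rejected(self, balanced_table):
        bad = balanced_table.copy()
        bad.loc[bad.index[-1], "mouse_id"] = "c1"
        with pytest.raises(ValueError, match="multiple genotypes"):
            genotype_f_test(bad)

    def test_unknown_method_rejected(self, balanced_table):
        with pytest.raises(ValueError, match="method"):
            genotype_f_test(balanced_table, "mixed_model")


class TestFrequencyCurves:
    def _hist(self, thickness_px, width_px=16):
        stripe = generate_stripe_mask(24, thickness_px, width_px)
        tm = distance_map(stripe, border_is_background=False)
        return thickness_histogram(tm, stripe.pixel_size_um)

    def test_single_mouse_single_image_identity(self):
        h = self._hist(5)
        mouse, geno = genotype_frequency_curves(
            [dict(image_id="i", mouse_id="m1", genotype="control", histogram=h)]
        )
        got = mouse["relative_frequency"].to_numpy()
        assert np.allclose(got, h.relative_frequency)
        assert np.allclose(
            geno["relative_frequency"].to_numpy(), h.relative_frequency
        )

    def test_genotype_mean_curves_sum_to_one(self):
        records = [
            dict(image_id="i1", mouse_id="c1", genotype="control", histogram=self._hist(3)),
            dict(image_id="i2", mouse_id="c1", genotype="control", histogram=self._hist(5)),
            dict(image_id="i3", mouse_id="c2", genotype="control", histogram=self._hist(7)),
            dict(image_id="i4", mouse_id="k1", genotype="cKO", histogram=self._hist(9)),
            dict(image_id="i5", mouse_id="k2", genotype="cKO", histogram=self._hist(5)),
        ]
        mouse, geno = genotype_frequency_curves(records)
        for _, grp in geno.groupby("genotype"):
            assert abs(grp["relative_frequency"].sum() - 1.0) < 1e-12
        for _, grp in mouse.groupby("mouse_id"):
            assert abs(grp["relative_frequency"].sum() - 1.0) < 1e-12

    def test_mouse_curve_pools_counts_not_frequencies(self):
        # images of unequal foreground size: pooling counts weights by size
        h_small = self._hist(3, width_px=8)
        h_big = self._hist(5, width_px=64)
        mouse, _ = genotype_frequency_curves(
            [
                dict(image_id="a", mouse_id="m", genotype="control", histogram=h_small),
                dict(image_id="b", mouse_id="m", genotype="control", histogram=h_big),
            ]
        )
        n_bins = mouse.shape[0]
        pooled = np.zeros(n_bins)
        for h in (h_small, h_big):
            pooled[: h.counts.size] += h.counts
        assert np.allclose(
            mouse["relative_frequency"].to_numpy(), pooled / pooled.sum()
        )

    def test_mismatched_bin_grids_rejected(self):
        stripe = generate_stripe_mask(24, 5, 16)
        tm = distance_map(stripe, border_is_background=False)
        h1 = thickness_histogram(tm, 0.276)
        h2 = thickness_histogram(tm, 0.5)
        with pytest.raises(ValueError, match="mismatched bin grids"):
            genotype_frequency_curves(
                [
                    dict(image_id="a", mouse_id="m1", genotype="control", histogram=h1),
                    dict(image_id="b", mouse_id="m2", genotype="cKO", histogram=h2),
                ]
            )
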