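"""OCR reductions, TIC normalization, NADH/NAD+ ratios and the
ANOVA + FDR metabolite filter."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from septamorph import (
    anova_fdr_filter,
    basal_ocr,
    coupled_ocr,
    nadh_nad_ratio,
    tic_normalize,
)


def make_trace(wells: dict[str, dict[str, list[float]]]) -> pd.DataFrame:
    rows = []
    for well, phases in wells.items():
        for phase, values in phases.items():
            for cycle, v in enumerate(values, start=1):
                rows.append({"well": well, "phase": phase, "cycle": cycle, "ocr": v})
    return pd.DataFrame(rows)


SIMPLE = {
    "A1": {
        "baseline": [100.0, 98.0, 102.0],
        "oligomycin": [50.0],
        "antimycin_piericidin": [20.0, 20.0, 20.0],
    }
}


class TestOCR:
    def test_basal_is_baseline_minus_nonmito(self):
        out = basal_ocr(make_trace(SIMPLE))
        assert np.isclose(out.loc[0, "basal_ocr"], 80.0)
        assert not out.loc[0, "negative_basal"]

    def test_all_phases_equal_gives_zero_basal(self):
        trace = make_trace(
            {"A1": {p: [42.0, 42.0] for p in
                    ("baseline", "oligomycin", "antimycin_piericidin")}}
        )
        assert basal_ocr(trace).loc[0, "basal_ocr"] == 0.0

    def test_negative_basal_flagged_not_clamped(self):
        trace = make_trace(
            {"A1": {"baseline": [10.0], "oligomycin": [5.0],
                    "antimycin_piericidin": [30.0]}}
        )
        out = basal_ocr(trace)
        assert out.loc[0, "basal_ocr"] == -20.0
        assert out.loc[0, "negative_basal"]

    def test_coupled_as_written(self):
        out = coupled_ocr(make_trace(SIMPLE))
        assert np.isclose(out.loc[0, "coupled_ocr"], 30.0)  # (100-20) - 50

    def test_coupled_when_oligo_equals_baseline(self):
        trace = make_trace(
            {"A1": {"baseline": [100.0], "oligomycin": [100.0],
                    "antimycin_piericidin": [20.0]}}
        )
        out = coupled_ocr(trace)
        assert np.isclose(out.loc[0, "coupled_ocr"], -20.0)  # -(non-mito)

    def test_coupled_variant_corrects_oligo_for_nonmito(self):
        out = coupled_ocr(make_trace(SIMPLE), correct_oligo_for_nonmito=True)
        assert np.isclose(out.loc[0, "coupled_ocr"], 50.0)  # (100-20) - (50-20)

    def test_missing_phase_rejected(self):
        trace = make_trace({"A1": {"baseline": [100.0], "oligomycin": [50.0]}})
        with pytest.raises(ValueError, match="missing phase"):
            basal_ocr(trace)

    def test_constant_offset_cancels(self):
        """Basal OCR is offset-invariant; coupled OCR is only under the
        non-mito-corrected variant (the as-written rule subtracts one more
        baseline-free term than it adds, shifting by -c)."""
        trace = make_trace(SIMPLE)
        shifted = trace.assign(ocr=trace["ocr"] + 37.5)
        base, base_s = basal_ocr(trace), basal_ocr(shifted)
        assert np.isclose(base.loc[0, "basal_ocr"], base_s.loc[0, "basal_ocr"])
        coup = coupled_ocr(trace, correct_oligo_for_nonmito=True)
        coup_s = coupled_ocr(shifted, correct_oligo_for_nonmito=True)
        assert np.isclose(coup.loc[0, "coupled_ocr"], coup_s.loc[0, "coupled_ocr"])
        # the as-written rule shifts by exactly -c
        raw = coupled_ocr(trace)
        raw_s = coupled_ocr(shifted)
        assert np.isclose(raw_s.loc[0, "coupled_ocr"],
                          raw.loc[0, "coupled_ocr"] - 37.5)

    def test_last_k_cycles_summary(self):
        trace = make_trace(
            {"A1": {"baseline": [80.0, 100.0, 120.0], "oligomycin": [50.0],
                    "antimycin_piericidin": [20.0, 20.0]}}
        )
        out = basal_ocr(trace, last_k_cycles=1)
        assert np.isclose(out.loc[0, "basal_ocr"], 100.0)  # last baseline cycle only


class TestTICNormalization:
    @pytest.fixture
    def matrix(self):
        return pd.DataFrame(
            {"NADH": [20.0, 80.0], "NAD+": [30.0, 40.0], "lactate": [50.0, 80.0]},
            index=["s1", "s2"],
        )

    def test_two_sample_toy_matches_direct_formula(self, matrix):
        # totals 100 and 200; cohort mean total 150
        normed = tic_normalize(matrix)
        expected = matrix.to_numpy() / np.array([[100.0], [200.0]]) * 150.0
        assert np.allclose(normed.to_numpy(), expected)
        assert np.allclose(normed.sum(axis=1), 150.0)

    def test_equal_totals_unchanged(self):
        m = pd.DataFrame({"a": [10.0, 30.0], "b": [40.0, 20.0]}, index=["s1", "s2"])
        assert np.allclose(tic_normalize(m).to_numpy(), m.to_numpy())

    def test_idempotent(self, matrix):
        once = tic_normalize(matrix)
        twice = tic_normalize(once)
        assert np.allclose(once.to_numpy(), twice.to_numpy())

    def test_within_sample_ratios_preserved(self, matrix):
        normed = tic_normalize(matrix)
        for s in matrix.index:
            assert np.isclose(
                normed.at[s, "NADH"] / normed.at[s, "lactate"],
                matrix.at[s, "NADH"] / matrix.at[s, "lactate"],
            )

    def test_zero_total_sample_rejected(self):
        m = pd.DataFrame({"a": [1.0, 0.0], "b": [2.0, 0.0]}, index=["s1", "s2"])
        with pytest.raises(ValueError, match="total ion count"):
            tic_normalize(m)


class TestNADHRatio:
    def test_simple_ratio(self):
        m = pd.DataFrame({"NADH": [200.0], "NAD+": [100.0]}, index=["s1"])
        assert nadh_nad_ratio(m, "s1") == 2.0

    def test_invariant_under_tic_normalization(self):
        m = pd.DataFrame(
            {"NADH": [200.0, 90.0], "NAD+": [100.0, 60.0], "lactate": [5.0, 250.0]},
            index=["s1", "s2"],
        )
        normed = tic_normalize(m)
        for s in m.index:
            assert np.isclose(nadh_nad_ratio(m, s), nadh_nad_ratio(normed, s))

    def test_zero_nad_rejected(self):
        m = pd.DataFrame({"NADH": [200.0], "NAD+": [0.0]}, index=["s1"])
        with pytest.raises(ValueError, match="detection"):
            nadh_nad_ratio(m, "s1")

    def test_missing_feature_rejected(self):
        m = pd.DataFrame({"NADH": [200.0]}, index=["s1"])
        with pytest.raises(ValueError, match="not in matrix"):
            nadh_nad_ratio(m, "s1")


class TestAnovaFdrFilter:
    @staticmethod
    def bh_adjust_oracle(pvals):
        """Textbook step-up BH adjustment."""
        p = np.asarray(pvals, float)
        m = p.size
        order = np.argsort(p)
        adj = np.empty(m)
        running = 1.0
        for rank_from_top, idx in enumerate(order[::-1]):
            rank = m - rank_from_top
            running = min(running, p[idx] * m / rank)
            adj[idx] = running
        return adj

    def test_three_group_toy_matches_direct_formulas(self):
        rng = np.random.default_rng(11)
        X = rng.normal(10.0, 1.0, size=(9, 6))
        X[:3, 0] += 4.0  # one shifted metabolite
        groups = ["g1"] * 3 + ["g2"] * 3 + ["g3"] * 3
        matrix = pd.DataFrame(X, columns=[f"met{i}" for i in range(6)])
        anova, lsd = anova_fdr_filter(matrix, groups, fdr_threshold=0.05)

        for j, met in enumerate(matrix.columns):
            F, p = stats.f_oneway(X[:3, j], X[3:6, j], X[6:, j])
            assert abs(anova.loc[j, "F"] - F) < 1e-10 * max(F, 1)
            assert abs(anova.loc[j, "p_value"] - p) < 1e-12
        assert np.allclose(
            anova["p_adj"].to_numpy(),
            self.bh_adjust_oracle(anova["p_value"].to_numpy()),
            atol=1e-12,
        )

    def test_large_shift_always_selected_with_lsd_labels(self):
        rng = np.random.default_rng(5)
        X = rng.normal(100.0, 1.0, size=(12, 20))
        X[:6, 3] += 10.0  # 10 pooled SDs
        groups = ["a"] * 6 + ["b"] * 6
        matrix = pd.DataFrame(X, columns=[f"met{i}" for i in range(20)])
        anova, lsd = anova_fdr_filter(matrix, groups)
        assert bool(anova.loc[3, "selected"])
        pair = lsd[lsd["metabolite"] == "met3"]
        assert len(pair) == 1 and pair.iloc[0]["p_value"] < 1e-6

    def test_lsd_uses_pooled_error(self):
        rng = np.random.default_rng(2)
        X = rng.normal(0.0, 1.0, size=(9, 3))
        X[:, 1] += np.repeat([0.0, 5.0, 10.0], 3)
        groups = ["a"] * 3 + ["b"] * 3 + ["c"] * 3
        _, lsd = anova_fdr_filter(pd.DataFrame(X, columns=list("xyz")), groups)
        row = lsd[(lsd["metabolite"] == "y") & (lsd["group_a"] == "a")
                  & (lsd["group_b"] == "b")].iloc[0]
        # oracle: pooled within-group MSE with N-k df
        sub = X[:, 1]
        mse = sum(((sub[i:i + 3] - sub[i:i + 3].mean()) ** 2).sum()
                  for i in (0, 3, 6)) / 6
        t = (sub[:3].mean() - sub[3:6].mean()) / np.sqrt(mse * (2 / 3))
        assert np.isclose(row["t"], t)
        assert np.isclose(row["p_value"], 2 * stats.t.sf(abs(t), 6))

    def test_threshold_monotonicity(self):
        rng = np.random.default_rng(21)
        X = rng.normal(0, 1, size=(12, 40))
        X[:6, :5] += rng.uniform(1, 3, size=5)
        groups = ["a"] * 6 + ["b"] * 6
        matrix = pd.DataFrame(X, columns=[f"m{i}" for i in range(40)])
        prev = None
        for thr in (0.2, 0.1, 0.05, 0.01):
            sel = set(
                anova_fdr_filter(matrix, groups, fdr_threshold=thr)[0]
                .query("selected")["metabolite"]
            )
            if prev is not None:
                assert sel <= prev
            prev = sel

    def test_degenerate_groups_rejected(self):
        m = pd.DataFrame(np.ones((3, 2)), columns=["a", "b"])
        with pytest.raises(ValueError, match=">= 2 samples"):
            anova_fdr_filter(m, ["g1", "g1", "g2"])
        with pytest.raises(ValueError, match="2 groups"):
            anova_fdr_filter(m, ["g1", "g1", "g1"])
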