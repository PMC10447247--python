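"""Genotype inference on per-image mean septal thickness.

The readout is one mean thickness per field of view, with 4-6 fields per
mouse and several mice per genotype.  The model of record regresses
thickness on genotype plus per-mouse indicator terms,

    Thickness = b0 + b1 * Condition(genotype) + sum_i bi * Mouse_i,

and reports an F-test for the genotype term.  Because every mouse belongs
to exactly one genotype, the mouse indicators are nested in genotype and
the design is rank deficient as written: the genotype coefficient is not
separately identifiable.  Three operationalizations are provided:

``sequential_anova``
    Pivoted least squares with rank-deficient columns dropped, genotype
    entered before mouse; F for genotype from the sequential (type-I)
    ANOVA table against the image-level residual mean square.  This treats
    fields of view as independent replicates and is anti-conservative with
    respect to mouse-to-mouse variation.
``mouse_stratum``
    Tests genotype against mouse-within-genotype variation on per-mouse
    mean thickness — the correctly calibrated test for a nested design.
``mouse_aggregated``
    Pooled two-sample comparison of per-mouse means (t^2 = F; identical to
    mouse_stratum for two genotypes).

Per-genotype relative-frequency curves (one pooled, renormalized curve per
mouse; per-genotype mean of mouse curves) are aggregated here as well.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .morphometry import GENOTYPES, ThicknessHistogram

__all__ = [
    "FTestResult",
    "F_TEST_METHODS",
    "validate_cohort_table",
    "genotype_f_test",
    "genotype_frequency_curves",
]

F_TEST_METHODS = ("sequential_anova", "mouse_stratum", "mouse_aggregated")

REQUIRED_COLUMNS = ("image_id", "mouse_id", "genotype", "mean_thickness_um")


@dataclass(frozen=True)
class FTestResult:
    """Genotype F-test with the fitted coefficients of retained terms."""

    F_statistic: float
    df_num: int
    df_den: int
    p_value: float
    coefficients: dict[str, float]
    method: str

    def __post_init__(self):
        if self.F_statistic < 0:
            raise ValueError("F statistic must be non-negative")
        if self.df_num < 1 or self.df_den < 1:
            raise ValueError("degrees of freedom must be positive")
        if not 0 <= self.p_value <= 1:
            raise ValueError("p-value must lie in [0, 1]")


def validate_cohort_table(table: pd.DataFrame) -> pd.DataFrame:
    """Check the per-image summary table invariants.

    Every mouse must map to exactly one genotype and genotypes must be
    known labels.  Returns the table (untouched) for chaining.
    """
    missing = [c for c in REQUIRED_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"cohort table missing columns: {missing}")
    bad = set(table["genotype"].unique()) - set(GENOTYPES)
    if bad:
        raise ValueError(f"unknown genotype labels: {sorted(bad)}")
    geno_per_mouse = table.groupby("mouse_id")["genotype"].nunique()
    if (geno_per_mouse > 1).any():
        offenders = geno_per_mouse[geno_per_mouse > 1].index.tolist()
        raise ValueError(f"mice mapped to multiple genotypes: {offenders}")
    return table


def _pivoted_ols(X: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, float, int, list[int]]:
    """Least squares with rank-deficient columns dropped by QR pivoting.

    Returns (coefficients over retained columns, SSE, rank, retained column
    indices).  Mirrors how standard statistical software resolves aliased
    terms: the first linearly independent columns, in pivot order, are kept.
    """
    from scipy.linalg import qr

    Q, R, piv = qr(X, mode="economic", pivoting=True)
    diag = np.abs(np.diag(R))
    tol = max(X.shape) * np.finfo(float).eps * (diag[0] if diag.size else 0.0)
    rank = int((diag > tol).sum())
    keep = sorted(piv[:rank])
    Xr = X[:, keep]
    beta, _, _, _ = np.linalg.lstsq(Xr, y, rcond=None)
    resid = y - Xr @ beta
    return beta, float(resid @ resid), rank, keep


def _sequential_anova(table: pd.DataFrame) -> FTestResult:
    y = table["mean_thickness_um"].to_numpy(dtype=float)
    n = y.size
    cond = (table["genotype"].to_numpy() == "cKO").astype(float)
    mice = pd.get_dummies(table["mouse_id"], dtype=float)
    mouse_names = [f"mouse[{m}]" for m in mice.columns]

    X0 = np.ones((n, 1))
    X1 = np.column_stack([X0, cond])
    X2 = np.column_stack([X1, mice.to_numpy()])
    names = ["intercept", "condition[cKO]", *mouse_names]

    _, sse0, _, _ = _pivoted_ols(X0, y)
    _, sse1, rank1, _ = _pivoted_ols(X1, y)
    beta, sse2, rank2, keep = _pivoted_ols(X2, y)

    df_cond = rank1 - 1
    df_resid = n - rank2
    if df_cond < 1:
        raise ValueError("genotype term is aliased; need both genotypes present")
    if df_resid < 1:
        raise ValueError("no residual degrees of freedom")
    ss_cond = sse0 - sse1
    ms_resid = sse2 / df_resid
    coefs = {names[j]: float(b) for j, b in zip(keep, beta)}
    if ms_resid <= 0:
        # perfect within-cell fit: a genotype shift with no residual noise
        F = float("inf") if ss_cond > 0 else 0.0
        p = 0.0 if ss_cond > 0 else 1.0
        return FTestResult(F, df_cond, df_resid, p, coefs, "sequential_anova")
    F = (ss_cond / df_cond) / ms_resid
    p = float(stats.f.sf(F, df_cond, df_resid))
    return FTestResult(float(F), df_cond, df_resid, p, coefs, "sequential_anova")


def _mouse_means(table: pd.DataFrame) -> pd.DataFrame:
    per_mouse = (
        table.groupby(["mouse_id", "genotype"], observed=True)["mean_thickness_um"]
        .mean()
        .reset_index()
    )
    counts = per_mouse.groupby("genotype", observed=True)["mouse_id"].count()
    if (counts < 2).any() or counts.size < 2:
        raise ValueError("mouse-level methods need >= 2 mice in each genotype")
    return per_mouse


def _mouse_stratum(table: pd.DataFrame) -> FTestResult:
    per_mouse = _mouse_means(table)
    y = per_mouse["mean_thickness_um"].to_numpy(dtype=float)
    g = per_mouse["genotype"].to_numpy()
    groups = [y[g == lab] for lab in np.unique(g)]
    m = y.size
    k = len(groups)
    grand = y.mean()
    ss_between = sum(len(gr) * (gr.mean() - grand) ** 2 for gr in groups)
    ss_within = sum(((gr - gr.mean()) ** 2).sum() for gr in groups)
    df_num, df_den = k - 1, m - k
    if ss_within <= 0 and ss_between <= 0:
        raise ValueError("zero variance: all mouse means identical; F-test undefined")
    if ss_within <= 0:
        return FTestResult(
            float("inf"), df_num, df_den, 0.0,
            _genotype_means(per_mouse), "mouse_stratum",
        )
    F = (ss_between / df_num) / (ss_within / df_den)
    p = float(stats.f.sf(F, df_num, df_den))
    return FTestResult(float(F), df_num, df_den, p, _genotype_means(per_mouse),
                       "mouse_stratum")


def _mouse_aggregated(table: pd.DataFrame) -> FTestResult:
    per_mouse = _mouse_means(table)
    a = per_mouse.loc[per_mouse["genotype"] == "control", "mean_thickness_um"].to_numpy()
    b = per_mouse.loc[per_mouse["genotype"] == "cKO", "mean_thickness_um"].to_numpy()
    t, p = stats.ttest_ind(b, a, equal_var=True)
    df_den = a.size + b.size - 2
    if np.isnan(t):
        raise ValueError("zero variance: all mouse means identical; test undefined")
    return FTestResult(
        float(t) ** 2, 1, df_den, float(p), _genotype_means(per_mouse),
        "mouse_aggregated",
    )


def _genotype_means(per_mouse: pd.DataFrame) -> dict[str, float]:
    means = per_mouse.groupby("genotype", observed=True)["mean_thickness_um"].mean()
    out = {f"mean[{g}]": float(v) for g, v in means.items()}
    if {"control", "cKO"} <= set(means.index):
        out["effect[cKO-control]"] = float(means["cKO"] - means["control"])
    return out


def genotype_f_test(
    table: pd.DataFrame, method: str = "sequential_anova"
) -> FTestResult:
    """F-test for genotype on per-image mean thickness.

    ``table`` is the per-image summary (columns image_id, mouse_id,
    genotype, mean_thickness_um).  Results are invariant to row order and
    to mouse relabeling.
    """
    if method not in F_TEST_METHODS:
        raise ValueError(f"method must be one of {F_TEST_METHODS}")
    table = validate_cohort_table(table)
    if table["genotype"].nunique() < 2:
        raise ValueError("need both genotypes present")
    if float(np.var(table["mean_thickness_um"].to_numpy(dtype=float))) == 0.0:
        raise ValueError("all thickness values identical; F-test undefined")
    if method == "sequential_anova":
        return _sequential_anova(table)
    if method == "mouse_stratum":
        return _mouse_stratum(table)
    return _mouse_aggregated(table)


def genotype_frequency_curves(
    histograms: pd.DataFrame | list[dict],
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Aggregate per-image thickness histograms into per-mouse and
    per-genotype relative-frequency curves.

    Input: records with fields ``image_id``, ``mouse_id``, ``genotype`` and
    ``histogram`` (a :class:`~septamorph.morphometry.ThicknessHistogram`).
    All histograms must share the bin grid (same width and zero origin);
    since trailing empty bins are trimmed per image, shorter histograms are
    padded with empty bins to the common length.

    A mouse's curve pools the raw counts over its images and renormalizes;
    the genotype curve is the unweighted mean of its mouse curves (so it
    sums to one as well).  Returns ``(mouse_curves, genotype_curves)`` as
    tidy frames with columns bin_low_um, bin_high_um, relative_frequency.
    """
    if isinstance(histograms, pd.DataFrame):
        records = histograms.to_dict("records")
    else:
        records = list(histograms)
    if not records:
        raise ValueError("no histograms supplied")

    widths = {round(r["histogram"].bin_width_um, 12) for r in records}
    origins = {round(float(r["histogram"].bin_edges_um[0]), 12) for r in records}
    if len(widths) > 1 or len(origins) > 1:
        raise ValueError("histograms are on mismatched bin grids; rebin first")
    width = records[0]["histogram"].bin_width_um
    n_bins = max(r["histogram"].counts.size for r in records)

    def padded(hist: ThicknessHistogram) -> np.ndarray:
        out = np.zeros(n_bins, dtype=np.int64)
        out[: hist.counts.size] = hist.counts
        return out

    mouse_geno: dict[str, str] = {}
    mouse_counts: dict[str, np.ndarray] = {}
    for r in records:
        mid = r["mouse_id"]
        prev = mouse_geno.setdefault(mid, r["genotype"])
        if prev != r["genotype"]:
            raise ValueError(f"mouse {mid} mapped to multiple genotypes")
        mouse_counts[mid] = mouse_counts.get(mid, 0) + padded(r["histogram"])

    lows = np.arange(n_bins) * width
    highs = lows + width
    mouse_rows = []
    curves: dict[str, np.ndarray] = {}
    for mid, counts in mouse_counts.items():
        freq = counts / counts.sum()
        curves[mid] = freq
        for lo, hi, f, c in zip(lows, highs, freq, counts):
            mouse_rows.append(
                {
                    "mouse_id": mid,
                    "genotype": mouse_geno[mid],
                    "bin_low_um": lo,
                    "bin_high_um": hi,
                    "count": int(c),
                    "relative_frequency": f,
                }
            )
    mouse_curves = pd.DataFrame(mouse_rows)

    geno_rows = []
    for geno in sorted({g for g in mouse_geno.values()}):
        members = [curves[mid] for mid, g in mouse_geno.items() if g == geno]
        mean_curve = np.mean(members, axis=0)
        for lo, hi, f in zip(lows, highs, mean_curve):
            geno_rows.append(
                {
                    "genotype": geno,
                    "bin_low_um": lo,
                    "bin_high_um": hi,
                    "relative_frequency": f,
                }
            )
    genotype_curves = pd.DataFrame(geno_rows)
    return mouse_curves, genotype_curves
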