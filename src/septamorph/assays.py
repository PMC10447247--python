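"""Formula-level reductions of extracellular-flux and metabolomics assays.

Oxygen consumption rate (OCR) traces from a plate-based flux assay are
reduced to two per-well numbers: basal mitochondrial respiration (baseline
minus the non-mitochondrial OCR remaining under antimycin A + piericidin A)
and coupled respiration (basal minus the OCR under the ATP-synthase
inhibitor oligomycin).  By default the oligomycin term is used as written;
a flag additionally subtracts the non-mitochondrial OCR from it first,
the conventional correction.

Metabolite peak-area matrices are normalized by total ion count (TIC) per
sample, rescaled to the cohort mean total so magnitudes stay comparable to
the raw data.  NADH/NAD+ ratios are computed within a sample, so they are
invariant to any per-sample scaling.  Group-differential metabolites are
selected by per-metabolite one-way ANOVA with Benjamini-Hochberg FDR
control, and Fisher's least-significant-difference pairwise comparisons
(pooled within-group error) label which groups differ.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "OCR_PHASES",
    "validate_ocr_trace",
    "basal_ocr",
    "coupled_ocr",
    "tic_normalize",
    "nadh_nad_ratio",
    "anova_fdr_filter",
]

OCR_PHASES = ("baseline", "oligomycin", "antimycin_piericidin")


def validate_ocr_trace(trace: pd.DataFrame) -> pd.DataFrame:
    """Check a tidy OCR trace (columns well, phase, cycle, ocr).

    Every well must carry at least one measurement cycle in every phase.
    """
    required = {"well", "phase", "cycle", "ocr"}
    missing = required - set(trace.columns)
    if missing:
        raise ValueError(f"OCR trace missing columns: {sorted(missing)}")
    bad = set(trace["phase"].unique()) - set(OCR_PHASES)
    if bad:
        raise ValueError(f"unknown OCR phases: {sorted(bad)}; expected {OCR_PHASES}")
    have = trace.groupby("well")["phase"].agg(lambda s: frozenset(s))
    for well, phases in have.items():
        absent = set(OCR_PHASES) - phases
        if absent:
            raise ValueError(f"well {well!r} is missing phase(s): {sorted(absent)}")
    return trace


def _phase_means(trace: pd.DataFrame, last_k_cycles: int | None) -> pd.DataFrame:
    """Per-well, per-phase summary OCR (mean over cycles).

    ``last_k_cycles`` restricts the summary to the final k cycles of each
    phase (by cycle number); the default uses all cycles.
    """
    df = trace
    if last_k_cycles is not None:
        if last_k_cycles < 1:
            raise ValueError("last_k_cycles must be >= 1")
        df = (
            df.sort_values("cycle")
            .groupby(["well", "phase"], observed=True)
            .tail(last_k_cycles)
        )
    wide = (
        df.groupby(["well", "phase"], observed=True)["ocr"]
        .mean()
        .unstack("phase")
    )
    return wide


def basal_ocr(
    trace: pd.DataFrame, last_k_cycles: int | None = None
) -> pd.DataFrame:
    """Per-well basal mitochondrial OCR.

    basal = mean(baseline cycles) - mean(antimycin+piericidin cycles).
    Negative values are flagged (``negative_basal``), never clamped: they
    indicate a well whose non-mitochondrial signal exceeded baseline.
    """
    validate_ocr_trace(trace)
    wide = _phase_means(trace, last_k_cycles)
    basal = wide["baseline"] - wide["antimycin_piericidin"]
    return pd.DataFrame(
        {
            "well": basal.index,
            "basal_ocr": basal.to_numpy(),
            "negative_basal": (basal < 0).to_numpy(),
        }
    ).reset_index(drop=True)


def coupled_ocr(
    trace: pd.DataFrame,
    correct_oligo_for_nonmito: bool = False,
    last_k_cycles: int | None = None,
) -> pd.DataFrame:
    """Per-well coupled (ATP-synthesis-linked) OCR.

    As written: coupled = basal - mean(oligomycin cycles).  With
    ``correct_oligo_for_nonmito`` the non-mitochondrial OCR is subtracted
    from the oligomycin term first, i.e.
    coupled = basal - (oligo - nonmito) = baseline - oligo.
    """
    validate_ocr_trace(trace)
    wide = _phase_means(trace, last_k_cycles)
    basal = wide["baseline"] - wide["antimycin_piericidin"]
    oligo = wide["oligomycin"]
    if correct_oligo_for_nonmito:
        oligo = oligo - wide["antimycin_piericidin"]
    coupled = basal - oligo
    return pd.DataFrame(
        {
            "well": coupled.index,
            "basal_ocr": basal.to_numpy(),
            "coupled_ocr": coupled.to_numpy(),
            "negative_coupled": (coupled < 0).to_numpy(),
        }
    ).reset_index(drop=True)


def tic_normalize(matrix: pd.DataFrame) -> pd.DataFrame:
    """Total-ion-count normalization of a samples x metabolites matrix.

    Each sample's peak areas are divided by that sample's total and rescaled
    by the cohort mean total, so post-normalization all sample totals equal
    the cohort mean and magnitudes stay on the raw a.u. scale.  Idempotent,
    and within-sample ratios are unchanged.  Raises on a non-positive
    sample total.
    """
    X = matrix.to_numpy(dtype=float)
    if (X < 0).any():
        raise ValueError("peak areas must be non-negative")
    totals = X.sum(axis=1)
    if (totals <= 0).any():
        zeros = matrix.index[totals <= 0].tolist()
        raise ValueError(f"samples with non-positive total ion count: {zeros}")
    scale = totals.mean()
    normed = X / totals[:, None] * scale
    return pd.DataFrame(normed, index=matrix.index, columns=matrix.columns)


def nadh_nad_ratio(
    matrix: pd.DataFrame,
    sample,
    nadh_feature: str = "NADH",
    nad_feature: str = "NAD+",
) -> float:
    """NADH/NAD+ peak-area ratio within one sample.

    Both features must be present and NAD+ must be positive; a zero area
    means the metabolite was below the detection limit and the ratio is
    undefined.
    """
    for feat in (nadh_feature, nad_feature):
        if feat not in matrix.columns:
            raise ValueError(f"feature {feat!r} not in matrix")
    if sample not in matrix.index:
        raise ValueError(f"sample {sample!r} not in matrix")
    nad = float(matrix.at[sample, nad_feature])
    if nad <= 0:
        raise ValueError(
            f"sample {sample!r}: {nad_feature} is {nad:g} (below detection "
            "limit); ratio undefined"
        )
    return float(matrix.at[sample, nadh_feature]) / nad


def _one_way_anova(X: np.ndarray, group_idx: list[np.ndarray]) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized one-way ANOVA over the columns of X.

    Returns (F, p, MSE) arrays, one entry per metabolite column.
    """
    n, _ = X.shape
    k = len(group_idx)
    grand = X.mean(axis=0)
    ss_between = np.zeros(X.shape[1])
    ss_within = np.zeros(X.shape[1])
    for idx in group_idx:
        sub = X[idx]
        gm = sub.mean(axis=0)
        ss_between += idx.size * (gm - grand) ** 2
        ss_within += ((sub - gm) ** 2).sum(axis=0)
    df_num, df_den = k - 1, n - k
    mse = ss_within / df_den
    with np.errstate(divide="ignore", invalid="ignore"):
        F = (ss_between / df_num) / mse
    F = np.where(np.isfinite(F), F, np.inf)
    p = stats.f.sf(F, df_num, df_den)
    p = np.where(np.isfinite(F), p, 0.0)
    return F, p, mse


def anova_fdr_filter(
    matrix: pd.DataFrame,
    groups: pd.Series | np.ndarray | list,
    fdr_threshold: float = 0.05,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Select group-differential metabolites by ANOVA + BH-FDR, with
    Fisher-LSD post hoc labels.

    Per metabolite: one-way ANOVA across groups; p-values are
    Benjamini-Hochberg adjusted over all metabolites; metabolites with
    adjusted p < ``fdr_threshold`` are selected.  For each selected
    metabolite, Fisher's LSD pairwise comparisons use the pooled
    within-group mean square with N - k degrees of freedom.

    Returns ``(anova_table, lsd_table)``: the ANOVA table covers every
    metabolite (columns metabolite, F, p_value, p_adj, selected); the LSD
    table covers selected metabolites only (group_a, group_b, mean_diff,
    t, p_value).
    """
    groups = np.asarray(pd.Series(list(groups)).astype(str))
    if groups.size != matrix.shape[0]:
        raise ValueError("groups length must match the number of samples")
    labels = np.unique(groups)
    if labels.size < 2:
        raise ValueError("need at least 2 groups")
    group_idx = [np.flatnonzero(groups == lab) for lab in labels]
    if any(idx.size < 2 for idx in group_idx):
        raise ValueError("every group needs >= 2 samples")
    if not 0 < fdr_threshold <= 1:
        raise ValueError("fdr_threshold must lie in (0, 1]")

    X = matrix.to_numpy(dtype=float)
    F, p, mse = _one_way_anova(X, group_idx)
    reject, p_adj, _, _ = multipletests(p, alpha=fdr_threshold, method="fdr_bh")
    selected = p_adj < fdr_threshold

    anova_table = pd.DataFrame(
        {
            "metabolite": matrix.columns,
            "F": F,
            "p_value": p,
            "p_adj": p_adj,
            "selected": selected,
        }
    )

    df_den = groups.size - labels.size
    lsd_rows = []
    for j in np.flatnonzero(selected):
        for a in range(labels.size):
            for b in range(a + 1, labels.size):
                ia, ib = group_idx[a], group_idx[b]
                diff = X[ia, j].mean() - X[ib, j].mean()
                se = np.sqrt(mse[j] * (1.0 / ia.size + 1.0 / ib.size))
                if se == 0:
                    t_ab, p_ab = (np.inf if diff != 0 else 0.0), (0.0 if diff != 0 else 1.0)
                else:
                    t_ab = diff / se
                    p_ab = 2.0 * stats.t.sf(abs(t_ab), df_den)
                lsd_rows.append(
                    {
                        "metabolite": matrix.columns[j],
                        "group_a": labels[a],
                        "group_b": labels[b],
                        "mean_diff": diff,
                        "t": t_ab,
                        "p_value": p_ab,
                    }
                )
    lsd_table = pd.DataFrame(
        lsd_rows,
        columns=["metabolite", "group_a", "group_b", "mean_diff", "t", "p_value"],
    )
    return anova_table, lsd_table
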