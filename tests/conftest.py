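"""Shared fixtures and independent oracles.

The oracles here are deliberately naive re-derivations (explicit loops,
all-pairs searches, closed-form sums of squares) kept independent of the
library code paths they check.
"""

from __future__ import annotations

import math

import numpy as np
import pytest


def brute_force_distance_map(mask: np.ndarray, border_is_background: bool = True) -> np.ndarray:
    """All-pairs nearest-background search, optionally against a padded array.

    Returns distances on foreground pixels (0 elsewhere).
    """
    work = (
        np.pad(mask, 1, mode="constant", constant_values=False)
        if border_is_background
        else mask
    )
    fg = np.argwhere(work)
    bg = np.argwhere(~work)
    assert bg.size, "oracle needs at least one background pixel"
    out = np.zeros(work.shape, dtype=float)
    # chunk the all-pairs distance computation to bound memory
    for start in range(0, fg.shape[0], 4096):
        chunk = fg[start : start + 4096]
        d2 = (
            (chunk[:, 0, None] - bg[None, :, 0]) ** 2
            + (chunk[:, 1, None] - bg[None, :, 1]) ** 2
        )
        out[chunk[:, 0], chunk[:, 1]] = np.sqrt(d2.min(axis=1))
    return out[1:-1, 1:-1] if border_is_background else out


def huang_threshold_oracle(pixels: np.ndarray) -> int:
    """Exhaustive fuzziness minimization with plain Python loops.

    Evaluates every candidate threshold t in 0..255 for which both classes
    are populated and returns the smallest argmin of

        S(t) = -(1/N) sum_g h(g) [u ln u + (1-u) ln(1-u)],
        u(g) = 1 / (1 + |g - mu_class(g)| / (g_max - g_min)).
    """
    hist = [0] * 256
    for v in np.asarray(pixels).ravel():
        hist[int(v)] += 1
    levels = [g for g in range(256) if hist[g] > 0]
    if len(levels) < 2:
        raise ValueError("constant image")
    g_min, g_max = levels[0], levels[-1]
    c = float(g_max - g_min)
    n = sum(hist)

    best_t, best_s = None, None
    for t in range(256):
        lo = [(g, hist[g]) for g in range(0, t + 1) if hist[g] > 0]
        hi = [(g, hist[g]) for g in range(t + 1, 256) if hist[g] > 0]
        if not lo or not hi:
            continue
        mu0 = sum(g * h for g, h in lo) / sum(h for _, h in lo)
        mu1 = sum(g * h for g, h in hi) / sum(h for _, h in hi)
        s = 0.0
        for g in range(256):
            if hist[g] == 0:
                continue
            mu = mu0 if g <= t else mu1
            u = 1.0 / (1.0 + abs(g - mu) / c)
            ent = 0.0
            if 0.0 < u < 1.0:
                ent = -(u * math.log(u) + (1.0 - u) * math.log(1.0 - u))
            s += hist[g] * ent
        s /= n
        if best_s is None or s < best_s - 1e-15:
            best_t, best_s = t, s
    return best_t


def dice(a: np.ndarray, b: np.ndarray) -> float:
    inter = np.logical_and(a, b).sum()
    return 2.0 * inter / (a.sum() + b.sum())


@pytest.fixture
def rng():
    return np.random.default_rng(20230423)


@pytest.fixture
def stripe5():
    """The analytic 5-px stripe fixture (32x32, 0.276 um pixels)."""
    from septamorph import generate_stripe_mask

    return generate_stripe_mask(32, 5, 32)


def make_cohort_table(values_by_mouse: dict[str, tuple[str, list[float]]]):
    """Build a per-image summary table from {mouse: (genotype, thicknesses)}."""
    import pandas as pd

    rows = []
    for mouse, (geno, vals) in values_by_mouse.items():
        for i, v in enumerate(vals):
            rows.append(
                {
                    "image_id": f"{mouse}_img{i}",
                    "mouse_id": mouse,
                    "genotype": geno,
                    "mean_thickness_um": v,
                }
            )
    return pd.DataFrame(rows)
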