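"""Septal-wall segmentation of histology fields of view.

A field of view is reduced to a binary septal-tissue mask in three steps:
greyscale conversion (Rec. 601 luma), automatic threshold selection by
Huang–Wang fuzzy-entropy minimization, and filling of small enclosed
background holes so that the downstream distance map measures distance to
true airspace rather than to staining dropouts.

Tissue in H&E images is darker than airspace, so the default polarity takes
pixels at or below the threshold as foreground.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage

__all__ = [
    "GreyImage",
    "SeptalMask",
    "SegmentationConfig",
    "MaskProvenance",
    "to_greyscale",
    "huang_threshold",
    "binarize",
    "fill_small_holes",
    "segment_image",
]

#: Rec. 601 luma weights used for colour -> greyscale conversion.
LUMA_WEIGHTS = (0.299, 0.587, 0.114)


@dataclass(frozen=True)
class GreyImage:
    """2-D 8-bit intensity grid with a physical pixel size.

    Parameters
    ----------
    pixels
        2-D ``uint8`` array of intensities in [0, 255].
    pixel_size_um
        Physical edge length of one pixel in micrometres (> 0).
    """

    pixels: np.ndarray
    pixel_size_um: float

    def __post_init__(self):
        px = np.asarray(self.pixels)
        if px.ndim != 2 or px.shape[0] < 2 or px.shape[1] < 2:
            raise ValueError("GreyImage requires a 2-D grid of at least 2x2 pixels")
        if px.dtype != np.uint8:
            if px.min() < 0 or px.max() > 255:
                raise ValueError("intensities must lie in [0, 255]")
            px = px.astype(np.uint8)
        if not self.pixel_size_um > 0:
            raise ValueError("pixel_size_um must be positive")
        object.__setattr__(self, "pixels", px)

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape


@dataclass(frozen=True)
class MaskProvenance:
    """How a mask was obtained: threshold, polarity and holes filled."""

    threshold: int | None = None
    polarity: str | None = None
    holes_filled: int = 0

    def __post_init__(self):
        if self.threshold is not None and not 0 <= self.threshold <= 255:
            raise ValueError("provenance threshold must lie in [0, 255]")


@dataclass(frozen=True)
class SeptalMask:
    """Binary septal-tissue mask (True = tissue foreground)."""

    pixels: np.ndarray
    pixel_size_um: float
    provenance: MaskProvenance = field(default_factory=MaskProvenance)

    def __post_init__(self):
        px = np.asarray(self.pixels)
        if px.ndim != 2:
            raise ValueError("SeptalMask requires a 2-D grid")
        if px.dtype != bool:
            px = px.astype(bool)
        if not self.pixel_size_um > 0:
            raise ValueError("pixel_size_um must be positive")
        object.__setattr__(self, "pixels", px)

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape

    @property
    def foreground_fraction(self) -> float:
        return float(self.pixels.mean())


@dataclass(frozen=True)
class SegmentationConfig:
    """Options for binarization and hole filling.

    ``hole_max_area_px`` applies strictly: only enclosed background
    components of area < ``hole_max_area_px`` are filled.  Holes use
    4-connectivity by default, the dual of the usual 8-connected
    foreground convention.
    """

    polarity: str = "dark_foreground"
    hole_max_area_px: int = 5
    hole_connectivity: int = 4
    border_is_background: bool = True

    def __post_init__(self):
        if self.polarity not in ("dark_foreground", "bright_foreground"):
            raise ValueError(f"unknown polarity {self.polarity!r}")
        if self.hole_max_area_px < 1:
            raise ValueError("hole_max_area_px must be >= 1")
        if self.hole_connectivity not in (4, 8):
            raise ValueError("hole_connectivity must be 4 or 8")


def to_greyscale(rgb_image: np.ndarray, pixel_size_um: float) -> GreyImage:
    """Convert a 3-channel 8-bit colour image to greyscale.

    Luminance is the Rec. 601 weighted sum ``0.299 R + 0.587 G + 0.114 B``,
    rounded to the nearest integer and clipped to [0, 255].
    """
    rgb = np.asarray(rgb_image)
    if rgb.ndim != 3 or rgb.shape[2] != 3:
        raise ValueError(f"expected an HxWx3 image, got shape {rgb.shape}")
    if rgb.min() < 0 or rgb.max() > 255:
        raise ValueError("channel values must lie in [0, 255]")
    w = np.asarray(LUMA_WEIGHTS)
    luma = np.tensordot(rgb.astype(np.float64), w, axes=([2], [0]))
    grey = np.clip(np.rint(luma), 0, 255).astype(np.uint8)
    return GreyImage(grey, pixel_size_um)


def huang_threshold(image: GreyImage | np.ndarray) -> int:
    """Select a threshold by Huang–Wang fuzzy-entropy minimization.

    For each candidate threshold ``t`` the grey levels are split into a low
    class (g <= t) and a high class (g > t) with means ``mu0`` and ``mu1``.
    Each level's membership to its class is ``1 / (1 + |g - mu| / C)`` with
    ``C = g_max - g_min``, and the image fuzziness is the mean Shannon
    entropy of the memberships,

        S(t) = -(1/N) * sum_g h(g) * [u ln u + (1 - u) ln(1 - u)].

    The returned threshold minimizes ``S`` over all candidates that leave
    both classes non-empty; ties go to the smallest threshold.

    Raises
    ------
    ValueError
        If the image is constant (no threshold definable).
    """
    px = image.pixels if isinstance(image, GreyImage) else np.asarray(image)
    hist = np.bincount(px.ravel().astype(np.int64), minlength=256).astype(np.float64)
    nonzero = np.flatnonzero(hist)
    if nonzero.size < 2:
        raise ValueError("no threshold definable: image is constant")
    g_min, g_max = int(nonzero[0]), int(nonzero[-1])
    n_px = hist.sum()
    c = float(g_max - g_min)

    levels = np.arange(256, dtype=np.float64)
    cum_h = np.cumsum(hist)
    cum_gh = np.cumsum(levels * hist)

    # Candidates keep both classes populated: g_min <= t < g_max.
    ts = np.arange(g_min, g_max)
    mu0 = cum_gh[ts] / cum_h[ts]
    mu1 = (cum_gh[-1] - cum_gh[ts]) / (cum_h[-1] - cum_h[ts])

    low = levels[None, :] <= ts[:, None]
    mu = np.where(low, mu0[:, None], mu1[:, None])
    u = 1.0 / (1.0 + np.abs(levels[None, :] - mu) / c)

    with np.errstate(divide="ignore", invalid="ignore"):
        ent = -(u * np.log(u) + (1.0 - u) * np.log1p(-u))
    ent[~np.isfinite(ent)] = 0.0  # u == 1 contributes 0 (0 ln 0 := 0)

    fuzziness = (ent * hist[None, :]).sum(axis=1) / n_px
    return int(ts[np.argmin(fuzziness)])  # argmin takes the first (smallest t)


def binarize(
    image: GreyImage,
    threshold: int,
    config: SegmentationConfig | None = None,
) -> SeptalMask:
    """Threshold a grey image into a septal mask.

    With ``dark_foreground`` (default) pixels with intensity <= threshold
    become foreground; with ``bright_foreground`` pixels >= threshold do.
    """
    config = config or SegmentationConfig()
    if not 0 <= threshold <= 255:
        raise ValueError("threshold must lie in [0, 255]")
    if config.polarity == "dark_foreground":
        fg = image.pixels <= threshold
    else:
        fg = image.pixels >= threshold
    prov = MaskProvenance(threshold=int(threshold), polarity=config.polarity)
    return SeptalMask(fg, image.pixel_size_um, prov)


def fill_small_holes(
    mask: SeptalMask, config: SegmentationConfig | None = None
) -> SeptalMask:
    """Fill enclosed background components smaller than the hole limit.

    A hole is a background connected component (4- or 8-connectivity per the
    config) that does not touch the image border.  Holes of pixel area
    strictly less than ``hole_max_area_px`` are converted to foreground;
    everything else is preserved.  Idempotent and never removes foreground.
    """
    config = config or SegmentationConfig()
    bg = ~mask.pixels
    structure = (
        ndimage.generate_binary_structure(2, 1)
        if config.hole_connectivity == 4
        else ndimage.generate_binary_structure(2, 2)
    )
    labels, n_comp = ndimage.label(bg, structure=structure)
    if n_comp == 0:
        return replace(mask, provenance=replace(mask.provenance, holes_filled=0))

    border_labels = np.unique(
        np.concatenate(
            [labels[0, :], labels[-1, :], labels[:, 0], labels[:, -1]]
        )
    )
    areas = np.bincount(labels.ravel(), minlength=n_comp + 1)
    fill = np.zeros(n_comp + 1, dtype=bool)
    fill[1:] = areas[1:] < config.hole_max_area_px
    fill[border_labels] = False

    filled = mask.pixels | fill[labels]
    n_filled = int(fill.sum())
    prov = replace(mask.provenance, holes_filled=mask.provenance.holes_filled + n_filled)
    return SeptalMask(filled, mask.pixel_size_um, prov)


def segment_image(
    image: GreyImage, config: SegmentationConfig | None = None
) -> SeptalMask:
    """Full segmentation stage: Huang threshold, binarize, fill small holes."""
    config = config or SegmentationConfig()
    t = huang_threshold(image)
    return fill_small_holes(binarize(image, t, config), config)
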