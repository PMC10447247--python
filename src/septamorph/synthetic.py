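"""Synthetic histology-like image generation with known thickness structure.

Real alveolar parenchyma looks like a foam: thin tissue walls (septa)
separating airspaces.  The generator emulates that geometry as the set of
pixels within a fixed Euclidean distance of the edges of a Voronoi
tessellation of random sites — the simplest structure with tunable,
approximately uniform wall thickness.  Masks are rendered to two-level
pseudo-histology images with additive Gaussian noise, and whole multi-mouse
cohorts are simulated with mouse-level variance and a genotype shift in true
wall thickness, so every downstream stage can be validated against known
ground truth.

Everything is seeded: identical specs yield bitwise-identical outputs
within this implementation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.spatial import cKDTree

from .morphometry import distance_map, mean_thickness
from .segmentation import GreyImage, MaskProvenance, SeptalMask

__all__ = [
    "FoamSpec",
    "RenderSpec",
    "CohortSpec",
    "SyntheticCohort",
    "DEFAULT_PIXEL_SIZE_UM",
    "generate_foam_mask",
    "generate_stripe_mask",
    "render_histology",
    "generate_cohort",
]

#: Default physical calibration: 5 px = 1.38 um.
DEFAULT_PIXEL_SIZE_UM = 0.276


@dataclass(frozen=True)
class FoamSpec:
    """Geometry of one synthetic foam (Voronoi-wall) mask.

    ``wall_half_width_px`` is the dilation radius around the one-pixel
    Voronoi boundary; the resulting wall is about ``2*r + 1`` pixels thick.
    """

    image_height_px: int
    image_width_px: int
    n_seeds: int = 20
    wall_half_width_px: float = 2.0
    seed: int = 0
    pixel_size_um: float = DEFAULT_PIXEL_SIZE_UM

    def __post_init__(self):
        if self.image_height_px < 2 or self.image_width_px < 2:
            raise ValueError("image must be at least 2x2 pixels")
        if self.n_seeds < 2:
            raise ValueError("n_seeds must be >= 2")
        if self.wall_half_width_px < 0:
            raise ValueError("wall_half_width_px must be non-negative")
        if not self.pixel_size_um > 0:
            raise ValueError("pixel_size_um must be positive")


@dataclass(frozen=True)
class RenderSpec:
    """Intensity rendering of a mask into pseudo-histology.

    Tissue is darker than airspace in H&E, so the defaults put tissue at 60
    and airspace at 230.  Noise is additive Gaussian, clipped to [0, 255].
    """

    tissue_intensity: int = 60
    airspace_intensity: int = 230
    noise_sd: float = 10.0
    seed: int = 0

    def __post_init__(self):
        for name in ("tissue_intensity", "airspace_intensity"):
            v = getattr(self, name)
            if not 0 <= v <= 255:
                raise ValueError(f"{name} must lie in [0, 255]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if self.tissue_intensity == self.airspace_intensity and self.noise_sd > 0:
            raise ValueError(
                "tissue and airspace intensities must differ when noise is present"
            )


@dataclass(frozen=True)
class CohortSpec:
    """A simulated two-genotype mouse cohort.

    Each mouse's true wall thickness is
    ``base_thickness_um + genotype_effect_um * [cKO] + Normal(0, mouse_sd_um)``;
    every mouse contributes ``images_per_mouse`` foam fields of view rendered
    at that thickness.  Defaults follow the study design this emulates:
    4 mice per genotype with 4-6 (default 5) fields of view each.
    """

    n_mice_per_genotype: int = 4
    images_per_mouse: int = 5
    genotype_effect_um: float = 3.0
    mouse_sd_um: float = 0.5
    base_thickness_um: float = 5.0
    pixel_size_um: float = DEFAULT_PIXEL_SIZE_UM
    seed: int = 0
    image_px: int = 512
    n_seeds: int = 20
    tissue_intensity: int = 60
    airspace_intensity: int = 230
    noise_sd: float = 10.0

    def __post_init__(self):
        if self.n_mice_per_genotype < 1:
            raise ValueError("n_mice_per_genotype must be positive")
        if self.images_per_mouse < 1:
            raise ValueError("images_per_mouse must be >= 1")
        if self.mouse_sd_um < 0:
            raise ValueError("mouse_sd_um must be non-negative")
        if not self.base_thickness_um > 0:
            raise ValueError("base_thickness_um must be positive")
        if not self.pixel_size_um > 0:
            raise ValueError("pixel_size_um must be positive")


@dataclass(frozen=True)
class SyntheticCohort:
    """Generated images with their manifest and ground truth.

    ``images`` maps image_id -> GreyImage; ``masks`` maps image_id -> the
    generating SeptalMask.  ``manifest`` has one row per image (image_id,
    mouse_id, genotype, fov_id); ``ground_truth`` records the per-mouse true
    thickness and the per-image realized mean distance-map thickness of the
    generating mask.
    """

    images: dict[str, GreyImage]
    masks: dict[str, SeptalMask]
    manifest: pd.DataFrame
    ground_truth: pd.DataFrame


def generate_foam_mask(spec: FoamSpec) -> SeptalMask:
    """Voronoi-foam septal mask: walls within a radius of cell boundaries.

    Sites are sampled uniformly over the image; each pixel is labelled by
    its nearest site, boundary pixels are those whose label differs from the
    right or lower neighbour (a one-pixel-wide edge set), and the foreground
    is every pixel within ``wall_half_width_px`` (Euclidean) of that edge
    set.  Deterministic given the seed.
    """
    rng = np.random.default_rng(spec.seed)
    h, w = spec.image_height_px, spec.image_width_px
    sites = np.column_stack(
        [rng.uniform(0, h, spec.n_seeds), rng.uniform(0, w, spec.n_seeds)]
    )
    if np.unique(np.round(sites, 9), axis=0).shape[0] < 2:
        raise ValueError("degenerate geometry: fewer than 2 distinct sites")

    rows, cols = np.mgrid[0:h, 0:w]
    centres = np.column_stack([rows.ravel(), cols.ravel()]).astype(float)
    _, labels = cKDTree(sites).query(centres)
    labels = labels.reshape(h, w)

    boundary = np.zeros((h, w), dtype=bool)
    boundary[:, :-1] |= labels[:, :-1] != labels[:, 1:]
    boundary[:-1, :] |= labels[:-1, :] != labels[1:, :]
    if not boundary.any():
        raise ValueError("degenerate geometry: no Voronoi boundary in frame")

    if spec.wall_half_width_px == 0:
        fg = boundary
    else:
        dist = ndimage.distance_transform_edt(~boundary)
        fg = dist <= spec.wall_half_width_px
    return SeptalMask(fg, spec.pixel_size_um, MaskProvenance())


def generate_stripe_mask(
    height_px: int,
    stripe_thickness_px: int,
    width_px: int | None = None,
    pixel_size_um: float = DEFAULT_PIXEL_SIZE_UM,
) -> SeptalMask:
    """Analytic fixture: a full-width horizontal stripe of exact thickness.

    The stripe is centred vertically with background above and below, so
    its distance-map values are known in closed form.
    """
    width_px = height_px if width_px is None else width_px
    if stripe_thickness_px < 1:
        raise ValueError("stripe_thickness_px must be positive")
    if stripe_thickness_px >= height_px:
        raise ValueError("stripe must be thinner than the image height")
    fg = np.zeros((height_px, width_px), dtype=bool)
    top = (height_px - stripe_thickness_px) // 2
    fg[top : top + stripe_thickness_px, :] = True
    return SeptalMask(fg, pixel_size_um, MaskProvenance())


def render_histology(mask: SeptalMask, spec: RenderSpec) -> GreyImage:
    """Render a mask to a two-level grey image with additive Gaussian noise."""
    rng = np.random.default_rng(spec.seed)
    img = np.where(
        mask.pixels, float(spec.tissue_intensity), float(spec.airspace_intensity)
    )
    if spec.noise_sd > 0:
        img = img + rng.normal(0.0, spec.noise_sd, size=img.shape)
    img = np.clip(np.rint(img), 0, 255).astype(np.uint8)
    return GreyImage(img, mask.pixel_size_um)


def _thickness_to_half_width(thickness_um: float, pixel_size_um: float) -> float:
    """Convert full wall thickness (um) to the foam dilation radius (px).

    A one-pixel boundary dilated by radius r is ~(2r + 1) px thick, so
    r = (t_px - 1) / 2.
    """
    t_px = thickness_um / pixel_size_um
    return (t_px - 1.0) / 2.0


def generate_cohort(spec: CohortSpec) -> SyntheticCohort:
    """Simulate a two-genotype cohort of rendered foam fields of view.

    Raises if any mouse's drawn thickness is non-positive or thinner than
    one pixel (the simulation is rejected rather than silently clamped).
    """
    rng = np.random.default_rng(spec.seed)
    images: dict[str, GreyImage] = {}
    masks: dict[str, SeptalMask] = {}
    manifest_rows = []
    truth_rows = []

    for genotype in ("control", "cKO"):
        effect = spec.genotype_effect_um if genotype == "cKO" else 0.0
        for m in range(spec.n_mice_per_genotype):
            mouse_id = f"{genotype}_m{m + 1}"
            offset = rng.normal(0.0, spec.mouse_sd_um) if spec.mouse_sd_um > 0 else 0.0
            true_um = spec.base_thickness_um + effect + offset
            if true_um <= 0:
                raise ValueError(
                    f"mouse {mouse_id}: drawn thickness {true_um:.3f} um is not "
                    "positive; reduce mouse_sd_um or raise base_thickness_um"
                )
            half_px = _thickness_to_half_width(true_um, spec.pixel_size_um)
            if half_px < 0:
                raise ValueError(
                    f"mouse {mouse_id}: thickness {true_um:.3f} um is below one "
                    f"pixel at {spec.pixel_size_um} um/px"
                )
            for fov in range(spec.images_per_mouse):
                image_id = f"{mouse_id}_fov{fov + 1}"
                foam_seed = int(rng.integers(0, 2**31 - 1))
                noise_seed = int(rng.integers(0, 2**31 - 1))
                mask = generate_foam_mask(
                    FoamSpec(
                        image_height_px=spec.image_px,
                        image_width_px=spec.image_px,
                        n_seeds=spec.n_seeds,
                        wall_half_width_px=half_px,
                        seed=foam_seed,
                        pixel_size_um=spec.pixel_size_um,
                    )
                )
                img = render_histology(
                    mask,
                    RenderSpec(
                        tissue_intensity=spec.tissue_intensity,
                        airspace_intensity=spec.airspace_intensity,
                        noise_sd=spec.noise_sd,
                        seed=noise_seed,
                    ),
                )
                realized = mean_thickness(distance_map(mask))
                images[image_id] = img
                masks[image_id] = mask
                manifest_rows.append(
                    {
                        "image_id": image_id,
                        "mouse_id": mouse_id,
                        "genotype": genotype,
                        "fov_id": f"fov{fov + 1}",
                    }
                )
                truth_rows.append(
                    {
                        "image_id": image_id,
                        "mouse_id": mouse_id,
                        "genotype": genotype,
                        "true_thickness_um": true_um,
                        "realized_mean_thickness_um": realized,
                    }
                )

    return SyntheticCohort(
        images=images,
        masks=masks,
        manifest=pd.DataFrame(manifest_rows),
        ground_truth=pd.DataFrame(truth_rows),
    )
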