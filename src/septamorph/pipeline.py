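"""End-to-end morphometry pipeline: images in, thickness statistics out.

For every manifest row: read the image, convert to greyscale if colour,
select the Huang threshold, binarize, fill small holes, compute the
distance map, and record the thickness histogram and per-image mean.  Then
aggregate per-mouse/per-genotype frequency curves and run the genotype
F-test.  Per-image provenance (threshold, polarity, holes filled,
foreground fraction) is logged because audits of manual exclusions demand
it.  Individual image failures become error records; the run fails only if
every image fails.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
import tifffile

from . import morphometry, segmentation
from .cohort import FTestResult, genotype_f_test, genotype_frequency_curves
from .config import RunConfig, validate_manifest
from .synthetic import SyntheticCohort

__all__ = [
    "PipelineResult",
    "read_image",
    "write_mask",
    "process_image",
    "run_pipeline",
    "write_cohort",
]

FLOAT_FORMAT = "%.10g"  # fixed CSV float rendering => byte-identical reruns


@dataclass(frozen=True)
class PipelineResult:
    """Everything a run produces, before/after writing to disk."""

    summary: pd.DataFrame
    histograms: pd.DataFrame
    mouse_curves: pd.DataFrame
    genotype_curves: pd.DataFrame
    stats: FTestResult | None
    run_log: pd.DataFrame
    errors: pd.DataFrame


def read_image(path: str | Path, pixel_size_um: float) -> segmentation.GreyImage:
    """Read a TIFF/PNG field of view as a grey image.

    RGB(A) images are converted with Rec. 601 luma; an alpha channel is
    dropped.
    """
    arr = np.asarray(iio.imread(path))
    if arr.ndim == 3 and arr.shape[2] == 4:
        arr = arr[:, :, :3]
    if arr.ndim == 3:
        return segmentation.to_greyscale(arr, pixel_size_um)
    if arr.ndim != 2:
        raise ValueError(f"{path}: unsupported image dimensionality {arr.shape}")
    return segmentation.GreyImage(arr, pixel_size_um)


def write_mask(mask: segmentation.SeptalMask, path: str | Path) -> None:
    """Write a binary mask as an 8-bit TIFF (foreground = 255)."""
    tifffile.imwrite(str(path), mask.pixels.astype(np.uint8) * 255)


def process_image(
    image: segmentation.GreyImage, config: RunConfig
) -> tuple[segmentation.SeptalMask, morphometry.ThicknessMap, morphometry.ThicknessHistogram]:
    """Segmentation + thickness measurement for one field of view."""
    seg_cfg = config.segmentation_config()
    mask = segmentation.segment_image(image, seg_cfg)
    if not mask.pixels.any():
        raise ValueError("empty foreground after segmentation")
    tmap = morphometry.distance_map(
        mask, config.border_is_background, config.thickness_mode
    )
    hist = morphometry.thickness_histogram(tmap, config.bin_width_um)
    return mask, tmap, hist


def run_pipeline(
    manifest: pd.DataFrame,
    config: RunConfig,
    output_dir: str | Path | None = None,
    images: dict[str, segmentation.GreyImage] | None = None,
    write_masks: bool = False,
) -> PipelineResult:
    """Run the full morphometry pipeline over a manifest.

    ``images`` allows passing in-memory images keyed by image_path (or
    image_id), e.g. a synthetic cohort, bypassing file reads.  When
    ``output_dir`` is given, summary/histogram/curve/stats CSVs, the run
    log and the config are written there.
    """
    if images is not None and "image_path" not in manifest.columns:
        manifest = manifest.assign(image_path=manifest["image_id"])
    manifest = validate_manifest(manifest, require_paths=images is None)
    summaries, hist_rows, hist_records, log_rows, error_rows = [], [], [], [], []

    for row in manifest.itertuples(index=False):
        image_key = row.image_path
        image_id = Path(str(image_key)).stem
        try:
            if images is not None:
                image = images[image_key]
            else:
                image = read_image(image_key, config.pixel_size_um)
            mask, tmap, hist = process_image(image, config)
            summary = morphometry.summarize_image(
                mask,
                image_id=image_id,
                mouse_id=row.mouse_id,
                genotype=row.genotype,
                border_is_background=config.border_is_background,
                thickness_mode=config.thickness_mode,
            )
        except Exception as exc:  # per-image failure -> error record
            error_rows.append(
                {"image_path": str(image_key), "error": f"{type(exc).__name__}: {exc}"}
            )
            continue

        summaries.append(summary)
        hist_records.append(
            {
                "image_id": image_id,
                "mouse_id": row.mouse_id,
                "genotype": row.genotype,
                "histogram": hist,
            }
        )
        freq = hist.relative_frequency
        for i, c in enumerate(hist.counts):
            hist_rows.append(
                {
                    "image_id": image_id,
                    "bin_low_um": hist.bin_edges_um[i],
                    "bin_high_um": hist.bin_edges_um[i + 1],
                    "count": int(c),
                    "relative_frequency": freq[i],
                }
            )
        log_rows.append(
            {
                "image_id": image_id,
                "mouse_id": row.mouse_id,
                "genotype": row.genotype,
                "threshold": mask.provenance.threshold,
                "polarity": mask.provenance.polarity,
                "holes_filled": mask.provenance.holes_filled,
                "foreground_fraction": mask.foreground_fraction,
                "mean_thickness_um": summary.mean_thickness_um,
            }
        )
        if write_masks and output_dir is not None:
            mask_dir = Path(output_dir) / "masks"
            mask_dir.mkdir(parents=True, exist_ok=True)
            write_mask(mask, mask_dir / f"{image_id}_mask.tif")

    if not summaries:
        raise RuntimeError(
            "all images failed; first error: "
            + (error_rows[0]["error"] if error_rows else "none recorded")
        )

    summary_df = pd.DataFrame(
        [
            {
                "image_id": s.image_id,
                "mouse_id": s.mouse_id,
                "genotype": s.genotype,
                "mean_thickness_um": s.mean_thickness_um,
                "total_foreground_px": s.total_foreground_px,
                "threshold_used": s.threshold_used,
            }
            for s in summaries
        ]
    )
    mouse_curves, genotype_curves = genotype_frequency_curves(hist_records)

    stats: FTestResult | None = None
    stats_error: str | None = None
    try:
        stats = genotype_f_test(summary_df, config.stats_method)
    except ValueError as exc:  # e.g. single-genotype manifest: still a valid run
        stats_error = str(exc)

    result = PipelineResult(
        summary=summary_df,
        histograms=pd.DataFrame(hist_rows),
        mouse_curves=mouse_curves,
        genotype_curves=genotype_curves,
        stats=stats,
        run_log=pd.DataFrame(log_rows),
        errors=pd.DataFrame(error_rows, columns=["image_path", "error"]),
    )
    if output_dir is not None:
        _write_result(result, config, Path(output_dir))
    return result


def _write_result(result: PipelineResult, config: RunConfig, outdir: Path) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    kw = dict(index=False, float_format=FLOAT_FORMAT)
    result.summary.to_csv(outdir / "summary.csv", **kw)
    result.histograms.to_csv(outdir / "histograms.csv", **kw)
    result.mouse_curves.to_csv(outdir / "mouse_curves.csv", **kw)
    result.genotype_curves.to_csv(outdir / "genotype_curves.csv", **kw)
    result.run_log.to_csv(outdir / "run_log.csv", **kw)
    result.errors.to_csv(outdir / "errors.csv", **kw)
    config.to_yaml(outdir / "config.yaml")
    if result.stats is not None:
        stats_df = pd.DataFrame(
            [
                {
                    "method": result.stats.method,
                    "F": result.stats.F_statistic,
                    "df_num": result.stats.df_num,
                    "df_den": result.stats.df_den,
                    "p_value": result.stats.p_value,
                    "coefficients": json.dumps(
                        {k: round(v, 12) for k, v in result.stats.coefficients.items()}
                    ),
                }
            ]
        )
        stats_df.to_csv(outdir / "stats.csv", **kw)


def write_cohort(cohort: SyntheticCohort, outdir: str | Path, fmt: str = "png") -> Path:
    """Write a synthetic cohort to disk: images + manifest.csv + ground_truth.csv.

    Returns the manifest path; the manifest's image_path column points at
    the written files (relative to the manifest), so run_pipeline can
    consume it directly.
    """
    if fmt not in ("png", "tif"):
        raise ValueError("fmt must be 'png' or 'tif'")
    outdir = Path(outdir)
    img_dir = outdir / "images"
    img_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for row in cohort.manifest.itertuples(index=False):
        img = cohort.images[row.image_id]
        rel = f"images/{row.image_id}.{fmt}"
        path = outdir / rel
        if fmt == "tif":
            tifffile.imwrite(str(path), img.pixels)
        else:
            iio.imwrite(path, img.pixels)
        rows.append(
            {
                "image_path": rel,
                "mouse_id": row.mouse_id,
                "genotype": row.genotype,
                "fov_id": row.fov_id,
            }
        )
    manifest_path = outdir / "manifest.csv"
    pd.DataFrame(rows).to_csv(manifest_path, index=False)
    cohort.ground_truth.to_csv(
        outdir / "ground_truth.csv", index=False, float_format=FLOAT_FORMAT
    )
    return manifest_path
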