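"""Run configuration and image manifest handling.

A run is fully described by a RunConfig (physical calibration, segmentation
options, thickness mode, statistics method, seed) plus a manifest CSV that
assigns each image file to a mouse and genotype.  Configs round-trip
losslessly through YAML so a run can be audited and reproduced.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from .cohort import F_TEST_METHODS
from .morphometry import GENOTYPES
from .segmentation import SegmentationConfig
from .synthetic import DEFAULT_PIXEL_SIZE_UM

__all__ = ["RunConfig", "load_manifest", "validate_manifest"]

MANIFEST_COLUMNS = ("image_path", "mouse_id", "genotype", "fov_id")


@dataclass(frozen=True)
class RunConfig:
    """All knobs of a morphometry run.

    Defaults reproduce the reference analysis: 0.276 um pixels (5 px =
    1.38 um), 1-pixel-wide thickness bins, dark-tissue polarity, the
    strict "< 5 px" hole rule, raw distance-map thickness, and the
    sequential-ANOVA genotype test.
    """

    pixel_size_um: float = DEFAULT_PIXEL_SIZE_UM
    bin_width_um: float = DEFAULT_PIXEL_SIZE_UM
    polarity: str = "dark_foreground"
    hole_max_area_px: int = 5
    hole_connectivity: int = 4
    border_is_background: bool = True
    thickness_mode: str = "edt"
    stats_method: str = "sequential_anova"
    seed: int = 0
    output_dir: str = "results"

    def __post_init__(self):
        if not self.pixel_size_um > 0:
            raise ValueError("pixel_size_um must be positive")
        if not self.bin_width_um > 0:
            raise ValueError("bin_width_um must be positive")
        if self.thickness_mode not in ("edt", "double_edt"):
            raise ValueError("thickness_mode must be 'edt' or 'double_edt'")
        if self.stats_method not in F_TEST_METHODS:
            raise ValueError(f"stats_method must be one of {F_TEST_METHODS}")
        # delegate segmentation-option validation
        self.segmentation_config()

    def segmentation_config(self) -> SegmentationConfig:
        return SegmentationConfig(
            polarity=self.polarity,
            hole_max_area_px=self.hole_max_area_px,
            hole_connectivity=self.hole_connectivity,
            border_is_background=self.border_is_background,
        )

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text())
        if not isinstance(data, dict):
            raise ValueError("config file must contain a mapping")
        known = set(cls.__dataclass_fields__)
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config fields: {sorted(unknown)}")
        return cls(**data)


def validate_manifest(manifest: pd.DataFrame, require_paths: bool = True) -> pd.DataFrame:
    """Validate a manifest table.

    Checks required columns, duplicate image paths, one genotype per mouse,
    known genotype labels, and (optionally) that image files exist.
    """
    missing = [c for c in MANIFEST_COLUMNS if c not in manifest.columns]
    if missing:
        raise ValueError(f"manifest missing columns: {missing}")
    dupes = manifest["image_path"][manifest["image_path"].duplicated()]
    if not dupes.empty:
        raise ValueError(f"duplicate image paths in manifest: {dupes.tolist()}")
    bad = set(manifest["genotype"].unique()) - set(GENOTYPES)
    if bad:
        raise ValueError(f"unknown genotype labels: {sorted(bad)}")
    per_mouse = manifest.groupby("mouse_id")["genotype"].nunique()
    if (per_mouse > 1).any():
        offenders = per_mouse[per_mouse > 1].index.tolist()
        raise ValueError(f"mice mapped to multiple genotypes: {offenders}")
    if require_paths:
        absent = [p for p in manifest["image_path"] if not Path(p).exists()]
        if absent:
            raise ValueError(f"manifest image files not found: {absent[:5]}")
    return manifest


def load_manifest(path: str | Path, require_paths: bool = True) -> pd.DataFrame:
    """Read and validate a manifest CSV; relative paths resolve against the
    CSV's own directory."""
    path = Path(path)
    manifest = pd.read_csv(path, dtype=str)
    if "image_path" in manifest.columns:
        base = path.parent
        manifest["image_path"] = [
            str(p) if Path(p).is_absolute() else str(base / p)
            for p in manifest["image_path"]
        ]
    return validate_manifest(manifest, require_paths=require_paths)
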