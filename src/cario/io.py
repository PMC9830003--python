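"""Readers/writers and configuration for the pipeline.

Interchange formats: multi-page 32-bit-float TIFF for image stacks (one page
per frame), single-page uint8 TIFF for binary ROI masks, CSV with documented
headers for tables, JSON sidecars for image metadata (pixel pitch, modality,
frame interval — TIFF tags are dialect-prone), YAML for pipeline
configuration with unknown keys rejected.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from .dehydration import ImageStack
from .synth import CohortConfig

__all__ = [
    "PipelineConfig",
    "read_stack",
    "write_stack",
    "read_mask",
    "write_mask",
    "read_records",
    "write_records",
    "load_config",
    "save_config",
    "RECORD_COLUMNS",
]

#: required columns of the joined per-lesion record table
RECORD_COLUMNS = (
    "lesion_id",
    "surface_type",
    "dI_diff",
    "dI_ratio",
    "dQ_diff",
    "dQ_ratio",
    "ld_oct_um",
    "delta_R",
    "tsl_um",
    "tsl_detected",
    "ld_ct_um",
    "sl_um",
)


class SchemaError(ValueError):
    """A file failed validation against its documented schema."""


@dataclass
class PipelineConfig:
    """End-to-end pipeline configuration.

    ``cohort`` embeds the synthetic-generator configuration; the analysis
    options mirror the defaults documented in :mod:`cario.activity_stats`.
    """

    out_dir: str = "cario_report"
    cohort: CohortConfig = field(default_factory=CohortConfig)
    tsl_cut_um: float = 70.0
    include_undetected_tsl: bool = False
    equal_var_ttest: bool = False
    seed: int = 0
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if isinstance(self.cohort, dict):
            self.cohort = _cohort_from_dict(self.cohort)
        if self.tsl_cut_um < 0:
            raise SchemaError("tsl_cut_um must be nonnegative")


def _cohort_from_dict(d: dict) -> CohortConfig:
    known = {f.name for f in dataclasses.fields(CohortConfig)}
    unknown = set(d) - known
    if unknown:
        raise SchemaError(f"unknown cohort config keys: {sorted(unknown)}")
    d = dict(d)
    for key in ("tsl_range_um", "depth_range_um", "image_shape",
                "surface_type_weights", "mineral_loss_range"):
        if key in d and isinstance(d[key], list):
            d[key] = tuple(d[key])
    return CohortConfig(**d)


def load_config(path: str | Path) -> PipelineConfig:
    """Load and validate a YAML pipeline configuration; unknown keys are rejected."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise SchemaError(f"{path}: top level must be a mapping")
    known = {f.name for f in dataclasses.fields(PipelineConfig)}
    unknown = set(raw) - known
    if unknown:
        raise SchemaError(f"{path}: unknown config keys: {sorted(unknown)}")
    return PipelineConfig(**raw)


def save_config(config: PipelineConfig, path: str | Path) -> None:
    data = dataclasses.asdict(config)
    with open(path, "w") as fh:
        yaml.safe_dump(data, fh, sort_keys=True)


def write_stack(stack: ImageStack, path: str | Path) -> None:
    """Write a stack as multi-page float32 TIFF plus a JSON metadata sidecar."""
    path = Path(path)
    tifffile.imwrite(path, stack.frames.astype(np.float32))
    meta = {
        "frame_interval_s": stack.frame_interval_s,
        "modality": stack.modality,
        "n_frames": int(stack.n_frames),
    }
    path.with_suffix(".json").write_text(json.dumps(meta, sort_keys=True, indent=1))


def read_stack(path: str | Path) -> ImageStack:
    """Read a multi-page TIFF stack; metadata comes from the JSON sidecar
    when present (defaults: 1-s frames, SWIR)."""
    path = Path(path)
    frames = np.asarray(tifffile.imread(path), dtype=np.float64)
    if frames.ndim == 2:
        raise SchemaError(f"{path}: expected a multi-page stack, got a single page")
    meta_path = path.with_suffix(".json")
    interval, modality = 1.0, "swir"
    if meta_path.exists():
        meta = json.loads(meta_path.read_text())
        interval = float(meta.get("frame_interval_s", 1.0))
        modality = str(meta.get("modality", "swir"))
    return ImageStack(frames=frames, frame_interval_s=interval, modality=modality)


def write_mask(mask: np.ndarray, path: str | Path) -> None:
    tifffile.imwrite(Path(path), np.asarray(mask, dtype=bool).astype(np.uint8))


def read_mask(path: str | Path) -> np.ndarray:
    """Read a binary mask TIFF; nonbinary pixel values are rejected."""
    arr = np.asarray(tifffile.imread(Path(path)))
    if not np.isin(arr, (0, 1)).all():
        raise SchemaError(f"{path}: mask contains nonbinary values")
    return arr.astype(bool)


def write_records(frame: pd.DataFrame, path: str | Path) -> None:
    missing = [c for c in RECORD_COLUMNS if c not in frame.columns]
    if missing:
        raise SchemaError(f"record table missing required columns: {missing}")
    frame.to_csv(path, index=False, float_format="%.10g")


def read_records(path: str | Path) -> pd.DataFrame:
    try:
        frame = pd.read_csv(path)
    except Exception as exc:  # pragma: no cover - message wrapping
        raise SchemaError(f"{path}: could not parse CSV: {exc}") from exc
    missing = [c for c in RECORD_COLUMNS if c not in frame.columns]
    if missing:
        raise SchemaError(f"{path}: missing required columns: {missing}")
    return frame
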