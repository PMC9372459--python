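"""File formats and the end-to-end per-image pipeline.

Canonical on-disk dialects: RGB as PNG/JPEG, depth as 16-bit PNG in
integer millimetres (0 = missing; 16 bits cover 0-65 m against a sensor
envelope of 300-1500 mm) or as a whitespace float grid, masks as 8-bit
0/255 PNG, boxes/records/metrics as JSON, intrinsics and configs as
YAML.  Detection is an input boundary: boxes come from any detector or
from ground-truth files.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml
from PIL import Image

from .geometry import CameraIntrinsics, DzModel, Localization3D, localize_fruit
from .kriging import KrigingConfig, krige_fill
from .losses import (
    BBox2D,
    boxes_from_json,
    match_detections,
    metrics_to_json,
)
from .segmentation import (
    DegenerateInputError,
    EmptyRegionError,
    MorphologyConfig,
    extract_fruit_region,
    pad_and_clamp_box,
)

logger = logging.getLogger(__name__)

__all__ = [
    "FormatError",
    "PipelineConfig",
    "LocalizationRecord",
    "read_rgb",
    "write_rgb",
    "read_depth",
    "write_depth",
    "read_mask",
    "write_mask",
    "read_intrinsics",
    "write_intrinsics",
    "run_pipeline",
    "run_pipeline_arrays",
    "eval_detection",
]


class FormatError(ValueError):
    """A file exists but is not in the expected dialect."""


# ---------------------------------------------------------------------------
# raster I/O


def read_rgb(path: str | Path) -> np.ndarray:
    img = Image.open(path).convert("RGB")
    return np.asarray(img, dtype=np.uint8)


def write_rgb(image: np.ndarray, path: str | Path) -> None:
    Image.fromarray(np.asarray(image, dtype=np.uint8), mode="RGB").save(path)


def read_depth(path: str | Path, dialect: str = "png16_mm") -> np.ndarray:
    """Depth map in float mm; 0 is preserved as the missing marker."""
    if dialect == "png16_mm":
        img = Image.open(path)
        if img.mode not in ("I", "I;16", "I;16B"):
            raise FormatError(
                f"{path}: mode {img.mode!r} is not 16-bit; "
                "expected a 16-bit integer-mm PNG (dialect png16_mm)"
            )
        return np.asarray(img, dtype=np.float64)
    if dialect == "float_grid":
        arr = np.loadtxt(path, dtype=np.float64, ndmin=2)
        if not np.isfinite(arr).all() or (arr < 0).any():
            raise FormatError(f"{path}: float grid must be finite and non-negative")
        return arr
    raise ValueError(f"unknown depth dialect {dialect!r}")


def write_depth(depth: np.ndarray, path: str | Path, dialect: str = "png16_mm") -> None:
    d = np.asarray(depth, dtype=np.float64)
    if (d < 0).any() or not np.isfinite(d).all():
        raise ValueError("depth values must be finite and non-negative")
    if dialect == "png16_mm":
        q = np.round(d).astype(np.uint16)
        Image.fromarray(q).save(path)  # uint16 -> 16-bit grayscale PNG
    elif dialect == "float_grid":
        np.savetxt(path, d, fmt="%.6f")
    else:
        raise ValueError(f"unknown depth dialect {dialect!r}")


def read_mask(path: str | Path) -> np.ndarray:
    arr = np.asarray(Image.open(path).convert("L"))
    return arr > 127


def write_mask(mask: np.ndarray, path: str | Path) -> None:
    arr = (np.asarray(mask).astype(bool) * np.uint8(255))
    Image.fromarray(arr, mode="L").save(path)


# ---------------------------------------------------------------------------
# configuration


def read_intrinsics(path: str | Path) -> CameraIntrinsics:
    data = yaml.safe_load(Path(path).read_text())
    try:
        if "fx" in data:
            return CameraIntrinsics(
                fx=float(data["fx"]), fy=float(data["fy"]),
                u0=float(data["u0"]), v0=float(data["v0"]),
            )
        return CameraIntrinsics.from_physical(
            f=float(data["f"]), du=float(data["du"]), dv=float(data["dv"]),
            u0=float(data["u0"]), v0=float(data["v0"]),
        )
    except (KeyError, TypeError) as exc:
        raise FormatError(f"{path}: expected keys fx/fy/u0/v0 or f/du/dv/u0/v0") from exc


def write_intrinsics(K: CameraIntrinsics, path: str | Path) -> None:
    Path(path).write_text(
        yaml.safe_dump({"fx": K.fx, "fy": K.fy, "u0": K.u0, "v0": K.v0})
    )


@dataclass(frozen=True)
class PipelineConfig:
    intrinsics: CameraIntrinsics
    morphology: MorphologyConfig = MorphologyConfig()
    kriging: KrigingConfig = KrigingConfig()
    dz_model: DzModel = DzModel()
    gamma: float = 20.0
    iou_threshold: float = 0.5
    center_from: str = "box"


@dataclass(frozen=True)
class LocalizationRecord:
    image_id: str
    box_id: int
    localization: Localization3D
    threshold: int
    restoration_stats: dict

    def to_dict(self) -> dict:
        return {
            "image_id": self.image_id,
            "box_id": self.box_id,
            "threshold": self.threshold,
            "restoration_stats": self.restoration_stats,
            **self.localization.to_dict(),
        }


# ---------------------------------------------------------------------------
# pipeline


def run_pipeline_arrays(
    image: np.ndarray,
    depth: np.ndarray,
    boxes: list[BBox2D],
    config: PipelineConfig,
    image_id: str = "image",
) -> tuple[list[LocalizationRecord], int]:
    """Segment, restore and localize every box; returns (records, n_skipped).

    A failure on one box (no fruit pixels, too few depth observations,
    degenerate geometry) is logged and skipped; the others continue.
    """
    if image.shape[:2] != depth.shape:
        raise ValueError(
            f"RGB {image.shape[:2]} and depth {depth.shape} sizes differ"
        )
    records: list[LocalizationRecord] = []
    skipped = 0
    t_start = time.perf_counter()
    for i, box in enumerate(boxes):
        try:
            t0 = time.perf_counter()
            seg = extract_fruit_region(image, box, config.morphology)
            logger.info("%s box %d: segmented (threshold=%d) in %.3fs",
                        image_id, i, seg.threshold, time.perf_counter() - t0)
            u0, v0, u1, v1 = pad_and_clamp_box(
                box, image.shape[0], image.shape[1], config.morphology.bbox_padding
            )
            depth_crop = depth[v0:v1, u0:u1]
            valid = seg.otsu_mask & seg.refined_mask
            t0 = time.perf_counter()
            restored = krige_fill(depth_crop, seg.convex_mask, valid, config.kriging)
            n_filled = int((seg.convex_mask & ~(valid & (depth_crop > 0))).sum())
            logger.info("%s box %d: restored %d px in %.3fs",
                        image_id, i, n_filled, time.perf_counter() - t0)
            t0 = time.perf_counter()
            loc = localize_fruit(
                seg, restored, box, config.intrinsics, config.dz_model,
                center_from=config.center_from,
            )
            logger.info("%s box %d: localized d=%.1f mm in %.3fs",
                        image_id, i, loc.d, time.perf_counter() - t0)
            records.append(
                LocalizationRecord(
                    image_id=image_id,
                    box_id=i,
                    localization=loc,
                    threshold=seg.threshold,
                    restoration_stats={
                        "n_observed": int((valid & (depth_crop > 0)).sum()),
                        "n_filled": n_filled,
                    },
                )
            )
        except (DegenerateInputError, EmptyRegionError, ValueError) as exc:
            logger.warning("%s box %d skipped: %s", image_id, i, exc)
            skipped += 1
    logger.info("%s: %d boxes processed, %d skipped, %.3fs total",
                image_id, len(records), skipped, time.perf_counter() - t_start)
    if not boxes:
        logger.warning("%s: empty box list", image_id)
    return records, skipped


def run_pipeline(
    rgb_path: str | Path,
    depth_path: str | Path,
    boxes_path: str | Path,
    config: PipelineConfig,
    depth_dialect: str = "png16_mm",
) -> tuple[list[LocalizationRecord], int]:
    image = read_rgb(rgb_path)
    depth = read_depth(depth_path, depth_dialect)
    if image.shape[:2] != depth.shape:
        raise FormatError(
            f"{depth_path}: depth shape {depth.shape} does not match RGB "
            f"{image.shape[:2]}"
        )
    boxes = boxes_from_json(boxes_path)
    return run_pipeline_arrays(image, depth, boxes, config, image_id=Path(rgb_path).stem)


def eval_detection(
    pred_path: str | Path,
    truth_path: str | Path,
    iou_threshold: float = 0.5,
) -> dict:
    """Match predicted boxes to truth and report the metric summary JSON."""
    pred = boxes_from_json(pred_path)
    truth = boxes_from_json(truth_path)
    counts = match_detections(pred, truth, iou_threshold)
    try:
        return metrics_to_json(counts)
    except ZeroDivisionError:
        result = {"tp": counts.tp, "fp": counts.fp, "fn": counts.fn}
        if counts.tp + counts.fp == 0:
            result["precision_pct"] = None
        if counts.tp + counts.fn == 0:
            result["recall_pct"] = None
        else:
            result.setdefault(
                "recall_pct", 100.0 * counts.tp / (counts.tp + counts.fn)
            )
        return result


def records_to_json(records: list[LocalizationRecord], path: str | Path) -> None:
    Path(path).write_text(json.dumps([r.to_dict() for r in records], indent=1))
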