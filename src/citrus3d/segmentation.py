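"""Chromatic extraction of the complete fruit region from a 2D bounding box.

Mature citrus against foliage separates cleanly in the Cr-Cb chroma
difference of full-range BT.601 YCbCr: orange pulls Cr up and Cb down,
foliage and sky do the opposite, so ``clip(Cr - Cb, 0, 255)`` is a
single-channel map that is bright on fruit and near zero elsewhere.  The
pipeline is: Cr-Cb map -> Otsu threshold -> morphological clean-up
(opening, hole fill, component selection) -> convex-hull completion of
the occluded silhouette -> extreme points A/B/C/D used downstream for
3D sizing.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from scipy.spatial import ConvexHull, QhullError
from skimage.morphology import disk

from .losses import BBox2D

__all__ = [
    "DegenerateInputError",
    "EmptyRegionError",
    "MorphologyConfig",
    "ExtremePoints",
    "SegmentationResult",
    "crcb_map",
    "otsu_threshold",
    "refine_mask",
    "convex_completion",
    "extreme_points",
    "extract_fruit_region",
    "default_opening_radius",
]


class DegenerateInputError(ValueError):
    """Input carries no usable contrast (e.g. constant chroma map)."""


class EmptyRegionError(ValueError):
    """No foreground region survives (e.g. mask emptied by opening)."""


@dataclass(frozen=True)
class MorphologyConfig:
    """Clean-up parameters for the Otsu mask.

    opening_radius : disk radius in pixels for the noise-removing opening;
        ``None`` selects a scale-adaptive default of 1.5% of the larger
        crop side (fruit crops range roughly 50-400 px).
    closing_radius : disk radius for the gap-bridging closing that re-joins
        fruit parts separated by thin occluders (branches); ``None`` selects
        9% of the larger crop side, enough to bridge a branch of ~1/5 fruit
        width.  0 disables the closing.
    min_component_area : components smaller than this (px^2) are dropped
        before selection.
    bbox_padding : fractional padding added to the detector box before
        cropping, so fruit pixels clipped by a tight box are recoverable.
    min_fruit_chroma : plausibility floor on the mean Cr-Cb of the refined
        region; even deeply shadowed ripe fruit exceeds ~35 while foliage,
        soil and branches stay below ~25, so a region under the floor means
        the crop holds no fruit.
    """

    opening_radius: int | None = None
    closing_radius: int | None = None
    min_component_area: int = 16
    bbox_padding: float = 0.05
    min_fruit_chroma: float = 30.0

    def __post_init__(self) -> None:
        if self.opening_radius is not None and self.opening_radius < 1:
            raise ValueError("opening_radius must be >= 1")
        if self.closing_radius is not None and self.closing_radius < 0:
            raise ValueError("closing_radius must be >= 0")


@dataclass(frozen=True)
class ExtremePoints:
    """Leftmost / topmost / rightmost / bottom-most region pixels, (u, v)."""

    A: tuple[int, int]
    B: tuple[int, int]
    C: tuple[int, int]
    D: tuple[int, int]


@dataclass(frozen=True)
class SegmentationResult:
    otsu_mask: np.ndarray  # I_O, crop frame
    refined_mask: np.ndarray
    convex_mask: np.ndarray  # I_C
    extremes: ExtremePoints  # crop-frame coordinates
    threshold: int
    crop_origin: tuple[int, int]  # (u, v) of the crop's top-left in the image

    def to_dict(self) -> dict:
        e = self.extremes
        return {
            "threshold": self.threshold,
            "crop_origin": list(self.crop_origin),
            "extremes": {k: list(getattr(e, k)) for k in "ABCD"},
        }


def default_opening_radius(height: int, width: int) -> int:
    return max(1, round(0.015 * max(height, width)))


def default_closing_radius(height: int, width: int) -> int:
    return max(2, round(0.09 * max(height, width)))


def crcb_map(crop: np.ndarray) -> np.ndarray:
    """Cr - Cb chroma difference (full-range BT.601), clipped to [0, 255].

    The 128 offsets of Cr and Cb cancel in the difference, leaving a pure
    linear combination of R, G, B; negative (green/blue-dominated) values
    clip to zero.  Returns float64 with the crop's spatial shape.
    """
    a = np.asarray(crop, dtype=np.float64)
    if a.ndim != 3 or a.shape[2] < 3 or a.shape[0] == 0 or a.shape[1] == 0:
        raise ValueError(f"expected a non-empty HxWx3 RGB crop, got shape {a.shape}")
    r, g, b = a[..., 0], a[..., 1], a[..., 2]
    cr_minus_cb = (0.5 + 0.168736) * r + (0.331264 - 0.418688) * g - (0.081312 + 0.5) * b
    return np.clip(cr_minus_cb, 0.0, 255.0)


def otsu_threshold(chroma: np.ndarray) -> int:
    """Threshold maximizing between-class variance over the 256-bin histogram.

    Pixels whose integer chroma level (floor) strictly exceeds the returned
    threshold are foreground, so the mask rule agrees exactly with the
    histogram classing (bin t counts as background).  Ties are broken
    toward the smallest threshold.  A constant map has no two classes to
    separate and raises :class:`DegenerateInputError`.
    """
    a = np.asarray(chroma, dtype=np.float64)
    if a.size == 0:
        raise ValueError("empty chroma map")
    if np.ptp(a) == 0:
        raise DegenerateInputError("constant chroma map: no threshold separates two classes")
    hist, _ = np.histogram(np.clip(a, 0, 255), bins=256, range=(0.0, 256.0))
    n = hist.sum()
    levels = np.arange(256, dtype=np.float64)
    w0 = np.cumsum(hist)[:-1]  # class 0 = levels <= t, t = 0..254
    w1 = n - w0
    m0 = np.cumsum(hist * levels)[:-1]
    mu_total = (hist * levels).sum()
    with np.errstate(divide="ignore", invalid="ignore"):
        mu0 = m0 / w0
        mu1 = (mu_total - m0) / w1
        sigma_b = w0 * w1 * (mu0 - mu1) ** 2
    sigma_b = np.where((w0 > 0) & (w1 > 0), sigma_b, -np.inf)
    if not np.isfinite(sigma_b).any():
        raise DegenerateInputError("all mass in a single histogram bin")
    return int(np.argmax(sigma_b))  # argmax takes the first (smallest) maximizer


def refine_mask(mask: np.ndarray, config: MorphologyConfig = MorphologyConfig()) -> np.ndarray:
    """Opening, gap-bridging closing, hole filling, component selection.

    Opening removes speckle noise; the closing re-joins fruit parts split
    by thin occluders (branches) so they survive as one component; hole
    filling removes interior holes (specular dropouts, leaves).  The
    retained component is the one overlapping the central-third window
    of the crop the most (a detector box centres its fruit); if none touches
    that window the largest component is kept.  The result has no interior
    holes.  Raises :class:`EmptyRegionError` if nothing survives.
    """
    m = np.asarray(mask).astype(bool)
    if not m.any():
        raise EmptyRegionError("empty input mask")
    h, w = m.shape
    radius = config.opening_radius or default_opening_radius(h, w)
    opened = ndimage.binary_opening(m, structure=disk(radius))
    if not opened.any():
        raise EmptyRegionError(f"mask vanished under opening with radius {radius}")
    c_radius = (
        config.closing_radius
        if config.closing_radius is not None
        else default_closing_radius(h, w)
    )
    if c_radius > 0:
        # pad so the dilation can spill past the crop edge and the erosion
        # gives it back: closing must not eat fruit touching the border
        pad = c_radius + 1
        padded = np.pad(opened, pad)
        closed = ndimage.binary_closing(padded, structure=disk(c_radius))
        opened = closed[pad:-pad, pad:-pad]
    filled = ndimage.binary_fill_holes(opened)
    labels, n = ndimage.label(filled)
    if n > 1:
        areas = ndimage.sum_labels(np.ones_like(labels), labels, index=np.arange(1, n + 1))
        keep = areas >= config.min_component_area
        if not keep.any():
            keep = areas == areas.max()
        central = np.zeros_like(filled)
        central[h // 3 : max(h // 3 + 1, 2 * h // 3), w // 3 : max(w // 3 + 1, 2 * w // 3)] = True
        overlaps = ndimage.sum_labels(central.astype(float), labels, index=np.arange(1, n + 1))
        overlaps = np.where(keep, overlaps, -1.0)
        if overlaps.max() > 0:
            chosen = int(np.argmax(overlaps)) + 1
        else:
            chosen = int(np.argmax(np.where(keep, areas, -1.0))) + 1
        filled = labels == chosen
    return ndimage.binary_fill_holes(filled)


def convex_completion(mask: np.ndarray) -> np.ndarray:
    """Filled convex hull of the foreground; approximates the occluded fruit.

    The hull polygon is taken over foreground pixel *centers* and
    rasterized by center-inclusion, which makes the operator idempotent
    (the hull of the output's centers is the same polygon) and keeps the
    pixel area within a half-perimeter of the polygon area.  Degenerate
    (collinear) foregrounds are returned unchanged.
    """
    m = np.asarray(mask).astype(bool)
    if not m.any():
        raise EmptyRegionError("empty mask has no convex hull")
    vs, us = np.nonzero(m)
    pts = np.column_stack([us, vs]).astype(np.float64)
    try:
        hull = ConvexHull(pts)
    except QhullError:  # single pixel, line, or otherwise flat point set
        return m.copy()
    vv, uu = np.nonzero(np.ones_like(m))
    centers = np.column_stack([uu, vv]).astype(np.float64)
    # inside-or-on test via the hull's facet inequalities A x + b <= 0
    a, b = hull.equations[:, :2], hull.equations[:, 2]
    inside = (centers @ a.T + b <= 1e-7).all(axis=1)
    out = np.zeros_like(m)
    out[vv[inside], uu[inside]] = True
    return out | m


def extreme_points(mask: np.ndarray) -> ExtremePoints:
    """Extreme pixels of the region in (u, v) = (col, row) coordinates.

    Ties along the extremal coordinate are broken by the pixel whose other
    coordinate is closest to the region centroid (lower index on exact ties).
    """
    m = np.asarray(mask).astype(bool)
    vs, us = np.nonzero(m)
    if vs.size == 0:
        raise EmptyRegionError("empty mask has no extreme points")
    cu, cv = us.mean(), vs.mean()

    def pick(primary: np.ndarray, other: np.ndarray, val: float, centroid: float) -> int:
        idx = np.nonzero(primary == val)[0]
        return int(idx[np.argmin(np.abs(other[idx] - centroid))])

    iA = pick(us, vs, us.min(), cv)
    iC = pick(us, vs, us.max(), cv)
    iB = pick(vs, us, vs.min(), cu)
    iD = pick(vs, us, vs.max(), cu)
    pt = lambda i: (int(us[i]), int(vs[i]))
    return ExtremePoints(A=pt(iA), B=pt(iB), C=pt(iC), D=pt(iD))


def pad_and_clamp_box(
    box: BBox2D, height: int, width: int, padding: float
) -> tuple[int, int, int, int]:
    """Integer crop window (u0, v0, u1, v1) for a padded, clamped box."""
    du = (box.u_max - box.u_min) * padding
    dv = (box.v_max - box.v_min) * padding
    u0 = max(0, int(np.floor(box.u_min - du)))
    v0 = max(0, int(np.floor(box.v_min - dv)))
    u1 = min(width, int(np.ceil(box.u_max + du)))
    v1 = min(height, int(np.ceil(box.v_max + dv)))
    if u1 <= u0 or v1 <= v0:
        raise ValueError(f"box {box} lies outside the {height}x{width} image")
    return u0, v0, u1, v1


def extract_fruit_region(
    image: np.ndarray,
    box: BBox2D,
    config: MorphologyConfig = MorphologyConfig(),
) -> SegmentationResult:
    """Full per-box pipeline; masks come back in crop coordinates.

    Crops the padded box, then chroma map -> Otsu -> morphology -> convex
    hull -> extreme points.  ``crop_origin`` records where the crop sits in
    the source image.
    """
    img = np.asarray(image)
    if img.ndim != 3:
        raise ValueError("expected an HxWx3 RGB image")
    u0, v0, u1, v1 = pad_and_clamp_box(box, img.shape[0], img.shape[1], config.bbox_padding)
    crop = img[v0:v1, u0:u1]
    chroma = crcb_map(crop)
    threshold = otsu_threshold(chroma)
    # floor-quantize so the mask rule matches the histogram's binning
    otsu_mask = np.floor(chroma) > threshold
    refined = refine_mask(otsu_mask, config)
    mean_chroma = float(chroma[refined].mean())
    if mean_chroma < config.min_fruit_chroma:
        raise DegenerateInputError(
            f"region mean chroma {mean_chroma:.1f} below the fruit floor "
            f"{config.min_fruit_chroma}: no fruit in this crop"
        )
    convex = convex_completion(refined)
    return SegmentationResult(
        otsu_mask=otsu_mask,
        refined_mask=refined,
        convex_mask=convex,
        extremes=extreme_points(convex),
        threshold=threshold,
        crop_origin=(u0, v0),
    )
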