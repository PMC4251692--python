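"""Vein segmentation, marker-hit adjudication and the depth-visibility sweep.

Segmentation operates on ridge-response frames (DoG/LoG output, where
vein-like structure sits below the 0.5 neutral value): the darkest
quantile of the response is thresholded, cleaned morphologically, and
small components are dropped; centerlines are the skeletons of what
survives.

In the field study a "positive match" — a marked venipuncture point with
a vein underneath — was adjudicated visually by supervising clinicians.
Here it is operationalized as a distance rule: the mark hits if a mask
pixel lies within ``hit_tolerance`` (default 2 mm, roughly an
antecubital vein radius) of it. This is a proxy for human judgement,
not a reproduction of it; the tolerance stays configurable.
"""

from __future__ import annotations

from dataclasses import dataclass, replace as dc_replace

import numpy as np
from scipy.ndimage import distance_transform_edt
from skimage.measure import label as sk_label
from skimage.morphology import closing, disk, opening, skeletonize

from .camera import CameraSettings
from .enhance import EnhanceConfig, process_frame
from .image import NIRImage
from .phantom import (
    PhantomSpec,
    VeinSegment,
    michelson_contrast,
    rasterize_centerlines,
    render_phantom,
)

__all__ = [
    "DetectConfig",
    "VeinMask",
    "segment_veins",
    "is_vein_at",
    "count_visible_veins",
    "centerline_recall",
    "max_visible_depth",
    "SWEEP_VEIN_RADIUS",
]

SWEEP_VEIN_RADIUS = 1.0  # mm; typical antecubital vein used for the depth sweep


@dataclass(frozen=True)
class DetectConfig:
    threshold_quantile: float = 0.05   # fraction of darkest response kept
    min_component_area: int = 50       # pixels
    morph_radius: int = 1              # pixels
    hit_tolerance: float = 2.0         # mm
    min_centerline_length: float = 5.0 # mm
    contrast_floor: float = 0.02       # Michelson contrast detectability floor

    def __post_init__(self) -> None:
        if not 0 <= self.threshold_quantile < 0.5:
            raise ValueError("threshold_quantile must be in [0, 0.5)")
        for name in ("min_component_area", "morph_radius", "hit_tolerance",
                     "min_centerline_length", "contrast_floor"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")


@dataclass(frozen=True)
class VeinMask:
    """Binary vein mask, its skeleton centerlines, and the source frame."""

    mask: np.ndarray                    # bool, same shape as source frame
    centerlines: tuple                  # of (N, 2) int pixel arrays
    source_frame: NIRImage

    def __post_init__(self) -> None:
        if self.mask.shape != self.source_frame.shape:
            raise ValueError("mask and source frame shapes differ")

    @property
    def centerline_pixels(self) -> np.ndarray:
        """All centerline pixels stacked into one (M, 2) array."""
        if not self.centerlines:
            return np.empty((0, 2), dtype=int)
        return np.vstack(self.centerlines)


_NEIGHBORS = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]


def _trace_polyline(pixels: np.ndarray) -> np.ndarray:
    """Order skeleton pixels of one component into a polyline by DFS.

    Starts at a degree-1 pixel (an endpoint) when one exists; branched
    skeletons come out in DFS order, which is sufficient because all
    length measures count pixels rather than fit arcs.
    """
    pset = {tuple(p) for p in pixels}
    deg = {
        p: sum((p[0] + dr, p[1] + dc) in pset for dr, dc in _NEIGHBORS) for p in pset
    }
    start = min((p for p in pset if deg[p] <= 1), default=min(pset))
    order, seen, stack = [], set(), [start]
    while stack:
        p = stack.pop()
        if p in seen:
            continue
        seen.add(p)
        order.append(p)
        for dr, dc in _NEIGHBORS:
            q = (p[0] + dr, p[1] + dc)
            if q in pset and q not in seen:
                stack.append(q)
    return np.array(order, dtype=int)


def segment_veins(enhanced: NIRImage, config: DetectConfig) -> VeinMask:
    """Threshold the darkest response quantile into a cleaned vein mask.

    Pipeline: quantile threshold (strictly below) -> morphological
    closing then opening with a ``morph_radius`` disk -> drop components
    smaller than ``min_component_area`` (8-connectivity) -> skeletonize
    the survivors into centerline polylines. A constant frame yields an
    empty mask, not an error.
    """
    resp = enhanced.pixels
    if resp.max() == resp.min():
        return VeinMask(
            np.zeros(enhanced.shape, dtype=bool), (), enhanced
        )
    thr = np.quantile(resp, config.threshold_quantile)
    mask = resp < thr
    if config.morph_radius > 0:
        selem = disk(config.morph_radius)
        mask = opening(closing(mask, selem), selem)
    labels = sk_label(mask, connectivity=2)
    keep = np.zeros_like(mask)
    for lab in range(1, labels.max() + 1):
        comp = labels == lab
        if comp.sum() >= config.min_component_area:
            keep |= comp
    skel = skeletonize(keep)
    skel_labels = sk_label(keep, connectivity=2)
    centerlines = []
    for lab in range(1, skel_labels.max() + 1):
        pix = np.argwhere(skel & (skel_labels == lab))
        if len(pix):
            centerlines.append(_trace_polyline(pix))
    # skeleton pixels sit inside the mask by construction
    return VeinMask(keep, tuple(centerlines), enhanced)


def is_vein_at(mask: VeinMask, point: tuple[int, int], tolerance: float) -> bool:
    """True iff a mask pixel lies within ``tolerance`` mm of ``point`` (pixels)."""
    r, c = point
    rows, cols = mask.mask.shape
    if not (0 <= r < rows and 0 <= c < cols):
        raise ValueError(f"point {point} outside frame {mask.mask.shape}")
    if not mask.mask.any():
        return False
    tol_px = tolerance / mask.source_frame.pixel_pitch
    on = np.argwhere(mask.mask)
    d = np.hypot(on[:, 0] - r, on[:, 1] - c)
    return bool(d.min() <= tol_px)


def count_visible_veins(mask: VeinMask, min_centerline_length: float) -> int:
    """Connected components whose skeleton arc-length reaches the minimum.

    Arc length is skeleton pixel count times pixel pitch (no subpixel
    fitting).
    """
    if not mask.mask.any():
        return 0
    pitch = mask.source_frame.pixel_pitch
    labels = sk_label(mask.mask, connectivity=2)
    skel = skeletonize(mask.mask)
    count = 0
    for lab in range(1, labels.max() + 1):
        if (skel & (labels == lab)).sum() * pitch >= min_centerline_length:
            count += 1
    return count


def centerline_recall(
    detected: VeinMask, truth_centerline: np.ndarray, tolerance: float
) -> float:
    """Fraction of true centerline pixels within ``tolerance`` mm of a
    detected centerline pixel."""
    truth_pts = np.argwhere(truth_centerline)
    if len(truth_pts) == 0:
        return 1.0
    det = detected.centerline_pixels
    if len(det) == 0:
        return 0.0
    det_img = np.zeros(detected.mask.shape, dtype=bool)
    det_img[det[:, 0], det[:, 1]] = True
    dist_px = distance_transform_edt(~det_img)
    tol_px = tolerance / detected.source_frame.pixel_pitch
    return float((dist_px[truth_pts[:, 0], truth_pts[:, 1]] <= tol_px).mean())


def _straight_vein(spec: PhantomSpec, depth: float, radius: float) -> VeinSegment:
    h_mm, w_mm = spec.field_of_view_mm
    margin = min(2.0, 0.1 * w_mm)
    return VeinSegment(
        centerline=np.array([[h_mm / 2, margin], [h_mm / 2, w_mm - margin]]),
        radius=radius,
        depth=depth,
    )


def max_visible_depth(
    spec: PhantomSpec,
    config: DetectConfig,
    depth_grid,
    enhance_config: EnhanceConfig | None = None,
    radius: float = SWEEP_VEIN_RADIUS,
) -> float:
    """Deepest straight vein the default pipeline still detects.

    One phantom per grid depth (noise seeded per depth), run through the
    default enhancement (dog1) and segmentation; a depth counts as
    detected when centerline recall >= 0.5 AND the rendered Michelson
    contrast >= ``contrast_floor``. Returns 0 when nothing is detected.
    """
    depth_grid = list(depth_grid)
    if not depth_grid:
        raise ValueError("depth_grid must be nonempty")
    if any(b < a for a, b in zip(depth_grid[:-1], depth_grid[1:])):
        raise ValueError("depth_grid must be sorted ascending")
    if enhance_config is None:
        enhance_config = EnhanceConfig.for_mode("dog1")
    settings = CameraSettings()
    deepest = 0.0
    for i, depth in enumerate(depth_grid):
        sp = dc_replace(spec, rng_seed=spec.rng_seed + 1000 * i)
        vein = _straight_vein(sp, depth, radius)
        out = render_phantom(sp, [vein])
        enhanced = process_frame(out.image, settings, enhance_config)
        seg = segment_veins(enhanced, config)
        truth_cl = rasterize_centerlines(out.veins, out.image.shape, sp.pixel_pitch)
        recall = centerline_recall(seg, truth_cl, config.hit_tolerance)
        contrast = michelson_contrast(out)
        if recall >= 0.5 and contrast >= config.contrast_floor:
            deepest = float(depth)
    return deepest
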