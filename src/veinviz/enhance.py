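"""NIR image-processing operators: contrast stretch, DoG, Laplacian, ROI.

The raw NIR frames are high-contrast but low-detail; veins become usable
for navigation after band-pass filtering. Two operator families are
provided, each at two scales:

* ``dog1`` / ``dog2`` — difference of Gaussians, a band-pass that
  highlights curvilinear structure near the scale ``sigma_narrow``;
* ``log1`` / ``log2`` — Laplacian of Gaussian (``log2`` degenerates to
  the raw 4-neighbour Laplacian).

Both produce a signed response that is renormalized affinely to [0, 1]
with zero mapped to 0.5, so dark (vein-like) structure always sits below
0.5 regardless of scale. Sigmas are given in mm and converted through
the frame's pixel pitch; borders are reflect-padded throughout.

The scale defaults (dog1: 0.4/2.0 mm, dog2: 0.8/4.0 mm, log1: 1.0 mm)
are tuned to vein radii of 1-2 mm; the hardware prototype's exact
filter constants were never published, so these are reconstructions.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, replace

import numpy as np
from scipy.ndimage import convolve, gaussian_filter

from .camera import CameraSettings, apply_settings
from .image import NIRImage

__all__ = [
    "EnhanceConfig",
    "MODES",
    "contrast_enhance",
    "difference_of_gaussians",
    "dog_response",
    "laplacian",
    "log_response",
    "apply_roi",
    "process_frame",
    "process_stream",
    "StreamReport",
]

MODES = ("raw-contrast", "dog1", "dog2", "log1", "log2")

# (sigma_narrow, sigma_wide) mm for DoG modes; sigma mm for LoG modes
_DOG_SCALES = {"dog1": (0.4, 2.0), "dog2": (0.8, 4.0)}
_LOG_SCALES = {"log1": 1.0, "log2": 0.0}

LAPLACIAN_KERNEL = np.array([[0, 1, 0], [1, -4, 1], [0, 1, 0]], dtype=np.float64)


@dataclass(frozen=True)
class EnhanceConfig:
    """Which operator to run and at what physical scale."""

    mode: str = "dog1"
    sigma_narrow: float = 0.4       # mm
    sigma_wide: float = 2.0         # mm
    log_sigma: float = 1.0          # mm
    stretch_percentiles: tuple[float, float] = (1.0, 99.0)
    roi: tuple[int, int, int, int] | None = None  # (row0, col0, row1, col1) half-open

    def __post_init__(self) -> None:
        mode = "raw-contrast" if self.mode == "none" else self.mode
        if mode not in MODES:
            raise ValueError(f"mode must be one of {MODES}, got {self.mode!r}")
        object.__setattr__(self, "mode", mode)
        lo, hi = self.stretch_percentiles
        if not (0 <= lo < hi <= 100):
            raise ValueError(f"need 0 <= low < high <= 100, got {lo}, {hi}")
        if not (0 < self.sigma_narrow < self.sigma_wide):
            raise ValueError("need 0 < sigma_narrow < sigma_wide")
        if self.log_sigma < 0:
            raise ValueError("log_sigma must be >= 0")

    @classmethod
    def for_mode(cls, mode: str, **overrides) -> "EnhanceConfig":
        """Config with the packaged scale defaults for a named mode."""
        kw: dict = {"mode": mode}
        if mode in _DOG_SCALES:
            kw["sigma_narrow"], kw["sigma_wide"] = _DOG_SCALES[mode]
        elif mode in _LOG_SCALES:
            kw["log_sigma"] = _LOG_SCALES[mode]
        kw.update(overrides)
        return cls(**kw)


def _renormalize(signed: np.ndarray) -> np.ndarray:
    """Map a signed response to [0,1] symmetrically about 0.5.

    Responses below 1e-12 (float round-off of a DC frame, intensities
    being O(1)) are treated as zero signal.
    """
    m = np.max(np.abs(signed))
    if m < 1e-12:
        return np.full_like(signed, 0.5)
    return np.clip(0.5 + 0.5 * signed / m, 0.0, 1.0)


def contrast_enhance(
    image: NIRImage, percentiles: tuple[float, float] = (1.0, 99.0)
) -> NIRImage:
    """Linear percentile stretch: low-th percentile -> 0, high-th -> 1.

    Constant (degenerate) frames are returned unchanged.
    """
    lo, hi = percentiles
    if lo >= hi:
        raise ValueError(f"need low < high percentile, got {lo} >= {hi}")
    p_lo, p_hi = np.percentile(image.pixels, [lo, hi])
    if p_hi <= p_lo:
        return image
    out = np.clip((image.pixels - p_lo) / (p_hi - p_lo), 0.0, 1.0)
    return image.with_pixels(out)


def dog_response(
    image: NIRImage, sigma_narrow: float, sigma_wide: float
) -> np.ndarray:
    """Signed DoG response G(sigma_narrow)*I - G(sigma_wide)*I (sigmas in mm)."""
    if not 0 < sigma_narrow < sigma_wide:
        raise ValueError(
            f"need 0 < sigma_narrow < sigma_wide, got {sigma_narrow}, {sigma_wide}"
        )
    sn = sigma_narrow / image.pixel_pitch
    sw = sigma_wide / image.pixel_pitch
    return gaussian_filter(image.pixels, sn, mode="reflect") - gaussian_filter(
        image.pixels, sw, mode="reflect"
    )


def difference_of_gaussians(
    image: NIRImage, sigma_narrow: float, sigma_wide: float
) -> NIRImage:
    """Band-pass DoG, renormalized to [0,1] about a 0.5 neutral value."""
    return image.with_pixels(_renormalize(dog_response(image, sigma_narrow, sigma_wide)))


def log_response(image: NIRImage, log_sigma: float) -> np.ndarray:
    """Signed (Gaussian-smoothed) discrete-Laplacian response.

    log_sigma = 0 gives the raw 4-neighbour Laplacian; > 0 smooths first
    (Laplacian of Gaussian). Sigma in mm.
    """
    if log_sigma < 0:
        raise ValueError(f"log_sigma must be >= 0, got {log_sigma}")
    px = image.pixels
    if log_sigma > 0:
        px = gaussian_filter(px, log_sigma / image.pixel_pitch, mode="reflect")
    return convolve(px, LAPLACIAN_KERNEL, mode="reflect")


def laplacian(image: NIRImage, log_sigma: float = 0.0) -> NIRImage:
    """Laplacian / LoG operator with the same symmetric renormalization as DoG."""
    return image.with_pixels(_renormalize(log_response(image, log_sigma)))


def apply_roi(image: NIRImage, roi, stage) -> NIRImage:
    """Run ``stage`` on the ROI crop only; outside pixels pass through.

    The crop is processed as its own frame (so operators reflect-pad at
    the ROI borders) and pasted back. ``roi = None`` processes the whole
    frame. ``stage`` maps NIRImage -> NIRImage.
    """
    if roi is None:
        return stage(image)
    r0, c0, r1, c1 = roi
    rows, cols = image.shape
    if not (0 <= r0 < r1 <= rows and 0 <= c0 < c1 <= cols):
        raise ValueError(f"roi {roi} outside image bounds {image.shape}")
    crop = image.with_pixels(image.pixels[r0:r1, c0:c1])
    processed = stage(crop)
    out = image.pixels.copy()
    out[r0:r1, c0:c1] = processed.pixels
    return image.with_pixels(out)


def _mode_stage(config: EnhanceConfig):
    """The enhancement chain for one frame: stretch, then the mode operator."""

    def stage(img: NIRImage) -> NIRImage:
        img = contrast_enhance(img, config.stretch_percentiles)
        if config.mode in _DOG_SCALES or config.mode.startswith("dog"):
            return difference_of_gaussians(img, config.sigma_narrow, config.sigma_wide)
        if config.mode.startswith("log"):
            return laplacian(img, config.log_sigma)
        return img  # raw-contrast

    return stage


def process_frame(
    image: NIRImage, settings: CameraSettings, config: EnhanceConfig
) -> NIRImage:
    """Full per-frame pipeline: capture settings, then enhancement in the ROI."""
    image = apply_settings(image, settings)
    return apply_roi(image, config.roi, _mode_stage(config))


@dataclass(frozen=True)
class StreamReport:
    """Informational throughput report for a processed frame stream."""

    frame_count: int
    elapsed_seconds: float
    frames_per_second: float


def process_stream(frames, settings: CameraSettings, config: EnhanceConfig):
    """Process a sequence of frames; returns (outputs, StreamReport).

    Stateless per frame; the measured frames/second is informational
    only (it depends on the host, not the algorithm).
    """
    frames = list(frames)
    if not frames:
        raise ValueError("frame stream must contain at least one frame")
    t0 = time.perf_counter()
    out = [
        replace(process_frame(f, settings, config), frame_index=i)
        for i, f in enumerate(frames)
    ]
    elapsed = time.perf_counter() - t0
    fps = len(frames) / elapsed if elapsed > 0 else float("inf")
    return out, StreamReport(len(frames), elapsed, fps)
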