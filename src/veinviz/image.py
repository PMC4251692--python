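"""Single-channel NIR intensity frames and their disk formats.

Every pipeline stage consumes and produces :class:`NIRImage`: a 2-D float
array of intensities in [0, 1] with a physical pixel pitch in mm/pixel.
Sigma values and tolerances elsewhere in the package are specified in mm
and converted through the pitch, so results are resolution-invariant.

On disk, frames are 8- or 16-bit grayscale PNG or TIFF; depth maps are
32-bit float TIFF (mm, ``inf`` where no vessel).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import tifffile
from PIL import Image as PILImage

__all__ = ["NIRImage", "load_image", "save_image", "save_depth_tiff"]


@dataclass(frozen=True)
class NIRImage:
    """A single NIR reflectance frame.

    Parameters
    ----------
    pixels : ndarray
        2-D float array, intensities in [0, 1].
    pixel_pitch : float
        Physical size of one pixel in mm. Physical position of pixel
        (r, c) is (r * pixel_pitch, c * pixel_pitch) mm, origin top-left.
    frame_index : int, optional
        Position in a frame stream, if any.
    """

    pixels: np.ndarray
    pixel_pitch: float = 0.1
    frame_index: int | None = None

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels, dtype=np.float64)
        if px.ndim != 2:
            raise ValueError(f"pixels must be 2-D, got shape {px.shape}")
        if px.shape[0] < 8 or px.shape[1] < 8:
            raise ValueError(f"image must be at least 8x8 pixels, got {px.shape}")
        if not np.all(np.isfinite(px)):
            raise ValueError("pixel intensities must be finite")
        if px.min() < 0.0 or px.max() > 1.0:
            raise ValueError("pixel intensities must lie in [0, 1]")
        if not (np.isfinite(self.pixel_pitch) and self.pixel_pitch > 0):
            raise ValueError(f"pixel_pitch must be positive, got {self.pixel_pitch}")
        object.__setattr__(self, "pixels", px)

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape

    @property
    def field_of_view_mm(self) -> tuple[float, float]:
        """Physical extent (rows_mm, cols_mm) spanned by pixel coordinates."""
        r, c = self.pixels.shape
        return (r * self.pixel_pitch, c * self.pixel_pitch)

    def with_pixels(self, pixels: np.ndarray) -> "NIRImage":
        """Same metadata, new pixel data."""
        return replace(self, pixels=pixels)

    def mm_to_px(self, mm: float) -> float:
        return mm / self.pixel_pitch


def load_image(path: str | Path, pixel_pitch: float = 0.1) -> NIRImage:
    """Read an 8/16-bit grayscale PNG or TIFF as intensities in [0, 1]."""
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        arr = tifffile.imread(path)
    else:
        arr = np.asarray(PILImage.open(path))
    if arr.ndim == 3:  # collapse accidental RGB
        arr = arr[..., 0]
    if arr.dtype == np.uint8:
        px = arr / 255.0
    elif arr.dtype == np.uint16:
        px = arr / 65535.0
    else:
        px = np.clip(arr.astype(np.float64), 0.0, 1.0)
    return NIRImage(px, pixel_pitch=pixel_pitch)


def save_image(image: NIRImage, path: str | Path, bit_depth: int = 16) -> None:
    """Write a frame as grayscale PNG/TIFF at 8 or 16 bits."""
    path = Path(path)
    if bit_depth == 16:
        arr = np.round(image.pixels * 65535.0).astype(np.uint16)
    elif bit_depth == 8:
        arr = np.round(image.pixels * 255.0).astype(np.uint8)
    else:
        raise ValueError(f"bit_depth must be 8 or 16, got {bit_depth}")
    if path.suffix.lower() in (".tif", ".tiff"):
        tifffile.imwrite(path, arr)
    else:
        PILImage.fromarray(arr).save(path)  # uint16 -> I;16, uint8 -> L


def save_depth_tiff(depth_mm: np.ndarray, path: str | Path) -> None:
    """Write a per-pixel depth map (mm, inf = no vessel) as float32 TIFF."""
    tifffile.imwrite(Path(path), depth_mm.astype(np.float32))
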