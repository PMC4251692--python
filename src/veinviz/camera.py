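"""Capture-settings layer: gain, exposure and contrast before enhancement.

Mirrors the external-camera management step of the hardware prototype,
where the sensor settings are optimized before capture to minimise
post-processing artifacts. All three controls act as a pointwise
transform on normalized intensities:

    out = clip01( (in * exposure * gain - 0.5) * contrast + 0.5 )

Exposure is modelled multiplicatively (indistinguishable from gain for
static frames) and contrast pivots about mid-gray 0.5, the standard
linear-contrast convention.

Five named profiles are shipped (Low light, Medium light, Very bright,
LED profile, Custom). The field prototype's values were determined
experimentally on hardware and never published, so the packaged presets
are uncalibrated placeholders, overridable from a JSON config.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from importlib import resources

from numpy import clip

from .image import NIRImage

__all__ = [
    "CameraSettings",
    "CameraProfile",
    "PROFILE_NAMES",
    "apply_settings",
    "profile_settings",
    "load_profiles",
]

PROFILE_NAMES = ("Low light", "Medium light", "Very bright", "LED profile", "Custom")

IDENTITY = None  # set after the dataclass is defined


@dataclass(frozen=True)
class CameraSettings:
    """Multiplicative gain/exposure and linear contrast slope, all > 0."""

    gain: float = 1.0
    exposure: float = 1.0
    contrast: float = 1.0

    def __post_init__(self) -> None:
        for name in ("gain", "exposure", "contrast"):
            v = getattr(self, name)
            if not (math.isfinite(v) and v > 0):
                raise ValueError(f"{name} must be finite and positive, got {v}")


IDENTITY = CameraSettings(1.0, 1.0, 1.0)


@dataclass(frozen=True)
class CameraProfile:
    name: str
    settings: CameraSettings

    def __post_init__(self) -> None:
        if self.name not in PROFILE_NAMES:
            raise ValueError(
                f"unknown profile {self.name!r}; valid names: {', '.join(PROFILE_NAMES)}"
            )


class UnknownProfileError(KeyError):
    pass


def apply_settings(image: NIRImage, settings: CameraSettings) -> NIRImage:
    """Apply gain/exposure/contrast to a frame; dimensions preserved."""
    # algebraically (in*e*g - 0.5)*c + 0.5, factored so identity settings
    # reproduce the input bit-exactly
    slope = settings.exposure * settings.gain * settings.contrast
    offset = 0.5 * (1.0 - settings.contrast)
    return image.with_pixels(clip(image.pixels * slope + offset, 0.0, 1.0))


def load_profiles() -> dict[str, CameraSettings]:
    """Packaged presets for the four fixed profiles (Custom excluded)."""
    raw = json.loads(
        resources.files("veinviz.data").joinpath("camera_profiles.json").read_text()
    )
    return {name: CameraSettings(**vals) for name, vals in raw.items()}


def profile_settings(
    name: str,
    custom: CameraSettings | None = None,
    profiles: dict[str, CameraSettings] | None = None,
) -> CameraSettings:
    """Resolve a profile name (case-insensitive) to its settings.

    ``Custom`` requires explicit ``custom`` settings. ``profiles``
    overrides the packaged presets.
    """
    canonical = {n.lower(): n for n in PROFILE_NAMES}
    key = canonical.get(name.strip().lower())
    if key is None:
        raise UnknownProfileError(
            f"unknown profile {name!r}; valid names: {', '.join(PROFILE_NAMES)}"
        )
    if key == "Custom":
        if custom is None:
            raise ValueError("profile 'Custom' requires explicit CameraSettings")
        return custom
    table = profiles if profiles is not None else load_profiles()
    return table[key]
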