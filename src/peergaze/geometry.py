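"""Screen geometry and pixel/visual-angle conversions.

The recording setup is a fixed-head desktop arrangement: a 1920 x 1080 panel
at 94 pixels per inch viewed from 57 cm, with the 1200 x 750 px scene centred
horizontally and raised 2.65 degrees of visual angle above the screen centre.

Conversions use the *linear* small-angle convention

    deg_per_px = (pixel_pitch_cm / distance_cm) * 180 / pi

rather than the arctangent form.  At desktop distances the two differ by well
under 1%, and the linear form is the one consistent with the screen spans
quoted for this geometry (51.7 degrees for a 51.9 cm wide panel at 57 cm).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

__all__ = [
    "ScreenGeometry",
    "deg_per_px",
    "px_to_deg",
    "deg_to_px",
    "screen_span_deg",
    "scene_rect_px",
    "scene_center_px",
]

_CM_PER_INCH = 2.54


@dataclass(frozen=True)
class ScreenGeometry:
    """Physical display layout of the recording setup.

    Parameters
    ----------
    viewing_distance_cm
        Eye-to-screen distance, cm.
    screen_px
        Display resolution (width, height) in pixels.
    pixels_per_inch
        Pixel density of the panel.
    scene_px
        Size of the photographic scene (width, height) in pixels.
    scene_offset_deg
        Vertical offset of the scene centre *above* the screen centre, in
        degrees of visual angle.
    """

    viewing_distance_cm: float = 57.0
    screen_px: tuple[int, int] = (1920, 1080)
    pixels_per_inch: float = 94.0
    scene_px: tuple[int, int] = (1200, 750)
    scene_offset_deg: float = 2.65

    def __post_init__(self) -> None:
        if self.viewing_distance_cm <= 0:
            raise ValueError("viewing_distance_cm must be positive")
        if self.pixels_per_inch <= 0:
            raise ValueError("pixels_per_inch must be positive")
        if min(self.screen_px) <= 0 or min(self.scene_px) <= 0:
            raise ValueError("screen and scene sizes must be positive")


def deg_per_px(geometry: ScreenGeometry) -> float:
    """Degrees of visual angle subtended by one pixel (linear convention)."""
    px_cm = _CM_PER_INCH / geometry.pixels_per_inch
    return (px_cm / geometry.viewing_distance_cm) * 180.0 / math.pi


def px_to_deg(value_px, geometry: ScreenGeometry):
    """Convert a pixel distance (scalar or array) to degrees."""
    return value_px * deg_per_px(geometry)


def deg_to_px(value_deg, geometry: ScreenGeometry):
    """Convert a visual-angle distance (scalar or array) to pixels."""
    return value_deg / deg_per_px(geometry)


def screen_span_deg(geometry: ScreenGeometry) -> tuple[float, float]:
    """(width, height) of the full display in degrees."""
    k = deg_per_px(geometry)
    return geometry.screen_px[0] * k, geometry.screen_px[1] * k


def scene_rect_px(geometry: ScreenGeometry) -> tuple[float, float, float, float]:
    """Scene placement on screen as (x, y, w, h) in screen pixels.

    The scene is centred horizontally; its centre sits ``scene_offset_deg``
    above the screen centre.
    """
    sw, sh = geometry.screen_px
    w, h = geometry.scene_px
    cy = sh / 2.0 - deg_to_px(geometry.scene_offset_deg, geometry)
    return (sw - w) / 2.0, cy - h / 2.0, float(w), float(h)


def scene_center_px(geometry: ScreenGeometry) -> tuple[float, float]:
    """Centre of the scene in screen pixels (also the fixation-cross position)."""
    x, y, w, h = scene_rect_px(geometry)
    return x + w / 2.0, y + h / 2.0
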