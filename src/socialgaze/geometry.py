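"""Viewing geometry: visual-angle / pixel conversions shared by all stages.

The experiment presents images of fixed physical size on a screen at a fixed
viewing distance, so degrees of visual angle map onto pixels through a single
:class:`ViewingGeometry`. All velocity thresholds (deg/s), smoothing kernels
and analysis windows are specified in degrees and converted here.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

__all__ = [
    "ViewingGeometry",
    "PixelPoint",
    "visual_angle_deg",
    "default_geometry",
]


@dataclass(frozen=True)
class PixelPoint:
    """A (sub-pixel) image position; origin top-left, x rightward, y downward."""

    x: float
    y: float

    def __iter__(self):
        yield self.x
        yield self.y


def visual_angle_deg(extent_cm: float, distance_cm: float) -> float:
    """Visual angle subtended by a physical extent at a viewing distance.

    Uses the exact tangent formula ``2*atan(extent / (2*distance))``.

    Parameters
    ----------
    extent_cm : float
        Physical size of the stimulus, >= 0.
    distance_cm : float
        Eye-to-screen distance, > 0.

    Returns
    -------
    float
        Angle in degrees; zero at zero extent, monotone increasing.
    """
    if distance_cm <= 0:
        raise ValueError(f"viewing distance must be positive, got {distance_cm}")
    if extent_cm < 0:
        raise ValueError(f"extent must be non-negative, got {extent_cm}")
    return math.degrees(2.0 * math.atan2(extent_cm, 2.0 * distance_cm))


@dataclass(frozen=True)
class ViewingGeometry:
    """Screen size, viewing distance and image raster tying degrees to pixels."""

    screen_width_cm: float
    screen_height_cm: float
    viewing_distance_cm: float
    image_width_px: int
    image_height_px: int

    def __post_init__(self):
        for name in ("screen_width_cm", "screen_height_cm", "viewing_distance_cm"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.image_width_px <= 0 or self.image_height_px <= 0:
            raise ValueError("image dimensions must be positive integers")

    @property
    def horizontal_angle_deg(self) -> float:
        return visual_angle_deg(self.screen_width_cm, self.viewing_distance_cm)

    @property
    def vertical_angle_deg(self) -> float:
        return visual_angle_deg(self.screen_height_cm, self.viewing_distance_cm)

    @property
    def px_per_deg_x(self) -> float:
        return self.image_width_px / self.horizontal_angle_deg

    @property
    def px_per_deg_y(self) -> float:
        return self.image_height_px / self.vertical_angle_deg

    def deg_to_px(self, angle_deg: float, axis: str = "x") -> float:
        """Convert an angular extent to pixels by linear scaling.

        The full image extent maps exactly onto the full screen angle; small
        angles scale proportionally (curvature across the screen is ignored,
        standard practice for desktop eye tracking).
        """
        return angle_deg * self._scale(axis)

    def px_to_deg(self, length_px: float, axis: str = "x") -> float:
        """Inverse of :meth:`deg_to_px`."""
        return length_px / self._scale(axis)

    def _scale(self, axis: str) -> float:
        if axis == "x":
            return self.px_per_deg_x
        if axis == "y":
            return self.px_per_deg_y
        raise ValueError(f"axis must be 'x' or 'y', got {axis!r}")

    @property
    def center(self) -> PixelPoint:
        return PixelPoint(self.image_width_px / 2.0, self.image_height_px / 2.0)


def default_geometry() -> ViewingGeometry:
    """Geometry of the reference setup: 30.6 x 23.0 cm at 52.5 cm, 1200 x 900 px.

    This subtends 32.5 x 24.7 degrees of visual angle.
    """
    return ViewingGeometry(
        screen_width_cm=30.6,
        screen_height_cm=23.0,
        viewing_distance_cm=52.5,
        image_width_px=1200,
        image_height_px=900,
    )
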