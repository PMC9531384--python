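"""Core containers and polar geometry shared across the pipeline.

Conventions (fixed for the whole package):

* pixel coordinates are 0-based ``(row, col)``;
* angles are in degrees, measured counterclockwise from the image "up"
  direction (decreasing row), which stands in for the anterior wall;
* T1 values are in milliseconds.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

SliceLevel = str  # "basal" | "mid" | "apical" | "excluded"

_VALID_LEVELS = ("basal", "mid", "apical", "excluded")


@dataclass
class T1Map:
    """A single short-axis native T1 parametric map.

    ``pixels`` holds per-pixel T1 in milliseconds (0 outside the body).
    """

    pixels: np.ndarray
    pixel_spacing: float = 1.4
    slice_index: int = 0
    slice_level: SliceLevel = "mid"

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=float)
        if self.pixels.ndim != 2:
            raise ValueError("T1Map.pixels must be a 2-D array")
        if not np.all(np.isfinite(self.pixels)):
            raise ValueError("T1Map.pixels must be finite")
        if np.any(self.pixels < 0):
            raise ValueError("T1 values must be nonnegative")
        if self.slice_level not in _VALID_LEVELS:
            raise ValueError(f"unknown slice_level {self.slice_level!r}")


@dataclass
class T1Study:
    """An ordered base-to-apex stack of T1 maps for one case."""

    maps: list[T1Map]
    case_id: str = "case"

    @property
    def analysis_maps(self) -> list[T1Map]:
        """The slices tagged for segmental analysis (excluded slices dropped)."""
        return [m for m in self.maps if m.slice_level != "excluded"]

    def validate_middle_six(self) -> None:
        """Check the 2 basal / 2 mid / 2 apical tagging contract."""
        counts = {lvl: 0 for lvl in ("basal", "mid", "apical")}
        for m in self.analysis_maps:
            counts[m.slice_level] += 1
        if counts != {"basal": 2, "mid": 2, "apical": 2}:
            raise ValueError(
                f"study {self.case_id!r}: expected 2 basal / 2 mid / 2 apical "
                f"analysis slices, got {counts}"
            )


@dataclass(frozen=True)
class NormalRange:
    """Institutional normal native T1 range; values above ``upper`` are abnormal."""

    lower: float = 900.0
    upper: float = 1050.0

    def __post_init__(self) -> None:
        if not self.lower < self.upper:
            raise ValueError("NormalRange requires lower < upper")


def polar_grid(shape: tuple[int, int], center: tuple[float, float]):
    """Per-pixel radius (pixels) and angle (degrees CCW from image up)."""
    rows, cols = np.indices(shape)
    dy = center[0] - rows  # positive towards the top of the image
    dx = cols - center[1]
    radius = np.hypot(dx, dy)
    theta = np.degrees(np.arctan2(-dx, dy)) % 360.0
    return radius, theta


def in_angular_window(theta: np.ndarray, center_angle: float, width: float):
    """Boolean membership in the half-open wedge [center-width/2, center+width/2).

    Half-open so that adjacent wedges tile the circle without overlap.
    """
    d = (theta - center_angle + 180.0) % 360.0 - 180.0
    return (d >= -width / 2.0) & (d < width / 2.0)


def angular_distance(theta: np.ndarray, center_angle: float) -> np.ndarray:
    """Absolute angular distance (degrees, in [0, 180]) from ``center_angle``."""
    d = (theta - center_angle + 180.0) % 360.0 - 180.0
    return np.abs(d)


def middle_six_levels(n_slices: int) -> list[str]:
    """Slice-level tags for an n-slice base→apex stack.

    The middle six slices are tagged 2 basal / 2 mid / 2 apical; any extra
    slices at the ends (most basal first) are tagged ``excluded`` to avoid
    through-plane motion artifacts.
    """
    if n_slices < 6:
        raise ValueError("need at least 6 slices")
    n_excl = n_slices - 6
    base_excl = n_excl // 2
    apex_excl = n_excl - base_excl
    return (
        ["excluded"] * base_excl
        + ["basal", "basal", "mid", "mid", "apical", "apical"]
        + ["excluded"] * apex_excl
    )
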