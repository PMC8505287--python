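"""Rectangular observation windows and planar point patterns.

The observation window of a field has its origin fixed at (0, 0); a point
pattern is the set of positive-cell coordinates observed inside it.
Coordinates follow the raster convention used throughout the package:
x = column, y = row, pixel centers at integer positions, origin at the
top-left corner of the field.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass(frozen=True)
class Window:
    """Rectangular observation region with origin at (0, 0).

    Parameters
    ----------
    width, height : float
        Side lengths, in pixels or micrometres (the unit is carried by the
        caller; all statistics are unit-consistent).
    """

    width: float
    height: float

    def __post_init__(self) -> None:
        if not (self.width > 0 and self.height > 0):
            raise ValueError(
                f"window sides must be positive, got {self.width} x {self.height}"
            )

    @property
    def area(self) -> float:
        return self.width * self.height

    @property
    def shorter_side(self) -> float:
        return min(self.width, self.height)

    @property
    def perimeter(self) -> float:
        return 2.0 * (self.width + self.height)

    def contains(self, x, y) -> np.ndarray:
        """Boolean mask of which (x, y) locations fall inside the window."""
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        return (x >= 0) & (x <= self.width) & (y >= 0) & (y <= self.height)


@dataclass(frozen=True)
class PointPattern:
    """Positive-cell coordinates inside a rectangular observation window.

    Invariants enforced at construction: coordinates are finite, x and y
    have equal length, and every point lies inside the window (boundary
    included).
    """

    x: np.ndarray
    y: np.ndarray
    window: Window
    field_id: str = ""
    marker: str = "synthetic"

    def __post_init__(self) -> None:
        x = np.atleast_1d(np.asarray(self.x, dtype=float))
        y = np.atleast_1d(np.asarray(self.y, dtype=float))
        if x.shape != y.shape or x.ndim != 1:
            raise ValueError("x and y must be 1-D arrays of equal length")
        if x.size and not (np.isfinite(x).all() and np.isfinite(y).all()):
            raise ValueError("coordinates must be finite")
        if x.size and not self.window.contains(x, y).all():
            raise ValueError("all points must lie inside the observation window")
        x.setflags(write=False)
        y.setflags(write=False)
        object.__setattr__(self, "x", x)
        object.__setattr__(self, "y", y)

    @property
    def n(self) -> int:
        return int(self.x.size)

    @property
    def coords(self) -> np.ndarray:
        """(n, 2) array of (x, y) pairs."""
        return np.column_stack([self.x, self.y])

    @property
    def intensity(self) -> float:
        """Points per unit window area."""
        return self.n / self.window.area

    def rotated90(self) -> "PointPattern":
        """Pattern-plus-window rotated by 90 degrees (x, y) -> (y, W - x)."""
        return PointPattern(
            x=self.y.copy(),
            y=self.window.width - self.x,
            window=Window(self.window.height, self.window.width),
            field_id=self.field_id,
            marker=self.marker,
        )
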