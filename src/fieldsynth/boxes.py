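"""Axis-aligned integer bounding boxes.

Convention used throughout the package: row-major pixel grids with the origin
at the top-left, 0-based coordinates, and half-open boxes ``[x0, x1) x
[y0, y1)`` so that ``area = (x1 - x0) * (y1 - y0)``. Label exporters convert
to each dialect's own convention at the boundary.
"""

from __future__ import annotations

from typing import NamedTuple


class BBox(NamedTuple):
    """Half-open pixel box: columns ``[x0, x1)``, rows ``[y0, y1)``."""

    x0: int
    y0: int
    x1: int
    y1: int

    @property
    def width(self) -> int:
        return self.x1 - self.x0

    @property
    def height(self) -> int:
        return self.y1 - self.y0

    @property
    def area(self) -> int:
        return self.width * self.height

    def validate(self) -> "BBox":
        if not (0 <= self.x0 < self.x1 and 0 <= self.y0 < self.y1):
            raise ValueError(f"degenerate or negative box: {self}")
        return self

    def shift(self, dx: int, dy: int) -> "BBox":
        return BBox(self.x0 + dx, self.y0 + dy, self.x1 + dx, self.y1 + dy)

    def clip(self, height: int, width: int) -> "BBox":
        return BBox(
            max(self.x0, 0),
            max(self.y0, 0),
            min(self.x1, width),
            min(self.y1, height),
        )

    def contains(self, other: "BBox") -> bool:
        return (
            self.x0 <= other.x0
            and self.y0 <= other.y0
            and other.x1 <= self.x1
            and other.y1 <= self.y1
        )


def intersection_area(a: BBox, b: BBox) -> int:
    """Overlap area of two half-open boxes (0 when disjoint)."""
    w = min(a.x1, b.x1) - max(a.x0, b.x0)
    h = min(a.y1, b.y1) - max(a.y0, b.y0)
    if w <= 0 or h <= 0:
        return 0
    return w * h
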