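"""Axis-aligned rectangles on an abstract planar map.

All simple (non-range-polygon) scenarios live on a flat plane measured in
arbitrary "map units".  Rectangles serve double duty as range supports and
as sampling-area footprints.  Boundary points count as inside (closed
intervals): containment of a point that falls exactly on an edge is a
measure-zero event, and a closed convention keeps results deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

__all__ = ["Rect"]


@dataclass(frozen=True)
class Rect:
    """Axis-aligned rectangle ``[xmin, xmax] x [ymin, ymax]`` in map units."""

    xmin: float
    ymin: float
    xmax: float
    ymax: float

    def __post_init__(self) -> None:
        if not (self.xmax > self.xmin and self.ymax > self.ymin):
            raise ValueError(
                f"degenerate rectangle: need xmax > xmin and ymax > ymin, "
                f"got [{self.xmin}, {self.xmax}] x [{self.ymin}, {self.ymax}]"
            )

    @classmethod
    def centred_square(cls, cx: float, cy: float, side: float) -> "Rect":
        h = side / 2.0
        return cls(cx - h, cy - h, cx + h, cy + h)

    @property
    def width(self) -> float:
        return self.xmax - self.xmin

    @property
    def height(self) -> float:
        return self.ymax - self.ymin

    @property
    def area(self) -> float:
        return self.width * self.height

    @property
    def centroid(self) -> tuple[float, float]:
        return ((self.xmin + self.xmax) / 2.0, (self.ymin + self.ymax) / 2.0)

    @property
    def diameter(self) -> float:
        """Length of the diagonal — the largest pairwise distance the
        rectangle can contain."""
        return float(np.hypot(self.width, self.height))

    def contains(self, xy: np.ndarray) -> np.ndarray:
        """Vectorised closed-interval containment for an (n, 2) array."""
        xy = np.asarray(xy, dtype=float)
        if xy.ndim == 1:
            xy = xy[None, :]
        return (
            (xy[:, 0] >= self.xmin)
            & (xy[:, 0] <= self.xmax)
            & (xy[:, 1] >= self.ymin)
            & (xy[:, 1] <= self.ymax)
        )

    def shifted(self, dx: float, dy: float) -> "Rect":
        return Rect(self.xmin + dx, self.ymin + dy, self.xmax + dx, self.ymax + dy)

    def intersects(self, other: "Rect") -> bool:
        """Open-interior overlap: rectangles that merely share an edge do
        not count as intersecting."""
        return (
            self.xmin < other.xmax
            and other.xmin < self.xmax
            and self.ymin < other.ymax
            and other.ymin < self.ymax
        )


def union_contains(rects: Sequence[Rect], xy: np.ndarray) -> np.ndarray:
    """True for points inside the union of ``rects`` (closed intervals)."""
    xy = np.asarray(xy, dtype=float)
    mask = np.zeros(len(xy), dtype=bool)
    for r in rects:
        mask |= r.contains(xy)
    return mask


def bounding_rect(rects: Iterable[Rect]) -> Rect:
    """Axis-aligned bounding rectangle of a collection of rectangles."""
    rects = list(rects)
    if not rects:
        raise ValueError("bounding_rect of an empty collection")
    return Rect(
        min(r.xmin for r in rects),
        min(r.ymin for r in rects),
        max(r.xmax for r in rects),
        max(r.ymax for r in rects),
    )
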