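"""Shared pixel-coordinate conventions.

Origin is the top-left corner of the slide; ``x`` increases rightward
(columns), ``y`` downward (rows); indices are 0-based. All rectangles are
half-open: the right and bottom edges are *exclusive*, so abutting
rectangles partition the plane with no pixel counted twice.
"""

from __future__ import annotations

from dataclasses import dataclass


@dataclass(frozen=True)
class Bounds:
    """Half-open pixel rectangle [x0, x1) x [y0, y1)."""

    x0: int
    y0: int
    x1: int
    y1: int

    def __post_init__(self) -> None:
        if self.x1 < self.x0 or self.y1 < self.y0:
            raise ValueError(f"inverted bounds: {self}")

    @property
    def width(self) -> int:
        return self.x1 - self.x0

    @property
    def height(self) -> int:
        return self.y1 - self.y0

    @property
    def area(self) -> int:
        return self.width * self.height

    def contains(self, x: float, y: float) -> bool:
        """Half-open containment: left/top edges in, right/bottom out."""
        return self.x0 <= x < self.x1 and self.y0 <= y < self.y1

    def shift(self, dx: int, dy: int) -> "Bounds":
        return Bounds(self.x0 + dx, self.y0 + dy, self.x1 + dx, self.y1 + dy)

    def expand(self, margin: int) -> "Bounds":
        return Bounds(self.x0 - margin, self.y0 - margin,
                      self.x1 + margin, self.y1 + margin)

    def clip(self, width: int, height: int) -> "Bounds":
        """Clip to the extent [0, width) x [0, height)."""
        return Bounds(max(self.x0, 0), max(self.y0, 0),
                      min(self.x1, width), min(self.y1, height))

    def covers(self, other: "Bounds") -> bool:
        return (self.x0 <= other.x0 and self.y0 <= other.y0
                and self.x1 >= other.x1 and self.y1 >= other.y1)

    def as_tuple(self) -> tuple[int, int, int, int]:
        return (self.x0, self.y0, self.x1, self.y1)
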