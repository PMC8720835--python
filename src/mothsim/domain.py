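"""Simulation arena geometry.

The benchmark arena is a 2-D rectangle, 2.0 m along the mean wind (x) by
1.0 m across it (y).  The odor source sits at the midpoint of the upwind
edge and navigators are released at the midpoint of the downwind edge.
"""

from __future__ import annotations

from dataclasses import dataclass


@dataclass(frozen=True)
class Domain:
    """Axis-aligned rectangular flow domain (meters)."""

    x_min: float = 0.0
    x_max: float = 2.0
    y_min: float = 0.0
    y_max: float = 1.0

    def __post_init__(self) -> None:
        if not (self.x_max > self.x_min and self.y_max > self.y_min):
            raise ValueError("domain must have positive extent")

    def contains(self, x: float, y: float) -> bool:
        """Boundary-inclusive membership test."""
        return self.x_min <= x <= self.x_max and self.y_min <= y <= self.y_max


#: Default benchmark arena.
DEFAULT_DOMAIN = Domain()

#: Odor source: midpoint of the upwind (left) edge.
SOURCE_POSITION = (0.0, 0.5)

#: Navigator release point: midpoint of the downwind (right) edge.
START_POSITION = (2.0, 0.5)

#: A trial succeeds when the navigator comes within this distance of the source (m).
SUCCESS_RADIUS = 0.15
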