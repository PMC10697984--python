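"""Geometry of a scoring point in the water phantom."""

from __future__ import annotations

from dataclasses import dataclass


@dataclass(frozen=True)
class GeometryPoint:
    """A scoring location: square field side, water depth, off-axis distance.

    All lengths in cm; ``off_axis`` is the lateral distance from the beam's
    central axis, so the field edge sits at ``field_side / 2``.
    """

    field_side_cm: float
    depth_cm: float
    off_axis_cm: float

    def __post_init__(self) -> None:
        if self.field_side_cm <= 0:
            raise ValueError("field side must be positive")
        if self.depth_cm < 0 or self.off_axis_cm < 0:
            raise ValueError("depth and off-axis distance must be non-negative")

    @property
    def edge_cm(self) -> float:
        return self.field_side_cm / 2.0

    @property
    def beyond_edge_cm(self) -> float:
        """Distance past the field edge (0 inside the field)."""
        return max(0.0, self.off_axis_cm - self.edge_cm)
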