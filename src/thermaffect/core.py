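"""Shared primitive types used across the pipeline.

Coordinate conventions, used everywhere in the package:

* images are row-major 2-D arrays, 0-based indexing;
* pixel rectangles are half-open ``(r0, r1, c0, c1)`` intervals;
* normalized rectangles live in the unit square of the face bounding box,
  ``(x0, y0, x1, y1)`` with x = column fraction, y = row fraction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np

EMOTIONS = ("happy", "disgust", "fear", "surprise", "anger", "sad")


class ThermaffectError(Exception):
    """Base class for all package-specific errors."""


class GeometryError(ThermaffectError):
    """A mask or rectangle falls outside the image or collapses."""


class ValidationError(ThermaffectError):
    """A configuration or layout failed its invariants."""


class Calibration(NamedTuple):
    """Linear gray-level <-> temperature mapping, in degrees Celsius.

    Gray level 0 maps to ``t_min``, the dtype maximum maps to ``t_max``.
    """

    t_min: float
    t_max: float

    def validate(self) -> "Calibration":
        if not self.t_max > self.t_min:
            raise ValidationError(
                f"degenerate calibration: t_max={self.t_max} <= t_min={self.t_min}"
            )
        return self


class Rect(NamedTuple):
    """Axis-aligned rectangle in face-normalized coordinates ([0, 1]^2)."""

    x0: float
    y0: float
    x1: float
    y1: float

    def validate(self) -> "Rect":
        if not (0.0 <= self.x0 < self.x1 <= 1.0 and 0.0 <= self.y0 < self.y1 <= 1.0):
            raise ValidationError(f"invalid normalized rectangle {self}")
        return self

    def to_pixels(self, bbox: tuple[int, int, int, int]) -> tuple[int, int, int, int]:
        """Map onto a pixel bounding box ``(r0, r1, c0, c1)``; half-open output.

        Rounding is half-away-from-zero and monotone, so rectangles sharing a
        normalized edge share the pixel edge exactly (no gap, no overlap).
        """
        r0, r1, c0, c1 = bbox
        h, w = r1 - r0, c1 - c0
        return (
            r0 + _round_half_up(self.y0 * h),
            r0 + _round_half_up(self.y1 * h),
            c0 + _round_half_up(self.x0 * w),
            c0 + _round_half_up(self.x1 * w),
        )


def _round_half_up(v: float) -> int:
    return int(math.floor(v + 0.5))


@dataclass
class ThermogramPair:
    """Registered onset/apex temperature matrices for one subject.

    ``onset`` is the thermal baseline at emotion start; ``apex`` is the frame
    at peak emotion intensity. Both are float64 degree-Celsius matrices of
    identical shape. ``emotion`` is one of :data:`EMOTIONS`.
    """

    onset: np.ndarray
    apex: np.ndarray
    emotion: str
    subject_id: str
    calibration: Calibration
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.onset = np.asarray(self.onset, dtype=np.float64)
        self.apex = np.asarray(self.apex, dtype=np.float64)
        if self.onset.shape != self.apex.shape or self.onset.ndim != 2:
            raise ValidationError(
                f"onset/apex shape mismatch: {self.onset.shape} vs {self.apex.shape}"
            )

    @property
    def shape(self) -> tuple[int, int]:
        return self.onset.shape


def spawn_seed(seed: int, *path: int) -> int:
    """Derive a deterministic child seed (< 2**31) from a master seed."""
    ss = np.random.SeedSequence(entropy=int(seed), spawn_key=tuple(int(p) for p in path))
    return int(ss.generate_state(1, dtype=np.uint32)[0] % (2**31 - 1))
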