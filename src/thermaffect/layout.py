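"""ROI layouts for the three classification models.

Three region schemes are defined on the face bounding box, in normalized
coordinates:

* ``main6`` — six main facial regions: forehead, nose tip, left/right cheek,
  mouth, chin (the eye band is deliberately excluded: eyeglasses are opaque
  in long-wave infrared).
* ``sub27`` — the six main regions tiled into 27 sub-regions R1..R27
  (forehead 3x4 grid = R1-R12, nose tip = R13, each cheek a 3-row strip =
  R14-R16 / R17-R19, mouth 3x2 grid = R20-R25, chin 1x2 = R26-R27).
* ``sel11`` — the 11 sub-regions guaranteed free of eyeglass and facial-hair
  occlusion: R9-R13, R14, R17, R22-R25 (lower forehead row, nose tip, upper
  cheeks, upper and lower lips).

Sub-region numbering is row-major, top-left to bottom-right, within each
parent, parents ordered forehead, nose, left cheek, right cheek, mouth, chin.
The geometry was chosen to keep every region inside a squareness-8
superellipse face silhouette and is fully overridable via a config mapping.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from .core import GeometryError, Rect, ThermogramPair, ValidationError

MODEL_IDS = ("main6", "sub27", "sel11")

MAIN_REGIONS = ("forehead", "nose_tip", "left_cheek", "right_cheek", "mouth", "chin")

#: Default normalized rectangles of the six main regions (x0, y0, x1, y1).
DEFAULT_MAIN6: dict[str, Rect] = {
    "forehead": Rect(0.10, 0.02, 0.90, 0.30),
    "nose_tip": Rect(0.44, 0.44, 0.56, 0.56),
    "left_cheek": Rect(0.10, 0.38, 0.36, 0.72),
    "right_cheek": Rect(0.64, 0.38, 0.90, 0.72),
    "mouth": Rect(0.30, 0.74, 0.70, 0.88),
    "chin": Rect(0.34, 0.90, 0.66, 0.98),
}

#: Eye band, used by the synthetic generator only; not an analysis region.
EYES_RECT = Rect(0.20, 0.31, 0.80, 0.37)

#: (rows, cols) tiling of each main region into sub-regions (total 27).
SUBDIVISION: dict[str, tuple[int, int]] = {
    "forehead": (3, 4),
    "nose_tip": (1, 1),
    "left_cheek": (3, 1),
    "right_cheek": (3, 1),
    "mouth": (3, 2),
    "chin": (1, 2),
}

#: The 11 occlusion-free sub-regions of the third model.
SEL11_LABELS = ("R9", "R10", "R11", "R12", "R13", "R14", "R17", "R22", "R23", "R24", "R25")

EXPECTED_GROUP_SIZES = (12, 1, 3, 3, 6, 2)


@dataclass(frozen=True)
class ROILayout:
    """An ordered, validated set of named normalized rectangles."""

    model_id: str
    regions: tuple[tuple[str, Rect], ...]
    parents: Mapping[str, str] = field(default_factory=dict)

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(name for name, _ in self.regions)

    def __len__(self) -> int:
        return len(self.regions)

    def group_sizes(self) -> tuple[int, ...]:
        """Number of regions per main-region parent, in canonical order."""
        counts = {p: 0 for p in MAIN_REGIONS}
        for name, _ in self.regions:
            counts[self.parents.get(name, name)] += 1
        return tuple(counts[p] for p in MAIN_REGIONS)


@dataclass
class ROIPatch:
    """Apex/onset temperature windows of one region, plus their difference.

    ``difference = apex - onset``: an emotion-induced change is positive when
    the apex frame is warmer.
    """

    name: str
    apex_values: np.ndarray
    onset_values: np.ndarray
    window: tuple[int, int, int, int]

    def __post_init__(self) -> None:
        a, o = np.asarray(self.apex_values), np.asarray(self.onset_values)
        if a.shape != o.shape or a.ndim != 2:
            raise ValidationError(f"patch {self.name}: shape mismatch {a.shape} vs {o.shape}")
        if a.size < 4 or min(a.shape) < 2:
            raise GeometryError(f"patch {self.name}: window {a.shape} below 2x2 pixels")
        self.apex_values = a.astype(np.float64)
        self.onset_values = o.astype(np.float64)

    @property
    def difference(self) -> np.ndarray:
        return self.apex_values - self.onset_values


def _grid_edges(lo: float, hi: float, n: int) -> list[float]:
    step = (hi - lo) / n
    return [lo + k * step for k in range(n)] + [hi]


def subdivide(main_rects: Mapping[str, Rect]) -> dict[str, tuple[Rect, str]]:
    """Tile the main regions into the 27 numbered sub-regions.

    Returns ``label -> (rect, parent name)``, labels R1..R27 in canonical
    order. Shared grid edges are computed once per parent, so sibling
    rectangles tile the parent exactly.
    """
    out: dict[str, tuple[Rect, str]] = {}
    idx = 1
    for parent in MAIN_REGIONS:
        rect = main_rects[parent]
        rows, cols = SUBDIVISION[parent]
        xs = _grid_edges(rect.x0, rect.x1, cols)
        ys = _grid_edges(rect.y0, rect.y1, rows)
        for r in range(rows):
            for c in range(cols):
                out[f"R{idx}"] = (Rect(xs[c], ys[r], xs[c + 1], ys[r + 1]), parent)
                idx += 1
    return out


def build_layout(
    model_id: str, layout_config: Mapping[str, Rect] | None = None
) -> ROILayout:
    """Build one of the three ROI schemes.

    Parameters
    ----------
    model_id
        ``"main6"``, ``"sub27"`` or ``"sel11"``.
    layout_config
        Optional override of the main-region rectangles (name -> Rect or
        4-tuple). The sub-region tiling counts are fixed by the scheme.
    """
    if model_id not in MODEL_IDS:
        raise ValidationError(f"unknown layout model {model_id!r}; expected one of {MODEL_IDS}")
    main = dict(DEFAULT_MAIN6)
    if layout_config:
        for name, rect in layout_config.items():
            if name not in MAIN_REGIONS:
                raise ValidationError(f"unknown main region {name!r}")
            main[name] = Rect(*rect).validate()
    for name, rect in main.items():
        rect.validate()
    _check_main_disjoint(main)

    if model_id == "main6":
        regions = tuple((name, main[name]) for name in MAIN_REGIONS)
        return ROILayout("main6", regions, {})

    subs = subdivide(main)
    if len(subs) != 27:
        raise ValidationError(f"sub-region tiling produced {len(subs)} regions, expected 27")
    parents = {label: parent for label, (_, parent) in subs.items()}
    if model_id == "sub27":
        regions = tuple((label, subs[label][0]) for label in subs)
        layout = ROILayout("sub27", regions, parents)
    else:
        regions = tuple((label, subs[label][0]) for label in SEL11_LABELS)
        layout = ROILayout("sel11", regions, {k: parents[k] for k in SEL11_LABELS})
    return layout


def _check_main_disjoint(main: Mapping[str, Rect]) -> None:
    names = list(main)
    for i, a in enumerate(names):
        for b in names[i + 1 :]:
            ra, rb = main[a], main[b]
            if ra.x0 < rb.x1 and rb.x0 < ra.x1 and ra.y0 < rb.y1 and rb.y0 < ra.y1:
                raise ValidationError(f"main regions {a} and {b} overlap")


def crop_rois(
    pair: ThermogramPair,
    face_bbox: tuple[int, int, int, int],
    layout: ROILayout,
) -> list[ROIPatch]:
    """Cut identical pixel windows from apex and onset for every region.

    The normalized rectangles are mapped onto the face bounding box detected
    on the apex frame; the very same windows are applied to the registered
    onset frame, mirroring the manual same-coordinates protocol.
    """
    r0, r1, c0, c1 = face_bbox
    h, w = pair.shape
    if not (0 <= r0 < r1 <= h and 0 <= c0 < c1 <= w):
        raise GeometryError(f"face bbox {face_bbox} outside image of shape {pair.shape}")
    patches = []
    for name, rect in layout.regions:
        pr0, pr1, pc0, pc1 = rect.to_pixels(face_bbox)
        if pr1 - pr0 < 2 or pc1 - pc0 < 2:
            raise GeometryError(
                f"region {name} collapses to {(pr1 - pr0, pc1 - pc0)} px on bbox {face_bbox}"
            )
        patches.append(
            ROIPatch(
                name=name,
                apex_values=pair.apex[pr0:pr1, pc0:pc1],
                onset_values=pair.onset[pr0:pr1, pc0:pc1],
                window=(pr0, pr1, pc0, pc1),
            )
        )
    return patches


def layout_to_config(layout: ROILayout) -> dict[str, list[float]]:
    """Serializable form of a layout (for YAML round-trips)."""
    return {name: list(rect) for name, rect in layout.regions}
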