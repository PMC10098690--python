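"""Preprocessing: gray/temperature calibration, face extraction, registration.

Face extraction follows the classical thermal-face recipe: median filter,
Gaussian smoothing, Otsu binarization, then the largest connected component
(a warm face on a cool background has strongly bimodal intensities, so Otsu
separates it cleanly and the step is invariant to adding a constant to all
temperatures).

Onset-to-apex registration is intensity-based: a 4-parameter similarity
transform (rotation, uniform scale, 2-D shift) is estimated by least squares
on smoothed images, initialized from the face masks' centroids and areas and
refined with Powell's method on a half-resolution level followed by a
full-resolution polish. No landmarks are available in thermal imagery, which
is why an intensity metric is used.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import ndimage as ndi
from scipy import optimize
from skimage import measure
from skimage import transform as sktransform
from skimage.filters import threshold_otsu

from .core import Calibration, ThermaffectError, ValidationError


class SegmentationError(ThermaffectError):
    """Face segmentation found no foreground component."""


class RegistrationError(ThermaffectError):
    """Registration failed to converge below the residual threshold."""

    def __init__(self, message: str, residual: float):
        super().__init__(message)
        self.residual = residual


@dataclass
class TemperatureImage:
    """A 2-D matrix of temperatures (degrees C) plus its calibration."""

    matrix: np.ndarray
    calibration: Calibration
    source: str | None = None

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=np.float64)
        if self.matrix.ndim != 2 or self.matrix.size == 0:
            raise ValidationError("temperature image must be a non-empty 2-D matrix")
        self.calibration = Calibration(*self.calibration).validate()


@dataclass
class FaceRegion:
    """Binary face mask and its tight half-open bounding box."""

    mask: np.ndarray
    bbox: tuple[int, int, int, int]

    @property
    def area(self) -> int:
        return int(self.mask.sum())

    @property
    def centroid(self) -> tuple[float, float]:
        rr, cc = np.nonzero(self.mask)
        return float(rr.mean()), float(cc.mean())


def _gray_max(gray: np.ndarray) -> int:
    if gray.dtype == np.uint8:
        return 255
    if gray.dtype == np.uint16:
        return 65535
    raise ValidationError(f"expected 8- or 16-bit grayscale input, got dtype {gray.dtype}")


def gray_to_temperature(
    gray: np.ndarray, calibration: Calibration | tuple[float, float], source: str | None = None
) -> TemperatureImage:
    """Linear radiometric conversion: T = T_min + g / g_max * (T_max - T_min).

    Gray level 0 maps to ``T_min`` and the dtype maximum to ``T_max``; the
    mapping is strictly monotone and exactly invertible at grid points.
    """
    gray = np.asarray(gray)
    cal = Calibration(*calibration).validate()
    gmax = _gray_max(gray)
    t = cal.t_min + gray.astype(np.float64) / gmax * (cal.t_max - cal.t_min)
    return TemperatureImage(t, cal, source)


def temperature_to_gray(
    matrix: np.ndarray, calibration: Calibration | tuple[float, float], bits: int = 8
) -> np.ndarray:
    """Inverse of :func:`gray_to_temperature`; rounds to the nearest level."""
    cal = Calibration(*calibration).validate()
    if bits not in (8, 16):
        raise ValidationError("bits must be 8 or 16")
    gmax = 255 if bits == 8 else 65535
    g = (np.asarray(matrix, dtype=np.float64) - cal.t_min) / (cal.t_max - cal.t_min) * gmax
    g = np.clip(np.rint(g), 0, gmax)
    return g.astype(np.uint8 if bits == 8 else np.uint16)


def extract_face(
    image: TemperatureImage | np.ndarray,
    median_size: int = 5,
    gaussian_sigma: float = 2.0,
) -> FaceRegion:
    """Segment the face: median -> Gaussian -> Otsu -> largest component."""
    matrix = image.matrix if isinstance(image, TemperatureImage) else np.asarray(image, float)
    if min(matrix.shape) <= median_size:
        raise ValidationError(
            f"image {matrix.shape} not larger than the {median_size}x{median_size} median kernel"
        )
    filtered = ndi.median_filter(matrix, size=median_size)
    smoothed = ndi.gaussian_filter(filtered, sigma=gaussian_sigma)
    if float(smoothed.max() - smoothed.min()) < 1e-6:
        raise SegmentationError("uniform image: no foreground/background contrast")
    thr = threshold_otsu(smoothed)
    binary = smoothed > thr
    labels, n = measure.label(binary, return_num=True)
    if n == 0:
        raise SegmentationError("no foreground component found")
    sizes = np.bincount(labels.ravel())
    sizes[0] = 0
    biggest = int(sizes.argmax())
    mask = labels == biggest
    rows = np.flatnonzero(mask.any(axis=1))
    cols = np.flatnonzero(mask.any(axis=0))
    bbox = (int(rows[0]), int(rows[-1]) + 1, int(cols[0]), int(cols[-1]) + 1)
    return FaceRegion(mask=mask, bbox=bbox)


@dataclass(frozen=True)
class SimilarityTransform:
    """Rotation + uniform scale + translation about an anchor point.

    Forward map (xy = column/row order): ``p' = s R(theta) (p - c) + c + t``
    with ``c`` the anchor (defaults to the image center at apply time) and
    ``t = translation`` in pixels. Rotation is in degrees, counterclockwise
    in xy coordinates.
    """

    rotation: float = 0.0
    scale: float = 1.0
    translation: tuple[float, float] = (0.0, 0.0)
    center: tuple[float, float] | None = None  # (cx, cy); image center if None

    def __post_init__(self) -> None:
        if not self.scale > 0:
            raise ValidationError("similarity scale must be positive")

    def _anchored(self, shape: tuple[int, int]) -> tuple[float, float]:
        if self.center is not None:
            return self.center
        return ((shape[1] - 1) / 2.0, (shape[0] - 1) / 2.0)

    def to_skimage(self, shape: tuple[int, int]) -> sktransform.SimilarityTransform:
        cx, cy = self._anchored(shape)
        to_origin = sktransform.SimilarityTransform(translation=(-cx, -cy))
        rot = sktransform.SimilarityTransform(
            rotation=math.radians(self.rotation), scale=self.scale
        )
        back = sktransform.SimilarityTransform(
            translation=(cx + self.translation[0], cy + self.translation[1])
        )
        return to_origin + rot + back

    def apply(self, image: np.ndarray, fill: float = 0.0, order: int = 1) -> np.ndarray:
        """Resample ``image`` under the forward map (bilinear by default)."""
        tform = self.to_skimage(image.shape)
        return sktransform.warp(
            image.astype(np.float64),
            inverse_map=tform.inverse,
            order=order,
            cval=fill,
            preserve_range=True,
            mode="constant",
        )

    def inverse(self, shape: tuple[int, int]) -> "SimilarityTransform":
        """The inverse similarity, anchored at the same point."""
        cx, cy = self._anchored(shape)
        th = math.radians(-self.rotation)
        s = 1.0 / self.scale
        tx, ty = self.translation
        # p = s' R(-theta) (p' - c - t) + c  ->  t' = -s' R(-theta) t
        nx = -s * (math.cos(th) * tx - math.sin(th) * ty)
        ny = -s * (math.sin(th) * tx + math.cos(th) * ty)
        return SimilarityTransform(
            rotation=-self.rotation, scale=s, translation=(nx, ny), center=(cx, cy)
        )

    @property
    def params(self) -> tuple[float, float, float, float]:
        return (self.rotation, self.scale, self.translation[0], self.translation[1])


def _background_level(matrix: np.ndarray, mask: np.ndarray) -> float:
    bg = matrix[~mask]
    return float(np.median(bg)) if bg.size else float(matrix.min())


def register_pair(
    onset: TemperatureImage | np.ndarray,
    apex: TemperatureImage | np.ndarray,
    smooth_sigma: float = 1.5,
    residual_threshold: float = 0.5,
    refine_full_res: bool = True,
) -> tuple[np.ndarray, SimilarityTransform, float]:
    """Align the onset frame to the apex frame under a similarity transform.

    Returns ``(onset resampled into apex coordinates, estimated transform,
    residual)``. The residual is the median absolute temperature difference
    over the apex face mask — a robust statistic, insensitive to the thin
    set of pixels along sharp internal edges (eyeglass rims, hair lines)
    where bilinear interpolation of a 5-10 degC step is inherently large
    even for a perfect alignment. The estimate is anchored at the image
    center, so its parameters are directly comparable with a motion
    specification expressed the same way.

    Raises
    ------
    RegistrationError
        If the residual (degrees C) exceeds ``residual_threshold``.
    """
    on = onset.matrix if isinstance(onset, TemperatureImage) else np.asarray(onset, float)
    ap = apex.matrix if isinstance(apex, TemperatureImage) else np.asarray(apex, float)
    if on.shape != ap.shape:
        raise ValidationError("onset and apex must share shape for registration")

    face_on = extract_face(on)
    face_ap = extract_face(ap)
    fill = _background_level(on, face_on.mask)

    # Initialization from the segmented masks: translation = centroid shift,
    # scale = sqrt of the area ratio, rotation = 0.
    cy0, cx0 = face_on.centroid
    cy1, cx1 = face_ap.centroid
    s0 = math.sqrt(face_ap.area / face_on.area)
    cx, cy = (on.shape[1] - 1) / 2.0, (on.shape[0] - 1) / 2.0
    # with p' = s(p - c) + c + t and centroids matching: t = c1 - c - s(c0 - c)
    tx0 = cx1 - cx - s0 * (cx0 - cx)
    ty0 = cy1 - cy - s0 * (cy0 - cy)

    sm_on = ndi.gaussian_filter(on, smooth_sigma)
    sm_ap = ndi.gaussian_filter(ap, smooth_sigma)
    weight = ndi.binary_dilation(face_ap.mask, iterations=3)

    def objective_factory(ref: np.ndarray, mov: np.ndarray, w: np.ndarray, factor: float):
        wi = np.where(w)

        def objective(p: np.ndarray) -> float:
            rot, log_s, tx, ty = p
            tf = SimilarityTransform(
                rotation=rot,
                scale=math.exp(log_s),
                translation=(tx, ty),
                center=((mov.shape[1] - 1) / 2.0, (mov.shape[0] - 1) / 2.0),
            )
            warped = tf.apply(mov, fill=fill)
            d = warped[wi] - ref[wi]
            return float(np.mean(d * d))

        return objective

    # Plausible head-motion range between onset and apex frames; keeps the
    # optimizer away from the degenerate no-overlap plateau.
    bounds = [(-15.0, 15.0), (math.log(0.85), math.log(1.18)), (-25.0, 25.0), (-25.0, 25.0)]
    s0 = min(max(s0, 0.9), 1.1)
    x0 = np.array([0.0, math.log(s0), float(np.clip(tx0, -20, 20)), float(np.clip(ty0, -20, 20))])

    # Half-resolution main optimization.
    half_on = sm_on[::2, ::2]
    half_ap = sm_ap[::2, ::2]
    half_w = weight[::2, ::2]
    obj_half = objective_factory(half_ap, half_on, half_w, 0.5)
    x_half = x0.copy()
    x_half[2:] /= 2.0
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = optimize.minimize(
            obj_half,
            x_half,
            method="Powell",
            bounds=[(b[0], b[1]) if i < 2 else (b[0] / 2, b[1] / 2) for i, b in enumerate(bounds)],
            options={"xtol": 1e-3, "ftol": 1e-6, "maxiter": 40},
        )
    x = res.x.copy()
    x[2:] *= 2.0

    if refine_full_res:
        obj_full = objective_factory(sm_ap, sm_on, weight, 1.0)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = optimize.minimize(
                obj_full,
                x,
                method="Powell",
                bounds=bounds,
                options={"xtol": 1e-4, "ftol": 1e-8, "maxiter": 10},
            )
        x = res.x

    tform = SimilarityTransform(
        rotation=float(x[0]),
        scale=float(math.exp(x[1])),
        translation=(float(x[2]), float(x[3])),
        center=(cx, cy),
    )
    registered = tform.apply(on, fill=fill)
    diff = (registered - ap)[face_ap.mask]
    residual = float(np.median(np.abs(diff)))
    if residual > residual_threshold:
        raise RegistrationError(
            f"registration residual {residual:.3f} degC above threshold "
            f"{residual_threshold:.3f}",
            residual=residual,
        )
    return registered, tform, residual
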