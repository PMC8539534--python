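"""Marker-based affine co-registration of HS, RGB and IR images.

The registration target frame is the step-1 hyperspectral reference image:
IR maps (and annotations) are warped *into* that frame.  Coordinates are
0-based ``(x=column, y=row)``, pixel-center.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .io import MarkerSet


@dataclass
class AffineTransform2D:
    """A 2x3 affine ``[x', y']^T = A @ [x, y, 1]^T`` (source -> destination)."""

    matrix: np.ndarray
    residual_rms: float = 0.0

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=np.float64).reshape(2, 3)
        if not np.all(np.isfinite(self.matrix)):
            raise ValueError("affine coefficients must be finite")

    @classmethod
    def identity(cls) -> "AffineTransform2D":
        return cls(np.array([[1.0, 0.0, 0.0], [0.0, 1.0, 0.0]]))

    @property
    def linear(self) -> np.ndarray:
        return self.matrix[:, :2]

    @property
    def translation(self) -> np.ndarray:
        return self.matrix[:, 2]

    def apply(self, points: np.ndarray) -> np.ndarray:
        pts = np.asarray(points, dtype=np.float64).reshape(-1, 2)
        return pts @ self.linear.T + self.translation

    def compose(self, other: "AffineTransform2D") -> "AffineTransform2D":
        """Return the transform equivalent to applying *self* then *other*."""
        lin = other.linear @ self.linear
        trans = other.linear @ self.translation + other.translation
        return AffineTransform2D(np.column_stack([lin, trans]))

    def inverse(self) -> "AffineTransform2D":
        det = np.linalg.det(self.linear)
        if abs(det) < 1e-12:
            raise ValueError("transform is not invertible (singular linear part)")
        inv_lin = np.linalg.inv(self.linear)
        return AffineTransform2D(
            np.column_stack([inv_lin, -inv_lin @ self.translation])
        )


def fit_affine(src: MarkerSet | np.ndarray, dst: MarkerSet | np.ndarray) -> AffineTransform2D:
    """Least-squares affine from corresponding fiducial markers.

    Minimises ``sum_k || A [src_k; 1] - dst_k ||^2`` over the six coefficients
    of ``A``; correspondence is by point order.  Requires >= 3 non-collinear
    correspondences.  The RMS point residual is stored on the result.
    """
    s = src.points if isinstance(src, MarkerSet) else np.asarray(src, float).reshape(-1, 2)
    d = dst.points if isinstance(dst, MarkerSet) else np.asarray(dst, float).reshape(-1, 2)
    if len(s) != len(d):
        raise ValueError(f"marker counts differ: {len(s)} vs {len(d)}")
    if len(s) < 3:
        raise ValueError("affine fitting needs at least 3 correspondences")
    design = np.column_stack([s, np.ones(len(s))])
    if np.linalg.matrix_rank(design) < 3:
        raise ValueError("degenerate marker configuration (collinear points)")
    # Two independent 3-parameter linear systems (x and y rows of A).
    coef, *_ = np.linalg.lstsq(design, d, rcond=None)
    matrix = coef.T  # (2, 3)
    resid = design @ coef - d
    rms = float(np.sqrt(np.mean(np.sum(resid**2, axis=1))))
    return AffineTransform2D(matrix, residual_rms=rms)


def warp_image(
    img: np.ndarray,
    transform: AffineTransform2D,
    out_shape: tuple[int, int] | None = None,
    interpolation: str = "bilinear",
    fill: float = np.nan,
) -> tuple[np.ndarray, np.ndarray]:
    """Warp *img* (source frame) into the destination frame of *transform*.

    The destination grid is sampled via the inverse mapping.  Returns
    ``(warped, coverage)`` where ``coverage`` is True wherever the inverse-
    mapped coordinate falls inside the source image; outside pixels hold
    *fill*.  Use nearest-neighbour interpolation for label/mask images to
    preserve discreteness.
    """
    order = {"nearest": 0, "bilinear": 1}.get(interpolation)
    if order is None:
        raise ValueError(f"unknown interpolation {interpolation!r}")
    if out_shape is None:
        out_shape = img.shape[:2]
    inv = transform.inverse()
    yy, xx = np.mgrid[0 : out_shape[0], 0 : out_shape[1]]
    src = inv.apply(np.column_stack([xx.ravel(), yy.ravel()]))
    sx = src[:, 0].reshape(out_shape)
    sy = src[:, 1].reshape(out_shape)
    h, w = img.shape[:2]
    eps = 1e-9
    coverage = (sx >= -eps) & (sx <= w - 1 + eps) & (sy >= -eps) & (sy <= h - 1 + eps)
    warped = ndimage.map_coordinates(
        np.asarray(img, dtype=np.float64), [sy, sx], order=order, mode="constant",
        cval=np.nan if order == 1 else 0.0,
    )
    warped = np.where(coverage, warped, fill)
    if img.dtype.kind in "iub" and order == 0:
        out = np.full(out_shape, fill, dtype=np.float64)
        out[coverage] = warped[coverage]
        if np.isfinite(fill):
            warped = out.astype(img.dtype)
    return warped, coverage


@dataclass
class ROI:
    """Circular region of interest centred on the ablation spot."""

    center: tuple[float, float]  # (x, y) in reference-image coordinates
    diameter: float

    def __post_init__(self) -> None:
        if self.diameter <= 0:
            raise ValueError("ROI diameter must be positive")

    def mask(self, shape: tuple[int, int]) -> np.ndarray:
        """Boolean disk mask on a (height, width) grid."""
        yy, xx = np.mgrid[0 : shape[0], 0 : shape[1]]
        cx, cy = self.center
        return (xx - cx) ** 2 + (yy - cy) ** 2 <= (self.diameter / 2.0) ** 2


def propagate_roi(
    roi: ROI, transform: AffineTransform2D, out_shape: tuple[int, int]
) -> np.ndarray:
    """Transform the ROI disk into another image frame as a boolean mask.

    A destination pixel belongs to the propagated ROI iff its inverse-mapped
    coordinate lies inside the source disk — exact for circular ROIs, no
    rasterisation error.  Emits a warning when part of the transformed ROI
    falls outside *out_shape*.
    """
    cx, cy = roi.center
    r = roi.diameter / 2.0
    inv = transform.inverse()
    yy, xx = np.mgrid[0 : out_shape[0], 0 : out_shape[1]]
    src = inv.apply(np.column_stack([xx.ravel(), yy.ravel()]))
    mask = (
        (src[:, 0] - cx) ** 2 + (src[:, 1] - cy) ** 2 <= r**2
    ).reshape(out_shape)
    # Truncation check: compare against the analytic area of the mapped disk
    # (5% slack absorbs rasterisation error at the disk boundary).
    det = abs(np.linalg.det(transform.linear))
    expected = np.pi * r**2 * det
    if mask.sum() < 0.95 * expected:
        warnings.warn(
            "ROI maps partially outside the destination image; mask truncated",
            stacklevel=2,
        )
    return mask


def detect_marker_centroids(
    image: np.ndarray, n_markers: int, threshold: float | None = None
) -> MarkerSet:
    """Blob-centroid detector for synthetic scenes.

    Thresholds *image*, labels connected components and returns the *n_markers*
    largest components' centroids ordered by scan position (top-left first).
    Intended for synthetic marker disks only; real markers are annotated
    manually.
    """
    img = np.asarray(image, dtype=np.float64)
    if threshold is None:
        threshold = 0.5 * (img.min() + img.max())
    labels, n = ndimage.label(img > threshold)
    if n < n_markers:
        raise ValueError(f"found only {n} blobs, need {n_markers}")
    sizes = ndimage.sum_labels(np.ones_like(img), labels, index=np.arange(1, n + 1))
    keep = np.argsort(sizes)[::-1][:n_markers] + 1
    cents = ndimage.center_of_mass(img, labels, index=keep)  # (y, x)
    pts = np.array([[c[1], c[0]] for c in cents])
    order = np.lexsort((pts[:, 0], pts[:, 1]))
    return MarkerSet(pts[order], image_ref="detected")
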