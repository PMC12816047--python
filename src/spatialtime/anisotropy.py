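"""Collagen-fiber alignment from grayscale images via an averaged nematic tensor.

For each pixel with usable intensity gradient, the local fiber direction is
taken as the unit tangent perpendicular to the gradient; its outer product
t t^T is averaged (unweighted) over the ROI to give a symmetric 2x2 tensor
with unit trace. The anisotropy score AU is the eigenvalue difference
lambda1 - lambda2 (0 = isotropic, 1 = perfectly aligned) and the mean fiber
orientation is the leading eigenvector's angle, reported in (-90, 90] with
0 deg along +x and angles increasing toward +y (nematic symmetry). This is
the construction behind FibrilTool-style anisotropy readouts; a
Hessian-based variant (principal directions of the second-derivative
matrix) is available for comparison via ``method="hessian"``.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .exceptions import (
    ConfigurationError,
    InsufficientSignalError,
    ValidationError,
)

__all__ = [
    "Roi",
    "AnisotropyResult",
    "roi_nematic_tensor",
    "anisotropy_from_tensor",
    "image_anisotropy",
]

logger = logging.getLogger(__name__)

GRADIENT_EPS_REL = 1e-6  # of the image intensity range
MIN_USABLE_PIXELS = 32
MAX_ROIS = 8


@dataclass(frozen=True)
class Roi:
    """Axis-aligned rectangular region of interest (pixel units)."""

    roi_id: str
    x0: int
    y0: int
    width: int
    height: int

    def slices(self) -> tuple[slice, slice]:
        return (
            slice(self.y0, self.y0 + self.height),
            slice(self.x0, self.x0 + self.width),
        )


@dataclass
class AnisotropyResult:
    """Per-ROI anisotropy score and mean fibril orientation."""

    roi_id: str
    au: float
    orientation_deg: float  # NaN when the tensor is isotropic
    n_pixels_used: int
    tensor: np.ndarray | None = None


def _validate_image(image: np.ndarray) -> np.ndarray:
    img = np.asarray(image, dtype=float)
    if img.ndim != 2:
        raise ValidationError(f"fibril image must be 2-D, got shape {img.shape}")
    if img.shape[0] < 3 or img.shape[1] < 3:
        raise ValidationError("fibril image must be at least 3x3 pixels")
    return img


def _tangent_field_gradient(sub: np.ndarray, eps: float):
    """Per-pixel unit tangents (perpendicular to the smoothed gradient)."""
    sm = ndimage.uniform_filter(sub, size=3, mode="nearest")
    gy, gx = np.gradient(sm)
    mag = np.hypot(gx, gy)
    usable = mag > eps
    tx = np.where(usable, gy, 0.0) / np.where(usable, mag, 1.0)
    ty = np.where(usable, -gx, 0.0) / np.where(usable, mag, 1.0)
    return tx, ty, usable


def _tangent_field_hessian(sub: np.ndarray, eps: float):
    """Fiber direction as the ridge axis of the per-pixel Hessian."""
    sm = ndimage.gaussian_filter(sub, sigma=1.0, mode="nearest")
    gy, gx = np.gradient(sm)
    hyy, hyx = np.gradient(gy)
    hxy, hxx = np.gradient(gx)
    hb = 0.5 * (hxy + hyx)
    # Principal axis of [[hxx, hb], [hb, hyy]]; the ridge (fiber) direction
    # is the eigenvector of the smaller-|eigenvalue| eigenvalue.
    disc = np.sqrt(((hxx - hyy) / 2) ** 2 + hb**2)
    usable = disc > eps
    theta_major = 0.5 * np.arctan2(2 * hb, hxx - hyy)
    mean_l = (hxx + hyy) / 2
    l1 = mean_l + disc
    l2 = mean_l - disc
    major_is_ridge = np.abs(l1) < np.abs(l2)
    theta = np.where(major_is_ridge, theta_major, theta_major + np.pi / 2)
    return np.cos(theta), np.sin(theta), usable


def roi_nematic_tensor(
    image: np.ndarray,
    roi: Roi,
    method: str = "gradient",
    min_pixels: int = MIN_USABLE_PIXELS,
) -> tuple[np.ndarray, int]:
    """Average nematic tensor of fiber tangents within one ROI.

    Returns the symmetric trace-1 tensor and the number of pixels used.
    Raises :class:`InsufficientSignalError` when fewer than ``min_pixels``
    pixels carry gradient above the epsilon threshold.
    """
    img = _validate_image(image)
    ny, nx = img.shape
    if (
        roi.width <= 0
        or roi.height <= 0
        or roi.x0 < 0
        or roi.y0 < 0
        or roi.x0 + roi.width > nx
        or roi.y0 + roi.height > ny
    ):
        raise ValidationError(f"ROI {roi.roi_id!r} is not inside the image")
    # Evaluate derivatives with a small context margin around the ROI so
    # the finite-difference stencils never see the crop boundary; pixels
    # whose context runs off the image are excluded from the average.
    margin = 3
    y0m, x0m = max(0, roi.y0 - margin), max(0, roi.x0 - margin)
    y1m = min(ny, roi.y0 + roi.height + margin)
    x1m = min(nx, roi.x0 + roi.width + margin)
    sub = img[y0m:y1m, x0m:x1m]
    rng = float(img.max() - img.min())
    eps = GRADIENT_EPS_REL * rng if rng > 0 else np.inf
    if method == "gradient":
        tx, ty, usable = _tangent_field_gradient(sub, eps)
    elif method == "hessian":
        tx, ty, usable = _tangent_field_hessian(sub, eps)
    else:
        raise ConfigurationError(f"unknown anisotropy method {method!r}")
    # crop back to the ROI proper
    ys = slice(roi.y0 - y0m, roi.y0 - y0m + roi.height)
    xs = slice(roi.x0 - x0m, roi.x0 - x0m + roi.width)
    tx, ty, usable = tx[ys, xs], ty[ys, xs], usable[ys, xs].copy()
    # drop pixels too close to the image border for a clean stencil
    if roi.y0 < margin:
        usable[: margin - roi.y0, :] = False
    if roi.x0 < margin:
        usable[:, : margin - roi.x0] = False
    if roi.y0 + roi.height > ny - margin:
        usable[ny - margin - roi.y0 - roi.height :, :] = False
    if roi.x0 + roi.width > nx - margin:
        usable[:, nx - margin - roi.x0 - roi.width :] = False
    n_used = int(usable.sum())
    if n_used < min_pixels:
        raise InsufficientSignalError(
            f"ROI {roi.roi_id!r}: only {n_used} pixels with usable gradient "
            f"(need >= {min_pixels})"
        )
    txx = float((tx[usable] ** 2).mean())
    tyy = float((ty[usable] ** 2).mean())
    txy = float((tx[usable] * ty[usable]).mean())
    return np.array([[txx, txy], [txy, tyy]]), n_used


def anisotropy_from_tensor(
    tensor: np.ndarray, roi_id: str = "", n_pixels_used: int = 0
) -> AnisotropyResult:
    """Anisotropy score and orientation from a trace-1 nematic tensor.

    ``au = lambda1 - lambda2`` (eigenvalues sorted descending); orientation
    is the leading eigenvector's angle in (-90, 90]. An isotropic tensor
    (au ~ 0) has undefined orientation, reported as NaN.
    """
    t = np.asarray(tensor, dtype=float)
    if t.shape != (2, 2):
        raise ValidationError(f"tensor must be 2x2, got {t.shape}")
    if not np.allclose(t, t.T, atol=1e-9):
        raise ValidationError("tensor is not symmetric")
    evals, evecs = np.linalg.eigh(t)  # ascending
    au = float(evals[1] - evals[0])
    if au < 1e-12:
        orientation = float("nan")
    else:
        vx, vy = evecs[:, 1]
        ang = np.degrees(np.arctan2(vy, vx)) % 180.0
        if ang > 90.0:
            ang -= 180.0
        orientation = float(ang)
    return AnisotropyResult(
        roi_id=roi_id, au=au, orientation_deg=orientation,
        n_pixels_used=n_pixels_used, tensor=t,
    )


def _rois_overlap(a: Roi, b: Roi) -> bool:
    return (
        a.x0 < b.x0 + b.width
        and b.x0 < a.x0 + a.width
        and a.y0 < b.y0 + b.height
        and b.y0 < a.y0 + a.height
    )


def image_anisotropy(
    image: np.ndarray,
    rois: list[Roi],
    method: str = "gradient",
) -> tuple[list[AnisotropyResult], float]:
    """Per-ROI anisotropy plus the unweighted mean AU for the image.

    One to eight ROIs are accepted (three to four per image is the typical
    sampling density). Overlapping ROIs trigger a warning, not an error.
    """
    if not 1 <= len(rois) <= MAX_ROIS:
        raise ConfigurationError(
            f"expected 1-{MAX_ROIS} ROIs, got {len(rois)}"
        )
    for i, a in enumerate(rois):
        for b in rois[i + 1 :]:
            if _rois_overlap(a, b):
                warnings.warn(
                    f"ROIs {a.roi_id!r} and {b.roi_id!r} overlap", stacklevel=2
                )
    results = []
    for roi in rois:
        tensor, n_used = roi_nematic_tensor(image, roi, method=method)
        results.append(anisotropy_from_tensor(tensor, roi.roi_id, n_used))
    mean_au = float(np.mean([r.au for r in results]))
    return results, mean_au
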