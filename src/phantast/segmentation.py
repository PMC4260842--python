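"""Local-contrast segmentation of phase-contrast microscopy images.

Cell-free background in PCM is nearly uniform while cell regions are
textured, so the local contrast

    C = std_w(I) / mean_w(I)

computed in a soft Gaussian window ``w`` of scale ``sigma`` separates the two:
a single global threshold ``epsilon`` on ``C`` yields a coarse binary mask.
The mask is then cleaned by filling small holes (area < ``f_max``), removing
small objects (area < ``r_max``) and, optionally, stripping the bright halo
flank with the gradient tracker in :mod:`phantast.halo`.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
from scipy import ndimage

#: Windowed means at or below this value give contrast 0 (background); guards
#: the division for all-dark windows, which the method never meets in practice.
MU_FLOOR = 1e-6

_CROSS = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]], dtype=bool)  # 4-connectivity
_SQUARE = np.ones((3, 3), dtype=bool)  # 8-connectivity


@dataclass
class SegmentationParams:
    """Tunable parameters of the segmentation pipeline.

    sigma:
        Gaussian window scale of the local-contrast map, in pixels.  Of the
        order of the cell-edge width; default 1.2 px for 10x magnification.
    epsilon:
        Global local-contrast threshold (dimensionless).
    f_max:
        Holes with area strictly below this (px) are filled.
    r_max:
        Objects with area strictly below this (px) are removed.
    halo_correction:
        Whether to run the post hoc halo flank removal.
    a_ratio:
        Maximum fraction of its area any single object may lose during halo
        correction, in [0, 1].
    gradient_sigma:
        Scale (px) at which the Kirsch gradient direction field is
        estimated; 0 applies the 3x3 filters to the raw image.
    """

    sigma: float = 1.2
    epsilon: float = 0.03
    f_max: int = 200
    r_max: int = 200
    halo_correction: bool = True
    a_ratio: float = 0.5
    gradient_sigma: float = 1.25

    def __post_init__(self) -> None:
        if self.sigma <= 0:
            raise ValueError(f"sigma must be > 0, got {self.sigma}")
        if self.gradient_sigma < 0:
            raise ValueError(f"gradient_sigma must be >= 0, got {self.gradient_sigma}")
        if self.epsilon < 0:
            raise ValueError(f"epsilon must be >= 0, got {self.epsilon}")
        if self.f_max < 0 or self.r_max < 0:
            raise ValueError("f_max and r_max must be >= 0")
        if not 0.0 <= self.a_ratio <= 1.0:
            raise ValueError(f"a_ratio must be in [0, 1], got {self.a_ratio}")

    def replace(self, **kwargs) -> "SegmentationParams":
        return replace(self, **kwargs)


def gaussian_window(sigma: float) -> np.ndarray:
    """Unit-sum 2-D Gaussian kernel truncated at 4*sigma.

    Truncation keeps the support bounded; renormalization after truncation
    keeps windowed means unbiased on constant images.
    """
    if sigma <= 0:
        raise ValueError(f"sigma must be > 0, got {sigma}")
    radius = int(np.ceil(4.0 * sigma))
    x = np.arange(-radius, radius + 1, dtype=np.float64)
    g = np.exp(-0.5 * (x / sigma) ** 2)
    k = np.outer(g, g)
    return k / k.sum()


def local_contrast(image: np.ndarray, sigma: float) -> np.ndarray:
    """Windowed std / windowed mean of ``image`` under a Gaussian window.

    Implemented with two convolutions (replicate padding at the borders):
    ``mu = I * w`` and ``m2 = I^2 * w`` give ``var = m2 - mu^2`` which is
    clamped at 0 before the square root to absorb floating-point residuals.
    Pixels whose windowed mean is at or below :data:`MU_FLOOR` get contrast 0.

    The ratio is invariant to rescaling the image by a positive constant.
    """
    image = np.asarray(image, dtype=np.float64)
    if image.ndim != 2:
        raise ValueError(f"expected a 2-D image, got shape {image.shape}")
    w = gaussian_window(sigma)
    mu = ndimage.convolve(image, w, mode="nearest")
    m2 = ndimage.convolve(image * image, w, mode="nearest")
    var = np.maximum(m2 - mu * mu, 0.0)
    contrast = np.zeros_like(image)
    ok = mu > MU_FLOOR
    contrast[ok] = np.sqrt(var[ok]) / mu[ok]
    return contrast


def threshold_contrast(contrast: np.ndarray, epsilon: float) -> np.ndarray:
    """Binary mask of pixels with local contrast strictly above ``epsilon``."""
    if epsilon < 0:
        raise ValueError(f"epsilon must be >= 0, got {epsilon}")
    return np.asarray(contrast) > epsilon


def fill_holes(mask: np.ndarray, f_max: int) -> np.ndarray:
    """Fill background holes with area strictly below ``f_max`` pixels.

    A hole is a 4-connected background component that does not touch the
    image border (border-touching background is open background, not a
    hole).  ``f_max = 0`` is the identity.  The result is a superset of the
    input mask.
    """
    mask = np.asarray(mask, dtype=bool)
    if f_max <= 0:
        return mask.copy()
    labels, n = ndimage.label(~mask, structure=_CROSS)
    if n == 0:
        return mask.copy()
    border = np.zeros_like(mask)
    border[0, :] = border[-1, :] = border[:, 0] = border[:, -1] = True
    touches_border = np.zeros(n + 1, dtype=bool)
    touches_border[np.unique(labels[border])] = True
    areas = np.bincount(labels.ravel(), minlength=n + 1)
    fill = (areas < f_max) & ~touches_border
    fill[0] = False
    return mask | fill[labels]


def remove_small_objects(mask: np.ndarray, r_max: int) -> np.ndarray:
    """Remove 8-connected objects with area strictly below ``r_max`` pixels.

    ``r_max = 0`` is the identity.  The result is a subset of the input mask.
    """
    mask = np.asarray(mask, dtype=bool)
    if r_max <= 0:
        return mask.copy()
    labels, n = ndimage.label(mask, structure=_SQUARE)
    if n == 0:
        return mask.copy()
    areas = np.bincount(labels.ravel(), minlength=n + 1)
    keep = areas >= r_max
    keep[0] = False
    return keep[labels]


def segment(
    image: np.ndarray,
    params: Optional[SegmentationParams] = None,
    direction_map: Optional["np.ndarray"] = None,
) -> np.ndarray:
    """Full segmentation pipeline: contrast map -> threshold -> cleanup -> halo.

    Deterministic for a fixed input and parameter set.  ``direction_map``
    may carry a precomputed Kirsch direction map (as returned by
    :func:`phantast.halo.kirsch_direction_map`) to avoid recomputation when
    segmenting the same image repeatedly during parameter sweeps.
    """
    from .halo import correct_halo, kirsch_direction_map

    if params is None:
        params = SegmentationParams()
    contrast = local_contrast(image, params.sigma)
    mask = threshold_contrast(contrast, params.epsilon)
    mask = fill_holes(mask, params.f_max)
    mask = remove_small_objects(mask, params.r_max)
    if params.halo_correction:
        dirs = direction_map
        if dirs is None:
            dirs = kirsch_direction_map(image, smooth_sigma=params.gradient_sigma).directions
        elif hasattr(dirs, "directions"):
            dirs = dirs.directions
        mask = correct_halo(mask, image, dirs, params.a_ratio)
    return mask
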