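"""Confluency and per-object morphometry from binary masks.

Image confluency is the fraction of pixels labelled as cell; culture
confluency averages it over images sampled at random locations (at least 20
images are recommended for a stable estimate).  Morphometry works on
8-connected components, excluding objects that touch the image border, and
reports for each object its area, perimeter, solidity (area over convex-hull
area) and form factor (4*pi*area/perimeter^2; 1 for a circle).

The perimeter estimator is the 8-connected boundary chain length: 1 per
axial step, sqrt(2) per diagonal step, obtained by Moore boundary tracing of
the outer contour.  Form-factor values depend on the estimator, so its name
is carried in output metadata.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np
from scipy import ndimage
from scipy.spatial import ConvexHull, QhullError

PERIMETER_ESTIMATOR = "chain8(axial=1, diagonal=sqrt2)"

#: Recommended minimum number of images for a culture-level estimate.
MIN_CULTURE_IMAGES = 20

# Compass steps, clockwise from North, in (row, col) image coordinates.
_STEPS = [(-1, 0), (-1, 1), (0, 1), (1, 1), (1, 0), (1, -1), (0, -1), (-1, -1)]
_STEP_TO_DIR = {s: d for d, s in enumerate(_STEPS)}
_SQRT2 = float(np.sqrt(2.0))


@dataclass
class CellObject:
    """Morphometric record of one connected component."""

    label: int
    area: int
    perimeter: float
    convex_area: int
    solidity: float
    form_factor: float
    touches_border: bool
    centroid: Tuple[float, float]


@dataclass
class ConfluencyResult:
    """Culture-level confluency: mean and SEM over per-image fractions."""

    per_image: List[float]
    culture_mean: float
    culture_sem: float
    n_images: int
    under_sampled: bool


def image_confluency(mask: np.ndarray) -> float:
    """Fraction of pixels labelled as cell, in [0, 1]."""
    mask = np.asarray(mask, dtype=bool)
    if mask.size == 0 or mask.ndim != 2:
        raise ValueError(f"expected a non-empty 2-D mask, got shape {mask.shape}")
    return float(np.count_nonzero(mask)) / mask.size


def culture_confluency(masks: Sequence[np.ndarray]) -> ConfluencyResult:
    """Mean and standard error of per-image confluency over a culture.

    Emits an under-sampling warning (never an error) when fewer than
    :data:`MIN_CULTURE_IMAGES` images are supplied, since a whole-culture
    estimate needs enough random fields of view to tame sampling error.
    """
    if len(masks) == 0:
        raise ValueError("need at least one mask")
    fractions = [image_confluency(m) for m in masks]
    n = len(fractions)
    mean = float(np.mean(fractions))
    sem = float(np.std(fractions, ddof=1) / np.sqrt(n)) if n > 1 else float("nan")
    under = n < MIN_CULTURE_IMAGES
    if under:
        warnings.warn(
            f"culture confluency estimated from only {n} images; "
            f"{MIN_CULTURE_IMAGES} or more are recommended",
            stacklevel=2,
        )
    return ConfluencyResult(
        per_image=fractions,
        culture_mean=mean,
        culture_sem=sem,
        n_images=n,
        under_sampled=under,
    )


def form_factor(area: float, perimeter: float) -> float:
    """``4*pi*area / perimeter**2``: 1 for an ideal circle, pi/4 for a square,
    smaller for irregular boundaries."""
    if area < 1:
        raise ValueError(f"area must be >= 1, got {area}")
    if perimeter <= 0:
        raise ValueError(f"perimeter must be > 0, got {perimeter}")
    return 4.0 * np.pi * area / perimeter**2


def solidity(area: float, convex_area: float) -> float:
    """Object area over convex-hull area, in (0, 1]."""
    if area < 1:
        raise ValueError(f"area must be >= 1, got {area}")
    if convex_area < area:
        raise ValueError(
            f"convex_area ({convex_area}) must be >= area ({area})"
        )
    return area / convex_area


def chain_perimeter(obj_mask: np.ndarray) -> float:
    """Outer-boundary chain length of a single connected object.

    Moore boundary tracing with Jacob's stopping criterion; each axial move
    contributes 1 and each diagonal move sqrt(2).  A single pixel gets the
    perimeter of its square outline (4).
    """
    obj_mask = np.asarray(obj_mask, dtype=bool)
    n_pixels = int(np.count_nonzero(obj_mask))
    if n_pixels == 0:
        raise ValueError("empty object")
    if n_pixels == 1:
        return 4.0
    crop = np.pad(obj_mask, 1)
    pts = np.argwhere(crop)
    b = (int(pts[0][0]), int(pts[0][1]))  # uppermost-leftmost foreground pixel
    c_dir = 6  # its west neighbor is background by row-major minimality
    first_move = None
    perim = 0.0
    for _ in range(4 * n_pixels + 8):
        found = None
        for i in range(1, 9):
            d = (c_dir + i) % 8
            nb = (b[0] + _STEPS[d][0], b[1] + _STEPS[d][1])
            if crop[nb]:
                found = (d, i, nb)
                break
        if found is None:  # isolated pixel; handled above but keep safe
            return 4.0
        d, i, nb = found
        move = (b, d)
        if first_move is None:
            first_move = move
        elif move == first_move:
            break
        perim += 1.0 if d % 2 == 0 else _SQRT2
        # last background neighbor checked before the hit; start of next scan
        prev_bg = (b[0] + _STEPS[(c_dir + i - 1) % 8][0],
                   b[1] + _STEPS[(c_dir + i - 1) % 8][1])
        b = nb
        c_dir = _STEP_TO_DIR[(prev_bg[0] - b[0], prev_bg[1] - b[1])]
    return perim


def convex_pixel_area(obj_mask: np.ndarray) -> int:
    """Number of pixels whose centers lie inside or on the convex hull of
    the object's pixel centers.

    Keeps both terms of solidity in pixel-count units.  Degenerate point
    sets (single pixel, collinear pixels) have hull area equal to the pixel
    count itself.
    """
    pts = np.argwhere(np.asarray(obj_mask, dtype=bool))
    if len(pts) == 0:
        raise ValueError("empty object")
    if len(pts) < 3:
        return len(pts)
    try:
        hull = ConvexHull(pts.astype(np.float64))
    except QhullError:  # collinear pixel centers
        return len(pts)
    r0, c0 = pts.min(axis=0)
    r1, c1 = pts.max(axis=0)
    rr, cc = np.mgrid[r0 : r1 + 1, c0 : c1 + 1]
    grid = np.column_stack([rr.ravel(), cc.ravel()]).astype(np.float64)
    # hull.equations: A @ x + b <= 0 inside (tolerance for points on facets)
    inside = np.all(
        grid @ hull.equations[:, :2].T + hull.equations[:, 2] <= 1e-9, axis=1
    )
    return int(np.count_nonzero(inside))


def extract_objects(
    mask: np.ndarray, include_border: bool = False
) -> List[CellObject]:
    """Connected-component morphometry of a binary mask.

    Components are 8-connected.  Objects with any pixel on the image border
    are flagged and, by default, excluded (their shape is truncated by the
    field of view, so their morphometry is meaningless); they still count
    toward confluency, which is computed from the mask directly.
    """
    mask = np.asarray(mask, dtype=bool)
    labels, n = ndimage.label(mask, structure=np.ones((3, 3), dtype=bool))
    objects: List[CellObject] = []
    if n == 0:
        return objects
    slices = ndimage.find_objects(labels)
    rows, cols = mask.shape
    for lab, slc in enumerate(slices, start=1):
        touches = (
            slc[0].start == 0
            or slc[1].start == 0
            or slc[0].stop == rows
            or slc[1].stop == cols
        )
        if touches and not include_border:
            continue
        obj = labels[slc] == lab
        area = int(np.count_nonzero(obj))
        perim = chain_perimeter(obj)
        convex_area = convex_pixel_area(obj)
        coords = np.argwhere(obj)
        centroid = (
            float(coords[:, 0].mean() + slc[0].start),
            float(coords[:, 1].mean() + slc[1].start),
        )
        objects.append(
            CellObject(
                label=lab,
                area=area,
                perimeter=perim,
                convex_area=convex_area,
                solidity=solidity(area, convex_area),
                form_factor=form_factor(area, perim),
                touches_border=touches,
                centroid=centroid,
            )
        )
    return objects
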