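"""Cell density estimation via packing-corrected confluency (PCC).

Confluency alone is a poor proxy for cell density in colony-forming
cultures: as colonies pack, mean cell area shrinks and confluency
saturates.  PCC corrects for packing by dividing image confluency by the
mean distance to the nearest nucleus-like texture feature:

1. classify every pixel into one of seven basic image features (BIF) from
   scale-normalized Gaussian-derivative responses at scale ``sigma_bif``
   (default 4) and flatness threshold ``eps_flat`` (default 0);
2. take the centroids of bright-blob components that fall inside the cell
   mask — these act as surrogates for nuclei in unlabeled images;
3. average the Euclidean distance transform of the binary centroid image;
4. PCC = confluency / mean distance (units 1/px).

PCC grows linearly with cell density, so a linear calibration against a few
reference counts turns it into an absolute density estimator.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import IntEnum
from typing import List, Optional, Sequence, Tuple

import numpy as np
from scipy import ndimage


class BIFClass(IntEnum):
    """The seven basic image feature classes."""

    FLAT = 0
    SLOPE = 1
    DARK_BLOB = 2
    BRIGHT_BLOB = 3
    DARK_LINE = 4
    BRIGHT_LINE = 5
    SADDLE = 6


@dataclass
class BIFMap:
    """Per-pixel BIF classification with the parameters that produced it."""

    classes: np.ndarray
    scale: float
    flatness: float


@dataclass
class PCCResult:
    confluency: float
    mean_blob_distance: float
    pcc: float
    n_blobs: int


@dataclass
class CalibrationModel:
    """Linear map from PCC to cell density (``density = slope*pcc + intercept``)."""

    slope: float
    intercept: float
    adj_r2: float
    nrmse: float

    def predict(self, pcc_values) -> np.ndarray:
        return self.slope * np.asarray(pcc_values, dtype=np.float64) + self.intercept

    def evaluate_nrmse(self, pcc_values, densities) -> float:
        """NRMSE of predictions on held-out data, normalized by the observed
        density range (error if the range is zero)."""
        densities = np.asarray(densities, dtype=np.float64)
        span = densities.max() - densities.min()
        if span <= 0:
            raise ValueError("density range of evaluation data is zero; NRMSE undefined")
        resid = self.predict(pcc_values) - densities
        return float(np.sqrt(np.mean(resid**2)) / span)


def bif_classify(
    image: np.ndarray, sigma_bif: float = 4.0, eps_flat: float = 0.0
) -> BIFMap:
    """Classify each pixel into one of the seven BIF classes.

    Scale-normalized responses ``s_ij = sigma**(i+j) * (d^i_x d^j_y G_sigma * I)``
    up to second order feed the classifier.  With ``lam = s20 + s02`` (the
    Laplacian) and ``gamma = sqrt((s20 - s02)^2 + 4*s11^2)`` (the
    eigenvalue spread), the class is the largest of the scores

    ========  =========================
    flat      ``eps_flat * s00``
    slope     ``2*sqrt(s10^2 + s01^2)``
    dark blob   ``+lam``
    bright blob ``-lam``
    dark line   ``(gamma + lam)/sqrt(2)``
    bright line ``(gamma - lam)/sqrt(2)``
    saddle    ``gamma``
    ========  =========================

    Ties never go to flat, so ``eps_flat = 0`` produces no flat pixels
    (``gamma >= 0`` always matches the zero flat score).  With
    ``eps_flat = 0`` only derivative responses contribute, so the
    classification is invariant to adding a constant to the image up to the
    truncation error of the sampled derivative kernels (pixels sitting on
    near-exact score ties may flip).
    """
    if sigma_bif <= 0:
        raise ValueError(f"sigma_bif must be > 0, got {sigma_bif}")
    if eps_flat < 0:
        raise ValueError(f"eps_flat must be >= 0, got {eps_flat}")
    image = np.asarray(image, dtype=np.float64)

    def g(order_r, order_c):
        resp = ndimage.gaussian_filter(
            image, sigma_bif, order=(order_r, order_c), mode="nearest"
        )
        return sigma_bif ** (order_r + order_c) * resp

    s00 = g(0, 0)
    s10, s01 = g(1, 0), g(0, 1)
    s20, s02, s11 = g(2, 0), g(0, 2), g(1, 1)
    lam = s20 + s02
    gamma = np.sqrt((s20 - s02) ** 2 + 4.0 * s11**2)
    inv_sqrt2 = 1.0 / np.sqrt(2.0)
    # stacked in an order that prefers structure over flat on exact ties
    scores = np.stack(
        [
            2.0 * np.sqrt(s10**2 + s01**2),  # slope
            lam,  # dark blob
            -lam,  # bright blob
            (gamma + lam) * inv_sqrt2,  # dark line
            (gamma - lam) * inv_sqrt2,  # bright line
            gamma,  # saddle
            eps_flat * s00,  # flat
        ]
    )
    order = np.array(
        [
            BIFClass.SLOPE,
            BIFClass.DARK_BLOB,
            BIFClass.BRIGHT_BLOB,
            BIFClass.DARK_LINE,
            BIFClass.BRIGHT_LINE,
            BIFClass.SADDLE,
            BIFClass.FLAT,
        ],
        dtype=np.uint8,
    )
    classes = order[np.argmax(scores, axis=0)]
    return BIFMap(classes=classes, scale=float(sigma_bif), flatness=float(eps_flat))


def blob_centroids(
    bif: BIFMap, cell_mask: Optional[np.ndarray] = None
) -> List[Tuple[int, int]]:
    """Centroids of 8-connected bright-blob components, as pixel coordinates.

    Each component's centroid (mean pixel coordinate) is rounded to the
    nearest pixel; centroids whose pixel falls outside ``cell_mask`` are
    discarded — blobs in cell-free background are texture noise, not nuclei.
    """
    classes = bif.classes if isinstance(bif, BIFMap) else np.asarray(bif)
    blob = classes == int(BIFClass.BRIGHT_BLOB)
    if cell_mask is not None and np.shape(cell_mask) != blob.shape:
        raise ValueError("cell_mask shape does not match BIF map shape")
    labels, n = ndimage.label(blob, structure=np.ones((3, 3), dtype=bool))
    if n == 0:
        return []
    centroids = ndimage.center_of_mass(blob, labels, index=range(1, n + 1))
    out: List[Tuple[int, int]] = []
    for r, c in centroids:
        ri, ci = int(round(r)), int(round(c))
        if cell_mask is None or cell_mask[ri, ci]:
            out.append((ri, ci))
    return out


def mean_centroid_distance(
    centroids: Sequence[Tuple[int, int]],
    shape: Tuple[int, int],
    within: Optional[np.ndarray] = None,
) -> float:
    """Mean of the Euclidean distance transform of the binary centroid image.

    Every pixel is assigned its distance to the nearest centroid; the mean
    is taken over all pixels by default, or over ``within`` (e.g. the cell
    mask) when given.  With no centroids the distance is undefined and a
    ``ValueError`` is raised (PCC is then not computable).
    """
    if len(centroids) == 0:
        raise ValueError("no centroids; mean distance (and PCC) undefined")
    rows, cols = shape
    if rows <= 0 or cols <= 0:
        raise ValueError(f"invalid shape {shape}")
    cent_img = np.zeros(shape, dtype=bool)
    for r, c in centroids:
        cent_img[r, c] = True
    dist = ndimage.distance_transform_edt(~cent_img)
    if within is not None:
        within = np.asarray(within, dtype=bool)
        if within.shape != cent_img.shape:
            raise ValueError("within-mask shape does not match image shape")
        if not within.any():
            raise ValueError("within-mask is empty")
        return float(dist[within].mean())
    return float(dist.mean())


def pcc(confluency: float, mean_distance: float) -> float:
    """Packing-corrected confluency: confluency / mean blob distance (1/px)."""
    if mean_distance <= 0:
        raise ValueError(f"mean_distance must be > 0, got {mean_distance}")
    return confluency / mean_distance


def compute_pcc(
    image: np.ndarray,
    cell_mask: np.ndarray,
    sigma_bif: float = 4.0,
    eps_flat: float = 0.0,
    within_cells: bool = False,
) -> PCCResult:
    """End-to-end PCC of one image given its segmentation mask.

    ``within_cells`` restricts the mean-distance average to cell pixels
    (the default averages over all pixels).
    """
    from .features import image_confluency

    conf = image_confluency(cell_mask)
    bif = bif_classify(image, sigma_bif=sigma_bif, eps_flat=eps_flat)
    cents = blob_centroids(bif, cell_mask)
    dist = mean_centroid_distance(
        cents, cell_mask.shape, within=cell_mask if within_cells else None
    )
    return PCCResult(
        confluency=conf,
        mean_blob_distance=dist,
        pcc=pcc(conf, dist),
        n_blobs=len(cents),
    )


def calibrate_density(
    pcc_values: Sequence[float], densities: Sequence[float]
) -> CalibrationModel:
    """Ordinary least-squares line mapping PCC to cell density.

    Reports the adjusted r^2, ``1 - (1 - r^2)(n - 1)/(n - 2)``, and the
    NRMSE on the calibration data (RMSE normalized by the density range).
    Requires at least 3 points with non-constant PCC.
    """
    x = np.asarray(pcc_values, dtype=np.float64)
    y = np.asarray(densities, dtype=np.float64)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("pcc_values and densities must be 1-D and equally long")
    n = len(x)
    if n < 3:
        raise ValueError(f"need at least 3 calibration points, got {n}")
    if np.ptp(x) == 0:
        raise ValueError("PCC values are constant; calibration is degenerate")
    slope, intercept = np.polyfit(x, y, 1)
    pred = slope * x + intercept
    ss_res = float(np.sum((y - pred) ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    adj_r2 = 1.0 - (1.0 - r2) * (n - 1) / (n - 2)
    model = CalibrationModel(
        slope=float(slope), intercept=float(intercept), adj_r2=float(adj_r2), nrmse=0.0
    )
    model.nrmse = model.evaluate_nrmse(x, y)
    return model


def rotating_calibration(
    cultures: Sequence[Tuple[Sequence[float], Sequence[float]]]
) -> List[float]:
    """Rotate calibration across cultures: fit on one, score on the others.

    Each culture is a ``(pcc_values, densities)`` pair.  For every rotation
    the model calibrated on one culture is evaluated (NRMSE) on the pooled
    remaining cultures; the list of per-rotation NRMSEs is returned.
    """
    if len(cultures) < 2:
        raise ValueError("need at least 2 cultures")
    out = []
    for i, (cal_pcc, cal_dens) in enumerate(cultures):
        model = calibrate_density(cal_pcc, cal_dens)
        eval_pcc = np.concatenate(
            [np.asarray(p, dtype=np.float64) for j, (p, _) in enumerate(cultures) if j != i]
        )
        eval_dens = np.concatenate(
            [np.asarray(d, dtype=np.float64) for j, (_, d) in enumerate(cultures) if j != i]
        )
        out.append(model.evaluate_nrmse(eval_pcc, eval_dens))
    return out
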