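"""Synthetic PCM phantoms with pixel-exact ground truth.

The generator emulates the three features of phase-contrast images that the
segmentation pipeline lives off: a near-uniform background, textured cell
interiors whose *mean* intensity matches the background (no global-threshold
shortcut), and a bright halo band around every cell, 10-30 px wide by
default.  The halo peaks at the cell boundary and decays to background with
a half-cosine profile, while the interior sits well below the peak — so the
intensity gradient points toward the cell edge throughout the band and
reverses abruptly at the halo/cell interface, exactly the structure the
gradient-tracking halo correction exploits.

Cells are disks perturbed by low-order radial harmonics (so non-convex
shapes exist for solidity tests), each with a nucleus-like Gaussian bump at
its center (so the BIF bright-blob detector has something real to find) and
an optional fluorescence channel with per-cell expression levels.  All
randomness flows from a single seeded generator; identical specs give
bit-identical bundles.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import List, Optional, Sequence, Tuple

import numpy as np
from scipy import ndimage


class PlacementError(RuntimeError):
    """Raised when cells cannot be placed without exceeding the packing limit."""


@dataclass
class PhantomSpec:
    """Parameters of one synthetic PCM field of view.

    Intensity parameters are in normalized [0, 1] units; geometric ones in
    pixels.  ``halo_gain`` is the peak halo brightness above background,
    ``interior_texture_sd`` the speckle SD inside cells (the sole cue the
    local-contrast map has for cell interiors), ``shape_irregularity`` the
    relative amplitude of the radial harmonics deforming each disk.
    """

    shape: Tuple[int, int] = (512, 512)
    n_cells: int = 4
    radius_range: Tuple[float, float] = (30.0, 45.0)
    halo_width_range: Tuple[float, float] = (10.0, 30.0)
    halo_gain: float = 0.35
    interior_texture_sd: float = 0.10
    background_level: float = 0.45
    background_noise_sd: float = 0.005
    illumination_gradient: float = 0.0
    defocus_sigma: float = 0.8
    shape_irregularity: float = 0.12
    nucleus_amplitude: float = 0.25
    nucleus_sigma: float = 3.0
    min_separation: float = 3.0
    allow_overlap: bool = False
    fluor_levels: Tuple[float, ...] = (0.05, 0.15, 0.5)
    fluor_background: float = 0.02
    fluor_noise_sd: float = 0.003
    max_place_tries: int = 500
    seed: int = 0

    def __post_init__(self) -> None:
        if self.radius_range[0] <= 0 or self.radius_range[1] < self.radius_range[0]:
            raise ValueError(f"invalid radius_range {self.radius_range}")
        if self.halo_width_range[0] < 0 or self.halo_width_range[1] < self.halo_width_range[0]:
            raise ValueError(f"invalid halo_width_range {self.halo_width_range}")
        if not 0 <= self.background_level <= 1:
            raise ValueError("background_level must be in [0, 1]")
        if self.n_cells < 0:
            raise ValueError("n_cells must be >= 0")


@dataclass
class PhantomBundle:
    """One phantom with its exact ground truth."""

    image: np.ndarray
    truth_mask: np.ndarray
    centers: List[Tuple[int, int]]
    fluor: Optional[np.ndarray]
    cell_radii: List[float]
    halo_widths: List[float]
    fluor_levels: List[float]
    spec: PhantomSpec


def _cell_profile(rng: np.random.Generator, radius: float, irregularity: float):
    """Radial harmonic coefficients of one deformed disk."""
    orders = (2, 3, 4)
    amps = rng.uniform(-irregularity, irregularity, size=len(orders)) / np.arange(
        1, len(orders) + 1
    )
    phases = rng.uniform(0, 2 * np.pi, size=len(orders))
    return orders, amps, phases


def _rasterize_cell(radius, orders, amps, phases, halfwidth):
    """Boolean crop of a star-shaped cell centered in a (2H+1)^2 grid."""
    ax = np.arange(-halfwidth, halfwidth + 1, dtype=np.float64)
    yy, xx = np.meshgrid(ax, ax, indexing="ij")
    rho = np.hypot(yy, xx)
    theta = np.arctan2(xx, yy)
    r_theta = radius * (
        1.0
        + sum(a * np.cos(k * theta + p) for k, a, p in zip(orders, amps, phases))
    )
    return rho <= r_theta


def generate_phantom(spec: PhantomSpec) -> PhantomBundle:
    """Render one phantom field of view (deterministic for a fixed spec)."""
    rng = np.random.default_rng(spec.seed)
    rows, cols = spec.shape
    truth = np.zeros(spec.shape, dtype=bool)
    halo_field = np.zeros(spec.shape, dtype=np.float64)
    nucleus_field = np.zeros(spec.shape, dtype=np.float64)

    centers: List[Tuple[int, int]] = []
    radii: List[float] = []
    widths: List[float] = []
    placed_geom: List[Tuple[int, int, float]] = []

    for _ in range(spec.n_cells):
        radius = rng.uniform(*spec.radius_range)
        width = rng.uniform(*spec.halo_width_range)
        orders, amps, phases = _cell_profile(rng, radius, spec.shape_irregularity)
        r_max = radius * (1.0 + np.sum(np.abs(amps)))
        margin = int(np.ceil(r_max)) + 2
        if 2 * margin >= min(rows, cols):
            raise PlacementError(
                f"cell radius {radius:.1f} does not fit in a {spec.shape} image"
            )
        placed = False
        for _try in range(spec.max_place_tries):
            cr = int(rng.integers(margin, rows - margin))
            cc = int(rng.integers(margin, cols - margin))
            ok = spec.allow_overlap or all(
                np.hypot(cr - pr, cc - pc) >= r_max + prmax + spec.min_separation
                for pr, pc, prmax in placed_geom
            )
            if ok:
                placed = True
                break
        if not placed:
            raise PlacementError(
                f"could not place {spec.n_cells} cells of radius "
                f"~{radius:.0f} px in a {spec.shape} image (packing limit)"
            )
        halfwidth = int(np.ceil(r_max + width)) + 2
        cell = _rasterize_cell(radius, orders, amps, phases, halfwidth)
        # halo: peak at the cell boundary, half-cosine decay over `width`
        dist_out = ndimage.distance_transform_edt(~cell)
        halo = np.where(
            (dist_out > 0) & (dist_out <= width),
            spec.halo_gain * 0.5 * (1.0 + np.cos(np.pi * dist_out / width)),
            0.0,
        )
        # nucleus-like bright bump for the BIF blob detector
        ax = np.arange(-halfwidth, halfwidth + 1, dtype=np.float64)
        yy, xx = np.meshgrid(ax, ax, indexing="ij")
        bump = spec.nucleus_amplitude * np.exp(
            -(yy**2 + xx**2) / (2.0 * spec.nucleus_sigma**2)
        )

        r0, r1 = cr - halfwidth, cr + halfwidth + 1
        c0, c1 = cc - halfwidth, cc + halfwidth + 1
        sr0, sr1 = max(r0, 0), min(r1, rows)
        sc0, sc1 = max(c0, 0), min(c1, cols)
        lr0, lc0 = sr0 - r0, sc0 - c0
        lr1, lc1 = lr0 + (sr1 - sr0), lc0 + (sc1 - sc0)

        truth[sr0:sr1, sc0:sc1] |= cell[lr0:lr1, lc0:lc1]
        np.maximum(
            halo_field[sr0:sr1, sc0:sc1],
            halo[lr0:lr1, lc0:lc1],
            out=halo_field[sr0:sr1, sc0:sc1],
        )
        nucleus_field[sr0:sr1, sc0:sc1] += bump[lr0:lr1, lc0:lc1]

        centers.append((cr, cc))
        radii.append(float(radius))
        widths.append(float(width))
        placed_geom.append((cr, cc, float(r_max)))

    # --- assemble the PCM image ---------------------------------------
    ramp = np.linspace(-0.5, 0.5, cols)[np.newaxis, :]
    base = spec.background_level * (1.0 + spec.illumination_gradient * ramp)
    halo_field[truth] = 0.0  # halos belong to the background side
    base_full = np.broadcast_to(base, spec.shape)
    image = base_full + halo_field
    # interior: background-level mean plus speckle texture
    n_inside = int(np.count_nonzero(truth))
    texture = rng.normal(0.0, spec.interior_texture_sd, size=n_inside)
    image[truth] = base_full[truth] + texture
    image += nucleus_field
    image += rng.normal(0.0, spec.background_noise_sd, size=spec.shape)
    if spec.defocus_sigma > 0:
        image = ndimage.gaussian_filter(image, spec.defocus_sigma, mode="nearest")
    image = np.clip(image, 0.0, 1.0)

    # --- fluorescence channel -----------------------------------------
    fluor = None
    levels: List[float] = []
    if spec.fluor_levels:
        fluor = np.full(spec.shape, spec.fluor_background, dtype=np.float64)
        level_choices = rng.choice(spec.fluor_levels, size=len(centers))
        # per-cell level painted on that cell's pixels (redo crops cheaply
        # via a label image to honor overlaps deterministically)
        labels, _ = ndimage.label(truth, structure=np.ones((3, 3), dtype=bool))
        for (cr, cc), level in zip(centers, level_choices):
            lab = labels[cr, cc]
            fluor[labels == lab] = spec.fluor_background + float(level)
            levels.append(float(level))
        fluor += rng.normal(0.0, spec.fluor_noise_sd, size=spec.shape)
        fluor = np.clip(fluor, 0.0, 1.0)

    return PhantomBundle(
        image=image,
        truth_mask=truth,
        centers=centers,
        fluor=fluor,
        cell_radii=radii,
        halo_widths=widths,
        fluor_levels=levels,
        spec=spec,
    )


def generate_series(
    base_spec: PhantomSpec,
    n_cells_list: Sequence[int],
    seeds: Sequence[int],
) -> List[PhantomBundle]:
    """One bundle per (cell count, seed), e.g. a density calibration series."""
    if len(n_cells_list) != len(seeds):
        raise ValueError("n_cells_list and seeds must have equal length")
    return [
        generate_phantom(replace(base_spec, n_cells=int(n), seed=int(s)))
        for n, s in zip(n_cells_list, seeds)
    ]
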