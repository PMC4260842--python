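# Methods note

This note records the model behind each component, the numerical choices,
the synthetic-data design, and the known limitations. Nothing here claims
empirical results beyond what the test suite and `scripts/acceptance.py`
compute.

## Segmentation model

**Local contrast.** PCM backgrounds are nearly uniform while cell regions
are textured, so the pipeline thresholds the local contrast
`C = std_w(I) / mean_w(I)` rather than intensity. The window `w` is a 2-D
Gaussian of scale `sigma`, truncated at `4*sigma` and renormalized to unit
sum (bounded support; windowed means stay unbiased on constant images).
Both moments are computed by convolution with replicate padding, the
variance `m2 - mu^2` is clamped at zero before the square root to absorb
floating-point residuals, and windows with mean at or below `1e-6` get
contrast 0 (an all-dark guard the method never meets on real data). Because
`C` is a ratio, it is invariant to a positive global rescaling of the image,
which makes the threshold `epsilon` bit-depth independent.

**Cleanup.** Holes are 4-connected background components that do not touch
the image border; holes with area strictly below `f_max` are filled.
Objects are 8-connected foreground components; objects with area strictly
below `r_max` are removed. Both operations are idempotent and monotone
(fill only adds, removal only deletes).

**Defaults.** `sigma = 1.2`, `epsilon = 0.03`, `f_max = r_max = 200`,
`a_ratio = 0.5`. The window scale is of the order of the cell-edge width at
10× magnification; the area bounds are far below a single cell's footprint.
All are overridable per call, per config file, and per CLI flag.

## Halo correction

The eight Kirsch kernels (North `[[5,5,5],[-3,0,-3],[-3,-3,-3]]`, the others
rotating the border coefficients in 45° steps) are correlated with the
image; the per-pixel argmax points toward increasing intensity, with ties
resolved to the smallest compass index. A FIFO queue is seeded with the
mask's boundary pixels in row-major order. Popping a location, the three
pixels one king-move step along its direction and the two adjacent (±45°)
directions are examined: if at least one is currently a cell pixel the
popped location is on the halo flank — it is relabelled background and the
cell candidates are enqueued; otherwise the gradient leads out of the mask,
meaning the halo/cell interface (where the direction field reverses) has
been reached, and the location is confirmed. Every pixel is decided at most
once, so the iteration count is bounded by the mask size. Per 8-connected
object, removal stops as soon as one more removal would exceed
`a_ratio × area`; an object with no interface anywhere (constant interior)
therefore loses exactly `floor(a_ratio × area)` pixels. The output is
always a subset of the input, and `a_ratio = 0` is the identity.

**Direction-field scale (design choice).** The 3×3 kernels estimate the
gradient at pixel scale. In the weak-gradient outskirts of wide halo bands
the pixel-scale direction field is dominated by camera noise, which stalls
the tracker or lets it wander. The direction map may therefore be computed
on a Gaussian-smoothed copy of the image (`gradient_sigma`, default
1.25 px); `gradient_sigma = 0` recovers raw-image filtering. On the phantom
suite, smoothing at 1.25 px brings the mean corrected-to-true boundary
displacement within 3 px across the whole 10–30 px halo-width range,
whereas the raw-scale field leaves displacements of 6+ px at either end of
the range. This changes only where the direction field is evaluated, not
the tracking algorithm.

## Confluency and morphometry

Image confluency is the cell-pixel fraction. Culture confluency averages
it over fields of view sampled at random stage positions; fewer than 20
fields triggers an under-sampling warning (never an error), and the SEM of
the per-image fractions quantifies the sampling error.

Morphometry runs on 8-connected components, excluding objects touching the
image border (their shapes are truncated by the field of view); excluded
objects still count toward confluency. The perimeter is the 8-connected
Moore boundary chain length — 1 per axial move, √2 per diagonal, 4.0 for a
single pixel — and the estimator name is written into output metadata
because form-factor values are estimator-dependent. Solidity divides the
pixel count by the number of pixel centers inside the convex hull of the
object's pixel centers, keeping both terms in the same discrete units.

## Error statistics

Pixelwise scoring uses cells-as-positives: F1 = 2TP/(2TP+FP+FN), the
Matthews correlation coefficient (0 when a marginal vanishes), and the
segmentation error 1 − MCC. Confluency estimation error decomposes as
`rmse² = bias² + precision²`; independent components combine in quadrature.
Observer-survey variability splits into the pooled SD of estimates about
per-image means (`v_both`, denominator m(n−1)), the paired-repeat
intra-rater estimator `sqrt(Σd²/2n)`, and the quadrature remainder
(clamped at zero). Parameter tuning scores every grid point (Cartesian
product, keys in lexicographic order) on every annotated image by 1 − MCC
and reports both the overall best point (first minimum on ties) and a
leave-one-out cross-validation estimate of its generalization error.

## Density estimation (PCC)

Confluency saturates once colonies pile up, while mean cell area keeps
shrinking. PCC divides confluency by the mean distance to nucleus-like
texture features: the BIF classifier assigns each pixel the argmax of seven
scores built from scale-normalized Gaussian-derivative responses at scale
`sigma_bif = 4` (flat `eps_flat·s00`; slope `2√(s10²+s01²)`; dark/bright
blob `±(s20+s02)`; dark/bright line `(γ±λ)/√2`; saddle `γ`). Ties never go
to flat, so the default `eps_flat = 0` classifies every pixel as structure.
Centroids of bright-blob components inside the cell mask act as nucleus
surrogates; the mean of the Euclidean distance transform of the centroid
image (over all pixels by default) is the packing term. A `within`
restriction to cell pixels is provided: under the all-pixels default the
mean distance scales like n^(−1/2) for fixed-size cells, so PCC is linear
in density only to the extent a line fits a ~n^1.5 trend over the working
range, whereas the within-cells average is density-independent per cell and
makes PCC strictly proportional to cell count for non-overlapping cells.
The all-pixels form remains the default because calibration absorbs the
residual curvature; the protocol quantifies exactly that (adjusted r² and
rotating leave-one-culture-out NRMSE, normalized by the density range).

## Augmented fluorescence images

The PCM mask gates a co-registered fluorescence image; cell pixels are
binned at two normalized thresholds, 0.094 (detectable expression) and
0.24 (high expression), with boundary values going to the lower class.
Thresholds live in [0, 1] units so they are bit-depth independent (0.094
corresponds to 24 on a uint8 scale). An empty mask yields NaN summary
statistics with a `defined = False` flag rather than an error.

## Phantom generator

The phantoms reproduce the three properties the method exploits, each tied
to a pipeline stage:

- a near-uniform background (level 0.45, noise SD 0.005) — the
  local-contrast floor;
- textured cell interiors (speckle SD 0.10) whose mean equals the
  background level, so no global intensity threshold can work — the
  local-contrast signal;
- a bright halo band of specified width around every cell — the
  halo-correction target. The band peaks at the cell boundary
  (`halo_gain = 0.35` above background) and decays to background as a
  half-cosine over the band width. With the peak at the interface, the
  intensity gradient points toward the cell edge throughout the band and
  reverses abruptly at the halo/cell boundary — the structure the tracker
  requires. A mid-band crest would instead put the reversal inside the
  halo and the tracker would stop there, contradicting the mechanism being
  modeled.

Cells are disks perturbed by radial harmonics of orders 2–4 (relative
amplitude 0.12), providing non-convex shapes for solidity tests; each cell
carries a Gaussian nucleus bump (amplitude 0.25, σ 3 px) so the BIF blob
detector has a real target, and an optional fluorescence channel paints
per-cell expression levels (0.05 / 0.15 / 0.5 over a 0.02 background) that
straddle the AFI thresholds. Defocus blur (σ 0.8) is applied last. Cells
are rendered on per-cell crops for speed; all randomness flows from one
seeded generator, so identical specs give bit-identical bundles. By
default cells may not overlap (with a placement-failure error at the
packing limit); `allow_overlap` permits colony-like piling.

## Evaluation protocols

Both protocols live in `phantast.suites` and fix their parameters up front:
`sigma = 2.5`, `epsilon = 0.03`, `f_max = r_max = 200`,
`a_ratio = 0.85`, `gradient_sigma = 1.25`.

- **Window scale 2.5.** The windowed contrast of the band's outer slope
  must exceed `epsilon` for the mask to stay connected across the widest
  band: roughly `sigma × halo_gain / (width × background) ≥ epsilon`, i.e.
  `sigma ≳ 2` at width 30. With the library default 1.2 the thresholded
  mask splits into the cell body plus a detached halo annulus.
- **Area cap 0.85.** For a planted cell of radius r with halo width w the
  band contributes up to `1 − (r/(r+w))² ≈ 0.77` of the thresholded
  object, so the per-object removal budget must exceed that share.

The **segmentation suite** renders 20 phantoms of 512×512 px with 4 cells
each (radii 30–45 px, halo widths spanning 10–30 px; per-image seeds are
31-bit values derived from one master seed) and scores the pipeline with
and without halo correction against exact ground truth. The **density
series** renders 3 simulated cultures of 4 fields each (480×640 px, radii
18–22 px, planted counts 10/140/270/400 with overlap allowed, giving ~4–80 %
confluency with colony piling), computes PCC per field, fits the pooled
PCC–count line, and rotates a one-culture calibration against the pooled
remaining cultures. Field sizes and counts are this package's protocol
choices, sized to run in seconds on one CPU.

## Limitations

- The halo tracker can strand small mask shards (1–5 px) when it severs a
  flank unevenly; the pipeline applies `r_max` before halo correction (its
  specified position), so these shards survive into the final mask.
  Morphometric analyses should filter by area.
- The chain-code perimeter underestimates objects of only 1–2 px in a way
  that can push the form factor above 1; form factor and solidity are
  meaningful only well above the pixel scale.
- The BIF blob detector also fires on halo residues and interior texture,
  so the blob count can exceed the true cell count at high density. This
  biases the PCC packing term but preserves monotonicity, and the linear
  calibration absorbs it; planted nuclei themselves are recovered nearly
  completely on the phantoms.
- BIF classification with `eps_flat = 0` is offset-invariant only up to
  the truncation error of the sampled derivative kernels: pixels on
  near-exact score ties may flip under a constant intensity shift.
- Phantoms model halo geometry, contrast statistics and nucleus texture,
  not PCM optics: no shade-off inside large cells, no mottled debris, no
  uneven illumination by default (a linear gradient is available). Scores
  on phantoms therefore bound the method's behavior under its stated
  assumptions, not its performance on any particular microscope.
- The mean-distance packing term is resolution- and magnification-
  dependent; PCC calibrations are only transferable between images with
  identical pixel size and optics.
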