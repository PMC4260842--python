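# phantast

Segmentation and quantification of adherent cell cultures in phase-contrast
microscopy (PCM) images.

PCM is the standard label-free modality for routine inspection of adherent
cell cultures, but its images resist naive segmentation: cell interiors have
nearly the same mean intensity as the cell-free background, and every cell is
surrounded by a bright optical halo, typically 10–30 px wide. This package
implements a two-stage segmentation that exploits exactly those properties:

1. **Local-contrast thresholding.** The per-pixel local contrast
   `C = std_w(I) / mean_w(I)` (windowed standard deviation over windowed mean,
   soft Gaussian window of scale `sigma`) is near zero on the uniform
   background and elevated on textured cell regions, so a single global
   threshold `epsilon` on `C` yields a coarse cell mask. Small holes
   (area < `f_max`) are filled and small objects (area < `r_max`) removed.
2. **Halo correction by gradient tracking.** The coarse mask still contains
   the bright halo flank. Starting from the mask boundary, each pixel is
   walked one step toward brighter intensities — along the compass direction
   given by the eight 3×3 Kirsch filters — and relabelled background, until
   the halo/cell interface is reached, where the gradient direction reverses
   abruptly. A per-object cap `a_ratio` bounds the removable area fraction.

On top of the segmentation the package provides the standard downstream
quantities:

- **Confluency** (cell-covered area fraction) per image and per culture, with
  the precision statistics to interpret it: RMSE/bias/precision decomposition
  and quadrature combination of independent error sources. Published
  observer-survey numbers put human estimation variability at 6.8 % (intra-
  rater) and 9.5 % (inter-rater) confluency points — 11.7 % combined — while
  the automated estimate achieves ~2.7 % per image, or ~3.2 % overall when a
  1.74 % field-sampling error is folded in.
- **Morphometry** per connected component: area, chain-code perimeter,
  solidity (against the pixel-discretized convex hull) and form factor.
- **Packing-corrected confluency (PCC)** for cell-density estimation:
  confluency divided by the mean distance to nucleus-like bright-blob
  features found by a basic-image-features (BIF) classifier built from
  scale-normalized Gaussian derivatives. PCC grows linearly with cell
  density even after colonies pile up and confluency saturates, so a linear
  calibration against a few reference counts turns it into an absolute
  density estimator.
- **Augmented fluorescence images (AFI)**: a paired fluorescence channel is
  gated by the PCM mask and binned into negative / low / high expression.
- **Evaluation and tuning**: pixelwise F-score and Matthews correlation
  against ground truth, and leave-one-out cross-validated grid search of the
  segmentation parameters.
- **Synthetic phantoms** with pixel-exact ground truth that reproduce the
  three properties the method lives off (uniform background, textured
  interiors at background mean intensity, bright halo bands), making the
  entire pipeline testable without microscope data.

See `docs/methods.md` for the model, parameter derivations and limitations.

## Library quickstart

```python
import phantast as ph

bundle = ph.generate_phantom(ph.PhantomSpec(seed=0))       # synthetic PCM field
params = ph.SegmentationParams(sigma=2.5, a_ratio=0.85)
mask = ph.segment(bundle.image, params)

print(ph.image_confluency(mask))                           # area fraction
m = ph.roc_metrics(ph.confusion_counts(mask, bundle.truth_mask))
print(m.f_score, m.mcc)

res = ph.compute_pcc(bundle.image, mask)                   # density surrogate
print(res.pcc, res.n_blobs)
```

## Worked example (CLI)

Everything below is real output of the installed package. Generate a
synthetic 384×384 field with three cells (halo widths 10–20 px), segment it,
and score the mask against the exact ground truth:

```bash
$ cat spec.json
{"shape": [384, 384], "n_cells": 3, "radius_range": [25, 35], "halo_width_range": [10, 20]}
$ phantast phantom --spec spec.json --seed 12 -o field
wrote phantom with 3 cells to field
$ phantast segment field/image.tif -o field/mask.png --sigma 2.5 --aratio 0.85
threshold: 19122 cell px
fill_holes: 19122 cell px
remove_small_objects: 19122 cell px
halo_correction: 9462 cell px
segmented image.tif in 0.18 s
wrote field/mask.png
```

The halo flank makes up half of the thresholded mask (19 122 → 9 462 px).
Scoring against ground truth (directories of name-matched masks):

```bash
$ phantast evaluate pred truth -o scores.csv && cat scores.csv
image,accuracy,precision,recall,f_score,mcc,seg_error
field.png,0.9923434787326388,0.8806806172056648,1.0,0.9365552121382411,0.9346302944485646,0.0653697055514354
```

Morphometry of the mask (border-touching objects excluded; the three large
objects are the planted cells — the tracker also strands a few 1–5 px halo
shards, which a downstream area filter removes):

```bash
$ phantast morpho field/mask.png -o morpho.csv && head -5 morpho.csv
# perimeter_estimator=chain8(axial=1, diagonal=sqrt2)
label,area_px,perimeter_px,solidity,form_factor
1,2825,236.14927829866778,0.9812434873219869,0.6365830502650258
2,1,4.0,1.0,0.7853981633974483
3,2741,217.4213562373099,0.9913200723327306,0.7286424993339088
```

Packing-corrected confluency and the augmented fluorescence image (this
phantom plants one cell at each expression level 0.05 / 0.15 / 0.5, so about
two thirds of the cell pixels are GFP-positive):

```bash
$ phantast pcc field/image.tif --mask field/mask.png -o pcc.csv && cat pcc.csv
image,confluency,mean_blob_distance_px,n_blobs,pcc_per_px
image.tif,0.06416829427083333,122.56715091854883,4,0.0005235358233420628
$ phantast afi field/image.tif field/fluor.tif --mask field/mask.png -o afi.png --summary afi.csv && cat afi.csv
image,fraction_positive,mean_intensity,confluency,n_cell_pixels,defined
image.tif,0.6286197421264004,0.21574108410367446,0.06416829427083333,9462,True
```

Other subcommands: `confluency` (directory of masks → per-image CSV with a
culture summary row), `halo-correct` (standalone halo removal),
`calibrate` (PCC → density line fit), `tune` (LOOCV grid search).

## Reproduction

Two fixed protocols exercise the pipeline end to end on synthetic data
(`phantast.suites`); the test suite asserts their acceptance bounds and
`scripts/acceptance.py` recomputes and reports the headline numbers:

```bash
pytest -q                                           # 89 tests, ~25 s
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

With `--seed 1` the script prints (values recomputed at run time; `n` is the
sample size behind each value):

| quantity | value | n |
|---|---|---|
| survey_combined_variability_pct | 11.68 | 2 |
| overall_confluency_precision_pct | 3.21 | 2 |
| phantom_mean_f_score | 0.932 | 20 |
| phantom_min_f_score | 0.867 | 20 |
| phantom_mean_pixel_precision_halo_corrected | 0.874 | 20 |
| phantom_mean_pixel_precision_uncorrected | 0.432 | 20 |
| phantom_mean_mcc | 0.930 | 20 |
| pcc_density_adjusted_r2 | 0.991 | 12 |
| pcc_rotating_calibration_mean_nrmse_pct | 3.86 | 3 |
| pcc_rotating_calibration_max_nrmse_pct | 4.29 | 3 |
| local_contrast_oracle_max_abs_dev | 3.7e-15 | 10 |
| centroid_distance_oracle_max_abs_dev | 0.0 | 5 |

Halo correction roughly doubles the mean pixel precision on the phantom
suite (0.43 → 0.87) while keeping recall near 1, and the PCC–density
relation is linear (adjusted r² 0.99) with cross-culture calibration errors
under 5 % NRMSE. All randomness derives from `--seed`; the protocol seeds
used by the tests are fixed (suite seed 0, density seed 1).

## Package layout

| module | contents |
|---|---|
| `phantast.image_io` | TIFF/PNG loading, bit-depth normalization, RGB→luminance |
| `phantast.segmentation` | local contrast, thresholding, mask cleanup, `segment` |
| `phantast.halo` | Kirsch direction maps, gradient-tracking halo correction |
| `phantast.features` | confluency, chain perimeter, solidity, form factor |
| `phantast.density` | BIF classifier, PCC, linear density calibration |
| `phantast.afi` | augmented fluorescence images |
| `phantast.evaluation` | confusion metrics, precision statistics, LOOCV tuning |
| `phantast.phantoms` | synthetic PCM generator with exact ground truth |
| `phantast.suites` | the two fixed evaluation protocols |
| `phantast.cli` | `phantast` command-line interface |
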