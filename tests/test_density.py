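import numpy as np
import pytest

from phantast.density import (
    BIFClass,
    bif_classify,
    blob_centroids,
    calibrate_density,
    compute_pcc,
    mean_centroid_distance,
    pcc,
    rotating_calibration,
)


def gaussian_spot(shape=(65, 65), sigma=6.0, center=None):
    rows, cols = shape
    cr, cc = center if center else (rows // 2, cols // 2)
    yy, xx = np.mgrid[:rows, :cols]
    return np.exp(-((yy - cr) ** 2 + (xx - cc) ** 2) / (2 * sigma**2))


def test_bif_detects_blob_polarity():
    spot = gaussian_spot()
    bright = bif_classify(spot, sigma_bif=4.0)
    dark = bif_classify(-spot, sigma_bif=4.0)
    assert BIFClass(bright.classes[32, 32]) == BIFClass.BRIGHT_BLOB
    assert BIFClass(dark.classes[32, 32]) == BIFClass.DARK_BLOB


def test_zero_flatness_threshold_yields_no_flat_pixels(rng):
    img = rng.uniform(0, 1, size=(48, 48))
    b = bif_classify(img, sigma_bif=4.0, eps_flat=0.0)
    assert np.count_nonzero(b.classes == int(BIFClass.FLAT)) == 0


def test_large_flatness_threshold_flattens_everything():
    b = bif_classify(np.full((32, 32), 0.5), sigma_bif=4.0, eps_flat=10.0)
    assert np.all(b.classes == int(BIFClass.FLAT))


def test_bif_offset_invariance_on_structured_features():
    # with eps_flat = 0 only derivative responses contribute, so adding a
    # constant must not change the class wherever scores are not in a
    # near-exact tie; test it at the unambiguous blob cores
    spot = gaussian_spot()
    core = gaussian_spot(sigma=20.0) > 0.995  # pixels at the blob center
    a = bif_classify(spot, sigma_bif=4.0, eps_flat=0.0).classes
    b = bif_classify(spot + 5.0, sigma_bif=4.0, eps_flat=0.0).classes
    assert np.array_equal(a[core], b[core])
    assert np.all(a[core] == int(BIFClass.BRIGHT_BLOB))


def test_blob_centroids_recover_planted_spots_and_respect_mask():
    img = gaussian_spot((80, 80), 4.0, (20, 20)) + gaussian_spot((80, 80), 4.0, (60, 55))
    bif = bif_classify(img, sigma_bif=4.0)
    cents = blob_centroids(bif)
    assert len(cents) == 2
    found = sorted(cents)
    assert abs(found[0][0] - 20) <= 1 and abs(found[0][1] - 20) <= 1
    assert abs(found[1][0] - 60) <= 1 and abs(found[1][1] - 55) <= 1
    # a mask covering only the first spot discards the other centroid
    mask = np.zeros((80, 80), dtype=bool)
    mask[:40, :40] = True
    assert len(blob_centroids(bif, cell_mask=mask)) == 1


def test_mean_centroid_distance_hand_case():
    # single centroid at (0, 0) on a 1x3 image: distances 0, 1, 2
    assert mean_centroid_distance([(0, 0)], (1, 3)) == pytest.approx(1.0)
    with pytest.raises(ValueError):
        mean_centroid_distance([], (4, 4))
    # restricting the average to a mask changes the support
    within = np.zeros((1, 3), dtype=bool)
    within[0, 2] = True
    assert mean_centroid_distance([(0, 0)], (1, 3), within=within) == pytest.approx(2.0)
    with pytest.raises(ValueError):
        mean_centroid_distance([(0, 0)], (1, 3), within=np.zeros((1, 3), bool))


def test_pcc_definition_and_guards():
    assert pcc(0.5, 2.0) == 0.25
    with pytest.raises(ValueError):
        pcc(0.5, 0.0)


def test_compute_pcc_on_phantom(small_bundle):
    res = compute_pcc(small_bundle.image, small_bundle.truth_mask)
    assert res.n_blobs >= len(small_bundle.centers)
    assert res.confluency == pytest.approx(small_bundle.truth_mask.mean())
    assert res.pcc == pytest.approx(res.confluency / res.mean_blob_distance)
    restricted = compute_pcc(
        small_bundle.image, small_bundle.truth_mask, within_cells=True
    )
    # averaging over cell pixels only cannot use the far-field distances
    assert restricted.mean_blob_distance < res.mean_blob_distance


def test_calibration_recovers_exact_line():
    x = np.array([0.1, 0.2, 0.3, 0.4])
    y = 50.0 * x + 7.0
    model = calibrate_density(x, y)
    assert model.slope == pytest.approx(50.0)
    assert model.intercept == pytest.approx(7.0)
    assert model.adj_r2 == pytest.approx(1.0)
    assert model.nrmse == pytest.approx(0.0, abs=1e-12)
    assert model.predict([0.5])[0] == pytest.approx(32.0)


def test_calibration_validation():
    with pytest.raises(ValueError):
        calibrate_density([0.1, 0.2], [1, 2])
    with pytest.raises(ValueError):
        calibrate_density([0.1, 0.1, 0.1], [1, 2, 3])
    model = calibrate_density([0.1, 0.2, 0.3], [1.0, 2.0, 3.0])
    with pytest.raises(ValueError):
        model.evaluate_nrmse([0.1, 0.2], [5.0, 5.0])  # zero density range


def test_rotating_calibration_on_identical_cultures():
    culture = ([0.1, 0.2, 0.3, 0.4], [10.0, 20.0, 30.0, 40.0])
    out = rotating_calibration([culture, culture, culture])
    assert len(out) == 3
    assert max(out) == pytest.approx(0.0, abs=1e-9)
    with pytest.raises(ValueError):
        rotating_calibration([culture])
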