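import numpy as np
import pytest

from phantast.evaluation import (
    ConfusionCounts,
    combine_precision,
    confusion_counts,
    estimation_precision,
    grid_search_params,
    roc_metrics,
    survey_stats,
)


def test_confusion_counts_hand_case():
    pred = np.array([[1, 1, 0], [0, 1, 0]], dtype=bool)
    truth = np.array([[1, 0, 0], [1, 1, 0]], dtype=bool)
    c = confusion_counts(pred, truth)
    assert (c.tp, c.fp, c.tn, c.fn) == (2, 1, 2, 1)
    assert c.total == pred.size
    with pytest.raises(ValueError):
        confusion_counts(pred, truth.T)


def test_metrics_frozen_hand_values():
    m = roc_metrics(ConfusionCounts(tp=40, fp=10, tn=45, fn=5))
    assert m.f_score == pytest.approx(0.8421052631578947)
    assert m.mcc == pytest.approx(0.7035264706814484)
    assert m.seg_error == pytest.approx(1.0 - 0.7035264706814484)
    assert m.accuracy == pytest.approx(0.85)
    assert m.precision == pytest.approx(0.8)
    assert m.recall == pytest.approx(8 / 9)


def test_metrics_extreme_agreement():
    perfect = roc_metrics(ConfusionCounts(tp=30, fp=0, tn=70, fn=0))
    assert perfect.mcc == 1.0 and perfect.f_score == 1.0
    inverted = roc_metrics(ConfusionCounts(tp=0, fp=70, tn=0, fn=30))
    assert inverted.mcc == -1.0
    # degenerate marginals fall back to 0, never raise
    empty = roc_metrics(ConfusionCounts(tp=0, fp=0, tn=100, fn=0))
    assert empty.mcc == 0.0 and empty.f_score == 0.0 and empty.accuracy == 1.0


def test_estimation_precision_decomposition(rng):
    truths = rng.uniform(0, 100, size=50)
    estimates = truths + rng.normal(3.0, 2.0, size=50)
    s = estimation_precision(estimates, truths)
    assert s.rmse**2 == pytest.approx(s.bias**2 + s.precision**2)
    # pure offset: all error is bias
    s2 = estimation_precision(truths + 5.0, truths)
    assert s2.bias == pytest.approx(5.0)
    assert s2.precision == pytest.approx(0.0, abs=1e-9)
    with pytest.raises(ValueError):
        estimation_precision([1.0], [1.0])


def test_survey_stats_hand_case():
    # two raters per image deviating +/-2 from the image mean: pooled SD
    # about the means is sqrt(2 * 4 * m / (m * 1)) = 2*sqrt(2)
    e = np.array([[48.0, 52.0], [18.0, 22.0], [68.0, 72.0]])
    pairs = [(50.0, 52.0), (30.0, 28.0)]  # sum d^2 = 8, v_intra = sqrt(8/4)
    s = survey_stats(e, pairs)
    assert s.v_both == pytest.approx(2 * np.sqrt(2))
    assert s.v_intra == pytest.approx(np.sqrt(2))
    assert s.v_inter == pytest.approx(np.sqrt(8 - 2))
    # quadrature closure
    assert s.v_both**2 == pytest.approx(s.v_intra**2 + s.v_inter**2)


def test_survey_inter_rater_clamped_at_zero():
    e = np.array([[50.0, 50.1], [20.0, 20.1]])
    pairs = [(40.0, 60.0)]  # huge intra-rater spread
    s = survey_stats(e, pairs)
    assert s.v_inter == 0.0


def test_survey_validation():
    with pytest.raises(ValueError):
        survey_stats(np.array([[1.0], [2.0]]), [(1.0, 2.0)])
    with pytest.raises(ValueError):
        survey_stats(np.array([[1.0, 2.0]]), [(1.0, 2.0)])
    with pytest.raises(ValueError):
        survey_stats(np.array([[1.0, 2.0], [3.0, 4.0]]), [])


def test_combine_precision_quadrature():
    assert combine_precision([3.0, 4.0]) == pytest.approx(5.0)
    assert combine_precision([]) == 0.0
    with pytest.raises(ValueError):
        combine_precision([1.0, -2.0])


def test_grid_search_prefers_sensible_threshold():
    from phantast.phantoms import PhantomSpec, generate_phantom
    from phantast.segmentation import SegmentationParams

    specs = [
        PhantomSpec(
            shape=(128, 128),
            n_cells=1,
            radius_range=(14.0, 18.0),
            halo_width_range=(6.0, 9.0),
            seed=s,
        )
        for s in (11, 22, 33)
    ]
    bundles = [generate_phantom(s) for s in specs]
    images = [b.image for b in bundles]
    truths = [b.truth_mask for b in bundles]
    base = SegmentationParams(sigma=2.0, a_ratio=0.85, f_max=100, r_max=100)
    grid = {"epsilon": [0.03, 5.0]}  # 5.0 leaves an empty mask
    best, loocv_err, details = grid_search_params(images, truths, grid, base)
    assert best.epsilon == 0.03
    assert 0.0 <= loocv_err < 0.5
    assert details["errors"].shape == (2, 3)
    # an absurd threshold scores maximally badly (MCC 0 -> error 1)
    assert details["mean_errors"][details["points"].index({"epsilon": 5.0})] == pytest.approx(1.0)
    with pytest.raises(ValueError):
        grid_search_params(images, truths, {})
    with pytest.raises(ValueError):
        grid_search_params(images, truths[:2], grid)
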