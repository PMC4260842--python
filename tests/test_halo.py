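import numpy as np
import pytest

from phantast.halo import (
    COMPASS,
    STEPS,
    boundary_pixels,
    correct_halo,
    kirsch_direction_map,
    kirsch_kernels,
)

NORTH = np.array([[5, 5, 5], [-3, 0, -3], [-3, -3, -3]], dtype=float)
EAST = np.array([[-3, -3, 5], [-3, 0, 5], [-3, -3, 5]], dtype=float)


def test_kirsch_kernel_bank_layout():
    k = kirsch_kernels()
    assert k.shape == (8, 3, 3)
    assert np.array_equal(k[COMPASS.index("N")], NORTH)
    assert np.array_equal(k[COMPASS.index("E")], EAST)
    # each kernel: three 5s, five -3s, zero center, zero sum
    for d in range(8):
        assert k[d, 1, 1] == 0.0
        assert np.count_nonzero(k[d] == 5.0) == 3
        assert np.count_nonzero(k[d] == -3.0) == 5
        assert k[d].sum() == 0.0
    # S is N flipped vertically, W is E flipped horizontally
    assert np.array_equal(k[COMPASS.index("S")], NORTH[::-1, :])
    assert np.array_equal(k[COMPASS.index("W")], EAST[:, ::-1])


def test_directions_point_toward_brighter_side():
    ramp = np.tile(np.arange(12.0), (12, 1))  # brightens to the East
    dirs = kirsch_direction_map(ramp).directions
    assert np.all(dirs[1:-1, 1:-1] == COMPASS.index("E"))
    dirs_w = kirsch_direction_map(ramp[:, ::-1]).directions
    assert np.all(dirs_w[1:-1, 1:-1] == COMPASS.index("W"))


def test_constant_image_ties_resolve_to_north():
    dirs = kirsch_direction_map(np.full((6, 6), 0.3)).directions
    assert np.all(dirs == 0)


def test_rotating_the_image_rotates_the_direction_field(rng):
    img = rng.uniform(0, 1, size=(20, 20))
    d0 = kirsch_direction_map(img).directions
    d90 = kirsch_direction_map(np.rot90(img)).directions
    # rot90 is a 90-degree CCW rotation: E (2) becomes N (0), etc.
    expected = np.rot90((d0 - 2) % 8)
    interior = np.s_[2:-2, 2:-2]
    assert np.array_equal(d90[interior], expected[interior])


def test_step_vectors_match_compass():
    assert tuple(STEPS[COMPASS.index("N")]) == (-1, 0)
    assert tuple(STEPS[COMPASS.index("SE")]) == (1, 1)
    # all eight are distinct king moves
    assert len({tuple(s) for s in STEPS}) == 8


def test_boundary_pixels_of_a_square():
    mask = np.zeros((9, 9), dtype=bool)
    mask[2:7, 2:7] = True
    b = boundary_pixels(mask)
    inner = np.zeros_like(mask)
    inner[3:6, 3:6] = True
    assert np.array_equal(b, mask & ~inner)
    # mask touching the image border: border pixels are boundary
    edge = np.zeros((5, 5), dtype=bool)
    edge[0:3, 0:3] = True
    assert boundary_pixels(edge)[0, 0]


def test_halo_output_is_subset_and_zero_cap_is_identity(small_bundle):
    img = small_bundle.image
    mask = img > np.quantile(img, 0.7)
    out = correct_halo(mask, image=img, a_ratio=0.6)
    assert not np.any(out & ~mask)
    assert np.array_equal(correct_halo(mask, image=img, a_ratio=0.0), mask)


def test_constant_interior_object_hits_the_cap_exactly():
    # 21x21 square on a constant image: no interface exists, so removal
    # runs until the per-object budget floor(a_ratio * area) is exhausted.
    mask = np.zeros((31, 31), dtype=bool)
    mask[5:26, 5:26] = True
    out = correct_halo(mask, image=np.ones((31, 31)), a_ratio=0.5)
    assert int(mask.sum() - out.sum()) == int(0.5 * 441)  # 220


def test_per_object_budget_respected_on_random_masks(rng):
    from scipy import ndimage

    for _ in range(5):
        blob = ndimage.gaussian_filter(rng.normal(size=(64, 64)), 3.0) > 0.12
        img = rng.uniform(0, 1, size=blob.shape)
        a_ratio = float(rng.uniform(0.2, 0.9))
        out = correct_halo(blob, image=img, a_ratio=a_ratio)
        labels, n = ndimage.label(blob, structure=np.ones((3, 3), bool))
        for lab in range(1, n + 1):
            obj = labels == lab
            removed = int(np.count_nonzero(obj & ~out))
            assert removed <= a_ratio * obj.sum() + 1e-9


def test_halo_input_validation():
    mask = np.zeros((4, 4), dtype=bool)
    with pytest.raises(ValueError):
        correct_halo(mask)  # neither image nor directions
    with pytest.raises(ValueError):
        correct_halo(mask, directions=np.zeros((3, 3), dtype=np.uint8))
    with pytest.raises(ValueError):
        correct_halo(mask, image=np.zeros((4, 4)), a_ratio=2.0)
    with pytest.raises(ValueError):
        kirsch_direction_map(np.zeros((4, 4)), smooth_sigma=-1.0)
    with pytest.raises(ValueError):
        kirsch_direction_map(np.zeros(4))
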