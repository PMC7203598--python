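"""Image I/O, calibration, histogram segmentation and alignment."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import osteoadapt as oa
from osteoadapt.image import GreyHistogram, _translate

from conftest import small_spec


# ---------------------------------------------------------------------------
# I/O round trips
# ---------------------------------------------------------------------------


@pytest.mark.parametrize("ext", ["mhd", "nii", "tif"])
def test_write_read_round_trip(tmp_path, ext):
    rng = np.random.default_rng(0)
    img = oa.VoxelImage(np.round(rng.uniform(0, 4000, (5, 6, 7))), spacing=10.4)
    path = tmp_path / f"vol.{ext}"
    oa.write_image(img, path)
    back = oa.read_image(path, spacing=10.4 if ext == "tif" else None)
    np.testing.assert_array_equal(back.data, img.data)
    assert back.spacing == pytest.approx(10.4)


def test_cross_format_round_trip(tmp_path):
    """The same phantom written as TIFF stack and as MHD reads back voxelwise equal."""
    img = oa.make_phantom(small_spec())
    oa.write_image(img, tmp_path / "p.mhd")
    oa.write_image(img, tmp_path / "p.tif")
    a = oa.read_image(tmp_path / "p.mhd")
    b = oa.read_image(tmp_path / "p.tif", spacing=img.spacing)
    np.testing.assert_array_equal(a.data, b.data)


def test_tiff_without_spacing_errors(tmp_path):
    img = oa.VoxelImage(np.zeros((3, 3, 3)), spacing=10.4)
    oa.write_image(img, tmp_path / "v.tif")
    with pytest.raises(IOError):
        oa.read_image(tmp_path / "v.tif")


def test_missing_file_errors(tmp_path):
    with pytest.raises(IOError):
        oa.read_image(tmp_path / "nope.mhd")


# ---------------------------------------------------------------------------
# Densitometric calibration
# ---------------------------------------------------------------------------


def test_identity_calibration_is_identity():
    img = oa.VoxelImage(np.arange(27.0).reshape(3, 3, 3), spacing=1)
    cal = oa.DensitometricCalibration(slope=1.0, intercept=0.0)
    np.testing.assert_array_equal(cal.grey_to_tmd(img).data, img.data)


def test_calibration_intercept_at_origin():
    img = oa.VoxelImage(np.zeros((2, 2, 2)), spacing=1)
    cal = oa.DensitometricCalibration(slope=0.7, intercept=-15.0)
    assert cal.grey_to_tmd(img).data.flat[0] == pytest.approx(-15.0)


@settings(derandomize=True, max_examples=25)
@given(slope=st.floats(0.05, 10), intercept=st.floats(-200, 200), seed=st.integers(0, 100))
def test_calibration_round_trip(slope, intercept, seed):
    rng = np.random.default_rng(seed)
    img = oa.VoxelImage(rng.uniform(0, 4000, (4, 4, 4)), spacing=10.4)
    cal = oa.DensitometricCalibration(slope=slope, intercept=intercept)
    back = cal.tmd_to_grey(cal.grey_to_tmd(img))
    assert np.abs(back.data - img.data).max() < 1e-9 * np.ptp(img.data)


# ---------------------------------------------------------------------------
# Thresholding
# ---------------------------------------------------------------------------


def _delta_histogram(a, b, n=1000):
    counts = np.zeros(301)
    counts[a] = n
    counts[b] = n
    edges = np.arange(302) - 0.5
    return GreyHistogram(edges, counts)


def test_threshold_of_two_delta_peaks():
    hist = _delta_histogram(100, 300)
    assert oa.compute_threshold(hist) == pytest.approx(200.0)


def test_threshold_invariant_under_count_rescaling():
    hist = _delta_histogram(100, 300)
    scaled = GreyHistogram(hist.edges, hist.counts * 7.3)
    assert oa.compute_threshold(scaled) == oa.compute_threshold(hist)


def test_threshold_two_gaussian_mixture():
    """Threshold lands within one bin width of the midpoint of the modes of
    a realistic background/bone grey-value mixture (exhaustive-scan oracle:
    the histogram argmax in each half locates the component modes)."""
    rng = np.random.default_rng(0)
    n = 1_000_000
    n_bone = int(0.15 * n)
    values = np.concatenate([
        rng.normal(200.0, 40.0, n - n_bone),
        rng.normal(1800.0, 90.0, n_bone),
    ])
    img = oa.VoxelImage(values.reshape(100, 100, 100), spacing=10.4)
    hist = GreyHistogram.from_image(img)
    thr = oa.compute_threshold(hist)
    assert abs(thr - 1000.0) <= hist.bin_width


def test_flat_histogram_errors():
    hist = GreyHistogram(np.arange(11.0), np.full(10, 5.0))
    with pytest.raises(oa.SegmentationError):
        oa.compute_threshold(hist)


def test_unimodal_histogram_errors():
    rng = np.random.default_rng(1)
    img = oa.VoxelImage(rng.normal(500, 30, (20, 20, 20)), spacing=1)
    with pytest.raises(oa.SegmentationError):
        oa.compute_threshold(GreyHistogram.from_image(img))


# ---------------------------------------------------------------------------
# Transition zone
# ---------------------------------------------------------------------------


def _brute_force_tz(counts, t):
    """Independent outward scan for the nearest bins with >= 2x the
    threshold-bin count."""
    lo = next((i for i in range(t - 1, -1, -1) if counts[i] >= 2 * counts[t]), 0)
    hi = next((i for i in range(t + 1, len(counts)) if counts[i] >= 2 * counts[t]),
              len(counts) - 1)
    return lo, hi


@pytest.mark.parametrize("counts,t", [
    ([80, 40, 20, 10, 15, 25, 50], 3),
    ([100, 60, 30, 10, 12, 15, 18, 22, 60], 3),
    ([5, 10, 20, 4, 9, 18, 36], 3),  # monotone on both sides
])
def test_transition_zone_matches_brute_force(counts, t):
    counts = np.asarray(counts, dtype=float)
    edges = np.arange(len(counts) + 1.0)
    hist = GreyHistogram(edges, counts)
    lo, hi = _brute_force_tz(counts, t)
    tz_low, tz_high = oa.compute_transition_zone(hist, hist.centers[t])
    assert tz_low == pytest.approx(hist.centers[lo])
    assert tz_high == pytest.approx(hist.centers[hi])


def test_transition_zone_zero_count_threshold_bin():
    counts = np.array([50.0, 0.0, 0.0, 0.0, 50.0])
    hist = GreyHistogram(np.arange(6.0), counts)
    tz_low, tz_high = oa.compute_transition_zone(hist, hist.centers[2])
    assert tz_low == pytest.approx(hist.centers[1])
    assert tz_high == pytest.approx(hist.centers[3])


def test_transition_zone_clips_at_extremes_with_warning():
    counts = np.array([1.0, 2.0, 10.0, 2.0, 1.0])
    hist = GreyHistogram(np.arange(6.0), counts)
    with pytest.warns(UserWarning):
        tz_low, tz_high = oa.compute_transition_zone(hist, hist.centers[2])
    assert tz_low == pytest.approx(hist.centers[0])
    assert tz_high == pytest.approx(hist.centers[-1])


# ---------------------------------------------------------------------------
# Binarisation and masks
# ---------------------------------------------------------------------------


def test_binarise_strict_inequality():
    img = oa.VoxelImage(np.array([[[1.0, 2.0, 3.0]]]), spacing=1)
    mask = oa.binarise(img, 2.0)
    assert mask.data.tolist() == [[[False, False, True]]]


def test_binarise_all_below_gives_empty_mask():
    img = oa.VoxelImage(np.zeros((3, 3, 3)), spacing=1)
    assert oa.binarise(img, 1.0).count() == 0


def test_binarise_affine_monotonicity(small_phantom, small_seg, cal):
    """Binarising after grey->TMD with the mapped threshold gives the same mask."""
    tmd = cal.grey_to_tmd(small_phantom)
    a = oa.binarise(small_phantom, small_seg.threshold)
    b = oa.binarise(tmd, cal.value_to_tmd(small_seg.threshold))
    np.testing.assert_array_equal(a.data, b.data)


def test_phantom_mask_count_matches_geometric_oracle():
    spec = small_spec(seed=3)
    img = oa.make_phantom(oa.PhantomSpec(**{**spec.__dict__, "blur_sigma": 0.0,
                                            "bone_sigma": 0.0, "bg_sigma": 0.0}))
    mask = oa.binarise(img, 1000.0)
    assert mask.count() == oa.geometric_mask(spec).count()


def test_largest_component_keeps_biggest():
    data = np.zeros((10, 5, 5), dtype=bool)
    data[:4] = True  # 100 voxels
    data[7, 2, 2] = True
    data[9, 0, 0] = True
    mask = oa.BoneMask(data, 10.4)
    kept = oa.largest_component(mask)
    assert kept.count() == 100
    assert not kept.data[7, 2, 2]


def test_largest_component_single_component_unchanged(tube_mask):
    np.testing.assert_array_equal(oa.largest_component(tube_mask).data, tube_mask.data)


def test_largest_component_empty_errors():
    with pytest.raises(ValueError):
        oa.largest_component(oa.BoneMask(np.zeros((2, 2, 2), dtype=bool), 1))


# ---------------------------------------------------------------------------
# Cropping and alignment
# ---------------------------------------------------------------------------


def test_crop_fraction_slice_count():
    data = np.zeros((4, 4, 120))
    data[:, :, 10:110] = 50.0  # 100 occupied slices
    img = oa.VoxelImage(data, spacing=10.4)
    out = oa.crop_longitudinal_fraction(img, 0.8, "proximal", threshold=10.0)
    assert out.shape[2] == 80
    # proximal = max z: retained window ends at the last occupied slice
    assert (out.data[:, :, -1] > 10).all()


def test_crop_fraction_one_keeps_occupied_extent():
    data = np.zeros((4, 4, 50))
    data[:, :, 5:45] = 50.0
    img = oa.VoxelImage(data, spacing=10.4)
    out = oa.crop_longitudinal_fraction(img, 1.0, threshold=10.0)
    assert out.shape[2] == 40


def test_crop_fraction_out_of_range_errors():
    img = oa.VoxelImage(np.ones((2, 2, 2)), spacing=1)
    with pytest.raises(ValueError):
        oa.crop_longitudinal_fraction(img, 1.5)


def test_align_recovers_integer_shift(small_phantom, small_seg):
    # pad in z so the translation does not push bone off the grid
    padded = small_phantom.with_data(
        np.pad(small_phantom.data, ((0, 0), (0, 0), (8, 8))))
    shift = np.array([3, -2, 5])
    moved = padded.with_data(_translate(padded.data, shift))
    ref, mov, rec = oa.align_for_comparison(padded, moved, small_seg.threshold)
    assert tuple(rec) == (-3, 2, -5)
    assert ref.shape == mov.shape
    a = ref.data > small_seg.threshold
    b = mov.data > small_seg.threshold
    assert oa.overlap_ratio(oa.BoneMask(a, 10.4), oa.BoneMask(b, 10.4)) == 1.0


def test_align_is_idempotent(small_phantom, small_seg):
    ref, mov, rec = oa.align_for_comparison(small_phantom, small_phantom,
                                            small_seg.threshold)
    assert tuple(rec) == (0, 0, 0)
    np.testing.assert_array_equal(ref.data, mov.data)


def test_align_empty_mask_errors(small_phantom):
    empty = small_phantom.with_data(np.zeros(small_phantom.shape))
    with pytest.raises(ValueError):
        oa.align_for_comparison(small_phantom, empty, 1000.0)
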