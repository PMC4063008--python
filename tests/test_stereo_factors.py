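import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays
from scipy.ndimage import gaussian_filter

from foveastrain.errors import ChannelError, ShapeError, ZeroImage
from foveastrain.foveation import FoveationPoint, WaveletMask, build_mask
from foveastrain.gaze import FoveationGeometry
from foveastrain.stereo_factors import (
    DisparityMap,
    StereoPair,
    compute_csd,
    compute_disparity,
    compute_ec,
    compute_fce,
    compute_sd,
    gradient_magnitude,
    normalize_brightness,
    split_anaglyph,
)

GEOM = FoveationGeometry(N=64, v=3.0, e=1.12)


def make_texture(shape=(64, 96), seed=7):
    rng = np.random.default_rng(seed)
    tex = gaussian_filter(rng.normal(scale=60, size=shape) + 128, 1.0)
    return np.clip(tex, 0, 255)


def unit_mask(shape):
    pt = FoveationPoint(xf=(shape[1] / 2, shape[0] / 2),
                        xcf=(shape[1] / 2, shape[0] / 2), tmsm=0.0)
    m = build_mask(shape, pt, GEOM)
    return WaveletMask(weights={k: np.ones_like(v) for k, v in m.weights.items()},
                       geometry=m.geometry, point=m.point, levels=m.levels,
                       order=m.order, shape=m.shape, padded_shape=m.padded_shape)


class TestSplitAnaglyph:
    def test_pure_red(self):
        frame = np.zeros((16, 16, 3), dtype=np.uint8)
        frame[..., 0] = 255
        pair = split_anaglyph(frame)
        assert (pair.right == 255).all() and (pair.left == 0).all()

    def test_pure_green(self):
        frame = np.zeros((16, 16, 3), dtype=np.uint8)
        frame[..., 1] = 255
        pair = split_anaglyph(frame)
        assert (pair.left == 255).all() and (pair.right == 0).all()

    def test_gray_frame(self):
        frame = np.full((16, 16, 3), 120, dtype=np.uint8)
        pair = split_anaglyph(frame)
        np.testing.assert_array_equal(pair.left, pair.right)

    def test_non_rgb_raises(self):
        with pytest.raises(ChannelError):
            split_anaglyph(np.zeros((16, 16), dtype=np.uint8))


class TestNormalizeBrightness:
    def test_equal_means_unchanged(self, rng):
        img = rng.random((32, 32)) * 200
        pair = normalize_brightness(StereoPair(left=img, right=img.copy()))
        np.testing.assert_allclose(pair.right, img, atol=1e-9)

    def test_double_brightness_matched(self, rng):
        left = rng.random((32, 32)) * 100  # headroom: no clipping after /2
        pair = normalize_brightness(StereoPair(left=left, right=2 * left))
        np.testing.assert_allclose(pair.right, left, atol=1.0)
        assert abs(pair.left.mean() - pair.right.mean()) < 0.5

    def test_both_zero_noop(self):
        z = np.zeros((8, 8))
        pair = normalize_brightness(StereoPair(left=z, right=z.copy()))
        assert (pair.right == 0).all()

    def test_zero_right_raises(self):
        with pytest.raises(ZeroImage):
            normalize_brightness(StereoPair(left=np.full((8, 8), 100.0),
                                            right=np.zeros((8, 8))))


def sad_oracle(left, right, y, x, block, search_range):
    """Exhaustive per-pixel SAD: direct block loops, no vectorization."""
    h, w = left.shape
    half = block // 2
    best = (np.inf, None)
    for d in sorted(range(-search_range, search_range + 1), key=lambda q: (abs(q), q)):
        total = 0.0
        ok = True
        for dy in range(-half, half + 1):
            for dx in range(-half, half + 1):
                yy, xx = y + dy, x + dx
                if not (0 <= yy < h and 0 <= xx < w and 0 <= xx + d < w):
                    ok = False
                    break
                total += abs(left[yy, xx] - right[yy, xx + d])
            if not ok:
                break
        if ok and total < best[0] - 1e-9:
            best = (total, d)
    return best[1]


class TestComputeDisparity:
    def test_identical_pair_zero(self):
        tex = make_texture()
        dm = compute_disparity(StereoPair(left=tex, right=tex.copy()), 9, 16)
        assert (dm.values[dm.valid] == 0).all()
        assert dm.valid.any()

    def test_known_shift_modal(self):
        tex = make_texture()
        # right[x + 5] == left[x]
        dm = compute_disparity(StereoPair(left=tex, right=np.roll(tex, 5, axis=1)), 9, 16)
        vals, counts = np.unique(dm.values[dm.valid], return_counts=True)
        assert vals[np.argmax(counts)] == 5

    def test_flat_pair_resolves_to_zero(self):
        # uniform cost: the |d|-then-d tie-break keeps disparity 0 (documented)
        flat = np.full((32, 48), 90.0)
        dm = compute_disparity(StereoPair(left=flat, right=flat.copy()), 9, 8)
        assert (dm.values[dm.valid] == 0).all()

    def test_against_per_pixel_sad_oracle(self):
        tex = make_texture(shape=(24, 40), seed=3)
        right = np.roll(tex, 4, axis=1)
        dm = compute_disparity(StereoPair(left=tex, right=right), 5, 6)
        for y, x in [(12, 20), (10, 15), (15, 25)]:
            expect = sad_oracle(tex, right, y, x, 5, 6)
            if dm.valid[y, x]:
                assert dm.values[y, x] == expect

    @pytest.mark.parametrize("shift", range(1, 9))
    def test_shift_recovery_sweep(self, shift):
        tex = make_texture(seed=shift)
        dm = compute_disparity(
            StereoPair(left=tex, right=np.roll(tex, shift, axis=1)), 9, 16)
        vals, counts = np.unique(dm.values[dm.valid], return_counts=True)
        assert vals[np.argmax(counts)] == shift

    def test_parameter_validation(self):
        tex = make_texture()
        pair = StereoPair(left=tex, right=tex)
        with pytest.raises(ValueError):
            compute_disparity(pair, 4, 16)  # even block
        with pytest.raises(ValueError):
            compute_disparity(pair, 9, 0)


class TestComputeSd:
    def test_zero_map(self):
        shape = (32, 32)
        dm = DisparityMap(values=np.zeros(shape), valid=np.ones(shape, dtype=bool))
        assert compute_sd(dm, unit_mask(shape)) == 0.0

    def test_constant_map_unit_mask(self):
        shape = (16, 16)
        dm = DisparityMap(values=np.full(shape, 2.0), valid=np.ones(shape, dtype=bool))
        assert compute_sd(dm, unit_mask(shape)) == pytest.approx(512.0, abs=1e-6)

    def test_against_linear_operator_oracle(self):
        # apply_mask is linear; build its matrix column by column and compare
        shape = (16, 16)
        pt = FoveationPoint(xf=(8.0, 8.0), xcf=(8.0, 8.0), tmsm=0.0)
        mask = build_mask(shape, pt, GEOM, levels=2)
        from foveastrain.foveation import apply_mask
        dm_values = np.full(shape, 3.0)
        dm = DisparityMap(values=dm_values, valid=np.ones(shape, dtype=bool))
        cols = []
        for i in range(shape[0] * shape[1]):
            e = np.zeros(shape[0] * shape[1])
            e[i] = 1.0
            cols.append(apply_mask(e.reshape(shape), mask, clip=False).ravel())
        M = np.column_stack(cols)
        expected = float((M @ dm_values.ravel()).sum())
        got = float(apply_mask(np.abs(dm.filled(0.0)), mask, clip=False).sum())
        assert got == pytest.approx(expected, rel=1e-9)

    def test_shape_mismatch(self):
        dm = DisparityMap(values=np.zeros((16, 16)), valid=np.ones((16, 16), dtype=bool))
        with pytest.raises(ShapeError):
            compute_sd(dm, unit_mask((32, 32)))


class TestComputeCsd:
    def test_identical_zero(self, rng):
        a = rng.random((16, 16))
        assert compute_csd(a, a.copy()) == 0.0

    def test_plus_one_everywhere(self):
        a = np.zeros((10, 10))
        assert compute_csd(a, a + 1) == pytest.approx(100.0)

    def test_random_pair_oracle(self, rng):
        a, b = rng.random((16, 16)), rng.random((16, 16))
        expected = sum(abs(b[i, j] - a[i, j]) for i in range(16) for j in range(16))
        assert compute_csd(a, b) == pytest.approx(expected, rel=1e-12)

    @settings(max_examples=25, deadline=None)
    @given(arrays(np.float64, (4, 4), elements=st.floats(0, 255)),
           arrays(np.float64, (4, 4), elements=st.floats(0, 255)),
           arrays(np.float64, (4, 4), elements=st.floats(0, 255)))
    def test_triangle_inequality(self, a, b, c):
        assert compute_csd(a, c) <= compute_csd(a, b) + compute_csd(b, c) + 1e-9


class TestComputeFce:
    def test_paper_worked_examples(self):
        assert compute_fce(20, 1280) == 620.0
        assert compute_fce(1270, 1280) == 630.0

    def test_center_gaze_zero(self):
        assert compute_fce(640, 1280) == 0.0

    @settings(max_examples=50, deadline=None)
    @given(x=st.integers(0, 1279))
    def test_mirror_symmetry(self, x):
        assert compute_fce(x, 1280) == compute_fce(1280 - x, 1280)


class TestComputeEc:
    def test_two_constant_images_zero(self):
        a = np.full((32, 32), 128.0)
        assert compute_ec(a, a.copy()) == 0.0

    def test_single_step_edge(self):
        img = np.zeros((32, 32))
        img[:, 16:] = 200.0
        flat = np.full((32, 32), 100.0)
        ec = compute_ec(img, flat)
        # oracle: gradient magnitude summed over the canny edge pixels of img
        from skimage.feature import canny
        edges = canny(img / 255.0, sigma=1.0,
                      low_threshold=50 / 1020.0, high_threshold=150 / 1020.0)
        expected = float(gradient_magnitude(img)[edges].sum())
        assert ec == pytest.approx(expected)
        assert ec > 0

    def test_swap_symmetric(self, rng):
        a = np.clip(gaussian_filter(rng.normal(scale=80, size=(32, 32)) + 128, 1), 0, 255)
        b = np.clip(gaussian_filter(rng.normal(scale=80, size=(32, 32)) + 128, 1), 0, 255)
        assert compute_ec(a, b) == compute_ec(b, a)


def test_brightness_invariance_of_factors():
    # adding a constant to both channels before normalization leaves the
    # disparity stage unchanged (within clipping limits)
    tex = make_texture(shape=(32, 48), seed=11) * 0.5 + 30
    pair0 = normalize_brightness(StereoPair(left=tex, right=np.roll(tex, 3, axis=1)))
    shifted = tex + 20
    pair1 = normalize_brightness(
        StereoPair(left=shifted, right=np.roll(shifted, 3, axis=1)))
    d0 = compute_disparity(pair0, 9, 8)
    d1 = compute_disparity(pair1, 9, 8)
    m0 = d0.values[d0.valid & d1.valid]
    m1 = d1.values[d0.valid & d1.valid]
    assert (m0 == m1).mean() > 0.99
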