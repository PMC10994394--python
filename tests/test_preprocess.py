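"""Unit tests for silhouette extraction: grayscale, Otsu, morphology, smoothing."""

import numpy as np
import pytest

from syrdose import (
    GaussianParams,
    SynthScene,
    binarize,
    histogram,
    otsu_threshold,
    preprocess_pipeline,
    render,
    to_gray,
)
from syrdose.errors import (
    DegenerateImageError,
    EmptyInputError,
    InvalidGaussianError,
    ThresholdRangeError,
    UnsupportedImageError,
)
from syrdose.preprocess import (
    close_op,
    dilate,
    erode,
    fill_holes,
    gaussian_kernel,
    gaussian_smooth,
    open_op,
    structuring_element,
)

# ---------------------------------------------------------------- oracles


def brute_histogram(img):
    counts = np.zeros(256, dtype=int)
    for row in img:
        for v in row:
            counts[int(v)] += 1
    return counts


def brute_otsu(p):
    """Exhaustive scan of the between-class variance over every split.

    Ties (the curve is flat across empty gray levels) are broken toward
    the smallest k, with a small relative tolerance so that float jitter
    in the per-split sums cannot break an exact plateau.
    """
    L = len(p)
    i = np.arange(L)
    curve = []
    for k in range(L):
        w0 = p[:k].sum()
        w1 = 1.0 - w0
        if w0 <= 0 or w1 <= 0:
            curve.append(0.0)
            continue
        mu0 = (i[:k] * p[:k]).sum() / w0
        mu1 = (i[k:] * p[k:]).sum() / w1
        curve.append(w0 * w1 * (mu1 - mu0) ** 2)
    curve = np.array(curve)
    vmax = curve.max()
    best_k = int(np.argmax(curve >= vmax - 1e-12 * max(vmax, 1.0)))
    return best_k, curve


def brute_erode(b, se):
    """Min filter; outside the frame counts as foreground."""
    h, w = b.shape
    r = se.shape[0] // 2
    out = np.ones_like(b)
    for y in range(h):
        for x in range(w):
            for dy in range(-r, r + 1):
                for dx in range(-r, r + 1):
                    if se[dy + r, dx + r]:
                        yy, xx = y + dy, x + dx
                        if 0 <= yy < h and 0 <= xx < w and not b[yy, xx]:
                            out[y, x] = 0
    return out


def brute_dilate(b, se):
    """Max filter; outside the frame counts as background."""
    h, w = b.shape
    r = se.shape[0] // 2
    out = np.zeros_like(b)
    for y in range(h):
        for x in range(w):
            for dy in range(-r, r + 1):
                for dx in range(-r, r + 1):
                    if se[dy + r, dx + r]:
                        yy, xx = y + dy, x + dx
                        if 0 <= yy < h and 0 <= xx < w and b[yy, xx]:
                            out[y, x] = 1
    return out


def brute_fill(b):
    """Flood-fill the background from the border (4-connectivity)."""
    h, w = b.shape
    outside = np.zeros((h, w), dtype=bool)
    stack = [(y, x) for y in range(h) for x in (0, w - 1) if not b[y, x]]
    stack += [(y, x) for x in range(w) for y in (0, h - 1) if not b[y, x]]
    while stack:
        y, x = stack.pop()
        if outside[y, x] or b[y, x]:
            continue
        outside[y, x] = True
        for yy, xx in ((y - 1, x), (y + 1, x), (y, x - 1), (y, x + 1)):
            if 0 <= yy < h and 0 <= xx < w and not outside[yy, xx] and not b[yy, xx]:
                stack.append((yy, xx))
    return np.where(outside, 0, 1).astype(b.dtype)


def _reflect(i, n):
    while not 0 <= i < n:
        i = -1 - i if i < 0 else 2 * n - 1 - i
    return i


def brute_convolve(img, kernel):
    """Direct convolution with symmetric (edge-repeating) padding."""
    h, w = img.shape
    r = kernel.shape[0] // 2
    out = np.zeros((h, w))
    for y in range(h):
        for x in range(w):
            acc = 0.0
            for dy in range(-r, r + 1):
                for dx in range(-r, r + 1):
                    acc += kernel[r + dy, r + dx] * img[_reflect(y - dy, h), _reflect(x - dx, w)]
            out[y, x] = acc
    return out


# ---------------------------------------------------------------- to_gray


class TestToGray:
    def test_gray_passthrough(self):
        img = np.array([[3, 200], [0, 255]], dtype=np.uint8)
        assert np.array_equal(to_gray(img), img)

    def test_equal_channels_collapse(self):
        img = np.full((4, 5, 3), 77, dtype=np.uint8)
        assert np.array_equal(to_gray(img), np.full((4, 5), 77))

    def test_rec601_red_pixel(self):
        img = np.zeros((1, 1, 3), dtype=np.uint8)
        img[0, 0, 0] = 255
        assert to_gray(img)[0, 0] == 76  # round(0.299 * 255)

    def test_errors(self):
        with pytest.raises(EmptyInputError):
            to_gray(np.zeros((0, 3)))
        with pytest.raises(UnsupportedImageError):
            to_gray(np.zeros((4, 4, 2)))


# ---------------------------------------------------------------- histogram / Otsu


class TestHistogram:
    def test_two_level(self):
        h = histogram(np.array([[0, 0], [255, 255]], dtype=np.uint8))
        assert h.counts[0] == 2 and h.counts[255] == 2
        assert h.probabilities[0] == h.probabilities[255] == 0.5

    def test_constant(self):
        h = histogram(np.full((3, 3), 42, dtype=np.uint8))
        assert h.probabilities[42] == 1.0 and h.counts.sum() == 9

    def test_matches_per_pixel_tally(self, rng):
        img = rng.integers(0, 256, size=(8, 8)).astype(np.uint8)
        h = histogram(img)
        assert np.array_equal(h.counts, brute_histogram(img))
        assert h.probabilities.sum() == pytest.approx(1.0)


class TestOtsu:
    def test_two_delta_histogram(self):
        img = np.repeat([[50, 200]], 8, axis=0).astype(np.uint8)
        res = otsu_threshold(histogram(img))
        assert res.threshold == 51  # smallest maximizing k
        assert res.between_class_variance == pytest.approx(0.25 * 150**2)

    def test_degenerate(self):
        with pytest.raises(DegenerateImageError):
            otsu_threshold(histogram(np.full((4, 4), 9, dtype=np.uint8)))

    def test_matches_exhaustive_scan_on_toy_histograms(self, rng):
        for _ in range(25):
            p = rng.random(16)
            p /= p.sum()
            padded = np.zeros(256)
            padded[:16] = p
            from syrdose.preprocess import Histogram

            res = otsu_threshold(Histogram(counts=(padded * 1000).astype(int), probabilities=padded))
            k_ref, curve_ref = brute_otsu(padded)
            assert res.threshold == k_ref
            assert np.allclose(res.curve, curve_ref, atol=1e-12)

    def test_class_statistics_consistent(self, rng):
        img = rng.integers(0, 256, size=(32, 32)).astype(np.uint8)
        res = otsu_threshold(histogram(img))
        w0, w1 = res.class_weights
        m0, m1 = res.class_means
        assert w0 + w1 == pytest.approx(1.0)
        assert w0 * m0 + w1 * m1 == pytest.approx(img.mean(), abs=1e-9)
        # total variance decomposes into between- plus within-class parts
        v0, v1 = res.class_variances
        within = w0 * v0 + w1 * v1
        assert res.between_class_variance + within == pytest.approx(img.var(), rel=1e-9)

    def test_agrees_with_skimage_split(self, rng):
        skfilters = pytest.importorskip("skimage.filters")
        img = np.concatenate(
            [rng.normal(80, 10, 500), rng.normal(200, 12, 500)]
        ).clip(0, 255).astype(np.uint8).reshape(25, 40)
        ours = otsu_threshold(histogram(img)).threshold
        ref = skfilters.threshold_otsu(img)
        # skimage labels foreground as img > ref; our k splits at i < k
        assert np.array_equal(binarize(img, ours), (img > ref).astype(np.uint8))


class TestBinarize:
    def test_split(self):
        img = np.array([[100, 200], [50, 150]], dtype=np.uint8)
        assert np.array_equal(binarize(img, 128), [[0, 1], [0, 1]])

    def test_k_zero_is_all_background(self):
        img = np.arange(9, dtype=np.uint8).reshape(3, 3)
        assert binarize(img, 0).all()

    def test_out_of_range(self):
        with pytest.raises(ThresholdRangeError):
            binarize(np.zeros((2, 2), dtype=np.uint8), 256)

    def test_matches_per_pixel_rule(self, rng):
        img = rng.integers(0, 256, size=(6, 6)).astype(np.uint8)
        k = int(rng.integers(0, 256))
        b = binarize(img, k)
        for y in range(6):
            for x in range(6):
                assert b[y, x] == (0 if img[y, x] < k else 1)


# ---------------------------------------------------------------- morphology


class TestMorphology:
    se = structuring_element(3)

    def test_isolated_pixel_erodes_away(self):
        b = np.zeros((7, 7), dtype=np.uint8)
        b[3, 3] = 1
        assert erode(b, self.se).sum() == 0

    def test_dilate_empty_stays_empty(self):
        assert dilate(np.zeros((5, 5), dtype=np.uint8), self.se).sum() == 0

    def test_erode_dilate_match_sliding_window_oracle(self, rng):
        for _ in range(10):
            b = (rng.random((7, 7)) < 0.5).astype(np.uint8)
            assert np.array_equal(erode(b, self.se), brute_erode(b, self.se))
            assert np.array_equal(dilate(b, self.se), brute_dilate(b, self.se))

    def test_open_removes_speck_keeps_square(self):
        b = np.zeros((12, 12), dtype=np.uint8)
        b[2:7, 2:7] = 1
        b[10, 10] = 1
        out = open_op(b, self.se)
        assert out[10, 10] == 0
        assert np.array_equal(out[2:7, 2:7], np.ones((5, 5)))

    def test_close_bridges_one_pixel_gap(self):
        b = np.zeros((9, 11), dtype=np.uint8)
        b[2:7, 1:5] = 1
        b[2:7, 6:10] = 1
        out = close_op(b, self.se)
        assert out[2:7, 5].all()
        # and it matches the composition of the oracle primitives
        assert np.array_equal(out, brute_erode(brute_dilate(b, self.se), self.se))

    def test_laws_on_random_masks(self, rng):
        for _ in range(20):
            b = (rng.random((16, 16)) < rng.uniform(0.2, 0.8)).astype(np.uint8)
            opened = open_op(b, self.se)
            closed = close_op(b, self.se)
            assert np.array_equal(open_op(opened, self.se), opened)  # idempotent
            assert np.array_equal(close_op(closed, self.se), closed)
            assert (opened <= b).all()  # anti-extensive
            assert (closed >= b).all()  # extensive
            dual = 1 - open_op(1 - b, self.se)
            assert np.array_equal(closed, dual)  # duality


class TestFillHoles:
    def test_ring_becomes_solid(self):
        b = np.zeros((7, 7), dtype=np.uint8)
        b[1:6, 1:6] = 1
        b[2:5, 2:5] = 0
        assert np.array_equal(fill_holes(b)[1:6, 1:6], np.ones((5, 5)))

    def test_no_holes_unchanged(self):
        b = np.zeros((6, 6), dtype=np.uint8)
        b[2:5, 1:4] = 1
        assert np.array_equal(fill_holes(b), b)

    def test_matches_border_flood_oracle(self, rng):
        for _ in range(10):
            b = (rng.random((12, 12)) < 0.55).astype(np.uint8)
            assert np.array_equal(fill_holes(b), brute_fill(b))

    def test_monotone(self, rng):
        b = (rng.random((15, 15)) < 0.5).astype(np.uint8)
        assert (fill_holes(b) >= b).all()


# ---------------------------------------------------------------- Gaussian


class TestGaussian:
    def test_kernel_normalized_symmetric_peaked(self):
        k = gaussian_kernel(GaussianParams(sigma=1.3, size=7))
        assert k.sum() == pytest.approx(1.0)
        assert np.allclose(k, k[::-1, :]) and np.allclose(k, k[:, ::-1])
        assert k.max() == k[3, 3]

    def test_tiny_sigma_approaches_identity(self):
        k = gaussian_kernel(GaussianParams(sigma=0.1, size=3))
        assert k[1, 1] == pytest.approx(1.0, abs=1e-9)

    def test_sigma_one_matches_formula(self):
        k = gaussian_kernel(GaussianParams(sigma=1.0, size=3))
        raw = np.array(
            [[np.exp(-(x * x + y * y) / 2.0) for x in (-1, 0, 1)] for y in (-1, 0, 1)]
        ) / (2 * np.pi)
        assert np.allclose(k, raw / raw.sum())

    def test_invalid_params(self):
        for sigma, size in [(0.0, 3), (-1.0, 5), (1.0, 4)]:
            with pytest.raises(InvalidGaussianError):
                GaussianParams(sigma=sigma, size=size)

    def test_constant_preserved(self):
        img = np.full((9, 9), 7.0)
        assert np.allclose(gaussian_smooth(img, GaussianParams()), img)

    def test_impulse_reproduces_kernel(self):
        p = GaussianParams(sigma=1.0, size=5)
        img = np.zeros((11, 11))
        img[5, 5] = 1.0
        out = gaussian_smooth(img, p)
        assert np.allclose(out[3:8, 3:8], gaussian_kernel(p))

    def test_matches_direct_convolution(self, rng):
        img = rng.random((9, 9))
        p = GaussianParams(sigma=0.8, size=5)
        assert np.allclose(gaussian_smooth(img, p), brute_convolve(img, gaussian_kernel(p)))

    def test_linearity(self, rng):
        p = GaussianParams()
        f, g = rng.random((8, 8)), rng.random((8, 8))
        lhs = gaussian_smooth(2.5 * f + g, p)
        rhs = 2.5 * gaussian_smooth(f, p) + gaussian_smooth(g, p)
        assert np.allclose(lhs, rhs)


# ---------------------------------------------------------------- pipeline


class TestPipeline:
    def test_clean_render_silhouette_area(self, clean_scene, default_cfg):
        _, img, truth = clean_scene
        area = preprocess_pipeline(img, default_cfg).silhouette.sum()
        expected = _syringe_area(truth)
        assert abs(area - expected) / expected < 0.05

    def test_noisy_render_silhouette_area(self, default_cfg):
        img, truth = render(SynthScene(capacity_ml=5, fill_fraction=0.4, noise_sigma=10, seed=1))
        area = preprocess_pipeline(img, default_cfg).silhouette.sum()
        expected = _syringe_area(truth)
        assert abs(area - expected) / expected < 0.10

    def test_flat_frame_is_degenerate(self, default_cfg):
        with pytest.raises(DegenerateImageError):
            preprocess_pipeline(np.full((40, 60), 255, dtype=np.uint8), default_cfg)

    def test_polarity_picks_class_away_from_border(self, clean_scene, default_cfg):
        _, img, _ = clean_scene
        res = preprocess_pipeline(img, default_cfg)
        border = np.concatenate(
            [res.silhouette[0], res.silhouette[-1], res.silhouette[:, 0], res.silhouette[:, -1]]
        )
        assert border.sum() == 0  # syringe never touches the frame


def _syringe_area(truth) -> float:
    """Expected silhouette area: walls + liquid + piston, from scene truth.

    The barrel mask covers walls + interior; the air gap behind the piston
    (interior minus liquid minus piston band) is not part of the syringe.
    """
    from syrdose.synthgen import _REF

    barrel = truth.barrel_mask.sum()
    interior = barrel * (1 - 2 * _REF["wall"] / _REF["width"])
    piston = interior * _REF["piston"] / _REF["length"]
    air_gap = interior - truth.liquid_mask.sum() - piston
    return barrel - air_gap
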