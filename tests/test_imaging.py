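"""Image representation, bicubic degradation, patch geometry and metrics."""

import numpy as np
import pytest

from ffasr.imaging import (
    Image,
    assemble_image,
    bicubic_resize,
    degrade,
    extract_training_patches,
    load_image,
    psnr,
    save_image,
    ssim,
)
from ffasr.imaging import _cubic_kernel


def _naive_bicubic(px, out_h, out_w):
    """Independent direct (non-separable loop) bicubic evaluation as oracle."""
    def taps_1d(n_in, n_out, i):
        scale = n_in / n_out
        kw = max(scale, 1.0)
        c = (i + 0.5) * scale - 0.5
        support = 2 * kw
        left = int(np.floor(c - support)) + 1
        js = np.arange(left, left + int(np.ceil(2 * support)) + 2)
        w = _cubic_kernel((c - js) / kw)
        return np.clip(js, 0, n_in - 1), w / w.sum()

    out = np.zeros((out_h, out_w))
    for i in range(out_h):
        ri, wi = taps_1d(px.shape[0], out_h, i)
        for j in range(out_w):
            cj, wj = taps_1d(px.shape[1], out_w, j)
            out[i, j] = wi @ px[np.ix_(ri, cj)] @ wj
    return out


class TestImageInvariants:
    def test_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            Image(np.full((4, 4), 1.5))

    def test_rejects_empty(self):
        with pytest.raises(ValueError):
            Image(np.empty((0, 3)))


class TestIO:
    @pytest.mark.parametrize("value,expected", [(255, 1.0), (0, 0.0)])
    def test_8bit_normalization(self, tmp_path, value, expected):
        import imageio.v3 as iio

        path = tmp_path / "im.png"
        iio.imwrite(path, np.full((8, 8), value, dtype=np.uint8))
        img = load_image(path)
        assert np.allclose(img.pixels, expected)
        assert img.source_bit_depth == 8

    def test_rgb_collapses_to_luminance(self, tmp_path):
        import imageio.v3 as iio

        path = tmp_path / "rgb.png"
        iio.imwrite(path, np.full((8, 8, 3), 128, dtype=np.uint8))
        img = load_image(path)
        # equal channels: any convex luminance weighting returns the channel value
        assert np.allclose(img.pixels, 128 / 255, atol=1e-9)

    def test_save_load_roundtrip(self, tmp_path):
        rng = np.random.default_rng(0)
        img = Image(np.round(rng.random((16, 16)) * 255) / 255)
        save_image(img, tmp_path / "x.png")
        again = load_image(tmp_path / "x.png")
        assert np.allclose(again.pixels, img.pixels, atol=1 / 510)


class TestBicubic:
    def test_constant_preserved(self):
        img = Image(np.full((12, 10), 0.37))
        out = bicubic_resize(img, 30, 7)
        assert np.allclose(out.pixels, 0.37)

    def test_identity_size(self):
        rng = np.random.default_rng(1)
        img = Image(rng.random((9, 9)))
        assert np.array_equal(bicubic_resize(img, 9, 9).pixels, img.pixels)

    def test_rejects_nonpositive_dims(self):
        with pytest.raises(ValueError):
            bicubic_resize(Image(np.zeros((4, 4))), 0, 4)

    def test_matches_independent_kernel_evaluation(self):
        """Down-then-up resampling agrees with a directly coded bicubic oracle."""
        ramp = np.tile(np.linspace(0, 1, 8), (8, 1))
        img = Image(ramp)
        down = bicubic_resize(img, 4, 4)
        up = bicubic_resize(down, 8, 8)
        o_down = np.clip(_naive_bicubic(ramp, 4, 4), 0, 1)
        o_up = np.clip(_naive_bicubic(o_down, 8, 8), 0, 1)
        p_impl = psnr(img, up)
        p_oracle = psnr(img, Image(o_up))
        assert abs(p_impl - p_oracle) <= 1e-6

    def test_pil_sanity(self):
        """Loose agreement with PIL's antialiased bicubic on a smooth image."""
        from PIL import Image as PILImage

        rng = np.random.default_rng(3)
        px = np.clip(
            0.5 + 0.2 * np.cumsum(rng.standard_normal((32, 32)), axis=1) / 6, 0, 1
        )
        ours = bicubic_resize(Image(px), 16, 16).pixels
        pil = np.asarray(
            PILImage.fromarray(px.astype(np.float32), mode="F").resize(
                (16, 16), PILImage.BICUBIC
            )
        )
        # boundary conventions differ (replicate vs PIL's tap renormalization),
        # so compare away from the 2-pixel border
        assert np.abs(ours - np.clip(pil, 0, 1))[2:-2, 2:-2].max() < 5e-3


class TestDegrade:
    def test_shapes_and_crop(self):
        rng = np.random.default_rng(2)
        pair = degrade(Image(rng.random((64, 64))), 2)
        assert pair.lr.shape == (32, 32) and pair.hr.shape == (64, 64)
        pair = degrade(Image(rng.random((65, 65))), 4)
        assert pair.hr.shape == (64, 64) and pair.lr.shape == (16, 16)

    def test_constant_hr_gives_constant_lr(self):
        pair = degrade(Image(np.full((32, 32), 0.6)), 2)
        assert np.allclose(pair.lr.pixels, 0.6)

    def test_too_small_rejected(self):
        with pytest.raises(ValueError):
            degrade(Image(np.zeros((3, 3))), 4)


class TestMetrics:
    def test_psnr_identities(self):
        rng = np.random.default_rng(4)
        x = Image(rng.random((16, 16)))
        assert psnr(x, x) == float("inf")
        zeros, ones = Image(np.zeros((8, 8))), Image(np.ones((8, 8)))
        assert psnr(zeros, ones) == pytest.approx(0.0, abs=1e-12)
        shifted = Image(np.full((8, 8), 1 / 255))
        assert psnr(zeros, shifted) == pytest.approx(20 * np.log10(255), abs=1e-9)

    def test_psnr_dimension_mismatch(self):
        with pytest.raises(ValueError):
            psnr(Image(np.zeros((4, 4))), Image(np.zeros((4, 5))))

    def test_psnr_decreases_with_noise(self):
        rng = np.random.default_rng(5)
        base = np.clip(rng.random((32, 32)), 0.2, 0.8)
        noise = rng.standard_normal((32, 32))
        vals = [
            psnr(Image(base), Image(np.clip(base + amp * noise, 0, 1)))
            for amp in (0.01, 0.05, 0.1)
        ]
        assert vals[0] > vals[1] > vals[2]

    def test_ssim_identities_and_symmetry(self):
        rng = np.random.default_rng(6)
        a = Image(rng.random((16, 16)))
        b = Image(rng.random((16, 16)))
        assert ssim(a, a) == pytest.approx(1.0, abs=1e-12)
        assert ssim(a, b) == pytest.approx(ssim(b, a), abs=1e-12)

    def test_ssim_constant_images_closed_form(self):
        mu1, mu2 = 0.25, 0.75
        c1 = 0.01**2
        expected = (2 * mu1 * mu2 + c1) / (mu1**2 + mu2**2 + c1)
        val = ssim(Image(np.full((16, 16), mu1)), Image(np.full((16, 16), mu2)))
        assert val == pytest.approx(expected, abs=1e-10)

    def test_ssim_range_on_random_pairs(self):
        rng = np.random.default_rng(7)
        for _ in range(1000):
            a = Image(rng.random((12, 12)))
            b = Image(rng.random((12, 12)))
            assert -1.0 <= ssim(a, b) <= 1.0

    def test_ssim_window_validation(self):
        with pytest.raises(ValueError):
            ssim(Image(np.zeros((8, 8))), Image(np.zeros((8, 8))))


class TestPatches:
    def test_grid_count_9x9(self):
        pair = degrade(Image(np.random.default_rng(8).random((18, 18))), 2)
        ps = extract_training_patches(pair)  # LR is 9x9
        assert ps.n_pairs == 16  # 4 anchors per axis

    def test_hr_geometry_factor2(self):
        pair = degrade(Image(np.random.default_rng(9).random((20, 20))), 2)
        ps = extract_training_patches(pair)
        assert ps.X_h.shape[0] == 36  # 6x6 = (3M)^2 at M=2
        # HR anchors are exactly 2x the LR anchors by construction: verify the
        # HR patch content matches a direct crop at 2x the anchor
        r, c = ps.positions[3]
        direct = pair.hr.pixels[2 * r : 2 * r + 6, 2 * c : 2 * c + 6].ravel()
        assert np.allclose(ps.X_h[:, 3] + ps.lr_means[3], direct)

    def test_constant_image_zero_after_mean_removal(self):
        pair = degrade(Image(np.full((16, 16), 0.42)), 2)
        ps = extract_training_patches(pair)
        assert np.allclose(ps.X_l, 0) and np.allclose(ps.X_h, 0)
        assert np.allclose(ps.lr_means, 0.42)

    def test_flush_border_covers_all_pixels(self):
        # 10x10 LR: stride grid ends at 7 but the last patch must reach col 9
        pair = degrade(Image(np.random.default_rng(10).random((20, 20))), 2)
        ps = extract_training_patches(pair)
        assert ps.positions[:, 0].max() == 7 and (ps.positions[:, 0] == 7).any()

    def test_serialization_roundtrip(self, tmp_path):
        pair = degrade(Image(np.random.default_rng(11).random((20, 20))), 2)
        ps = extract_training_patches(pair)
        ps.save(tmp_path / "ps.npz")
        from ffasr.imaging import PatchPairSet

        again = PatchPairSet.load(tmp_path / "ps.npz")
        assert np.array_equal(again.X_h, ps.X_h) and again.factor == ps.factor


class TestAssemble:
    def test_extract_assemble_roundtrip_identity(self):
        rng = np.random.default_rng(12)
        for size, factor in [(20, 2), (24, 4)]:
            pair = degrade(Image(rng.random((size, size))), factor)
            ps = extract_training_patches(pair)
            rec = assemble_image(
                ps.X_h, ps.positions, ps.lr_means, pair.hr.shape, factor
            )
            assert np.abs(rec.pixels - pair.hr.pixels).max() < 1e-10

    def test_overlap_average(self):
        # two 3x3 patches side by side with 1-col overlap, values 0 and 1
        patches = np.stack([np.zeros(9), np.ones(9)], axis=1)
        positions = np.array([[0, 0], [0, 2]])
        img = assemble_image(patches, positions, np.zeros(2), (3, 5), 1)
        assert np.allclose(img.pixels[:, 2], 0.5)
        assert np.allclose(img.pixels[:, :2], 0.0) and np.allclose(img.pixels[:, 3:], 1.0)

    def test_uncovered_pixel_rejected(self):
        patches = np.zeros((9, 1))
        with pytest.raises(ValueError, match=r"\(3, 3\)|\(0, 3\)|\(3, 0\)"):
            assemble_image(patches, np.array([[0, 0]]), np.zeros(1), (4, 4), 1)
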