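import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from colpoqc.color import (
    LabColor,
    PatchReading,
    color_error_report,
    delta_c_ab,
    delta_e_ab,
    extract_patches,
    lab_to_srgb_8bit,
    match_color,
    srgb_array_to_lab,
    srgb_to_lab,
)
from colpoqc.core_io import RasterImage
from colpoqc.errors import InputError
from colpoqc.synthetic import SceneSpec, gen_color_chart

lab_colors = st.builds(
    LabColor,
    L=st.floats(0, 100),
    a=st.floats(-100, 100),
    b=st.floats(-100, 100),
)


class TestSrgbToLab:
    @pytest.mark.parametrize("white", ["D65", "D50"])
    def test_white_maps_to_white(self, white):
        lab = srgb_to_lab((255, 255, 255), white)
        assert lab.L == pytest.approx(100.0, abs=0.01)
        assert abs(lab.a) < 0.5 and abs(lab.b) < 0.5

    def test_black(self):
        lab = srgb_to_lab((0, 0, 0))
        assert lab.L == 0.0 and lab.a == 0.0 and lab.b == 0.0

    def test_mid_gray_l50(self):
        lab = srgb_to_lab((119, 119, 119), "D65")
        assert lab.L == pytest.approx(50.0, abs=1.0)
        assert abs(lab.a) < 0.1 and abs(lab.b) < 0.1

    def test_matches_skimage_d65(self, rng):
        from skimage.color import rgb2lab

        rgb = rng.random((8, 8, 3))
        ours = srgb_array_to_lab(rgb, white="D65")
        theirs = rgb2lab(rgb, illuminant="D65")
        np.testing.assert_allclose(ours, theirs, atol=0.02)

    def test_round_trip_8bit(self, rng):
        for _ in range(50):
            rgb = tuple(int(v) for v in rng.integers(0, 256, 3))
            back = lab_to_srgb_8bit(srgb_to_lab(rgb, "D50"), "D50")
            assert max(abs(a - b) for a, b in zip(rgb, back)) <= 1

    def test_bad_triple(self):
        with pytest.raises(InputError):
            srgb_to_lab((300, 0, 0))


class TestDeltaMetrics:
    def test_identical_zero(self):
        x = LabColor(50, 10, -10)
        assert delta_e_ab(x, x) == 0.0
        assert delta_c_ab(x, x) == 0.0

    def test_3_4_5(self):
        a = LabColor(50, 0, 0)
        b = LabColor(50, 3, 4)
        assert delta_e_ab(a, b) == pytest.approx(5.0)
        assert delta_c_ab(a, b) == pytest.approx(5.0)

    def test_luminance_only(self):
        a, b = LabColor(50, 5, 5), LabColor(55, 5, 5)
        assert delta_e_ab(a, b) == pytest.approx(5.0)
        assert delta_c_ab(a, b) == 0.0

    @given(x=lab_colors, y=lab_colors, z=lab_colors)
    @settings(max_examples=200, deadline=None)
    def test_metric_properties(self, x, y, z):
        assert delta_e_ab(x, y) == pytest.approx(delta_e_ab(y, x))
        assert delta_e_ab(x, y) <= delta_e_ab(x, z) + delta_e_ab(z, y) + 1e-9
        assert delta_c_ab(x, y) <= delta_e_ab(x, y) + 1e-12

    def test_de_ge_dc_bulk(self, rng):
        # 10^4 random pairs: dE >= dC, equality iff dL == 0
        labs = rng.uniform([0, -100, -100], [100, 100, 100], (10_000, 2, 3))
        d = labs[:, 0] - labs[:, 1]
        de = np.sqrt((d**2).sum(axis=1))
        dc = np.sqrt((d[:, 1:] ** 2).sum(axis=1))
        assert (de >= dc - 1e-12).all()
        # strict dominance whenever dL is materially nonzero...
        assert (de[np.abs(d[:, 0]) > 1e-6] > dc[np.abs(d[:, 0]) > 1e-6]).all()
        # ...and exact equality when dL is zero
        d0 = d.copy()
        d0[:, 0] = 0.0
        assert np.array_equal(np.sqrt((d0**2).sum(axis=1)), np.sqrt((d0[:, 1:] ** 2).sum(axis=1)))


class TestExtractPatches:
    def test_noiseless_chart_exact(self, scene):
        img, boxes = gen_color_chart(scene, noise_sd=0.0)
        means = extract_patches(img, (5, 6))
        for mean, (r0, c0, r1, c1) in zip(means, boxes):
            fill = img.pixels[(r0 + r1) // 2, (c0 + c1) // 2].astype(float)
            np.testing.assert_allclose(mean, fill)

    def test_inset_invariant_on_uniform_patches(self, scene):
        img, _ = gen_color_chart(scene, noise_sd=0.0)
        a = extract_patches(img, (5, 6), inset=0.25)
        b = extract_patches(img, (5, 6), inset=0.45)
        np.testing.assert_allclose(a, b)

    def test_noisy_mean_within_standard_error(self, scene):
        noiseless, _ = gen_color_chart(scene, noise_sd=0.0)
        noisy, boxes = gen_color_chart(scene, noise_sd=2.0)
        means_clean = extract_patches(noiseless, (5, 6))
        means_noisy = extract_patches(noisy, (5, 6))
        r0, c0, r1, c1 = boxes[0]
        n = ((r1 - r0) // 2) * ((c1 - c0) // 2)  # central region pixel count
        tol = 3 * 2.0 / np.sqrt(n) + 0.5  # 3 sigma / sqrt(n) plus quantization
        for a, b in zip(means_clean, means_noisy):
            assert np.abs(a - b).max() < tol

    def test_cells_too_small(self):
        img = RasterImage(np.zeros((20, 20, 3), dtype=np.uint8))
        with pytest.raises(InputError):
            extract_patches(img, (5, 6))


class TestColorErrorReport:
    def test_identity_all_zero(self):
        readings = [
            PatchReading(f"p{i}", LabColor(50, i, -i), LabColor(50, i, -i)) for i in range(5)
        ]
        rep = color_error_report(readings)
        assert rep.mean_de == rep.max_de == rep.mean_dc == rep.max_dc == 0.0

    def test_single_luminance_shift(self):
        rep = color_error_report(
            [PatchReading("p0", LabColor(55, 0, 0), LabColor(50, 0, 0))]
        )
        assert rep.mean_de == rep.max_de == 5.0
        assert rep.mean_dc == 0.0

    def test_matches_brute_force(self, rng):
        readings = []
        for i in range(24):
            m = LabColor(*rng.uniform([0, -50, -50], [100, 50, 50]))
            r = LabColor(*rng.uniform([0, -50, -50], [100, 50, 50]))
            readings.append(PatchReading(f"p{i}", m, r))
        rep = color_error_report(readings)
        de = [delta_e_ab(p.measured, p.reference) for p in readings]
        dc = [delta_c_ab(p.measured, p.reference) for p in readings]
        assert rep.mean_de == pytest.approx(sum(de) / len(de))
        assert rep.max_de == pytest.approx(max(de))
        assert rep.mean_dc == pytest.approx(sum(dc) / len(dc))
        assert rep.max_dc == pytest.approx(max(dc))
        # invariant: dE >= dC per patch, mean <= max
        assert all(e >= c for e, c in zip(rep.delta_e, rep.delta_c))
        assert rep.mean_de <= rep.max_de and rep.mean_dc <= rep.max_dc

    def test_luminance_cast_mirrors_reported_asymmetry(self, scene):
        # luminance-only cast: mean dC stays near zero while mean dE grows
        img_ref, _ = gen_color_chart(scene, noise_sd=0.0)
        img_dim, _ = gen_color_chart(scene, cast=0.55 * np.eye(3), noise_sd=0.0)
        ref = extract_patches(img_ref, (5, 6))
        dim = extract_patches(img_dim, (5, 6))
        readings = [
            PatchReading(
                f"p{i}",
                srgb_to_lab(tuple(int(round(v)) for v in m), "D50"),
                srgb_to_lab(tuple(int(round(v)) for v in r), "D50"),
            )
            for i, (m, r) in enumerate(zip(dim, ref))
        ]
        rep = color_error_report(readings)
        assert rep.mean_de > 5.0
        assert rep.mean_dc < rep.mean_de / 2

    def test_empty_chart(self):
        with pytest.raises(InputError):
            color_error_report([])

    def test_duplicate_ids(self):
        p = PatchReading("p0", LabColor(50, 0, 0), LabColor(50, 0, 0))
        with pytest.raises(InputError):
            color_error_report([p, p])


class TestMatchColor:
    def _scene_image(self, seed=3):
        rng = np.random.default_rng(seed)
        base = rng.integers(40, 200, (64, 64, 3), dtype=np.uint8)
        return RasterImage(base)

    def test_identity_transfer(self):
        img = self._scene_image()
        roi = (0, 0, 64, 64)
        out = match_color(img, roi, img, roi)
        assert np.abs(out.pixels.astype(int) - img.pixels.astype(int)).max() <= 1

    def test_pure_l_shift_cancelled(self):
        img = self._scene_image()
        lab = srgb_array_to_lab(img.pixels / 255.0, white="D50")
        shifted = lab.copy()
        shifted[..., 0] = np.clip(shifted[..., 0] + 10.0, 0, 100)
        from colpoqc.color import lab_to_srgb

        ref = RasterImage(
            np.clip(lab_to_srgb(shifted, white="D50") * 255.0, 0, 255).round().astype(np.uint8)
        )
        roi = (0, 0, 64, 64)
        out = match_color(img, roi, ref, roi)
        out_lab = srgb_array_to_lab(out.pixels / 255.0, white="D50")
        ref_lab = srgb_array_to_lab(ref.pixels / 255.0, white="D50")
        assert abs(out_lab[..., 0].mean() - ref_lab[..., 0].mean()) < 0.5

    def test_mean_de_reduced(self):
        src = self._scene_image(seed=3)
        ref = self._scene_image(seed=4)
        roi = (0, 0, 64, 64)
        out = match_color(src, roi, ref, roi)
        def roi_mean_lab(im):
            return srgb_array_to_lab(im.pixels / 255.0, white="D50").reshape(-1, 3).mean(axis=0)
        pre = np.linalg.norm(roi_mean_lab(src) - roi_mean_lab(ref))
        post = np.linalg.norm(roi_mean_lab(out) - roi_mean_lab(ref))
        assert post < pre

    def test_affine_cast_recovery(self):
        # an affine Lab cast is cancelled to < 1.0 mean dE between ROI stats
        src = self._scene_image(seed=5)
        lab = srgb_array_to_lab(src.pixels / 255.0, white="D50")
        cast = lab.copy()
        cast[..., 0] = np.clip(0.8 * cast[..., 0] + 12.0, 0, 100)
        cast[..., 1] = np.clip(1.2 * cast[..., 1] - 5.0, -128, 128)
        cast[..., 2] = np.clip(0.9 * cast[..., 2] + 3.0, -128, 128)
        from colpoqc.color import lab_to_srgb

        ref = RasterImage(
            np.clip(lab_to_srgb(cast, white="D50") * 255.0, 0, 255).round().astype(np.uint8)
        )
        roi = (0, 0, 64, 64)
        out = match_color(src, roi, ref, roi)
        out_stats = srgb_array_to_lab(out.pixels / 255.0, white="D50").reshape(-1, 3).mean(axis=0)
        ref_stats = srgb_array_to_lab(ref.pixels / 255.0, white="D50").reshape(-1, 3).mean(axis=0)
        assert np.linalg.norm(out_stats - ref_stats) < 1.0

    def test_zero_variance_channel_mean_shift(self):
        flat = RasterImage(np.full((64, 64, 3), 100, dtype=np.uint8))
        ref = self._scene_image()
        roi = (0, 0, 64, 64)
        out = match_color(flat, roi, ref, roi)  # must not divide by zero
        assert out.pixels.shape == flat.pixels.shape

    def test_small_roi_rejected(self):
        img = self._scene_image()
        with pytest.raises(InputError):
            match_color(img, (0, 0, 16, 16), img, (0, 0, 64, 64))

    def test_l_levels_compression(self):
        img = self._scene_image()
        roi = (0, 0, 64, 64)
        out = match_color(img, roi, img, roi, l_levels=(20, 240))
        out_lab = srgb_array_to_lab(out.pixels / 255.0, white="D50")
        assert out_lab[..., 0].min() >= 20 / 255 * 100 - 1.0
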