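"""Stimulus battery: construction invariants of every generator."""

import numpy as np
import pytest
from scipy import ndimage

from v1bright import (
    make_sbc,
    make_grating_induction,
    make_white,
    make_mach,
    make_chevreul,
    make_rossi_paradiso,
    make_sine_grating,
)


class TestSBC:
    def test_patches_share_exact_luminance(self):
        img = make_sbc(128, 0.25, left_bg=1.0, right_bg=0.0, patch_lum=0.5)
        assert img.shape == (128, 256)
        left = img[:, :128]
        right = img[:, 128:]
        assert np.all(left[left != 1.0] == 0.5)
        assert np.all(right[right != 0.0] == 0.5)
        assert (left == 0.5).sum() == (right == 0.5).sum() == 32 * 32

    def test_degenerate_constant(self):
        img = make_sbc(64, 0.25, 0.5, 0.5, 0.5)
        assert np.all(img == 0.5)

    def test_half_field_mean_by_pixel_count(self):
        # mean of each half = bg*(1-f^2) + patch*f^2 for exact patch sides
        img = make_sbc(128, 0.25, left_bg=0.9, right_bg=0.1, patch_lum=0.4)
        f2 = 0.25**2
        assert img[:, :128].mean() == pytest.approx(0.9 * (1 - f2) + 0.4 * f2)
        assert img[:, 128:].mean() == pytest.approx(0.1 * (1 - f2) + 0.4 * f2)

    def test_mirror_symmetry(self):
        a = make_sbc(64, 0.25, 1.0, 0.0, 0.5)
        b = make_sbc(64, 0.25, 0.0, 1.0, 0.5)
        np.testing.assert_array_equal(np.fliplr(a), b)

    @pytest.mark.parametrize("bad", [{"left_bg": 1.2}, {"patch_lum": -0.1}])
    def test_out_of_range_luminance_rejected(self, bad):
        with pytest.raises(ValueError):
            make_sbc(64, 0.25, **{"left_bg": 1.0, "right_bg": 0.0,
                                  "patch_lum": 0.5, **bad})


class TestGratingInduction:
    def test_central_band_is_uniform_mean(self):
        img = make_grating_induction(128, inducer_freq=4, mean_lum=0.5)
        band = img[48:80, :]
        assert np.all(band == 0.5)

    def test_zero_contrast_is_constant(self):
        img = make_grating_induction(64, contrast=0.0, mean_lum=0.4)
        assert np.all(img == 0.4)

    def test_inducer_rows_average_to_mean_for_integer_cycles(self):
        img = make_grating_induction(128, inducer_freq=4, mean_lum=0.5,
                                     contrast=0.5)
        assert abs(img[0, :].mean() - 0.5) < 1e-12

    def test_band_taller_than_image_rejected(self):
        with pytest.raises(ValueError):
            make_grating_induction(64, test_height_frac=1.5)


class TestWhite:
    def test_patch_regions_identical(self):
        img = make_white(128, n_bars=8, patch_lum=0.5)
        vals = img[img == 0.5]
        assert vals.size > 0
        comp, n = ndimage.label(img == 0.5)
        assert n == 2
        sizes = ndimage.sum_labels(np.ones_like(img), comp, [1, 2])
        assert sizes[0] == sizes[1]

    def test_four_bars_two_components(self):
        img = make_white(64, n_bars=4, patch_lum=0.5)
        _, n = ndimage.label(img == 0.5)
        assert n == 2

    def test_swapping_bar_luminances_swaps_patch_contexts(self):
        a = make_white(64, n_bars=8, lum_black=0.0, lum_white=1.0)
        b = make_white(64, n_bars=8, lum_black=1.0, lum_white=0.0)
        # bars swap colors; the patches stay in place
        np.testing.assert_array_equal(a == 0.5, b == 0.5)
        np.testing.assert_array_equal(a[a != 0.5], 1.0 - b[b != 0.5])

    def test_odd_bar_count_rejected(self):
        with pytest.raises(ValueError):
            make_white(64, n_bars=5)


class TestMach:
    def test_rows_identical_and_monotone(self):
        img = make_mach(64)
        np.testing.assert_array_equal(img, np.tile(img[0], (64, 1)))
        assert np.all(np.diff(img[0]) >= 0)

    def test_ramp_slope_exact(self):
        img = make_mach(128, ramp_width_frac=0.25, low_lum=0.2, high_lum=0.8)
        ramp = img[0, 48:80]
        slopes = np.diff(ramp)
        np.testing.assert_allclose(slopes, (0.8 - 0.2) / 32, atol=1e-14)

    def test_zero_width_ramp_is_step(self):
        img = make_mach(64, ramp_width_frac=0.0, low_lum=0.0, high_lum=1.0)
        assert set(np.unique(img)) == {0.0, 1.0}

    def test_inverted_plateaus_rejected(self):
        with pytest.raises(ValueError):
            make_mach(64, low_lum=0.9, high_lum=0.1)


class TestChevreul:
    def test_band_census(self):
        img = make_chevreul(128, n_steps=5, low_lum=0.1, high_lum=0.9)
        vals = np.unique(img)
        np.testing.assert_allclose(vals, np.linspace(0.1, 0.9, 5))

    def test_two_steps_is_single_edge(self):
        img = make_chevreul(64, n_steps=2, low_lum=0.0, high_lum=1.0)
        assert set(np.unique(img)) == {0.0, 1.0}
        assert np.count_nonzero(np.diff(img[0])) == 1


class TestRossiParadiso:
    def test_fifty_frames_per_period_at_2hz(self):
        seq = make_rossi_paradiso(mod_freq_hz=2.0, tau_ms=10.0, n_periods=2)
        assert seq.meta["frames_per_period"] == 50
        assert seq.n_frames == 100

    def test_flank_time_average_equals_mean(self):
        seq = make_rossi_paradiso(mod_freq_hz=2.0, n_periods=2, mean_lum=0.5,
                                  mod_depth=0.4)
        flank = seq.frames[:50, 5, 5]  # one full period, a flank pixel
        assert abs(flank.mean() - 0.5) < 1e-12

    def test_variant_b_center_is_dark_every_frame(self):
        seq = make_rossi_paradiso(variant="B", n_periods=2)
        w = seq.shape[1]
        rw = seq.meta["region_width"]
        assert np.all(seq.frames[:, :, rw : w - rw] == 0.0)

    def test_temporal_aliasing_rejected(self):
        with pytest.raises(ValueError):
            make_rossi_paradiso(mod_freq_hz=20.0, tau_ms=10.0)

    def test_variant_a_bars_are_static(self):
        seq = make_rossi_paradiso(variant="A", n_periods=2)
        w = seq.shape[1]
        rw = seq.meta["region_width"]
        center = seq.frames[:, :, rw : w - rw]
        np.testing.assert_array_equal(center, np.broadcast_to(center[0], center.shape))


class TestSineGrating:
    def test_zero_contrast_constant(self):
        assert np.all(make_sine_grating(64, contrast=0.0, mean_lum=0.3) == 0.3)

    def test_orientation_transpose(self):
        a = make_sine_grating(64, freq=4, orientation=0.0)
        b = make_sine_grating(64, freq=4, orientation=90.0)
        np.testing.assert_allclose(a, b.T, atol=1e-12)

    def test_spatial_mean_for_integer_cycles(self):
        img = make_sine_grating(128, freq=8, mean_lum=0.5, contrast=0.4)
        assert abs(img.mean() - 0.5) < 1e-12


@pytest.mark.parametrize(
    "maker",
    [
        lambda: make_sbc(64),
        lambda: make_grating_induction(64),
        lambda: make_white(64),
        lambda: make_mach(64),
        lambda: make_chevreul(64),
        lambda: make_sine_grating(64),
        lambda: make_rossi_paradiso(n_periods=2).frames,
    ],
)
def test_all_generators_emit_unit_range(maker):
    arr = np.asarray(maker())
    assert np.isfinite(arr).all()
    assert arr.min() >= 0.0 and arr.max() <= 1.0


@pytest.mark.parametrize("maker", [lambda: make_sbc(64)] * 2)
def test_generators_are_deterministic(maker):
    np.testing.assert_array_equal(maker(), maker())
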