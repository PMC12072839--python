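"""Phantom generator: exact ground truth, determinism, dose-response."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

import microdamage as md
from microdamage.labels import BACKGROUND, BOUNDARY, DAMAGE, SOLID


def _scenario(**kw):
    defaults = dict(load_type="static", orientation="vertical",
                    load_fraction=0.3, baseline_fraction=0.02)
    defaults.update(kw)
    return md.LoadScenario(**defaults)


class TestGenerateSlice:
    def test_no_cracks_gives_zero_fraction(self, small_spec):
        spec = md.PhantomSpec(pixel_pitch=0.12, image_shape=(90, 130),
                              noise_sd=0.0, crack_count=0)
        _, _, truth = md.generate_slice(spec, _scenario(), 0, seed=1)
        assert truth.weighted_fraction == 0.0
        assert truth.area_damage_px == 0

    def test_fully_damaged_body_gives_fraction_one(self):
        spec = md.PhantomSpec(pixel_pitch=0.12, image_shape=(90, 130),
                              noise_sd=0.0, fill_body_with_damage=True)
        _, mask, truth = md.generate_slice(spec, _scenario(), 0, seed=1)
        assert truth.weighted_fraction == 1.0
        assert not np.any(mask == SOLID)

    def test_rectangular_crack_fraction_matches_pixel_count(self):
        """Weighted fraction equals an independent tally of the rectangle
        clipped to the body ellipse."""
        spec = md.PhantomSpec(pixel_pitch=0.12, image_shape=(90, 130),
                              noise_sd=0.0, rect_cracks=[(40, 40, 10, 50)])
        _, mask, truth = md.generate_slice(spec, _scenario(), 0, seed=1)
        # independent geometry: ellipse membership computed from first principles
        rows, cols = spec.image_shape
        a, b = spec.semi_axes_px
        cy, cx = (rows - 1) / 2.0, (cols - 1) / 2.0
        yy, xx = np.mgrid[:rows, :cols]
        ellipse = ((xx - cx) / a) ** 2 + ((yy - cy) / b) ** 2 <= 1.0
        rect = np.zeros_like(ellipse)
        rect[40:50, 40:90] = True
        expected = np.count_nonzero(rect & ellipse) / np.count_nonzero(ellipse)
        assert truth.weighted_fraction == pytest.approx(expected, abs=0)
        assert expected > 0

    def test_ground_truth_equals_mask_retally(self, small_spec):
        _, mask, truth = md.generate_slice(
            small_spec, _scenario(load_fraction=0.9), 3, seed=11)
        assert truth.area_object_px == np.count_nonzero(mask != BACKGROUND)
        assert truth.area_damage_px == np.count_nonzero(mask == DAMAGE)
        assert truth.area_boundary_px == np.count_nonzero(mask == BOUNDARY)
        assert truth.weighted_fraction == md.exact_damage_fraction(mask)

    def test_bitwise_determinism(self, small_spec):
        out1 = md.generate_slice(small_spec, _scenario(), 2, seed=9)
        out2 = md.generate_slice(small_spec, _scenario(), 2, seed=9)
        assert np.array_equal(out1[0].pixels, out2[0].pixels)
        assert np.array_equal(out1[1], out2[1])
        assert out1[2] == out2[2]

    def test_noise_free_raster_has_exactly_three_levels(self, small_spec):
        slc, _, _ = md.generate_slice(
            small_spec, _scenario(load_fraction=0.9), 0, seed=2)
        levels = set(np.unique(slc.pixels).tolist())
        assert levels == {small_spec.intensity_background,
                          small_spec.intensity_solid,
                          small_spec.intensity_damage}

    def test_disjoint_crack_strictly_increases_fraction(self):
        base = dict(pixel_pitch=0.12, image_shape=(90, 130), noise_sd=0.0)
        one = md.PhantomSpec(rect_cracks=[(42, 40, 4, 20)], **base)
        two = md.PhantomSpec(rect_cracks=[(42, 40, 4, 20), (50, 60, 4, 20)], **base)
        wf1 = md.generate_slice(one, _scenario(), 0, 1)[2].weighted_fraction
        wf2 = md.generate_slice(two, _scenario(), 0, 1)[2].weighted_fraction
        assert wf2 > wf1

    def test_bright_polarity_inverts_raster(self):
        kw = dict(pixel_pitch=0.12, image_shape=(90, 130), noise_sd=0.0)
        dark = md.PhantomSpec(polarity="cracks-dark", **kw)
        bright = md.PhantomSpec(polarity="cracks-bright", **kw)
        d, _, _ = md.generate_slice(dark, _scenario(), 0, seed=4)
        b, _, _ = md.generate_slice(bright, _scenario(), 0, seed=4)
        assert np.array_equal(b.pixels, 255 - d.pixels)
        assert np.array_equal(md.normalize_polarity(b).pixels, d.pixels)

    def test_boundary_band_appears_in_truth(self):
        spec = md.PhantomSpec(pixel_pitch=0.12, image_shape=(90, 130),
                              noise_sd=0.0, boundary_band_px=1)
        _, mask, truth = md.generate_slice(
            spec, _scenario(load_fraction=0.6), 0, seed=3)
        assert truth.area_boundary_px > 0
        assert truth.weighted_fraction == pytest.approx(
            (truth.area_damage_px + 0.5 * truth.area_boundary_px)
            / truth.area_object_px)


class TestSpecValidation:
    def test_body_too_large_raises(self):
        with pytest.raises(md.SizingError):
            md.PhantomSpec(pixel_pitch=0.01, image_shape=(100, 100))

    def test_zero_crack_width_with_cracks_raises(self):
        with pytest.raises(md.ParameterError):
            md.PhantomSpec(crack_width_px=0, crack_count=5)

    def test_equal_intensities_raise(self):
        with pytest.raises(md.ParameterError):
            md.PhantomSpec(intensity_solid=100, intensity_damage=100)

    def test_default_body_within_measured_kernel_ranges(self):
        spec = md.PhantomSpec()
        width, height = (2 * s for s in spec.body_semi_axes)
        assert md.phantom.KERNEL_LENGTH_MM[0] <= width <= md.phantom.KERNEL_LENGTH_MM[1]
        assert md.phantom.KERNEL_WIDTH_MM[0] <= height <= md.phantom.KERNEL_WIDTH_MM[1]


class TestDamageResponse:
    def test_baseline_and_fold_anchors(self):
        sc = _scenario(baseline_fraction=0.02, fold_span=6.0)
        assert md.damage_response(sc) == pytest.approx(0.02)
        sc9 = _scenario(load_fraction=0.9, baseline_fraction=0.02, fold_span=6.0)
        assert md.damage_response(sc9) == pytest.approx(0.12)

    def test_midpoint_between_anchors(self):
        r = [md.damage_response(_scenario(load_fraction=f, fold_span=6.0))
             for f in (0.3, 0.6, 0.9)]
        assert r[0] <= r[1] <= r[2]

    def test_fold_span_below_one_raises(self):
        with pytest.raises(md.ParameterError):
            _scenario(fold_span=0.5)

    def test_default_fold_spans_by_load_type(self):
        assert _scenario(load_type="static").resolved_fold_span == 6.0
        assert _scenario(load_type="dynamic").resolved_fold_span == 3.0

    @given(f1=st.floats(0.05, 1.0), f2=st.floats(0.05, 1.0),
           fold=st.floats(1.0, 10.0), shape=st.floats(0.3, 3.0))
    def test_monotone_in_load_fraction(self, f1, f2, fold, shape):
        lo, hi = sorted((f1, f2))
        r_lo = md.damage_response(_scenario(load_fraction=lo, fold_span=fold, shape=shape))
        r_hi = md.damage_response(_scenario(load_fraction=hi, fold_span=fold, shape=shape))
        assert r_lo <= r_hi + 1e-12


class TestGenerateStack:
    def test_twenty_sections_half_horizontal(self, small_spec):
        stack = md.generate_stack(small_spec, _scenario(), seed=0)
        assert len(stack.slices) == 20
        orients = [s.orientation for s in stack.slices]
        assert orients[:10] == ["horizontal"] * 10
        assert orients[10:] == ["vertical"] * 10
        assert [s.slice_index for s in stack.slices] == list(range(20))

    def test_mean_fraction_tracks_target(self, small_spec):
        sc = _scenario(load_fraction=0.75, fold_span=6.0)
        target = md.damage_response(sc)
        stack = md.generate_stack(small_spec, sc, seed=21)
        assert stack.mean_weighted_fraction == pytest.approx(target, rel=0.20)

    def test_same_seed_identical_stacks(self, small_spec):
        s1 = md.generate_stack(small_spec, _scenario(), seed=13)
        s2 = md.generate_stack(small_spec, _scenario(), seed=13)
        for a, b in zip(s1.masks, s2.masks):
            assert np.array_equal(a, b)

    def test_replicate_noise_spreads_fractions(self, small_spec):
        sc = _scenario(load_fraction=0.6, replicate_noise_sd=0.02)
        stack = md.generate_stack(small_spec, sc, seed=5)
        wf = [t.weighted_fraction for t in stack.truths]
        assert np.std(wf) > 0.005


class TestStackIO:
    def test_write_read_round_trip(self, tmp_path, small_spec):
        stack = md.generate_stack(small_spec, _scenario(), seed=3)
        manifest = md.write_stack(stack, tmp_path / "stack")
        slices = md.read_stack(manifest)
        assert len(slices) == 20
        for orig, loaded in zip(stack.slices, slices):
            assert np.array_equal(orig.pixels, loaded.pixels)
            assert loaded.orientation == orig.orientation
        masks = md.read_masks(manifest)
        for orig, loaded in zip(stack.masks, masks):
            assert np.array_equal(orig, loaded)
        gt = pd.read_csv(tmp_path / "stack" / "ground_truth.csv")
        assert len(gt) == 20
        np.testing.assert_allclose(
            gt["weighted_fraction"].to_numpy(),
            [t.weighted_fraction for t in stack.truths])

    def test_png_format(self, tmp_path, small_spec):
        stack = md.generate_stack(small_spec, _scenario(), seed=3)
        manifest = md.write_stack(stack, tmp_path / "p", image_format="png")
        slices = md.read_stack(manifest)
        assert np.array_equal(slices[0].pixels, stack.slices[0].pixels)


def test_exact_damage_fraction_weighted_counts():
    mask = np.full((10, 10), BACKGROUND, dtype=np.uint8)
    mask[0:10, 0:10] = SOLID
    mask.flat[:20] = DAMAGE
    mask.flat[20:30] = BOUNDARY
    assert md.exact_damage_fraction(mask) == pytest.approx((20 + 5) / 100)


def test_exact_damage_fraction_empty_mask_raises():
    with pytest.raises(md.EmptyDomainError):
        md.exact_damage_fraction(np.zeros((5, 5), dtype=np.uint8))
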