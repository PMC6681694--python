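import numpy as np
import pytest

from repeatquant import (
    EmptyMaskError,
    SphereKernel,
    ValueKind,
    ValueKindError,
    extract_metric_set,
    metric_extremum,
    metric_mean_median,
    metric_peak_sphere,
    percent_isocontour,
    roi_volume,
    total_lesion_glycolysis,
)
from repeatquant import PhantomConfig, generate_lesion_phantom

from conftest import make_mask, make_volume, random_volume_and_mask
from oracles import brute_isocontour, brute_peak_sphere


class TestSphereKernel:
    def test_radius_of_one_cm3_sphere(self):
        k = SphereKernel((2.0, 2.0, 2.0))
        assert k.radius_mm == pytest.approx((3000.0 / (4 * np.pi)) ** (1 / 3), rel=1e-9)
        assert k.radius_mm == pytest.approx(6.2035, abs=1e-3)

    @pytest.mark.parametrize("spacing", [(1.0, 1.0, 1.0), (2.0, 2.0, 2.0), (1.0, 1.5, 3.0)])
    def test_realized_volume_near_target(self, spacing):
        k = SphereKernel(spacing)
        # voxelization error shrinks with spacing; coarse grids stay within ~20%
        assert k.realized_volume_mL == pytest.approx(1.0, rel=0.2)
        assert k.n_voxels >= 1

    def test_coarser_than_sphere_keeps_center(self):
        assert SphereKernel((20.0, 20.0, 20.0)).n_voxels == 1


class TestExtremumMeanMedian:
    def test_uniform_value(self):
        vol = make_volume(np.full((4, 4, 4), 7.0))
        mask = make_mask(np.ones((4, 4, 4)))
        assert metric_extremum(vol, mask, "max") == 7.0
        assert metric_extremum(vol, mask, "min") == 7.0
        assert metric_mean_median(vol, mask) == (7.0, 7.0)

    def test_single_hot_voxel(self):
        vals = np.zeros((5, 5, 5))
        vals[2, 2, 2] = 10.0
        vol, mask = make_volume(vals), make_mask(np.ones((5, 5, 5)))
        assert metric_extremum(vol, mask, "max") == 10.0
        assert metric_extremum(vol, mask, "min") == 0.0

    def test_even_count_median_midpoint(self):
        vals = np.zeros((1, 1, 4))
        vals[0, 0] = [1, 2, 3, 4]
        vol, mask = make_volume(vals), make_mask(np.ones((1, 1, 4)))
        assert metric_mean_median(vol, mask) == (2.5, 2.5)

    def test_matches_brute_force_on_random_inputs(self, rng):
        for _ in range(20):
            vol, mask = random_volume_and_mask(rng, shape=(7, 7, 7))
            vals = [vol.values[tuple(c)] for c in np.argwhere(mask.mask)]
            assert metric_extremum(vol, mask, "max") == pytest.approx(max(vals))
            assert metric_extremum(vol, mask, "min") == pytest.approx(min(vals))
            mean, median = metric_mean_median(vol, mask)
            assert mean == pytest.approx(sum(vals) / len(vals))
            s = sorted(vals)
            n = len(s)
            expect = s[n // 2] if n % 2 else (s[n // 2 - 1] + s[n // 2]) / 2
            assert median == pytest.approx(expect)

    def test_empty_mask_rejected(self):
        vol = make_volume(np.ones((3, 3, 3)))
        with pytest.raises(EmptyMaskError):
            metric_extremum(vol, make_mask(np.zeros((3, 3, 3))), "max")


class TestPeakSphere:
    def test_uniform_volume_gives_value_everywhere(self):
        vol = make_volume(np.full((9, 9, 9), 3.5))
        mask = make_mask(np.ones((9, 9, 9)))
        for mode in ("max", "min"):
            assert metric_peak_sphere(vol, mask, mode=mode).value == pytest.approx(3.5)

    def test_single_hot_voxel_peak_is_value_over_kernel_size(self):
        vals = np.zeros((11, 11, 11))
        vals[5, 5, 5] = 10.0
        vol, mask = make_volume(vals), make_mask(np.ones((11, 11, 11)))
        k = SphereKernel(vol.spacing)
        res = metric_peak_sphere(vol, mask, k, "max")
        assert res.value == pytest.approx(10.0 / k.n_voxels)
        assert not res.clipped

    def test_min_mode_is_negated_max_of_negated_volume(self, rng):
        vol, mask = random_volume_and_mask(rng, shape=(9, 9, 9))
        neg = make_volume(-vol.values, vol.spacing)
        lo = metric_peak_sphere(vol, mask, mode="min").value
        hi = metric_peak_sphere(neg, mask, mode="max").value
        assert lo == pytest.approx(-hi)

    def test_matches_brute_force(self, rng):
        for _ in range(10):
            vol, mask = random_volume_and_mask(rng, shape=(9, 9, 9))
            for mode in ("max", "min"):
                expected = brute_peak_sphere(vol.values, mask.mask, vol.spacing, mode)
                got = metric_peak_sphere(vol, mask, mode=mode)
                if expected is None:
                    assert got.clipped
                else:
                    assert not got.clipped
                    assert got.value == pytest.approx(expected[0])

    def test_clipped_fallback_when_no_center_fits(self):
        # tiny image: every kernel overhangs the boundary
        vals = np.arange(27, dtype=float).reshape(3, 3, 3)
        vol, mask = make_volume(vals), make_mask(np.ones((3, 3, 3)))
        res = metric_peak_sphere(vol, mask, mode="max")
        assert res.clipped
        assert np.isfinite(res.value)

    def test_peak_between_mean_and_max(self, rng):
        vol, mask = random_volume_and_mask(rng, shape=(9, 9, 9))
        res = metric_peak_sphere(vol, mask, mode="max")
        if not res.clipped:
            assert res.value <= metric_extremum(vol, mask, "max") + 1e-12


class TestIsocontour:
    def test_uniform_volume_keeps_whole_mask(self):
        vol = make_volume(np.full((4, 4, 4), 2.0))
        mask = make_mask(np.ones((4, 4, 4)))
        assert percent_isocontour(vol, mask).n_voxels == 64

    def test_inclusive_threshold_example(self):
        vals = np.zeros((3, 3, 1))
        vals[:, :, 0] = np.array([[10, 5, 4], [3.9, 1, 0], [0, 0, 0]])
        vol, mask = make_volume(vals), make_mask(np.ones((3, 3, 1)))
        iso = percent_isocontour(vol, mask, 0.40)  # threshold 4.0, inclusive
        assert iso.n_voxels == 3
        assert iso.mask[0, 0, 0] and iso.mask[0, 1, 0] and iso.mask[0, 2, 0]

    def test_fraction_one_keeps_argmax_only(self, rng):
        vol, mask = random_volume_and_mask(rng, shape=(6, 6, 6))
        iso = percent_isocontour(vol, mask, 1.0)
        vmax = vol.values[mask.mask].max()
        assert iso.n_voxels >= 1
        assert np.all(vol.values[iso.mask] == vmax)

    def test_antitone_in_fraction(self, rng):
        vol, mask = random_volume_and_mask(rng, shape=(8, 8, 8))
        iso_lo = percent_isocontour(vol, mask, 0.3)
        iso_hi = percent_isocontour(vol, mask, 0.7)
        assert np.all(~iso_hi.mask | iso_lo.mask)  # hi subset of lo

    def test_matches_brute_force(self, rng):
        for _ in range(20):
            vol, mask = random_volume_and_mask(rng, shape=(6, 6, 6))
            frac = float(rng.uniform(0.1, 1.0))
            np.testing.assert_array_equal(
                percent_isocontour(vol, mask, frac).mask,
                brute_isocontour(vol.values, mask.mask, frac),
            )

    def test_non_positive_max_rejected(self):
        vol = make_volume(np.full((3, 3, 3), -1.0))
        with pytest.raises(ValueError, match="undefined"):
            percent_isocontour(vol, make_mask(np.ones((3, 3, 3))))


class TestVolumesAndTLG:
    def test_thousand_unit_voxels_is_one_mL(self):
        mask = make_mask(np.ones((10, 10, 10)), spacing=(1.0, 1.0, 1.0))
        assert roi_volume(mask) == pytest.approx(1.0)

    def test_empty_mask_is_zero(self):
        assert roi_volume(make_mask(np.zeros((3, 3, 3)))) == 0.0

    def test_ellipsoid_volume_near_analytic(self):
        cfg = PhantomConfig(
            shape=(40, 40, 40), spacing=(1.0, 1.0, 1.0), semi_axes_mm=(12, 10, 10),
            amplitude=2000.0, background=0.0, psf_fwhm_mm=0.0, noise_sd=0.0,
        )
        _, mask, truth = generate_lesion_phantom(cfg)
        analytic = truth["ellipsoid_volume_mL"]
        # within one voxel-layer: surface area * voxel edge
        a, b, c = 12.0, 10.0, 10.0
        surface_mm2 = 4 * np.pi * (((a * b) ** 1.6 + (a * c) ** 1.6 + (b * c) ** 1.6) / 3) ** (1 / 1.6)
        layer_mL = surface_mm2 * 1.0 / 1000.0
        assert abs(roi_volume(mask) - analytic) < layer_mL

    def test_tlg_uniform_example(self):
        # uniform SUV 2 over a 1 mL mask -> TLG 2 g
        mask = make_mask(np.ones((10, 10, 10)), spacing=(1.0, 1.0, 1.0))
        vol = make_volume(np.full((10, 10, 10), 2.0), spacing=(1.0, 1.0, 1.0))
        assert total_lesion_glycolysis(vol, mask) == pytest.approx(2.0)

    def test_tlg_two_formulas_agree(self, rng):
        vol, mask = random_volume_and_mask(rng, shape=(8, 8, 8))
        direct = total_lesion_glycolysis(vol, mask)
        mean, _ = metric_mean_median(vol, mask)
        assert direct == pytest.approx(mean * roi_volume(mask))

    def test_tlg_requires_suv_or_sul(self, rng):
        vol, mask = random_volume_and_mask(rng, kind=ValueKind.ADC)
        with pytest.raises(ValueKindError):
            total_lesion_glycolysis(vol, mask)


class TestExtractMetricSet:
    def test_adc_request(self, rng):
        vol, mask = random_volume_and_mask(rng, shape=(9, 9, 9), kind=ValueKind.ADC)
        ms = extract_metric_set(vol, mask, ["adc_median", "adc_trough", "diffusional_tumor_volume_mL"])
        assert set(ms.values) == {"adc_median", "adc_trough", "diffusional_tumor_volume_mL"}

    def test_incompatible_pairing_rejected(self, rng):
        vol, mask = random_volume_and_mask(rng, kind=ValueKind.SUV)
        with pytest.raises(ValueKindError, match="adc_trough"):
            extract_metric_set(vol, mask, ["adc_trough"])

    def test_invariant_orderings_on_phantom(self):
        cfg = PhantomConfig(
            shape=(24, 24, 24), spacing=(2.0, 2.0, 2.0), semi_axes_mm=(12, 11, 11),
            amplitude=3.0, background=5.0, psf_fwhm_mm=4.0, noise_sd=0.2,
            value_kind=ValueKind.ADC, invert_contrast=True, seed=11,
        )
        vol, mask, _ = generate_lesion_phantom(cfg)
        ms = extract_metric_set(vol, mask, ["adc_max", "adc_min", "adc_mean", "adc_median", "adc_trough"])
        v = ms.values
        assert v["adc_min"] <= v["adc_trough"] <= v["adc_mean"] <= v["adc_max"]
        assert v["adc_min"] <= v["adc_median"] <= v["adc_max"]

    def test_mask_external_voxels_ignored_except_sphere_overhang(self, rng):
        vol, _ = random_volume_and_mask(rng, shape=(8, 8, 8))
        core = np.zeros((8, 8, 8), dtype=bool)
        core[3:6, 3:6, 3:6] = True
        mask = make_mask(core)
        vol2 = make_volume(vol.values + 100.0 * ~core, vol.spacing)  # perturb outside only
        assert metric_extremum(vol, mask, "max") == metric_extremum(vol2, mask, "max")
        assert metric_mean_median(vol, mask) == metric_mean_median(vol2, mask)
        # sphere means legitimately see outside-mask voxels
        p1 = metric_peak_sphere(vol, mask, mode="max")
        p2 = metric_peak_sphere(vol2, mask, mode="max")
        assert p2.value > p1.value
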