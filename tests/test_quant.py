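"""Count-to-SUV chain and VOI metric extraction against independent oracles."""

import math

import numpy as np
import pytest

from bonetrack import (
    AcquisitionMeta,
    EllipsoidVOI,
    GridGeometry,
    concentration_to_suv,
    counts_to_concentration,
    decay_factor,
    net_injected_activity,
    suv_max,
    suv_mean,
    suv_peak,
    uptake_ratio,
    voi_mask,
)
from bonetrack.quant import PEAK_SPHERE_RADIUS_1ML_MM, peak_sphere_center
from bonetrack.volumes import count_volume, concentration_volume, suv_volume

from conftest import brute_force_ellipsoid_count, brute_force_sphere_voxels


class TestDecayFactor:
    def test_one_half_life_doubles(self):
        assert decay_factor(360.4, 360.4) == pytest.approx(2.0, abs=1e-12)

    def test_zero_delta_is_identity(self):
        assert decay_factor(0.0, 360.4) == 1.0

    def test_matches_exponential_form(self):
        # 231 min is a typical injection-to-acquisition delay for Tc-99m bone SPECT
        expected = math.exp(math.log(2) * 231 / 360.4)
        assert decay_factor(231, 360.4) == pytest.approx(expected, rel=1e-14)

    def test_forward_then_backward_is_identity(self):
        assert decay_factor(123.4, 360.4) * decay_factor(-123.4, 360.4) == pytest.approx(
            1.0, abs=1e-12
        )

    def test_rejects_nonpositive_half_life(self):
        with pytest.raises(ValueError):
            decay_factor(10.0, 0.0)


def _meta(prepared, t_prep, residual, t_res, t_inj=0.0, t_acq=0.0, **kw):
    return AcquisitionMeta(
        prepared_activity_mbq=prepared,
        t_prepared_min=t_prep,
        residual_activity_mbq=residual,
        t_residual_min=t_res,
        t_injection_min=t_inj,
        t_acquisition_start_min=t_acq,
        body_weight_kg=kw.pop("weight", 70.0),
        **kw,
    )


class TestNetInjectedActivity:
    def test_no_residual_measured_at_injection(self):
        assert net_injected_activity(_meta(600, 0, 0, 0)) == pytest.approx(600.0)

    def test_prepared_one_half_life_early(self):
        meta = _meta(600, -360.4, 0, 0)
        assert net_injected_activity(meta) == pytest.approx(300.0, rel=1e-12)

    def test_two_term_formula(self):
        # prepared 30 min before injection, residual measured 5 min after
        meta = _meta(600, -30, 20, 5)
        expected = 600 * 2 ** (-30 / 360.4) - 20 * 2 ** (5 / 360.4)
        assert net_injected_activity(meta) == pytest.approx(expected, rel=1e-12)

    def test_residual_exceeding_prepared_after_decay(self):
        meta = _meta(10.0, -3604.0, 9.0, 0.0)  # prepared decays through 10 half-lives
        with pytest.raises(ValueError, match="residual"):
            net_injected_activity(meta)


class TestCountsToConcentration:
    def test_unit_example(self, simple_meta):
        # 150 counts, 1 mL voxel, S=10 cps/kBq, T=15 s, acquisition at injection
        grid = GridGeometry((4, 4, 4), (10.0, 10.0, 10.0))
        counts = count_volume(np.full(grid.shape, 150.0), grid)
        conc = counts_to_concentration(counts, simple_meta)
        assert conc.unit == "kBq/mL"
        np.testing.assert_allclose(conc.data, 1.0)

    def test_zero_counts_give_zero_concentration(self, simple_meta, small_grid):
        counts = count_volume(np.zeros(small_grid.shape), small_grid)
        conc = counts_to_concentration(counts, simple_meta)
        assert not conc.data.any()

    def test_forward_inverse_identity(self):
        """Painted concentration -> expected counts -> concentration round trip."""
        from bonetrack.phantom import expected_counts

        grid = GridGeometry((8, 8, 8), (2.4, 2.4, 2.4))
        meta = _meta(500, 0, 0, 0, t_acq=231.0, calibration_cps_per_kbq=3.0)
        painted = concentration_volume(np.full(grid.shape, 5.0), grid)
        recovered = counts_to_concentration(expected_counts(painted, meta), meta)
        np.testing.assert_allclose(recovered.data, 5.0, atol=1e-9)

    def test_rejects_wrong_unit(self, simple_meta, small_grid):
        conc = concentration_volume(np.ones(small_grid.shape), small_grid)
        with pytest.raises(ValueError, match="counts"):
            counts_to_concentration(conc, simple_meta)


class TestConcentrationToSuv:
    def test_unit_arithmetic(self, small_grid):
        conc = concentration_volume(np.full(small_grid.shape, 5.0), small_grid)
        suv = concentration_to_suv(conc, a_net_mbq=500.0, weight_kg=70.0)
        np.testing.assert_allclose(suv.data, 0.7, rtol=1e-12)

    def test_zero_concentration(self, small_grid):
        conc = concentration_volume(np.zeros(small_grid.shape), small_grid)
        assert not concentration_to_suv(conc, 500.0, 70.0).data.any()

    def test_invert_reapply_identity_subject_p001(self, small_grid):
        # heaviest subject in the cohort: 95 kg, 656 MBq injected
        target_suv = 5.6
        conc_value = target_suv * 656000.0 / 95000.0
        conc = concentration_volume(np.full(small_grid.shape, conc_value), small_grid)
        suv = concentration_to_suv(conc, 656.0, 95.0)
        np.testing.assert_allclose(suv.data, target_suv, rtol=1e-12)

    @pytest.mark.parametrize("a_net,weight", [(0.0, 70.0), (-1.0, 70.0), (500.0, 0.0)])
    def test_rejects_nonpositive_inputs(self, small_grid, a_net, weight):
        conc = concentration_volume(np.ones(small_grid.shape), small_grid)
        with pytest.raises(ValueError):
            concentration_to_suv(conc, a_net, weight)

    def test_suv_invariant_to_dose_and_weight(self, three_lesion_phantom):
        """SUV normalisation cancels injected dose and body weight (noiseless)."""
        from dataclasses import replace

        from bonetrack.phantom import build_activity_volume, expected_counts
        from bonetrack.quant import quantify_counts

        spec = three_lesion_phantom
        suvs = []
        for dose, weight in ((573.0, 73.0), (330.0, 110.0)):
            variant = replace(
                spec, injected_activity_mbq=(dose, dose), subject_weight_kg=weight
            )
            meta = variant.meta(1)
            lam = expected_counts(build_activity_volume(variant, 1), meta)
            suvs.append(quantify_counts(lam, meta).data)
        np.testing.assert_allclose(suvs[0], suvs[1], atol=1e-9)


class TestVoiMask:
    def test_tiny_ellipsoid_selects_one_voxel(self, small_grid):
        center = tuple(small_grid.origin[d] + small_grid.spacing[d] * 8 for d in range(3))
        voi = EllipsoidVOI("v", center, tuple(0.6 * s for s in small_grid.spacing))
        assert voi_mask(voi, small_grid).sum() == 1

    def test_sphere_count_matches_brute_force(self, small_grid):
        voi = EllipsoidVOI("v", (18.0, 19.0, 20.0), (9.0, 9.0, 9.0))
        assert voi_mask(voi, small_grid).sum() == brute_force_ellipsoid_count(voi, small_grid)

    def test_anisotropic_ellipsoid_matches_brute_force(self):
        grid = GridGeometry((12, 10, 14), (2.0, 3.0, 1.5), origin=(-5.0, 0.0, 2.0))
        voi = EllipsoidVOI("v", (6.0, 13.0, 11.0), (7.0, 10.0, 4.0))
        assert voi_mask(voi, grid).sum() == brute_force_ellipsoid_count(voi, grid)

    def test_voi_outside_grid_raises(self, small_grid):
        voi = EllipsoidVOI("v", (1000.0, 1000.0, 1000.0), (5.0, 5.0, 5.0))
        with pytest.raises(ValueError, match="no voxel centers"):
            voi_mask(voi, small_grid)


class TestVoiStatistics:
    def test_uniform_region(self, small_grid):
        suv = suv_volume(np.full(small_grid.shape, 4.2), small_grid)
        mask = np.zeros(small_grid.shape, bool)
        mask[4:8, 4:8, 4:8] = True
        assert suv_mean(suv, mask) == pytest.approx(4.2)
        assert suv_max(suv, mask) == pytest.approx(4.2)

    def test_small_value_set(self, small_grid):
        data = np.zeros(small_grid.shape)
        data[0, 0, :3] = [1.0, 2.0, 3.0]
        mask = np.zeros(small_grid.shape, bool)
        mask[0, 0, :3] = True
        suv = suv_volume(data, small_grid)
        assert suv_mean(suv, mask) == pytest.approx(2.0)
        assert suv_max(suv, mask) == pytest.approx(3.0)

    def test_random_volume_matches_exhaustive_recomputation(self, small_grid):
        rng = np.random.default_rng(42)
        data = rng.gamma(2.0, 2.0, small_grid.shape)
        mask = rng.random(small_grid.shape) < 0.3
        suv = suv_volume(data, small_grid)
        vals = [data[i, j, k] for (i, j, k) in np.argwhere(mask)]
        assert suv_mean(suv, mask) == pytest.approx(sum(vals) / len(vals))
        assert suv_max(suv, mask) == pytest.approx(max(vals))

    def test_empty_mask_rejected(self, small_grid):
        suv = suv_volume(np.ones(small_grid.shape), small_grid)
        empty = np.zeros(small_grid.shape, bool)
        for fn in (suv_mean, suv_max, suv_peak):
            with pytest.raises(ValueError, match="empty mask"):
                fn(suv, empty)


class TestSuvPeak:
    def test_homogeneous_lesion_much_larger_than_sphere(self, small_grid):
        data = np.full(small_grid.shape, 0.5)
        voi = EllipsoidVOI("v", (18.0, 18.0, 18.0), (14.0, 14.0, 14.0))
        mask = voi_mask(voi, small_grid)
        data[mask] = 20.4
        assert suv_peak(suv_volume(data, small_grid), mask) == pytest.approx(20.4)

    def test_single_hot_voxel_equals_h_over_sphere_count(self, small_grid):
        h = 100.0
        data = np.zeros(small_grid.shape)
        data[8, 8, 8] = h
        mask = np.zeros(small_grid.shape, bool)
        mask[6:11, 6:11, 6:11] = True
        center = tuple(small_grid.origin[d] + small_grid.spacing[d] * 8 for d in range(3))
        n_sphere = len(
            brute_force_sphere_voxels(center, PEAK_SPHERE_RADIUS_1ML_MM, small_grid)
        )
        assert suv_peak(suv_volume(data, small_grid), mask) == pytest.approx(h / n_sphere)

    def test_matches_brute_force_sphere_average_on_random_volume(self, small_grid):
        """Full brute-force oracle: argmax voxel, exhaustive sphere membership, mean."""
        rng = np.random.default_rng(7)
        data = rng.gamma(2.0, 3.0, small_grid.shape)
        voi = EllipsoidVOI("v", (18.0, 18.0, 18.0), (10.0, 12.0, 9.0))
        mask = voi_mask(voi, small_grid)
        # oracle: unique max voxel in mask (random floats never tie)
        masked = np.where(mask, data, -np.inf)
        idx = np.unravel_index(np.argmax(masked), data.shape)
        center = tuple(small_grid.origin[d] + small_grid.spacing[d] * idx[d] for d in range(3))
        voxels = brute_force_sphere_voxels(center, PEAK_SPHERE_RADIUS_1ML_MM, small_grid)
        expected = np.mean([data[v] for v in voxels])
        assert suv_peak(suv_volume(data, small_grid), mask) == pytest.approx(expected, rel=1e-12)

    def test_sphere_clipped_at_grid_border(self):
        grid = GridGeometry((8, 8, 8), (2.4, 2.4, 2.4))
        data = np.zeros(grid.shape)
        data[0, 0, 0] = 50.0
        mask = np.zeros(grid.shape, bool)
        mask[:2, :2, :2] = True
        voxels = brute_force_sphere_voxels(grid.origin, PEAK_SPHERE_RADIUS_1ML_MM, grid)
        expected = 50.0 / len(voxels)
        assert suv_peak(suv_volume(data, grid), mask) == pytest.approx(expected)

    def test_peak_never_exceeds_max(self, small_grid):
        rng = np.random.default_rng(3)
        voi = EllipsoidVOI("v", (18.0, 18.0, 18.0), (12.0, 12.0, 12.0))
        mask = voi_mask(voi, small_grid)
        for _ in range(20):
            suv = suv_volume(rng.gamma(1.5, 2.0, small_grid.shape), small_grid)
            assert suv_peak(suv, mask) <= suv_max(suv, mask) + 1e-12

    def test_mean_le_peak_le_max_when_sphere_inside_voi(self, small_grid):
        """Ordering holds when the peak sphere is a subset of a hot uniform core."""
        data = np.full(small_grid.shape, 1.0)
        voi = EllipsoidVOI("v", (18.0, 18.0, 18.0), (14.0, 14.0, 14.0))
        mask = voi_mask(voi, small_grid)
        data[mask] = 10.0
        data[7, 7, 7] = 12.0  # unique max deep inside, sphere stays in the VOI
        suv = suv_volume(data, small_grid)
        assert suv_mean(suv, mask) <= suv_peak(suv, mask) <= suv_max(suv, mask)

    def test_tie_break_prefers_interior_then_lowest_index(self, small_grid):
        """Two tied hot voxels: the one whose sphere average is larger wins."""
        data = np.zeros(small_grid.shape)
        data[2, 2, 2] = 10.0  # near border: sphere partially clipped
        data[8, 8, 8] = 10.0
        data[9, 8, 8] = 4.0  # boosts the interior candidate's sphere average
        mask = np.ones(small_grid.shape, bool)
        suv = suv_volume(data, small_grid)
        assert peak_sphere_center(suv, mask) == (8, 8, 8)


class TestUptakeRatio:
    def test_cohort_mean_values(self):
        assert uptake_ratio(20.4, 5.6) == pytest.approx(20.4 / 5.6)

    def test_lesion_equal_to_reference(self):
        assert uptake_ratio(5.6, 5.6) == pytest.approx(1.0)

    @pytest.mark.parametrize("scale", [0.5, 1.0, 7.3])
    def test_scale_invariance(self, scale):
        assert uptake_ratio(scale * 20.4, scale * 5.6) == pytest.approx(20.4 / 5.6)

    def test_missing_reference_rejected(self):
        with pytest.raises(ValueError, match="reference"):
            uptake_ratio(20.4, 0.0)


class TestAcquisitionMeta:
    def test_timestamps_must_be_ordered(self):
        with pytest.raises(ValueError, match="timestamps"):
            _meta(500, 10.0, 0, 0, t_inj=0.0, t_acq=5.0)

    def test_residual_cannot_exceed_prepared(self):
        with pytest.raises(ValueError):
            _meta(500, 0, 600, 0)

    def test_json_round_trip(self, tmp_path, simple_meta):
        path = tmp_path / "meta.json"
        simple_meta.to_json(path)
        assert AcquisitionMeta.from_json(path) == simple_meta

    def test_malformed_json_named_in_error(self, tmp_path):
        path = tmp_path / "meta.json"
        path.write_text("{not json")
        with pytest.raises(ValueError, match="meta.json"):
            AcquisitionMeta.from_json(path)
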