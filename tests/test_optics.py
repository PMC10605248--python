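"""Focal-ratio measurement: closed forms, invariances, segmentation, dose trends."""

import numpy as np
import pytest

import lenscope as L
from lenscope.errors import InputError, MeasurementError
from lenscope.optics import RoiPair, SpheroidSegmentation
from lenscope.synthetic import spot_amplitude


def uniform_stack(value=1000.0, side=64, n_slices=5):
    return L.ZStack(
        intensities=np.full((n_slices, side, side), value),
        z_positions=np.linspace(-40, 0, n_slices),
    )


def border_rois(side, center=None, half_side=3, band=6):
    bg = np.zeros((side, side), dtype=bool)
    bg[:band, :] = bg[-band:, :] = True
    bg[:, :band] = bg[:, -band:] = True
    if center is None:
        center = (side // 2, side // 2)
    return RoiPair(center=center, half_side=half_side, background_mask=bg)


# odd image side puts a pixel exactly on the optical axis, so the peak
# pixel equals the closed-form amplitude
LENSING_CFG = L.StackSimConfig(image_side=129, spheroid_radius=40,
                               spot_flux_F=5e5, noise_model="none")


class TestFocalRatioCurve:
    def test_uniform_stack_has_unit_ratio(self):
        stack = uniform_stack()
        curve = L.focal_ratio_curve(stack, border_rois(64))
        np.testing.assert_allclose(curve.ratio, 1.0)

    def test_peak_ratio_matches_generator_closed_form(self):
        cfg = LENSING_CFG
        stack = L.simulate_zstack(cfg)
        curve = L.focal_ratio_curve(stack, border_rois(cfg.image_side))
        k = int(np.argmin(np.abs(curve.z_positions - cfg.z_f)))
        expected = (cfg.background_b + spot_amplitude(cfg, cfg.z_f)) / cfg.background_b
        assert curve.ratio[k] == pytest.approx(expected, abs=2e-3)

    def test_ratio_decreases_away_from_focus(self):
        cfg = LENSING_CFG
        curve = L.focal_ratio_curve(L.simulate_zstack(cfg),
                                    border_rois(cfg.image_side))
        z = curve.z_positions
        assert np.all(np.diff(curve.ratio[z <= cfg.z_f]) > 0)
        assert np.all(np.diff(curve.ratio[z >= cfg.z_f]) < 0)

    def test_scale_invariance(self):
        cfg = LENSING_CFG
        base = L.simulate_zstack(cfg)
        scaled = L.ZStack(intensities=base.intensities.astype(float) * 3.7,
                          z_positions=base.z_positions)
        rois = border_rois(cfg.image_side)
        np.testing.assert_allclose(
            L.focal_ratio_curve(base, rois).ratio,
            L.focal_ratio_curve(scaled, rois).ratio,
        )

    def test_constant_offset_moves_ratio_toward_one(self):
        cfg = LENSING_CFG
        base = L.simulate_zstack(cfg)
        offset = L.ZStack(intensities=base.intensities.astype(float) + 500.0,
                          z_positions=base.z_positions)
        rois = border_rois(cfg.image_side)
        r0 = L.focal_ratio_curve(base, rois).ratio
        r1 = L.focal_ratio_curve(offset, rois).ratio
        assert np.all(r1 <= r0)
        assert np.all(r1 >= 1.0)

    def test_zero_background_raises_measurement_error(self):
        stack = uniform_stack(value=0.0)
        with pytest.raises(MeasurementError):
            L.focal_ratio_curve(stack, border_rois(64))

    def test_roi_out_of_bounds_raises_input_error(self):
        stack = uniform_stack()
        with pytest.raises(InputError, match="bounds"):
            L.focal_ratio_curve(stack, border_rois(64, center=(2, 2), half_side=5))

    def test_overlapping_rois_rejected(self):
        bg = np.ones((64, 64), dtype=bool)
        rois = RoiPair(center=(32, 32), half_side=3, background_mask=bg)
        with pytest.raises(InputError, match="overlap"):
            L.focal_ratio_curve(uniform_stack(), rois)


class TestSegmentation:
    def test_disk_centroid_and_area(self):
        cfg = L.StackSimConfig(disk_transmittance=0.85, noise_model="none")
        seg = L.segment_spheroid(L.simulate_zstack(cfg), reference_slice=0)
        assert not seg.no_object
        center = (cfg.image_side - 1) / 2
        assert abs(seg.centroid[0] - center) <= 2
        assert abs(seg.centroid[1] - center) <= 2
        area = seg.mask.sum()
        assert area == pytest.approx(np.pi * cfg.spheroid_radius**2, rel=0.10)

    def test_uniform_image_falls_back_to_centre(self):
        seg = L.segment_spheroid(uniform_stack(side=80))
        assert seg.no_object
        assert seg.centroid == (39.5, 39.5)

    def test_two_disks_picks_larger(self):
        img = np.full((200, 200), 1000.0)
        yy, xx = np.mgrid[0:200, 0:200]
        img[(yy - 60) ** 2 + (xx - 60) ** 2 <= 40**2] = 700.0
        img[(yy - 150) ** 2 + (xx - 150) ** 2 <= 20**2] = 700.0
        stack = L.ZStack(intensities=img[None], z_positions=np.array([0.0]))
        seg = L.segment_spheroid(stack)
        assert abs(seg.centroid[0] - 60) <= 2
        assert abs(seg.centroid[1] - 60) <= 2


class TestFocusSummary:
    def test_flat_curve_does_not_focus(self):
        curve = L.focal_ratio_curve(uniform_stack(), border_rois(64))
        summary = L.focus_summary(curve)
        assert summary.peak_ratio == pytest.approx(1.0)
        assert not summary.focuses_light

    def test_peak_z_matches_planted_focus_noise_free(self):
        cfg = LENSING_CFG
        curve = L.focal_ratio_curve(L.simulate_zstack(cfg),
                                    border_rois(cfg.image_side))
        assert L.focus_summary(curve).peak_z == cfg.z_f

    def test_tie_breaks_to_smallest_abs_z(self):
        curve = L.FocalCurve(
            z_positions=np.array([-20.0, -10.0, 0.0]),
            ratio=np.array([2.0, 1.0, 2.0]),
            max_center=np.ones(3),
            mean_background=np.ones(3),
        )
        assert L.focus_summary(curve).peak_z == 0.0

    def test_full_opacity_gives_unit_peak(self):
        cfg = L.StackSimConfig(image_side=129, spheroid_radius=40,
                               opacity_tau=1.0, noise_model="none")
        curve = L.focal_ratio_curve(L.simulate_zstack(cfg), border_rois(129))
        assert L.focus_summary(curve).peak_ratio == pytest.approx(1.0, abs=1e-3)

    def test_poisson_noise_peak_localization(self):
        # peak z within one slice of the planted focus in >= 95% of runs
        cfg = L.StackSimConfig(noise_model="poisson")
        dz = (cfg.z_max - cfg.z_min) / (cfg.n_slices - 1)
        hits = 0
        n_runs = 200
        for seed in range(n_runs):
            stack = L.simulate_zstack(
                L.StackSimConfig(noise_model="poisson", seed=seed)
            )
            curve = L.focal_ratio_curve(stack, border_rois(cfg.image_side, band=12))
            if abs(L.focus_summary(curve).peak_z - cfg.z_f) <= dz:
                hits += 1
        assert hits / n_runs >= 0.95


class TestCompareConditions:
    def test_identical_conditions_identical_summaries(self):
        cfg = LENSING_CFG
        curve = L.focal_ratio_curve(L.simulate_zstack(cfg),
                                    border_rois(cfg.image_side))
        comparison = L.compare_conditions({"a": [curve, curve], "b": [curve, curve]})
        s = comparison.summary
        assert s.loc[0, "peak_ratio_mean"] == s.loc[1, "peak_ratio_mean"]
        assert s.loc[0, "peak_ratio_sd"] == s.loc[1, "peak_ratio_sd"] == 0.0

    def test_mean_peak_ratio_decreases_with_opacity_dose(self):
        base = L.StackSimConfig(image_side=128, spheroid_radius=40,
                                spot_flux_F=5e5, noise_model="poisson")
        taus = (0.0, 0.3, 0.6, 0.9)
        stacks = L.simulate_dose_series(base, taus, n_per_dose=12, seed=4)
        curves = {
            cond: [L.focal_ratio_curve(s, border_rois(128, band=12)) for s in group]
            for cond, group in stacks.items()
        }
        doses = {f"tau={t:g}": t for t in taus}
        comparison = L.compare_conditions(curves, doses=doses)
        means = comparison.summary["peak_ratio_mean"].to_numpy()
        assert np.all(np.diff(means) < 0)
        assert comparison.trend_rho < -0.9

    def test_empty_condition_rejected(self):
        with pytest.raises(InputError, match="no curves"):
            L.compare_conditions({"a": []})
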