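"""Photobleaching inversion chain: dF/F0, bleach fit, inversion, summaries."""

import numpy as np
import pandas as pd
import pytest

from optospread import lightmap, synthgen
from optospread.lightmap import (
    BleachFit, LightField, ROITable, compute_dff, extract_roi_intensities,
    fit_bleach_constant, invert_intensity, profile_summary,
    separable_light_field,
)


def make_roi_table(x, y, z, F, **kw):
    return ROITable(pd.DataFrame({"x_um": x, "y_um": y, "z_um": z, "F": F}), **kw)


def analytic_field(axial_um=433.0, lateral_sigma_um=None, voxel=10.0,
                   extent_xy=400.0, extent_z=1000.0):
    """LightField sampled from an analytic profile on a fine grid."""
    xs = np.arange(-extent_xy, extent_xy, voxel) + voxel / 2
    ys = xs.copy()
    zs = np.arange(0, extent_z, voxel) + voxel / 2
    X, Y, Z = np.meshgrid(xs, ys, zs, indexing="ij")
    vals = np.exp(-Z / axial_um)
    if lateral_sigma_um is not None:
        vals = vals * np.exp(-(X ** 2 + Y ** 2) / (2 * lateral_sigma_um ** 2))
    vals /= vals.max()
    return LightField(vals, xs, ys, zs, voxel)


# ---------------------------------------------------------------------------
# dF/F0
# ---------------------------------------------------------------------------

class TestComputeDff:
    def test_uniform_fluorescence_gives_zero_dff(self):
        rois = make_roi_table([0, 100, 800], [0, 0, 0], [0, 0, 0], [50.0] * 3)
        out = compute_dff(rois, 700.0)
        assert np.allclose(out.data["f"], 0.0)

    def test_center_dff_against_far_baseline(self):
        rois = make_roi_table([0, 800, 900], [0, 0, 0], [0, 0, 0],
                              [40.0, 100.0, 100.0])
        out = compute_dff(rois, 700.0)
        assert out.f0 == pytest.approx(100.0)
        assert out.data["f"].iloc[0] == pytest.approx(-0.6)

    def test_lateral_mode_matches_3d_when_far_is_lateral(self):
        # all far ROIs beyond threshold in lateral distance: identical F0
        rois = make_roi_table([0, 750, -750], [0, 100, 0], [0, 400, 900],
                              [30.0, 90.0, 110.0])
        a = compute_dff(rois, 700.0, distance_mode="3d")
        b = compute_dff(rois, 700.0, distance_mode="lateral")
        assert a.f0 == pytest.approx(b.f0)

    def test_no_far_rois_raises(self):
        rois = make_roi_table([0, 100], [0, 0], [0, 0], [1.0, 2.0])
        with pytest.raises(ValueError, match="beyond"):
            compute_dff(rois, 700.0)

    def test_scale_invariance(self):
        rois = make_roi_table([0, 800], [0, 0], [0, 0], [40.0, 100.0])
        f1 = compute_dff(rois, 700.0).data["f"]
        rois2 = make_roi_table([0, 800], [0, 0], [0, 0], [400.0, 1000.0])
        f2 = compute_dff(rois2, 700.0).data["f"]
        assert np.allclose(f1, f2)


# ---------------------------------------------------------------------------
# bleach constant fit
# ---------------------------------------------------------------------------

class TestBleachFit:
    def test_recovers_exact_k_from_forward_values(self):
        k = 0.01
        doses = np.array([50.0, 100.0, 200.0])
        f = -1.0 + np.exp(-k * doses)   # -0.3935, -0.6321, -0.8647
        fit = fit_bleach_constant(list(zip(doses, f)))
        assert fit.k_per_mw_min == pytest.approx(k, abs=1e-6)

    def test_zero_dose_point_is_consistent(self):
        k = 0.02
        doses = np.array([0.0, 50.0, 150.0])
        f = -1.0 + np.exp(-k * doses)
        fit = fit_bleach_constant(list(zip(doses, f)))
        assert fit.k_per_mw_min == pytest.approx(k, rel=1e-6)
        assert fit.predict(np.array([0.0]))[0] == pytest.approx(0.0)

    def test_noisy_points_recover_k_within_ten_percent(self, rng):
        k = 0.015
        doses = np.repeat([25.0, 50.0, 100.0, 200.0, 400.0], 8)
        f = (-1.0 + np.exp(-k * doses)) * (1 + 0.05 * rng.standard_normal(len(doses)))
        fit = fit_bleach_constant(list(zip(doses, np.clip(f, -0.999, None))))
        assert fit.k_per_mw_min == pytest.approx(k, rel=0.10)

    def test_single_dose_raises(self):
        with pytest.raises(ValueError, match="distinct doses"):
            fit_bleach_constant([(100.0, -0.5), (100.0, -0.5)])

    def test_no_bleaching_signal_raises(self):
        with pytest.raises(ValueError, match="no bleaching"):
            fit_bleach_constant([(50.0, 0.01), (100.0, 0.02)])


# ---------------------------------------------------------------------------
# inversion
# ---------------------------------------------------------------------------

class TestInvertIntensity:
    def test_requires_dff_column(self):
        rois = make_roi_table([0], [0], [0], [1.0])
        with pytest.raises(ValueError, match="compute_dff"):
            invert_intensity(rois)

    def test_flat_field_raises(self):
        rois = make_roi_table([0, 100], [0, 0], [0, 0], [1.0, 1.0])
        rois.data["f"] = [-0.5, -0.5]
        with pytest.raises(ValueError, match="flat"):
            invert_intensity(rois)

    def test_complete_bleach_rois_excluded_and_flagged(self):
        rois = make_roi_table([0, 50, 100, 150], [0] * 4, [0] * 4, [0.0, 1, 2, 3])
        rois.data["f"] = [-1.0, -0.6, -0.3, 0.0]
        field = invert_intensity(rois, voxel_um=50.0)
        assert field.metadata["n_excluded"] == 1

    def test_inversion_is_monotone_in_bleach_depth(self):
        # stronger bleaching (more negative f) -> larger recovered intensity
        f = np.array([-0.9, -0.6, -0.3, -0.1, 0.0])
        x = 25.0 + np.arange(5) * 100.0   # ROIs at voxel centers
        rois = make_roi_table(x, np.zeros(5), np.zeros(5), np.ones(5))
        rois.data["f"] = f
        field = invert_intensity(rois, voxel_um=50.0)
        vals = field.values.squeeze()[::2]   # voxels holding the ROIs
        assert np.all(np.diff(vals) < 0)
        assert vals[0] == pytest.approx(1.0)

    def test_inverse_of_exponential_closed_form(self):
        # f = e^-1 - 1  =>  unnormalized -ln(f+1) = 1 exactly
        assert -np.log1p(np.exp(-1) - 1) == pytest.approx(1.0)

    def test_forward_inverse_round_trip_noiseless(self):
        """bleach -> dF/F0 -> inversion recovers the field, <5% max error."""
        voxel = 50.0
        xs = np.arange(-500, 500, voxel) + voxel / 2
        zs = np.arange(0, 1000, voxel) + voxel / 2
        X, Y, Z = np.meshgrid(xs, xs, zs, indexing="ij")
        pos = np.column_stack([X.ravel(), Y.ravel(), Z.ravel()])
        vol = synthgen.NucleiVolume(pos, np.full(len(pos), 100.0),
                                    (1000.0, 1000.0, 1000.0))
        true_fn = separable_light_field(400.0, 300.0)
        rois = synthgen.bleach_forward(vol, true_fn, k_dose=3.0 / 200, dose_mw_min=200,
                                       noise_cv=0.0, seed=0)
        dff = compute_dff(rois, f0=100.0)
        rec = invert_intensity(dff, voxel_um=voxel)
        truth = true_fn(pos).reshape(rec.values.shape)
        truth /= truth.max()
        assert np.max(np.abs(rec.values - truth)) < 0.05


# ---------------------------------------------------------------------------
# ROI extraction
# ---------------------------------------------------------------------------

class TestExtractRois:
    def make_spot_stack(self, centers, amp=100.0, background=10.0,
                        shape=(30, 60, 60)):
        z, y, x = np.mgrid[0:shape[0], 0:shape[1], 0:shape[2]]
        stack = np.full(shape, background)
        for cz, cy, cx in centers:
            stack = stack + amp * np.exp(
                -((z - cz) ** 2 + (y - cy) ** 2 + (x - cx) ** 2) / (2 * 2.0 ** 2))
        return stack

    def test_blank_stack_gives_empty_table(self):
        rois = extract_roi_intensities(np.zeros((5, 5, 5)), (5.0, 5.0, 5.0))
        assert len(rois) == 0

    def test_five_spots_detected_at_centers(self):
        centers = [(10, 10, 10), (10, 40, 40), (20, 15, 45), (20, 45, 12),
                   (15, 30, 30)]
        stack = self.make_spot_stack(centers)
        rois = extract_roi_intensities(stack, (5.0, 5.0, 5.0),
                                       origin_um=(0.0, 0.0, 0.0),
                                       min_distance_um=20.0)
        assert len(rois) == 5
        found = rois.data[["z_um", "y_um", "x_um"]].to_numpy() / 5.0
        for c in centers:
            d = np.abs(found - np.asarray(c)).max(axis=1)
            assert d.min() <= 1.0  # within one voxel

    def test_roi_intensity_between_background_and_peak(self):
        stack = self.make_spot_stack([(15, 30, 30)])
        rois = extract_roi_intensities(stack, (5.0, 5.0, 5.0))
        F = rois.data["F"].iloc[0]
        assert 10.0 < F < 110.0

    def test_missing_voxel_size_raises(self):
        with pytest.raises(ValueError, match="voxel"):
            extract_roi_intensities(np.ones((5, 5, 5)), None)


# ---------------------------------------------------------------------------
# profile summaries
# ---------------------------------------------------------------------------

class TestProfileSummary:
    def test_axial_exponential_half_max_depth(self):
        field = analytic_field(axial_um=433.0, lateral_sigma_um=300.0)
        s = profile_summary(field, axis_radius_um=20.0)
        assert s["half_max_depth_um"] == pytest.approx(433.0 * np.log(2), abs=3.0)

    def test_lateral_gaussian_half_width(self):
        field = analytic_field(axial_um=433.0, lateral_sigma_um=114.7)
        s = profile_summary(field, axis_radius_um=20.0)
        expected = 114.7 * np.sqrt(2 * np.log(2))   # 135.0 µm
        assert s["lateral_half_width_um"] == pytest.approx(expected, abs=6.0)

    def test_uniform_field_raises(self):
        voxel = 25.0
        xs = np.arange(-100, 100, voxel) + voxel / 2
        zs = np.arange(0, 500, voxel) + voxel / 2
        field = LightField(np.ones((len(xs), len(xs), len(zs))), xs, xs, zs, voxel)
        with pytest.raises(ValueError, match="never falls"):
            profile_summary(field)

    def test_bootstrap_sem_shrinks_with_roi_count(self):
        """Half-max-depth bootstrap s.e.m. scales roughly as 1/sqrt(n)."""
        sems = {}
        for n in (1500, 6000):
            vol = synthgen.make_nuclei_volume(n, (600.0, 600.0, 600.0), seed=5)
            fn = separable_light_field(200.0, 150.0)
            rois = synthgen.bleach_forward(vol, fn, k_dose=3.0 / 200,
                                           dose_mw_min=200, noise_cv=0.10, seed=6)
            dff = compute_dff(rois, f0=1000.0)
            res = lightmap.bootstrap_half_max_depth(
                dff, n_resamples=120, seed=7, voxel_um=50.0, axis_radius_um=150.0)
            sems[n] = res["sem"]
        ratio = sems[1500] / sems[6000]
        assert 1.2 < ratio < 3.5   # ideal 2.0 for a 4x sample-size increase


class TestFullRecovery:
    def test_blue_light_study_recovers_printed_profile(self):
        """Full chain on the blue-light synthetic volume: ~300 µm depth,
        ~135 µm lateral half-width."""
        from optospread import studies
        res = studies.light_profile_study(seed=1)
        assert res["half_max_depth_um"] == pytest.approx(300.0, rel=0.12)
        assert res["lateral_half_width_um"] == pytest.approx(135.0, rel=0.12)
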