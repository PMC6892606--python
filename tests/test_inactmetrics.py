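"""Inactivation metrics: PSTHs, relative rates, spatial spread, latencies,
rebound, intensity conversion, paradoxical scan."""

import warnings

import numpy as np
import pandas as pd
import pytest

from optospread import inactmetrics, isnmodel, studies, synthgen, unitclass
from optospread.core import PhotostimProtocol, SpikeDataset
from optospread.inactmetrics import (
    PSTH, SpatialProfile, bootstrap_stat, compute_psth,
    earliest_significant_change, first_significant_bin, half_max_radius,
    intensity_from_power, onset_latency, paradoxical_scan, rebound_index,
    relative_rate_population, relative_rate_unit, spatial_profile,
)


def manual_dataset(unit_rates, n_trials=10, duration=1.0, post_rates=None):
    """Dataset with deterministic spike trains: per unit (base_hz, stim_hz),
    spikes laid out on regular grids so window rates are exact."""
    units, spikes = [], []
    trials = pd.DataFrame({"trial_id": [f"t{i}" for i in range(n_trials)],
                           "condition_id": "stim"})
    def lay_spikes(uid, rate, t0, width):
        # exact mean rate across trials: spread fractional counts over trials
        total = int(round(rate * width * n_trials))
        for i, t in enumerate(trials["trial_id"]):
            n = total // n_trials + (1 if i < total % n_trials else 0)
            for j in range(n):
                spikes.append((uid, t, t0 + (j + 0.5) * width / max(n, 1)))

    for k, (base, stim) in enumerate(unit_rates):
        uid = f"u{k}"
        units.append({"unit_id": uid, "lateral_distance_um": 0.0,
                      "depth_um": 300.0})
        lay_spikes(uid, base, -0.5, 0.5)
        lay_spikes(uid, stim, 0.0, duration)
        if post_rates is not None:
            lay_spikes(uid, post_rates[k], duration, 0.5)
    proto = PhotostimProtocol(duration_s=duration, ramp_ms=0.0)
    ds = SpikeDataset(pd.DataFrame(units),
                      pd.DataFrame(spikes, columns=["unit_id", "trial_id",
                                                    "spike_time_s"]),
                      trials, {"stim": proto},
                      trial_window_s=(-0.5, duration + 0.6))
    ds.validate()
    return ds


class TestPSTH:
    def test_single_spike_per_trial_lands_in_one_bin(self):
        units = pd.DataFrame({"unit_id": ["u0"], "lateral_distance_um": [0.0],
                              "depth_um": [0.0]})
        trials = pd.DataFrame({"trial_id": [f"t{i}" for i in range(20)],
                               "condition_id": "stim"})
        spikes = pd.DataFrame({"unit_id": "u0", "trial_id": trials["trial_id"],
                               "spike_time_s": 0.0055})
        ds = SpikeDataset(units, spikes, trials,
                          {"stim": PhotostimProtocol()}, trial_window_s=(-0.5, 1.9))
        psth = compute_psth(ds, bin_ms=1.0, window_ms=(0.0, 10.0))
        rates = psth.rate_hz
        assert rates[5] == pytest.approx(1000.0)   # 1 spike / (1 ms * n_trials)
        assert np.count_nonzero(rates) == 1

    def test_no_spikes_gives_zero_psth(self):
        units = pd.DataFrame({"unit_id": ["u0"], "lateral_distance_um": [0.0],
                              "depth_um": [0.0]})
        trials = pd.DataFrame({"trial_id": ["t0"], "condition_id": "stim"})
        spikes = pd.DataFrame(columns=["unit_id", "trial_id", "spike_time_s"])
        ds = SpikeDataset(units, spikes, trials, {"stim": PhotostimProtocol()})
        psth = compute_psth(ds, bin_ms=10.0, window_ms=(0.0, 100.0))
        assert np.allclose(psth.rate_hz, 0.0)

    def test_homogeneous_poisson_mean_rate(self):
        trains = synthgen.sample_inhomogeneous_poisson(
            lambda t: np.full_like(t, 10.0), 2.0, 100, seed=1,
            t_start_s=-0.5, refractory_s=0.0)
        units = pd.DataFrame({"unit_id": ["u0"], "lateral_distance_um": [0.0],
                              "depth_um": [0.0]})
        trials = pd.DataFrame({"trial_id": [f"t{i}" for i in range(100)],
                               "condition_id": "stim"})
        rows = [( "u0", f"t{i}", t) for i, tr in enumerate(trains) for t in tr]
        ds = SpikeDataset(units,
                          pd.DataFrame(rows, columns=["unit_id", "trial_id",
                                                      "spike_time_s"]),
                          trials, {"stim": PhotostimProtocol()})
        psth = compute_psth(ds, bin_ms=10.0, window_ms=(0.0, 1000.0))
        mean = psth.rate_hz.mean()
        sigma = np.sqrt(10.0 / (100 * 1.0))   # across the 1 s window
        assert abs(mean - 10.0) < 3 * sigma

    def test_empty_selection_raises(self, small_dataset):
        with pytest.raises(ValueError, match="empty"):
            compute_psth(small_dataset, unit_ids=[])


class TestRelativeRates:
    def test_unit_ratio_basic(self):
        ds = manual_dataset([(10.0, 2.0)])
        assert relative_rate_unit(ds, "u0") == pytest.approx(0.2)

    def test_unit_ratio_unchanged_is_one(self):
        ds = manual_dataset([(10.0, 10.0)])
        assert relative_rate_unit(ds, "u0") == pytest.approx(1.0)

    def test_activated_fs_exceeds_one(self):
        ds = manual_dataset([(10.0, 30.0)])
        assert relative_rate_unit(ds, "u0") == pytest.approx(3.0)

    def test_zero_baseline_unit_raises(self):
        ds = manual_dataset([(0.0, 5.0), (10.0, 5.0)])
        with pytest.raises(ValueError, match="zero baseline"):
            relative_rate_unit(ds, "u0")

    def test_population_convention_differs_from_mean_of_ratios(self):
        # (base 10, stim 0) and (base 2, stim 2): population = 2/12
        ds = manual_dataset([(10.0, 0.0), (2.0, 2.0)])
        pop = relative_rate_population(ds)
        assert pop == pytest.approx(1 / 6, abs=1e-9)
        # mean of unit ratios would be 0.5
        ratios = [relative_rate_unit(ds, u) for u in ("u0", "u1")]
        assert np.mean(ratios) == pytest.approx(0.5)

    def test_all_silenced_gives_zero(self):
        ds = manual_dataset([(10.0, 0.0), (4.0, 0.0)])
        assert relative_rate_population(ds) == 0.0

    def test_population_equals_baseline_weighted_mean_of_ratios(self, rng):
        """Algebraic identity: population relative rate equals the
        baseline-rate-weighted mean of unit ratios."""
        pairs = [(b, s) for b, s in zip(rng.integers(2, 20, 8),
                                        rng.integers(0, 12, 8))]
        ds = manual_dataset([(float(b), float(s)) for b, s in pairs])
        pop = relative_rate_population(ds)
        uids = [f"u{k}" for k in range(len(pairs))]
        base = inactmetrics.unit_window_rates(ds, uids, (-0.5, 0.0))
        stim = inactmetrics.unit_window_rates(
            ds, uids, inactmetrics.default_stim_window(ds))
        ratios = np.where(base > 0, stim / np.maximum(base, 1e-12), 0.0)
        weighted = np.sum(base * ratios) / np.sum(base)
        assert pop == pytest.approx(weighted, rel=1e-9)


class TestSpatialProfileAndRadius:
    def analytic_profile(self, sigma=0.68, reduction=0.9, step=0.01,
                         rmax=2.5):
        r = np.arange(step / 2, rmax, step)
        rel = 1 - reduction * np.exp(-r ** 2 / (2 * sigma ** 2))
        table = pd.DataFrame({"unit_id": [f"u{i}" for i in range(len(r))],
                              "distance_mm": r, "base_rate": 1.0,
                              "stim_rate": rel})
        edges = np.arange(0.0, rmax + step / 2, step)
        return SpatialProfile(r, edges, rel, np.zeros_like(r),
                              np.ones(len(r), dtype=int), table)

    def test_gaussian_suppression_crossing_closed_form(self):
        prof = self.analytic_profile(sigma=0.68, reduction=0.9)
        radius, _ = half_max_radius(prof, n_resamples=10, seed=0)
        assert radius == pytest.approx(0.68 * np.sqrt(2 * np.log(2)), abs=0.01)

    def test_linear_reduction_crossing(self):
        r = np.arange(0.005, 2.0, 0.01)
        rel = 1 - 0.8 * (1 - r / 2.0)
        table = pd.DataFrame({"unit_id": [f"u{i}" for i in range(len(r))],
                              "distance_mm": r, "base_rate": 1.0,
                              "stim_rate": rel})
        edges = np.arange(0.0, 2.0 + 0.005, 0.01)
        prof = SpatialProfile(r, edges, rel, np.zeros_like(r),
                              np.ones(len(r), dtype=int), table)
        radius, _ = half_max_radius(prof, n_resamples=10, seed=0)
        assert radius == pytest.approx(1.0, abs=0.02)

    def test_flat_profile_raises(self):
        prof = self.analytic_profile(reduction=0.0)
        with pytest.raises(ValueError):
            half_max_radius(prof, n_resamples=5, seed=0)

    def test_radius_monotone_in_generative_sigma(self):
        radii = []
        for sigma in (0.2, 0.4, 0.6, 0.8, 1.0, 1.2):
            prof = self.analytic_profile(sigma=sigma, rmax=4.0)
            radii.append(half_max_radius(prof, n_resamples=5, seed=0)[0])
        assert np.all(np.diff(radii) > 0)

    def test_profile_tracks_generator_truth(self, small_dataset):
        prof = spatial_profile(small_dataset, label="PYR", seed=0)
        # expected per-bin value: baseline-weighted mean of the generator's
        # relative rate at each unit's actual distance
        tab = prof.unit_table
        idx = np.digitize(tab["distance_mm"], prof.bin_edges_mm) - 1
        r_true = 1 - 0.9 * np.exp(-tab["distance_mm"] ** 2 / (2 * 0.68 ** 2))
        for b in range(len(prof.bin_centers_mm)):
            if np.isnan(prof.relative_rate[b]):
                continue
            sel = idx == b
            expected = np.average(r_true[sel], weights=tab["base_rate"][sel])
            tol = max(4 * prof.sem[b], 0.08)
            assert abs(prof.relative_rate[b] - expected) < tol

    def test_single_unit_bin_has_zero_sem(self):
        ds = manual_dataset([(10.0, 5.0)])
        prof = spatial_profile(ds, label=None, bin_width_mm=0.25, seed=0)
        assert prof.n_units[0] == 1
        assert prof.sem[0] == 0.0

    def test_full_pipeline_half_max_radius_near_truth(self):
        """Scaled-down spatial-spread study recovers sigma*sqrt(2 ln 2)."""
        res = studies.spatial_spread_study(
            seed=11, n_units_per_distance=8, n_trials=20, n_boot=200)
        assert res["half_max_radius_mm"] == pytest.approx(0.80, abs=0.12)
        boot = res["bootstrap"]
        assert boot.ci_lo <= res["half_max_radius_mm"] <= boot.ci_hi


class TestBootstrap:
    def test_identical_units_zero_width_ci(self):
        res = bootstrap_stat(np.full(20, 3.0), np.mean, n_resamples=100, seed=0)
        assert res.ci_lo == res.ci_hi == res.point == 3.0
        assert res.sem == 0.0

    def test_single_resample_warns_and_degenerates(self):
        with warnings.catch_warnings(record=True) as w:
            warnings.simplefilter("always")
            res = bootstrap_stat(np.arange(5.0), np.mean, n_resamples=1, seed=0)
        assert res.sem == 0.0
        assert any("n_resamples" in str(x.message) for x in w)

    def test_ci_coverage_near_nominal(self, rng):
        """90% bootstrap CI covers the true mean in 85-95% of 500
        synthetic repetitions (n = 100 standard-normal units)."""
        n_rep, n, n_boot = 500, 100, 300
        covered = 0
        for _ in range(n_rep):
            x = rng.standard_normal(n)
            draws = rng.integers(0, n, size=(n_boot, n))
            means = x[draws].mean(axis=1)
            lo, hi = np.percentile(means, [5, 95])
            covered += lo <= 0.0 <= hi
        assert 0.85 <= covered / n_rep <= 0.95

    def test_bootstrap_stat_matches_direct_resampling_distribution(self, rng):
        x = rng.standard_normal(100)
        res = bootstrap_stat(x, np.mean, n_resamples=500, seed=3)
        assert res.point == pytest.approx(x.mean())
        assert res.sem == pytest.approx(x.std(ddof=1) / 10, rel=0.3)


class TestOnsetLatency:
    def exponential_psth(self, tau=8.0, base=8.0, floor=0.8, bin_ms=1.0,
                         dur_ms=1300.0):
        edges = np.arange(-200.0, dur_ms + bin_ms / 2, bin_ms)
        centers = (edges[:-1] + edges[1:]) / 2
        rate = np.where(centers < 0, base,
                        floor + (base - floor) * np.exp(-centers / tau))
        return PSTH(edges, np.maximum(rate, 0), 1, 1)

    def test_noiseless_exponential_matches_closed_form(self):
        """For decay to 10% with tau = 8 ms the 90%-of-average-reduction
        rule crosses at ~tau*ln 10 = 18.4 ms."""
        psth = self.exponential_psth()
        onset = onset_latency(psth, stim_window_ms=(0.0, 1300.0))
        # exact crossing of the reference computed from the binned trace
        centers = psth.bin_centers_ms
        stim = centers >= 0
        mean_stim = psth.rate_hz[stim].mean()
        ref = 8.0 - 0.9 * (8.0 - mean_stim)
        expected = 8.0 * np.log(7.2 / (ref - 0.8))
        assert onset == pytest.approx(expected, abs=0.5)

    def test_expfit_method_agrees_on_noiseless_input(self):
        psth = self.exponential_psth()
        a = onset_latency(psth, stim_window_ms=(0.0, 1300.0))
        b = onset_latency(psth, stim_window_ms=(0.0, 1300.0), method="expfit")
        assert a == pytest.approx(b, abs=0.5)

    def test_step_suppression_first_bin(self):
        edges = np.arange(-50.0, 200.0, 1.0)
        centers = (edges[:-1] + edges[1:]) / 2
        rate = np.where(centers < 0, 10.0, 0.5)
        psth = PSTH(edges, rate, 1, 1)
        onset = onset_latency(psth, stim_window_ms=(0.0, 199.0))
        assert 0.0 <= onset <= 1.0

    def test_activity_increase_raises(self):
        edges = np.arange(-50.0, 200.0, 1.0)
        centers = (edges[:-1] + edges[1:]) / 2
        rate = np.where(centers < 0, 5.0, 15.0)
        with pytest.raises(ValueError, match="increase"):
            onset_latency(PSTH(edges, rate, 1, 1),
                          stim_window_ms=(0.0, 199.0))

    def test_full_study_reproduces_published_onset(self):
        """Poisson spiking through the full PSTH chain: ~18.4 ms onset."""
        res = studies.onset_latency_study(seed=3)
        assert res["onset_latency_ms"] == pytest.approx(18.4, abs=2.0)


class TestEarliestChange:
    def test_strong_suppression_detected_in_first_bin(self, rng):
        n_units, baseline = 100, 20.0
        base = rng.poisson(baseline, n_units) / 1.0
        rates = np.tile(rng.poisson(baseline * 0.1, (n_units, 5)) / 0.01 / 100,
                        1)  # 10 ms bins, strongly suppressed
        t = first_significant_bin(rates, base, np.arange(0, 50, 10.0))
        assert t == 0.0

    def test_null_data_rarely_flags(self, rng):
        """Per-bin false-positive rate ~ alpha on null data."""
        n_sim, n_units = 400, 30
        fp = 0
        for _ in range(n_sim):
            base = rng.normal(10, 1, n_units)
            binr = base[:, None] + rng.normal(0, 1, (n_units, 1))
            t = first_significant_bin(binr, base, np.array([0.0]), alpha=0.05)
            fp += t is not None
        rate = fp / n_sim
        assert 0.02 <= rate <= 0.09

    def test_single_unit_raises(self, small_dataset):
        ds = unitclass.classify_dataset(small_dataset)
        one = ds.units["unit_id"].iloc[:1]
        with pytest.raises(ValueError, match=">= 2"):
            first_significant_bin(np.ones((1, 3)), np.ones(1),
                                  np.arange(0, 30, 10.0))

    def test_dataset_level_detection(self, small_dataset):
        ds = unitclass.classify_dataset(small_dataset)
        t = earliest_significant_change(ds, label="PYR",
                                        max_distance_um=600.0,
                                        window_ms=(0.0, 100.0))
        assert t == 0.0   # strong immediate suppression at the center


class TestRebound:
    def test_rebound_fraction_closed_cases(self):
        ds = manual_dataset([(10.0, 5.0)], post_rates=[13.0])
        assert rebound_index(ds, label=None) == pytest.approx(0.3, abs=1e-9)
        ds2 = manual_dataset([(10.0, 5.0)], post_rates=[8.0])
        assert rebound_index(ds2, label=None) == pytest.approx(-0.2, abs=1e-9)
        ds3 = manual_dataset([(10.0, 5.0)], post_rates=[10.0])
        assert rebound_index(ds3, label=None) == pytest.approx(0.0, abs=1e-9)


class TestIntensityFromPower:
    def test_published_convention(self):
        assert intensity_from_power(2 * np.pi, 1.0) == pytest.approx(1.0)
        assert intensity_from_power(6.2832, 1.0) == pytest.approx(1.0, abs=1e-4)

    def test_zero_power(self):
        assert intensity_from_power(0.0, 1.0) == 0.0

    def test_disc_area_convention_is_twice_default(self):
        p, r = 3.7, 0.8
        assert intensity_from_power(p, r, convention="pi") == pytest.approx(
            2 * intensity_from_power(p, r))

    def test_invalid_radius_raises(self):
        with pytest.raises(ValueError):
            intensity_from_power(1.0, 0.0)


@pytest.fixture(scope="module")
def isn_scan():
    return studies.paradoxical_study(seed=7, n_trials=15)


class TestParadoxicalScan:

    def test_fs_minimum_at_pyramidal_silencing(self, isn_scan):
        """FS minimum within one grid step of the lowest intensity where the
        pyramidal relative rate reaches <= 0.1."""
        tab = isn_scan["table"]
        inten = tab["intensity_mw_mm2"].to_numpy()
        pyr = tab["pyr_relative_rate"].to_numpy()
        silenced = inten[pyr <= 0.1]
        assert len(silenced) > 0
        step = np.diff(inten).max()
        assert abs(isn_scan["fs_minimum_intensity"] - silenced[0]) <= step + 1e-9
        assert isn_scan["paradoxical_regime"] is not None

    def test_no_regime_flagged_without_recurrent_excitation(self):
        """Networks with w_ee < 1 never show the paradoxical signature."""
        p = isnmodel.ISNParams(w_ee=0.5, w_ei=1.0, w_ie=1.0, w_ii=0.5,
                               h_e=1.0, h_i=0.3)
        scan = studies.paradoxical_study(seed=8, isn_params=p, n_trials=15)
        assert scan["paradoxical_regime"] is None

    def test_too_few_levels_raises(self, small_dataset):
        ds = unitclass.classify_dataset(small_dataset)
        with pytest.raises(ValueError, match=">= 3"):
            paradoxical_scan(ds)
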