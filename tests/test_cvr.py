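"""CVR estimation: regressor construction, delay search, voxel/ROI fits."""

import numpy as np
import pytest

from cerebroflow import (
    BoldSeries,
    EtCO2Trace,
    GroundTruth,
    build_regressor,
    extract_end_tidal,
    fit_cvr,
    fit_cvr_map,
    gen_bold_series,
    roi_cvr,
)
from cerebroflow.exceptions import (
    CoverageError,
    DegenerateDesignError,
    EmptyMaskError,
    EmptyTraceError,
    NormalizationError,
)

GRID = np.arange(0.0, 16.0, 1.0)


class TestExtractEndTidal:
    def test_sinusoid_peaks(self):
        t = np.arange(0, 60, 0.05)
        co2 = 40 + 5 * np.sin(2 * np.pi * 0.25 * t - np.pi / 2)
        trace = extract_end_tidal(t, co2, min_breath_interval=2.0)
        assert np.allclose(trace.value, 45.0, atol=0.01)
        assert np.allclose(np.diff(trace.time), 4.0, atol=0.1)

    def test_passthrough_when_already_end_tidal(self):
        t = np.arange(0, 40, 4.0)
        v = np.full_like(t, 42.0)
        trace = extract_end_tidal(t, v, already_end_tidal=True)
        assert np.array_equal(trace.time, t)
        assert np.array_equal(trace.value, v)

    def test_peaks_track_slow_ramp(self):
        t = np.arange(0, 60, 0.05)
        ramp = 5.0 * t / 60.0
        co2 = 40 + 5 * np.sin(2 * np.pi * 0.25 * t - np.pi / 2) + ramp
        trace = extract_end_tidal(t, co2, min_breath_interval=2.0)
        expected = 45.0 + 5.0 * trace.time / 60.0
        assert np.all(np.abs(trace.value - expected) < 0.5)

    def test_no_peaks_raises(self):
        t = np.arange(0, 20, 0.1)
        with pytest.raises(EmptyTraceError):
            extract_end_tidal(t, np.linspace(38, 42, t.size))


class TestBuildRegressor:
    def test_constant_trace_gives_constant_regressor(self):
        trace = EtCO2Trace(np.arange(0, 100, 4.0), np.full(25, 40.0))
        reg = build_regressor(trace, tr=3.0, n_volumes=20, delay=7.0)
        assert np.all(reg == 40.0)

    def test_step_shifts_by_exactly_two_volumes(self):
        tr = 3.0
        t = np.arange(0, 40) * tr
        v = np.where(t < 60, 40.0, 50.0)
        trace = EtCO2Trace(t, v)
        r0 = build_regressor(trace, tr, 40, delay=0.0, instrument_offset=0.0)
        r2 = build_regressor(trace, tr, 40, delay=2 * tr,
                             instrument_offset=0.0)
        assert np.array_equal(r2[2:], r0[:-2])

    def test_window_outside_trace_raises(self):
        trace = EtCO2Trace(np.array([0.0, 4.0, 8.0]), np.full(3, 40.0))
        with pytest.raises(CoverageError):
            build_regressor(trace, tr=3.0, n_volumes=10, delay=500.0,
                            instrument_offset=0.0)


class TestFitCVR:
    def test_noiseless_round_trip(self, noiseless_trace, wm_truth):
        bold, _ = gen_bold_series(noiseless_trace, wm_truth, shape=(2, 2, 1))
        res = fit_cvr(bold.data[0, 0, 0], noiseless_trace, bold.tr,
                      delay_grid=GRID, instrument_offset=0.0)
        assert res.cvr == pytest.approx(0.03, abs=1e-8)
        assert res.delay == 6.0
        assert res.r_squared == pytest.approx(1.0)

    def test_instrument_offset_reported_separately(self, noiseless_trace,
                                                   wm_truth):
        bold, _ = gen_bold_series(noiseless_trace, wm_truth, shape=(2, 2, 1))
        res = fit_cvr(bold.data[0, 0, 0], noiseless_trace, bold.tr,
                      delay_grid=GRID, instrument_offset=4.0)
        assert res.delay == 2.0
        assert res.total_delay == 6.0
        assert res.cvr == pytest.approx(0.03, abs=1e-8)

    def test_constant_signal_gives_zero_cvr(self, noiseless_trace):
        res = fit_cvr(np.full(100, 500.0), noiseless_trace, 3.0, GRID)
        assert res.cvr == pytest.approx(0.0, abs=1e-12)
        assert res.r_squared == 0.0

    def test_pure_drift_absorbed_by_scan_number(self, noiseless_trace):
        y = 800.0 + 0.5 * np.arange(200)
        res = fit_cvr(y, noiseless_trace, 3.0, GRID)
        assert res.cvr == pytest.approx(0.0, abs=1e-10)
        assert res.drift_slope == pytest.approx(0.5, abs=1e-10)

    def test_flat_etco2_is_degenerate(self):
        trace = EtCO2Trace(np.arange(0, 400, 4.0), np.full(100, 40.0))
        with pytest.raises(DegenerateDesignError):
            fit_cvr(np.random.default_rng(0).normal(1000, 1, 100),
                    trace, 3.0, GRID)

    def test_zero_mean_signal_raises(self, noiseless_trace):
        with pytest.raises(NormalizationError):
            fit_cvr(np.zeros(100), noiseless_trace, 3.0, GRID)

    def test_scale_invariance(self, noiseless_trace, wm_truth, rng):
        bold, _ = gen_bold_series(noiseless_trace, wm_truth, shape=(2, 2, 1),
                                  noise_sd=3.0, seed=11)
        y = bold.data[0, 0, 0]
        a = fit_cvr(y, noiseless_trace, bold.tr, GRID, 0.0)
        b = fit_cvr(7.3 * y, noiseless_trace, bold.tr, GRID, 0.0)
        assert b.cvr == pytest.approx(a.cvr, rel=1e-12)
        assert b.delay == a.delay

    def test_offset_covariance_through_denominator(self, noiseless_trace,
                                                   wm_truth):
        bold, _ = gen_bold_series(noiseless_trace, wm_truth, shape=(2, 2, 1))
        y = bold.data[0, 0, 0]
        c = 250.0
        a = fit_cvr(y, noiseless_trace, bold.tr, GRID, 0.0)
        b = fit_cvr(y + c, noiseless_trace, bold.tr, GRID, 0.0)
        m = y.mean()
        assert b.cvr == pytest.approx(a.cvr * m / (m + c), rel=1e-10)

    def test_rss_minimal_over_grid(self, noiseless_trace, wm_truth):
        """Exhaustive check: reported RSS <= RSS refit at each grid delay."""
        bold, _ = gen_bold_series(noiseless_trace, wm_truth, shape=(2, 2, 1),
                                  noise_sd=5.0, seed=3)
        y = bold.data[0, 0, 0]
        small = np.arange(0.0, 12.0, 2.0)
        res = fit_cvr(y, noiseless_trace, bold.tr, small, 0.0)
        n = y.size
        for d in small:
            reg = build_regressor(noiseless_trace, bold.tr, n, d, 0.0)
            X = np.column_stack([np.ones(n), reg, np.arange(n)])
            beta, *_ = np.linalg.lstsq(X, y, rcond=None)
            rss = float(np.sum((y - X @ beta) ** 2))
            assert res.rss <= rss + 1e-9

    def test_recovery_sd_decreases_with_noise(self, noiseless_trace, wm_truth):
        sds = []
        for noise in (8.0, 2.0, 0.5):
            est = []
            for seed in range(25):
                bold, _ = gen_bold_series(noiseless_trace, wm_truth,
                                          shape=(1, 1, 1), noise_sd=noise,
                                          seed=seed)
                est.append(fit_cvr(bold.data[0, 0, 0], noiseless_trace,
                                   bold.tr, GRID, 0.0).cvr)
            sds.append(np.std(est))
        assert sds[0] > sds[1] > sds[2]


class TestFitCVRMap:
    def test_two_tissue_label_means(self, noiseless_trace, two_tissue_truth):
        bold, labels = gen_bold_series(noiseless_trace, two_tissue_truth,
                                       shape=(6, 4, 2))
        cmap = fit_cvr_map(bold, noiseless_trace, labels > 0, GRID, 0.0)
        gm_mean = np.nanmean(cmap.cvr[labels == 1])
        wm_mean = np.nanmean(cmap.cvr[labels == 2])
        assert gm_mean == pytest.approx(0.10, rel=0.01)
        assert wm_mean == pytest.approx(0.03, rel=0.01)

    def test_single_voxel_mask_reduces_to_fit_cvr(self, noiseless_trace,
                                                  wm_truth):
        bold, _ = gen_bold_series(noiseless_trace, wm_truth, shape=(3, 3, 1),
                                  noise_sd=2.0, seed=8)
        mask = np.zeros(bold.shape, dtype=bool)
        mask[1, 1, 0] = True
        cmap = fit_cvr_map(bold, noiseless_trace, mask, GRID, 0.0)
        single = fit_cvr(bold.data[1, 1, 0], noiseless_trace, bold.tr,
                         GRID, 0.0)
        assert cmap.cvr[1, 1, 0] == pytest.approx(single.cvr, rel=1e-12)
        assert cmap.delay[1, 1, 0] == single.delay

    def test_pure_noise_mean_cvr_near_zero(self, noiseless_trace):
        rng = np.random.default_rng(21)
        data = 1000.0 + rng.normal(0, 5, size=(8, 8, 2, 240))
        bold = BoldSeries(data, tr=3.0)
        mask = np.ones(bold.shape, dtype=bool)
        cmap = fit_cvr_map(bold, noiseless_trace, mask, GRID, 0.0)
        vals = cmap.cvr[mask]
        se = vals.std() / np.sqrt(vals.size)
        assert abs(vals.mean()) < 3 * se

    def test_outside_mask_is_nan(self, noiseless_trace, wm_truth):
        bold, _ = gen_bold_series(noiseless_trace, wm_truth, shape=(3, 3, 1))
        mask = np.zeros(bold.shape, dtype=bool)
        mask[0, 0, 0] = True
        cmap = fit_cvr_map(bold, noiseless_trace, mask, GRID, 0.0)
        assert np.isnan(cmap.cvr[~mask]).all()

    def test_empty_mask_raises(self, noiseless_trace, wm_truth):
        bold, _ = gen_bold_series(noiseless_trace, wm_truth, shape=(3, 3, 1))
        with pytest.raises(EmptyMaskError):
            fit_cvr_map(bold, noiseless_trace,
                        np.zeros(bold.shape, dtype=bool), GRID)


class TestRoiCVR:
    def test_homogeneous_roi_equals_voxel_mean(self, noiseless_trace,
                                               wm_truth):
        bold, labels = gen_bold_series(noiseless_trace, wm_truth,
                                       shape=(4, 4, 2))
        table = roi_cvr(bold, {"wm": labels == 1}, noiseless_trace,
                        delay_grid=GRID, instrument_offset=0.0)
        cmap = fit_cvr_map(bold, noiseless_trace, labels == 1, GRID, 0.0)
        assert table.loc[0, "cvr_pct_per_mmhg"] == pytest.approx(
            np.nanmean(cmap.cvr[labels == 1]), abs=1e-10)

    def test_mixed_roi_returns_average_response(self, noiseless_trace,
                                                two_tissue_truth):
        # equal gm/wm split with equal delays: mean series responds with the
        # average gain (linearity of the noiseless forward model)
        truth = GroundTruth(cvr_gain={"gm": 0.10, "wm": 0.03},
                            true_delay={"gm": 6.0, "wm": 6.0})
        bold, labels = gen_bold_series(noiseless_trace, truth, shape=(6, 2, 2))
        table = roi_cvr(bold, {"all": labels > 0}, noiseless_trace,
                        delay_grid=GRID, instrument_offset=0.0)
        assert table.loc[0, "cvr_pct_per_mmhg"] == pytest.approx(
            0.065, abs=1e-8)

    def test_exclusion_recovers_tissue_gain(self, noiseless_trace):
        # half the ROI is lesion with zero gain; excluding it restores the
        # tissue response
        truth = GroundTruth(cvr_gain={"lesion": 0.0, "tissue": 0.08},
                            true_delay={"lesion": 6.0, "tissue": 6.0})
        bold, labels = gen_bold_series(noiseless_trace, truth, shape=(6, 2, 2))
        roi = labels > 0
        with_lesion = roi_cvr(bold, {"roi": roi}, noiseless_trace,
                              delay_grid=GRID, instrument_offset=0.0)
        excluded = roi_cvr(bold, {"roi": roi}, noiseless_trace,
                           exclusion_mask=labels == 1, delay_grid=GRID,
                           instrument_offset=0.0)
        assert excluded.loc[0, "cvr_pct_per_mmhg"] == pytest.approx(
            0.08, abs=1e-8)
        assert (with_lesion.loc[0, "cvr_pct_per_mmhg"]
                < excluded.loc[0, "cvr_pct_per_mmhg"])

    def test_fully_excluded_roi_recorded_others_proceed(self, noiseless_trace,
                                                        two_tissue_truth):
        bold, labels = gen_bold_series(noiseless_trace, two_tissue_truth,
                                       shape=(6, 2, 2))
        table = roi_cvr(bold, {"gm": labels == 1, "wm": labels == 2},
                        noiseless_trace, exclusion_mask=labels == 1,
                        delay_grid=GRID, instrument_offset=0.0)
        gm = table[table.roi == "gm"].iloc[0]
        wm = table[table.roi == "wm"].iloc[0]
        assert gm["error"] == "fully excluded" and gm["n_voxels"] == 0
        assert wm["cvr_pct_per_mmhg"] == pytest.approx(0.03, abs=1e-8)

    def test_group_rows_are_unweighted_means(self, noiseless_trace):
        truth = GroundTruth(
            cvr_gain={"wm_a": 0.02, "wm_b": 0.06},
            true_delay={"wm_a": 6.0, "wm_b": 6.0},
        )
        bold, labels = gen_bold_series(noiseless_trace, truth, shape=(6, 2, 2))
        table = roi_cvr(
            bold, {"wm_a": labels == 1, "wm_b": labels == 2},
            noiseless_trace, delay_grid=GRID, instrument_offset=0.0,
            groups={"white_matter": ["wm_a", "wm_b"]})
        combined = table[table.roi == "white_matter"].iloc[0]
        assert combined["cvr_pct_per_mmhg"] == pytest.approx(0.04, abs=1e-8)
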