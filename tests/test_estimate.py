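import numpy as np
import pytest
from scipy.optimize import brentq

import flimca as fc
from flimca.decode import CaTimeline, FLAG_OK
from flimca.errors import BelowFloorError, ConfigurationError, QCError, SaturationError
from flimca.estimate import DeltaEstimate, IntensityTrace


def constant_timeline(ca, n_bins=100, bin_ms=7.0, photons=1e5):
    t = (np.arange(n_bins) + 0.5) * bin_ms
    return CaTimeline(
        time_ms=t,
        bin_width_ms=bin_ms,
        photons=np.full(n_bins, photons),
        ntc=np.full(n_bins, np.nan),
        ca_nM=np.full(n_bins, float(ca)),
        ca_sd_nM=np.full(n_bins, 1.0),
        flags=np.full(n_bins, FLAG_OK, dtype=object),
    )


class TestEstimateBasal:
    def test_constant_timeline(self):
        tl = constant_timeline(30.0)
        assert fc.estimate_basal(tl, ap_time_ms=600.0) == 30.0

    def test_window_before_recording_rejected(self):
        tl = constant_timeline(30.0)
        with pytest.raises(ConfigurationError):
            fc.estimate_basal(tl, ap_time_ms=300.0, window_ms=500.0)

    def test_too_few_usable_bins_is_qc_failure(self):
        tl = constant_timeline(30.0)
        tl.flags[:] = "low_signal"
        with pytest.raises(QCError):
            fc.estimate_basal(tl, ap_time_ms=600.0)

    def test_simulated_recovery_within_ten_percent(self, model, binning,
                                                   truth_curve):
        vals = []
        for seed in range(20):
            sc = fc.CaScenario(ca0=45.0, delta_ca=0.0, ap_time_ms=600.0,
                               photon_rate=1e5 / 7)
            cube = fc.simulate_trial(sc, model, fc.TrialGeometry(), 650.0,
                                     binning, seed=seed)
            tl = fc.decode_timeline(cube, truth_curve)
            vals.append(fc.estimate_basal(tl, 600.0))
        assert np.median(vals) == pytest.approx(45.0, rel=0.10)


class TestEstimateFmax:
    def test_zero_ca_limit(self, model):
        assert fc.estimate_fmax(2.0, 0.0, model) == pytest.approx(12.0)

    def test_saturating_limit(self, model):
        assert fc.estimate_fmax(1.0, 1e12, model) == pytest.approx(1.0, rel=1e-6)

    def test_printed_arithmetic(self, model):
        # f_rest = 1, ca0 = 31 nM: F_max = 271/71
        assert fc.estimate_fmax(1.0, 31.0, model) == pytest.approx(271 / 71)

    def test_nonpositive_frest_rejected(self, model):
        with pytest.raises(ConfigurationError):
            fc.estimate_fmax(0.0, 31.0, model)


class TestEstimatePeak:
    def test_identity_with_saturation_curve(self, model):
        # the two estimator equations are mutual inverses of F(ca)
        f_max = 3.0
        for ca in np.linspace(1.0, 10 * model.kd, 200):
            f = f_max * fc.saturation_fluorescence(ca, model)
            if f >= 0.95 * f_max:
                continue
            assert fc.estimate_peak(f, f_max, model) == pytest.approx(
                ca, rel=1e-9
            )

    def test_no_transient_returns_ca0(self, model):
        ca0 = 40.0
        f_rest = 1.0
        f_max = fc.estimate_fmax(f_rest, ca0, model)
        assert fc.estimate_peak(f_rest, f_max, model) == pytest.approx(
            ca0, rel=1e-12
        )

    def test_matches_root_finding_oracle(self, model):
        f_max = 2.0
        f_peak = f_max * (1 + 1 / model.gamma) / 2
        expected = brentq(
            lambda ca: f_max * fc.saturation_fluorescence(ca, model) - f_peak,
            1e-6,
            1e7,
        )
        assert fc.estimate_peak(f_peak, f_max, model) == pytest.approx(
            expected, rel=1e-9
        )

    def test_saturated_peak_rejected(self, model):
        with pytest.raises(SaturationError):
            fc.estimate_peak(0.96, 1.0, model)

    def test_below_floor_peak_rejected(self, model):
        with pytest.raises(BelowFloorError):
            fc.estimate_peak(1 / 6.5, 1.0, model)

    def test_large_gamma_limit_is_single_site_form(self):
        # gamma -> inf: ca_peak -> kd * f_peak / (f_max - f_peak)
        model = fc.IndicatorModel(gamma=1e6)
        f_max, f_peak = 1.0, 0.5
        assert fc.estimate_peak(f_peak, f_max, model) == pytest.approx(
            model.kd * f_peak / (f_max - f_peak), rel=1e-5
        )


def run_trial(ca0, delta, seed, model, binning, curve, photon_rate=14286.0):
    sc = fc.CaScenario(ca0=ca0, delta_ca=delta, rise_ms=2.0,
                       decay_tau_ms=400.0, ap_time_ms=600.0,
                       photon_rate=photon_rate)
    cube = fc.simulate_trial(sc, model, fc.TrialGeometry(), 1000.0, binning,
                             seed=seed)
    tl = fc.decode_timeline(cube, curve)
    trace = IntensityTrace.from_cube(cube)
    return tl, trace


class TestEstimateDelta:
    def test_simulated_recovery_within_fifteen_percent(self, model, binning,
                                                       truth_curve):
        deltas = []
        for seed in range(10):
            tl, trace = run_trial(40.0, 160.0, seed, model, binning,
                                  truth_curve)
            est = fc.estimate_delta(tl, trace, 600.0, model)
            deltas.append(est.delta_nM)
        assert np.median(deltas) == pytest.approx(160.0, rel=0.15)

    def test_null_transient_ci_covers_zero(self, model, binning, truth_curve):
        from scipy import stats as sps

        deltas = [
            fc.estimate_delta(*run_trial(40.0, 0.0, s, model, binning,
                                         truth_curve), 600.0, model).delta_nM
            for s in range(20)
        ]
        lo, hi = sps.t.interval(0.95, len(deltas) - 1,
                                loc=np.mean(deltas), scale=sps.sem(deltas))
        assert lo <= 0.0 <= hi

    def test_scale_invariance_of_delta(self, model, binning, truth_curve):
        tl, trace = run_trial(40.0, 120.0, 3, model, binning, truth_curve)
        est1 = fc.estimate_delta(tl, trace, 600.0, model)
        scaled = IntensityTrace(trace.time_ms, trace.values * 37.5,
                                ap_time_ms=trace.ap_time_ms)
        est2 = fc.estimate_delta(tl, scaled, 600.0, model)
        assert est2.delta_nM == pytest.approx(est1.delta_nM, rel=1e-12)

    def test_saturated_peak_leaves_delta_missing(self, model):
        tl = constant_timeline(40.0, n_bins=100)
        t = np.arange(0, 700.0)
        vals = np.ones_like(t)
        vals[t >= 600] = 100.0  # absurdly large step -> saturation
        est = fc.estimate_delta(tl, IntensityTrace(t, vals), 600.0, model)
        assert est.delta_nM is None
        assert "saturated_peak" in est.qc_flags

    def test_max_peak_method_available(self, model, binning, truth_curve):
        tl, trace = run_trial(40.0, 160.0, 5, model, binning, truth_curve)
        est = fc.estimate_delta(tl, trace, 600.0, model, peak_method="max")
        assert est.delta_nM == pytest.approx(160.0, rel=0.15)


class TestQCTrialStability:
    @pytest.mark.parametrize(
        "values, passed, cv",
        [
            ([50.0, 50.0, 50.0], True, 0.0),
            ([100.0, 160.0], False, 0.3262),
            ([100.0, 105.0, 95.0], True, 0.05),
        ],
    )
    def test_cv_gate(self, values, passed, cv):
        ok, got_cv = fc.qc_trial_stability(values)
        assert ok is passed
        assert got_cv == pytest.approx(cv, abs=0.01)

    def test_single_trial_passes_with_flag(self):
        ok, cv = fc.qc_trial_stability([42.0])
        assert ok
        assert np.isnan(cv)


class TestCrossvalidateDecay:
    def test_self_consistent_simulation_scores_below_cutoff(
        self, model, binning, truth_curve
    ):
        tl, trace = run_trial(30.0, 80.0, 8, model, binning, truth_curve,
                              photon_rate=3e4)
        score, applicable = fc.crossvalidate_decay(tl, trace, 600.0, model)
        assert applicable
        assert score < 0.35

    def test_constant_trace_detected_as_mismatch(self, model, binning,
                                                 truth_curve):
        tl, trace = run_trial(30.0, 80.0, 8, model, binning, truth_curve,
                              photon_rate=3e4)
        flat = IntensityTrace(trace.time_ms,
                              np.full_like(trace.values, trace.values.mean()))
        score, applicable = fc.crossvalidate_decay(tl, flat, 600.0, model)
        assert applicable
        assert not score < 0.35

    def test_amplitude_rescaling_invariance(self, model, binning, truth_curve):
        tl, trace = run_trial(30.0, 80.0, 8, model, binning, truth_curve,
                              photon_rate=3e4)
        s1, _ = fc.crossvalidate_decay(tl, trace, 600.0, model)
        scaled = IntensityTrace(trace.time_ms, trace.values * 0.01)
        s2, _ = fc.crossvalidate_decay(tl, scaled, 600.0, model)
        assert s2 == pytest.approx(s1, rel=1e-9)

    def test_no_in_range_segment_flagged_not_applicable(self, model):
        tl = constant_timeline(800.0)  # far above the linear range
        t = np.arange(0, 700.0)
        _, applicable = fc.crossvalidate_decay(
            tl, IntensityTrace(t, np.ones_like(t)), 600.0, model
        )
        assert not applicable
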