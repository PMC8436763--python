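import numpy as np
import pytest

import flimca as fc
from flimca.decay import DecayHistogram
from flimca.errors import (
    CalibrationRangeError,
    ConfigurationError,
    FitError,
    LowSignalError,
    UndefinedNTCError,
)

from conftest import noiseless_histogram, noiseless_ntc


class TestComputeNTC:
    def test_single_bin_histogram_gives_one(self, binning):
        counts = np.zeros(binning.n_bins)
        counts[0] = 5000
        hist = DecayHistogram(binning.edges, counts)
        assert fc.compute_ntc(hist, smooth=False) == 1.0

    def test_matches_monoexponential_closed_form(self, binning):
        # noiseless tau = 4 ns decay: NTC ~ (tau/dt)(1 - exp(-9/tau)) = 71.6
        tau = 4.0
        counts = 1e9 * np.diff(1 - np.exp(-binning.edges / tau))
        hist = DecayHistogram(binning.edges, counts)
        ntc = fc.compute_ntc(hist, smooth=False)
        closed_form = (tau / binning.bin_width_ns) * (1 - np.exp(-9 / tau))
        assert ntc == pytest.approx(closed_form, rel=0.01)

    def test_increases_with_ca_on_simulated_histograms(self, model, binning):
        wins = 0
        for seed in range(20):
            lo = fc.compute_ntc(fc.simulate_decay(0.0, model, 1e5, binning,
                                                  seed=seed))
            hi = fc.compute_ntc(fc.simulate_decay(300.0, model, 1e5, binning,
                                                  seed=1000 + seed))
            wins += hi > lo
        assert wins == 20

    def test_noiseless_ntc_strictly_increasing_in_ca(self, model, binning):
        grid = np.linspace(0, 1000, 80)
        ntcs = [noiseless_ntc(ca, model, binning) for ca in grid]
        assert np.all(np.diff(ntcs) > 0)

    def test_all_zero_histogram_rejected(self, binning):
        hist = DecayHistogram(binning.edges, np.zeros(binning.n_bins))
        with pytest.raises(UndefinedNTCError):
            fc.compute_ntc(hist)

    def test_low_peak_rejected(self, binning):
        counts = np.zeros(binning.n_bins)
        counts[0] = 4
        with pytest.raises(LowSignalError):
            fc.compute_ntc(DecayHistogram(binning.edges, counts))


class TestCollapseCube:
    @pytest.fixture()
    def cube(self, model, binning):
        sc = fc.CaScenario(ca0=60.0, photon_rate=3000.0)
        return fc.simulate_trial(sc, model, fc.TrialGeometry(), 140.0,
                                 binning, seed=3)

    def test_photon_conservation_exact(self, cube):
        series = fc.collapse_cube(cube, time_bin_ms=7.0)
        assert series.total == cube.total

    def test_full_duration_bin_gives_single_histogram(self, cube):
        series = fc.collapse_cube(cube, time_bin_ms=cube.duration_ms)
        assert len(series) == 1
        assert series.total == cube.total

    def test_seven_ms_bins_pool_seven_cycles(self, model, binning):
        # deterministic bookkeeping: cycle c contributes c photons in bin 0
        n_cycles = 21
        counts = np.zeros((binning.n_bins, 1, 1, n_cycles), dtype=int)
        counts[0, 0, 0, :] = np.arange(n_cycles)
        cube = fc.ScanCube(counts, binning.edges, cycle_period_ms=1.0)
        series = fc.collapse_cube(cube, time_bin_ms=7.0)
        expected = [np.arange(i * 7, (i + 1) * 7).sum() for i in range(3)]
        assert series.counts[:, 0].tolist() == expected

    def test_bin_shorter_than_cycle_rejected(self, cube):
        with pytest.raises(ConfigurationError):
            fc.collapse_cube(cube, time_bin_ms=0.5)


class TestFitCalibration:
    def test_noiseless_fit_recovers_midpoint_e50(self, model, binning,
                                                 truth_curve):
        # independent oracle: E50 is where the noiseless NTC curve crosses
        # the midpoint of its asymptotes (root finding, no logistic fit)
        from scipy.optimize import brentq

        lo = noiseless_ntc(0.0, model, binning)
        hi = noiseless_ntc(1e9, model, binning)
        mid = (lo + hi) / 2
        e50_root = brentq(
            lambda ca: noiseless_ntc(ca, model, binning) - mid, 1.0, 2000.0
        )
        assert truth_curve.e50 == pytest.approx(e50_root, rel=0.02)
        assert truth_curve.hill == pytest.approx(1.0, abs=1e-3)

    def test_order_invariance(self, model, binning):
        levels = np.array([17.0, 38.0, 100.0, 150.0, 300.0, 602.0])
        ntcs = np.array([noiseless_ntc(lv, model, binning) for lv in levels])
        c1 = fc.fit_calibration(levels, ntcs)
        perm = [3, 0, 5, 1, 4, 2]
        c2 = fc.fit_calibration(levels[perm], ntcs[perm])
        assert c1.e50 == pytest.approx(c2.e50, rel=1e-9)
        assert c1.hill == pytest.approx(c2.hill, rel=1e-9)

    def test_simulated_ladder_monotone_positive_hill(self, model, binning):
        levels = [17.0, 38.0, 100.0, 150.0, 300.0, 602.0]
        rng = np.random.default_rng(0)
        ntcs = [
            fc.compute_ntc(
                fc.simulate_decay(lv, model, 1e6, binning,
                                  seed=int(rng.integers(2**31)))
            )
            for lv in levels
        ]
        curve = fc.fit_calibration(levels, ntcs, binning=binning)
        assert curve.hill > 0
        grid = np.logspace(0, 3, 50)
        assert np.all(np.diff(curve.predict(grid)) > 0)

    def test_too_few_levels_rejected(self):
        with pytest.raises(FitError):
            fc.fit_calibration([10, 100, 1000, 10], [1, 2, 3, 1])

    def test_zero_level_mapped_to_floor(self, model, binning):
        levels = [0.0, 38.0, 100.0, 150.0, 300.0, 602.0]
        ntcs = [noiseless_ntc(max(lv, 1.0), model, binning) for lv in levels]
        curve = fc.fit_calibration(levels, ntcs)
        assert curve.valid_range[0] == 1.0


class TestInvertCalibration:
    def test_round_trip_at_e50(self, truth_curve):
        ntc = truth_curve.predict(truth_curve.e50)
        assert fc.invert_calibration(truth_curve, float(ntc)) == pytest.approx(
            truth_curve.e50, rel=1e-9
        )

    def test_asymptote_midpoint_maps_to_e50(self, truth_curve):
        mid = (truth_curve.ntc_low + truth_curve.ntc_high) / 2
        assert fc.invert_calibration(truth_curve, mid) == pytest.approx(
            truth_curve.e50, rel=1e-9
        )

    def test_out_of_range_rejected(self, truth_curve):
        with pytest.raises(CalibrationRangeError):
            fc.invert_calibration(truth_curve, truth_curve.ntc_high + 1.0)

    def test_uncertainty_scales_inversely_with_sqrt_photons(
        self, model, binning, truth_curve
    ):
        # Monte-Carlo oracle: decoded-ca spread at 1e4 vs 1e6 photons
        def decoded(n_photons, n_draws, base):
            out = []
            for s in range(n_draws):
                h = fc.simulate_decay(100.0, model, n_photons, binning,
                                      seed=base + s)
                ntc = fc.compute_ntc(h)
                out.append(fc.invert_calibration(truth_curve, ntc))
            return np.std(out)

        ratio = decoded(1e4, 400, 0) / decoded(1e6, 400, 10_000)
        assert ratio == pytest.approx(10.0, rel=0.25)


class TestDecodeTimeline:
    def test_constant_ca_recovered_within_five_percent(
        self, model, binning, truth_curve
    ):
        sc = fc.CaScenario(ca0=50.0, photon_rate=1e5 / 7)
        cube = fc.simulate_trial(sc, model, fc.TrialGeometry(), 210.0,
                                 binning, seed=7)
        tl = fc.decode_timeline(cube, truth_curve)
        assert tl.ok().all()
        assert np.nanmean(tl.ca_nM) == pytest.approx(50.0, rel=0.05)

    def test_null_transient_has_no_outlier_bins(self, model, binning,
                                                truth_curve):
        devs = []
        for seed in range(5):
            sc = fc.CaScenario(ca0=40.0, delta_ca=0.0, ap_time_ms=600.0,
                               photon_rate=1e5 / 7)
            cube = fc.simulate_trial(sc, model, fc.TrialGeometry(), 900.0,
                                     binning, seed=seed)
            tl = fc.decode_timeline(cube, truth_curve)
            ca = tl.ca_nM[tl.ok()]
            devs.append(np.abs(ca - ca.mean()).max() / ca.std(ddof=1))
        assert np.mean(np.array(devs) < 4.5) >= 0.8

    def test_bit_level_determinism(self, model, binning, truth_curve):
        sc = fc.CaScenario(ca0=30.0, photon_rate=5000.0)
        cube = fc.simulate_trial(sc, model, fc.TrialGeometry(), 140.0,
                                 binning, seed=9)
        t1 = fc.decode_timeline(cube, truth_curve)
        t2 = fc.decode_timeline(cube, truth_curve)
        assert np.array_equal(t1.ca_nM, t2.ca_nM)
        assert np.array_equal(t1.ntc, t2.ntc)

    def test_low_signal_bins_flagged_not_clamped(self, model, binning,
                                                 truth_curve):
        sc = fc.CaScenario(ca0=30.0, photon_rate=50.0)  # far too dim
        cube = fc.simulate_trial(sc, model, fc.TrialGeometry(), 140.0,
                                 binning, seed=4)
        tl = fc.decode_timeline(cube, truth_curve)
        assert not tl.ok().any()
        assert np.isnan(tl.ca_nM).all()

    def test_uncertainty_decreases_with_photons(self, model, binning,
                                                truth_curve):
        sds = []
        for rate in (2000.0, 50_000.0):
            sc = fc.CaScenario(ca0=60.0, photon_rate=rate)
            cube = fc.simulate_trial(sc, model, fc.TrialGeometry(), 140.0,
                                     binning, seed=11)
            tl = fc.decode_timeline(cube, truth_curve)
            sds.append(np.nanmean(tl.ca_sd_nM))
        assert sds[1] < sds[0]
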