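"""In-silico validation experiments for the decoding and estimation chain.

Each function runs one self-contained recovery or calibration experiment
on synthetic data — the package's substitute for bench validation on
clamped solutions and patched neurons — and returns plain numbers. The
test suite asserts tolerances on these outputs and the reproduction
script reports them; both call the same code, so the numbers the README
quotes are the numbers the suite checks.

All experiments derive their randomness from a single integer seed via
``numpy.random.SeedSequence`` spawning.
"""

from __future__ import annotations

from typing import Iterable, Optional

import numpy as np
import pandas as pd
from scipy import stats as sps

from .decay import DecayBinning, DecayHistogram
from .decode import (
    CalibrationCurve,
    compute_ntc,
    decode_timeline,
    fit_calibration,
)
from .estimate import IntensityTrace, estimate_delta, estimate_fmax, estimate_peak
from .indicator import OGB1, IndicatorModel, saturation_fluorescence
from .pipeline import DEFAULT_CALIBRATION_LADDER
from .simulate import (
    CaScenario,
    TrialGeometry,
    paired_condition_samples,
    simulate_decay,
    simulate_trial,
)
from .stats import branch_order_analysis, paired_condition_test

__all__ = [
    "noiseless_calibration",
    "equation_identity_max_rel_error",
    "calibration_recovery",
    "decode_recovery",
    "delta_recovery_grid",
    "null_delta_ci",
    "kruskal_power",
    "kruskal_type1",
    "paired_power",
    "paired_type1",
    "stability_slope",
]


def _child_seeds(seed: int, n: int) -> list[int]:
    return [int(s) for s in
            np.random.SeedSequence(seed).generate_state(n) % (2**31)]


def noiseless_calibration(
    model: IndicatorModel = OGB1,
    binning: DecayBinning = DecayBinning(),
    levels: Iterable[float] = DEFAULT_CALIBRATION_LADDER,
) -> CalibrationCurve:
    """Ground-truth calibration: logistic fit to shot-noise-free NTC values."""
    from .decay import decay_bin_probabilities

    levels = np.asarray(list(levels), dtype=float)
    ntcs = []
    for lv in levels:
        probs = decay_bin_probabilities(lv, model, binning)
        ntcs.append(compute_ntc(DecayHistogram(binning.edges, probs * 1e12)))
    return fit_calibration(levels, ntcs, binning=binning)


def equation_identity_max_rel_error(
    model: IndicatorModel = OGB1, n: int = 400
) -> float:
    """Max relative error of peak-[Ca] recovery through F_max correction.

    The two saturation-correction equations are mutual inverses of the
    fluorescence curve F(ca); composing them across ca in (0, 10*kd)
    must return ca to numerical precision.
    """
    ca0 = 40.0
    f_rest = float(saturation_fluorescence(ca0, model))
    f_max = estimate_fmax(f_rest, ca0, model)
    worst = 0.0
    for ca in np.linspace(1.0, 10 * model.kd, n):
        f = f_max * float(saturation_fluorescence(ca, model))
        if f >= 0.95 * f_max:
            continue
        rec = estimate_peak(f, f_max, model)
        worst = max(worst, abs(rec / ca - 1.0))
    return worst


def calibration_recovery(
    seed: int = 0,
    photons: float = 1e6,
    model: IndicatorModel = OGB1,
    binning: DecayBinning = DecayBinning(),
    levels: Iterable[float] = DEFAULT_CALIBRATION_LADDER,
) -> dict:
    """Fit the logistic calibration on simulated histograms.

    Returns the fitted and ground-truth E50 (nM), their relative error in
    percent, and whether the fitted curve is monotone over 10-300 nM.
    """
    levels = np.asarray(list(levels), dtype=float)
    truth = noiseless_calibration(model, binning, levels)
    seeds = _child_seeds(seed, len(levels))
    ntcs = [
        compute_ntc(simulate_decay(lv, model, photons, binning, seed=s))
        for lv, s in zip(levels, seeds)
    ]
    curve = fit_calibration(levels, ntcs, binning=binning)
    grid = np.linspace(10.0, 300.0, 100)
    return dict(
        e50_fit=curve.e50,
        e50_truth=truth.e50,
        rel_error_pct=100.0 * abs(curve.e50 / truth.e50 - 1.0),
        monotone=bool(np.all(np.diff(curve.predict(grid)) > 0)),
        curve=curve,
    )


def _constant_cube(ca, photon_rate, duration_ms, model, binning, seed):
    scenario = CaScenario(ca0=ca, photon_rate=photon_rate)
    return simulate_trial(scenario, model, TrialGeometry(), duration_ms,
                          binning, seed=seed)


def decode_recovery(
    seed: int = 0,
    levels: Iterable[float] = (10.0, 30.0, 100.0, 300.0),
    n_seeds: int = 20,
    photons_per_bin: float = 1e5,
    time_bin_ms: float = 7.0,
    duration_ms: float = 210.0,
    model: IndicatorModel = OGB1,
    binning: DecayBinning = DecayBinning(),
    curve: Optional[CalibrationCurve] = None,
) -> dict:
    """Decode constant-[Ca2+] recordings back through the calibration.

    For each true level, simulates ``n_seeds`` independent recordings at
    ``photons_per_bin`` photons per FLIM time bin, decodes them, and
    takes the median across seeds of the per-recording mean. Returns the
    per-level medians and the worst absolute relative error in percent.
    """
    if curve is None:
        curve = noiseless_calibration(model, binning)
    rate = photons_per_bin / (time_bin_ms / TrialGeometry().cycle_period_ms)
    seeds = _child_seeds(seed, n_seeds * len(list(levels)))
    out = {}
    it = iter(seeds)
    for ca in levels:
        means = []
        for _ in range(n_seeds):
            cube = _constant_cube(ca, rate, duration_ms, model, binning,
                                  next(it))
            tl = decode_timeline(cube, curve, time_bin_ms=time_bin_ms)
            means.append(float(np.nanmean(tl.ca_nM)))
        out[float(ca)] = float(np.median(means))
    errs = {ca: 100.0 * abs(v / ca - 1.0) for ca, v in out.items()}
    return dict(medians=out, errors_pct=errs,
                max_abs_error_pct=max(errs.values()))


def _ap_trial(ca0, delta, photon_rate, model, binning, seed,
              ap_time_ms=600.0, duration_ms=1000.0):
    scenario = CaScenario(ca0=ca0, delta_ca=delta, rise_ms=2.0,
                          decay_tau_ms=400.0, ap_time_ms=ap_time_ms,
                          photon_rate=photon_rate)
    cube = simulate_trial(scenario, model, TrialGeometry(), duration_ms,
                          binning, seed=seed)
    return cube


def delta_recovery_grid(
    seed: int = 0,
    ca0_levels: Iterable[float] = (20.0, 40.0, 80.0),
    delta_levels: Iterable[float] = (30.0, 100.0, 250.0),
    n_seeds: int = 12,
    photon_rate: float = 14286.0,
    model: IndicatorModel = OGB1,
    binning: DecayBinning = DecayBinning(),
) -> dict:
    """Joint recovery of (ca0, delta) over a scenario grid.

    Returns per-combination median estimates and biases (percent), and
    the worst absolute median bias for each quantity.
    """
    curve = noiseless_calibration(model, binning)
    combos = [(a, d) for a in ca0_levels for d in delta_levels]
    seeds = _child_seeds(seed, n_seeds * len(combos))
    it = iter(seeds)
    rows = []
    for ca0, delta in combos:
        ests = []
        for _ in range(n_seeds):
            cube = _ap_trial(ca0, delta, photon_rate, model, binning, next(it))
            tl = decode_timeline(cube, curve)
            est = estimate_delta(tl, IntensityTrace.from_cube(cube), 600.0,
                                 model)
            if est.delta_nM is not None:
                ests.append((est.ca0_nM, est.delta_nM))
        med_ca0 = float(np.median([e[0] for e in ests]))
        med_delta = float(np.median([e[1] for e in ests]))
        rows.append(
            dict(
                true_ca0=ca0,
                true_delta=delta,
                median_ca0=med_ca0,
                median_delta=med_delta,
                ca0_bias_pct=100.0 * (med_ca0 / ca0 - 1.0),
                delta_bias_pct=100.0 * (med_delta / delta - 1.0),
            )
        )
    grid = pd.DataFrame(rows)
    return dict(
        grid=grid,
        max_abs_ca0_bias_pct=float(grid.ca0_bias_pct.abs().max()),
        max_abs_delta_bias_pct=float(grid.delta_bias_pct.abs().max()),
    )


def null_delta_ci(
    seed: int = 0,
    n_runs: int = 20,
    ca0: float = 40.0,
    photon_rate: float = 14286.0,
    model: IndicatorModel = OGB1,
    binning: DecayBinning = DecayBinning(),
) -> dict:
    """Decoded evoked entry in a no-transient scenario: mean and 95% CI."""
    curve = noiseless_calibration(model, binning)
    deltas = []
    for s in _child_seeds(seed, n_runs):
        cube = _ap_trial(ca0, 0.0, photon_rate, model, binning, s)
        tl = decode_timeline(cube, curve)
        est = estimate_delta(tl, IntensityTrace.from_cube(cube), 600.0, model)
        deltas.append(est.delta_nM)
    lo, hi = sps.t.interval(0.95, len(deltas) - 1, loc=np.mean(deltas),
                            scale=sps.sem(deltas))
    return dict(mean_nM=float(np.mean(deltas)), ci_low=float(lo),
                ci_high=float(hi), covers_zero=bool(lo <= 0.0 <= hi))


def _order_records(rng, means, sd, n_per_order):
    rows = []
    for order, mu in means.items():
        vals = rng.normal(mu, sd, n_per_order)
        for i, v in enumerate(vals):
            rows.append(
                dict(
                    bouton_id=f"o{order}b{i}",
                    cell_id=f"o{order}c{i // 4}",   # 1-4 boutons per cell
                    animal_id=f"o{order}a{i // 8}",
                    branch_order=order,
                    condition="control",
                    delta_nM=float(v),
                )
            )
    return pd.DataFrame(rows)


def kruskal_power(
    seed: int = 0,
    n_runs: int = 200,
    means: dict = None,
    sd: float = 30.0,
    n_per_order: int = 20,
    alpha: float = 0.05,
) -> float:
    """Rejection rate of the Kruskal-Wallis branch-order test.

    Defaults reproduce the observed evoked-entry effect: group means
    42/76/101 nM, within-group SD 30 nM, 20 boutons per order.
    """
    if means is None:
        means = {1: 42.0, 2: 76.0, 3: 101.0}
    rng = np.random.default_rng(seed)
    rejected = 0
    for _ in range(n_runs):
        df = _order_records(rng, means, sd, n_per_order)
        res = branch_order_analysis(df, "delta", include_anova=False)
        rejected += res.kruskal.p_value < alpha
    return rejected / n_runs


def kruskal_type1(seed: int = 0, n_runs: int = 2000, mean: float = 60.0,
                  sd: float = 30.0, n_per_order: int = 20,
                  alpha: float = 0.05) -> float:
    """False-positive rate of the branch-order test under a null design."""
    return kruskal_power(seed, n_runs, {1: mean, 2: mean, 3: mean}, sd,
                         n_per_order, alpha)


def paired_power(seed: int = 0, n_runs: int = 200, mean_before: float = 99.0,
                 effect_ratio: float = 0.31, n: int = 9,
                 alpha: float = 0.05) -> float:
    """Power of the gated paired test on a TBOA-sized evoked-entry drop."""
    rejected = 0
    for s in _child_seeds(seed, n_runs):
        b, a = paired_condition_samples(mean_before, effect_ratio, n, seed=s)
        rejected += paired_condition_test(b, a).p_value < alpha
    return rejected / n_runs


def paired_type1(seed: int = 0, n_runs: int = 2000, mean: float = 99.0,
                 n: int = 9, alpha: float = 0.05) -> float:
    """False-positive rate of the gated paired test (effect ratio 1)."""
    return paired_power(seed, n_runs, mean, 1.0, n, alpha)


def stability_slope(
    seed: int = 0,
    n_boutons: int = 16,
    n_repeats: int = 10,
    ca0: float = 40.0,
    photons_per_bin: float = 1e5,
    duration_ms: float = 105.0,
    model: IndicatorModel = OGB1,
    binning: DecayBinning = DecayBinning(),
) -> dict:
    """Repeated-measure stability of the basal readout.

    Simulates ``n_repeats`` measurement cycles (nominally 2 min apart)
    for each bouton at a fixed resting level and regresses the decoded
    basal [Ca2+], averaged across boutons, on the cycle index. A flat
    readout has a slope whose 95% CI covers zero.
    """
    import statsmodels.api as sm

    curve = noiseless_calibration(model, binning)
    rate = photons_per_bin / 7.0
    seeds = iter(_child_seeds(seed, n_boutons * n_repeats))
    per_cycle = np.zeros((n_repeats, n_boutons))
    for b in range(n_boutons):
        for r in range(n_repeats):
            cube = _constant_cube(ca0, rate, duration_ms, model, binning,
                                  next(seeds))
            tl = decode_timeline(cube, curve)
            per_cycle[r, b] = float(np.nanmean(tl.ca_nM))
    cycle_means = per_cycle.mean(axis=1)
    X = sm.add_constant(np.arange(n_repeats, dtype=float))
    fit = sm.OLS(cycle_means, X).fit()
    lo, hi = fit.conf_int()[1]
    return dict(
        slope_nM_per_cycle=float(fit.params[1]),
        ci_low=float(lo),
        ci_high=float(hi),
        covers_zero=bool(lo <= 0.0 <= hi),
        cycle_means=cycle_means,
    )
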