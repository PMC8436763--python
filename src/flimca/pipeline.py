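"""End-to-end scenario runner: simulate -> calibrate -> decode -> estimate -> stats.

A :class:`ScenarioConfig` (validated pydantic model, loadable from YAML)
describes one in-silico experiment: the indicator and TCSPC binning, a
clamped-[Ca2+] calibration ladder, a nested bouton population with
condition effects, and per-trial acquisition settings. The runner chains
the full pipeline deterministically from a single seed (sub-seeds are
spawned per stage and per trial), writes every intermediate artifact to
disk, and logs seeds, parameters and QC drop counts.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import Dict, Optional, Tuple

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, Field, field_validator

from . import __version__
from .decay import DecayBinning
from .decode import decode_timeline, fit_calibration, compute_ntc
from .errors import FlimcaError, PipelineError
from .estimate import IntensityTrace, estimate_delta, qc_trial_stability
from .indicator import IndicatorModel
from .io import save_cube, save_records
from .simulate import (
    CaScenario,
    ConditionEffect,
    PopulationDesign,
    TrialGeometry,
    simulate_decay,
    simulate_population,
    simulate_trial,
)
from .stats import branch_order_analysis, paired_condition_test

__all__ = ["ScenarioConfig", "ScenarioResult", "run_scenario", "DEFAULT_CALIBRATION_LADDER"]

log = logging.getLogger("flimca")

#: Clamped free-[Ca2+] calibration ladder (nM), spanning the sigmoid.
DEFAULT_CALIBRATION_LADDER = (17.0, 38.0, 100.0, 150.0, 300.0, 602.0)


class IndicatorConfig(BaseModel):
    kd: float = 240.0
    gamma: float = 6.0
    tau_free: float = 0.7
    tau_bound: float = 3.7
    rep_window: float = 12.5

    def build(self) -> IndicatorModel:
        return IndicatorModel(**self.model_dump())


class BinningConfig(BaseModel):
    n_bins: int = 250
    bin_width_ns: float = 0.05

    def build(self) -> DecayBinning:
        return DecayBinning(**self.model_dump())


class CalibrationConfig(BaseModel):
    levels_nM: Tuple[float, ...] = DEFAULT_CALIBRATION_LADDER
    photons_per_level: float = 1e6


class PopulationConfig(BaseModel):
    n_cells: int = 8
    boutons_per_cell: int = 3
    branch_order_means: Dict[int, Tuple[float, float]] = Field(
        default_factory=lambda: {1: (31.0, 42.0), 2: (45.0, 76.0), 3: (34.0, 101.0)}
    )
    cell_sd: float = 8.0
    bouton_sd: float = 10.0
    condition_effects: Dict[str, Tuple[float, float]] = Field(
        default_factory=lambda: {"control": (1.0, 1.0)}
    )

    def build(self, seed: int) -> PopulationDesign:
        return PopulationDesign(
            n_cells=self.n_cells,
            boutons_per_cell=self.boutons_per_cell,
            branch_order_means=dict(self.branch_order_means),
            cell_sd=self.cell_sd,
            bouton_sd=self.bouton_sd,
            condition_effects={
                k: ConditionEffect(*v) for k, v in self.condition_effects.items()
            },
            seed=seed,
        )


class TrialConfig(BaseModel):
    photon_rate: float = 14000.0   # expected photons per scan cycle at rest
    cycle_period_ms: float = 1.0
    pixels_per_cycle: int = 4
    duration_ms: float = 1000.0
    ap_time_ms: float = 600.0
    rise_ms: float = 2.0
    decay_tau_ms: float = 400.0
    n_trials: int = 1

    @field_validator("n_trials")
    @classmethod
    def _at_least_one(cls, v):
        if v < 1:
            raise ValueError("n_trials must be >= 1")
        return v


class DecodeConfig(BaseModel):
    time_bin_ms: float = 7.0
    window_ns: float = 9.0
    min_photons: float = 1000.0


class ScenarioConfig(BaseModel):
    """Validated configuration of one end-to-end synthetic experiment."""

    indicator: IndicatorConfig = IndicatorConfig()
    binning: BinningConfig = BinningConfig()
    calibration: CalibrationConfig = CalibrationConfig()
    population: PopulationConfig = PopulationConfig()
    trial: TrialConfig = TrialConfig()
    decode: DecodeConfig = DecodeConfig()
    baseline_condition: str = "control"
    seed: int = 0
    keep_cubes: bool = False

    @classmethod
    def from_yaml(cls, path) -> "ScenarioConfig":
        with open(path) as fh:
            return cls.model_validate(yaml.safe_load(fh) or {})

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(json.loads(self.model_dump_json()), fh)


class ScenarioResult(BaseModel):
    outdir: str
    curve_path: str
    records_path: str
    stats_path: str
    n_boutons: int
    n_qc_dropped: int

    model_config = dict(frozen=True)


def _fit_curve(config: ScenarioConfig, model, binning, rng):
    levels = np.asarray(config.calibration.levels_nM, dtype=float)
    ntcs = []
    for lv in levels:
        hist = simulate_decay(
            lv, model, config.calibration.photons_per_level, binning,
            seed=int(rng.integers(2**31)),
        )
        ntcs.append(compute_ntc(hist, window_ns=config.decode.window_ns))
    return fit_calibration(levels, ntcs, binning=binning)


def run_scenario(config: ScenarioConfig, outdir) -> ScenarioResult:
    """Run one scenario end to end; deterministic for a fixed config.

    Writes ``curve.json``, ``records.csv``, per-bouton timelines,
    ``stats.json`` and (optionally) raw cubes under ``outdir``. Any stage
    failure aborts with a stage-tagged :class:`PipelineError`.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    (outdir / "timelines").mkdir(exist_ok=True)
    log.info("flimca %s scenario seed=%d outdir=%s", __version__, config.seed, outdir)
    model = config.indicator.build()
    binning = config.binning.build()
    geometry = TrialGeometry(config.trial.pixels_per_cycle,
                             config.trial.cycle_period_ms)
    root = np.random.default_rng(config.seed)

    # --- calibration ---------------------------------------------------
    try:
        curve = _fit_curve(config, model, binning, root)
    except FlimcaError as exc:
        raise PipelineError("calibrate", str(exc)) from exc
    curve_path = outdir / "curve.json"
    curve.to_json(curve_path)
    log.info("calibration: E50=%.1f nM hill=%.3f asymptotes=(%.2f, %.2f)",
             curve.e50, curve.hill, curve.ntc_low, curve.ntc_high)

    # --- population ground truth ---------------------------------------
    try:
        design = config.population.build(seed=int(root.integers(2**31)))
        truth = simulate_population(design)
    except FlimcaError as exc:
        raise PipelineError("population", str(exc)) from exc
    truth.to_csv(outdir / "population_truth.csv", index=False)

    # --- per-bouton trials: simulate, decode, estimate -----------------
    rows = []
    n_dropped = 0
    for _, row in truth.iterrows():
        scenario = CaScenario(
            ca0=row.true_ca0_nM,
            delta_ca=row.true_delta_nM,
            rise_ms=config.trial.rise_ms,
            decay_tau_ms=config.trial.decay_tau_ms,
            ap_time_ms=config.trial.ap_time_ms,
            photon_rate=config.trial.photon_rate,
        )
        ca0s, deltas = [], []
        flags: list = []
        try:
            for trial in range(config.trial.n_trials):
                cube = simulate_trial(
                    scenario, model, geometry, config.trial.duration_ms,
                    binning, seed=int(root.integers(2**31)),
                    meta=dict(bouton_id=row.bouton_id, cell_id=row.cell_id,
                              condition=row.condition, trial=trial),
                )
                if config.keep_cubes:
                    save_cube(cube, outdir / f"{row.bouton_id}_{row.condition}_t{trial}.h5")
                timeline = decode_timeline(
                    cube, curve,
                    window_ns=config.decode.window_ns,
                    time_bin_ms=config.decode.time_bin_ms,
                    min_photons=config.decode.min_photons,
                )
                timeline.to_csv(
                    outdir / "timelines" /
                    f"{row.bouton_id}_{row.condition}_t{trial}.csv"
                )
                trace = IntensityTrace.from_cube(cube)
                est = estimate_delta(timeline, trace, config.trial.ap_time_ms,
                                     model)
                ca0s.append(est.ca0_nM)
                if est.delta_nM is not None:
                    deltas.append(est.delta_nM)
                flags.extend(est.qc_flags)
        except FlimcaError as exc:
            raise PipelineError(
                "decode", f"bouton {row.bouton_id} ({row.condition}): {exc}"
            ) from exc
        stable, cv = qc_trial_stability(ca0s)
        if not stable:
            n_dropped += 1
            log.info("QC drop %s/%s: basal CV %.2f > 0.20",
                     row.bouton_id, row.condition, cv)
            continue
        rows.append(
            dict(
                bouton_id=row.bouton_id,
                cell_id=row.cell_id,
                animal_id=row.animal_id,
                branch_order=row.branch_order,
                distance_um=row.distance_um,
                condition=row.condition,
                ca0_nM=round(float(np.mean(ca0s)), 4),
                delta_nM=(round(float(np.mean(deltas)), 4) if deltas else np.nan),
                qc_flags=";".join(sorted(set(flags))),
            )
        )
    records = pd.DataFrame(rows)
    records_path = outdir / "records.csv"
    save_records(records, records_path)
    log.info("estimated %d bouton-condition records (%d QC-dropped)",
             len(records), n_dropped)

    # --- statistics -----------------------------------------------------
    try:
        stats_out = _run_stats(records, config.baseline_condition)
    except FlimcaError as exc:
        raise PipelineError("stats", str(exc)) from exc
    stats_path = outdir / "stats.json"
    with open(stats_path, "w") as fh:
        json.dump(stats_out, fh, indent=2)
    return ScenarioResult(
        outdir=str(outdir),
        curve_path=str(curve_path),
        records_path=str(records_path),
        stats_path=str(stats_path),
        n_boutons=len(records),
        n_qc_dropped=n_dropped,
    )


def _run_stats(records: pd.DataFrame, baseline: str) -> dict:
    out: dict = {}
    base = records[records.condition == baseline]
    if base.branch_order.nunique() >= 2:
        for resp in ("ca0", "delta"):
            try:
                res = branch_order_analysis(base, resp)
            except FlimcaError as exc:
                log.info("branch-order analysis (%s) skipped: %s", resp, exc)
                continue
            out[f"branch_order_{resp}"] = dict(
                kruskal=vars(res.kruskal),
                anova_order=vars(res.anova_order),
                anova_cell=vars(res.anova_cell),
            )
    for cond in records.condition.unique():
        if cond == baseline:
            continue
        after = records[records.condition == cond]
        for resp, col in (("ca0", "ca0_nM"), ("delta", "delta_nM")):
            try:
                r = paired_condition_test(base, after, value=col)
            except FlimcaError:
                continue
            mb = base[col].dropna().mean()
            ma = after[col].dropna().mean()
            out[f"paired_{cond}_{resp}"] = dict(
                **vars(r), mean_before=mb, mean_after=ma,
                percent_change=100.0 * (1.0 - ma / mb) if mb > 0 else np.nan,
            )
    return out
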