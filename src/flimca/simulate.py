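"""Synthetic TCSPC / tornado-scan data generation.

Three generators mirror the three kinds of data the analysis consumes:

* :func:`simulate_decay` — clamped-[Ca2+] calibration histograms
  (Poisson photon counts whose expectation follows the two-state decay
  model);
* :func:`simulate_trial` — a single-bouton tornado-scan recording as a
  ``t x x x y x T`` photon-count cube, with a resting level, an optional
  action-potential-evoked step (linear equilibration over ``rise_ms``)
  and exponential relaxation;
* :func:`simulate_population` — a nested population of boutons in cells
  with branch-order structure, between-cell random effects and condition
  labels, as the statistics module expects.

The spiral (tornado) trajectory is abstracted to ``pixels_per_cycle``
equal-dwell pixels: the analysis collapses all spatial structure before
decoding, so no point-spread model is simulated. All randomness flows
from explicit integer seeds via ``numpy.random.default_rng``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .decay import DecayBinning, DecayHistogram, decay_bin_probabilities
from .errors import ConfigurationError, EmptyDesignError
from .indicator import OGB1, IndicatorModel, saturation_fluorescence

__all__ = [
    "CaScenario",
    "TrialGeometry",
    "ScanCube",
    "ConditionEffect",
    "PopulationDesign",
    "simulate_decay",
    "ca_profile",
    "simulate_trial",
    "simulate_population",
    "paired_condition_samples",
]


@dataclass(frozen=True)
class CaScenario:
    """Ground-truth [Ca2+] time course for one simulated trial.

    ``ap_time_ms=None`` means no stimulus: [Ca2+] stays at ``ca0`` for the
    whole recording (calibration-style or stability recordings). With a
    stimulus, [Ca2+] rises linearly from ``ca0`` to ``ca0 + delta_ca``
    over ``rise_ms`` (diffusion equilibration across the bouton takes
    2-3 ms) and then relaxes exponentially with ``decay_tau_ms``.
    """

    ca0: float = 40.0            # resting [Ca2+], nM
    delta_ca: float = 0.0        # evoked increment, nM
    rise_ms: float = 2.0         # equilibration time, ms (<= 3)
    decay_tau_ms: float = 400.0  # transient decay constant, ms
    ap_time_ms: Optional[float] = None  # stimulus onset, ms
    photon_rate: float = 5000.0  # expected photons per scan cycle at rest

    def __post_init__(self) -> None:
        if self.ca0 < 0 or self.delta_ca < 0:
            raise ConfigurationError("ca0 and delta_ca must be >= 0 nM")
        if not (0 < self.rise_ms <= 3):
            raise ConfigurationError(
                f"rise_ms must be in (0, 3] ms, got {self.rise_ms}"
            )
        if self.decay_tau_ms <= 0:
            raise ConfigurationError("decay_tau_ms must be > 0")
        if self.photon_rate < 0:
            raise ConfigurationError("photon_rate must be >= 0")
        if self.ap_time_ms is not None and self.ap_time_ms < 500:
            raise ConfigurationError(
                "ap_time_ms must be >= 500 ms so a full ~500 ms basal "
                f"averaging window exists, got {self.ap_time_ms}"
            )


@dataclass(frozen=True)
class TrialGeometry:
    """Abstracted tornado-scan geometry: N equal-dwell pixels per cycle."""

    pixels_per_cycle: int = 4
    cycle_period_ms: float = 1.0

    def __post_init__(self) -> None:
        if self.pixels_per_cycle < 1:
            raise ConfigurationError("pixels_per_cycle must be >= 1")
        if not (0.5 <= self.cycle_period_ms <= 2.0):
            raise ConfigurationError(
                "cycle_period_ms outside the plausible spiral-scan range "
                f"[0.5, 2] ms: {self.cycle_period_ms}"
            )


@dataclass
class ScanCube:
    """Photon counts from one tornado-scan trial, indexed (t, x, y, T).

    ``t`` is the nanosecond decay bin, ``(x, y)`` the scan pixels and
    ``T`` the scan-cycle index. ``meta`` carries bouton/cell/trial ids.
    """

    counts: np.ndarray           # (t, x, y, T) non-negative ints
    bin_edges: np.ndarray        # ns, len t+1
    cycle_period_ms: float
    ap_time_ms: Optional[float] = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 4:
            raise ConfigurationError("counts must be a t*x*y*T 4-D array")
        if np.any(self.counts < 0):
            raise ConfigurationError("photon counts must be >= 0")

    @property
    def n_cycles(self) -> int:
        return self.counts.shape[3]

    @property
    def duration_ms(self) -> float:
        return self.n_cycles * self.cycle_period_ms

    def cycle_times_ms(self) -> np.ndarray:
        """Mid-cycle timestamps in ms."""
        return (np.arange(self.n_cycles) + 0.5) * self.cycle_period_ms

    def intensity_trace(self) -> np.ndarray:
        """Total photons per scan cycle (the analogue-intensity readout)."""
        return self.counts.sum(axis=(0, 1, 2))

    @property
    def total(self) -> int:
        return int(self.counts.sum())


def simulate_decay(
    ca: float,
    model: IndicatorModel = OGB1,
    n_photons: float = 1e5,
    binning: DecayBinning = DecayBinning(),
    seed: int = 0,
    irf_sigma_ns: Optional[float] = None,
) -> DecayHistogram:
    """Simulate one clamped-[Ca2+] calibration histogram.

    Counts are independent Poisson draws with per-bin expectation
    ``n_photons`` times the exact bin integral of the decay density, so
    the total count is Poisson(``n_photons``). ``irf_sigma_ns`` optionally
    blurs the expectation with a Gaussian instrument response.
    """
    if n_photons <= 0:
        raise ConfigurationError("n_photons must be > 0")
    lam = n_photons * decay_bin_probabilities(ca, model, binning)
    if irf_sigma_ns is not None:
        from scipy.ndimage import gaussian_filter1d

        lam = gaussian_filter1d(lam, irf_sigma_ns / binning.bin_width_ns,
                                mode="constant")
    rng = np.random.default_rng(seed)
    counts = rng.poisson(lam)
    return DecayHistogram(binning.edges, counts, origin=int(np.argmax(lam)))


def ca_profile(times_ms: np.ndarray, scenario: CaScenario) -> np.ndarray:
    """Ground-truth [Ca2+] (nM) at the given timestamps."""
    t = np.asarray(times_ms, dtype=float)
    if np.any(np.diff(t) < 0):
        raise ConfigurationError("time axis must be non-decreasing")
    ca = np.full_like(t, scenario.ca0)
    if scenario.ap_time_ms is None:
        return ca
    t0, rise = scenario.ap_time_ms, scenario.rise_ms
    rising = (t >= t0) & (t < t0 + rise)
    ca[rising] = scenario.ca0 + scenario.delta_ca * (t[rising] - t0) / rise
    after = t >= t0 + rise
    ca[after] = scenario.ca0 + scenario.delta_ca * np.exp(
        -(t[after] - t0 - rise) / scenario.decay_tau_ms
    )
    return ca


def simulate_trial(
    scenario: CaScenario,
    model: IndicatorModel = OGB1,
    geometry: TrialGeometry = TrialGeometry(),
    duration_ms: float = 2000.0,
    binning: DecayBinning = DecayBinning(),
    seed: int = 0,
    meta: Optional[dict] = None,
) -> ScanCube:
    """Simulate one tornado-scan trial as a ScanCube.

    The expected photon flux per cycle scales with total fluorescence
    F([Ca2+](t)) of the saturation curve, normalized so the basal flux
    equals ``scenario.photon_rate``; the decay-bin distribution follows
    the two-state decay density at the instantaneous [Ca2+]. Photons are
    split evenly across pixels (equal dwell).
    """
    if duration_ms <= 0:
        raise ConfigurationError("duration_ms must be > 0")
    if scenario.ap_time_ms is not None and duration_ms < (
        scenario.ap_time_ms + scenario.rise_ms
    ):
        raise ConfigurationError(
            "duration_ms must cover ap_time_ms + rise_ms"
        )
    n_cycles = int(round(duration_ms / geometry.cycle_period_ms))
    if n_cycles < 1:
        raise ConfigurationError("recording shorter than one scan cycle")
    times = (np.arange(n_cycles) + 0.5) * geometry.cycle_period_ms
    ca_t = ca_profile(times, scenario)

    f_rest = saturation_fluorescence(scenario.ca0, model)
    rate_t = scenario.photon_rate * saturation_fluorescence(ca_t, model) / f_rest

    probs = decay_bin_probabilities(ca_t, model, binning)  # (t_bins, T)
    npx = geometry.pixels_per_cycle
    lam = probs * (rate_t / npx)[None, :]                  # (t_bins, T)
    rng = np.random.default_rng(seed)
    counts = rng.poisson(lam[:, None, :], size=(binning.n_bins, npx, n_cycles))
    counts = counts[:, :, None, :]                         # y-axis singleton
    return ScanCube(
        counts=counts,
        bin_edges=binning.edges,
        cycle_period_ms=geometry.cycle_period_ms,
        ap_time_ms=scenario.ap_time_ms,
        meta={**(meta or {}), "seed": seed},
    )


@dataclass(frozen=True)
class ConditionEffect:
    """Multiplicative condition effect on true (ca0, delta_ca) means."""

    ca0_scale: float = 1.0
    delta_scale: float = 1.0


@dataclass
class PopulationDesign:
    """Nested bouton-in-cell population with branch-order structure.

    Per-bouton ground truth is
    ``branch-order mean * condition effect + cell random effect + bouton
    noise``, truncated at zero. 1-4 boutons per cell and ~2 cells per
    animal reflect the typical recording yield; branch orders are drawn
    uniformly from the keys of ``branch_order_means``.
    """

    n_cells: int = 10
    boutons_per_cell: int = 3
    branch_order_means: dict = field(
        default_factory=lambda: {1: (31.0, 42.0), 2: (45.0, 76.0), 3: (34.0, 101.0)}
    )  # order -> (mean ca0, mean delta), nM
    cell_sd: float = 8.0         # between-cell random-effect SD, nM
    bouton_sd: float = 10.0      # within-cell bouton SD, nM
    condition_effects: dict = field(
        default_factory=lambda: {"control": ConditionEffect()}
    )
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cells < 1 or self.boutons_per_cell < 1:
            raise EmptyDesignError("need at least one cell and one bouton")
        if self.cell_sd < 0 or self.bouton_sd < 0:
            raise ConfigurationError("SDs must be >= 0")
        if not set(self.branch_order_means) <= {1, 2, 3}:
            raise ConfigurationError("branch orders must be in {1, 2, 3}")
        for k, v in self.condition_effects.items():
            if not isinstance(v, ConditionEffect):
                self.condition_effects[k] = ConditionEffect(*np.atleast_1d(v)[:2])


def simulate_population(design: PopulationDesign) -> pd.DataFrame:
    """Draw a nested bouton population; one row per bouton x condition.

    Returns a table with columns ``bouton_id, cell_id, animal_id,
    branch_order, distance_um, condition, true_ca0_nM, true_delta_nM,
    seed``. The same bouton keeps its cell effect and noise draw across
    conditions (paired design); condition effects act multiplicatively
    on the branch-order means.
    """
    rng = np.random.default_rng(design.seed)
    orders = sorted(design.branch_order_means)
    rows = []
    for ci in range(design.n_cells):
        cell_id = f"cell{ci:03d}"
        animal_id = f"animal{ci // 2:03d}"
        cell_eff = rng.normal(0.0, design.cell_sd, size=2)  # (ca0, delta)
        for bi in range(design.boutons_per_cell):
            bouton_id = f"{cell_id}_b{bi}"
            order = int(rng.choice(orders))
            distance = float(rng.uniform(30, 100) * order)
            noise = rng.normal(0.0, design.bouton_sd, size=2)
            mu_ca0, mu_delta = design.branch_order_means[order]
            for cond, eff in design.condition_effects.items():
                ca0 = max(0.0, mu_ca0 * eff.ca0_scale + cell_eff[0] + noise[0])
                delta = max(0.0, mu_delta * eff.delta_scale + cell_eff[1] + noise[1])
                rows.append(
                    dict(
                        bouton_id=bouton_id,
                        cell_id=cell_id,
                        animal_id=animal_id,
                        branch_order=order,
                        distance_um=round(distance, 1),
                        condition=cond,
                        true_ca0_nM=ca0,
                        true_delta_nM=delta,
                        seed=design.seed,
                    )
                )
    return pd.DataFrame(rows)


def paired_condition_samples(
    mean_before: float,
    effect_ratio: float,
    n: int,
    cv_between: float = 0.45,
    cv_measure: float = 0.2,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Paired lognormal before/after samples for one pharmacology effect.

    Each bouton has a shared lognormal random effect (CV ``cv_between``);
    each condition adds independent lognormal measurement noise (CV
    ``cv_measure``), so the per-group coefficient of variation is about
    ``sqrt((1+cv_between^2)(1+cv_measure^2) - 1)`` (~0.5 with defaults).
    The after-condition mean is ``mean_before * effect_ratio``; pairing
    correlation mimics repeated measurement of the same boutons.
    """
    rng = np.random.default_rng(seed)

    def ln(mean, cv, size):
        sigma2 = np.log1p(cv**2)
        mu = np.log(mean) - sigma2 / 2
        return rng.lognormal(mu, np.sqrt(sigma2), size)

    base = ln(mean_before, cv_between, n)
    before = base * ln(1.0, cv_measure, n)
    after = base * effect_ratio * ln(1.0, cv_measure, n)
    return before, after
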