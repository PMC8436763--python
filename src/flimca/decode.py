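"""FLIM decoding: the NTC lifetime statistic and logistic calibration.

The Normalized Total Count (NTC) summarizes a TCSPC decay histogram as
the photon count integrated over a fixed 9 ns post-pulse window divided
by the histogram's peak value. Because a slower decay spreads counts
away from the peak, NTC increases monotonically with [Ca2+] for a
Ca-sensitive lifetime dye. A logistic curve on log10[Ca2+],

    NTC(ca) = low + (high - low) / (1 + 10^(hill * (log10 E50 - log10 ca))),

is fitted to clamped-[Ca2+] calibration measurements and inverted in
closed form to decode [Ca2+] from measured NTC values. For the
two-state decay model used by the simulator this logistic is exact with
hill = 1 (the NTC of a two-component mixture is a Moebius function of
the brightness-weighted bound fraction, which is itself a single-site
isotherm in ca), so the fit is a parameter estimate, not an
approximation.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy.ndimage import uniform_filter1d
from scipy.optimize import curve_fit

from .decay import DecayBinning, DecayHistogram
from .errors import (
    CalibrationRangeError,
    ConfigurationError,
    FitError,
    LowSignalError,
    UndefinedNTCError,
)
from .simulate import ScanCube

__all__ = [
    "compute_ntc",
    "HistogramSeries",
    "collapse_cube",
    "CalibrationCurve",
    "fit_calibration",
    "invert_calibration",
    "ntc_shot_noise_sd",
    "CaTimeline",
    "decode_timeline",
]

#: Calibration points nominally at zero [Ca2+] are mapped to this floor
#: (nM) so the fit can work on a log axis.
ZERO_CA_FLOOR_NM = 1.0


def compute_ntc(
    hist: DecayHistogram,
    window_ns: float = 9.0,
    smooth: bool = True,
    min_peak_counts: float = 10.0,
) -> float:
    """Normalized Total Count of a decay histogram.

    Counts are summed from the origin (pulse-peak bin) over ``window_ns``
    and divided by the peak value. The origin and peak are taken from the
    histogram after a 3-bin moving-average smooth (reduces shot-noise
    bias in the peak at low counts); pass ``smooth=False`` for the raw
    maximum. The sum always uses raw counts.

    Raises
    ------
    UndefinedNTCError
        All-zero histogram.
    LowSignalError
        Peak below ``min_peak_counts``.
    ConfigurationError
        Window does not fit inside the acquisition span.
    """
    counts = np.asarray(hist.counts, dtype=float)
    if counts.sum() == 0:
        raise UndefinedNTCError("all-zero histogram: NTC undefined")
    ref = uniform_filter1d(counts, 3, mode="nearest") if smooth else counts
    peak = float(ref.max())
    if peak < min_peak_counts:
        raise LowSignalError(
            f"histogram peak {peak:.1f} below min_peak_counts={min_peak_counts}"
        )
    origin = int(np.argmax(ref))
    n_win = int(round(window_ns / hist.bin_width_ns))
    if origin + n_win > len(counts):
        raise ConfigurationError(
            f"{window_ns} ns window does not fit after the origin bin"
        )
    return float(counts[origin : origin + n_win].sum() / peak)


@dataclass
class HistogramSeries:
    """Time-binned decay histograms from one collapsed ScanCube."""

    times_ms: np.ndarray       # time-bin centers
    bin_width_ms: float
    counts: np.ndarray         # (n_time_bins, n_decay_bins)
    bin_edges: np.ndarray      # decay-bin edges, ns

    def __len__(self) -> int:
        return len(self.times_ms)

    def histogram(self, i: int) -> DecayHistogram:
        return DecayHistogram(self.bin_edges, self.counts[i])

    @property
    def total(self) -> int:
        return int(self.counts.sum())


def collapse_cube(
    cube: ScanCube,
    pixel_pool: Optional[int] = None,
    time_bin_ms: float = 7.0,
) -> HistogramSeries:
    """Collapse spatial structure and pool scan cycles into time bins.

    Sums photon counts over pixels (all of them by default, or the first
    ``pixel_pool`` neighbouring pixels) and over the scan cycles falling
    in each ``time_bin_ms`` window. With ``pixel_pool=None`` the total
    photon number is preserved exactly.
    """
    if cube.total == 0 and cube.n_cycles == 0:
        raise ConfigurationError("empty cube")
    if time_bin_ms < cube.cycle_period_ms:
        raise ConfigurationError(
            "time_bin_ms must be >= the scan cycle period"
        )
    counts = cube.counts
    if pixel_pool is not None:
        if pixel_pool < 1:
            raise ConfigurationError("pixel_pool must be >= 1")
        flat = counts.reshape(counts.shape[0], -1, counts.shape[3])
        counts = flat[:, :pixel_pool, None, :]
    spatial = counts.sum(axis=(1, 2))                     # (t_bins, T)
    cyc_per_bin = int(round(time_bin_ms / cube.cycle_period_ms))
    n_full = spatial.shape[1] // cyc_per_bin
    if n_full == 0:
        raise ConfigurationError("recording shorter than one time bin")
    trimmed = spatial[:, : n_full * cyc_per_bin]
    pooled = trimmed.reshape(spatial.shape[0], n_full, cyc_per_bin).sum(axis=2)
    width = cyc_per_bin * cube.cycle_period_ms
    times = (np.arange(n_full) + 0.5) * width
    return HistogramSeries(
        times_ms=times,
        bin_width_ms=width,
        counts=pooled.T,
        bin_edges=cube.bin_edges,
    )


def _logistic(logca, low, high, loge50, hill):
    return low + (high - low) / (1.0 + 10.0 ** (hill * (loge50 - logca)))


@dataclass
class CalibrationCurve:
    """Fitted logistic mapping between NTC and log10[Ca2+], invertible."""

    ntc_low: float             # asymptote at zero Ca
    ntc_high: float            # asymptote at saturating Ca
    e50: float                 # nM
    hill: float                # slope on log10[Ca2+], > 0
    fit_cov: np.ndarray = field(default_factory=lambda: np.full((4, 4), np.nan))
    valid_range: tuple = (1.0, 1000.0)   # nM
    binning_digest: Optional[str] = None
    n_points: int = 0

    def __post_init__(self) -> None:
        if self.ntc_low == self.ntc_high:
            raise FitError("degenerate calibration: equal asymptotes")
        if self.e50 <= 0:
            raise FitError("E50 must be > 0")
        if self.hill <= 0 or self.ntc_high < self.ntc_low:
            raise FitError("calibration must be monotone increasing in ca")

    def predict(self, ca) -> np.ndarray:
        """NTC expected at free [Ca2+] ``ca`` (nM)."""
        ca = np.maximum(np.asarray(ca, dtype=float), 1e-12)
        return _logistic(np.log10(ca), self.ntc_low, self.ntc_high,
                         np.log10(self.e50), self.hill)

    def slope(self, ca) -> np.ndarray:
        """d NTC / d ca at ``ca`` (per nM); used for error propagation."""
        u = (self.predict(ca) - self.ntc_low) / (self.ntc_high - self.ntc_low)
        return (self.ntc_high - self.ntc_low) * self.hill * u * (1 - u) / ca

    # serialization -----------------------------------------------------
    def to_dict(self) -> dict:
        return dict(
            ntc_low=self.ntc_low,
            ntc_high=self.ntc_high,
            e50=self.e50,
            hill=self.hill,
            fit_cov=np.asarray(self.fit_cov).tolist(),
            valid_range=list(self.valid_range),
            binning_digest=self.binning_digest,
            n_points=self.n_points,
        )

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)

    @classmethod
    def from_dict(cls, d: dict) -> "CalibrationCurve":
        d = dict(d)
        d["fit_cov"] = np.asarray(d.get("fit_cov", np.full((4, 4), np.nan)))
        d["valid_range"] = tuple(d.get("valid_range", (1.0, 1000.0)))
        return cls(**d)

    @classmethod
    def from_json(cls, path) -> "CalibrationCurve":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


def fit_calibration(
    ca_levels,
    ntc_values,
    weights=None,
    binning: Optional[DecayBinning] = None,
) -> CalibrationCurve:
    """Least-squares logistic fit of NTC against log10[Ca2+].

    ``ca_levels`` are clamped free-[Ca2+] levels in nM (zeros are mapped
    to a 1 nM floor for the log axis); ``weights`` are optional relative
    precisions (1/variance scale). Requires >= 5 distinct levels; the fit
    is refused if the recovered curve is not monotone increasing.
    """
    ca = np.asarray(ca_levels, dtype=float)
    y = np.asarray(ntc_values, dtype=float)
    if ca.shape != y.shape:
        raise ConfigurationError("ca_levels and ntc_values must match")
    if np.any(ca < 0):
        raise ConfigurationError("ca_levels must be >= 0")
    ca = np.where(ca == 0, ZERO_CA_FLOOR_NM, ca)
    if len(np.unique(ca)) < 5:
        raise FitError("need >= 5 distinct calibration levels")
    order = np.argsort(ca, kind="stable")
    ca, y = ca[order], y[order]
    sigma = None
    if weights is not None:
        w = np.asarray(weights, dtype=float)[order]
        if np.any(w <= 0):
            raise ConfigurationError("weights must be > 0")
        sigma = 1.0 / np.sqrt(w)
    logca = np.log10(ca)
    p0 = [y.min(), y.max(), np.log10(np.median(ca)), 1.0]
    try:
        popt, pcov = curve_fit(_logistic, logca, y, p0=p0, sigma=sigma,
                               maxfev=20000)
    except RuntimeError as exc:  # pragma: no cover - rare non-convergence
        raise FitError(f"logistic fit did not converge: {exc}") from exc
    low, high, loge50, hill = popt
    if high < low:  # same curve re-parameterized; canonicalize
        low, high, hill = high, low, -hill
    if hill <= 0 or high <= low:
        raise FitError(
            f"fitted curve is not monotone increasing (hill={hill:.3g}); "
            "check the calibration data"
        )
    return CalibrationCurve(
        ntc_low=float(low),
        ntc_high=float(high),
        e50=float(10**loge50),
        hill=float(hill),
        fit_cov=pcov,
        valid_range=(float(ca.min()), float(ca.max())),
        binning_digest=binning.digest() if binning is not None else None,
        n_points=len(ca),
    )


def invert_calibration(
    curve: CalibrationCurve, ntc: float, ntc_sd: Optional[float] = None
):
    """Decode [Ca2+] (nM) from an NTC value via the closed-form inverse.

    Requires ``ntc`` strictly inside the open asymptote interval;
    otherwise a :class:`CalibrationRangeError` is raised (the caller
    decides whether to clamp or drop). If ``ntc_sd`` is given, the
    delta-method uncertainty is returned as a second value.
    """
    lo, hi = curve.ntc_low, curve.ntc_high
    if not (lo < ntc < hi):
        raise CalibrationRangeError(
            f"NTC {ntc:.3f} outside the open interval ({lo:.3f}, {hi:.3f})"
        )
    z = (ntc - lo) / (hi - ntc)
    ca = float(10 ** (np.log10(curve.e50) + np.log10(z) / curve.hill))
    if ntc_sd is None:
        return ca
    ca_sd = float(ntc_sd / curve.slope(ca))
    return ca, ca_sd


def ntc_shot_noise_sd(hist: DecayHistogram, ntc: float,
                      smooth: bool = True) -> float:
    """Shot-noise (Poisson) standard deviation of the NTC of ``hist``.

    First-order approximation Var(S/P)/NTC^2 ~ 1/S + 1/P with S the
    window sum and P the peak count; halves per fourfold photons, i.e.
    scales as 1/sqrt(N).
    """
    counts = np.asarray(hist.counts, dtype=float)
    ref = uniform_filter1d(counts, 3, mode="nearest") if smooth else counts
    peak = float(ref.max())
    s = ntc * peak
    if s <= 0 or peak <= 0:
        raise UndefinedNTCError("cannot propagate noise for empty histogram")
    return float(ntc * np.sqrt(1.0 / s + 1.0 / peak))


#: CaTimeline bin flags.
FLAG_OK = "ok"
FLAG_LOW_SIGNAL = "low_signal"
FLAG_OUT_OF_RANGE = "out_of_range"


@dataclass
class CaTimeline:
    """Decoded [Ca2+] versus time for one bouton trial.

    One row per FLIM time bin (~7 ms): photon count, NTC, decoded
    [Ca2+] with shot-noise uncertainty, and a QC flag. Flagged bins have
    NaN concentration and are excluded, never clamped.
    """

    time_ms: np.ndarray
    bin_width_ms: float
    photons: np.ndarray
    ntc: np.ndarray
    ca_nM: np.ndarray
    ca_sd_nM: np.ndarray
    flags: np.ndarray          # str array, FLAG_* values
    ap_time_ms: Optional[float] = None
    meta: dict = field(default_factory=dict)

    def ok(self) -> np.ndarray:
        return self.flags == FLAG_OK

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            dict(
                time_ms=self.time_ms,
                photons=self.photons,
                ntc=self.ntc,
                ca_nM=self.ca_nM,
                ca_sd_nM=self.ca_sd_nM,
                flag=self.flags,
            )
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def decode_timeline(
    cube: ScanCube,
    curve: CalibrationCurve,
    window_ns: float = 9.0,
    time_bin_ms: float = 7.0,
    min_photons: float = 1000.0,
    smooth: bool = True,
) -> CaTimeline:
    """Decode a ScanCube into a [Ca2+] timeline.

    Composition of :func:`collapse_cube`, :func:`compute_ntc` and
    :func:`invert_calibration` per time bin. Bins with fewer than
    ``min_photons`` total photons (too little signal in the decay tail)
    or with NTC outside the calibration asymptotes are flagged and get
    NaN concentration.
    """
    binning = DecayBinning(
        n_bins=len(cube.bin_edges) - 1,
        bin_width_ns=float(cube.bin_edges[1] - cube.bin_edges[0]),
    )
    if curve.binning_digest is not None and curve.binning_digest != binning.digest():
        raise ConfigurationError(
            "calibration was fitted for a different TCSPC binning"
        )
    series = collapse_cube(cube, time_bin_ms=time_bin_ms)
    n = len(series)
    photons = series.counts.sum(axis=1)
    ntc = np.full(n, np.nan)
    ca = np.full(n, np.nan)
    ca_sd = np.full(n, np.nan)
    flags = np.full(n, FLAG_OK, dtype=object)
    for i in range(n):
        hist = series.histogram(i)
        if photons[i] < min_photons:
            flags[i] = FLAG_LOW_SIGNAL
            continue
        try:
            ntc[i] = compute_ntc(hist, window_ns=window_ns, smooth=smooth)
            sd = ntc_shot_noise_sd(hist, ntc[i], smooth=smooth)
            ca[i], ca_sd[i] = invert_calibration(curve, ntc[i], ntc_sd=sd)
        except (LowSignalError, UndefinedNTCError):
            flags[i] = FLAG_LOW_SIGNAL
        except CalibrationRangeError:
            flags[i] = FLAG_OUT_OF_RANGE
    return CaTimeline(
        time_ms=series.times_ms,
        bin_width_ms=series.bin_width_ms,
        photons=photons,
        ntc=ntc,
        ca_nM=ca,
        ca_sd_nM=ca_sd,
        flags=np.asarray(flags, dtype=object),
        ap_time_ms=cube.ap_time_ms,
        meta=dict(cube.meta),
    )
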