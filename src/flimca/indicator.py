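"""Photophysical model of a single-wavelength Ca2+ indicator (OGB-1 style).

The indicator is described by an equilibrium two-state model: a Ca-free
state with fluorescence lifetime ``tau_free`` and a Ca-bound state with
lifetime ``tau_bound``. Binding follows a single-site isotherm with
dissociation constant ``kd``; the bound state is ``gamma`` times brighter
than the free state (``gamma`` is the dynamic range F_max / F_min).

Two consequences of this model are used throughout the package:

* total fluorescence at free-calcium concentration ``ca`` is proportional
  to ``(ca + kd/gamma) / (ca + kd)`` — the classic single-wavelength
  saturation curve; and
* the probability that a *detected* photon originates from the bound
  state is the brightness-weighted bound fraction
  ``w = gamma*f / (gamma*f + 1 - f)`` with ``f = ca/(ca+kd)``, which
  controls the shape of the lifetime decay.

Default parameter values describe OGB-1: kd = 240 nM, gamma = 6.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ConfigurationError

__all__ = [
    "IndicatorModel",
    "OGB1",
    "bound_fraction",
    "brightness_weight",
    "saturation_fluorescence",
]


@dataclass(frozen=True)
class IndicatorModel:
    """Equilibrium photophysics of the Ca2+ dye.

    Parameters
    ----------
    kd
        Dissociation constant, nM.
    gamma
        Dynamic range (saturated / Ca-free fluorescence), unitless, > 1.
    tau_free
        Fluorescence lifetime of the Ca-free state, ns.
    tau_bound
        Fluorescence lifetime of the Ca-bound state, ns.
    rep_window
        Laser inter-pulse window, ns (12.5 ns for an 80 MHz source).
    """

    kd: float = 240.0
    gamma: float = 6.0
    tau_free: float = 0.7
    tau_bound: float = 3.7
    rep_window: float = 12.5

    def __post_init__(self) -> None:
        if self.kd <= 0:
            raise ConfigurationError(f"kd must be > 0, got {self.kd}")
        if self.gamma <= 1:
            raise ConfigurationError(f"gamma must be > 1, got {self.gamma}")
        if not (0 < self.tau_free < self.tau_bound < self.rep_window):
            raise ConfigurationError(
                "need 0 < tau_free < tau_bound < rep_window, got "
                f"{self.tau_free}, {self.tau_bound}, {self.rep_window}"
            )


#: Default OGB-1 parameterization (kd = 240 nM, gamma = 6).
OGB1 = IndicatorModel()


def _check_ca(ca):
    ca = np.asarray(ca, dtype=float)
    if np.any(ca < 0):
        raise ConfigurationError("ca must be >= 0 nM")
    return ca


def bound_fraction(ca, model: IndicatorModel = OGB1):
    """Equilibrium fraction of dye in the Ca-bound state, f = ca/(ca+kd)."""
    ca = _check_ca(ca)
    return ca / (ca + model.kd)


def brightness_weight(ca, model: IndicatorModel = OGB1):
    """Probability that a detected photon came from the bound state.

    w = gamma*f / (gamma*f + (1-f)); equivalently ca / (ca + kd/gamma),
    i.e. a single-site isotherm with midpoint kd/gamma.
    """
    ca = _check_ca(ca)
    return ca / (ca + model.kd / model.gamma)


def saturation_fluorescence(ca, model: IndicatorModel = OGB1):
    """Relative total fluorescence F(ca) = (ca + kd/gamma) / (ca + kd).

    Normalized so that F -> 1 at saturating ca; F(0) = 1/gamma.
    """
    ca = _check_ca(ca)
    return (ca + model.kd / model.gamma) / (ca + model.kd)
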