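"""Oral dosing: Weibull dissolution, gut transit, absorption, recirculation.

Dissolution follows a Weibull law parameterized by the time to 50% dissolved:

    f(t) = 1 - exp(-ln2 * ((t - lag)/t50)**b)   for t > lag, else 0

so that f(lag + t50) = 0.5 exactly. The engine applies the *rate* df/dt to an
undissolved depot, which makes superposition of multiple doses exact. The gut
lumen is discretized into a small number of first-order transit segments;
dissolved drug leaving the last segment is booked as fecal excretion.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

LN2 = math.log(2.0)


@dataclass
class FormulationSpec:
    """Release kinetics of one oral dosage form."""

    kind: str = "solution"         # solution | weibull
    shape_b: float = 1.0
    t50: float = 1.0               # min, time to 50% dissolved (after lag)
    lag: float = 0.0               # min

    def __post_init__(self):
        if self.kind not in ("solution", "weibull"):
            raise ValueError(f"unknown formulation kind: {self.kind!r}")
        if self.kind == "weibull":
            if self.shape_b <= 0 or self.t50 <= 0:
                raise ValueError("weibull formulation requires shape_b > 0 and t50 > 0")
        if self.lag < 0:
            raise ValueError("lag must be >= 0")

    @classmethod
    def from_config(cls, cfg: dict) -> "FormulationSpec":
        if cfg.get("kind") == "solution":
            return cls(kind="solution")
        return cls(
            kind="weibull",
            shape_b=float(cfg["shape_b"]),
            t50=float(cfg["t50_min"]),
            lag=float(cfg.get("lag_min", 0.0)),
        )


@dataclass
class GutLumenState:
    """Plumbing record of the lumen contents (amounts in µmol)."""

    undissolved: float = 0.0
    dissolved: list[float] = field(default_factory=list)
    transit_rates: list[float] = field(default_factory=list)

    def __post_init__(self):
        if self.undissolved < 0 or any(a < 0 for a in self.dissolved):
            raise ValueError("lumen amounts must be >= 0")


def weibull_fraction_dissolved(t: float | np.ndarray, spec: FormulationSpec):
    """Cumulative fraction of the dose dissolved at time ``t`` (min)."""
    t = np.asarray(t, dtype=float)
    if not np.all(np.isfinite(t)):
        raise ValueError("time must be finite")
    if spec.kind == "solution":
        out = np.where(t >= 0.0, 1.0, 0.0)
        return float(out) if out.ndim == 0 else out
    tau = np.clip((t - spec.lag) / spec.t50, 0.0, None)
    out = -np.expm1(-LN2 * tau ** spec.shape_b)
    return float(out) if out.ndim == 0 else out


def weibull_release_rate(t: float | np.ndarray, spec: FormulationSpec):
    """Instantaneous release rate df/dt (1/min) of the Weibull law."""
    t = np.asarray(t, dtype=float)
    if spec.kind == "solution":
        out = np.zeros_like(t)
        return float(out) if out.ndim == 0 else out
    tau = (t - spec.lag) / spec.t50
    with np.errstate(invalid="ignore", divide="ignore"):
        rate = np.where(
            tau > 0.0,
            (LN2 * spec.shape_b / spec.t50)
            * np.power(np.clip(tau, 1e-300, None), spec.shape_b - 1.0)
            * np.exp(-LN2 * np.clip(tau, 0.0, None) ** spec.shape_b),
            0.0,
        )
    return float(rate) if rate.ndim == 0 else rate


def absorption_flux(
    dissolved_conc: float,
    wall_conc_unbound: float,
    peff: float,
    area: float,
) -> float:
    """Transcellular absorption flux (µmol/min) across the gut wall.

    ``peff`` in cm/min, ``area`` in cm², concentrations in µmol/L. The flux is
    bidirectional and vanishes when luminal and unbound wall concentrations
    are equal.
    """
    if area < 0:
        raise ValueError("area must be >= 0")
    if peff < 0:
        raise ValueError("permeability must be >= 0")
    if not (np.isfinite(dissolved_conc) and np.isfinite(wall_conc_unbound)):
        raise ValueError("concentrations must be finite")
    # cm/min * cm² = cm³/min; /1000 -> L/min
    return peff * area / 1000.0 * (dissolved_conc - wall_conc_unbound)


def biliary_recirculation_flux(
    hepatic_biliary_output: float, compound_or_fraction
) -> tuple[float, float]:
    """Split hepatic biliary output into recirculated and stored parts.

    Accepts a :class:`~bupnet.compounds.Compound` (its continuous enterohepatic
    recirculation fraction is used) or the fraction itself. Returns
    ``(to_duodenum, to_gallbladder)`` in µmol/min; with the continuous fraction
    of 1.0 all biliary output recirculates to the first lumen segment.
    """
    if hepatic_biliary_output < 0:
        raise ValueError("biliary output must be >= 0")
    fraction = getattr(compound_or_fraction, "ehc_continuous_fraction", compound_or_fraction)
    recirculated = float(fraction) * hepatic_biliary_output
    return recirculated, hepatic_biliary_output - recirculated
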