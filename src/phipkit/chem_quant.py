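"""Hydrogenation kinetics, polarization accounting, reactor geometry and
reproducibility statistics.

Polarization bookkeeping
------------------------
The thermal ¹H polarization at field B and temperature T is
tanh(γħB/(2k_B T)) ≈ 3.2×10⁻⁵ at 9.4 T and 300 K — the five-orders-of-
magnitude gap PHIP exists to close.  A two-proton OPE experiment can at
best place 50% polarization on the proton pair at 100% parahydrogen; at
enrichment f the ceiling scales by (4f-1)/3.  Achieved polarization is
quantified against a thermal reference signal from the same sample, with
a correction coefficient for the fraction of the thermal spectrum that
belongs to the product.  Molar polarization (n_protons × concentration ×
polarization) is the sequence-independent figure of merit: a sequence
that focuses the order on one proton doubles P but halves the polarized
proton count.

Hydrogenation kinetics
----------------------
The hydrogenated product concentration after bubbling parahydrogen for a
time τ_b follows

    [PC_H] = [PC₀]·P₀·(1 - R/k₁)⁻¹·(e^{-τ_b R} - e^{-τ_b k₁})

a rise-and-fall competition between product formation (rate constant k₁)
and the decay term R.  The second exponent is negative: a positive sign
would diverge with bubbling time, contradicting the rise-and-fall
behaviour the expression describes (the equation is sometimes printed
with a sign typo).  At R = k₁ the closed form has the analytic limit
[PC₀]·P₀·k₁·τ_b·e^{-k₁τ_b}.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .constants import GAMMA_1H, HBAR, K_B

__all__ = [
    "KineticsParams",
    "PolarizationQuant",
    "ReactorGeometry",
    "hydrogenated_concentration",
    "optimal_bubbling_time",
    "thermal_polarization",
    "max_polarization",
    "quantify_polarization",
    "reactor_volume",
    "coefficient_of_variation",
]


@dataclass(frozen=True)
class KineticsParams:
    """Parameters of the bubbling-time kinetics model.

    ``r`` is kept deliberately neutral in name — it plays the role of the
    decay term in the closed form, whether read as a reaction rate or as
    the hyperpolarization decay rate.
    """

    pc0: float      #: initial precursor concentration, mM
    p0: float       #: reached polarization (fraction)
    r: float        #: decay term, s⁻¹
    k1: float       #: first-order hydrogenation rate constant, s⁻¹
    tb: float       #: bubbling time, s

    def __post_init__(self) -> None:
        if self.pc0 < 0:
            raise ValueError("pc0 must be >= 0")
        if not self.k1 > 0:
            raise ValueError("k1 must be positive")
        if self.r < 0:
            raise ValueError("r must be >= 0")
        if self.tb < 0:
            raise ValueError("tb must be >= 0")


def hydrogenated_concentration(p: KineticsParams) -> float:
    """Hydrogenated product concentration [PC_H] in mM after bubbling.

    Uses the analytic limit when R ≈ k₁ (the closed form is 0/0 there);
    the two branches agree to better than 1e-9 relative at
    |R - k₁|/k₁ = 1e-5.
    """
    if p.r == p.k1 or abs(p.r - p.k1) < 1e-10 * p.k1:
        return p.pc0 * p.p0 * p.k1 * p.tb * math.exp(-p.k1 * p.tb)
    scale = 1.0 / (1.0 - p.r / p.k1)
    return p.pc0 * p.p0 * scale * (math.exp(-p.tb * p.r) - math.exp(-p.tb * p.k1))


def optimal_bubbling_time(r: float, k1: float) -> float:
    """Bubbling time maximizing [PC_H]: τ_b* = ln(k₁/R)/(k₁ - R)."""
    if not (r > 0 and k1 > 0):
        raise ValueError("rates must be positive")
    if r == k1:
        return 1.0 / k1
    return math.log(k1 / r) / (k1 - r)


def thermal_polarization(b0: float, temp: float,
                         gamma: float = GAMMA_1H) -> float:
    """Thermal equilibrium polarization tanh(γħB₀/(2 k_B T))."""
    if b0 < 0 or not temp > 0 or not gamma > 0:
        raise ValueError("need b0 >= 0, temp > 0, gamma > 0")
    return math.tanh(gamma * HBAR * b0 / (2.0 * K_B * temp))


def max_polarization(f: float) -> float:
    """Two-proton OPE polarization ceiling 0.5·(4f-1)/3 at para fraction f.

    50% in the ideal case (f = 1); sub-thermal enrichment (f < 0.25) is out
    of scope and rejected.
    """
    if not 0.25 <= f <= 1.0:
        raise ValueError(f"para fraction must be in [0.25, 1], got {f}")
    return 0.5 * (4.0 * f - 1.0) / 3.0


@dataclass
class PolarizationQuant:
    """Hyperpolarization quantified against a thermal reference."""

    s_hyp: float              #: hyperpolarized signal integral
    s_th: float               #: thermal reference integral
    correction: float         #: product fraction of the thermal spectrum
    p_thermal: float          #: thermal polarization at the measurement field
    p: float                  #: resulting polarization fraction
    enhancement: float        #: p / p_thermal
    molar_polarization: float  #: n_protons × conc × p, mM


def quantify_polarization(
    s_hyp: float,
    s_th: float,
    correction: float,
    p_thermal: float,
    conc: float,
    n_protons: int = 2,
) -> PolarizationQuant:
    """Polarization from the hyperpolarized/thermal signal ratio.

    P = (S_hyp/S_th)·c·P_thermal, with c ∈ (0, 1] the fraction of the
    thermal spectrum belonging to the product (the polarizer's spectral
    resolution cannot isolate the product line, so the thermal integral
    overcounts by 1/c).  Enhancement is P/P_thermal and molar polarization
    is n_protons·conc·P (mM).
    """
    if s_th == 0:
        raise ValueError("thermal reference integral must be nonzero")
    if not 0.0 < correction <= 1.0:
        raise ValueError("correction must be in (0, 1]")
    if conc < 0 or n_protons < 1:
        raise ValueError("need conc >= 0 and n_protons >= 1")
    p = (s_hyp / s_th) * correction * p_thermal
    if not -1.0 <= p <= 1.0:
        raise ValueError(f"computed polarization {p} outside [-1, 1]")
    return PolarizationQuant(
        s_hyp=s_hyp, s_th=s_th, correction=correction, p_thermal=p_thermal,
        p=p, enhancement=p / p_thermal,
        molar_polarization=n_protons * conc * p,
    )


@dataclass(frozen=True)
class ReactorGeometry:
    """Fill geometry of a tubular reactor."""

    inner_diameter: float   #: mm
    fill_height: float      #: mm
    bottom: str = "hemispherical"   #: "flat" or "hemispherical"

    def __post_init__(self) -> None:
        if not (self.inner_diameter > 0 and self.fill_height > 0):
            raise ValueError("dimensions must be positive")
        if self.bottom not in ("flat", "hemispherical"):
            raise ValueError(f"unknown bottom shape {self.bottom!r}")
        if self.bottom == "hemispherical" and \
                self.fill_height < self.inner_diameter / 2.0:
            raise ValueError("fill height below the hemisphere apex")


def reactor_volume(g: ReactorGeometry) -> float:
    """Fill volume in mL.

    Flat bottom: πr²h.  Hemispherical bottom: a cylinder of height h whose
    bottom r is a hemisphere, πr²h - (1/3)πr³ (the hemisphere replaces the
    lowest cylinder slice and holds (2/3)πr³ of the πr³ it displaces).
    """
    r = g.inner_diameter / 2.0
    h = g.fill_height
    vol_mm3 = math.pi * r * r * h
    if g.bottom == "hemispherical":
        vol_mm3 -= math.pi * r ** 3 / 3.0
    return vol_mm3 / 1000.0


def coefficient_of_variation(values: Sequence[float]) -> float:
    """Sample standard deviation over mean (fraction, not percent)."""
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        raise ValueError("need at least 2 values")
    mean = float(v.mean())
    if mean == 0.0:
        raise ValueError("coefficient of variation undefined for zero mean")
    return float(v.std(ddof=1)) / mean
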