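"""CPMG relaxometry fitting stages.

The analysis is two-staged, mirroring how CPMG data from a bubbling
polarizer are reduced in practice:

1. per-τ monoexponential fit of the echo train
   M_n = M₀·exp(-R₂ᵒᵇˢ·2nτ), yielding one R₂ᵒᵇˢ per echo spacing;
2. ordinary least squares of R₂ᵒᵇˢ against (2τ)² over a configurable
   window of 2τ (default 40–400 ms):  R₂ᵒᵇˢ = 1/T₂ + D*·(2τ)².

The slope D* is the effective diffusion-homogeneity coefficient,
D* = (1/12)γ²G²D; G and D are never recovered separately.  Short echo
spacings (2τ < 40 ms) are excluded by default: there the observed rate is
inflated by RF-heating-driven convection, which the model does not cover.

Also here: T₂* = 1/(π·FWHM), ppm↔Hz conversion, and the D*–FWHM
correlation used to attribute the (2τ)² term to B0 inhomogeneity.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import lmfit
import numpy as np

__all__ = [
    "CpmgSeries",
    "EchoDecayFit",
    "HahnFitResult",
    "LinearCorrelation",
    "fit_echo_decay",
    "fit_hahn",
    "analyze_cpmg",
    "t2star_from_fwhm",
    "ppm_to_hz",
    "hz_to_ppm",
    "correlate_dstar_fwhm",
]


@dataclass
class CpmgSeries:
    """One CPMG echo train at a fixed inter-pulse half-spacing τ."""

    tau: float                #: half echo spacing, s (echoes occur at 2nτ)
    echo_index: np.ndarray    #: 1..n, strictly increasing
    amplitude: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.echo_index = np.asarray(self.echo_index, dtype=int)
        self.amplitude = np.asarray(self.amplitude, dtype=float)
        if not self.tau > 0:
            raise ValueError(f"tau must be positive, got {self.tau}")
        if self.echo_index.shape != self.amplitude.shape:
            raise ValueError("echo_index and amplitude must have equal length")
        if np.any(np.diff(self.echo_index) <= 0):
            raise ValueError("echo_index must be strictly increasing")
        if not np.all(np.isfinite(self.amplitude)):
            raise ValueError("amplitudes must be finite")

    @property
    def times(self) -> np.ndarray:
        """Acquisition times 2nτ of the echoes, s."""
        return 2.0 * self.echo_index * self.tau


@dataclass
class EchoDecayFit:
    """Monoexponential fit of one echo train."""

    r2obs: float          #: s⁻¹
    r2obs_stderr: float
    m0: float
    method: str           #: "loglinear+refine" or "nonlinear"


@dataclass
class HahnFitResult:
    """R₂ᵒᵇˢ vs (2τ)² fit: T₂ at τ→0 and the diffusion term D*."""

    t2: float                       #: s
    dstar: float                    #: s⁻³
    fit_window: tuple[float, float]  #: (2τ_min, 2τ_max), s
    r2obs_table: np.ndarray         #: (τ, R₂ᵒᵇˢ) rows actually fitted
    cov: np.ndarray                 #: covariance of (1/T₂, D*)

    @property
    def t2_stderr(self) -> float:
        # delta method: var(T2) = var(1/T2)/ (1/T2)^4
        return math.sqrt(self.cov[0, 0]) * self.t2 ** 2

    @property
    def dstar_stderr(self) -> float:
        return math.sqrt(self.cov[1, 1])


def _exp_model(t, m0, r):
    return m0 * np.exp(-r * t)


def _nonlinear_exp_fit(t: np.ndarray, y: np.ndarray,
                       p0: tuple[float, float]) -> tuple[float, float, float]:
    model = lmfit.Model(_exp_model)
    params = model.make_params(m0=p0[0], r=p0[1])
    params["r"].min = 0.0
    out = model.fit(y, params, t=t)
    r = out.params["r"]
    return float(out.params["m0"].value), float(r.value), float(r.stderr or 0.0)


def fit_echo_decay(series: CpmgSeries, refine: bool = True) -> EchoDecayFit:
    """Fit M_n = M₀·exp(-R₂ᵒᵇˢ·2nτ) to one echo train.

    The default route is weighted log-linear least squares (weights ∝
    amplitude², the correct weighting for additive noise mapped through
    the log) followed by a nonlinear refinement pass.  Trains containing
    non-positive amplitudes — routine once the decay reaches the noise
    floor — skip the log step and go straight to the nonlinear fit.
    An all-equal train returns R₂ᵒᵇˢ = 0.
    """
    if series.amplitude.size < 3:
        raise ValueError("need at least 3 echoes")
    t = series.times
    y = series.amplitude
    if np.ptp(y) == 0.0:
        return EchoDecayFit(r2obs=0.0, r2obs_stderr=0.0, m0=float(y[0]),
                            method="constant")
    if np.all(y > 0):
        w = y ** 2
        coef, cov = np.polyfit(t, np.log(y), 1, w=np.sqrt(w), cov="unscaled")
        # polyfit cov is unscaled by residuals when cov="unscaled"; rescale
        r0, m00 = -coef[0], math.exp(coef[1])
        method = "loglinear"
        if refine:
            m0, r, se = _nonlinear_exp_fit(t, y, (m00, max(r0, 0.0)))
            return EchoDecayFit(r2obs=r, r2obs_stderr=se, m0=m0,
                                method="loglinear+refine")
        resid = np.log(y) - np.polyval(coef, t)
        dof = max(y.size - 2, 1)
        se = math.sqrt(cov[0, 0] * (w * resid ** 2).sum() / w.sum() * y.size / dof)
        return EchoDecayFit(r2obs=r0, r2obs_stderr=se, m0=m00, method=method)
    # noise floor reached: nonlinear fit with a coarse rate guess
    m00 = float(np.max(np.abs(y)))
    pos = y > 0
    if pos.sum() >= 2:
        r0 = max((np.log(y[pos][0]) - np.log(y[pos][-1]))
                 / (t[pos][-1] - t[pos][0]), 1e-3)
    else:
        r0 = 1.0 / t[-1]
    m0, r, se = _nonlinear_exp_fit(t, y, (m00, r0))
    return EchoDecayFit(r2obs=r, r2obs_stderr=se, m0=m0, method="nonlinear")


def fit_hahn(
    r2obs_table: Iterable[tuple[float, float]] | np.ndarray,
    window: tuple[float, float] = (0.040, 0.400),
) -> HahnFitResult:
    """OLS of R₂ᵒᵇˢ against (2τ)²; intercept = 1/T₂, slope = D*.

    ``r2obs_table`` holds (τ, R₂ᵒᵇˢ) pairs; rows with 2τ outside
    ``window`` are excluded before fitting.  At least 3 points must
    survive the window cut.
    """
    table = np.asarray([(float(t), float(r)) for t, r in r2obs_table])
    if table.ndim != 2 or table.shape[1] != 2:
        raise ValueError("r2obs_table must be (tau, r2obs) pairs")
    two_tau = 2.0 * table[:, 0]
    lo, hi = window
    keep = (two_tau >= lo) & (two_tau <= hi)
    if keep.sum() < 3:
        raise ValueError(
            f"need >= 3 tau values with 2*tau inside {window}, have {keep.sum()}")
    sub = table[keep]
    x = (2.0 * sub[:, 0]) ** 2
    y = sub[:, 1]
    design = np.column_stack([np.ones_like(x), x])
    coef, res, *_ = np.linalg.lstsq(design, y, rcond=None)
    intercept, slope = coef
    if not intercept > 0:
        raise ValueError("fitted intercept 1/T2 is non-positive; data do not "
                         "follow a Hahn-type decay in the window")
    dof = max(x.size - 2, 1)
    resid = y - design @ coef
    sigma2 = float(resid @ resid) / dof
    cov = sigma2 * np.linalg.inv(design.T @ design)
    return HahnFitResult(t2=1.0 / intercept, dstar=float(slope),
                         fit_window=window, r2obs_table=sub, cov=cov)


def analyze_cpmg(series_list: Sequence[CpmgSeries],
                 window: tuple[float, float] = (0.040, 0.400)) -> HahnFitResult:
    """Full two-stage CPMG analysis: echo fits per τ, then the Hahn fit."""
    pairs = [(s.tau, fit_echo_decay(s).r2obs) for s in series_list]
    return fit_hahn(pairs, window=window)


def t2star_from_fwhm(fwhm: float) -> float:
    """Effective T₂* (s) from a spectral FWHM (Hz): T₂* = 1/(π·FWHM)."""
    if not fwhm > 0:
        raise ValueError(f"fwhm must be positive, got {fwhm}")
    return 1.0 / (math.pi * fwhm)


def ppm_to_hz(value: float, ref_freq: float) -> float:
    """Convert ppm to Hz at reference frequency ``ref_freq`` (Hz)."""
    if not ref_freq > 0:
        raise ValueError(f"ref_freq must be positive, got {ref_freq}")
    return value * ref_freq * 1e-6


def hz_to_ppm(value: float, ref_freq: float) -> float:
    """Inverse of :func:`ppm_to_hz`."""
    if not ref_freq > 0:
        raise ValueError(f"ref_freq must be positive, got {ref_freq}")
    return value / ref_freq * 1e6


@dataclass
class LinearCorrelation:
    slope: float
    intercept: float
    r2: float
    n: int


def correlate_dstar_fwhm(
    points: Iterable[tuple[float, float]],
    include_origin: bool = True,
    through_origin: bool = False,
) -> LinearCorrelation:
    """Linear correlation of D* against spectral FWHM across reactors.

    With ``include_origin`` the point (0, 0) is appended before fitting —
    zero linewidth should imply no inhomogeneity-driven diffusion term.
    R² is computed about the mean of the (possibly augmented) y values.
    A strict through-origin fit is available but the default keeps the
    intercept free.
    """
    pts = np.asarray([(float(a), float(b)) for a, b in points])
    if pts.shape[0] < 2:
        raise ValueError("need at least 2 points")
    if include_origin:
        pts = np.vstack([pts, [0.0, 0.0]])
    x, y = pts[:, 0], pts[:, 1]
    if np.ptp(x) == 0.0:
        raise ValueError("x values are degenerate (all equal)")
    if through_origin:
        slope = float(x @ y / (x @ x))
        intercept = 0.0
    else:
        slope, intercept = (float(v) for v in np.polyfit(x, y, 1))
    yhat = slope * x + intercept
    ss_res = float(((y - yhat) ** 2).sum())
    ss_tot = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 - ss_res / ss_tot
    return LinearCorrelation(slope=slope, intercept=intercept, r2=r2,
                             n=int(x.size))
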