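"""Synthetic-data generators for every input the analysis stages consume.

Each generator is a bit-reproducible function of (parameters, seed) and
embeds its ground truth in the ``meta`` dict of what it returns, so
round-trip tests (generate → fit → compare with truth) are
self-describing.  Default noise is 1% additive, referenced to the maximum
amplitude of the noiseless trace — the scale of a well-adjusted
spectrometer acquisition.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .field_characterization import NutationCurve
from .presets import preset_ope_config, preset_state, preset_system
from .relaxometry import CpmgSeries
from .sequences import (B1Distribution, CpmgModel, OpeConfig, cpmg_signal,
                        nutation_ensemble, ope_tau_scan)

__all__ = [
    "NoiseSpec",
    "DampedSineParams",
    "gen_nutation",
    "gen_cpmg",
    "gen_injection_series",
    "gen_ope_dataset",
    "DEFAULT_CPMG_TWO_TAU",
]

#: Default CPMG echo spacings: ten 2τ values spanning the Hahn-fit window.
DEFAULT_CPMG_TWO_TAU: np.ndarray = np.linspace(0.040, 0.400, 10)


@dataclass(frozen=True)
class NoiseSpec:
    """Reproducible noise description.

    ``level`` is a fraction of the maximum absolute amplitude of the
    noiseless trace (additive) or of each point (multiplicative).
    """

    kind: str = "additive"       #: "additive" or "multiplicative"
    level: float = 0.01
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in ("additive", "multiplicative"):
            raise ValueError(f"unknown noise kind {self.kind!r}")
        if self.level < 0:
            raise ValueError("noise level must be >= 0")

    def apply(self, y: np.ndarray, rng: np.random.Generator | None = None) -> np.ndarray:
        if self.level == 0.0:
            return np.array(y, dtype=float, copy=True)
        if rng is None:
            rng = np.random.default_rng(self.seed)
        z = rng.standard_normal(np.shape(y))
        if self.kind == "additive":
            return y + self.level * float(np.max(np.abs(y))) * z
        return y * (1.0 + self.level * z)


@dataclass(frozen=True)
class DampedSineParams:
    """Ground truth for the damped-sine nutation generator."""

    k: float          #: decay rate, s⁻¹
    period: float     #: s
    a: float = 1.0


def gen_nutation(
    dist: B1Distribution | DampedSineParams,
    t_max: float = 1.2e-3,
    dt: float = 2e-6,
    noise: NoiseSpec | None = None,
) -> NutationCurve:
    """Synthetic nutation curve from either generator model.

    A :class:`B1Distribution` produces the Gaussian-ensemble curve (exact
    Gaussian envelope); :class:`DampedSineParams` produces the empirical
    A·e^{-kt}·sin(2πt/T) shape.  ``meta`` records the generator truth.
    """
    noise = noise or NoiseSpec(level=0.0)
    if isinstance(dist, B1Distribution):
        period = dist.period
    else:
        period = dist.period
    if not dt < period / 8.0:
        raise ValueError("dt must resolve the oscillation (dt < T/8)")
    t = np.arange(0.0, t_max + 0.5 * dt, dt)
    if isinstance(dist, B1Distribution):
        y = nutation_ensemble(dist, t)
        truth = {"model": "gaussian_ensemble", "period_s": dist.period,
                 "sigma_rel": dist.sigma_rel}
    else:
        y = dist.a * np.exp(-dist.k * t) * np.sin(2.0 * math.pi * t / dist.period)
        truth = {"model": "damped_sine", "period_s": dist.period,
                 "k_s1": dist.k, "a": dist.a}
    y = noise.apply(y)
    truth["noise"] = {"kind": noise.kind, "level": noise.level,
                      "seed": noise.seed}
    return NutationCurve(t, y, meta=truth)


def gen_cpmg(
    model: CpmgModel,
    taus: Sequence[float] | None = None,
    n_echoes: int = 169,
    noise: NoiseSpec | None = None,
) -> list[CpmgSeries]:
    """Synthetic CPMG echo trains, one per τ.

    Defaults cover ten echo spacings with 2τ in [40, 400] ms and 169
    echoes per train.  Noise is drawn from a single seeded stream in τ
    order, so the whole dataset is one reproducible draw.
    """
    if taus is None:
        taus = DEFAULT_CPMG_TWO_TAU / 2.0
    taus = np.asarray(list(taus), dtype=float)
    if np.any(taus <= 0):
        raise ValueError("taus must be positive")
    noise = noise or NoiseSpec(level=0.0)
    rng = np.random.default_rng(noise.seed)
    out = []
    for tau in taus:
        clean = cpmg_signal(model, tau, n_echoes)
        amp = noise.apply(clean, rng=rng)
        truth = {"t2_s": model.t2, "dstar_s3": model.dstar, "m0": model.m0,
                 "r2obs_s1": model.r2obs(tau),
                 "noise": {"kind": noise.kind, "level": noise.level,
                           "seed": noise.seed}}
        out.append(CpmgSeries(tau=float(tau),
                              echo_index=np.arange(1, n_echoes + 1),
                              amplitude=amp, meta=truth))
    return out


def gen_injection_series(
    mean: float,
    cv: float,
    n: int = 10,
    n_series: int = 3,
    seed: int = 0,
) -> pd.DataFrame:
    """Synthetic injection-reproducibility signal integrals.

    Draws mean·(1 + cv·z) with z standard normal: ``n`` repetitions per
    series, ``n_series`` series (the shuttle protocol repeats an inject/
    measure/eject cycle and the whole experiment is itself repeated).
    """
    if n < 2:
        raise ValueError("need n >= 2 repetitions")
    if cv < 0:
        raise ValueError("cv must be >= 0")
    rng = np.random.default_rng(seed)
    rows = []
    for s in range(n_series):
        vals = mean * (1.0 + cv * rng.standard_normal(n))
        rows.extend({"series": s, "rep": r, "integral": float(v)}
                    for r, v in enumerate(vals))
    df = pd.DataFrame(rows)
    df.attrs["truth"] = {"mean": mean, "cv": cv, "seed": seed}
    return df


def gen_ope_dataset(
    preset: str = "EA-d6",
    cfg: OpeConfig | None = None,
    taus: Sequence[float] | None = None,
    noise: NoiseSpec | None = None,
    enrichment: float = 1.0,
) -> pd.DataFrame:
    """Synthetic OPE τ-scan table for an EA preset.

    Columns ``tau_s`` and ``integral``; ``attrs["truth"]`` records the
    preset, T_d, enrichment and the noiseless argmax.
    """
    if cfg is None:
        cfg = preset_ope_config(preset)
    if taus is None:
        taus = np.arange(0.001, 0.0301, 0.0001)
    noise = noise or NoiseSpec(level=0.0)
    system = preset_system(preset)
    scan = ope_tau_scan(
        lambda: preset_state(preset, enrichment=enrichment, system=system),
        cfg, taus)
    integrals = noise.apply(scan.integrals)
    df = pd.DataFrame({"tau_s": scan.taus, "integral": integrals})
    df.attrs["truth"] = {
        "preset": preset, "td_s": cfg.td, "enrichment_f": enrichment,
        "tau_opt_s": scan.tau_opt,
        "noise": {"kind": noise.kind, "level": noise.level, "seed": noise.seed},
    }
    return df
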