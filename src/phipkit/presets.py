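"""Ethyl acetate (EA) spin-system presets for OPE simulations.

Hydrogenation of vinyl acetate delivers the two parahydrogen-born protons
to the methyl (δ ≈ 1.26 ppm) and the O-CH₂ (δ ≈ 4.12 ppm) positions of
ethyl acetate, with a vicinal ³J of 7.1 Hz between the groups (literature
proton parameters of EA).

* ``EA-d6``: the deuterated isotopologue is reduced to the two nascent
  protons; deuteron couplings and relaxation are absorbed into the
  phenomenological damping T_d = 160 ms.
* ``EA-h6``: the protonated ethyl fragment is modelled as 5 protons, CH₃
  (3 equivalent spins) + OCH₂ (2 equivalent spins), every inter-group pair
  coupled at 7.1 Hz; intra-group couplings are set to zero (magnetically
  equivalent spins do not evolve under their mutual coupling).  The
  uncoupled, unpolarized acetate methyl is excluded.  T_d = 60 ms.
"""

from __future__ import annotations

from .sequences import OpeConfig
from .spin_core import SpinState, SpinSystem, build_spin_system, pasadena_state

__all__ = [
    "B0_TESLA",
    "REF_FREQ_HZ",
    "EA_J_HZ",
    "EA_SHIFT_CH3",
    "EA_SHIFT_OCH2",
    "TD_EA_D6",
    "TD_EA_H6",
    "ea_d6_system",
    "ea_h6_system",
    "preset_system",
    "preset_state",
    "preset_ope_config",
]

#: Polarizer static field, T.
B0_TESLA = 0.4454
#: Spectrometer 0-ppm reference frequency, Hz.  Set independently of B0:
#: the instrument's anchor (18.717 MHz) differs slightly from γB0/2π.
REF_FREQ_HZ = 18.717e6

EA_SHIFT_CH3 = 1.26    # ppm
EA_SHIFT_OCH2 = 4.12   # ppm
EA_J_HZ = 7.1          # vicinal 3J, Hz

#: Default OPE damping constants, s.
TD_EA_D6 = 0.160
TD_EA_H6 = 0.060


def ea_d6_system(b0: float = B0_TESLA, ref_freq: float = REF_FREQ_HZ,
                 coupling: str = "isotropic") -> SpinSystem:
    """Two-proton model of EA-d6 (the nascent pair only)."""
    return build_spin_system(
        shifts=[EA_SHIFT_CH3, EA_SHIFT_OCH2],
        j=[[0.0, EA_J_HZ], [EA_J_HZ, 0.0]],
        b0=b0, ref_freq=ref_freq,
        labels=["CH3*", "OCH2*"], coupling=coupling,
    )


def ea_h6_system(b0: float = B0_TESLA, ref_freq: float = REF_FREQ_HZ,
                 coupling: str = "isotropic") -> SpinSystem:
    """Five-proton model of EA-h6: CH₃ (spins 0-2) + OCH₂ (spins 3-4)."""
    shifts = [EA_SHIFT_CH3] * 3 + [EA_SHIFT_OCH2] * 2
    j = [[0.0] * 5 for _ in range(5)]
    for i in range(3):
        for k in range(3, 5):
            j[i][k] = j[k][i] = EA_J_HZ
    labels = ["CH3a*", "CH3b", "CH3c", "OCH2a*", "OCH2b"]
    return build_spin_system(shifts, j, b0=b0, ref_freq=ref_freq,
                             labels=labels, coupling=coupling)


_PRESETS = {"EA-d6": (ea_d6_system, (0, 1), TD_EA_D6),
            "EA-h6": (ea_h6_system, (0, 3), TD_EA_H6)}


def preset_system(name: str, **kwargs) -> SpinSystem:
    """Spin system for preset ``name`` ("EA-d6" or "EA-h6")."""
    try:
        factory, _, _ = _PRESETS[name]
    except KeyError:
        raise ValueError(f"unknown preset {name!r}; choose from {sorted(_PRESETS)}")
    return factory(**kwargs)


def preset_state(name: str, enrichment: float = 1.0, dephased: bool = True,
                 system: SpinSystem | None = None) -> SpinState:
    """PASADENA initial state on the preset's nascent proton pair."""
    _, pair, _ = _PRESETS[name] if name in _PRESETS else (None, None, None)
    if pair is None:
        raise ValueError(f"unknown preset {name!r}; choose from {sorted(_PRESETS)}")
    if system is None:
        system = preset_system(name)
    return pasadena_state(system, pair=pair, enrichment=enrichment,
                          dephased=dephased)


def preset_ope_config(name: str, tau: float = 0.010,
                      td: float | None = None) -> OpeConfig:
    """Default OPE configuration for the preset (its T_d unless overridden)."""
    if name not in _PRESETS:
        raise ValueError(f"unknown preset {name!r}; choose from {sorted(_PRESETS)}")
    _, _, default_td = _PRESETS[name]
    return OpeConfig(tau=tau, td=td if td is not None else default_td)
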