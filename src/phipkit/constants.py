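"""Physical constants (CODATA 2018, via scipy) used across the package."""

from scipy import constants as _const

#: Reduced Planck constant, J·s
HBAR: float = _const.hbar

#: Boltzmann constant, J/K
K_B: float = _const.k

#: Proton gyromagnetic ratio, rad·s⁻¹·T⁻¹
GAMMA_1H: float = _const.value("proton gyromag. ratio")

#: Proton gyromagnetic ratio over 2π, Hz/T
GAMMA_1H_HZ: float = GAMMA_1H / (2.0 * _const.pi)
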