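"""Minimal density-matrix engine for small spin-1/2 systems.

The engine covers exactly what a PASADENA/PHIP sequence simulation needs:
product-basis spin operators, a rotating-frame Hamiltonian with chemical
shifts and scalar couplings, ideal (zero-duration) pulses, free evolution by
exact eigendecomposition, quadrature detection with Lorentzian apodization,
and discrete Fourier transformation to a ppm-referenced spectrum.

Conventions
-----------
* The rotating-frame Hamiltonian (angular frequency units, rad/s) is

      H = Σ_i 2π δ_i 1e-6 f_ref I_iz  +  Σ_{i<j} 2π J_ij (I_i · I_j)

  with δ in ppm, f_ref the spectrometer reference frequency in Hz and J in
  Hz.  A ``coupling="weak"`` mode replaces I_i·I_j by the secular I_iz I_jz
  term; the weak-coupling product-operator closed forms (antiphase ↔
  in-phase interconversion at frequency πJ) are exact in that mode and are
  used as independent oracles in the test suite.
* Pulses are ideal rotations U = exp(-i β (I_x cos φ + I_y sin φ)) applied
  to a subset of spins.  B1 inhomogeneity is modelled at the ensemble level
  (see :mod:`phipkit.sequences`), never inside the propagator.
* Detection returns s(t) = c · Tr(ρ(t) Σ_i I_i⁺) with c = 4/2^N so that a
  unit I_x deviation on a single spin gives s(0) = 1.  The "signal
  integral" of a FID is defined as Re s(0), which equals the integral of
  the real part of its spectrum (with the spectrum scaled by the dwell
  time).  Antiphase terms present at the start of acquisition contribute
  nothing to the integral, matching the usual in-phase integral reading.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from functools import cached_property
from typing import Iterable, Sequence

import numpy as np

from .constants import GAMMA_1H

__all__ = [
    "Spin",
    "SpinSystem",
    "SpinState",
    "EnrichmentScale",
    "FidResult",
    "Spectrum",
    "build_spin_system",
    "pasadena_state",
    "thermal_state",
    "apply_pulse",
    "evolve_delay",
    "detect_fid",
    "fid_to_spectrum",
    "single_spin_op",
]

# Pauli matrices over 2; the spin-1/2 operators in the |α>,|β> basis.
_SIGMA = {
    "x": np.array([[0.0, 0.5], [0.5, 0.0]], dtype=complex),
    "y": np.array([[0.0, -0.5j], [0.5j, 0.0]], dtype=complex),
    "z": np.array([[0.5, 0.0], [0.0, -0.5]], dtype=complex),
}
_E2 = np.eye(2, dtype=complex)


@dataclass(frozen=True)
class Spin:
    """A single spin-1/2 nucleus.

    Parameters
    ----------
    label : str
        Short identifier (e.g. ``"CH3"``).
    shift : float
        Chemical shift in ppm relative to the spectrometer reference.
    gamma : float
        Gyromagnetic ratio in rad·s⁻¹·T⁻¹; defaults to the proton value.
    """

    label: str
    shift: float
    gamma: float = GAMMA_1H

    def __post_init__(self) -> None:
        if not math.isfinite(self.shift):
            raise ValueError(f"shift must be finite, got {self.shift}")
        if not self.gamma > 0:
            raise ValueError(f"gamma must be positive, got {self.gamma}")


def single_spin_op(n: int, i: int, axis: str) -> np.ndarray:
    """Product-basis operator I_{i,axis} for spin ``i`` of ``n`` spins."""
    op = np.array([[1.0 + 0.0j]])
    for k in range(n):
        op = np.kron(op, _SIGMA[axis] if k == i else _E2)
    return op


@dataclass(eq=False)
class SpinSystem:
    """An N-spin-1/2 system in the rotating frame.

    Attributes
    ----------
    spins : tuple of Spin
    j : ndarray
        Symmetric scalar-coupling matrix in Hz with zero diagonal.
    b0 : float
        Static field in T.
    ref_freq : float
        Spectrometer reference frequency in Hz (the 0-ppm position).  Kept
        independent of ``b0`` deliberately: instruments report both and
        they need not satisfy γB0/2π = f_ref exactly.
    coupling : {"isotropic", "weak"}
        Scalar-coupling model: full I_i·I_j (default) or secular I_iz I_jz.
    """

    spins: tuple[Spin, ...]
    j: np.ndarray
    b0: float
    ref_freq: float
    coupling: str = "isotropic"

    def __post_init__(self) -> None:
        self.spins = tuple(self.spins)
        n = len(self.spins)
        if not 1 <= n <= 8:
            raise ValueError(f"supported system sizes are 1..8 spins, got {n}")
        j = np.asarray(self.j, dtype=float)
        if j.shape != (n, n):
            raise ValueError(f"j must be {n}x{n}, got {j.shape}")
        if not np.allclose(j, j.T, atol=0.0, rtol=0.0):
            raise ValueError("coupling matrix j must be exactly symmetric")
        if np.any(np.diag(j) != 0.0):
            raise ValueError("coupling matrix j must have a zero diagonal")
        self.j = j
        if not self.b0 > 0:
            raise ValueError(f"b0 must be positive, got {self.b0}")
        if not self.ref_freq > 0:
            raise ValueError(f"ref_freq must be positive, got {self.ref_freq}")
        if self.coupling not in ("isotropic", "weak"):
            raise ValueError(f"unknown coupling model {self.coupling!r}")

    @property
    def n_spins(self) -> int:
        return len(self.spins)

    @property
    def dim(self) -> int:
        return 2 ** self.n_spins

    def op(self, i: int, axis: str) -> np.ndarray:
        """Single-spin product operator I_{i,axis} (cached)."""
        key = (i, axis)
        cache = self._op_cache
        if key not in cache:
            cache[key] = single_spin_op(self.n_spins, i, axis)
        return cache[key]

    @cached_property
    def _op_cache(self) -> dict:
        return {}

    def total_op(self, axis: str) -> np.ndarray:
        return sum(self.op(i, axis) for i in range(self.n_spins))

    @cached_property
    def hamiltonian(self) -> np.ndarray:
        """Rotating-frame Hamiltonian in rad/s."""
        h = np.zeros((self.dim, self.dim), dtype=complex)
        for i, spin in enumerate(self.spins):
            w = 2.0 * math.pi * spin.shift * 1e-6 * self.ref_freq
            h += w * self.op(i, "z")
        axes = ("x", "y", "z") if self.coupling == "isotropic" else ("z",)
        n = self.n_spins
        for i in range(n):
            for k in range(i + 1, n):
                if self.j[i, k] == 0.0:
                    continue
                wj = 2.0 * math.pi * self.j[i, k]
                for ax in axes:
                    h += wj * (self.op(i, ax) @ self.op(k, ax))
        return h

    @cached_property
    def _eig(self) -> tuple[np.ndarray, np.ndarray]:
        evals, evecs = np.linalg.eigh(self.hamiltonian)
        return evals, evecs

    def propagator(self, t: float) -> np.ndarray:
        """U(t) = exp(-i H t) via the cached eigendecomposition."""
        evals, v = self._eig
        return (v * np.exp(-1j * evals * t)) @ v.conj().T


@dataclass(frozen=True)
class EnrichmentScale:
    """Parahydrogen enrichment bookkeeping.

    A para fraction ``f`` delivers usable singlet spin order scaled by
    s = (4f - 1)/3: zero at the thermal 1:3 para:ortho mixture (f = 0.25)
    and unity for pure parahydrogen (f = 1).
    """

    f: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.f <= 1.0:
            raise ValueError(f"para fraction must be in [0, 1], got {self.f}")

    @property
    def s(self) -> float:
        return (4.0 * self.f - 1.0) / 3.0


@dataclass
class SpinState:
    """Density operator ρ over the 2^N product basis of ``system``."""

    rho: np.ndarray
    system: SpinSystem

    def __post_init__(self) -> None:
        rho = np.asarray(self.rho, dtype=complex)
        d = self.system.dim
        if rho.shape != (d, d):
            raise ValueError(f"rho must be {d}x{d}, got {rho.shape}")
        if not np.allclose(rho, rho.conj().T, atol=1e-12):
            raise ValueError("rho must be Hermitian (tol 1e-12)")
        if abs(np.trace(rho).real - 1.0) > 1e-12 or abs(np.trace(rho).imag) > 1e-12:
            raise ValueError("rho must have unit trace (tol 1e-12)")
        self.rho = rho

    def expect(self, op: np.ndarray) -> complex:
        return complex(np.trace(self.rho @ op))

    def copy(self) -> "SpinState":
        return SpinState(self.rho.copy(), self.system)


def build_spin_system(
    shifts: Sequence[float],
    j: Sequence[Sequence[float]] | np.ndarray,
    b0: float,
    ref_freq: float,
    labels: Sequence[str] | None = None,
    coupling: str = "isotropic",
) -> SpinSystem:
    """Build a validated :class:`SpinSystem` from shifts (ppm) and J (Hz).

    Examples
    --------
    >>> sys2 = build_spin_system([1.26, 4.12], [[0, 7.1], [7.1, 0]],
    ...                          b0=0.4454, ref_freq=18.717e6)
    >>> sys2.dim
    4
    """
    shifts = list(shifts)
    if labels is None:
        labels = [f"spin{i}" for i in range(len(shifts))]
    if len(labels) != len(shifts):
        raise ValueError("labels and shifts must have equal length")
    spins = tuple(Spin(lab, d) for lab, d in zip(labels, shifts))
    return SpinSystem(spins=spins, j=np.asarray(j, dtype=float), b0=b0,
                      ref_freq=ref_freq, coupling=coupling)


def _uniform(system: SpinSystem) -> np.ndarray:
    return np.eye(system.dim, dtype=complex) / system.dim


def thermal_state(system: SpinSystem, polarization: float = 1.0) -> SpinState:
    """High-temperature state E/2^N + p·Σ I_iz/2^{N-1} (deviation form).

    ``polarization`` is an arbitrary deviation amplitude; detected signals
    are linear in it, so the default 1 is a convenient reference scale.
    """
    n = system.n_spins
    # deviation form: only the traceless part is ever detected, so the
    # amplitude is a bookkeeping scale, not a physical polarization
    rho = _uniform(system) + polarization * system.total_op("z") / 2 ** (n - 1)
    return SpinState(rho, system)


def pasadena_state(
    system: SpinSystem,
    pair: tuple[int, int] = (0, 1),
    enrichment: EnrichmentScale | float = 1.0,
    dephased: bool = True,
) -> SpinState:
    """Initial state of a PASADENA experiment on the nascent proton pair.

    The pair carries the parahydrogen spin order scaled by s = (4f-1)/3; all
    other spins are unpolarized.  With ``dephased=True`` (default) the
    zero-quantum coherences of the singlet have averaged out during the
    seconds-long hydrogenation, leaving the longitudinal two-spin order
    deviation -s·I₁z I₂z; with ``dephased=False`` the full singlet-projector
    deviation -s·(I₁·I₂) is kept (for a bare pair at f = 1 this is exactly
    the pure singlet |S₀⟩⟨S₀|).
    """
    i, k = pair
    n = system.n_spins
    if i == k:
        raise ValueError("pair indices must be distinct")
    if not (0 <= i < n and 0 <= k < n):
        raise ValueError(f"pair indices out of range for {n} spins")
    if not isinstance(enrichment, EnrichmentScale):
        enrichment = EnrichmentScale(float(enrichment))
    s = enrichment.s
    if dephased:
        dev = system.op(i, "z") @ system.op(k, "z")
    else:
        dev = sum(system.op(i, ax) @ system.op(k, ax) for ax in ("x", "y", "z"))
    # Embedding of the pair state in the full space: ρ_pair ⊗ E/2^{N-2}.
    rho = _uniform(system) - s * dev / 2 ** (n - 2)
    return SpinState(rho, system)


def apply_pulse(
    state: SpinState,
    flip: float,
    phase: float = 0.0,
    targets: Iterable[int] | None = None,
) -> SpinState:
    """Ideal pulse: ρ → U ρ U† with U = exp(-i β (I_x cos φ + I_y sin φ)).

    ``flip`` and ``phase`` are in degrees; ``targets`` selects a spin
    subset (default: all spins).  Built as a Kronecker product of exact
    2×2 rotations, so unitarity holds to machine precision.
    """
    system = state.system
    n = system.n_spins
    if targets is None:
        targets = range(n)
    targets = set(targets)
    beta = math.radians(flip)
    phi = math.radians(phase)
    axis = math.cos(phi) * _SIGMA["x"] + math.sin(phi) * _SIGMA["y"]
    c, s = math.cos(beta / 2.0), math.sin(beta / 2.0)
    u2 = c * _E2 - 2j * s * axis  # exp(-i β n·I) for spin 1/2
    u = np.array([[1.0 + 0.0j]])
    for k in range(n):
        u = np.kron(u, u2 if k in targets else _E2)
    return SpinState(u @ state.rho @ u.conj().T, system)


def evolve_delay(state: SpinState, t: float) -> SpinState:
    """Free evolution ρ → e^{-iHt} ρ e^{+iHt} for a delay t ≥ 0 (s)."""
    if t < 0:
        raise ValueError(f"delay must be nonnegative, got {t}")
    if t == 0:
        return state.copy()
    u = state.system.propagator(t)
    return SpinState(u @ state.rho @ u.conj().T, state.system)


def detection_scale(system: SpinSystem) -> float:
    """Normalization making a unit single-spin I_x deviation give s(0) = 1."""
    return 4.0 / system.dim


def signal_integral(state: SpinState) -> float:
    """In-phase signal integral: Re of c·Tr(ρ Σ I_i⁺) at t = 0."""
    system = state.system
    fplus = system.total_op("x") + 1j * system.total_op("y")
    return float((detection_scale(system) * state.expect(fplus)).real)


@dataclass
class FidResult:
    """Complex free-induction decay and acquisition metadata."""

    time: np.ndarray        #: acquisition time axis, s
    signal: np.ndarray      #: complex signal, apodized
    dwell: float            #: dwell time, s
    lw: float               #: Lorentzian line broadening, Hz
    system: SpinSystem

    @property
    def integral(self) -> float:
        """In-phase signal integral (real part of the first point)."""
        return float(self.signal[0].real)


@dataclass
class Spectrum:
    """Discretely Fourier-transformed FID with a ppm-referenced axis."""

    freq_hz: np.ndarray
    ppm: np.ndarray
    values: np.ndarray      #: complex spectrum, scaled by the dwell time
    meta: dict = field(default_factory=dict)

    @property
    def real(self) -> np.ndarray:
        return self.values.real

    def integral(self) -> float:
        """Integral of the real part over the full spectral window (Hz)."""
        return float(np.trapezoid(self.values.real, self.freq_hz))


def detect_fid(
    state: SpinState,
    duration: float,
    dwell: float,
    lw: float = 0.0,
) -> FidResult:
    """Detect s(t_k) = c·Tr(ρ(t_k) Σ I_i⁺)·exp(-π·lw·t_k).

    The exponential apodization implements a homogeneous Lorentzian line
    broadening of ``lw`` Hz FWHM.  Propagation during acquisition uses the
    cached eigenbasis of H, so arbitrarily many points are cheap.
    """
    if not duration > dwell > 0:
        raise ValueError("need duration > dwell > 0")
    system = state.system
    n_pts = int(round(duration / dwell))
    t = np.arange(n_pts) * dwell
    evals, v = system._eig
    rho_e = v.conj().T @ state.rho @ v
    fplus = system.total_op("x") + 1j * system.total_op("y")
    f_e = v.conj().T @ fplus @ v
    # Tr(ρ(t)F) = Σ_ab ρ_e[a,b] e^{-i(λ_a-λ_b)t} F_e[b,a]
    omega = evals[:, None] - evals[None, :]
    w = (rho_e * f_e.T).ravel()
    ph = np.exp(-1j * np.outer(t, omega.ravel()))
    sig = detection_scale(system) * (ph @ w)
    sig *= np.exp(-math.pi * lw * t)
    return FidResult(time=t, signal=sig, dwell=dwell, lw=lw, system=system)


def fid_to_spectrum(fid: FidResult) -> Spectrum:
    """DFT of the FID; axis in Hz and ppm (ppm increases right-to-left).

    The first point is halved (the discrete correction that keeps the
    baseline flat) and the transform is scaled by twice the dwell time —
    the factor 2 compensates the one-sided time axis — so the integral of
    the real part over the full window equals the real first FID point,
    up to truncation of the decay.
    """
    sig = fid.signal.copy()
    sig[0] *= 0.5
    spec = np.fft.fftshift(np.fft.fft(sig)) * 2.0 * fid.dwell
    freq = np.fft.fftshift(np.fft.fftfreq(sig.size, d=fid.dwell))
    ppm = freq / fid.system.ref_freq * 1e6
    meta = {
        "ref_freq_hz": fid.system.ref_freq,
        "b0_t": fid.system.b0,
        "lw_hz": fid.lw,
        "ppm_axis": "increases right-to-left when plotted (NMR convention)",
    }
    return Spectrum(freq_hz=freq, ppm=ppm, values=spec, meta=meta)
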