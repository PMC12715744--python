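# Methods

This note documents the models implemented in `phipkit`, the assumptions
behind them, the defaults and why they were chosen, and what the synthetic
data do and do not establish about real instrument data.

## Spin-dynamics engine

States are density operators over the 2^N product basis (N ≤ 8). The
rotating-frame Hamiltonian is

    H = Σᵢ 2π δᵢ·10⁻⁶·f_ref·Iᵢz + Σᵢ<ⱼ 2π Jᵢⱼ (Iᵢ·Iⱼ)

with shifts δ in ppm, reference frequency f_ref in Hz, couplings J in Hz.
Propagation over a delay uses the exact eigendecomposition of the
time-independent H (computed once per system and cached), so there is no
step-size parameter and unitarity holds to machine precision. Pulses are
ideal zero-duration rotations built from exact 2×2 rotation matrices; B1
inhomogeneity is deliberately *not* modelled inside the propagator but at
the ensemble level (below), keeping the two concerns separable.

**Coupling model.** `SpinSystem(coupling=...)` selects the full isotropic
scalar coupling (default) or the secular weak-coupling term IᵢzIⱼz. The
distinction matters for testing: with isotropic coupling and *equal*
shifts, the PASADENA state, all pulses, and the detection operator are
exchange-symmetric while H is a scalar on each exchange sector, so
nothing evolves — the familiar product-operator closed forms (antiphase ↔
in-phase interconversion at frequency πJ; OPE integral ∝ sin(6πJτ)) are
weak-coupling results. The test suite therefore runs its closed-form
oracles in weak mode, where they are exact, and the physical ethyl
acetate presets use isotropic coupling with the real shift difference
(Δν ≈ 53.5 Hz ≫ J = 7.1 Hz, a mildly strong-coupled regime; the ~1%
strong-coupling correction is what moves the simulated EA-d6 OPE optimum
from the weak-coupling 11.4 ms to 10.5 ms).

**PASADENA state.** Hydrogenation takes seconds, far longer than the
inverse shift difference, so the singlet's zero-quantum coherences
average out before the sequence starts; the default initial state is
therefore the longitudinal two-spin order deviation −s·I₁zI₂z with
s = (4f−1)/3, the standard parahydrogen enrichment scaling (s = 0 at the
thermal 1:3 mixture, 1 at pure para). The full singlet-projector
deviation is available behind a flag for sequences sensitive to
zero-quantum terms. Detected signals are exactly linear in s; the
scaling is validated by 50%·s(0.92) = 44.67% against the quoted 44.6%
two-proton ceiling at 92% enrichment.

**Detection and integrals.** s(t) = c·Tr(ρ(t)ΣIᵢ⁺)·e^(−π·lw·t) with
c = 4/2^N, so a unit single-spin Ix deviation gives s(0) = 1; lw is a
homogeneous Lorentzian FWHM (8 Hz reproduces typical polarizer
linewidths in simulated spectra). The "signal integral" is defined as
Re s(0), which equals the integral of the real spectrum when the DFT is
scaled by 2·dwell with the first point halved; antiphase terms present
at acquisition contribute nothing to it, making it the in-phase integral
an experimentalist would quote. The receiver convention takes the real
channel as in-phase; shifts are refocused at the echo, so the OPE signal
lands in the real channel with no extra phase.

## Out-of-phase echo (OPE)

45x excitation, then n = 3 blocks of [τ — 90x180y90x — τ], then
acquisition. For ideal pulses the composite equals a 180°y rotation
exactly (kept as a composite because that is what runs on hardware).
Relaxation and couplings not carried by the simulated spin system
(deuterons in EA-d6, the acetate methyl in EA-h6) are absorbed into one
phenomenological factor e^(−τ/T_d) applied to the integrals: T_d = 160 ms
for the two-proton EA-d6 model, 60 ms for the five-proton EA-h6 model.
In the weak-coupling two-spin limit the integral is
(s/2)·sin(6πJτ)·e^(−τ/T_d), whose maximum satisfies tan(6πJτ*) = 6πJT_d.
τ-scans use a 0.1 ms grid (1–30 ms) with quadratic interpolation around
the grid maximum.

**Presets.** Ethyl acetate from vinyl acetate hydrogenation: nascent
protons at 1.26 ppm (CH₃) and 4.12 ppm (OCH₂), vicinal ³J = 7.1 Hz
(literature values; the simulations' own couplings are not stated
anywhere authoritative). EA-h6 is the 5-proton ethyl fragment — CH₃ and
OCH₂ groups with all six inter-group couplings at 7.1 Hz and intra-group
couplings zero (magnetically equivalent spins do not evolve under their
mutual coupling); the uncoupled acetate methyl is excluded. The field
(0.4454 T) and the 0-ppm anchor (18.717 MHz) are independent parameters:
instruments report both and they need not satisfy γB0/2π = f_ref, so the
package never derives one from the other.

## Gaussian-B1 nutation ensemble

S(t) = E_ν[sin(2πνt)] with ν ~ N(1/T, σ_rel/T), evaluated by 64-node
Gauss–Hermite quadrature (error < 1e-10 against the closed form
sin(2πν₀t)·e^(−2π²σ_ν²t²) for realistic σ_rel and t ≤ 1.2 ms). Only the
nutation frequency is scattered; detection sensitivity is left uniform,
which is the model's stated scope.

**σ(B1) estimation.** Instrument nutation curves are summarized by the
damped-sine fit A·e^(−kt)·sin(2πt/T) even though the ensemble envelope is
Gaussian. The inversion therefore fits the *same* damped-sine model to
the simulated ensemble curve over the *same* window and root-finds σ
(bisection/Brent on [0, 20%], tolerance 1e-4) to match the observed k.
This like-for-like construction is what makes the estimate well-defined —
but also window-dependent: the default window [0, 1.2 ms] (~13 periods at
T = 90.30 µs, the visual extent of a typical acquisition) is exposed as a
parameter, and σ values are only comparable when obtained with the same
window. The round trip σ → simulate → fit → σ̂ is exact to ±0.02
percentage points across σ ∈ {0.26, 1.03, 2.30, 4.08}%; a specific k↔σ
pairing from any one instrument is *not* reproducible without knowing its
window and noise level, and is not asserted anywhere.

**Damped-sine fitting.** Nonlinear least squares (lmfit) initialized from
the dominant FFT bin (parabolic refinement) and a log-linear fit to the
per-period envelope maxima. Curves with no detectable oscillation (peak
below 3× the mean FFT magnitude) are rejected rather than fitted.

## CPMG relaxometry

The model is signal-level — amplitudes M_n = M₀e^(−R₂ᵒᵇˢ·2nτ) with
R₂ᵒᵇˢ = 1/T₂ + D*(2τ)² — because that is what the measurement yields; no
density matrix is involved. Stage 1 fits each train: weighted log-linear
least squares (weights ∝ amplitude²) with a nonlinear refinement pass, or
directly nonlinear when the train contains non-positive amplitudes (the
noise floor, routine at long 2τ where 169 echoes reach e^(−26) of M₀).
Stage 2 regresses R₂ᵒᵇˢ on (2τ)² by OLS: intercept = 1/T₂, slope = D*.
The default window 2τ ∈ [40, 400] ms excludes short spacings, where
RF-heating-driven convection inflates the observed rate in real data — an
effect with no stated model, so it is excluded rather than imitated; the
window is a parameter.

The D*–FWHM correlation across reactors supports attributing the (2τ)²
term to static-field inhomogeneity. The fit optionally appends the origin
(zero linewidth ⇒ no diffusion term); R² is computed about the mean of
the augmented y values with a free intercept by default. On the published
rounded per-reactor values plus the origin this gives R² ≈ 0.985; the
higher value quoted alongside those tables evidently reflects unrounded
data and is not reproducible from them. T₂* = 1/(π·FWHM) and the ppm↔Hz
conversions round out the module. (The published per-reactor table prints
its ppm linewidths under a Hz heading and vice versa; the running text
disambiguates, and this package's tests treat the text as authoritative.)

## Kinetics, accounting, geometry

**Kinetics.** [PC_H] = [PC₀]P₀(1 − R/k₁)⁻¹(e^(−τ_bR) − e^(−τ_bk₁)), a
rise-and-fall in bubbling time with maximum at τ_b* = ln(k₁/R)/(k₁−R).
The second exponent is implemented negative: the occasionally printed
positive sign diverges and contradicts the curve it describes. The
R = k₁ degeneracy uses the analytic limit [PC₀]P₀k₁τ_be^(−k₁τ_b)
(branch switch at |R−k₁| < 1e-10·k₁; continuity verified). Whether R is
a reaction or a relaxation rate is left open; the name is neutral.

**Accounting.** P = (S_hyp/S_th)·c·P_thermal with P_thermal =
tanh(γħB/2k_BT) at an explicit temperature (the reference temperature is
an honest unknown of such measurements, so it is an argument, never a
constant). Molar polarization n·C·P is invariant under moving the order
between protons (2×50 mM×0.313 = 31.3 mM). Physical constants are CODATA
values via scipy.

**Geometry.** Fill volume πr²h (flat) or πr²h − πr³/3 (hemispherical
bottom). The hemispherical model matches the measured 16 mm (2.199 vs
2.215 mL) and 5 mm (0.267 vs 0.265 mL) volumes within 1–2%. It does
*not* reproduce the published 10 mm volume (1.202 vs 1.013 mL) under
either bottom; the geometry is validated on the 5 and 16 mm tubes only
and the 10 mm discrepancy is surfaced here rather than asserted away —
plausibly that tube's fill height or ID differs from the nominal values.

## Synthetic data

Generators cover all four input families: nutation curves (damped-sine or
Gaussian-ensemble truth), CPMG trains, injection series mean·(1+cv·z),
and OPE τ-scan tables from the full simulator. Every generator is a
bit-reproducible function of (parameters, seed) and embeds its truth in
the returned metadata (and in the `.meta.json` sidecar when written to
disk). Default noise is 1% additive of the maximum amplitude; default
problem sizes are 169 echoes × 10 echo spacings (CPMG), 2 µs steps over
[0, 1.2 ms] (nutation), a 0.1 ms τ-grid over [1, 30] ms (OPE), and 3
series × 10 repetitions (injection) — the sizes of the corresponding
bench acquisitions. Recovery figures quoted in the tests (T₂ within 2%,
D* within 5%, period within 0.5%, k within 10%; medians over 50 seeds)
are at these sizes and that noise level.

What the generators deliberately do not emulate: magnet thermal drift
(1–2 ppm/mK class), convection at short echo spacings, bubbling-induced
signal loss, radiation damping, finite pulses, deuterium spin dynamics,
and FLASH imaging. Passing round trips therefore establish that the
fitters recover the parameters of the stated models under realistic
noise — not that real data follow those models outside the windows where
they were designed to hold.

## Known limitations

- Spin-1 nuclei are not simulated; deuterated species enter only through
  the two nascent protons plus the empirical T_d damping.
- Relaxation exists only as apodization (detection) and e^(−τ/T_d)
  (OPE); there are no relaxation superoperators.
- G and D are never separated out of D* — only the product is
  identifiable from these measurements.
- The σ(B1) estimate is window-dependent by construction; it is a
  comparative homogeneity metric, not an absolute field map.
- Vendor spectrometer formats (JCAMP-DX, Bruker directories) are not
  read; inputs are plain CSV/TOML.
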