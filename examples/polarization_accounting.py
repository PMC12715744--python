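"""Hyperpolarization bookkeeping: ceilings, quantification, kinetics.

Walks through the numbers that summarize a polarizer run: the thermal
polarization the signal is referenced to, the sequence's enrichment-scaled
ceiling, the polarization quantified from a (synthetic) signal ratio, and
the bubbling time that maximizes the hydrogenated product concentration.
"""

import phipkit as pk

# Thermal reference polarization at the polarizer field and at 9.4 T
p_th_polarizer = pk.thermal_polarization(0.4454, 300.0)
print(f"thermal 1H polarization: {pk.thermal_polarization(9.4, 300.0):.2e} "
      f"at 9.4 T, {p_th_polarizer:.2e} at 0.4454 T (300 K)")

# Ceiling of the two-proton OPE experiment vs parahydrogen enrichment
for f in (1.0, 0.92):
    print(f"polarization ceiling at f = {f:.2f}: "
          f"{pk.max_polarization(f) * 100:.1f}%")

# Quantify a run whose hyperpolarized integral is 2.06e5 x thermal
q = pk.quantify_polarization(s_hyp=2.0634e5, s_th=1.0, correction=1.0,
                             p_thermal=p_th_polarizer, conc=50.0, n_protons=2)
frac = q.p / pk.max_polarization(0.92)
print(f"achieved P = {q.p * 100:.1f}% "
      f"({frac * 100:.0f}% of the f = 0.92 ceiling), "
      f"molar polarization {q.molar_polarization:.1f} mM")

# Reactor fill volume behind the molar-polarization volume
vol = pk.reactor_volume(pk.ReactorGeometry(12.5, 20.0))
print(f"16 mm reactor fill volume (ID 12.5 mm, h 20 mm): {vol:.3f} mL")

# Bubbling-time optimum of the hydrogenation kinetics
r, k1 = 0.1, 0.5
tb_star = pk.optimal_bubbling_time(r, k1)
conc = pk.hydrogenated_concentration(
    pk.KineticsParams(pc0=50.0, p0=0.313, r=r, k1=k1, tb=tb_star))
print(f"kinetics (R = {r}, k1 = {k1} 1/s): optimal bubbling "
      f"{tb_star:.1f} s -> {conc:.1f} mM polarized product")
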