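"""Two-stage CPMG analysis: echo-train fits, then the Hahn diffusion fit.

Generates synthetic echo trains for the 16 mm reactor parameters
(T2 = 3.91 s, D* = 0.83 s^-3, 169 echoes per train, 1% noise), fits each
train monoexponentially, and regresses the observed rates against (2*tau)^2
to separate true T2 from the diffusion-homogeneity term.
"""

import phipkit as pk

model = pk.CpmgModel(t2=3.91, dstar=0.83)
series = pk.gen_cpmg(model, noise=pk.NoiseSpec(level=0.01, seed=0))

result = pk.analyze_cpmg(series, window=(0.040, 0.400))
print(f"true      : T2 = {model.t2:.3f} s, D* = {model.dstar:.3f} s^-3")
print(f"recovered : T2 = {result.t2:.3f} +/- {result.t2_stderr:.3f} s, "
      f"D* = {result.dstar:.3f} +/- {result.dstar_stderr:.3f} s^-3")

# D* rises with the reactor's static-field inhomogeneity: regressing the
# published per-reactor values against their linewidths (plus the origin,
# since zero linewidth should mean no diffusion term) shows the trend.
points = [(19.855, 0.41), (29.847, 0.61), (47.254, 0.83)]  # (FWHM Hz, D*)
corr = pk.correlate_dstar_fwhm(points, include_origin=True)
print(f"D* vs FWHM: slope = {corr.slope:.4f} s^-3/Hz, R^2 = {corr.r2:.4f}")

# T2* from the 16 mm linewidth, for comparison with T2:
print(f"T2* at FWHM 2.50 Hz: {pk.t2star_from_fwhm(2.50):.3f} s "
      "(inhomogeneity-limited, ~30x shorter than T2)")
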