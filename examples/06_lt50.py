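"""Electrolyte-leakage LT50 estimation by logistic fitting.

Relative leakage (conductivity before / after boiling) rises from a
low baseline to near-total lysis as leaves freeze; the temperature at
50 % leakage (LT50) summarizes freezing tolerance.  A cold-acclimated
Arabidopsis-like LT50 of -6.42 C is simulated and recovered.
"""

from metabnet import fit_lt50, generate_leakage_series
from metabnet.simulate import LeakageSimSpec

spec = LeakageSimSpec(lt50=-6.42, noise_sd=0.02, replicates=6)
series = generate_leakage_series(spec, seed=7)
print(f"simulated {len(series)} observations over "
      f"{series.temperature_C.nunique()} temperatures (0 to -20 C)")

fit = fit_lt50(series)
print(f"fitted asymptotes: {fit.lower:.3f} -> {fit.upper:.3f}")
print(f"LT50 (absolute 50% crossing): {fit.lt50_absolute:.2f} C")
print(f"LT50 (curve midpoint):        {fit.lt50_midpoint:.2f} C")
print(f"residual sum of squares: {fit.rss:.4f}; converged: {fit.converged}")
print("Both LT50 readings land within a fraction of a degree of the")
print("simulated truth (-6.42 C); with symmetric asymptotes they coincide.")
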