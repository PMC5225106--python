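"""Genotype contrasts per design cell: signed fold changes and t-tests.

The signed fold-change convention reports a ratio r as r when r >= 1
and -1/r when r < 1, so -14.7 reads "14.7-fold lower in WT than adh1".
Features with VIP > 1 and p < 0.05 are flagged as discriminating.
"""

from metabnet import (
    differential_table,
    generate_peak_table,
    normalize_internal_standard,
    run_plsda,
    uv_scale,
)
from metabnet.simulate import study_preset

design, effects, corr = study_preset()
norm = normalize_internal_standard(generate_peak_table(design, effects, corr, seed=1))
model = run_plsda(uv_scale(norm), norm.metadata["genotype"],
                  n_components=2, n_perm=0)
diff = differential_table(norm, compare="genotype",
                          within=("condition", "timepoint"), vip=model.vip)

sucrose = diff[diff.feature == "sucrose"]
print(sucrose[["comparison", "fold", "log2fc", "p", "q", "selected"]]
      .to_string(index=False, float_format=lambda v: f"{v:.3g}"))
print(f"\n{int(diff.selected.sum())} (feature, comparison) pairs pass the "
      "VIP > 1 and p < 0.05 discriminant rule.")
print("The planted sucrose story: ~15-fold WT deficit at control that")
print("flips positive after acclimated freezing and stays negative under shock.")
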