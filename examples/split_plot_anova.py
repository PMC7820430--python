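"""Split-factorial ANOVA of soil salinity with Tukey letter display.

Tillage is a main-plot factor tested against the whole-plot error
"Error (a)"; irrigation and mulch are subplot factors tested against the
subplot residual.  Letters shared between levels mean the Tukey HSD test
cannot separate them at alpha = 0.05.
"""

from soilhealth import DesignSpec, fit_split_factorial_anova, generate_trial
from soilhealth.anova import factor_separation

table = generate_trial(seed=42)
wheat = table[table.season == "wheat"].reset_index(drop=True)

anova = fit_split_factorial_anova(wheat, "EC_e")
print("ANOVA of EC_e after wheat (split-factorial, two error strata):")
print(anova.round(3).to_string(index=False))
print("-> F for Replication/Year/Tillage uses Error (a) on 10 df; "
      "all irrigation/mulch terms use Error (b)\n")

design = DesignSpec()
sep = factor_separation(wheat, "EC_e", "irrigation", anova, design)
print("Irrigation means with Tukey letters:")
print(sep.table.round(2).to_string(index=False))
print(f"-> HSD = {sep.critical_difference:.2f} dS/m; deficit irrigation "
      "(CWR60) carries significantly less salt than full dose (CWR100)")
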