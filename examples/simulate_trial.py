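"""Generate a synthetic saline-irrigation trial and inspect its structure.

Builds the reference design (3 tillage x 3 irrigation x 2 mulch x 3
blocks x 2 years, soil sampled after each of the two crops) and shows
the planted salinity gradient and salinity-biology coupling.
"""

import numpy as np

from soilhealth import SyntheticConfig, generate_trial, ground_truth, treatment_means

table = generate_trial(SyntheticConfig(), seed=42)
print(f"rows: {len(table)} ({len(table)//2} per season)\n")

m = treatment_means(table, "EC_e", "irrigation", season="wheat")
print("EC_e after wheat by irrigation level (dS/m):")
print(m.round(2).to_string())
print("-> salinity rises with the saline-water dose; the configured "
      "100CWR-60CWR gap is "
      f"{ground_truth()['effects']['wheat']['EC_e']['irrigation']['CWR100'] - ground_truth()['effects']['wheat']['EC_e']['irrigation']['CWR60']:.2f} dS/m\n")

r = np.corrcoef(table.loc[table.season == 'sorghum', 'EC_e'],
                table.loc[table.season == 'sorghum', 'MBN'])[0, 1]
print(f"corr(EC_e, MBN) after sorghum: {r:.2f}")
print("-> the latent plot-salinity factor depresses microbial biomass, "
      "mimicking osmotic stress in the field data")
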