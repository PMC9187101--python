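"""The four single ecosystem functions and the averaging MF index.

Nutrient cycling (TP/TN/AP/AN composite), carbon stocks (SOC), water
regulation (SWC) and wood production (CWM height) are each z-scored across
plots; multifunctionality is their per-plot mean.
"""

import desertmf as d
from desertmf.diversity import cwm_table
from desertmf.functions_mf import ensure_cn

cfg = d.SimulationConfig(n_plots=10, pool_size=15, seed=3)
data = d.simulate_dataset(cfg)

soil = ensure_cn(data.landscape.soil)
heights = cwm_table(data.landscape.community, data.traits)
fm = d.function_matrix(soil, heights)

print(fm.round(3).to_string())
print()
print("Columns are standardized (mean 0, SD 1 across plots); MF is their")
print("per-plot mean, so MF > 0 marks plots performing above average across")
print("all four functions simultaneously. Wetter plots (low soil salinity,")
print("high SWC/SOC) sit at the top of the MF column.")
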