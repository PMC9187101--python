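"""Faith's PD and NRI/NTI under the taxa-shuffle null.

Simulates a 20-species phylogeny and 10 plots, then standardizes each
plot's mean pairwise distance (MPD) and mean nearest-taxon distance (MNTD)
against 199 randomizations of tip labels.  Positive NRI/NTI means the
plot's species are more closely related than a random draw of the same
size from the pool (phylogenetic clustering).
"""

import pandas as pd

import desertmf as d

cfg = d.SimulationConfig(n_plots=10, pool_size=20, clustering=0.9, seed=7)
data = d.simulate_dataset(cfg)
dist = d.patristic_distances(data.tree)

pd_per_plot = pd.Series({
    plot: d.faith_pd(data.tree,
                     data.landscape.community.columns[data.landscape.community.loc[plot] > 0])
    for plot in data.landscape.community.index
}, name="faith_pd")

ses = d.ses_table(data.landscape.community, dist, n_rand=199, seed=7)
nri = ses[ses["metric"] == "MPD"].set_index("plot")["ses"].rename("NRI")
nti = ses[ses["metric"] == "MNTD"].set_index("plot")["ses"].rename("NTI")

summary = pd.concat([pd_per_plot, nri, nti], axis=1)
print(summary.round(3).to_string())
print()
print("faith_pd is the branch length (root-inclusive) spanned by each plot's")
print("species; NRI/NTI > 0 indicates clustering, < 0 overdispersion. With a")
print("strong phylogenetic niche signal (clustering=0.9) most plots cluster.")
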