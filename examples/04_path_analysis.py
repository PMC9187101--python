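"""Recursive path analysis of multifunctionality drivers.

Fits a driver model on the per-plot table of a full synthetic run: soil pH
and C:N act on MF directly and through plant diversity.  Reports
standardized path coefficients, indirect effects and the NC / CFI fit
indices.
"""

import desertmf as d
from desertmf.pipeline import RunConfig, run

cfg = RunConfig(synthetic=d.SimulationConfig(seed=11), n_rand=199, seed=11,
                n_trees=200, n_perm=3)
result = run(cfg)

fit = result.path_fits["multifunctionality"]
print(f"model fit: chi2 = {fit.chi2:.3f}, df = {fit.df}, "
      f"NC = {fit.nc:.3f}, CFI = {fit.cfi:.3f}, n = {fit.n}")
for e in fit.edges:
    print(f"  {e.source:9s} -> {e.target:9s}  beta = {e.coefficient:+.3f}  p = {e.p_value:.3g}")
print(f"indirect effect of CN on MF: {d.indirect_effect(fit, 'CN', 'MF'):+.4f}")
print(f"total    effect of pH on MF: {d.total_effect(fit, 'pH', 'MF'):+.4f}")
print()
print("Coefficients are standardized regression weights; an indirect effect")
print("is the sum over multi-edge paths of the product of weights along each")
print("path. NC (chi2/df) near 1 and CFI near 1 indicate the DAG reproduces")
print("the sample correlations well.")
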