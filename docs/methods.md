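# Methods note

This note records the statistical model implemented by `desertmf`, the
assumptions behind each stage, the tunable parameters with their units and
defaults, what the synthetic generator emulates (and does not), and the
numerical conventions. It is the reference for anyone auditing or extending
the package.

## Data model

The pipeline operates on four inputs describing a network of vegetation
plots:

- **community** — plot × species abundance matrix (counts or cover;
  non-negative). Plots with zero total abundance are flagged and excluded
  from diversity and SES computation, with a logged warning.
- **tree** — a rooted phylogeny over (at least) the species in the community
  matrix, Newick format, branch lengths required (≥ 0, at least one > 0).
- **traits** — species × trait table; plant height (m) is the trait used for
  the wood-production function.
- **soil** — plot × variable table with SWC (soil water content, %), SSC
  (soil salt content, g/kg), pH, SOC (soil organic carbon, g/kg), TN, TP
  (total N/P, g/kg), AN, AP (available N/P, mg/kg), optionally per depth
  layer. C:N is derived as SOC/TN when not supplied.

Validation cross-checks species against the tree and trait table and plot
sets against each other (a soil-only plot is a warning; a community species
absent from the tree is an error), and range-checks pH (4–10) and SWC
(0–100 %).

## Diversity indices

With relative abundances pᵢ within a plot:

- richness D = number of species with pᵢ > 0;
- Shannon–Wiener H′ = −Σ pᵢ ln pᵢ (natural log, so H′ ≤ ln D with equality
  at perfect evenness);
- Simpson F = 1 − Σ pᵢ²;
- CWM of trait x = Σ pᵢ xᵢ.

## Phylogenetic diversity and structure

**Faith's PD** is root-inclusive: the sum of branch lengths on the union of
root-to-tip paths of the plot's species, so a one-species plot has PD equal
to that tip's depth. This convention keeps PD additive across the tree and
matches the most common software behaviour; it is verified in the test suite
against an independent implementation.

**MPD** is the mean patristic distance over unordered species pairs; **MNTD**
is the mean over species of the distance to the nearest other species in the
plot. Abundance-weighted variants weight pairs by pᵢpⱼ and nearest-neighbour
terms by pᵢ. Both are undefined (flagged `too_few_species`) for plots with
fewer than two species.

**Null model** — taxa shuffle: tip labels are permuted uniformly over the
full species pool with community size held fixed, equivalent to drawing
random k-subsets of the pool. Defaults: `n_rand = 999` randomizations; both
metrics for a plot share the same draws; the null SD uses the sample
convention (ddof = 1). Then

    NRI = −(MPD_obs − mean) / sd,    NTI = −(MNTD_obs − mean) / sd,

so clustering (observed below the null mean) is positive. One-sided rank
p = (r + 1)/(n_rand + 1) where r counts null draws ≤ observed; the reported
two-sided p is min(1, 2·min(p_low, p_high)). A zero null SD (e.g. the plot
contains the entire pool) is flagged `zero_null_sd` and yields NaN rather
than ±∞.

**Seeding** — each plot's randomization stream is derived as
`SeedSequence([master_seed, plot_index])`, so any single plot's SES can be
recomputed in isolation and the per-plot seeds logged in `run.log` are
sufficient to reproduce it.

## Single functions and multifunctionality

Four functions are assembled per plot:

1. nutrient cycling — TP, TN, AP, AN each z-scored across plots, averaged,
   and the composite re-z-scored (`nutrient_mode="zscore"`, default; `"raw"`
   averages the raw values before standardizing, which lets the indicator
   with the largest variance dominate and is provided only for comparison);
2. carbon stocks — SOC;
3. water regulation — SWC;
4. wood production — CWM plant height.

All four columns are z-scored (sample SD, ddof = 1) and MF is their per-plot
mean. Because every indicator is standardized first, MF is invariant to any
affine rescaling of the raw measurements (unit changes do not alter it); this
is tested to 1e-9. A zero-variance indicator raises `ZeroVarianceError`
naming the column rather than silently producing NaN. Multi-layer soil
profiles are aggregated per plot before standardization (`layer_mode="mean"`
default, or `"first"` for topsoil only).

## Association screens

For each predictor (defaults: richness, H′, Simpson, PD, NRI, NTI, pH, SSC,
C:N) the pipeline fits OLS models MF ~ x (linear) and MF ~ x + x² (quadratic)
via statsmodels, reporting coefficients, R² and the model F-test p-value.
Constant or rank-deficient predictors are skipped with a log line rather than
crashing the run. The quadratic form exists to detect hump-shaped
("single-peak") diversity–function relations.

## Path analysis

Models are recursive (acyclic) systems over observed variables, specified as
directed edges and validated as a DAG. All variables are standardized
(ddof = 1) and each endogenous variable is fit by its own OLS equation —
exact maximum likelihood for recursive models with independent errors.

Fit assessment: with B the standardized coefficient matrix and Ψ the error
(co)variance matrix — exogenous block fixed at the sample correlations,
endogenous diagonal 1 − R² — the implied correlation matrix is
Σ = (I − B)⁻¹ Ψ (I − B)⁻ᵀ and

    F_ML = ln|Σ| − ln|S| + tr(S Σ⁻¹) − p,    χ² = (n − 1) F_ML.

Degrees of freedom are p(p+1)/2 − (n_edges + n_endogenous + n_exogenous):
exogenous correlations are *fixed*, not counted as free parameters, which is
a deliberate design choice — it makes the χ² test sensitive only to the
structural part of the model. NC = χ²/df is the normed chi-square (values
near 1 indicate good fit; note the fixed-exogenous convention means NC/CFI
here are not numerically interchangeable with software that frees those
correlations). CFI is computed against the independence baseline
(χ²_b = −(n−1) ln|S|, df_b = p(p−1)/2) and clipped to [0, 1]. A saturated
model (df = 0) reports χ² = 0, CFI = 1 by convention. Standardized
coefficients with |β| > 1 are flagged as Heywood-type solutions.

Indirect effects sum the products of coefficients along every directed path
of length ≥ 2 between two variables; the total effect adds the direct edge.
For single-exogenous recursive models the total effect equals the marginal
regression slope (Wright's rule), which the tests verify.

The default driver model regresses MF on pH, C:N, richness and PD, with
richness and PD endogenous to the soil variables and richness → PD included
(species count mechanically drives PD; omitting that edge misattributes
their shared variance and inflates χ²).

## Importance ranking

A bootstrap ensemble of CART regression trees (own bootstrap over
scikit-learn `DecisionTreeRegressor`s, since the stock forest does not expose
out-of-bag permutation importance). Defaults: `n_trees = 500`,
`mtry = ⌈p/3⌉` features per split (the regression convention),
`min_samples_leaf = 5`, `n_perm = 10` permutations per tree. Importance of
feature j is the mean over trees and permutations of the increase in
out-of-bag MSE when column j is permuted among that tree's OOB rows, floored
at 0; ties in the ranking break by feature-name order for determinism. The
pipeline ranks the four single functions as drivers of MF (and logs the
caveat that MF is by construction their mean, so the ranking reflects
variance contributions, not causal strength).

## Synthetic data generator

`SimulationConfig` (all defaults chosen to produce a landscape with realistic
turnover on an 80-plot transect):

| parameter | default | units / meaning |
|---|---|---|
| `n_plots` | 80 | plots along the gradient |
| `pool_size` | 40 | species in the regional pool |
| `birth_rate` | 1.0 | Yule speciation rate (per unit branch time) |
| `bm_sigma2` | 0.2 | Brownian-motion rate of log plant height |
| `bm_root` | 0.7 | log height (m) at the root |
| `niche_width` | 0.35 | SD of each species' Gaussian response on the gradient |
| `clustering` | 0.5 | 0–1 blend of phylogenetically conserved vs random niche optima |
| `lambda_max` | 5.0 | peak Poisson abundance per species per plot |
| `max_empty_retries` | 20 | redraws before flagging an empty plot |
| `soil_model` | see below | per-variable linear response to the gradient |

Mechanism: a latent gradient g ∈ [−1, 1] (evenly spaced across plots;
g = −1 is the wet/low-salt end) drives (i) species occurrence through
Gaussian niches whose optima are partly inherited on the tree (the
`clustering` blend of standardized Brownian values and uniform draws), with
Poisson abundances; and (ii) soil chemistry through
`value = intercept + slope·g + Normal(0, sd)`, clipped to physical ranges.
The default soil model makes SWC, SOC, TN, TP, AP, AN decline and SSC rise
with g, with pH mildly declining — a dry/saline end that is poorer in every
resource, so diversity, soil fertility and MF all co-vary with the gradient.
Pendant edges of the simulated Yule tree are extended by an Exp(n·λ) draw so
no tip has a zero-length branch.

**What it does not emulate**: the gradient is one-dimensional (no independent
water and salt axes), there is no spatial autocorrelation between plots, no
real taxonomy or measured traits, no within-plot soil heterogeneity beyond
the optional layer structure, and abundances are independent Poisson (no
competition or zero-inflation). It is a test harness and demonstration
substrate, not a forecasting model.

All randomness is derived from a single master seed through per-purpose
`SeedSequence` spawns (tree, traits, niches, per-plot abundances, soil
noise), so every component is independently reproducible.

## Numerical conventions and degenerate cases

- All SDs used for standardization and null distributions are sample SDs
  (ddof = 1).
- Floating-point comparisons in tests use absolute tolerances of 1e-12 for
  algebraic identities (summation order makes bit-exact equality across
  implementations unattainable) and looser, pre-registered statistical bands
  for calibration checks.
- Output CSVs are written with `%.10g` formatting, making reruns of the same
  configuration byte-identical.
- Degenerate inputs fail loudly: empty plots, missing traits, zero-variance
  indicators, constant regression predictors, duplicate tip labels and
  cyclic path specifications each raise a named exception or set an explicit
  flag — never a silent NaN.
- Seeds must be below 2³¹; the CLI and acceptance script reduce larger
  inputs modulo 2³¹ − 1.

## Problem sizes

Defaults target the intended field scale: 80 plots, ~40-species pool,
999 randomizations per plot, 500-tree ensembles. The test suite uses smaller
sizes (e.g. 199 randomizations, 16–20 plots) where the property under test
does not require the full scale, and larger Monte Carlo sizes (e.g. n = 2000
per dataset for χ² calibration, n = 1000 per replicate for importance
recovery) where finite-sample noise in the *data* would otherwise obscure
whether the *estimator* is correct.

## Limitations

- Path analysis assumes linear relations among standardized observed
  variables, independent errors and recursive structure; no latent
  variables, no non-recursive loops, no robust/bootstrap standard errors.
- NC and CFI use the fixed-exogenous-correlation df convention described
  above; compare values across software with care.
- The taxa-shuffle null conditions only on community size; richness-gradient
  or dispersal-limited nulls are out of scope.
- Importance scores from the tree ensemble are descriptive rankings, not
  effect sizes, and are biased toward high-variance predictors like any
  permutation importance.
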