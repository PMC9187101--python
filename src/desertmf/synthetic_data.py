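"""Synthetic desert-gradient data with known statistical structure.

Emulates a plot network laid out along a water/salt gradient in an arid
basin: 80 plots of 30 m × 30 m by default, a pool of desert shrub/herb/tree
species with an ultrametric (Yule) phylogeny, log-normal plant heights from
Brownian motion on the tree, Gaussian niche responses of species to a
single latent gradient (optima optionally phylogenetically autocorrelated),
Poisson abundances, and soil variables that are linear in the gradient plus
Gaussian noise.

The gradient axis g runs over [−1, 1]; by convention larger g means drier
and saltier (farther from the river), so soil water content and nutrient
stocks decline with g while salinity rises.  Default coefficients were set
once to give soil values in the range a desert saline basin would show
(SWC around 6–18 %, pH 7.7–8.7, SOC 3.5–8.5 g/kg) and are part of the
simulated study design, not tuning knobs.

Every randomized quantity draws from a stream keyed to
``(master seed, purpose tag)`` so each module's inputs can be regenerated
independently.
"""

from __future__ import annotations

import json
import random
import zlib
from dataclasses import dataclass, field, asdict
from pathlib import Path

import dendropy
import numpy as np
import pandas as pd

from .phylo import Phylogeny, write_newick

__all__ = [
    "SimulationConfig",
    "LandscapeData",
    "simulate_phylogeny",
    "simulate_traits",
    "simulate_landscape",
    "simulate_dataset",
    "write_dataset",
]

# soil variable -> (intercept, slope on the gradient, noise SD, lower clip, upper clip)
DEFAULT_SOIL_MODEL = {
    "SWC": (12.0, -6.0, 1.5, 0.5, 100.0),
    "SSC": (6.0, 3.0, 0.8, 0.05, np.inf),
    "pH": (8.2, -0.5, 0.15, 4.0, 10.0),
    "SOC": (6.0, -2.5, 0.8, 0.05, np.inf),
    "TN": (0.5, -0.18, 0.06, 0.01, np.inf),
    "TP": (0.6, -0.15, 0.05, 0.01, np.inf),
    "AP": (8.0, -3.0, 1.0, 0.1, np.inf),
    "AN": (25.0, -8.0, 3.0, 0.5, np.inf),
}


def _rng(seed: int, tag: str) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(seed), zlib.crc32(tag.encode())]))


@dataclass(frozen=True)
class SimulationConfig:
    """Study-design parameters of the simulated plot network."""

    n_plots: int = 80              # 30 m × 30 m plots along the gradient
    pool_size: int = 40            # species pool of the basin
    birth_rate: float = 1.0        # Yule speciation rate (per unit tree time)
    bm_sigma2: float = 0.2         # Brownian variance of log plant height
    bm_root: float = 0.7           # log height at the root (exp(0.7) ≈ 2 m)
    soil_model: dict = field(default_factory=lambda: dict(DEFAULT_SOIL_MODEL))
    niche_width: float = 0.35      # SD of the Gaussian niche response on g
    clustering: float = 0.5        # 0 = random niche optima, 1 = fully phylogenetic
    lambda_max: float = 5.0        # Poisson mean of a species at its optimum
    max_empty_retries: int = 20
    seed: int = 0

    def __post_init__(self):
        if self.n_plots < 4 or self.pool_size < 4:
            raise ValueError("n_plots and pool_size must both be at least 4")
        if not (0.0 <= self.clustering <= 1.0):
            raise ValueError("clustering must lie in [0, 1]")
        for var, (_, _, sd, *_rest) in self.soil_model.items():
            if sd <= 0:
                raise ValueError(f"noise SD for {var} must be positive")
        if self.niche_width <= 0 or self.lambda_max <= 0:
            raise ValueError("niche_width and lambda_max must be positive")


@dataclass
class LandscapeData:
    community: pd.DataFrame     # plot × species abundances
    soil: pd.DataFrame          # plot × soil variables
    gradient: pd.Series         # latent g per plot
    niche_optima: pd.Series     # generating optimum per species
    flagged_empty: tuple = ()   # plots left empty after retries


def simulate_phylogeny(pool_size: int, birth_rate: float = 1.0, seed: int = 0,
                       max_time: float | None = None) -> Phylogeny:
    """Ultrametric Yule tree with tips sp001..spN.

    Stops at ``pool_size`` extant tips, or at ``max_time`` when given (the
    tip count is then random with mean growing as exp(birth_rate·t)).
    """
    if pool_size < 2 and max_time is None:
        raise ValueError("pool_size must be at least 2")
    from dendropy.simulate import treesim

    np_rng = _rng(seed, "yule")
    py_rng = random.Random(int(np_rng.integers(0, 2**31 - 1)))
    kwargs = dict(birth_rate=float(birth_rate), death_rate=0.0, rng=py_rng,
                  repeat_until_success=True)
    if max_time is not None:
        # condition on at least one speciation so the result is a proper tree
        for _ in range(200):
            tree = treesim.birth_death_tree(max_time=float(max_time), **kwargs)
            if len(tree.leaf_nodes()) >= 2:
                break
        else:
            raise RuntimeError("no speciation within max_time after repeated attempts")
    else:
        tree = treesim.birth_death_tree(num_extant_tips=int(pool_size), **kwargs)
        # the simulator stops exactly at the n-th speciation, leaving zero-length
        # pendant edges; continue the process for an Exp(n·birth_rate) time so the
        # tree is sampled strictly inside the n-lineage epoch
        extra = float(np_rng.exponential(1.0 / (int(pool_size) * float(birth_rate))))
        for leaf in tree.leaf_node_iter():
            leaf.edge.length = (leaf.edge.length or 0.0) + extra
    leaves = sorted(tree.leaf_node_iter(), key=lambda lf: lf.taxon.label if lf.taxon else "")
    ns = dendropy.TaxonNamespace()
    for i, leaf in enumerate(leaves, start=1):
        taxon = dendropy.Taxon(label=f"sp{i:03d}")
        ns.add_taxon(taxon)
        leaf.taxon = taxon
    tree.taxon_namespace = ns
    tree.seed_node.edge.length = None  # any stem above the root is not part of the tree
    return Phylogeny(tree)


def _bm_tip_values(phy: Phylogeny, sigma2: float, root_value: float,
                   rng: np.random.Generator) -> pd.Series:
    """Brownian motion along branches; returns the value at each tip."""
    values = {}
    tips = {}
    tree = phy.dendropy_tree
    values[id(tree.seed_node)] = float(root_value)
    for node in tree.preorder_node_iter():
        if node is tree.seed_node:
            continue
        parent_val = values[id(node.parent_node)]
        step_sd = np.sqrt(max(sigma2, 0.0) * (node.edge.length or 0.0))
        values[id(node)] = parent_val + (rng.normal(0.0, step_sd) if step_sd > 0 else 0.0)
        if node.is_leaf():
            tips[node.taxon.label] = values[id(node)]
    return pd.Series(tips).sort_index()


def simulate_traits(phy: Phylogeny, sigma2: float = 0.2, root_value: float = 0.7,
                    seed: int = 0) -> pd.Series:
    """Plant heights (m) with phylogenetic signal.

    Brownian motion on the log scale, exponentiated at the tips, so heights
    are positive and log-normally distributed with variance growing with
    root-to-tip depth.
    """
    log_h = _bm_tip_values(phy, sigma2, root_value, _rng(seed, "traits"))
    heights = np.exp(log_h)
    heights.name = "height_m"
    heights.index.name = "species"
    return heights


def _niche_optima(phy: Phylogeny, config: SimulationConfig) -> pd.Series:
    """Species optima on g, blending a Brownian (cladewise) and a uniform component."""
    species = list(phy.tip_labels)
    bm = _bm_tip_values(phy, 1.0, 0.0, _rng(config.seed, "niche-bm"))
    bm = bm.reindex(species)
    spread = bm.std(ddof=0)
    u_phylo = 0.7 * (bm - bm.mean()) / (spread if spread > 0 else 1.0)
    u_rand = pd.Series(_rng(config.seed, "niche-rand").uniform(-1.1, 1.1, len(species)),
                       index=species)
    u = config.clustering * u_phylo + (1.0 - config.clustering) * u_rand
    return u.clip(-1.3, 1.3)


def simulate_landscape(config: SimulationConfig, phy: Phylogeny) -> LandscapeData:
    """Communities and soil along the latent gradient.

    Plot j sits at g_j evenly spaced over [−1, 1].  Species k's abundance in
    plot j is Poisson with mean ``lambda_max · exp(−(g_j − u_k)²/(2w²))``;
    soil variables follow the linear-in-g model of the config with Gaussian
    noise, clipped to their physical ranges.  Plots that come out empty are
    redrawn up to a bound, then flagged.
    """
    species = list(phy.tip_labels)
    if len(species) != config.pool_size:
        raise ValueError("tree tip count does not match config.pool_size")
    plots = [f"plot{j + 1:03d}" for j in range(config.n_plots)]
    g = np.linspace(-1.0, 1.0, config.n_plots)

    optima = _niche_optima(phy, config)
    lam = config.lambda_max * np.exp(
        -((g[:, None] - optima.to_numpy()[None, :]) ** 2) / (2 * config.niche_width**2)
    )
    rng_comm = _rng(config.seed, "community")
    abundances = rng_comm.poisson(lam)
    flagged = []
    for j in range(config.n_plots):
        tries = 0
        while abundances[j].sum() == 0 and tries < config.max_empty_retries:
            abundances[j] = rng_comm.poisson(lam[j])
            tries += 1
        if abundances[j].sum() == 0:
            flagged.append(plots[j])
    community = pd.DataFrame(abundances, index=plots, columns=species)
    community.index.name = "plot"

    rng_soil = _rng(config.seed, "soil")
    soil = {}
    for var, (a0, a1, sd, lo, hi) in config.soil_model.items():
        vals = a0 + a1 * g + rng_soil.normal(0.0, sd, config.n_plots)
        soil[var] = np.clip(vals, lo, hi)
    soil = pd.DataFrame(soil, index=plots)
    soil.index.name = "plot"

    gradient = pd.Series(g, index=plots, name="gradient")
    gradient.index.name = "plot"
    optima.name = "niche_optimum"
    optima.index.name = "species"
    return LandscapeData(community=community, soil=soil, gradient=gradient,
                         niche_optima=optima, flagged_empty=tuple(flagged))


@dataclass
class Dataset:
    config: SimulationConfig
    tree: Phylogeny
    traits: pd.Series
    landscape: LandscapeData


def simulate_dataset(config: SimulationConfig) -> Dataset:
    """Tree + traits + communities + soil in one reproducible bundle."""
    phy = simulate_phylogeny(config.pool_size, config.birth_rate, seed=config.seed)
    traits = simulate_traits(phy, config.bm_sigma2, config.bm_root, seed=config.seed)
    landscape = simulate_landscape(config, phy)
    return Dataset(config=config, tree=phy, traits=traits, landscape=landscape)


def write_dataset(data: Dataset, outdir) -> dict:
    """Emit the exact file formats the pipeline readers consume.

    Writes tree.nwk, community.csv, traits.csv, soil.csv and a provenance
    JSON with all generating parameters and the master seed; returns the
    path map.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "tree": outdir / "tree.nwk",
        "community": outdir / "community.csv",
        "traits": outdir / "traits.csv",
        "soil": outdir / "soil.csv",
        "provenance": outdir / "provenance.json",
    }
    paths["tree"].write_text(write_newick(data.tree) + "\n")
    data.landscape.community.to_csv(paths["community"])
    data.traits.to_frame().to_csv(paths["traits"])
    data.landscape.soil.to_csv(paths["soil"])
    prov = asdict(data.config)
    prov["flagged_empty_plots"] = list(data.landscape.flagged_empty)
    paths["provenance"].write_text(json.dumps(prov, indent=2, default=str) + "\n")
    return {k: str(v) for k, v in paths.items()}
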