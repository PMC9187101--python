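import numpy as np
import pytest

import desertmf as d


def random_tree_newick(rng: np.random.Generator, n_tips: int) -> str:
    """A random binary topology with uniform(0.1, 2) branch lengths."""
    nodes = [f"t{i}" for i in range(1, n_tips + 1)]
    subtrees = [f"{name}:{rng.uniform(0.1, 2.0):.6f}" for name in nodes]
    while len(subtrees) > 1:
        i, j = sorted(rng.choice(len(subtrees), size=2, replace=False))
        b = subtrees.pop(j)
        a = subtrees.pop(i)
        if len(subtrees) == 0:
            subtrees.append(f"({a},{b})")
        else:
            subtrees.append(f"({a},{b}):{rng.uniform(0.1, 2.0):.6f}")
    return subtrees[0] + ";"


@pytest.fixture
def rng():
    return np.random.default_rng(20261002)


@pytest.fixture
def three_tip_tree():
    return d.parse_newick("((A:1,B:1):1,C:2);")


@pytest.fixture
def three_tip_dist(three_tip_tree):
    return d.patristic_distances(three_tip_tree)


def two_clade_tree(n_per_clade: int = 6, separation: float = 20.0,
                   within: float = 1.0) -> d.Phylogeny:
    """Two shallow clades joined by long stems: strong phylogenetic structure."""
    left = ",".join(f"L{i}:{within}" for i in range(1, n_per_clade + 1))
    right = ",".join(f"R{i}:{within}" for i in range(1, n_per_clade + 1))
    return d.parse_newick(f"(({left}):{separation},({right}):{separation});")


@pytest.fixture
def small_dataset():
    cfg = d.SimulationConfig(n_plots=20, pool_size=15, seed=11)
    return d.simulate_dataset(cfg)
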