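"""Species diversity indices and community-weighted mean (CWM) traits.

Per-plot quantities computed from a plot × species abundance matrix:
richness D (count of species present), Shannon–Wiener H' in nats,
Simpson dominance F_simpson = 1 − Σ p_i², and the abundance-weighted
community mean of a species-level trait (here: plant height, m).

The field's symbol F is overloaded (Simpson index vs. number of functions
in the multifunctionality index); this package uses ``F_simpson`` and
``n_functions`` respectively.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

__all__ = [
    "DegeneratePlotError",
    "MissingTraitError",
    "relative_abundances",
    "richness",
    "shannon",
    "simpson",
    "cwm",
    "diversity_table",
    "cwm_table",
]

logger = logging.getLogger(__name__)


class DegeneratePlotError(ValueError):
    """A plot with zero total abundance has no defined diversity."""


class MissingTraitError(ValueError):
    def __init__(self, species):
        self.species = sorted(species)
        super().__init__(f"missing trait values for present species: {', '.join(self.species)}")


def relative_abundances(counts) -> np.ndarray:
    """P_i: each species' share of the plot's individuals."""
    counts = np.asarray(counts, dtype=float)
    if np.any(counts < 0):
        raise ValueError("abundances must be non-negative")
    total = counts.sum()
    if total <= 0:
        raise DegeneratePlotError("plot has zero total abundance")
    return counts / total


def _check_probs(p) -> np.ndarray:
    p = np.asarray(p, dtype=float)
    if np.any(p < 0) or not np.isclose(p.sum(), 1.0, atol=1e-8):
        raise ValueError("not a valid probability vector")
    return p


def richness(counts) -> int:
    counts = np.asarray(counts, dtype=float)
    if np.any(counts < 0):
        raise ValueError("abundances must be non-negative")
    if counts.sum() <= 0:
        raise DegeneratePlotError("plot has zero total abundance")
    return int(np.count_nonzero(counts > 0))


def shannon(p) -> float:
    """H' = −Σ p_i ln p_i over positive entries (nats)."""
    p = _check_probs(p)
    pos = p[p > 0]
    return float(-np.sum(pos * np.log(pos)) + 0.0)  # +0.0 avoids -0.0 at S=1


def simpson(p) -> float:
    """Simpson dominance F_simpson = 1 − Σ p_i²."""
    p = _check_probs(p)
    return float(1.0 - np.sum(p**2))


def cwm(p, traits) -> float:
    """Community-weighted mean trait: Σ p_i · trait_i.

    ``traits`` is aligned with ``p``; every species with p_i > 0 must have a
    finite trait value.
    """
    p = _check_probs(p)
    traits = np.asarray(traits, dtype=float)
    if traits.shape != p.shape:
        raise ValueError("traits must align with the abundance vector")
    bad = (p > 0) & ~np.isfinite(traits)
    if np.any(bad):
        raise MissingTraitError([str(i) for i in np.flatnonzero(bad)])
    return float(np.sum(p[p > 0] * traits[p > 0]))


def _usable_plots(community: pd.DataFrame) -> pd.Index:
    totals = community.sum(axis=1)
    empty = community.index[totals <= 0]
    if len(empty):
        logger.warning("excluding %d plot(s) with zero total abundance: %s",
                       len(empty), ", ".join(map(str, empty)))
    return community.index[totals > 0]


def diversity_table(community: pd.DataFrame) -> pd.DataFrame:
    """Richness, Shannon and Simpson per plot.

    Plots with zero total abundance are excluded with a logged warning rather
    than aborting the run.
    """
    if (community.values < 0).any():
        raise ValueError("community matrix contains negative abundances")
    rows = {}
    for plot in _usable_plots(community):
        counts = community.loc[plot].to_numpy(dtype=float)
        p = relative_abundances(counts)
        rows[plot] = {
            "richness": richness(counts),
            "shannon": shannon(p),
            "simpson": simpson(p),
        }
    out = pd.DataFrame.from_dict(rows, orient="index")
    out.index.name = community.index.name or "plot"
    return out


def cwm_table(community: pd.DataFrame, traits: pd.Series) -> pd.Series:
    """CWM of a trait for every non-empty plot.

    ``traits`` is indexed by species name; species present in a plot but
    absent from the trait table raise :class:`MissingTraitError`.
    """
    vals = {}
    for plot in _usable_plots(community):
        counts = community.loc[plot]
        present = counts.index[counts > 0]
        missing = [s for s in present if s not in traits.index or not np.isfinite(traits[s])]
        if missing:
            raise MissingTraitError(missing)
        p = relative_abundances(counts.to_numpy(dtype=float))
        aligned = traits.reindex(counts.index).to_numpy(dtype=float)
        aligned = np.where(p > 0, aligned, 0.0)
        vals[plot] = float(np.sum(p * aligned))
    out = pd.Series(vals, name="cwm_height")
    out.index.name = community.index.name or "plot"
    return out
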