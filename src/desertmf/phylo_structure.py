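"""Community phylogenetic structure: MPD, MNTD and NRI/NTI.

MPD is the mean pairwise patristic distance between the species of a plot;
MNTD the mean distance from each species to its nearest co-occurring
relative.  Both are standardized against a *taxa-shuffle* null: species
labels are permuted uniformly over the full pool of the distance matrix,
holding community size fixed, and the metric is recomputed.  The
standardized effect sizes carry a leading −1,

    NRI = −(MPD_obs − mean MPD_null) / sd MPD_null
    NTI = −(MNTD_obs − mean MNTD_null) / sd MNTD_null

so phylogenetically *clustered* communities (observed distance below the
null mean) come out positive.

Abundance weighting is off by default (presence/absence metrics); pass
weights to enable it.  Null summaries use the sample standard deviation
(n−1 denominator) by default.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .phylo import DistanceMatrix

__all__ = [
    "SESResult",
    "mpd",
    "mntd",
    "null_distribution",
    "nri",
    "nti",
    "ses_table",
    "derive_plot_seed",
]

_METRICS = ("MPD", "MNTD")


@dataclass(frozen=True)
class SESResult:
    """Observed metric, null summary and standardized effect size for one plot.

    ``flag`` is None when the SES is defined; otherwise it names the
    degeneracy ("too_few_species" or "zero_null_sd") and ``ses``/``p`` are NaN.
    """

    plot: object
    metric: str
    observed: float
    null_mean: float
    null_sd: float
    ses: float
    p_low: float
    p_two: float
    n_rand: int
    seed: int
    flag: str | None = None


def _metric_from_indices(dist: np.ndarray, idx: np.ndarray, metric: str,
                         weights: np.ndarray | None) -> np.ndarray:
    """Evaluate MPD or MNTD for each row of index-subsets ``idx`` (2-D)."""
    k = idx.shape[1]
    sub = dist[idx[:, :, None], idx[:, None, :]]  # (n_draws, k, k)
    if metric == "MPD":
        if weights is None:
            off = sub.sum(axis=(1, 2))
            return off / (k * (k - 1))
        w = np.outer(weights, weights)
        np.fill_diagonal(w, 0.0)
        return (sub * w).sum(axis=(1, 2)) / w.sum()
    if metric == "MNTD":
        sub = sub.copy()
        rng_k = np.arange(k)
        sub[:, rng_k, rng_k] = np.inf
        nearest = sub.min(axis=2)
        if weights is None:
            return nearest.mean(axis=1)
        w = weights / weights.sum()
        return nearest @ w
    raise ValueError(f"unknown metric {metric!r}")


def _prepare(dist: DistanceMatrix, members, weights):
    idx = dist.indices(list(members))
    w = None
    if weights is not None:
        w = np.asarray(weights, dtype=float)
        if w.shape != idx.shape or np.any(w < 0) or w.sum() <= 0:
            raise ValueError("weights must be non-negative, aligned with members, with positive sum")
    return idx, w


def mpd(dist: DistanceMatrix, members, weights=None) -> float:
    """Mean pairwise distance; NaN for communities with fewer than 2 species."""
    idx, w = _prepare(dist, members, weights)
    if len(idx) < 2:
        return float("nan")
    return float(_metric_from_indices(dist.values, idx[None, :], "MPD", w)[0])


def mntd(dist: DistanceMatrix, members, weights=None) -> float:
    """Mean nearest-taxon distance; NaN for communities with fewer than 2 species."""
    idx, w = _prepare(dist, members, weights)
    if len(idx) < 2:
        return float("nan")
    return float(_metric_from_indices(dist.values, idx[None, :], "MNTD", w)[0])


def _null_draws(pool_size: int, k: int, n_rand: int, rng: np.random.Generator) -> np.ndarray:
    """n_rand random k-subsets of the pool (taxa-shuffle null, size held fixed)."""
    keys = rng.random((n_rand, pool_size))
    return np.argsort(keys, axis=1)[:, :k]


def null_distribution(metric: str, members, dist: DistanceMatrix, n_rand: int,
                      seed: int, weights=None, sd_ddof: int = 1):
    """Null mean/SD/samples of a metric under the taxa-shuffle null.

    Each randomization permutes tip labels uniformly over the whole pool of
    the distance matrix and recomputes the metric for the same community
    size.  Fully reproducible from ``seed``.
    """
    if metric not in _METRICS:
        raise ValueError(f"metric must be one of {_METRICS}")
    if n_rand < 2:
        raise ValueError("n_rand must be at least 2")
    idx, w = _prepare(dist, members, weights)
    if len(idx) < 2:
        raise ValueError("null distribution undefined for communities of fewer than 2 species")
    rng = np.random.default_rng(seed)
    draws = _null_draws(dist.n, len(idx), n_rand, rng)
    samples = _metric_from_indices(dist.values, draws, metric, w)
    return float(samples.mean()), float(samples.std(ddof=sd_ddof)), samples


def _rank_p(observed: float, samples: np.ndarray, n_rand: int):
    p_low = (np.sum(samples <= observed) + 1) / (n_rand + 1)
    p_high = (np.sum(samples >= observed) + 1) / (n_rand + 1)
    return float(p_low), float(min(1.0, 2 * min(p_low, p_high)))


def _ses(plot, metric, dist, members, n_rand, seed, weights, sd_ddof) -> SESResult:
    idx, w = _prepare(dist, members, weights)
    if len(idx) < 2:
        return SESResult(plot, metric, float("nan"), float("nan"), float("nan"),
                         float("nan"), float("nan"), float("nan"), n_rand, seed,
                         flag="too_few_species")
    observed = float(_metric_from_indices(dist.values, idx[None, :], metric, w)[0])
    null_mean, null_sd, samples = null_distribution(metric, members, dist, n_rand,
                                                    seed, weights=weights, sd_ddof=sd_ddof)
    if null_sd <= 0:
        return SESResult(plot, metric, observed, null_mean, null_sd,
                         float("nan"), float("nan"), float("nan"), n_rand, seed,
                         flag="zero_null_sd")
    p_low, p_two = _rank_p(observed, samples, n_rand)
    ses = -1.0 * (observed - null_mean) / null_sd
    return SESResult(plot, metric, observed, null_mean, null_sd, ses,
                     p_low, p_two, n_rand, seed)


def nri(dist: DistanceMatrix, members, n_rand: int = 999, seed: int = 0,
        weights=None, plot=None, sd_ddof: int = 1) -> SESResult:
    """Net relatedness index (−1 × SES of MPD) for one community."""
    return _ses(plot, "MPD", dist, members, n_rand, seed, weights, sd_ddof)


def nti(dist: DistanceMatrix, members, n_rand: int = 999, seed: int = 0,
        weights=None, plot=None, sd_ddof: int = 1) -> SESResult:
    """Nearest taxon index (−1 × SES of MNTD) for one community."""
    return _ses(plot, "MNTD", dist, members, n_rand, seed, weights, sd_ddof)


def derive_plot_seed(master_seed: int, plot_index: int) -> int:
    """Deterministic per-plot stream seed, so any plot can be recomputed alone."""
    ss = np.random.SeedSequence([int(master_seed), int(plot_index)])
    return int(ss.generate_state(1, dtype=np.uint32)[0])


def ses_table(community: pd.DataFrame, dist: DistanceMatrix, n_rand: int = 999,
              seed: int = 0, abundance_weighted: bool = False,
              sd_ddof: int = 1) -> pd.DataFrame:
    """NRI and NTI for every plot of a community matrix.

    Per-plot RNG streams are derived from ``(seed, plot position)`` so serial
    and parallel evaluation orders give identical results; both metrics share
    one set of randomizations per plot, as a joint run of the null would.
    Returns a long table (plot, metric, obs, null_mean, null_sd, ses, p,
    n_rand, seed) with MPD rows carrying NRI and MNTD rows carrying NTI.
    """
    records = []
    for pos, plot in enumerate(community.index):
        counts = community.loc[plot]
        present = list(counts.index[counts > 0])
        weights = counts[counts > 0].to_numpy(dtype=float) if abundance_weighted else None
        plot_seed = derive_plot_seed(seed, pos)
        for metric, fn in (("MPD", nri), ("MNTD", nti)):
            res = fn(dist, present, n_rand=n_rand, seed=plot_seed,
                     weights=weights, plot=plot, sd_ddof=sd_ddof)
            records.append({
                "plot": plot, "metric": metric, "obs": res.observed,
                "null_mean": res.null_mean, "null_sd": res.null_sd,
                "ses": res.ses, "p": res.p_two, "p_low": res.p_low,
                "n_rand": n_rand, "seed": plot_seed, "flag": res.flag or "",
            })
    return pd.DataFrame.from_records(records)
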