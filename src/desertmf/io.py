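"""Readers and writers for the pipeline's delimited-text formats.

All tabular inputs are delimited text with a header; the first column is
the plot (or species) identifier.  Trees are Newick with branch lengths.
Matching between tables is by exact string identifier — no fuzzy joins.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from .functions_mf import aggregate_layers
from .phylo import Phylogeny, parse_newick

__all__ = [
    "read_tree",
    "read_community",
    "read_traits",
    "read_soil",
    "write_table",
]


def _read_indexed(path, kind: str) -> pd.DataFrame:
    path = Path(path)
    try:
        df = pd.read_csv(path, sep=None, engine="python", index_col=0)
    except Exception as exc:
        raise ValueError(f"cannot read {kind} table {path}: {exc}") from exc
    if df.index.has_duplicates and kind != "soil":
        dupes = df.index[df.index.duplicated()].unique()
        raise ValueError(f"duplicate identifiers in {path}: {', '.join(map(str, dupes))}")
    df.index = df.index.map(str)
    return df


def read_tree(path) -> Phylogeny:
    return parse_newick(Path(path).read_text())


def read_community(path) -> pd.DataFrame:
    """Plot × species abundance table (rows = plots)."""
    df = _read_indexed(path, "community").astype(float)
    if (df.values < 0).any():
        raise ValueError(f"negative abundances in {path}")
    df.index.name = "plot"
    return df


def read_traits(path) -> pd.Series:
    """Species → trait value (first trait column is used)."""
    df = _read_indexed(path, "trait")
    s = df.iloc[:, 0].astype(float)
    s.index.name = "species"
    return s


def read_soil(path, layer_mode: str = "mean") -> pd.DataFrame:
    """Plot × soil-variable table; per-layer records are aggregated per plot."""
    df = _read_indexed(path, "soil")
    df = aggregate_layers(df, mode=layer_mode).astype(float)
    if df.index.has_duplicates:
        raise ValueError(f"duplicate plot rows in {path} after layer aggregation")
    df.index.name = "plot"
    return df


def write_table(df, path, float_format: str = "%.10g") -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, float_format=float_format)
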