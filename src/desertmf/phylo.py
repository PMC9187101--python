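"""Phylogeny handling: Newick I/O, patristic distances, and Faith's PD.

The tree is the source of all phylogenetic quantities downstream: Faith's
phylogenetic diversity (PD) per plot and the pairwise patristic distances
consumed by MPD/MNTD and their standardized effect sizes.

PD convention
-------------
:func:`faith_pd` is *root-inclusive* (Phylocom-style): the PD of a species
set is the total branch length of the subtree spanning those species *and*
the root of the supplied tree.  A single-species community therefore has
PD equal to its root-to-tip path length.  This matters when comparing PD
across plots whose species sit in different parts of the tree.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import dendropy
import numpy as np

__all__ = [
    "NewickParseError",
    "TreeValidationError",
    "UnknownSpeciesError",
    "Phylogeny",
    "DistanceMatrix",
    "parse_newick",
    "write_newick",
    "patristic_distances",
    "faith_pd",
]


class NewickParseError(ValueError):
    """Raised when a Newick string cannot be parsed; carries position info."""


class TreeValidationError(ValueError):
    """Raised when a parsed tree violates the Phylogeny invariants."""


class UnknownSpeciesError(KeyError):
    """Raised when a requested species is not a tip of the tree."""

    def __init__(self, offenders):
        self.offenders = sorted(offenders)
        super().__init__(f"species not found among tree tips: {', '.join(self.offenders)}")

    def __str__(self) -> str:  # KeyError quotes its arg; keep the message readable
        return self.args[0]


@dataclass(frozen=True)
class DistanceMatrix:
    """Symmetric matrix of patristic (tree-path) distances between tips.

    ``labels`` fixes the row/column order; ``values`` is in branch-length
    units with a zero diagonal.
    """

    labels: tuple
    values: np.ndarray
    _index: dict = field(init=False, repr=False, compare=False)

    def __post_init__(self):
        vals = np.asarray(self.values, dtype=float)
        if vals.shape != (len(self.labels), len(self.labels)):
            raise ValueError("distance matrix shape does not match labels")
        if not np.allclose(vals, vals.T, atol=1e-9):
            raise ValueError("distance matrix is not symmetric")
        if np.any(np.diag(vals) != 0):
            raise ValueError("distance matrix diagonal must be zero")
        if np.any(vals < 0):
            raise ValueError("distances must be non-negative")
        object.__setattr__(self, "values", vals)
        object.__setattr__(self, "_index", {lab: i for i, lab in enumerate(self.labels)})

    @property
    def n(self) -> int:
        return len(self.labels)

    def index_of(self, label: str) -> int:
        try:
            return self._index[label]
        except KeyError:
            raise UnknownSpeciesError([label]) from None

    def indices(self, labels) -> np.ndarray:
        missing = [lab for lab in labels if lab not in self._index]
        if missing:
            raise UnknownSpeciesError(missing)
        return np.asarray([self._index[lab] for lab in labels], dtype=int)

    def distance(self, a: str, b: str) -> float:
        return float(self.values[self.index_of(a), self.index_of(b)])

    def submatrix(self, labels) -> np.ndarray:
        idx = self.indices(labels)
        return self.values[np.ix_(idx, idx)]


class Phylogeny:
    """A rooted tree with branch lengths and uniquely labelled tips.

    Thin wrapper over a :class:`dendropy.Tree` that enforces the invariants
    the pipeline relies on (unique non-empty tip labels, non-negative branch
    lengths with at least one positive) and offers the handful of traversals
    the diversity metrics need.
    """

    def __init__(self, tree: dendropy.Tree):
        self._tree = tree
        self._validate()
        self._leaf_by_label = {leaf.taxon.label: leaf for leaf in tree.leaf_node_iter()}

    def _validate(self) -> None:
        labels = []
        for leaf in self._tree.leaf_node_iter():
            if leaf.taxon is None or not (leaf.taxon.label or "").strip():
                raise TreeValidationError("tree has an unlabelled tip")
            labels.append(leaf.taxon.label)
        dupes = {lab for lab in labels if labels.count(lab) > 1}
        if dupes:
            raise TreeValidationError(f"duplicate tip labels: {', '.join(sorted(dupes))}")
        any_positive = False
        root = self._tree.seed_node
        for node in self._tree.preorder_node_iter():
            length = node.edge.length
            if node is root:
                continue  # a stem above the root is ignored
            if length is None:
                raise TreeValidationError(
                    f"missing branch length on edge above {self._describe(node)}; "
                    "supply default_branch_length to fill"
                )
            if length < 0:
                raise TreeValidationError(f"negative branch length above {self._describe(node)}")
            if length > 0:
                any_positive = True
        if not any_positive:
            raise TreeValidationError("all branch lengths are zero")

    @staticmethod
    def _describe(node) -> str:
        if node.taxon is not None:
            return f"tip '{node.taxon.label}'"
        return "an internal node"

    @property
    def tip_labels(self) -> tuple:
        return tuple(sorted(self._leaf_by_label))

    @property
    def n_tips(self) -> int:
        return len(self._leaf_by_label)

    @property
    def dendropy_tree(self) -> dendropy.Tree:
        return self._tree

    def total_branch_length(self) -> float:
        root = self._tree.seed_node
        return float(
            sum(n.edge.length for n in self._tree.preorder_node_iter() if n is not root)
        )

    def root_to_tip_depths(self) -> dict:
        """Path length from the root to each tip, keyed by tip label."""
        depths = {}
        root = self._tree.seed_node
        stack = [(root, 0.0)]
        while stack:
            node, depth = stack.pop()
            if node.is_leaf():
                depths[node.taxon.label] = depth
            for child in node.child_nodes():
                stack.append((child, depth + (child.edge.length or 0.0)))
        return depths

    def _edges_to_root(self, label: str):
        """Edges (as node ids of their child end) on the tip→root path."""
        node = self._leaf_by_label[label]
        root = self._tree.seed_node
        edges = []
        while node is not root:
            edges.append(node)
            node = node.parent_node
        return edges


def parse_newick(text: str, default_branch_length: float | None = None) -> Phylogeny:
    """Parse a Newick string into a validated :class:`Phylogeny`.

    Branch lengths are required on every non-root edge; a missing length is
    an error unless ``default_branch_length`` supplies a fill value (silent
    defaults would corrupt PD, so there is no implicit one).
    """
    try:
        tree = dendropy.Tree.get(
            data=text,
            schema="newick",
            suppress_internal_node_taxa=True,
        )
    except Exception as exc:  # dendropy raises several DataError subclasses
        if "Multiple occurrences" in str(exc):
            raise TreeValidationError(f"duplicate tip labels: {exc}") from exc
        pos = ""
        col = getattr(exc, "col_num", None)
        line = getattr(exc, "line_num", None)
        if col is not None:
            pos = f" (line {line}, column {col})" if line is not None else f" (column {col})"
        raise NewickParseError(f"malformed Newick{pos}: {exc}") from exc
    if default_branch_length is not None:
        root = tree.seed_node
        for node in tree.preorder_node_iter():
            if node is not root and node.edge.length is None:
                node.edge.length = float(default_branch_length)
    return Phylogeny(tree)


def write_newick(phy: Phylogeny) -> str:
    """Serialize to Newick; write-then-parse is identity up to node order."""
    buf = io.StringIO()
    phy.dendropy_tree.write(file=buf, schema="newick", suppress_rooting=True)
    return buf.getvalue().strip() + ("" if buf.getvalue().strip().endswith(";") else ";")


def patristic_distances(phy: Phylogeny) -> DistanceMatrix:
    """Pairwise tree-path distances between all tips, in label-sorted order."""
    pdm = phy.dendropy_tree.phylogenetic_distance_matrix()
    labels = phy.tip_labels
    taxa = {t.label: t for t in phy.dendropy_tree.taxon_namespace if t.label in set(labels)}
    n = len(labels)
    vals = np.zeros((n, n), dtype=float)
    for i in range(n):
        for j in range(i + 1, n):
            d = pdm.patristic_distance(taxa[labels[i]], taxa[labels[j]])
            vals[i, j] = vals[j, i] = d
    return DistanceMatrix(labels=labels, values=vals)


def faith_pd(phy: Phylogeny, species) -> float:
    """Root-inclusive Faith's PD of a species set.

    Sum of branch lengths on the union of root-to-tip paths of the selected
    species.  Requires a non-empty subset of the tree's tips.
    """
    species = list(species)
    if not species:
        raise ValueError("faith_pd requires at least one species")
    missing = [s for s in species if s not in phy._leaf_by_label]
    if missing:
        raise UnknownSpeciesError(missing)
    spanned = {}
    for s in species:
        for node in phy._edges_to_root(s):
            spanned[id(node)] = node.edge.length
    return float(sum(spanned.values()))
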