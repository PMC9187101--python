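"""Newick round-tripping, patristic distances and Faith's PD."""

import numpy as np
import pytest

import desertmf as d
from desertmf.phylo import NewickParseError, TreeValidationError, UnknownSpeciesError

from .conftest import random_tree_newick


def brute_force_patristic(newick: str):
    """Independent oracle: root-to-tip edge sets, distance = symmetric difference sum.

    Parses the Newick string with a minimal recursive reader so it shares no
    code with the implementation under test.
    """
    pos = 0

    def parse_clade():
        nonlocal pos
        children = []
        if newick[pos] == "(":
            pos += 1
            while True:
                children.append(parse_clade())
                if newick[pos] == ",":
                    pos += 1
                    continue
                pos += 1  # ')'
                break
        label = ""
        while pos < len(newick) and newick[pos] not in ":,();":
            label += newick[pos]
            pos += 1
        length = None
        if pos < len(newick) and newick[pos] == ":":
            pos += 1
            num = ""
            while pos < len(newick) and newick[pos] not in ",();":
                num += newick[pos]
                pos += 1
            length = float(num)
        return {"label": label, "length": length, "children": children}

    root = parse_clade()
    paths = {}

    def walk(node, edges):
        key = (id(node), node["length"] or 0.0)
        edges = edges + [key] if node["length"] is not None else list(edges)
        if not node["children"]:
            paths[node["label"]] = edges
        for ch in node["children"]:
            walk(ch, edges)

    walk(root, [])
    labels = sorted(paths)
    dist = {}
    for a in labels:
        for b in labels:
            sym = set(paths[a]) ^ set(paths[b])
            dist[(a, b)] = sum(length for _, length in sym)
    return labels, dist


class TestParseNewick:
    def test_minimal_tree(self):
        t = d.parse_newick("(A:1,B:1);")
        assert t.tip_labels == ("A", "B")
        assert t.total_branch_length() == 2.0

    def test_internal_node(self):
        t = d.parse_newick("((A:1,B:1):1,C:2);")
        assert t.n_tips == 3

    def test_duplicate_labels_rejected(self):
        with pytest.raises(TreeValidationError, match="duplicate|Multiple"):
            d.parse_newick("(A:1,A:2);")

    def test_malformed_reports_position(self):
        with pytest.raises(NewickParseError, match="column"):
            d.parse_newick("((A:1,B:1:1,C:2);")

    def test_missing_branch_length_is_error(self):
        with pytest.raises(TreeValidationError, match="missing branch length"):
            d.parse_newick("(A:1,B);")

    def test_missing_branch_length_fill(self):
        t = d.parse_newick("(A:1,B);", default_branch_length=1.0)
        assert d.patristic_distances(t).distance("A", "B") == 2.0

    def test_roundtrip_preserves_distances(self, rng):
        for _ in range(10):
            nwk = random_tree_newick(rng, int(rng.integers(3, 10)))
            t1 = d.parse_newick(nwk)
            t2 = d.parse_newick(d.write_newick(t1))
            m1, m2 = d.patristic_distances(t1), d.patristic_distances(t2)
            assert m1.labels == m2.labels
            np.testing.assert_allclose(m1.values, m2.values, atol=1e-9)


class TestPatristicDistances:
    def test_two_tip_path_sum(self):
        dm = d.patristic_distances(d.parse_newick("(A:1,B:1);"))
        assert dm.distance("A", "B") == 2.0

    def test_three_tip_paths(self, three_tip_dist):
        assert three_tip_dist.distance("A", "C") == 4.0
        assert three_tip_dist.distance("A", "B") == 2.0

    def test_zero_diagonal_and_symmetry(self, three_tip_dist):
        assert np.all(np.diag(three_tip_dist.values) == 0)
        np.testing.assert_array_equal(three_tip_dist.values, three_tip_dist.values.T)

    def test_agrees_with_path_oracle_on_random_trees(self, rng):
        for _ in range(100):
            nwk = random_tree_newick(rng, int(rng.integers(3, 13)))
            dm = d.patristic_distances(d.parse_newick(nwk))
            labels, oracle = brute_force_patristic(nwk)
            assert list(labels) == list(dm.labels)
            for i, a in enumerate(labels):
                for j, b in enumerate(labels):
                    assert dm.values[i, j] == pytest.approx(oracle[(a, b)], abs=1e-9)


class TestFaithPD:
    def test_star_tree_counts_all_edges(self):
        t = d.parse_newick("(A:1,B:1,C:1);")
        assert d.faith_pd(t, {"A", "B", "C"}) == 3.0

    def test_root_inclusive_stem(self, three_tip_tree):
        # {A,B} spans A:1, B:1 and the stem of their clade to the root
        assert d.faith_pd(three_tip_tree, {"A", "B"}) == 3.0

    def test_full_tip_set_is_total_length(self, rng):
        nwk = random_tree_newick(rng, 9)
        t = d.parse_newick(nwk)
        assert d.faith_pd(t, t.tip_labels) == pytest.approx(t.total_branch_length())

    def test_single_species_is_root_to_tip_depth(self, three_tip_tree):
        assert d.faith_pd(three_tip_tree, {"A"}) == 2.0
        assert d.faith_pd(three_tip_tree, {"C"}) == 2.0

    def test_monotone_in_species_set(self, rng):
        for _ in range(20):
            t = d.parse_newick(random_tree_newick(rng, int(rng.integers(4, 12))))
            tips = list(t.tip_labels)
            k = int(rng.integers(1, len(tips)))
            s1 = set(rng.choice(tips, size=k, replace=False))
            extra = [x for x in tips if x not in s1]
            s2 = s1 | set(rng.choice(extra, size=int(rng.integers(1, len(extra) + 1)),
                                     replace=False))
            assert d.faith_pd(t, s1) <= d.faith_pd(t, s2) + 1e-12

    def test_unknown_species_lists_offenders(self, three_tip_tree):
        with pytest.raises(UnknownSpeciesError, match="X.*Z|Z.*X"):
            d.faith_pd(three_tip_tree, {"A", "X", "Z"})

    def test_empty_set_rejected(self, three_tip_tree):
        with pytest.raises(ValueError):
            d.faith_pd(three_tip_tree, set())

    def test_matches_independent_reference(self, rng):
        skbio_alpha = pytest.importorskip("skbio.diversity.alpha")
        from io import StringIO
        from skbio import TreeNode

        for _ in range(5):
            nwk = random_tree_newick(rng, 8)
            t = d.parse_newick(nwk)
            tips = list(t.tip_labels)
            ref_tree = TreeNode.read(StringIO(nwk))
            k = int(rng.integers(1, 8))
            chosen = set(rng.choice(tips, size=k, replace=False))
            counts = [1 if lab in chosen else 0 for lab in tips]
            ref = skbio_alpha.faith_pd(counts, tips, ref_tree)
            assert d.faith_pd(t, chosen) == pytest.approx(ref, rel=1e-9)
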