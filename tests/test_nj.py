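"""Neighbor joining: closed forms, additive-matrix recovery, Newick,
monophyly, and cross-checks against independent implementations."""

import numpy as np
import pytest

from satlineage import (
    DistanceMatrix,
    ValidationError,
    is_monophyletic,
    neighbor_joining,
    to_newick,
)
from satlineage.simulate import SimulationConfig, null_shuffle, simulate_two_lineages
from satlineage import distance_matrix


# ---------------------------------------------------------------------------
# Oracle machinery: random additive trees and their exact leaf distances
# ---------------------------------------------------------------------------


def random_additive_tree(rng, n_leaves):
    """Random binary unrooted tree with positive lengths, via leaf insertion.

    Returns (edges, labels): edges as {(u, v): length} on integer nodes,
    leaves 0..n-1 labeled T0..T{n-1}.
    """
    edges = {}
    nxt = n_leaves
    center = nxt
    nxt += 1
    for leaf in range(3):
        edges[(center, leaf)] = rng.uniform(0.1, 1.0)
    for leaf in range(3, n_leaves):
        u, v = list(edges)[rng.integers(len(edges))]
        length = edges.pop((u, v))
        mid = nxt
        nxt += 1
        split = rng.uniform(0.25, 0.75)
        edges[(u, mid)] = length * split
        edges[(mid, v)] = length * (1 - split)
        edges[(mid, leaf)] = rng.uniform(0.1, 1.0)
    return edges, {k: f"T{k}" for k in range(n_leaves)}


def tree_distances(edges, labels):
    """Exact path-length matrix between leaves (independent of NJ code)."""
    adj = {}
    for (u, v), l in edges.items():
        adj.setdefault(u, []).append((v, l))
        adj.setdefault(v, []).append((u, l))
    n = len(labels)
    out = np.zeros((n, n))
    for src in labels:
        dist = {src: 0.0}
        stack = [src]
        while stack:
            cur = stack.pop()
            for nbr, l in adj[cur]:
                if nbr not in dist:
                    dist[nbr] = dist[cur] + l
                    stack.append(nbr)
        for dst in labels:
            out[src, dst] = dist[dst]
    return out


def canonical_splits(edges, labels):
    """Nontrivial bipartitions (as frozensets not containing leaf 0) with
    their branch lengths — reference representation for topology comparison."""
    adj = {}
    for (u, v), l in edges.items():
        adj.setdefault(u, []).append(v)
        adj.setdefault(v, []).append(u)

    def leaves_below(node, parent):
        out, stack = set(), [(node, parent)]
        while stack:
            cur, par = stack.pop()
            if cur in labels:
                out.add(labels[cur])
            stack.extend((n, cur) for n in adj[cur] if n != par)
        return frozenset(out)

    all_leaves = frozenset(labels.values())
    splits = {}
    for (u, v), l in edges.items():
        side = leaves_below(v, u)
        if labels[0] in side:
            side = all_leaves - side
        splits[side] = l
    return splits


def nj_splits(tree):
    """Same canonical representation for a satlineage NJ tree."""
    all_leaves = frozenset(tree.leaf_labels.values())
    anchor = tree.leaf_labels[0]
    out = {}
    for side, length in tree.bipartitions():
        if anchor in side:
            side = all_leaves - side
        out[side] = length
    return out


class TestThreeTaxa:
    def test_closed_form_branch_lengths(self):
        d = DistanceMatrix(ids=["A", "B", "C"],
                           values=np.array([[0, 5, 9], [5, 0, 10], [9, 10, 0.0]]))
        tree = neighbor_joining(d)
        lengths = {tree.leaf_labels[v]: l
                   for v, l in tree.adjacency[tree.root]}
        assert lengths["A"] == pytest.approx((5 + 9 - 10) / 2)
        assert lengths["B"] == pytest.approx((5 + 10 - 9) / 2)
        assert lengths["C"] == pytest.approx((9 + 10 - 5) / 2)

    def test_newick_form(self):
        d = DistanceMatrix(ids=["A", "B", "C"],
                           values=np.array([[0, 2, 2], [2, 0, 2], [2, 2, 0.0]]))
        nwk = to_newick(neighbor_joining(d))
        assert nwk.startswith("(") and nwk.endswith(");")
        assert nwk.count(",") == 2


class TestFourTaxa:
    def test_recovers_generating_topology_against_brute_force(self):
        """On additive 4-taxon data, NJ picks the same split as exhaustive
        least-squares over all 3 unrooted topologies."""
        rng = np.random.default_rng(17)
        pairings = [((0, 1), (2, 3)), ((0, 2), (1, 3)), ((0, 3), (1, 2))]
        for _ in range(25):
            edges, labels = random_additive_tree(rng, 4)
            d = tree_distances(edges, labels)
            # brute force: the true pairing minimizes the 4-point sum
            sums = [d[a, b] + d[c, e] for (a, b), (c, e) in pairings]
            best = pairings[int(np.argmin(sums))]
            tree = neighbor_joining(
                DistanceMatrix(ids=[labels[k] for k in range(4)], values=d))
            split = frozenset({labels[best[0][0]], labels[best[0][1]]})
            assert is_monophyletic(tree, set(split))

    def test_exact_branch_length_recovery(self):
        rng = np.random.default_rng(23)
        for _ in range(25):
            edges, labels = random_additive_tree(rng, 4)
            d = tree_distances(edges, labels)
            tree = neighbor_joining(
                DistanceMatrix(ids=[labels[k] for k in range(4)], values=d))
            expected = canonical_splits(edges, labels)
            got = nj_splits(tree)
            assert set(got) == set(expected)
            for side in expected:
                assert got[side] == pytest.approx(expected[side], abs=1e-9)


class TestConsistencyOnAdditiveMatrices:
    def test_recovers_random_5_to_8_taxon_trees(self):
        rng = np.random.default_rng(31)
        for _ in range(100):
            n = int(rng.integers(5, 9))
            edges, labels = random_additive_tree(rng, n)
            d = tree_distances(edges, labels)
            tree = neighbor_joining(
                DistanceMatrix(ids=[labels[k] for k in range(n)], values=d))
            expected = canonical_splits(edges, labels)
            got = nj_splits(tree)
            assert set(got) == set(expected)
            for side, length in expected.items():
                assert got[side] == pytest.approx(length, abs=1e-9)

    def test_structural_invariants(self):
        rng = np.random.default_rng(37)
        for n in (5, 8, 13):
            edges, labels = random_additive_tree(rng, n)
            d = tree_distances(edges, labels)
            tree = neighbor_joining(
                DistanceMatrix(ids=[labels[k] for k in range(n)], values=d))
            assert tree.n_leaves == n
            assert tree.n_internal == n - 2
            assert tree.n_edges == 2 * n - 3
            degrees = {k: len(v) for k, v in tree.adjacency.items()}
            for node, deg in degrees.items():
                assert deg == (1 if node in tree.leaf_labels else 3)

    def test_permutation_equivariance(self):
        rng = np.random.default_rng(41)
        edges, labels = random_additive_tree(rng, 7)
        d = tree_distances(edges, labels)
        ids = [labels[k] for k in range(7)]
        t1 = neighbor_joining(DistanceMatrix(ids=ids, values=d))
        perm = rng.permutation(7)
        t2 = neighbor_joining(DistanceMatrix(
            ids=[ids[k] for k in perm], values=d[np.ix_(perm, perm)]))

        def split_set(tree):
            all_leaves = frozenset(tree.leaf_labels.values())
            anchor = min(all_leaves)
            return {
                (side if anchor not in side else all_leaves - side): round(l, 9)
                for side, l in tree.bipartitions()
            }

        assert split_set(t1) == split_set(t2)


class TestCrossChecks:
    def test_agrees_with_scikit_bio_on_additive_matrix(self):
        """Independent implementation check: same splits as skbio's NJ."""
        skbio = pytest.importorskip("skbio")
        from skbio import DistanceMatrix as SkDM
        from skbio.tree import nj as sk_nj

        rng = np.random.default_rng(43)
        for _ in range(5):
            edges, labels = random_additive_tree(rng, 7)
            d = tree_distances(edges, labels)
            d = (d + d.T) / 2  # exact symmetry for skbio's strict check
            ids = [labels[k] for k in range(7)]
            ours = nj_splits(neighbor_joining(DistanceMatrix(ids=ids, values=d)))
            sk_tree = sk_nj(SkDM(d, ids))
            theirs = set()
            all_leaves = frozenset(ids)
            for node in sk_tree.non_tips(include_self=False):
                side = frozenset(t.name for t in node.tips())
                if ids[0] in side:
                    side = all_leaves - side
                if 1 < len(side) < 6:
                    theirs.add(side)
            assert {s for s in ours if 1 < len(s) < 6} == theirs

    def test_newick_round_trip_preserves_bipartitions(self):
        dendropy = pytest.importorskip("dendropy")
        rng = np.random.default_rng(47)
        edges, labels = random_additive_tree(rng, 8)
        d = tree_distances(edges, labels)
        ids = [labels[k] for k in range(8)]
        tree = neighbor_joining(DistanceMatrix(ids=ids, values=d))
        nwk = to_newick(tree)
        dt = dendropy.Tree.get(data=nwk, schema="newick")
        dt.encode_bipartitions()
        all_leaves = frozenset(ids)
        theirs = set()
        for edge in dt.preorder_edge_iter():
            if edge.head_node is dt.seed_node:
                continue
            side = frozenset(
                l.taxon.label for l in edge.head_node.leaf_iter())
            if ids[0] in side:
                side = all_leaves - side
            theirs.add(side)
        assert set(nj_splits(tree)) == theirs

    def test_newick_quotes_labels_with_spaces(self):
        d = DistanceMatrix(ids=["tax A", "B", "C"],
                           values=np.array([[0, 1, 1], [1, 0, 1], [1, 1, 0.0]]))
        assert "'tax A'" in to_newick(neighbor_joining(d))


class TestMonophyly:
    def _quartet(self):
        # additive matrix for ((A,B),(C,D)) with internal edge 1.0
        d = np.array([
            [0.0, 0.4, 2.2, 2.3],
            [0.4, 0.0, 2.4, 2.5],
            [2.2, 2.4, 0.0, 0.7],
            [2.3, 2.5, 0.7, 0.0],
        ])
        return neighbor_joining(DistanceMatrix(ids=list("ABCD"), values=d))

    def test_constructed_quartet(self):
        tree = self._quartet()
        assert is_monophyletic(tree, {"A", "B"})
        assert is_monophyletic(tree, {"C", "D"})
        assert not is_monophyletic(tree, {"A", "C"})

    def test_single_leaf_is_always_monophyletic(self):
        assert is_monophyletic(self._quartet(), {"A"})

    def test_group_and_complement_agree(self):
        tree = self._quartet()
        assert is_monophyletic(tree, {"A", "B"}) == \
               is_monophyletic(tree, {"C", "D"})

    def test_unknown_leaf_named_in_error(self):
        with pytest.raises(ValidationError, match="ZZ"):
            is_monophyletic(self._quartet(), {"A", "ZZ"})

    def test_whole_leafset_rejected(self):
        with pytest.raises(ValidationError, match="proper subset"):
            is_monophyletic(self._quartet(), set("ABCD"))

    def test_isolated_lineages_are_monophyletic(self, isolated_table):
        tree = neighbor_joining(distance_matrix(isolated_table))
        asex = {i.id for i in isolated_table.individuals
                if i.lineage == "asexual"}
        sex = {i.id for i in isolated_table.individuals
               if i.lineage == "sexual"}
        assert is_monophyletic(tree, asex)
        assert is_monophyletic(tree, sex)

    def test_label_shuffle_destroys_monophyly(self, isolated_table):
        """Monte-Carlo: after random lineage relabeling the asexual label set
        is essentially never a clade."""
        hits = 0
        for seed in range(10):
            shuffled = null_shuffle(isolated_table, seed=seed)
            tree = neighbor_joining(distance_matrix(shuffled))
            asex = {i.id for i in shuffled.individuals
                    if i.lineage == "asexual"}
            hits += is_monophyletic(tree, asex)
        assert hits == 0


class TestValidation:
    def test_asymmetric_matrix_rejected(self):
        bad = np.array([[0, 1, 2], [1.5, 0, 1], [2, 1, 0.0]])
        with pytest.raises(ValidationError, match="symmetric"):
            neighbor_joining(_force_dm(list("ABC"), bad))

    def test_too_few_taxa(self):
        with pytest.raises(ValidationError, match="at least 3"):
            neighbor_joining(_force_dm(["A", "B"], np.zeros((2, 2))))

    def test_tie_breaking_is_deterministic(self):
        """Equidistant taxa: repeated runs give the identical Newick string."""
        d = np.ones((5, 5)) - np.eye(5)
        dm = _force_dm(list("ABCDE"), d)
        first = to_newick(neighbor_joining(dm))
        for _ in range(3):
            assert to_newick(neighbor_joining(dm)) == first


def _force_dm(ids, values):
    """Build a DistanceMatrix bypassing validation (to test NJ's own checks)."""
    dm = object.__new__(DistanceMatrix)
    dm.ids = ids
    dm.values = values
    dm.loci_used = None
    return dm
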