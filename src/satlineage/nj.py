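"""Neighbor joining, Newick export and monophyly queries on unrooted trees.

Canonical Saitou-Nei agglomeration: each round joins the pair minimizing
Q(i, j) = (n - 2) d(i, j) - sum_k d(i, k) - sum_k d(j, k), with the standard
branch-length and distance-update formulas. Ties on Q are broken by the
lexicographically smallest index pair in current matrix order, making the
output deterministic even on toy integer matrices. Negative branch lengths
are retained (not clamped) and reported as warnings; monophyly depends only
on topology.

The result is a binary unrooted tree: n leaves, n - 2 internal nodes of
degree 3, 2n - 3 edges. A leaf set is monophyletic exactly when some edge
induces the bipartition {group, complement} — equivalently when the
complement is monophyletic too.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .distance import DistanceMatrix
from .genotypes import ValidationError

__all__ = ["UnrootedTree", "neighbor_joining", "to_newick", "is_monophyletic"]


@dataclass
class UnrootedTree:
    """Unrooted tree as an adjacency map with branch lengths.

    Leaves carry individual ids; internal nodes are anonymous integers.
    ``root`` is an arbitrary-but-deterministic serialization anchor (the
    last-created internal node of the NJ agglomeration).
    """

    adjacency: dict[int, list[tuple[int, float]]]
    leaf_labels: dict[int, str]
    root: int
    _bipartitions: list[tuple[frozenset[str], float]] | None = field(
        default=None, repr=False
    )

    @property
    def leaves(self) -> list[str]:
        return [self.leaf_labels[k] for k in sorted(self.leaf_labels)]

    @property
    def n_leaves(self) -> int:
        return len(self.leaf_labels)

    @property
    def n_internal(self) -> int:
        return len(self.adjacency) - self.n_leaves

    @property
    def n_edges(self) -> int:
        return sum(len(v) for v in self.adjacency.values()) // 2

    def _leafset_below(self, node: int, parent: int) -> frozenset[str]:
        stack = [(node, parent)]
        out: set[str] = set()
        while stack:
            cur, par = stack.pop()
            if cur in self.leaf_labels:
                out.add(self.leaf_labels[cur])
            for nbr, _ in self.adjacency[cur]:
                if nbr != par:
                    stack.append((nbr, cur))
        return frozenset(out)

    def bipartitions(self) -> list[tuple[frozenset[str], float]]:
        """One (leaf-set, branch length) per edge; the side not containing
        the serialization root is reported."""
        if self._bipartitions is None:
            out = []
            seen = set()
            for u, nbrs in self.adjacency.items():
                for v, length in nbrs:
                    if (v, u) in seen or (u, v) in seen:
                        continue
                    seen.add((u, v))
                    # report the side away from the root anchor
                    side = self._leafset_below(v, u)
                    if self.root in self._nodes_below(v, u):
                        side = self._leafset_below(u, v)
                    out.append((side, length))
            self._bipartitions = out
        return self._bipartitions

    def _nodes_below(self, node: int, parent: int) -> set[int]:
        stack = [(node, parent)]
        out: set[int] = set()
        while stack:
            cur, par = stack.pop()
            out.add(cur)
            for nbr, _ in self.adjacency[cur]:
                if nbr != par:
                    stack.append((nbr, cur))
        return out

    def has_negative_branches(self) -> bool:
        return any(l < 0 for nbrs in self.adjacency.values() for _, l in nbrs)


def neighbor_joining(D: DistanceMatrix) -> UnrootedTree:
    """Saitou-Nei neighbor joining on a symmetric distance matrix."""
    d_full = np.asarray(D.values, dtype=float)
    n0 = len(D.ids)
    if n0 < 3:
        raise ValidationError("neighbor joining requires at least 3 taxa")
    if not np.allclose(d_full, d_full.T):
        raise ValidationError("distance matrix must be symmetric")
    if np.any(np.diag(d_full) != 0):
        raise ValidationError("distance matrix must have a zero diagonal")

    adjacency: dict[int, list[tuple[int, float]]] = {i: [] for i in range(n0)}
    leaf_labels = {i: D.ids[i] for i in range(n0)}
    next_id = n0

    def connect(u: int, v: int, length: float) -> None:
        adjacency[u].append((v, length))
        adjacency[v].append((u, length))

    active = list(range(n0))        # node ids, in current matrix order
    d = d_full.copy()               # working matrix over `active` positions

    while len(active) > 3:
        m = len(active)
        row_sums = d.sum(axis=1)
        q = (m - 2) * d - row_sums[:, None] - row_sums[None, :]
        np.fill_diagonal(q, np.inf)
        # lexicographically smallest (i, j) among Q minimizers, i < j
        iu = np.triu_indices(m, k=1)
        qv = q[iu]
        best = np.flatnonzero(qv <= qv.min() + 0.0)
        k = best[0]
        i, j = int(iu[0][k]), int(iu[1][k])

        dij = d[i, j]
        vi = 0.5 * dij + (row_sums[i] - row_sums[j]) / (2 * (m - 2))
        vj = dij - vi
        new = next_id
        next_id += 1
        adjacency[new] = []
        connect(new, active[i], vi)
        connect(new, active[j], vj)

        # distances from the new node to the remaining taxa
        d_new = 0.5 * (d[i, :] + d[j, :] - dij)
        keep = [k for k in range(m) if k not in (i, j)]
        d = np.vstack([d[np.ix_(keep, keep)], d_new[keep]])
        d = np.hstack([d, np.append(d_new[keep], 0.0)[:, None]])
        active = [active[k] for k in keep] + [new]

    # final three nodes join at one internal node (closed form)
    a, b, c = active
    dab, dac, dbc = d[0, 1], d[0, 2], d[1, 2]
    center = next_id
    adjacency[center] = []
    connect(center, a, 0.5 * (dab + dac - dbc))
    connect(center, b, 0.5 * (dab + dbc - dac))
    connect(center, c, 0.5 * (dac + dbc - dab))

    tree = UnrootedTree(adjacency=adjacency, leaf_labels=leaf_labels, root=center)
    if tree.has_negative_branches():
        warnings.warn(
            "neighbor joining produced negative branch lengths; they are "
            "retained (not clamped) — monophyly depends only on topology",
            stacklevel=2,
        )
    return tree


def _quote_label(label: str) -> str:
    if any(ch in label for ch in " \t()[]':;,"):
        return "'" + label.replace("'", "''") + "'"
    return label


def to_newick(tree: UnrootedTree, precision: int = 6) -> str:
    """Newick serialization rooted at the NJ center node (trifurcating root).

    Branch lengths are written at fixed precision; labels containing Newick
    metacharacters are single-quoted.
    """

    def render(node: int, parent: int) -> str:
        children = [(v, l) for v, l in tree.adjacency[node] if v != parent]
        if not children:  # leaf
            return _quote_label(tree.leaf_labels[node])
        inner = ",".join(
            f"{render(v, node)}:{l:.{precision}f}" for v, l in children
        )
        return f"({inner})"

    return render(tree.root, -1) + ";"


def is_monophyletic(tree: UnrootedTree, group: set[str]) -> bool:
    """True iff some edge of the unrooted tree separates ``group`` from the rest."""
    group = frozenset(group)
    if not group:
        raise ValidationError("monophyly query requires a nonempty group")
    all_leaves = frozenset(tree.leaf_labels.values())
    unknown = group - all_leaves
    if unknown:
        raise ValidationError(f"unknown leaf id(s) in group: {sorted(unknown)}")
    if group == all_leaves:
        raise ValidationError("group must be a proper subset of the leaves")
    complement = all_leaves - group
    for side, _ in tree.bipartitions():
        if side == group or side == complement:
            return True
    return False
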