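"""Neighbor-joining trees, column-resampling bootstrap, Newick output.

The agglomeration is the Saitou–Nei algorithm with the Studier–Keppler
Q-criterion.  Conventions (the classic software this emulates does not
publish its own): ties in Q are broken by the lowest (row, column) index
pair in the current node ordering, the merged node takes the row position
of its first child, and negative estimated branch lengths are clamped to
zero without redistribution (a display-level convention).

Bootstrap supports are percentages of column-resampled replicates whose
recomputed NJ tree contains each nontrivial bipartition of the reference
(full-data) tree; supports are mapped onto the reference tree rather than
a majority-rule consensus, matching the usual display convention of
distance-tree software.  The full bipartition tally is returned as well,
so a consensus view can be derived by the caller if preferred.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Literal

import numpy as np

from .distances import (
    DistanceMatrix,
    distance_matrix_from_encoded,
    encode_sequence,
)
from .errors import SaturationError, TreeError, UndefinedDistanceError
from .seqio import AlignedLocus

_NEWICK_UNSAFE = set("();,: \t\n[]'\"")


@dataclass
class Node:
    """A node of an (unrooted) phylogenetic tree.

    ``length`` is the length of the edge above this node (substitutions per
    site); it is meaningless for the root.  ``support`` is a bootstrap
    percentage attached to the edge above an internal node.
    """

    name: str | None = None
    length: float = 0.0
    support: float | None = None
    children: list["Node"] = field(default_factory=list)

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def walk(self) -> Iterator["Node"]:
        yield self
        for child in self.children:
            yield from child.walk()

    def leaf_names(self) -> list[str]:
        return [n.name for n in self.walk() if n.is_leaf]


@dataclass
class Tree:
    """Unrooted tree represented with a basal multifurcation."""

    root: Node

    @property
    def leaf_names(self) -> list[str]:
        return self.root.leaf_names()

    def bipartitions(self) -> set[frozenset[str]]:
        """Nontrivial bipartitions in a canonical (reference-leaf-free) form.

        Each internal edge splits the leaves in two; the side not containing
        the lexicographically smallest leaf represents the bipartition, so
        the set is invariant to rooting and leaf order.
        """
        all_leaves = frozenset(self.leaf_names)
        ref = min(all_leaves)
        out: set[frozenset[str]] = set()
        for node in self.root.walk():
            if node is self.root or node.is_leaf:
                continue
            side = frozenset(node.leaf_names())
            if 2 <= len(side) <= len(all_leaves) - 2:
                out.add(side if ref not in side else all_leaves - side)
        return out

    def internal_nodes(self) -> list[Node]:
        return [
            n for n in self.root.walk()
            if n is not self.root and not n.is_leaf
        ]

    def path_lengths(self) -> dict[tuple[str, str], float]:
        """Leaf-to-leaf path lengths (keys sorted pairs); for diagnostics."""
        # adjacency over the rooted representation; trees are small
        adj: dict[int, list[tuple[int, float]]] = {}
        nodes = list(self.root.walk())
        index = {id(n): i for i, n in enumerate(nodes)}
        for n in nodes:
            for c in n.children:
                i, j = index[id(n)], index[id(c)]
                adj.setdefault(i, []).append((j, c.length))
                adj.setdefault(j, []).append((i, c.length))
        leaves = [(index[id(n)], n.name) for n in nodes if n.is_leaf]
        out: dict[tuple[str, str], float] = {}
        for start, name_a in leaves:
            dist = {start: 0.0}
            stack = [start]
            while stack:
                u = stack.pop()
                for v, w in adj.get(u, []):
                    if v not in dist:
                        dist[v] = dist[u] + w
                        stack.append(v)
            for other, name_b in leaves:
                if name_a < name_b:
                    out[(name_a, name_b)] = dist[other]
        return out

    def to_newick(
        self,
        support_threshold: float | None = 50.0,
        include_supports: bool = True,
    ) -> str:
        """Newick string; branch lengths at 6 d.p.

        Supports are written as internal node labels and omitted below
        ``support_threshold`` (pass ``None`` to write all).
        """

        def fmt(node: Node, is_root: bool) -> str:
            if node.is_leaf:
                if node.name is None or set(node.name) & _NEWICK_UNSAFE:
                    raise TreeError(f"leaf name unsafe for Newick: {node.name!r}")
                body = node.name
            else:
                body = "(" + ",".join(fmt(c, False) for c in node.children) + ")"
                if (
                    include_supports
                    and not is_root
                    and node.support is not None
                    and (support_threshold is None or node.support >= support_threshold)
                ):
                    body += f"{node.support:g}"
            if is_root:
                return body
            return f"{body}:{node.length:.6f}"

        return fmt(self.root, True) + ";"


def write_newick(
    tree: Tree, path: str | Path, support_threshold: float | None = 50.0
) -> None:
    """Write a single-line Newick file with supports above the threshold."""
    with open(path, "w") as fh:
        fh.write(tree.to_newick(support_threshold=support_threshold) + "\n")


def nj(matrix: DistanceMatrix) -> Tree:
    """Neighbor-joining tree from a distance matrix.

    Requires at least three samples and finite distances.  For three
    samples the unique unrooted topology is returned with branch lengths
    from the three-point formulas.
    """
    n = matrix.n
    if n < 3:
        raise TreeError(f"neighbor-joining needs >= 3 samples, got {n}")
    if not np.all(np.isfinite(matrix.values)):
        raise TreeError("distance matrix contains non-finite entries")

    nodes: list[Node] = [Node(name=sid) for sid in matrix.sample_ids]
    d = matrix.values.astype(float).copy()

    while len(nodes) > 3:
        m = len(nodes)
        r = d.sum(axis=1)
        q = (m - 2) * d - r[:, None] - r[None, :]
        # only consider i < j; row-major argmin gives the lowest (i, j) tie
        iu = np.triu_indices(m, k=1)
        flat = q[iu]
        k = int(np.argmin(flat))
        i, j = int(iu[0][k]), int(iu[1][k])

        dij = d[i, j]
        li = 0.5 * dij + (r[i] - r[j]) / (2.0 * (m - 2))
        lj = dij - li
        child_i, child_j = nodes[i], nodes[j]
        child_i.length = max(li, 0.0)
        child_j.length = max(lj, 0.0)
        new = Node(children=[child_i, child_j])

        # distances from the new node to every remaining node
        dnew = 0.5 * (d[i, :] + d[j, :] - dij)
        d[i, :] = dnew
        d[:, i] = dnew
        d[i, i] = 0.0
        keep = [x for x in range(m) if x != j]
        d = d[np.ix_(keep, keep)]
        nodes[i] = new
        del nodes[j]

    # final three nodes joined at the basal trifurcation
    a, b, c = nodes
    dab, dac, dbc = d[0, 1], d[0, 2], d[1, 2]
    a.length = max(0.5 * (dab + dac - dbc), 0.0)
    b.length = max(0.5 * (dab + dbc - dac), 0.0)
    c.length = max(0.5 * (dac + dbc - dab), 0.0)
    return Tree(Node(children=[a, b, c]))


def canonical_bipartition(
    all_leaves: set[str] | frozenset[str], side: set[str] | frozenset[str]
) -> frozenset[str]:
    """Canonical form of a bipartition: the side without the smallest leaf.

    Use this to look up a clade of interest in bootstrap supports.
    """
    all_leaves = frozenset(all_leaves)
    side = frozenset(side)
    if not side < all_leaves:
        raise TreeError("bipartition side must be a proper subset of the leaves")
    return side if min(all_leaves) not in side else all_leaves - side


@dataclass(frozen=True)
class BootstrapResult:
    """Bipartition supports for a reference tree plus replicate diagnostics."""

    supports: dict[frozenset[str], float]  # reference bipartition -> percent
    bipartition_counts: dict[frozenset[str], int]  # all observed bipartitions
    replicates_requested: int
    replicates_used: int
    replicates_failed: int
    seed: int


def annotate_tree(tree: Tree, supports: dict[frozenset[str], float]) -> None:
    """Attach supports to the internal nodes of ``tree`` in place."""
    all_leaves = frozenset(tree.leaf_names)
    ref = min(all_leaves)
    for node in tree.internal_nodes():
        side = frozenset(node.leaf_names())
        if not (2 <= len(side) <= len(all_leaves) - 2):
            continue
        key = side if ref not in side else all_leaves - side
        if key in supports:
            node.support = supports[key]


def bootstrap_support(
    locus: AlignedLocus,
    reference: Tree,
    replicates: int,
    seed: int,
    annotate: bool = True,
    on_saturation: Literal["error", "inf"] = "error",
) -> BootstrapResult:
    """Nonparametric bootstrap over alignment columns.

    Each replicate resamples columns with replacement (same length),
    recomputes the K2P matrix and NJ tree, and tallies its bipartitions.
    Supports are percentages of *successful* replicates containing each
    reference bipartition.  Replicates whose matrix is undefined
    (saturation or an empty pairwise comparison) are skipped and counted.
    """
    if replicates < 1:
        raise TreeError("replicates must be >= 1")
    ref_leaves = set(reference.leaf_names)
    if ref_leaves != set(locus.sample_ids):
        raise TreeError("reference tree leaves do not match alignment samples")
    ref_biparts = reference.bipartitions()

    ids = locus.sample_ids
    encoded = np.asarray([encode_sequence(r.sequence) for r in locus.records])
    length = locus.length
    rng = np.random.default_rng(seed)

    counts: dict[frozenset[str], int] = {}
    ref_hits = {bp: 0 for bp in ref_biparts}
    used = failed = 0
    for _ in range(replicates):
        cols = rng.integers(0, length, size=length)
        resampled = [encoded[i, cols] for i in range(len(ids))]
        try:
            matrix = distance_matrix_from_encoded(
                ids, resampled, length, on_saturation
            )
            tree = nj(matrix)
        except (SaturationError, UndefinedDistanceError, TreeError):
            failed += 1
            continue
        used += 1
        biparts = tree.bipartitions()
        for bp in biparts:
            counts[bp] = counts.get(bp, 0) + 1
        for bp in ref_biparts:
            if bp in biparts:
                ref_hits[bp] += 1
    if used == 0:
        raise TreeError(f"all {replicates} bootstrap replicates failed")
    supports = {bp: 100.0 * hits / used for bp, hits in ref_hits.items()}
    if annotate:
        annotate_tree(reference, supports)
    return BootstrapResult(
        supports=supports,
        bipartition_counts=counts,
        replicates_requested=replicates,
        replicates_used=used,
        replicates_failed=failed,
        seed=seed,
    )
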