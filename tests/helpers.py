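"""Independent oracles and data builders shared across the test suite.

Everything here is deliberately written without reusing the package's
internals: site patterns are counted with plain dictionaries, tree
distances come from breadth-first search over an explicit adjacency
graph, and bipartitions from edge removal.  These serve as brute-force
references for the vectorised implementations.
"""

from __future__ import annotations

import math
import random
from collections import defaultdict, deque

from barcodegap.seqio import AlignedLocus, SequenceRecord

PURINES = {"A", "G"}
PYRIMIDINES = {"C", "T"}


def brute_force_counts(seq_a: str, seq_b: str) -> tuple[int, int, int, int]:
    """(compared, transitions, transversions, excluded) by direct column scan."""
    n = ts = tv = excluded = 0
    for x, y in zip(seq_a, seq_b, strict=True):
        if x not in "ACGT" or y not in "ACGT":
            excluded += 1
            continue
        n += 1
        if x == y:
            continue
        if (x in PURINES) == (y in PURINES):
            ts += 1
        else:
            tv += 1
    return n, ts, tv, excluded


def brute_force_k2p(seq_a: str, seq_b: str) -> float:
    n, ts, tv, _ = brute_force_counts(seq_a, seq_b)
    p, q = ts / n, tv / n
    if ts == 0 and tv == 0:
        return 0.0
    return -0.5 * math.log(1 - 2 * p - q) - 0.25 * math.log(1 - 2 * q)


def make_locus(name: str, seqs: dict[str, str]) -> AlignedLocus:
    return AlignedLocus(
        name, tuple(SequenceRecord(sid, s) for sid, s in seqs.items())
    )


def random_alignment(
    rng: random.Random,
    n_seqs: int,
    n_cols: int,
    gap_prob: float = 0.05,
    ambig_prob: float = 0.02,
) -> dict[str, str]:
    alphabet = "ACGT"
    out = {}
    for i in range(n_seqs):
        chars = []
        for _ in range(n_cols):
            u = rng.random()
            if u < gap_prob:
                chars.append("-")
            elif u < gap_prob + ambig_prob:
                chars.append(rng.choice("NRY"))
            else:
                chars.append(rng.choice(alphabet))
        out[f"s{i}"] = "".join(chars)
    return out


def random_additive_case(rng: random.Random, n_leaves: int):
    """A random unrooted binary tree and its exact leaf distance matrix.

    Returns (ids, matrix-as-dict, bipartitions) where the matrix maps
    (id_a, id_b) to the path length and bipartitions is the set of
    nontrivial splits canonicalised as the side not containing the
    lexicographically smallest leaf.
    """
    ids = [f"t{i:02d}" for i in range(n_leaves)]
    adj: dict[int, list[tuple[int, float]]] = defaultdict(list)
    edges: list[tuple[int, int]] = []

    def connect(u: int, v: int) -> None:
        w = rng.uniform(0.05, 1.0)
        adj[u].append((v, w))
        adj[v].append((u, w))
        edges.append((u, v))

    active = list(range(n_leaves))
    next_id = n_leaves
    while len(active) > 3:
        i, j = sorted(rng.sample(range(len(active)), 2))
        u, v = active[i], active[j]
        new = next_id
        next_id += 1
        connect(u, new)
        connect(v, new)
        active = [x for x in active if x not in (u, v)] + [new]
    hub = next_id
    next_id += 1
    for u in active:
        connect(u, hub)

    def bfs(start: int, skip_edge: tuple[int, int] | None = None) -> dict[int, float]:
        dist = {start: 0.0}
        queue = deque([start])
        while queue:
            u = queue.popleft()
            for v, w in adj[u]:
                if skip_edge and {u, v} == set(skip_edge):
                    continue
                if v not in dist:
                    dist[v] = dist[u] + w
                    queue.append(v)
        return dist

    matrix: dict[tuple[str, str], float] = {}
    for a in range(n_leaves):
        dist = bfs(a)
        for b in range(a, n_leaves):
            matrix[(ids[a], ids[b])] = dist[b]
            matrix[(ids[b], ids[a])] = dist[b]  # exactly symmetric

    all_leaves = frozenset(ids)
    ref = min(all_leaves)
    bipartitions: set[frozenset[str]] = set()
    for u, v in edges:
        if u < n_leaves or v < n_leaves:
            continue  # pendant edge -> trivial split
        reach = bfs(u, skip_edge=(u, v))
        side = frozenset(ids[x] for x in reach if x < n_leaves)
        if 2 <= len(side) <= n_leaves - 2:
            bipartitions.add(side if ref not in side else all_leaves - side)
    return ids, matrix, bipartitions
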