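"""Sequence simulation with known structure, for end-to-end testing.

Sequences evolve site-independently along a tree under the Kimura
2-parameter model: the root sequence is uniform over {A,C,G,T} and each
branch of length b (expected substitutions/site) applies the closed-form
K2P transition probabilities with transition/transversion rate ratio
kappa.  Optional features emulate the structure of real barcode data:

* a conserved island — a column range copied invariantly down the tree,
  as a planted target for conserved-window primer design;
* spacer-style indels — single-column insertion/deletion events placed
  uniformly per sequence after substitution, producing ragged ungapped
  lengths while keeping the matrix aligned;
* clone heterogeneity — each leaf emits several "clones" evolved an
  extra star-branch beyond the leaf, emulating a multi-copy locus whose
  paralogs are not homogeneous.

Every simulation emits a truth record (tree, rates, island coordinates)
beside the data so tests can assert against the generating model.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import dendropy
import numpy as np

from .errors import SimulationError
from .seqio import AlignedLocus, SampleMeta, SequenceRecord, write_fasta, write_sample_table

_BASES = "ACGT"
_TS_PARTNER = np.array([2, 3, 0, 1])  # A<->G, C<->T
_TV_FIRST = np.array([1, 0, 1, 0])    # first transversion target (A->C, C->A, G->C, T->A)
_TV_SECOND = np.array([3, 2, 3, 2])   # second (A->T, C->G, G->T, T->G)


def k2p_event_probabilities(branch_length: float, kappa: float) -> tuple[float, float]:
    """(P, Q): expected transition and total transversion probabilities.

    Closed-form site probabilities after evolving a branch of the given
    length under K2P with rate ratio ``kappa`` (alpha/beta).
    """
    if branch_length < 0:
        raise SimulationError("negative branch length")
    if kappa < 0:
        raise SimulationError("kappa must be >= 0")
    beta_t = branch_length / (kappa + 2.0)
    alpha_t = kappa * beta_t
    p_ts = 0.25 + 0.25 * math.exp(-4.0 * beta_t) - 0.5 * math.exp(-2.0 * (alpha_t + beta_t))
    q_tv = 0.5 - 0.5 * math.exp(-4.0 * beta_t)
    return p_ts, q_tv


def _evolve(
    parent: np.ndarray,
    branch_length: float,
    kappa: float,
    rng: np.random.Generator,
    frozen: np.ndarray | None,
) -> np.ndarray:
    """One branch of site-independent K2P evolution; ``frozen`` columns copy."""
    if branch_length == 0:
        return parent.copy()
    p_ts, q_tv = k2p_event_probabilities(branch_length, kappa)
    p_same = 1.0 - p_ts - q_tv
    u = rng.random(parent.shape[0])
    child = parent.copy()
    ts = (u >= p_same) & (u < p_same + p_ts)
    tv1 = (u >= p_same + p_ts) & (u < p_same + p_ts + q_tv / 2.0)
    tv2 = u >= p_same + p_ts + q_tv / 2.0
    child[ts] = _TS_PARTNER[parent[ts]]
    child[tv1] = _TV_FIRST[parent[tv1]]
    child[tv2] = _TV_SECOND[parent[tv2]]
    if frozen is not None:
        child[frozen] = parent[frozen]
    return child


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of one alignment simulation.

    ``tree`` is a Newick string with branch lengths in substitutions/site
    and unique leaf labels (the sample ids).  ``conserved_island`` is a
    1-based (start, length) column range held invariant everywhere.
    ``clone_count`` > 0 replaces each leaf with that many clones, each a
    further ``clone_divergence`` from the leaf along its own branch.
    """

    tree: str
    sequence_length: int
    kappa: float = 2.0
    indel_rate: float = 0.0
    clone_count: int = 0
    clone_divergence: float = 0.0
    conserved_island: tuple[int, int] | None = None
    seed: int = 0
    species_of: Mapping[str, str] | None = None
    group_of: Mapping[str, str] | None = None

    def __post_init__(self) -> None:
        if self.sequence_length < 1:
            raise SimulationError("sequence_length must be >= 1")
        if self.kappa < 0:
            raise SimulationError("kappa must be >= 0")
        if not 0.0 <= self.indel_rate <= 1.0:
            raise SimulationError("indel_rate must lie in [0, 1]")
        if self.clone_count < 0 or self.clone_divergence < 0:
            raise SimulationError("clone parameters must be nonnegative")
        if self.conserved_island is not None:
            start, length = self.conserved_island
            if start < 1 or length < 1 or start + length - 1 > self.sequence_length:
                raise SimulationError("conserved_island outside the sequence")


def simulate_alignment(
    config: SimulationConfig, locus_name: str = "simulated"
) -> tuple[AlignedLocus, list[SampleMeta], dict]:
    """Simulate an alignment; returns (locus, metadata, truth record)."""
    rng = np.random.default_rng(config.seed)
    tree = dendropy.Tree.get(data=config.tree, schema="newick")
    length = config.sequence_length

    frozen = None
    if config.conserved_island is not None:
        start, ilen = config.conserved_island
        frozen = np.zeros(length, dtype=bool)
        frozen[start - 1 : start - 1 + ilen] = True

    root_seq = rng.integers(0, 4, size=length)
    sequences: dict[str, np.ndarray] = {}
    leaf_order: list[str] = []

    def descend(node: dendropy.Node, seq: np.ndarray) -> None:
        for child in node.child_nodes():
            blen = child.edge.length or 0.0
            child_seq = _evolve(seq, blen, config.kappa, rng, frozen)
            if child.is_leaf():
                label = child.taxon.label if child.taxon else None
                if not label:
                    raise SimulationError("tree has an unlabelled leaf")
                label = label.replace(" ", "_")
                if label in sequences:
                    raise SimulationError(f"duplicate leaf label {label!r}")
                sequences[label] = child_seq
                leaf_order.append(label)
            else:
                descend(child, child_seq)

    seed_node = tree.seed_node
    if seed_node.is_leaf():
        raise SimulationError("tree must have internal structure")
    descend(seed_node, root_seq)
    if len(leaf_order) < 2:
        raise SimulationError("tree must have at least 2 leaves")

    # clone expansion: each leaf emits clone_count paralogs on a star
    emitted: list[tuple[str, str, str | None, np.ndarray]] = []  # (id, leaf, clone, seq)
    for leaf in leaf_order:
        if config.clone_count > 0:
            for k in range(1, config.clone_count + 1):
                cseq = _evolve(
                    sequences[leaf], config.clone_divergence, config.kappa, rng, frozen
                )
                emitted.append((f"{leaf}.c{k}", leaf, f"c{k}", cseq))
        else:
            emitted.append((leaf, leaf, None, sequences[leaf]))

    matrix = np.stack([seq for *_, seq in emitted])  # codes 0..3; 4 = gap
    island_start = config.conserved_island[0] if config.conserved_island else None
    n_del = n_ins = 0
    if config.indel_rate > 0:
        # deletions: single columns gapped in one sequence
        for row in range(matrix.shape[0]):
            k = rng.binomial(length, config.indel_rate / 2.0)
            if k:
                cols = rng.choice(length, size=k, replace=False)
                matrix[row, cols] = 4
                n_del += int(k)
        # insertions: new columns with a base in one sequence, gaps elsewhere
        events = []
        for row in range(matrix.shape[0]):
            k = rng.binomial(length, config.indel_rate / 2.0)
            for _ in range(k):
                events.append((int(rng.integers(0, matrix.shape[1] + 1)), row,
                               int(rng.integers(0, 4))))
        n_ins = len(events)
        for pos, row, base in sorted(events, reverse=True):
            col = np.full((matrix.shape[0], 1), 4, dtype=matrix.dtype)
            col[row, 0] = base
            matrix = np.concatenate([matrix[:, :pos], col, matrix[:, pos:]], axis=1)
            if island_start is not None and pos < island_start:
                island_start += 1

    alphabet = _BASES + "-"
    records = tuple(
        SequenceRecord(
            sid,
            "".join(alphabet[c] for c in matrix[i]),
            description=f"simulated from {leaf}",
        )
        for i, (sid, leaf, _clone, _seq) in enumerate(emitted)
    )
    locus = AlignedLocus(locus_name, records)

    species_of = config.species_of or {}
    group_of = config.group_of or {}
    meta = [
        SampleMeta(
            sample_id=sid,
            species=species_of.get(leaf, leaf),
            group=group_of.get(leaf, ""),
            voucher=leaf if clone else None,
            clone_id=clone,
        )
        for sid, leaf, clone, _seq in emitted
    ]

    truth = {
        "tree": config.tree,
        "kappa": config.kappa,
        "sequence_length": config.sequence_length,
        "alignment_length": locus.length,
        "seed": config.seed,
        "conserved_island": (
            [island_start, config.conserved_island[1]]
            if config.conserved_island
            else None
        ),
        "indel_events": {"deletions": n_del, "insertions": n_ins},
        "clone_count": config.clone_count,
        "clone_divergence": config.clone_divergence,
    }
    return locus, meta, truth


@dataclass(frozen=True)
class GapScenario:
    """A simulated dataset with a designed barcoding-gap geometry."""

    locus: AlignedLocus
    meta: list[SampleMeta]
    truth: dict
    group_a_label: str = "groupA"
    group_b_label: str = "groupB"


def simulate_gap_scenario(
    within: float,
    between: float,
    n_species_a: int,
    n_species_b: int,
    length: int,
    seed: int,
    samples_per_species: int = 2,
    kappa: float = 2.0,
    group_labels: tuple[str, str] = ("groupA", "groupB"),
) -> GapScenario:
    """Star-like two-group geometry with known expected divergences.

    Every sample sits ``within``/2 from its group hub, and the hubs are
    ``between`` − ``within`` apart, so conspecific pairs have expected
    K2P path length ``within`` and every cross-group pair ``between``.
    Requires 0 ≤ within < between.
    """
    if not (0.0 <= within < between):
        raise SimulationError(
            f"need 0 <= within < between, got within={within}, between={between}"
        )
    if n_species_a < 1 or n_species_b < 1 or samples_per_species < 1:
        raise SimulationError("species and sample counts must be >= 1")

    half = within / 2.0
    mid = between - within

    def leaves(prefix: str, n_species: int) -> list[str]:
        return [
            f"{prefix}{s}_{k}"
            for s in range(1, n_species + 1)
            for k in range(1, samples_per_species + 1)
        ]

    leaves_a = leaves("A", n_species_a)
    leaves_b = leaves("B", n_species_b)
    clade_a = ",".join(f"{l}:{half}" for l in leaves_a)
    clade_b = ",".join(f"{l}:{half}" for l in leaves_b)
    newick = f"(({clade_a}):{mid},({clade_b}):0.0);"

    species_of = {l: f"species_{l.rsplit('_', 1)[0]}" for l in leaves_a + leaves_b}
    group_of = {l: group_labels[0] for l in leaves_a}
    group_of.update({l: group_labels[1] for l in leaves_b})

    config = SimulationConfig(
        tree=newick,
        sequence_length=length,
        kappa=kappa,
        seed=seed,
        species_of=species_of,
        group_of=group_of,
    )
    locus, meta, truth = simulate_alignment(config, locus_name="gap_scenario")
    truth.update(
        {
            "expected_within": within,
            "expected_between": between,
            "group_labels": list(group_labels),
        }
    )
    return GapScenario(locus, meta, truth, *group_labels)


def write_dataset(
    locus: AlignedLocus,
    meta: list[SampleMeta],
    truth: dict,
    outdir: str | Path,
) -> None:
    """Write aligned FASTA + metadata TSV + truth JSON side by side."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_fasta(locus.records, outdir / f"{locus.locus_name}.fasta")
    write_sample_table(meta, outdir / f"{locus.locus_name}.meta.tsv")
    with open(outdir / f"{locus.locus_name}.truth.json", "w") as fh:
        json.dump(truth, fh, indent=2, sort_keys=True)
        fh.write("\n")
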