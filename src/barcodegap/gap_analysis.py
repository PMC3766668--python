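"""Barcoding-gap discrimination between sample groups.

A locus discriminates two groups when the minimum K2P divergence between
them exceeds the maximum intraspecific divergence among the species those
groups contain (strict inequality — equality fails).  Intraspecific pairs
include clone-vs-clone distances within one voucher, so multi-copy loci
with heterogeneous paralogs (a 5S-type spacer) legitimately show large
intraspecific maxima.

Across loci, differentiation power for a fixed group pair is ranked by
descending minimum interspecific divergence (competition ranking: ties
share the smaller rank and the following rank is skipped).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, replace
from typing import Iterable, Mapping, Sequence

from .distances import DistanceMatrix
from .errors import ConfigError, MetadataError
from .seqio import AlignedLocus, SampleMeta, metadata_index

logger = logging.getLogger(__name__)

#: Characters that count as an observed state at a diagnostic site. Gaps are
#: a legitimate state (a fixed deletion separates groups); ambiguity codes
#: are missing data.
_STATE_CHARS = frozenset("ACGT-")


@dataclass(frozen=True)
class GroupDef:
    """A named set of samples being compared as one group."""

    label: str
    sample_ids: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.sample_ids:
            raise ConfigError(f"group {self.label!r} is empty")


@dataclass(frozen=True)
class GroupComparison:
    """One group-vs-group discrimination test at one locus."""

    locus_name: str
    group_a: GroupDef
    group_b: GroupDef
    min_interspecific: float
    max_intraspecific: float
    success: bool
    intra_pairs: int = 0  # number of within-species pairs seen (0 => max is a placeholder)
    rank: int | None = None

    @property
    def pair_label(self) -> tuple[str, str]:
        return (self.group_a.label, self.group_b.label)


def _index(meta: Iterable[SampleMeta] | Mapping[str, SampleMeta]) -> Mapping[str, SampleMeta]:
    return meta if isinstance(meta, Mapping) else metadata_index(meta)


def group_from_label(
    meta: Iterable[SampleMeta] | Mapping[str, SampleMeta], label: str
) -> GroupDef:
    """All samples whose metadata ``group`` equals ``label``."""
    index = _index(meta)
    members = tuple(sid for sid, m in index.items() if m.group == label)
    if not members:
        raise ConfigError(f"no samples carry group label {label!r}")
    return GroupDef(label, members)


def group_from_species(
    meta: Iterable[SampleMeta] | Mapping[str, SampleMeta],
    species: Sequence[str],
    label: str | None = None,
) -> GroupDef:
    """All samples belonging to the listed species."""
    index = _index(meta)
    wanted = set(species)
    unknown = wanted - {m.species for m in index.values()}
    if unknown:
        raise MetadataError(f"unknown species in group selector: {sorted(unknown)}")
    members = tuple(sid for sid, m in index.items() if m.species in wanted)
    return GroupDef(label or "+".join(species), members)


def within_species_max(
    matrix: DistanceMatrix,
    meta: Iterable[SampleMeta] | Mapping[str, SampleMeta],
    species_set: Iterable[str],
) -> tuple[float, int]:
    """Maximum distance over same-species pairs within ``species_set``.

    Clones are ordinary samples, so clone-vs-clone pairs count.  Returns
    ``(max_distance, n_pairs)``; when no same-species pair exists the
    maximum is reported as 0.0 with ``n_pairs == 0`` and a warning.
    """
    index = _index(meta)
    species_set = set(species_set)
    known = {m.species for m in index.values()}
    unknown = species_set - known
    if unknown:
        raise MetadataError(f"unknown species: {sorted(unknown)}")
    in_matrix = set(matrix.sample_ids)
    by_species: dict[str, list[str]] = {}
    for sid, m in index.items():
        if m.species in species_set and sid in in_matrix:
            by_species.setdefault(m.species, []).append(sid)
    best = 0.0
    n_pairs = 0
    for members in by_species.values():
        for i in range(len(members)):
            for j in range(i + 1, len(members)):
                best = max(best, matrix.distance(members[i], members[j]))
                n_pairs += 1
    if n_pairs == 0:
        warnings.warn(
            "no within-species pair available; intraspecific maximum "
            "reported as 0.0",
            stacklevel=2,
        )
    return best, n_pairs


def between_groups_min(
    matrix: DistanceMatrix,
    meta: Iterable[SampleMeta] | Mapping[str, SampleMeta],
    group_a: GroupDef | str,
    group_b: GroupDef | str,
) -> float:
    """Minimum distance over all cross-group sample pairs."""
    index = _index(meta)
    ga = group_from_label(index, group_a) if isinstance(group_a, str) else group_a
    gb = group_from_label(index, group_b) if isinstance(group_b, str) else group_b
    overlap = set(ga.sample_ids) & set(gb.sample_ids)
    if overlap:
        raise ConfigError(
            f"groups {ga.label!r} and {gb.label!r} overlap: {sorted(overlap)}"
        )
    return min(
        matrix.distance(a, b) for a in ga.sample_ids for b in gb.sample_ids
    )


def _restrict_group(group: GroupDef, matrix: DistanceMatrix, locus_name: str) -> GroupDef:
    present = set(matrix.sample_ids)
    kept = tuple(sid for sid in group.sample_ids if sid in present)
    dropped = [sid for sid in group.sample_ids if sid not in present]
    if dropped:
        logger.warning(
            "locus %s: group %s: samples missing from alignment, excluded: %s",
            locus_name, group.label, dropped,
        )
    if not kept:
        raise ConfigError(
            f"locus {locus_name!r}: group {group.label!r} has no samples in "
            "the alignment"
        )
    return GroupDef(group.label, kept)


def compare_groups(
    matrix: DistanceMatrix,
    meta: Iterable[SampleMeta] | Mapping[str, SampleMeta],
    group_a: GroupDef | str,
    group_b: GroupDef | str,
    locus_name: str,
) -> GroupComparison:
    """Run the barcoding-gap criterion for one group pair at one locus.

    The intraspecific maximum is restricted to species represented in the
    two groups; species outside the comparison are ignored.
    """
    index = _index(meta)
    ga = group_from_label(index, group_a) if isinstance(group_a, str) else group_a
    gb = group_from_label(index, group_b) if isinstance(group_b, str) else group_b
    ga = _restrict_group(ga, matrix, locus_name)
    gb = _restrict_group(gb, matrix, locus_name)
    min_inter = between_groups_min(matrix, index, ga, gb)
    species = {index[sid].species for sid in ga.sample_ids + gb.sample_ids}
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        max_intra, n_pairs = within_species_max(matrix, index, species)
    return GroupComparison(
        locus_name=locus_name,
        group_a=ga,
        group_b=gb,
        min_interspecific=min_inter,
        max_intraspecific=max_intra,
        success=min_inter > max_intra,
        intra_pairs=n_pairs,
    )


def rank_loci(comparisons: Sequence[GroupComparison]) -> list[GroupComparison]:
    """Rank loci for one fixed group pair by differentiation power.

    The key is descending minimum interspecific divergence.  Ties receive
    the smaller rank; the next rank is skipped (competition ranking).
    Output preserves input order, with ``rank`` populated.
    """
    if len(comparisons) < 2:
        raise ConfigError("ranking needs at least two loci")
    pairs = {c.pair_label for c in comparisons}
    if len(pairs) != 1:
        raise ConfigError(f"cannot rank across mixed group pairs: {sorted(pairs)}")
    ordered = sorted(
        range(len(comparisons)),
        key=lambda i: -comparisons[i].min_interspecific,
    )
    ranks: dict[int, int] = {}
    prev_value: float | None = None
    prev_rank = 0
    for pos, idx in enumerate(ordered, start=1):
        value = comparisons[idx].min_interspecific
        if prev_value is not None and value == prev_value:
            ranks[idx] = prev_rank
        else:
            ranks[idx] = prev_rank = pos
            prev_value = value
    return [replace(c, rank=ranks[i]) for i, c in enumerate(comparisons)]


@dataclass(frozen=True)
class DiagnosticSite:
    """An alignment column where each group is fixed and groups differ."""

    column: int  # 1-based alignment coordinate
    states: Mapping[str, str]  # group label -> fixed state ('-' allowed)


def diagnostic_sites(
    locus: AlignedLocus,
    meta: Iterable[SampleMeta] | Mapping[str, SampleMeta],
    partition: Mapping[str, Sequence[str]],
) -> list[DiagnosticSite]:
    """Columns where every group is fixed for one state and groups differ.

    A group is "fixed" at a column when all its non-missing characters are
    identical; gaps count as a state, ambiguity codes as missing.  A group
    with no observed state at a column disqualifies the column.
    """
    for label, members in partition.items():
        if not members:
            raise ConfigError(f"diagnostic-site group {label!r} is empty")
    seqs = {
        label: [locus.record(sid).sequence for sid in members]
        for label, members in partition.items()
    }
    sites: list[DiagnosticSite] = []
    for col in range(locus.length):
        states: dict[str, str] = {}
        ok = True
        for label, group_seqs in seqs.items():
            observed = {s[col] for s in group_seqs if s[col] in _STATE_CHARS}
            if len(observed) != 1:
                ok = False
                break
            states[label] = next(iter(observed))
        if ok and len(set(states.values())) > 1:
            sites.append(DiagnosticSite(column=col + 1, states=states))
    return sites


@dataclass(frozen=True)
class LocusSummary:
    """Per-species sequence properties of one locus."""

    locus_name: str
    avg_length: Mapping[str, float]  # species -> mean ungapped length (bp)
    gc_percent: Mapping[str, float]  # species -> mean GC content (%)
    diagnostic: tuple[DiagnosticSite, ...]


def _gc_percent(seq: str) -> float:
    counts = {b: seq.count(b) for b in "ACGT"}
    denom = sum(counts.values())
    if denom == 0:
        return 0.0
    return 100.0 * (counts["G"] + counts["C"]) / denom


def locus_summary(
    locus: AlignedLocus,
    meta: Iterable[SampleMeta] | Mapping[str, SampleMeta],
    partition: Mapping[str, Sequence[str]] | None = None,
) -> LocusSummary:
    """Per-species average ungapped length and GC content.

    GC% is G+C over A+C+G+T per sequence (gaps and ambiguity excluded from
    numerator and denominator), averaged over the species' samples.  The
    default diagnostic-site partition groups samples by species.
    """
    index = _index(meta)
    by_species: dict[str, list[str]] = {}
    for sid in locus.sample_ids:
        if sid not in index:
            raise MetadataError(f"sample {sid!r} missing from metadata")
        by_species.setdefault(index[sid].species, []).append(sid)
    avg_length: dict[str, float] = {}
    gc: dict[str, float] = {}
    for species, members in by_species.items():
        lengths = [len(locus.record(sid).ungapped) for sid in members]
        gcs = [_gc_percent(locus.record(sid).sequence) for sid in members]
        avg_length[species] = sum(lengths) / len(lengths)
        gc[species] = sum(gcs) / len(gcs)
    if partition is None:
        partition = by_species
    diag = tuple(diagnostic_sites(locus, index, partition))
    return LocusSummary(locus.locus_name, avg_length, gc, diag)
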