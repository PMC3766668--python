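"""IUPAC-aware primer–template complementarity profiling and design.

A primer is placed ungapped on a template at the position maximising the
number of compatible bases (template base contained in the primer code's
IUPAC set), leftmost on ties.  Matches are rendered in dot notation as in
classical primer-survey tables: a dot where the template is compatible,
the *template* base where it is not.  An indel in the binding site shows
up as a poor best placement and is flagged when the mismatch count
exceeds a third of the primer length.

Candidate design slides fixed windows over gap-free alignment columns,
takes the majority-rule consensus (IUPAC degeneracy when no strict
majority), and keeps windows whose worst per-sequence mismatch count and
GC content pass the configured filters and whose 3'-terminal bases are
invariant across all sequences.  Thermodynamics (Tm, hairpins, dimers)
are deliberately out of scope: GC% and 3'-conservation are the only
quality filters.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

from Bio.Seq import Seq

from .errors import PrimerError
from .seqio import AlignedLocus, SequenceRecord

#: IUPAC nucleotide codes mapped to the base sets they stand for.
IUPAC_SETS: dict[str, frozenset[str]] = {
    "A": frozenset("A"), "C": frozenset("C"), "G": frozenset("G"),
    "T": frozenset("T"),
    "R": frozenset("AG"), "Y": frozenset("CT"), "S": frozenset("CG"),
    "W": frozenset("AT"), "K": frozenset("GT"), "M": frozenset("AC"),
    "B": frozenset("CGT"), "D": frozenset("AGT"), "H": frozenset("ACT"),
    "V": frozenset("ACG"), "N": frozenset("ACGT"),
}

_SET_TO_CODE = {v: k for k, v in IUPAC_SETS.items()}


@dataclass(frozen=True)
class Primer:
    """An oligonucleotide written 5'→3', possibly with degenerate codes."""

    name: str
    sequence: str
    orientation: str = "forward"  # forward | reverse

    def __post_init__(self) -> None:
        seq = self.sequence.upper().replace("U", "T")
        object.__setattr__(self, "sequence", seq)
        if not seq:
            raise PrimerError(f"primer {self.name!r}: empty sequence")
        bad = set(seq) - set(IUPAC_SETS)
        if bad:
            raise PrimerError(
                f"primer {self.name!r}: invalid IUPAC codes {sorted(bad)!r}"
            )
        if self.orientation not in ("forward", "reverse"):
            raise PrimerError(
                f"primer {self.name!r}: orientation must be forward/reverse"
            )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class PrimerMatch:
    """Best ungapped placement of a primer on one template."""

    primer: Primer
    template_id: str
    position: int  # 1-based start on the strand that was searched
    pattern: str  # dot = compatible; letter = template base at a mismatch
    mismatch_count: int
    three_prime_mismatch_in_last3: bool
    plus_strand_start: int  # 1-based leftmost coordinate on the input strand

    @property
    def indel_suspected(self) -> bool:
        """Best placement is poor enough to suggest an indel in the site."""
        return self.mismatch_count > len(self.primer) / 3


def _normalise_template(record: SequenceRecord) -> str:
    seq = record.sequence.upper().replace("U", "T")
    if "-" in seq:
        raise PrimerError(
            f"template {record.sample_id!r} contains gaps; primer matching "
            "is defined on ungapped templates"
        )
    return seq


def match_primer(primer: Primer, template: SequenceRecord) -> PrimerMatch:
    """Place ``primer`` at its best ungapped position on ``template``.

    Reverse-orientation primers are matched against the reverse complement
    of the template; ``plus_strand_start`` always reports the leftmost
    coordinate of the binding site on the input strand.
    """
    target = _normalise_template(template)
    if primer.orientation == "reverse":
        target = str(Seq(target).reverse_complement())
    plen, tlen = len(primer), len(target)
    if plen > tlen:
        raise PrimerError(
            f"primer {primer.name!r} ({plen} nt) longer than template "
            f"{template.sample_id!r} ({tlen} nt)"
        )
    sets = [IUPAC_SETS[c] for c in primer.sequence]
    best_pos, best_hits = 0, -1
    for start in range(tlen - plen + 1):
        hits = sum(
            1 for k in range(plen) if target[start + k] in sets[k]
        )
        if hits > best_hits:
            best_pos, best_hits = start, hits
    window = target[best_pos : best_pos + plen]
    pattern = "".join(
        "." if window[k] in sets[k] else window[k] for k in range(plen)
    )
    mism = plen - best_hits
    last3 = pattern[-3:]
    if primer.orientation == "reverse":
        plus_start = tlen - (best_pos + plen) + 1
    else:
        plus_start = best_pos + 1
    return PrimerMatch(
        primer=primer,
        template_id=template.sample_id,
        position=best_pos + 1,
        pattern=pattern,
        mismatch_count=mism,
        three_prime_mismatch_in_last3=any(c != "." for c in last3),
        plus_strand_start=plus_start,
    )


def mismatch_report(
    primers: Iterable[Primer], templates: Iterable[SequenceRecord]
) -> list[PrimerMatch]:
    """All primer × template best placements (one row each)."""
    primers = list(primers)
    templates = list(templates)
    if not primers or not templates:
        raise PrimerError("mismatch_report needs at least one primer and template")
    return [match_primer(p, t) for p in primers for t in templates]


def render_mismatch_report(matches: Sequence[PrimerMatch]) -> str:
    """Fixed-width text rendering: primer sequence on top, dot rows beneath."""
    lines: list[str] = []
    by_primer: dict[str, list[PrimerMatch]] = {}
    for m in matches:
        by_primer.setdefault(m.primer.name, []).append(m)
    id_width = max(len(m.template_id) for m in matches)
    id_width = max(id_width, len("template"))
    for name, rows in by_primer.items():
        primer = rows[0].primer
        lines.append(f"# primer {name} ({primer.orientation}, 5'->3')")
        lines.append(f"{'template':<{id_width}}  {primer.sequence}")
        for m in rows:
            lines.append(f"{m.template_id:<{id_width}}  {m.pattern}")
        lines.append("")
    return "\n".join(lines)


def write_mismatch_tsv(matches: Sequence[PrimerMatch], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(
            "primer\torientation\ttemplate\tposition\tplus_strand_start\t"
            "pattern\tmismatches\tthree_prime_mismatch\tindel_suspected\n"
        )
        for m in matches:
            fh.write(
                f"{m.primer.name}\t{m.primer.orientation}\t{m.template_id}\t"
                f"{m.position}\t{m.plus_strand_start}\t{m.pattern}\t"
                f"{m.mismatch_count}\t{m.three_prime_mismatch_in_last3}\t"
                f"{m.indel_suspected}\n"
            )


def read_primer_tsv(path: str | Path) -> list[Primer]:
    """Primer list as TSV with header name/sequence/orientation."""
    primers: list[Primer] = []
    with open(path) as fh:
        header = fh.readline().strip().split("\t")
        required = {"name", "sequence", "orientation"}
        if not required <= set(header):
            raise PrimerError(f"{path}: primer TSV needs columns {sorted(required)}")
        idx = {c: header.index(c) for c in required}
        for line in fh:
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            primers.append(
                Primer(
                    name=parts[idx["name"]],
                    sequence=parts[idx["sequence"]],
                    orientation=parts[idx["orientation"]],
                )
            )
    if not primers:
        raise PrimerError(f"{path}: no primers found")
    return primers


@dataclass(frozen=True)
class PrimerCandidate:
    """A conserved-window primer candidate from an alignment."""

    start: int  # 1-based alignment column, inclusive
    end: int  # 1-based alignment column, inclusive
    consensus: str  # 5'->3', may contain IUPAC degeneracy
    max_mismatches: int  # worst per-sequence incompatibility count
    gc_percent: float
    length: int


def _consensus_column(chars: Sequence[str]) -> str:
    counts: dict[str, int] = {}
    for c in chars:
        counts[c] = counts.get(c, 0) + 1
    best = max(counts.values())
    winners = sorted(c for c, k in counts.items() if k == best)
    if len(winners) == 1 and best * 2 > len(chars):
        return winners[0]
    # no strict majority: emit the degeneracy covering every observed base
    return _SET_TO_CODE[frozenset(counts)]


def _candidate_gc(consensus: str) -> float:
    # S counts as G/C; other degeneracies count by their G+C fraction
    gc = sum(
        len(IUPAC_SETS[c] & {"G", "C"}) / len(IUPAC_SETS[c]) for c in consensus
    )
    return 100.0 * gc / len(consensus)


def design_conserved_primers(
    locus: AlignedLocus,
    min_len: int = 18,
    max_len: int = 25,
    max_mismatch: int = 0,
    gc_bounds: tuple[float, float] = (0.0, 100.0),
    require_conserved_3prime: int = 3,
) -> list[PrimerCandidate]:
    """Rank conserved windows of an alignment as forward-primer candidates.

    Windows may not contain a gap in any sequence; ambiguity codes in the
    input count as mismatches against the consensus unless compatible.
    Candidates are ranked by (max mismatches ascending, length descending,
    start ascending).  An empty result is legitimate.
    """
    if min_len < 1 or max_len < min_len:
        raise PrimerError("invalid primer length bounds")
    seqs = [r.sequence for r in locus.records]
    ncols = locus.length
    gap_free = [all(s[c] != "-" for s in seqs) for c in range(ncols)]
    consensus_all = [
        _consensus_column([s[c] for s in seqs]) if gap_free[c] else ""
        for c in range(ncols)
    ]
    invariant = [
        gap_free[c] and len({s[c] for s in seqs}) == 1 for c in range(ncols)
    ]

    candidates: list[PrimerCandidate] = []
    for length in range(min_len, max_len + 1):
        for start in range(ncols - length + 1):
            end = start + length
            if not all(gap_free[start:end]):
                continue
            tail = invariant[end - require_conserved_3prime : end]
            if require_conserved_3prime > 0 and not all(tail):
                continue
            consensus = "".join(consensus_all[start:end])
            worst = 0
            for s in seqs:
                mism = sum(
                    1
                    for k in range(length)
                    if s[start + k] not in IUPAC_SETS[consensus[k]]
                )
                worst = max(worst, mism)
            if worst > max_mismatch:
                continue
            gc = _candidate_gc(consensus)
            if not (gc_bounds[0] <= gc <= gc_bounds[1]):
                continue
            candidates.append(
                PrimerCandidate(
                    start=start + 1,
                    end=end,
                    consensus=consensus,
                    max_mismatches=worst,
                    gc_percent=gc,
                    length=length,
                )
            )
    candidates.sort(key=lambda c: (c.max_mismatches, -c.length, c.start))
    return candidates


def write_candidates_tsv(
    candidates: Sequence[PrimerCandidate], path: str | Path
) -> None:
    with open(path, "w") as fh:
        fh.write("start\tend\tlength\tconsensus\tmax_mismatches\tgc_percent\n")
        for c in candidates:
            fh.write(
                f"{c.start}\t{c.end}\t{c.length}\t{c.consensus}\t"
                f"{c.max_mismatches}\t{c.gc_percent:.1f}\n"
            )
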