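"""Sequence and metadata I/O.

Reads plain and aligned FASTA into light-weight record types and sample
metadata from tab-delimited tables.  Sequences are normalised on read:
uppercased, with RNA ``U`` converted to ``T`` (all downstream analyses are
DNA-level).  The only gap character accepted is ``-``; the ``.`` gap dialect
is rejected explicitly rather than silently reinterpreted.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from Bio import SeqIO

from .errors import AlignmentIntegrityError, FastaParseError, MetadataError

#: Characters permitted in a normalised sequence: the four bases, the IUPAC
#: ambiguity codes, and the gap character.
IUPAC_AMBIGUITY = frozenset("RYSWKMBDHVN")
ALPHABET = frozenset("ACGT") | IUPAC_AMBIGUITY | {"-"}


@dataclass(frozen=True)
class SequenceRecord:
    """A named nucleotide sequence (aligned or not)."""

    sample_id: str
    sequence: str
    description: str = ""

    def __post_init__(self) -> None:
        if not self.sample_id:
            raise FastaParseError("empty sample_id")
        if not self.sequence:
            raise FastaParseError(f"record {self.sample_id!r}: empty sequence")
        object.__setattr__(self, "sequence", _normalise(self.sequence))
        bad = set(self.sequence) - ALPHABET
        if bad:
            if "." in bad:
                raise FastaParseError(
                    f"record {self.sample_id!r}: '.' gap characters are not "
                    "accepted; use '-' for gaps"
                )
            raise FastaParseError(
                f"record {self.sample_id!r}: illegal characters {sorted(bad)!r}"
            )

    @property
    def ungapped(self) -> str:
        return self.sequence.replace("-", "")


@dataclass(frozen=True)
class SampleMeta:
    """Metadata for one sample: species assignment and trade-group label.

    ``group`` is a free label such as ``GL`` (Guanlongdan), ``JL``
    (Jianlongdan) or ``adulterant``; it may be empty for samples outside any
    configured group.  Multi-copy clones sequenced from one voucher are
    distinct samples sharing ``voucher`` but differing in ``clone_id``.
    """

    sample_id: str
    species: str
    group: str = ""
    voucher: str | None = None
    clone_id: str | None = None

    def __post_init__(self) -> None:
        if not self.sample_id:
            raise MetadataError("empty sample_id in metadata")
        if not self.species:
            raise MetadataError(f"sample {self.sample_id!r}: empty species")


@dataclass(frozen=True)
class AlignedLocus:
    """A multiple sequence alignment for one locus.

    Invariants: all sequences share one length, at least two records are
    present, and every sequence carries at least one non-gap character.
    """

    locus_name: str
    records: tuple[SequenceRecord, ...]

    def __post_init__(self) -> None:
        if len(self.records) < 2:
            raise AlignmentIntegrityError(
                f"locus {self.locus_name!r}: need at least 2 sequences, "
                f"got {len(self.records)}"
            )
        lengths = {len(r.sequence) for r in self.records}
        if len(lengths) != 1:
            detail = ", ".join(
                f"{r.sample_id}={len(r.sequence)}" for r in self.records
            )
            raise AlignmentIntegrityError(
                f"locus {self.locus_name!r}: ragged alignment ({detail})"
            )
        for r in self.records:
            if set(r.sequence) == {"-"}:
                raise AlignmentIntegrityError(
                    f"locus {self.locus_name!r}: sequence {r.sample_id!r} is all gaps"
                )

    @property
    def length(self) -> int:
        return len(self.records[0].sequence)

    @property
    def sample_ids(self) -> tuple[str, ...]:
        return tuple(r.sample_id for r in self.records)

    def record(self, sample_id: str) -> SequenceRecord:
        for r in self.records:
            if r.sample_id == sample_id:
                return r
        raise KeyError(sample_id)

    def subset(self, sample_ids: Iterable[str]) -> "AlignedLocus":
        """Restrict to the given samples, preserving alignment order."""
        wanted = set(sample_ids)
        kept = tuple(r for r in self.records if r.sample_id in wanted)
        return AlignedLocus(self.locus_name, kept)


def _normalise(seq: str) -> str:
    return seq.upper().replace("U", "T")


def read_fasta(path: str | Path) -> list[SequenceRecord]:
    """Read a FASTA file into records, normalising case and U→T.

    Raises :class:`FastaParseError` on an empty file, duplicate ids or
    illegal characters, naming the offending record.
    """
    path = Path(path)
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    try:
        parsed = list(SeqIO.parse(str(path), "fasta"))
    except ValueError as exc:
        raise FastaParseError(f"{path}: not valid FASTA ({exc})") from exc
    for rec in parsed:
        if rec.id in seen:
            raise FastaParseError(f"{path}: duplicate sequence id {rec.id!r}")
        seen.add(rec.id)
        desc = rec.description[len(rec.id):].strip() if rec.description else ""
        records.append(
            SequenceRecord(rec.id, _normalise(str(rec.seq)), description=desc)
        )
    if not records:
        raise FastaParseError(f"{path}: no FASTA records found")
    return records


def write_fasta(records: Iterable[SequenceRecord], path: str | Path, width: int = 70) -> None:
    """Write records as FASTA, wrapping sequence lines at ``width`` columns."""
    with open(path, "w") as fh:
        for r in records:
            header = f">{r.sample_id}"
            if r.description:
                header += f" {r.description}"
            fh.write(header + "\n")
            for i in range(0, len(r.sequence), width):
                fh.write(r.sequence[i : i + width] + "\n")


def read_alignment(path: str | Path, locus_name: str) -> AlignedLocus:
    """Read an aligned FASTA and verify the equal-length invariant."""
    return AlignedLocus(locus_name, tuple(read_fasta(path)))


REQUIRED_COLUMNS = ("sample_id", "species", "group")
OPTIONAL_COLUMNS = ("voucher", "clone_id")


def read_sample_table(path: str | Path) -> list[SampleMeta]:
    """Read a tab-delimited sample table.

    The header must contain ``sample_id``, ``species`` and ``group``
    (group values may be empty); ``voucher`` and ``clone_id`` are optional.
    Unknown columns are ignored.
    """
    path = Path(path)
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        if reader.fieldnames is None:
            raise MetadataError(f"{path}: empty metadata table")
        missing = [c for c in REQUIRED_COLUMNS if c not in reader.fieldnames]
        if missing:
            raise MetadataError(f"{path}: missing required column(s) {missing}")
        rows: list[SampleMeta] = []
        seen: set[str] = set()
        for lineno, row in enumerate(reader, start=2):
            sid = (row.get("sample_id") or "").strip()
            if not sid:
                raise MetadataError(f"{path}:{lineno}: empty sample_id")
            if sid in seen:
                raise MetadataError(f"{path}:{lineno}: duplicate sample_id {sid!r}")
            seen.add(sid)
            species = (row.get("species") or "").strip()
            if not species:
                raise MetadataError(f"{path}:{lineno}: sample {sid!r} missing species")
            rows.append(
                SampleMeta(
                    sample_id=sid,
                    species=species,
                    group=(row.get("group") or "").strip(),
                    voucher=(row.get("voucher") or "").strip() or None,
                    clone_id=(row.get("clone_id") or "").strip() or None,
                )
            )
    if not rows:
        raise MetadataError(f"{path}: no metadata rows")
    return rows


def write_sample_table(meta: Iterable[SampleMeta], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(REQUIRED_COLUMNS + OPTIONAL_COLUMNS)
        for m in meta:
            writer.writerow(
                [m.sample_id, m.species, m.group, m.voucher or "", m.clone_id or ""]
            )


def metadata_index(meta: Iterable[SampleMeta]) -> dict[str, SampleMeta]:
    return {m.sample_id: m for m in meta}


def check_alignment_metadata(
    locus: AlignedLocus, meta: Mapping[str, SampleMeta] | Sequence[SampleMeta]
) -> dict[str, SampleMeta]:
    """Verify every aligned sample has a metadata row; abort otherwise.

    A sample present in the alignment but absent from the table would be
    silently excluded from its species/group, corrupting the gap analysis,
    so this is a hard error rather than a warning.
    """
    index = meta if isinstance(meta, Mapping) else metadata_index(meta)
    missing = [sid for sid in locus.sample_ids if sid not in index]
    if missing:
        raise MetadataError(
            f"locus {locus.locus_name!r}: samples missing from metadata: {missing}"
        )
    return dict(index)
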