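"""Pairwise site-pattern counting and Kimura 2-parameter distances.

For every sequence pair, alignment columns holding a gap or any IUPAC
ambiguity code in either sequence are excluded (pairwise deletion); the
remaining columns are classified as identical, transition (A↔G, C↔T) or
transversion.  With P and Q the transition and transversion proportions
over the n compared sites, the K2P distance is

    d = -1/2 ln(1 - 2P - Q) - 1/4 ln(1 - 2Q)

Distances carry full floating precision internally; report writers round
to 4 decimal places.  Saturation (a log argument reaching zero or below)
raises by default; ``on_saturation="inf"`` substitutes +infinity for
exploratory runs, at the caller's own risk — infinities silently corrupt
min/max gap statistics.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterator, Literal

import numpy as np
import pandas as pd

from .errors import SaturationError, UndefinedDistanceError
from .seqio import AlignedLocus

# A/C/G/T -> 0..3; gap and every ambiguity code -> -1 (missing for the pair).
_ENCODE = np.full(256, -1, dtype=np.int8)
for _i, _b in enumerate("ACGT"):
    _ENCODE[ord(_b)] = _i

_PURINE = np.zeros(4, dtype=bool)
_PURINE[[0, 2]] = True  # A, G


def encode_sequence(seq: str) -> np.ndarray:
    """Encode a normalised sequence as int8 codes (missing = -1)."""
    return _ENCODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


@dataclass(frozen=True)
class SiteCounts:
    """Pairwise site-pattern tallies under pairwise deletion."""

    compared_sites: int
    transitions: int
    transversions: int
    excluded_sites: int

    def __post_init__(self) -> None:
        if self.transitions + self.transversions > self.compared_sites:
            raise ValueError("more differences than compared sites")

    @property
    def p(self) -> float:
        """Transition proportion P."""
        return self.transitions / self.compared_sites

    @property
    def q(self) -> float:
        """Transversion proportion Q."""
        return self.transversions / self.compared_sites

    @property
    def p_distance(self) -> float:
        """Observed proportion of differing sites."""
        return (self.transitions + self.transversions) / self.compared_sites


def count_site_pattern(seq_a: str, seq_b: str) -> SiteCounts:
    """Classify aligned columns for one sequence pair.

    A column is excluded iff either character is a gap or a non-ACGT
    ambiguity code; the rest are identical, transitions or transversions.
    """
    if len(seq_a) != len(seq_b):
        raise ValueError(
            f"sequences have unequal lengths ({len(seq_a)} vs {len(seq_b)})"
        )
    a = encode_sequence(seq_a)
    b = encode_sequence(seq_b)
    return _count_encoded(a, b, len(seq_a))


def _count_encoded(a: np.ndarray, b: np.ndarray, length: int) -> SiteCounts:
    valid = (a >= 0) & (b >= 0)
    n = int(valid.sum())
    diff = valid & (a != b)
    ts = int((diff & (_PURINE[a] == _PURINE[b])).sum())
    tv = int(diff.sum()) - ts
    return SiteCounts(n, ts, tv, length - n)


def k2p_distance(
    counts: SiteCounts,
    on_saturation: Literal["error", "inf"] = "error",
    pair: tuple[str, str] | None = None,
) -> float:
    """Kimura 2-parameter distance from site-pattern counts."""
    label = f" for pair {pair[0]!r}/{pair[1]!r}" if pair else ""
    if counts.compared_sites == 0:
        raise UndefinedDistanceError(f"no comparable sites{label}")
    if counts.transitions == 0 and counts.transversions == 0:
        return 0.0
    p, q = counts.p, counts.q
    w1 = 1.0 - 2.0 * p - q
    w2 = 1.0 - 2.0 * q
    if w1 <= 0.0 or w2 <= 0.0:
        if on_saturation == "inf":
            return math.inf
        raise SaturationError(
            f"divergence saturated{label}: P={p:.4g}, Q={q:.4g} outside the "
            "K2P log domain"
        )
    return -0.5 * math.log(w1) - 0.25 * math.log(w2)


def k2p_from_pair(
    seq_a: str, seq_b: str, on_saturation: Literal["error", "inf"] = "error"
) -> float:
    """Convenience: site counts + K2P distance for two aligned sequences."""
    return k2p_distance(count_site_pattern(seq_a, seq_b), on_saturation)


@dataclass(frozen=True)
class DistanceMatrix:
    """Symmetric pairwise K2P distances with per-pair count provenance."""

    sample_ids: tuple[str, ...]
    values: np.ndarray  # (n, n) float64, zero diagonal
    counts: dict[tuple[int, int], SiteCounts]  # keyed by (i, j), i < j

    def __post_init__(self) -> None:
        n = len(self.sample_ids)
        if self.values.shape != (n, n):
            raise ValueError("matrix shape does not match sample ids")

    @property
    def n(self) -> int:
        return len(self.sample_ids)

    def index(self, sample_id: str) -> int:
        return self.sample_ids.index(sample_id)

    def distance(self, id_a: str, id_b: str) -> float:
        return float(self.values[self.index(id_a), self.index(id_b)])

    def pair_counts(self, id_a: str, id_b: str) -> SiteCounts:
        i, j = sorted((self.index(id_a), self.index(id_b)))
        return self.counts[(i, j)]

    def iter_pairs(self) -> Iterator[tuple[str, str, float, SiteCounts]]:
        for i in range(self.n):
            for j in range(i + 1, self.n):
                yield (
                    self.sample_ids[i],
                    self.sample_ids[j],
                    float(self.values[i, j]),
                    self.counts[(i, j)],
                )

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=self.sample_ids, columns=self.sample_ids
        )

    def to_long_tsv(self, path: str | Path) -> None:
        """Long-format export: id_a, id_b, d, n, ts, tv."""
        rows = [
            {
                "id_a": a,
                "id_b": b,
                "d": d,
                "n": c.compared_sites,
                "ts": c.transitions,
                "tv": c.transversions,
            }
            for a, b, d, c in self.iter_pairs()
        ]
        pd.DataFrame(rows).to_csv(path, sep="\t", index=False, float_format="%.10g")

    def to_phylip(self, path: str | Path) -> None:
        """PHYLIP square distance matrix (relaxed names, 6 d.p.)."""
        with open(path, "w") as fh:
            fh.write(f"{self.n}\n")
            for i, sid in enumerate(self.sample_ids):
                row = " ".join(f"{self.values[i, j]:.6f}" for j in range(self.n))
                fh.write(f"{sid}  {row}\n")


def distance_matrix(
    locus: AlignedLocus, on_saturation: Literal["error", "inf"] = "error"
) -> DistanceMatrix:
    """All pairwise K2P distances, with deletion applied per pair."""
    ids = locus.sample_ids
    encoded = [encode_sequence(r.sequence) for r in locus.records]
    return distance_matrix_from_encoded(ids, encoded, locus.length, on_saturation)


def distance_matrix_from_encoded(
    sample_ids: tuple[str, ...],
    encoded: list[np.ndarray],
    length: int,
    on_saturation: Literal["error", "inf"] = "error",
) -> DistanceMatrix:
    """Distance matrix from pre-encoded sequences (used by the bootstrap)."""
    n = len(sample_ids)
    values = np.zeros((n, n), dtype=float)
    counts: dict[tuple[int, int], SiteCounts] = {}
    for i in range(n):
        for j in range(i + 1, n):
            c = _count_encoded(encoded[i], encoded[j], length)
            d = k2p_distance(
                c, on_saturation, pair=(sample_ids[i], sample_ids[j])
            )
            values[i, j] = values[j, i] = d
            counts[(i, j)] = c
    return DistanceMatrix(tuple(sample_ids), values, counts)
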