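import numpy as np
import pytest

from barcodegap.distances import DistanceMatrix
from barcodegap.seqio import SampleMeta


@pytest.fixture
def study_metadata() -> list[SampleMeta]:
    """Twelve samples mirroring the medicinal-Gentiana study design:
    six species in the groups GL, JL, rhodantha and adulterant."""
    rows = [
        ("s01", "G. manshurica", "GL", "2005-2701C"),
        ("s02", "G. manshurica", "GL", "2005-2701D"),
        ("s03", "G. scabra", "GL", "2005-2702A"),
        ("s04", "G. scabra", "GL", "2005-2702B"),
        ("s05", "G. triflora", "GL", "2005-2703A"),
        ("s06", "G. triflora", "GL", "2005-2703B"),
        ("s07", "G. rigescens", "JL", "2005-2704A"),
        ("s08", "G. rigescens", "JL", "2005-2704B"),
        ("s09", "G. rhodantha", "rhodantha", "2005-2706A"),
        ("s10", "G. rhodantha", "rhodantha", "2005-2706B"),
        ("s11", "P. hexandrum", "adulterant", "ICM686"),
        ("s12", "P. hexandrum", "adulterant", "ICM2148"),
    ]
    return [
        SampleMeta(sid, species, group, voucher)
        for sid, species, group, voucher in rows
    ]


def matrix_from_dict(ids: list[str], dists: dict[tuple[str, str], float]) -> DistanceMatrix:
    """Build a DistanceMatrix directly from pairwise values (no alignments)."""
    n = len(ids)
    values = np.zeros((n, n))
    for i, a in enumerate(ids):
        for j, b in enumerate(ids):
            if i < j:
                d = dists.get((a, b), dists.get((b, a)))
                values[i, j] = values[j, i] = d
    return DistanceMatrix(tuple(ids), values, {})
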