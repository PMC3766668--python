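"""Reference data for the medicinal Gentiana / Podophyllum study system.

Four medicinal *Gentiana* species (the Guanlongdan trade group:
*G. manshurica*, *G. scabra*, *G. triflora*; and the Jianlongdan group:
*G. rigescens*) are commonly adulterated with *G. rhodantha* and the
toxic *Podophyllum hexandrum*.  Seven candidate barcode loci are in play:
the coding genes rbcL and matK, the chloroplast spacers trnH-psbA,
trnL-F and rpl36-rps8, the nuclear ITS, and the multi-copy 5S rRNA
intergenic spacer (sequenced clone-by-clone because its copies are not
homogeneous).

This module carries the community primer set for those loci, the matK
forward-primer binding-site survey of GenBank *Gentiana* records (in dot
notation against the primer), and the reported K2P divergence extremes
for the three standard group comparisons, so that ranking and primer
diagnostics can be exercised without network access.
"""

from __future__ import annotations

from .primer_scan import IUPAC_SETS, Primer

LOCI = ("rbcL", "matK", "trnH-psbA", "trnL-F", "rpl36-rps8", "ITS", "5S")

#: Community primer pairs per locus (name, 5'->3' sequence, orientation).
UNIVERSAL_PRIMERS: dict[str, tuple[Primer, Primer]] = {
    "rbcL": (
        Primer("rbcLaF", "ATGTCACCACAAACAGAGACTAAAGC", "forward"),
        Primer("rbcLaR", "GTAAAATCAAGTCCACCRCG", "reverse"),
    ),
    "matK": (
        Primer("3F_KIM_f", "CGTACAGTACTTTTGTGTTTACGAG", "forward"),
        Primer("1R_KIM_r", "ACCCAGTCCATCTGGAAATCTTGGTTC", "reverse"),
    ),
    "trnH-psbA": (
        Primer("trnHf", "CGCGCATGGTGGATTCACAATCC", "forward"),
        Primer("psbA3f", "GTTATGCATGAACGTAATGCTC", "reverse"),
    ),
    "trnL-F": (
        Primer("TabC", "CGAAATCGGTAGACGCTACG", "forward"),
        Primer("TabF", "ATTTGAACTGGTGACACGAG", "reverse"),
    ),
    "rpl36-rps8": (
        Primer("rpl36f", "CACAAATTTTACGAACGAAG", "forward"),
        Primer("rps8r", "TAATGACAGAYCGAGARGCTCGAC", "reverse"),
    ),
    "ITS": (
        Primer("ITS5", "GGAAGTAAAAGTCGTAACAAGG", "forward"),
        Primer("ITS4", "TCCTCCGCTTATTGATATGC", "reverse"),
    ),
    "5S": (
        Primer("S1", "GGATCCGTGCTTGGGCGAGAGTAGTA", "forward"),
        Primer("AS1", "GGATCCTTAGTGCTGGTATGATCGCA", "reverse"),
    ),
}

#: Replacement matK pair designed from the conserved region shared by the
#: available Gentiana and P. hexandrum sequences after the community pair
#: failed to amplify several samples.
MATK_GSC_PRIMERS: tuple[Primer, Primer] = (
    Primer("matK_GSC_F", "TATATATTGTATTCGATACAAAC", "forward"),
    Primer("matK_GSC_R", "TTCTACGAATATTGGAATTGGAA", "reverse"),
)

#: Dot-notation binding-site survey of the matK forward primer 3F KIM f
#: against GenBank Gentiana records: accession -> (species, pattern).
#: A dot marks a template base compatible with the primer; a letter is the
#: template base at a mismatch.
MATK_3F_KIM_F_SURVEY: dict[str, tuple[str, str]] = {
    "EF552125.1": ("Gentiana acaulis", "....T..A............C..G."),
    "EF552079.1": ("Gentiana bavarica", "....T..A............C..G."),
    "EF552126.1": ("Gentiana prostrata", "....T..A.T..........C..G."),
    "EF552124.1": ("Gentiana nivalis", "....T..A............C..G."),
    "EF552105.1": ("Gentiana verna", "....T..A............C..G."),
}


def reconstruct_template(primer: Primer, pattern: str) -> str:
    """Rebuild a binding-site template from a dot-notation pattern.

    Dots copy the primer base (for a degenerate code, its first listed
    base); letters are the template base at a mismatch.  Valid only for
    patterns whose dotted positions are genuinely compatible.
    """
    if len(pattern) != len(primer):
        raise ValueError("pattern length does not match primer length")
    out = []
    for p, c in zip(primer.sequence, pattern):
        if c == ".":
            out.append(sorted(IUPAC_SETS[p])[0] if p not in "ACGT" else p)
        else:
            out.append(c)
    return "".join(out)


#: Reported K2P divergence extremes per locus for the three standard
#: comparisons of the study system.  For each comparison:
#: ``min_inter`` is the minimum between-group divergence, ``max_intra``
#: the maximum intraspecific divergence among the species of the two
#: groups, and ``ranking`` the differentiation-power rank per locus.
REPORTED_DIVERGENCE: dict[str, dict[str, dict[str, float] | dict[str, int]]] = {
    "medicinal_vs_P_hexandrum": {
        "min_inter": {
            "rbcL": 0.0995, "matK": 0.3399, "trnH-psbA": 0.3908,
            "trnL-F": 0.3888, "rpl36-rps8": 0.2211, "ITS": 0.4781,
            "5S": 0.6154,
        },
        "max_intra": {
            "rbcL": 0.0018, "matK": 0.0042, "trnH-psbA": 0.0101,
            "trnL-F": 0.0026, "rpl36-rps8": 0.0033, "ITS": 0.0058,
            "5S": 0.0939,
        },
        "ranking": {
            "rbcL": 7, "matK": 5, "trnH-psbA": 3, "trnL-F": 4,
            "rpl36-rps8": 6, "ITS": 2, "5S": 1,
        },
    },
    "medicinal_vs_G_rhodantha": {
        "min_inter": {
            "rbcL": 0.0128, "matK": 0.0597, "trnH-psbA": 0.1349,
            "trnL-F": 0.1562, "rpl36-rps8": 0.0958, "ITS": 0.0862,
            "5S": 0.3098,
        },
        "max_intra": {
            "rbcL": 0.0018, "matK": 0.0042, "trnH-psbA": 0.0101,
            "trnL-F": 0.0026, "rpl36-rps8": 0.0033, "ITS": 0.0058,
            "5S": 0.0914,
        },
        "ranking": {
            "rbcL": 7, "matK": 6, "trnH-psbA": 3, "trnL-F": 2,
            "rpl36-rps8": 4, "ITS": 5, "5S": 1,
        },
    },
    "GL_vs_JL": {
        "min_inter": {
            "rbcL": 0.0109, "matK": 0.0521, "trnH-psbA": 0.0780,
            "trnL-F": 0.0332, "rpl36-rps8": 0.0392, "ITS": 0.0462,
            "5S": 0.4897,
        },
        "max_intra": {
            "rbcL": 0.0018, "matK": 0.0042, "trnH-psbA": 0.0101,
            "trnL-F": 0.0026, "rpl36-rps8": 0.0000, "ITS": 0.0043,
            "5S": 0.0914,
        },
        "ranking": {
            "rbcL": 7, "matK": 3, "trnH-psbA": 2, "trnL-F": 6,
            "rpl36-rps8": 5, "ITS": 4, "5S": 1,
        },
    },
}
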