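import warnings

import pytest

from barcodegap.errors import ConfigError, MetadataError
from barcodegap.gap_analysis import (
    GroupComparison,
    GroupDef,
    between_groups_min,
    compare_groups,
    diagnostic_sites,
    locus_summary,
    rank_loci,
    within_species_max,
)
from barcodegap.gentiana import LOCI, REPORTED_DIVERGENCE
from barcodegap.seqio import SampleMeta
from conftest import matrix_from_dict
from helpers import make_locus


def meta(*rows):
    return [SampleMeta(*r) for r in rows]


class TestWithinSpeciesMax:
    def test_identical_conspecifics_give_zero(self):
        m = matrix_from_dict(["x1", "x2"], {("x1", "x2"): 0.0})
        md = meta(("x1", "X", "g"), ("x2", "X", "g"))
        value, pairs = within_species_max(m, md, {"X"})
        assert value == 0.0 and pairs == 1

    def test_max_over_two_species(self):
        m = matrix_from_dict(
            ["x1", "x2", "y1", "y2"],
            {("x1", "x2"): 0.01, ("y1", "y2"): 0.03,
             ("x1", "y1"): 0.5, ("x1", "y2"): 0.5,
             ("x2", "y1"): 0.5, ("x2", "y2"): 0.5},
        )
        md = meta(("x1", "X", ""), ("x2", "X", ""), ("y1", "Y", ""), ("y2", "Y", ""))
        value, pairs = within_species_max(m, md, {"X", "Y"})
        assert value == 0.03 and pairs == 2

    def test_no_pair_warns_and_returns_zero(self):
        m = matrix_from_dict(["x1", "y1"], {("x1", "y1"): 0.2})
        md = meta(("x1", "X", ""), ("y1", "Y", ""))
        with pytest.warns(UserWarning, match="no within-species pair"):
            value, pairs = within_species_max(m, md, {"X", "Y"})
        assert value == 0.0 and pairs == 0

    def test_unknown_species_rejected(self):
        m = matrix_from_dict(["x1", "y1"], {("x1", "y1"): 0.2})
        md = meta(("x1", "X", ""), ("y1", "Y", ""))
        with pytest.raises(MetadataError, match="Z"):
            within_species_max(m, md, {"Z"})


class TestBetweenGroupsMin:
    def test_single_members(self):
        m = matrix_from_dict(["a", "b"], {("a", "b"): 0.2})
        md = meta(("a", "A", "ga"), ("b", "B", "gb"))
        assert between_groups_min(m, md, "ga", "gb") == 0.2

    def test_minimum_over_cross_product(self):
        dists = {("a1", "b1"): 0.11, ("a1", "b2"): 0.12,
                 ("a2", "b1"): 0.13, ("a2", "b2"): 0.14,
                 ("a1", "a2"): 0.0, ("b1", "b2"): 0.0}
        m = matrix_from_dict(["a1", "a2", "b1", "b2"], dists)
        md = meta(("a1", "A", "ga"), ("a2", "A", "ga"),
                  ("b1", "B", "gb"), ("b2", "B", "gb"))
        assert between_groups_min(m, md, "ga", "gb") == 0.11

    def test_overlapping_groups_rejected(self):
        m = matrix_from_dict(["a", "b"], {("a", "b"): 0.2})
        md = meta(("a", "A", "ga"), ("b", "B", "gb"))
        with pytest.raises(ConfigError, match="overlap"):
            between_groups_min(
                m, md, GroupDef("x", ("a", "b")), GroupDef("y", ("b",))
            )

    def test_empty_group_label_rejected(self):
        m = matrix_from_dict(["a", "b"], {("a", "b"): 0.2})
        md = meta(("a", "A", "ga"), ("b", "B", "gb"))
        with pytest.raises(ConfigError, match="nope"):
            between_groups_min(m, md, "nope", "gb")


class TestCompareGroups:
    def make(self, min_inter, max_intra):
        dists = {("a1", "a2"): max_intra, ("b1", "b2"): 0.0,
                 ("a1", "b1"): min_inter, ("a1", "b2"): min_inter,
                 ("a2", "b1"): min_inter + 0.01, ("a2", "b2"): min_inter + 0.01}
        m = matrix_from_dict(["a1", "a2", "b1", "b2"], dists)
        md = meta(("a1", "A", "ga"), ("a2", "A", "ga"),
                  ("b1", "B", "gb"), ("b2", "B", "gb"))
        return compare_groups(m, md, "ga", "gb", "toy")

    def test_clear_gap_succeeds(self):
        comp = self.make(0.0995, 0.0018)
        assert comp.success
        assert comp.min_interspecific == 0.0995
        assert comp.max_intraspecific == 0.0018

    def test_boundary_equality_fails(self):
        assert not self.make(0.05, 0.05).success

    def test_shared_haplotype_fails(self):
        assert not self.make(0.0, 0.0).success

    def test_intraspecific_restricted_to_compared_groups(self):
        # species C has huge intraspecific spread but is outside the comparison
        dists = {("a1", "a2"): 0.001, ("b1", "b2"): 0.001, ("c1", "c2"): 0.9}
        ids = ["a1", "a2", "b1", "b2", "c1", "c2"]
        for i, x in enumerate(ids):
            for y in ids[i + 1:]:
                dists.setdefault((x, y), 0.1)
        m = matrix_from_dict(ids, dists)
        md = meta(("a1", "A", "ga"), ("a2", "A", "ga"),
                  ("b1", "B", "gb"), ("b2", "B", "gb"),
                  ("c1", "C", ""), ("c2", "C", ""))
        comp = compare_groups(m, md, "ga", "gb", "toy")
        assert comp.max_intraspecific == 0.001
        assert comp.success

    def test_monotone_success(self):
        # raising the gap never flips success off
        assert not self.make(0.01, 0.02).success
        assert self.make(0.03, 0.02).success
        assert self.make(0.05, 0.02).success

    def test_samples_missing_from_matrix_are_excluded(self, caplog):
        dists = {("a1", "b1"): 0.2}
        m = matrix_from_dict(["a1", "b1"], dists)
        md = meta(("a1", "A", "ga"), ("a2", "A", "ga"), ("b1", "B", "gb"))
        comp = compare_groups(m, md, "ga", "gb", "toy")
        assert comp.group_a.sample_ids == ("a1",)
        assert comp.min_interspecific == 0.2


def comparison(locus, min_inter, pair=("ga", "gb")):
    return GroupComparison(
        locus_name=locus,
        group_a=GroupDef(pair[0], ("a",)),
        group_b=GroupDef(pair[1], ("b",)),
        min_interspecific=min_inter,
        max_intraspecific=0.0,
        success=True,
    )


class TestRankLoci:
    @pytest.mark.parametrize("comparison_key", sorted(REPORTED_DIVERGENCE))
    def test_reproduces_reported_rankings(self, comparison_key):
        """Descending min-between-group divergence reproduces the published
        differentiation-power rankings of the study system."""
        table = REPORTED_DIVERGENCE[comparison_key]
        comps = [comparison(locus, table["min_inter"][locus]) for locus in LOCI]
        ranked = rank_loci(comps)
        assert {c.locus_name: c.rank for c in ranked} == table["ranking"]

    def test_tie_shares_smaller_rank_and_skips_next(self):
        comps = [comparison("l1", 0.5), comparison("l2", 0.5), comparison("l3", 0.1)]
        ranked = rank_loci(comps)
        assert [c.rank for c in ranked] == [1, 1, 3]

    def test_order_invariance(self):
        comps = [comparison("l1", 0.1), comparison("l2", 0.3), comparison("l3", 0.2)]
        fwd = {c.locus_name: c.rank for c in rank_loci(comps)}
        rev = {c.locus_name: c.rank for c in rank_loci(comps[::-1])}
        assert fwd == rev == {"l1": 3, "l2": 1, "l3": 2}

    def test_output_is_permutation_consistent_with_order(self):
        comps = [comparison(f"l{i}", v) for i, v in enumerate([0.4, 0.1, 0.9, 0.2])]
        ranked = rank_loci(comps)
        assert {c.locus_name for c in ranked} == {c.locus_name for c in comps}
        by_rank = sorted(ranked, key=lambda c: c.rank)
        values = [c.min_interspecific for c in by_rank]
        assert values == sorted(values, reverse=True)

    def test_mixed_group_pairs_rejected(self):
        comps = [comparison("l1", 0.1), comparison("l2", 0.2, pair=("gx", "gy"))]
        with pytest.raises(ConfigError, match="mixed group pairs"):
            rank_loci(comps)

    def test_single_locus_rejected(self):
        with pytest.raises(ConfigError, match="at least two"):
            rank_loci([comparison("l1", 0.1)])


class TestDiagnosticSites:
    def test_fixed_difference_reported_one_based(self):
        locus = make_locus("toy", {
            "a1": "ACGTA", "a2": "ACGTA", "b1": "ACGTG", "b2": "ACGTG",
        })
        md = meta(("a1", "A", ""), ("a2", "A", ""), ("b1", "B", ""), ("b2", "B", ""))
        sites = diagnostic_sites(locus, md, {"A": ["a1", "a2"], "B": ["b1", "b2"]})
        assert len(sites) == 1
        assert sites[0].column == 5
        assert dict(sites[0].states) == {"A": "A", "B": "G"}

    def test_within_group_polymorphism_disqualifies(self):
        locus = make_locus("toy", {"a1": "A", "a2": "G", "b1": "T", "b2": "T"})
        md = meta(("a1", "A", ""), ("a2", "A", ""), ("b1", "B", ""), ("b2", "B", ""))
        assert diagnostic_sites(locus, md, {"A": ["a1", "a2"], "B": ["b1", "b2"]}) == []

    def test_gap_counts_as_a_state_and_ambiguity_is_missing(self):
        locus = make_locus("toy", {"a1": "A-", "a2": "AN", "b1": "AA", "b2": "AA"})
        md = meta(("a1", "A", ""), ("a2", "A", ""), ("b1", "B", ""), ("b2", "B", ""))
        sites = diagnostic_sites(locus, md, {"A": ["a1", "a2"], "B": ["b1", "b2"]})
        assert [s.column for s in sites] == [2]
        assert dict(sites[0].states) == {"A": "-", "B": "A"}

    def test_empty_group_rejected(self):
        locus = make_locus("toy", {"a1": "A", "b1": "G"})
        md = meta(("a1", "A", ""), ("b1", "B", ""))
        with pytest.raises(ConfigError, match="empty"):
            diagnostic_sites(locus, md, {"A": ["a1"], "B": []})


class TestLocusSummary:
    def test_gc_and_length_basics(self):
        locus = make_locus("toy", {"a": "GGCC", "b": "AT-T"})
        md = meta(("a", "A", ""), ("b", "B", ""))
        s = locus_summary(locus, md)
        assert s.avg_length == {"A": 4.0, "B": 3.0}
        assert s.gc_percent == {"A": 100.0, "B": 0.0}

    def test_mean_length_across_conspecifics(self):
        locus = make_locus("toy", {"a1": "ACGTA", "a2": "ACGT-"})
        md = meta(("a1", "A", ""), ("a2", "A", ""))
        s = locus_summary(locus, md)
        assert s.avg_length["A"] == pytest.approx(4.5)

    def test_ambiguity_excluded_from_gc(self):
        locus = make_locus("toy", {"a": "GCNN", "b": "ATNN"})
        md = meta(("a", "A", ""), ("b", "B", ""))
        s = locus_summary(locus, md)
        assert s.gc_percent == {"A": 100.0, "B": 0.0}
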