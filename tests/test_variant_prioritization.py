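"""The recessive-model filter cascade: per-filter behavior, order
invariance, audit-trail completeness, and end-to-end candidate recovery on
synthetic data."""

import itertools

import numpy as np
import pytest

from rohmap.errors import ValidationError
from rohmap.intervals import Segment, SegmentSet
from rohmap.formats_io import segment_from_display
from rohmap.variants import AnnotatedVariant
from rohmap.variant_prioritization import (
    CascadeConfig,
    filter_functional,
    filter_rare,
    filter_recessive_pattern,
    parental_segregation_check,
    restrict_to_regions,
    run_prioritization,
)


def mkvar(pos=100, csq="missense", afs=None, gts=None, chrom="chr6", ref="G", alt="A"):
    base_gts = {"FA": 1, "MO": 1, "P1": 2, "P2": 2, "P3": 2, "S1": 1, "S2": 0}
    if gts:
        base_gts.update(gts)
    return AnnotatedVariant(
        chrom, pos, ref, alt, gene="GX", consequence=csq,
        pop_afs={"ExAC": 0.001} if afs is None else afs,
        genotypes=base_gts,
    )


class TestFilterFunctional:
    @pytest.mark.parametrize(
        "csq,expected",
        [
            ("missense", True),
            ("splice_acceptor", True),
            ("frameshift", True),
            ("synonymous", False),
            ("intronic", False),
        ],
    )
    def test_consequence_classes(self, csq, expected):
        survivors, trails = filter_functional([mkvar(csq=csq)])
        assert bool(survivors) is expected

    def test_unannotated_fails_by_default_but_is_configurable(self):
        v = mkvar(csq=None)
        survivors, trails = filter_functional([v])
        assert not survivors
        assert trails[v.key].verdicts[0][2] == "unannotated"
        survivors, _ = filter_functional(
            [v], CascadeConfig(unannotated_policy="pass")
        )
        assert survivors


class TestFilterRare:
    def test_rare_in_all_databases_passes(self):
        v = mkvar(afs={"ExAC": 0.00014, "1KG": 0.0, "TOPMED": 0.0002})
        assert filter_rare([v])[0] == [v]

    def test_common_in_one_database_fails(self):
        # a 2.8%-frequency splice-type allele is excluded
        v = mkvar(afs={"ExAC": 0.028})
        assert filter_rare([v])[0] == []

    def test_boundary_is_strict(self):
        v = mkvar(afs={"ExAC": 0.01})
        assert filter_rare([v])[0] == []
        v2 = mkvar(afs={"ExAC": 0.0099999})
        assert filter_rare([v2])[0] == [v2]

    def test_missing_af_policy(self):
        v = mkvar(afs={})
        assert filter_rare([v])[0] == [v]  # absent everywhere: treat as rare
        assert (
            filter_rare([v], CascadeConfig(missing_af_policy="fail"))[0] == []
        )


class TestFilterRecessivePattern:
    def test_textbook_pattern_passes(self, family):
        v = mkvar()
        assert filter_recessive_pattern([v], family)[0] == [v]

    @pytest.mark.parametrize(
        "gts",
        [
            {"P3": 1},  # one affected only het
            {"S1": 2},  # unaffected hom-alt
            {"P2": -1},  # missing genotype in a required sample
            {"S2": -1},
        ],
    )
    def test_violations_fail(self, family, gts):
        v = mkvar(gts=gts)
        assert filter_recessive_pattern([v], family)[0] == []

    def test_absent_sample_is_an_error(self, family):
        v = mkvar()
        del v.genotypes["S2"]
        with pytest.raises(ValidationError):
            filter_recessive_pattern([v], family)


class TestRestrictToRegions:
    def test_table_membership(self):
        segs = SegmentSet([segment_from_display("chr6", 23_584_375, 26_148_311)])
        inside = mkvar(pos=25_000_000)
        outside = mkvar(pos=22_000_000)  # in the gap between array segments
        assert restrict_to_regions([inside, outside], segs)[0] == [inside]

    def test_empty_region_set_fails_all(self):
        assert restrict_to_regions([mkvar()], SegmentSet())[0] == []


class TestParentalSegregation:
    def test_both_parents_het_is_consistent(self, family):
        verdict, detail = parental_segregation_check(mkvar(), family)
        assert verdict == "consistent"

    def test_hom_parent_inconsistent(self, family):
        verdict, _ = parental_segregation_check(mkvar(gts={"FA": 2}), family)
        assert verdict == "inconsistent"

    def test_missing_parent_genotype_untestable(self, family):
        verdict, _ = parental_segregation_check(mkvar(gts={"MO": -1}), family)
        assert verdict == "untestable"


class TestRunPrioritization:
    def region(self):
        return SegmentSet([Segment("chr6", 0, 10_000_000)])

    def fixture_variants(self):
        return [
            mkvar(pos=100),  # the true candidate
            mkvar(pos=200, csq="synonymous"),  # fails functional
            mkvar(pos=300, afs={"ExAC": 0.2}),  # fails rare
            mkvar(pos=400, gts={"S1": 2}),  # fails recessive pattern
            mkvar(pos=20_000_000),  # fails region restriction
        ]

    def test_single_survivor_with_trails(self, family):
        report = run_prioritization(self.fixture_variants(), family, self.region())
        assert [v.pos for v in report.survivors] == [100]
        frame = report.to_frame()
        assert len(frame) == 5
        # trail completeness: every non-survivor has exactly one failing filter
        failed = frame[~frame["survived"]]
        assert (failed["failing_filter"] != "").all()
        assert report.segregation[report.survivors[0].key][0] == "consistent"

    def test_filter_order_permutation_invariance(self, family):
        """The filters are independent predicates: applying them in any order
        yields the same survivor set."""
        variants = self.fixture_variants()
        region = self.region()
        config = CascadeConfig()
        stages = {
            "functional": lambda vs: filter_functional(vs, config)[0],
            "rare": lambda vs: filter_rare(vs, config)[0],
            "recessive": lambda vs: filter_recessive_pattern(vs, family, config)[0],
            "region": lambda vs: restrict_to_regions(vs, region)[0],
        }
        reference = None
        for order in itertools.permutations(stages):
            vs = list(variants)
            for name in order:
                vs = stages[name](vs)
            keys = sorted(v.key for v in vs)
            if reference is None:
                reference = keys
            assert keys == reference

    def test_without_region_restriction_superset(self, family):
        region = self.region()
        strict = run_prioritization(self.fixture_variants(), family, region)
        loose = run_prioritization(
            self.fixture_variants(), family, None,
            CascadeConfig(require_region_overlap=False),
        )
        strict_keys = {v.key for v in strict.survivors}
        loose_keys = {v.key for v in loose.survivors}
        assert strict_keys <= loose_keys

    def test_empty_input(self, family):
        report = run_prioritization([], family, self.region())
        assert report.survivors == [] and report.trails == {}

    def test_not_evaluated_after_failure(self, family):
        v = mkvar(csq="synonymous")
        report = run_prioritization([v], family, self.region())
        statuses = dict(
            (name, status) for name, status, _ in report.trails[v.key].verdicts
        )
        assert statuses["functional"] == "fail"
        assert statuses["rare"] == "not-evaluated"
        assert statuses["region_overlap"] == "not-evaluated"


class TestEndToEndSynthetic:
    def test_planted_variant_is_sole_survivor(self, default_dataset):
        """The full discovery pipeline on the default synthetic family finds
        exactly the planted recessive variant."""
        from rohmap.autozygosity import detect_roh, shared_loh

        ds = default_dataset
        ped = ds.pedigree
        roh = {
            s: detect_roh(ds.panel, s)
            for s in ped.affected_ids + ped.unaffected_sibling_ids()
        }
        shared = shared_loh(roh, ped.affected_ids, ped.unaffected_sibling_ids())
        report = run_prioritization(ds.variants, ped, shared)
        assert [v.key for v in report.survivors] == [ds.truth.causal_variant.key]
        assert report.segregation[report.survivors[0].key][0] == "consistent"

    def test_decoy_failing_one_predicate_never_survives(self, default_dataset):
        """Negative controls: clones of the causal variant broken in exactly
        one predicate are each removed by the cascade."""
        import dataclasses

        ds = default_dataset
        truth = ds.truth.causal_variant
        decoys = [
            dataclasses.replace(truth, pos=truth.pos + 1, consequence="synonymous"),
            dataclasses.replace(truth, pos=truth.pos + 2, pop_afs={"ExAC": 0.3}),
            dataclasses.replace(
                truth, pos=truth.pos + 3,
                genotypes={**truth.genotypes, "P1": 1},
            ),
            dataclasses.replace(truth, pos=truth.pos + 4, chrom="chrZ"),
        ]
        from rohmap.autozygosity import detect_roh, shared_loh

        ped = ds.pedigree
        roh = {
            s: detect_roh(ds.panel, s)
            for s in ped.affected_ids + ped.unaffected_sibling_ids()
        }
        shared = shared_loh(roh, ped.affected_ids, ped.unaffected_sibling_ids())
        report = run_prioritization(
            list(ds.variants) + decoys, ped, shared
        )
        assert [v.key for v in report.survivors] == [truth.key]
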