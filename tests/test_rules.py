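"""Decision engine: triage composition, allele counting, versioned recall."""

import itertools

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from nbscreen import (
    AssayKind,
    Classification,
    CnvCall,
    CnvState,
    ConfigurationError,
    Marker,
    MarkerStatus,
    ReasonCode,
    RuleVersion,
    Zygosity,
    classify_first_tier,
    count_pathogenic_alleles,
    decide_historical_single_tier,
    default_cutoffs,
    decide_second_tier,
    rule_version_for_date,
    screen_sample,
)
from nbscreen.rules import GENE_PANELS

from .conftest import make_result, make_variant


def _cnv(state, sample_id="S1"):
    ratio = {CnvState.NORMAL: 1.0, CnvState.HET_DROPOUT: 0.5,
             CnvState.HOM_DROPOUT: 0.0, CnvState.INDETERMINATE: 0.72}[state]
    return CnvCall(sample_id=sample_id, copy_ratio=ratio, state=state, z_score=0.0)


class TestFirstTier:
    def test_borderline_citrulline_triggers_slc25a13_panel(self, cutoffs):
        outcome = classify_first_tier(make_result(CIT=27.0, C0=30.0), cutoffs)
        assert outcome.statuses[Marker.CIT] is MarkerStatus.SECOND_TIER
        assert outcome.statuses[Marker.C0] is MarkerStatus.NEGATIVE
        assert outcome.panel == frozenset({"SLC25A13"})

    def test_extreme_citrulline_recalls_without_genetics(self, cutoffs):
        outcome = classify_first_tier(make_result(CIT=55.0), cutoffs)
        assert outcome.statuses[Marker.CIT] is MarkerStatus.IMMEDIATE_RECALL
        assert outcome.panel == frozenset()

    def test_very_low_carnitine_recalls_immediately(self, cutoffs):
        outcome = classify_first_tier(make_result(C0=4.5), cutoffs)
        assert outcome.statuses[Marker.C0] is MarkerStatus.IMMEDIATE_RECALL

    def test_all_normal_is_all_negative(self, cutoffs):
        outcome = classify_first_tier(
            make_result(C0=30.0, CIT=12.0, C5DC=0.06, C5OH=0.25), cutoffs
        )
        assert all(s is MarkerStatus.NEGATIVE for s in outcome.statuses.values())
        assert outcome.panel == frozenset()

    def test_multi_marker_panel_is_union(self, cutoffs):
        outcome = classify_first_tier(
            make_result(CIT=27.0, C5DC=0.4, assay=AssayKind.MASSCHROM), cutoffs
        )
        assert outcome.panel == frozenset({"SLC25A13", "GCDH"})


class TestAlleleCounting:
    def test_hom_pathogenic_counts_two(self):
        v = make_variant("SLC25A13", Zygosity.HOM)
        assert count_pathogenic_alleles([v], {"SLC25A13"}) == 2

    def test_het_variant_plus_het_dropout_under_hotspot_rules(self):
        v = make_variant("SLC25A13", Zygosity.HET)
        count = count_pathogenic_alleles(
            [v], {"SLC25A13"}, cnv=_cnv(CnvState.HET_DROPOUT),
            rule_version=RuleVersion.V2023_05,
        )
        assert count == 2

    def test_dropout_ignored_before_hotspot_rules(self):
        v = make_variant("SLC25A13", Zygosity.HET)
        count = count_pathogenic_alleles(
            [v], {"SLC25A13"}, cnv=_cnv(CnvState.HET_DROPOUT),
            rule_version=RuleVersion.V2021_10,
        )
        assert count == 1

    def test_vus_never_counts(self):
        v = make_variant("SLC25A13", classification=Classification.VUS)
        assert count_pathogenic_alleles([v], {"SLC25A13"}) == 0

    def test_out_of_panel_gene_never_counts(self):
        v = make_variant("GCDH")
        assert count_pathogenic_alleles([v], {"SLC25A13"}) == 0

    def test_empty_variant_list_counts_cnv_only(self):
        count = count_pathogenic_alleles(
            [], {"SLC25A13"}, cnv=_cnv(CnvState.HOM_DROPOUT),
            rule_version=RuleVersion.V2023_05,
        )
        assert count == 2

    def test_matches_brute_force_enumeration(self):
        """Closed-form count equals a naive per-allele expansion over all
        genotype combinations of <=3 variants x zygosity x class x CNV state."""
        variant_space = list(
            itertools.product(
                ["SLC25A13", "GCDH"],
                list(Zygosity),
                [Classification.P, Classification.LP, Classification.VUS],
            )
        )
        cnv_space = [None] + [
            _cnv(s) for s in (CnvState.NORMAL, CnvState.HET_DROPOUT,
                              CnvState.HOM_DROPOUT, CnvState.INDETERMINATE)
        ]
        genes = frozenset({"SLC25A13"})
        for n_variants in range(0, 3):
            for combo in itertools.product(variant_space, repeat=n_variants):
                variants = [
                    make_variant(g, z, c, hgvs=f"c.{i}A>G")
                    for i, (g, z, c) in enumerate(combo)
                ]
                for cnv in cnv_space:
                    for version in RuleVersion:
                        # Independent oracle: expand every contributing allele
                        # into a list and take its length.
                        alleles = []
                        for g, z, c in combo:
                            if g in genes and c in (Classification.P, Classification.LP):
                                alleles.extend([g] * (2 if z is Zygosity.HOM else 1))
                        if version is RuleVersion.V2023_05 and cnv is not None:
                            if cnv.state is CnvState.HET_DROPOUT:
                                alleles.append("IVS16ins3kb")
                            if cnv.state is CnvState.HOM_DROPOUT:
                                alleles.extend(["IVS16ins3kb"] * 2)
                        assert count_pathogenic_alleles(
                            variants, genes, cnv=cnv, rule_version=version
                        ) == len(alleles)


class TestSecondTierDecision:
    @pytest.mark.parametrize(
        "value,count,version,expected",
        [
            # Borderline band: the initial rules recalled single-allele cases;
            # the refinement requires two alleles.
            (26.0, 1, RuleVersion.V2021_09, ReasonCode.GENOTYPE_POSITIVE),
            (26.0, 1, RuleVersion.V2021_10, ReasonCode.GENOTYPE_INSUFFICIENT),
            (26.0, 1, RuleVersion.V2023_05, ReasonCode.GENOTYPE_INSUFFICIENT),
            (26.0, 2, RuleVersion.V2021_10, ReasonCode.GENOTYPE_POSITIVE),
            (26.0, 0, RuleVersion.V2021_09, ReasonCode.GENOTYPE_INSUFFICIENT),
            # At >=35 μmol/L one allele suffices under every version.
            (36.0, 1, RuleVersion.V2021_09, ReasonCode.GENOTYPE_POSITIVE),
            (36.0, 1, RuleVersion.V2021_10, ReasonCode.GENOTYPE_POSITIVE),
            (35.0, 1, RuleVersion.V2023_05, ReasonCode.GENOTYPE_POSITIVE),
            (36.0, 0, RuleVersion.V2021_10, ReasonCode.GENOTYPE_INSUFFICIENT),
        ],
    )
    def test_citrulline_versioned_cutoffs(self, value, count, version, expected):
        assert decide_second_tier(Marker.CIT, value, count, version) is expected

    @pytest.mark.parametrize("marker,value", [
        (Marker.C0, 6.3), (Marker.C5DC, 0.18), (Marker.C5OH, 0.95),
    ])
    def test_other_markers_need_one_allele(self, marker, value):
        for version in RuleVersion:
            assert decide_second_tier(marker, value, 1, version) is (
                ReasonCode.GENOTYPE_POSITIVE
            )
            assert decide_second_tier(marker, value, 0, version) is (
                ReasonCode.GENOTYPE_INSUFFICIENT
            )

    def test_citrulline_outside_window_is_a_precondition_error(self):
        with pytest.raises(ConfigurationError, match="window"):
            decide_second_tier(Marker.CIT, 55.0, 2, RuleVersion.V2021_10)


class TestHistoricalSingleTier:
    @pytest.mark.parametrize(
        "markers,expected",
        [
            ({"CIT": 27.0}, False),  # borderline citrin case: missed
            ({"CIT": 26.0}, False),
            ({"CIT": 36.0}, True),
            ({"CIT": 35.0}, True),   # inclusive >=35
            ({"C0": 6.2}, True),     # inclusive <=6.2
            ({"C0": 6.3}, False),
            ({"C5DC": 0.20}, False),
            ({"C5DC": 0.35}, True),
            ({"C5OH": 0.78}, True),
        ],
    )
    def test_historical_cutoffs(self, cutoffs, markers, expected):
        assert decide_historical_single_tier(make_result(**markers), cutoffs) is expected


class TestScreenSample:
    def test_homozygous_citrin_case_recalled(self, cutoffs):
        decision = screen_sample(
            make_result(CIT=27.0),
            [make_variant("SLC25A13", Zygosity.HOM)],
            cutoffs=cutoffs,
            rule_version=RuleVersion.V2021_10,
        )
        assert decision.recall
        md = decision.markers[Marker.CIT]
        assert md.reason is ReasonCode.GENOTYPE_POSITIVE
        assert md.allele_count == 2
        assert "citrin deficiency" in decision.conditions

    def test_het_gcdh_case_recalled(self, cutoffs):
        decision = screen_sample(
            make_result(C5DC=0.18, assay=AssayKind.NEOBASE2),
            [make_variant("GCDH", Zygosity.HET)],
            cutoffs=cutoffs,
        )
        assert decision.recall
        assert decision.conditions == ("glutaric acidemia type I",)

    def test_no_pathogenic_alleles_no_recall(self, cutoffs):
        decision = screen_sample(make_result(CIT=26.0), [], cutoffs=cutoffs)
        assert not decision.recall
        assert decision.markers[Marker.CIT].reason is ReasonCode.GENOTYPE_INSUFFICIENT

    def test_immediate_recall_short_circuits_genetics(self, cutoffs):
        decision = screen_sample(make_result(CIT=60.0), [], cutoffs=cutoffs)
        assert decision.recall
        md = decision.markers[Marker.CIT]
        assert md.reason is ReasonCode.IMMEDIATE_BIOCHEMICAL
        assert md.allele_count is None

    def test_recall_flag_is_or_of_marker_decisions(self, cutoffs):
        decision = screen_sample(
            make_result(CIT=26.0, C0=6.3),
            [make_variant("SLC22A5", Zygosity.HET)],
            cutoffs=cutoffs,
        )
        assert decision.recall  # C0 positive even though CIT insufficient
        assert decision.markers[Marker.CIT].reason is ReasonCode.GENOTYPE_INSUFFICIENT
        assert decision.markers[Marker.C0].reason is ReasonCode.GENOTYPE_POSITIVE

    def test_missing_coverage_under_hotspot_rules_flags_review(self, cutoffs):
        decision = screen_sample(
            make_result(CIT=26.0),
            [make_variant("SLC25A13", Zygosity.HET)],
            cutoffs=cutoffs,
            rule_version=RuleVersion.V2023_05,
        )
        assert not decision.recall
        assert decision.needs_review

    def test_recall_invariant(self, cutoffs):
        decision = screen_sample(make_result(CIT=12.0), [], cutoffs=cutoffs)
        assert decision.recall == any(
            md.reason in (ReasonCode.IMMEDIATE_BIOCHEMICAL, ReasonCode.GENOTYPE_POSITIVE)
            for md in decision.markers.values()
        )


def _recall_for(value, n_alleles, version, cutoffs):
    variants = [
        make_variant("SLC25A13", Zygosity.HET, hgvs=f"c.{i}A>G")
        for i in range(n_alleles)
    ]
    return screen_sample(
        make_result(CIT=value), variants, cutoffs=cutoffs, rule_version=version
    ).recall


@settings(derandomize=True, max_examples=200, deadline=None)
@given(
    lo=st.floats(min_value=0.0, max_value=200.0),
    hi=st.floats(min_value=0.0, max_value=200.0),
    n_alleles=st.integers(min_value=0, max_value=3),
    version=st.sampled_from(list(RuleVersion)),
)
def test_recall_monotone_in_citrulline(lo, hi, n_alleles, version):
    """Raising citrulline while holding genotype fixed never cancels a recall."""
    lo, hi = sorted((lo, hi))
    cutoffs = default_cutoffs()
    if _recall_for(lo, n_alleles, version, cutoffs):
        assert _recall_for(hi, n_alleles, version, cutoffs)


@settings(derandomize=True, max_examples=200, deadline=None)
@given(
    lo=st.floats(min_value=0.0, max_value=50.0),
    hi=st.floats(min_value=0.0, max_value=50.0),
    n_alleles=st.integers(min_value=0, max_value=2),
)
def test_recall_antitone_in_free_carnitine(lo, hi, n_alleles):
    """Lowering C0 while holding genotype fixed never cancels a recall."""
    lo, hi = sorted((lo, hi))
    cutoffs = default_cutoffs()
    variants = [
        make_variant("SLC22A5", Zygosity.HET, hgvs=f"c.{i}A>G")
        for i in range(n_alleles)
    ]

    def recall(v):
        return screen_sample(make_result(C0=v), variants, cutoffs=cutoffs).recall

    if recall(hi):
        assert recall(lo)


@settings(derandomize=True, max_examples=200, deadline=None)
@given(
    value=st.floats(min_value=0.0, max_value=200.0),
    n_alleles=st.integers(min_value=0, max_value=3),
)
def test_refined_rules_only_remove_recalls(value, n_alleles):
    """Every sample recalled under V2021_10 is also recalled under V2021_09."""
    cutoffs = default_cutoffs()
    if _recall_for(value, n_alleles, RuleVersion.V2021_10, cutoffs):
        assert _recall_for(value, n_alleles, RuleVersion.V2021_09, cutoffs)


def test_rule_version_date_mapping():
    import datetime

    assert rule_version_for_date(datetime.date(2021, 9, 15)) is RuleVersion.V2021_09
    assert rule_version_for_date(datetime.date(2021, 10, 1)) is RuleVersion.V2021_10
    assert rule_version_for_date(datetime.date(2022, 6, 1)) is RuleVersion.V2021_10
    assert rule_version_for_date(datetime.date(2023, 5, 1)) is RuleVersion.V2023_05


def test_gene_panels_are_disjoint():
    seen = set()
    for genes in GENE_PANELS.values():
        assert not (genes & seen)
        seen |= genes
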