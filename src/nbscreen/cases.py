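"""Replay of the programme's seven second-tier recalled cases.

The first-year experience of the screening programme this package models
produced seven screen-positive newborns: three true positives (two citrin
deficiency, one carnitine uptake defect) and four carriers recalled as
false positives (two citrin-deficiency carriers in the first month, before
the borderline-band rule was tightened; one CUD carrier; one GA1 carrier).
Their published profiles — first-tier analyte values plus second-tier
genetic findings — serve as a worked end-to-end validation set for the
decision engine.

Each case is replayed through :func:`nbscreen.rules.count_pathogenic_alleles`
and :func:`nbscreen.rules.decide_second_tier` with the rule version in
force in its era.  The profiles are fed directly into the second-tier
decision with their recorded indications rather than re-deriving first-tier
triage: case ``C0-1`` was worked up for low free carnitine at a printed C0
of 6.9 μmol/L, just above the configured 6.5 window bound, so its triage
cannot be reconstructed from the cutoffs alone.

One detail matters for ``Cit-2``: with sequence analysis alone the case has
a single detectable P allele and screens negative in the borderline band;
only the later hotspot exon-17 dropout screening (rule version V2023_05)
supplies the second allele.  The replay encodes that era's rules, with the
het dropout call attached.
"""

from __future__ import annotations

from dataclasses import dataclass

from .cnv import CnvCall, CnvState
from .cutoffs import AssayKind, Marker, MarkerStatus
from .rules import (
    GENE_PANELS,
    MARKER_CONDITIONS,
    Classification,
    MarkerDecision,
    ReasonCode,
    RuleVersion,
    ScreeningDecision,
    VariantCall,
    count_pathogenic_alleles,
    decide_second_tier,
)

_P = Classification.P
_HET = "HET"
_HOM = "HOM"


@dataclass(frozen=True)
class RecalledCase:
    """One recalled newborn's profile: biochemistry, genetics, era, truth."""

    case_id: str
    assay: AssayKind
    #: analyte values (μmol/L) with the markers that indicated second-tier
    indications: dict[Marker, float]
    variants: tuple[VariantCall, ...]
    #: exon-17 dropout state, when hotspot screening applied
    cnv_state: CnvState | None
    rule_version: RuleVersion
    affected: bool
    condition: str


def _v(case_id: str, gene: str, hgvs: str, zygosity: str) -> VariantCall:
    from .rules import Zygosity

    return VariantCall(case_id, gene, hgvs, Zygosity(zygosity), _P)


def recalled_cases() -> tuple[RecalledCase, ...]:
    """The seven recalled-case profiles with era-appropriate rule versions."""
    return (
        RecalledCase(
            case_id="Cit-1",
            assay=AssayKind.MASSCHROM,
            indications={Marker.CIT: 27.0},
            variants=(_v("Cit-1", "SLC25A13", "c.852_855del", _HOM),),
            cnv_state=None,
            rule_version=RuleVersion.V2021_10,
            affected=True,
            condition="citrin deficiency",
        ),
        RecalledCase(
            case_id="Cit-2",
            assay=AssayKind.MASSCHROM,
            indications={Marker.CIT: 26.0},
            variants=(_v("Cit-2", "SLC25A13", "c.1311+1G>A", _HET),),
            cnv_state=CnvState.HET_DROPOUT,
            rule_version=RuleVersion.V2023_05,
            affected=True,
            condition="citrin deficiency",
        ),
        RecalledCase(
            case_id="Cit-3",
            assay=AssayKind.MASSCHROM,
            indications={Marker.CIT: 26.0},
            variants=(_v("Cit-3", "SLC25A13", "c.615+5G>A", _HET),),
            cnv_state=None,
            rule_version=RuleVersion.V2021_09,
            affected=False,
            condition="citrin deficiency",
        ),
        RecalledCase(
            case_id="Cit-4",
            assay=AssayKind.MASSCHROM,
            indications={Marker.CIT: 26.0},
            variants=(_v("Cit-4", "SLC25A13", "c.615+5G>A", _HET),),
            cnv_state=None,
            rule_version=RuleVersion.V2021_09,
            affected=False,
            condition="citrin deficiency",
        ),
        RecalledCase(
            case_id="C0-1",
            assay=AssayKind.MASSCHROM,
            indications={Marker.C0: 6.9, Marker.CIT: 26.0},
            variants=(
                _v("C0-1", "SLC22A5", "c.51C>G", _HET),
                _v("C0-1", "SLC22A5", "c.1400C>G", _HET),
            ),
            cnv_state=None,
            rule_version=RuleVersion.V2021_10,
            affected=True,
            condition="carnitine uptake defect",
        ),
        RecalledCase(
            case_id="C0-2",
            assay=AssayKind.MASSCHROM,
            indications={Marker.C0: 6.3},
            variants=(_v("C0-2", "SLC22A5", "c.1400C>G", _HET),),
            cnv_state=None,
            rule_version=RuleVersion.V2021_10,
            affected=False,
            condition="carnitine uptake defect",
        ),
        RecalledCase(
            case_id="C5DC-1",
            assay=AssayKind.NEOBASE2,
            indications={Marker.C5DC: 0.18},
            variants=(_v("C5DC-1", "GCDH", "c.1156C>T", _HET),),
            cnv_state=None,
            rule_version=RuleVersion.V2021_10,
            affected=False,
            condition="glutaric acidemia type I",
        ),
    )


def replay_case(case: RecalledCase) -> ScreeningDecision:
    """Run one case's recorded indications through the second-tier decision."""
    markers: dict[Marker, MarkerDecision] = {}
    cnv_call = None
    if case.cnv_state is not None:
        cnv_call = CnvCall(
            sample_id=case.case_id,
            copy_ratio=0.5 if case.cnv_state is CnvState.HET_DROPOUT else 0.0,
            state=case.cnv_state,
            z_score=float("nan"),
        )
    for marker, value in case.indications.items():
        genes = GENE_PANELS[marker]
        count = count_pathogenic_alleles(
            case.variants,
            genes,
            cnv=cnv_call if marker is Marker.CIT else None,
            rule_version=case.rule_version,
        )
        reason = decide_second_tier(marker, value, count, case.rule_version)
        markers[marker] = MarkerDecision(
            marker=marker,
            value=value,
            status=MarkerStatus.SECOND_TIER,
            reason=reason,
            allele_count=count,
            conditions=MARKER_CONDITIONS[marker]
            if reason is ReasonCode.GENOTYPE_POSITIVE
            else (),
        )
    return ScreeningDecision(
        sample_id=case.case_id,
        rule_version=case.rule_version,
        markers=markers,
        cnv=cnv_call,
    )


def replay_all() -> tuple[dict[str, ScreeningDecision], dict[str, bool]]:
    """Replay every recalled case; returns (decisions, affected-truth)."""
    decisions: dict[str, ScreeningDecision] = {}
    truth: dict[str, bool] = {}
    for case in recalled_cases():
        decisions[case.case_id] = replay_case(case)
        truth[case.case_id] = case.affected
    return decisions, truth
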