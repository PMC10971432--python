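"""Two-tier newborn-screening decision engine.

The screening algorithm modelled here reflexes borderline first-tier
biochemistry (tandem-MS analytes from a dried blood spot) to a targeted
gene-panel sequencing test, and recalls a newborn as screen-positive only
when the genotype corroborates the biochemistry:

1.  *First tier* — each measured analyte is triaged against its assay's
    cutoffs into NEGATIVE / SECOND_TIER / IMMEDIATE_RECALL
    (:func:`classify_first_tier`).  Extreme values (C0 < 5.0 μmol/L,
    citrulline > 50 μmol/L) recall immediately without genetics.
2.  *Second tier* — for each SECOND_TIER marker, the variants from the
    panel are filtered to the marker's condition genes, pathogenic and
    likely-pathogenic (P/LP) alleles are counted
    (:func:`count_pathogenic_alleles`, optionally including a hotspot
    copy-number dropout call in *SLC25A13*), and the versioned genotyping
    cutoff decides recall (:func:`decide_second_tier`).

Citrulline is the special case: its genotyping cutoff depends on the
analyte value (≥1 P/LP allele suffices at ≥35 μmol/L, whereas the
borderline 25–<35 μmol/L band requires ≥2 alleles under every rule version
except the initial one), because the borderline band is heavily populated
by citrin-deficiency carriers.

:func:`screen_sample` composes the full per-sample pipeline and
:func:`decide_historical_single_tier` reproduces the pre-NGS single-tier
rule for comparison.
"""

from __future__ import annotations

import datetime
import enum
import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from .cnv import AmpliconCoverage, CnvCall, CnvState, CnvThresholds, CoverageReference, call_exon17
from .cutoffs import AssayKind, CutoffProfile, Marker, MarkerStatus, default_cutoffs
from .errors import ConfigurationError

# Marker -> condition gene panel.  Panels are disjoint by design: each gene's
# condition is screened through exactly one analyte.
GENE_PANELS: dict[Marker, frozenset[str]] = {
    Marker.C0: frozenset({"SLC22A5"}),
    Marker.CIT: frozenset({"SLC25A13"}),
    Marker.C5DC: frozenset({"GCDH"}),
    Marker.C5OH: frozenset({"ACAT1", "HLCS", "HMGCL"}),
}

GENE_CONDITIONS: dict[str, str] = {
    "SLC22A5": "carnitine uptake defect",
    "SLC25A13": "citrin deficiency",
    "GCDH": "glutaric acidemia type I",
    "ACAT1": "beta-ketothiolase deficiency",
    "HLCS": "holocarboxylase synthetase deficiency",
    "HMGCL": "3-hydroxy-3-methylglutaryl-CoA lyase deficiency",
}

# The C5OH analyte cannot discriminate its three conditions, so a C5OH recall
# carries all three candidate labels.
MARKER_CONDITIONS: dict[Marker, tuple[str, ...]] = {
    marker: tuple(sorted(GENE_CONDITIONS[g] for g in genes))
    for marker, genes in GENE_PANELS.items()
}


class Zygosity(enum.Enum):
    HET = "HET"
    HOM = "HOM"

    @property
    def allele_count(self) -> int:
        return 2 if self is Zygosity.HOM else 1


class Classification(enum.Enum):
    """ACMG-style variant classification, consumed as input."""

    P = "P"
    LP = "LP"
    VUS = "VUS"
    OTHER = "OTHER"

    @property
    def is_reportable(self) -> bool:
        return self in (Classification.P, Classification.LP)


class RuleVersion(enum.Enum):
    """Dated configuration of the citrulline genotyping cutoff.

    * ``V2021_09`` — initial rules: one P/LP allele recalls even in the
      borderline citrulline band (25–<35 μmol/L).
    * ``V2021_10`` — refinement: the borderline band requires two P/LP
      alleles, to stop recalling carriers.
    * ``V2023_05`` — additionally counts a het/hom exon-17 allelic-dropout
      CNV call as one/two pathogenic *SLC25A13* alleles (hotspot
      IVS16ins3kb screening).
    """

    V2021_09 = "V2021_09"
    V2021_10 = "V2021_10"
    V2023_05 = "V2023_05"


def rule_version_for_date(day: datetime.date) -> RuleVersion:
    """Convenience mapping from a sampling date to the rule version in force."""
    if day < datetime.date(2021, 10, 1):
        return RuleVersion.V2021_09
    if day < datetime.date(2023, 5, 1):
        return RuleVersion.V2021_10
    return RuleVersion.V2023_05


class ReasonCode(enum.Enum):
    NEGATIVE = "NEGATIVE"
    IMMEDIATE_BIOCHEMICAL = "IMMEDIATE_BIOCHEMICAL"
    GENOTYPE_POSITIVE = "GENOTYPE_POSITIVE"
    GENOTYPE_INSUFFICIENT = "GENOTYPE_INSUFFICIENT"


@dataclass(frozen=True)
class BiochemicalResult:
    """One newborn's first-tier analyte panel (μmol/L), possibly partial."""

    sample_id: str
    assay: AssayKind
    values: Mapping[Marker, float]

    def __post_init__(self) -> None:
        for marker, value in self.values.items():
            if not isinstance(marker, Marker):
                raise ConfigurationError(f"unknown marker {marker!r}")
            if not math.isfinite(value) or value < 0:
                raise ConfigurationError(
                    f"{self.sample_id}: {marker.value} value {value!r} must be "
                    "finite and non-negative"
                )


@dataclass(frozen=True)
class VariantCall:
    """A classified sequence variant in a panel gene."""

    sample_id: str
    gene: str
    hgvs: str
    zygosity: Zygosity
    classification: Classification


@dataclass(frozen=True)
class TriageOutcome:
    sample_id: str
    statuses: Mapping[Marker, MarkerStatus]
    panel: frozenset[str]


@dataclass(frozen=True)
class MarkerDecision:
    """Outcome for one triggered (or measured) marker."""

    marker: Marker
    value: float
    status: MarkerStatus
    reason: ReasonCode
    allele_count: int | None = None
    conditions: tuple[str, ...] = ()
    needs_review: bool = False

    @property
    def positive(self) -> bool:
        return self.reason in (
            ReasonCode.IMMEDIATE_BIOCHEMICAL,
            ReasonCode.GENOTYPE_POSITIVE,
        )


@dataclass(frozen=True)
class ScreeningDecision:
    """End-to-end decision for one sample under one rule version."""

    sample_id: str
    rule_version: RuleVersion
    markers: Mapping[Marker, MarkerDecision]
    cnv: CnvCall | None = None

    @property
    def recall(self) -> bool:
        return any(d.positive for d in self.markers.values())

    @property
    def needs_review(self) -> bool:
        return any(d.needs_review for d in self.markers.values())

    @property
    def conditions(self) -> tuple[str, ...]:
        out: list[str] = []
        for d in self.markers.values():
            if d.positive:
                out.extend(c for c in d.conditions if c not in out)
        return tuple(out)

    @property
    def triggered_markers(self) -> tuple[Marker, ...]:
        return tuple(
            m
            for m, d in self.markers.items()
            if d.status is MarkerStatus.SECOND_TIER
        )


# ---------------------------------------------------------------------------
# Tier 1


def classify_first_tier(
    result: BiochemicalResult, cutoffs: CutoffProfile | None = None
) -> TriageOutcome:
    """Triage every measured marker and collect the triggered gene panel.

    Markers absent from the result are skipped; the triggered panel is the
    union of the panels of all SECOND_TIER markers (IMMEDIATE_RECALL markers
    contribute nothing — they bypass genetics).
    """
    cutoffs = cutoffs if cutoffs is not None else default_cutoffs()
    statuses: dict[Marker, MarkerStatus] = {}
    panel: set[str] = set()
    for marker, value in result.values.items():
        mc = cutoffs.for_marker(marker, result.assay)
        status = mc.classify(value)
        statuses[marker] = status
        if status is MarkerStatus.SECOND_TIER:
            panel |= GENE_PANELS[marker]
    return TriageOutcome(
        sample_id=result.sample_id, statuses=statuses, panel=frozenset(panel)
    )


def decide_historical_single_tier(
    result: BiochemicalResult, cutoffs: CutoffProfile | None = None
) -> bool:
    """Recall decision under the pre-NGS single-tier rule.

    True iff any measured marker crosses its historical cutoff
    (C0 ≤ 6.2, citrulline ≥ 35, C5DC ≥ 0.35, C5OH ≥ 0.78 μmol/L).
    """
    cutoffs = cutoffs if cutoffs is not None else default_cutoffs()
    return any(
        cutoffs.historical_for(marker).crossed(value)
        for marker, value in result.values.items()
    )


# ---------------------------------------------------------------------------
# Tier 2


def count_pathogenic_alleles(
    variants: Iterable[VariantCall],
    genes: frozenset[str] | set[str],
    cnv: CnvCall | None = None,
    rule_version: RuleVersion = RuleVersion.V2021_10,
) -> int:
    """Count P/LP alleles in ``genes``: HOM contributes 2, HET 1, VUS/OTHER 0.

    Under ``V2023_05`` a heterozygous exon-17 dropout call adds one
    *SLC25A13* allele and a homozygous dropout adds two; earlier rule
    versions ignore the CNV call.  Two het variants in one gene count as two
    alleles without requiring phase (screening errs toward recall).
    """
    count = sum(
        v.zygosity.allele_count
        for v in variants
        if v.gene in genes and v.classification.is_reportable
    )
    if (
        rule_version is RuleVersion.V2023_05
        and cnv is not None
        and "SLC25A13" in genes
    ):
        if cnv.state is CnvState.HET_DROPOUT:
            count += 1
        elif cnv.state is CnvState.HOM_DROPOUT:
            count += 2
    return count


def decide_second_tier(
    marker: Marker,
    value: float,
    allele_count: int,
    rule_version: RuleVersion = RuleVersion.V2021_10,
) -> ReasonCode:
    """Genotyping cutoff for one second-tier marker.

    For C0/C5DC/C5OH one P/LP allele is positive.  For citrulline the
    cutoff is value-dependent: ≥1 allele at ≥35 μmol/L, ≥2 alleles in the
    borderline 25–<35 band — except under the initial ``V2021_09`` rules,
    where one allele sufficed in the borderline band too.
    """
    if allele_count < 0:
        raise ConfigurationError("allele_count must be non-negative")
    if marker is Marker.CIT:
        # Citrulline is the only marker whose value enters the genotype rule,
        # so it is the only one whose second-tier window is enforced here.
        if not (25.0 <= value <= 50.0):
            raise ConfigurationError(
                f"citrulline {value} μmol/L is outside the second-tier window "
                "(25–50); it should not have reached the genotype decision"
            )
        if value >= 35.0:
            positive = allele_count >= 1
        elif rule_version is RuleVersion.V2021_09:
            positive = allele_count >= 1
        else:
            positive = allele_count >= 2
    else:
        positive = allele_count >= 1
    return ReasonCode.GENOTYPE_POSITIVE if positive else ReasonCode.GENOTYPE_INSUFFICIENT


def _cit_could_flip_with_cnv(value: float, allele_count: int) -> bool:
    # Would a hotspot CNV call (+1 or +2 alleles) change a non-positive
    # citrulline decision?  Used to flag samples for manual review when
    # coverage is unavailable under V2023_05.
    required = 1 if value >= 35.0 else 2
    return allele_count < required and allele_count + 2 >= required


def screen_sample(
    result: BiochemicalResult,
    variants: Sequence[VariantCall] = (),
    coverage: AmpliconCoverage | None = None,
    cutoffs: CutoffProfile | None = None,
    rule_version: RuleVersion = RuleVersion.V2021_10,
    *,
    cnv_reference: CoverageReference | None = None,
    cnv_thresholds: CnvThresholds | None = None,
) -> ScreeningDecision:
    """Run the full two-tier algorithm for one sample.

    Immediate-recall markers short-circuit genetics for that marker; every
    SECOND_TIER marker gets an independent gene-panel decision and the recall
    flag is their OR.  When ``rule_version`` is ``V2023_05`` and the
    citrulline band is triggered, the exon-17 dropout caller runs on
    ``coverage`` against ``cnv_reference``; if either is missing and a CNV
    call could have changed the decision, the sample is flagged
    ``needs_review`` rather than silently decided.
    """
    cutoffs = cutoffs if cutoffs is not None else default_cutoffs()
    triage = classify_first_tier(result, cutoffs)

    cnv_call: CnvCall | None = None
    if (
        rule_version is RuleVersion.V2023_05
        and coverage is not None
        and cnv_reference is not None
        and triage.statuses.get(Marker.CIT) is MarkerStatus.SECOND_TIER
    ):
        cnv_call = call_exon17(coverage, cnv_reference, cnv_thresholds)

    decisions: dict[Marker, MarkerDecision] = {}
    for marker, status in triage.statuses.items():
        value = result.values[marker]
        if status is MarkerStatus.IMMEDIATE_RECALL:
            decisions[marker] = MarkerDecision(
                marker=marker,
                value=value,
                status=status,
                reason=ReasonCode.IMMEDIATE_BIOCHEMICAL,
                conditions=MARKER_CONDITIONS[marker],
            )
            continue
        if status is MarkerStatus.NEGATIVE:
            decisions[marker] = MarkerDecision(
                marker=marker, value=value, status=status, reason=ReasonCode.NEGATIVE
            )
            continue
        genes = GENE_PANELS[marker]
        cnv_for_marker = cnv_call if marker is Marker.CIT else None
        count = count_pathogenic_alleles(
            variants, genes, cnv=cnv_for_marker, rule_version=rule_version
        )
        reason = decide_second_tier(marker, value, count, rule_version)
        needs_review = (
            marker is Marker.CIT
            and rule_version is RuleVersion.V2023_05
            and cnv_call is None
            and reason is not ReasonCode.GENOTYPE_POSITIVE
            and _cit_could_flip_with_cnv(value, count)
        )
        decisions[marker] = MarkerDecision(
            marker=marker,
            value=value,
            status=status,
            reason=reason,
            allele_count=count,
            conditions=MARKER_CONDITIONS[marker] if reason is ReasonCode.GENOTYPE_POSITIVE else (),
            needs_review=needs_review,
        )
    return ScreeningDecision(
        sample_id=result.sample_id,
        rule_version=rule_version,
        markers=decisions,
        cnv=cnv_call,
    )
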