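"""Allelic-dropout copy-number caller for the *SLC25A13* exon-17 amplicon.

The common ~3-kb intronic insertion allele IVS16ins3kb of *SLC25A13*
destroys the binding context of the exon-17 amplicon in an amplicon panel,
so the allele simply fails to amplify.  A heterozygous insertion therefore
halves the exon-17 read depth relative to expectation and a homozygous
insertion abolishes it; no other amplicon is affected.  The caller turns
that signature into a copy-ratio test:

1.  each sample's per-amplicon depths are normalised by the sample's median
    depth, with the exon-17 amplicon *excluded from the median* so a genuine
    dropout cannot depress its own baseline (:func:`normalize_sample`);
2.  a reference of per-amplicon normalised means/SDs is built from control
    samples (:func:`build_reference`);
3.  the copy ratio is the sample's normalised exon-17 depth over the
    control mean, banded into NORMAL (~1), HET_DROPOUT (~0.5),
    HOM_DROPOUT (~0) or INDETERMINATE (:func:`call_exon17`).

Ratios in no band are surfaced as INDETERMINATE for manual review — a
screening pipeline must flag, never force, an ambiguous call.  The whole
procedure is invariant to rescaling a sample's depths, so it is insensitive
to per-run yield differences.
"""

from __future__ import annotations

import enum
import math
import statistics
from dataclasses import dataclass
from typing import Mapping, Sequence

from .errors import ConfigurationError, DegenerateInputError, SchemaError

#: Target label that marks the dropout-sensitive amplicon.
EXON17_TARGET = "SLC25A13_ex17"

#: Minimum amplicons per sample for a stable median normalisation.
MIN_AMPLICONS = 8


@dataclass(frozen=True)
class AmpliconRecord:
    amplicon_id: str
    gene: str
    target: str
    depth: int

    def __post_init__(self) -> None:
        if self.depth < 0:
            raise SchemaError(
                f"amplicon {self.amplicon_id}: depth must be non-negative"
            )


@dataclass(frozen=True)
class AmpliconCoverage:
    """Raw per-amplicon read depths for one sample.

    Exactly one amplicon must carry the exon-17 target label.
    """

    sample_id: str
    records: tuple[AmpliconRecord, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "records", tuple(self.records))
        ids = [r.amplicon_id for r in self.records]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise SchemaError(
                f"{self.sample_id}: duplicate amplicon ids {dupes}"
            )
        n_ex17 = sum(r.target == EXON17_TARGET for r in self.records)
        if n_ex17 != 1:
            raise SchemaError(
                f"{self.sample_id}: expected exactly one '{EXON17_TARGET}' "
                f"amplicon, found {n_ex17}"
            )

    @property
    def exon17(self) -> AmpliconRecord:
        return next(r for r in self.records if r.target == EXON17_TARGET)

    def amplicon_ids(self) -> frozenset[str]:
        return frozenset(r.amplicon_id for r in self.records)


@dataclass(frozen=True)
class CoverageReference:
    """Per-amplicon normalised-depth statistics across control samples."""

    mean: Mapping[str, float]
    sd: Mapping[str, float]
    n_controls: int
    exon17_amplicon_id: str
    exon17_mean_raw_depth: float

    def __post_init__(self) -> None:
        if self.n_controls < 2:
            raise ConfigurationError(
                f"coverage reference needs >= 2 controls, got {self.n_controls}"
            )
        for amp, m in self.mean.items():
            if m <= 0:
                raise ConfigurationError(
                    f"reference mean for amplicon {amp} must be > 0, got {m}"
                )


class CnvState(enum.Enum):
    NORMAL = "NORMAL"
    HET_DROPOUT = "HET_DROPOUT"
    HOM_DROPOUT = "HOM_DROPOUT"
    INDETERMINATE = "INDETERMINATE"


@dataclass(frozen=True)
class CnvThresholds:
    """Copy-ratio bands for the exon-17 call.

    Defaults centre on the theoretical ratios 1 / 0.5 / 0 with symmetric
    noise margins; ``min_control_depth`` guards against calling on a
    low-coverage reference, where the ratio estimate is unstable.
    """

    hom_max: float = 0.15  # ratio < hom_max        -> HOM_DROPOUT
    het_low: float = 0.35  # het_low <= r <= het_high -> HET_DROPOUT
    het_high: float = 0.65
    normal_min: float = 0.80  # ratio >= normal_min  -> NORMAL
    min_control_depth: float = 100.0

    def __post_init__(self) -> None:
        ok = (
            0.0 <= self.hom_max <= self.het_low <= self.het_high < self.normal_min
        )
        if not ok:
            raise ConfigurationError(
                "CNV bands must satisfy 0 <= hom_max <= het_low <= het_high "
                f"< normal_min; got {self}"
            )
        if self.min_control_depth < 0:
            raise ConfigurationError("min_control_depth must be non-negative")

    def state_for(self, ratio: float) -> CnvState:
        if ratio < self.hom_max:
            return CnvState.HOM_DROPOUT
        if self.het_low <= ratio <= self.het_high:
            return CnvState.HET_DROPOUT
        if ratio >= self.normal_min:
            return CnvState.NORMAL
        return CnvState.INDETERMINATE


@dataclass(frozen=True)
class CnvCall:
    sample_id: str
    copy_ratio: float
    state: CnvState
    z_score: float


def normalize_sample(coverage: AmpliconCoverage) -> dict[str, float]:
    """Per-amplicon depths divided by the sample median depth.

    The exon-17 amplicon is excluded from the median so that a dropout in
    the amplicon under test cannot bias its own baseline; the median of the
    remaining normalised depths is exactly 1.
    """
    if len(coverage.records) < MIN_AMPLICONS:
        raise DegenerateInputError(
            f"{coverage.sample_id}: need >= {MIN_AMPLICONS} amplicons for "
            f"normalisation, got {len(coverage.records)}"
        )
    others = [r.depth for r in coverage.records if r.target != EXON17_TARGET]
    med = statistics.median(others)
    if med <= 0:
        raise DegenerateInputError(
            f"{coverage.sample_id}: median depth is {med}; coverage too low "
            "or all-zero"
        )
    return {r.amplicon_id: r.depth / med for r in coverage.records}


def build_reference(controls: Sequence[AmpliconCoverage]) -> CoverageReference:
    """Mean and SD of normalised depths per amplicon across controls.

    All controls must share the same amplicon set (the reference is
    per-amplicon); the statistics are permutation-invariant in the control
    order.
    """
    if len(controls) < 2:
        raise ConfigurationError(
            f"need >= 2 control samples to build a reference, got {len(controls)}"
        )
    amp_ids = controls[0].amplicon_ids()
    for c in controls[1:]:
        if c.amplicon_ids() != amp_ids:
            missing = sorted(amp_ids - c.amplicon_ids())
            extra = sorted(c.amplicon_ids() - amp_ids)
            raise SchemaError(
                f"control {c.sample_id}: amplicon set differs from "
                f"{controls[0].sample_id} (missing {missing}, extra {extra})"
            )
    normalized = [normalize_sample(c) for c in controls]
    mean: dict[str, float] = {}
    sd: dict[str, float] = {}
    for amp in sorted(amp_ids):
        vals = [norm[amp] for norm in normalized]
        mean[amp] = statistics.fmean(vals)
        sd[amp] = statistics.stdev(vals)
    ex17_id = controls[0].exon17.amplicon_id
    ex17_raw = statistics.fmean(c.exon17.depth for c in controls)
    return CoverageReference(
        mean=mean,
        sd=sd,
        n_controls=len(controls),
        exon17_amplicon_id=ex17_id,
        exon17_mean_raw_depth=ex17_raw,
    )


def call_exon17(
    sample: AmpliconCoverage,
    reference: CoverageReference,
    thresholds: CnvThresholds | None = None,
) -> CnvCall:
    """Band the sample's exon-17 copy ratio against the control reference.

    copy_ratio = (sample normalised exon-17 depth) / (control mean);
    ~1 is two amplifiable alleles, ~0.5 one, ~0 none.  The call is
    INDETERMINATE when the control exon-17 depth is below
    ``thresholds.min_control_depth``.
    """
    thresholds = thresholds if thresholds is not None else CnvThresholds()
    ex17_id = sample.exon17.amplicon_id
    if ex17_id not in reference.mean:
        raise SchemaError(
            f"reference does not cover exon-17 amplicon {ex17_id!r}"
        )
    norm = normalize_sample(sample)[ex17_id]
    ref_mean = reference.mean[ex17_id]
    ref_sd = reference.sd[ex17_id]
    ratio = norm / ref_mean
    if ref_sd > 0:
        z = (norm - ref_mean) / ref_sd
    else:
        z = 0.0 if norm == ref_mean else math.copysign(math.inf, norm - ref_mean)
    if reference.exon17_mean_raw_depth < thresholds.min_control_depth:
        state = CnvState.INDETERMINATE
    else:
        state = thresholds.state_for(ratio)
    return CnvCall(
        sample_id=sample.sample_id, copy_ratio=ratio, state=state, z_score=z
    )
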