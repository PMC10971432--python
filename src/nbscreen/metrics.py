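"""Screening-programme performance arithmetic.

Confusion counts and programme rates in the screening sense: a *false
positive* is a recalled newborn whose confirmatory work-up shows carrier or
unaffected status, and the recall rate (recalls / all screened) measures
the programme's burden on families.  Rates are kept as exact
:class:`fractions.Fraction` objects alongside display strings that follow
screening-report convention: two significant figures for cohort-level
percentages, one decimal place for indication-mix percentages.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from fractions import Fraction
from typing import Mapping

from .cutoffs import Marker
from .errors import ConfigurationError
from .rules import ScreeningDecision


@dataclass(frozen=True)
class ProgramCounts:
    """Integer bookkeeping for one screening period."""

    total_screened: int
    recalls: int
    true_positives: int
    false_positives: int
    false_negatives: int
    second_tier_cases: int = 0
    second_tier_tests: int = 0
    indication_tests: Mapping[Marker, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        counts = [
            self.total_screened,
            self.recalls,
            self.true_positives,
            self.false_positives,
            self.false_negatives,
            self.second_tier_cases,
            self.second_tier_tests,
        ]
        if any(c < 0 for c in counts):
            raise ConfigurationError("all counts must be non-negative")
        if self.recalls != self.true_positives + self.false_positives:
            raise ConfigurationError(
                f"recalls ({self.recalls}) must equal TP+FP "
                f"({self.true_positives}+{self.false_positives})"
            )
        if self.second_tier_tests < self.second_tier_cases:
            raise ConfigurationError(
                "second_tier_tests cannot be fewer than second_tier_cases"
            )

    @property
    def true_negatives(self) -> int:
        # Derived, never supplied: everything not recalled and not affected.
        return self.total_screened - (
            self.true_positives + self.false_positives + self.false_negatives
        )


@dataclass(frozen=True)
class RateValue:
    """An exact fraction with its report display string."""

    fraction: Fraction
    display: str


@dataclass(frozen=True)
class ProgramRates:
    second_tier_fraction: RateValue
    recall_rate: RateValue
    false_positive_rate: RateValue
    ppv: RateValue | None
    sensitivity: RateValue | None


def format_percent_2sf(fraction: Fraction | float) -> str:
    """Percentage at two significant figures, e.g. 7/22883 -> '0.031%'."""
    pct = float(fraction) * 100.0
    if pct == 0.0:
        return "0.0%"
    decimals = max(0, 1 - math.floor(math.log10(abs(pct))))
    return f"{pct:.{decimals}f}%"


def format_percent_1dp(fraction: Fraction | float) -> str:
    """Percentage at one decimal place, e.g. 355/424 -> '83.7%'."""
    return f"{float(fraction) * 100.0:.1f}%"


def parse_percent(display: str) -> float:
    """Inverse of the display formatters, returning the fraction."""
    if not display.endswith("%"):
        raise ConfigurationError(f"not a percentage string: {display!r}")
    return float(display[:-1]) / 100.0


def tabulate(
    decisions: Mapping[str, ScreeningDecision],
    truth: Mapping[str, bool],
    total_screened: int | None = None,
) -> ProgramCounts:
    """Confusion counts from per-sample decisions against affected-truth.

    ``decisions`` and ``truth`` must cover the same samples.  When the
    decisions are for a subset of a larger screened cohort, pass the full
    cohort size as ``total_screened`` (defaults to the number of decided
    samples).
    """
    orphans_d = sorted(set(decisions) - set(truth))
    orphans_t = sorted(set(truth) - set(decisions))
    if orphans_d or orphans_t:
        raise ConfigurationError(
            f"decision/truth key mismatch: only in decisions {orphans_d[:5]}, "
            f"only in truth {orphans_t[:5]}"
        )
    tp = fp = fn = 0
    second_tier_cases = 0
    indication: dict[Marker, int] = {}
    for sid, decision in decisions.items():
        recalled = decision.recall
        affected = truth[sid]
        if recalled and affected:
            tp += 1
        elif recalled:
            fp += 1
        elif affected:
            fn += 1
        triggered = decision.triggered_markers
        if triggered:
            second_tier_cases += 1
            for m in triggered:
                indication[m] = indication.get(m, 0) + 1
    total = total_screened if total_screened is not None else len(decisions)
    return ProgramCounts(
        total_screened=total,
        recalls=tp + fp,
        true_positives=tp,
        false_positives=fp,
        false_negatives=fn,
        second_tier_cases=second_tier_cases,
        second_tier_tests=sum(indication.values()),
        indication_tests=indication,
    )


def compute_rates(counts: ProgramCounts) -> ProgramRates:
    """Programme rates as exact fractions plus report strings."""
    if counts.total_screened <= 0:
        raise ConfigurationError("total_screened must be > 0")
    total = counts.total_screened

    def rate(num: int, denom: int) -> RateValue:
        frac = Fraction(num, denom)
        return RateValue(frac, format_percent_2sf(frac))

    affected = counts.true_positives + counts.false_negatives
    return ProgramRates(
        second_tier_fraction=rate(counts.second_tier_cases, total),
        recall_rate=rate(counts.recalls, total),
        false_positive_rate=rate(counts.false_positives, total),
        ppv=rate(counts.true_positives, counts.recalls) if counts.recalls else None,
        sensitivity=rate(counts.true_positives, affected) if affected else None,
    )


def indication_breakdown(
    indication_tests: Mapping[Marker, int],
    second_tier_tests: int | None = None,
) -> dict[Marker, RateValue]:
    """Per-indication share of second-tier tests, displayed at 1 dp.

    When ``second_tier_tests`` is supplied it must equal the sum of the
    per-indication counts (a consistency check on externally provided
    totals).
    """
    total = sum(indication_tests.values())
    if second_tier_tests is not None and second_tier_tests != total:
        raise ConfigurationError(
            f"indication counts sum to {total}, expected {second_tier_tests}"
        )
    if total == 0:
        raise ConfigurationError("no second-tier tests to break down")
    return {
        marker: RateValue(Fraction(count, total), format_percent_1dp(Fraction(count, total)))
        for marker, count in indication_tests.items()
    }


def sensitivity_display(rates: ProgramRates) -> str:
    """Sensitivity string; 'undefined' when no affected case was screened."""
    return rates.sensitivity.display if rates.sensitivity is not None else "undefined"
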