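"""Analyte cutoff profiles for first-tier biochemical triage.

A newborn's dried-blood-spot analytes (free carnitine C0, citrulline,
C5DC-carnitine, C5OH-carnitine, all in μmol/L) are triaged into three
regions per marker:

* ``NEGATIVE`` — inside the healthy reference range;
* ``SECOND_TIER`` — borderline abnormal, reflexed to gene-panel sequencing;
* ``IMMEDIATE_RECALL`` — so extreme that the newborn is recalled without
  waiting for genetics (defined only for C0, very low, and citrulline,
  very high).

Cutoffs are assay-specific because the two tandem-MS kits in routine use
(MassChrom and NeoBase 2) are not harmonised for the acylcarnitines.  The
shipped defaults encode the two-assay scheme of the screening programme this
package models, including the pre-NGS single-tier recall cutoffs retained as
a historical comparator.

Every boundary carries an explicit comparator so that a value maps to
exactly one region; this partition property is validated when a profile is
constructed and is fuzz-tested in the suite.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field
from typing import Mapping

import yaml

from .errors import ConfigurationError


class AssayKind(enum.Enum):
    """Tandem-MS assay used for the first-tier biochemistry."""

    MASSCHROM = "MASSCHROM"
    NEOBASE2 = "NEOBASE2"


class Marker(enum.Enum):
    """First-tier analyte, with its direction of abnormality."""

    C0 = "C0"
    CIT = "CIT"
    C5DC = "C5DC"
    C5OH = "C5OH"

    @property
    def low_is_abnormal(self) -> bool:
        return self is Marker.C0


class MarkerStatus(enum.Enum):
    NEGATIVE = "NEGATIVE"
    SECOND_TIER = "SECOND_TIER"
    IMMEDIATE_RECALL = "IMMEDIATE_RECALL"


class Comparator(enum.Enum):
    LT = "<"
    LE = "<="
    GT = ">"
    GE = ">="

    def crossed(self, value: float, threshold: float) -> bool:
        if self is Comparator.LT:
            return value < threshold
        if self is Comparator.LE:
            return value <= threshold
        if self is Comparator.GT:
            return value > threshold
        return value >= threshold


@dataclass(frozen=True)
class Threshold:
    """A single cutoff with an explicit comparator, e.g. ``>= 35``."""

    comparator: Comparator
    value: float

    def crossed(self, value: float) -> bool:
        return self.comparator.crossed(value, self.value)

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"{self.comparator.value}{self.value:g}"


@dataclass(frozen=True)
class SecondTierWindow:
    """The borderline band that triggers reflex gene-panel sequencing.

    ``high`` is ``None`` for markers with no upper bound (an arbitrarily
    high C5DC still goes through genetics; only C0 and citrulline have
    immediate-recall extremes carved out).
    """

    low: float
    low_inclusive: bool = True
    high: float | None = None
    high_inclusive: bool = True

    def contains(self, value: float) -> bool:
        if self.low_inclusive:
            if value < self.low:
                return False
        elif value <= self.low:
            return False
        if self.high is not None:
            if self.high_inclusive:
                if value > self.high:
                    return False
            elif value >= self.high:
                return False
        return True


@dataclass(frozen=True)
class MarkerCutoffs:
    """All cutoffs for one (marker, assay) pair."""

    window: SecondTierWindow
    immediate: Threshold | None = None

    def classify(self, value: float) -> MarkerStatus:
        if not math.isfinite(value) or value < 0:
            raise ConfigurationError(
                f"marker value must be finite and non-negative, got {value!r}"
            )
        if self.immediate is not None and self.immediate.crossed(value):
            return MarkerStatus.IMMEDIATE_RECALL
        if self.window.contains(value):
            return MarkerStatus.SECOND_TIER
        return MarkerStatus.NEGATIVE


@dataclass(frozen=True)
class CutoffProfile:
    """Complete cutoff configuration: per-(marker, assay) triage cutoffs plus
    the per-marker historical single-tier recall cutoffs.

    The historical cutoffs are stored once per marker: they predate the
    two-assay era and are used only by the single-tier comparator.
    """

    triage: Mapping[tuple[Marker, AssayKind], MarkerCutoffs]
    historical: Mapping[Marker, Threshold] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for (marker, assay), mc in self.triage.items():
            self._check_partition(marker, assay, mc)

    @staticmethod
    def _check_partition(marker: Marker, assay: AssayKind, mc: MarkerCutoffs) -> None:
        # The immediate-recall region must butt up against the second-tier
        # window with no gap and no overlap, so that triage is a partition.
        imm = mc.immediate
        if imm is None:
            return
        w = mc.window
        if imm.comparator in (Comparator.LT, Comparator.LE):
            ok = (
                imm.value == w.low
                and imm.comparator is Comparator.LT
                and w.low_inclusive
            )
        else:
            ok = (
                w.high is not None
                and imm.value == w.high
                and imm.comparator is Comparator.GT
                and w.high_inclusive
            )
        if not ok:
            raise ConfigurationError(
                f"{marker.value}/{assay.value}: immediate-recall threshold "
                f"{imm} does not partition against the second-tier window"
            )

    def for_marker(self, marker: Marker, assay: AssayKind) -> MarkerCutoffs:
        try:
            return self.triage[(marker, assay)]
        except KeyError:
            raise ConfigurationError(
                f"no cutoffs configured for marker {marker.value} on assay {assay.value}"
            ) from None

    def historical_for(self, marker: Marker) -> Threshold:
        try:
            return self.historical[marker]
        except KeyError:
            raise ConfigurationError(
                f"no historical single-tier cutoff configured for {marker.value}"
            ) from None


def default_cutoffs() -> CutoffProfile:
    """The shipped default profile.

    C0 and citrulline share cutoffs across assays (closed second-tier
    windows, strict immediate-recall extremes); C5DC and C5OH use strict
    lower bounds that differ by assay.  Historical single-tier cutoffs are
    the MassChrom-era values.
    """
    c0 = MarkerCutoffs(
        window=SecondTierWindow(low=5.0, high=6.5),
        immediate=Threshold(Comparator.LT, 5.0),
    )
    cit = MarkerCutoffs(
        window=SecondTierWindow(low=25.0, high=50.0),
        immediate=Threshold(Comparator.GT, 50.0),
    )
    triage: dict[tuple[Marker, AssayKind], MarkerCutoffs] = {}
    for assay in AssayKind:
        triage[(Marker.C0, assay)] = c0
        triage[(Marker.CIT, assay)] = cit
    triage[(Marker.C5DC, AssayKind.NEOBASE2)] = MarkerCutoffs(
        window=SecondTierWindow(low=0.17, low_inclusive=False)
    )
    triage[(Marker.C5DC, AssayKind.MASSCHROM)] = MarkerCutoffs(
        window=SecondTierWindow(low=0.35, low_inclusive=False)
    )
    triage[(Marker.C5OH, AssayKind.NEOBASE2)] = MarkerCutoffs(
        window=SecondTierWindow(low=0.9, low_inclusive=False)
    )
    triage[(Marker.C5OH, AssayKind.MASSCHROM)] = MarkerCutoffs(
        window=SecondTierWindow(low=0.7, low_inclusive=False)
    )
    historical = {
        Marker.C0: Threshold(Comparator.LE, 6.2),
        Marker.CIT: Threshold(Comparator.GE, 35.0),
        Marker.C5DC: Threshold(Comparator.GE, 0.35),
        Marker.C5OH: Threshold(Comparator.GE, 0.78),
    }
    return CutoffProfile(triage=triage, historical=historical)


# ---------------------------------------------------------------------------
# YAML round-trip


def _threshold_to_dict(t: Threshold) -> dict:
    return {"cmp": t.comparator.value, "value": t.value}


def _threshold_from_dict(d: Mapping) -> Threshold:
    try:
        return Threshold(Comparator(d["cmp"]), float(d["value"]))
    except (KeyError, ValueError) as exc:
        raise ConfigurationError(f"bad threshold entry {d!r}: {exc}") from exc


def profile_to_yaml(profile: CutoffProfile, path) -> None:
    doc: dict = {"triage": {}, "historical": {}}
    for (marker, assay), mc in profile.triage.items():
        entry: dict = {
            "window": {
                "low": mc.window.low,
                "low_inclusive": mc.window.low_inclusive,
                "high": mc.window.high,
                "high_inclusive": mc.window.high_inclusive,
            }
        }
        if mc.immediate is not None:
            entry["immediate"] = _threshold_to_dict(mc.immediate)
        doc["triage"].setdefault(assay.value, {})[marker.value] = entry
    for marker, t in profile.historical.items():
        doc["historical"][marker.value] = _threshold_to_dict(t)
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=True)


def profile_from_yaml(path) -> CutoffProfile:
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    if not isinstance(doc, dict) or "triage" not in doc:
        raise ConfigurationError(f"{path}: not a cutoff-profile document")
    triage: dict[tuple[Marker, AssayKind], MarkerCutoffs] = {}
    for assay_name, markers in doc["triage"].items():
        try:
            assay = AssayKind(assay_name)
        except ValueError:
            raise ConfigurationError(f"{path}: unknown assay {assay_name!r}") from None
        for marker_name, entry in markers.items():
            try:
                marker = Marker(marker_name)
            except ValueError:
                raise ConfigurationError(
                    f"{path}: unknown marker {marker_name!r}"
                ) from None
            w = entry["window"]
            window = SecondTierWindow(
                low=float(w["low"]),
                low_inclusive=bool(w.get("low_inclusive", True)),
                high=None if w.get("high") is None else float(w["high"]),
                high_inclusive=bool(w.get("high_inclusive", True)),
            )
            immediate = (
                _threshold_from_dict(entry["immediate"])
                if "immediate" in entry
                else None
            )
            triage[(marker, assay)] = MarkerCutoffs(window=window, immediate=immediate)
    historical = {
        Marker(name): _threshold_from_dict(entry)
        for name, entry in doc.get("historical", {}).items()
    }
    return CutoffProfile(triage=triage, historical=historical)
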