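"""Readers and writers for the pipeline's external formats.

Four inputs and two outputs:

* biochemistry — delimited text, one row per (sample, marker) measurement;
* classified variants — VCF with ``GENE`` and ``CLASS`` INFO annotations
  (single-sample files, one per screened newborn), or the equivalent
  sidecar TSV for upstream pipelines that cannot write INFO keys;
* amplicon coverage — TSV of per-amplicon read depths;
* cutoff profiles — YAML (see :mod:`nbscreen.cutoffs`);
* decisions — a JSON report (lossless, round-trippable) plus a flat
  cohort-level TSV for spreadsheets.

All readers validate strictly and reject rather than coerce: an unknown
assay name, a negative concentration or a VCF record without its
classification is an error with file/line (or record) context, never a
silent default.
"""

from __future__ import annotations

import json
import math
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
import pysam

from .cnv import AmpliconCoverage, AmpliconRecord, CnvCall, CnvState
from .cutoffs import AssayKind, Marker, MarkerStatus
from .errors import ParseError, SchemaError
from .rules import (
    BiochemicalResult,
    Classification,
    MarkerDecision,
    ReasonCode,
    RuleVersion,
    ScreeningDecision,
    VariantCall,
    Zygosity,
)

# ---------------------------------------------------------------------------
# Biochemistry

_BIOCHEM_COLUMNS = ["sample_id", "assay", "marker", "value"]


def read_biochem(path, delimiter: str = ",") -> list[BiochemicalResult]:
    """Read per-sample marker measurements from delimited text.

    Expected columns: ``sample_id, assay, marker, value``.  Rows for the
    same sample are merged into one :class:`BiochemicalResult`; duplicate
    (sample, marker) pairs and inconsistent per-sample assays are rejected.
    """
    try:
        df = pd.read_csv(path, sep=delimiter, dtype=str)
    except Exception as exc:  # pandas raises several parser error types
        raise ParseError(f"{path}: {exc}") from exc
    missing = [c for c in _BIOCHEM_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing columns {missing}")

    results: dict[str, dict] = {}
    for idx, row in enumerate(df.itertuples(index=False), start=2):  # 1 = header
        sid = str(row.sample_id)
        try:
            assay = AssayKind(row.assay)
        except ValueError:
            raise ParseError(
                f"{path}:{idx}: unknown assay {row.assay!r}"
            ) from None
        try:
            marker = Marker(row.marker)
        except ValueError:
            raise ParseError(
                f"{path}:{idx}: unknown marker {row.marker!r}"
            ) from None
        try:
            value = float(row.value)
        except (TypeError, ValueError):
            raise ParseError(
                f"{path}:{idx}: malformed value {row.value!r}"
            ) from None
        if not math.isfinite(value) or value < 0:
            raise ParseError(
                f"{path}:{idx}: value {value} must be finite and non-negative"
            )
        entry = results.setdefault(sid, {"assay": assay, "values": {}})
        if entry["assay"] is not assay:
            raise ParseError(
                f"{path}:{idx}: sample {sid} reported on two assays"
            )
        if marker in entry["values"]:
            raise ParseError(
                f"{path}:{idx}: duplicate marker {marker.value} for sample {sid}"
            )
        entry["values"][marker] = value
    return [
        BiochemicalResult(sample_id=sid, assay=e["assay"], values=e["values"])
        for sid, e in results.items()
    ]


def write_biochem(results: Iterable[BiochemicalResult], path, delimiter: str = ",") -> None:
    rows = [
        {
            "sample_id": r.sample_id,
            "assay": r.assay.value,
            "marker": m.value,
            "value": repr(v) if isinstance(v, float) else v,
        }
        for r in results
        for m, v in sorted(r.values.items(), key=lambda kv: kv[0].value)
    ]
    pd.DataFrame(rows, columns=_BIOCHEM_COLUMNS).to_csv(
        path, sep=delimiter, index=False
    )


# ---------------------------------------------------------------------------
# Classified variants (VCF and sidecar TSV)


def _info_get(rec, key):
    # pysam raises ValueError for keys absent from the header; treat any
    # unreadable annotation as missing so the caller can reject it by name.
    try:
        return rec.info.get(key)
    except (KeyError, ValueError):
        return None


def _zygosity_from_gt(gt, record_name: str, path) -> Zygosity:
    alleles = tuple(a for a in gt if a is not None)
    if alleles == (0, 1) or alleles == (1, 0):
        return Zygosity.HET
    if alleles == (1, 1):
        return Zygosity.HOM
    raise SchemaError(
        f"{path}: record {record_name}: genotype {gt!r} is neither 0/1 nor 1/1"
    )


def read_classified_vcf(
    path, panel: frozenset[str] | set[str] | None = None
) -> list[VariantCall]:
    """Read classified variants from a single-sample VCF.

    Each record needs INFO keys ``GENE`` and ``CLASS`` (P/LP/VUS/OTHER) and
    a 0/1 or 1/1 genotype; ``HGVS`` is carried when present, otherwise a
    ``chrom:pos ref>alt`` description is synthesised.  When ``panel`` is
    given, only records whose gene is in the panel are returned (gene-panel
    filtering).
    """
    calls: list[VariantCall] = []
    with pysam.VariantFile(str(path)) as vcf:
        samples = list(vcf.header.samples)
        if len(samples) != 1:
            raise SchemaError(
                f"{path}: expected a single-sample VCF, found {len(samples)} samples"
            )
        sample = samples[0]
        for rec in vcf:
            name = f"{rec.chrom}:{rec.pos}"
            gene = _info_get(rec, "GENE")
            if gene is None:
                raise SchemaError(f"{path}: record {name}: missing GENE annotation")
            raw_class = _info_get(rec, "CLASS")
            if raw_class is None:
                raise SchemaError(f"{path}: record {name}: missing CLASS annotation")
            try:
                classification = Classification(str(raw_class))
            except ValueError:
                raise SchemaError(
                    f"{path}: record {name}: unknown CLASS {raw_class!r}"
                ) from None
            if panel is not None and gene not in panel:
                continue
            gt = rec.samples[sample].get("GT")
            if gt is None:
                raise SchemaError(f"{path}: record {name}: missing genotype")
            zygosity = _zygosity_from_gt(gt, name, path)
            hgvs = _info_get(rec, "HGVS")
            if hgvs is None:
                alts = rec.alts or ("?",)
                hgvs = f"{rec.chrom}:{rec.pos}{rec.ref}>{alts[0]}"
            calls.append(
                VariantCall(
                    sample_id=sample,
                    gene=str(gene),
                    hgvs=str(hgvs),
                    zygosity=zygosity,
                    classification=classification,
                )
            )
    return calls


def write_classified_vcf(
    path,
    sample_id: str,
    records: Sequence[tuple[str, int, str, str, VariantCall]],
) -> None:
    """Write a single-sample classified VCF.

    ``records`` are ``(chrom, pos, ref, alt, call)`` tuples; coordinates are
    carried verbatim, never interpreted.
    """
    header = pysam.VariantHeader()
    for chrom in dict.fromkeys(r[0] for r in records):
        header.add_line(f"##contig=<ID={chrom}>")
    header.info.add("GENE", 1, "String", "Gene symbol")
    header.info.add("CLASS", 1, "String", "Variant classification (P/LP/VUS/OTHER)")
    header.info.add("HGVS", 1, "String", "HGVS cDNA description")
    header.formats.add("GT", 1, "String", "Genotype")
    header.add_sample(sample_id)
    with pysam.VariantFile(str(path), "w", header=header) as out:
        for chrom, pos, ref, alt, call in records:
            rec = out.new_record(
                contig=chrom, start=pos - 1, alleles=(ref, alt), filter="PASS"
            )
            rec.info["GENE"] = call.gene
            rec.info["CLASS"] = call.classification.value
            rec.info["HGVS"] = call.hgvs.replace(" ", "_")
            rec.samples[sample_id]["GT"] = (
                (1, 1) if call.zygosity is Zygosity.HOM else (0, 1)
            )
            out.write(rec)


_VARIANT_TSV_COLUMNS = ["sample_id", "gene", "hgvs", "zygosity", "classification"]


def read_variant_table(path, delimiter: str = "\t") -> list[VariantCall]:
    """Sidecar-TSV fallback for classified variants (one row per call)."""
    df = pd.read_csv(path, sep=delimiter, dtype=str)
    missing = [c for c in _VARIANT_TSV_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing columns {missing}")
    calls = []
    for idx, row in enumerate(df.itertuples(index=False), start=2):
        try:
            calls.append(
                VariantCall(
                    sample_id=str(row.sample_id),
                    gene=str(row.gene),
                    hgvs=str(row.hgvs),
                    zygosity=Zygosity(row.zygosity),
                    classification=Classification(row.classification),
                )
            )
        except ValueError as exc:
            raise ParseError(f"{path}:{idx}: {exc}") from None
    return calls


def write_variant_table(calls: Iterable[VariantCall], path, delimiter: str = "\t") -> None:
    rows = [
        {
            "sample_id": c.sample_id,
            "gene": c.gene,
            "hgvs": c.hgvs,
            "zygosity": c.zygosity.value,
            "classification": c.classification.value,
        }
        for c in calls
    ]
    pd.DataFrame(rows, columns=_VARIANT_TSV_COLUMNS).to_csv(
        path, sep=delimiter, index=False
    )


# ---------------------------------------------------------------------------
# Amplicon coverage

_COVERAGE_COLUMNS = ["sample_id", "amplicon_id", "gene", "target", "depth"]


def read_coverage(path) -> list[AmpliconCoverage]:
    """Read per-sample per-amplicon read depths from TSV."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in _COVERAGE_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing columns {missing}")
    samples: dict[str, list[AmpliconRecord]] = {}
    for idx, row in enumerate(df.itertuples(index=False), start=2):
        try:
            depth = int(row.depth)
        except (TypeError, ValueError):
            raise ParseError(
                f"{path}:{idx}: malformed depth {row.depth!r}"
            ) from None
        samples.setdefault(str(row.sample_id), []).append(
            AmpliconRecord(
                amplicon_id=str(row.amplicon_id),
                gene=str(row.gene),
                target=str(row.target),
                depth=depth,
            )
        )
    out = []
    for sid, records in samples.items():
        try:
            out.append(AmpliconCoverage(sample_id=sid, records=tuple(records)))
        except SchemaError as exc:
            raise SchemaError(f"{path}: {exc}") from None
    return out


def write_coverage(coverages: Iterable[AmpliconCoverage], path) -> None:
    rows = [
        {
            "sample_id": cov.sample_id,
            "amplicon_id": r.amplicon_id,
            "gene": r.gene,
            "target": r.target,
            "depth": r.depth,
        }
        for cov in coverages
        for r in cov.records
    ]
    pd.DataFrame(rows, columns=_COVERAGE_COLUMNS).to_csv(path, sep="\t", index=False)


def write_cnv_calls(calls: Iterable[CnvCall], path) -> None:
    rows = [
        {
            "sample_id": c.sample_id,
            "copy_ratio": f"{c.copy_ratio:.4f}",
            "z_score": f"{c.z_score:.3f}",
            "state": c.state.value,
        }
        for c in calls
    ]
    pd.DataFrame(rows, columns=["sample_id", "copy_ratio", "z_score", "state"]).to_csv(
        path, sep="\t", index=False
    )


# ---------------------------------------------------------------------------
# Decision reports


def _decision_to_dict(d: ScreeningDecision) -> dict:
    return {
        "sample_id": d.sample_id,
        "rule_version": d.rule_version.value,
        "recall": d.recall,
        "needs_review": d.needs_review,
        "conditions": list(d.conditions),
        "markers": {
            m.value: {
                "value": md.value,
                "status": md.status.value,
                "reason": md.reason.value,
                "allele_count": md.allele_count,
                "conditions": list(md.conditions),
                "needs_review": md.needs_review,
            }
            for m, md in d.markers.items()
        },
        "cnv": None
        if d.cnv is None
        else {
            "copy_ratio": d.cnv.copy_ratio,
            "z_score": d.cnv.z_score,
            "state": d.cnv.state.value,
        },
    }


def _decision_from_dict(doc: Mapping) -> ScreeningDecision:
    markers = {}
    for name, md in doc["markers"].items():
        marker = Marker(name)
        markers[marker] = MarkerDecision(
            marker=marker,
            value=float(md["value"]),
            status=MarkerStatus(md["status"]),
            reason=ReasonCode(md["reason"]),
            allele_count=md["allele_count"],
            conditions=tuple(md["conditions"]),
            needs_review=bool(md["needs_review"]),
        )
    cnv = None
    if doc.get("cnv") is not None:
        cnv = CnvCall(
            sample_id=doc["sample_id"],
            copy_ratio=float(doc["cnv"]["copy_ratio"]),
            z_score=float(doc["cnv"]["z_score"]),
            state=CnvState(doc["cnv"]["state"]),
        )
    return ScreeningDecision(
        sample_id=doc["sample_id"],
        rule_version=RuleVersion(doc["rule_version"]),
        markers=markers,
        cnv=cnv,
    )


def write_report(
    decisions: Sequence[ScreeningDecision],
    json_path,
    tsv_path=None,
) -> None:
    """Write the per-sample JSON report and (optionally) a cohort TSV.

    The JSON report is lossless: :func:`read_report` reproduces the decision
    objects field-for-field, and re-writing re-read decisions is
    byte-identical.
    """
    doc = {"decisions": [_decision_to_dict(d) for d in decisions]}
    Path(json_path).write_text(json.dumps(doc, indent=2, sort_keys=True) + "\n")
    if tsv_path is not None:
        rows = [
            {
                "sample_id": d.sample_id,
                "rule_version": d.rule_version.value,
                "recall": int(d.recall),
                "needs_review": int(d.needs_review),
                "conditions": ";".join(d.conditions),
                "triggered_markers": ";".join(m.value for m in d.triggered_markers),
                "reasons": ";".join(
                    f"{m.value}={md.reason.value}" for m, md in d.markers.items()
                ),
            }
            for d in decisions
        ]
        pd.DataFrame(
            rows,
            columns=[
                "sample_id",
                "rule_version",
                "recall",
                "needs_review",
                "conditions",
                "triggered_markers",
                "reasons",
            ],
        ).to_csv(tsv_path, sep="\t", index=False)


def read_report(json_path) -> list[ScreeningDecision]:
    doc = json.loads(Path(json_path).read_text())
    if "decisions" not in doc:
        raise SchemaError(f"{json_path}: not a decision report")
    return [_decision_from_dict(d) for d in doc["decisions"]]
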