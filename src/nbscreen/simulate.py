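"""Synthetic newborn-cohort generator.

Produces cohorts with the statistical structure the screening programme
operates on, so every pipeline stage is testable without patient data:

* genotypes drawn under Hardy–Weinberg equilibrium, with a citrin-deficiency
  (*SLC25A13*) carrier rate of 1/40 — the high-carrier-frequency regime that
  motivates the two-allele borderline rule;
* a configurable fraction of pathogenic *SLC25A13* alleles are the
  IVS16ins3kb insertion, which is invisible to sequence calling and only
  detectable as exon-17 allelic dropout;
* healthy citrulline drawn from a log-normal calibrated in closed form so
  its 99th percentile sits exactly on the 25 μmol/L first-tier cutoff;
  affected citrin-deficiency neonates draw citrulline from a triangular
  distribution on 17–34 μmol/L with median 26 — i.e. mostly *below* the old
  single-tier cutoff of 35, the false-negative mechanism the second tier
  exists to fix; carriers draw a modestly up-shifted healthy distribution
  (the borderline-band false-positive mechanism);
* per-amplicon read depths drawn negative-binomially around
  amplicon-specific efficiencies, with the exon-17 amplicon's expected
  depth scaled by the fraction of amplifiable alleles (1, 0.5, 0 for
  zero/one/two insertion alleles).

The healthy C0/C5DC/C5OH distributions are documented placeholders (no
published population distributions are modelled); they are calibrated only
so the per-marker second-tier trigger fractions sit at a realistic order of
magnitude, dominated by the citrulline band.  Everything is reproducible:
the seed fully determines the cohort and the fixture files.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy import stats

from .cnv import AmpliconCoverage, AmpliconRecord, EXON17_TARGET
from .cutoffs import AssayKind, Marker
from .errors import ConfigurationError
from .formats import (
    write_biochem,
    write_classified_vcf,
    write_coverage,
    write_variant_table,
)
from .rules import GENE_CONDITIONS, BiochemicalResult, Classification, VariantCall, Zygosity

# ---------------------------------------------------------------------------
# Variant catalogue (coordinates are carried, never interpreted)


@dataclass(frozen=True)
class CatalogVariant:
    gene: str
    hgvs: str
    chrom: str
    pos: int
    ref: str
    alt: str
    classification: Classification


_P = Classification.P
_LP = Classification.LP
_VUS = Classification.VUS

VARIANT_CATALOG: dict[str, list[CatalogVariant]] = {
    "SLC25A13": [
        CatalogVariant("SLC25A13", "c.852_855del", "7", 95825235, "CTATG", "C", _P),
        CatalogVariant("SLC25A13", "c.1311+1G>A", "7", 95818703, "C", "T", _P),
        CatalogVariant("SLC25A13", "c.615+5G>A", "7", 95830555, "C", "T", _P),
        CatalogVariant("SLC25A13", "c.1399C>T", "7", 95817201, "G", "A", _LP),
    ],
    "SLC22A5": [
        CatalogVariant("SLC22A5", "c.51C>G", "5", 131705665, "C", "G", _P),
        CatalogVariant("SLC22A5", "c.1400C>G", "5", 131721261, "C", "G", _P),
        CatalogVariant("SLC22A5", "c.760C>T", "5", 131714210, "C", "T", _LP),
    ],
    "GCDH": [
        CatalogVariant("GCDH", "c.1156C>T", "19", 13008614, "C", "T", _P),
        CatalogVariant("GCDH", "c.416C>G", "19", 13004533, "C", "G", _LP),
    ],
    "ACAT1": [CatalogVariant("ACAT1", "c.622C>T", "11", 108121551, "C", "T", _P)],
    "HLCS": [CatalogVariant("HLCS", "c.1522C>T", "21", 38123411, "G", "A", _P)],
    "HMGCL": [CatalogVariant("HMGCL", "c.122G>A", "1", 24130521, "C", "T", _P)],
}

# One VUS per gene, used to exercise (and only to exercise) VUS filtering.
VUS_CATALOG: dict[str, CatalogVariant] = {
    "SLC25A13": CatalogVariant("SLC25A13", "c.2T>C", "7", 95832200, "A", "G", _VUS),
    "SLC22A5": CatalogVariant("SLC22A5", "c.394G>A", "5", 131711000, "G", "A", _VUS),
    "GCDH": CatalogVariant("GCDH", "c.281G>A", "19", 13002900, "G", "A", _VUS),
    "ACAT1": CatalogVariant("ACAT1", "c.100A>G", "11", 108120000, "A", "G", _VUS),
    "HLCS": CatalogVariant("HLCS", "c.710T>C", "21", 38120001, "A", "G", _VUS),
    "HMGCL": CatalogVariant("HMGCL", "c.31C>T", "1", 24128800, "C", "T", _VUS),
}

# The amplicon panel: exon tiles over the six-condition genes, one of which
# is the dropout-sensitive SLC25A13 exon-17 amplicon.
AMPLICON_PANEL: list[tuple[str, str, str]] = (
    [
        (f"SLC25A13_amp{i:02d}", "SLC25A13",
         EXON17_TARGET if i == 17 else f"SLC25A13_ex{i}")
        for i in range(1, 19)
    ]
    + [(f"SLC22A5_amp{i:02d}", "SLC22A5", f"SLC22A5_ex{i}") for i in (1, 2)]
    + [(f"GCDH_amp{i:02d}", "GCDH", f"GCDH_ex{i}") for i in (1, 2)]
    + [("ACAT1_amp01", "ACAT1", "ACAT1_ex1")]
    + [("HLCS_amp01", "HLCS", "HLCS_ex1")]
)


# ---------------------------------------------------------------------------
# Calibration helpers


def calibrate_healthy_citrulline(
    p99: float = 25.0, median: float = 12.0
) -> tuple[float, float]:
    """Log-normal (mu, sigma) with the given median and 99th percentile.

    Closed-form inversion: mu = ln(median), sigma = (ln(p99) - mu) / z_0.99,
    so P(X > p99) = 0.01 exactly.
    """
    if not (0 < median < p99):
        raise ConfigurationError(
            f"need 0 < median < p99, got median={median}, p99={p99}"
        )
    mu = math.log(median)
    sigma = (math.log(p99) - mu) / stats.norm.ppf(0.99)
    return mu, sigma


def allele_frequency_from_carrier_rate(carrier_rate: float) -> float:
    """Invert 2q(1-q) = carrier_rate under Hardy–Weinberg (exact)."""
    if not (0 < carrier_rate < 0.5):
        raise ConfigurationError(
            f"carrier rate must be in (0, 0.5), got {carrier_rate}"
        )
    return (1.0 - math.sqrt(1.0 - 2.0 * carrier_rate)) / 2.0


def triangular_mode_for_median(low: float, high: float, median: float) -> float:
    """Mode of a triangular(low, mode, high) with the requested median."""
    if not (low < median < high):
        raise ConfigurationError(
            f"need low < median < high, got {low}, {median}, {high}"
        )
    span = high - low
    mode = low + 2.0 * (median - low) ** 2 / span
    if median > mode:  # median lies on the descending segment
        mode = high - 2.0 * (high - median) ** 2 / span
    return mode


def hardy_weinberg_pvalue(genotype_counts: Sequence[int], q: float) -> float:
    """Chi-square goodness of fit of (n_00, n_01, n_11) against HWE at known q."""
    n = int(sum(genotype_counts))
    if n == 0:
        raise ConfigurationError("empty genotype table")
    p = 1.0 - q
    expected = np.array([p * p, 2 * p * q, q * q]) * n
    observed = np.asarray(genotype_counts, dtype=float)
    # q is known a priori (not estimated from the table), so df = 2.
    return float(stats.chisquare(observed, expected).pvalue)


# ---------------------------------------------------------------------------
# Configuration and sample container


@dataclass(frozen=True)
class LognormalSpec:
    """Healthy log-normal for one analyte plus carrier/affected multipliers."""

    median: float
    sigma: float
    carrier_scale: float
    affected_scale: float


@dataclass(frozen=True)
class SimulationConfig:
    n: int
    seed: int
    assay: AssayKind = AssayKind.NEOBASE2

    # Citrin deficiency: carrier rate and allele make-up.
    cd_carrier_rate: float = 1.0 / 40.0
    #: Per-allele probability that a pathogenic SLC25A13 allele is the
    #: IVS16ins3kb insertion.  1 - sqrt(0.6) makes 40% of affected cases
    #: carry at least one insertion allele.
    ins_allele_fraction: float = 1.0 - math.sqrt(0.6)
    #: Carrier rate for each of SLC22A5, GCDH, ACAT1, HLCS, HMGCL
    #: (placeholder values; not population estimates).
    other_carrier_rate: float = 1.0 / 200.0

    # Citrulline model (μmol/L).
    healthy_cit_median: float = 12.0
    healthy_cit_p99: float = 25.0
    carrier_cit_scale: float = 1.3
    affected_cit_low: float = 17.0
    affected_cit_high: float = 34.0
    affected_cit_median: float = 26.0

    # Placeholder healthy distributions for the other analytes.
    c0: LognormalSpec = field(
        default_factory=lambda: LognormalSpec(30.0, 0.45, 0.85, 0.18)
    )
    c5dc: LognormalSpec = field(
        default_factory=lambda: LognormalSpec(0.06, 0.37, 1.5, 8.0)
    )
    c5oh: LognormalSpec = field(
        default_factory=lambda: LognormalSpec(0.25, 0.37, 1.3, 6.0)
    )

    #: Probability that a sample carries one incidental VUS in a panel gene.
    vus_rate: float = 0.02

    # Coverage model.
    mean_depth: float = 800.0
    #: Excess-variance factor d: Var(depth) = mu * (1 + d); d = 0 is Poisson.
    dispersion: float = 0.05
    efficiency_sigma: float = 0.15
    include_coverage: bool = True

    def __post_init__(self) -> None:
        if self.n < 0:
            raise ConfigurationError("cohort size must be >= 0")
        if not (0.0 <= self.ins_allele_fraction <= 1.0):
            raise ConfigurationError("ins_allele_fraction must be in [0, 1]")
        if not (0.0 <= self.vus_rate <= 1.0):
            raise ConfigurationError("vus_rate must be in [0, 1]")
        if self.dispersion < 0:
            raise ConfigurationError("dispersion must be >= 0")
        # Fail fast on infeasible analyte anchors.
        calibrate_healthy_citrulline(self.healthy_cit_p99, self.healthy_cit_median)
        triangular_mode_for_median(
            self.affected_cit_low, self.affected_cit_high, self.affected_cit_median
        )


@dataclass(frozen=True)
class SimulatedSample:
    """One synthetic newborn with full ground truth."""

    sample_id: str
    result: BiochemicalResult
    variants: tuple[VariantCall, ...]
    coverage: AmpliconCoverage | None
    #: pathogenic allele count per gene (sequence + insertion combined)
    genotypes: dict[str, int]
    #: number of IVS16ins3kb alleles (subset of the SLC25A13 count)
    ins_alleles: int
    affected_conditions: tuple[str, ...]
    carrier_conditions: tuple[str, ...]

    @property
    def affected(self) -> bool:
        return bool(self.affected_conditions)


_GENES = ["SLC25A13", "SLC22A5", "GCDH", "ACAT1", "HLCS", "HMGCL"]


def _nb_draw(rng: np.random.Generator, mu: np.ndarray, dispersion: float) -> np.ndarray:
    """Negative-binomial draws with Var = mu(1+d); Poisson when d = 0."""
    mu = np.asarray(mu, dtype=float)
    out = np.zeros(mu.shape, dtype=np.int64)
    pos = mu > 0
    if dispersion == 0:
        out[pos] = rng.poisson(mu[pos])
    else:
        r = mu[pos] / dispersion
        p = 1.0 / (1.0 + dispersion)
        out[pos] = rng.negative_binomial(r, p)
    return out


def _draw_panel_depths(
    rng: np.random.Generator,
    n_samples: int,
    ex17_multiplier: np.ndarray,
    mean_depth: float,
    dispersion: float,
    efficiency_sigma: float,
) -> np.ndarray:
    """(n_samples, n_amplicons) depth matrix for the shipped panel."""
    n_amp = len(AMPLICON_PANEL)
    efficiency = rng.lognormal(0.0, efficiency_sigma, size=n_amp)
    mu = mean_depth * np.tile(efficiency, (n_samples, 1))
    ex17_col = next(
        i for i, (_, _, target) in enumerate(AMPLICON_PANEL) if target == EXON17_TARGET
    )
    mu[:, ex17_col] *= ex17_multiplier
    return _nb_draw(rng, mu, dispersion)


def _coverage_from_row(sample_id: str, depths: np.ndarray) -> AmpliconCoverage:
    return AmpliconCoverage(
        sample_id=sample_id,
        records=tuple(
            AmpliconRecord(amp_id, gene, target, int(depths[j]))
            for j, (amp_id, gene, target) in enumerate(AMPLICON_PANEL)
        ),
    )


def _variants_for_gene(
    rng: np.random.Generator, sample_id: str, gene: str, n_seq_alleles: int
) -> list[tuple[CatalogVariant, VariantCall]]:
    """Assign concrete catalogue variants to a gene's sequence alleles."""
    if n_seq_alleles == 0:
        return []
    catalog = VARIANT_CATALOG[gene]
    idx = rng.integers(0, len(catalog), size=n_seq_alleles)
    out = []
    if n_seq_alleles == 2 and idx[0] == idx[1]:
        cv = catalog[int(idx[0])]
        out.append(
            (cv, VariantCall(sample_id, gene, cv.hgvs, Zygosity.HOM, cv.classification))
        )
    else:
        for i in idx:
            cv = catalog[int(i)]
            out.append(
                (cv, VariantCall(sample_id, gene, cv.hgvs, Zygosity.HET, cv.classification))
            )
    return out


def simulate_cohort(config: SimulationConfig) -> list[SimulatedSample]:
    """Draw a fully labelled cohort; the seed determines every byte."""
    rng = np.random.default_rng(config.seed)
    n = config.n
    if n == 0:
        return []

    # --- genotypes ---------------------------------------------------------
    q_cd = allele_frequency_from_carrier_rate(config.cd_carrier_rate)
    q_other = allele_frequency_from_carrier_rate(config.other_carrier_rate)
    alleles: dict[str, np.ndarray] = {}
    alleles["SLC25A13"] = rng.binomial(2, q_cd, size=n)
    for gene in _GENES[1:]:
        alleles[gene] = rng.binomial(2, q_other, size=n)
    ins = rng.binomial(alleles["SLC25A13"], config.ins_allele_fraction)

    # --- analytes ----------------------------------------------------------
    mu_cit, sigma_cit = calibrate_healthy_citrulline(
        config.healthy_cit_p99, config.healthy_cit_median
    )
    cit = rng.lognormal(mu_cit, sigma_cit, size=n)
    c0 = rng.lognormal(math.log(config.c0.median), config.c0.sigma, size=n)
    c5dc = rng.lognormal(math.log(config.c5dc.median), config.c5dc.sigma, size=n)
    c5oh = rng.lognormal(math.log(config.c5oh.median), config.c5oh.sigma, size=n)

    cd_alleles = alleles["SLC25A13"]
    cit[cd_alleles == 1] *= config.carrier_cit_scale
    affected_cd = cd_alleles == 2
    n_aff = int(affected_cd.sum())
    if n_aff:
        mode = triangular_mode_for_median(
            config.affected_cit_low, config.affected_cit_high, config.affected_cit_median
        )
        cit[affected_cd] = rng.triangular(
            config.affected_cit_low, mode, config.affected_cit_high, size=n_aff
        )

    for gene, values, spec in (
        ("SLC22A5", c0, config.c0),
        ("GCDH", c5dc, config.c5dc),
    ):
        values[alleles[gene] == 1] *= spec.carrier_scale
        values[alleles[gene] == 2] *= spec.affected_scale
    c5oh_alleles = np.maximum.reduce([alleles[g] for g in ("ACAT1", "HLCS", "HMGCL")])
    c5oh[c5oh_alleles == 1] *= config.c5oh.carrier_scale
    c5oh[c5oh_alleles == 2] *= config.c5oh.affected_scale

    # --- incidental VUS ----------------------------------------------------
    vus_mask = rng.random(n) < config.vus_rate
    vus_gene_idx = rng.integers(0, len(_GENES), size=n)

    # --- coverage ----------------------------------------------------------
    depths = None
    if config.include_coverage:
        multiplier = (2.0 - ins) / 2.0
        depths = _draw_panel_depths(
            rng,
            n,
            multiplier,
            config.mean_depth,
            config.dispersion,
            config.efficiency_sigma,
        )

    # --- assemble ----------------------------------------------------------
    samples: list[SimulatedSample] = []
    for i in range(n):
        sid = f"S{i + 1:06d}"
        genotypes = {gene: int(alleles[gene][i]) for gene in _GENES}
        variants: list[VariantCall] = []
        for gene in _GENES:
            n_seq = genotypes[gene] - (int(ins[i]) if gene == "SLC25A13" else 0)
            variants.extend(
                vc for _, vc in _variants_for_gene(rng, sid, gene, n_seq)
            )
        if vus_mask[i]:
            cv = VUS_CATALOG[_GENES[int(vus_gene_idx[i])]]
            variants.append(
                VariantCall(sid, cv.gene, cv.hgvs, Zygosity.HET, cv.classification)
            )
        affected = tuple(
            GENE_CONDITIONS[g] for g in _GENES if genotypes[g] == 2
        )
        carriers = tuple(
            GENE_CONDITIONS[g] for g in _GENES if genotypes[g] == 1
        )
        result = BiochemicalResult(
            sample_id=sid,
            assay=config.assay,
            values={
                Marker.C0: float(c0[i]),
                Marker.CIT: float(cit[i]),
                Marker.C5DC: float(c5dc[i]),
                Marker.C5OH: float(c5oh[i]),
            },
        )
        coverage = (
            _coverage_from_row(sid, depths[i]) if depths is not None else None
        )
        samples.append(
            SimulatedSample(
                sample_id=sid,
                result=result,
                variants=tuple(variants),
                coverage=coverage,
                genotypes=genotypes,
                ins_alleles=int(ins[i]),
                affected_conditions=affected,
                carrier_conditions=carriers,
            )
        )
    return samples


# ---------------------------------------------------------------------------
# Fixture generation


def generate_coverage_fixtures(
    n_carriers: int = 9,
    n_controls: int = 29,
    seed: int = 0,
    mean_depth: float = 800.0,
    dispersion: float = 0.05,
    efficiency_sigma: float = 0.15,
    out_dir=None,
) -> tuple[list[AmpliconCoverage], list[AmpliconCoverage]]:
    """Synthetic CNV validation cohort: het-insertion carriers + controls.

    Mirrors the structure of the caller's wet-lab validation set (9
    long-range-PCR-confirmed carriers against 29 controls) at the
    configured depth model.  Writes ``carriers.tsv``/``controls.tsv`` under
    ``out_dir`` when given.
    """
    if n_carriers < 0 or n_controls < 0:
        raise ConfigurationError("cohort sizes must be >= 0")
    rng = np.random.default_rng(seed)
    multiplier = np.concatenate(
        [np.full(n_carriers, 0.5), np.ones(n_controls)]
    )
    depths = _draw_panel_depths(
        rng, n_carriers + n_controls, multiplier, mean_depth, dispersion,
        efficiency_sigma,
    )
    carriers = [
        _coverage_from_row(f"CAR{i + 1:03d}", depths[i]) for i in range(n_carriers)
    ]
    controls = [
        _coverage_from_row(f"CTL{i + 1:03d}", depths[n_carriers + i])
        for i in range(n_controls)
    ]
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        write_coverage(carriers, out_dir / "carriers.tsv")
        write_coverage(controls, out_dir / "controls.tsv")
    return carriers, controls


def write_cohort(samples: Sequence[SimulatedSample], out_dir) -> None:
    """Write a simulated cohort as the pipeline's input files.

    ``biochem.csv``, ``coverage.tsv`` (when simulated), ``variants.tsv``,
    a per-sample classified VCF under ``vcf/`` for every sample with at
    least one variant, and ``truth.tsv`` with the ground-truth labels.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    write_biochem((s.result for s in samples), out_dir / "biochem.csv")
    with_cov = [s.coverage for s in samples if s.coverage is not None]
    if with_cov:
        write_coverage(with_cov, out_dir / "coverage.tsv")
    all_calls = [v for s in samples for v in s.variants]
    write_variant_table(all_calls, out_dir / "variants.tsv")

    by_hgvs = {
        (cv.gene, cv.hgvs): cv
        for entries in VARIANT_CATALOG.values()
        for cv in entries
    }
    by_hgvs.update({(cv.gene, cv.hgvs): cv for cv in VUS_CATALOG.values()})
    vcf_dir = out_dir / "vcf"
    for s in samples:
        if not s.variants:
            continue
        vcf_dir.mkdir(exist_ok=True)
        records = []
        for vc in s.variants:
            cv = by_hgvs[(vc.gene, vc.hgvs)]
            records.append((cv.chrom, cv.pos, cv.ref, cv.alt, vc))
        records.sort(key=lambda r: (r[0], r[1]))
        write_classified_vcf(vcf_dir / f"{s.sample_id}.vcf", s.sample_id, records)

    truth_lines = ["sample_id\taffected\taffected_conditions\tcarrier_conditions\tins_alleles"]
    for s in samples:
        truth_lines.append(
            "\t".join(
                [
                    s.sample_id,
                    str(int(s.affected)),
                    ";".join(s.affected_conditions),
                    ";".join(s.carrier_conditions),
                    str(s.ins_alleles),
                ]
            )
        )
    (out_dir / "truth.tsv").write_text("\n".join(truth_lines) + "\n")
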