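# Methods

This note documents the models, parameters and design choices behind
`nbscreen`: the two-tier decision rules, the exon-17 allelic-dropout
caller, the cohort simulator and the programme metrics.

## Decision rules

### Triage partition

Each measured analyte is mapped to exactly one of three regions —
negative, second-tier, immediate-recall — by explicit comparators. The
second-tier windows are closed at their printed bounds (C0: 5.0 ≤ v ≤ 6.5;
citrulline: 25 ≤ v ≤ 50 μmol/L) and the immediate-recall extremes are
strict (C0 < 5.0; citrulline > 50), so the three regions tile the
non-negative reals with no gap or overlap; profile construction rejects any
configuration that breaks this partition, and the suite fuzz-tests it.
C5DC and C5OH use strict assay-specific lower bounds with no upper bound
and no immediate-recall region: an arbitrarily high acylcarnitine still
goes through genetics.

Historical single-tier cutoffs (C0 ≤ 6.2, citrulline ≥ 35, C5DC ≥ 0.35,
C5OH ≥ 0.78 μmol/L) are stored once per marker — they predate the
two-assay era — and drive only the comparator
`decide_historical_single_tier`.

### Allele counting

A HOM P/LP variant contributes 2 alleles, HET contributes 1, VUS and
other classifications contribute 0 under every rule version: screening
cutoffs are defined on P/LP only, and counting VUS would re-import exactly
the false-positive burden the second tier exists to remove. Two HET
variants in the same gene count as 2 without phase confirmation — amplicon
panels give essentially no phasing information, and a screening (not
diagnostic) context errs toward recall; confirmatory parental testing
resolves phase downstream. Under the hotspot-era rule version a het/hom
exon-17 dropout call adds 1/2 *SLC25A13* allele(s); earlier versions
ignore the CNV call entirely, which reproduces the documented near-miss
mode in which a compound het (one sequence variant, one insertion) screens
negative on sequence analysis alone.

### Rule versions

Rule versions are explicit configuration values, not date arithmetic
(`rule_version_for_date` is provided as a convenience): the initial rules
(one allele suffices in the borderline citrulline band), the refined rules
(two alleles in the band), and the hotspot-era rules (refined + CNV
counting). Dominance holds by construction: the refinement only removes
recalls. When the hotspot-era rules are selected but coverage (or a
control reference) is missing for a sample whose citrulline decision could
flip with a CNV call, the sample is flagged `needs_review` rather than
silently decided.

Multi-indication samples get one sequencing test but independent per-marker
gene-panel decisions; the recall flag is their OR. A C5OH recall carries
all three candidate condition labels, since the analyte cannot
discriminate them. One profile ambiguity is handled explicitly: in the
replay set, one carnitine-uptake-defect case is recorded with C0 just above
the configured second-tier window, so the replay harness feeds recorded
indications straight into the second-tier decision instead of re-deriving
triage; consistently, the value-window precondition is enforced only for
citrulline, the single marker whose value enters the genotype rule.

## Exon-17 dropout caller

Normalisation divides each amplicon's depth by the sample median depth
computed *excluding the exon-17 amplicon*, so a genuine dropout cannot
depress its own baseline; the median (rather than the mean) is robust to a
single failed amplicon. The reference is the per-amplicon mean ± SD of
normalised depths over ≥ 2 control samples — by default a supplied control
cohort; nothing prevents using a historical baseline as the reference
object. The copy ratio divides the sample's normalised exon-17 depth by
the control mean, cancelling amplicon efficiency, and is banded:

- HOM dropout: ratio < 0.15
- HET dropout: 0.35 ≤ ratio ≤ 0.65
- normal: ratio ≥ 0.80
- otherwise INDETERMINATE (surfaced, never forced to a call)

Bands centre on the theoretical ratios 0 / 0.5 / 1 with symmetric noise
margins and are configurable; band coherence (no overlap) is validated at
construction. Calls are additionally forced INDETERMINATE when the control
exon-17 mean raw depth is below 100×, where the ratio estimate is
unstable. The procedure is scale-invariant in the sample's total yield.

## Cohort simulator

The simulator draws what the decision rules consume, with ground truth:

- **Genotypes** under Hardy–Weinberg. The citrin-deficiency carrier rate
  defaults to 1/40; the allele frequency is obtained by exact inversion
  q = (1 − √(1 − 2c))/2 so the expected carrier fraction equals the
  configured rate. Each pathogenic *SLC25A13* allele is independently the
  IVS16ins3kb insertion with probability 1 − √0.6 ≈ 0.225, which makes 40%
  of affected cases carry at least one insertion allele (the hotspot is
  common, but no published mixture fraction exists; configurable). The
  other five genes default to 1/200 carrier rates — placeholder values,
  not population estimates.
- **Citrulline.** Healthy newborns draw from a log-normal calibrated in
  closed form (mu = ln median, sigma from the normal 99th-percentile
  quantile) so that P(X > 25 μmol/L) = 0.01 exactly, anchoring the
  first-tier cutoff at the healthy 99th percentile; the default median is
  12 μmol/L. Affected CD cases draw from a triangular distribution on
  17–34 μmol/L whose mode is solved so the median is 26 — i.e. below the
  old 35 μmol/L single-tier cutoff, which is the false-negative mechanism
  of interest. Carriers draw the healthy distribution scaled by 1.3,
  producing borderline-band elevations (the carrier false-positive
  mechanism); the paper trail for a carrier distribution does not exist,
  so the scale is configurable.
- **Other analytes.** Healthy C0/C5DC/C5OH are log-normal placeholders
  (medians 30 / 0.06 / 0.25 μmol/L, sigma 0.45 / 0.37 / 0.37) chosen so the
  per-marker second-tier trigger fractions sit at a realistic order of
  magnitude — a citrulline-dominated total around 1–2% of samples — with
  multiplicative carrier/affected shifts (e.g. affected carnitine-uptake
  cases at scale 0.18, landing near and below the 5.0–6.5 band). These are
  structural stand-ins, not fitted population distributions; conclusions
  about real analyte distributions cannot be read off them.
- **Coverage.** Per-amplicon depths are negative-binomial around
  mean_depth × amplicon efficiency, with efficiencies log-normal
  (sigma 0.15) and the exon-17 expectation scaled by the fraction of
  amplifiable alleles (1, 0.5, 0). Dispersion is parameterised as an
  excess-variance factor d with Var = μ(1 + d), default d = 0.05 (d = 0
  recovers Poisson): after median normalisation and reference division,
  run- and amplicon-level effects cancel, and the residual per-amplicon
  noise of a well-behaved panel is mildly super-Poissonian. The default
  depth is 800×.
- A 2% incidental VUS rate exercises classification filtering.

Everything is drawn from one `numpy` generator in fixed order, so a seed
determines the cohort byte-for-byte, including written fixture files.

What passing simulator-based tests shows: the *mechanisms* — borderline
affected cases invisible to the single-tier rule but recalled by the
two-tier rules, carriers recalled only under the initial rules, insertion
alleles recovered only via the dropout caller — and the caller's
separation at realistic depths. What it does not show: the real
programme's specific integers (numbers of second-tier tests, historical
false-positive rates), which depend on unpublished population analyte
distributions and are deliberately out of the simulator's scope.

## Metrics

Confusion counts use the screening-sense definitions (FP = recalled,
confirmed carrier/unaffected); TN is always derived as
total − (TP + FP + FN), never supplied. Rates are exact
`fractions.Fraction`s with display strings at reporting precision: two
significant figures for cohort-level percentages, one decimal place for
indication-mix percentages; formatting is idempotent under parse/reformat.
Sensitivity with zero affected cases reports "undefined", not 100%.

## Problem sizes and numerical choices

The test suite and the acceptance script size their simulations as: 100
seeded replicates of the 9-carrier / 29-control CNV validation shape at
800× (separation), n = 100,000 for carrier-fraction and Hardy–Weinberg
checks (expected ~16 homozygotes, enough for a stable chi-square),
n = 2,000 × 30 replicates in an inflated-frequency regime for the
HWE-across-replicates property (at the default 1/40 rate the homozygote
class is too sparse for a per-replicate chi-square at small n), and
10⁶ Monte-Carlo draws for the calibration tail check. The HWE chi-square
uses df = 2 since the allele frequency is known a priori rather than
estimated from the table.

## Known limitations

- No ACMG classification, annotation or alignment: classifications arrive
  in the input, and coordinates in VCFs are carried, never interpreted.
- The CNV caller tests a single configured target; it is not a segmenting
  multi-exon caller and does not resolve breakpoints.
- Citrulline > 50 μmol/L is emitted as an undifferentiated immediate
  recall; distinguishing citrullinemia type I / argininosuccinic acidemia
  / CD is confirmatory territory.
- Phase is never inferred; two same-gene het P/LP variants count as
  biallelic for screening purposes.
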