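# Methods

This note documents the statistical model behind `csftdna`, the design
choices made where several formulations were defensible, and what the
bundled simulator does and does not emulate.

## Problem setting

Patients with advanced lung cancer and suspected leptomeningeal disease
(LMD) undergo lumbar puncture; CSF, plasma and tissue are sequenced with a
targeted capture panel to a deduplicated (molecular-barcode-collapsed)
depth. The package starts from per-position count tables — deduplicated
depth and alternate-allele count per (chrom, pos, ref, alt) — and produces
tumor-DNA quantification, detection calls, copy-number calls, resistance
comparisons and clinical statistics. Read alignment, barcode deduplication
and wet-lab steps are upstream and out of scope.

## Background error model

Deep targeted sequencing has position- and substitution-specific
("stereotyped") error rates. We estimate them by pooling tumor-free control
samples: for each (position, substitution),

    error_rate = (sum of control alt counts + a) / (sum of control depths + b).

Pseudocounts keep every rate strictly positive, which the Monte Carlo null
requires. Two policies exist:

- **`"shrink"` (default)** — `b = m`, `a = m × pooled_rate`, where
  `pooled_rate` is the panel-wide alt fraction over all controls and
  `m = 1000` is the prior pseudo-depth. This shrinks each position toward
  the global background. An absolute pseudocount (e.g. `a = 0.5`) instead
  shrinks toward a fixed *count*, which at a true rate of ~1e-4 and a pooled
  control depth of tens of thousands inflates the rate by tens of percent
  and makes the null detectably too heavy; the shrinkage prior removes that
  bias while preserving positivity.
- **explicit `(a, b)`** — the classical form, available for reproducing
  fixed-pseudocount behaviour.

Positions with zero pooled control depth are flagged unusable rather than
assigned a rate; downstream stages either skip them (caller, with a QC
count) or raise (detection index, where a silent skip would bias the
statistic's meaning).

## Tumor-naive variant calling

A variant is called at a position when the one-sided binomial tail
probability `P(X ≥ alt_count)` with `X ~ Binomial(depth, error_rate)` falls
at or below `alpha / n_tests` (Bonferroni over the panel positions,
`alpha = 0.05`). An alt count of zero is never called. This is a
transparent stand-in for proprietary adaptive callers: it is exactly
testable and preserves the error-suppression intent.

Filters applied to candidates, in order:

1. **Germline exclusion** — a candidate is removed when its VAF in the
   matched germline sample is at or above `germline_vaf_threshold`
   (default 0.02, boundary inclusive — tolerant of index hopping while
   catching heterozygous and homozygous SNPs), or when the same binomial
   test calls it in the germline. The VAF rule only applies where the
   germline covers the position at ≥ 20× so a stray read over negligible
   depth cannot masquerade as a SNP. A missing germline sample either
   fails the patient or passes candidates through with a
   `germline_checked=False` flag, by policy. No population-database filter
   is applied; matched germline is the only SNP source.
2. **Coding filter** — only positions flagged protein-coding in the panel
   survive; unannotated positions count as non-coding and are logged.

The **reporter set** is the union of filtered calls across the patient's
baseline samples (tumor and pleural-effusion samples always; CSF/plasma
when pre-treatment), with per-variant provenance. The construction is
invariant to sample ordering.

## Detection index

The sample-level burden statistic is the unweighted arithmetic mean VAF
over reporters with depth > 0 (zero-depth reporters are excluded from both
the observed and the null statistic, symmetrically; zero *evaluable*
reporters is an explicit undefined result, never 0). The index is

    index = (1 + #{null mean VAF ≥ observed}) / (B + 1),

with B = 10,000 null draws `Binomial(observed depth, error_rate)` per
reporter. The `+1` makes the index a valid p-value with lower bound
1/(B+1). The null **conditions on the observed depths** rather than
resampling them: depth carries no tumor signal in this design, and
conditioning removes a nuisance dimension. Detection is declared at
index ≤ 0.05, boundary inclusive.

Random streams are derived per (seed, sample id, reporter-set content
hash), so adding or removing other samples from a run never changes a
sample's index.

The mean over reporters matches the study's quantification statistic; a
precision-weighted mean would be more efficient when depths vary strongly
across reporters but would decouple the null statistic from the reported
burden estimate, so it was not adopted.

## Copy-number calling

Per gene: normalized depth = (mean depth over the gene's panel positions) /
(mean depth over all panel positions), which cancels library size. Against
a background cohort (any designated control set; its identity is recorded
in output), `z = (x − mean_bg) / sd_bg` with the unbiased sd, and
`log2_ratio = log2(x / mean_bg)`. Calls use symmetric thresholds
`z_amp = z_del = 3` (conventional 3-sigma focal-event calling; the
thresholds are configurable and no GC or mappability correction is applied
— panel-normalized counts and the simulator induce none; a correction layer
is the natural extension point). Genes whose background sd is zero are
flagged uncallable. Background self-consistency is assessed by
leave-one-out z-scores; note that at n background samples these are
`sqrt(n/(n−1))`-scaled t-variates with n−2 degrees of freedom, so their
standard deviation sits slightly above 1 (≈1.09 at n = 20) even under a
perfect model.

## Resistance analysis

Post-TKI alterations are restricted to whitelists (SNVs: EGFR, PIK3CA,
KRAS, CDKN2A, RB1, ALK, KIT, MET; CNVs: MET, ERBB2, EGFR), with "exonic"
enforced through the panel's coding flag. An alteration is **emergent**
when present post and absent pre, identity being (chrom, pos, ref, alt)
for SNVs and (gene, direction) for CNVs. Absence is strict non-detection
*plus* a coverage guard: if the pre-TKI sample covers the position below
50×, emergence is not claimed (logged `low_pre_depth`) — an uncovered
position cannot certify absence. Plasma/CSF comparisons require samples
collected within 14 days of each other (inclusive), and every emergent
alteration lands in exactly one of plasma-only / CSF-only / shared.

## Clinical statistics

**LMD classification.** Study scheme: *definitive* = positive cytology or
positive clinical EGFR CSF PCR, or unequivocal MRI evidence together with
progressive symptoms; *possible* = symptoms or MRI findings short of that;
otherwise non-LMD. EANO–ESMO: *confirmed* = cytology-positive; *probable* =
cytology-negative with MRI findings and symptoms; *possible* = symptoms
with negative cytology and MRI. Unknown fields count as negative and clear
a completeness flag, since the classification rules admit no unknown
branch.

**Sensitivity** of a modality = positives / evaluable definitive-LMD
patients, reported with numerator and denominator so denominators can be
audited.

**Survival.** Two-group log-rank test with the standard hypergeometric
variance at tied event times; p from the 1-df chi-square tail. Two hazard
ratios are reported: the O/E form `(O2/E2)/(O1/E1)` with log-normal CI via
`se(log HR) = sqrt(1/E1 + 1/E2)` (the form commercial survival software
derives from the log-rank table), and the Cox partial-likelihood HR. The
O/E form is exactly reproducible by hand from the log-rank table but is
intrinsically attenuated toward 1 for large effects — in simulation it
saturates near 4 when the generating ratio is 6.6 while the Cox estimate
recovers the truth — so effect-size recovery is validated on the Cox field
and both are exposed. A group with zero events yields an undefined HR
(None) while the p-value is still computed.

**Rank statistics.** Spearman correlation and Mann–Whitney U use average
ranks for ties and two-sided p-values; the Mann–Whitney null is exact for
combined n ≤ 20 without ties, normal-approximated with tie correction
otherwise. Constant vectors are an explicit undefined result.

**Median dichotomization** uses the midpoint convention for even n and
places ties at the median in the at-or-below (lower-risk) group.
**Penetration rate** = 100 × CSF / plasma drug concentration (undefined at
zero plasma). **VAF percent change** = 100 × (post − pre)/pre; a new
detection (pre = 0, post > 0) is reported as such, not as a percentage.

## Synthetic cohort generator

The generator's defaults encode the study conditions: 24 patients, CSF
mean-VAF median 32.7% vs plasma 1.8% (correlated log-normals, ρ = 0.45,
exposed as a knob since only the sign and rough size of the correlation is
established), deduplicated depth medians 150× (CSF), 1879× (plasma), 1099×
(germline), per-position error rates Beta-distributed with mean 1e-4, and
~20% of patients tumor-DNA-negative in CSF/plasma.

Mechanics and assumptions:

- **Tumor-fraction parameterization.** Reporters share a clonal VAF of 0.5
  (heterozygous, copy-neutral clonal mutations), so a sample with tumor
  fraction `tf` has expected reporter VAF `tf × 0.5`. The configured
  medians are on the *observed mean-VAF* scale (what the assay reports);
  the internal tumor fraction is the target divided by the clonal VAF,
  clipped at 1. Clipping truncates only the upper tail, leaving the median
  intact. An optional subclone fraction at half the clonal VAF is off by
  default so bias checks stay interpretable.
- **Depths** are negative-binomial around the compartment mean (dispersion
  parameter 20) — capture data are over-dispersed relative to Poisson.
- **Counts**: alt ~ Binomial(depth, clip(tf × truth_vaf + constant_vaf +
  error_rate, 0, 1)); `constant_vaf` carries tumor-fraction-independent
  signal (five heterozygous germline SNPs per patient, present at 0.5 in
  every compartment, exercising SNP exclusion end to end).
- **Samples per patient**: germline, baseline tumor biopsy (purity 0.6),
  baseline CSF and plasma; half the cohort gets post-treatment CSF+plasma
  at day 180 with a log-normal burden drift. A tissue sample exists for
  every patient because reporter sets in the emulated study derive from
  tumor/pre-treatment material — without it, a CSF/plasma-negative patient
  would have no reporters and the survival contrast would be degenerate.
- **Resistance scenarios**: ~30% of patients gain a plasma-restricted
  emergent SNV in a whitelist gene at half the clonal VAF; a subset
  additionally carries an emergent 3-fold MET amplification, applied as a
  depth multiplier on the gene.
- **Error-model controls**: 30 tumor-free samples at plasma-like depth.
  The pooled per-position control depth (~56,000×) keeps the rate
  estimation noise small enough for a calibrated Monte Carlo null; a
  handful of shallow controls would not.
- **Clinical fields**: cytology positivity is logistic in log10 tumor
  fraction (intercept 2.46, slope 1.5 on the VAF scale), which reproduces
  cytology-negative/tDNA-positive patients at low burden; MRI, symptoms and
  PCR are burden-conditional Bernoullis. Overall survival is exponential
  with baseline hazard ln2/730 per day (24-month median in tDNA-negative
  patients), multiplied by a configurable hazard ratio (default 6.6) when
  CSF-tDNA is positive, censored at 1500 days. Osimertinib plasma
  concentrations are log-normal around 500 nM with a ~2.5% median CSF
  penetration ratio.
- **Determinism**: one master seed; every sample draws from a child stream
  keyed by CRC-32 hashes of (patient, compartment, timepoint), so outputs
  are byte-identical under a fixed seed and insensitive to cohort
  composition changes elsewhere.

**What the simulator does not emulate** — and hence what passing tests do
not establish about real data: read-level artifacts (strand bias, fragment
length, UMI family structure), GC/mappability coverage waves, trinucleotide
error context, indels and structural variants beyond generic alleles,
clonal heterogeneity beyond a single optional subclone level, informative
censoring, and correlation between error rates of neighbouring positions.
Real-data calibration of the error model and caller thresholds must be
re-established per assay.

## Numerical conventions

- Boundary inclusivity: detection at index ≤ cutoff; germline exclusion at
  VAF ≥ threshold; SCNA calls at z ≥ z_amp / z ≤ −z_del; the 14-day
  time-match window includes day 14.
- The detection index never reaches 0 (pseudocount) and mean VAF over zero
  evaluable reporters, correlations of constant vectors, penetration at
  zero plasma and percent change from zero all raise an explicit
  undefined-result error instead of returning a sentinel.
- Bonferroni uses the panel position count as the test family size by
  default, independent of how many positions a particular sample covers,
  so thresholds do not drift with coverage dropout.
- Coordinates are 1-based inside the package (counts, VCF); BED
  serialization converts to 0-based half-open in the I/O layer only.

## Validation scales

The statistical checks run at desk scale, chosen to bound Monte Carlo
error without excess: 1000 null samples (B = 10,000) for index calibration,
200 samples for power and copy-number power, 300 samples for family-wise
error, a 100-patient cohort for quantification recovery, 200 replicate
cohorts per hazard ratio for survival recovery, and 30 replicate background
cohorts (n = 20) for the leave-one-out calibration.

## Known limitations

- The binomial caller ignores overdispersion beyond the position-specific
  rate; a beta-binomial tail is the natural refinement if control
  replicates show residual dispersion.
- Error rates are keyed by (position, alt), not trinucleotide context;
  context pooling would stabilize rates at thinly covered positions.
- The O/E hazard ratio should not be read as an unbiased effect size when
  it is large; use the Cox field (both are reported).
- Gene-level copy-number calling cannot resolve sub-genic events or
  allele-specific copy number, and purity/ploidy are not modelled.
- The resistance logic treats non-detection as absence subject only to a
  depth guard; a formal absence posterior (from the error model) would be
  stricter.
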