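# Methods

## Scope and model

`ppglval` implements the analytical-validation workflow of an NGS-based
germline test for pheochromocytoma/paraganglioma (PPGL) susceptibility
genes.  Germline predisposing variants in this setting are heterozygous,
so a true call should show a ~1:1 ratio of reference and alternate reads
at its site.  The package treats that expectation as a quantitative QC
statistic and builds the whole validation chain on top of it: per-call
allele-fraction statistics, a symmetric allele-fraction acceptance window,
an ordered filter cascade with a per-stage audit, truth-set concordance
(sensitivity/specificity), per-gene coverage assessment, read-backed
cis/trans phasing, and cohort diagnostic-yield summaries.

Alignment, variant calling and annotation are out of scope: the pipeline
consumes already-called variants (VCF with FORMAT/AD, or a flat TSV) whose
annotations (consequence, population MAF, ACMG class, PolyPhen, SIFT) are
input fields.

## Allele-fraction statistics

For a call with `r` reference and `a` alternate reads:

* alternate fraction `f = a / (r + a)` (the statistic all windows are
  defined on; a 27/23 call has `f = 0.46`);
* allele balance `100 · min(r, a) / max(r, a)` (the "how balanced" form:
  15/20 reads give 75%).  The two are deterministic functions of each
  other (`balance = 100 · min(f, 1−f)/max(f, 1−f)`), and both are exposed
  because both formulations are in routine laboratory use.

A symmetric acceptance window `[50−d, 50+d]` percent retains a call iff
`lower ≤ 100·f ≤ upper`, bounds inclusive (the exclusion rule is strict:
a call is dropped only when its fraction is strictly below the lower or
strictly above the upper bound).  Comparisons carry a 1e-9 tolerance so
fractions that are exact decimals (9/30 = 0.3) are not lost to float
representation.

The *tightest symmetric window* over a call set is `[50−d*, 50+d*]` with
`d* = max |100·f − 50|`.  Bounds are rounded **outward** (floor on the
lower, ceiling on the upper) at the requested precision (integer or one
decimal).  Outward rounding is the only scheme under which the reported
window always contains every input call and coincides with a narrowest-
window grid-scan oracle at the reporting precision; half-up rounding can
round a bound inward past the binding call.  On the packaged
read-count reconstruction it yields 27–73% for the BGI/Complete Genomics
calls and 44.8–55.2% for the Agilent calls.  For the Rapid Capture calls
the max-deviation definition gives 45.2–54.8%; the historically reported
45.4–54.6% band mirrors only the largest fraction and excludes the
printed 93/77 call (45.3%) — the discrepancy is asserted in a test and
that band is not treated as a correctness target.

## Filter cascade

Stages run in a fixed order — region, consequence, common, benign, depth,
blacklist, allele fraction — and each stage records its removals, so the
audit telescopes (stage k's survivors are stage k+1's input; removals plus
final survivors partition the input).  All stages are per-call predicates,
so the surviving *set* is invariant under stage permutations; a test
asserts this on random fixtures.

* **region** — keep calls inside any panel interval expanded by the
  intronic padding (default ±30 bp, matching exon±30 bp probe designs).
* **consequence** — drop UTR, intronic and synonymous calls.  Splice-site
  calls (consequence `splice`, or an HGVS c. offset of ±1/±2 such as
  `c.286+2T>A`) are never dropped as intronic: such variants are
  reportable findings.
* **common** — drop calls with known population MAF strictly above 1%
  (`MAF = 0.01` exactly is kept).
* **benign** — drop calls matching the conjunction: ACMG benign AND
  PolyPhen benign AND SIFT not deleterious.  The SIFT clause direction is
  configurable (`sift_literal`): the conventional reading treats
  SIFT < 0.05 as deleterious evidence vetoing the benign call; the literal
  reading of some published filter descriptions requires SIFT < 0.05 for
  the rule to fire.  The conventional reading is the default so a likely
  transcription error cannot discard damaging variants.
* **depth** — per-allele minimum read count: heterozygous (and
  unknown-zygosity) claims need the minimum on *both* alleles, homozygous
  claims on the alternate only.  Defaults per platform profile: 10
  reads/allele for the Illumina exome workflows, 5 for Complete Genomics,
  20 (40x) for the targeted panel.
* **blacklist** — exact (chrom, pos, ref, alt) matches to known
  systematic artifacts, motivated by reference-mismatch loci: where the
  reference genome carries the minor allele of a common polymorphism
  (the MEN1 rs2959656 situation), nearly every sample yields a spurious
  heterozygous call.
* **allele fraction** — keep calls inside the configured window
  (default 30–70%).

Unknown-annotation policy: unknown MAF, ACMG class and consequence are
retained (a diagnostic pipeline must not silently discard unassessed
variants); unknown consequence is additionally flagged in the audit.

## Truth-set concordance

Matching is by normalized (sample, chrom, pos, ref, alt).  Normalization
trims shared suffix then shared prefix bases and adjusts the position —
the reference-free part of indel left-alignment.  Full left-shifting
through repeat tracts would need the reference sequence and is a
documented limitation.

TP/FN are counted truth-side (a confirmed variant is detected or missed);
FP are surviving calls matching no truth variant.  TN require a negative
universe and two modes are provided:

* **per_variant** (default): TN are artifact calls — members of the
  pre-filter call universe matching no truth variant — that the cascade
  eliminated.  On the packaged v1.0 validation cohort this reproduces
  113/114 = 99.1% specificity.
* **per_position**: TN are bases of Sanger-confirmed wild-type spans not
  falsely called; provided as the alternative denominator convention.

Sensitivity for the v1.0 cohort is computed over the pathogenic-classified
truth subset.  This follows from the cohort's published accounting, which
does not close under any single-denominator reading (41 true calls vs 12
pathogenic + 2 VUS + 25 retained polymorphisms): the encoded reading is
that the two remaining true calls are common polymorphisms removed by the
MAF stage — correct clinical behaviour that must not count against
sensitivity of mutation detection.  All of these choices are constants in
one fixture-builder module.

## Window grid and optimization

`window_grid` applies *only* the allele-fraction window to each platform's
calls and tabulates detected / false-negative / false-positive counts per
platform × window; sensitivity is non-increasing as the window narrows
(nested windows give nested detected sets — property-tested).
`optimize_window` returns the tightest symmetric window over truth-matched
calls; re-evaluating it through the grid always gives 100% sensitivity,
and one rounding step narrower gives less.

## Coverage

Per-gene mean depth follows bedcov semantics: sum of per-base depth over
the gene's merged CDS intervals divided by merged length, with positions
absent from the depth table counting as zero.  Overlapping intervals are
merged first so no base contributes twice; the mean is invariant under
interval splitting and equals the length-weighted mean of per-exon means
(both property-tested).  The SD is per-base over the same span (the
across-samples alternative would need multi-sample depth input; with it,
per-position depths are averaged across samples first).  Under-coverage
flagging takes a mean-depth floor and a minimum fraction of bases above a
depth threshold, returning worst-first.

## Phasing

Input is a read × variant support matrix (`alt`/`ref`/`none`), extracted
upstream of this package.  Reads covering ≥2 sites are informative.  The
verdict is cis when at least a concordance threshold (default 0.9) of
informative reads are all-alt or all-ref at their covered sites *and*
both classes hold at least `min_informative_reads` (default 5) — the
"half the reads fully mutant, half fully wild-type" picture; trans when
alt-supporting reads of different variants are near-disjoint (at most
1 − threshold of alt-carrying informative reads carry alt at ≥2 sites,
with ≥2 variants each having the minimum alt support); otherwise
ambiguous (including zero informative reads, which is a result, not an
error).  The thresholds are this package's own defaults: tolerant of
sequencing error yet requiring real evidence on both haplotype classes.
The statistic depends on co-segregation only, so globally swapping
alt↔ref maps cis to cis, and read/variant order never matters.

## Synthetic data

The generator emulates the statistical structure the analysis assumes:

* site depth ~ negative binomial (mean per platform, dispersion k = 8–10;
  exome means 100–150x, panel 150x, matching the ≥100x means the
  platforms deliver), with optional per-gene capture-efficiency factors —
  the Agilent-like profile depresses SDHA/SDHC/SDHD to 20–25%, planting
  the under-coverage pattern the coverage module must flag;
* true-het alternate reads ~ binomial(depth, 0.5) at
  `af_overdispersion_rho = 0`, else beta-binomial with that intra-class
  correlation (concentration `(1−rho)/rho`, symmetric shapes).  Defaults:
  rho = 0.04 for the BGI-like profile, 0.005 elsewhere — tuning constants
  chosen so simulated tightest windows bracket the wide (~27–73%) vs
  narrow (~45–55%) platform behaviour, not measured values;
* artifact calls at an expected rate per sample (default 6) with
  alternate fractions drawn 85% outside the 30–70% band (mostly
  low-fraction noise) and 15% inside;
* a reference-mismatch locus emitted as a genuine binomial het in every
  sample.

`clean` mode clamps true-het reads into the window and above the depth
minimum, making generated truth unremovable by construction (used for
conservation tests).  What the simulator does *not* model: strand bias,
mapping-quality structure, error-motif context, CNVs, somatic fractions
and inter-sample contamination — so passing tests demonstrate the
pipeline's arithmetic and decision logic, not robustness to every failure
mode of real libraries.

Alongside the simulator, deterministic fixtures reconstruct the
validation cohorts at desk scale: the 20-sample WES cohort with the 13
printed per-call read-count pairs, the 15-sample panel v1.0 cohort (155
coding calls: 41 true, 114 artifacts of which 15 are the
reference-mismatch locus and exactly one other is in-window), and the
76-patient cohort findings and novel-variant tables shipped as packaged
TSVs.  Positions use synthetic per-gene coordinate blocks; the fixtures
are labelled synthetic reconstructions, not sequencing data.

## Problem sizes and numerical choices

All fixture computations are instantaneous; Monte-Carlo checks use 10^4
draws for the binomial false-negative-rate comparison (asserted within 3
standard errors), 30 replicates for the overdispersion window-width
ordering, and 40 seeded trials for phasing recovery.  Window membership
uses a 1e-9 absolute tolerance; window bounds are quantized with decimal
floor/ceiling after snapping float noise at 1e-7.  Degenerate inputs
raise rather than guess: zero-read fraction requests, empty call sets for
window optimization, empty cohorts for yield, genes absent from a panel.

## Known limitations

* Indel matching is trim-normalization only (no reference-aware
  left-alignment), so representations anchored on different repeat copies
  may fail to match.
* Specificity in per-variant mode depends on the artifact universe
  supplied; without a pre-filter universe TN is zero and specificity
  undefined.
* The coverage SD convention (per-base within platform) is one of two
  defensible readings of "mean ± SD" per gene.
* Caller-internal quality annotations (QD, ReadPosRankSum) are not
  re-evaluated; calls are taken as emitted.
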