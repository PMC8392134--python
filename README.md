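# ppglval

Analytical-validation toolkit for NGS-based germline testing of
pheochromocytoma/paraganglioma (PPGL) susceptibility genes — for clinical
molecular-genetics laboratories validating a targeted panel or exome
workflow against Sanger-established truth sets.

Germline PPGL-predisposing variants are heterozygous, so a true call
should carry a ~1:1 ratio of reference and alternate reads.  `ppglval`
turns that expectation into a quantitative QC chain:

* **Allele-fraction statistics** — per call with `r` reference and `a`
  alternate reads, the alternate fraction `f = a/(r+a)` and the allele
  balance `100·min(r,a)/max(r,a)`; a symmetric acceptance window
  `[50−d, 50+d]` % retains a heterozygote iff `lower ≤ 100f ≤ upper`
  (bounds inclusive).  The *tightest* such window over a truth cohort,
  `d* = max|100f − 50|` with outward rounding, is the narrowest
  allele-fraction band that keeps sensitivity at 100%.
* **Filter cascade** — region (panel exons ± 30 bp), consequence
  (UTR/intronic/synonymous out, splice-site protected), common variants
  (MAF > 1%), a benign conjunction rule (ACMG ∧ PolyPhen ∧ SIFT), a
  per-allele depth minimum, a reference-mismatch blacklist, and the
  allele-fraction window — with a telescoping per-stage audit.
* **Truth-set concordance** — sensitivity `100·TP/(TP+FN)` and
  specificity `100·TN/(TN+FP)`, per-variant (TN = eliminated artifact
  calls) or per-position (TN over Sanger-confirmed wild-type bases).
* **Coverage, phasing, yield** — bedcov-style per-gene mean CDS depth
  with under-coverage flagging, read-backed cis/trans phasing from
  read-support matrices, and cohort diagnostic-yield tables.
* **Synthetic data** — a seeded generator (negative-binomial depths,
  binomial/beta-binomial het fractions, skewed artifact fractions, a
  reference-mismatch locus in every sample) plus deterministic fixtures
  reconstructing the validation cohorts at desk scale.

## Worked example

Run the filter cascade on the packaged panel v1.0 validation cohort
(15 samples, 155 coding calls of which 41 are Sanger-confirmed):

```text
$ ppglval filter --fixture v1 --out-dir runs/v1
155 calls in, 40 surviving; audit written

$ cat runs/v1/audit.tsv
stage	input_count	removed_count	surviving_count
region	155	0	155
consequence	155	0	155
common	155	2	153
benign	153	0	153
depth	153	0	153
blacklist	153	15	138
afr	138	98	40
```

The blacklist stage removes the 15 copies of the reference-mismatch
locus (one per sample: the reference genome carries the minor allele of a
common MEN1 polymorphism, so every sample is spuriously "variant" there);
the 30–70% allele-fraction window then removes 98 of the 99 remaining
artifact calls.  Scoring the survivors against the truth set:

```text
$ ppglval validate --fixture v1 --out-dir runs/v1
sensitivity 100.0%, specificity 99.1%
```

All 12 pathogenic-classified truth variants survive (sensitivity 100%),
and 113 of the 114 artifact calls are eliminated (specificity
113/114 = 99.1%).  The platform-specific allele-fraction windows are
recovered from the exome cohort's printed per-call read counts:

```text
$ ppglval validate --fixture table1 --optimize --out-dir runs/opt
agilent_sureselect: 44.8-55.2
bgi_complete_genomics: 27.2-72.8
illumina_rapid_capture: 45.2-54.8
```

(with integer rounding the BGI/Complete Genomics window is 27–73: the
wider heterozygote allele-fraction spread of that library preparation
demands a wider acceptance band).  Cohort diagnostic yield:

```text
$ ppglval yield --cohort ep2 --out-dir runs/yield
10/37 carriers (27.0%)
```

i.e. 10 of the 37 prospectively tested panel v2.0 patients carry a
pathogenic or likely pathogenic variant.

The same operations are available as a library:

```python
from ppglval import balance_ratio, tightest_symmetric_window
balance_ratio(15, 20)   # 75.0 — a 15/20-read het is 75% balanced
```

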