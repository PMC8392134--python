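"""Deterministic desk-scale fixtures reconstructing the validation cohorts.

Three reconstructions are provided:

* the WES analytical-validation cohort — 20 samples across three exome
  library preparations, 13 of which carry a known mutation with exact
  per-allele read counts (the inputs from which the platform-specific
  allele-fraction windows are derived);
* the targeted-panel v1.0 validation cohort — 15 samples, 155 coding
  calls (41 true, 114 artifacts including a reference-mismatch locus
  called in every sample), constructed so the full filter cascade yields
  100% sensitivity over the pathogenic truth subset and 113/114 = 99.1%
  specificity over the artifact universe;
* the prospective cohort tables (variant findings and novel variants),
  shipped as packaged TSVs.

The v1.0 cohort's published aggregate counts do not close exactly (41
true calls vs 12 pathogenic + 2 VUS + 25 polymorphisms retained); this
builder encodes the consistent reading: the two remaining true calls are
common polymorphisms removed by the MAF stage, and sensitivity is defined
over the pathogenic-classified truth subset.  Every such choice is a
constant in this file.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from typing import Dict, List, Tuple

import pandas as pd

from .cascade import FilterConfig
from .models import (
    AcmgClass,
    BlacklistEntry,
    Consequence,
    PanelDesign,
    PlatformProfile,
    TruthRecord,
    TruthStatus,
    VariantCall,
    Zygosity,
)
from .simulate import (
    DEFAULT_PROFILES,
    GENE_REGIONS,
    REFERENCE_MISMATCH,
    default_panel,
)

AGILENT = "agilent_sureselect"
CG = "bgi_complete_genomics"
RAPID = "illumina_rapid_capture"


def _pos(gene: str, offset: int) -> Tuple[str, int]:
    chrom, start, _ = GENE_REGIONS[gene]
    return chrom, start + offset


# One row per mutation-positive WES sample: (sample, platform, gene,
# transcript, hgvs_c, hgvs_p, ref allele, alt allele, CDS offset,
# consequence, ACMG class, ref reads, alt reads).
_WES_ROWS = [
    ("1/F1", AGILENT, "SDHB", "NM_003000.3", "c.586T>G", "p.Cys196Gly", "T", "G", 586, Consequence.MISSENSE, AcmgClass.PATHOGENIC, 27, 23),
    ("2/F1", AGILENT, "SDHB", "NM_003000.3", "c.586T>G", "p.Cys196Gly", "T", "G", 586, Consequence.MISSENSE, AcmgClass.PATHOGENIC, 26, 32),
    ("5", CG, "SDHB", "NM_003000.2", "c.649C>T", "p.Arg217Cys", "C", "T", 649, Consequence.MISSENSE, AcmgClass.PATHOGENIC, 36, 23),
    ("6", CG, "SDHB", "NM_003000.2", "c.758G>A", "p.Cys253Tyr", "G", "A", 758, Consequence.MISSENSE, AcmgClass.PATHOGENIC, 23, 33),
    ("7", CG, "SDHB", "NM_003000.3", "c.728G>A", "p.Cys243Tyr", "G", "A", 728, Consequence.MISSENSE, AcmgClass.PATHOGENIC, 14, 23),
    ("8", CG, "SDHB", "NM_003000.2", "c.286+1G>A", "", "G", "A", 287, Consequence.SPLICE, AcmgClass.PATHOGENIC, 17, 17),
    ("9", CG, "SDHB", "NM_003000.2", "c.607G>T", "p.Gly203*", "G", "T", 607, Consequence.NONSENSE, AcmgClass.PATHOGENIC, 21, 12),
    ("10", CG, "SDHC", "NM_003001.3", "c.405+1G>T", "", "G", "T", 406, Consequence.SPLICE, AcmgClass.PATHOGENIC, 29, 21),
    ("11", CG, "SDHD", "NM_003002.4", "c.147_148dupA", "p.His50fs", "A", "AA", 147, Consequence.FRAMESHIFT, AcmgClass.PATHOGENIC, 24, 9),
    ("12", CG, "SDHD", "NM_003002.4", "c.149A>G", "p.His50Arg", "A", "G", 149, Consequence.MISSENSE, AcmgClass.VUS, 19, 17),
    ("18/F2", RAPID, "SDHB", "NM_003000.3", "c.586T>C", "p.Cys196Arg", "T", "C", 586, Consequence.MISSENSE, AcmgClass.PATHOGENIC, 84, 101),
    ("19/F2", RAPID, "SDHB", "NM_003000.3", "c.586T>C", "p.Cys196Arg", "T", "C", 586, Consequence.MISSENSE, AcmgClass.PATHOGENIC, 53, 49),
    ("20/F2", RAPID, "SDHB", "NM_003000.3", "c.586T>C", "p.Cys196Arg", "T", "C", 586, Consequence.MISSENSE, AcmgClass.PATHOGENIC, 93, 77),
]

#: WES samples in which Sanger found no mutation (empty call sets)
_WES_NEGATIVE_SAMPLES = ["3/F1", "4/F1", "13", "14", "15", "16", "17"]


@dataclass
class WesFixture:
    calls: List[VariantCall]
    truth: List[TruthRecord]
    sample_ids: List[str]

    def calls_by_platform(self) -> Dict[str, List[VariantCall]]:
        out: Dict[str, List[VariantCall]] = {}
        for c in self.calls:
            out.setdefault(c.platform, []).append(c)
        return out


def build_table1_fixture() -> WesFixture:
    """The 20-sample WES cohort with the exact printed read-count pairs."""
    calls: List[VariantCall] = []
    truth: List[TruthRecord] = []
    samples: List[str] = []
    for (sample, platform, gene, tx, hgvs_c, hgvs_p, ref, alt, offset,
         csq, acmg, ref_reads, alt_reads) in _WES_ROWS:
        chrom, pos = _pos(gene, offset)
        calls.append(
            VariantCall(
                sample_id=sample,
                chrom=chrom,
                pos=pos,
                ref_allele=ref,
                alt_allele=alt,
                ref_reads=ref_reads,
                alt_reads=alt_reads,
                gene=gene,
                transcript=tx,
                hgvs_c=hgvs_c,
                hgvs_p=hgvs_p,
                consequence=csq,
                acmg_class=acmg,
                zygosity_claim=Zygosity.HET,
                platform=platform,
            )
        )
        truth.append(
            TruthRecord(
                sample_id=sample,
                chrom=chrom,
                pos=pos,
                ref_allele=ref,
                alt_allele=alt,
                status=TruthStatus.VARIANT_PRESENT,
            )
        )
        samples.append(sample)
    samples.extend(_WES_NEGATIVE_SAMPLES)
    return WesFixture(calls=calls, truth=truth, sample_ids=samples)


# ---------------------------------------------------------------------------
# targeted-panel v1.0 validation cohort

_V1_SAMPLES = [f"V{i:02d}" for i in range(1, 16)]

# (sample, gene, transcript, hgvs_c, CDS offset, ref, alt, ACMG,
#  ref reads, alt reads) — the 12 pathogenic-classified true calls:
# 10 distinct verified mutations, two of them shared by a relative.
_V1_PATHOGENIC = [
    ("V01", "SDHB", "NM_003000.3", "c.728G>A", 728, "G", "A", AcmgClass.PATHOGENIC, 30, 26),
    ("V02", "SDHB", "NM_003000.3", "c.586T>G", 586, "T", "G", AcmgClass.PATHOGENIC, 27, 29),
    ("V03", "SDHB", "NM_003000.3", "c.586T>G", 586, "T", "G", AcmgClass.PATHOGENIC, 25, 28),
    ("V04", "SDHB", "NM_003000.3", "c.728G>A", 728, "G", "A", AcmgClass.PATHOGENIC, 31, 27),
    ("V06", "RET", "NM_020975.6", "c.1832G>A", 1832, "G", "A", AcmgClass.PATHOGENIC, 28, 30),
    ("V07", "TMEM127", "NM_001193304.3", "c.419G>A", 419, "G", "A", AcmgClass.LIKELY_PATHOGENIC, 26, 24),
    ("V09", "SDHB", "NM_003000.3", "c.745T>C", 745, "T", "C", AcmgClass.LIKELY_PATHOGENIC, 33, 29),
    ("V10", "SDHB", "NM_003000.3", "c.649C>T", 649, "C", "T", AcmgClass.LIKELY_PATHOGENIC, 24, 26),
    ("V11", "SDHB", "NM_003000.3", "c.758G>A", 758, "G", "A", AcmgClass.PATHOGENIC, 29, 31),
    ("V12", "RET", "NM_020975.6", "c.2753T>C", 2753, "T", "C", AcmgClass.PATHOGENIC, 27, 25),
    ("V13", "TMEM127", "NM_001193304.3", "c.320delG", 320, "TG", "T", AcmgClass.LIKELY_PATHOGENIC, 30, 28),
    ("V14", "VHL", "NM_000551.4", "c.407T>G", 407, "T", "G", AcmgClass.LIKELY_PATHOGENIC, 26, 28),
]

_V1_VUS = [
    ("V05", "SDHD", "NM_003002.4", "c.149A>G", 149, "A", "G", AcmgClass.VUS, 24, 22),
    ("V08", "SDHA", "NM_004168.4", "c.837G>T", 837, "G", "T", AcmgClass.VUS, 28, 30),
]

# True common polymorphisms removed by the >1% MAF stage (still truth
# variants: Sanger confirms them, the clinical filter just does not
# report them).
_V1_COMMON = [
    ("V01", "EGLN1", 512, "C", "T", 0.05, 30, 30),
    ("V02", "EPAS1", 611, "G", "A", 0.12, 25, 27),
]

_POLY_GENES = [
    "SDHB", "SDHD", "SDHA", "NF1", "RET", "VHL", "MAX", "FH", "KIF1B",
    "EPAS1", "EGLN1", "TMEM127", "SDHC", "SDHAF2",
]
_ARTIFACT_GENES = _POLY_GENES

N_V1_TRUE = 41
N_V1_ARTIFACTS = 114
N_V1_CODING = 155


@dataclass
class V1ValidationFixture:
    calls: List[VariantCall]
    truth: List[TruthRecord]              # all 41 confirmed variants
    truth_pathogenic: List[TruthRecord]   # the 12 pathogenic-classified ones
    blacklist: Tuple[BlacklistEntry, ...]
    panel: PanelDesign
    profile: PlatformProfile
    config: FilterConfig


def build_v1_validation_fixture() -> V1ValidationFixture:
    """The 15-sample panel validation cohort: 155 coding calls, 41 true."""
    calls: List[VariantCall] = []
    truth: List[TruthRecord] = []
    truth_pathogenic: List[TruthRecord] = []

    def add_true(sample, gene, tx, hgvs_c, offset, ref, alt, acmg, rr, ar,
                 maf=None, csq=Consequence.MISSENSE):
        chrom, pos = _pos(gene, offset)
        call = VariantCall(
            sample_id=sample, chrom=chrom, pos=pos,
            ref_allele=ref, alt_allele=alt, ref_reads=rr, alt_reads=ar,
            gene=gene, transcript=tx, hgvs_c=hgvs_c,
            consequence=csq, population_maf=maf, acmg_class=acmg,
            zygosity_claim=Zygosity.HET, platform="endogene_panel",
        )
        rec = TruthRecord(
            sample_id=sample, chrom=chrom, pos=pos,
            ref_allele=ref, alt_allele=alt,
            status=TruthStatus.VARIANT_PRESENT,
        )
        calls.append(call)
        truth.append(rec)
        return rec

    for sample, gene, tx, hgvs_c, offset, ref, alt, acmg, rr, ar in _V1_PATHOGENIC:
        csq = Consequence.FRAMESHIFT if "del" in hgvs_c else Consequence.MISSENSE
        rec = add_true(sample, gene, tx, hgvs_c, offset, ref, alt, acmg, rr, ar, csq=csq)
        truth_pathogenic.append(rec)
    for sample, gene, tx, hgvs_c, offset, ref, alt, acmg, rr, ar in _V1_VUS:
        add_true(sample, gene, tx, hgvs_c, offset, ref, alt, acmg, rr, ar)
    for sample, gene, offset, ref, alt, maf, rr, ar in _V1_COMMON:
        add_true(sample, gene, "", "", offset, ref, alt, AcmgClass.BENIGN, rr, ar, maf=maf)

    # 25 benign-classified true polymorphisms, retained by the cascade
    # (rare enough to pass the MAF stage; PolyPhen disagrees with the
    # benign conjunction rule, so the benign stage keeps them too).
    for i in range(25):
        sample = _V1_SAMPLES[i % 15]
        gene = _POLY_GENES[i % len(_POLY_GENES)]
        chrom, pos = _pos(gene, 1000 + 17 * i)
        rr, ar = 24 + i % 6, 22 + i % 5
        call = VariantCall(
            sample_id=sample, chrom=chrom, pos=pos,
            ref_allele="C", alt_allele="G", ref_reads=rr, alt_reads=ar,
            gene=gene, consequence=Consequence.MISSENSE,
            population_maf=0.008, acmg_class=AcmgClass.BENIGN,
            zygosity_claim=Zygosity.HET, platform="endogene_panel",
        )
        calls.append(call)
        truth.append(
            TruthRecord(
                sample_id=sample, chrom=chrom, pos=pos,
                ref_allele="C", alt_allele="G",
                status=TruthStatus.VARIANT_PRESENT,
            )
        )

    assert len(calls) == N_V1_TRUE

    # the reference-mismatch locus: one genuine-looking het per sample
    b = REFERENCE_MISMATCH
    for i, sample in enumerate(_V1_SAMPLES):
        calls.append(
            VariantCall(
                sample_id=sample, chrom=b.chrom, pos=b.pos,
                ref_allele=b.ref_allele, alt_allele=b.alt_allele,
                ref_reads=24 + i % 4, alt_reads=25 + i % 3,
                gene="MEN1", consequence=Consequence.MISSENSE,
                zygosity_claim=Zygosity.HET, platform="endogene_panel",
            )
        )

    # 98 artifact calls with out-of-window alternate fractions
    # (min 20 reads/allele so only the allele-fraction stage removes them)
    for i in range(98):
        sample = _V1_SAMPLES[i % 15]
        gene = _ARTIFACT_GENES[i % len(_ARTIFACT_GENES)]
        chrom, pos = _pos(gene, 2000 + 7 * i)
        if i % 2 == 0:
            rr, ar = 70 + i % 7, 20 + i % 5     # alt fraction < 0.26
        else:
            rr, ar = 20 + i % 5, 70 + i % 7     # alt fraction > 0.74
        calls.append(
            VariantCall(
                sample_id=sample, chrom=chrom, pos=pos,
                ref_allele="G", alt_allele="T", ref_reads=rr, alt_reads=ar,
                gene=gene, consequence=Consequence.MISSENSE,
                zygosity_claim=Zygosity.HET, platform="endogene_panel",
            )
        )

    # the one artifact with an in-window fraction: survives the cascade
    chrom, pos = _pos("KIF1B", 2900)
    calls.append(
        VariantCall(
            sample_id="V15", chrom=chrom, pos=pos,
            ref_allele="A", alt_allele="C", ref_reads=26, alt_reads=28,
            gene="KIF1B", consequence=Consequence.MISSENSE,
            zygosity_claim=Zygosity.HET, platform="endogene_panel",
        )
    )

    assert len(calls) == N_V1_CODING

    return V1ValidationFixture(
        calls=calls,
        truth=truth,
        truth_pathogenic=truth_pathogenic,
        blacklist=(b,),
        panel=default_panel(version=1),
        profile=DEFAULT_PROFILES["endogene_panel"],
        config=FilterConfig(blacklist=(b,)),
    )


# ---------------------------------------------------------------------------
# cohort tables (prospective findings and novel variants)

@dataclass
class CohortFixtures:
    variants: pd.DataFrame       # one row per patient x reported variant
    novel_variants: pd.DataFrame

    def cohort(self, panel: str) -> pd.DataFrame:
        """Subset of the findings table for one panel cohort
        (``EP1.0V``, ``EP1.0P`` or ``EP2.0``)."""
        sub = self.variants[self.variants["panel"] == panel]
        if sub.empty:
            raise KeyError(f"unknown cohort {panel!r}")
        return sub.reset_index(drop=True)


def _read_packaged_tsv(name: str) -> pd.DataFrame:
    with resources.files("ppglval").joinpath("data", name).open("r") as fh:
        df = pd.read_csv(fh, sep="\t", dtype=str)
    for col in ("gene", "hgvs", "clinical_class"):
        if col in df.columns:
            df[col] = df[col].fillna("")
    return df


def build_cohort_fixtures() -> CohortFixtures:
    """Machine-readable reconstructions of the published cohort tables."""
    return CohortFixtures(
        variants=_read_packaged_tsv("cohort_variants.tsv"),
        novel_variants=_read_packaged_tsv("novel_variants.tsv"),
    )
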