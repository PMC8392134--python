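"""Synthetic call-set generator with the statistical structure the
pipeline assumes.

What is emulated:

* platform-specific site depths — negative-binomial around a per-platform
  mean, optionally scaled per gene to mimic capture kits whose probes
  under-perform on specific genes (the SDHA/SDHC/SDHD depression of one
  exome kit);
* heterozygous allele-fraction spread — binomial(depth, 0.5) for a
  well-behaved library, beta-binomial with intra-class correlation
  ``af_overdispersion_rho`` for libraries whose het calls scatter more
  widely around 50%;
* artifact (false-positive) calls whose alternate fractions are drawn
  mostly *outside* the 30-70% band, so the allele-fraction window removes
  the bulk of them;
* one reference-mismatch locus, called as a genuine heterozygote in every
  sample — the signature of a reference genome carrying the minor allele
  of a common polymorphism.

Outputs are deterministic given a seed (identical spec + seed give
byte-identical files through the package's writers).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy import stats

from .models import (
    AcmgClass,
    BlacklistEntry,
    Consequence,
    DepthRecord,
    PanelDesign,
    PlatformProfile,
    PpglValError,
    Region,
    TruthRecord,
    TruthStatus,
    VariantCall,
    Zygosity,
)

# Synthetic single-CDS-block coordinates per panel gene.  Chromosome
# assignments follow the real genes; start/end are invented and spaced so
# loci of different genes never collide.
GENE_REGIONS: Dict[str, Tuple[str, int, int]] = {
    "SDHB": ("chr1", 17_000_000, 17_003_000),
    "EGLN1": ("chr1", 231_500_000, 231_503_000),
    "KIF1B": ("chr1", 10_270_000, 10_273_000),
    "FH": ("chr1", 241_660_000, 241_663_000),
    "SDHC": ("chr1", 161_280_000, 161_283_000),
    "EPAS1": ("chr2", 46_520_000, 46_523_000),
    "TMEM127": ("chr2", 96_920_000, 96_923_000),
    "VHL": ("chr3", 10_183_000, 10_186_000),
    "SDHA": ("chr5", 218_000, 221_000),
    "MDH2": ("chr7", 75_677_000, 75_680_000),
    "RET": ("chr10", 43_570_000, 43_573_000),
    "SDHD": ("chr11", 111_957_000, 111_960_000),
    "MEN1": ("chr11", 64_570_000, 64_573_000),
    "SDHAF2": ("chr11", 61_197_000, 61_200_000),
    "MAX": ("chr14", 65_540_000, 65_543_000),
    "GOT2": ("chr16", 58_740_000, 58_743_000),
    "NF1": ("chr17", 29_420_000, 29_423_000),
    "SLC25A11": ("chr22", 4_840_000, 4_843_000),
}

PANEL_V1_GENES = (
    "EGLN1", "EPAS1", "FH", "KIF1B", "MAX", "MEN1", "NF1", "RET",
    "SDHA", "SDHAF2", "SDHB", "SDHC", "SDHD", "TMEM127", "VHL",
)
PANEL_V2_GENES = PANEL_V1_GENES + ("GOT2", "MDH2", "SLC25A11")

#: the reference-mismatch locus: the reference carries the minor allele of
#: a common MEN1 polymorphism, so nearly every sample is "variant" here
REFERENCE_MISMATCH = BlacklistEntry(
    chrom="chr11",
    pos=64_572_018,
    ref_allele="T",
    alt_allele="C",
    note="reference genome carries minor allele (rs2959656-like); systematic call",
)

# Per-platform defaults.  Depth minima follow the stated workflow
# thresholds (10 reads/allele for the Illumina exome workflows, 5 for
# Complete Genomics, 20 for the targeted panel).  The beta-binomial rho
# values are tuning constants: the BGI-like libraries get the visibly
# wider het allele-fraction spread, the others a nearly binomial one.
DEFAULT_PROFILES: Dict[str, PlatformProfile] = {
    "agilent_sureselect": PlatformProfile(
        name="agilent_sureselect",
        min_reads_per_allele=10,
        mean_depth=100.0,
        depth_dispersion=8.0,
        af_overdispersion_rho=0.005,
        gene_depth_factors={"SDHA": 0.2, "SDHC": 0.25, "SDHD": 0.25},
    ),
    "bgi_complete_genomics": PlatformProfile(
        name="bgi_complete_genomics",
        min_reads_per_allele=5,
        mean_depth=100.0,
        depth_dispersion=8.0,
        af_overdispersion_rho=0.04,
    ),
    "illumina_rapid_capture": PlatformProfile(
        name="illumina_rapid_capture",
        min_reads_per_allele=10,
        mean_depth=150.0,
        depth_dispersion=8.0,
        af_overdispersion_rho=0.005,
    ),
    "endogene_panel": PlatformProfile(
        name="endogene_panel",
        min_reads_per_allele=20,
        mean_depth=150.0,
        depth_dispersion=10.0,
        af_overdispersion_rho=0.005,
    ),
}


def default_panel(version: int = 1, intronic_padding_bp: int = 30) -> PanelDesign:
    """The synthetic-coordinate panel design (one CDS block per gene)."""
    genes = PANEL_V1_GENES if version == 1 else PANEL_V2_GENES
    regions = tuple(
        Region(GENE_REGIONS[g][0], GENE_REGIONS[g][1], GENE_REGIONS[g][2], g)
        for g in genes
    )
    return PanelDesign(
        name=f"ENDOGENE v{version}.0 (synthetic coordinates)",
        regions=regions,
        intronic_padding_bp=intronic_padding_bp,
    )


@dataclass
class SimulationSpec:
    """Study conditions for one simulated validation cohort."""

    platform_profiles: Tuple[PlatformProfile, ...] = (
        DEFAULT_PROFILES["endogene_panel"],
    )
    n_samples: int = 15
    true_variants_per_sample: int = 3
    artifact_rate: float = 6.0  # expected artifact calls per sample
    #: fraction of artifact alt fractions drawn outside the 30-70% band
    artifact_out_of_window: float = 0.85
    reference_mismatch: Optional[BlacklistEntry] = REFERENCE_MISMATCH
    #: clean mode clamps true-het reads into the window and above the
    #: platform depth minimum, so no filter can remove a truth call
    clean: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        self.platform_profiles = tuple(self.platform_profiles)
        if not self.platform_profiles:
            raise PpglValError("at least one platform profile is required")
        if self.n_samples < 0 or self.true_variants_per_sample < 0:
            raise PpglValError("counts must be non-negative")
        if self.artifact_rate < 0:
            raise PpglValError("artifact_rate must be non-negative")
        if not 0.0 <= self.artifact_out_of_window <= 1.0:
            raise PpglValError("artifact_out_of_window must lie in [0,1]")


@dataclass
class SimulationResult:
    calls: List[VariantCall]
    truth: List[TruthRecord]
    panel: PanelDesign
    depth_records: List[DepthRecord]
    spec: SimulationSpec


def simulate_het_alt_counts(
    n: int, depth, rho: float, rng: np.random.Generator
) -> np.ndarray:
    """Alt-read counts of ``n`` true heterozygotes at the given depth(s).

    ``rho = 0`` gives binomial(depth, 0.5); ``rho > 0`` a beta-binomial
    with that intra-class correlation (concentration ``s = (1-rho)/rho``,
    symmetric shape ``a = b = s/2``).
    """
    depth = np.broadcast_to(np.asarray(depth, dtype=int), (n,))
    if rho <= 0.0:
        return rng.binomial(depth, 0.5)
    s = (1.0 - rho) / rho
    p = rng.beta(s / 2.0, s / 2.0, size=n)
    return rng.binomial(depth, p)


def _site_depth(
    profile: PlatformProfile, gene: str, size: int, rng: np.random.Generator
) -> np.ndarray:
    mean = profile.mean_depth * profile.gene_depth_factors.get(gene, 1.0)
    k = profile.depth_dispersion
    p = k / (k + mean)
    return np.maximum(rng.negative_binomial(k, p, size=size), 1)


def _artifact_fraction(
    spec: SimulationSpec, rng: np.random.Generator
) -> float:
    if rng.random() < spec.artifact_out_of_window:
        # skewed away from 50%: low- or high-fraction noise
        if rng.random() < 0.7:
            return rng.uniform(0.03, 0.27)
        return rng.uniform(0.73, 0.97)
    return rng.uniform(0.31, 0.69)


def simulate_calls(spec: SimulationSpec) -> SimulationResult:
    """Generate (calls, truth, panel, depth records) under ``spec``.

    Samples are assigned to platforms round-robin.  Depth records are
    emitted for one representative sample per platform over the whole
    panel (the input the coverage module consumes).
    """
    rng = np.random.default_rng(spec.seed)
    panel = default_panel(version=1)
    genes = [g for g in panel.genes if g != "MEN1"]
    calls: List[VariantCall] = []
    truth: List[TruthRecord] = []

    for i in range(spec.n_samples):
        sample = f"S{i + 1:03d}"
        profile = spec.platform_profiles[i % len(spec.platform_profiles)]

        # true heterozygous variants
        for j in range(spec.true_variants_per_sample):
            gene = genes[int(rng.integers(len(genes)))]
            chrom, start, end = GENE_REGIONS[gene]
            pos = int(rng.integers(start + 1, end + 1))
            depth = int(_site_depth(profile, gene, 1, rng)[0])
            if spec.clean:
                depth = max(depth, 4 * profile.min_reads_per_allele)
            alt = int(
                simulate_het_alt_counts(1, depth, profile.af_overdispersion_rho, rng)[0]
            )
            if spec.clean:
                lo = max(int(np.ceil(0.31 * depth)), profile.min_reads_per_allele)
                hi = min(int(np.floor(0.69 * depth)), depth - profile.min_reads_per_allele)
                alt = int(np.clip(alt, lo, hi))
            ref_reads = depth - alt
            call = VariantCall(
                sample_id=sample,
                chrom=chrom,
                pos=pos,
                ref_allele="A",
                alt_allele="G",
                ref_reads=ref_reads,
                alt_reads=alt,
                gene=gene,
                consequence=Consequence.MISSENSE,
                acmg_class=AcmgClass.VUS,
                zygosity_claim=Zygosity.HET,
                platform=profile.name,
            )
            calls.append(call)
            truth.append(
                TruthRecord(
                    sample_id=sample,
                    chrom=chrom,
                    pos=pos,
                    ref_allele="A",
                    alt_allele="G",
                    status=TruthStatus.VARIANT_PRESENT,
                )
            )

        # artifact calls with skewed alternate fractions
        n_art = int(rng.poisson(spec.artifact_rate))
        for j in range(n_art):
            gene = genes[int(rng.integers(len(genes)))]
            chrom, start, end = GENE_REGIONS[gene]
            pos = int(rng.integers(start + 1, end + 1))
            depth = int(_site_depth(profile, gene, 1, rng)[0])
            f = _artifact_fraction(spec, rng)
            alt = min(max(int(round(f * depth)), 1), depth - 1) if depth > 1 else 1
            calls.append(
                VariantCall(
                    sample_id=sample,
                    chrom=chrom,
                    pos=pos,
                    ref_allele="C",
                    alt_allele="T",
                    ref_reads=depth - alt,
                    alt_reads=alt,
                    gene=gene,
                    consequence=Consequence.MISSENSE,
                    zygosity_claim=Zygosity.HET,
                    platform=profile.name,
                )
            )

        # the reference-mismatch locus: a genuine het in every sample
        if spec.reference_mismatch is not None:
            b = spec.reference_mismatch
            depth = int(_site_depth(profile, "MEN1", 1, rng)[0])
            depth = max(depth, 2 * profile.min_reads_per_allele + 2)
            alt = int(np.clip(rng.binomial(depth, 0.5), profile.min_reads_per_allele,
                              depth - profile.min_reads_per_allele))
            calls.append(
                VariantCall(
                    sample_id=sample,
                    chrom=b.chrom,
                    pos=b.pos,
                    ref_allele=b.ref_allele,
                    alt_allele=b.alt_allele,
                    ref_reads=depth - alt,
                    alt_reads=alt,
                    gene="MEN1",
                    consequence=Consequence.MISSENSE,
                    zygosity_claim=Zygosity.HET,
                    platform=profile.name,
                )
            )

    # per-base depth for one representative sample per platform
    depth_records: List[DepthRecord] = []
    for profile in spec.platform_profiles:
        sample = f"{profile.name}_rep"
        for region in panel.regions:
            depths = _site_depth(profile, region.gene, region.length, rng)
            for offset, d in enumerate(depths):
                depth_records.append(
                    DepthRecord(
                        chrom=region.chrom,
                        pos=region.start + 1 + offset,
                        depth=int(d),
                        sample_id=sample,
                    )
                )

    return SimulationResult(
        calls=calls, truth=truth, panel=panel, depth_records=depth_records, spec=spec
    )
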