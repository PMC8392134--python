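"""Core domain types for germline panel variant QC.

The pipeline consumes *called* variants (with per-allele read depths and
external annotations), Sanger-established truth records, capture-panel
designs, per-base depth tables and per-platform sequencing profiles.  All
downstream stages (allele-fraction statistics, the filter cascade,
truth-set concordance, coverage assessment) share the types defined here.

Coordinate conventions: variant and depth positions are 1-based (VCF
style); panel intervals are 0-based half-open (BED style).  A 1-based
position ``p`` lies inside the BED interval ``[s, e)`` iff ``s < p <= e``.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Iterable, Optional, Tuple


class PpglValError(Exception):
    """Base class for all errors raised by this package."""


class ParseError(PpglValError):
    """A malformed input record; carries the offending line number."""

    def __init__(self, message: str, line: Optional[int] = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)


class NoAlleleDepthsError(PpglValError):
    """Input lacks per-allele read depths (AD); allele-fraction stages cannot run."""


class NoCoverageError(PpglValError):
    """An allele-fraction statistic was requested for a call with zero reads."""


class InvalidRecordError(PpglValError):
    """A domain-type invariant was violated."""


class Consequence(str, enum.Enum):
    MISSENSE = "missense"
    NONSENSE = "nonsense"
    FRAMESHIFT = "frameshift"
    INFRAME_INDEL = "inframe_indel"
    SPLICE = "splice"
    SYNONYMOUS = "synonymous"
    UTR = "utr"
    INTRONIC = "intronic"
    COMPLEX = "complex"
    UNKNOWN = "unknown"


class AcmgClass(str, enum.Enum):
    PATHOGENIC = "pathogenic"
    LIKELY_PATHOGENIC = "likely_pathogenic"
    VUS = "vus"
    LIKELY_BENIGN = "likely_benign"
    BENIGN = "benign"
    UNKNOWN = "unknown"


class PolyphenCategory(str, enum.Enum):
    BENIGN = "benign"
    POSSIBLY_DAMAGING = "possibly_damaging"
    PROBABLY_DAMAGING = "probably_damaging"
    UNKNOWN = "unknown"


class Zygosity(str, enum.Enum):
    HET = "het"
    HOM = "hom"
    UNKNOWN = "unknown"


class TruthStatus(str, enum.Enum):
    VARIANT_PRESENT = "variant_present"
    WILDTYPE_CONFIRMED = "wildtype_confirmed"


def normalize_variant(pos: int, ref: str, alt: str) -> Tuple[int, str, str]:
    """Trim shared suffix then shared prefix of ``(ref, alt)``, adjusting ``pos``.

    This is the reference-free part of indel left-alignment: it produces a
    canonical minimal representation so that e.g. ``(100, "CTT", "CT")`` and
    ``(101, "TT", "T")`` compare equal.  Full left-shifting through repeat
    tracts needs the reference sequence, which is out of scope here.
    """
    ref, alt = ref.upper(), alt.upper()
    while len(ref) > 1 and len(alt) > 1 and ref[-1] == alt[-1]:
        ref, alt = ref[:-1], alt[:-1]
    while len(ref) > 1 and len(alt) > 1 and ref[0] == alt[0]:
        ref, alt = ref[1:], alt[1:]
        pos += 1
    return pos, ref, alt


@dataclass
class VariantCall:
    """One called variant in one sample, with read support and annotations.

    ``ref_reads``/``alt_reads`` come from the caller's per-allele depths
    (VCF FORMAT/AD); the total depth column, where inconsistent with AD, is
    ignored — AD is the quantity the allele-fraction statistics are defined
    on.  Annotation fields absent from the input are ``unknown``/``None``
    and each filter stage declares its own policy for unknowns.
    """

    sample_id: str
    chrom: str
    pos: int
    ref_allele: str
    alt_allele: str
    ref_reads: int
    alt_reads: int
    gene: str = ""
    transcript: str = ""
    hgvs_c: str = ""
    hgvs_p: str = ""
    consequence: Consequence = Consequence.UNKNOWN
    population_maf: Optional[float] = None
    acmg_class: AcmgClass = AcmgClass.UNKNOWN
    polyphen_category: PolyphenCategory = PolyphenCategory.UNKNOWN
    sift_score: Optional[float] = None
    zygosity_claim: Zygosity = Zygosity.UNKNOWN
    platform: str = ""

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise InvalidRecordError(f"pos must be >= 1, got {self.pos}")
        if self.ref_reads < 0 or self.alt_reads < 0:
            raise InvalidRecordError("read counts must be non-negative")
        if not self.ref_allele or not self.alt_allele:
            raise InvalidRecordError("ref and alt alleles must be non-empty")
        if self.ref_allele == self.alt_allele:
            raise InvalidRecordError(
                f"ref and alt alleles must differ, got {self.ref_allele!r}"
            )
        if self.population_maf is not None and not 0.0 <= self.population_maf <= 1.0:
            raise InvalidRecordError(
                f"population_maf must lie in [0,1], got {self.population_maf}"
            )
        if self.sift_score is not None and not 0.0 <= self.sift_score <= 1.0:
            raise InvalidRecordError(
                f"sift_score must lie in [0,1], got {self.sift_score}"
            )
        self.consequence = Consequence(self.consequence)
        self.acmg_class = AcmgClass(self.acmg_class)
        self.polyphen_category = PolyphenCategory(self.polyphen_category)
        self.zygosity_claim = Zygosity(self.zygosity_claim)

    @property
    def total_reads(self) -> int:
        return self.ref_reads + self.alt_reads

    def locus_key(self) -> Tuple[str, str, int, str, str]:
        """Normalized (sample, chrom, pos, ref, alt) key used for matching."""
        pos, ref, alt = normalize_variant(self.pos, self.ref_allele, self.alt_allele)
        return (self.sample_id, self.chrom, pos, ref, alt)


@dataclass
class TruthRecord:
    """Sanger-established ground truth: a confirmed variant or wild-type span."""

    sample_id: str
    chrom: str
    pos: int
    ref_allele: str = ""
    alt_allele: str = ""
    status: TruthStatus = TruthStatus.VARIANT_PRESENT
    #: for wildtype_confirmed records, the Sanger-covered 1-based inclusive span
    region_span: Optional[Tuple[int, int]] = None

    def __post_init__(self) -> None:
        self.status = TruthStatus(self.status)
        if self.status is TruthStatus.VARIANT_PRESENT:
            if not self.alt_allele:
                raise InvalidRecordError(
                    "variant_present truth record requires a non-empty alt allele"
                )
        else:
            span = self.region_span
            if span is None or span[1] < span[0]:
                raise InvalidRecordError(
                    "wildtype_confirmed truth record requires a span of >= 1 base"
                )

    def locus_key(self) -> Tuple[str, str, int, str, str]:
        pos, ref, alt = normalize_variant(
            self.pos, self.ref_allele or "N", self.alt_allele or "-"
        )
        return (self.sample_id, self.chrom, pos, ref, alt)


@dataclass(frozen=True)
class Region:
    """A 0-based half-open genomic interval, optionally tagged with a gene."""

    chrom: str
    start: int
    end: int
    gene: str = ""

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise InvalidRecordError(
                f"degenerate interval {self.chrom}:{self.start}-{self.end}"
            )

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class PanelDesign:
    """A targeted capture design: named intervals plus intronic padding.

    Probes cover every exon plus ``intronic_padding_bp`` flanking bases, so
    region membership tests expand each interval by the padding.
    """

    name: str
    regions: Tuple[Region, ...]
    intronic_padding_bp: int = 30

    def __post_init__(self) -> None:
        self.regions = tuple(self.regions)
        if self.intronic_padding_bp < 0:
            raise InvalidRecordError("intronic_padding_bp must be >= 0")

    @property
    def genes(self) -> Tuple[str, ...]:
        seen: list[str] = []
        for r in self.regions:
            if r.gene and r.gene not in seen:
                seen.append(r.gene)
        return tuple(seen)

    def contains(self, chrom: str, pos: int, padding: Optional[int] = None) -> bool:
        """True iff the 1-based ``pos`` lies inside any (padded) interval."""
        pad = self.intronic_padding_bp if padding is None else padding
        for r in self.regions:
            if r.chrom == chrom and r.start - pad < pos <= r.end + pad:
                return True
        return False

    def gene_regions(self, gene: str) -> Tuple[Region, ...]:
        return tuple(r for r in self.regions if r.gene == gene)


@dataclass
class PlatformProfile:
    """Per-platform configuration for depth thresholds and simulation.

    ``min_reads_per_allele`` is the depth threshold applied per allele of a
    heterozygous call (e.g. 10 reads/allele = 20x for an exome workflow,
    20 reads/allele = 40x for the targeted panel).  ``af_overdispersion_rho``
    is the beta-binomial intra-class correlation of the heterozygous allele
    fraction: 0 means pure binomial sampling, larger values give the wider
    allele-fraction spread some library preparations show.
    ``gene_depth_factors`` optionally scales simulated capture efficiency
    per gene (e.g. the depressed SDHA/SDHC/SDHD coverage of one exome kit).
    """

    name: str
    min_reads_per_allele: int
    mean_depth: float
    depth_dispersion: float = 10.0
    af_overdispersion_rho: float = 0.0
    gene_depth_factors: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.min_reads_per_allele < 1:
            raise InvalidRecordError("min_reads_per_allele must be >= 1")
        if self.mean_depth <= 0 or self.depth_dispersion <= 0:
            raise InvalidRecordError("mean_depth and depth_dispersion must be > 0")
        if not 0.0 <= self.af_overdispersion_rho < 1.0:
            raise InvalidRecordError("af_overdispersion_rho must lie in [0,1)")


@dataclass(frozen=True)
class DepthRecord:
    """Per-base sequencing depth at a 1-based position for one sample."""

    chrom: str
    pos: int
    depth: int
    sample_id: str = ""

    def __post_init__(self) -> None:
        if self.depth < 0:
            raise InvalidRecordError("depth must be non-negative")
        if self.pos < 1:
            raise InvalidRecordError("pos must be >= 1")


@dataclass(frozen=True)
class BlacklistEntry:
    """A systematic-artifact locus removed by exact (chrom,pos,ref,alt) match.

    The motivating case is a reference-genome minor allele: where the
    reference carries the minor allele of a common polymorphism, nearly every
    sample yields a spurious heterozygous "variant" call at that position.
    """

    chrom: str
    pos: int
    ref_allele: str
    alt_allele: str
    note: str = ""

    def key(self) -> Tuple[str, int, str, str]:
        pos, ref, alt = normalize_variant(self.pos, self.ref_allele, self.alt_allele)
        return (self.chrom, pos, ref, alt)


def variant_key(chrom: str, pos: int, ref: str, alt: str) -> Tuple[str, int, str, str]:
    """Sample-agnostic normalized variant key."""
    npos, nref, nalt = normalize_variant(pos, ref, alt)
    return (chrom, npos, nref, nalt)


def check_unique_truth(truth: Iterable[TruthRecord]) -> None:
    """Raise if two variant_present truth records share one sample+locus."""
    seen = set()
    for t in truth:
        if t.status is not TruthStatus.VARIANT_PRESENT:
            continue
        k = t.locus_key()
        if k in seen:
            raise InvalidRecordError(f"duplicate truth record for {k}")
        seen.add(k)
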