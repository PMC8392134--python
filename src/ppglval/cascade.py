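"""Ordered variant-filter cascade with a per-stage audit trail.

The cascade mirrors a clinical germline-panel workflow: keep only calls on
target (panel exons plus intronic padding), discard consequence classes
that cannot be reported (UTR, deep intronic, synonymous), discard common
polymorphisms (population MAF above 1%), discard variants annotated benign
by the conjunction rule (ACMG benign AND PolyPhen benign AND SIFT not
deleterious), enforce a per-allele depth minimum, remove known systematic
artifacts via an exact-match blacklist, and finally apply the
allele-fraction window that suppresses spurious heterozygote calls.

Every stage returns both the surviving calls and the removed ones, and
``run_cascade`` assembles a telescoping audit (stage input = previous
stage's survivors; removals + final survivors = initial input).

Policy for unknown annotations: a diagnostic pipeline must not discard a
variant it has not assessed, so unknown MAF, unknown ACMG class and unknown
consequence are all retained (unknown consequence is additionally flagged
in the audit).  Splice-site calls (HGVS c. offset +-1/+-2) are never
dropped as intronic.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import yaml

from .afr import AfrWindow, alt_fraction
from .models import (
    AcmgClass,
    BlacklistEntry,
    Consequence,
    PanelDesign,
    PlatformProfile,
    PolyphenCategory,
    PpglValError,
    VariantCall,
    Zygosity,
)

DEFAULT_DROP_CONSEQUENCES = frozenset(
    {Consequence.UTR, Consequence.INTRONIC, Consequence.SYNONYMOUS}
)

#: HGVS c. notation with an intronic offset of 1 or 2 (e.g. c.286+2T>A)
_SPLICE_OFFSET_RE = re.compile(r"c\.[0-9_*-]*\d[+-][12](?![0-9])")


@dataclass
class FilterConfig:
    """Tunable parameters of the cascade; ``None`` disables a stage.

    ``sift_literal`` selects the direction of the SIFT clause in the benign
    rule.  The conventional reading (default) treats SIFT < 0.05 as
    deleterious evidence that *vetoes* a benign call; the literal reading
    of some published filter descriptions instead requires SIFT < 0.05 for
    the benign rule to fire.
    """

    maf_threshold: Optional[float] = 0.01
    afr_window: Optional[AfrWindow] = field(default_factory=lambda: AfrWindow(30.0, 70.0))
    drop_consequences: frozenset = DEFAULT_DROP_CONSEQUENCES
    benign_filter_enabled: bool = True
    sift_deleterious_below: float = 0.05
    sift_literal: bool = False
    blacklist: Tuple[BlacklistEntry, ...] = ()

    def __post_init__(self) -> None:
        if self.maf_threshold is not None and not 0.0 < self.maf_threshold <= 1.0:
            raise PpglValError("maf_threshold must lie in (0, 1]")
        self.drop_consequences = frozenset(
            Consequence(c) for c in self.drop_consequences
        )
        self.blacklist = tuple(self.blacklist)

    @classmethod
    def disabled(cls) -> "FilterConfig":
        """A configuration under which the cascade is the identity."""
        return cls(
            maf_threshold=None,
            afr_window=None,
            drop_consequences=frozenset(),
            benign_filter_enabled=False,
            blacklist=(),
        )

    @classmethod
    def from_yaml(cls, path) -> "FilterConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        window = raw.get("afr_window")
        if window is not None:
            window = AfrWindow(float(window[0]), float(window[1]))
        blacklist = tuple(
            BlacklistEntry(
                chrom=str(b["chrom"]),
                pos=int(b["pos"]),
                ref_allele=b["ref_allele"],
                alt_allele=b["alt_allele"],
                note=b.get("note", ""),
            )
            for b in raw.get("blacklist", [])
        )
        return cls(
            maf_threshold=raw.get("maf_threshold", 0.01),
            afr_window=window,
            drop_consequences=frozenset(
                Consequence(c)
                for c in raw.get(
                    "drop_consequences", [c.value for c in DEFAULT_DROP_CONSEQUENCES]
                )
            ),
            benign_filter_enabled=raw.get("benign_filter_enabled", True),
            sift_deleterious_below=raw.get("sift_deleterious_below", 0.05),
            sift_literal=raw.get("sift_literal", False),
            blacklist=blacklist,
        )

    def to_yaml(self, path) -> None:
        raw = {
            "maf_threshold": self.maf_threshold,
            "afr_window": (
                [self.afr_window.lower_pct, self.afr_window.upper_pct]
                if self.afr_window
                else None
            ),
            "drop_consequences": sorted(c.value for c in self.drop_consequences),
            "benign_filter_enabled": self.benign_filter_enabled,
            "sift_deleterious_below": self.sift_deleterious_below,
            "sift_literal": self.sift_literal,
            "blacklist": [
                {
                    "chrom": b.chrom,
                    "pos": b.pos,
                    "ref_allele": b.ref_allele,
                    "alt_allele": b.alt_allele,
                    "note": b.note,
                }
                for b in self.blacklist
            ],
        }
        with open(path, "w") as fh:
            yaml.safe_dump(raw, fh, sort_keys=False)


@dataclass(frozen=True)
class Removal:
    call: VariantCall
    stage: str
    reason: str


@dataclass(frozen=True)
class StageResult:
    name: str
    n_in: int
    n_removed: int
    n_out: int


@dataclass
class CascadeAudit:
    """Per-stage accounting of the cascade; counts telescope by construction."""

    stages: List[StageResult]
    removals: List[Removal]
    survivors: List[VariantCall]
    flags: List[Tuple[VariantCall, str]] = field(default_factory=list)

    def removed_by_stage(self, stage: str) -> List[Removal]:
        return [r for r in self.removals if r.stage == stage]

    def counts(self) -> Dict[str, Tuple[int, int, int]]:
        return {s.name: (s.n_in, s.n_removed, s.n_out) for s in self.stages}

    def validate(self) -> None:
        for prev, nxt in zip(self.stages, self.stages[1:]):
            if prev.n_out != nxt.n_in:
                raise PpglValError(
                    f"audit does not telescope: {prev.name} out {prev.n_out} != "
                    f"{nxt.name} in {nxt.n_in}"
                )
        if self.stages:
            total = self.stages[0].n_in
            if len(self.removals) + len(self.survivors) != total:
                raise PpglValError("removals + survivors != input size")

    def as_rows(self) -> List[dict]:
        return [
            {
                "stage": s.name,
                "input_count": s.n_in,
                "removed_count": s.n_removed,
                "surviving_count": s.n_out,
            }
            for s in self.stages
        ]


SplitResult = Tuple[List[VariantCall], List[Removal]]


def is_splice_protected(call: VariantCall) -> bool:
    """Splice-site calls (consequence, or c. offset of 1-2 bp) are protected."""
    if call.consequence is Consequence.SPLICE:
        return True
    return bool(_SPLICE_OFFSET_RE.search(call.hgvs_c))


def filter_region(calls: Sequence[VariantCall], panel: PanelDesign) -> SplitResult:
    """Keep calls inside any panel interval expanded by the intronic padding."""
    kept, removed = [], []
    for c in calls:
        if panel.contains(c.chrom, c.pos):
            kept.append(c)
        else:
            removed.append(Removal(c, "region", "outside padded panel regions"))
    return kept, removed


def filter_consequence(
    calls: Sequence[VariantCall], config: FilterConfig
) -> SplitResult:
    kept, removed = [], []
    for c in calls:
        if (
            c.consequence in config.drop_consequences
            and c.consequence is not Consequence.UNKNOWN
            and not is_splice_protected(c)
        ):
            removed.append(Removal(c, "consequence", f"consequence={c.consequence.value}"))
        else:
            kept.append(c)
    return kept, removed


def filter_common(calls: Sequence[VariantCall], config: FilterConfig) -> SplitResult:
    """Drop calls with known population MAF strictly above the threshold."""
    if config.maf_threshold is None:
        return list(calls), []
    kept, removed = [], []
    for c in calls:
        if c.population_maf is not None and c.population_maf > config.maf_threshold:
            removed.append(
                Removal(c, "common", f"population_maf={c.population_maf:g}")
            )
        else:
            kept.append(c)
    return kept, removed


def _benign_rule_matches(c: VariantCall, config: FilterConfig) -> bool:
    if c.acmg_class is not AcmgClass.BENIGN:
        return False
    if c.polyphen_category is not PolyphenCategory.BENIGN:
        return False
    sift_deleterious = (
        c.sift_score is not None and c.sift_score < config.sift_deleterious_below
    )
    if config.sift_literal:
        return sift_deleterious
    return not sift_deleterious


def filter_benign(calls: Sequence[VariantCall], config: FilterConfig) -> SplitResult:
    """Drop calls matching the benign conjunction rule; unknown ACMG is kept."""
    if not config.benign_filter_enabled:
        return list(calls), []
    kept, removed = [], []
    for c in calls:
        if _benign_rule_matches(c, config):
            removed.append(Removal(c, "benign", "acmg+polyphen+sift benign rule"))
        else:
            kept.append(c)
    return kept, removed


def filter_depth(
    calls: Sequence[VariantCall], profile: PlatformProfile
) -> SplitResult:
    """Enforce the per-allele depth minimum.

    Heterozygous (or unknown-zygosity) claims must carry at least the
    minimum reads on *both* alleles; homozygous claims only on the alt.
    """
    kept, removed = [], []
    m = profile.min_reads_per_allele
    for c in calls:
        if c.zygosity_claim is Zygosity.HOM:
            ok = c.alt_reads >= m
        else:
            ok = min(c.ref_reads, c.alt_reads) >= m
        if ok:
            kept.append(c)
        else:
            removed.append(
                Removal(c, "depth", f"reads {c.ref_reads}/{c.alt_reads} below {m}/allele")
            )
    return kept, removed


def apply_blacklist(calls: Sequence[VariantCall], config: FilterConfig) -> SplitResult:
    """Remove exact (chrom, pos, ref, alt) matches to blacklist entries."""
    index = {b.key(): b for b in config.blacklist}
    kept, removed = [], []
    for c in calls:
        k = c.locus_key()[1:]  # drop sample_id
        entry = index.get(k)
        if entry is not None:
            removed.append(Removal(c, "blacklist", entry.note or "blacklisted locus"))
        else:
            kept.append(c)
    return kept, removed


def filter_afr(calls: Sequence[VariantCall], config: FilterConfig) -> SplitResult:
    """Keep calls whose alternate-allele fraction lies inside the window."""
    if config.afr_window is None:
        return list(calls), []
    kept, removed = [], []
    for c in calls:
        f = alt_fraction(c.ref_reads, c.alt_reads)
        if config.afr_window.contains_fraction(f):
            kept.append(c)
        else:
            removed.append(
                Removal(c, "afr", f"alt fraction {f:.3f} outside {config.afr_window}")
            )
    return kept, removed


def run_cascade(
    calls: Iterable[VariantCall],
    panel: Optional[PanelDesign] = None,
    profile: Optional[PlatformProfile] = None,
    config: Optional[FilterConfig] = None,
) -> Tuple[List[VariantCall], CascadeAudit]:
    """Apply the full cascade in order: region, consequence, common, benign,
    depth, blacklist, AFR.  Stages whose inputs are absent (no panel, no
    profile, disabled config entries) pass calls through unchanged.
    """
    config = config or FilterConfig()
    current = list(calls)
    stages: List[StageResult] = []
    removals: List[Removal] = []
    flags: List[Tuple[VariantCall, str]] = []

    def record(name: str, result: SplitResult) -> List[VariantCall]:
        kept, removed = result
        stages.append(StageResult(name, len(kept) + len(removed), len(removed), len(kept)))
        removals.extend(removed)
        return kept

    if panel is not None:
        current = record("region", filter_region(current, panel))
    current = record("consequence", filter_consequence(current, config))
    for c in current:
        if c.consequence is Consequence.UNKNOWN:
            flags.append((c, "consequence unknown: retained"))
    current = record("common", filter_common(current, config))
    current = record("benign", filter_benign(current, config))
    if profile is not None:
        current = record("depth", filter_depth(current, profile))
    current = record("blacklist", apply_blacklist(current, config))
    current = record("afr", filter_afr(current, config))

    audit = CascadeAudit(stages=stages, removals=removals, survivors=current, flags=flags)
    audit.validate()
    return current, audit
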