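"""Read-backed cis/trans phasing of co-occurring variants.

When several variants are called in one gene in one patient, the clinical
interpretation depends on whether they sit on the same chromosome copy
(cis) or on opposite copies (trans).  Sequencing reads spanning two or
more of the variant sites answer this directly: under a cis configuration
reads split into an all-mutant class and an all-wild-type class, while
under trans the mutant support of different variants lies on disjoint
reads.

Input is a pre-extracted read-support matrix (read x variant, each cell
``alt``/``ref``/``none``), keeping alignment files out of scope.  The
verdict is a threshold decision, not a statistical haplotype assembly:

* ``cis``   — at least ``concordance_threshold`` of informative reads
  (reads covering >=2 sites) are concordant (all-alt or all-ref at the
  sites they cover), with at least ``min_informative_reads`` in each of
  the two classes;
* ``trans`` — alt-supporting reads of different variants are (near-)
  disjoint: at most ``1 - concordance_threshold`` of alt-carrying
  informative reads carry alt at more than one site, with at least
  ``min_informative_reads`` alt reads for two or more variants;
* ``ambiguous`` otherwise (including no informative reads at all).
"""

from __future__ import annotations

import csv
import enum
import json
from collections import Counter
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Tuple

from .models import ParseError, PpglValError


class Support(str, enum.Enum):
    ALT = "alt"
    REF = "ref"
    NONE = "none"


class Verdict(str, enum.Enum):
    CIS = "cis"
    TRANS = "trans"
    AMBIGUOUS = "ambiguous"


@dataclass
class ReadSupportMatrix:
    """Rows = reads, columns = variants, cells in {alt, ref, none}."""

    reads: Tuple[str, ...]
    variants: Tuple[str, ...]
    support: Dict[Tuple[str, str], Support]

    def __post_init__(self) -> None:
        self.reads = tuple(self.reads)
        self.variants = tuple(self.variants)
        if not self.reads:
            raise PpglValError("support matrix needs at least one read")
        if len(self.variants) < 2:
            raise PpglValError("support matrix needs at least two variants")
        for read in self.reads:
            if not any(
                self.support.get((read, v), Support.NONE) is not Support.NONE
                for v in self.variants
            ):
                raise PpglValError(f"read {read!r} covers no variant site")

    def covered(self, read: str) -> List[str]:
        return [
            v
            for v in self.variants
            if self.support.get((read, v), Support.NONE) is not Support.NONE
        ]

    @classmethod
    def from_records(
        cls, records: Iterable[Tuple[str, str, str]]
    ) -> "ReadSupportMatrix":
        reads: List[str] = []
        variants: List[str] = []
        support: Dict[Tuple[str, str], Support] = {}
        for read_id, variant_id, value in records:
            if read_id not in reads:
                reads.append(read_id)
            if variant_id not in variants:
                variants.append(variant_id)
            support[(read_id, variant_id)] = Support(value)
        return cls(tuple(reads), tuple(variants), support)

    @classmethod
    def from_tsv(cls, path) -> "ReadSupportMatrix":
        records = []
        with open(path, newline="") as fh:
            reader = csv.DictReader(fh, delimiter="\t")
            if reader.fieldnames is None or not {
                "read_id",
                "variant_id",
                "support",
            }.issubset(reader.fieldnames):
                raise ParseError(
                    f"{path}: expected columns read_id, variant_id, support"
                )
            for lineno, row in enumerate(reader, start=2):
                try:
                    records.append(
                        (row["read_id"], row["variant_id"], Support(row["support"]))
                    )
                except ValueError as exc:
                    raise ParseError(f"{path}: {exc}", line=lineno) from exc
        return cls.from_records(records)


@dataclass
class PhaseResult:
    verdict: Verdict
    n_informative: int
    n_all_alt: int
    n_all_ref: int
    n_mixed: int
    n_multi_alt: int
    counts_per_variant: Dict[str, int] = field(default_factory=dict)

    def as_row(self) -> dict:
        return {
            "verdict": self.verdict.value,
            "n_informative": self.n_informative,
            "n_all_alt": self.n_all_alt,
            "n_all_ref": self.n_all_ref,
            "n_mixed": self.n_mixed,
            "n_multi_alt": self.n_multi_alt,
        }

    def to_json(self, path) -> None:
        payload = self.as_row()
        payload["alt_reads_per_variant"] = dict(sorted(self.counts_per_variant.items()))
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)
            fh.write("\n")


def phase(
    matrix: ReadSupportMatrix,
    concordance_threshold: float = 0.9,
    min_informative_reads: int = 5,
) -> PhaseResult:
    """Decide cis/trans/ambiguous from read co-segregation (see module docs)."""
    if not 0.5 < concordance_threshold <= 1.0:
        raise PpglValError("concordance_threshold must lie in (0.5, 1]")

    n_all_alt = n_all_ref = n_mixed = 0
    n_multi_alt = n_any_alt = 0
    alt_per_variant: Counter = Counter()
    n_informative = 0
    for read in matrix.reads:
        states = [
            matrix.support.get((read, v), Support.NONE)
            for v in matrix.variants
        ]
        covered = [s for s in states if s is not Support.NONE]
        if len(covered) < 2:
            continue
        n_informative += 1
        n_alt = sum(1 for s in covered if s is Support.ALT)
        for v in matrix.variants:
            if matrix.support.get((read, v), Support.NONE) is Support.ALT:
                alt_per_variant[v] += 1
        if n_alt == len(covered):
            n_all_alt += 1
        elif n_alt == 0:
            n_all_ref += 1
        else:
            n_mixed += 1
        if n_alt >= 1:
            n_any_alt += 1
        if n_alt >= 2:
            n_multi_alt += 1

    result = PhaseResult(
        verdict=Verdict.AMBIGUOUS,
        n_informative=n_informative,
        n_all_alt=n_all_alt,
        n_all_ref=n_all_ref,
        n_mixed=n_mixed,
        n_multi_alt=n_multi_alt,
        counts_per_variant=dict(alt_per_variant),
    )
    if n_informative == 0:
        return result

    concordant_fraction = (n_all_alt + n_all_ref) / n_informative
    if (
        concordant_fraction >= concordance_threshold
        and n_all_alt >= min_informative_reads
        and n_all_ref >= min_informative_reads
    ):
        result.verdict = Verdict.CIS
        return result

    if n_any_alt > 0:
        disjoint_fraction = 1.0 - n_multi_alt / n_any_alt
        variants_with_support = sum(
            1 for v in alt_per_variant if alt_per_variant[v] >= min_informative_reads
        )
        if disjoint_fraction >= concordance_threshold and variants_with_support >= 2:
            result.verdict = Verdict.TRANS
    return result
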