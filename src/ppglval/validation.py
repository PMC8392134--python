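"""Truth-set concordance, window sensitivity grids and cohort summaries.

Concordance is computed against Sanger-established truth: TP are surviving
calls matching a confirmed variant, FN are confirmed variants no surviving
call matches, FP are surviving calls matching no truth record.  TN need a
negative universe, for which two modes exist:

* ``per_variant`` (default): TN are artifact calls — members of the
  *pre-filter* call universe matching no truth variant — that the cascade
  eliminated.  This is the denominator under which a panel that removes
  113 of 114 artifact calls scores 99.1% specificity.
* ``per_position``: TN are counted over Sanger-confirmed wild-type spans
  (bases confirmed wild type and not falsely called).

Matching is by normalized (sample, chrom, pos, ref, alt): shared
prefix/suffix bases of indel representations are trimmed so that
differently written delins/dup forms compare equal.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Set, Tuple

import pandas as pd

from .afr import AfrWindow, alt_fraction, tightest_symmetric_window
from .models import (
    PpglValError,
    TruthRecord,
    TruthStatus,
    VariantCall,
    check_unique_truth,
)


@dataclass
class ConfusionSummary:
    """TP/FP/FN/TN with derived sensitivity/specificity (percent)."""

    tp: int
    fp: int
    fn: int
    tn: int
    mode: str = "per_variant"

    @property
    def sensitivity(self) -> Optional[float]:
        if self.tp + self.fn == 0:
            return None
        return 100.0 * self.tp / (self.tp + self.fn)

    @property
    def specificity(self) -> Optional[float]:
        if self.tn + self.fp == 0:
            return None
        return 100.0 * self.tn / (self.tn + self.fp)

    def as_row(self) -> dict:
        return {
            "tp": self.tp,
            "fp": self.fp,
            "fn": self.fn,
            "tn": self.tn,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "mode": self.mode,
        }


def _truth_variant_keys(truth: Sequence[TruthRecord]) -> Set[tuple]:
    return {
        t.locus_key()
        for t in truth
        if t.status is TruthStatus.VARIANT_PRESENT
    }


def compare_to_truth(
    calls: Sequence[VariantCall],
    truth: Sequence[TruthRecord],
    mode: str = "per_variant",
    universe: Optional[Sequence[VariantCall]] = None,
) -> ConfusionSummary:
    """Confusion summary of (surviving) ``calls`` against ``truth``.

    ``universe`` is the pre-filter call set; in ``per_variant`` mode it
    defines the artifact calls from which TN (eliminated artifacts) are
    counted.  In ``per_position`` mode TN are counted over the
    wildtype_confirmed spans of the truth set instead.
    """
    check_unique_truth(truth)
    truth_keys = _truth_variant_keys(truth)
    call_keys = [c.locus_key() for c in calls]
    surviving_keys = set(call_keys)

    tp = sum(1 for k in truth_keys if k in surviving_keys)
    fn = len(truth_keys) - tp
    fp = sum(1 for k in call_keys if k not in truth_keys)

    if mode == "per_variant":
        tn = 0
        if universe is not None:
            for c in universe:
                k = c.locus_key()
                if k not in truth_keys and k not in surviving_keys:
                    tn += 1
    elif mode == "per_position":
        spans = [
            t
            for t in truth
            if t.status is TruthStatus.WILDTYPE_CONFIRMED and t.region_span
        ]
        total_bases = sum(s.region_span[1] - s.region_span[0] + 1 for s in spans)
        fp_in_spans = 0
        for c in calls:
            if c.locus_key() in truth_keys:
                continue
            for s in spans:
                if (
                    c.sample_id == s.sample_id
                    and c.chrom == s.chrom
                    and s.region_span[0] <= c.pos <= s.region_span[1]
                ):
                    fp_in_spans += 1
                    break
        tn = total_bases - fp_in_spans
    else:
        raise PpglValError(f"unknown confusion mode {mode!r}")

    return ConfusionSummary(tp=tp, fp=fp, fn=fn, tn=tn, mode=mode)


@dataclass
class WindowGridRow:
    """One platform x window cell of the sensitivity grid."""

    platform: str
    window: AfrWindow
    true_variants: int
    detected: int
    false_positive: int
    false_negative: int

    @property
    def sensitivity(self) -> Optional[float]:
        if self.true_variants == 0:
            return None
        return 100.0 * self.detected / self.true_variants

    def as_row(self) -> dict:
        return {
            "platform": self.platform,
            "window": str(self.window),
            "true_variants": self.true_variants,
            "detected": self.detected,
            "false_positive": self.false_positive,
            "false_negative": self.false_negative,
            "sensitivity": self.sensitivity,
        }


def window_grid(
    calls_by_platform: Mapping[str, Sequence[VariantCall]],
    truth: Sequence[TruthRecord],
    windows: Sequence[AfrWindow],
) -> List[WindowGridRow]:
    """Apply each allele-fraction window (alone — no other filter) to each
    platform's call set and tabulate detections against the truth set.

    A truth variant counts toward a platform when one of that platform's
    calls matches it, or — for truth variants never called at all — when
    its sample appears in the platform's call set.
    """
    if not windows:
        raise PpglValError("window_grid requires at least one window")
    check_unique_truth(truth)
    truth_keys = _truth_variant_keys(truth)
    truth_samples = {
        t.sample_id: t.locus_key()
        for t in truth
        if t.status is TruthStatus.VARIANT_PRESENT
    }
    rows: List[WindowGridRow] = []
    for platform, calls in calls_by_platform.items():
        matched = [c for c in calls if c.locus_key() in truth_keys]
        artifacts = [c for c in calls if c.locus_key() not in truth_keys]
        matched_keys = {c.locus_key() for c in matched}
        platform_samples = {c.sample_id for c in calls}
        uncalled_truth = sum(
            1
            for t in truth
            if t.status is TruthStatus.VARIANT_PRESENT
            and t.locus_key() not in matched_keys
            and t.sample_id in platform_samples
        )
        n_true = len(matched_keys) + uncalled_truth
        for window in windows:
            detected = sum(
                1
                for c in matched
                if window.contains_fraction(alt_fraction(c.ref_reads, c.alt_reads))
            )
            fp = sum(
                1
                for c in artifacts
                if window.contains_fraction(alt_fraction(c.ref_reads, c.alt_reads))
            )
            rows.append(
                WindowGridRow(
                    platform=platform,
                    window=window,
                    true_variants=n_true,
                    detected=detected,
                    false_positive=fp,
                    false_negative=n_true - detected,
                )
            )
    return rows


def optimize_window(
    calls: Sequence[VariantCall],
    truth: Sequence[TruthRecord],
    rounding: str = "one_decimal",
) -> AfrWindow:
    """Tightest symmetric window retaining every truth-matched call.

    Only truth variants belonging to samples present in ``calls`` are
    considered (so per-platform call subsets can be optimized against a
    cohort-wide truth set); each of those must have a matching call with
    reads.  The result is guaranteed to give 100% sensitivity when
    re-evaluated on the same calls, because the window derives from the
    maximum observed deviation of the truth-matched calls themselves.
    """
    samples = {c.sample_id for c in calls}
    truth_keys = {
        t.locus_key()
        for t in truth
        if t.status is TruthStatus.VARIANT_PRESENT and t.sample_id in samples
    }
    true_calls = [c for c in calls if c.locus_key() in truth_keys]
    if not true_calls:
        raise PpglValError("no calls match the truth set; window undefined")
    missing = truth_keys - {c.locus_key() for c in true_calls}
    if missing:
        raise PpglValError(
            f"{len(missing)} truth variants have no corresponding call"
        )
    return tightest_symmetric_window(true_calls, rounding=rounding)


PATHOGENIC_CLASSES = frozenset({"pathogenic", "likely_pathogenic"})


@dataclass
class YieldSummary:
    """Diagnostic yield of a cohort: carriers of reportable variants."""

    cohort: str
    n_tested: int
    n_carriers: int
    per_gene: Dict[str, int] = field(default_factory=dict)

    @property
    def yield_pct(self) -> float:
        return 100.0 * self.n_carriers / self.n_tested

    def as_row(self) -> dict:
        row = {
            "cohort": self.cohort,
            "n_tested": self.n_tested,
            "n_carriers": self.n_carriers,
            "yield_pct": self.yield_pct,
        }
        for gene in sorted(self.per_gene):
            row[f"carriers_{gene}"] = self.per_gene[gene]
        return row


def diagnostic_yield(
    cohort: pd.DataFrame,
    cohort_name: str = "",
    mode: str = "clinical_class",
    genes: Optional[Iterable[str]] = None,
) -> YieldSummary:
    """Count carrier patients in a cohort table.

    The table has one row per patient x reported variant (patients without
    findings carry one row with empty ``gene``/``hgvs``), with columns
    ``patient_id``, ``gene``, ``hgvs``, ``clinical_class``.

    ``mode="clinical_class"`` counts patients with >=1 variant classified
    pathogenic/likely_pathogenic.  ``mode="any_variant"`` counts patients
    with *any* reported variant in ``genes`` (regardless of class) — the
    counting convention some cohort reports use for syndromic genes.
    """
    required = {"patient_id", "gene", "hgvs", "clinical_class"}
    if not required.issubset(cohort.columns):
        raise PpglValError(f"cohort table must have columns {sorted(required)}")
    n_tested = cohort["patient_id"].nunique()
    if n_tested == 0:
        raise PpglValError("cannot compute diagnostic yield of an empty cohort")

    has_variant = cohort["hgvs"].fillna("").astype(str).str.len() > 0
    if mode == "clinical_class":
        qualifying = cohort[
            has_variant & cohort["clinical_class"].isin(PATHOGENIC_CLASSES)
        ]
    elif mode == "any_variant":
        if genes is None:
            qualifying = cohort[has_variant]
        else:
            qualifying = cohort[has_variant & cohort["gene"].isin(set(genes))]
    else:
        raise PpglValError(f"unknown yield mode {mode!r}")

    carriers = qualifying["patient_id"].unique()
    per_gene = (
        qualifying.groupby("gene")["patient_id"].nunique().to_dict()
        if len(qualifying)
        else {}
    )
    return YieldSummary(
        cohort=cohort_name,
        n_tested=int(n_tested),
        n_carriers=int(len(carriers)),
        per_gene={str(g): int(n) for g, n in per_gene.items() if g},
    )


def _normalize_hgvs(hgvs: str) -> str:
    return "".join(str(hgvs).split())


def count_novel(
    variants: Sequence[Tuple[str, str]],
    known_index: Iterable[str],
) -> Tuple[List[str], Counter]:
    """Split variants into novel vs known against an HGVS index.

    ``variants`` is a sequence of ``(hgvs, clinical_class)`` pairs;
    ``known_index`` a collection of HGVS strings (compared after whitespace
    normalization; no online lookup).  Returns the novel HGVS list (input
    order, deduplicated) and a tally of novel variants by clinical class.
    Unparseable entries (no recognizable c./p./g. description) raise.
    """
    known = {_normalize_hgvs(k) for k in known_index}
    novel: List[str] = []
    seen: Set[str] = set()
    tally: Counter = Counter()
    for hgvs, clin in variants:
        norm = _normalize_hgvs(hgvs)
        if not norm:
            continue
        if not any(tag in norm for tag in ("c.", "p.", "g.", "m.", "n.")):
            raise PpglValError(f"unparseable HGVS description: {hgvs!r}")
        if norm in known or norm in seen:
            continue
        seen.add(norm)
        novel.append(hgvs)
        tally[str(clin)] += 1
    return novel, tally
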