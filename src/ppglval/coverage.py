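"""Per-gene depth-of-coverage over CDS regions.

Implements bedcov-style averaging: the mean of the per-base depth over a
gene's (merged) coding intervals, with positions absent from the depth
table counting as zero.  Overlapping intervals of one gene are merged
before averaging so no base contributes twice.  The standard deviation is
likewise per-base over the merged span.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass
from typing import Dict, Iterable, List, Sequence, Tuple

import numpy as np

from .models import DepthRecord, PanelDesign, PpglValError, Region


@dataclass(frozen=True)
class CoverageRecord:
    gene: str
    platform: str
    mean_depth: float
    sd_depth: float
    fraction_above_threshold: float

    def as_row(self) -> dict:
        return {
            "gene": self.gene,
            "platform": self.platform,
            "mean_depth": round(self.mean_depth, 2),
            "sd_depth": round(self.sd_depth, 2),
            "fraction_above_threshold": self.fraction_above_threshold,
        }


def merge_regions(regions: Sequence[Region]) -> List[Tuple[str, int, int]]:
    """Merge overlapping/adjacent half-open intervals per chromosome."""
    by_chrom: Dict[str, List[Tuple[int, int]]] = defaultdict(list)
    for r in regions:
        by_chrom[r.chrom].append((r.start, r.end))
    merged: List[Tuple[str, int, int]] = []
    for chrom in sorted(by_chrom):
        intervals = sorted(by_chrom[chrom])
        cur_s, cur_e = intervals[0]
        for s, e in intervals[1:]:
            if s <= cur_e:
                cur_e = max(cur_e, e)
            else:
                merged.append((chrom, cur_s, cur_e))
                cur_s, cur_e = s, e
        merged.append((chrom, cur_s, cur_e))
    return merged


def _depth_lookup(depth_records: Iterable[DepthRecord]) -> Dict[Tuple[str, int], float]:
    """Per-position depth; if several samples report a position, their mean."""
    sums: Dict[Tuple[str, int], float] = defaultdict(float)
    counts: Dict[Tuple[str, int], int] = defaultdict(int)
    for d in depth_records:
        key = (d.chrom, d.pos)
        sums[key] += d.depth
        counts[key] += 1
    return {k: sums[k] / counts[k] for k in sums}


def gene_mean_depth(
    depth_records: Sequence[DepthRecord],
    panel: PanelDesign,
    gene: str,
    platform: str = "",
    depth_threshold: float = 20.0,
) -> CoverageRecord:
    """Mean/SD per-base depth over the gene's merged CDS intervals.

    Positions without a depth record contribute zero (the convention of
    bedcov-style summaries, where uncovered bases count against the mean).
    ``fraction_above_threshold`` is the fraction of CDS bases at or above
    ``depth_threshold``.
    """
    regions = panel.gene_regions(gene)
    if not regions:
        raise PpglValError(f"gene {gene!r} absent from panel {panel.name!r}")
    lookup = _depth_lookup(depth_records)
    depths: List[float] = []
    for chrom, start, end in merge_regions(regions):
        # 1-based positions inside the half-open interval [start, end)
        for pos in range(start + 1, end + 1):
            depths.append(lookup.get((chrom, pos), 0.0))
    arr = np.asarray(depths, dtype=float)
    return CoverageRecord(
        gene=gene,
        platform=platform,
        mean_depth=float(arr.mean()),
        sd_depth=float(arr.std()),
        fraction_above_threshold=float((arr >= depth_threshold).mean()),
    )


def panel_coverage(
    depth_records: Sequence[DepthRecord],
    panel: PanelDesign,
    platform: str = "",
    depth_threshold: float = 20.0,
) -> List[CoverageRecord]:
    """Coverage record for every gene in the panel."""
    return [
        gene_mean_depth(depth_records, panel, gene, platform, depth_threshold)
        for gene in panel.genes
    ]


def flag_undercovered(
    records: Sequence[CoverageRecord],
    min_mean_depth: float,
    min_fraction: float = 0.9,
) -> List[CoverageRecord]:
    """Genes failing either coverage criterion, worst (lowest mean) first."""
    flagged = [
        r
        for r in records
        if r.mean_depth < min_mean_depth or r.fraction_above_threshold < min_fraction
    ]
    return sorted(flagged, key=lambda r: r.mean_depth)
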