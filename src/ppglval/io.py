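"""Readers and writers for the formats the pipeline touches.

Two call dialects are supported: VCF v4.2 (FORMAT/AD required — without
per-allele depths the allele-fraction stages cannot run) and a flat TSV
with one call per row whose columns match :class:`~ppglval.models.VariantCall`
fields exactly.  Truth sets, blacklists, depth tables and read-support
matrices are all plain TSV; panels are BED3/BED4 (0-based half-open, the
optional 4th column being the gene symbol).

Report floats follow the house precision: percentages to 1 decimal place,
fractions to 2.
"""

from __future__ import annotations

import csv
import dataclasses
import json
import math
from typing import Any, Iterable, List, Optional, Sequence

import pysam

from .models import (
    AcmgClass,
    BlacklistEntry,
    Consequence,
    DepthRecord,
    InvalidRecordError,
    NoAlleleDepthsError,
    PanelDesign,
    ParseError,
    PolyphenCategory,
    Region,
    TruthRecord,
    TruthStatus,
    VariantCall,
    Zygosity,
)

CALL_COLUMNS = [
    "sample_id",
    "chrom",
    "pos",
    "ref_allele",
    "alt_allele",
    "gene",
    "transcript",
    "hgvs_c",
    "hgvs_p",
    "ref_reads",
    "alt_reads",
    "consequence",
    "population_maf",
    "acmg_class",
    "polyphen_category",
    "sift_score",
    "zygosity_claim",
    "platform",
]

TRUTH_COLUMNS = [
    "sample_id",
    "chrom",
    "pos",
    "ref_allele",
    "alt_allele",
    "status",
    "span_start",
    "span_end",
]


def _opt_float(value: str) -> Optional[float]:
    value = (value or "").strip()
    if value in ("", "NA", "nan", "."):
        return None
    return float(value)


def read_calls(path, dialect: str = "tsv") -> List[VariantCall]:
    """Read a call set; ``dialect`` is ``"vcf"`` or ``"tsv"``.

    VCF records are decomposed per sample x ALT allele (a tri-allelic
    record yields two calls per genotyped sample, sharing the REF depth).
    Annotation fields absent from the input are set to unknown.
    """
    if dialect == "vcf":
        return _read_calls_vcf(path)
    if dialect == "tsv":
        return _read_calls_tsv(path)
    raise ParseError(f"unknown call dialect {dialect!r}")


def _read_calls_vcf(path) -> List[VariantCall]:
    try:
        vcf = pysam.VariantFile(str(path))
    except (ValueError, OSError) as exc:
        raise ParseError(f"cannot parse VCF {path}: {exc}") from exc
    if "AD" not in vcf.header.formats:
        raise NoAlleleDepthsError(
            f"{path}: no FORMAT/AD field — per-allele depths are required"
        )
    calls: List[VariantCall] = []
    with vcf:
        for rec in vcf:
            alts = rec.alts or ()
            for sample_name, sample in rec.samples.items():
                gt = sample.get("GT")
                if gt is None or all(a is None for a in gt):
                    continue
                ad = sample.get("AD")
                if ad is None or all(a is None for a in ad):
                    raise NoAlleleDepthsError(
                        f"{path}: sample {sample_name} at {rec.chrom}:{rec.pos} "
                        "has no allele depths (AD)"
                    )
                ref_reads = int(ad[0] or 0)
                for i, alt in enumerate(alts):
                    if alt is None:
                        continue
                    alleles = set(a for a in gt if a is not None)
                    zyg = Zygosity.UNKNOWN
                    if alleles == {0, i + 1}:
                        zyg = Zygosity.HET
                    elif alleles == {i + 1}:
                        zyg = Zygosity.HOM
                    calls.append(
                        VariantCall(
                            sample_id=sample_name,
                            chrom=rec.chrom,
                            pos=rec.pos,
                            ref_allele=rec.ref,
                            alt_allele=alt,
                            ref_reads=ref_reads,
                            alt_reads=int(ad[i + 1] or 0),
                            zygosity_claim=zyg,
                        )
                    )
    return calls


def _read_calls_tsv(path) -> List[VariantCall]:
    calls: List[VariantCall] = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        if reader.fieldnames is None:
            raise ParseError(f"{path}: empty file, header row required")
        missing = {"sample_id", "chrom", "pos", "ref_allele", "alt_allele"} - set(
            reader.fieldnames
        )
        if missing:
            raise ParseError(f"{path}: missing required columns {sorted(missing)}")
        if "ref_reads" not in reader.fieldnames or "alt_reads" not in reader.fieldnames:
            raise NoAlleleDepthsError(
                f"{path}: no ref_reads/alt_reads columns — per-allele depths required"
            )
        for lineno, row in enumerate(reader, start=2):
            try:
                calls.append(
                    VariantCall(
                        sample_id=row["sample_id"],
                        chrom=row["chrom"],
                        pos=int(row["pos"]),
                        ref_allele=row["ref_allele"],
                        alt_allele=row["alt_allele"],
                        ref_reads=int(row["ref_reads"]),
                        alt_reads=int(row["alt_reads"]),
                        gene=row.get("gene", "") or "",
                        transcript=row.get("transcript", "") or "",
                        hgvs_c=row.get("hgvs_c", "") or "",
                        hgvs_p=row.get("hgvs_p", "") or "",
                        consequence=Consequence(
                            row.get("consequence") or "unknown"
                        ),
                        population_maf=_opt_float(row.get("population_maf", "")),
                        acmg_class=AcmgClass(row.get("acmg_class") or "unknown"),
                        polyphen_category=PolyphenCategory(
                            row.get("polyphen_category") or "unknown"
                        ),
                        sift_score=_opt_float(row.get("sift_score", "")),
                        zygosity_claim=Zygosity(row.get("zygosity_claim") or "unknown"),
                        platform=row.get("platform", "") or "",
                    )
                )
            except (ValueError, KeyError) as exc:
                raise ParseError(f"{path}: {exc}", line=lineno) from exc
    return calls


def write_calls(calls: Sequence[VariantCall], path) -> None:
    """Write calls in the TSV dialect; lossless round-trip with read_calls."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(CALL_COLUMNS)
        for c in calls:
            writer.writerow(
                [
                    c.sample_id,
                    c.chrom,
                    c.pos,
                    c.ref_allele,
                    c.alt_allele,
                    c.gene,
                    c.transcript,
                    c.hgvs_c,
                    c.hgvs_p,
                    c.ref_reads,
                    c.alt_reads,
                    c.consequence.value,
                    "" if c.population_maf is None else repr(c.population_maf),
                    c.acmg_class.value,
                    c.polyphen_category.value,
                    "" if c.sift_score is None else repr(c.sift_score),
                    c.zygosity_claim.value,
                    c.platform,
                ]
            )


def read_truth(path) -> List[TruthRecord]:
    """Read a truth-set TSV (columns of :data:`TRUTH_COLUMNS`)."""
    records: List[TruthRecord] = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        if reader.fieldnames is None:
            raise ParseError(f"{path}: empty file, header row required")
        for lineno, row in enumerate(reader, start=2):
            try:
                span = None
                if row.get("span_start") and row.get("span_end"):
                    span = (int(row["span_start"]), int(row["span_end"]))
                records.append(
                    TruthRecord(
                        sample_id=row["sample_id"],
                        chrom=row["chrom"],
                        pos=int(row["pos"]),
                        ref_allele=row.get("ref_allele", "") or "",
                        alt_allele=row.get("alt_allele", "") or "",
                        status=TruthStatus(row["status"]),
                        region_span=span,
                    )
                )
            except (ValueError, KeyError, InvalidRecordError) as exc:
                raise ParseError(f"{path}: {exc}", line=lineno) from exc
    return records


def write_truth(records: Sequence[TruthRecord], path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(TRUTH_COLUMNS)
        for t in records:
            span = t.region_span or ("", "")
            writer.writerow(
                [
                    t.sample_id,
                    t.chrom,
                    t.pos,
                    t.ref_allele,
                    t.alt_allele,
                    t.status.value,
                    span[0],
                    span[1],
                ]
            )


def read_panel_bed(path, name: Optional[str] = None, intronic_padding_bp: int = 30) -> PanelDesign:
    """Read a BED3/BED4 panel design (4th column = gene symbol)."""
    regions: List[Region] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t") if "\t" in line else line.split()
            if len(parts) < 3:
                raise ParseError(f"{path}: expected >=3 BED columns", line=lineno)
            try:
                start, end = int(parts[1]), int(parts[2])
            except ValueError as exc:
                raise ParseError(f"{path}: non-integer coordinates", line=lineno) from exc
            if end <= start:
                raise ParseError(
                    f"{path}: degenerate interval {parts[0]}:{start}-{end}", line=lineno
                )
            gene = parts[3] if len(parts) > 3 else ""
            regions.append(Region(parts[0], start, end, gene))
    return PanelDesign(
        name=name or str(path),
        regions=tuple(regions),
        intronic_padding_bp=intronic_padding_bp,
    )


def write_panel_bed(panel: PanelDesign, path) -> None:
    with open(path, "w") as fh:
        for r in panel.regions:
            fh.write(f"{r.chrom}\t{r.start}\t{r.end}\t{r.gene}\n")


def read_depth_tsv(path, sample_id: str = "") -> List[DepthRecord]:
    """Read a samtools-depth-like TSV: chrom, 1-based pos, depth."""
    records: List[DepthRecord] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t") if "\t" in line else line.split()
            if len(parts) < 3:
                raise ParseError(f"{path}: expected 3 columns", line=lineno)
            try:
                records.append(
                    DepthRecord(
                        chrom=parts[0],
                        pos=int(parts[1]),
                        depth=int(parts[2]),
                        sample_id=parts[3] if len(parts) > 3 else sample_id,
                    )
                )
            except ValueError as exc:
                raise ParseError(f"{path}: {exc}", line=lineno) from exc
    return records


def write_depth_tsv(records: Sequence[DepthRecord], path) -> None:
    with open(path, "w") as fh:
        for d in records:
            fh.write(f"{d.chrom}\t{d.pos}\t{d.depth}\t{d.sample_id}\n")


def read_blacklist(path) -> List[BlacklistEntry]:
    """Read a blacklist TSV: chrom, pos, ref, alt, note."""
    entries: List[BlacklistEntry] = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        if reader.fieldnames is None:
            return entries
        for lineno, row in enumerate(reader, start=2):
            try:
                entries.append(
                    BlacklistEntry(
                        chrom=row["chrom"],
                        pos=int(row["pos"]),
                        ref_allele=row["ref_allele"],
                        alt_allele=row["alt_allele"],
                        note=row.get("note", "") or "",
                    )
                )
            except (ValueError, KeyError) as exc:
                raise ParseError(f"{path}: {exc}", line=lineno) from exc
    return entries


# ---------------------------------------------------------------------------
# generic report writing

#: field-name suffixes rendered as percentages (1 dp) vs fractions (2 dp)
_PERCENT_FIELDS = ("_pct", "sensitivity", "specificity")
_FRACTION_FIELDS = ("fraction", "_maf", "alt_fraction")


def _format_value(key: str, value: Any) -> Any:
    if isinstance(value, bool) or value is None:
        return value
    if isinstance(value, float):
        if math.isnan(value):
            return ""
        if any(key.endswith(s) or key == s.strip("_") for s in _PERCENT_FIELDS):
            return f"{value:.1f}"
        if any(s in key for s in _FRACTION_FIELDS):
            return f"{value:.2f}"
        return f"{value:g}"
    return value


def _to_rows(results: Any) -> List[dict]:
    if hasattr(results, "as_rows"):
        results = results.as_rows()
    elif hasattr(results, "as_row"):
        results = [results.as_row()]
    if dataclasses.is_dataclass(results) and not isinstance(results, type):
        results = [results]
    if isinstance(results, dict):
        results = [results]
    rows = []
    for item in results:
        if hasattr(item, "as_row"):
            item = item.as_row()
        elif dataclasses.is_dataclass(item) and not isinstance(item, type):
            item = dataclasses.asdict(item)
        rows.append(dict(item))
    return rows


def write_report(results: Any, path, format: str = "tsv") -> None:
    """Write a report with deterministic column order and fixed float precision.

    ``results`` may be a dataclass, a dict, or a sequence of either; columns
    follow the field order of the first row.  Writing the same results twice
    yields byte-identical files.
    """
    rows = _to_rows(results)
    if format == "json":
        formatted = [
            {k: _format_value(k, v) for k, v in row.items()} for row in rows
        ]
        with open(path, "w") as fh:
            json.dump(formatted if len(formatted) != 1 else formatted[0], fh, indent=2)
            fh.write("\n")
        return
    if format != "tsv":
        raise ParseError(f"unknown report format {format!r}")
    columns = list(rows[0].keys()) if rows else []
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(columns)
        for row in rows:
            writer.writerow([_format_value(k, row.get(k, "")) for k in columns])
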