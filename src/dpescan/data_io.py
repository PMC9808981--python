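"""Readers/writers for the formats the pipeline touches, and exon counting.

Supported inputs: exon annotation as GTF (Ensembl attribute dialect,
1-based inclusive, converted to 0-based half-open on read) or BED4+
(used as-is), TSV count matrices with exon ids in the first column,
CSV/TSV sample sheets, GMT gene-set collections, and coordinate-sorted
BAM/SAM alignments for per-exon fragment counting with HTSeq-style
"union" assignment.
"""

from __future__ import annotations

import re
import warnings
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd
import pysam

from .types import CountMatrix, ExonCatalog, ExonRecord, GeneSet, SampleInfo

_GTF_ATTR_RE = re.compile(r'(\w+)\s+"([^"]*)"')


class ParseError(ValueError):
    """Malformed input file; message names the offending line."""


def _dedup_ids(raw_ids: list[str]) -> list[str]:
    """Disambiguate missing/duplicate ids by appending an ordinal suffix."""
    seen: dict[str, int] = {}
    out = []
    for rid in raw_ids:
        n = seen.get(rid, 0) + 1
        seen[rid] = n
        out.append(rid if n == 1 else f"{rid}_{n}")
    return out


def read_exon_annotation(path: str | Path, format: str = "gtf") -> ExonCatalog:
    """Read an exon catalog from a GTF or BED file.

    GTF rows with feature type "exon" become records; coordinates are
    converted from 1-based inclusive to 0-based half-open.  BED intervals
    are used as-is.  Missing or duplicated exon ids get an ordinal suffix.
    """
    path = Path(path)
    if format not in {"gtf", "bed"}:
        raise ValueError(f"unsupported annotation format {format!r}")
    raw: list[tuple[str, str, str, int, int, str]] = []  # id,gene,chrom,start,end,strand
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if format == "gtf":
                if len(fields) < 9:
                    raise ParseError(f"{path}:{lineno}: GTF line has {len(fields)} fields, expected 9")
                if fields[2] != "exon":
                    continue
                try:
                    start1, end1 = int(fields[3]), int(fields[4])
                except ValueError:
                    raise ParseError(f"{path}:{lineno}: non-integer coordinates") from None
                attrs = dict(_GTF_ATTR_RE.findall(fields[8]))
                gene = attrs.get("gene_id")
                if gene is None:
                    raise ParseError(f"{path}:{lineno}: missing gene_id attribute")
                exon_id = attrs.get("exon_id", "")
                raw.append((exon_id, gene, fields[0], start1 - 1, end1, fields[6]))
            else:  # bed
                if len(fields) < 3:
                    raise ParseError(f"{path}:{lineno}: BED line has {len(fields)} fields, expected >=3")
                try:
                    start, end = int(fields[1]), int(fields[2])
                except ValueError:
                    raise ParseError(f"{path}:{lineno}: non-integer coordinates") from None
                name = fields[3] if len(fields) > 3 else ""
                strand = fields[5] if len(fields) > 5 and fields[5] in "+-" else "."
                # BED carries no gene linkage; fall back to the name itself
                raw.append((name, name or f"{fields[0]}:{start}-{end}", fields[0], start, end, strand))
    ids = _dedup_ids([r[0] if r[0] else f"{r[2]}:{r[3]}-{r[4]}" for r in raw])
    records = [
        ExonRecord(exon_id=i, gene_id=g, chrom=c, start=s, end=e, strand=st)
        for i, (_, g, c, s, e, st) in zip(ids, raw)
    ]
    return ExonCatalog(records)


def read_sample_sheet(path: str | Path) -> list[SampleInfo]:
    """Read a CSV/TSV sample sheet with columns sample_id, group, sex."""
    df = pd.read_csv(path, sep=None, engine="python", dtype=str)
    required = {"sample_id", "group"}
    if not required.issubset(df.columns):
        raise ParseError(f"{path}: sample sheet must have columns {sorted(required)}")
    if "sex" not in df.columns:
        df["sex"] = "unknown"
    df["sex"] = df["sex"].fillna("unknown")
    dupes = df["sample_id"][df["sample_id"].duplicated()].tolist()
    if dupes:
        raise ParseError(f"{path}: duplicate sample ids: {dupes}")
    samples = []
    for i, row in df.iterrows():
        try:
            samples.append(SampleInfo(row["sample_id"], row["group"], row["sex"]))
        except ValueError as exc:
            raise ParseError(f"{path}: row {i + 2}: {exc}") from None
    return samples


def write_sample_sheet(samples: Iterable[SampleInfo], path: str | Path) -> None:
    pd.DataFrame(
        [(s.sample_id, s.group, s.sex) for s in samples],
        columns=["sample_id", "group", "sex"],
    ).to_csv(path, index=False)


def read_count_matrix(path: str | Path) -> CountMatrix:
    """Read a TSV count matrix: exon ids in the first column, samples in header."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    arr = df.to_numpy()
    if not np.issubdtype(arr.dtype, np.integer):
        bad = np.argwhere((arr != np.floor(arr)) | ~np.isfinite(arr))
        if bad.size:
            r, c = bad[0]
            raise ParseError(
                f"{path}: non-integer count {arr[r, c]!r} at exon "
                f"{df.index[r]!r}, sample {df.columns[c]!r}"
            )
        arr = arr.astype(np.int64)
    if np.any(arr < 0):
        r, c = np.argwhere(arr < 0)[0]
        raise ParseError(
            f"{path}: negative count at exon {df.index[r]!r}, sample {df.columns[c]!r}"
        )
    return CountMatrix(arr, [str(i) for i in df.index], [str(c) for c in df.columns])


def write_count_matrix(matrix: CountMatrix, path: str | Path) -> None:
    matrix.to_frame().rename_axis("exon_id").to_csv(path, sep="\t")


def read_gmt(path: str | Path) -> list[GeneSet]:
    """Read a GMT file: one gene set per tab-separated line."""
    sets = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(f"{path}:{lineno}: GMT line has fewer than 3 fields")
            members = frozenset(g for g in fields[2:] if g)
            sets.append(GeneSet(name=fields[0], description=fields[1], members=members))
    return sets


def count_reads_per_exon(
    alignments: str | Path,
    catalog: ExonCatalog,
    min_mapq: int = 10,
    mode: str = "union",
) -> tuple[np.ndarray, dict[str, int]]:
    """Count fragments per exon from a BAM/SAM file with union assignment.

    Each primary, non-duplicate alignment with MAPQ >= ``min_mapq`` is
    assigned by union semantics: a fragment overlapping exactly one exon id
    counts there; overlapping two or more distinct exon ids it is ambiguous
    and counted nowhere; no overlap leaves it unassigned.  Read pairs count
    once per fragment (the union of both mates' overlaps); singletons count
    once.  Returns (counts aligned to catalog order, assignment stats).
    """
    if mode != "union":
        raise ValueError(f"unsupported assignment mode {mode!r}; only 'union' implemented")
    counts = {rec.exon_id: 0 for rec in catalog}
    stats = {"assigned": 0, "ambiguous": 0, "unassigned": 0}
    pending: dict[str, set[str]] = {}  # qname -> overlap set of the first-seen mate

    def assign(hits: set[str]) -> None:
        if len(hits) == 1:
            counts[next(iter(hits))] += 1
            stats["assigned"] += 1
        elif len(hits) > 1:
            stats["ambiguous"] += 1
        else:
            stats["unassigned"] += 1

    mode_flag = "rb" if str(alignments).endswith(".bam") else "r"
    with pysam.AlignmentFile(str(alignments), mode_flag) as bam:
        any_mapped = False
        for aln in bam:
            if aln.is_unmapped or aln.is_secondary or aln.is_supplementary or aln.is_duplicate:
                continue
            if aln.mapping_quality < min_mapq:
                continue
            any_mapped = True
            hits = set()
            for start, end in aln.get_blocks():
                hits |= catalog.overlapping(aln.reference_name, start, end)
            if aln.is_paired and not aln.mate_is_unmapped:
                if aln.query_name in pending:
                    assign(pending.pop(aln.query_name) | hits)
                else:
                    pending[aln.query_name] = hits
            else:
                assign(hits)
    # mates whose partner never appeared still count once
    for hits in pending.values():
        assign(hits)
    if not any_mapped:
        warnings.warn(f"{alignments}: no mapped reads passed filters; all-zero column")
    return np.array([counts[r.exon_id] for r in catalog], dtype=np.int64), stats


def count_matrix_from_bams(
    bam_paths: dict[str, str | Path],
    catalog: ExonCatalog,
    min_mapq: int = 10,
) -> CountMatrix:
    """Build a CountMatrix by counting each BAM as one sample column."""
    cols, ids = [], []
    for sample_id, path in bam_paths.items():
        col, _ = count_reads_per_exon(path, catalog, min_mapq=min_mapq)
        cols.append(col)
        ids.append(sample_id)
    return CountMatrix(np.stack(cols, axis=1), catalog.exon_ids, ids)
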