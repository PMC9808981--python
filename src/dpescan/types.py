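"""Core domain containers shared across the pipeline.

The central object is :class:`CountMatrix` — an exons x samples integer
count matrix with per-sample library sizes.  Coordinates are 0-based
half-open everywhere inside the package; GTF input is converted on read.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator, Sequence

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

VALID_GROUPS = frozenset({"M", "N", "U", "H"})
VALID_SEXES = frozenset({"male", "female", "unknown"})


@dataclass(frozen=True)
class ExonRecord:
    """A single exon interval with gene linkage (0-based, half-open)."""

    exon_id: str
    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError(f"exon {self.exon_id!r}: empty chromosome name")
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"exon {self.exon_id!r}: invalid interval [{self.start}, {self.end})"
            )
        if self.strand not in {"+", "-", "."}:
            raise ValueError(f"exon {self.exon_id!r}: invalid strand {self.strand!r}")


class ExonCatalog:
    """Ordered exon records with an id index and per-chromosome interval trees."""

    def __init__(self, records: Iterable[ExonRecord]):
        self.records: list[ExonRecord] = list(records)
        self._by_id: dict[str, ExonRecord] = {}
        for rec in self.records:
            if rec.exon_id in self._by_id:
                raise ValueError(f"duplicate exon_id {rec.exon_id!r} in catalog")
            self._by_id[rec.exon_id] = rec
        self._trees: dict[str, IntervalTree] = {}
        for rec in self.records:
            self._trees.setdefault(rec.chrom, IntervalTree()).addi(
                rec.start, rec.end, rec.exon_id
            )

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[ExonRecord]:
        return iter(self.records)

    def __contains__(self, exon_id: str) -> bool:
        return exon_id in self._by_id

    def get(self, exon_id: str) -> ExonRecord:
        return self._by_id[exon_id]

    @property
    def exon_ids(self) -> list[str]:
        return [r.exon_id for r in self.records]

    def overlapping(self, chrom: str, start: int, end: int) -> set[str]:
        """Exon ids overlapping [start, end) on chrom (0-based, half-open)."""
        tree = self._trees.get(chrom)
        if tree is None or start >= end:
            return set()
        return {iv.data for iv in tree.overlap(start, end)}

    def genes_of(self, exon_ids: Iterable[str]) -> set[str]:
        missing = [e for e in exon_ids if e not in self._by_id]
        if missing:
            raise KeyError(f"exon ids not in catalog: {sorted(missing)[:10]}")
        return {self._by_id[e].gene_id for e in exon_ids}


@dataclass(frozen=True)
class SampleInfo:
    """One cohort sample: id, group code (M/N/U/H) and sex."""

    sample_id: str
    group: str
    sex: str = "unknown"

    def __post_init__(self) -> None:
        if self.group not in VALID_GROUPS:
            raise ValueError(
                f"sample {self.sample_id!r}: group {self.group!r} not in "
                f"{sorted(VALID_GROUPS)}"
            )
        if self.sex not in VALID_SEXES:
            raise ValueError(f"sample {self.sample_id!r}: invalid sex {self.sex!r}")


@dataclass
class CountMatrix:
    """Exons x samples integer counts with per-sample library sizes.

    ``lib_sizes`` defaults to column sums but is carried independently so
    that filtering steps can preserve the original assay depth.
    """

    counts: np.ndarray
    exon_ids: list[str]
    sample_ids: list[str]
    lib_sizes: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 2:
            raise ValueError("counts must be a 2-D matrix")
        if not np.issubdtype(self.counts.dtype, np.integer):
            if not np.all(self.counts == np.floor(self.counts)):
                raise ValueError("counts must be integers")
            self.counts = self.counts.astype(np.int64)
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")
        g, s = self.counts.shape
        if len(self.exon_ids) != g:
            raise ValueError("exon_ids length does not match count rows")
        if len(self.sample_ids) != s:
            raise ValueError("sample_ids length does not match count columns")
        if len(set(self.exon_ids)) != g:
            raise ValueError("duplicate exon ids")
        if len(set(self.sample_ids)) != s:
            raise ValueError("duplicate sample ids")
        if self.lib_sizes is None:
            self.lib_sizes = self.counts.sum(axis=0).astype(float)
        else:
            self.lib_sizes = np.asarray(self.lib_sizes, dtype=float)
            if self.lib_sizes.shape != (s,):
                raise ValueError("lib_sizes length does not match samples")
        if np.any(self.lib_sizes <= 0):
            bad = [self.sample_ids[i] for i in np.where(self.lib_sizes <= 0)[0]]
            raise ValueError(f"non-positive library size for samples: {bad}")

    @property
    def n_exons(self) -> int:
        return self.counts.shape[0]

    @property
    def n_samples(self) -> int:
        return self.counts.shape[1]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.exon_ids, columns=self.sample_ids)

    def subset_exons(self, keep: Sequence[int] | np.ndarray) -> "CountMatrix":
        keep = np.asarray(keep)
        return CountMatrix(
            counts=self.counts[keep],
            exon_ids=[self.exon_ids[i] for i in keep],
            sample_ids=list(self.sample_ids),
            lib_sizes=self.lib_sizes.copy(),
        )

    def subset_samples(self, keep: Sequence[int] | np.ndarray) -> "CountMatrix":
        keep = np.asarray(keep)
        return CountMatrix(
            counts=self.counts[:, keep],
            exon_ids=list(self.exon_ids),
            sample_ids=[self.sample_ids[i] for i in keep],
            lib_sizes=self.lib_sizes[keep],
        )


@dataclass(frozen=True)
class GeneSet:
    """A named gene set (e.g. one GMT line)."""

    name: str
    members: frozenset[str]
    description: str = ""

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError(f"gene set {self.name!r} has no members")
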