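"""Core genomic coordinate types and interval algebra.

All coordinates are 0-based, half-open ``[start, end)`` — the BED convention.
Strand is carried as metadata and never flips interval coordinates; a TSS
position is the strand-aware transcription start, precomputed by the provider.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "GenomicInterval",
    "Tss",
    "Peak",
    "window_around",
    "overlaps",
    "overlap_join",
    "merge_intervals",
]


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A half-open genomic span ``chrom:[start, end)``."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}: "
                "require 0 <= start < end"
            )

    def __len__(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2

    def contains(self, pos: int) -> bool:
        return self.start <= pos < self.end


@dataclass(frozen=True)
class Tss:
    """A transcription start site with per-cell-type expression levels.

    ``pos`` is the strand-aware start base; ``expression`` maps cell-type
    name to a non-negative level (or a 0/1 activity flag).
    """

    gene: str
    chrom: str
    pos: int
    strand: str
    expression: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.pos < 0:
            raise ValueError(f"TSS {self.gene}: pos must be >= 0")
        if self.strand not in ("+", "-"):
            raise ValueError(f"TSS {self.gene}: strand must be + or -")
        for cell, level in self.expression.items():
            if level < 0:
                raise ValueError(f"TSS {self.gene}: expression[{cell}] < 0")


@dataclass(frozen=True)
class Peak:
    """A ChIP-seq peak: an interval with a summit and an enrichment signal."""

    interval: GenomicInterval
    summit: int
    signal: float = 0.0
    name: str = "."

    def __post_init__(self) -> None:
        if not self.interval.contains(self.summit):
            raise ValueError(
                f"peak {self.name}: summit {self.summit} outside "
                f"{self.interval.chrom}:{self.interval.start}-{self.interval.end}"
            )
        if self.signal < 0:
            raise ValueError(f"peak {self.name}: signal must be >= 0")

    @property
    def chrom(self) -> str:
        return self.interval.chrom

    @property
    def start(self) -> int:
        return self.interval.start

    @property
    def end(self) -> int:
        return self.interval.end


def window_around(pos: int, radius: int, chrom: str, chrom_len: int) -> GenomicInterval:
    """Half-open window of ``radius`` bp either side of ``pos``, clamped to
    ``[0, chrom_len)``.

    Raises if ``pos`` lies outside the chromosome or ``radius <= 0``.
    """
    if radius <= 0:
        raise ValueError("radius must be > 0")
    if not (0 <= pos < chrom_len):
        raise ValueError(f"position {pos} outside chromosome {chrom} (len {chrom_len})")
    return GenomicInterval(chrom, max(0, pos - radius), min(chrom_len, pos + radius))


def overlaps(a: GenomicInterval, b: GenomicInterval) -> bool:
    """True iff the two intervals share at least one base."""
    return a.chrom == b.chrom and a.start < b.end and b.start < a.end


def overlap_join(
    query: Sequence[GenomicInterval], subject: Sequence[GenomicInterval]
) -> list[tuple[int, int]]:
    """All index pairs ``(i, j)`` with ``overlaps(query[i], subject[j])``,
    sorted by ``(i, j)``.

    Vectorised per chromosome; suited to the desk-scale inputs this package
    works with (up to ~1e4 intervals a side).
    """
    if not query or not subject:
        return []
    out: list[tuple[int, int]] = []
    s_by_chrom: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
    for chrom in {s.chrom for s in subject}:
        idx = np.array([j for j, s in enumerate(subject) if s.chrom == chrom])
        starts = np.array([subject[j].start for j in idx])
        ends = np.array([subject[j].end for j in idx])
        order = np.argsort(starts, kind="stable")
        s_by_chrom[chrom] = (idx[order], starts[order], ends[order])
    for i, q in enumerate(query):
        if q.chrom not in s_by_chrom:
            continue
        idx, starts, ends = s_by_chrom[q.chrom]
        # subjects starting before the query ends; filter those ending too early
        hi = np.searchsorted(starts, q.end, side="left")
        hit = idx[:hi][ends[:hi] > q.start]
        out.extend((i, int(j)) for j in np.sort(hit))
    return out


def merge_intervals(intervals: Iterable[GenomicInterval]) -> list[GenomicInterval]:
    """Union of possibly-overlapping intervals, returned sorted and disjoint.

    Abutting intervals (shared boundary, zero shared bases) are NOT merged.
    """
    ivs = sorted(intervals)
    merged: list[GenomicInterval] = []
    for iv in ivs:
        if merged and merged[-1].chrom == iv.chrom and iv.start < merged[-1].end:
            last = merged[-1]
            merged[-1] = GenomicInterval(last.chrom, last.start, max(last.end, iv.end))
        else:
            merged.append(iv)
    return merged
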