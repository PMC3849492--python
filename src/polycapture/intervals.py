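"""Genomic interval utilities shared across the pipeline.

All coordinates are 0-based, half-open.  Conversion to/from the 1-based
closed convention happens only at GFF3/VCF boundaries (see :mod:`io`).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from intervaltree import IntervalTree


Interval = tuple[int, int]


def merge_intervals(ivs: Iterable[Interval]) -> list[Interval]:
    """Merge overlapping or adjacent half-open intervals into a sorted,
    disjoint list."""
    ivs = sorted((int(a), int(b)) for a, b in ivs if b > a)
    out: list[Interval] = []
    for a, b in ivs:
        if out and a <= out[-1][1]:
            out[-1] = (out[-1][0], max(out[-1][1], b))
        else:
            out.append((a, b))
    return out


def total_length(ivs: Iterable[Interval]) -> int:
    return sum(b - a for a, b in ivs)


def complement_intervals(ivs: Sequence[Interval], length: int) -> list[Interval]:
    """Intervals of [0, length) not covered by the (merged) input."""
    out: list[Interval] = []
    prev = 0
    for a, b in merge_intervals(ivs):
        if a > prev:
            out.append((prev, a))
        prev = max(prev, b)
    if prev < length:
        out.append((prev, length))
    return out


def in_intervals(pos: int, ivs: Sequence[Interval]) -> bool:
    for a, b in ivs:
        if a <= pos < b:
            return True
    return False


def positions_mask(ivs: Sequence[Interval], length: int) -> np.ndarray:
    """Boolean per-base mask for a set of intervals."""
    mask = np.zeros(length, dtype=bool)
    for a, b in ivs:
        mask[max(0, a):min(length, b)] = True
    return mask


@dataclass
class GeneModel:
    """A gene with its CDS exons; introns are implied (gene minus exons)."""

    seq_name: str
    strand: str
    gene_interval: Interval
    exon_intervals: list[Interval]
    gene_id: str = ""

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"strand must be + or -, got {self.strand!r}")
        g0, g1 = self.gene_interval
        if g1 <= g0:
            raise ValueError("empty gene interval")
        self.exon_intervals = sorted((int(a), int(b)) for a, b in self.exon_intervals)
        prev_end = g0
        for a, b in self.exon_intervals:
            if a < g0 or b > g1:
                raise ValueError("exon outside gene interval")
            if a < prev_end:
                raise ValueError("overlapping or unsorted exons")
            prev_end = b

    @property
    def intron_intervals(self) -> list[Interval]:
        """Gaps between consecutive exons (never stored, always derived)."""
        out = []
        for (a0, b0), (a1, b1) in zip(self.exon_intervals, self.exon_intervals[1:]):
            if a1 > b0:
                out.append((b0, a1))
        return out


class GeneAnnotationIndex:
    """Interval index over gene spans and CDS spans, one tree pair per
    sequence, answering region queries in O(log n)."""

    def __init__(self, seq_lengths: dict[str, int] | None = None):
        self._genes: dict[str, IntervalTree] = {}
        self._cds: dict[str, IntervalTree] = {}
        self.seq_lengths = seq_lengths or {}

    @classmethod
    def from_gene_models(
        cls, models: Iterable[GeneModel], seq_lengths: dict[str, int] | None = None
    ) -> "GeneAnnotationIndex":
        idx = cls(seq_lengths)
        for gm in models:
            gtree = idx._genes.setdefault(gm.seq_name, IntervalTree())
            ctree = idx._cds.setdefault(gm.seq_name, IntervalTree())
            gtree.addi(*gm.gene_interval)
            for a, b in gm.exon_intervals:
                ctree.addi(a, b)
        return idx

    def classify(self, seq_name: str, pos: int) -> str:
        """Region of a position: ``CDS`` > ``intron`` > ``intergenic``.
        CDS wins over intron across overlapping gene models."""
        if self.seq_lengths:
            length = self.seq_lengths.get(seq_name)
            if length is not None and not (0 <= pos < length):
                raise ValueError(
                    f"position {pos} outside sequence {seq_name} (length {length})"
                )
        if seq_name in self._cds and self._cds[seq_name].overlaps_point(pos):
            return "CDS"
        if seq_name in self._genes and self._genes[seq_name].overlaps_point(pos):
            return "intron"
        return "intergenic"
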