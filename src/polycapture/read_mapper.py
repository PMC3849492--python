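"""Unique-best read placement at a minimum identity, and the RM/RMp/RMpi
mapping bookkeeping.

A read is placed by k-mer seeding against an indexed reference followed by
gapless full-length comparison (the synthetic model is substitution-only, so
alignment columns equal read length).  Identity is matches over alignment
columns.  A read is reported only when exactly one placement attains the
best identity at or above the floor — ties mean the read cannot be assigned
to a single homoeolog and it is dropped, which is the point of the 98%
identity floor in an allopolyploid.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from ._util import revcomp, round_half_away, seq_to_arr
from .reference_builder import ReferenceSet


@dataclass
class AlignmentRecord:
    """A unique-best, gapless placement of one read."""

    read_id: str
    seq_name: str
    start: int
    end: int
    strand: str
    identity: float
    mismatch_offsets: np.ndarray  # offsets into the reference slice
    mismatch_bases: bytes  # oriented read base at each mismatch offset
    read_seq: str = ""  # oriented (reference-strand) read sequence
    unique: bool = True

    @property
    def read_length(self) -> int:
        return self.end - self.start

    def aligned_pairs(self) -> Iterable[tuple[int, int]]:
        """(read_offset, reference_position) pairs of the gapless alignment."""
        for i in range(self.read_length):
            yield i, self.start + i


@dataclass
class MappingStats:
    """Table-2-style bookkeeping: SR, RM and the derived RMp percentage."""

    reference_label: str
    sr: int
    rm: int
    per_line: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.sr == 0:
            raise ValueError("SR must be positive")
        if not (0 <= self.rm <= self.sr):
            raise ValueError("RM must satisfy 0 <= RM <= SR")

    @property
    def rmp(self) -> int:
        """Percent of reads mapped, printed as an integer."""
        return int(round_half_away(100.0 * self.rm / self.sr))


class ReferenceIndex:
    """k-mer position index over a reference set's forward strands."""

    def __init__(self, sequences: dict[str, str], k: int, max_hits: int = 32):
        self.k = k
        self.names: list[str] = sorted(sequences)
        self.arrs: list[np.ndarray] = [seq_to_arr(sequences[n]) for n in self.names]
        self.lengths: list[int] = [a.size for a in self.arrs]
        self._index: dict[bytes, list[tuple[int, int]] | None] = {}
        for si, name in enumerate(self.names):
            data = sequences[name].encode("ascii")
            for i in range(len(data) - k + 1):
                kmer = data[i : i + k]
                slot = self._index.get(kmer, [])
                if slot is None:
                    continue
                slot.append((si, i))
                if len(slot) > max_hits:
                    self._index[kmer] = None  # repeat-masked
                else:
                    self._index[kmer] = slot

    def lookup(self, kmer: bytes) -> list[tuple[int, int]]:
        hits = self._index.get(kmer)
        return hits if hits else []


def _seed_offsets(read_len: int, k: int) -> list[int]:
    if read_len < k:
        return []
    offs = {0, read_len - k, (read_len - k) // 2}
    if read_len >= 4 * k:
        offs.add((read_len - k) // 4)
        offs.add(3 * (read_len - k) // 4)
    return sorted(offs)


def map_reads(
    reads,
    reference: ReferenceSet | dict[str, str],
    min_identity: float = 0.98,
    seed_k: int | None = None,
    index: ReferenceIndex | None = None,
    store_seq: bool = False,
) -> list[AlignmentRecord]:
    """Place every read in ``reads`` (a ReadSet or parallel id/seq lists)
    on the reference; emit only unique-best placements with identity at or
    above ``min_identity``.

    Seed length defaults to 17 for long reads and 13 for short reads.
    """
    sequences = reference.sequences if isinstance(reference, ReferenceSet) else reference
    if not sequences:
        raise ValueError("reference is empty")
    ids, seqs = reads.ids, reads.seqs
    if seed_k is None:
        mean_len = reads.mean_length if seqs else 0
        seed_k = 13 if mean_len and mean_len < 100 else 17
    if index is None or index.k != seed_k:
        index = ReferenceIndex(sequences, seed_k)
    out: list[AlignmentRecord] = []
    k = seed_k
    for rid, seq in zip(ids, seqs):
        L = len(seq)
        if L < k:
            continue  # counted unmapped
        best: tuple[float, tuple] | None = None
        tie = False
        seen: set[tuple] = set()
        for oriented, strand in ((seq, "+"), (revcomp(seq), "-")):
            data = oriented.encode("ascii")
            rarr = np.frombuffer(data, dtype=np.uint8)
            for off in _seed_offsets(L, k):
                for si, pos in index.lookup(data[off : off + k]):
                    start = pos - off
                    key = (si, start, strand)
                    if key in seen:
                        continue
                    seen.add(key)
                    if start < 0 or start + L > index.lengths[si]:
                        continue
                    ref_slice = index.arrs[si][start : start + L]
                    mm = int(np.count_nonzero(ref_slice != rarr))
                    ident = (L - mm) / L
                    if ident < min_identity:
                        continue
                    if best is None or ident > best[0]:
                        best = (ident, (si, start, strand, rarr, ref_slice))
                        tie = False
                    elif ident == best[0] and key != best[1][:3]:
                        tie = True
        if best is None or tie:
            continue
        ident, (si, start, strand, rarr, ref_slice) = best
        mm_off = np.flatnonzero(ref_slice != rarr)
        out.append(
            AlignmentRecord(
                read_id=rid,
                seq_name=index.names[si],
                start=start,
                end=start + L,
                strand=strand,
                identity=ident,
                mismatch_offsets=mm_off,
                mismatch_bases=rarr[mm_off].tobytes(),
                read_seq=rarr.tobytes().decode("ascii") if store_seq else "",
            )
        )
    return out


def mapping_stats(
    alignments: Sequence[AlignmentRecord],
    reads,
    reference_label: str,
) -> MappingStats:
    """RM = uniquely mapped reads; RMp = round(100*RM/SR) as an integer."""
    sr = reads.count if hasattr(reads, "count") else len(reads)
    if sr == 0:
        raise ValueError("no sequenced reads (SR = 0)")
    rm = sum(1 for a in alignments if a.unique)
    return MappingStats(reference_label=reference_label, sr=sr, rm=rm)


def rmpi(stats_prev: MappingStats, stats_new: MappingStats) -> float:
    """Percent increase in reads mapped over the previous reference set,
    to one decimal; negative when the new reference maps fewer reads."""
    if stats_prev.rm == 0:
        raise ValueError("RMpi undefined: previous RM is zero")
    return round_half_away(
        100.0 * (stats_new.rm - stats_prev.rm) / stats_prev.rm, 1
    )
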