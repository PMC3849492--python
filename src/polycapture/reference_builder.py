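"""Orthologous-region discovery and reference-set assembly.

For each capture-design sequence, its orthologue in the complementary
subgenome is found by unique-k-mer-seeded maximal exact matching (MUM-style
anchors), repetitive-anchor filtering, and collinear chaining.  Three
mapping reference sets are then assembled: the capture design sequences
alone, the design plus extracted orthologous subsequences, and the full
pseudomolecules.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np

from ._util import revcomp, seq_to_arr
from .intervals import Interval, merge_intervals, total_length


@dataclass
class AnchorMatch:
    """A maximal exact match seeded at a k-mer unique in both query and
    subject.  Subject coordinates are always on the subject's forward
    strand; ``strand`` records the orientation of the match."""

    query_name: str
    query_pos: int
    subject_name: str
    subject_pos: int
    length: int
    strand: str

    @property
    def query_interval(self) -> Interval:
        return (self.query_pos, self.query_pos + self.length)

    @property
    def subject_interval(self) -> Interval:
        return (self.subject_pos, self.subject_pos + self.length)


@dataclass
class OrthologousRegion:
    capture_seq_name: str
    subject_name: str
    subject_interval: Interval
    anchor_count: int
    anchor_coverage: float
    strand: str = "+"
    is_primary: bool = False


@dataclass
class ReferenceSet:
    label: Literal["capture_design", "capture_with_orthologues", "pseudomolecules"]
    sequences: dict[str, str]


def _kmer_positions(seq: str, k: int) -> dict[bytes, list[int]]:
    data = seq.encode("ascii")
    out: dict[bytes, list[int]] = {}
    for i in range(len(data) - k + 1):
        out.setdefault(data[i : i + k], []).append(i)
    return out


def find_unique_anchors(
    query: str,
    subject: str,
    k: int = 15,
    query_name: str = "query",
    subject_name: str = "subject",
) -> list[AnchorMatch]:
    """Maximal exact matches seeded at k-mers occurring exactly once in the
    query and exactly once in the subject (either strand) — the MUM
    semantics of whole-genome anchoring, at desk scale."""
    if k < 11:
        raise ValueError("k must be >= 11")
    if not query or not subject:
        return []
    qpos = _kmer_positions(query, k)
    # subject uniqueness counts hits on both strands together
    spos_fwd = _kmer_positions(subject, k)
    subject_rc = revcomp(subject)
    spos_rev = _kmer_positions(subject_rc, k)

    qarr = seq_to_arr(query)
    sarr_by_strand = {"+": seq_to_arr(subject), "-": seq_to_arr(subject_rc)}
    slen = len(subject)

    anchors: dict[tuple, AnchorMatch] = {}
    for kmer, qhits in qpos.items():
        if len(qhits) != 1:
            continue
        fwd = spos_fwd.get(kmer, [])
        rev = spos_rev.get(kmer, [])
        if len(fwd) + len(rev) != 1:
            continue
        qp = qhits[0]
        strand = "+" if fwd else "-"
        sp = (fwd or rev)[0]
        sarr = sarr_by_strand[strand]
        # maximal extension on the working (strand-adjusted) coordinates
        left = 0
        while qp - left - 1 >= 0 and sp - left - 1 >= 0 and qarr[qp - left - 1] == sarr[sp - left - 1]:
            left += 1
        right = k
        while (
            qp + right < qarr.size
            and sp + right < sarr.size
            and qarr[qp + right] == sarr[sp + right]
        ):
            right += 1
        q0 = qp - left
        s0 = sp - left
        length = left + right
        if strand == "-":
            # map back to subject forward-strand coordinates
            s0_fwd = slen - (s0 + length)
        else:
            s0_fwd = s0
        key = (q0, s0_fwd, length, strand)
        if key not in anchors:
            anchors[key] = AnchorMatch(
                query_name, q0, subject_name, s0_fwd, length, strand
            )
    return sorted(anchors.values(), key=lambda a: (a.query_pos, a.subject_pos))


def filter_repetitive(
    anchors: list[AnchorMatch], max_subject_hits_per_query_window: int = 2
) -> list[AnchorMatch]:
    """Drop anchors whose query span is placed at more than the allowed
    number of distinct subject loci (a desk-scale stand-in for repetitive-
    hit cleanup).  Distinct loci are subject intervals separated by >1 kb
    after merging the overlapping-query anchors' subject spans."""
    if not anchors:
        return []
    kept: list[AnchorMatch] = []
    for a in anchors:
        qa, qb = a.query_interval
        overlapping = [
            o
            for o in anchors
            if not (o.query_interval[1] <= qa or o.query_interval[0] >= qb)
        ]
        n_loci = 0
        for sname in {o.subject_name for o in overlapping}:
            loci: list[Interval] = []
            for o in sorted(
                (o for o in overlapping if o.subject_name == sname),
                key=lambda x: x.subject_pos,
            ):
                sa, sb = o.subject_interval
                if loci and sa <= loci[-1][1] + 1000:
                    loci[-1] = (loci[-1][0], max(loci[-1][1], sb))
                else:
                    loci.append((sa, sb))
            n_loci += len(loci)
        if n_loci <= max_subject_hits_per_query_window:
            kept.append(a)
    return kept


def chain_anchors(
    anchors: list[AnchorMatch],
    max_gap: int = 5000,
    query_length: int | None = None,
    min_coverage: float = 0.0,
    max_diag_drift: int = 100,
) -> list[OrthologousRegion]:
    """Group strand-consistent collinear anchors with inter-anchor gaps of
    at most ``max_gap`` (on both query and subject) into candidate
    orthologous regions.  Collinearity also bounds the drift between the
    query gap and subject gap (``max_diag_drift``): without indels,
    neighbouring anchors of a real orthologue sit on one alignment
    diagonal, so a chance k-mer match off-diagonal must not extend the
    region.  The region with the greatest anchor coverage is flagged
    primary; secondary regions are retained."""
    if not anchors:
        return []
    regions: list[OrthologousRegion] = []
    by_key: dict[tuple, list[AnchorMatch]] = {}
    for a in anchors:
        by_key.setdefault((a.subject_name, a.strand), []).append(a)
    qname = anchors[0].query_name
    for (sname, strand), group in by_key.items():
        # bucket by alignment diagonal: real orthologue anchors share one
        # diagonal (anti-diagonal on '-'), chance matches land elsewhere
        def diag(a: AnchorMatch) -> int:
            if strand == "+":
                return a.subject_pos - a.query_pos
            return a.subject_pos + a.query_pos
        group = sorted(group, key=lambda a: (diag(a), a.query_pos))
        chains: list[list[AnchorMatch]] = []
        cur = [group[0]]
        for a in group[1:]:
            prev = cur[-1]
            qgap = a.query_pos - (prev.query_pos + prev.length)
            if abs(diag(a) - diag(prev)) <= max_diag_drift and qgap <= max_gap:
                cur.append(a)
            else:
                chains.append(cur)
                cur = [a]
        chains.append(cur)
        for chain in chains:
            s0 = min(a.subject_pos for a in chain)
            s1 = max(a.subject_pos + a.length for a in chain)
            covered = total_length(merge_intervals(a.query_interval for a in chain))
            denom = query_length if query_length else max(
                covered,
                max(a.query_pos + a.length for a in chain)
                - min(a.query_pos for a in chain),
            )
            regions.append(
                OrthologousRegion(
                    capture_seq_name=qname,
                    subject_name=sname,
                    subject_interval=(s0, s1),
                    anchor_count=len(chain),
                    anchor_coverage=covered / denom if denom else 0.0,
                    strand=strand,
                )
            )
    regions = [r for r in regions if r.anchor_coverage >= min_coverage]
    if regions:
        best = max(regions, key=lambda r: r.anchor_coverage)
        best.is_primary = True
    return sorted(regions, key=lambda r: -r.anchor_coverage)


def find_orthologous_regions(
    capture_sequences: dict[str, str],
    pseudomolecules: dict[str, str],
    complement_of: dict[str, list[str]],
    k: int = 15,
    max_gap: int = 5000,
    min_coverage: float = 0.2,
) -> list[OrthologousRegion]:
    """Run anchor/filter/chain for every capture sequence against the
    pseudomolecules of its complementary subgenome.  ``complement_of`` maps
    each capture sequence name to candidate subject pseudomolecule names."""
    out: list[OrthologousRegion] = []
    for qname, qseq in capture_sequences.items():
        candidates: list[OrthologousRegion] = []
        for sname in complement_of.get(qname, []):
            anchors = find_unique_anchors(
                qseq, pseudomolecules[sname], k, query_name=qname, subject_name=sname
            )
            anchors = filter_repetitive(anchors)
            for r in chain_anchors(
                anchors, max_gap, query_length=len(qseq), min_coverage=min_coverage
            ):
                r.is_primary = False
                candidates.append(r)
        if candidates:
            best = max(candidates, key=lambda r: r.anchor_coverage)
            best.is_primary = True
        out.extend(candidates)
    return out


def build_reference_sets(
    capture_sequences: dict[str, str],
    pseudomolecules: dict[str, str],
    orthologous_regions: list[OrthologousRegion],
) -> tuple[ReferenceSet, ReferenceSet, ReferenceSet]:
    """Assemble the three mapping reference sets: design sequences alone,
    design plus extracted primary orthologues, and the pseudomolecules."""
    set1 = ReferenceSet("capture_design", dict(capture_sequences))
    set2_seqs = dict(capture_sequences)
    for r in orthologous_regions:
        if not r.is_primary:
            continue
        a, b = r.subject_interval
        subject = pseudomolecules.get(r.subject_name)
        if subject is None:
            raise ValueError(f"unknown subject sequence {r.subject_name}")
        if a < 0 or b > len(subject) or b <= a:
            raise ValueError(
                f"orthologous region {a}-{b} outside subject {r.subject_name}"
            )
        name = f"{r.capture_seq_name}|orth|{r.subject_name}:{a}-{b}"
        set2_seqs[name] = subject[a:b]
    set2 = ReferenceSet("capture_with_orthologues", set2_seqs)
    set3 = ReferenceSet("pseudomolecules", dict(pseudomolecules))
    return set1, set2, set3


def extract_capture_sequences(bundle) -> dict[str, str]:
    """Cut the capture-design sequences (target subsequences) out of a
    synthetic genome bundle; names carry provenance coordinates."""
    out: dict[str, str] = {}
    for t in bundle.targets:
        name = f"cap|{t.seq_name}:{t.start}-{t.end}"
        out[name] = bundle.sequences[t.seq_name][t.start:t.end]
    return out
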