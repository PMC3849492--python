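"""Pileup construction and binomial maximum-posterior genotype calling.

The caller scores {hom_ref, het, hom_alt} on the ref/alt read counts of a
pileup column under a binomial read-sampling model with a symmetric base
error rate and a uniform genotype prior, after a per-chemistry minimum
depth gate (3 reads for long/454-style data, 8 for short/Illumina-style).
Columns whose called homozygote carries a conflicting-read fraction of at
least ``bias_fraction``, or whose called het has an allele balance outside
the accepted band, are flagged biased; flagged calls are never dropped here
— that is the filter stage's decision.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from ._util import DNA, seq_to_arr
from .read_mapper import AlignmentRecord

DEFAULT_MIN_DEPTH = {"long": 3, "short": 8}


@dataclass
class PileupColumn:
    seq_name: str
    position: int
    ref_base: str
    counts: dict[str, int]

    @property
    def depth(self) -> int:
        return sum(self.counts.values())

    def top_alt(self) -> tuple[str | None, int]:
        """Most-observed non-reference base and its count."""
        best, best_n = None, 0
        for b in DNA:
            if b == self.ref_base:
                continue
            n = self.counts.get(b, 0)
            if n > best_n:
                best, best_n = b, n
        return best, best_n


@dataclass
class GenotypeCall:
    line_id: str
    genotype: str  # hom_ref | hom_alt | het | no_call
    alt_allele: str | None
    depth: int
    alt_fraction: float
    biased: bool = False


@dataclass
class RawSnp:
    """A candidate variant position with the per-line call vector — the
    unit that flows through the filtering funnel."""

    seq_name: str
    position: int
    ref_allele: str
    alt_alleles: set[str]
    calls: dict[str, GenotypeCall]

    @property
    def called(self) -> list[GenotypeCall]:
        return [c for c in self.calls.values() if c.genotype != "no_call"]


class PileupMatrix:
    """Per-sequence 4xL base-count matrices for one line's alignments.
    Built with a coverage running-sum plus sparse mismatch corrections."""

    def __init__(self, seq_name: str, ref_arr: np.ndarray):
        self.seq_name = seq_name
        self.ref_arr = ref_arr
        L = ref_arr.size
        self.counts = np.zeros((4, L), dtype=np.int32)
        self._cov_diff = np.zeros(L + 1, dtype=np.int32)
        self._mm_pos: list[np.ndarray] = []
        self._mm_base: list[np.ndarray] = []

    def add(self, aln: AlignmentRecord) -> None:
        if aln.end > self.ref_arr.size:
            raise ValueError("alignment beyond reference bounds")
        self._cov_diff[aln.start] += 1
        self._cov_diff[aln.end] -= 1
        if aln.mismatch_offsets.size:
            self._mm_pos.append(aln.mismatch_offsets + aln.start)
            self._mm_base.append(np.frombuffer(aln.mismatch_bases, dtype=np.uint8))

    def finalize(self) -> None:
        L = self.ref_arr.size
        cov = np.cumsum(self._cov_diff[:-1])
        mm_total = np.zeros(L, dtype=np.int32)
        if self._mm_pos:
            pos = np.concatenate(self._mm_pos)
            base = np.concatenate(self._mm_base)
            np.add.at(mm_total, pos, 1)
            for bi, b in enumerate(DNA):
                sel = pos[base == ord(b)]
                if sel.size:
                    np.add.at(self.counts[bi], sel, 1)
        ref_idx = np.searchsorted(seq_to_arr(DNA), self.ref_arr)
        np.add.at(
            self.counts, (ref_idx, np.arange(L)), (cov - mm_total).astype(np.int32)
        )
        self._mm_pos, self._mm_base = [], []

    def column(self, pos: int) -> PileupColumn:
        return PileupColumn(
            seq_name=self.seq_name,
            position=pos,
            ref_base=chr(self.ref_arr[pos]),
            counts={b: int(self.counts[i, pos]) for i, b in enumerate(DNA)},
        )

    @property
    def depth(self) -> np.ndarray:
        return self.counts.sum(axis=0)


def build_pileups(
    alignments: Sequence[AlignmentRecord], reference: dict[str, str]
) -> dict[str, PileupMatrix]:
    mats = {
        name: PileupMatrix(name, seq_to_arr(seq)) for name, seq in reference.items()
    }
    for aln in alignments:
        mats[aln.seq_name].add(aln)
    for m in mats.values():
        m.finalize()
    return mats


def pileup(
    alignments: Sequence[AlignmentRecord], reference: dict[str, str]
) -> Iterable[PileupColumn]:
    """Stream one column per covered reference position (depth >= 1)."""
    mats = build_pileups(alignments, reference)
    for name in sorted(mats):
        m = mats[name]
        for pos in np.flatnonzero(m.depth > 0):
            yield m.column(int(pos))


def _genotype_logliks(n_ref: int, n_alt: int, error_rate: float):
    """Log-likelihoods (hom_ref, het, hom_alt) for the ref/alt counts under
    the binomial error model; the shared binomial coefficient is omitted."""
    e = error_rate
    n = n_ref + n_alt
    k = n_alt
    ll_ref = k * math.log(e) + (n - k) * math.log(1 - e)
    ll_het = n * math.log(0.5)
    ll_alt = k * math.log(1 - e) + (n - k) * math.log(e)
    return ll_ref, ll_het, ll_alt


def call_genotype(
    column: PileupColumn,
    line_id: str = "",
    min_depth: int = 3,
    error_rate: float = 0.005,
    bias_fraction: float = 0.10,
    het_band: tuple[float, float] = (0.2, 0.8),
) -> GenotypeCall:
    """Maximum-posterior genotype for one line at one column.

    Ties between genotypes break toward hom_ref, then het (conservative:
    never invents an alt homozygote on even evidence).
    """
    if not (0 < error_rate < 0.5):
        raise ValueError("error_rate must be in (0, 0.5)")
    depth = column.depth
    if depth < min_depth:
        return GenotypeCall(line_id, "no_call", None, depth, 0.0)
    alt, n_alt = column.top_alt()
    n_ref = column.counts.get(column.ref_base, 0)
    if alt is None or n_alt == 0:
        # conflicting evidence can still exist as third-base noise
        conflict = (depth - n_ref) / depth if depth else 0.0
        return GenotypeCall(
            line_id, "hom_ref", None, depth, 0.0, biased=conflict >= bias_fraction
        )
    lls = _genotype_logliks(n_ref, n_alt, error_rate)
    gt = ("hom_ref", "het", "hom_alt")[int(np.argmax(lls))]
    pair = n_ref + n_alt
    alt_fraction = n_alt / pair if pair else 0.0
    if gt == "hom_ref":
        conflict = (depth - n_ref) / depth
        biased = conflict >= bias_fraction
        alt_out = None
    elif gt == "hom_alt":
        conflict = (depth - n_alt) / depth
        biased = conflict >= bias_fraction
        alt_out = alt
    else:
        biased = not (het_band[0] <= alt_fraction <= het_band[1])
        alt_out = alt
    return GenotypeCall(line_id, gt, alt_out, depth, alt_fraction, biased)


def collect_snps(
    calls_by_line: dict[str, dict[tuple[str, int], GenotypeCall]],
    reference: dict[str, str],
) -> list[RawSnp]:
    """Merge per-line calls into one RawSnp per position where at least one
    line carries a non-reference call; lines without coverage at a position
    are padded with no_call."""
    line_ids = sorted(calls_by_line)
    positions: set[tuple[str, int]] = set()
    for calls in calls_by_line.values():
        for key, call in calls.items():
            if call.genotype in ("hom_alt", "het"):
                positions.add(key)
    out: list[RawSnp] = []
    for seq_name, pos in sorted(positions):
        ref = reference[seq_name][pos]
        vector: dict[str, GenotypeCall] = {}
        alts: set[str] = set()
        for lid in line_ids:
            call = calls_by_line[lid].get(
                (seq_name, pos), GenotypeCall(lid, "no_call", None, 0, 0.0)
            )
            vector[lid] = call
            if call.genotype in ("hom_alt", "het") and call.alt_allele:
                alts.add(call.alt_allele)
        if alts:
            out.append(RawSnp(seq_name, pos, ref, alts, vector))
    return out


def discover_snps(
    alignments_by_line: dict[str, Sequence[AlignmentRecord]],
    reference: dict[str, str],
    min_depth: int = 3,
    error_rate: float = 0.005,
    bias_fraction: float = 0.10,
    het_band: tuple[float, float] = (0.2, 0.8),
) -> list[RawSnp]:
    """Fast path over all lines: pileup matrices per line, candidate
    positions where any line shows non-reference evidence, then the same
    per-column caller as :func:`call_genotype` (equivalence is tested)."""
    mats = {
        lid: build_pileups(alignments, reference)
        for lid, alignments in alignments_by_line.items()
    }
    return discover_snps_from_pileups(
        mats, reference, min_depth, error_rate, bias_fraction, het_band
    )


def discover_snps_from_pileups(
    mats: dict[str, dict[str, PileupMatrix]],
    reference: dict[str, str],
    min_depth: int = 3,
    error_rate: float = 0.005,
    bias_fraction: float = 0.10,
    het_band: tuple[float, float] = (0.2, 0.8),
) -> list[RawSnp]:
    if not (0 < error_rate < 0.5):
        raise ValueError("error_rate must be in (0, 0.5)")
    line_ids = sorted(mats)
    out: list[RawSnp] = []
    ref_arrs = {name: seq_to_arr(seq) for name, seq in reference.items()}
    for seq_name in sorted(reference):
        L = ref_arrs[seq_name].size
        ref_idx = np.searchsorted(seq_to_arr(DNA), ref_arrs[seq_name])
        cand = np.zeros(L, dtype=bool)
        arange = np.arange(L)
        log_e, log_1me, log_half = (
            math.log(error_rate),
            math.log(1 - error_rate),
            math.log(0.5),
        )
        for lid in line_ids:
            counts = mats[lid][seq_name].counts
            depth = counts.sum(axis=0)
            n_ref = counts[ref_idx, arange]
            tmp = counts.copy()
            tmp[ref_idx, arange] = -1
            k = tmp.max(axis=0)  # top non-ref count
            k = np.maximum(k, 0)
            n = n_ref + k
            # decision boundary of the scalar caller, vectorized: a position
            # can only yield a non-ref call if het or hom_alt strictly beats
            # hom_ref on the pair counts (ties resolve to hom_ref)
            ll_ref = k * log_e + (n - k) * log_1me
            ll_het = n * log_half
            ll_alt = k * log_1me + (n - k) * log_e
            cand |= (depth >= min_depth) & (k >= 1) & (
                (ll_het > ll_ref) | (ll_alt > ll_ref)
            )
        for pos in np.flatnonzero(cand):
            pos = int(pos)
            vector: dict[str, GenotypeCall] = {}
            alts: set[str] = set()
            any_nonref = False
            for lid in line_ids:
                col = mats[lid][seq_name].column(pos)
                call = call_genotype(
                    col, lid, min_depth, error_rate, bias_fraction, het_band
                )
                vector[lid] = call
                if call.genotype in ("hom_alt", "het"):
                    any_nonref = True
                    if call.alt_allele:
                        alts.add(call.alt_allele)
            if any_nonref and alts:
                out.append(
                    RawSnp(seq_name, pos, chr(ref_arrs[seq_name][pos]), alts, vector)
                )
    return out
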