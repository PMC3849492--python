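"""SNP annotation (genic context, substitution spectrum), capture-coverage
enrichment and SNP density summaries."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from ._util import is_transition, round_half_away
from .intervals import (
    GeneAnnotationIndex,
    Interval,
    complement_intervals,
    merge_intervals,
    total_length,
)
from .read_mapper import AlignmentRecord
from .variant_caller import RawSnp

REGIONS = ("CDS", "intron", "intergenic")

# the twelve ordered ref->alt substitution types: four transitions and
# eight transversions, as spectra are conventionally reported
SUBSTITUTION_LABELS = tuple(
    f"{r}/{a}" for r in "ACGT" for a in "ACGT" if r != a
)


def annotate_location(
    seq_name: str, position: int, index: GeneAnnotationIndex
) -> str:
    """CDS if inside any CDS span, intron if inside a gene but no CDS,
    intergenic otherwise; CDS wins across overlapping gene models."""
    return index.classify(seq_name, position)


def classify_substitution(ref_base: str, alt_base: str) -> tuple[str, str]:
    """(transition|transversion, ordered type label e.g. ``A/G``)."""
    ref_base, alt_base = ref_base.upper(), alt_base.upper()
    if ref_base not in "ACGT" or alt_base not in "ACGT":
        raise ValueError(f"ambiguity codes unsupported: {ref_base}/{alt_base}")
    if ref_base == alt_base:
        raise ValueError("ref and alt must differ")
    cls = "transition" if is_transition(ref_base, alt_base) else "transversion"
    return cls, f"{ref_base}/{alt_base}"


@dataclass
class AnnotatedSnp:
    seq_name: str
    position: int
    ref_allele: str
    alt_allele: str
    region: str
    substitution: str
    type_label: str


def annotate_snps(
    snps: Iterable[RawSnp], index: GeneAnnotationIndex
) -> list[AnnotatedSnp]:
    out = []
    for s in snps:
        alt = sorted(s.alt_alleles)[0]
        cls, label = classify_substitution(s.ref_allele, alt)
        out.append(
            AnnotatedSnp(
                seq_name=s.seq_name,
                position=s.position,
                ref_allele=s.ref_allele,
                alt_allele=alt,
                region=annotate_location(s.seq_name, s.position, index),
                substitution=cls,
                type_label=label,
            )
        )
    return out


@dataclass
class TsTvSummary:
    """Transition/transversion counts and ratios, overall and per region;
    genic = CDS + intron.  Ratios print to 2 decimals, shares to 1."""

    ts: dict[str, int]
    tv: dict[str, int]

    REGION_KEYS = ("CDS", "intron", "intergenic", "genic", "overall")

    @classmethod
    def from_counts(cls, ts_by_region: dict[str, int], tv_by_region: dict[str, int]):
        ts = dict(ts_by_region)
        tv = dict(tv_by_region)
        for d in (ts, tv):
            for r in REGIONS:
                d.setdefault(r, 0)
            d["genic"] = d["CDS"] + d["intron"]
            d["overall"] = d["genic"] + d["intergenic"]
        return cls(ts=ts, tv=tv)

    @classmethod
    def from_annotated(cls, snps: Sequence[AnnotatedSnp]) -> "TsTvSummary":
        ts = {r: 0 for r in REGIONS}
        tv = {r: 0 for r in REGIONS}
        for s in snps:
            (ts if s.substitution == "transition" else tv)[s.region] += 1
        return cls.from_counts(ts, tv)

    def total(self, region: str = "overall") -> int:
        return self.ts[region] + self.tv[region]

    def ratio(self, region: str = "overall") -> float | None:
        """ts/tv to 2 decimals; None (undefined) when tv is zero."""
        if self.tv[region] == 0:
            return None
        return round_half_away(self.ts[region] / self.tv[region], 2)

    def ts_share_percent(self, region: str = "overall") -> float:
        tot = self.total(region)
        return round_half_away(100.0 * self.ts[region] / tot, 1) if tot else 0.0

    def region_share_percent(self, region: str, of: str = "overall") -> float:
        denom = self.total(of)
        return (
            round_half_away(100.0 * self.total(region) / denom, 1) if denom else 0.0
        )


@dataclass
class CoverageSummary:
    target_mean_depth: float
    nontarget_mean_depth: float
    snps_in_target: int = 0
    snps_total: int = 0

    @property
    def fold_enrichment(self) -> float:
        if self.nontarget_mean_depth == 0:
            return float("inf")
        return self.target_mean_depth / self.nontarget_mean_depth

    @property
    def snp_in_target_fraction(self) -> float:
        if self.snps_total == 0:
            return 0.0
        return self.snps_in_target / self.snps_total

    @property
    def snp_in_target_percent(self) -> float:
        return round_half_away(100.0 * self.snp_in_target_fraction, 1)


def depth_arrays(
    alignments: Sequence[AlignmentRecord], seq_lengths: dict[str, int]
) -> dict[str, np.ndarray]:
    """Per-base depth from gapless alignments (running-sum construction)."""
    diffs = {
        name: np.zeros(L + 1, dtype=np.int64) for name, L in seq_lengths.items()
    }
    for a in alignments:
        d = diffs[a.seq_name]
        d[a.start] += 1
        d[min(a.end, d.size - 1)] -= 1
    return {name: np.cumsum(d[:-1]) for name, d in diffs.items()}


def coverage_summary(
    alignments: Sequence[AlignmentRecord],
    targets_by_seq: dict[str, list[Interval]],
    seq_lengths: dict[str, int],
    filtered_snps: Sequence[RawSnp] | None = None,
) -> CoverageSummary:
    """Mean per-base depth inside and outside the (merged) target region,
    and the fraction of filtered SNPs falling in target."""
    return coverage_summary_from_depths(
        depth_arrays(alignments, seq_lengths),
        targets_by_seq,
        seq_lengths,
        filtered_snps,
    )


def coverage_summary_from_depths(
    depths: dict[str, np.ndarray],
    targets_by_seq: dict[str, list[Interval]],
    seq_lengths: dict[str, int],
    filtered_snps: Sequence[RawSnp] | None = None,
) -> CoverageSummary:
    if not any(targets_by_seq.values()):
        raise ValueError("empty target set")
    t_bases = t_len = n_bases = n_len = 0
    for name, L in seq_lengths.items():
        tivs = merge_intervals(targets_by_seq.get(name, []))
        d = depths[name]
        for a, b in tivs:
            t_bases += int(d[a:b].sum())
            t_len += b - a
        for a, b in complement_intervals(tivs, L):
            n_bases += int(d[a:b].sum())
            n_len += b - a
    summary = CoverageSummary(
        target_mean_depth=t_bases / t_len if t_len else 0.0,
        nontarget_mean_depth=n_bases / n_len if n_len else 0.0,
    )
    if filtered_snps is not None:
        summary.snps_total = len(filtered_snps)
        for s in filtered_snps:
            tivs = targets_by_seq.get(s.seq_name, [])
            if any(a <= s.position < b for a, b in tivs):
                summary.snps_in_target += 1
    return summary


def snp_density(
    snp_positions: Sequence[tuple[str, int]] | Sequence[RawSnp],
    regions_by_seq: dict[str, list[Interval]],
) -> float:
    """bp per SNP inside the region set, to one decimal; infinite spacing
    when no SNP falls in the region."""
    region_bp = sum(total_length(merge_intervals(v)) for v in regions_by_seq.values())
    if region_bp <= 0:
        raise ValueError("region length must be positive")
    n = 0
    for item in snp_positions:
        if isinstance(item, RawSnp):
            name, pos = item.seq_name, item.position
        else:
            name, pos = item
        if any(a <= pos < b for a, b in regions_by_seq.get(name, [])):
            n += 1
    if n == 0:
        return float("inf")
    return round_half_away(region_bp / n, 1)


def snp_density_per_line(
    snps: Sequence[RawSnp],
    regions_by_seq: dict[str, list[Interval]],
    line_ids: Sequence[str],
) -> float:
    """Average over lines of bp-per-SNP, counting for each line the SNPs
    where that line carries a non-reference call; lines with no such SNP
    in the region are skipped."""
    densities = []
    for lid in line_ids:
        positions = [
            (s.seq_name, s.position)
            for s in snps
            if s.calls.get(lid) is not None
            and s.calls[lid].genotype in ("hom_alt", "het")
        ]
        d = snp_density(positions, regions_by_seq)
        if np.isfinite(d):
            densities.append(d)
    return round_half_away(float(np.mean(densities)), 1) if densities else float("inf")
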