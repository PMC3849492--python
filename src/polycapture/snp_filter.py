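"""The three-stage SNP filtering funnel and assay-design suitability.

Stage order follows the discovery pipeline: (i) drop positions with more
than one observed alternate allele across the line panel, (ii) drop
positions supported only by heterozygous/biased calls or with a
heterozygous-call proportion strictly over the threshold, (iii) drop
positions whose flanking sequence suits neither KASP nor Infinium assay
design.  KASP needs 100 bp of sequence on both sides of the SNP; Infinium
needs, on at least one side, 60 bp of sequence containing no other kept
SNP.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .variant_caller import RawSnp

ASSAY_CLASSES = ("kaspar_only", "infinium_only", "both", "neither")


@dataclass
class FilterConfig:
    het_threshold: float = 0.2
    kaspar_flank: int = 100
    infinium_flank: int = 60
    # whether the Infinium SNP-free window consults the post-het/bias kept
    # set (assay design would see the surviving SNPs) or the raw set
    infinium_window_uses_kept: bool = True

    def validate(self) -> None:
        if not (0 < self.het_threshold < 1):
            raise ValueError("het_threshold must be in (0, 1)")
        if self.kaspar_flank <= 0 or self.infinium_flank <= 0:
            raise ValueError("flank lengths must be positive")


@dataclass
class FunnelStage:
    criterion: str
    excluded: int
    remaining: int


@dataclass
class FunnelReport:
    """Ordered stage-by-stage exclusion bookkeeping; ``remaining[i]`` must
    equal ``remaining[i-1] - excluded[i]``."""

    total: int
    stages: list[FunnelStage] = field(default_factory=list)

    def __post_init__(self) -> None:
        prev = self.total
        for st in self.stages:
            if st.remaining != prev - st.excluded:
                raise ValueError(
                    f"funnel inconsistency at {st.criterion!r}: "
                    f"{prev} - {st.excluded} != {st.remaining}"
                )
            prev = st.remaining

    @classmethod
    def from_exclusions(
        cls, total: int, labels: Sequence[str], exclusions: Sequence[int]
    ) -> "FunnelReport":
        stages = []
        remaining = total
        for label, exc in zip(labels, exclusions):
            remaining -= exc
            stages.append(FunnelStage(label, exc, remaining))
        return cls(total=total, stages=stages)

    @property
    def final_count(self) -> int:
        return self.stages[-1].remaining if self.stages else self.total

    def to_dataframe(self):
        import pandas as pd

        rows = [{"criterion": "None", "excluded": 0, "remaining": self.total}]
        rows += [
            {"criterion": s.criterion, "excluded": s.excluded, "remaining": s.remaining}
            for s in self.stages
        ]
        return pd.DataFrame(rows)


def filter_multiallelic(snps: Sequence[RawSnp]) -> tuple[list[RawSnp], list[RawSnp]]:
    """Criterion i: remove SNPs with multiple variations within the panel
    (observed alternate-allele set larger than one)."""
    kept, excluded = [], []
    for s in snps:
        (kept if len(s.alt_alleles) == 1 else excluded).append(s)
    return kept, excluded


def het_proportion(snp: RawSnp) -> float | None:
    """Het calls over lines with calls; None when no line was called."""
    called = snp.called
    if not called:
        return None
    n_het = sum(1 for c in called if c.genotype == "het")
    return n_het / len(called)


def filter_het_bias(
    snps: Sequence[RawSnp], het_threshold: float = 0.2
) -> tuple[list[RawSnp], list[RawSnp]]:
    """Criterion ii: remove SNPs supported only by heterozygous or biased
    variant calls — i.e. no line carries a clean homozygous-alt call (the
    signature of homoeolog co-assembly or stray errors rather than a real
    allelic difference between inbred lines) — and SNPs whose het
    proportion over called lines is strictly over the threshold; exactly
    0.2 is kept."""
    kept, excluded = [], []
    for s in snps:
        called = s.called
        if not called:
            excluded.append(s)  # zero called lines: no usable evidence
            continue
        variant_calls = [c for c in called if c.genotype in ("het", "hom_alt")]
        no_clean_hom_alt = all(
            c.genotype == "het" or c.biased for c in variant_calls
        )
        prop = sum(1 for c in called if c.genotype == "het") / len(called)
        if no_clean_hom_alt or prop > het_threshold:
            excluded.append(s)
        else:
            kept.append(s)
    return kept, excluded


def classify_assay_suitability(
    snp: RawSnp,
    kept_positions_by_seq: dict[str, np.ndarray],
    sequence_lengths: dict[str, int],
    config: FilterConfig | None = None,
) -> str:
    """KASP suitability needs ``kaspar_flank`` bp of sequence on both sides;
    Infinium needs one side with ``infinium_flank`` bp of sequence free of
    other kept SNPs.  ``kept_positions_by_seq`` holds sorted position
    arrays of the SNP set an assay designer would see."""
    config = config or FilterConfig()
    L = sequence_lengths[snp.seq_name]
    pos = snp.position
    if not (0 <= pos < L):
        raise ValueError(f"position {pos} outside sequence {snp.seq_name}")
    kf, inf = config.kaspar_flank, config.infinium_flank
    kaspar_ok = pos >= kf and (L - 1 - pos) >= kf

    neighbors = kept_positions_by_seq.get(snp.seq_name, np.empty(0, dtype=int))

    def side_free(lo: int, hi: int) -> bool:
        i = np.searchsorted(neighbors, lo, side="left")
        j = np.searchsorted(neighbors, hi, side="right")
        for p in neighbors[i:j]:
            if p != pos:
                return False
        return True

    left_ok = pos >= inf and side_free(pos - inf, pos - 1)
    right_ok = (L - 1 - pos) >= inf and side_free(pos + 1, pos + inf)
    infinium_ok = left_ok or right_ok

    if kaspar_ok and infinium_ok:
        return "both"
    if kaspar_ok:
        return "kaspar_only"
    if infinium_ok:
        return "infinium_only"
    return "neither"


def classify_all(
    snps: Sequence[RawSnp],
    sequence_lengths: dict[str, int],
    config: FilterConfig | None = None,
) -> dict[tuple[str, int], str]:
    """Assay class for every SNP, with the SNP-free window consulting the
    supplied (kept) set itself."""
    by_seq: dict[str, np.ndarray] = {}
    for s in snps:
        by_seq.setdefault(s.seq_name, [])  # type: ignore[arg-type]
    tmp: dict[str, list[int]] = {k: [] for k in by_seq}
    for s in snps:
        tmp[s.seq_name].append(s.position)
    positions = {k: np.array(sorted(v), dtype=int) for k, v in tmp.items()}
    return {
        (s.seq_name, s.position): classify_assay_suitability(
            s, positions, sequence_lengths, config
        )
        for s in snps
    }


def filter_flanking(
    snps: Sequence[RawSnp], classes: dict[tuple[str, int], str]
) -> tuple[list[RawSnp], list[RawSnp]]:
    """Criterion iii: remove SNPs suiting neither assay."""
    kept, excluded = [], []
    for s in snps:
        cls = classes[(s.seq_name, s.position)]
        (excluded if cls == "neither" else kept).append(s)
    return kept, excluded


@dataclass
class FunnelResult:
    report: FunnelReport
    kept: list[RawSnp]
    classes: dict[tuple[str, int], str]


def run_funnel(
    snps: Sequence[RawSnp],
    sequence_lengths: dict[str, int],
    config: FilterConfig | None = None,
) -> FunnelResult:
    """Apply the three filters in pipeline order and report counts."""
    config = config or FilterConfig()
    config.validate()
    total = len(snps)
    k1, e1 = filter_multiallelic(snps)
    k2, e2 = filter_het_bias(k1, config.het_threshold)
    basis = k2 if config.infinium_window_uses_kept else list(snps)
    classes = classify_all(basis, sequence_lengths, config)
    if not config.infinium_window_uses_kept:
        classes = {
            key: cls for key, cls in classes.items()
            if key in {(s.seq_name, s.position) for s in k2}
        }
    k3, e3 = filter_flanking(k2, classes)
    report = FunnelReport.from_exclusions(
        total,
        ["Multiple Variants hits", "Heterozygous and Bias", "Flanking Sequence"],
        [len(e1), len(e2), len(e3)],
    )
    # classes cover every SNP entering the flanking stage, so the four
    # assay classes partition the pre-flanking kept set
    return FunnelResult(report=report, kept=k3, classes=classes)


def assay_partition(
    classes: dict[tuple[str, int], str]
) -> dict[str, int]:
    out = {c: 0 for c in ASSAY_CLASSES}
    for cls in classes.values():
        out[cls] += 1
    return out
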