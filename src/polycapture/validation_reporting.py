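"""Validation-panel summaries and report assembly.

KASP panels are summarized into positive-amplification (PA) and
polymorphic-SNP (PS) percentages, with a corrected PS that excludes
assays showing no amplification (an assay-chemistry failure, not a SNP
failure).  Infinium array records are classified by cluster geometry:
AA cluster theta in [0, 0.2], BB in [0.8, 1] and a heterozygote frequency
of at most 0.15 mark a high-quality marker.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

from ._util import round_half_away
from .read_mapper import MappingStats
from .snp_characterization import CoverageSummary, TsTvSummary
from .snp_filter import FunnelReport

OUTCOMES = ("no_amplification", "monomorphic", "multiple_loci", "polymorphic")


@dataclass
class KasparPanelResult:
    label: str
    n_individuals: int
    tested: int
    outcomes: dict[str, int]
    # dominant presence/absence markers counted inside 'polymorphic'
    dominant_polymorphic: int = 0

    def validate(self) -> None:
        unknown = set(self.outcomes) - set(OUTCOMES)
        if unknown:
            raise ValueError(f"unknown outcomes: {sorted(unknown)}")
        if sum(self.outcomes.values()) != self.tested:
            raise ValueError("outcome counts must sum to tested SNPs")
        if self.dominant_polymorphic > self.outcomes.get("polymorphic", 0):
            raise ValueError("dominant markers are a subset of polymorphic")


@dataclass
class ValidationSummary:
    label: str
    tested: int
    outcomes: dict[str, int]
    pa_percent: int
    ps_percent: int
    ps_corrected_percent: int | None


@dataclass
class InfiniumRecord:
    snp_id: str
    aa_theta: float | None
    bb_theta: float | None
    ab_frequency: float


@dataclass
class InfiniumThresholds:
    aa_theta: tuple[float, float] = (0.0, 0.2)
    bb_theta: tuple[float, float] = (0.8, 1.0)
    ab_max: float = 0.15


def summarize_kaspar(panel: KasparPanelResult) -> ValidationSummary:
    """PA = 100*(tested - no_amplification)/tested; PS = 100*polymorphic/
    tested; corrected PS = 100*polymorphic/(tested - no_amplification).
    All integer-rounded half away from zero."""
    panel.validate()
    if panel.tested == 0:
        raise ValueError("no SNPs tested")
    no_amp = panel.outcomes.get("no_amplification", 0)
    poly = panel.outcomes.get("polymorphic", 0)
    amplified = panel.tested - no_amp
    pa = int(round_half_away(100.0 * amplified / panel.tested))
    ps = int(round_half_away(100.0 * poly / panel.tested))
    corrected = (
        int(round_half_away(100.0 * poly / amplified)) if amplified else None
    )
    return ValidationSummary(
        label=panel.label,
        tested=panel.tested,
        outcomes=dict(panel.outcomes),
        pa_percent=pa,
        ps_percent=ps,
        ps_corrected_percent=corrected,
    )


def classify_infinium(
    record: InfiniumRecord, thresholds: InfiniumThresholds | None = None
) -> str:
    """high_quality on good cluster separation (bounds inclusive), fail
    when no clusters formed (missing theta), other otherwise."""
    t = thresholds or InfiniumThresholds()
    if record.aa_theta is None or record.bb_theta is None:
        return "fail"
    for theta in (record.aa_theta, record.bb_theta):
        if not (0.0 <= theta <= 1.0):
            raise ValueError("theta must lie in [0, 1]")
    if (
        t.aa_theta[0] <= record.aa_theta <= t.aa_theta[1]
        and t.bb_theta[0] <= record.bb_theta <= t.bb_theta[1]
        and record.ab_frequency <= t.ab_max
    ):
        return "high_quality"
    return "other"


@dataclass
class ReportDocument:
    """Assembled end-of-pipeline report; every derived percentage is
    recomputed from the component counts, never copied in."""

    sections: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return self.sections

    def to_text(self) -> str:
        lines = ["polycapture pipeline report", "=" * 28]
        for name, payload in self.sections.items():
            lines.append("")
            lines.append(f"[{name}]")
            if isinstance(payload, dict):
                for k, v in payload.items():
                    lines.append(f"  {k}: {v}")
            else:
                lines.append(f"  {payload}")
        return "\n".join(lines) + "\n"


def assemble_report(
    funnel: FunnelReport | None = None,
    mapping: Sequence[MappingStats] = (),
    tstv: TsTvSummary | None = None,
    coverage: CoverageSummary | None = None,
    validations: Sequence[ValidationSummary] = (),
    assay_counts: dict[str, int] | None = None,
) -> ReportDocument:
    """Build one structured report; totals are cross-checked across
    components and any mismatch raises with the discrepancy named."""
    doc = ReportDocument()
    if funnel is not None:
        doc.sections["snp_filtering_funnel"] = {
            "unfiltered": funnel.total,
            **{
                s.criterion: {"excluded": s.excluded, "remaining": s.remaining}
                for s in funnel.stages
            },
            "candidate_snps": funnel.final_count,
        }
    if mapping:
        doc.sections["read_mapping"] = {
            m.reference_label: {"SR": m.sr, "RM": m.rm, "RMp": m.rmp} for m in mapping
        }
    if tstv is not None:
        if funnel is not None and tstv.total() != funnel.final_count:
            raise ValueError(
                "inconsistent totals: annotated SNPs "
                f"({tstv.total()}) != funnel survivors ({funnel.final_count})"
            )
        doc.sections["substitution_spectrum"] = {
            "transitions": tstv.ts["overall"],
            "transversions": tstv.tv["overall"],
            "ts_share_percent": tstv.ts_share_percent(),
            "tstv_overall": tstv.ratio("overall"),
            "tstv_CDS": tstv.ratio("CDS"),
            "tstv_intron": tstv.ratio("intron"),
            "genic_percent": tstv.region_share_percent("genic"),
            "cds_share_of_genic_percent": (
                round_half_away(100.0 * tstv.total("CDS") / tstv.total("genic"), 1)
                if tstv.total("genic")
                else 0.0
            ),
        }
    if coverage is not None:
        doc.sections["capture_coverage"] = {
            "target_mean_depth": round_half_away(coverage.target_mean_depth, 1),
            "nontarget_mean_depth": round_half_away(coverage.nontarget_mean_depth, 1),
            "fold_enrichment": round_half_away(coverage.fold_enrichment, 2),
            "snps_in_target": coverage.snps_in_target,
            "snp_in_target_percent": coverage.snp_in_target_percent,
        }
        if funnel is not None and coverage.snps_total not in (0, funnel.final_count):
            raise ValueError(
                "inconsistent totals: coverage SNP denominator "
                f"({coverage.snps_total}) != funnel survivors ({funnel.final_count})"
            )
    if assay_counts is not None:
        kaspar_valid = assay_counts.get("kaspar_only", 0) + assay_counts.get("both", 0)
        infinium_valid = assay_counts.get("infinium_only", 0) + assay_counts.get(
            "both", 0
        )
        doc.sections["assay_suitability"] = {
            **assay_counts,
            "kaspar_valid": kaspar_valid,
            "infinium_valid": infinium_valid,
        }
    if validations:
        doc.sections["kaspar_validation"] = {
            v.label: {
                "tested": v.tested,
                **v.outcomes,
                "PA_percent": v.pa_percent,
                "PS_percent": v.ps_percent,
                "PS_corrected_percent": v.ps_corrected_percent,
            }
            for v in validations
        }
    if not doc.sections:
        doc.sections["empty"] = "no pipeline components supplied"
    return doc
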