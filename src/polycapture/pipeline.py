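"""End-to-end synthetic pipeline orchestration.

Wires the stages together on a simulated world: genome + truth ->
orthologue discovery -> staged reference sets -> per-line read simulation
and unique-best mapping -> pileup/genotype calling -> filtering funnel ->
characterization, coverage and report.  This is what the CLI ``run-all``
command, the examples, and the acceptance script drive.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .read_mapper import MappingStats, ReferenceIndex, map_reads, mapping_stats, rmpi
from .reference_builder import (
    OrthologousRegion,
    ReferenceSet,
    build_reference_sets,
    extract_capture_sequences,
    find_orthologous_regions,
)
from .snp_characterization import (
    CoverageSummary,
    TsTvSummary,
    annotate_snps,
    coverage_summary_from_depths,
    snp_density,
)
from .snp_filter import FilterConfig, FunnelResult, assay_partition, run_funnel
from .synth_data import (
    GenomeBundle,
    SimulationConfig,
    TruthTable,
    simulate_reads,
    simulate_world,
)
from .validation_reporting import ReportDocument, assemble_report
from .variant_caller import (
    DEFAULT_MIN_DEPTH,
    RawSnp,
    build_pileups,
    discover_snps_from_pileups,
)

logger = logging.getLogger("polycapture")


@dataclass
class PipelineResult:
    config: SimulationConfig
    bundle: GenomeBundle
    truth: TruthTable
    reference_sets: dict[str, ReferenceSet]
    orthologous_regions: list[OrthologousRegion]
    stats: dict[str, list[MappingStats]]
    rmpi_orthologues: float | None
    raw_snps: list[RawSnp]
    funnel: FunnelResult
    tstv: TsTvSummary
    coverage: CoverageSummary
    density_in_target: float
    density_off_target: float
    report: ReportDocument

    @property
    def assay_counts(self) -> dict[str, int]:
        return assay_partition(self.funnel.classes)


def run_synthetic_pipeline(
    config: SimulationConfig,
    filter_config: FilterConfig | None = None,
    reference_comparison: str = "first_line",
) -> PipelineResult:
    """Simulate, map, call, filter and characterize one full panel.

    ``reference_comparison`` controls the staged-reference mapping audit
    (RM against capture-design vs capture-with-orthologues): ``first_line``
    maps one line's reads to all three sets, ``all`` every line, ``none``
    skips it.  SNP calling always runs against the pseudomolecules, the
    most complete reference.
    """
    config.validate()
    filter_config = filter_config or FilterConfig()
    bundle, truth = simulate_world(config)
    logger.info("world: %d sequences, %d truth variants",
                len(bundle.sequences), len(truth))

    capture = extract_capture_sequences(bundle)
    complement_of = {
        name: [GenomeBundle.partner_name(name.split("|")[1].split(":")[0])]
        for name in capture
    }
    regions = find_orthologous_regions(capture, bundle.sequences, complement_of)
    set1, set2, set3 = build_reference_sets(capture, bundle.sequences, regions)
    reference_sets = {rs.label: rs for rs in (set1, set2, set3)}

    min_depth = DEFAULT_MIN_DEPTH[config.chemistry]
    seed_k = 17 if config.chemistry == "long" else 13
    idx3 = ReferenceIndex(set3.sequences, seed_k)
    idx1 = idx2 = None
    stats: dict[str, list[MappingStats]] = {rs.label: [] for rs in (set1, set2, set3)}
    mats_by_line: dict[str, dict] = {}
    pooled_depth = {
        name: np.zeros(L, dtype=np.int64) for name, L in bundle.seq_lengths.items()
    }
    rmpi_value: float | None = None
    for li in range(config.n_lines):
        lid = f"line_{li}"
        reads = simulate_reads(bundle, truth, li, config)
        alns = map_reads(reads, set3, seed_k=seed_k, index=idx3)
        stats["pseudomolecules"].append(mapping_stats(alns, reads, set3.label))
        mats = build_pileups(alns, set3.sequences)
        mats_by_line[lid] = mats
        for name, mat in mats.items():
            pooled_depth[name] += mat.depth
        compare = reference_comparison == "all" or (
            reference_comparison == "first_line" and li == 0
        )
        if compare:
            if idx1 is None:
                idx1 = ReferenceIndex(set1.sequences, seed_k)
                idx2 = ReferenceIndex(set2.sequences, seed_k)
            a1 = map_reads(reads, set1, seed_k=seed_k, index=idx1)
            a2 = map_reads(reads, set2, seed_k=seed_k, index=idx2)
            s1 = mapping_stats(a1, reads, set1.label)
            s2 = mapping_stats(a2, reads, set2.label)
            stats[set1.label].append(s1)
            stats[set2.label].append(s2)
            if rmpi_value is None and s1.rm > 0:
                rmpi_value = rmpi(s1, s2)
        logger.info("%s: %d reads, RM=%d", lid, reads.count,
                    stats["pseudomolecules"][-1].rm)

    raw_snps = discover_snps_from_pileups(
        mats_by_line, set3.sequences, min_depth=min_depth,
        error_rate=config.base_error_rate or 0.005,
    )
    funnel = run_funnel(raw_snps, bundle.seq_lengths, filter_config)

    index = bundle.annotation_index()
    annotated = annotate_snps(funnel.kept, index)
    tstv = TsTvSummary.from_annotated(annotated)

    enriched = {
        name: bundle.enriched_intervals(name) for name in bundle.sequences
    }
    # per-line mean depth: pooled depth over the panel divided by panel size
    per_line_depth = {
        name: d / config.n_lines for name, d in pooled_depth.items()
    }
    coverage = coverage_summary_from_depths(
        per_line_depth, enriched, bundle.seq_lengths, funnel.kept
    )
    from .intervals import complement_intervals

    off = {
        name: complement_intervals(enriched[name], L)
        for name, L in bundle.seq_lengths.items()
    }
    density_in = snp_density(funnel.kept, enriched)
    density_off = snp_density(funnel.kept, off)

    report = assemble_report(
        funnel=funnel.report,
        mapping=[s[-1] for s in stats.values() if s],
        tstv=tstv,
        coverage=coverage,
        assay_counts=assay_partition(funnel.classes),
    )
    return PipelineResult(
        config=config,
        bundle=bundle,
        truth=truth,
        reference_sets=reference_sets,
        orthologous_regions=regions,
        stats=stats,
        rmpi_orthologues=rmpi_value,
        raw_snps=raw_snps,
        funnel=funnel,
        tstv=tstv,
        coverage=coverage,
        density_in_target=density_in,
        density_off_target=density_off,
        report=report,
    )


def evaluate_against_truth(
    truth: TruthTable, kept: list[RawSnp], in_target_only: bool = True
) -> dict[str, float]:
    """Parameter-recovery metrics against the planted truth: fraction of
    planted homozygous SNPs recovered, and genotype concordance over the
    recovered ones."""
    kept_by_pos = {(s.seq_name, s.position): s for s in kept}
    planted = [
        v for v in truth.variants
        if (v.in_target or not in_target_only)
        and any(g == "alt/alt" for g in v.genotypes)
    ]
    if not planted:
        return {"recovery": float("nan"), "genotype_concordance": float("nan")}
    recovered = 0
    gt_match = gt_total = 0
    for v in planted:
        s = kept_by_pos.get((v.seq_name, v.position))
        if s is None or v.alt_allele not in s.alt_alleles:
            continue
        recovered += 1
        for li, g_true in enumerate(v.genotypes):
            call = s.calls.get(f"line_{li}")
            if call is None or call.genotype == "no_call":
                continue
            gt_total += 1
            want = {"ref/ref": "hom_ref", "alt/alt": "hom_alt", "het": "het"}[g_true]
            if call.genotype == want:
                gt_match += 1
    return {
        "recovery": recovered / len(planted),
        "genotype_concordance": gt_match / gt_total if gt_total else float("nan"),
        "n_planted": float(len(planted)),
        "n_recovered": float(recovered),
    }
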