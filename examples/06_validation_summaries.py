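"""Summarize KASP validation panels and apply the Infinium cluster-QC
rule.

PA is the positive-amplification rate, PS the polymorphic rate over all
tested SNPs, and the corrected PS excludes assays that failed to amplify
(an assay failure, not a SNP failure).
"""

from polycapture import (
    InfiniumRecord,
    KasparPanelResult,
    classify_infinium,
    summarize_kaspar,
)

panels = [
    KasparPanelResult(
        label="diversity_set", n_individuals=25, tested=100,
        outcomes={"no_amplification": 12, "monomorphic": 9,
                  "multiple_loci": 8, "polymorphic": 71},
    ),
    KasparPanelResult(
        label="spring_population", n_individuals=30, tested=19,
        outcomes={"no_amplification": 0, "monomorphic": 1,
                  "multiple_loci": 2, "polymorphic": 16},
    ),
]
for panel in panels:
    s = summarize_kaspar(panel)
    print(f"{s.label}: tested {s.tested}, PA {s.pa_percent}%, "
          f"PS {s.ps_percent}%, corrected PS {s.ps_corrected_percent}%")

records = [
    InfiniumRecord("snp_a", aa_theta=0.05, bb_theta=0.95, ab_frequency=0.02),
    InfiniumRecord("snp_b", aa_theta=0.30, bb_theta=0.95, ab_frequency=0.02),
    InfiniumRecord("snp_c", aa_theta=0.10, bb_theta=0.90, ab_frequency=0.40),
    InfiniumRecord("snp_d", aa_theta=None, bb_theta=None, ab_frequency=0.0),
]
print("\nInfinium cluster QC (AA theta in [0,0.2], BB in [0.8,1], "
      "AB frequency <= 0.15):")
for rec in records:
    print(f"  {rec.snp_id}: {classify_infinium(rec)}")
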