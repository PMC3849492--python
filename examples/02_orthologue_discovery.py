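"""Find the orthologue of each capture-design sequence in the partner
subgenome and assemble the three staged mapping reference sets.

Anchoring uses maximal exact matches seeded at k-mers unique in both
query and subject; collinear anchors on one alignment diagonal are
chained into candidate regions and the best-covered one is flagged as
the orthologue.
"""

from polycapture import (
    SimulationConfig,
    build_ancestral_genome,
    build_reference_sets,
    derive_homoeolog,
    design_capture_targets,
    extract_capture_sequences,
    find_orthologous_regions,
)

cfg = SimulationConfig(seed=11, chrom_length=50_000)
bundle = build_ancestral_genome(cfg)
derive_homoeolog(bundle, identity=0.94, seed=cfg.seed)
design_capture_targets(bundle, cfg)

capture = extract_capture_sequences(bundle)
complement_of = {
    name: [bundle.partner_name(name.split("|")[1].split(":")[0])]
    for name in capture
}
regions = find_orthologous_regions(capture, bundle.sequences, complement_of)

print(f"{len(capture)} capture-design sequences")
for r in regions:
    tag = "orthologue" if r.is_primary else "secondary "
    a, b = r.subject_interval
    print(f"  {tag} of {r.capture_seq_name:<22} -> {r.subject_name}:"
          f"{a}-{b}  anchors={r.anchor_count:3d} "
          f"coverage={r.anchor_coverage:.2f}")
# coverage is the fraction of the query tiled by exact-match anchors;
# at 94% identity roughly 0.6-0.8 of each region is anchored

set1, set2, set3 = build_reference_sets(capture, bundle.sequences, regions)
for rs in (set1, set2, set3):
    bp = sum(len(s) for s in rs.sequences.values())
    print(f"reference set {rs.label:<26} {len(rs.sequences):3d} sequences, "
          f"{bp:,} bp")
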