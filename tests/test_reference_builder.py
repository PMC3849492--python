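"""Anchoring, repetitive-hit filtering, chaining and reference-set
assembly, checked against brute-force fixtures and the synthetic truth."""

import numpy as np
import pytest

from polycapture import (
    AnchorMatch,
    SimulationConfig,
    build_ancestral_genome,
    build_reference_sets,
    chain_anchors,
    derive_homoeolog,
    design_capture_targets,
    extract_capture_sequences,
    filter_repetitive,
    find_orthologous_regions,
    find_unique_anchors,
)
from polycapture._util import revcomp


def random_seq(n, seed=0):
    rng = np.random.default_rng(seed)
    return "".join(rng.choice(list("ACGT"), size=n))


class TestUniqueAnchors:
    def test_self_match_spans_full_length(self):
        q = random_seq(2000, seed=1)
        anchors = find_unique_anchors(q, q, k=15)
        assert len(anchors) == 1
        a = anchors[0]
        assert (a.query_pos, a.subject_pos, a.length, a.strand) == (0, 0, 2000, "+")

    def test_reverse_complement_reported_on_minus_strand(self):
        q = random_seq(2000, seed=2)
        anchors = find_unique_anchors(q, revcomp(q), k=15)
        assert len(anchors) == 1
        a = anchors[0]
        assert a.strand == "-"
        assert a.length == 2000
        assert a.subject_pos == 0

    def test_homoeolog_coverage_at_94_percent_identity(self):
        # 94%-identity homoeolog: anchors must tile at least half the query
        rng = np.random.default_rng(3)
        q = random_seq(2000, seed=3)
        s = list(q)
        n_sub = rng.binomial(len(s), 0.06)
        for p in rng.choice(len(s), size=n_sub, replace=False):
            s[p] = "ACGT"[("ACGT".index(s[p]) + 1 + rng.integers(3)) % 4]
        anchors = find_unique_anchors(q, "".join(s), k=15)
        covered = np.zeros(2000, dtype=bool)
        for a in anchors:
            covered[a.query_pos : a.query_pos + a.length] = True
        assert covered.mean() >= 0.5

    def test_symmetry_of_query_and_subject(self):
        q = random_seq(1500, seed=4)
        s = random_seq(1500, seed=5) + q[300:900] + random_seq(500, seed=6)
        fwd = find_unique_anchors(q, s, k=15)
        rev = find_unique_anchors(s, q, k=15)
        mirrored = {(a.subject_pos, a.query_pos, a.length) for a in rev if a.strand == "+"}
        for a in fwd:
            if a.strand == "+":
                assert (a.query_pos, a.subject_pos, a.length) in mirrored

    def test_small_k_rejected_and_empty_input(self):
        with pytest.raises(ValueError):
            find_unique_anchors("ACGT" * 100, "ACGT" * 100, k=9)
        assert find_unique_anchors("", "ACGTACGTACGTACGT", k=11) == []


def mk_anchor(qp, sp, length=100, strand="+", subject="S"):
    return AnchorMatch("Q", qp, subject, sp, length, strand)


class TestFilterRepetitive:
    def test_single_locus_untouched(self):
        anchors = [mk_anchor(0, 5000), mk_anchor(120, 5120)]
        assert filter_repetitive(anchors, 2) == anchors

    def test_multi_locus_query_window_removed(self):
        # one query segment anchored at 5 distant subject loci
        anchors = [mk_anchor(0, i * 50_000) for i in range(5)]
        assert filter_repetitive(anchors, 2) == []

    def test_empty(self):
        assert filter_repetitive([], 2) == []


class TestChainAnchors:
    def test_single_anchor_region(self):
        regions = chain_anchors([mk_anchor(0, 7000, 150)])
        assert len(regions) == 1
        assert regions[0].subject_interval == (7000, 7150)
        assert regions[0].is_primary

    def test_nearby_collinear_anchors_merge(self):
        a1 = mk_anchor(0, 7000, 150)
        a2 = mk_anchor(250, 7250, 150)  # 100 bp gap on both coordinates
        regions = chain_anchors([a1, a2], max_gap=1000)
        assert len(regions) == 1
        assert regions[0].subject_interval == (7000, 7400)
        assert regions[0].anchor_count == 2

    def test_distant_clusters_stay_separate(self):
        a1 = mk_anchor(0, 7000, 150)
        a2 = mk_anchor(250, 57_250, 150)  # 50 kb away on subject
        regions = chain_anchors([a1, a2], max_gap=1000)
        assert len(regions) == 2
        assert sum(r.is_primary for r in regions) == 1

    def test_no_anchors(self):
        assert chain_anchors([]) == []


class TestReferenceSets:
    def test_no_orthologues_set2_equals_set1(self):
        capture = {"c1": "ACGT" * 100}
        pseudo = {"P1": "ACGT" * 1000}
        s1, s2, s3 = build_reference_sets(capture, pseudo, [])
        assert s2.sequences == s1.sequences
        assert s3.sequences == pseudo

    def test_design_plus_orthologue_counts(self):
        # 883 design sequences + 1,074 orthologues -> 1,957 in set 2
        from polycapture.reference_builder import OrthologousRegion

        capture = {f"c{i}": "ACGTACGTAC" for i in range(883)}
        pseudo = {"P1": random_seq(3000, seed=8)}
        regions = [
            OrthologousRegion(
                capture_seq_name=f"c{i % 883}",
                subject_name="P1",
                subject_interval=(i, i + 1),
                anchor_count=1,
                anchor_coverage=1.0,
                is_primary=True,
            )
            for i in range(1074)
        ]
        s1, s2, s3 = build_reference_sets(capture, pseudo, regions)
        assert len(s1.sequences) == 883
        assert len(s2.sequences) == 883 + 1074 == 1957

    def test_half_open_extraction_length(self):
        from polycapture.reference_builder import OrthologousRegion

        capture = {"c1": "AC"}
        pseudo = {"P1": random_seq(1000, seed=9)}
        region = OrthologousRegion("c1", "P1", (100, 200), 1, 1.0, is_primary=True)
        _, s2, _ = build_reference_sets(capture, pseudo, [region])
        (extracted,) = [v for k, v in s2.sequences.items() if "orth" in k]
        assert len(extracted) == 100
        assert extracted == pseudo["P1"][100:200]

    def test_out_of_bounds_region_rejected(self):
        from polycapture.reference_builder import OrthologousRegion

        region = OrthologousRegion("c1", "P1", (900, 1200), 1, 1.0, is_primary=True)
        with pytest.raises(ValueError):
            build_reference_sets({"c1": "AC"}, {"P1": "A" * 1000}, [region])


class TestOrthologueRecovery:
    def test_flagged_orthologue_overlaps_truth_jaccard(self):
        """With coordinates preserved between subgenomes, the primary
        orthologue of each capture extract must align with the mirrored
        interval on the partner chromosome (Jaccard >= 0.8)."""
        cfg = SimulationConfig(seed=11, chrom_length=50_000)
        bundle = build_ancestral_genome(cfg)
        derive_homoeolog(bundle, 0.94, cfg.seed)
        design_capture_targets(bundle, cfg)
        capture = extract_capture_sequences(bundle)
        complement_of = {
            name: [bundle.partner_name(name.split("|")[1].split(":")[0])]
            for name in capture
        }
        regions = find_orthologous_regions(capture, bundle.sequences, complement_of)
        primaries = {r.capture_seq_name: r for r in regions if r.is_primary}
        assert len(primaries) == len(capture)
        for name, r in primaries.items():
            coords = name.split("|")[1].split(":")[1]
            t0, t1 = (int(x) for x in coords.split("-"))
            a0, a1 = r.subject_interval
            inter = max(0, min(t1, a1) - max(t0, a0))
            union = max(t1, a1) - min(t0, a0)
            assert inter / union >= 0.8
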