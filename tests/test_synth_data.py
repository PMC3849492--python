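"""Generator behaviour: determinism, homoeolog divergence, planted-SNP
densities and spectrum, and capture-enrichment depth structure."""

import numpy as np
import pytest

from polycapture import (
    SimulationConfig,
    build_ancestral_genome,
    derive_homoeolog,
    design_capture_targets,
    plant_line_variants,
    simulate_reads,
    simulate_world,
)
from polycapture.intervals import total_length
from polycapture.snp_characterization import depth_arrays
from polycapture._util import revcomp


def cfg(**kw):
    base = dict(seed=1, chrom_length=50_000)
    base.update(kw)
    return SimulationConfig(**base)


class TestAncestralGenome:
    def test_exact_length_and_determinism(self):
        b1 = build_ancestral_genome(cfg())
        b2 = build_ancestral_genome(cfg())
        assert len(b1.sequences["A1"]) == 50_000
        assert b1.sequences == b2.sequences
        assert [g.gene_interval for g in b1.gene_models] == [
            g.gene_interval for g in b2.gene_models
        ]

    def test_different_seeds_diverge(self):
        s1 = build_ancestral_genome(cfg(seed=1)).sequences["A1"]
        s2 = build_ancestral_genome(cfg(seed=2)).sequences["A1"]
        diff = sum(a != b for a, b in zip(s1, s2)) / len(s1)
        assert diff > 0.10

    def test_gene_fraction_roughly_honoured(self):
        b = build_ancestral_genome(cfg())
        genic = sum(
            g.gene_interval[1] - g.gene_interval[0] for g in b.gene_models
        )
        assert 0.25 < genic / 50_000 < 0.55

    def test_tiny_chromosome_rejected(self):
        with pytest.raises(ValueError, match="too small"):
            build_ancestral_genome(cfg(chrom_length=1000))


class TestHomoeolog:
    def test_identity_one_gives_identical_copy(self):
        b = build_ancestral_genome(cfg())
        derive_homoeolog(b, 1.0, seed=1)
        assert b.sequences["C1"] == b.sequences["A1"]

    def test_divergence_rate_within_binomial_noise(self):
        b = build_ancestral_genome(cfg())
        derive_homoeolog(b, 0.94, seed=1)
        L = 50_000
        diff = sum(a != c for a, c in zip(b.sequences["A1"], b.sequences["C1"]))
        p = 0.06
        sd = np.sqrt(p * (1 - p) * L)
        assert abs(diff - p * L) <= 3 * sd

    def test_gene_coordinates_carried_over(self):
        b = build_ancestral_genome(cfg())
        a_genes = {g.gene_id: g.gene_interval for g in b.gene_models}
        derive_homoeolog(b, 0.94, seed=1)
        for g in b.gene_models:
            if g.seq_name.startswith("C"):
                assert g.gene_interval == a_genes[g.gene_id.replace("C", "A", 1)]

    def test_identity_bounds_enforced(self):
        b = build_ancestral_genome(cfg())
        with pytest.raises(ValueError):
            derive_homoeolog(b, 0.4, seed=1)


class TestPlantedVariants:
    def test_transition_fraction_matches_tstv(self):
        # ~830 planted SNPs at the default spacings on a 500 kb genome
        config = cfg(chrom_length=250_000)
        bundle, truth = simulate_world(config)
        n = len(truth)
        ts = sum(1 for v in truth if v.substitution_class == "transition")
        p = 1.52 / 2.52
        sd = np.sqrt(p * (1 - p) / n)
        assert abs(ts / n - p) <= 3 * sd

    def test_in_target_density_matches_spacing(self):
        config = cfg(chrom_length=250_000)
        bundle, truth = simulate_world(config)
        enriched_bp = sum(
            total_length(bundle.enriched_intervals(n)) for n in bundle.sequences
        )
        n_in = len(truth.in_target())
        assert abs(n_in - enriched_bp / 421.3) <= 3 * np.sqrt(enriched_bp / 421.3)

    def test_no_targets_means_all_off_target(self):
        bundle, truth = simulate_world(cfg(target_fraction=0.0))
        assert len(truth) > 0
        assert all(not v.in_target for v in truth)

    def test_ref_differs_from_alt_and_genotypes_complete(self):
        bundle, truth = simulate_world(cfg())
        for v in truth:
            assert v.ref_allele != v.alt_allele
            assert len(v.genotypes) == 10
            assert any(g == "alt/alt" for g in v.genotypes)

    def test_unresolvable_spacing_rejected(self):
        bundle = build_ancestral_genome(cfg())
        derive_homoeolog(bundle, 0.94, seed=1)
        config = cfg(in_target_snp_spacing=5.0)
        with pytest.raises(ValueError):
            plant_line_variants(bundle, config)


class TestReadSimulation:
    def test_error_free_reads_are_exact_substrings(self, small_world=None):
        config = cfg(chrom_length=20_000, base_error_rate=0.0,
                     target_depth=5, offtarget_depth=5)
        bundle, truth = simulate_world(config)
        reads = simulate_reads(bundle, truth, 0, config)
        # personalised genomes of line 0
        genomes = {}
        for name, seq in bundle.sequences.items():
            arr = list(seq)
            for v in truth:
                if v.seq_name == name and v.genotypes[0] == "alt/alt":
                    arr[v.position] = v.alt_allele
            genomes[name] = "".join(arr)
        blob = " ".join(genomes.values())
        for seq in reads.seqs[:200]:
            assert seq in blob or revcomp(seq) in blob

    def test_depth_fold_enrichment_at_defaults(self):
        config = cfg(seed=3)  # 2 x 50 kb, depths 77 / 19.6
        bundle, truth = simulate_world(config)
        reads = simulate_reads(bundle, truth, 0, config)
        # truth depth from read origins (mapper not involved)
        diffs = {n: np.zeros(L + 1) for n, L in bundle.seq_lengths.items()}
        for name, s, e, strand in reads.origins:
            diffs[name][s] += 1
            diffs[name][e] -= 1
        t_sum = t_len = o_sum = o_len = 0
        from polycapture.intervals import complement_intervals

        for name, L in bundle.seq_lengths.items():
            depth = np.cumsum(diffs[name][:-1])
            enriched = bundle.enriched_intervals(name)
            for a, b in enriched:
                t_sum += depth[a:b].sum(); t_len += b - a
            for a, b in complement_intervals(enriched, L):
                o_sum += depth[a:b].sum(); o_len += b - a
        fold = (t_sum / t_len) / (o_sum / o_len)
        assert 3.2 <= fold <= 4.8

    def test_equal_depths_give_unit_ratio(self):
        config = cfg(target_depth=20.0, offtarget_depth=20.0)
        bundle, truth = simulate_world(config)
        reads = simulate_reads(bundle, truth, 0, config)
        diffs = {n: np.zeros(L + 1) for n, L in bundle.seq_lengths.items()}
        for name, s, e, strand in reads.origins:
            diffs[name][s] += 1
            diffs[name][e] -= 1
        from polycapture.intervals import complement_intervals

        t = []
        o = []
        for name, L in bundle.seq_lengths.items():
            depth = np.cumsum(diffs[name][:-1])
            enriched = bundle.enriched_intervals(name)
            for a, b in enriched:
                t.append(depth[a:b])
            for a, b in complement_intervals(enriched, L):
                o.append(depth[a:b])
        ratio = np.concatenate(t).mean() / np.concatenate(o).mean()
        assert 0.85 <= ratio <= 1.18

    def test_reads_deterministic_under_seed(self):
        config = cfg(chrom_length=20_000)
        bundle, truth = simulate_world(config)
        r1 = simulate_reads(bundle, truth, 0, config)
        r2 = simulate_reads(bundle, truth, 0, config)
        assert r1.ids == r2.ids and r1.seqs == r2.seqs

    def test_short_chemistry_emits_fixed_length_pairs(self):
        config = cfg(
            chrom_length=20_000, chemistry="short",
            target_depth=8, offtarget_depth=8,
        )
        bundle, truth = simulate_world(config)
        reads = simulate_reads(bundle, truth, 0, config)
        assert reads.paired
        assert set(len(s) for s in reads.seqs) == {54}
        assert all(len(q) == len(s) for q, s in zip(reads.quals, reads.seqs))

    def test_invalid_depth_rejected(self):
        config = cfg()
        bundle, truth = simulate_world(config)
        config.target_depth = -1
        with pytest.raises(ValueError):
            simulate_reads(bundle, truth, 0, config)
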