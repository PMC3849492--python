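"""The three-stage filtering funnel, assay suitability windows, and the
funnel report arithmetic."""

import numpy as np
import pytest

from conftest import make_call, make_snp
from polycapture import (
    FilterConfig,
    FunnelReport,
    classify_assay_suitability,
    filter_flanking,
    filter_het_bias,
    filter_multiallelic,
    run_funnel,
)
from polycapture.snp_filter import assay_partition, classify_all


class TestMultiallelic:
    def test_biallelic_kept_multiallelic_excluded(self):
        kept, excl = filter_multiallelic(
            [make_snp(alts=("G",)), make_snp(pos=2000, alts=("G", "T"))]
        )
        assert len(kept) == 1 and len(excl) == 1
        assert excl[0].alt_alleles == {"G", "T"}

    def test_counts_on_mixed_fixture(self):
        snps = [
            make_snp(pos=p, alts=("G", "T") if i < 3 else ("G",))
            for i, p in enumerate(range(0, 5000, 500))
        ]
        kept, excl = filter_multiallelic(snps)
        assert (len(kept), len(excl)) == (7, 3)


def hom(lid, alt="G"):
    return make_call(lid, "hom_alt", alt=alt, alt_fraction=1.0)


def het(lid, alt="G"):
    return make_call(lid, "het", alt=alt, alt_fraction=0.5)


class TestHetBias:
    def test_proportion_strictly_over_threshold_excluded(self):
        calls = {f"l{i}": het(f"l{i}") for i in range(3)}
        calls.update({f"l{i}": hom(f"l{i}") for i in range(3, 10)})
        kept, excl = filter_het_bias([make_snp(calls=calls)], 0.2)
        assert kept == [] and len(excl) == 1  # 3/10 = 0.3 > 0.2

    def test_exactly_at_threshold_kept(self):
        calls = {f"l{i}": het(f"l{i}") for i in range(2)}
        calls.update({f"l{i}": hom(f"l{i}") for i in range(2, 10)})
        kept, excl = filter_het_bias([make_snp(calls=calls)], 0.2)
        assert len(kept) == 1 and excl == []  # 0.2 is not over 0.2

    def test_only_biased_homozygotes_excluded(self):
        calls = {
            f"l{i}": make_call(f"l{i}", "hom_alt", alt="G", alt_fraction=0.85,
                               biased=True)
            for i in range(5)
        }
        kept, excl = filter_het_bias([make_snp(calls=calls)], 0.2)
        assert kept == [] and len(excl) == 1

    def test_het_only_support_excluded_even_below_threshold(self):
        # one het line among nine clean reference lines: no clean
        # homozygous-alt evidence anywhere, the hemi-SNP/error signature
        calls = {"l0": het("l0")}
        calls.update(
            {f"l{i}": make_call(f"l{i}", "hom_ref") for i in range(1, 10)}
        )
        kept, excl = filter_het_bias([make_snp(calls=calls)], 0.2)
        assert kept == [] and len(excl) == 1

    def test_zero_called_lines_excluded(self):
        calls = {f"l{i}": make_call(f"l{i}", "no_call", depth=0) for i in range(3)}
        kept, excl = filter_het_bias([make_snp(calls=calls)], 0.2)
        assert kept == [] and len(excl) == 1


class TestAssaySuitability:
    LEN = {"A1": 400}

    def classify(self, pos, neighbors=(), length=400, cfg=None):
        snp = make_snp(pos=pos)
        arr = np.array(sorted(set(neighbors) | {pos}), dtype=int)
        return classify_assay_suitability(
            snp, {"A1": arr}, {"A1": length}, cfg or FilterConfig()
        )

    def test_interior_snp_with_distant_neighbor_is_both(self):
        assert self.classify(150, neighbors=[350]) == "both"

    def test_short_left_flank_with_clean_right_side_is_infinium_only(self):
        assert self.classify(50) == "infinium_only"

    def test_close_neighbors_on_both_sides_is_kaspar_only(self):
        assert self.classify(150, neighbors=[120, 180]) == "kaspar_only"

    def test_edge_snp_with_neighbor_is_neither(self):
        assert self.classify(30, neighbors=[50]) == "neither"

    def test_position_outside_sequence_rejected(self):
        with pytest.raises(ValueError):
            self.classify(500)

    def test_kaspar_boundary_is_inclusive(self):
        # flanks of exactly 100 bp on both sides satisfy the rule
        assert self.classify(100, length=201) in ("both", "kaspar_only")
        assert self.classify(99, length=201) != "both"


class TestFlankingFilter:
    def test_partition_and_exclusion(self):
        snps = [make_snp(pos=p) for p in (0, 1, 2, 3, 4, 5)]
        classes = {
            ("A1", 0): "both", ("A1", 1): "kaspar_only",
            ("A1", 2): "infinium_only", ("A1", 3): "neither",
            ("A1", 4): "neither", ("A1", 5): "both",
        }
        kept, excl = filter_flanking(snps, classes)
        assert (len(kept), len(excl)) == (4, 2)
        part = assay_partition(classes)
        assert sum(part.values()) == 6
        assert part["neither"] == 2


class TestFunnel:
    def test_report_invariant_on_printed_scale_counts(self):
        report = FunnelReport.from_exclusions(
            2_740_205,
            ["Multiple Variants hits", "Heterozygous and Bias", "Flanking Sequence"],
            [33_917, 2_111_439, 5_482],
        )
        remaining = [s.remaining for s in report.stages]
        assert remaining == [2_706_288, 594_849, 589_367]
        assert report.final_count == 589_367

    def test_inconsistent_report_rejected(self):
        from polycapture.snp_filter import FunnelStage

        with pytest.raises(ValueError, match="funnel inconsistency"):
            FunnelReport(total=100, stages=[FunnelStage("x", 10, 80)])

    def test_empty_input_all_zero(self):
        res = run_funnel([], {"A1": 1000})
        assert res.report.total == 0
        assert all(s.excluded == 0 and s.remaining == 0 for s in res.report.stages)

    def test_stage_counts_match_independent_recount(self):
        """Funnel stage attribution equals a brute-force per-rule recount
        on a fixture with planted violations of each rule."""
        rng = np.random.default_rng(5)
        snps = []
        for i in range(100):
            pos = 150 + i * 300
            kind = i % 5
            if kind == 0:  # multiallelic
                snps.append(make_snp(pos=pos, alts=("G", "T"),
                                     calls={"l0": "hom_alt", "l1": "hom_alt"}))
            elif kind == 1:  # het-heavy: 3 het of 10 called
                calls = {f"l{j}": het(f"l{j}") for j in range(3)}
                calls.update({f"l{j}": hom(f"l{j}") for j in range(3, 10)})
                snps.append(make_snp(pos=pos, calls=calls))
            elif kind == 2:  # het-only support
                calls = {"l0": het("l0"), "l1": make_call("l1", "hom_ref")}
                snps.append(make_snp(pos=pos, calls=calls))
            else:  # clean
                snps.append(make_snp(pos=pos, calls={"l0": hom("l0"),
                                                     "l1": make_call("l1", "hom_ref")}))
        res = run_funnel(snps, {"A1": 40_000})
        # independent recount, rule by rule
        n_multi = sum(1 for s in snps if len(s.alt_alleles) > 1)
        bi = [s for s in snps if len(s.alt_alleles) == 1]
        def het_bias_excluded(s):
            called = s.called
            nonref = [c for c in called if c.genotype in ("het", "hom_alt")]
            a = all(c.genotype == "het" or c.biased for c in nonref)
            b = sum(1 for c in called if c.genotype == "het") / len(called) > 0.2
            return a or b
        n_hb = sum(1 for s in bi if het_bias_excluded(s))
        stages = {s.criterion: s.excluded for s in res.report.stages}
        assert stages["Multiple Variants hits"] == n_multi == 20
        assert stages["Heterozygous and Bias"] == n_hb == 40
        assert res.report.final_count == len(res.kept)

    def test_total_exclusion_invariant_to_first_two_stage_order(self):
        calls_clean = {"l0": hom("l0"), "l1": make_call("l1", "hom_ref")}
        calls_hetty = {f"l{j}": het(f"l{j}") for j in range(5)}
        snps = [
            make_snp(pos=500, alts=("G", "T"), calls=dict(calls_hetty)),
            make_snp(pos=1500, alts=("G",), calls=dict(calls_hetty)),
            make_snp(pos=2500, alts=("G", "T"), calls=dict(calls_clean)),
            make_snp(pos=3500, alts=("G",), calls=dict(calls_clean)),
        ]
        k1, e1 = filter_multiallelic(snps)
        k2, e2 = filter_het_bias(k1, 0.2)
        forward_total = len(e1) + len(e2)
        k1b, e1b = filter_het_bias(snps, 0.2)
        k2b, e2b = filter_multiallelic(k1b)
        assert forward_total == len(e1b) + len(e2b)
        assert {id(s) for s in k2} == {id(s) for s in k2b}

    def test_funnel_idempotent_on_own_output(self):
        calls = {"l0": hom("l0"), "l1": make_call("l1", "hom_ref")}
        snps = [make_snp(pos=p, calls=dict(calls)) for p in range(200, 4000, 700)]
        first = run_funnel(snps, {"A1": 10_000})
        second = run_funnel(first.kept, {"A1": 10_000})
        assert all(s.excluded == 0 for s in second.report.stages)
        assert second.report.final_count == first.report.final_count

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            run_funnel([], {"A1": 100}, FilterConfig(het_threshold=1.5))
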