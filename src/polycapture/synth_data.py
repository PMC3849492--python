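"""Synthetic allotetraploid capture-sequencing world.

Generates a miniature two-subgenome (A/C) genome with gene models, capture
target intervals, a panel of inbred lines with planted biallelic SNPs, and
capture-enriched sequencing reads with known truth.  The defaults encode the
statistical structure the downstream analysis assumes: ~94% homoeolog
identity, transition-biased substitutions (ts/tv 1.52), one in-target SNP
per ~421.3 bp and one off-target SNP per ~697.8 bp, and ~4-fold depth
enrichment of capture targets (77X vs 19.6X).

Divergence between subgenomes is substitution-only, so coordinates are
shared between the A and C copies of a chromosome; this keeps the truth
directly comparable to calls on either subgenome.  Long-read chemistry is
modelled as single ~350 bp reads with substitution errors; short chemistry
as fixed-length paired 54 bp reads.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Literal

import numpy as np

from ._util import DNA, DNA_BYTES, arr_to_seq, is_transition, revcomp_arr, seq_to_arr
from .intervals import (
    GeneAnnotationIndex,
    GeneModel,
    Interval,
    complement_intervals,
    merge_intervals,
    total_length,
)

# per-operation RNG stream offsets, so stages can be regenerated independently
_SEED_ANCESTRAL = 11
_SEED_HOMOEOLOG = 13
_SEED_TARGETS = 17
_SEED_VARIANTS = 19
_SEED_READS = 23  # + line_index

_TRANSITION_OF = {"A": "G", "G": "A", "C": "T", "T": "C"}
_TRANSVERSIONS_OF = {"A": "CT", "G": "CT", "C": "AG", "T": "AG"}


@dataclass
class SimulationConfig:
    """Knobs of the synthetic world.  Defaults are the study conditions."""

    seed: int = 0
    n_chrom_per_subgenome: int = 1
    chrom_length: int = 250_000
    homoeolog_identity: float = 0.94
    n_lines: int = 10
    target_fraction: float = 0.12
    in_target_snp_spacing: float = 421.3
    off_target_snp_spacing: float = 697.8
    tstv_ratio: float = 1.52
    target_depth: float = 77.0
    offtarget_depth: float = 19.6
    chemistry: Literal["long", "short"] = "long"
    long_read_length_mean: int = 350
    long_read_length_sd: float = 30.0
    short_read_length: int = 54
    short_insert_range: tuple[int, int] = (130, 180)
    base_error_rate: float = 0.005
    gene_fraction: float = 0.4
    het_rate: float = 0.0
    design_a_fraction: float = 0.757
    n_targets_per_chrom: int = 3

    def validate(self) -> None:
        if not (0 <= self.target_fraction < 1):
            raise ValueError("target_fraction must be in [0, 1)")
        if not (0.5 < self.homoeolog_identity <= 1.0):
            raise ValueError("homoeolog_identity must be in (0.5, 1]")
        if self.target_depth <= 0 or self.offtarget_depth <= 0:
            raise ValueError("depths must be positive")
        if self.n_lines < 1:
            raise ValueError("need at least one line")
        if self.chemistry not in ("long", "short"):
            raise ValueError(f"unknown chemistry {self.chemistry!r}")
        read_len = (
            self.long_read_length_mean
            if self.chemistry == "long"
            else self.short_read_length
        )
        if min(self.in_target_snp_spacing, self.off_target_snp_spacing) <= read_len:
            raise ValueError("SNP spacing must exceed the read length")
        if not (0 <= self.base_error_rate < 0.5):
            raise ValueError("base_error_rate must be in [0, 0.5)")
        if not (0 <= self.gene_fraction < 1):
            raise ValueError("gene_fraction must be in [0, 1)")


@dataclass
class Target:
    """A capture target interval, tagged by the subgenome it was designed
    from (its own sequence's subgenome)."""

    seq_name: str
    start: int
    end: int
    design_subgenome: str


@dataclass
class GenomeBundle:
    """The world every pipeline stage reads: sequences, gene models,
    capture targets and (later) orthologous target intervals."""

    sequences: dict[str, str] = field(default_factory=dict)
    gene_models: list[GeneModel] = field(default_factory=list)
    targets: list[Target] = field(default_factory=list)
    orthologous_targets: list[Target] = field(default_factory=list)
    homoeolog_divergence: dict[str, np.ndarray] = field(default_factory=dict)

    @property
    def seq_lengths(self) -> dict[str, int]:
        return {name: len(seq) for name, seq in self.sequences.items()}

    @staticmethod
    def subgenome_of(seq_name: str) -> str:
        return seq_name[0]

    @staticmethod
    def partner_name(seq_name: str) -> str:
        head = {"A": "C", "C": "A"}[seq_name[0]]
        return head + seq_name[1:]

    def targets_on(self, seq_name: str) -> list[Interval]:
        return merge_intervals(
            (t.start, t.end) for t in self.targets if t.seq_name == seq_name
        )

    def enriched_intervals(self, seq_name: str) -> list[Interval]:
        """Capture-enriched region of one sequence: its own targets plus the
        mirror of the partner chromosome's targets (capture pulls both
        homoeologous copies, and coordinates are shared by construction)."""
        own = self.targets_on(seq_name)
        partner = self.targets_on(self.partner_name(seq_name))
        return merge_intervals(own + partner)

    def annotation_index(self) -> GeneAnnotationIndex:
        return GeneAnnotationIndex.from_gene_models(
            self.gene_models, self.seq_lengths
        )

    def validate(self) -> None:
        lengths = self.seq_lengths
        for gm in self.gene_models:
            if gm.seq_name not in lengths:
                raise ValueError(f"gene on unknown sequence {gm.seq_name}")
            if gm.gene_interval[1] > lengths[gm.seq_name]:
                raise ValueError("gene extends past sequence end")
        for t in self.targets:
            if t.end > lengths[t.seq_name] or t.start < 0 or t.end <= t.start:
                raise ValueError("malformed target interval")


@dataclass
class TruthVariant:
    seq_name: str
    position: int
    ref_allele: str
    alt_allele: str
    genotypes: list[str]  # per line, in {"ref/ref", "alt/alt", "het"}
    in_target: bool
    region_class: str  # CDS | intron | intergenic
    substitution_class: str  # transition | transversion


@dataclass
class TruthTable:
    """Planted variants with per-line genotypes; ground truth for
    parameter-recovery tests."""

    variants: list[TruthVariant]
    n_lines: int

    def __len__(self) -> int:
        return len(self.variants)

    def __iter__(self):
        return iter(self.variants)

    def in_target(self) -> list[TruthVariant]:
        return [v for v in self.variants if v.in_target]

    def to_dataframe(self):
        import pandas as pd

        rows = []
        for v in self.variants:
            row = {
                "seq_name": v.seq_name,
                "position": v.position,
                "ref": v.ref_allele,
                "alt": v.alt_allele,
                "in_target": v.in_target,
                "region_class": v.region_class,
                "substitution_class": v.substitution_class,
            }
            for i, g in enumerate(v.genotypes):
                row[f"line_{i}"] = g
            rows.append(row)
        return pd.DataFrame(rows)


@dataclass
class ReadSet:
    """Simulated reads for one line.  ``origins`` records where each read
    was drawn from; it is truth metadata for tests and is never consulted
    by the pipeline."""

    ids: list[str]
    seqs: list[str]
    quals: list[str]
    chemistry: str
    paired: bool = False
    origins: list[tuple] = field(default_factory=list)

    @property
    def count(self) -> int:
        return len(self.seqs)

    @property
    def mean_length(self) -> float:
        return float(np.mean([len(s) for s in self.seqs])) if self.seqs else 0.0

    @property
    def mean_quality(self) -> float:
        if not self.quals:
            return 0.0
        tot = n = 0
        for q in self.quals:
            tot += sum(q.encode()) - 33 * len(q)
            n += len(q)
        return tot / n


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------


def build_ancestral_genome(config: SimulationConfig) -> GenomeBundle:
    """Random A-subgenome chromosomes with gene models occupying roughly
    ``gene_fraction`` of each chromosome.  Deterministic under the seed."""
    config.validate()
    if config.chrom_length < 1500:
        raise ValueError(
            "chrom_length too small to host a gene; use >= 1500 bp"
        )
    rng = np.random.default_rng([config.seed, _SEED_ANCESTRAL])
    bundle = GenomeBundle()
    for ci in range(1, config.n_chrom_per_subgenome + 1):
        name = f"A{ci}"
        arr = rng.choice(DNA_BYTES, size=config.chrom_length)
        bundle.sequences[name] = arr_to_seq(arr)
        bundle.gene_models.extend(_lay_out_genes(name, config, rng))
    bundle.validate()
    return bundle


def _lay_out_genes(seq_name: str, config: SimulationConfig, rng) -> list[GeneModel]:
    L = config.chrom_length
    genic_goal = int(L * config.gene_fraction)
    models: list[GeneModel] = []
    cursor = int(rng.integers(100, 800))
    genic = 0
    gi = 0
    while genic < genic_goal:
        glen = int(rng.integers(1200, 3200))
        if cursor + glen > L - 50:
            break
        gi += 1
        n_exon = int(rng.integers(2, 7))
        exons = _split_exons(cursor, cursor + glen, n_exon, rng)
        models.append(
            GeneModel(
                seq_name=seq_name,
                strand="+" if rng.random() < 0.5 else "-",
                gene_interval=(cursor, cursor + glen),
                exon_intervals=exons,
                gene_id=f"{seq_name}g{gi:04d}",
            )
        )
        genic += glen
        cursor += glen + int(rng.integers(200, 1400))
    return models


def _split_exons(g0: int, g1: int, n_exon: int, rng) -> list[Interval]:
    # partition the gene into 2*n_exon - 1 segments; even segments are exons
    n_seg = 2 * n_exon - 1
    w = rng.random(n_seg) + 0.25
    lens = np.maximum((w / w.sum() * (g1 - g0)).astype(int), 15)
    # fix rounding drift on the last segment
    lens[-1] += (g1 - g0) - lens.sum()
    if lens[-1] < 15:
        lens = np.full(n_seg, (g1 - g0) // n_seg)
        lens[-1] += (g1 - g0) - lens.sum()
    bounds = np.concatenate([[g0], g0 + np.cumsum(lens)])
    return [(int(bounds[i]), int(bounds[i + 1])) for i in range(0, n_seg, 2)]


def derive_homoeolog(
    bundle: GenomeBundle,
    identity: float,
    seed: int,
    tstv_ratio: float = 1.52,
) -> GenomeBundle:
    """Add C-subgenome copies of every A sequence with substitutions planted
    at rate ``1 - identity``; gene models carry over with identical
    coordinates.  Substitution positions are recorded on the bundle."""
    if not (0.5 < identity <= 1.0):
        raise ValueError("identity must be in (0.5, 1]")
    if any(name.startswith("C") for name in bundle.sequences):
        raise ValueError("bundle already contains C-subgenome sequences")
    rng = np.random.default_rng([seed, _SEED_HOMOEOLOG])
    ts_p = tstv_ratio / (1.0 + tstv_ratio)
    for name in sorted(bundle.sequences):
        arr = seq_to_arr(bundle.sequences[name]).copy()
        L = arr.size
        n_sub = rng.binomial(L, 1.0 - identity)
        pos = np.sort(rng.choice(L, size=n_sub, replace=False)) if n_sub else np.array([], int)
        for p in pos:
            old = chr(arr[p])
            if rng.random() < ts_p:
                new = _TRANSITION_OF[old]
            else:
                new = _TRANSVERSIONS_OF[old][int(rng.integers(2))]
            arr[p] = ord(new)
        cname = GenomeBundle.partner_name(name)
        bundle.sequences[cname] = arr_to_seq(arr)
        bundle.homoeolog_divergence[cname] = pos
    for gm in [g for g in bundle.gene_models if g.seq_name.startswith("A")]:
        bundle.gene_models.append(
            GeneModel(
                seq_name=GenomeBundle.partner_name(gm.seq_name),
                strand=gm.strand,
                gene_interval=gm.gene_interval,
                exon_intervals=list(gm.exon_intervals),
                gene_id=gm.gene_id.replace("A", "C", 1),
            )
        )
    bundle.validate()
    return bundle


def design_capture_targets(bundle: GenomeBundle, config: SimulationConfig) -> GenomeBundle:
    """Place merged capture-target intervals covering ``target_fraction`` of
    the genome, split ``design_a_fraction``:rest between the A and C
    subgenomes (the study's design was A-biased)."""
    config.validate()
    rng = np.random.default_rng([config.seed, _SEED_TARGETS])
    genome_bp = sum(bundle.seq_lengths.values())
    total_target = int(genome_bp * config.target_fraction)
    if total_target == 0:
        bundle.targets = []
        return bundle
    per_sub = {
        "A": int(total_target * config.design_a_fraction),
        "C": total_target - int(total_target * config.design_a_fraction),
    }
    targets: list[Target] = []
    for sub in ("A", "C"):
        names = sorted(n for n in bundle.sequences if n.startswith(sub))
        if not names or per_sub[sub] == 0:
            continue
        bp_per_chrom = per_sub[sub] // len(names)
        for name in names:
            L = len(bundle.sequences[name])
            n_iv = max(1, config.n_targets_per_chrom)
            iv_len = max(200, bp_per_chrom // n_iv)
            free = L - iv_len * n_iv
            if free <= n_iv:
                raise ValueError("target_fraction too large for chromosome length")
            gaps = np.sort(rng.choice(free, size=n_iv, replace=False))
            cursor = 0
            for j in range(n_iv):
                start = int(gaps[j]) + cursor
                targets.append(Target(name, start, start + iv_len, sub))
                cursor += iv_len
    bundle.targets = _merge_targets(targets)
    bundle.validate()
    return bundle


def _merge_targets(targets: list[Target]) -> list[Target]:
    out: list[Target] = []
    by_seq: dict[str, list[Target]] = {}
    for t in targets:
        by_seq.setdefault(t.seq_name, []).append(t)
    for name in sorted(by_seq):
        sub = by_seq[name][0].design_subgenome
        for a, b in merge_intervals((t.start, t.end) for t in by_seq[name]):
            out.append(Target(name, a, b, sub))
    return out


def plant_line_variants(bundle: GenomeBundle, config: SimulationConfig) -> TruthTable:
    """Plant biallelic SNPs: in-target density 1/``in_target_snp_spacing``,
    off-target density 1/``off_target_snp_spacing``, transition probability
    tstv/(1+tstv) with the four transition types equiprobable.  Each SNP is
    carried homozygous-alt by a random non-empty subset of lines; true
    heterozygotes appear only at ``het_rate`` (inbred default 0)."""
    config.validate()
    if min(config.in_target_snp_spacing, config.off_target_snp_spacing) < 10:
        raise ValueError("SNP spacing below 10 bp is unresolvable at read scale")
    rng = np.random.default_rng([config.seed, _SEED_VARIANTS])
    ts_p = config.tstv_ratio / (1.0 + config.tstv_ratio)
    index = bundle.annotation_index()
    variants: list[TruthVariant] = []
    for name in sorted(bundle.sequences):
        L = len(bundle.sequences[name])
        arr = seq_to_arr(bundle.sequences[name])
        enriched = bundle.enriched_intervals(name)
        off = complement_intervals(enriched, L)
        for ivs, spacing, flag in (
            (enriched, config.in_target_snp_spacing, True),
            (off, config.off_target_snp_spacing, False),
        ):
            bp = total_length(ivs)
            n = int(round(bp / spacing))
            if n == 0 or bp == 0:
                continue
            pool = np.concatenate([np.arange(a, b) for a, b in ivs])
            pos = np.sort(rng.choice(pool, size=n, replace=False))
            for p in pos:
                p = int(p)
                ref = chr(arr[p])
                if rng.random() < ts_p:
                    alt = _TRANSITION_OF[ref]
                else:
                    alt = _TRANSVERSIONS_OF[ref][int(rng.integers(2))]
                n_alt = int(rng.integers(1, config.n_lines + 1))
                carriers = rng.choice(config.n_lines, size=n_alt, replace=False)
                gts = ["ref/ref"] * config.n_lines
                for li in carriers:
                    if config.het_rate > 0 and rng.random() < config.het_rate:
                        gts[li] = "het"
                    else:
                        gts[li] = "alt/alt"
                variants.append(
                    TruthVariant(
                        seq_name=name,
                        position=p,
                        ref_allele=ref,
                        alt_allele=alt,
                        genotypes=gts,
                        in_target=flag,
                        region_class=index.classify(name, p),
                        substitution_class=(
                            "transition" if is_transition(ref, alt) else "transversion"
                        ),
                    )
                )
    return TruthTable(variants=variants, n_lines=config.n_lines)


def simulate_reads(
    bundle: GenomeBundle,
    truth: TruthTable,
    line_index: int,
    config: SimulationConfig,
) -> ReadSet:
    """Capture-enriched reads for one line: per-base expected depth
    ``target_depth`` inside the enriched region (targets plus their
    homoeologous mirrors), ``offtarget_depth`` elsewhere, with substitution
    errors at ``base_error_rate``."""
    config.validate()
    if line_index >= truth.n_lines:
        raise ValueError("line_index out of range")
    if config.target_depth <= 0 or config.offtarget_depth <= 0:
        raise ValueError("depths must be positive")
    rng = np.random.default_rng([config.seed, _SEED_READS + line_index])
    ids: list[str] = []
    seqs: list[str] = []
    quals: list[str] = []
    origins: list[tuple] = []
    serial = 0
    for name in sorted(bundle.sequences):
        arr = seq_to_arr(bundle.sequences[name]).copy()
        het_positions: list[tuple[int, int, int]] = []
        for v in truth.variants:
            if v.seq_name != name:
                continue
            g = v.genotypes[line_index]
            if g == "alt/alt":
                arr[v.position] = ord(v.alt_allele)
            elif g == "het":
                het_positions.append(
                    (v.position, ord(v.ref_allele), ord(v.alt_allele))
                )
        enriched = bundle.enriched_intervals(name)
        pieces = [(iv, config.target_depth) for iv in enriched]
        pieces += [
            (iv, config.offtarget_depth)
            for iv in complement_intervals(enriched, arr.size)
        ]
        for (a, b), depth in pieces:
            if config.chemistry == "long":
                serial = _emit_long(
                    arr, name, a, b, depth, config, rng, het_positions,
                    ids, seqs, quals, origins, line_index, serial,
                )
            else:
                serial = _emit_short_pairs(
                    arr, name, a, b, depth, config, rng, het_positions,
                    ids, seqs, quals, origins, line_index, serial,
                )
    return ReadSet(
        ids=ids,
        seqs=seqs,
        quals=quals,
        chemistry=config.chemistry,
        paired=(config.chemistry == "short"),
        origins=origins,
    )


def _apply_errors(read: np.ndarray, n_err: int, rng) -> np.ndarray:
    if n_err == 0:
        return read
    pos = rng.choice(read.size, size=min(n_err, read.size), replace=False)
    for p in pos:
        old = DNA.index(chr(read[p]))
        read[p] = ord(DNA[(old + 1 + int(rng.integers(3))) % 4])
    return read


def _apply_het(read: np.ndarray, start: int, het_positions, rng) -> None:
    for p, ref_b, alt_b in het_positions:
        off = p - start
        if 0 <= off < read.size:
            read[off] = alt_b if rng.random() < 0.5 else ref_b


def _emit_long(
    arr, name, a, b, depth, config, rng, het_positions,
    ids, seqs, quals, origins, line_index, serial,
) -> int:
    span = b - a
    mean_len = config.long_read_length_mean
    # start window is [a - L + 1, b): width span + L - 1, so dose reads to
    # give expected per-base depth ~`depth` across the whole interval
    n_reads = rng.poisson(depth * (span + mean_len - 1) / mean_len)
    if n_reads == 0:
        return serial
    lens = np.clip(
        rng.normal(mean_len, config.long_read_length_sd, size=n_reads).astype(int),
        60, None,
    )
    starts = rng.integers(max(0, a - mean_len + 1), b, size=n_reads)
    n_errs = rng.binomial(lens, config.base_error_rate)
    flips = rng.random(n_reads) < 0.5
    qchar = chr(33 + 33)
    for i in range(n_reads):
        s = int(starts[i])
        e = min(s + int(lens[i]), arr.size)
        if e - s < 60:
            continue
        read = arr[s:e].copy()
        _apply_het(read, s, het_positions, rng)
        read = _apply_errors(read, int(n_errs[i]), rng)
        strand = "-" if flips[i] else "+"
        if flips[i]:
            read = revcomp_arr(read)
        serial += 1
        ids.append(f"L{line_index}_r{serial}")
        seqs.append(arr_to_seq(read))
        quals.append(qchar * read.size)
        origins.append((name, s, e, strand))
    return serial


def _emit_short_pairs(
    arr, name, a, b, depth, config, rng, het_positions,
    ids, seqs, quals, origins, line_index, serial,
) -> int:
    span = b - a
    rl = config.short_read_length
    lo, hi = config.short_insert_range
    mean_insert = (lo + hi) / 2
    # each fragment contributes 2*rl sequenced bases; widen the dose for
    # the start window as in the long-read case
    n_frags = rng.poisson(depth * (span + mean_insert - 1) / (2 * rl))
    if n_frags == 0:
        return serial
    inserts = rng.integers(lo, hi + 1, size=n_frags)
    starts = rng.integers(max(0, a - int(np.mean(inserts)) + 1), b, size=n_frags)
    qchar = chr(33 + 40)
    for i in range(n_frags):
        s = int(starts[i])
        e = min(s + int(inserts[i]), arr.size)
        if e - s < rl:
            continue
        frag = arr[s:e]
        r1 = frag[:rl].copy()
        r2 = frag[-rl:].copy()
        _apply_het(r1, s, het_positions, rng)
        _apply_het(r2, e - rl, het_positions, rng)
        r1 = _apply_errors(r1, int(rng.binomial(rl, config.base_error_rate)), rng)
        r2 = _apply_errors(r2, int(rng.binomial(rl, config.base_error_rate)), rng)
        r2 = revcomp_arr(r2)
        serial += 1
        ids.append(f"L{line_index}_f{serial}/1")
        seqs.append(arr_to_seq(r1))
        quals.append(qchar * rl)
        origins.append((name, s, s + rl, "+"))
        ids.append(f"L{line_index}_f{serial}/2")
        seqs.append(arr_to_seq(r2))
        quals.append(qchar * rl)
        origins.append((name, e - rl, e, "-"))
    return serial


def simulate_world(config: SimulationConfig) -> tuple[GenomeBundle, TruthTable]:
    """Convenience: ancestral genome -> homoeolog -> targets -> truth."""
    bundle = build_ancestral_genome(config)
    derive_homoeolog(
        bundle, config.homoeolog_identity, config.seed, config.tstv_ratio
    )
    design_capture_targets(bundle, config)
    truth = plant_line_variants(bundle, config)
    return bundle, truth
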