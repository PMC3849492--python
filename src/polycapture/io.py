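"""Readers and writers for the standard formats the pipeline touches.

Conventions: FASTA/FASTQ/BED/SAM are 0-based half-open internally; GFF3 and
VCF are 1-based (GFF3 closed intervals) and converted at this boundary.
SAM and VCF output is deliberately minimal but valid — pysam can read both
back, which the tests rely on.
"""

from __future__ import annotations

import io as _io
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO

from .intervals import GeneModel
from .read_mapper import AlignmentRecord
from .synth_data import GenomeBundle, ReadSet, Target, TruthTable
from .variant_caller import RawSnp


# --- FASTA / FASTQ ---------------------------------------------------------

def write_fasta(sequences: dict[str, str], path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name in sequences:
            fh.write(f">{name}\n")
            seq = sequences[name]
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_fasta(path: str | Path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fastq(reads: ReadSet, path: str | Path) -> None:
    with open(path, "w") as fh:
        for rid, seq, qual in zip(reads.ids, reads.seqs, reads.quals):
            fh.write(f"@{rid}\n{seq}\n+\n{qual}\n")


def read_fastq(path: str | Path, chemistry: str = "long") -> ReadSet:
    ids, seqs, quals = [], [], []
    for rec in SeqIO.parse(str(path), "fastq"):
        ids.append(rec.id)
        seqs.append(str(rec.seq).upper())
        quals.append(
            "".join(chr(q + 33) for q in rec.letter_annotations["phred_quality"])
        )
    return ReadSet(ids=ids, seqs=seqs, quals=quals, chemistry=chemistry)


# --- BED -------------------------------------------------------------------

def write_bed(targets: Iterable[Target], path: str | Path) -> None:
    with open(path, "w") as fh:
        for t in targets:
            fh.write(f"{t.seq_name}\t{t.start}\t{t.end}\t{t.design_subgenome}\n")


def read_bed(path: str | Path) -> list[Target]:
    out = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            name = parts[3] if len(parts) > 3 else "."
            out.append(Target(parts[0], int(parts[1]), int(parts[2]), name))
    return out


def write_regions_bed(
    regions, path: str | Path
) -> None:
    """Orthologous regions as BED with a provenance name column."""
    with open(path, "w") as fh:
        for r in regions:
            a, b = r.subject_interval
            flag = "primary" if r.is_primary else "secondary"
            fh.write(
                f"{r.subject_name}\t{a}\t{b}\t"
                f"{r.capture_seq_name}|{flag}|cov={r.anchor_coverage:.3f}\t"
                f"{r.anchor_count}\t{r.strand}\n"
            )


# --- GFF3 ------------------------------------------------------------------

def write_gff3(models: Iterable[GeneModel], path: str | Path) -> None:
    """gene/CDS features; GFF3 is 1-based with closed intervals."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for gm in models:
            g0, g1 = gm.gene_interval
            gid = gm.gene_id or f"{gm.seq_name}:{g0}"
            fh.write(
                f"{gm.seq_name}\tpolycapture\tgene\t{g0 + 1}\t{g1}\t.\t"
                f"{gm.strand}\t.\tID={gid}\n"
            )
            for a, b in gm.exon_intervals:
                fh.write(
                    f"{gm.seq_name}\tpolycapture\tCDS\t{a + 1}\t{b}\t.\t"
                    f"{gm.strand}\t0\tParent={gid}\n"
                )


def read_gff3(path: str | Path) -> list[GeneModel]:
    """Parse gene/CDS features back into gene models, converting 1-based
    closed coordinates to 0-based half-open."""
    genes: dict[str, dict] = {}
    order: list[str] = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            f = line.rstrip("\n").split("\t")
            seq, ftype, start, end, strand, attrs = (
                f[0], f[2], int(f[3]), int(f[4]), f[6], f[8],
            )
            iv = (start - 1, end)  # 1-based closed -> 0-based half-open
            attr = dict(
                kv.split("=", 1) for kv in attrs.split(";") if "=" in kv
            )
            if ftype == "gene":
                gid = attr.get("ID", f"{seq}:{start}")
                genes[gid] = {
                    "seq": seq, "strand": strand, "gene": iv, "exons": [],
                }
                order.append(gid)
            elif ftype == "CDS":
                pid = attr.get("Parent")
                if pid in genes:
                    genes[pid]["exons"].append(iv)
    return [
        GeneModel(
            seq_name=g["seq"],
            strand=g["strand"],
            gene_interval=g["gene"],
            exon_intervals=g["exons"],
            gene_id=gid,
        )
        for gid, g in ((gid, genes[gid]) for gid in order)
    ]


# --- VCF -------------------------------------------------------------------

_GT_CODE = {"hom_ref": "0/0", "hom_alt": "1/1", "het": "0/1", "no_call": "./."}


def write_vcf(
    snps: Sequence[RawSnp],
    line_ids: Sequence[str],
    seq_lengths: dict[str, int],
    path: str | Path,
    classes: dict[tuple[str, int], str] | None = None,
) -> None:
    """Multi-sample VCF (1-based) with GT, DP, AD and a BIAS flag per
    sample; assay class, when supplied, as an INFO tag."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=polycapture\n")
        for name in sorted(seq_lengths):
            fh.write(f"##contig=<ID={name},length={seq_lengths[name]}>\n")
        fh.write('##INFO=<ID=ASSAY,Number=1,Type=String,Description="Assay suitability class">\n')
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">\n')
        fh.write('##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Ref,alt allele depths">\n')
        fh.write('##FORMAT=<ID=BI,Number=1,Type=Integer,Description="Allele-balance bias flag">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(line_ids)
            + "\n"
        )
        for s in sorted(snps, key=lambda x: (x.seq_name, x.position)):
            alts = sorted(s.alt_alleles)
            info = "."
            if classes is not None:
                cls = classes.get((s.seq_name, s.position))
                info = f"ASSAY={cls}" if cls else "."
            cols = [
                s.seq_name, str(s.position + 1), ".", s.ref_allele,
                ",".join(alts), ".", "PASS", info, "GT:DP:AD:BI",
            ]
            for lid in line_ids:
                c = s.calls.get(lid)
                if c is None:
                    cols.append("./.:0:0,0:0")
                    continue
                n_alt = (
                    int(round(c.alt_fraction * c.depth)) if c.alt_allele else 0
                )
                gt = _GT_CODE[c.genotype]
                if c.genotype in ("hom_alt", "het") and c.alt_allele in alts:
                    ai = alts.index(c.alt_allele) + 1
                    gt = gt.replace("1", str(ai))
                cols.append(f"{gt}:{c.depth}:{c.depth - n_alt},{n_alt}:{int(c.biased)}")
            fh.write("\t".join(cols) + "\n")


def write_truth_vcf(truth: TruthTable, bundle: GenomeBundle, path: str | Path) -> None:
    """Planted truth as a VCF-like table with per-line GT columns and
    region/substitution annotations in INFO."""
    line_ids = [f"line_{i}" for i in range(truth.n_lines)]
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=polycapture-truth\n")
        for name, L in sorted(bundle.seq_lengths.items()):
            fh.write(f"##contig=<ID={name},length={L}>\n")
        fh.write('##INFO=<ID=REGION,Number=1,Type=String,Description="CDS/intron/intergenic">\n')
        fh.write('##INFO=<ID=SUB,Number=1,Type=String,Description="transition/transversion">\n')
        fh.write('##INFO=<ID=TARGET,Number=0,Type=Flag,Description="In capture-enriched region">\n')
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(line_ids)
            + "\n"
        )
        code = {"ref/ref": "0/0", "alt/alt": "1/1", "het": "0/1"}
        for v in truth.variants:
            info = f"REGION={v.region_class};SUB={v.substitution_class}"
            if v.in_target:
                info += ";TARGET"
            fh.write(
                "\t".join(
                    [
                        v.seq_name, str(v.position + 1), ".", v.ref_allele,
                        v.alt_allele, ".", "PASS", info, "GT",
                    ]
                    + [code[g] for g in v.genotypes]
                )
                + "\n"
            )


# --- SAM -------------------------------------------------------------------

def write_sam(
    alignments: Sequence[AlignmentRecord],
    seq_lengths: dict[str, int],
    path: str | Path,
) -> None:
    """Minimal SAM: header plus mandatory fields; gapless CIGAR."""
    with open(path, "w") as fh:
        fh.write("@HD\tVN:1.6\tSO:unsorted\n")
        for name in sorted(seq_lengths):
            fh.write(f"@SQ\tSN:{name}\tLN:{seq_lengths[name]}\n")
        for a in alignments:
            flag = 16 if a.strand == "-" else 0
            seq = a.read_seq or "*"
            fh.write(
                f"{a.read_id}\t{flag}\t{a.seq_name}\t{a.start + 1}\t60\t"
                f"{a.read_length}M\t*\t0\t0\t{seq}\t*\n"
            )


def write_manifest(reference_sets, path: str | Path) -> None:
    """Reference-set manifest: label, sequence count, total bp."""
    with open(path, "w") as fh:
        fh.write("label\tn_sequences\ttotal_bp\n")
        for rs in reference_sets:
            total = sum(len(s) for s in rs.sequences.values())
            fh.write(f"{rs.label}\t{len(rs.sequences)}\t{total}\n")
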