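# polycapture

SNP discovery from targeted sequence-capture data in an allotetraploid
genome, as a tested, reusable Python pipeline.

Allopolyploid crops such as oilseed rape carry two homoeologous subgenomes
(A and C) that are ~94% identical on average. Resequencing capture-enriched
regions of such a genome and calling SNPs naively confounds true allelic
variation between lines with fixed differences between the subgenomes
(hemi-SNPs). `polycapture` implements the homoeolog-aware workflow that
resolves this:

1. **Staged mapping references** — for every capture-design sequence, the
   orthologous region in the complementary subgenome is located by
   unique-k-mer-seeded maximal exact matches (MUM-style anchors), filtered
   for repetitive placements and chained along alignment diagonals. Three
   reference sets are assembled: the capture design alone, the design plus
   extracted orthologues, and the full pseudomolecules.
2. **Unique-best read mapping at ≥98% identity** — reads are placed by
   k-mer seeding and gapless comparison; a read is kept only when exactly
   one placement attains the best identity ≥ 0.98, so reads from locally
   identical homoeologous stretches are dropped rather than misassigned.
   Mapping bookkeeping follows the RM / RMp (percent mapped, integer) /
   RMpi (percent increase over the previous reference, one decimal)
   conventions.
3. **Depth-thresholded genotype calling** — per-line pileups feed a
   binomial maximum-posterior caller over {hom_ref, het, hom_alt} with a
   symmetric base-error rate ε and uniform prior, gated at a minimum depth
   of 3 reads (long-read chemistry) or 8 (short-read chemistry):
   for ref/alt counts (n−k, k),
   L(hom_ref) ∝ ε^k (1−ε)^(n−k), L(het) ∝ 0.5^n, L(hom_alt) ∝ (1−ε)^k ε^(n−k).
   Homozygous calls with ≥10% conflicting reads and het calls with allele
   balance outside [0.2, 0.8] are flagged *biased*.
4. **Three-stage filtering funnel** — (i) drop multiallelic positions;
   (ii) drop positions with no clean homozygous-alt call (het/bias-only
   support, the co-assembly signature) or with a het proportion strictly
   over 0.2; (iii) drop positions whose flanks suit neither KASP (100 bp
   of sequence both sides) nor Infinium (60 bp free of other kept SNPs on
   at least one side) assay design.
5. **Characterization and reporting** — genic context (CDS / intron /
   intergenic) from GFF3 gene models, transition/transversion spectra
   (ts/tv), per-base capture-coverage enrichment (target vs non-target
   mean depth), SNP densities (bp per SNP), KASP validation-panel
   summaries (PA / PS / corrected PS) and Infinium cluster QC
   (AA θ ∈ [0, 0.2], BB θ ∈ [0.8, 1], AB frequency ≤ 0.15).

Because raw capture data at the original scale is not practical to ship,
the package includes a first-class synthetic generator
(`polycapture.synth_data`) that emulates the statistical structure the
analysis assumes — two subgenomes at 94% identity, capture targets with
~4-fold depth enrichment (77X vs 19.6X), a 10-line inbred panel with
planted biallelic SNPs every ~421.3 bp in-target / ~697.8 bp off-target
and a transition-biased spectrum (ts/tv 1.52) — with full ground truth,
so every stage is testable by parameter recovery.

## Worked example

`examples/` contains one short script per capability. Running
`python examples/05_characterize_coverage.py` (a 5-line panel on a
2 × 60 kb world) prints:

```
region breakdown of filtered SNPs:
  CDS           47  ts/tv=1.76
  intron        35  ts/tv=0.84
  intergenic   116  ts/tv=1.9
overall ts/tv 1.61 (planted 1.52); transition share 61.6%

mean depth: target 79.1X, non-target 23.1X, fold enrichment 3.43 (simulated 77X / 19.6X ~ 3.9)
filtered SNPs in target: 68/198 (34.3%)
SNP spacing: 423.4 bp in-target (planted 421.3), 701.6 bp off-target (planted 697.8)

recovery of planted in-target SNPs: 100.0% (68/68), genotype concordance 100.0%
```

Reading this: the funnel's surviving SNPs recover the planted in-target
density (423.4 vs 421.3 bp per SNP) and spectrum (ts/tv 1.61 vs 1.52 at
this panel size), the capture dose is recovered as a ~3.4–3.9-fold depth
enrichment, and every planted in-target SNP is found with the correct
per-line genotype — i.e. the pipeline measures back what the generator
planted.

The same flow is available from a shell:

```bash
polycapture run-all --seed 1 --outdir out/   # FASTA/GFF3/BED/VCF + report
polycapture simulate --seed 1 --outdir world/
polycapture filter --het-threshold 0.2
```

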