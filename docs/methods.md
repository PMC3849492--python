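# Methods

## The problem being modelled

An allotetraploid genome carries two homoeologous subgenomes (labelled A
and C here) whose sequences are on average ~94% identical. Capture
enrichment pulls down both homoeologous copies of every targeted region,
so reads must be assigned to the correct subgenome before line-to-line
SNPs can be separated from fixed inter-subgenome differences
(hemi-SNPs). The package implements that assignment (unique-best mapping
at a high identity floor against staged references), a depth-gated
genotype caller, and the downstream filtering/characterization, and pairs
them with a synthetic world in which every quantity has a known planted
value.

## Synthetic world

`synth_data.SimulationConfig` defaults are the study conditions and are
treated as fixed:

| parameter | default | meaning |
|---|---|---|
| `n_chrom_per_subgenome`, `chrom_length` | 1, 250 000 bp | one 250 kb chromosome per subgenome (500 kb genome) |
| `homoeolog_identity` | 0.94 | per-base substitution identity between A and C copies |
| `n_lines` | 10 | inbred panel size |
| `target_fraction` | 0.12 | fraction of the genome covered by designed capture targets |
| `design_a_fraction` | 0.757 | share of target bp designed from the A subgenome |
| `in/off_target_snp_spacing` | 421.3 / 697.8 bp | planted SNP density inside/outside the enriched region |
| `tstv_ratio` | 1.52 | planted transition:transversion ratio (four transition types equiprobable) |
| `target_depth`, `offtarget_depth` | 77, 19.6 | expected per-base read depth in/outside the enriched region |
| `chemistry` | `long` | ~N(350, 30) bp single reads; `short` gives 54 bp pairs, insert 130–180 bp |
| `base_error_rate` | 0.005 | per-base substitution error |
| `gene_fraction` | 0.4 | genic fraction of each chromosome (genes 1.2–3.2 kb, 2–6 CDS exons) |
| `het_rate` | 0.0 | inbred lines: planted genotypes are homozygous by default |

Design choices worth knowing:

* **Substitution-only divergence.** Homoeologs and sequencing errors
  introduce no indels, so coordinates are shared between the A and C
  copies of a chromosome; the mirrored interval on the partner chromosome
  is the ground-truth orthologue, and alignments are gapless. This is
  what makes truth evaluation exact; it is also why the mapper needs no
  gap model.
* **Enriched region = targets ∪ mirrored targets.** Capture cannot
  distinguish homoeologs, so the read-depth dose and the "in-target"
  truth flag use the union of each chromosome's own targets and the
  mirror of its partner's targets. With `target_fraction` 0.12 the
  enriched region is ~24% of the genome.
* **Deterministic planted counts.** Each region class receives
  `round(bp / spacing)` SNPs placed uniformly without replacement, so a
  density-recovery test at a 10% band is not dominated by Poisson noise
  in the planted count itself. Per-SNP alt-carrier subsets are uniform
  over non-empty line subsets.
* **Read dosing.** Reads for an interval `[a, b)` start uniformly in
  `[a − L + 1, b)` with a Poisson count of mean
  `depth · (b − a + L − 1) / L`, which gives flat expected depth `depth`
  across the interval with linear shoulders outside it — the shoulder
  bases are deliberately left in the neighbouring regime's account, as a
  capture experiment would show.
* **One RNG stream per operation** (`seed` combined with a per-stage
  offset), so a stage can be regenerated without replaying the others.
* **454-style chemistry is "long single reads with substitution
  errors"**; homopolymer indel errors are out of scope because the
  pipeline under test calls SNPs only, at a 98% identity floor.

What the generator does *not* emulate: GC/probe-affinity bias, duplicate
reads, indel variation, structural rearrangements between subgenomes,
base-quality variation within reads, or residual heterozygosity beyond
the configurable `het_rate`. Passing recovery tests therefore shows the
pipeline's logic is correct under the stated statistical structure, not
that it is robust to artefacts absent from that structure.

## Orthologue discovery

`find_unique_anchors` seeds at k-mers (default k = 15) occurring exactly
once in the query and once in the subject (both strands counted
together) and extends each seed to a maximal exact match — MUM semantics
at desk scale. `filter_repetitive` drops anchors whose query span is
placed at more than 2 distinct subject loci (loci = subject spans
separated by > 1 kb). `chain_anchors` buckets anchors by alignment
diagonal (anti-diagonal on the minus strand, drift tolerance 100 bp) and
splits on query gaps > `max_gap` (default 5 kb); chance 15-mer matches
land off-diagonal and cannot stretch a region. Each chain reports the
subject interval from first to last anchor and its anchor coverage
(covered query bp / query length); the best-covered chain is flagged as
the orthologue and secondaries are retained above a coverage floor
(default 0.2), since the data motivating this design allowed several
orthologues per capture region. At identity 0.94 and k = 15 roughly
60–80% of a region is anchored, and the flagged interval overlaps the
true mirrored interval with Jaccard ≥ 0.8 (tested).

## Mapping and identity

Seeds: k = 17 for long reads, 13 for short, sampled at up to five
offsets per read and both orientations; k-mers with more than 32
reference hits are repeat-masked. Every candidate placement is scored by
gapless full-length comparison; identity = matching columns / read
length. A read is emitted only if exactly one placement attains the best
identity ≥ `min_identity` (default 0.98); ties are unmapped. A read
overhanging a reference sequence end has no valid placement there —
which is precisely why the capture-design reference set maps fewer reads
than the set with orthologues, and that set fewer than the
pseudomolecules (RMpi is positive for long reads by construction).
RMp is printed as an integer, RMpi to one decimal; both round half away
from zero (one shared helper, `decimal`-based so printed ties behave as
a reader expects).

## Genotype model

For a pileup column with ref count `n−k` and top-alt count `k`
(min column depth 3 long / 8 short, configurable), the caller maximises
the binomial likelihoods given in the README under a uniform prior.
Ties break toward hom_ref, then het. The *bias* flag operationalises the
otherwise undefined allele-balance notion: a called homozygote with
conflicting-read fraction ≥ 0.10 of total depth, or a called het with
ref/alt balance outside [0.2, 0.8]. Biased calls are flagged, never
dropped, at this stage — discarding is the funnel's decision. A
consequence of the uniform prior is that a single error read at depth
3–7 yields a het call; such positions enter the raw SNP table (their
exclusion downstream is observable in the funnel's het/bias stage, which
dominates the exclusions exactly as in the motivating analysis).
The fast multi-line path (`discover_snps`) prefilters candidate columns
with a vectorised replica of the caller's decision boundary and then
runs the scalar caller; equivalence with the plain column-wise route is
tested exactly, and the scalar caller is tested against an exhaustive
scipy-pmf oracle for every depth ≤ 12 split.

## Funnel semantics

* Stage order is fixed: multiallelic → het/bias → flanking. Total
  exclusion is order-invariant for the first two stages (tested); stage
  attribution is not.
* "Over a threshold (0.2)" is strict: a het proportion of exactly 0.2 is
  kept. The proportion's denominator is lines with calls (no_call
  carries no evidence).
* The het/bias stage excludes a SNP when no line carries a clean
  (unbiased) homozygous-alt call. Support consisting only of het or
  biased calls is the signature of homoeolog co-assembly or stray
  errors, not of an allelic difference between inbred lines.
* The Infinium SNP-free window consults the *kept* set at classification
  time (assay design would see the surviving SNPs); a config switch
  (`infinium_window_uses_kept`) exposes the alternative. The KASP rule
  checks sequence availability only, with inclusive 100 bp flanks.
* The funnel is idempotent on its own output (tested).

## Numerical and boundary conventions

* All internal coordinates are 0-based half-open; GFF3 (1-based closed)
  and VCF (1-based) are converted at the I/O boundary only.
* A SNP on a gene-boundary base belongs to the gene; CDS beats intron
  beats intergenic across overlapping gene models; strand is ignored for
  region classification.
* Substitution types are the 12 ordered ref→alt labels (4 transitions, 8
  transversions); ts/tv ratios print to 2 decimals, shares to 1,
  validation percentages to integers, all half-away-from-zero.
* ts/tv with zero transversions is reported as undefined (None), not an
  error; zero SNPs in a density region is infinite spacing.
* Infinium θ thresholds are inclusive at both ends; records with missing
  θ (no clusters formed) classify as `fail`.
* An empty called-line vector at the het/bias stage is excluded by
  convention.

## Problem sizes used by the test suite and acceptance script

The end-to-end property run uses the full default world: 10 lines on a
500 kb genome at the 77X/19.6X dose (~38 000 long reads per line,
~830 planted SNPs), run once per session; it completes in well under a
minute. Unit and fixture tests use 5–100 kb worlds. The staged-reference
mapping audit (RM on capture-design vs with-orthologues vs
pseudomolecules) runs on the first line's reads; `reference_comparison`
widens it to all lines when desired.

## Known limitations

* The mapper is gapless by design and unsuitable for data with indels.
* Repeat handling is k-mer masking plus the unique-best rule; no
  mapping-quality model.
* The caller assumes diploid genotypes per subgenome position and does
  not model polyploid dosage.
* Coverage shoulders at enriched-interval edges slightly lift off-target
  depth, so the measured enrichment fold (~3.7–3.9) sits a little below
  the raw dose ratio 77/19.6 ≈ 3.93, as it would in a real experiment.
* `summarize_kaspar` recomputes all percentages from the category
  counts; a published table whose percentage disagrees with its own
  counts will not be reproduced verbatim.
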