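# Methods notes

This note records the models, conventions, numerical choices and known
limitations behind `spotvar`, in the order the pipeline runs.

## Allele counting from a tagged alignment

The canonical workflow splits the array's single BAM into one file per
spot and pileups each; `spotvar` instead fetches reads overlapping each
variant site once and routes them to spots by the barcode tag (`CB` by
default). The two paths give identical counts — an equivalence the test
suite asserts on simulated BAMs — and `split_by_barcode` is retained for
compatibility with per-spot tooling.

Read filters and their defaults:

* `min_base_quality = 13` (phred). The classic samtools-pileup default;
  applied to the base covering the site.
* `min_mapping_quality = 0`. Off by default; 3' tag libraries map
  unevenly and a MAPQ floor is a deliberate opt-in.
* `max_mismatch_fraction = 0.1`. NM edit distance over aligned length;
  reads riddled with mismatches are mapping artifacts. Reads lacking an
  NM tag are kept with a warning rather than silently dropped.
* `require_proper_orientation = True`. Paired reads must be proper
  pairs; single-end reads must align to the forward strand, since
  3'-capture libraries sequence the sense strand and an antisense read
  at a variant site is suspect. This codifies, as an automatic filter,
  curation that is otherwise done by inspecting alignments by hand.
* `dedup_by_umi = False`. Pileup reads are counted, not UMIs, matching
  the upstream convention; UMI collapse is available as an option.

Deletions and reference skips spanning a site support neither allele;
they are excluded by default (`count_deletions_as_other` reports them in
the `other` column instead). "Other" bases (neither ref nor alt) are
always tallied separately and never enter allele-fraction denominators.

## Spot classification

Counts are summed over all somatic sites per spot (the map colors spots,
not sites; per-site resolution lives in the tiling matrix). Categories:
`mutant_ge2`, `mutant_1`, then `ref_5plus` … `ref_1`, `no_coverage`.
Mutant evidence always outranks reference evidence because a heterozygous
mutation yields wild-type reads from tumor cells; five or more reference
reads without any mutant read is the threshold at which a spot is called
tumor-unlikely.

"Detected" mutation, in the detection summary, defaults to *any* read
covering the site in at least one spot; a stricter mutant-read-only mode
is provided, since either reading of "detected" is defensible and the
two differ on sparse data.

## Diffusion QC

Spots are partitioned into non-tissue / benign-tissue / tumor-tissue
(off-tissue from the layout's tissue flag, the tumor mask supplied by the
user). The area attributed to a spot is, by default, the hexagonal
lattice unit cell at the 100 µm array pitch, √3/2 · (0.1 mm)² ≈
0.00866 mm² — the tissue area the spot tiles, which is the natural
denominator for a "spots per mm²" density. The 55 µm capture-disc area
(`spot_disc`) is selectable for readers who prefer the physical spot.
Densities carry exact (Garwood) Poisson 95% CIs: low =
χ²(α/2, 2k)/2/area (0 at k = 0), high = χ²(1−α/2, 2k+2)/2/area. The
printed fold between two densities is also reported rounded to the
nearest integer, as such contrasts are usually quoted.

## Copy-number inference

* **Log ratios.** Counts are scaled per spot to 10,000 (the standard
  library-size normalization target), a pseudocount of 1 is added, and
  each gene is centered on its median across spots. Genes detected in
  < 5% of spots, or missing from the annotation, are dropped.
* **Gene weights** = prior × stability × expression rank. The prior (in
  [0, 1], default 0.5 when no table is supplied) encodes how well the
  gene's expression tracks DNA copy number in external reference
  cohorts; stability is 1/(1+CV²) of scaled expression across spots;
  expression level enters as the gene's average rank mapped to (0, 1].
  The composition is a declared design choice: the three ingredients are
  standard, their exact combination is not canonical anywhere.
* **Weighted median.** The lower weighted median: after sorting by
  value, the smallest value whose cumulative weight reaches half the
  total. Fixing the convention matters for reproducibility; ties go to
  the first occurrence.
* **Arm signals.** Arms with fewer than 10 kept genes are excluded
  (sparse arms produce unstable medians); DNA-profile arms absent from
  the RNA signal contribute zero to the score rather than an error.
  Spots with zero total UMIs are all-missing, never zero — a zero is a
  claim of copy neutrality, which no data cannot support.
* **Low-coverage filter and rescue.** Spots with no UMIs on ≥ 2 arms are
  dropped, then greedily pooled: seed at the highest-UMI dropped spot
  (ties by barcode order), repeatedly absorb the highest-UMI adjacent
  (6-neighbour hex adjacency), same-cluster, still-ungrouped dropped
  neighbour until the pool exceeds 5000 UMIs; pools that never clear the
  threshold are discarded. The algorithm is greedy and deterministic;
  the constraints (adjacency, shared cluster, 5000-UMI target, typical
  group sizes of 2–10) are the method's, the tie-breaking is ours.
* **Re-centering.** Median-centering against the whole dataset splits a
  clonal CNA's amplitude between tumor and normal spots with opposite
  signs; subtracting the per-arm median of a user-chosen non-tumor
  reference pool (e.g. an immune cluster) restores zero at true copy
  neutral.
* **Similarity score and null.** Score = Σ weighted gains − Σ weighted
  losses with Wt = arm gene count / largest arm's gene count. The null
  permutes each spot's arm labels independently (missing arms stay
  missing), preserving the spot's value multiset while destroying its
  genomic arrangement; permutations are drawn uniformly and
  independently per replicate from a seeded generator, 100 per spot by
  default (a 100-fold inflated null).
* **q-values.** At a threshold s, FP = (#null ≥ s)/inflation and TP =
  #observed ≥ s, ties inclusive on both sides. A spot's q is the minimum
  FP/TP over thresholds at or below its score — the usual q-value
  monotonization, which guarantees higher score ⇒ lower q — capped at 1.
* **Categories.** q-cut bins (defaults 0.05 / 0.25 / 0.5 → likely /
  probable / possible / not-likely tumor) are configuration, not
  doctrine; the appropriate cuts depend on coverage.

When no DNA profile exists, scoring is impossible; the tool then orders
arm-signal rows by expression cluster and descending UMI count, the
layout used to read CNA structure off cohorts without matched DNA.

## Allelic imbalance

Filters (normal depth ≥ 10, VAF in [0.40, 0.60], population frequency
> 0.01, all inclusive at the boundary except the strictly-greater
frequency test) guard against homozygous or artifactual calls, either of
which fakes mono-allelic expression. A missing population-frequency
column is an error, never a silent pass. The major allele is the
tumor-DNA argmax; exact ties go to the reference allele and are flagged
`arbitrary` — the label is then just a record of sampling noise.
Mono-allelic flags use strict thresholds (coverage > 25, selected-allele
fraction > 0.9). Regional skew pools raw reads (not per-spot fractions)
across all covered SNPs of an arm or interval, with a Clopper–Pearson
CI. "Other" reads are reported but never filtered on — whether trace
third alleles should disqualify a measurement is left to the user.

Mapping-artifact warnings fire when a SNP's site coverage strictly
exceeds 50× the same gene's 3'-terminus coverage (in 3'-capture data the
site cannot legitimately dwarf the poly-A end) or when the gene belongs
to a user-supplied homology cluster. Warnings only; nothing is removed
automatically.

## Simulator

The generator emulates the data regimes the pipeline targets: a hex
lattice with the Visium row-parity convention and a non-tissue border; a
contiguous tumor region (default half the tissue); negative-binomial UMI
counts (dispersion 0.1 — mild overdispersion typical of spatial counts)
over eight arms of 40 genes with lognormal relative abundances; planted
log2 shifts of ±0.3 on four arms in tumor spots (an amplitude consistent
with single-copy events diluted by normal cells); 5000 mean UMIs per
spot, between the sparse (~1300) and deep (~15,000) regimes of real
fresh-frozen arrays; heterozygous somatic SNVs (tumor VAF 0.5, mean one
read per site per spot); germline SNPs with a 3:1 tumor haplotype skew;
and off-tissue background at 2% of tissue depth, representing mRNA
diffusion. An optional co-regulated gene block models a lineage-specific
expression cluster — a confounder, not a CNA.

Emitted BAMs realize a count table exactly: one 60 bp forward-strand
read per counted event, with barcode and UMI tags, correct NM values and
base quality 37, over a seed-derived toy reference written alongside.
Optional artifact reads each violate exactly one filter. What the
simulator does *not* model — realistic transcriptome structure, spatial
autocorrelation beyond the tumor mask, sequencing error beyond a flat
rate, soft-clipping, doublet spots — bounds what passing tests show: the
pipeline's arithmetic and statistics are correct under the stated
generative model, not that real-tissue sensitivity matches it.

## Problem sizes and determinism

Recovery checks use a 500-tissue-spot fixture (50% tumor, ±0.3 shifts,
≥ 5000 UMIs/spot), calibration a 144-spot null fixture, and the
permutation-size check a 1,384-spot matrix — sizes chosen so the full
suite and the acceptance script each run in seconds on one core while
keeping Monte-Carlo error well below the asserted margins. All
randomness flows from explicit seeds; two runs with the same
configuration and seed produce byte-identical outputs.

## Known limitations

SNVs only (no indels, no realignment); arm-level CNAs only (no sub-arm
segmentation or HMMs); no phasing or VDJ reconstruction; replicate
sections are analyzed per replicate and merged at the presentation
layer; the population-frequency check is an input column, not a live
lookup.
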