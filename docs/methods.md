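# Methods

This note records the models implemented in `mosaicevo`, the defaults and
why they were chosen, what the synthetic cohort does and does not emulate,
and the numerical conventions that make results reproducible.

## Editing-efficiency statistic

For each targeted gene, read pileups span a 50-bp window (51 positions,
offsets −25..+25) centered on the expected Cas9 cut site, in tumor and
matched normal. Each position contributes a 2×2 table (ref/alt × tumor/
normal). The statistic is the natural log of the closed-form sample odds
ratio, with a Haldane–Anscombe +0.5 added to all four cells whenever any
cell is zero; the two-sided Fisher exact p-value is computed and carried in
the result table but does not enter the score. The sample odds ratio (rather
than the conditional-MLE odds ratio underlying the exact test) keeps the
statistic deterministic, closed-form and defined for boundary tables.

Log odds ratios are z-transformed against the mean and **population
(n-denominator) standard deviation** of the same gene's window positions;
a zero-variance window maps to all-zero z. Because a gene's z scores
average to zero over the full window by construction, the per-gene summary
averages z only over the central offsets |offset| ≤ 2 bp — Cas9 cleaves
blunt ~3 bp upstream of the PAM and indels concentrate there — and the
sample score is the mean of those per-gene central means. The half-width
is configurable (`central_halfwidth`).

A targeted gene is called *altered* if ≥ 2 reads share the identical
base-alteration pattern at the cut site **or** region coverage falls below
50% of a healthy control's median. The clauses are combined with OR by
design: frameshift indels need not depress coverage, and homozygous
deletions leave no altered reads at all; the per-clause evidence is
recorded, and a strict-AND mode is exposed (`combine="and"`) for
sensitivity analysis.

## Somatic-variant filters

Two profiles. Murine: tumor depth strictly > 20×, normal depth strictly
> 10×, tumor VAF ≥ 0.1 (depth thresholds strict, the VAF floor inclusive).
MSK-style human: tumor depth ≥ 10×, ≥ 5 alt reads, tumor VAF ≥ 0.05,
matched-normal VAF < 0.07 (no normal-depth floor). VAFs are re-derived as
alt/depth from the supplied read counts; zero depth yields VAF 0 with an
explicit flag. Each rejected variant carries the first failing rule id, so
filtering is auditable and idempotent.

Indel calls are screened against their 20 downstream nucleotides: the call
fails if any motif of length 1–6 occurs as **three or more consecutive
tandem copies** entirely within the window — the standard microsatellite
false-positive rationale; `N` never
matches. A non-tandem "any 3 occurrences" mode exists behind a flag, noting
that for 1-mers it rejects nearly every window (pigeonhole) and is useful
only for sensitivity analysis. Variants overlapping any sgRNA-targeted
interval padded by 50 bp (BED, 0-based half-open; overlap against the
variant's reference span) are excluded as engineered drivers before any
evolutionary summary.

Mutational burden is kept exonic mutations divided by the callable target
span in Mb. Spectra map each SNV to the 96 pyrimidine-context classes
(purine-reference variants are reverse-complemented), deduplicate identical
(chrom, pos, ref, alt) entries across samples of the same mouse, and report
counts and frequencies per cohort plus a pooled `ALL` cohort.

## Karyotype profiling

Inputs are per-exon log2 tumor/normal read-depth ratios with weights.
Ratios are median-centered per sample (weighted median) before arm calling
so a genome-wide ploidy shift does not saturate every arm; no purity
correction is applied by default. The arm statistic is the weight-weighted
mean of exon log2 ratios, thresholded inclusively at ±0.2 — a
direct statistic in place of a broad-level GISTIC2 analysis at the same
threshold (GISTIC2's peak-significance machinery is out of scope). Focal regions are called only if *every* exon reaches
|log2| ≥ 0.4 with a consistent sign; mixed-sign regions are neutral, since
the all-exons rule presumes one coherent event.

Aneuploidy score is the count of arms called gained or lost. fCNA is
implemented arm-length-weighted — altered-arm length over total arm length,
the natural reading of "fraction of genome altered"; because several
aneuploidy-to-fCNA transformations circulate in the clinical-genomics
literature, the length-weighted definition is stated explicitly here and
an arm-count mode is provided for cross-checks. Ploidy selection restricts a cellularity–ploidy
probability grid to the cellularity nearest the external purity estimate
and takes the maximum-probability ploidy, ties resolving to the lowest
ploidy. WGD is called at ploidy ≥ 3.0; published WGD rules vary (some
condition on allele-specific copy state), so the cutoff is a documented
config knob.

Heterozygous SNPs require normal coverage ≥ 15× and strictly
0.2 < normal BAF < 0.8. Allelic imbalance of a segment is the mean mirrored
deviation |tumor BAF − 0.5|; 0 means balance, and a pure single-copy loss
drives it toward 0.5 as B-allele fractions split to 0 or 1.

Arm tables: mouse chromosomes are acrocentric, so the mm10 model has 19
single-"q"-arm autosomes; the GRCh37 model has the conventional 39
autosomal arms (centromere-split, acrocentric p arms excluded).

## Progression trees

The distance between two samples is 1 − |A∩B|/|A∪B| over their nondriver
somatic mutation keys (this shared-over-union similarity is sometimes
labelled a "hamming" similarity in the tumor-phylogeny literature; it is
the Jaccard similarity, and engineered driver mutations are excluded
upstream). Presence of a mutation in a sample means
≥ 2 supporting alt reads there (union re-genotyping), so a truncal
mutation narrowly missed by a caller in one sample is not spuriously
privatized. Two empty sets are at distance 0 by convention.

Agglomeration is complete linkage, implemented directly in O(n³) (n =
samples per mouse, always small) so tie-breaking can be deterministic:
among tied minimum-distance pairs, the pair whose sorted member tuple is
lexicographically smallest merges first. scipy's implementation serves as
an independent cross-check on tie-free matrices in the tests, alongside a
naive oracle with the same tie rule. Internal edges of length ≤ 1e-12
collapse into polytomies; leaves are never removed.

Each mutation is assigned to exactly one branch: the largest clade all of
whose descendant leaves carry it (a branch only counts mutations detected
in all of its descendants). Root branch = truncal, leaf branch = private, otherwise shared.
When a carrier set is not a clade of the tree, the mutation goes to the
largest clade fully contained in its carriers and the conflict is recorded
per mutation — how to place topology-conflicting mutations is a genuinely
open choice, and this rule is the package's explicit answer. Per site class (primary /
metastasis / cell-line), truncal/shared/private fractions are computed over
the union of that class's mutations and sum to 1; empty classes are
omitted.

Trees serialize to Newick with branch length = parent height − child
height; polytomies are emitted directly.

## Synthetic cohort generator

The generator emulates the cohort structure the pipeline is designed for:
`n_mice` animals, each with one matched normal and `samples_per_mouse`
tumor samples sharing a clone tree — a truncal trunk, optionally two
nested clades (`nested_clades`, for topology-recovery tests), and one
private branch per sample.

Models:

* **VAF**: a clonal heterozygous mutation with multiplicity m on tumor
  copy number C at purity p has expected VAF p·m/(2(1−p) + p·C); depth is
  Poisson around `mean_depth` (floored at 1), alt counts binomial. Normal
  samples carry a 0.001 alt-read error rate. Under WGD, truncal mutations
  predate the doubling (m = 2); private mutations stay at m = 1.
* **Exon log ratios**: per arm, `n_exons_per_arm` exons at
  log2((2(1−p) + p·C)/2) plus Gaussian noise `noise_sd_log2`.
* **BAF**: heterozygous SNPs at normal BAF 0.5; in the tumor the retained
  B-copy count b is drawn per SNP (which haplotype an event hits is
  random), giving ((1−p) + p·b)/(2(1−p) + p·C).
* **Cellularity–ploidy grid**: a Gaussian bump over a 0.05-step
  cellularity × 0.5-step ploidy lattice centered on the true (purity,
  length-weighted mean copy number), shaped like the output of
  allele-specific CNA fitters.
* **Cut-site pileups**: flat background alteration rate (default 0.002 per
  base, configurable — chosen so position 2×2 tables are non-degenerate)
  everywhere; the tumor adds editing at |offset| ≤ 2, i.e. central rate
  `editing_rate + (1 − editing_rate)·background`.
* **Trinucleotide classes** are drawn from `signature_mix`; half of the
  simulated SNVs are reported on the purine strand to exercise
  normalization. Indel downstream 20-mers are uniform, with an optional
  forced-tandem fraction so the repeat screen has positive cases. Each
  targeted gene also receives a driver deletion at its cut site (removable
  by the sgRNA-region exclusion).

Defaults are fixed study conditions, not tuning knobs: purity 0.7 and mean
depth 80× (typical exome tumor material), 50 truncal + 20 private
mutations per sample (truncal-dominant clonal structure), 4 samples per
mouse, editing rate 0.5, arm events chr5 gain and chr12/chr16 loss (the
recurrent murine RCC events this pipeline is parameterized around), and an
aging-like default signature (60% C>T, CpG-weighted — spontaneous cytidine
deamination). The tumors' true purity distribution is not known
numerically, so purity is a free parameter with a realistic default.

All randomness flows from one seed through spawned numpy `SeedSequence`
substreams; a fixed config serializes byte-identically across runs.

What the generator does **not** emulate — and hence what passing tests do
not show about real data: read-level artifacts (mapping, strand bias,
FFPE damage), subclonal copy-number mosaicism within a sample, caller-
specific false-negative patterns, germline contamination beyond a flat
error rate, and non-uniform genomic mutation rates. Recovery results on
synthetic cohorts demonstrate correctness of the estimators under the
stated generative models, not robustness to those artifacts.

## Numerical conventions and problem sizes

Coordinates: variants 1-based (VCF), intervals 0-based half-open (BED/SEG);
overlap uses the variant's reference span. Zero-branch collapse tolerance
1e-12; spectrum frequencies sum to 1 within 1e-9; z-transform uses ddof=0.
Ties: lowest ploidy at equal grid probability; lexicographic smallest
member in agglomeration; first-listed rule id on multi-rule filter
failures.

The test suite and the acceptance script run on deliberately compact
problem sizes — 200-sample null calibrations, 20-replicate karyotype and
clade-recovery studies, 1,000–1,100-case oracle comparisons, 200 random
linkage matrices (n ≤ 8, a few label permutations each), cohorts of 1–3
mice — sizes at which the binomial/Gaussian standard errors quoted in the
tests are already decisive while the whole suite stays fast.

## Known limitations

* fCNA and WGD use explicit, documented definitions chosen from among the
  variants circulating in the literature (see above).
* The editing score's central-window averaging is a design decision:
  averaging z over a gene's whole window is ~0 by construction, so only
  the cut-site neighborhood enters the score.
* No purity correction of log ratios before arm calling; heavily impure
  samples compress toward 0 and lose sensitivity at the fixed ±0.2
  threshold (visible in the simulator by lowering `purity`).
* The grid-based ploidy call inherits whatever bias the upstream
  cellularity–ploidy fitter has; the simulator's grids are idealized.
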