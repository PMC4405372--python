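# Methods

This note documents the models, rules and numerical choices behind each
stage, what the synthetic data does and does not emulate, and the known
limitations.

## Synthetic study design

The generator (`diapipe.simulate`) is the package's source of inputs and of
ground truth. It emits, as a deterministic function of one seed:

* **Genomic references.** `n_scaffolds` scaffolds carrying `n_genes`
  non-overlapping gene models separated by 2.5 kb intergenic gaps. Each gene
  is a random in-frame CDS (ATG … stop, 600–1,800 bp by default) flanked by
  100–250 bp UTRs, split by 0–2 introns of 50–500 bp, placed on a random
  strand. Proteins are the in-frame translations; the protein reference
  plays the role of a non-redundant cross-species ortholog set.
* **Contig sets** per life stage (adult plus pre-adult stages; the adult
  stage carries every gene so full recovery is attainable). Texture planted
  per gene: full-length transcripts, pairs of overlapping fragments
  (80–150 bp overlaps), allelic near-duplicates (SNPs at rate 0.003, i.e.
  ≥ 99% identity, so the clustering threshold separates them from true
  paralogs), UTR-flank pieces placed within 1 kb of gene models, deep
  intergenic pieces, and two-gene chimeras at `chimera_rate` whose segments
  both exceed the 50 bp chimera-rule floor. Every contig carries a truth
  label.
* **Reads.** 16 libraries in the 2×2×4 photoperiod × blood-meal design.
  Per-gene fragment counts are negative binomial with variance
  μ + μ²·φ (φ = `nb_dispersion`, default 0.1 — a typical bulk RNA-seq
  value for outbred replicate cages; the study does not report one).
  Condition means carry planted log2 effects (default ±2 on 10% of genes per
  effect, 70% up-biased, mirroring the observed excess of up-regulation) on
  a lognormal baseline. Fragments are placed uniformly with normal insert
  sizes (203 ± 20 bp at 101 bp reads, the study's library geometry).
  `contamination_rate` of pairs are vector-derived or carry an exact 3'
  adapter read-through. Phred qualities follow a logistic decay from ~39
  toward ~22 crossing the phred-30 trimming threshold around cycle 85, so
  trimming typically keeps a 70–90 bp prefix.

Base-call errors are deliberately absent (sequencing error profiles are a
non-goal): qualities decay but bases stay correct, so mapping sensitivity
reflects the pipeline, not an error model. Consequences: the realized
top-95% identity cutoffs sit at 1.0 rather than the 70–75% seen on real
divergent data, and mapped fractions are near-total. Passing tests
demonstrate the rules and statistics are implemented correctly, not that
the pipeline is robust to real error processes, genomic repeats, or
cross-species divergence.

Determinism: every phase draws from `default_rng([seed, phase])`, and each
library from `default_rng([seed, 3, library_index])`, so stages and
libraries reproduce independently.

## Read cleaning

The contaminant rule is "any local alignment to a database sequence with
≥ 18 matching bases at ≥ 95% identity" (100% identity for adapters), with a
contaminated read removing its mate. Alignment scoring is unit
match/mismatch with gap −2. Because the rule is existential, testing only
the single optimal alignment under one scoring scheme can miss qualifying
alignments; the implementation therefore (a) reduces the adapter rule to
its exact equivalent — presence of a shared exact 18-mer — and (b) verifies
vector candidates from a lossless 10-mer seed index (any qualifying
alignment contains an exact 10-run) with an exact prefix-sum search over
all gap-free segments on the seed diagonal, falling back to full
Smith-Waterman (two scoring schemes) when a diagonal comes within 6 matches
of qualifying. Gapped contaminants weaker than that fallback trigger are
the one theoretical miss; the generator plants none.

Trimming keeps the longest contiguous run with phred strictly > 30 and
discards reads whose best run is ≤ 50 bp, both strict as printed; ties go
to the leftmost run.

Digital normalization uses an exact canonical-k-mer counter (k = 20,
cutoff 20): a read is kept iff the median abundance of its k-mers at
decision time is below the cutoff, and kept reads increment the counter.
Pairs are kept when either mate qualifies. Exact counting (not a sketch)
removes approximation error from tests; at desk scale memory is trivial.

## Consolidation

Clustering is greedy longest-first (ties by id) at ≥ 99% identity, with
identity computed globally over the alignable span of the shorter sequence
(edit-distance based, both strands) — the convention under which contained
fragments cluster with their parents. Merging repeatedly joins the longest
suffix–prefix or containment overlap with identity > 0.95 over ≥ 40 bp
(an explicit stand-in for an assembler's default), building a per-column
majority consensus with ties resolved from the longer parent; the merged
contig inherits the longer parent's id, which makes the operation
idempotent.

## Hybrid re-assembly and annotation

The protein path translates all six frames, prefilters candidates by two
shared exact 6-aa words, aligns locally with BLOSUM62 (open −11 / extend
−1), and converts scores to e-values with the standard gapped
Karlin–Altschul parameters (λ = 0.267, K = 0.041) over the actual database
size. Hits need e ≤ 1e-6; contigs group by best hit (lowest e, ties by
score then target id), merge within groups, are re-searched, and are kept
only if the best hit still names the group's reference at > 70% identity.

The chimera rule flags a contig when a non-primary hit extends > 50 bp
beyond the primary's query interval at identity > 0.8 × the primary's
identity (the relative reading; an absolute 80% floor is available as an
option). Secondary hits to the primary's own reference are ignored —
extra alignment to the same protein is extension, not chimerism. On the
genome path, where a contig gets only its best spliced alignment, the rule
is applied by re-aligning any > 50 bp unaligned tail and treating a strong
hit at a different locus as the secondary alignment.

The genome path assigns each contig its best scaffold by shared 15-mer
votes, then chains exact seeds colinearly, calling target-side gaps > 30 bp
introns, and rescoring the implied exon alignment by edit distance so
identity is exact rather than seed-derived. Retention keeps the top 95% of
contigs by percent identity — the cutoff is the nearest-rank 5th percentile,
recomputed per dataset and logged in the manifest (ties at the cutoff are
retained); it is an output, not a constant. Contigs merge by overlapping
genomic locus (minus-strand alignments are reverse-complemented first),
are re-verified against their locus, filtered again, chimera-checked, and
classified: overlapping a gene model → gene-model-annotated; within 1 kb of
a model with ≥ 90% of the contig aligned → UTR (distances strand-agnostic,
measured from the alignment interval to the nearer model boundary);
otherwise unannotated genomic.

Assembly statistics use the descending-cumulative-sum N50. Gene-model
accounting reports distinct models per path, their union and (by
inclusion–exclusion) intersection, and the union as a fraction of the
reference model count.

## Quantification

Counting units collapse unigenes that annotate to the same reference gene
(protein- or gene-model-annotated); UTR and unannotated contigs count as
themselves. Effective length is max(1, length − mean insert + 1). Pairs map
by exact 31-mer seeding at three offsets with mismatch-bounded
verification (≤ 2 by default) and must be concordant (opposite
orientations, implied insert within 50–600 bp). The EM assigns each
multi-mapping pair fractionally ∝ θ_u / effective_length_u over its
candidates, re-estimating θ from fractional counts to a 1e-8 max-change
tolerance (≤ 1,000 iterations), θ initialized uniform; expected counts are
conserved exactly and unique pairs are fixed points.

## Differential expression

TMM follows the standard recipe: reference library = upper-quartile CPM
closest to the mean; M-values weighted by inverse asymptotic binomial
variance; double trimming (30% per tail of M, 5% per tail of A); factors
rescaled to geometric mean 1. Log-CPM uses effective (TMM-scaled) library
sizes; the MDS transform uses prior count 0.5. The expression filter keeps
genes with log2 CPM ≥ 1 in ≥ 4 libraries (the smallest group size) — the
sensible reading of an ambiguously worded rule whose literal form discards
nearly everything (that form is available behind `literal=True`). The
filter's CPM carries **no** prior count: at desk-scale library sizes
(~2×10⁴ rather than ~10⁷) a 0.25 prior alone exceeds the threshold, and a
gene with zero counts everywhere must fail any expression floor.

Dispersion is estimated by conditional maximum likelihood on counts
linearly rescaled to the geometric-mean library size (a desk-scale
approximation to quantile adjustment; library sizes here vary by ~±15%,
where linear scaling and quantile mapping agree closely). The common value
maximizes the summed conditional log-likelihood over a dispersion grid
(81 points, 1e-6…5); per-gene values maximize the gene's own likelihood
plus 10 (prior weight) times the average, shrinking isolated genes toward
the common value.

The pairwise test conditions the NB group sums on their total (sums of n
iid NB(μ, φ) are NB(nμ, φ/n); group sums are rounded independently so the
test is exactly label-symmetric) and sums the probabilities of all splits
no more likely than the observed one — the minimum-likelihood two-sided
convention, which reduces to the exact binomial test in the Poisson limit.
log2 fold-changes use group means with a 0.125 prior count. The DE call is
|log2FC| > 0.5 with BH FDR < 0.05. The interaction is tested per gene by a
likelihood-ratio test between NB GLMs (log link, library-size offsets,
terms photoperiod + bloodmeal + interaction vs. without interaction) at the
gene's shrunk dispersion, fitted by IRLS via statsmodels; non-convergent
fits yield a missing p-value and a logged warning. Whether such interaction
p-values should be adjusted within a table or genome-wide is unspecified in
general; they are BH-adjusted across all tested genes here.

MDS is classical Torgerson scaling (double-centered squared Euclidean
distances over the 500 most variable genes, top-2 eigenvectors scaled by
√eigenvalue), with axis signs fixed so the largest-magnitude loading is
positive. Three points always embed their distances exactly in 2-D, which
the tests exploit as an oracle.

## Pathway statistics

Enrichment corrects for length bias: a monotone P(DE | length) is fitted by
isotonic regression on the binary DE flags, and the null distribution of
each pathway's DE count comes from resampling gene sets of the observed DE
size without replacement with inclusion probability ∝ the fitted weight
(exponential-race sampling, vectorized in chunks; default 100,000
resamples, seed-controlled). p = (exceedances + 1)/(resamples + 1). With
equal lengths this converges to the hypergeometric tail, which is the
test oracle. A pathway is enriched iff it has ≥ 5 DE members and BH
FDR < 0.05. Resampling (not a noncentral-hypergeometric approximation) was
chosen because it is independently verifiable against that oracle.

Fisher proportion comparisons are two-sided by the minimum-likelihood
convention (the default of the common statistical environments). Z-score
matrices standardize each gene row by its sample mean and SD, mapping
constant rows to zero so heat maps stay total; leaf orders come from
complete-linkage Euclidean clustering and are deterministic. Diapause
incidence is the plain ratio DI = embryonated-unhatched / (hatched +
embryonated-unhatched), an error on an empty clutch.

## Orchestration and problem sizes

`run_pipeline` executes cleaning → digital normalization → consolidation →
protein re-assembly → genome re-assembly → final assembly → quantification
→ DE → enrichment, recording every stage's parameters, counts and realized
data-dependent thresholds in a JSON-serializable manifest whose digest is
reproducible for a fixed configuration. De novo assembly proper is out of
scope; the generator's contig sets stand in for assembler output, and the
digital-normalization stage reports what it would pass to an assembler.
Inputs load from a directory of plain-text files (the generator's output
format) or are simulated in memory.

Problem sizes were chosen so the whole suite runs comfortably on one CPU:
the bundled study configuration is 200 genes on 4 scaffolds with 16
libraries of ~20,000 pairs (a full pipeline run takes ~2 minutes); unit
tests use 15–120 genes; statistical calibration tests use 2,000 genes.
The enrichment driver uses 100,000 resamples; the in-pipeline enrichment
default is 10,000.

## Known limitations

* No base-call errors, PCR duplicates, rRNA structure, or expression-level
  isoform diversity (counts are generated at the gene level; isoform-like
  variation exists only in the contig sets).
* The screen's gapped-alignment fallback is heuristic below its trigger
  threshold (exact for all gap-free contamination, which is all the
  generator plants).
* The spliced aligner assumes colinear, non-overlapping exon structure and
  is not splice-site aware.
* Dispersion shrinkage uses a fixed prior weight rather than an empirical
  Bayes fit of the prior degrees of freedom.
* The interaction GLM and the exact test use the same shrunk dispersions;
  no trended (mean-dependent) dispersion is fitted.
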