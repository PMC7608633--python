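# Methods

This note documents the models and procedures implemented in `toxy`, the
assumptions behind them, the choices made where the design was genuinely
open, and what the synthetic test-bed does and does not establish about
real data.

## The problem

Young Y chromosomes (neo-Ys) are repeat-rich but still carry functional
genes. In early embryos, zygotic transcription begins before
heterochromatin is fully established, so Y-linked TEs can be transiently
expressed — predominantly in males, since only males carry a Y. Detecting
and quantifying this requires: (1) TE expression estimates that are not
distorted by sex-chromosome dosage; (2) ChIP enrichment that is comparable
across libraries with different antibody pulldown efficiencies; (3)
interval statistics relating heterochromatin, genes and TE insertions on
the Y; (4) a caller for new (de novo) TE insertions from read-pair
evidence; and (5) count models that separate sequencing depth from
biological effects on insertion numbers.

## Expression quantification (`toxy.repeatquant`)

Raw counts are primary-alignment tallies per gene or per TE consensus
family. Normalization divides each library's counts by that library's
**median autosomal gene count** — the median is taken over autosomal genes
only, so that massive sex-chromosome expression differences (especially
from the Y) cannot shift the normalizer between sexes. One pseudocount is
then added to every normalized value before any log transform.

*Pseudocount scope.* The source procedure adds the pseudocount "to each
gene"; here it is added to every feature (genes and TEs), because TE
values are log-transformed downstream exactly as gene values are. A
`pseudocount_genes_only` flag restores the narrower behaviour.

*Copy-number normalization.* TE expression divided by the TE's normalized
DNA-seq abundance in the **matched sex** (mean over that sex's DNA
libraries). This cancels expression differences that merely reflect copy
number: a TE twice as abundant in the male genome and twice as expressed
in males has a copy-number-normalized sex fold of 1. DNA abundance of 0
yields a missing value, never 0 or infinity.

*Y-enriched classification.* A TE family is Y-enriched when its
male/female normalized DNA abundance ratio is **≥ 2** (boundary
inclusive; the threshold is a parameter). Zero female abundance with
positive male abundance classifies as Y-enriched with an infinite,
flagged ratio.

*Rank-sum tests.* Sex comparisons use the two-sided two-sample rank-sum
(Mann-Whitney/Wilcoxon) test with no multiple-testing correction,
matching the single-test-per-stage design. Implementation: exact
enumeration over all label assignments when C(n1+n2, n1) ≤ 20 000 (exact
enumeration handles ties, which the usual exact algorithms refuse);
otherwise the normal approximation with tie correction. Single-element
groups degrade gracefully to the two-point exact test (p = 1).

*Clustering.* Pearson correlation of log2 values between samples;
agglomerative clustering with complete linkage on 1 − r (linkage is
configurable; the source procedure does not state one). Leaf order is
deterministic.

## ChIP enrichment and spike-in normalization (`toxy.chipnorm`)

Window enrichment (default 50-kb windows):

```
(ChIP reads in window / median autosomal per-bp ChIP coverage)
--------------------------------------------------------------
(input reads in window / median autosomal per-bp input coverage)
```

Reads are assigned to windows by midpoint (no double counting at
boundaries). Windows with zero input reads are **missing**, not infinite.
The formula is invariant to uniform depth rescaling of either library.

Every library carries the same foreign-genome spike-in chromatin, so all
libraries' spike-in enrichment distributions estimate one common truth;
systematic differences between them are pulldown-efficiency artifacts.
The **reference** is the per-window mean of all libraries' spike tracks,
sorted into a distribution. Each library's spike values are
quantile-matched to the reference, defining a value→value correction that
is then applied to the library's sample windows.

*Interpolation (open point, decided).* Sample windows take values absent
from the spike distribution. The correction map interpolates linearly
between sorted (spike value, matched reference value) pairs and
extrapolates as a constant beyond the observed range. Tied spike values
receive the mean of their reference block, so equal inputs always receive
equal corrections and the map is monotone — sample rank order is
preserved, and at observed spike values the map reduces exactly to the
stated rule (a spike value of 1.5 corrected to 2 sends sample windows at
1.5 to 2).

## Interval analyses (`toxy.chromstruct`)

All coordinates are 0-based half-open; "overlap" is any-overlap on
half-open intervals. Window classes (all / overlapping a gene /
overlapping a zygotically expressed gene) are nested by construction and
compared pairwise by rank-sum tests. Meta-profiles take the **median**
per-bp enrichment at each position within ±5 kb of anchors; TSS profiles
are strand-oriented (negative positions are upstream of the gene), TE
profiles anchor at the unoriented midpoint. Anchors truncated by contig
ends contribute missing values, not zeros. Gene–TE distance is the gap in
bp between closest interval edges, 0 for any overlap; genes on TE-free
chromosomes have missing distance. Insertions near genes are counted once
per placement per family, with the ±5 kb boundary **inclusive** (distance
≤ 5000 qualifies). "Zygotically expressed" is an input flag on genes, not
derived from expression data. Every interval operation is tested against
a quadratic brute-force oracle.

## De novo insertion calling (`toxy.tecaller`)

Reads are treated as single ends against (a) the repeat-masked genome and
(b) the TE consensus library. A **junction pair** has one read mapping
uniquely to the genome (operationalized as mapping quality ≥ 30 and a
single record for the read — the source procedure never defines
"uniquely") and a mate with TE-library records and no genome record. No
orientation is imposed on the TE-side mate, since TEs insert in either
direction.

Genome-side reads of one orientation within < 100 bp chain into a
**junction cluster** (single linkage; the pairwise "< 100 bp of each
other" rule is ambiguous for chains, and transitive chaining is its
natural clustering reading). The cluster's representative position is its
innermost mapped base toward the presumed insertion point: last base of
the rightmost forward read, first base of the leftmost reverse read.

An **insertion call** requires both junctions: a forward (5′) cluster
followed by a reverse (3′) cluster less than 100 bp downstream, of the
same TE family (cross-family pairing available by flag). Candidate
pairings resolve greedily one-to-one by nearest distance, then higher
support, then leftmost position. This dual-junction gate is what defeats
chimeric library artifacts, which produce single junctions at random
positions; it also structurally ignores full-length germline TE copies,
whose two junctions lie a copy length apart.

The **novelty filter** removes, mutually, any call with another sample's
call strictly closer than 50 bp (same chromosome, 5′ positions). A single
mutual-proximity pass subsumes both "found in more than one sample" and
the "< 50 bp" wording. The **exon control** reruns the identical pipeline
with exon sequences in place of the TE library; since real insertions
cannot implicate exons, its per-library call count estimates the
false-positive floor.

## Insertion-count models (`toxy.insertstats`)

The ANOVA `insertions ~ coverage + sex + stage` is **sequential (type I)
in that term order**, with stage categorical by default (ordinal by
flag). The implementation builds the design matrix explicitly and
computes each term's sum of squares as the drop in residual sum of
squares when the term enters, with F against the full model's residual
mean square — verified identical to R's `aov`. (The statsmodels formula
interface reorders terms, which silently changes type-I attributions;
hence the explicit construction.) Collinear designs — e.g. sex aliased
with stage — are rejected with an error naming the terms.

Depth removal for residual comparisons regresses counts on coverage (OLS
with intercept); residuals are compared male vs female within each stage
by rank-sum tests.

Chromosomal expectations distribute the observed genome-wide total in
proportion to chromosome length × sex-specific diploid copy number
(female: autosome 2, X 2, Y 0; male: autosome 2, X 1, Y 1; configurable
for neo-sex karyotypes), rounded by **largest remainder** so expectations
sum exactly to the observed total. Each chromosome is tested by a 2×2
Fisher's exact test of (on vs off chromosome) × (observed vs expected).
This construction is valid but **conservative**: the expectation margin
carries no sampling variance, yet the test budgets for two random
margins, so its null rejection rate is far below nominal (measured
≈ 0.004 at α = 0.05). The exact binomial alternative
(`method="binomial"`), testing the observed on-chromosome count against
its expected proportion, is the correctly calibrated version (measured
≈ 0.04) and is reported alongside.

## Synthetic data (`toxy.synthdata`)

The generator emulates the study's data classes with known truth:
uniform-random chromosome sequences with TE consensus copies planted
disjointly at per-chromosome densities (the default architecture gives
the Y four times the autosomal repeat density), genes with a zygotic
flag, and optional per-copy divergence. One RNG seed governs everything;
identical spec + seed reproduces byte-identical output.

*Reads.* Fragment lengths are Gaussian (default 350 ± 30 bp, configurable
— the real libraries' insert distribution is not stated anywhere);
fragments yield a forward read at the start and a reverse read at the
end. Reads are emitted directly as alignment records derived from
simulation coordinates (unique genome / TE-library-only / ambiguous at
masked boundaries / unmapped across junctions), so the caller is testable
without an external aligner; FASTQ emission reconstructs the actual
sequences for end-to-end runs.

*Cell fraction.* Somatic mosaicism is simulated at the fragment level: a
reference fragment spanning a planted insertion point is replaced, with
probability equal to the cell fraction, by a fragment from the
insertion-bearing haplotype; haplotype fragments are drawn at rate
depth · cf · (L + insert − 1)/(2 · read length) uniformly over all starts
overlapping the inserted TE, which reproduces uniform physical coverage
across the inserted sequence and both junctions. Consequence: the
pair-count conservation rule (pairs = ⌈depth · G/(2 · read len)⌉) holds
exactly for non-carrier libraries; carriers gain fragments in proportion
to their inserted base pairs, as a real carrier genome would.

*RNA counts.* Negative-binomial (gamma–Poisson) counts with per-feature
log-normal baselines. Pre-transition stages draw from a sex-independent
maternal pool; at and after the transition stage (default 5), zygotic
genes switch on and male samples multiply Y-linked TE means by the fold
effect. Dispersion 0 returns the means themselves (a deterministic
diagnostic mode).

*ChIP reads.* Input reads fall uniformly over sample + spike contigs
(spike fraction default 0.2, the wet-lab mixing ratio); ChIP reads are
drawn per window in proportion to a monotone distortion of the true
enrichment. The spike genome's landscape is fixed across libraries —
the premise of spike-in normalization.

What the generator does **not** model: sequencing errors and quality
scores, polymorphism, GC and mappability bias, germline-vs-somatic
lineage structure, fragment-size dependence on chromatin state.
Consequently, passing tests establish the correctness of the algorithms
and their statistical behaviour under idealized mapping, not robustness
to alignment artifacts on real libraries.

## Validation experiments (`toxy.benchmarks`)

Problem sizes are fixed at desk scale: a 2-Mb genome at 30× for caller
recovery (≈ 300 k read pairs), 1 Mb at 20× for chimera robustness, four
samples for the novelty filter, 200 spike + 400 sample windows for
normalization agreement, 300 TEs × 3 replicates/group for fold recovery,
1000 replicates for test calibrations, 500 simulations × 120 libraries
for model recovery. Two calibration experiments isolate the statistic
under test:

- The rank-sum **type-I calibration** uses iid per-TE baselines and the
  exact (simulation-true) normalizer. Shared per-TE baselines between the
  sex vectors make the test conservative (dependent units), while a
  normalizer *estimated* from a small gene set adds a coherent scale
  shift across all TEs that a test whose units are TEs correctly reads as
  a group difference (measured type-I 0.40 with a 100-gene normalizer).
  Neither effect is a property of the test itself. The fold-recovery
  experiment, which targets the median estimate rather than test size,
  uses a 1000-gene annotation so normalizer noise is negligible.
- Coefficient recovery counts, per coefficient, how often the estimate
  lies within 2 estimated standard errors of truth; the theoretical
  coverage of ±2 SE is ≈ 95.5%, so rates hover just above 95% by design.

## Known limitations

- The caller uses read-pair evidence only; split-read (clipped-base)
  evidence, insertion zygosity and excision detection are out of scope.
- TE family assignment takes the mate's first TE-library record;
  cross-family mapping ambiguity within the library is not modelled.
- Per-bp enrichment tracks are held densely in memory per chromosome —
  appropriate for the multi-Mb genomes simulated here, not for whole
  mammalian genomes.
- The exact rank-sum enumerator is O(C(n1+n2, n1)) and intentionally
  capped; beyond the cap the asymptotic approximation is used.
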