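# Methods

This note documents the models, parameter choices, numerical decisions,
and known limitations of circscape. It states no empirical result that
the test suite or `scripts/acceptance.py` does not itself compute.

## Coordinates and data model

All internal coordinates are 0-based half-open on named contigs. GFF3
I/O converts to/from the 1-based closed convention; BED output stays
0-based. A BSJ candidate is (contig, acceptor, donor, strand) with
acceptor < donor; the acceptor is the 5′-most genomic coordinate and
the donor the exclusive 3′ end, so the junction interval is
[acceptor, donor). Gene models are genes → transcripts → exons with
introns derived as the gaps between consecutive exons; zero-length gaps
(abutting exons) are dropped as annotation artifacts. The exon count
reported per gene is the maximum over isoforms, the isoform count the
number of annotated transcripts — one number per gene, stable under
partial annotations. Gene-overlap queries are strand-agnostic by
default (with an opt-in strand-matched mode) because strandedness of
BSJ-to-gene assignment is ambiguous in practice; contigs without genes
(unanchored scaffolds, organelles) can be registered so queries on them
return the empty set.

## Filtering

Retention uses strict inequalities — score > 0.1 for RNase R-treated
libraries, > 0.9 for controls — and a maximum junction span of 100 kb
(default, configurable) to exclude trans-like "ultra-long"
circularization artifacts; 100 kb keeps any realistic gene-scale circle.
A junction is *intragenic* only when a single gene's interval contains
both endpoints: a junction spanning two distinct genes is not a
canonical back-splice. Retained candidates from the two library types
are unioned (each merged circRNA records which libraries support it);
an intersection mode is available through `require_intragenic` plus
caller-side filtering of the `libraries` field. Condition-specific
detection is presence of ≥ 1 retained candidate in that condition; a
minimum-read floor is available. The CLR contrast between library types
is tested two ways: Fisher's exact test on the 2×2 of library type ×
(CLR above/below 0.5) and a two-sided rank-sum test on the raw ratios.

## Structural classification

A circRNA is multi-/single-exonic when its acceptor matches an exon
start and its donor a not-earlier exon end of the same transcript
within a boundary tolerance (default 0 nt exact; ±2 nt available for
noisy junctions); intronic when the junction lies inside one intron
(containment, since exact intron-boundary matching is not required of
intron-derived circles); otherwise unclassified — a value, not an
error. When several transcripts match, the one spanning the fewest
exons wins, ties broken by transcript id, so assignment is
deterministic. Spliced length is the summed length of spanned exons
(exonic) or the genomic span (intronic).

## Biogenesis features

Flanking introns are the introns immediately upstream of the acceptor
and downstream of the donor in the matched transcript; internal introns
lie between spanned exons. Genome-wide introns are counted once per
unique genomic interval so multi-isoform genes are not over-weighted.
ICS detection is a local alignment of the upstream intron against the
reverse complement of the downstream intron with match +1, mismatch −1,
gap −2 (Smith–Waterman optimum computed by Biopython's PairwiseAligner);
a match is reported when it reaches 10 aligned columns at ≥ 0.8
identity (defaults). Ties between equal-scoring optima resolve to the
aligner's first (deterministic) alignment. Repeat density is a
self-contained proxy — the fraction of positions covered by a k-mer
(k = 13) occurring ≥ 2 times within the sequence — not a reimplementation
of a repeat-library annotator. The matched control comparison samples
internal exons (both flanking introns present) of non-host transcripts
without replacement under a caller-provided seed and reports a
two-sided rank-sum p per metric. Continuous comparisons use rank-sum
tests; proportion panels use Fisher's exact test.

## Conservation

The host-ortholog overlap statistic treats ortholog pairs as the
sampling universe: with N pairs, K having a circ-producing member in
species A, n in species B, and an observed overlap k,
p = P(X ≥ k), X ~ Hypergeometric(N, K, n). Splice sites are projected
through a global alignment of the two orthologs' spliced transcript
sequences (match +1, mismatch −1, gap open −5, extend −1); aligning
spliced rather than genomic sequences keeps the alignment quadratic in
kilobases, and exonic circRNA boundaries exist exactly in spliced
coordinates. A site aligning into a gap is unmappable and counts as not
conserved. A site is conserved when its projection lands within 10 nt
(default) of the partner circRNA's site; Accordant / Half-accordant /
Unaccordant means both / exactly one / neither. With several circRNAs
per gene pair, every A×B pair is classified and the most-conserved
category per A-circRNA is reported.

## Expression coupling

Normalization: RPM = count × 10⁶ / library size, RPKM = RPM × 10³ /
length. For correlations and fold changes the library sizes are
*effective* sizes — a trimmed-mean-of-ratios size factor (25 % trim per
side, geometric-mean reference) times the geometric-mean raw depth.
Plain total-count RPM has a compositional artifact: a minority of
strongly regulated features inflates the library sum of their samples
and thereby shifts every other feature's normalized value, which
systematically biases circ–host correlation estimates. Effective sizes
are how the field's count-based DE tools normalize, and the trimmed
mean is used rather than the plain median for its lower estimator
variance on matrices with a few hundred features.

The DE test is an exact conditional binomial: pooled treat counts *a*
vs pooled control counts *b*, with a | a+b ~ Binomial(a+b, p₀) under
the null, p₀ being the treat share of the effective library sizes;
two-sided p sums outcomes no more likely than the observed one, and
q-values are Benjamini–Hochberg. A feature is up/down iff q < 0.05 and
|log2FC| ≥ 1 (defaults), with log2FC computed on effective-RPM group
means with a 1-RPM pseudocount — exactly antisymmetric under group
exchange. The test is dispersion-free and therefore anti-conservative
under biological overdispersion; a `dispersion` factor (> 1 deflates
counts before testing) is provided as a crude guard, and the fold-change
floor is what keeps overdispersed null features out of the called sets.
Correlations use all samples on the effective-RPM scale; zero-variance
features yield a missing correlation, never 0. The joint pattern of a
pair is Reversed / Coordinated when both members are DE in opposite /
the same directions, HostStable / CircStable when only the circRNA /
only the host is DE, NS otherwise.

## ceRNA network

One penalty scorer replaces consensus over three external target
predictors: the target window is aligned against the reverse complement
of the miRNA charging 1 per mismatch, 0.5 per G:U wobble, 2 per gap,
doubled at miRNA positions 2–13 (plant-style expectation scoring); the
thermodynamic filter is approximated by the penalty cutoff, with no
folding computation. Three stringency profiles (cutoffs 0 / 2.5 / 5.0)
preserve the intersection-of-three logic: an interaction is retained
only when found under every profile. Scanning slides windows of miRNA
length; circRNA targets are rotated (sequence + first L−1 nt) so
junction-spanning sites — the circRNA-specific ones — are scannable.
Overlapping candidate sites are resolved greedily by ascending penalty.
The batch scanner prunes windows whose running DP row minimum exceeds
the cutoff; since every DP step cost is non-negative this pruning is
exact, and all penalties are dyadic rationals so float32 arithmetic is
lossless. Networks are tripartite by construction (edges only touch
miRNAs); hub ranking ties break on miRNA id; sponge consistency is the
fraction of circRNA partners up-regulated and mRNA targets
down-regulated, with a zero-denominator flag when no partners carry DE
states.

## Organellar analysis

The chloroplast share is reported both as a read fraction and as a
unique-junction fraction per library type, since "share of the circRNA
pool" can be counted either way. The 3′-terminal window defaults to
20 % of the gene length (absolute override available), strand-aware.
Clustering is tested by permutation: both endpoints of each distinct
junction are points (single-endpoint modes available); the null places
the same number of points uniformly in the gene;
p = (1 + #{null fraction ≥ observed}) / (n_perm + 1) — never exactly 0,
reproducible under the seed.

## Synthetic data: what it emulates, and what it does not

The generator builds a toy nuclear genome of 360 genes on 3 contigs:
60 circRNA hosts (6–12 exons, introns 500–1000 bp, 2–4 isoforms) and
300 non-hosts (2–4 exons, introns 80–200 bp, single isoform), exons
80–300 bp — the host/non-host asymmetries are the biogenesis
propensities the analysis stages measure. It plants 60 circRNAs
(20 multi-exonic, 20 single-exonic, 20 intronic, one per host, placed
so both flanking introns exist), 40 artifact junctions (half with at
least one intergenic endpoint) and 3 ultra-long artifacts on a
dedicated 152-kb scaffold. Reliability scores are Beta-shaped:
true candidates 0.15 + 0.85·Beta(8, 2) (always above the RNase R
threshold), artifacts 0.1·Beta(2, 8) in treated libraries and
0.9·Beta(2, 8) in controls (always below) — only the ordering relative
to the thresholds matters downstream. Libraries cover five conditions
(CK, cold, heat, salt, UV-B) × 2 replicates; each true circRNA is seen
in a condition with probability 0.4 and per replicate 0.7 (at least one
observation forced), with 1 + Poisson(1.2) junction reads, so a
realistic minority are single-read singletons. Linear reads at BSJ
sites are Poisson(0.5) in treated and Poisson(25) in control libraries,
producing the CLR contrast.

Expression: each circ–host pair shares a latent bivariate normal with
correlation ρ (default 0.34) on the log scale (sd 0.15), mean depth
5000, Poisson-sampled (a no-noise mode emits the latent means).
Condition effects of ±2 log2 units implement the planted DE plan —
cold: 3 sponge circRNAs up with stable hosts plus 5 reversed pairs;
UV-B: 3 coordinated pairs; salt: 2 circRNAs down; heat: 1 up — giving
the cold > UV-B > salt > heat response ordering and a Reversed-over-
Coordinated excess. The gene matrix contains every nuclear gene and the
circ matrix also carries the (stable, 10× deeper) chloroplast
circRNAs, so size-factor estimation has a realistic stable majority.
With log-sd 0.15 and depth 5000 the log-normal/Poisson distortion of
the count-scale Pearson correlation stays within the ±0.05 recovery
band across ρ ∈ [−0.8, 0.8].

miRNAs: 10 random 21-mers; each plants exact reverse-complement sites
in exonic circRNAs (2 each; the hub in 3) and non-host mRNAs (3 each;
the hub in 4), positions recorded in spliced coordinates. A site
planted in a circ-forming exon is necessarily also present in the host
mRNA — the emitted interaction counts reflect that. The ortholog
species copies host spliced sequences as single-exon genes; circRNA
splice sites are copied (Accordant), donor-shifted by 50 nt
(Half-accordant), or both-shifted (Unaccordant), 5/5/5 by default, plus
10 host-only and 15 non-host pairs for the overlap universe. The
chloroplast is a 4-kb contig with one intronless 1.2-kb psbA-like gene
carrying 24 clustered junctions whose endpoints all fall in the 20 %
3′ window; treated-library read counts (~40/sample) dominate the pool,
controls stay sparse.

What the generator does *not* emulate: read-level data (no FASTQ, no
alignment, no sequencing-error or RNase R efficiency model beyond score
separation), overdispersed counts (Poisson only), paralogy or multi-
mapping, isoform-level expression, real repeat families, or RNA
secondary structure. Passing tests therefore demonstrate the
correctness of the downstream logic under its stated assumptions — not
the upstream caller's behavior on real libraries, nor robustness to
overdispersion beyond what the fold-change floor provides.

## Problem sizes and determinism

Default analyses run on the 360-gene study: 60 + 24 planted junctions,
~300 candidate rows, 10 expression samples, 10 miRNAs, 40 ortholog
pairs, 10 000 permutations for the clustering test. Calibration checks
use 10 000 null features (DE) and 100 replicate datasets × 500
permutations (clustering). Every random stage derives its generator
from an explicit seed; two runs with the same configuration produce
byte-identical summary JSON, which the test suite asserts.

## Interfaces

The package is primarily a Python library; `examples/` holds one
narrative script per capability. The `circscape` CLI is a thin layer
with three subcommands (generate / run / summarize) — stage-by-stage
execution is the library API, which keeps the CLI surface small while
`run` executes all stages in dependency order and skips optional stages
whose inputs are absent.
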