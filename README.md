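# circscape

Characterization of a plant circular-RNA (circRNA) landscape from
back-splice junction (BSJ) calls: credibility filtering, structural
classification, biogenesis-feature statistics, cross-species splice-site
conservation, circRNA–host expression coupling, ceRNA (miRNA sponge)
network construction, and chloroplast locus-clustering analysis.

The package is aimed at plant transcriptomics analysts who already have
BSJ candidate tables from an upstream caller (with per-candidate
reliability scores), a genome + GFF3 annotation, expression count
matrices, and small-RNA annotations — and want a tested, reproducible
implementation of the downstream characterization, together with a
synthetic-data generator that plants ground truth for every stage so the
whole pipeline can be validated end to end without any external data.

## The model in brief

* **Filtering.** A candidate BSJ on contig *c* with acceptor *a* <
  donor *d* (0-based, half-open) is retained iff its reliability score
  *s* satisfies *s* > 0.1 in RNase R-treated libraries or *s* > 0.9 in
  untreated controls, and *d − a* ≤ 100 kb (ultra-long artifacts).
  Junctions are merged on the key (*c*, *a*, *d*, strand). The
  low-score bins are dominated by intergenic junctions — the
  credibility diagnostic behind the thresholds. Circular-to-linear
  ratio at a site: CLR = circ/(circ + linear).
* **Classification.** multi-exonic if *a* matches an exon start and *d*
  a later exon end of one transcript (≥ 2 exons spanned); single-exonic
  if the junction is one exon's boundaries; intronic if [*a*, *d*) lies
  inside one intron.
* **Biogenesis.** Flanking/internal/genome-wide intron-length classes;
  host vs non-host exon and isoform counts (rank-sum), per-bin
  circRNA-production propensity (Fisher exact); inverted complementary
  sequences (ICS) found by local alignment of the upstream intron
  against the reverse complement of the downstream intron (match +1,
  mismatch −1, gap −2); a k-mer coverage proxy for repeat density.
* **Conservation.** Host-ortholog overlap tested with the upper-tail
  hypergeometric P(X ≥ overlap); splice sites projected through a
  global alignment of ortholog transcript sequences and circRNA pairs
  labelled Accordant / Half-accordant / Unaccordant (both / one /
  neither site within 10 nt).
* **Coupling.** Pearson r between circRNA and host expression (RPM with
  effective, trimmed-mean-of-ratios library sizes); per-stress log2
  fold changes; an exact conditional binomial DE test with
  Benjamini–Hochberg correction; pattern calls Reversed / Coordinated /
  HostStable / CircStable from the joint DE states.
* **ceRNA network.** Plant-style target penalty (mismatch 1, G:U wobble
  0.5, gap 2; doubled in miRNA positions 2–13), one scorer under three
  stringency cutoffs (0 / 2.5 / 5.0) whose intersection defines the
  consensus interactions; tripartite circRNA–miRNA–mRNA graph, hub
  ranking, and sponge consistency (circ partners up, mRNA targets down).
* **Organellar.** Chloroplast share of BSJ reads per library type and a
  permutation test for clustering of BSJ endpoints in the 3′-terminal
  window of the psbA-like gene (p = (1 + #{null ≥ observed})/(n + 1)).

## Worked example

```bash
python examples/01_filter_bsj_candidates.py
```

prints, for the default synthetic study (seed 1):

```
retained 60 unique circRNAs (4 supported by a single read in a single sample)
condition-specific circRNAs: {'UVB': 5, 'cold': 6, 'heat': 9, 'salt': 8}
shared by all four stresses: 2
```

All 60 planted circRNAs are recovered (none of the 43 artifacts
survive), a few are singletons — rare junctions seen once in one
sample — and most circRNAs are condition-specific. The other examples
walk through classification and biogenesis features (`02`), expression
coupling — median circ–host Pearson r ≈ 0.33 against the planted 0.34
(`03`), the ceRNA network with its miR8633-like hub sponge (`04`), and
conservation plus chloroplast clustering (`05`).

The same workflow is available from the shell:

```bash
circscape generate --seed 1 --outdir inputs/
circscape run --indir inputs/ --outdir report/
circscape summarize report/
```

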