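"""Biogenesis-feature statistics for circRNA-producing loci.

Covers the intron-length class comparison (flanking vs circ-internal vs
genome-wide introns), host-gene exon/isoform propensities with exact and
rank-based tests, detection of inverted complementary sequences (ICS) in
flanking introns via local alignment against the reverse complement, a
self-contained k-mer repeat-density proxy, and the matched comparison of
circ flanks against randomly drawn linear-exon flanks.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from Bio import Align
from scipy import stats

from .annotate import CircClassification, _find_transcript
from .filtering import CircRNA
from .genome import AnnotationSet, GenomeSequence, VALID_BASES, reverse_complement


@dataclass
class IcsMatch:
    """Best inverted-complementary match between two flanking introns.

    Coordinates are 0-based offsets within the respective intron
    sequences as given (up in the upstream intron, down in the original
    orientation of the downstream intron)."""

    up_start: int
    up_end: int
    down_start: int
    down_end: int
    match_length: int
    identity: float
    score: float


# -- intron length classes --------------------------------------------------

def intron_length_classes(
    circs: list[CircRNA],
    classifications: dict[str, CircClassification],
    annotation: AnnotationSet,
) -> dict[str, list[int]]:
    """Lengths of flanking, circ-internal, and genome-wide introns.

    Flanking introns are the introns immediately upstream of the acceptor
    and downstream of the donor (when present in the matched transcript);
    internal introns sit between the spanned exons.  Intronic circRNAs
    have no exon span and contribute to neither circ class.
    """
    flanking: list[int] = []
    internal: list[int] = []
    for circ in circs:
        cls = classifications.get(circ.circ_id)
        if cls is None or cls.circ_type not in ("multi-exonic", "single-exonic"):
            continue
        tx = _find_transcript(annotation, cls.matched_transcript_id)
        introns = tx.introns
        if cls.first_exon >= 1:
            flanking.append(len(introns[cls.first_exon - 1]))
        if cls.last_exon < len(tx.exons) - 1:
            flanking.append(len(introns[cls.last_exon]))
        for i in range(cls.first_exon, cls.last_exon):
            internal.append(len(introns[i]))
    # genome-wide introns are counted once per unique genomic interval,
    # not once per isoform, so multi-isoform genes are not over-weighted
    genome_wide = [
        len(i)
        for i in {
            (iv.contig, iv.start, iv.end): iv
            for iv in annotation.all_introns()
        }.values()
    ]
    return {
        "flanking": flanking,
        "circ_internal": internal,
        "genome_wide": genome_wide,
    }


# -- host gene propensity ---------------------------------------------------

def host_feature_comparison(
    annotation: AnnotationSet, host_ids: set[str]
) -> dict:
    """Exon-count and isoform-count summaries, hosts vs non-hosts, with a
    two-sided rank-sum p-value per feature."""
    unknown = host_ids - {g.gene_id for g in annotation.genes}
    if unknown:
        raise ValueError(f"host ids absent from annotation: {sorted(unknown)[:5]}")
    hosts = [g for g in annotation.genes if g.gene_id in host_ids]
    others = [g for g in annotation.genes if g.gene_id not in host_ids]
    if not hosts or not others:
        raise ValueError("both host and non-host groups must be non-empty")
    out = {}
    for feature, fn in (
        ("exons", lambda g: g.n_exons_max),
        ("isoforms", lambda g: g.n_isoforms),
    ):
        hv = np.array([fn(g) for g in hosts], dtype=float)
        ov = np.array([fn(g) for g in others], dtype=float)
        if np.array_equal(np.sort(hv), np.sort(ov)):
            p = 1.0
        else:
            p = float(stats.mannwhitneyu(hv, ov, alternative="two-sided").pvalue)
        out[feature] = {
            "host_mean": float(hv.mean()),
            "host_median": float(np.median(hv)),
            "nonhost_mean": float(ov.mean()),
            "nonhost_median": float(np.median(ov)),
            "p_value": p,
        }
    return out


def propensity_by_bin(
    annotation: AnnotationSet,
    host_ids: set[str],
    feature: str = "exons",
    bin_edges: list[int] | None = None,
) -> list[dict]:
    """Fraction of genes producing circRNAs per exon-count (or
    isoform-count) bin; bins with no genes report an undefined fraction."""
    fn = (
        (lambda g: g.n_exons_max)
        if feature == "exons"
        else (lambda g: g.n_isoforms)
    )
    values = {g.gene_id: fn(g) for g in annotation.genes}
    if bin_edges is None:
        hi = max(values.values())
        bin_edges = list(range(1, hi + 2))
    rows = []
    for lo, hi in zip(bin_edges, bin_edges[1:]):
        in_bin = [g for g, v in values.items() if lo <= v < hi]
        n_host = sum(1 for g in in_bin if g in host_ids)
        rows.append(
            {
                "bin_left": lo,
                "bin_right": hi,
                "n_genes": len(in_bin),
                "n_hosts": n_host,
                "fraction": (n_host / len(in_bin)) if in_bin else None,
            }
        )
    return rows


def fisher_exact_2x2(table) -> float:
    """Two-sided Fisher exact p: the sum of hypergeometric probabilities
    of tables (at fixed margins) no more likely than the observed one."""
    t = np.asarray(table)
    if t.shape != (2, 2) or (t < 0).any() or not np.issubdtype(t.dtype, np.integer):
        raise ValueError("need a non-negative integer 2x2 table")
    _, p = stats.fisher_exact(t, alternative="two-sided")
    return float(p)


# -- inverted complementary sequences ---------------------------------------

_ALIGNER = Align.PairwiseAligner(
    mode="local",
    match_score=1,
    mismatch_score=-1,
    open_gap_score=-2,
    extend_gap_score=-2,
)


def find_ics(
    upstream_seq: str,
    downstream_seq: str,
    min_length: int = 10,
    min_identity: float = 0.8,
) -> IcsMatch | None:
    """Best local alignment of the upstream intron against the reverse
    complement of the downstream intron (match +1, mismatch -1, gap -2).

    Returns None when either sequence is empty or the best match is
    shorter than ``min_length`` or below ``min_identity``.  The reported
    down coordinates are mapped back to the original downstream
    orientation.
    """
    for seq in (upstream_seq, downstream_seq):
        if not set(seq) <= VALID_BASES:
            raise ValueError("sequences must be over {A,C,G,T,N}")
    if not upstream_seq or not downstream_seq:
        return None
    rc = reverse_complement(downstream_seq)
    alignments = _ALIGNER.align(upstream_seq, rc)
    if alignments.score <= 0:
        return None
    aln = alignments[0]
    blocks_up, blocks_rc = aln.aligned
    up_start = int(blocks_up[0][0])
    up_end = int(blocks_up[-1][1])
    rc_start = int(blocks_rc[0][0])
    rc_end = int(blocks_rc[-1][1])
    matches = sum(
        1
        for (a0, a1), (b0, b1) in zip(blocks_up, blocks_rc)
        for k in range(a1 - a0)
        if upstream_seq[a0 + k] == rc[b0 + k]
    )
    # columns = aligned pairs + gap columns
    n_pairs = sum(a1 - a0 for (a0, a1) in blocks_up)
    n_gaps = (up_end - up_start - n_pairs) + (rc_end - rc_start - n_pairs)
    columns = n_pairs + n_gaps
    identity = matches / columns if columns else 0.0
    if columns < min_length or identity < min_identity:
        return None
    return IcsMatch(
        up_start=up_start,
        up_end=up_end,
        down_start=len(downstream_seq) - rc_end,
        down_end=len(downstream_seq) - rc_start,
        match_length=columns,
        identity=identity,
        score=float(alignments.score),
    )


def repeat_density(seq: str, k: int = 13, min_occurrences: int = 2) -> float:
    """Fraction of positions covered by a k-mer occurring at least
    ``min_occurrences`` times within the sequence — a self-contained
    proxy for repetitive-sequence abundance."""
    if k < 2:
        raise ValueError("k must be >= 2")
    if len(seq) < k:
        raise ValueError("sequence shorter than k")
    counts: dict[str, int] = {}
    for i in range(len(seq) - k + 1):
        kmer = seq[i : i + k]
        counts[kmer] = counts.get(kmer, 0) + 1
    covered = np.zeros(len(seq), dtype=bool)
    for i in range(len(seq) - k + 1):
        if counts[seq[i : i + k]] >= min_occurrences:
            covered[i : i + k] = True
    return float(covered.mean())


# -- matched control comparison ---------------------------------------------

def _flank_metrics(
    up: str, down: str, min_length: int, min_identity: float, k: int
) -> tuple[float, float, float]:
    m = find_ics(up, down, min_length=min_length, min_identity=min_identity)
    length = float(m.match_length) if m else 0.0
    ident = float(m.identity) if m else 0.0
    joined = up + down
    dens = repeat_density(joined, k=k) if len(joined) >= k else 0.0
    return length, ident, dens


def circ_flank_pairs(
    circs: list[CircRNA],
    classifications: dict[str, CircClassification],
    annotation: AnnotationSet,
    genome: GenomeSequence,
) -> list[tuple[str, str]]:
    """(upstream intron seq, downstream intron seq) for each exonic circ
    that has both flanking introns."""
    pairs = []
    for circ in circs:
        cls = classifications.get(circ.circ_id)
        if cls is None or cls.circ_type not in ("multi-exonic", "single-exonic"):
            continue
        tx = _find_transcript(annotation, cls.matched_transcript_id)
        if cls.first_exon < 1 or cls.last_exon >= len(tx.exons) - 1:
            continue
        introns = tx.introns
        contig_seq = genome.contigs[circ.contig]
        up_iv = introns[cls.first_exon - 1]
        down_iv = introns[cls.last_exon]
        pairs.append(
            (
                contig_seq[up_iv.start : up_iv.end],
                contig_seq[down_iv.start : down_iv.end],
            )
        )
    return pairs


def ics_control_comparison(
    circs: list[CircRNA],
    classifications: dict[str, CircClassification],
    annotation: AnnotationSet,
    genome: GenomeSequence,
    n_controls: int,
    seed: int,
    min_length: int = 10,
    min_identity: float = 0.8,
    k: int = 13,
) -> dict:
    """Compare ICS length/identity and repeat density of circ flanks with
    flanks of randomly drawn internal exons of non-host transcripts.

    Controls are sampled without replacement; first/last exons are
    excluded so every control exon has both flanking introns.  A
    two-sided rank-sum p-value is reported per metric.
    """
    rng = np.random.default_rng(seed)
    host_ids = {g for c in circs for g in c.host_gene_ids}
    pool = []
    for gene in annotation.genes:
        if gene.gene_id in host_ids:
            continue
        tx = gene.transcripts[0]
        for i in range(1, len(tx.exons) - 1):
            pool.append((tx, i))
    if len(pool) < n_controls:
        raise ValueError(
            f"only {len(pool)} eligible control exons for {n_controls} requested"
        )
    picks = rng.choice(len(pool), size=n_controls, replace=False)

    def metrics_for(up: str, down: str):
        return _flank_metrics(up, down, min_length, min_identity, k)

    circ_vals = []
    for up, down in circ_flank_pairs(circs, classifications, annotation, genome):
        circ_vals.append(metrics_for(up, down))
    ctrl_vals = []
    for j in picks:
        tx, i = pool[int(j)]
        introns = tx.introns
        up = genome.contigs[tx.exons[0].contig][
            introns[i - 1].start : introns[i - 1].end
        ]
        down = genome.contigs[tx.exons[0].contig][
            introns[i].start : introns[i].end
        ]
        ctrl_vals.append(metrics_for(up, down))
    if not circ_vals:
        raise ValueError("no circ flank pairs available")

    out = {"n_circ": len(circ_vals), "n_control": len(ctrl_vals), "seed": seed}
    names = ("ics_length", "ics_identity", "repeat_density")
    for i, name in enumerate(names):
        cv = np.array([v[i] for v in circ_vals])
        kv = np.array([v[i] for v in ctrl_vals])
        if np.array_equal(np.sort(cv), np.sort(kv)):
            p = 1.0
        else:
            p = float(stats.mannwhitneyu(cv, kv, alternative="two-sided").pvalue)
        out[name] = {
            "circ_mean": float(cv.mean()),
            "control_mean": float(kv.mean()),
            "p_value": p,
        }
    return out
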