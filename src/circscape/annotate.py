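"""Structural classification of circRNAs against gene models.

A circRNA whose acceptor matches a transcript exon start and whose donor
matches the end of a later exon of the same transcript is exonic
(multi-exonic when it spans >= 2 exons, single-exonic when the junction
coincides with the boundaries of one exon); a junction lying entirely
inside one intron is intronic; anything else is unclassified.
"""

from __future__ import annotations

from dataclasses import dataclass

from .genome import AnnotationSet, GenomeSequence, Transcript
from .filtering import CircRNA

CIRC_TYPES = ("multi-exonic", "single-exonic", "intronic", "unclassified")


@dataclass
class CircClassification:
    circ_id: str
    circ_type: str
    matched_transcript_id: str | None
    spliced_length: int | None
    n_exons_in_circ: int
    first_exon: int = -1
    last_exon: int = -1


def _exonic_match(
    circ: CircRNA, tx: Transcript, tolerance: int
) -> tuple[int, int] | None:
    """Indices (first, last) of spanned exons when the junction matches
    exon boundaries of this transcript within tolerance."""
    first = last = None
    for i, e in enumerate(tx.exons):
        if abs(e.start - circ.acceptor) <= tolerance:
            first = i
            break
    for j, e in enumerate(tx.exons):
        if abs(e.end - circ.donor) <= tolerance:
            last = j
    if first is None or last is None or last < first:
        return None
    return first, last


def classify_type(
    circ: CircRNA, annotation: AnnotationSet, tolerance: int = 0
) -> CircClassification:
    """Assign exactly one structural type to a retained circRNA.

    When several transcripts match, the one minimizing the number of
    spanned exons wins; remaining ties break on transcript id so the
    assignment is deterministic.
    """
    hosts = annotation.genes_containing(circ.contig, circ.acceptor, circ.donor)
    exonic: list[tuple[int, str, int, int]] = []
    intronic_tx: list[str] = []
    for gid in sorted(hosts):
        for tx in annotation.gene(gid).transcripts:
            m = _exonic_match(circ, tx, tolerance)
            if m is not None:
                first, last = m
                exonic.append((last - first + 1, tx.transcript_id, first, last))
            else:
                for intron in tx.introns:
                    if intron.start <= circ.acceptor and circ.donor <= intron.end:
                        intronic_tx.append(tx.transcript_id)
                        break
    if exonic:
        n_ex, tid, first, last = min(exonic)
        circ_type = "multi-exonic" if n_ex >= 2 else "single-exonic"
        return CircClassification(
            circ.circ_id, circ_type, tid, None, n_ex, first, last
        )
    if intronic_tx:
        return CircClassification(
            circ.circ_id, "intronic", sorted(intronic_tx)[0], None, 0
        )
    return CircClassification(circ.circ_id, "unclassified", None, None, 0)


def spliced_length(
    classification: CircClassification,
    circ: CircRNA,
    annotation: AnnotationSet,
) -> int:
    """Mature-sequence length: summed exon lengths for exonic circRNAs,
    genomic span for intronic ones."""
    if classification.circ_type == "unclassified":
        raise ValueError(f"{circ.circ_id}: length undefined for unclassified circ")
    if classification.circ_type == "intronic":
        return circ.donor - circ.acceptor
    tx = _find_transcript(annotation, classification.matched_transcript_id)
    exons = tx.exons[classification.first_exon : classification.last_exon + 1]
    return sum(len(e) for e in exons)


def circ_sequence(
    classification: CircClassification,
    circ: CircRNA,
    annotation: AnnotationSet,
    genome: GenomeSequence,
) -> str:
    """Spliced circRNA sequence in transcript orientation (5'->3')."""
    if classification.circ_type == "unclassified":
        raise ValueError(f"{circ.circ_id}: sequence undefined for unclassified circ")
    if classification.circ_type == "intronic":
        return genome.fetch(circ.interval)
    tx = _find_transcript(annotation, classification.matched_transcript_id)
    exons = tx.exons[classification.first_exon : classification.last_exon + 1]
    sub = Transcript(f"{tx.transcript_id}.circ", exons)
    return sub.spliced_sequence(genome)


def _find_transcript(annotation: AnnotationSet, tid: str) -> Transcript:
    for gene in annotation.genes:
        for tx in gene.transcripts:
            if tx.transcript_id == tid:
                return tx
    raise KeyError(tid)


def classify_all(
    circs: list[CircRNA], annotation: AnnotationSet, tolerance: int = 0
) -> dict[str, CircClassification]:
    out = {}
    for circ in circs:
        cls = classify_type(circ, annotation, tolerance)
        if cls.circ_type != "unclassified":
            cls.spliced_length = spliced_length(cls, circ, annotation)
        out[circ.circ_id] = cls
    return out


def chromosome_distribution(
    circs: list[CircRNA], scaffold_prefixes: tuple[str, ...] = ("scaffold",)
) -> dict:
    """Per-contig circRNA and host-gene counts; unanchored scaffolds are
    pooled into a separate category."""
    circ_counts: dict[str, int] = {}
    host_genes: dict[str, set] = {}
    scaffold_circs = 0
    for circ in circs:
        if circ.contig.startswith(scaffold_prefixes):
            scaffold_circs += 1
            continue
        circ_counts[circ.contig] = circ_counts.get(circ.contig, 0) + 1
        host_genes.setdefault(circ.contig, set()).update(circ.host_gene_ids)
    return {
        "circ_per_contig": dict(sorted(circ_counts.items())),
        "host_genes_per_contig": {
            k: len(v) for k, v in sorted(host_genes.items())
        },
        "unanchored_scaffold_circs": scaffold_circs,
    }
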