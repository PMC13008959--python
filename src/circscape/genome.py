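"""Sequence and annotation data model.

All internal coordinates are 0-based half-open intervals on the forward
strand of a named contig.  GFF3 input/output converts from/to the 1-based
closed convention of that format; BED output stays 0-based.  Every other
module builds on the types defined here.
"""

from __future__ import annotations

import io
import os
from dataclasses import dataclass, field

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord
from intervaltree import IntervalTree

VALID_BASES = frozenset("ACGTN")

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


class AnnotationError(ValueError):
    """Structurally invalid annotation (overlapping exons, bad intervals)."""


class LookupContigError(KeyError):
    """Query against a contig unknown to the genome or annotation."""


def reverse_complement(seq: str) -> str:
    """Reversed Watson-Crick complement over the {A,C,G,T,N} alphabet."""
    if not set(seq) <= VALID_BASES:
        bad = sorted(set(seq) - VALID_BASES)
        raise ValueError(f"illegal characters in sequence: {bad}")
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """Half-open interval [start, end) on a contig; strand in {+, -, .}."""

    contig: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval [{self.start}, {self.end}) on {self.contig}"
            )
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def contains(self, pos: int) -> bool:
        return self.start <= pos < self.end

    def contains_interval(self, other: "GenomicInterval") -> bool:
        return (
            self.contig == other.contig
            and self.start <= other.start
            and other.end <= self.end
        )

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.contig == other.contig
            and self.start < other.end
            and other.start < self.end
        )


class GenomeSequence:
    """Uppercase nucleotide sequences keyed by contig name."""

    def __init__(self, contigs: dict[str, str]):
        self.contigs: dict[str, str] = {}
        for name, seq in contigs.items():
            seq = seq.upper()
            if not set(seq) <= VALID_BASES:
                bad = sorted(set(seq) - VALID_BASES)
                raise ValueError(f"contig {name}: illegal characters {bad}")
            self.contigs[name] = seq

    @property
    def lengths(self) -> dict[str, int]:
        return {name: len(seq) for name, seq in self.contigs.items()}

    def fetch(self, interval: GenomicInterval) -> str:
        """Sequence of *interval*; reverse-complemented for '-' strand."""
        if interval.contig not in self.contigs:
            raise LookupContigError(interval.contig)
        seq = self.contigs[interval.contig]
        if interval.end > len(seq):
            raise ValueError(
                f"interval end {interval.end} beyond contig "
                f"{interval.contig} ({len(seq)} bp)"
            )
        sub = seq[interval.start : interval.end]
        return reverse_complement(sub) if interval.strand == "-" else sub

    @classmethod
    def from_fasta(cls, path: str | os.PathLike) -> "GenomeSequence":
        return cls({rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")})

    def to_fasta(self, path: str | os.PathLike) -> None:
        records = [
            SeqRecord(Seq(seq), id=name, description="")
            for name, seq in self.contigs.items()
        ]
        SeqIO.write(records, str(path), "fasta")


def derive_introns(exons: list[GenomicInterval]) -> list[GenomicInterval]:
    """Gaps between consecutive exons of one transcript.

    Exons must be sorted, non-overlapping, and share contig/strand.
    Zero-length gaps (abutting exons) are dropped: they are annotation
    artifacts, not introns.
    """
    introns = []
    for left, right in zip(exons, exons[1:]):
        if left.contig != right.contig or left.strand != right.strand:
            raise AnnotationError("exons span multiple contigs/strands")
        if right.start < left.end:
            raise AnnotationError(
                f"overlapping exons {left} / {right} in transcript"
            )
        if right.start > left.end:
            introns.append(
                GenomicInterval(left.contig, left.end, right.start, left.strand)
            )
    return introns


@dataclass
class Transcript:
    transcript_id: str
    exons: list[GenomicInterval]

    def __post_init__(self) -> None:
        self.exons = sorted(self.exons, key=lambda e: e.start)
        # validates sortedness/overlap as a side effect
        derive_introns(self.exons)

    @property
    def introns(self) -> list[GenomicInterval]:
        return derive_introns(self.exons)

    @property
    def span(self) -> GenomicInterval:
        first, last = self.exons[0], self.exons[-1]
        return GenomicInterval(first.contig, first.start, last.end, first.strand)

    @property
    def spliced_length(self) -> int:
        return sum(len(e) for e in self.exons)

    def spliced_sequence(self, genome: GenomeSequence) -> str:
        """Exonic sequence in transcription order (5'->3')."""
        parts = [
            genome.fetch(
                GenomicInterval(e.contig, e.start, e.end, "+")
            )
            for e in self.exons
        ]
        seq = "".join(parts)
        return reverse_complement(seq) if self.span.strand == "-" else seq


@dataclass
class GeneModel:
    gene_id: str
    interval: GenomicInterval
    transcripts: list[Transcript] = field(default_factory=list)

    @property
    def n_isoforms(self) -> int:
        return len(self.transcripts)

    @property
    def n_exons_max(self) -> int:
        """Exon count reported per gene: the maximum over its isoforms."""
        return max(len(t.exons) for t in self.transcripts)

    @property
    def strand(self) -> str:
        return self.interval.strand


class AnnotationSet:
    """Genes -> transcripts -> exons, interval-indexed per contig."""

    def __init__(
        self, genes: list[GeneModel], known_contigs: set[str] | None = None
    ):
        ids = [g.gene_id for g in genes]
        if len(ids) != len(set(ids)):
            raise AnnotationError("duplicate gene ids")
        self.genes: list[GeneModel] = sorted(
            genes, key=lambda g: (g.interval.contig, g.interval.start, g.gene_id)
        )
        self._by_id = {g.gene_id: g for g in self.genes}
        self._trees: dict[str, IntervalTree] = {}
        for gene in self.genes:
            tree = self._trees.setdefault(gene.interval.contig, IntervalTree())
            tree[gene.interval.start : gene.interval.end] = gene.gene_id
        # gene-free contigs (e.g. unanchored scaffolds) may be registered
        # so queries on them return the empty set instead of erroring
        self.known_contigs: set[str] = set(self._trees) | (known_contigs or set())

    def __len__(self) -> int:
        return len(self.genes)

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self._by_id

    def gene(self, gene_id: str) -> GeneModel:
        return self._by_id[gene_id]

    @property
    def contigs(self) -> set[str]:
        return set(self._trees)

    def locate_genes(
        self, query: GenomicInterval, strand_matched: bool = False
    ) -> set[str]:
        """Ids of genes overlapping *query* by >= 1 bp.

        Strand-agnostic by default; with ``strand_matched`` only genes on
        the query strand are returned.
        """
        if query.contig not in self.known_contigs:
            raise LookupContigError(query.contig)
        tree = self._trees.get(query.contig)
        hits = {iv.data for iv in tree[query.start : query.end]} if tree else set()
        if strand_matched and query.strand != ".":
            hits = {
                g for g in hits if self._by_id[g].interval.strand == query.strand
            }
        return hits

    def genes_containing(
        self, contig: str, start: int, end: int
    ) -> set[str]:
        """Genes whose interval contains [start, end) entirely."""
        if contig not in self.known_contigs:
            raise LookupContigError(contig)
        tree = self._trees.get(contig)
        if tree is None:
            return set()
        return {
            iv.data
            for iv in tree[start:end]
            if iv.begin <= start and end <= iv.end
        }

    def all_introns(self) -> list[GenomicInterval]:
        """Every intron of every transcript (with multiplicity)."""
        out: list[GenomicInterval] = []
        for gene in self.genes:
            for tx in gene.transcripts:
                out.extend(tx.introns)
        return out

    # -- GFF3 I/O ---------------------------------------------------------

    @classmethod
    def from_gff3(cls, path: str | os.PathLike) -> "AnnotationSet":
        import gffutils

        db = gffutils.create_db(
            str(path),
            dbfn=":memory:",
            force=True,
            keep_order=True,
            merge_strategy="create_unique",
        )
        genes = []
        for g in db.features_of_type("gene"):
            transcripts = []
            for t in db.children(g, featuretype="mRNA", order_by="start"):
                exons = [
                    GenomicInterval(e.seqid, e.start - 1, e.end, e.strand)
                    for e in db.children(t, featuretype="exon", order_by="start")
                ]
                transcripts.append(Transcript(t.id, exons))
            genes.append(
                GeneModel(
                    g.id,
                    GenomicInterval(g.seqid, g.start - 1, g.end, g.strand),
                    transcripts,
                )
            )
        return cls(genes)

    def to_gff3(self, path: str | os.PathLike) -> None:
        with open(path, "w") as fh:
            fh.write("##gff-version 3\n")
            for gene in self.genes:
                gi = gene.interval
                fh.write(
                    f"{gi.contig}\tcircscape\tgene\t{gi.start + 1}\t{gi.end}\t.\t"
                    f"{gi.strand}\t.\tID={gene.gene_id}\n"
                )
                for tx in gene.transcripts:
                    sp = tx.span
                    fh.write(
                        f"{gi.contig}\tcircscape\tmRNA\t{sp.start + 1}\t{sp.end}"
                        f"\t.\t{gi.strand}\t.\tID={tx.transcript_id};"
                        f"Parent={gene.gene_id}\n"
                    )
                    for i, e in enumerate(tx.exons, 1):
                        fh.write(
                            f"{gi.contig}\tcircscape\texon\t{e.start + 1}\t{e.end}"
                            f"\t.\t{gi.strand}\t.\t"
                            f"ID={tx.transcript_id}.exon{i};"
                            f"Parent={tx.transcript_id}\n"
                        )


def write_bed6(
    intervals: list[tuple[GenomicInterval, str, float]], path: str | os.PathLike
) -> None:
    """BED6: (interval, name, score) triples, 0-based half-open as-is."""
    with open(path, "w") as fh:
        for iv, name, score in intervals:
            fh.write(
                f"{iv.contig}\t{iv.start}\t{iv.end}\t{name}\t{score:g}\t"
                f"{iv.strand}\n"
            )
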