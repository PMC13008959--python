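"""Cross-species conservation of circRNA production and splice sites.

Gene-level conservation is tested by the hypergeometric overlap of
circRNA-host orthologs; site-level conservation classifies orthologous
circRNA pairs as Accordant (both splice sites positionally conserved),
Half-accordant (one site), or Unaccordant (neither), after projecting
the first species' sites through a pairwise global alignment of the
ortholog sequences.
"""

from __future__ import annotations

from dataclasses import dataclass

from Bio import Align
from scipy import stats

CATEGORIES = ("Accordant", "Half-accordant", "Unaccordant")


@dataclass
class OrthologMap:
    pairs: list[tuple[str, str]]

    def __post_init__(self) -> None:
        if len(self.pairs) != len(set(self.pairs)):
            raise ValueError("ortholog pairs must be unique")

    def __len__(self) -> int:
        return len(self.pairs)


@dataclass
class ConservationCall:
    gene_a: str
    gene_b: str
    circ_a: str
    circ_b: str
    acceptor_conserved: bool
    donor_conserved: bool

    @property
    def category(self) -> str:
        n = int(self.acceptor_conserved) + int(self.donor_conserved)
        return CATEGORIES[2 - n]


def ortholog_overlap_test(
    hosts_a: set[str], hosts_b: set[str], ortholog_map: OrthologMap
) -> tuple[int, float]:
    """Overlap of circRNA-producing orthologs and its upper-tail
    hypergeometric p-value.

    The sampling universe is the set of ortholog pairs (size N); K pairs
    have a circ-producing A member, n pairs a circ-producing B member,
    and the overlap counts pairs where both members are hosts.
    p = P(X >= overlap) with X ~ Hypergeometric(N, K, n).
    """
    if not ortholog_map.pairs:
        raise ValueError("empty ortholog map: overlap test undefined")
    N = len(ortholog_map)
    K = sum(1 for a, _ in ortholog_map.pairs if a in hosts_a)
    n = sum(1 for _, b in ortholog_map.pairs if b in hosts_b)
    overlap = sum(
        1 for a, b in ortholog_map.pairs if a in hosts_a and b in hosts_b
    )
    p = float(stats.hypergeom.sf(overlap - 1, N, K, n))
    return overlap, min(p, 1.0)


_GLOBAL_ALIGNER = Align.PairwiseAligner(
    mode="global",
    match_score=1,
    mismatch_score=-1,
    open_gap_score=-5,
    extend_gap_score=-1,
)


def align_pair(seq_a: str, seq_b: str):
    """Global alignment (match +1, mismatch -1, gap open -5, extend -1);
    returns the aligned block coordinates used for projection."""
    aln = _GLOBAL_ALIGNER.align(seq_a, seq_b)[0]
    blocks_a, blocks_b = aln.aligned
    return [
        (int(a0), int(a1), int(b0))
        for (a0, a1), (b0, _b1) in zip(blocks_a, blocks_b)
    ]


def project_position(blocks, pos: int) -> int | None:
    """Coordinate of base *pos* of sequence A in sequence B, or None when
    the base aligns to a gap."""
    if pos < 0:
        raise ValueError("position outside sequence A")
    for a0, a1, b0 in blocks:
        if a0 <= pos < a1:
            return b0 + (pos - a0)
    return None


def map_splice_site(blocks, site: int, is_donor: bool = False) -> int | None:
    """Project a splice-site coordinate through the alignment.

    Acceptors are start coordinates (project the base itself); donors are
    exclusive end coordinates (project the last covered base, then shift
    back past it).
    """
    if is_donor:
        mapped = project_position(blocks, site - 1)
        return None if mapped is None else mapped + 1
    return project_position(blocks, site)


def classify_conservation(
    blocks,
    acceptor_a: int,
    donor_a: int,
    acceptor_b: int,
    donor_b: int,
    tolerance: int = 10,
    gene_a: str = "",
    gene_b: str = "",
    circ_a: str = "",
    circ_b: str = "",
) -> ConservationCall:
    """A site is conserved iff its projected coordinate lands within
    ``tolerance`` nt of the partner circRNA's site; unmappable sites
    (gaps) count as not conserved."""
    ma = map_splice_site(blocks, acceptor_a, is_donor=False)
    md = map_splice_site(blocks, donor_a, is_donor=True)
    acc_ok = ma is not None and abs(ma - acceptor_b) <= tolerance
    don_ok = md is not None and abs(md - donor_b) <= tolerance
    return ConservationCall(gene_a, gene_b, circ_a, circ_b, acc_ok, don_ok)


def best_call_per_circ(calls: list[ConservationCall]) -> list[ConservationCall]:
    """When a gene pair yields several B circRNAs per A circRNA, report
    the most-conserved category per A circ (deterministic tie-break on
    the B circ id)."""
    best: dict[str, ConservationCall] = {}
    rank = {c: i for i, c in enumerate(CATEGORIES)}
    for call in sorted(calls, key=lambda c: (c.circ_a, rank[c.category], c.circ_b)):
        best.setdefault(call.circ_a, call)
    return [best[k] for k in sorted(best)]


def conservation_summary(calls: list[ConservationCall]) -> dict[str, int]:
    counts = {c: 0 for c in CATEGORIES}
    for call in calls:
        counts[call.category] += 1
    return counts
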