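"""miRNA target scanning and ceRNA (sponge) network construction.

Targets are scored with a plant-style expectation penalty: the target
window is aligned against the reverse complement of the miRNA, charging
1 per mismatch, 0.5 per G:U wobble, 2 per gap, with all penalties
doubled inside the seed region (miRNA positions 2-13, 5' numbering);
lower is better.  One scorer evaluated under three stringency profiles
(strict / medium / lenient penalty cutoffs) replaces consensus over
independent predictors: an interaction is kept only when every profile
reports it.  Retained interactions form a tripartite
circRNA-miRNA-mRNA graph whose node attributes carry per-condition DE
fold changes, supporting hub ranking and sponge-consistency checks.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np

from .genome import VALID_BASES, reverse_complement

SEED_RANGE = (2, 13)  # miRNA positions with doubled penalties, 1-based 5'->3'

DEFAULT_PROFILES = {"strict": 0.0, "medium": 2.5, "lenient": 5.0}

_CODE = {b: i for i, b in enumerate("ACGTN")}


@dataclass(frozen=True)
class TargetSite:
    mirna_id: str
    target_id: str
    target_kind: str  # circRNA | mRNA
    position: int  # 0-based offset in the target sequence
    penalty: float
    alignment: str = ""


def _pair_penalty_matrix() -> np.ndarray:
    """Penalty for target base (row) vs reverse-complement-miRNA base
    (column): 0 match, 0.5 G:U wobble, 1 mismatch; N never pairs."""
    P = np.ones((5, 5))
    for b in "ACGT":
        P[_CODE[b], _CODE[b]] = 0.0
    # wobble pairs expressed in revcomp space:
    # target G : miRNA U  -> rc base A;   target U(T) : miRNA G -> rc base C
    P[_CODE["G"], _CODE["A"]] = 0.5
    P[_CODE["T"], _CODE["C"]] = 0.5
    P[_CODE["N"], :] = 1.0
    P[:, _CODE["N"]] = 1.0
    return P


_PAIR_PENALTY = _pair_penalty_matrix()


def _weights(mirna_len: int) -> np.ndarray:
    """Per-column weight in revcomp orientation: column j corresponds to
    miRNA position (L - j) in 1-based 5' numbering."""
    w = np.ones(mirna_len)
    for j in range(mirna_len):
        pos = mirna_len - j
        if SEED_RANGE[0] <= pos <= SEED_RANGE[1]:
            w[j] = 2.0
    return w


def _encode(seq: str) -> np.ndarray:
    if not set(seq) <= VALID_BASES:
        raise ValueError("sequence must be over {A,C,G,T,N}")
    return np.array([_CODE[b] for b in seq], dtype=np.int8)


def score_site(mirna_seq: str, target_window: str) -> tuple[float, str]:
    """Optimal gapped alignment penalty of one window vs the miRNA.

    The window length must be within +/-5 nt of the miRNA length.
    Returns (penalty, alignment string 'target / pairing / revcomp-miRNA');
    ties resolve to the leftmost alignment via the traceback preference
    pair > target-gap > miRNA-gap.
    """
    L = len(mirna_seq)
    if abs(len(target_window) - L) > 5:
        raise ValueError("window length must be within +/-5 nt of the miRNA")
    rc = reverse_complement(mirna_seq)
    t = _encode(target_window)
    m = _encode(rc)
    w = _weights(L)
    n_t, n_m = len(t), len(m)
    D = np.zeros((n_t + 1, n_m + 1))
    # leading gaps: gap in target consumes miRNA base j-1; gap in miRNA
    # is charged at the weight of the next miRNA column (or last, at the end)
    for j in range(1, n_m + 1):
        D[0, j] = D[0, j - 1] + 2.0 * w[j - 1]
    for i in range(1, n_t + 1):
        D[i, 0] = D[i - 1, 0] + 2.0 * w[0]
    for i in range(1, n_t + 1):
        for j in range(1, n_m + 1):
            pair = D[i - 1, j - 1] + _PAIR_PENALTY[t[i - 1], m[j - 1]] * w[j - 1]
            gap_t = D[i, j - 1] + 2.0 * w[j - 1]
            gap_m = D[i - 1, j] + 2.0 * w[min(j, n_m - 1)]
            D[i, j] = min(pair, gap_t, gap_m)
    # traceback for the alignment string
    i, j = n_t, n_m
    top, mid, bot = [], [], []
    sym = {0.0: "|", 0.5: "o", 1.0: " "}
    while i > 0 or j > 0:
        if i > 0 and j > 0 and np.isclose(
            D[i, j], D[i - 1, j - 1] + _PAIR_PENALTY[t[i - 1], m[j - 1]] * w[j - 1]
        ):
            top.append(target_window[i - 1])
            mid.append(sym[float(_PAIR_PENALTY[t[i - 1], m[j - 1]])])
            bot.append(rc[j - 1])
            i, j = i - 1, j - 1
        elif j > 0 and np.isclose(D[i, j], D[i, j - 1] + 2.0 * w[j - 1]):
            top.append("-")
            mid.append(" ")
            bot.append(rc[j - 1])
            j -= 1
        else:
            top.append(target_window[i - 1])
            mid.append(" ")
            bot.append("-")
            i -= 1
    aln = "\n".join("".join(reversed(x)) for x in (top, mid, bot))
    return float(D[n_t, n_m]), aln


def _batch_penalties(
    mirna_seq: str, windows: np.ndarray, cutoff: float | None = None
) -> np.ndarray:
    """Alignment penalty for a batch of encoded windows (n, L), computed
    with the same recurrence as :func:`score_site`, vectorized over the
    batch axis.

    With a ``cutoff``, windows whose running row minimum already exceeds
    it are dropped early (every DP step cost is non-negative, so the
    final penalty can never fall below any row minimum); their reported
    penalty is +inf.  All penalties are exact dyadic rationals, so
    float32 arithmetic is lossless.
    """
    L = len(mirna_seq)
    rc = reverse_complement(mirna_seq)
    m = _encode(rc)
    w = _weights(L).astype(np.float32)
    n_win = windows.shape[0]
    out = np.full(n_win, np.inf, dtype=np.float64)
    if n_win == 0:
        return out
    alive = np.arange(n_win)
    wmat = windows
    prev = np.empty((n_win, L + 1), dtype=np.float32)
    prev[:, 0] = 0.0
    prev[:, 1:] = np.cumsum(2.0 * w)[None, :]
    pen32 = _PAIR_PENALTY.astype(np.float32)
    bound = None if cutoff is None else np.float32(cutoff + 1e-6)
    for i in range(1, L + 1):
        cur = np.empty_like(prev)
        cur[:, 0] = prev[:, 0] + 2.0 * w[0]
        col = wmat[:, i - 1]
        for j in range(1, L + 1):
            pair = prev[:, j - 1] + pen32[col, m[j - 1]] * w[j - 1]
            gap_t = cur[:, j - 1] + 2.0 * w[j - 1]
            gap_m = prev[:, j] + 2.0 * w[min(j, L - 1)]
            cur[:, j] = np.minimum(pair, np.minimum(gap_t, gap_m))
        if bound is not None and i < L:
            keep = cur.min(axis=1) <= bound
            if not keep.all():
                alive = alive[keep]
                cur = cur[keep]
                wmat = wmat[keep]
                if alive.size == 0:
                    return out
        prev = cur
    out[alive] = prev[:, L].astype(np.float64)
    return out


def _window_matrix(target_seq: str, L: int) -> np.ndarray:
    t = _encode(target_seq)
    n_win = len(t) - L + 1
    if n_win <= 0:
        return np.empty((0, L), dtype=np.int8)
    idx = np.arange(n_win)[:, None] + np.arange(L)[None, :]
    return t[idx]


def _scan_penalties(mirna_seq: str, target_seq: str) -> np.ndarray:
    return _batch_penalties(
        mirna_seq, _window_matrix(target_seq, len(mirna_seq))
    )


def scan_targets(
    mirna_id: str,
    mirna_seq: str,
    target_id: str,
    target_seq: str,
    target_kind: str = "mRNA",
    cutoff: float = 5.0,
    circular: bool = False,
) -> list[TargetSite]:
    """All non-overlapping sites with penalty <= cutoff.

    Windows of miRNA length slide over the target (for circular targets
    the sequence is rotated so junction-spanning windows are scanned);
    candidates are retained greedily by ascending penalty, position.
    """
    L = len(mirna_seq)
    if len(target_seq) < L:
        return []
    orig_len = len(target_seq)
    seq = target_seq + target_seq[: L - 1] if circular else target_seq
    penalties = _batch_penalties(mirna_seq, _window_matrix(seq, L), cutoff)
    return _sites_from_penalties(
        mirna_id, target_id, target_kind, penalties, L, orig_len, cutoff, circular
    )


def _sites_from_penalties(
    mirna_id, target_id, target_kind, penalties, L, orig_len, cutoff, circular
) -> list[TargetSite]:
    order = sorted(
        (float(p), i) for i, p in enumerate(penalties) if p <= cutoff + 1e-9
    )
    taken: list[tuple[int, int]] = []
    sites = []
    for pen, start in order:
        s, e = start, start + L
        if any(s < b and a < e for a, b in taken):
            continue
        taken.append((s, e))
        sites.append(
            TargetSite(
                mirna_id,
                target_id,
                target_kind,
                position=start % orig_len if circular else start,
                penalty=round(pen, 6),
            )
        )
    sites.sort(key=lambda s: s.position)
    return sites


def scan_all(
    mirnas: dict[str, str],
    targets: dict[str, str],
    target_kind: str,
    profiles: dict[str, float] = DEFAULT_PROFILES,
    circular: bool = False,
) -> dict[str, list[TargetSite]]:
    """Sites per stringency profile over all miRNA x target pairs.

    The window DP runs once per miRNA over the concatenated windows of
    every target, so large target sets stay fast; results are identical
    to per-target :func:`scan_targets` calls.
    """
    out: dict[str, list[TargetSite]] = {name: [] for name in profiles}
    max_cut = max(profiles.values())
    tids = sorted(targets)
    for mid in sorted(mirnas):
        L = len(mirnas[mid])
        mats, spans = [], []
        for tid in tids:
            seq = targets[tid]
            if len(seq) < L:
                spans.append((tid, len(seq), 0))
                continue
            ext = seq + seq[: L - 1] if circular else seq
            mat = _window_matrix(ext, L)
            mats.append(mat)
            spans.append((tid, len(seq), mat.shape[0]))
        if not mats:
            continue
        penalties = _batch_penalties(mirnas[mid], np.concatenate(mats), max_cut)
        off = 0
        for tid, orig_len, n_win in spans:
            if n_win == 0:
                continue
            sites = _sites_from_penalties(
                mid,
                tid,
                target_kind,
                penalties[off : off + n_win],
                L,
                orig_len,
                max_cut,
                circular,
            )
            off += n_win
            for name, cut in profiles.items():
                out[name].extend(s for s in sites if s.penalty <= cut + 1e-9)
    return out


def consensus_filter(
    sites_per_profile: dict[str, list[TargetSite]]
) -> list[TargetSite]:
    """Interactions (mirna, target) present under every profile; the
    best-penalty site of the most lenient profile represents each."""
    if not sites_per_profile:
        raise ValueError("need at least one profile")
    keys = [
        {(s.mirna_id, s.target_id) for s in sites}
        for sites in sites_per_profile.values()
    ]
    kept = set.intersection(*keys)
    lenient = max(
        sites_per_profile.items(), key=lambda kv: max((s.penalty for s in kv[1]), default=0)
    )[1]
    best: dict[tuple, TargetSite] = {}
    for s in sorted(lenient, key=lambda s: (s.penalty, s.position)):
        k = (s.mirna_id, s.target_id)
        if k in kept and k not in best:
            best[k] = s
    return [best[k] for k in sorted(best)]


def build_network(
    circ_sites: list[TargetSite],
    mrna_sites: list[TargetSite],
    de_states: dict[str, dict],
    condition: str,
) -> nx.Graph:
    """Tripartite circRNA-miRNA-mRNA graph for one condition.

    ``de_states`` maps node id -> {"state": .., "log2fc": ..}; every edge
    endpoint must resolve to a node created from the interaction lists.
    """
    g = nx.Graph(condition=condition)
    for sites, kind in ((circ_sites, "circRNA"), (mrna_sites, "mRNA")):
        for s in sites:
            if s.target_kind != kind:
                raise ValueError(
                    f"site {s.mirna_id}->{s.target_id} has kind {s.target_kind}, "
                    f"expected {kind}"
                )
            info = de_states.get(s.target_id, {})
            g.add_node(s.target_id, kind=kind, **info)
            g.add_node(s.mirna_id, kind="miRNA", **de_states.get(s.mirna_id, {}))
            g.add_edge(s.mirna_id, s.target_id, penalty=s.penalty)
    for u, v in g.edges:
        ku, kv = g.nodes[u]["kind"], g.nodes[v]["kind"]
        if "miRNA" not in (ku, kv) or ku == kv:
            raise ValueError(f"non-tripartite edge {u}({ku}) -- {v}({kv})")
    return g


def hub_rank(network: nx.Graph, k: int = 10) -> dict[str, list[tuple[str, int]]]:
    """Top-k miRNAs by circRNA-partner count and by DE-mRNA-target count
    (ties break on miRNA id)."""
    if k < 1:
        raise ValueError("k must be >= 1")
    mirnas = [n for n, d in network.nodes(data=True) if d["kind"] == "miRNA"]
    by_circ, by_de_mrna = [], []
    for m in mirnas:
        nbrs = list(network.neighbors(m))
        n_circ = sum(1 for n in nbrs if network.nodes[n]["kind"] == "circRNA")
        n_de = sum(
            1
            for n in nbrs
            if network.nodes[n]["kind"] == "mRNA"
            and network.nodes[n].get("state", "ns") != "ns"
        )
        by_circ.append((m, n_circ))
        by_de_mrna.append((m, n_de))
    key = lambda t: (-t[1], t[0])
    return {
        "by_circ_targets": sorted(by_circ, key=key)[:k],
        "by_de_mrna_targets": sorted(by_de_mrna, key=key)[:k],
    }


def sponge_consistency(network: nx.Graph, mirna_id: str) -> dict:
    """Fractions of circRNA partners up-regulated and mRNA targets
    down-regulated; (1.0, 1.0) is the ideal sponge signature."""
    if mirna_id not in network:
        raise KeyError(f"{mirna_id} absent from network")
    circs = [
        n
        for n in network.neighbors(mirna_id)
        if network.nodes[n]["kind"] == "circRNA"
    ]
    mrnas = [
        n
        for n in network.neighbors(mirna_id)
        if network.nodes[n]["kind"] == "mRNA"
    ]
    n_circ_up = sum(1 for n in circs if network.nodes[n].get("state") == "up")
    n_mrna_down = sum(1 for n in mrnas if network.nodes[n].get("state") == "down")
    return {
        "fraction_circ_up": n_circ_up / len(circs) if circs else 0.0,
        "fraction_mrna_down": n_mrna_down / len(mrnas) if mrnas else 0.0,
        "n_circ_partners": len(circs),
        "n_mrna_targets": len(mrnas),
        "zero_denominator": not circs or not mrnas,
    }
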