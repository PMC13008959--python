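"""Synthetic multi-stress circRNA-seq data with planted ground truth.

Emulates every input the pipeline consumes: a toy multi-gene nuclear
genome (host genes with long introns / many exons / several isoforms,
non-host genes with short introns / few exons), planted circRNAs of the
three structural types, score-stratified artifact back-splice junctions
(enriched intergenic at low score), RNase R-treated and control library
candidate tables over five conditions, circRNA/gene expression matrices
with a configurable circ-host correlation, planted miRNA binding sites,
a second species with known splice-site-conservation categories, and a
toy chloroplast whose psbA-like gene carries 3'-terminus-clustered BSJs.

Everything is deterministic under the configured seed.  The generator's
defaults define the study conditions exercised by the test suite.
"""

from __future__ import annotations

import dataclasses
import json
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genome import (
    AnnotationSet,
    GeneModel,
    GenomeSequence,
    GenomicInterval,
    Transcript,
    reverse_complement,
)

STRESSES = ("cold", "heat", "salt", "UVB")
CONDITIONS = ("CK",) + STRESSES

_BASES = np.frombuffer(b"ACGT", dtype="S1")


class ConfigError(ValueError):
    """Generator configuration that cannot be satisfied."""


@dataclass
class GeneratorConfig:
    """All knobs of the synthetic study, with the default study design."""

    seed: int = 0

    # nuclear genome layout
    n_contigs: int = 3
    n_genes: int = 360
    host_exon_count_range: tuple[int, int] = (6, 12)
    nonhost_exon_count_range: tuple[int, int] = (2, 4)
    host_intron_length_range: tuple[int, int] = (500, 1000)
    nonhost_intron_length_range: tuple[int, int] = (80, 200)
    exon_length_range: tuple[int, int] = (80, 300)
    host_isoform_range: tuple[int, int] = (2, 4)
    nonhost_isoform_range: tuple[int, int] = (1, 1)
    intergenic_gap_range: tuple[int, int] = (500, 1500)

    # planted circRNAs (true positives)
    n_multi_exonic: int = 20
    n_single_exonic: int = 20
    n_intronic: int = 20
    ics_length: int = 0  # perfect inverted repeat planted in flanks; 0 = off

    # artifact BSJs (true negatives)
    n_artifact: int = 40
    artifact_intergenic_fraction: float = 0.5
    n_ultralong: int = 3
    ultralong_span: int = 150_000

    # reliability-score model (Beta shapes; see methods note)
    true_score_beta: tuple[float, float] = (8.0, 2.0)
    artifact_score_beta: tuple[float, float] = (2.0, 8.0)

    # library design: five conditions, RNase R + control
    n_replicates: int = 2
    p_condition_detect: float = 0.4
    p_sample_detect: float = 0.7
    p_control_detect: float = 0.3
    mean_extra_bsj_reads: float = 1.2

    # linear reads at BSJ sites
    rnaser_linear_mean: float = 0.5
    control_linear_mean: float = 25.0
    control_circ_mean: float = 1.0

    # expression matrices
    n_expr_replicates: int = 2
    expression_rho: float = 0.34
    expression_log_sd: float = 0.15
    expression_mean_depth: float = 5000.0
    poisson_noise: bool = True  # False emits the latent means directly
    plant_de: bool = True
    de_log2fc: float = 2.0

    # miRNAs and planted target sites
    n_mirna: int = 10
    mirna_length: int = 21
    sites_per_mirna_circ: int = 2
    sites_per_mirna_mrna: int = 3

    # orthologs / conservation
    n_accordant: int = 5
    n_half_accordant: int = 5
    n_unaccordant: int = 5
    n_host_only_pairs: int = 10
    n_nonhost_pairs: int = 15
    ortholog_shift: int = 50

    # chloroplast
    chloroplast_contig: str = "chloroplast"
    chloroplast_length: int = 4000
    psba_start: int = 1500
    psba_length: int = 1200
    terminal_window_fraction: float = 0.2
    n_clustered_bsj: int = 24
    n_uniform_bsj: int = 0
    chloro_rnaser_read_mean: float = 40.0
    chloro_control_read_mean: float = 1.0

    def __post_init__(self) -> None:
        if self.n_genes < self.n_true_circ + 1:
            raise ConfigError("need more genes than planted circRNAs")
        if not 0.0 <= self.artifact_intergenic_fraction <= 1.0:
            raise ConfigError("artifact_intergenic_fraction must be in [0,1]")
        if not -1.0 <= self.expression_rho <= 1.0:
            raise ConfigError("expression_rho must be in [-1,1]")
        if self.host_exon_count_range[0] < 4:
            raise ConfigError("host genes need >= 4 exons to plant circRNAs")
        if not 19 <= self.mirna_length <= 25:
            raise ConfigError("mirna_length outside [19, 25]")

    @property
    def n_true_circ(self) -> int:
        return self.n_multi_exonic + self.n_single_exonic + self.n_intronic

    @property
    def rnaser_samples(self) -> list[str]:
        return [
            f"{c}_R{r}"
            for c in CONDITIONS
            for r in range(1, self.n_replicates + 1)
        ]

    @property
    def control_samples(self) -> list[str]:
        return [f"CK_C{r}" for r in range(1, self.n_replicates + 1)]

    @property
    def expr_samples(self) -> list[str]:
        return [
            f"{c}_E{r}"
            for c in CONDITIONS
            for r in range(1, self.n_expr_replicates + 1)
        ]


@dataclass
class SyntheticTruth:
    """Planted ground truth keyed consistently with every emitted record."""

    planted_circs: list[dict] = field(default_factory=list)
    artifacts: list[dict] = field(default_factory=list)
    host_genes: list[str] = field(default_factory=list)
    all_nuclear_genes: list[str] = field(default_factory=list)
    pair_rho: dict[str, float] = field(default_factory=dict)
    circ_effects: dict[str, dict[str, float]] = field(default_factory=dict)
    gene_effects: dict[str, dict[str, float]] = field(default_factory=dict)
    mirna_seqs: dict[str, str] = field(default_factory=dict)
    planted_sites: list[dict] = field(default_factory=list)
    ortholog_pairs: list[tuple[str, str]] = field(default_factory=list)
    conservation: list[dict] = field(default_factory=list)
    species_b_genes: dict[str, str] = field(default_factory=dict)  # id -> seq
    species_b_circs: list[dict] = field(default_factory=list)
    chloro_clustered: list[dict] = field(default_factory=list)
    chloro_uniform: list[dict] = field(default_factory=list)
    psba_gene: str = "psbA_like"

    def circ_by_id(self, circ_id: str) -> dict:
        for c in self.planted_circs:
            if c["circ_id"] == circ_id:
                return c
        raise KeyError(circ_id)

    def to_json(self, path: str | os.PathLike) -> None:
        payload = dataclasses.asdict(self)
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1, sort_keys=True)


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return rng.choice(_BASES, size=length).tobytes().decode()


def _rint(rng: np.random.Generator, lohi: tuple[int, int]) -> int:
    return int(rng.integers(lohi[0], lohi[1] + 1))


class _GeneBuild:
    """Scratch record for one gene while its contig is being assembled."""

    def __init__(self, gene_id, contig, strand, exons, is_host):
        self.gene_id = gene_id
        self.contig = contig
        self.strand = strand
        self.exons = exons  # list[(start, end)] genomic, sorted
        self.is_host = is_host
        self.isoform_drops: list[tuple[int, ...]] = []  # dropped exon indices
        self.circ_plan: tuple | None = None

    def to_model(self) -> GeneModel:
        ivs = [
            GenomicInterval(self.contig, s, e, self.strand) for s, e in self.exons
        ]
        txs = [Transcript(f"{self.gene_id}.t1", ivs)]
        for i, drop in enumerate(self.isoform_drops, start=2):
            kept = [iv for j, iv in enumerate(ivs) if j not in drop]
            txs.append(Transcript(f"{self.gene_id}.t{i}", kept))
        gene_iv = GenomicInterval(
            self.contig, self.exons[0][0], self.exons[-1][1], self.strand
        )
        return GeneModel(self.gene_id, gene_iv, txs)


def _spliced_offsets(exons: list[tuple[int, int]]) -> list[int]:
    offs, acc = [], 0
    for s, e in exons:
        offs.append(acc)
        acc += e - s
    return offs


def spliced_interval_of_span(
    exons: list[tuple[int, int]], strand: str, first: int, last: int
) -> tuple[int, int]:
    """Spliced-coordinate interval (transcript orientation) covered by
    exons ``first..last`` (inclusive) of a transcript given as genomic
    (start, end) pairs in genomic order."""
    offs = _spliced_offsets(exons)
    total = offs[-1] + (exons[-1][1] - exons[-1][0])
    lo = offs[first]
    hi = offs[last] + (exons[last][1] - exons[last][0])
    if strand == "-":
        lo, hi = total - hi, total - lo
    return lo, hi


def _write_in_exon(
    contig_chars: list[str],
    exon: tuple[int, int],
    strand: str,
    exon_spliced_offset: int,
    spliced_pos: int,
    pattern: str,
    total_spliced: int,
) -> None:
    """Overwrite genome characters so that the transcript's spliced
    sequence carries *pattern* starting at *spliced_pos* (transcript
    orientation).  The pattern must fall within the given exon."""
    if strand == "+":
        g0 = exon[0] + (spliced_pos - exon_spliced_offset)
        contig_chars[g0 : g0 + len(pattern)] = list(pattern)
    else:
        # transcript position p maps to genomic base (exon.end-1) - (p - off')
        # where off' is the exon's offset in reversed orientation
        rev_off = total_spliced - (exon_spliced_offset + (exon[1] - exon[0]))
        g_hi = exon[1] - (spliced_pos - rev_off)
        g0 = g_hi - len(pattern)
        contig_chars[g0:g_hi] = list(reverse_complement(pattern))


def generate_reference(
    config: GeneratorConfig,
) -> tuple[GenomeSequence, AnnotationSet, SyntheticTruth]:
    """Build genome + annotation with all planted features and the truth.

    Host genes are drawn with longer introns and more exons/isoforms than
    non-hosts, so the biogenesis propensities analysed downstream are
    present by construction.
    """
    rng = np.random.default_rng([config.seed, 11])
    truth = SyntheticTruth()

    n_true = config.n_true_circ
    circ_types = (
        ["multi-exonic"] * config.n_multi_exonic
        + ["single-exonic"] * config.n_single_exonic
        + ["intronic"] * config.n_intronic
    )

    # gene plan: hosts first (carrying one planted circ each), then non-hosts
    plans = [("host", t) for t in circ_types] + [
        ("nonhost", None) for _ in range(config.n_genes - n_true)
    ]
    order = rng.permutation(len(plans))

    contig_chars: dict[str, list[str]] = {
        f"chr{i + 1}": [] for i in range(config.n_contigs)
    }
    cursor = {c: 0 for c in contig_chars}
    builds: list[_GeneBuild] = []
    gap_regions: dict[str, list[tuple[int, int]]] = {c: [] for c in contig_chars}

    host_counter = 0
    nonhost_counter = 0
    gene_meta: dict[str, dict] = {}

    for k, idx in enumerate(order):
        kind, circ_type = plans[idx]
        contig = f"chr{(k % config.n_contigs) + 1}"
        chars = contig_chars[contig]

        gap = _rint(rng, config.intergenic_gap_range)
        gap_start = cursor[contig]
        chars.extend(_random_seq(rng, gap))
        cursor[contig] += gap
        gap_regions[contig].append((gap_start, cursor[contig]))

        if kind == "host":
            host_counter += 1
            gene_id = f"gH{host_counter:03d}"
            n_exons = _rint(rng, config.host_exon_count_range)
            intron_range = config.host_intron_length_range
        else:
            nonhost_counter += 1
            gene_id = f"gN{nonhost_counter:03d}"
            n_exons = _rint(rng, config.nonhost_exon_count_range)
            intron_range = config.nonhost_intron_length_range

        strand = "+" if rng.random() < 0.5 else "-"
        exons: list[tuple[int, int]] = []
        pos = cursor[contig]
        for e in range(n_exons):
            elen = _rint(rng, config.exon_length_range)
            chars.extend(_random_seq(rng, elen))
            exons.append((pos, pos + elen))
            pos += elen
            if e < n_exons - 1:
                ilen = _rint(rng, intron_range)
                chars.extend(_random_seq(rng, ilen))
                pos += ilen
        cursor[contig] = pos

        build = _GeneBuild(gene_id, contig, strand, exons, kind == "host")

        # plan the planted circRNA now so isoform construction can keep
        # clear of its exons (the classifier must recover the primary
        # transcript deterministically)
        protected: set[int] = set()
        circ_plan = None
        if kind == "host":
            if circ_type == "multi-exonic":
                first = int(rng.integers(1, n_exons - 3))
                span = int(rng.integers(2, min(4, n_exons - 1 - first) + 1))
                last = first + span - 1
                circ_plan = ("exonic", first, last)
            elif circ_type == "single-exonic":
                first = last = int(rng.integers(1, n_exons - 1))
                circ_plan = ("exonic", first, last)
            else:
                i = int(rng.integers(0, n_exons - 1))
                ist, ien = exons[i][1], exons[i + 1][0]
                margin = max(1, min(10, (ien - ist - 50) // 2))
                acc = ist + int(rng.integers(1, margin + 1))
                don = ien - int(rng.integers(1, margin + 1))
                circ_plan = ("intronic", i, acc, don)
                first, last = i, i + 1
            protected = set(range(first, last + 1))
        build.circ_plan = circ_plan

        # extra isoforms drop one random internal exon each
        iso_range = (
            config.host_isoform_range
            if kind == "host"
            else config.nonhost_isoform_range
        )
        n_iso = _rint(rng, iso_range)
        droppable = [
            i for i in range(1, n_exons - 1) if i not in protected
        ]
        for _ in range(n_iso - 1):
            if droppable:
                drop = droppable[int(rng.integers(0, len(droppable)))]
                build.isoform_drops.append((drop,))
        builds.append(build)
        gene_meta[gene_id] = {"build": build, "circ_type": circ_type}
        if kind == "host":
            truth.host_genes.append(gene_id)

    # trailing gap on each contig
    for contig in contig_chars:
        gap = _rint(rng, config.intergenic_gap_range)
        gap_start = cursor[contig]
        contig_chars[contig].extend(_random_seq(rng, gap))
        cursor[contig] += gap
        gap_regions[contig].append((gap_start, cursor[contig]))

    # ---- plant true circRNAs on host primary transcripts ----------------
    host_ids = sorted(truth.host_genes, key=lambda g: int(g[2:]))
    truth.host_genes = host_ids
    circ_no = 0
    for gene_id in host_ids:
        build: _GeneBuild = gene_meta[gene_id]["build"]
        circ_type = gene_meta[gene_id]["circ_type"]
        circ_no += 1
        circ_id = f"circ{circ_no:03d}"
        exons = build.exons
        plan = build.circ_plan
        if plan[0] == "exonic":
            first, last = plan[1], plan[2]
            acceptor, donor = exons[first][0], exons[last][1]
        else:  # intronic: strictly inside one intron
            _, _i, acceptor, donor = plan
            first = last = -1
        truth.planted_circs.append(
            {
                "circ_id": circ_id,
                "contig": build.contig,
                "acceptor": int(acceptor),
                "donor": int(donor),
                "strand": build.strand,
                "circ_type": circ_type,
                "host_gene": gene_id,
                "transcript_id": f"{gene_id}.t1",
                "first_exon": int(first),
                "last_exon": int(last),
            }
        )

    # ---- optional perfect ICS in flanking introns -----------------------
    if config.ics_length > 0:
        for circ in truth.planted_circs:
            if circ["circ_type"] == "intronic":
                continue
            build: _GeneBuild = gene_meta[circ["host_gene"]]["build"]
            exons = build.exons
            fi, la = circ["first_exon"], circ["last_exon"]
            up = (exons[fi - 1][1], exons[fi][0])  # intron left of acceptor
            down = (exons[la][1], exons[la + 1][0])  # intron right of donor
            L = config.ics_length
            if up[1] - up[0] < L + 4 or down[1] - down[0] < L + 4:
                continue
            seq = _random_seq(rng, L)
            chars = contig_chars[build.contig]
            u0 = (up[0] + up[1] - L) // 2
            d0 = (down[0] + down[1] - L) // 2
            chars[u0 : u0 + L] = list(seq)
            chars[d0 : d0 + L] = list(reverse_complement(seq))
            circ["ics"] = {"seq": seq, "up_pos": u0, "down_pos": d0}

    # ---- miRNAs and planted binding sites -------------------------------
    mirna_ids = ["miR8633"] + [
        f"miR{900 + i:03d}" for i in range(1, config.n_mirna)
    ]
    for mid in mirna_ids:
        truth.mirna_seqs[mid] = _random_seq(rng, config.mirna_length)

    nonhost_ids = sorted(
        (g for g in gene_meta if g.startswith("gN")), key=lambda g: int(g[2:])
    )
    exonic_circs = [
        c for c in truth.planted_circs if c["circ_type"] != "intronic"
    ]
    hub_circ_targets = [c["circ_id"] for c in exonic_circs[:3]]
    hub_gene_targets = nonhost_ids[:4]
    used_exon_ranges: dict[tuple[str, int], list[tuple[int, int]]] = {}

    def _plant_site(mid: str, target_kind: str, target_id: str) -> None:
        """Write revcomp(miRNA) into one exon so the spliced target
        sequence carries a perfect site; records spliced position."""
        mseq = truth.mirna_seqs[mid]
        site = reverse_complement(mseq)
        L = len(site)
        if target_kind == "circRNA":
            circ = truth.circ_by_id(target_id)
            if circ["circ_type"] == "intronic":
                raise ConfigError("sites are planted in exonic circRNAs only")
            build = gene_meta[circ["host_gene"]]["build"]
            lo_e, hi_e = circ["first_exon"], circ["last_exon"]
        else:
            build = gene_meta[target_id]["build"]
            lo_e, hi_e = 0, len(build.exons) - 1
        exons = build.exons
        offs = _spliced_offsets(exons)
        total = offs[-1] + (exons[-1][1] - exons[-1][0])
        order_e = list(rng.permutation(range(lo_e, hi_e + 1)))
        for ei in order_e:
            s, e = exons[ei]
            if e - s < L + 4:
                continue
            key = (build.gene_id, ei)
            taken = used_exon_ranges.setdefault(key, [])
            for _try in range(20):
                off = int(rng.integers(2, e - s - L - 1))
                if all(
                    off + L <= a or off >= b for a, b in taken
                ):
                    taken.append((off, off + L))
                    spliced_pos = offs[ei] + off
                    if build.strand == "-":
                        # transcript orientation position of the site start
                        spliced_pos = total - (spliced_pos + L)
                    _write_in_exon(
                        contig_chars[build.contig],
                        exons[ei],
                        build.strand,
                        offs[ei],
                        spliced_pos,
                        site,
                        total,
                    )
                    if target_kind == "circRNA":
                        lo, _hi = spliced_interval_of_span(
                            exons, build.strand, lo_e, hi_e
                        )
                        pos_in_target = spliced_pos - lo
                    else:
                        pos_in_target = spliced_pos
                    truth.planted_sites.append(
                        {
                            "mirna_id": mid,
                            "target_id": target_id,
                            "target_kind": target_kind,
                            "position": int(pos_in_target),
                        }
                    )
                    return
        raise ConfigError(
            f"could not place site for {mid} in {target_kind} {target_id}"
        )

    # hub miRNA: fixed sponge wiring (circ partners / mRNA targets)
    for cid in hub_circ_targets:
        _plant_site(mirna_ids[0], "circRNA", cid)
    for gid in hub_gene_targets:
        _plant_site(mirna_ids[0], "mRNA", gid)
    # remaining miRNAs: random targets
    for i, mid in enumerate(mirna_ids[1:], start=1):
        circ_pool = [
            c["circ_id"]
            for c in exonic_circs
            if c["circ_id"] not in hub_circ_targets
        ]
        picks_c = rng.choice(
            len(circ_pool), size=config.sites_per_mirna_circ, replace=False
        )
        for j in picks_c:
            _plant_site(mid, "circRNA", circ_pool[int(j)])
        gene_pool = nonhost_ids[4:]
        picks_g = rng.choice(
            len(gene_pool), size=config.sites_per_mirna_mrna, replace=False
        )
        for j in picks_g:
            _plant_site(mid, "mRNA", gene_pool[int(j)])

    # ---- differential-expression plan (condition effects) ---------------
    if config.plant_de:
        lfc = config.de_log2fc
        hosts_of = {
            c["circ_id"]: c["host_gene"] for c in truth.planted_circs
        }
        # cold: hub sponge circs up (hosts stable) + 8 reversed pairs
        for cid in hub_circ_targets:
            truth.circ_effects.setdefault(cid, {})["cold"] = lfc
        for gid in hub_gene_targets:
            truth.gene_effects.setdefault(gid, {})["cold"] = -lfc
        reversed_ids = [f"circ{i:03d}" for i in range(10, 15)]
        for cid in reversed_ids:
            truth.circ_effects.setdefault(cid, {})["cold"] = lfc
            truth.gene_effects.setdefault(hosts_of[cid], {})["cold"] = -lfc
        # UVB: 3 coordinated pairs
        for cid in [f"circ{i:03d}" for i in range(20, 23)]:
            truth.circ_effects.setdefault(cid, {})["UVB"] = lfc
            truth.gene_effects.setdefault(hosts_of[cid], {})["UVB"] = lfc
        # salt: 2 circs down; heat: 1 circ up (weakest response)
        for cid in ("circ025", "circ026"):
            truth.circ_effects.setdefault(cid, {})["salt"] = -lfc
        truth.circ_effects.setdefault("circ030", {})["heat"] = lfc

    # ---- artifact BSJs --------------------------------------------------
    n_intergenic = round(config.n_artifact * config.artifact_intergenic_fraction)
    contigs = sorted(contig_chars)
    for a in range(config.n_artifact):
        intergenic = a < n_intergenic
        bsj_id = f"art{a + 1:03d}"
        if intergenic:
            contig = contigs[a % len(contigs)]
            gaps = [g for g in gap_regions[contig] if g[1] - g[0] > 200]
            gs, ge = gaps[int(rng.integers(0, len(gaps)))]
            acceptor = int(rng.integers(gs + 5, ge - 100))
            donor = int(rng.integers(acceptor + 50, ge - 1))
        else:
            build = builds[int(rng.integers(0, len(builds)))]
            g0, g1 = build.exons[0][0], build.exons[-1][1]
            acceptor = int(rng.integers(g0 + 3, g1 - 60))
            donor = int(rng.integers(acceptor + 40, g1))
            contig = build.contig
        truth.artifacts.append(
            {
                "bsj_id": bsj_id,
                "contig": contig,
                "acceptor": acceptor,
                "donor": donor,
                "strand": "+" if rng.random() < 0.5 else "-",
                "intergenic": bool(intergenic),
                "ultralong": False,
            }
        )

    # ultra-long artifacts live on a dedicated long scaffold
    if config.n_ultralong > 0:
        name = "scaffold_UL"
        length = config.ultralong_span + 2000
        contig_chars[name] = list(_random_seq(rng, length))
        gap_regions[name] = [(0, length)]
        for u in range(config.n_ultralong):
            acceptor = int(rng.integers(0, 500))
            donor = acceptor + config.ultralong_span + int(rng.integers(0, 500))
            truth.artifacts.append(
                {
                    "bsj_id": f"ultra{u + 1:03d}",
                    "contig": name,
                    "acceptor": acceptor,
                    "donor": donor,
                    "strand": "+",
                    "intergenic": True,
                    "ultralong": True,
                }
            )

    # ---- chloroplast ----------------------------------------------------
    cp = config.chloroplast_contig
    contig_chars[cp] = list(_random_seq(rng, config.chloroplast_length))
    ps, pe = config.psba_start, config.psba_start + config.psba_length
    if pe > config.chloroplast_length:
        raise ConfigError("psbA-like gene exceeds chloroplast length")
    win = int(round(config.psba_length * config.terminal_window_fraction))
    wstart, wend = pe - win, pe  # '+' strand: 3' end is the right end
    seen = set()
    for b in range(config.n_clustered_bsj):
        for _try in range(100):
            acceptor = int(rng.integers(wstart, wend - 30))
            donor = int(rng.integers(acceptor + 25, wend))
            if (acceptor, donor) not in seen:
                seen.add((acceptor, donor))
                break
        truth.chloro_clustered.append(
            {
                "bsj_id": f"cp{b + 1:03d}",
                "contig": cp,
                "acceptor": acceptor,
                "donor": donor,
                "strand": "+",
            }
        )
    for b in range(config.n_uniform_bsj):
        acceptor = int(rng.integers(ps, pe - 60))
        donor = int(rng.integers(acceptor + 50, pe))
        truth.chloro_uniform.append(
            {
                "bsj_id": f"cpu{b + 1:03d}",
                "contig": cp,
                "acceptor": acceptor,
                "donor": donor,
                "strand": "+",
            }
        )

    # ---- finalize genome / annotation -----------------------------------
    genome = GenomeSequence(
        {name: "".join(chars) for name, chars in contig_chars.items()}
    )
    truth.all_nuclear_genes = sorted(b.gene_id for b in builds)
    models = [b.to_model() for b in builds]
    models.append(
        GeneModel(
            truth.psba_gene,
            GenomicInterval(cp, ps, pe, "+"),
            [
                Transcript(
                    f"{truth.psba_gene}.t1",
                    [GenomicInterval(cp, ps, pe, "+")],
                )
            ],
        )
    )
    annotation = AnnotationSet(models)

    # ---- ortholog species B + conservation categories -------------------
    _build_species_b(config, rng, truth, annotation, genome, gene_meta)

    # expression correlation plan
    for circ in truth.planted_circs:
        truth.pair_rho[circ["circ_id"]] = config.expression_rho

    return genome, annotation, truth


def _build_species_b(config, rng, truth, annotation, genome, gene_meta):
    """Species-B genes copy the A host's primary spliced sequence; B circ
    splice sites are copied (Accordant) or shifted past tolerance."""
    cats = (
        ["Accordant"] * config.n_accordant
        + ["Half-accordant"] * config.n_half_accordant
        + ["Unaccordant"] * config.n_unaccordant
    )
    all_exonic = [
        c for c in truth.planted_circs if c["circ_type"] != "intronic"
    ]
    hub = {c["circ_id"] for c in all_exonic[:3]}  # hub sponge partners
    exonic = [c for c in all_exonic if c["circ_id"] not in hub]
    if len(exonic) < len(cats):
        raise ConfigError("not enough exonic circRNAs for conservation mix")
    conserved_circs = exonic[: len(cats)]
    used_hosts = []

    for circ, cat in zip(conserved_circs, cats):
        gid = circ["host_gene"]
        used_hosts.append(gid)
        bgid = f"B_{gid}"
        tx = annotation.gene(gid).transcripts[0]
        seq = tx.spliced_sequence(genome)
        truth.species_b_genes[bgid] = seq
        build = gene_meta[gid]["build"]
        lo, hi = spliced_interval_of_span(
            build.exons, build.strand, circ["first_exon"], circ["last_exon"]
        )
        shift = config.ortholog_shift
        if cat == "Accordant":
            b_acc, b_don = lo, hi
        elif cat == "Half-accordant":
            b_acc, b_don = lo, min(hi + shift, len(seq))
        else:
            b_acc, b_don = max(lo - shift, 0) if lo >= shift else lo + shift, hi + shift
            b_don = min(b_don, len(seq))
            if b_acc >= b_don:
                b_acc = max(0, b_don - 60)
        truth.ortholog_pairs.append((gid, bgid))
        truth.species_b_circs.append(
            {
                "circ_id": f"B_{circ['circ_id']}",
                "gene": bgid,
                "acceptor": int(b_acc),
                "donor": int(b_don),
            }
        )
        truth.conservation.append(
            {
                "gene_a": gid,
                "gene_b": bgid,
                "circ_a": circ["circ_id"],
                "circ_b": f"B_{circ['circ_id']}",
                "category": cat,
            }
        )

    # host pairs whose B ortholog produces no circRNA
    remaining_hosts = [g for g in truth.host_genes if g not in used_hosts]
    for gid in remaining_hosts[: config.n_host_only_pairs]:
        bgid = f"B_{gid}"
        tx = annotation.gene(gid).transcripts[0]
        truth.species_b_genes[bgid] = tx.spliced_sequence(genome)
        truth.ortholog_pairs.append((gid, bgid))

    # non-host pairs
    nonhosts = sorted(
        (g.gene_id for g in annotation.genes if g.gene_id.startswith("gN")),
        key=lambda g: int(g[2:]),
    )
    for gid in nonhosts[: config.n_nonhost_pairs]:
        bgid = f"B_{gid}"
        tx = annotation.gene(gid).transcripts[0]
        truth.species_b_genes[bgid] = tx.spliced_sequence(genome)
        truth.ortholog_pairs.append((gid, bgid))


def species_b_resources(
    truth: SyntheticTruth,
) -> tuple[GenomeSequence, AnnotationSet, pd.DataFrame]:
    """Assemble the second species: genome, single-exon annotation, and
    its BSJ table (genomic coordinates on contig ``B_chr1``)."""
    chars: list[str] = []
    genes = []
    offsets: dict[str, int] = {}
    pos = 0
    for bgid in sorted(truth.species_b_genes):
        seq = truth.species_b_genes[bgid]
        chars.append("N" * 200)
        pos += 200
        offsets[bgid] = pos
        chars.append(seq)
        iv = GenomicInterval("B_chr1", pos, pos + len(seq), "+")
        genes.append(
            GeneModel(bgid, iv, [Transcript(f"{bgid}.t1", [iv])])
        )
        pos += len(seq)
    chars.append("N" * 200)
    genome = GenomeSequence({"B_chr1": "".join(chars)})
    annotation = AnnotationSet(genes)
    rows = [
        {
            "circ_id": c["circ_id"],
            "gene": c["gene"],
            "contig": "B_chr1",
            "acceptor": offsets[c["gene"]] + c["acceptor"],
            "donor": offsets[c["gene"]] + c["donor"],
            "strand": "+",
        }
        for c in truth.species_b_circs
    ]
    return genome, annotation, pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# candidate tables
# ---------------------------------------------------------------------------

def _true_score(rng, config) -> float:
    a, b = config.true_score_beta
    return 0.15 + 0.85 * float(rng.beta(a, b))


def _artifact_score(rng, config, ceiling: float) -> float:
    a, b = config.artifact_score_beta
    return ceiling * float(rng.beta(a, b))


def simulate_bsj_candidates(
    truth: SyntheticTruth, config: GeneratorConfig
) -> pd.DataFrame:
    """Nuclear BSJ candidate table over RNase R and control libraries.

    True circRNAs receive scores above the RNase R retention threshold;
    artifacts stay below their library's threshold, with the configured
    intergenic fraction.  Every candidate carries sample/condition/library
    labels.
    """
    rng = np.random.default_rng([config.seed, 23])
    rows = []

    def emit(rec, sample, condition, library, score, reads, bsj_id):
        rows.append(
            {
                "chrom": rec["contig"],
                "acceptor": rec["acceptor"],
                "donor": rec["donor"],
                "strand": rec["strand"],
                "score": round(float(score), 6),
                "bsj_reads": int(reads),
                "sample": sample,
                "condition": condition,
                "library": library,
                "bsj_id": bsj_id,
            }
        )

    for circ in truth.planted_circs:
        emitted = 0
        for cond in CONDITIONS:
            if rng.random() >= config.p_condition_detect:
                continue
            for r in range(1, config.n_replicates + 1):
                if rng.random() >= config.p_sample_detect:
                    continue
                reads = 1 + int(rng.poisson(config.mean_extra_bsj_reads))
                emit(
                    circ,
                    f"{cond}_R{r}",
                    cond,
                    "rnaser",
                    _true_score(rng, config),
                    reads,
                    circ["circ_id"],
                )
                emitted += 1
        if emitted == 0:  # guarantee detection somewhere
            cond = CONDITIONS[int(rng.integers(0, len(CONDITIONS)))]
            emit(
                circ,
                f"{cond}_R1",
                cond,
                "rnaser",
                _true_score(rng, config),
                1,
                circ["circ_id"],
            )
        if rng.random() < config.p_control_detect:
            for sample in config.control_samples:
                if rng.random() < 0.7:
                    emit(
                        circ,
                        sample,
                        "CK",
                        "control",
                        0.905 + 0.094 * rng.random(),
                        1 + int(rng.poisson(config.control_circ_mean)),
                        circ["circ_id"],
                    )

    samples = config.rnaser_samples
    for art in truth.artifacts:
        k = 1 + int(rng.integers(0, 2))
        picks = rng.choice(len(samples), size=k, replace=False)
        if art["ultralong"]:
            score = 0.5 + 0.5 * float(rng.beta(*config.true_score_beta))
        else:
            score = _artifact_score(rng, config, 0.0999)
        for j in picks:
            sample = samples[int(j)]
            emit(
                art,
                sample,
                sample.rsplit("_", 1)[0],
                "rnaser",
                score,
                1 + int(rng.poisson(0.5)),
                art["bsj_id"],
            )
        if not art["ultralong"] and rng.random() < 0.5:
            emit(
                art,
                config.control_samples[0],
                "CK",
                "control",
                _artifact_score(rng, config, 0.8999),
                1,
                art["bsj_id"],
            )

    return pd.DataFrame(rows)


def simulate_chloroplast_bsjs(
    truth: SyntheticTruth, config: GeneratorConfig
) -> pd.DataFrame:
    """Chloroplast BSJ candidates: abundant in RNase R libraries, sparse
    in controls, clustered in the psbA-like 3' window per the truth."""
    rng = np.random.default_rng([config.seed, 31])
    rows = []
    for rec in truth.chloro_clustered + truth.chloro_uniform:
        for sample in config.rnaser_samples:
            rows.append(
                {
                    "chrom": rec["contig"],
                    "acceptor": rec["acceptor"],
                    "donor": rec["donor"],
                    "strand": rec["strand"],
                    "score": round(0.3 + 0.7 * float(rng.beta(8, 2)), 6),
                    "bsj_reads": 1 + int(rng.poisson(config.chloro_rnaser_read_mean)),
                    "sample": sample,
                    "condition": sample.rsplit("_", 1)[0],
                    "library": "rnaser",
                    "bsj_id": rec["bsj_id"],
                }
            )
        for sample in config.control_samples:
            if rng.random() < 0.5:
                rows.append(
                    {
                        "chrom": rec["contig"],
                        "acceptor": rec["acceptor"],
                        "donor": rec["donor"],
                        "strand": rec["strand"],
                        "score": round(0.905 + 0.094 * rng.random(), 6),
                        "bsj_reads": 1 + int(rng.poisson(config.chloro_control_read_mean)),
                        "sample": sample,
                        "condition": "CK",
                        "library": "control",
                        "bsj_id": rec["bsj_id"],
                    }
                )
    return pd.DataFrame(rows)


def simulate_linear_counts(
    truth: SyntheticTruth,
    config: GeneratorConfig,
    candidates: pd.DataFrame,
) -> pd.DataFrame:
    """Linear read counts at each BSJ site, per library type.

    RNase R digestion removes most linear molecules, so linear support is
    low in treated libraries and high in controls -- the contrast behind
    the circular-to-linear-ratio comparison.
    """
    rng = np.random.default_rng([config.seed, 41])
    keys = candidates[["chrom", "acceptor", "donor", "strand"]].drop_duplicates()
    rows = []
    for _, k in keys.iterrows():
        for library, mean in (
            ("rnaser", config.rnaser_linear_mean),
            ("control", config.control_linear_mean),
        ):
            rows.append(
                {
                    "chrom": k["chrom"],
                    "acceptor": int(k["acceptor"]),
                    "donor": int(k["donor"]),
                    "strand": k["strand"],
                    "library": library,
                    "linear_reads": int(rng.poisson(mean)),
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# expression
# ---------------------------------------------------------------------------

def simulate_expression(
    truth: SyntheticTruth, config: GeneratorConfig
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """CircRNA and gene count matrices (features x samples).

    Each circ-host pair shares a latent bivariate log-normal with the
    configured correlation rho; counts are Poisson draws around the latent
    means.  Planted condition effects (log2 fold changes) are applied on
    top when ``plant_de`` is set.
    """
    if config.n_expr_replicates * len(CONDITIONS) < 3:
        raise ConfigError("need >= 3 expression samples for correlations")
    rng = np.random.default_rng([config.seed, 53])
    samples = config.expr_samples
    conds = [s.rsplit("_", 1)[0] for s in samples]
    n = len(samples)
    s = config.expression_log_sd
    base = np.log(config.expression_mean_depth) - s * s / 2.0
    ln2 = np.log(2.0)

    def draw(mu: np.ndarray) -> np.ndarray:
        lam = np.exp(mu)
        return rng.poisson(lam) if config.poisson_noise else np.round(lam, 6)

    circ_rows, circ_ids = [], []
    gene_rows_map: dict[str, np.ndarray] = {}

    for circ in truth.planted_circs:
        cid, gid = circ["circ_id"], circ["host_gene"]
        rho = truth.pair_rho.get(cid, config.expression_rho)
        z1 = rng.standard_normal(n)
        z_extra = rng.standard_normal(n)
        z2 = rho * z1 + np.sqrt(max(0.0, 1.0 - rho * rho)) * z_extra
        mu_c = base + s * z1
        mu_g = base + s * z2
        if config.plant_de:
            for j, cond in enumerate(conds):
                mu_c[j] += ln2 * truth.circ_effects.get(cid, {}).get(cond, 0.0)
                mu_g[j] += ln2 * truth.gene_effects.get(gid, {}).get(cond, 0.0)
        circ_ids.append(cid)
        circ_rows.append(draw(mu_c))
        gene_rows_map[gid] = draw(mu_g)

    # every other nuclear gene: independent expression, planted effects
    for gid in truth.all_nuclear_genes:
        if gid in gene_rows_map:
            continue
        mu = base + s * rng.standard_normal(n)
        if config.plant_de:
            for j, cond in enumerate(conds):
                mu[j] += ln2 * truth.gene_effects.get(gid, {}).get(cond, 0.0)
        gene_rows_map[gid] = draw(mu)

    # chloroplast circRNAs: stable and abundant (they dominate the pool)
    cp_base = np.log(10.0 * config.expression_mean_depth) - s * s / 2.0
    for rec in truth.chloro_clustered + truth.chloro_uniform:
        mu = cp_base + s * rng.standard_normal(n)
        circ_ids.append(rec["bsj_id"])
        circ_rows.append(draw(mu))

    circ_df = pd.DataFrame(circ_rows, index=circ_ids, columns=samples)
    gene_ids = sorted(gene_rows_map)
    gene_df = pd.DataFrame(
        [gene_rows_map[g] for g in gene_ids], index=gene_ids, columns=samples
    )
    circ_df.index.name = "feature"
    gene_df.index.name = "feature"
    return circ_df, gene_df


def simulate_mirna_expression(
    truth: SyntheticTruth, config: GeneratorConfig
) -> pd.DataFrame:
    """Per-miRNA basal RPM and per-stress log2 fold change (hub miRNA is
    strongly stress-responsive)."""
    rng = np.random.default_rng([config.seed, 61])
    rows = []
    for mid in truth.mirna_seqs:
        base = float(np.exp(rng.normal(4.0, 1.0)))
        rec = {"mirna_id": mid, "CK_rpm": round(base, 2)}
        for st in STRESSES:
            if mid == "miR8633":
                lfc = {"cold": 2.5, "heat": 1.2, "salt": 1.8, "UVB": 2.0}[st]
            else:
                lfc = float(rng.normal(0.0, 0.4))
            rec[f"{st}_log2fc"] = round(lfc, 3)
        rows.append(rec)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# bundle + file emission
# ---------------------------------------------------------------------------

@dataclass
class SyntheticBundle:
    """Everything the pipeline consumes, generated in one shot."""

    config: GeneratorConfig
    genome: GenomeSequence
    annotation: AnnotationSet
    truth: SyntheticTruth
    candidates: pd.DataFrame
    chloro_candidates: pd.DataFrame
    linear_counts: pd.DataFrame
    circ_counts: pd.DataFrame
    gene_counts: pd.DataFrame
    mirna_expression: pd.DataFrame
    genome_b: GenomeSequence
    annotation_b: AnnotationSet
    bsj_b: pd.DataFrame


def generate_bundle(config: GeneratorConfig) -> SyntheticBundle:
    genome, annotation, truth = generate_reference(config)
    candidates = simulate_bsj_candidates(truth, config)
    chloro = simulate_chloroplast_bsjs(truth, config)
    linear = simulate_linear_counts(
        truth, config, pd.concat([candidates, chloro], ignore_index=True)
    )
    circ_counts, gene_counts = simulate_expression(truth, config)
    mirna_expr = simulate_mirna_expression(truth, config)
    genome_b, annotation_b, bsj_b = species_b_resources(truth)
    return SyntheticBundle(
        config,
        genome,
        annotation,
        truth,
        candidates,
        chloro,
        linear,
        circ_counts,
        gene_counts,
        mirna_expr,
        genome_b,
        annotation_b,
        bsj_b,
    )


def write_bundle(bundle: SyntheticBundle, outdir: str | os.PathLike) -> dict:
    """Write every input file; returns the path map used by the pipeline."""
    outdir = str(outdir)
    os.makedirs(outdir, exist_ok=True)
    p = {k: os.path.join(outdir, v) for k, v in {
        "genome": "genome.fa",
        "annotation": "annotation.gff3",
        "candidates": "bsj_candidates.tsv",
        "chloro_candidates": "chloroplast_bsjs.tsv",
        "linear_counts": "linear_counts.tsv",
        "circ_counts": "circ_counts.tsv",
        "gene_counts": "gene_counts.tsv",
        "mirna_fasta": "mirna.fa",
        "mirna_expression": "mirna_expression.tsv",
        "orthologs": "orthologs.tsv",
        "genome_b": "species_b_genome.fa",
        "annotation_b": "species_b.gff3",
        "bsj_b": "species_b_bsjs.tsv",
        "truth": "truth.json",
    }.items()}
    bundle.genome.to_fasta(p["genome"])
    bundle.annotation.to_gff3(p["annotation"])
    bundle.candidates.to_csv(p["candidates"], sep="\t", index=False)
    bundle.chloro_candidates.to_csv(p["chloro_candidates"], sep="\t", index=False)
    bundle.linear_counts.to_csv(p["linear_counts"], sep="\t", index=False)
    bundle.circ_counts.to_csv(p["circ_counts"], sep="\t")
    bundle.gene_counts.to_csv(p["gene_counts"], sep="\t")
    with open(p["mirna_fasta"], "w") as fh:
        for mid, seq in sorted(bundle.truth.mirna_seqs.items()):
            fh.write(f">{mid}\n{seq}\n")
    bundle.mirna_expression.to_csv(p["mirna_expression"], sep="\t", index=False)
    pd.DataFrame(
        bundle.truth.ortholog_pairs, columns=["gene_a", "gene_b"]
    ).to_csv(p["orthologs"], sep="\t", index=False)
    bundle.genome_b.to_fasta(p["genome_b"])
    bundle.annotation_b.to_gff3(p["annotation_b"])
    bundle.bsj_b.to_csv(p["bsj_b"], sep="\t", index=False)
    bundle.truth.to_json(p["truth"])
    return p
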