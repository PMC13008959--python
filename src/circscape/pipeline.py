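"""End-to-end orchestration of the circRNAome characterization stages.

Stages run in dependency order: filtering -> structural annotation ->
biogenesis features -> conservation -> expression coupling -> ceRNA
network -> organellar analysis.  Optional stages whose inputs are absent
are skipped with a logged warning.  All randomness is seeded from the
single pipeline seed, and the summary JSON is byte-identical across
reruns with the same configuration.
"""

from __future__ import annotations

import hashlib
import json
import logging
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import annotate, biogenesis, cerna, conservation, coupling, filtering, organellar
from .genome import AnnotationSet, GenomeSequence, Transcript, write_bed6

logger = logging.getLogger("circscape")


class PipelineConfigError(ValueError):
    pass


@dataclass
class PipelineConfig:
    """Paths to every input plus all stage parameters."""

    paths: dict[str, str]
    retention: filtering.RetentionConfig = field(
        default_factory=filtering.RetentionConfig
    )
    classify_tolerance: int = 0
    conservation_tolerance: int = 10
    de_alpha: float = 0.05
    de_fc_floor: float = 1.0
    target_profiles: dict[str, float] = field(
        default_factory=lambda: dict(cerna.DEFAULT_PROFILES)
    )
    terminal_window_fraction: float = 0.2
    n_permutations: int = 10_000
    n_ics_controls: int = 30
    control_condition: str = "CK"
    chloroplast_contigs: tuple[str, ...] = ("chloroplast",)
    seed: int = 0

    MANDATORY = ("genome", "annotation", "candidates")

    def validate(self) -> None:
        for key in self.MANDATORY:
            if key not in self.paths:
                raise PipelineConfigError(f"missing mandatory input: {key}")
            if not os.path.exists(self.paths[key]):
                raise PipelineConfigError(
                    f"input file not found: {key} = {self.paths[key]}"
                )


@dataclass
class ReportBundle:
    tables: dict[str, object] = field(default_factory=dict)
    summary: dict = field(default_factory=dict)
    log: list[str] = field(default_factory=list)

    def note(self, msg: str) -> None:
        logger.info(msg)
        self.log.append(msg)


def _spliced_sites(tx: Transcript, first: int, last: int) -> tuple[int, int]:
    """Spliced-coordinate interval (transcript orientation) of the exon
    span first..last of a transcript."""
    offs, acc = [], 0
    for e in tx.exons:
        offs.append(acc)
        acc += len(e)
    total = acc
    lo = offs[first]
    hi = offs[last] + len(tx.exons[last])
    if tx.span.strand == "-":
        lo, hi = total - hi, total - lo
    return lo, hi


def _input_checksums(paths: dict[str, str]) -> dict[str, str]:
    out = {}
    for key, path in sorted(paths.items()):
        if os.path.exists(path):
            h = hashlib.sha256()
            with open(path, "rb") as fh:
                for chunk in iter(lambda: fh.read(1 << 20), b""):
                    h.update(chunk)
            out[key] = h.hexdigest()[:16]
    return out


def run_pipeline(config: PipelineConfig) -> ReportBundle:
    config.validate()
    bundle = ReportBundle()
    bundle.summary["parameters"] = {
        "retention": vars(config.retention),
        "classify_tolerance": config.classify_tolerance,
        "conservation_tolerance": config.conservation_tolerance,
        "de_alpha": config.de_alpha,
        "de_fc_floor": config.de_fc_floor,
        "target_profiles": config.target_profiles,
        "terminal_window_fraction": config.terminal_window_fraction,
        "n_permutations": config.n_permutations,
        "seed": config.seed,
    }
    bundle.summary["input_checksums"] = _input_checksums(config.paths)

    genome = GenomeSequence.from_fasta(config.paths["genome"])
    annotation = AnnotationSet.from_gff3(config.paths["annotation"])
    annotation.known_contigs |= set(genome.contigs)
    candidates = filtering.read_candidates(config.paths["candidates"])
    chloro = None
    if "chloro_candidates" in config.paths:
        chloro = filtering.read_candidates(config.paths["chloro_candidates"])

    # ---- stage 1: filtering --------------------------------------------
    strat = filtering.score_stratification(candidates, annotation)
    retained = filtering.apply_retention(candidates, config.retention, annotation)
    circs = filtering.merge_unique(retained, annotation)
    # carry the upstream caller's junction ids when present so expression
    # matrices and truth tables join on the same names
    if "bsj_id" in candidates.columns:
        key_to_ext: dict[tuple, str] = {}
        for r in candidates.itertuples():
            key_to_ext.setdefault(
                (r.chrom, int(r.acceptor), int(r.donor), r.strand), str(r.bsj_id)
            )
        seen: set[str] = set()
        for c in circs:
            ext = key_to_ext.get(c.key)
            if ext and ext not in seen:
                c.circ_id = ext
            seen.add(c.circ_id)
    sets = filtering.condition_sets(
        retained, conditions=[c for c in sorted(set(retained["condition"])) if c != config.control_condition]
    )
    venn = (
        filtering.condition_overlap(sets) if len(sets) >= 2 else None
    )
    bundle.tables["score_stratification"] = strat
    bundle.tables["retained_candidates"] = retained
    bundle.tables["circrnas"] = circs
    bundle.tables["condition_overlap"] = venn
    if "linear_counts" in config.paths:
        linear = pd.read_csv(config.paths["linear_counts"], sep="\t")
        clr = filtering.clr_table(
            pd.concat([candidates] + ([chloro] if chloro is not None else []),
                      ignore_index=True),
            linear,
        )
        bundle.tables["clr"] = clr
        bundle.tables["clr_contrast"] = filtering.clr_library_contrast(clr)
    bundle.note(f"retained {len(circs)} unique circRNAs")

    # ---- stage 2: structural annotation --------------------------------
    classifications = annotate.classify_all(
        circs, annotation, config.classify_tolerance
    )
    type_counts = {t: 0 for t in annotate.CIRC_TYPES}
    for cls in classifications.values():
        type_counts[cls.circ_type] += 1
    bundle.tables["classifications"] = classifications
    bundle.tables["chromosome_distribution"] = annotate.chromosome_distribution(circs)
    bundle.note(f"type counts: {type_counts}")

    # ---- stage 3: biogenesis features ----------------------------------
    host_ids = {g for c in circs for g in c.host_gene_ids}
    host_ids &= {g.gene_id for g in annotation.genes}
    intron_classes = biogenesis.intron_length_classes(
        circs, classifications, annotation
    )
    features = {
        "intron_medians": {
            k: float(np.median(v)) if v else None
            for k, v in intron_classes.items()
        },
        "host_comparison": biogenesis.host_feature_comparison(annotation, host_ids)
        if host_ids
        else None,
        "propensity_exons": biogenesis.propensity_by_bin(
            annotation, host_ids, "exons"
        ),
    }
    try:
        features["ics_control"] = biogenesis.ics_control_comparison(
            circs,
            classifications,
            annotation,
            genome,
            n_controls=config.n_ics_controls,
            seed=config.seed + 101,
        )
    except ValueError as exc:
        bundle.note(f"ICS control comparison skipped: {exc}")
        features["ics_control"] = None
    bundle.tables["biogenesis"] = features
    bundle.tables["intron_classes"] = intron_classes

    # ---- stage 4: conservation (optional) ------------------------------
    cons_keys = ("orthologs", "annotation_b", "genome_b", "bsj_b")
    if all(k in config.paths and os.path.exists(config.paths[k]) for k in cons_keys):
        ortho_df = pd.read_csv(config.paths["orthologs"], sep="\t")
        omap = conservation.OrthologMap(
            [tuple(r) for r in ortho_df.itertuples(index=False)]
        )
        annotation_b = AnnotationSet.from_gff3(config.paths["annotation_b"])
        genome_b = GenomeSequence.from_fasta(config.paths["genome_b"])
        bsj_b = pd.read_csv(config.paths["bsj_b"], sep="\t")
        hosts_b = set(bsj_b["gene"])
        overlap, p = conservation.ortholog_overlap_test(host_ids, hosts_b, omap)
        calls = _conservation_calls(
            circs,
            classifications,
            annotation,
            genome,
            annotation_b,
            genome_b,
            bsj_b,
            omap,
            config.conservation_tolerance,
        )
        bundle.tables["conservation_calls"] = calls
        bundle.tables["conservation"] = {
            "ortholog_overlap": overlap,
            "hypergeometric_p": p,
            "category_counts": conservation.conservation_summary(calls),
        }
        bundle.note(f"conservation: overlap={overlap}, p={p:.3g}")
    else:
        bundle.note("conservation stage skipped: ortholog inputs absent")
        bundle.tables["conservation"] = None

    # ---- stage 5: expression coupling (optional) ------------------------
    coupling_summary = None
    circ_states: dict[str, dict[str, dict]] = {}
    gene_de: dict[str, pd.DataFrame] = {}
    if all(k in config.paths for k in ("circ_counts", "gene_counts")):
        circ_counts = pd.read_csv(config.paths["circ_counts"], sep="\t", index_col=0)
        gene_counts = pd.read_csv(config.paths["gene_counts"], sep="\t", index_col=0)
        host_map = _host_map(circ_counts.index, circs, candidates)
        records, coupling_summary = coupling.coupling_profile(
            circ_counts,
            gene_counts,
            host_map,
            control_condition=config.control_condition,
            alpha=config.de_alpha,
            fc_floor=config.de_fc_floor,
            logger=logger,
        )
        bundle.tables["coupling_records"] = records
        bundle.tables["coupling"] = coupling_summary
        samples = list(circ_counts.columns)
        conds = sorted(
            {coupling.condition_of(s) for s in samples} - {config.control_condition}
        )
        ctrl = [
            s for s in samples
            if coupling.condition_of(s) == config.control_condition
        ]
        for st in conds:
            ts = [s for s in samples if coupling.condition_of(s) == st]
            gene_de[st] = coupling.de_test(
                gene_counts, ts, ctrl, alpha=config.de_alpha,
                fc_floor=config.de_fc_floor,
            )
            circ_de_t = coupling.de_test(
                circ_counts, ts, ctrl, alpha=config.de_alpha,
                fc_floor=config.de_fc_floor,
            )
            circ_states[st] = {
                cid: {
                    "state": str(circ_de_t.loc[cid, "state"]),
                    "log2fc": float(circ_de_t.loc[cid, "log2fc"]),
                }
                for cid in circ_de_t.index
            }
        bundle.note(
            f"coupling: median r = {coupling_summary['median_r']:.3f} over "
            f"{coupling_summary['n_pairs']} pairs"
        )
    else:
        bundle.note("coupling stage skipped: count matrices absent")
        bundle.tables["coupling"] = None

    # ---- stage 6: ceRNA network (optional) ------------------------------
    if "mirna_fasta" in config.paths and os.path.exists(config.paths["mirna_fasta"]):
        from Bio import SeqIO

        mirnas = {
            rec.id: str(rec.seq).upper().replace("U", "T")
            for rec in SeqIO.parse(config.paths["mirna_fasta"], "fasta")
        }
        circ_seqs = {}
        for circ in circs:
            cls = classifications[circ.circ_id]
            if cls.circ_type in ("multi-exonic", "single-exonic", "intronic"):
                circ_seqs[circ.circ_id] = annotate.circ_sequence(
                    cls, circ, annotation, genome
                )
        mrna_seqs = {
            g.gene_id: g.transcripts[0].spliced_sequence(genome)
            for g in annotation.genes
            if g.interval.contig not in config.chloroplast_contigs
        }
        if gene_de:
            # restrict mRNA scanning to genes in the expression matrix
            known = set(next(iter(gene_de.values())).index)
            mrna_seqs = {g: s for g, s in mrna_seqs.items() if g in known}
        circ_profiles = cerna.scan_all(
            mirnas, circ_seqs, "circRNA", config.target_profiles, circular=True
        )
        mrna_profiles = cerna.scan_all(
            mirnas, mrna_seqs, "mRNA", config.target_profiles, circular=False
        )
        circ_inter = cerna.consensus_filter(circ_profiles)
        mrna_inter = cerna.consensus_filter(mrna_profiles)
        mirna_states: dict[str, dict[str, dict]] = {}
        if "mirna_expression" in config.paths and os.path.exists(
            config.paths["mirna_expression"]
        ):
            mexp = pd.read_csv(config.paths["mirna_expression"], sep="\t")
            for row in mexp.itertuples():
                for col in mexp.columns:
                    if col.endswith("_log2fc"):
                        st = col[: -len("_log2fc")]
                        lfc = float(getattr(row, col))
                        mirna_states.setdefault(st, {})[row.mirna_id] = {
                            "state": ("up" if lfc > 0 else "down")
                            if abs(lfc) >= config.de_fc_floor
                            else "ns",
                            "log2fc": lfc,
                        }
        networks = {}
        conds = sorted(circ_states) if circ_states else []
        for st in conds:
            de_states = dict(circ_states[st])
            de_states.update(mirna_states.get(st, {}))
            for gid in gene_de[st].index:
                de_states[gid] = {
                    "state": str(gene_de[st].loc[gid, "state"]),
                    "log2fc": float(gene_de[st].loc[gid, "log2fc"]),
                }
            networks[st] = cerna.build_network(
                circ_inter, mrna_inter, de_states, st
            )
        bundle.tables["circ_interactions"] = circ_inter
        bundle.tables["mrna_interactions"] = mrna_inter
        bundle.tables["networks"] = networks
        net_summary = {
            "n_circ_interactions": len(circ_inter),
            "n_mrna_interactions": len(mrna_inter),
            "n_circ_with_sites": len({s.target_id for s in circ_inter}),
            "n_mrna_targets": len({s.target_id for s in mrna_inter}),
        }
        if networks:
            first = networks[conds[0]]
            net_summary["hubs"] = {
                st: cerna.hub_rank(networks[st], k=10) for st in conds
            }
            hub_id = max(
                (n for n, d in first.nodes(data=True) if d["kind"] == "miRNA"),
                key=lambda m: (
                    sum(
                        1
                        for x in first.neighbors(m)
                        if first.nodes[x]["kind"] == "circRNA"
                    ),
                    m,
                ),
                default=None,
            )
            if hub_id is not None:
                net_summary["sponge"] = {
                    st: cerna.sponge_consistency(networks[st], hub_id)
                    for st in conds
                }
                net_summary["hub_mirna"] = hub_id
        bundle.tables["cerna"] = net_summary
        bundle.note(
            f"network: {net_summary['n_circ_interactions']} circ and "
            f"{net_summary['n_mrna_interactions']} mRNA interactions"
        )
    else:
        bundle.note("network stage skipped: miRNA input absent")
        bundle.tables["cerna"] = None

    # ---- stage 7: organellar -------------------------------------------
    if chloro is not None:
        merged = pd.concat([candidates, chloro], ignore_index=True)
        frac = organellar.organelle_fraction(
            merged, set(config.chloroplast_contigs)
        )
        psba = [
            g
            for g in annotation.genes
            if g.interval.contig in config.chloroplast_contigs
        ]
        clustering = None
        if psba:
            gene = psba[0]
            clustering = organellar.clustering_enrichment(
                chloro,
                gene,
                window_fraction=config.terminal_window_fraction,
                n_perm=config.n_permutations,
                seed=config.seed + 211,
            )
        bundle.tables["organellar"] = {
            "fractions": frac,
            "clustering": vars(clustering) if clustering else None,
        }
        bundle.note("organellar stage complete")
    else:
        bundle.note("organellar stage skipped: chloroplast candidates absent")
        bundle.tables["organellar"] = None

    bundle.summary.update(summarize(bundle))
    return bundle


def _host_map(circ_index, circs, candidates) -> dict[str, str]:
    """circ feature id -> host gene id.

    Expression matrices may key circRNAs by the pipeline's merged ids or
    by the upstream caller's ids carried in the candidate table's
    ``bsj_id`` column; both are joined through the junction key.
    """
    by_key = {
        c.key: sorted(c.host_gene_ids)[0] for c in circs if c.host_gene_ids
    }
    by_id = {c.circ_id: k for c, k in zip(circs, [c.key for c in circs])}
    out = {}
    external = {}
    if "bsj_id" in candidates.columns:
        for r in candidates.itertuples():
            external.setdefault(
                str(r.bsj_id), (r.chrom, int(r.acceptor), int(r.donor), r.strand)
            )
    for cid in circ_index:
        key = by_id.get(cid) or external.get(cid)
        if key is not None and key in by_key:
            out[cid] = by_key[key]
    return out


def summarize(bundle: ReportBundle) -> dict:
    """Headline tallies recomputable from the stage tables."""
    circs = bundle.tables.get("circrnas", [])
    classifications = bundle.tables.get("classifications", {})
    type_counts = {t: 0 for t in annotate.CIRC_TYPES}
    for cls in classifications.values():
        type_counts[cls.circ_type] += 1
    summary: dict = {
        "n_unique_circrnas": len(circs),
        "n_single_read_single_sample": sum(1 for c in circs if c.low_support),
        "type_counts": type_counts,
        "n_intragenic": sum(1 for c in circs if c.context == "intragenic"),
        "n_intergenic": sum(1 for c in circs if c.context == "intergenic"),
    }
    venn = bundle.tables.get("condition_overlap")
    if venn:
        summary["condition_unique"] = venn["unique_per_condition"]
        summary["condition_shared_all"] = venn["shared_by_all"]
    if bundle.tables.get("coupling"):
        cp = bundle.tables["coupling"]
        summary["median_pearson_r"] = cp["median_r"]
        summary["de_circ_counts"] = cp["de_counts"]
        summary["pattern_counts"] = cp["pattern_counts"]
    if bundle.tables.get("cerna"):
        net = bundle.tables["cerna"]
        summary["n_circ_interactions"] = net["n_circ_interactions"]
        summary["n_mrna_interactions"] = net["n_mrna_interactions"]
        summary["n_circ_with_sites"] = net["n_circ_with_sites"]
    if bundle.tables.get("conservation"):
        summary["conservation"] = {
            "overlap": bundle.tables["conservation"]["ortholog_overlap"],
            "hypergeometric_p": bundle.tables["conservation"]["hypergeometric_p"],
            "category_counts": bundle.tables["conservation"]["category_counts"],
        }
    if bundle.tables.get("organellar"):
        org = bundle.tables["organellar"]
        rn = org["fractions"].get("rnaser")
        summary["chloroplast_read_fraction_rnaser"] = (
            rn["fraction_chloroplast_reads"] if rn else None
        )
        if org["clustering"]:
            summary["psba_clustering_p"] = org["clustering"]["permutation_p"]
            summary["psba_window_fraction_observed"] = org["clustering"][
                "observed_fraction"
            ]
    if bundle.tables.get("clr_contrast"):
        summary["clr_fisher_p"] = bundle.tables["clr_contrast"]["fisher_p"]
    return summary


def _conservation_calls(
    circs,
    classifications,
    annotation,
    genome,
    annotation_b,
    genome_b,
    bsj_b,
    omap,
    tolerance,
):
    """Classify all A x B circRNA pairs per ortholog gene pair; report
    the most-conserved category per A circ."""
    circ_by_gene: dict[str, list] = {}
    for circ in circs:
        cls = classifications.get(circ.circ_id)
        if cls is None or cls.circ_type not in ("multi-exonic", "single-exonic"):
            continue
        for gid in circ.host_gene_ids:
            circ_by_gene.setdefault(gid, []).append((circ, cls))
    b_circ_by_gene: dict[str, list] = {}
    for row in bsj_b.itertuples():
        b_circ_by_gene.setdefault(row.gene, []).append(row)

    calls = []
    for gene_a, gene_b in omap.pairs:
        if gene_a not in circ_by_gene or gene_b not in b_circ_by_gene:
            continue
        tx_a = annotation.gene(gene_a).transcripts[0]
        seq_a = tx_a.spliced_sequence(genome)
        gene_b_model = annotation_b.gene(gene_b)
        seq_b = gene_b_model.transcripts[0].spliced_sequence(genome_b)
        blocks = conservation.align_pair(seq_a, seq_b)
        pair_calls = []
        for circ, cls in circ_by_gene[gene_a]:
            tx = annotation.gene(gene_a).transcripts[0]
            if cls.matched_transcript_id != tx.transcript_id:
                # sites live on the matched transcript; use its splicing
                for g in annotation.genes:
                    for t in g.transcripts:
                        if t.transcript_id == cls.matched_transcript_id:
                            tx = t
                seq_a_m = tx.spliced_sequence(genome)
                blocks_m = conservation.align_pair(seq_a_m, seq_b)
            else:
                blocks_m = blocks
            lo, hi = _spliced_sites(tx, cls.first_exon, cls.last_exon)
            for b in b_circ_by_gene[gene_b]:
                b_lo = int(b.acceptor) - gene_b_model.interval.start
                b_hi = int(b.donor) - gene_b_model.interval.start
                pair_calls.append(
                    conservation.classify_conservation(
                        blocks_m,
                        lo,
                        hi,
                        b_lo,
                        b_hi,
                        tolerance=tolerance,
                        gene_a=gene_a,
                        gene_b=gene_b,
                        circ_a=circ.circ_id,
                        circ_b=str(b.circ_id),
                    )
                )
        calls.extend(conservation.best_call_per_circ(pair_calls))
    return calls


# ---------------------------------------------------------------------------
# serialization
# ---------------------------------------------------------------------------

def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating, float)):
        return round(float(obj), 10)
    return obj


def write_report(bundle: ReportBundle, outdir: str | os.PathLike) -> str:
    """Write stage tables (TSV/BED/JSON) and the summary JSON; returns the
    summary path."""
    outdir = str(outdir)
    os.makedirs(outdir, exist_ok=True)
    circs = bundle.tables.get("circrnas", [])
    classifications = bundle.tables.get("classifications", {})
    rows = []
    for c in circs:
        cls = classifications.get(c.circ_id)
        rows.append(
            {
                "circ_id": c.circ_id,
                "chrom": c.contig,
                "acceptor": c.acceptor,
                "donor": c.donor,
                "strand": c.strand,
                "context": c.context,
                "host_genes": ",".join(sorted(c.host_gene_ids)),
                "circ_type": cls.circ_type if cls else "NA",
                "spliced_length": cls.spliced_length if cls else None,
                "total_reads": c.total_reads,
                "n_samples": c.n_supporting_samples,
                "low_support": c.low_support,
                "max_score": c.max_score,
            }
        )
    pd.DataFrame(rows).to_csv(
        os.path.join(outdir, "circrnas.tsv"), sep="\t", index=False
    )
    write_bed6(
        [(c.interval, c.circ_id, c.max_score) for c in circs],
        os.path.join(outdir, "circrnas.bed"),
    )
    if isinstance(bundle.tables.get("score_stratification"), pd.DataFrame):
        bundle.tables["score_stratification"].to_csv(
            os.path.join(outdir, "score_stratification.tsv"), sep="\t", index=False
        )
    if bundle.tables.get("condition_overlap"):
        venn = bundle.tables["condition_overlap"]
        with open(os.path.join(outdir, "condition_overlap.json"), "w") as fh:
            json.dump(
                _jsonable(
                    {
                        "partition": {
                            "+".join(k): v for k, v in sorted(venn["partition"].items())
                        },
                        "unique_per_condition": venn["unique_per_condition"],
                        "shared_by_all": venn["shared_by_all"],
                        "union_size": venn["union_size"],
                    }
                ),
                fh,
                indent=1,
                sort_keys=True,
            )
    for key in ("circ_interactions", "mrna_interactions"):
        sites = bundle.tables.get(key)
        if sites:
            pd.DataFrame([vars(s) for s in sites]).to_csv(
                os.path.join(outdir, f"{key}.tsv"), sep="\t", index=False
            )
    networks = bundle.tables.get("networks") or {}
    for cond, g in networks.items():
        import networkx as nx

        with open(os.path.join(outdir, f"network_{cond}.json"), "w") as fh:
            json.dump(nx.node_link_data(g, edges="edges"), fh, indent=1, sort_keys=True)
        nx.write_edgelist(
            g, os.path.join(outdir, f"network_{cond}.edges.tsv"), delimiter="\t",
            data=["penalty"],
        )
    summary_path = os.path.join(outdir, "summary.json")
    with open(summary_path, "w") as fh:
        json.dump(_jsonable(bundle.summary), fh, indent=1, sort_keys=True)
    with open(os.path.join(outdir, "run.log"), "w") as fh:
        fh.write("\n".join(bundle.log) + "\n")
    return summary_path
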