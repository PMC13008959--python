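"""Back-splice junction credibility filtering and merging.

Candidates from RNase R-treated libraries are kept above a lenient
reliability-score threshold (scores in the lowest bin are dominated by
intergenic junctions and therefore untrustworthy), candidates from
untreated control libraries above a stringent one, and ultra-long-span
junctions are excluded as trans-like artifacts.  Retained candidates are
merged into unique circRNAs keyed by (contig, acceptor, donor, strand).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .genome import AnnotationSet, GenomicInterval

REQUIRED_COLUMNS = [
    "chrom",
    "acceptor",
    "donor",
    "strand",
    "score",
    "bsj_reads",
    "sample",
    "condition",
    "library",
]


@dataclass
class RetentionConfig:
    """Dual-threshold retention rules (strict inequalities)."""

    rnaser_min_score: float = 0.1
    control_min_score: float = 0.9
    max_span: int = 100_000
    require_intragenic: bool = False

    def __post_init__(self) -> None:
        for t in (self.rnaser_min_score, self.control_min_score):
            if not 0.0 <= t <= 1.0:
                raise ValueError("score thresholds must lie in [0,1]")
        if self.max_span <= 0:
            raise ValueError("max_span must be positive")


@dataclass
class CircRNA:
    """One unique retained junction with aggregated support."""

    circ_id: str
    contig: str
    acceptor: int
    donor: int
    strand: str
    host_gene_ids: set[str] = field(default_factory=set)
    context: str = "intergenic"
    reads_per_condition: dict[str, int] = field(default_factory=dict)
    n_supporting_samples: int = 0
    total_reads: int = 0
    max_score: float = 0.0
    libraries: set[str] = field(default_factory=set)

    @property
    def low_support(self) -> bool:
        """Exactly one BSJ read in exactly one sample."""
        return self.n_supporting_samples == 1 and self.total_reads == 1

    @property
    def key(self) -> tuple:
        return (self.contig, self.acceptor, self.donor, self.strand)

    @property
    def interval(self) -> GenomicInterval:
        return GenomicInterval(self.contig, self.acceptor, self.donor, self.strand)


def read_candidates(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"candidate table missing columns: {missing}")
    if (df["acceptor"] >= df["donor"]).any():
        raise ValueError("acceptor must be < donor for every candidate")
    if ((df["score"] < 0) | (df["score"] > 1)).any():
        raise ValueError("scores must lie in [0,1]")
    if (df["bsj_reads"] < 1).any():
        raise ValueError("bsj_reads must be >= 1")
    return df


def classify_context(
    contig: str, acceptor: int, donor: int, annotation: AnnotationSet
) -> tuple[str, set[str]]:
    """'intragenic' iff at least one gene's interval contains both the
    acceptor and the donor; the host set holds exactly those genes."""
    hosts = annotation.genes_containing(contig, acceptor, donor)
    return ("intragenic" if hosts else "intergenic"), hosts


def score_stratification(
    candidates: pd.DataFrame,
    annotation: AnnotationSet,
    bin_width: float = 0.1,
) -> pd.DataFrame:
    """Counts of distinct junctions per score bin and genomic context.

    Bins are inclusive-left / exclusive-right; a score of exactly 1.0
    falls in the last bin.  The per-bin intergenic fraction is the
    credibility diagnostic: artifact-dominated bins are intergenic-rich.
    """
    if candidates.empty:
        return pd.DataFrame(
            columns=["bin_left", "bin_right", "intragenic", "intergenic", "intergenic_fraction"]
        )
    uniq = (
        candidates.groupby(["chrom", "acceptor", "donor", "strand"])
        .agg(score=("score", "max"))
        .reset_index()
    )
    edges = np.round(np.arange(0.0, 1.0 + bin_width / 2, bin_width), 10)
    idx = np.minimum(
        np.floor(uniq["score"].to_numpy() / bin_width).astype(int),
        len(edges) - 2,
    )
    contexts = [
        classify_context(r.chrom, r.acceptor, r.donor, annotation)[0]
        for r in uniq.itertuples()
    ]
    rows = []
    for b in range(len(edges) - 1):
        mask = idx == b
        n_intra = sum(
            1 for m, c in zip(mask, contexts) if m and c == "intragenic"
        )
        n_inter = int(mask.sum()) - n_intra
        total = n_intra + n_inter
        rows.append(
            {
                "bin_left": edges[b],
                "bin_right": edges[b + 1],
                "intragenic": n_intra,
                "intergenic": n_inter,
                "intergenic_fraction": (n_inter / total) if total else np.nan,
            }
        )
    return pd.DataFrame(rows)


def apply_retention(
    candidates: pd.DataFrame,
    config: RetentionConfig,
    annotation: AnnotationSet | None = None,
) -> pd.DataFrame:
    """Keep candidates passing their library's score threshold (strictly
    greater) and the ultra-long span exclusion; optionally require an
    intragenic context."""
    score = candidates["score"]
    lib = candidates["library"]
    keep = (
        ((lib == "rnaser") & (score > config.rnaser_min_score))
        | ((lib == "control") & (score > config.control_min_score))
    ) & ((candidates["donor"] - candidates["acceptor"]) <= config.max_span)
    out = candidates[keep].copy()
    if config.require_intragenic:
        if annotation is None:
            raise ValueError("require_intragenic needs an annotation")
        ctx = [
            classify_context(r.chrom, r.acceptor, r.donor, annotation)[0]
            for r in out.itertuples()
        ]
        out = out[[c == "intragenic" for c in ctx]]
    return out.reset_index(drop=True)


def merge_unique(
    retained: pd.DataFrame, annotation: AnnotationSet | None = None
) -> list[CircRNA]:
    """One CircRNA per distinct (contig, acceptor, donor, strand), with
    per-condition read support summed and the low-support flag derived."""
    circs: list[CircRNA] = []
    if retained.empty:
        return circs
    grouped = retained.groupby(
        ["chrom", "acceptor", "donor", "strand"], sort=True
    )
    for i, ((contig, acc, don, strand), grp) in enumerate(grouped, start=1):
        per_cond = grp.groupby("condition")["bsj_reads"].sum().to_dict()
        circ = CircRNA(
            circ_id=f"cs{i:05d}",
            contig=contig,
            acceptor=int(acc),
            donor=int(don),
            strand=strand,
            reads_per_condition={k: int(v) for k, v in per_cond.items()},
            n_supporting_samples=int(grp["sample"].nunique()),
            total_reads=int(grp["bsj_reads"].sum()),
            max_score=float(grp["score"].max()),
            libraries=set(grp["library"]),
        )
        if annotation is not None and contig in annotation.contigs:
            circ.context, circ.host_gene_ids = classify_context(
                contig, circ.acceptor, circ.donor, annotation
            )
        circs.append(circ)
    return circs


def condition_overlap(
    sets_per_condition: dict[str, set], min_conditions: int = 2
) -> dict:
    """Full Venn partition of per-condition identification sets.

    Returns membership-pattern counts (keys are sorted tuples of condition
    names), per-condition unique counts, and the all-shared count; the
    partition sums to the size of the union.
    """
    conds = sorted(sets_per_condition)
    if len(conds) < min_conditions:
        raise ValueError("need at least two conditions for an overlap")
    union = set().union(*sets_per_condition.values())
    partition: dict[tuple, int] = {}
    for item in union:
        pattern = tuple(c for c in conds if item in sets_per_condition[c])
        partition[pattern] = partition.get(pattern, 0) + 1
    unique = {
        c: partition.get((c,), 0) for c in conds
    }
    shared_all = partition.get(tuple(conds), 0)
    return {
        "partition": partition,
        "unique_per_condition": unique,
        "shared_by_all": shared_all,
        "union_size": len(union),
    }


def circ_linear_ratio(circ_reads: int, linear_reads: int) -> float:
    """c / (c + l); defined as 0 when both counts are zero."""
    if circ_reads < 0 or linear_reads < 0:
        raise ValueError("read counts must be non-negative")
    total = circ_reads + linear_reads
    return circ_reads / total if total else 0.0


def clr_table(
    candidates: pd.DataFrame, linear_counts: pd.DataFrame
) -> pd.DataFrame:
    """Per-site, per-library circular-to-linear ratios.

    Circular support is the summed BSJ reads of the site in that library;
    linear support comes from the linear-read table (0 when absent).
    """
    circ = (
        candidates.groupby(["chrom", "acceptor", "donor", "strand", "library"])
        ["bsj_reads"]
        .sum()
        .rename("circ_reads")
        .reset_index()
    )
    merged = circ.merge(
        linear_counts,
        on=["chrom", "acceptor", "donor", "strand", "library"],
        how="left",
    )
    merged["linear_reads"] = merged["linear_reads"].fillna(0).astype(int)
    merged["clr"] = [
        circ_linear_ratio(c, l)
        for c, l in zip(merged["circ_reads"], merged["linear_reads"])
    ]
    return merged


def clr_library_contrast(
    clr: pd.DataFrame, cutoff: float = 0.5
) -> dict:
    """RNase R vs control CLR contrast.

    Fisher's exact test on the 2x2 of library type x (CLR above/below the
    cutoff), plus a two-sided rank-sum test on the raw ratios.
    """
    rn = clr.loc[clr["library"] == "rnaser", "clr"].to_numpy()
    ct = clr.loc[clr["library"] == "control", "clr"].to_numpy()
    table = [
        [int((rn > cutoff).sum()), int((rn <= cutoff).sum())],
        [int((ct > cutoff).sum()), int((ct <= cutoff).sum())],
    ]
    _, fisher_p = stats.fisher_exact(table, alternative="two-sided")
    if len(rn) and len(ct):
        rank_p = float(stats.mannwhitneyu(rn, ct, alternative="two-sided").pvalue)
    else:
        rank_p = float("nan")
    return {
        "table": table,
        "fisher_p": float(fisher_p),
        "ranksum_p": rank_p,
        "median_clr_rnaser": float(np.median(rn)) if len(rn) else float("nan"),
        "median_clr_control": float(np.median(ct)) if len(ct) else float("nan"),
    }


def condition_sets(
    retained: pd.DataFrame, conditions: list[str] | None = None, min_reads: int = 1
) -> dict[str, set]:
    """Junction keys detected per condition (presence of >= min_reads)."""
    df = retained
    if conditions is not None:
        df = df[df["condition"].isin(conditions)]
    out: dict[str, set] = {}
    for cond, grp in df.groupby("condition"):
        per_key = grp.groupby(["chrom", "acceptor", "donor", "strand"])[
            "bsj_reads"
        ].sum()
        out[str(cond)] = set(per_key[per_key >= min_reads].index)
    if conditions is not None:
        for cond in conditions:
            out.setdefault(cond, set())
    return out
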