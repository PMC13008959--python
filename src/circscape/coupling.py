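"""CircRNA-host expression coupling and differential expression.

Quantifies how independent circRNA accumulation is from host-gene
transcription: per-pair Pearson correlation on library-size-normalized
expression, per-condition log2 fold changes, a self-contained exact
conditional binomial differential-expression test with
Benjamini-Hochberg correction, and the Reversed / Coordinated /
HostStable / CircStable pattern call combining the two DE states.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

PATTERNS = ("Reversed", "Coordinated", "HostStable", "CircStable", "NS")


def condition_of(sample: str) -> str:
    """Condition label encoded in the sample name ('cold_E1' -> 'cold')."""
    return sample.rsplit("_", 1)[0]


def size_factors(counts: pd.DataFrame) -> pd.Series:
    """Trimmed-mean-of-ratios size factors (geometric-mean reference), a
    guard against compositional bias from a minority of strongly
    regulated features; factors are scaled to geometric mean 1.  Falls
    back to total-count factors when no feature is positive in all
    samples."""
    arr = counts.to_numpy(dtype=float)
    positive = (arr > 0).all(axis=1)
    if positive.sum() >= 1:
        logs = np.log(arr[positive])
        ref = logs.mean(axis=1, keepdims=True)
        sf = np.exp(stats.trim_mean(logs - ref, 0.25, axis=0))
    else:
        tot = arr.sum(axis=0)
        sf = tot / np.exp(np.mean(np.log(tot)))
    sf = sf / np.exp(np.mean(np.log(sf)))
    return pd.Series(sf, index=counts.columns)


def normalize(
    counts: pd.DataFrame,
    mode: str = "RPM",
    lengths: dict[str, float] | pd.Series | None = None,
    robust: bool = False,
) -> pd.DataFrame:
    """RPM = count * 1e6 / library size; RPKM additionally divides by
    feature length in kb.

    With ``robust`` the library sizes are effective sizes (median-of-
    ratios size factor times the geometric-mean raw library size), so a
    minority of strongly regulated features cannot shift every other
    feature's normalized value.
    """
    lib = counts.sum(axis=0)
    if (lib <= 0).any():
        bad = list(lib.index[lib <= 0])
        raise ValueError(f"zero library size for samples: {bad}")
    if robust:
        lib = size_factors(counts) * float(np.exp(np.mean(np.log(lib))))
    rpm = counts * 1e6 / lib
    if mode == "RPM":
        return rpm
    if mode == "RPKM":
        if lengths is None:
            raise ValueError("RPKM requires feature lengths")
        lens = pd.Series(lengths).reindex(counts.index)
        if lens.isna().any():
            raise ValueError("missing lengths for some features")
        return rpm.mul(1e3 / lens, axis=0)
    raise ValueError(f"unknown normalization mode {mode!r}")


def pearson(x, y) -> float | None:
    """Product-moment correlation; None (not 0) when undefined."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.size < 3:
        raise ValueError("need equal-length vectors of size >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return None
    return float(np.corrcoef(x, y)[0, 1])


@dataclass
class CouplingRecord:
    circ_id: str
    host_gene_id: str
    pearson_r: float | None
    circ_log2fc: dict[str, float]
    host_log2fc: dict[str, float]
    circ_de_state: dict[str, str]
    host_de_state: dict[str, str]
    pattern: dict[str, str]


def log2fc(
    rpm: pd.DataFrame, treat: list[str], control: list[str], pseudocount: float = 1.0
) -> pd.Series:
    """log2 of (mean treat RPM + pc) / (mean control RPM + pc); exactly
    antisymmetric under swapping the groups."""
    t = rpm[treat].mean(axis=1) + pseudocount
    c = rpm[control].mean(axis=1) + pseudocount
    return np.log2(t / c)


def de_test(
    counts: pd.DataFrame,
    treat: list[str],
    control: list[str],
    alpha: float = 0.05,
    fc_floor: float = 1.0,
    pseudocount: float = 1.0,
    dispersion: float = 1.0,
    lib_sizes: pd.Series | None = None,
) -> pd.DataFrame:
    """Exact conditional binomial test per feature.

    Pooled treat counts are compared against pooled control counts,
    conditioning on their sum, with success probability equal to the
    treat share of the two library sizes (effective median-of-ratios
    sizes unless explicit ``lib_sizes`` are given).  q-values are
    Benjamini-Hochberg; state is up/down iff q < alpha and
    |log2fc| >= fc_floor.  ``dispersion`` > 1 deflates the counts before
    testing, a crude guard against overdispersion.
    """
    if not treat or not control:
        raise ValueError("both groups need at least one sample")
    if lib_sizes is None:
        raw = counts.sum(axis=0)
        if (raw <= 0).any():
            raise ValueError("zero library size in a group")
        lib_sizes = size_factors(counts) * float(np.exp(np.mean(np.log(raw))))
    lib_t = float(lib_sizes[treat].sum())
    lib_c = float(lib_sizes[control].sum())
    if lib_t <= 0 or lib_c <= 0:
        raise ValueError("zero library size in a group")
    p0 = lib_t / (lib_t + lib_c)
    a = counts[treat].sum(axis=1).to_numpy()
    b = counts[control].sum(axis=1).to_numpy()
    if dispersion != 1.0:
        a = np.floor(a / dispersion).astype(int)
        b = np.floor(b / dispersion).astype(int)
    pvals = np.ones(len(a))
    for i in range(len(a)):
        n = int(a[i] + b[i])
        if n > 0:
            pvals[i] = stats.binomtest(int(a[i]), n, p0).pvalue
    qvals = stats.false_discovery_control(pvals, method="bh")
    rpm = normalize(counts, "RPM", robust=True)
    lfc = log2fc(rpm, treat, control, pseudocount).to_numpy()
    state = np.where(
        (qvals < alpha) & (np.abs(lfc) >= fc_floor),
        np.where(lfc > 0, "up", "down"),
        "ns",
    )
    return pd.DataFrame(
        {
            "log2fc": lfc,
            "p_value": pvals,
            "q_value": qvals,
            "state": state,
        },
        index=counts.index,
    )


def classify_pattern(circ_state: str, host_state: str) -> str:
    """Joint DE-state pattern of a circRNA and its host gene."""
    for s in (circ_state, host_state):
        if s not in ("up", "down", "ns"):
            raise ValueError(f"unknown DE state {s!r}")
    if circ_state == "ns" and host_state == "ns":
        return "NS"
    if circ_state == "ns":
        return "CircStable"
    if host_state == "ns":
        return "HostStable"
    return "Coordinated" if circ_state == host_state else "Reversed"


def coupling_profile(
    circ_counts: pd.DataFrame,
    gene_counts: pd.DataFrame,
    host_map: dict[str, str],
    control_condition: str = "CK",
    alpha: float = 0.05,
    fc_floor: float = 1.0,
    logger=None,
) -> tuple[list[CouplingRecord], dict]:
    """Per circ-host pair: Pearson r across all samples (RPM scale),
    per-condition fold changes, DE states, and pattern calls.

    Circs whose host is absent from the gene matrix are skipped with a
    warning.  The summary reports the median r over pairs.
    """
    circ_rpm = normalize(circ_counts, "RPM", robust=True)
    gene_rpm = normalize(gene_counts, "RPM", robust=True)
    samples = [s for s in circ_counts.columns if s in gene_counts.columns]
    conditions = sorted({condition_of(s) for s in samples})
    stresses = [c for c in conditions if c != control_condition]
    ctrl_samples = [s for s in samples if condition_of(s) == control_condition]

    circ_de: dict[str, pd.DataFrame] = {}
    gene_de: dict[str, pd.DataFrame] = {}
    for st in stresses:
        ts = [s for s in samples if condition_of(s) == st]
        circ_de[st] = de_test(
            circ_counts[samples], ts, ctrl_samples, alpha=alpha, fc_floor=fc_floor
        )
        gene_de[st] = de_test(
            gene_counts[samples], ts, ctrl_samples, alpha=alpha, fc_floor=fc_floor
        )

    records = []
    rs = []
    for circ_id, host in sorted(host_map.items()):
        if circ_id not in circ_rpm.index:
            continue
        if host not in gene_rpm.index:
            if logger is not None:
                logger.warning("host %s of %s missing from gene matrix", host, circ_id)
            continue
        r = pearson(circ_rpm.loc[circ_id, samples], gene_rpm.loc[host, samples])
        if r is not None:
            rs.append(r)
        rec = CouplingRecord(
            circ_id,
            host,
            r,
            circ_log2fc={st: float(circ_de[st].loc[circ_id, "log2fc"]) for st in stresses},
            host_log2fc={st: float(gene_de[st].loc[host, "log2fc"]) for st in stresses},
            circ_de_state={st: str(circ_de[st].loc[circ_id, "state"]) for st in stresses},
            host_de_state={st: str(gene_de[st].loc[host, "state"]) for st in stresses},
            pattern={},
        )
        rec.pattern = {
            st: classify_pattern(rec.circ_de_state[st], rec.host_de_state[st])
            for st in stresses
        }
        records.append(rec)

    summary = {
        "n_pairs": len(records),
        "median_r": float(np.median(rs)) if rs else math.nan,
        "mean_r": float(np.mean(rs)) if rs else math.nan,
        "de_counts": {
            st: int((circ_de[st]["state"] != "ns").sum()) for st in stresses
        },
        "pattern_counts": {
            st: {
                p: sum(1 for rec in records if rec.pattern[st] == p)
                for p in PATTERNS
            }
            for st in stresses
        },
    }
    return records, summary
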