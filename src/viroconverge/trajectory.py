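"""Prevalence/abundance trajectories of discriminant contigs in 5 d blocks.

Samples in the 25 d before the event are binned into five blocks
([0,5), [5,10), …, [20,25) days-before).  Per contig, group and block:
prevalence is the percentage of the block's samples with a detection, and
abundance is the RPK mean over *all* samples in the block (zeros included).
Blocks without samples are recorded as missing, never zero.

A Friedman test (contigs as repeated-measures subjects, blocks as
treatments) with a Dunn post-hoc checks whether the series shifts across
blocks, and per-contig OLS slopes against signed block midpoints
(−22.5 … −2.5 days) quantify direction: positive slope = increase while
approaching the event.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.stats as st

from .cohort_stats import GroupTestResult
from .event_anchor import AnchoredSample
from .normalization import AbundanceTable

__all__ = ["BlockSeries", "SlopePair", "block_series", "friedman_dunn", "slopes", "BLOCK_EDGES"]

BLOCK_EDGES = [0.0, 5.0, 10.0, 15.0, 20.0, 25.0]
#: signed block midpoints per block label (days-before negated so time runs
#: toward the event): block [0,5) sits at -2.5, block [20,25) at -22.5
BLOCK_MIDPOINTS = [-2.5, -7.5, -12.5, -17.5, -22.5]


@dataclass
class BlockSeries:
    """Per contig × group × block prevalence (%) and mean abundance (RPK).

    ``prevalence`` / ``abundance`` are DataFrames with a (contig, group)
    MultiIndex and one column per block label, NaN where the block is empty.
    """

    prevalence: pd.DataFrame
    abundance: pd.DataFrame
    block_labels: list[str]
    n_samples: pd.DataFrame  # group × block sample counts


@dataclass(frozen=True)
class SlopePair:
    contig_id: str
    group: str
    prevalence_slope: float  # % per day
    abundance_slope: float  # RPK per day


def _block_label(k: int) -> str:
    return f"{BLOCK_EDGES[k]:g}-{BLOCK_EDGES[k+1]:g}d"


def block_series(
    abundance: AbundanceTable,
    anchored: list[AnchoredSample],
    contigs: list[str],
) -> BlockSeries:
    labels = [_block_label(k) for k in range(len(BLOCK_EDGES) - 1)]
    members: dict[tuple[str, str], list[str]] = {
        (g, lab): [] for g in ("case", "control") for lab in labels
    }
    for a in anchored:
        if a.post_event:
            continue
        t = a.days_before_event
        for k in range(len(BLOCK_EDGES) - 1):
            if BLOCK_EDGES[k] <= t < BLOCK_EDGES[k + 1]:
                members[(a.group, labels[k])].append(a.sample_id)
                break

    prev_rows, abun_rows, index = [], [], []
    for contig in contigs:
        row = abundance.data.loc[contig]
        for group in ("case", "control"):
            prevs, means = [], []
            for lab in labels:
                sids = members[(group, lab)]
                if not sids:
                    prevs.append(np.nan)
                    means.append(np.nan)
                    continue
                vals = row[sids].to_numpy(dtype=float)
                prevs.append(100.0 * float((vals > 0).mean()))
                means.append(float(vals.mean()))
            index.append((contig, group))
            prev_rows.append(prevs)
            abun_rows.append(means)

    midx = pd.MultiIndex.from_tuples(index, names=["contig_id", "group"])
    counts = pd.DataFrame(
        {lab: [len(members[("case", lab)]), len(members[("control", lab)])] for lab in labels},
        index=["case", "control"],
    )
    return BlockSeries(
        prevalence=pd.DataFrame(prev_rows, index=midx, columns=labels),
        abundance=pd.DataFrame(abun_rows, index=midx, columns=labels),
        block_labels=labels,
        n_samples=counts,
    )


def friedman_dunn(
    series: BlockSeries, measure: str = "prevalence", group: str = "case", adjust: str = "bonferroni"
) -> GroupTestResult:
    """Friedman test across blocks, contigs as matched subjects, Dunn post-hoc.

    Contigs with any missing block value cannot supply a complete ranking and
    are dropped with a warning.
    """
    table = getattr(series, measure)
    table = table.xs(group, level="group")
    table = table.dropna(axis=1, how="all")  # blocks with no samples at all
    complete = table.dropna()
    dropped = len(table) - len(complete)
    if dropped:
        warnings.warn(f"{dropped} contig(s) dropped for missing block values")
    if complete.shape[0] < 2 or complete.shape[1] < 3:
        raise ValueError("need >= 2 complete contigs and >= 3 blocks")
    blocks = [complete[c].to_numpy() for c in complete.columns]
    if all(np.ptp(complete.to_numpy(), axis=1) == 0):
        stat, p = 0.0, 1.0
    else:
        stat, p = st.friedmanchisquare(*blocks)
    result = GroupTestResult(
        statistic=float(stat),
        p_value=float(p),
        test_name="friedman",
        group_sizes=(complete.shape[0],) * complete.shape[1],
    )
    result.extra["dunn"] = _dunn_friedman(complete.to_numpy(), list(complete.columns), adjust)
    return result


def _dunn_friedman(values: np.ndarray, labels: list[str], adjust: str) -> list[dict]:
    """Dunn's post-hoc for Friedman designs: within-subject rank sums,
    z = ΔR̄ / sqrt(k(k+1) / (6n))."""
    n, k = values.shape
    ranks = np.vstack([st.rankdata(row) for row in values])
    mean_ranks = ranks.mean(axis=0)
    se = math.sqrt(k * (k + 1) / (6.0 * n))
    raw = []
    for i in range(k):
        for j in range(i + 1, k):
            z = (mean_ranks[i] - mean_ranks[j]) / se
            p = 2.0 * st.norm.sf(abs(z))
            raw.append({"pair": (labels[i], labels[j]), "z": z, "p": p})
    m = len(raw)
    if adjust == "bonferroni":
        for r in raw:
            r["p_adjusted"] = min(1.0, r["p"] * m)
    elif adjust == "bh":
        order = np.argsort([r["p"] for r in raw])
        prev = 1.0
        adj = np.empty(m)
        for pos in range(m - 1, -1, -1):
            idx = order[pos]
            prev = min(prev, raw[idx]["p"] * m / (pos + 1))
            adj[idx] = prev
        for r, a in zip(raw, adj):
            r["p_adjusted"] = float(a)
    else:
        raise ValueError(f"unknown adjustment {adjust!r}")
    return raw


def slopes(series: BlockSeries) -> list[SlopePair]:
    """Per contig/group OLS slopes of prevalence and abundance on block
    midpoints (missing blocks omitted pairwise; <2 populated blocks → no
    slope for that contig/group)."""
    x_all = np.asarray(BLOCK_MIDPOINTS)
    out: list[SlopePair] = []
    for (contig, group) in series.prevalence.index:
        prow = series.prevalence.loc[(contig, group)].to_numpy(dtype=float)
        arow = series.abundance.loc[(contig, group)].to_numpy(dtype=float)
        pair = []
        for row in (prow, arow):
            ok = ~np.isnan(row)
            if ok.sum() < 2:
                pair.append(np.nan)
                continue
            slope = np.polyfit(x_all[ok], row[ok], 1)[0]
            pair.append(float(slope))
        if not (math.isnan(pair[0]) and math.isnan(pair[1])):
            out.append(SlopePair(contig, group, pair[0], pair[1]))
    return out


def slopes_to_frame(pairs: list[SlopePair]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "contig_id": p.contig_id,
                "group": p.group,
                "prevalence_slope": p.prevalence_slope,
                "abundance_slope": p.abundance_slope,
            }
            for p in pairs
        ],
        columns=["contig_id", "group", "prevalence_slope", "abundance_slope"],
    )
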