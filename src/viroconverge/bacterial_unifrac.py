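"""Bacterial-side processing: rarefaction and UniFrac distances.

Genus-level 16S count tables are rarefied to a fixed depth (2,500 reads;
samples below depth are dropped) by exact multivariate-hypergeometric
subsampling, then compared with unweighted and weighted UniFrac on a rooted
genus tree.  UniFrac is computed by a single postorder pass that propagates
per-sample presence (unweighted) or relative abundance (weighted) to every
branch:

* unweighted: D = Σ b·[branch in exactly one sample's spanned set] /
  Σ b·[branch in either sample's spanned set]
* weighted (raw): D = Σ b·|p_A − p_B|; the normalized variant divides by
  Σ b·(p_A + p_B), bounding it to [0, 1].

The window analysis on the bacterial distance matrix delegates to the same
event-anchored machinery used for the virome.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core_model import CountTable, PhyloTree, ReferentialError
from .diversity_metrics import DistanceResult
from .event_anchor import SamplePair, WindowSeries, convergence_series

__all__ = [
    "RarefiedTable",
    "rarefy",
    "unweighted_unifrac",
    "weighted_unifrac",
    "bacterial_convergence",
]


@dataclass
class RarefiedTable:
    """Genus × sample counts where every retained column sums to ``depth``."""

    data: pd.DataFrame
    depth: int
    dropped: list[str]
    seed: int | None = None

    def __post_init__(self) -> None:
        sums = self.data.sum(axis=0)
        if (sums != self.depth).any():
            bad = sums[sums != self.depth].index.tolist()
            raise ValueError(f"rarefied columns not summing to depth: {bad[:5]}")

    @property
    def sample_ids(self) -> list[str]:
        return self.data.columns.tolist()


def rarefy(counts: CountTable, depth: int = 2500, seed: int | None = None) -> RarefiedTable:
    """Subsample each column to ``depth`` reads without replacement.

    Samples with fewer than ``depth`` total reads are dropped (and listed).
    Columns already exactly at depth pass through unchanged.
    """
    if depth <= 0:
        raise ValueError("rarefaction depth must be > 0")
    rng = np.random.default_rng(seed)
    kept, dropped = {}, []
    for sid in counts.sample_ids:
        col = counts.data[sid].to_numpy()
        total = int(col.sum())
        if total < depth:
            dropped.append(sid)
            continue
        if total == depth:
            kept[sid] = col.copy()
        else:
            kept[sid] = rng.multivariate_hypergeometric(col, depth)
    data = pd.DataFrame(kept, index=counts.data.index)
    return RarefiedTable(data=data, depth=depth, dropped=dropped, seed=seed)


# ---------------------------------------------------------------------------
# UniFrac
# ---------------------------------------------------------------------------


def _branch_table(tree: PhyloTree, genus_ids: list[str]) -> tuple[np.ndarray, np.ndarray]:
    """(branch lengths, branch × genus membership) for all non-root branches.

    membership[b, g] is True when genus g lies below branch b, so a sample's
    mass/presence on branch b is the aggregate of its genera below b.
    """
    tree.require_leaves(genus_ids)
    idx = {g: i for i, g in enumerate(genus_ids)}
    lengths, members = [], []
    root = tree.tree
    for node in root.postorder(include_self=False):
        below = np.zeros(len(genus_ids), dtype=bool)
        for tip in node.tips(include_self=True):
            if tip.name in idx:
                below[idx[tip.name]] = True
        lengths.append(float(node.length or 0.0))
        members.append(below)
    return np.asarray(lengths), np.vstack(members)


def _unifrac_matrix(
    rarefied: RarefiedTable, tree: PhyloTree, weighted: bool, normalized: bool
) -> DistanceResult:
    genus_ids = rarefied.data.index.tolist()
    used = rarefied.data.index[(rarefied.data > 0).any(axis=1)].tolist()
    missing = set(used) - set(tree.leaf_names)
    if missing:
        raise ReferentialError(f"genera absent from tree: {sorted(missing)[:5]}")
    lengths, members = _branch_table(tree, genus_ids)

    counts = rarefied.data.to_numpy(dtype=float)
    totals = counts.sum(axis=0)
    props = counts / totals[None, :]
    # per-branch aggregates: branches × samples
    branch_prop = members.astype(float) @ props
    branch_present = (members.astype(float) @ (counts > 0)) > 0

    n = counts.shape[1]
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            if weighted:
                num = float((lengths * np.abs(branch_prop[:, i] - branch_prop[:, j])).sum())
                if normalized:
                    den = float((lengths * (branch_prop[:, i] + branch_prop[:, j])).sum())
                    d[i, j] = d[j, i] = num / den if den > 0 else 0.0
                else:
                    d[i, j] = d[j, i] = num
            else:
                a, b = branch_present[:, i], branch_present[:, j]
                union = float((lengths * (a | b)).sum())
                unique = float((lengths * (a ^ b)).sum())
                d[i, j] = d[j, i] = unique / union if union > 0 else 0.0
    name = ("weighted" if weighted else "unweighted") + "_unifrac"
    if weighted and normalized:
        name += "_normalized"
    return DistanceResult(
        pd.DataFrame(d, index=rarefied.sample_ids, columns=rarefied.sample_ids), metric=name
    )


def unweighted_unifrac(rarefied: RarefiedTable, tree: PhyloTree) -> DistanceResult:
    """Presence-based UniFrac: unique branch length over spanned branch length."""
    return _unifrac_matrix(rarefied, tree, weighted=False, normalized=False)


def weighted_unifrac(
    rarefied: RarefiedTable, tree: PhyloTree, normalized: bool = True
) -> DistanceResult:
    """Abundance-weighted UniFrac; ``normalized`` bounds it to [0, 1]."""
    return _unifrac_matrix(rarefied, tree, weighted=True, normalized=normalized)


def bacterial_convergence(
    d: DistanceResult, windows: WindowSeries, pairs: list[SamplePair] | None = None
) -> WindowSeries:
    """Event-anchored window series on the bacterial distance matrix."""
    return convergence_series(d, windows, pairs)
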