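"""LDA-effect-size discriminant screen for time-associated viral contigs.

Case samples are split into a *late* class ([0, 10) days before onset) and an
*early* class ([10, lookback] days before).  The screen then:

1. drops contigs detected in fewer than 10% of the samples analysed;
2. total-sum scales each sample to a fixed constant (one million);
3. runs a per-contig Kruskal–Wallis test and keeps p ≤ alpha;
4. scores each survivor with a bootstrapped linear-discriminant effect size:
   the average over seeded 2/3 subsamples of each class of
   (|w_i · Δm_i| + |Δm_i|) / 2, where w is the unit-norm discriminant
   coefficient vector over surviving contigs and Δm_i the class-mean
   difference of contig i, floored at 1 and log10-scaled;
5. keeps effect sizes ≥ 2.0 and assigns the class with the larger mean.

The same algorithm applied to control samples (anchored to their matched
case's onset) gives the control-side screen.  The subclass stage of the
original published tool is omitted: this design has no subclasses.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats as st
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis

from .event_anchor import AnchoredSample
from .normalization import AbundanceTable

__all__ = ["LefseConfig", "DiscriminantFeature", "lefse_screen", "control_side_screen"]

LATE = "late"
EARLY = "early"


@dataclass(frozen=True)
class LefseConfig:
    class_boundary_days: float = 10.0
    lookback_days: float = 46.0
    prevalence_threshold: float = 0.10
    kw_alpha: float = 0.05
    lda_threshold: float = 2.0
    n_bootstrap: int = 30
    bootstrap_fraction: float = 2.0 / 3.0
    tss_constant: float = 1_000_000.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.prevalence_threshold < 1):
            raise ValueError("prevalence_threshold must be in (0, 1)")
        if not self.lda_threshold > 0:
            raise ValueError("lda_threshold must be > 0")
        if not (0 < self.bootstrap_fraction <= 1):
            raise ValueError("bootstrap_fraction must be in (0, 1]")


@dataclass(frozen=True)
class DiscriminantFeature:
    contig_id: str
    assigned_class: str  # LATE | EARLY
    kw_p: float
    effect_size: float
    boundary_in_early: bool = True  # day `boundary` itself belongs to the early class


def _classes(
    anchored: list[AnchoredSample], group: str, config: LefseConfig
) -> tuple[list[str], np.ndarray]:
    """Sample ids of the given group inside the lookback, with late/early labels."""
    sids, labels = [], []
    for a in anchored:
        if a.group != group or a.post_event:
            continue
        t = a.days_before_event
        if t > config.lookback_days:
            continue
        sids.append(a.sample_id)
        labels.append(LATE if t < config.class_boundary_days else EARLY)
    return sids, np.asarray(labels)


def _screen(
    abundance: AbundanceTable, sids: list[str], labels: np.ndarray, config: LefseConfig
) -> list[DiscriminantFeature]:
    for cls in (LATE, EARLY):
        if int((labels == cls).sum()) < 3:
            raise ValueError(f"class {cls!r} has fewer than 3 samples: discriminant undefined")

    data = abundance.data[sids]
    # step 1: prevalence filter over the samples being analysed
    prevalence = (data > 0).mean(axis=1)
    data = data.loc[prevalence >= config.prevalence_threshold]
    if data.empty:
        return []

    # step 2: total-sum scaling to a fixed constant
    totals = data.sum(axis=0).replace(0, np.nan)
    tss = (data / totals) * config.tss_constant
    tss = tss.fillna(0.0)

    x = tss.to_numpy(dtype=float).T  # samples × contigs
    is_late = labels == LATE

    # step 3: per-contig Kruskal-Wallis gate
    keep_idx, kw_ps = [], []
    for i in range(x.shape[1]):
        a, b = x[is_late, i], x[~is_late, i]
        if np.unique(np.concatenate([a, b])).size == 1:
            continue
        _, p = st.kruskal(a, b)
        if p <= config.kw_alpha:
            keep_idx.append(i)
            kw_ps.append(float(p))
    if not keep_idx:
        return []
    xk = x[:, keep_idx]
    contig_ids = [tss.index[i] for i in keep_idx]

    # step 4: bootstrapped discriminant effect size
    rng = np.random.default_rng(config.seed)
    late_rows = np.flatnonzero(is_late)
    early_rows = np.flatnonzero(~is_late)
    n_late = max(2, int(round(config.bootstrap_fraction * late_rows.size)))
    n_early = max(2, int(round(config.bootstrap_fraction * early_rows.size)))
    scores = np.zeros(xk.shape[1])
    for _ in range(config.n_bootstrap):
        rows = np.concatenate(
            [
                rng.choice(late_rows, size=n_late, replace=False),
                rng.choice(early_rows, size=n_early, replace=False),
            ]
        )
        xb, yb = xk[rows], is_late[rows]
        m_diff = xb[yb].mean(axis=0) - xb[~yb].mean(axis=0)
        w = _discriminant_axis(xb, yb)
        scores += (np.abs(w * m_diff) + np.abs(m_diff)) / 2.0
    scores /= config.n_bootstrap
    effects = np.log10(np.maximum(scores, 1.0))

    # step 5: effect-size threshold and class assignment by larger class mean
    out = []
    overall_diff = xk[is_late].mean(axis=0) - xk[~is_late].mean(axis=0)
    for cid, p, ef, diff in zip(contig_ids, kw_ps, effects, overall_diff):
        if ef >= config.lda_threshold:
            out.append(
                DiscriminantFeature(
                    contig_id=cid,
                    assigned_class=LATE if diff > 0 else EARLY,
                    kw_p=p,
                    effect_size=float(ef),
                )
            )
    return out


def _discriminant_axis(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Unit-norm two-class LDA coefficient vector (shrinkage-regularized)."""
    if np.unique(y).size < 2:
        return np.zeros(x.shape[1])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        lda = LinearDiscriminantAnalysis(solver="lsqr", shrinkage="auto")
        try:
            lda.fit(x, y.astype(int))
        except Exception:
            return np.zeros(x.shape[1])
    w = lda.coef_.ravel()
    norm = np.linalg.norm(w)
    return w / norm if norm > 0 else w


def lefse_screen(
    abundance: AbundanceTable, anchored: list[AnchoredSample], config: LefseConfig = LefseConfig()
) -> list[DiscriminantFeature]:
    """Discriminant screen on case samples: late ([0, boundary)) vs early."""
    sids, labels = _classes(anchored, "case", config)
    return _screen(abundance, sids, labels, config)


def control_side_screen(
    abundance: AbundanceTable, anchored: list[AnchoredSample], config: LefseConfig = LefseConfig()
) -> list[DiscriminantFeature]:
    """Same screen on control samples, anchored to the matched case's onset."""
    sids, labels = _classes(anchored, "control", config)
    if not sids:
        raise ValueError("no control samples inside the lookback window")
    return _screen(abundance, sids, labels, config)


def features_to_frame(features: list[DiscriminantFeature]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "contig_id": f.contig_id,
                "class": f.assigned_class,
                "kw_p": f.kw_p,
                "effect_size": f.effect_size,
            }
            for f in features
        ],
        columns=["contig_id", "class", "kw_p", "effect_size"],
    )
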