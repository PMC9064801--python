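"""Backward anchoring to disease onset, matched pairing and sliding windows.

Every sample is re-timed as days-before-event: for a case infant the event is
their own onset day of life; for a control it is the onset day of the case
they were matched to.  Windows of width 7 d advance in 2 d steps over
days-before-event; each window collects between-case and between-control
dissimilarities (cross-infant pairs only) and is tested with a two-sided
Mann–Whitney U.  Half-open intervals [k, k+width) are used so the window
labelled "7–0 d" contains samples taken on the onset day itself.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import scipy.stats as st

from .cohort_stats import GroupTestResult, mann_whitney
from .core_model import CohortMetadata, ReferentialError
from .diversity_metrics import DistanceResult

__all__ = [
    "AnchoredSample",
    "WindowSpec",
    "Window",
    "WindowSeries",
    "SamplePair",
    "anchor",
    "pair_samples",
    "build_windows",
    "convergence_series",
    "across_window_test",
    "dunn_posthoc",
]


@dataclass(frozen=True)
class AnchoredSample:
    sample_id: str
    infant_id: str
    group: str  # case | control
    day_of_life: float
    days_before_event: float

    @property
    def post_event(self) -> bool:
        return self.days_before_event < 0


@dataclass(frozen=True)
class WindowSpec:
    width: float = 7.0
    step: float = 2.0
    max_lookback: float = 25.0

    def __post_init__(self) -> None:
        if not self.width > 0:
            raise ValueError("window width must be > 0")
        if not (0 < self.step <= self.width):
            raise ValueError("step must satisfy 0 < step <= width")


@dataclass
class Window:
    """One sliding window [start, start+width) in days-before-event."""

    start: float
    stop: float
    case_samples: list[AnchoredSample] = field(default_factory=list)
    control_samples: list[AnchoredSample] = field(default_factory=list)
    case_values: list[float] = field(default_factory=list)
    control_values: list[float] = field(default_factory=list)
    test: GroupTestResult | None = None
    insufficient: bool = False

    def contains(self, days_before: float) -> bool:
        return self.start <= days_before < self.stop

    @property
    def label(self) -> str:
        return f"{self.stop:g}-{self.start:g}d"


@dataclass
class WindowSeries:
    spec: WindowSpec
    windows: list[Window]


@dataclass(frozen=True)
class SamplePair:
    case_sample_id: str
    control_sample_id: str
    control_infant_id: str
    delta_days: float


# ---------------------------------------------------------------------------
# anchoring
# ---------------------------------------------------------------------------


def anchor(meta: CohortMetadata) -> list[AnchoredSample]:
    """Compute days-before-event for every sample.

    Controls borrow the event day of their matched case.  Post-event samples
    (negative days-before) are kept but flagged; window construction skips
    them.
    """
    out: list[AnchoredSample] = []
    for s in meta.samples.values():
        inf = meta.infants[s.infant_id]
        if inf.group == "case":
            event = inf.event_dol
        else:
            case = meta.infants[inf.matched_case_id]
            if case.event_dol is None:
                raise ReferentialError(
                    f"control {inf.infant_id}: matched case {case.infant_id} has no event day"
                )
            event = case.event_dol
        out.append(
            AnchoredSample(
                sample_id=s.sample_id,
                infant_id=s.infant_id,
                group=inf.group,
                day_of_life=s.day_of_life,
                days_before_event=event - s.day_of_life,
            )
        )
    return out


# ---------------------------------------------------------------------------
# matched case-control sample pairing
# ---------------------------------------------------------------------------


def pair_samples(
    anchored: list[AnchoredSample],
    meta: CohortMetadata,
    tolerance: float = 3.5,
) -> list[SamplePair]:
    """Pair each case sample with the nearest sample of each matched control.

    For every case sample and each control infant matched to that case, the
    control sample minimizing |Δ day of life| is paired if |Δ| ≤ tolerance;
    a control sample is used at most once per case sample set.  Ties break
    toward the earlier control sample.  Case samples with no admissible
    control remain unpaired.
    """
    by_infant: dict[str, list[AnchoredSample]] = {}
    for a in anchored:
        by_infant.setdefault(a.infant_id, []).append(a)

    controls_of: dict[str, list[str]] = {}
    for inf in meta.controls:
        controls_of.setdefault(inf.matched_case_id, []).append(inf.infant_id)

    pairs: list[SamplePair] = []
    for case in meta.cases:
        case_samples = sorted(by_infant.get(case.infant_id, []), key=lambda a: a.day_of_life)
        for ctrl_id in sorted(controls_of.get(case.infant_id, [])):
            used: set[str] = set()
            ctrl_samples = sorted(by_infant.get(ctrl_id, []), key=lambda a: a.day_of_life)
            for cs in case_samples:
                best = None
                for xs in ctrl_samples:
                    if xs.sample_id in used:
                        continue
                    delta = abs(xs.day_of_life - cs.day_of_life)
                    if delta > tolerance:
                        continue
                    # strict < keeps the earlier sample on ties (list is sorted)
                    if best is None or delta < best[0] - 1e-12:
                        best = (delta, xs)
                if best is not None:
                    used.add(best[1].sample_id)
                    pairs.append(
                        SamplePair(
                            case_sample_id=cs.sample_id,
                            control_sample_id=best[1].sample_id,
                            control_infant_id=ctrl_id,
                            delta_days=best[0],
                        )
                    )
    return pairs


# ---------------------------------------------------------------------------
# windows
# ---------------------------------------------------------------------------


def build_windows(spec: WindowSpec, anchored: list[AnchoredSample]) -> WindowSeries:
    """Lay out windows [k, k+width) for k = 0, step, … while k+width ≤ lookback
    and assign each pre-event sample to every window containing it."""
    windows: list[Window] = []
    k = 0.0
    while k + spec.width <= spec.max_lookback + 1e-9:
        windows.append(Window(start=k, stop=k + spec.width))
        k += spec.step
    for a in anchored:
        if a.post_event:
            continue
        for w in windows:
            if w.contains(a.days_before_event):
                (w.case_samples if a.group == "case" else w.control_samples).append(a)
    return WindowSeries(spec=spec, windows=windows)


def _median_ci(values: list[float], confidence: float = 0.95) -> tuple[float, float]:
    """Distribution-free CI for the median from binomial order statistics."""
    v = np.sort(np.asarray(values, dtype=float))
    n = v.size
    if n < 3:
        return (float("nan"), float("nan"))
    lo = int(st.binom.ppf((1 - confidence) / 2, n, 0.5))
    hi = int(st.binom.ppf(1 - (1 - confidence) / 2, n, 0.5))
    hi = min(hi, n - 1)
    return float(v[lo]), float(v[hi])


def _cross_infant_values(
    samples: list[AnchoredSample], d: DistanceResult
) -> list[float]:
    """All dissimilarities between samples of *distinct* infants in a window.

    Samples absent from the distance matrix (e.g. dropped at rarefaction) and
    undefined pairs (NaN) are skipped.
    """
    covered = set(d.sample_ids)
    vals = []
    for i in range(len(samples)):
        for j in range(i + 1, len(samples)):
            a, b = samples[i], samples[j]
            if a.infant_id == b.infant_id:
                continue
            if a.sample_id not in covered or b.sample_id not in covered:
                continue
            v = d.value(a.sample_id, b.sample_id)
            if not math.isnan(v):
                vals.append(v)
    return vals


def convergence_series(
    d: DistanceResult,
    series: WindowSeries,
    pairs: list[SamplePair] | None = None,
    min_infants: int = 2,
) -> WindowSeries:
    """Fill a window skeleton with between-case and between-control
    dissimilarity multisets and per-window Mann–Whitney tests.

    When ``pairs`` is given, only control samples that were matched to a case
    sample enter the control multisets (mirroring the matched design); pass
    ``None`` to use every control sample in a window.
    """
    paired_ids = None if pairs is None else {p.control_sample_id for p in pairs}
    for w in series.windows:
        ctrl = w.control_samples
        if paired_ids is not None:
            ctrl = [s for s in ctrl if s.sample_id in paired_ids]
        w.case_values = _cross_infant_values(w.case_samples, d)
        w.control_values = _cross_infant_values(ctrl, d)
        n_case_inf = len({s.infant_id for s in w.case_samples})
        n_ctrl_inf = len({s.infant_id for s in ctrl})
        if n_case_inf < min_infants or n_ctrl_inf < min_infants or not w.case_values or not w.control_values:
            w.insufficient = True
            w.test = None
            continue
        w.test = mann_whitney(w.case_values, w.control_values)
        w.test.extra["case_median"] = float(np.median(w.case_values))
        w.test.extra["control_median"] = float(np.median(w.control_values))
        w.test.extra["case_median_ci"] = _median_ci(w.case_values)
        w.test.extra["control_median_ci"] = _median_ci(w.control_values)
    return series


# ---------------------------------------------------------------------------
# across-window tests
# ---------------------------------------------------------------------------


def dunn_posthoc(groups: list[list[float]], adjust: str = "bonferroni") -> list[dict]:
    """Dunn's z post-hoc for all group pairs after a Kruskal–Wallis test.

    Uses pooled tie-corrected rank variance; adjustment is Bonferroni by
    default, Benjamini–Hochberg with ``adjust='bh'``.
    """
    pooled = np.concatenate([np.asarray(g, dtype=float) for g in groups])
    ranks = st.rankdata(pooled)
    n_total = pooled.size
    sizes = [len(g) for g in groups]
    mean_ranks = []
    start = 0
    for sz in sizes:
        mean_ranks.append(ranks[start : start + sz].mean())
        start += sz
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = (tie_counts**3 - tie_counts).sum() / (12.0 * (n_total - 1))
    var_base = n_total * (n_total + 1) / 12.0 - tie_term

    raw = []
    for i in range(len(groups)):
        for j in range(i + 1, len(groups)):
            se = math.sqrt(var_base * (1.0 / sizes[i] + 1.0 / sizes[j]))
            z = (mean_ranks[i] - mean_ranks[j]) / se if se > 0 else 0.0
            p = 2.0 * st.norm.sf(abs(z))
            raw.append({"pair": (i, j), "z": z, "p": p})
    m = len(raw)
    if adjust == "bonferroni":
        for r in raw:
            r["p_adjusted"] = min(1.0, r["p"] * m)
    elif adjust == "bh":
        order = np.argsort([r["p"] for r in raw])
        adj = np.empty(m)
        prev = 1.0
        for rank_idx in range(m - 1, -1, -1):
            idx = order[rank_idx]
            prev = min(prev, raw[idx]["p"] * m / (rank_idx + 1))
            adj[idx] = prev
        for r, a in zip(raw, adj):
            r["p_adjusted"] = float(a)
    else:
        raise ValueError(f"unknown adjustment {adjust!r}")
    return raw


def across_window_test(
    series: WindowSeries, group: str = "case", adjust: str = "bonferroni"
) -> GroupTestResult:
    """Kruskal–Wallis across windows within one group, with Dunn post-hoc."""
    key = "case_values" if group == "case" else "control_values"
    groups = [getattr(w, key) for w in series.windows if len(getattr(w, key)) >= 2]
    if len(groups) < 3:
        raise ValueError("need at least 3 windows with data")
    flat = np.concatenate(groups)
    if np.unique(flat).size == 1:
        stat, p = 0.0, 1.0
    else:
        stat, p = st.kruskal(*groups)
    result = GroupTestResult(
        statistic=float(stat),
        p_value=float(p),
        test_name="kruskal_wallis",
        group_sizes=tuple(len(g) for g in groups),
    )
    result.extra["dunn"] = dunn_posthoc(groups, adjust=adjust)
    return result
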