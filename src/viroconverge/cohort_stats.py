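"""Ordination, global tests, within/between comparisons and metadata tests.

PCoA is classical metric multidimensional scaling (Gower double-centering +
eigendecomposition).  PERMANOVA supports both categorical groupings and a
continuous covariate (postmenstrual age in the study design) through a
hat-matrix projection of the centered inner-product matrix; p-values come
from label permutations.  The scalar tests (Mann–Whitney, Fisher exact)
delegate to scipy, whose two-sided Fisher test uses probability-mass
summation and reproduces the cohort-characteristics table of the study
design this pipeline follows.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.stats as st
import statsmodels.api as sm
import statsmodels.formula.api as smf

from .core_model import SampleInfo
from .diversity_metrics import DistanceResult

__all__ = [
    "OrdinationResult",
    "GroupTestResult",
    "pcoa",
    "permanova",
    "within_between",
    "alpha_trend",
    "fisher_exact_2x2",
    "mann_whitney",
]

#: eigenvalues with |λ| below this are treated as numerically zero
EIGENVALUE_TOLERANCE = 1e-10


@dataclass
class GroupTestResult:
    statistic: float
    p_value: float
    test_name: str
    group_sizes: tuple[int, ...] = ()
    extra: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (math.isnan(self.p_value) or 0.0 <= self.p_value <= 1.0):
            raise ValueError(f"p-value {self.p_value} outside [0, 1]")


@dataclass
class OrdinationResult:
    """Sample coordinates on the positive principal axes of a PCoA."""

    coordinates: pd.DataFrame  # samples × axes
    eigenvalues: np.ndarray  # all eigenvalues, descending (negatives reported)
    proportion_explained: np.ndarray  # over positive eigenvalues


# ---------------------------------------------------------------------------
# ordination
# ---------------------------------------------------------------------------


def _gower_center(d: np.ndarray) -> np.ndarray:
    a = -0.5 * d**2
    row = a.mean(axis=1, keepdims=True)
    col = a.mean(axis=0, keepdims=True)
    return a - row - col + a.mean()


def pcoa(d: DistanceResult, k: int = 2) -> OrdinationResult:
    """Classical metric MDS of a distance matrix.

    Negative eigenvalues (non-Euclidean input) are reported but their axes are
    dropped; ``k`` is truncated to the number of positive eigenvalues.
    """
    mat = d.matrix.to_numpy(dtype=float)
    n = mat.shape[0]
    if n < 3:
        raise ValueError("PCoA needs at least 3 samples")
    if np.isnan(mat).any():
        raise ValueError("PCoA input contains undefined pairs")
    g = _gower_center(mat)
    eigvals, eigvecs = np.linalg.eigh((g + g.T) / 2.0)
    order = np.argsort(eigvals)[::-1]
    eigvals, eigvecs = eigvals[order], eigvecs[:, order]
    positive = eigvals > EIGENVALUE_TOLERANCE
    n_pos = int(positive.sum())
    if k > n_pos:
        warnings.warn(f"requested {k} axes but only {n_pos} positive eigenvalues; truncating")
        k = n_pos
    coords = eigvecs[:, :k] * np.sqrt(eigvals[:k])[None, :] if k else np.zeros((n, 0))
    pos_sum = eigvals[positive].sum()
    prop = eigvals[:k] / pos_sum if pos_sum > 0 else np.zeros(k)
    return OrdinationResult(
        coordinates=pd.DataFrame(
            coords, index=d.sample_ids, columns=[f"PC{i+1}" for i in range(k)]
        ),
        eigenvalues=eigvals,
        proportion_explained=prop,
    )


# ---------------------------------------------------------------------------
# PERMANOVA
# ---------------------------------------------------------------------------


def _design_matrix(covariate: pd.Series) -> np.ndarray:
    """Centered design: one column for continuous, k−1 dummies for categorical."""
    if pd.api.types.is_numeric_dtype(covariate):
        x = covariate.to_numpy(dtype=float)[:, None]
    else:
        dummies = pd.get_dummies(covariate, drop_first=True)
        if dummies.shape[1] == 0:
            raise ValueError("constant covariate: degenerate PERMANOVA design")
        x = dummies.to_numpy(dtype=float)
    x = x - x.mean(axis=0, keepdims=True)
    if np.allclose(x, 0):
        raise ValueError("constant covariate: degenerate PERMANOVA design")
    return x


def _pseudo_f(g: np.ndarray, x: np.ndarray) -> float:
    n, k = x.shape
    h = x @ np.linalg.pinv(x.T @ x) @ x.T
    ssr = float(np.trace(h @ g @ h))
    sse = float(np.trace(g) - ssr)
    return (ssr / k) / (sse / (n - k - 1))


def permanova(
    d: DistanceResult,
    covariate: pd.Series | dict | list,
    permutations: int = 999,
    seed: int | None = None,
    exhaustive: bool = False,
) -> GroupTestResult:
    """Permutational multivariate ANOVA of a distance matrix on one covariate.

    Continuous covariates enter as a single centered regression column;
    categorical ones as a dummy design.  p = (1 + #{permuted F ≥ observed F})
    / (1 + permutations); with ``exhaustive`` all n! label orders are
    enumerated and p is the exact tail fraction.
    """
    ids = d.sample_ids
    if isinstance(covariate, dict):
        covariate = pd.Series({i: covariate[i] for i in ids})
    elif isinstance(covariate, list):
        covariate = pd.Series(covariate, index=ids)
    covariate = covariate.reindex(ids)
    if covariate.isna().any():
        raise ValueError("covariate undefined for some samples")

    mat = d.matrix.to_numpy(dtype=float)
    g = _gower_center(mat)
    x = _design_matrix(covariate)
    n = len(ids)
    f_obs = _pseudo_f(g, x)

    if exhaustive:
        if n > 8:
            raise ValueError("exhaustive enumeration limited to n <= 8")
        count = total = 0
        for perm in itertools.permutations(range(n)):
            f_p = _pseudo_f(g, x[list(perm), :])
            count += f_p >= f_obs - 1e-12
            total += 1
        p = count / total
        permutations = total - 1
    else:
        if permutations < 99:
            raise ValueError("use at least 99 permutations")
        rng = np.random.default_rng(seed)
        count = 0
        for _ in range(permutations):
            perm = rng.permutation(n)
            count += _pseudo_f(g, x[perm, :]) >= f_obs - 1e-12
        p = (1 + count) / (1 + permutations)
    return GroupTestResult(
        statistic=f_obs,
        p_value=p,
        test_name="PERMANOVA",
        group_sizes=(n,),
        extra={"permutations": permutations},
    )


# ---------------------------------------------------------------------------
# within / between infants
# ---------------------------------------------------------------------------


def within_between(
    d: DistanceResult, samples: dict[str, SampleInfo] | list[SampleInfo]
) -> tuple[float, float, GroupTestResult]:
    """Median within-infant vs between-infant dissimilarity, Mann–Whitney tested."""
    if isinstance(samples, list):
        samples = {s.sample_id: s for s in samples}
    ids = d.sample_ids
    infant = {i: samples[i].infant_id for i in ids}
    mat = d.matrix.to_numpy()
    within, between = [], []
    for a in range(len(ids)):
        for b in range(a + 1, len(ids)):
            v = mat[a, b]
            if np.isnan(v):
                continue
            (within if infant[ids[a]] == infant[ids[b]] else between).append(v)
    if not within:
        raise ValueError("no within-infant pairs: every infant has a single sample")
    if not between:
        raise ValueError("no between-infant pairs: need at least two infants")
    test = mann_whitney(within, between)
    return float(np.median(within)), float(np.median(between)), test


# ---------------------------------------------------------------------------
# alpha-diversity trend (random-intercept mixed model)
# ---------------------------------------------------------------------------


def alpha_trend(
    alpha: pd.Series, samples: dict[str, SampleInfo] | list[SampleInfo]
) -> tuple[float, float]:
    """Fixed-effect slope of alpha diversity on PMA, infant as random intercept.

    Returns (slope per week of PMA, Wald p).  With a single infant the random
    intercept is unidentifiable and an OLS fallback is used (with a warning).
    """
    if isinstance(samples, list):
        samples = {s.sample_id: s for s in samples}
    df = pd.DataFrame(
        {
            "alpha": alpha,
            "pma": [samples[i].pma_weeks for i in alpha.index],
            "infant": [samples[i].infant_id for i in alpha.index],
        }
    ).dropna()
    if len(df) < 3:
        raise ValueError("need at least 3 samples")
    if df["infant"].nunique() < 2:
        warnings.warn("single infant: falling back to ordinary regression")
        fit = smf.ols("alpha ~ pma", data=df).fit()
        return float(fit.params["pma"]), float(fit.pvalues["pma"])
    if float(np.var(df["alpha"])) == 0.0:
        return 0.0, 1.0
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = smf.mixedlm("alpha ~ pma", data=df, groups=df["infant"])
        fit = model.fit(reml=True)
    return float(fit.params["pma"]), float(fit.pvalues["pma"])


# ---------------------------------------------------------------------------
# scalar tests
# ---------------------------------------------------------------------------


def fisher_exact_2x2(table) -> GroupTestResult:
    """Two-sided Fisher exact test by hypergeometric probability-mass summation."""
    t = np.asarray(table, dtype=int)
    if t.shape != (2, 2) or (t < 0).any():
        raise ValueError("need a 2x2 table of nonnegative integers")
    if (t.sum(axis=0) == 0).any() or (t.sum(axis=1) == 0).any():
        warnings.warn("zero margin in 2x2 table: p = 1 by convention")
        return GroupTestResult(statistic=np.nan, p_value=1.0, test_name="fisher_exact")
    odds, p = st.fisher_exact(t, alternative="two-sided")
    return GroupTestResult(
        statistic=float(odds),
        p_value=float(p),
        test_name="fisher_exact",
        group_sizes=tuple(t.sum(axis=1)),
    )


def mann_whitney(x, y, mode: str = "auto") -> GroupTestResult:
    """Two-sided Mann–Whitney U.

    ``auto`` uses exact enumeration when both samples have n ≤ 8 and there are
    no ties, else the tie-corrected normal approximation with continuity
    correction.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be nonempty")
    pooled = np.concatenate([x, y])
    has_ties = np.unique(pooled).size < pooled.size
    if mode == "auto":
        mode = "exact" if (x.size <= 8 and y.size <= 8 and not has_ties) else "approx"
    if mode == "exact" and has_ties:
        mode = "approx"
    method = "exact" if mode == "exact" else "asymptotic"
    res = st.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return GroupTestResult(
        statistic=float(res.statistic),
        p_value=float(res.pvalue),
        test_name=f"mann_whitney_{mode}",
        group_sizes=(int(x.size), int(y.size)),
    )
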