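"""Mixed-model association between viral contigs and bacterial genera.

For each (discriminant contig, genus) pair within one group (cases or
controls) a random-intercept linear mixed model is fitted:

    log(1 + TSS contig abundance) ~ genus relative abundance + (1 | infant)

Features below 10% prevalence in the group's samples are excluded before
modelling.  Wald p-values are Benjamini–Hochberg adjusted across all pairs
tested within the group; a pair is called significant only under the dual
gate p < 0.05 and q < 0.25.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from statsmodels.stats.multitest import multipletests

from .core_model import CohortMetadata, CountTable
from .normalization import AbundanceTable

__all__ = ["AssociationResult", "associate", "correlation_table"]

P_GATE = 0.05
Q_GATE = 0.25


@dataclass(frozen=True)
class AssociationResult:
    contig_id: str
    genus: str
    group: str
    coefficient: float
    p: float
    q: float
    significant: bool
    estimable: bool = True


def _group_samples(meta: CohortMetadata, group: str) -> list[str]:
    return [
        s.sample_id
        for s in meta.samples.values()
        if meta.infants[s.infant_id].group == group
    ]


def associate(
    contig_abundance: AbundanceTable,
    genus_counts: CountTable,
    meta: CohortMetadata,
    group: str,
    prevalence_threshold: float = 0.10,
    tss_constant: float = 1_000_000.0,
) -> list[AssociationResult]:
    """Fit one mixed model per (contig, genus) pair in one group.

    Both tables must cover the group's samples; samples present in only one
    table are dropped from the pairing.  Returns every tested pair with its
    coefficient, Wald p and BH q; inestimable fits are reported with NaN
    statistics and ``estimable=False``.
    """
    if group not in ("case", "control"):
        raise ValueError("group must be 'case' or 'control'")
    sids = [
        s
        for s in _group_samples(meta, group)
        if s in contig_abundance.data.columns and s in genus_counts.data.columns
    ]
    infants = {i.infant_id for i in meta.infants.values() if i.group == group}
    used_infants = {meta.samples[s].infant_id for s in sids}
    if len(used_infants) < 2:
        raise ValueError(f"group {group!r} has fewer than 2 infants with usable samples")

    vir = contig_abundance.data[sids]
    bac = genus_counts.data[sids].astype(float)

    # prevalence gate, then transforms
    vir = vir.loc[(vir > 0).mean(axis=1) >= prevalence_threshold]
    bac = bac.loc[(bac > 0).mean(axis=1) >= prevalence_threshold]
    bac_rel = bac / bac.sum(axis=0).replace(0, np.nan)
    vir_tss = (vir / vir.sum(axis=0).replace(0, np.nan)) * tss_constant
    vir_log = np.log1p(vir_tss.fillna(0.0))

    infant_of = pd.Series({s: meta.samples[s].infant_id for s in sids})

    rows: list[AssociationResult] = []
    fits: list[tuple[str, str, float, float]] = []
    inestimable: list[tuple[str, str]] = []
    for contig in vir_log.index:
        y = vir_log.loc[contig]
        if y.nunique() <= 1:
            # constant response: slope 0 by definition, nothing to test
            for genus in bac_rel.index:
                fits.append((contig, genus, 0.0, 1.0))
            continue
        y_arr = y.to_numpy(dtype=float)
        groups = infant_of[y.index].to_numpy()
        for genus in bac_rel.index:
            x = bac_rel.loc[genus, y.index].to_numpy(dtype=float)
            if np.unique(x[~np.isnan(x)]).size < 2:
                inestimable.append((contig, genus))
                continue
            ok = ~np.isnan(x)
            design = np.column_stack([np.ones(ok.sum()), x[ok]])
            try:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    fit = sm.MixedLM(y_arr[ok], design, groups=groups[ok]).fit(reml=True)
                coef = float(fit.params[1])
                p = float(fit.pvalues[1])
            except (np.linalg.LinAlgError, ValueError):
                inestimable.append((contig, genus))
                continue
            if not np.isfinite(p):
                inestimable.append((contig, genus))
                continue
            fits.append((contig, genus, coef, p))

    if fits:
        ps = np.array([f[3] for f in fits])
        _, qs, _, _ = multipletests(ps, method="fdr_bh")
    else:
        qs = np.array([])
    for (contig, genus, coef, p), q in zip(fits, qs):
        rows.append(
            AssociationResult(
                contig_id=contig,
                genus=genus,
                group=group,
                coefficient=coef,
                p=p,
                q=float(q),
                significant=bool(p < P_GATE and q < Q_GATE),
            )
        )
    for contig, genus in inestimable:
        rows.append(
            AssociationResult(
                contig_id=contig,
                genus=genus,
                group=group,
                coefficient=float("nan"),
                p=float("nan"),
                q=float("nan"),
                significant=False,
                estimable=False,
            )
        )
    return rows


def correlation_table(results: list[AssociationResult]) -> pd.DataFrame:
    """Contig × genus matrix of significant coefficients (zeros elsewhere).

    Rows and columns are ordered by mean coefficient — a deterministic,
    dendrogram-free surrogate for the usual clustered heat-map ordering.
    """
    contigs = sorted({r.contig_id for r in results})
    genera = sorted({r.genus for r in results})
    mat = pd.DataFrame(0.0, index=contigs, columns=genera)
    for r in results:
        if r.significant:
            mat.loc[r.contig_id, r.genus] = r.coefficient
    row_order = mat.mean(axis=1).sort_values(ascending=False).index
    col_order = mat.mean(axis=0).sort_values(ascending=False).index
    return mat.loc[row_order, col_order]


def results_to_frame(results: list[AssociationResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "contig_id": r.contig_id,
                "genus": r.genus,
                "group": r.group,
                "coefficient": r.coefficient,
                "p": r.p,
                "q": r.q,
                "significant": r.significant,
                "estimable": r.estimable,
            }
            for r in results
        ],
        columns=["contig_id", "genus", "group", "coefficient", "p", "q", "significant", "estimable"],
    )
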