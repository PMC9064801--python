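"""Synthetic longitudinal cohort generator with planted, labelled effects.

Emulates a matched preterm-infant cohort (9 cases who develop necrotizing
enterocolitis, 14 matched controls, 4–8 stool samples each) with the
statistical structure the downstream analyses assume:

* strong inter-individual virome variation with intra-individual stability —
  each infant draws a personal contig weight vector from heavy-tailed
  Gamma(0.05) variables (a Dirichlet community once normalized) that is
  reused for all of that infant's samples, with a persistence-thinned
  presence mask adding temporal turnover;
* a programmable pre-event convergence signature — a designated set of
  contigs whose per-sample occurrence probability ramps up and whose
  abundance is multiplied inside the 10 days before the (matched) event,
  in case infants only;
* early-period contigs that decay toward the event in cases, and a separate
  contig set that ramps with absolute age in controls;
* a genus-level bacterial table with low dispersion among case infants and
  signed contig–genus couplings in cases only;
* family labels drawn so the expected per-sample family profile matches an
  unclassified-dominated virome (~85% unclassified).

Every planted contig and coupling is reported in :class:`TruthLabels`, so
recovery rates are measurable, and the whole cohort is a deterministic
function of the seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core_model import (
    CohortMetadata,
    ContigCatalog,
    CountTable,
    InfantInfo,
    PhyloTree,
    SampleInfo,
    tree_from_newick,
)
from .normalization import AbundanceTable

__all__ = ["SyntheticParams", "TruthLabels", "generate_cohort", "family_profile", "GENUS_NAMES"]

FAMILY_PROBS = {
    "unclassified": 0.853,
    "Myoviridae": 0.051,
    "Siphoviridae": 0.038,
    "Podoviridae": 0.028,
    "Microviridae": 0.012,
    "Anelloviridae": 0.010,
    "Circoviridae": 0.008,
}

GENUS_NAMES = [
    "Escherichia", "Streptococcus", "Klebsiella", "Enterococcus", "Veillonella",
    "Staphylococcus", "Enterobacter", "Bifidobacterium", "Bacteroides", "Clostridium",
    "Citrobacter", "Serratia", "Proteus", "Haemophilus", "Lactobacillus",
    "Prevotella", "Finegoldia", "Peptoniphilus", "Corynebacterium", "Acinetobacter",
    "Pseudomonas", "Raoultella", "Morganella", "Anaerococcus", "Actinomyces",
    "Rothia", "Gemella", "Granulicatella", "Fusobacterium", "Eggerthella",
]


@dataclass(frozen=True)
class SyntheticParams:
    """Generator knobs; the defaults are the study conditions being emulated."""

    n_cases: int = 9
    n_controls: int = 14
    n_contigs: int = 2000
    n_signature_contigs: int = 137
    n_early_contigs: int = 11
    n_control_late_contigs: int = 100
    signature_window_days: float = 10.0
    #: occurrence probability added linearly across the window (baseline 5% → 60% at day 0)
    signature_prevalence_lift: float = 0.55
    signature_abundance_lift: float = 8.0
    baseline_occurrence: float = 0.05
    community_concentration: float = 0.05
    #: fraction of the ordinary contig pool each infant can carry at all —
    #: per-infant repertoires drive the strong inter-individual variation
    repertoire_fraction: float = 0.55
    temporal_persistence: float = 0.8
    presence_occupancy: float = 0.5
    reads_median: float = 412_905.0
    reads_log_sigma: float = 0.44
    n_genera: int = 30
    bacterial_reads_median: float = 6000.0
    n_couplings: int = 4
    coupling_strength: float = 0.45
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_cases, self.n_controls, self.n_contigs, self.n_genera) <= 0:
            raise ValueError("counts must be > 0")
        special = self.n_signature_contigs + self.n_early_contigs + self.n_control_late_contigs
        if special > self.n_contigs:
            raise ValueError("signature/early/late contig sets exceed the contig pool")
        for p in (self.baseline_occurrence, self.temporal_persistence, self.presence_occupancy):
            if not (0.0 <= p <= 1.0):
                raise ValueError("probabilities must be in [0, 1]")
        if self.signature_prevalence_lift < 0 or self.signature_abundance_lift <= 0:
            raise ValueError("lifts must be nonnegative (abundance lift > 0)")

    @property
    def planted(self) -> bool:
        """False = null cohort: every programmed effect switched off."""
        return self.signature_prevalence_lift > 0 or self.signature_abundance_lift != 1.0


@dataclass
class TruthLabels:
    """Names of every planted contig and contig–genus coupling (empty if null)."""

    signature_contigs: list[str] = field(default_factory=list)
    early_contigs: list[str] = field(default_factory=list)
    control_late_contigs: list[str] = field(default_factory=list)
    couplings: list[tuple[str, str, int]] = field(default_factory=list)  # contig, genus, sign

    def __post_init__(self) -> None:
        sets = [set(self.signature_contigs), set(self.early_contigs), set(self.control_late_contigs)]
        for i in range(3):
            for j in range(i + 1, 3):
                if sets[i] & sets[j]:
                    raise ValueError("planted contig sets must be disjoint")

    def to_frame(self) -> pd.DataFrame:
        rows = [{"feature": c, "label": "signature", "partner": "", "sign": 0} for c in self.signature_contigs]
        rows += [{"feature": c, "label": "early", "partner": "", "sign": 0} for c in self.early_contigs]
        rows += [{"feature": c, "label": "control_late", "partner": "", "sign": 0} for c in self.control_late_contigs]
        rows += [
            {"feature": c, "label": "coupling", "partner": g, "sign": s} for c, g, s in self.couplings
        ]
        return pd.DataFrame(rows, columns=["feature", "label", "partner", "sign"])


# ---------------------------------------------------------------------------
# cohort generation
# ---------------------------------------------------------------------------


def _draw_metadata(params: SyntheticParams, rng: np.random.Generator):
    infants: dict[str, InfantInfo] = {}
    samples: dict[str, SampleInfo] = {}
    case_days: dict[str, list[float]] = {}

    case_ids = [f"C{i+1:02d}" for i in range(params.n_cases)]
    for cid in case_ids:
        ga = float(rng.uniform(23.0, 27.0))
        weight = float(np.clip(rng.normal(780 + (ga - 25.0) * 100.0, 90.0), 420, 1400))
        event_pma = float(np.clip(rng.normal(31.4, 1.4), 29.5, 33.5))
        event_dol = max(36.0, round((event_pma - ga) * 7.0, 1))
        infants[cid] = InfantInfo(
            infant_id=cid,
            group="case",
            gestational_age_weeks=round(ga, 1),
            birth_weight_g=round(weight),
            event_dol=event_dol,
        )
        n_samp = int(rng.choice([4, 4, 5, 6]))
        lookback = min(46.0, event_dol - 2.0)
        # spread draws so the near-event windows and the antecedent period are
        # both populated: two samples inside the 10 d window, two before it
        days_before = [
            float(rng.uniform(0.0, 2.0)),
            float(rng.uniform(2.0, 6.0)),
            float(rng.uniform(12.0, 22.0)),
            float(rng.uniform(lookback - 5.0, lookback)),
        ]
        days_before += [float(rng.uniform(6.0, lookback - 6.0)) for _ in range(n_samp - 4)]
        days_before = sorted(days_before, reverse=True)
        case_days[cid] = days_before
        for k, t in enumerate(days_before):
            dol = round(event_dol - t, 1)
            sid = f"{cid}.S{k+1}"
            samples[sid] = SampleInfo(
                sample_id=sid,
                infant_id=cid,
                day_of_life=dol,
                pma_weeks=round(infants[cid].gestational_age_weeks + dol / 7.0, 2),
                total_qc_reads=_draw_reads(rng, params.reads_median, params.reads_log_sigma),
            )

    # one to two controls per case: with 14 controls and 9 cases the first
    # five cases get two controls, the rest one
    matched = sorted(case_ids[i % params.n_cases] for i in range(params.n_controls))

    for j, case_of in enumerate(matched):
        kid = f"K{j+1:02d}"
        case = infants[case_of]
        ga = float(np.clip(case.gestational_age_weeks + rng.uniform(-2.0, 2.0), 22.5, 27.5))
        weight = float(np.clip(case.birth_weight_g + rng.uniform(-200.0, 200.0), 420, 1400))
        infants[kid] = InfantInfo(
            infant_id=kid,
            group="control",
            matched_case_id=case_of,
            gestational_age_weeks=round(ga, 1),
            birth_weight_g=round(weight),
        )
        n_samp = int(rng.choice([6, 7, 7, 8]))
        mirrored = case_days[case_of]
        lookback = min(46.0, case.event_dol - 2.0)
        days_before = [
            float(np.clip(t + rng.uniform(-2.0, 2.0), 0.0, lookback)) for t in mirrored[: n_samp]
        ]
        while len(days_before) < n_samp:
            days_before.append(float(rng.uniform(0.0, lookback)))
        days_before = sorted(days_before, reverse=True)
        for k, t in enumerate(days_before):
            dol = max(1.0, round(case.event_dol - t, 1))
            sid = f"{kid}.S{k+1}"
            samples[sid] = SampleInfo(
                sample_id=sid,
                infant_id=kid,
                day_of_life=dol,
                pma_weeks=round(ga + dol / 7.0, 2),
                total_qc_reads=_draw_reads(rng, params.reads_median, params.reads_log_sigma),
            )
    return CohortMetadata(infants=infants, samples=samples)


def _draw_reads(rng: np.random.Generator, median: float, sigma: float) -> int:
    return int(round(math.exp(rng.normal(math.log(median), sigma))))


def _draw_catalog(params: SyntheticParams, rng: np.random.Generator) -> ContigCatalog:
    contig_ids = [f"V{i:04d}" for i in range(params.n_contigs)]
    lengths = np.exp(rng.normal(math.log(1562.0), 0.775, size=params.n_contigs))
    lengths = np.maximum(800, np.round(lengths)).astype(int)
    fams = rng.choice(
        list(FAMILY_PROBS), size=params.n_contigs, p=np.array(list(FAMILY_PROBS.values()))
    )
    circular = rng.random(params.n_contigs) < 0.02
    table = pd.DataFrame(
        {"length_bp": lengths, "family": fams, "circular": circular},
        index=pd.Index(contig_ids, name="contig_id"),
    )
    return ContigCatalog(table)


def _random_genus_tree(genera: list[str], rng: np.random.Generator) -> PhyloTree:
    """Random bifurcating rooted tree by successive joins, exponential lengths."""
    nodes = [f"{g}:{rng.exponential(0.4) + 0.05:.4f}" for g in genera]
    while len(nodes) > 2:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        b = nodes.pop(j)
        a = nodes.pop(i)
        nodes.append(f"({a},{b}):{rng.exponential(0.4) + 0.05:.4f}")
    newick = f"({nodes[0]},{nodes[1]});" if len(nodes) == 2 else f"({nodes[0]});"
    return tree_from_newick(newick)


def generate_cohort(params: SyntheticParams = SyntheticParams()):
    """Generate the full cohort.

    Returns (metadata, viral CountTable, ContigCatalog, bacterial CountTable,
    PhyloTree, TruthLabels).  Identical params + seed give bit-identical
    outputs.
    """
    rng = np.random.default_rng(params.seed)
    meta = _draw_metadata(params, rng)
    catalog = _draw_catalog(params, rng)
    contig_ids = catalog.contig_ids
    n = params.n_contigs

    # planted contig sets (named even for null cohorts the labels stay empty)
    sig = contig_ids[: params.n_signature_contigs]
    early = contig_ids[params.n_signature_contigs : params.n_signature_contigs + params.n_early_contigs]
    late = contig_ids[
        params.n_signature_contigs
        + params.n_early_contigs : params.n_signature_contigs
        + params.n_early_contigs
        + params.n_control_late_contigs
    ]
    special = np.zeros(n, dtype=bool)
    sig_idx = np.arange(params.n_signature_contigs)
    early_idx = np.arange(len(sig), len(sig) + len(early))
    late_idx = np.arange(len(sig) + len(early), len(sig) + len(early) + len(late))
    special[sig_idx] = special[early_idx] = special[late_idx] = True

    event_of: dict[str, float] = {}
    for inf in meta.infants.values():
        event_of[inf.infant_id] = (
            inf.event_dol if inf.group == "case" else meta.infants[inf.matched_case_id].event_dol
        )

    # per-infant base weights: heavy-tailed individuality for ordinary contigs,
    # moderate fixed-scale weights for planted contigs (so presence is programmable)
    base_weights: dict[str, np.ndarray] = {}
    # control-late contigs are active in a random subset of control infants:
    # each contig keeps a strong late-vs-early occurrence contrast while the
    # *set* shared between any two control infants stays small, so between-
    # control dissimilarity stays flat over the windows
    late_active: dict[str, np.ndarray] = {}
    for iid, inf in meta.infants.items():
        u = rng.gamma(shape=params.community_concentration, scale=1.0, size=n)
        u[rng.random(n) >= params.repertoire_fraction] = 0.0  # outside this infant's repertoire
        # zero the sub-detection tail at a fixed absolute cut (several times the
        # RPK noise floor): which contigs an infant carries is then a stable
        # property of the infant, not of its total community mass
        u[u < 0.005] = 0.0
        u[special] = rng.gamma(shape=2.0, scale=0.05, size=int(special.sum()))
        base_weights[iid] = u
        if inf.group == "control":
            late_active[iid] = rng.random(len(late_idx)) < 0.6

    occ = params.presence_occupancy
    stay = params.temporal_persistence
    turn_on = min(1.0, occ * (1.0 - stay) / max(1e-9, 1.0 - occ))

    viral_cols: dict[str, np.ndarray] = {}
    sample_order = sorted(meta.samples.values(), key=lambda s: (s.infant_id, s.day_of_life))
    current_infant = None
    mask = None
    for s in sample_order:
        inf = meta.infants[s.infant_id]
        u = base_weights[s.infant_id].copy()
        if s.infant_id != current_infant:
            current_infant = s.infant_id
            mask = rng.random(n) < occ
        else:
            flip = rng.random(n)
            mask = np.where(mask, flip < stay, flip < turn_on)

        t_before = event_of[s.infant_id] - s.day_of_life
        w = params.signature_window_days
        present = mask.copy()

        if params.planted:
            # signature contigs: baseline occurrence everywhere; ramped
            # occurrence + abundance lift inside the case window
            p_sig = np.full(len(sig_idx), params.baseline_occurrence)
            if inf.group == "case" and 0.0 <= t_before < w:
                ramp = 1.0 - t_before / w
                p_sig += params.signature_prevalence_lift * ramp
                u[sig_idx] *= params.signature_abundance_lift
            present[sig_idx] = rng.random(len(sig_idx)) < p_sig

            # early contigs: common before the window in cases, decaying toward it
            if inf.group == "case":
                p_early = 0.5 if t_before >= w else 0.05 + 0.45 * (t_before / w)
            else:
                p_early = params.baseline_occurrence
            present[early_idx] = rng.random(len(early_idx)) < p_early

            # control-late contigs: ramp with absolute age, in the active
            # subset of each control infant only
            if inf.group == "control":
                ramp_late = 0.05 + 0.55 / (1.0 + math.exp(-(s.day_of_life - 32.0) / 7.0))
                p_late = np.where(late_active[s.infant_id], ramp_late, params.baseline_occurrence)
            else:
                p_late = np.full(len(late_idx), params.baseline_occurrence)
            present[late_idx] = rng.random(len(late_idx)) < p_late
        else:
            present[special] = rng.random(int(special.sum())) < params.baseline_occurrence

        weights = u * present
        if weights.sum() == 0:
            weights[0] = 1.0
        viral_cols[s.sample_id] = rng.multinomial(s.total_qc_reads, weights / weights.sum())

    viral = CountTable(
        pd.DataFrame(viral_cols, index=pd.Index(contig_ids, name="contig_id"), dtype=np.int64)
    )

    # ---------------- bacterial side ----------------
    genera = GENUS_NAMES[: params.n_genera] + [
        f"Genus{k:02d}" for k in range(max(0, params.n_genera - len(GENUS_NAMES)))
    ]
    tree = _random_genus_tree(genera, rng)

    base_case_profile = rng.dirichlet(np.full(params.n_genera, 2.0))
    couplings: list[tuple[str, str, int]] = []
    if params.planted:
        coupled_genera = genera[: params.n_couplings]
        signs = [1, 1, 1, -1] * (params.n_couplings // 4 + 1)
        couplings = [
            (sig[k], coupled_genera[k], signs[k]) for k in range(params.n_couplings)
        ]

    # pre-compute each coupled contig's log viral signal per sample (for coupling)
    totals = viral.data.sum(axis=0)
    signal: dict[str, pd.Series] = {}
    for contig, _, _ in couplings:
        v = np.log1p(1e6 * viral.data.loc[contig] / totals)
        sd = v.std()
        signal[contig] = (v - v.mean()) / (sd if sd > 0 else 1.0)

    # case infants share a profile (low dispersion); controls are individual —
    # unless the cohort is null, in which case the two groups are exchangeable
    bac_profiles: dict[str, np.ndarray] = {}
    for iid, inf in meta.infants.items():
        if params.planted and inf.group == "case":
            bac_profiles[iid] = rng.dirichlet(base_case_profile * 500.0 + 1e-3)
        else:
            bac_profiles[iid] = rng.dirichlet(np.full(params.n_genera, 0.6))

    genus_index = {g: i for i, g in enumerate(genera)}
    bac_cols: dict[str, np.ndarray] = {}
    for s in sample_order:
        inf = meta.infants[s.infant_id]
        w = bac_profiles[s.infant_id].copy()
        if inf.group == "case":
            for contig, genus, sign in couplings:
                w[genus_index[genus]] *= math.exp(
                    sign * params.coupling_strength * float(signal[contig][s.sample_id])
                )
        reads = _draw_reads(rng, params.bacterial_reads_median, 0.4)
        bac_cols[s.sample_id] = rng.multinomial(reads, w / w.sum())

    bacteria = CountTable(
        pd.DataFrame(bac_cols, index=pd.Index(genera, name="genus"), dtype=np.int64)
    )

    truth = (
        TruthLabels(
            signature_contigs=list(sig),
            early_contigs=list(early),
            control_late_contigs=list(late),
            couplings=couplings,
        )
        if params.planted
        else TruthLabels()
    )
    return meta, viral, catalog, bacteria, tree, truth


# ---------------------------------------------------------------------------
# family profile
# ---------------------------------------------------------------------------


def family_profile(catalog: ContigCatalog, abundance: AbundanceTable) -> pd.DataFrame:
    """Per-sample virus family relative abundances (rows sum to 1).

    'unclassified' is a first-class reported category.  Samples with all-zero
    abundance have no defined composition and raise.
    """
    fams = catalog.families().reindex(abundance.feature_ids)
    totals = abundance.data.sum(axis=0)
    zero = totals.index[totals == 0].tolist()
    if zero:
        raise ValueError(f"undefined family shares for all-zero sample(s): {zero[:5]}")
    grouped = abundance.data.groupby(fams).sum()
    shares = (grouped / totals).T
    shares.index.name = "sample_id"
    return shares
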