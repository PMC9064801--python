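"""End-to-end orchestration: simulate/load → normalize → diversity →
convergence → discriminant screen → trajectories → bacterial side →
interactions, with a hash manifest for reproducibility checks.

Every stage output is a plain TSV consumable without the package; the
manifest records, per stage, the parameters and the SHA-256 of each output
with floats normalized to 10 significant digits, so identical config + seed
implies identical manifest hashes.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import bacterial_unifrac, cohort_stats, diversity_metrics, event_anchor
from .core_model import (
    CohortMetadata,
    read_catalog,
    read_count_table,
    read_metadata,
    read_tree,
    write_catalog,
    write_count_table,
    write_metadata,
    write_tree,
)
from .discriminant_lefse import LefseConfig, control_side_screen, features_to_frame, lefse_screen
from .event_anchor import WindowSpec
from .interactions import associate, correlation_table, results_to_frame
from .normalization import NormalizationConfig, presence_matrix, richness_and_shannon, rpk_normalize
from .synthetic_cohort import SyntheticParams, family_profile, generate_cohort
from .trajectory import block_series, slopes, slopes_to_frame

logger = logging.getLogger("viroconverge")

__all__ = ["PipelineConfig", "ConfigError", "run_all", "load_config"]


class ConfigError(ValueError):
    pass


@dataclass
class PipelineConfig:
    outdir: str = "viroconverge_out"
    seed: int = 0
    # exactly one of the two input modes
    simulate: dict | None = None
    inputs: dict | None = None  # metadata, viral_counts, catalog, bacterial_counts, tree
    normalization: NormalizationConfig = field(default_factory=NormalizationConfig)
    window: WindowSpec = field(default_factory=WindowSpec)
    lefse: LefseConfig = field(default_factory=LefseConfig)
    pairing_tolerance_days: float = 3.5
    rarefaction_depth: int = 2500
    #: mixed-model association stage is quadratic in features; cap the contig
    #: side at the strongest discriminant hits
    max_association_contigs: int = 20

    def __post_init__(self) -> None:
        if (self.simulate is None) == (self.inputs is None):
            raise ConfigError("config must set exactly one of 'simulate' or 'inputs'")


def load_config(path: str) -> PipelineConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    kwargs = dict(raw)
    if "normalization" in kwargs:
        kwargs["normalization"] = NormalizationConfig(**kwargs["normalization"])
    if "window" in kwargs:
        kwargs["window"] = WindowSpec(**kwargs["window"])
    if "lefse" in kwargs:
        kwargs["lefse"] = LefseConfig(**kwargs["lefse"])
    try:
        return PipelineConfig(**kwargs)
    except TypeError as exc:
        raise ConfigError(str(exc)) from exc


def _hash_tsv(path: Path) -> str:
    """SHA-256 of a TSV with numeric cells normalized to 10 significant digits."""
    h = hashlib.sha256()
    for line in path.read_text().splitlines():
        fields = []
        for cell in line.split("\t"):
            try:
                fields.append(format(float(cell), ".10g"))
            except ValueError:
                fields.append(cell)
        h.update(("\t".join(fields) + "\n").encode())
    return h.hexdigest()


def _window_frame(series: event_anchor.WindowSeries) -> pd.DataFrame:
    rows = []
    for w in series.windows:
        row = {
            "window": w.label,
            "start": w.start,
            "stop": w.stop,
            "n_case_pairs": len(w.case_values),
            "n_control_pairs": len(w.control_values),
            "insufficient": w.insufficient,
        }
        if w.test is not None:
            row.update(
                case_median=w.test.extra["case_median"],
                control_median=w.test.extra["control_median"],
                p=w.test.p_value,
            )
        else:
            row.update(case_median=np.nan, control_median=np.nan, p=np.nan)
        rows.append(row)
    return pd.DataFrame(rows)


def run_all(config: PipelineConfig) -> dict:
    """Run the whole pipeline; returns the manifest dict (also written to disk)."""
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"stages": [], "seed": config.seed}
    t_all = time.time()

    def record(stage: str, params: dict, outputs: list[Path]) -> None:
        manifest["stages"].append(
            {
                "stage": stage,
                "params": params,
                "outputs": {p.name: _hash_tsv(p) for p in outputs},
                "seconds": round(time.time() - t_stage, 3),
            }
        )
        logger.info("stage %s done (%d output(s))", stage, len(outputs))

    # ---- stage 1: inputs -------------------------------------------------
    t_stage = time.time()
    if config.simulate is not None:
        params = SyntheticParams(**{**config.simulate, "seed": config.seed})
        meta, viral, catalog, bacteria, tree, truth = generate_cohort(params)
        write_metadata(meta, str(out / "metadata.tsv"))
        write_count_table(viral, str(out / "viral_counts.tsv"))
        write_catalog(catalog, str(out / "catalog.tsv"))
        write_count_table(bacteria, str(out / "bacterial_counts.tsv"))
        write_tree(tree, str(out / "genus_tree.nwk"))
        truth.to_frame().to_csv(out / "truth.tsv", sep="\t", index=False)
        record(
            "simulate",
            asdict(params),
            [out / f for f in ("metadata.tsv", "viral_counts.tsv", "catalog.tsv", "bacterial_counts.tsv", "truth.tsv")],
        )
    else:
        paths = config.inputs
        meta = read_metadata(paths["metadata"])
        catalog = read_catalog(paths["catalog"])
        viral = read_count_table(paths["viral_counts"], catalog)
        bacteria = read_count_table(paths["bacterial_counts"])
        tree = read_tree(paths["tree"])
        record("load", dict(paths), [])

    # ---- stage 2: normalization -----------------------------------------
    t_stage = time.time()
    abundance = rpk_normalize(viral, catalog, meta.samples, config.normalization)
    abundance.data.to_csv(out / "abundance_rpk.tsv", sep="\t", float_format="%.10g")
    alpha = richness_and_shannon(abundance)
    alpha.to_csv(out / "alpha_diversity.tsv", sep="\t", float_format="%.10g")
    fam = family_profile(catalog, abundance)
    fam.to_csv(out / "family_profile.tsv", sep="\t", float_format="%.10g")
    record("normalize", asdict(config.normalization), [out / "abundance_rpk.tsv", out / "alpha_diversity.tsv"])

    # ---- stage 3: diversity ----------------------------------------------
    t_stage = time.time()
    bc = diversity_metrics.bray_curtis(abundance)
    soer = diversity_metrics.sorensen(presence_matrix(abundance))
    bc.to_tsv(str(out / "dist_bray_curtis.tsv"))
    soer.to_tsv(str(out / "dist_sorensen.tsv"))
    record("diversity", {}, [out / "dist_bray_curtis.tsv", out / "dist_sorensen.tsv"])

    # ---- stage 4: cohort structure ---------------------------------------
    t_stage = time.time()
    med_w, med_b, wb_test = cohort_stats.within_between(bc, meta.samples)
    ord_res = cohort_stats.pcoa(bc, k=2)
    ord_res.coordinates.to_csv(out / "pcoa_coordinates.tsv", sep="\t", float_format="%.10g")
    pma = pd.Series({s.sample_id: s.pma_weeks for s in meta.samples.values()})[bc.sample_ids]
    perma = cohort_stats.permanova(bc, pma, permutations=999, seed=config.seed)
    pd.DataFrame(
        [
            {"quantity": "median_within", "value": med_w},
            {"quantity": "median_between", "value": med_b},
            {"quantity": "within_between_p", "value": wb_test.p_value},
            {"quantity": "permanova_pma_F", "value": perma.statistic},
            {"quantity": "permanova_pma_p", "value": perma.p_value},
        ]
    ).to_csv(out / "cohort_structure.tsv", sep="\t", index=False, float_format="%.10g")
    record("structure", {"permutations": 999}, [out / "cohort_structure.tsv", out / "pcoa_coordinates.tsv"])

    # ---- stage 5: convergence windows ------------------------------------
    t_stage = time.time()
    anchored = event_anchor.anchor(meta)
    pairs = event_anchor.pair_samples(anchored, meta, tolerance=config.pairing_tolerance_days)
    windows = event_anchor.build_windows(config.window, anchored)
    series = event_anchor.convergence_series(soer, windows, pairs)
    _window_frame(series).to_csv(out / "convergence_sorensen.tsv", sep="\t", index=False, float_format="%.10g")
    record("convergence", asdict(config.window), [out / "convergence_sorensen.tsv"])

    # ---- stage 6: discriminant screen ------------------------------------
    t_stage = time.time()
    lefse_cfg = LefseConfig(**{**asdict(config.lefse), "seed": config.seed})
    case_features = lefse_screen(abundance, anchored, lefse_cfg)
    ctrl_features = control_side_screen(abundance, anchored, lefse_cfg)
    features_to_frame(case_features).to_csv(out / "lefse_case.tsv", sep="\t", index=False, float_format="%.10g")
    features_to_frame(ctrl_features).to_csv(out / "lefse_control.tsv", sep="\t", index=False, float_format="%.10g")
    record("lefse", asdict(lefse_cfg), [out / "lefse_case.tsv", out / "lefse_control.tsv"])

    # ---- stage 7: trajectories -------------------------------------------
    t_stage = time.time()
    late_ids = [f.contig_id for f in case_features if f.assigned_class == "late"]
    if late_ids:
        blocks = block_series(abundance, anchored, late_ids)
        blocks.prevalence.to_csv(out / "block_prevalence.tsv", sep="\t", float_format="%.10g")
        blocks.abundance.to_csv(out / "block_abundance.tsv", sep="\t", float_format="%.10g")
        slopes_to_frame(slopes(blocks)).to_csv(out / "slopes.tsv", sep="\t", index=False, float_format="%.10g")
        outs = [out / "block_prevalence.tsv", out / "block_abundance.tsv", out / "slopes.tsv"]
    else:
        outs = []
    record("trajectory", {"n_late_contigs": len(late_ids)}, outs)

    # ---- stage 8: bacterial UniFrac + interactions ------------------------
    t_stage = time.time()
    rarefied = bacterial_unifrac.rarefy(bacteria, depth=config.rarefaction_depth, seed=config.seed)
    wuf = bacterial_unifrac.weighted_unifrac(rarefied, tree, normalized=True)
    wuf.to_tsv(str(out / "dist_weighted_unifrac.tsv"))
    bac_windows = event_anchor.build_windows(config.window, anchored)
    bac_series = bacterial_unifrac.bacterial_convergence(wuf, bac_windows, pairs)
    _window_frame(bac_series).to_csv(out / "convergence_unifrac.tsv", sep="\t", index=False, float_format="%.10g")

    if late_ids:
        by_effect = sorted(
            (f for f in case_features if f.assigned_class == "late"),
            key=lambda f: -f.effect_size,
        )
        assoc_ids = [f.contig_id for f in by_effect[: config.max_association_contigs]]
        results = []
        for grp in ("case", "control"):
            sub_ab = type(abundance)(abundance.data.loc[assoc_ids], abundance.config)
            results += associate(sub_ab, bacteria, meta, group=grp)
        results_to_frame(results).to_csv(out / "associations.tsv", sep="\t", index=False, float_format="%.10g")
        correlation_table([r for r in results if r.group == "case"]).to_csv(
            out / "correlation_matrix_case.tsv", sep="\t", float_format="%.10g"
        )
        outs = [out / "convergence_unifrac.tsv", out / "associations.tsv", out / "correlation_matrix_case.tsv"]
    else:
        outs = [out / "convergence_unifrac.tsv"]
    record("bacterial_interactions", {"depth": config.rarefaction_depth}, outs)

    manifest["total_seconds"] = round(time.time() - t_all, 3)
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    return manifest
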