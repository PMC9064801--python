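"""RPK normalization with a noise floor, and per-sample alpha diversity.

Mapped-read counts are scaled to a fixed sequencing depth (default 79,000
reads), divided by contig length in kilobases (RPK) and then noise-floored:
any cell whose normalized value falls below 0.5 RPK is set to zero.  The
floored table is the basis of every downstream virome analysis, including
the presence/absence matrix used by Sorensen dissimilarity.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core_model import ContigCatalog, CountTable, SampleInfo, SchemaError

__all__ = [
    "NormalizationConfig",
    "AbundanceTable",
    "rpk_normalize",
    "presence_matrix",
    "richness_and_shannon",
]


@dataclass(frozen=True)
class NormalizationConfig:
    """Depth scaling constant and RPK noise floor.

    ``scale_reads`` is the study's fixed reference depth; it cancels out of
    all compositional analyses but keeps RPK values on an interpretable scale.
    """

    scale_reads: float = 79_000.0
    noise_floor: float = 0.5

    def __post_init__(self) -> None:
        if not self.scale_reads > 0:
            raise ValueError("scale_reads must be > 0")
        if self.noise_floor < 0:
            raise ValueError("noise_floor must be >= 0")


@dataclass
class AbundanceTable:
    """Contig × sample RPK matrix after noise-floor filtering.

    Every entry is either 0 or >= the floor used to build it; the source
    configuration travels with the table.
    """

    data: pd.DataFrame
    config: NormalizationConfig = field(default_factory=NormalizationConfig)

    def __post_init__(self) -> None:
        arr = self.data.to_numpy()
        nonzero = arr[arr != 0]
        if nonzero.size and (nonzero < self.config.noise_floor).any():
            raise ValueError("abundance table contains nonzero entries below the noise floor")

    @property
    def feature_ids(self) -> list[str]:
        return self.data.index.tolist()

    @property
    def sample_ids(self) -> list[str]:
        return self.data.columns.tolist()


def rpk_normalize(
    counts: CountTable,
    catalog: ContigCatalog,
    samples: dict[str, SampleInfo] | list[SampleInfo],
    config: NormalizationConfig = NormalizationConfig(),
) -> AbundanceTable:
    """Depth-scale, length-normalize and noise-floor a viral count table.

    entry = (scale_reads / total_qc_reads) * reads / (length_bp / 1000),
    then set to 0 where the result is below ``config.noise_floor``.
    """
    if isinstance(samples, list):
        samples = {s.sample_id: s for s in samples}
    missing = set(counts.sample_ids) - set(samples)
    if missing:
        raise SchemaError(f"samples without metadata: {sorted(missing)[:5]}")
    missing_contigs = set(counts.feature_ids) - set(catalog.contig_ids)
    if missing_contigs:
        raise SchemaError(f"contigs without catalog entry: {sorted(missing_contigs)[:5]}")

    totals = np.array([samples[s].total_qc_reads for s in counts.sample_ids], dtype=float)
    zero = [s for s, t in zip(counts.sample_ids, totals) if t == 0]
    if zero:
        raise ZeroDivisionError(f"total_qc_reads is 0 for sample(s) {zero[:5]}")

    lengths_kb = catalog.lengths_kb().reindex(counts.feature_ids).to_numpy()
    rpk = counts.data.to_numpy(dtype=float) * (config.scale_reads / totals)[None, :]
    rpk /= lengths_kb[:, None]
    rpk[rpk < config.noise_floor] = 0.0
    return AbundanceTable(
        pd.DataFrame(rpk, index=counts.data.index, columns=counts.data.columns),
        config=config,
    )


def presence_matrix(abundance: AbundanceTable) -> pd.DataFrame:
    """Boolean contig × sample matrix: present iff the RPK survived the floor."""
    return abundance.data > 0


def richness_and_shannon(abundance: AbundanceTable, base: float = math.e) -> pd.DataFrame:
    """Per-sample richness and Shannon diversity (natural log by default).

    Samples with no surviving contig cannot carry a diversity value; they are
    excluded from the result (callers can diff against ``sample_ids``).
    """
    out = {}
    for sid in abundance.sample_ids:
        col = abundance.data[sid].to_numpy()
        nz = col[col > 0]
        if nz.size == 0:
            continue
        p = nz / nz.sum()
        h = float(-(p * np.log(p)).sum() / math.log(base))
        out[sid] = {"richness": int(nz.size), "shannon": h}
    return pd.DataFrame.from_dict(out, orient="index").rename_axis("sample_id")
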