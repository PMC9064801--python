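"""Domain types, validation and TSV/newick I/O for the cohort pipeline.

The pipeline operates on four kinds of inputs: a cohort metadata table
(infants and stool samples), feature-by-sample count tables (viral contigs
or bacterial genera), a contig catalog (lengths, family labels, circularity)
and a rooted genus tree.  Everything is plain TSV (UTF-8, '.' decimal,
literal ``NA`` for missing optional values) or newick, so intermediate
results stay human-diffable.

Readers validate and reject; they never silently coerce.
"""

from __future__ import annotations

import io
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from skbio import TreeNode

__all__ = [
    "SchemaError",
    "ReferentialError",
    "FormatError",
    "InfantInfo",
    "SampleInfo",
    "CohortMetadata",
    "ContigCatalog",
    "CountTable",
    "PhyloTree",
    "read_metadata",
    "write_metadata",
    "read_catalog",
    "write_catalog",
    "read_count_table",
    "write_count_table",
    "read_tree",
    "write_tree",
]

MIN_CONTIG_LENGTH_BP = 800
#: tolerance (weeks) for the PMA = GA + DOL/7 consistency check
PMA_TOLERANCE_WEEKS = 0.2

NA = "NA"


class SchemaError(ValueError):
    """A required column is missing or a cell cannot be parsed."""


class ReferentialError(ValueError):
    """A cross-reference (matched case, infant id, feature id) does not resolve."""


class FormatError(ValueError):
    """A file is structurally malformed (e.g. newick without branch lengths)."""


# ---------------------------------------------------------------------------
# infants and samples
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class InfantInfo:
    """One enrolled infant.

    ``event_dol`` is the day of life of necrotizing-enterocolitis onset and is
    present for cases only.  Controls carry the id of the case infant they were
    matched to (by gestational age and birth weight).
    """

    infant_id: str
    group: str  # "case" | "control"
    matched_case_id: str | None = None
    gestational_age_weeks: float = math.nan
    birth_weight_g: float = math.nan
    event_dol: float | None = None

    def __post_init__(self) -> None:
        if self.group not in ("case", "control"):
            raise SchemaError(f"infant {self.infant_id}: group must be 'case' or 'control', got {self.group!r}")
        if self.group == "case":
            if self.event_dol is None or not self.event_dol > 0:
                raise ReferentialError(f"case infant {self.infant_id} must have event_dol > 0")
        if not math.isnan(self.gestational_age_weeks) and not self.gestational_age_weeks > 0:
            raise SchemaError(f"infant {self.infant_id}: gestational_age_weeks must be > 0")


@dataclass(frozen=True)
class SampleInfo:
    """One stool sample: collection day of life, PMA and sequencing depth."""

    sample_id: str
    infant_id: str
    day_of_life: float
    pma_weeks: float = math.nan
    total_qc_reads: int = 0

    def __post_init__(self) -> None:
        if not self.day_of_life > 0:
            raise SchemaError(f"sample {self.sample_id}: day_of_life must be > 0")
        if self.total_qc_reads < 0:
            raise SchemaError(f"sample {self.sample_id}: total_qc_reads must be >= 0")


@dataclass
class CohortMetadata:
    """Validated infant + sample tables with resolvable cross-references."""

    infants: dict[str, InfantInfo]
    samples: dict[str, SampleInfo]

    def __post_init__(self) -> None:
        self.validate()

    # -- accessors ----------------------------------------------------------

    @property
    def cases(self) -> list[InfantInfo]:
        return [i for i in self.infants.values() if i.group == "case"]

    @property
    def controls(self) -> list[InfantInfo]:
        return [i for i in self.infants.values() if i.group == "control"]

    def samples_of(self, infant_id: str) -> list[SampleInfo]:
        return [s for s in self.samples.values() if s.infant_id == infant_id]

    def sample_ids(self) -> list[str]:
        return list(self.samples)

    # -- validation ---------------------------------------------------------

    def validate(self) -> None:
        for inf in self.infants.values():
            if inf.group == "control":
                mc = inf.matched_case_id
                if mc is None or mc not in self.infants:
                    raise ReferentialError(
                        f"control {inf.infant_id}: matched_case_id {mc!r} does not resolve"
                    )
                if self.infants[mc].group != "case":
                    raise ReferentialError(
                        f"control {inf.infant_id}: matched_case_id {mc!r} is not a case"
                    )
        for s in self.samples.values():
            if s.infant_id not in self.infants:
                raise ReferentialError(f"sample {s.sample_id}: unknown infant {s.infant_id!r}")
            inf = self.infants[s.infant_id]
            if not math.isnan(s.pma_weeks) and not math.isnan(inf.gestational_age_weeks):
                expected = inf.gestational_age_weeks + s.day_of_life / 7.0
                if abs(expected - s.pma_weeks) > PMA_TOLERANCE_WEEKS:
                    raise SchemaError(
                        f"sample {s.sample_id}: pma_weeks {s.pma_weeks:.2f} inconsistent with "
                        f"GA + DOL/7 = {expected:.2f} (tolerance {PMA_TOLERANCE_WEEKS})"
                    )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, CohortMetadata):
            return NotImplemented
        return self.infants == other.infants and self.samples == other.samples


# ---------------------------------------------------------------------------
# contig catalog
# ---------------------------------------------------------------------------


@dataclass
class ContigCatalog:
    """Per-contig attributes: assembled length, family label, circularity.

    Contigs shorter than the 800 bp admission floor are rejected at
    construction: the analysis tables never see them.
    """

    table: pd.DataFrame  # index contig_id; columns length_bp, family, circular

    def __post_init__(self) -> None:
        required = {"length_bp", "family", "circular"}
        missing = required - set(self.table.columns)
        if missing:
            raise SchemaError(f"catalog missing columns: {sorted(missing)}")
        if self.table.index.has_duplicates:
            dups = self.table.index[self.table.index.duplicated()].tolist()
            raise SchemaError(f"duplicate contig ids: {dups[:5]}")
        bad = self.table.index[self.table["length_bp"] < MIN_CONTIG_LENGTH_BP].tolist()
        if bad:
            raise SchemaError(
                f"{len(bad)} contig(s) below the {MIN_CONTIG_LENGTH_BP} bp minimum, e.g. {bad[:5]}"
            )

    @property
    def contig_ids(self) -> list[str]:
        return self.table.index.tolist()

    def lengths_kb(self) -> pd.Series:
        return self.table["length_bp"].astype(float) / 1000.0

    def families(self) -> pd.Series:
        return self.table["family"]


# ---------------------------------------------------------------------------
# count table
# ---------------------------------------------------------------------------


@dataclass
class CountTable:
    """Feature (contig or genus) × sample matrix of mapped-read counts."""

    data: pd.DataFrame  # rows features, columns samples, integer >= 0

    def __post_init__(self) -> None:
        df = self.data
        if df.index.has_duplicates:
            raise SchemaError("duplicate feature ids in count table")
        if df.columns.has_duplicates:
            raise SchemaError("duplicate sample ids in count table")
        arr = df.to_numpy()
        if not np.issubdtype(arr.dtype, np.integer):
            raise SchemaError("count table cells must be integers")
        if (arr < 0).any():
            r, c = np.argwhere(arr < 0)[0]
            raise SchemaError(
                f"negative count at feature {df.index[r]!r}, sample {df.columns[c]!r}"
            )

    @property
    def feature_ids(self) -> list[str]:
        return self.data.index.tolist()

    @property
    def sample_ids(self) -> list[str]:
        return self.data.columns.tolist()

    def column_sums(self) -> pd.Series:
        return self.data.sum(axis=0)


# ---------------------------------------------------------------------------
# phylogenetic tree
# ---------------------------------------------------------------------------


@dataclass
class PhyloTree:
    """Rooted tree with genus-labelled leaves and nonnegative branch lengths."""

    tree: TreeNode

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for node in self.tree.postorder(include_self=True):
            if node.is_tip():
                if node.name is None:
                    raise FormatError("tree has an unlabelled leaf")
                if node.name in seen:
                    raise FormatError(f"duplicate leaf label {node.name!r}")
                seen.add(node.name)
            if node is not self.tree.root():
                if node.length is None:
                    raise FormatError(f"branch above {node.name or 'internal node'} has no length")
                if node.length < 0:
                    raise FormatError(f"negative branch length above {node.name!r}")

    @property
    def leaf_names(self) -> list[str]:
        return [t.name for t in self.tree.tips()]

    def total_branch_length(self) -> float:
        return sum(n.length or 0.0 for n in self.tree.postorder(include_self=False))

    def require_leaves(self, names: Iterable[str]) -> None:
        missing = set(names) - set(self.leaf_names)
        if missing:
            raise ReferentialError(f"genera absent from tree: {sorted(missing)[:5]}")


# ---------------------------------------------------------------------------
# metadata I/O
# ---------------------------------------------------------------------------

_INFANT_COLS = [
    "infant_id",
    "group",
    "matched_case_id",
    "gestational_age_weeks",
    "birth_weight_g",
    "event_dol",
]
_SAMPLE_COLS = ["sample_id", "infant_id", "day_of_life", "pma_weeks", "total_qc_reads"]


def _fmt(x: object) -> str:
    if x is None:
        return NA
    if isinstance(x, float):
        if math.isnan(x):
            return NA
        return format(x, ".10g")
    return str(x)


def _parse_float(cell: str, where: str) -> float:
    if cell == NA:
        return math.nan
    try:
        return float(cell)
    except ValueError:
        raise SchemaError(f"cannot parse {cell!r} as a number at {where}") from None


def write_metadata(meta: CohortMetadata, path: str) -> None:
    """Single TSV with embedded infant columns: one row per sample."""
    rows = []
    for s in meta.samples.values():
        inf = meta.infants[s.infant_id]
        rows.append(
            {
                "sample_id": s.sample_id,
                "infant_id": s.infant_id,
                "day_of_life": _fmt(s.day_of_life),
                "pma_weeks": _fmt(s.pma_weeks),
                "total_qc_reads": s.total_qc_reads,
                "group": inf.group,
                "matched_case_id": _fmt(inf.matched_case_id),
                "gestational_age_weeks": _fmt(inf.gestational_age_weeks),
                "birth_weight_g": _fmt(inf.birth_weight_g),
                "event_dol": _fmt(inf.event_dol),
            }
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_metadata(path: str) -> CohortMetadata:
    """Read the per-sample TSV with embedded infant columns."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    required = set(_SAMPLE_COLS) | {"group", "matched_case_id", "gestational_age_weeks", "birth_weight_g", "event_dol"}
    missing = required - set(df.columns)
    if missing:
        raise SchemaError(f"metadata missing required column(s): {sorted(missing)}")

    infants: dict[str, InfantInfo] = {}
    samples: dict[str, SampleInfo] = {}
    for _, row in df.iterrows():
        iid = row["infant_id"]
        if iid not in infants:
            event = row["event_dol"]
            matched = row["matched_case_id"]
            infants[iid] = InfantInfo(
                infant_id=iid,
                group=row["group"],
                matched_case_id=None if matched == NA else matched,
                gestational_age_weeks=_parse_float(row["gestational_age_weeks"], f"infant {iid}"),
                birth_weight_g=_parse_float(row["birth_weight_g"], f"infant {iid}"),
                event_dol=None if event == NA else _parse_float(event, f"infant {iid}"),
            )
        sid = row["sample_id"]
        if sid in samples:
            raise SchemaError(f"duplicate sample_id {sid!r}")
        reads_cell = row["total_qc_reads"]
        try:
            reads = int(reads_cell)
        except ValueError:
            raise SchemaError(f"total_qc_reads {reads_cell!r} is not an integer (sample {sid})") from None
        samples[sid] = SampleInfo(
            sample_id=sid,
            infant_id=iid,
            day_of_life=_parse_float(row["day_of_life"], f"sample {sid}"),
            pma_weeks=_parse_float(row["pma_weeks"], f"sample {sid}"),
            total_qc_reads=reads,
        )
    return CohortMetadata(infants=infants, samples=samples)


# ---------------------------------------------------------------------------
# catalog I/O
# ---------------------------------------------------------------------------


def write_catalog(catalog: ContigCatalog, path: str) -> None:
    out = catalog.table.copy()
    out["circular"] = out["circular"].map(lambda b: "true" if b else "false")
    out.to_csv(path, sep="\t", index_label="contig_id")


def read_catalog(path: str) -> ContigCatalog:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    for col in ("contig_id", "length_bp", "family", "circular"):
        if col not in df.columns:
            raise SchemaError(f"catalog missing required column {col!r}")
    table = pd.DataFrame(
        {
            "length_bp": df["length_bp"].astype(int).to_numpy(),
            "family": df["family"].to_numpy(),
            "circular": df["circular"].map({"true": True, "false": False}).to_numpy(),
        },
        index=pd.Index(df["contig_id"], name="contig_id"),
    )
    if table["circular"].isna().any():
        raise SchemaError("circular column must be 'true' or 'false'")
    return ContigCatalog(table)


# ---------------------------------------------------------------------------
# count table I/O
# ---------------------------------------------------------------------------


def write_count_table(counts: CountTable, path: str) -> None:
    counts.data.to_csv(path, sep="\t", index_label=counts.data.index.name or "feature_id")


def read_count_table(path: str, feature_ids: Sequence[str] | ContigCatalog | None = None) -> CountTable:
    """Read a feature × sample TSV of integer counts.

    When ``feature_ids`` (or a catalog) is given, rows whose id is not in it
    are rejected, so count tables stay keyed to their catalog.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    if df.columns[0] not in ("feature_id", "contig_id", "genus"):
        raise SchemaError(
            f"first column of a count table must be the feature key, got {df.columns[0]!r}"
        )
    df = df.set_index(df.columns[0])
    values = np.empty(df.shape, dtype=np.int64)
    for j, col in enumerate(df.columns):
        for i, cell in enumerate(df[col]):
            try:
                v = int(cell)
            except ValueError:
                raise SchemaError(
                    f"non-integer count {cell!r} at row {df.index[i]!r}, column {col!r}"
                ) from None
            if v < 0:
                raise SchemaError(f"negative count {v} at row {df.index[i]!r}, column {col!r}")
            values[i, j] = v
    table = CountTable(pd.DataFrame(values, index=df.index, columns=df.columns))
    if feature_ids is not None:
        known = set(feature_ids.contig_ids if isinstance(feature_ids, ContigCatalog) else feature_ids)
        unknown = set(table.feature_ids) - known
        if unknown:
            raise ReferentialError(f"unknown feature id(s) in count table: {sorted(unknown)[:5]}")
    return table


# ---------------------------------------------------------------------------
# tree I/O
# ---------------------------------------------------------------------------


def read_tree(path: str) -> PhyloTree:
    try:
        tree = TreeNode.read(path, format="newick")
    except Exception as exc:  # skbio raises several parser error types
        raise FormatError(f"cannot parse newick file {path}: {exc}") from exc
    return PhyloTree(tree)


def write_tree(ptree: PhyloTree, path: str) -> None:
    ptree.tree.write(path, format="newick")


def tree_from_newick(newick: str) -> PhyloTree:
    return PhyloTree(TreeNode.read(io.StringIO(newick)))
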