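"""Parsing and record-level filtering of protein-group quantitation tables.

The input dialect is the tab-delimited ``proteinGroups.txt`` table produced by
common MS identification/quantitation software: one row per protein group,
``+``/empty flag columns for decoy ("Reverse") and contaminant hits,
semicolon-separated multi-value cells, and per-experiment ``LFQ intensity <id>``
and ``iBAQ <id>`` columns where an intensity of 0 means "not quantified in this
run", never a measured zero.

Alongside the quantitation table an experiment-design table registers every IP
run: which bait was captured (or a tag-only control), under which extraction
condition, which replicate, and which screen (``target_set``) it belongs to.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

DESIGN_COLUMNS = (
    "experiment_id",
    "bait",
    "target_set",
    "condition_id",
    "replicate",
    "vessel",
    "role",
)

VESSELS = frozenset({"multiwell", "tube"})
ROLES = frozenset({"case", "control"})

#: Default homolog merge: the two near-identical exon-junction-complex subunits
#: whose peptides are largely shared, so their intensities are summed per run.
DEFAULT_MERGE_GROUPS: Mapping[str, frozenset[str]] = {
    "MAGOH*": frozenset({"MAGOH", "MAGOHB", "P61326", "Q96A72"}),
}


class DesignError(ValueError):
    """Raised when the experiment-design table violates its contract."""


class ProteinGroupsError(ValueError):
    """Raised when the protein-groups table cannot be parsed."""


@dataclass(frozen=True)
class ExperimentDesign:
    """Registry of IP runs with case/control pairing.

    ``table`` has one row per run with columns :data:`DESIGN_COLUMNS`.
    A ``(target_set, condition_id)`` cell is *testable* when it carries at
    least two case and two matched control replicates, the minimum for a
    two-sample comparison.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        validate_design(self.table)

    @property
    def experiment_ids(self) -> list[str]:
        return list(self.table["experiment_id"])

    @property
    def target_sets(self) -> list[str]:
        out: list[str] = []
        for t in self.table["target_set"]:
            if t not in out:
                out.append(t)
        return out

    def conditions(self, target_set: str) -> list[str]:
        sub = self.table[
            (self.table["target_set"] == target_set) & (self.table["role"] == "case")
        ]
        out: list[str] = []
        for c in sub["condition_id"]:
            if c not in out:
                out.append(c)
        return out

    def experiments(
        self, target_set: str, condition_id: str | None = None, role: str | None = None
    ) -> list[str]:
        sub = self.table[self.table["target_set"] == target_set]
        if condition_id is not None:
            sub = sub[sub["condition_id"] == condition_id]
        if role is not None:
            sub = sub[sub["role"] == role]
        return list(sub["experiment_id"])

    def case_experiments(self, target_set: str, condition_id: str | None = None) -> list[str]:
        return self.experiments(target_set, condition_id, "case")

    def control_experiments(self, target_set: str, condition_id: str | None = None) -> list[str]:
        return self.experiments(target_set, condition_id, "control")

    def testable_conditions(self) -> list[tuple[str, str]]:
        """All (target_set, condition_id) pairs with >=2 case and >=2 control runs."""
        out = []
        for ts in self.target_sets:
            for cond in self.conditions(ts):
                if (
                    len(self.case_experiments(ts, cond)) >= 2
                    and len(self.control_experiments(ts, cond)) >= 2
                ):
                    out.append((ts, cond))
        return out

    def replicate_groups(self) -> list[tuple[tuple[str, str, str], list[str]]]:
        """Runs grouped by (target_set, condition_id, role) — the unit within
        which replicate-informed imputation and the t-test operate."""
        groups: list[tuple[tuple[str, str, str], list[str]]] = []
        for (ts, cond, role), sub in self.table.groupby(
            ["target_set", "condition_id", "role"], sort=False
        ):
            groups.append(((str(ts), str(cond), str(role)), list(sub["experiment_id"])))
        return groups

    def n_case_runs(self) -> dict[str, int]:
        """Number of case IP runs per target set (each contributes one MDS dimension)."""
        cases = self.table[self.table["role"] == "case"]
        return {ts: int((cases["target_set"] == ts).sum()) for ts in self.target_sets}


def validate_design(table: pd.DataFrame) -> None:
    missing = [c for c in DESIGN_COLUMNS if c not in table.columns]
    if missing:
        raise DesignError(f"design table missing required column(s): {missing}")
    dup = table["experiment_id"][table["experiment_id"].duplicated()]
    if len(dup):
        raise DesignError(f"duplicate experiment_id(s): {sorted(set(dup))}")
    bad_role = set(table["role"]) - ROLES
    if bad_role:
        raise DesignError(f"unknown role value(s): {sorted(bad_role)} (expected case|control)")
    bad_vessel = set(table["vessel"]) - VESSELS
    if bad_vessel:
        raise DesignError(f"unknown vessel value(s): {sorted(bad_vessel)}")
    if (table["replicate"].astype(int) < 1).any():
        raise DesignError("replicate numbers must be positive integers")
    # every condition with case runs needs >=2 case and >=2 matched control runs
    for (ts, cond), sub in table.groupby(["target_set", "condition_id"], sort=False):
        n_case = int((sub["role"] == "case").sum())
        n_ctrl = int((sub["role"] == "control").sum())
        if n_case == 0:
            continue
        if n_case < 2 or n_ctrl < 2:
            raise DesignError(
                f"(target_set={ts!r}, condition={cond!r}) has {n_case} case / "
                f"{n_ctrl} control replicates; need >=2 on each side for testing"
            )


def read_design(path: str | Path) -> ExperimentDesign:
    """Read and validate a tab-delimited experiment-design table."""
    table = pd.read_csv(path, sep="\t", dtype=str)
    if "replicate" in table.columns:
        table["replicate"] = table["replicate"].astype(int)
    return ExperimentDesign(table.reset_index(drop=True))


@dataclass(frozen=True)
class ProteinRecord:
    """One protein group: leader accession, display symbol, evidence flags."""

    protein_id: str
    gene_symbol: str
    peptide_counts: tuple[int, ...]
    is_reverse: bool = False
    is_contaminant: bool = False

    @property
    def max_peptides(self) -> int:
        return max(self.peptide_counts) if self.peptide_counts else 0


@dataclass
class IntensityMatrix:
    """Protein x experiment quantitation grid with explicit missingness.

    ``values`` holds NaN where a protein was not quantified in a run; the
    ``mask`` property exposes that as a boolean grid. ``layer`` records which
    quantitation the grid carries (LFQ or iBAQ) and ``scale`` whether values
    are linear or log2.
    """

    values: pd.DataFrame
    layer: str = "LFQ"
    scale: str = "linear"

    def __post_init__(self) -> None:
        if self.layer not in ("LFQ", "iBAQ"):
            raise ValueError(f"unknown layer {self.layer!r}")
        if self.scale not in ("linear", "log2"):
            raise ValueError(f"unknown scale {self.scale!r}")
        if self.scale == "linear":
            arr = self.values.to_numpy(dtype=float)
            if np.any(arr[~np.isnan(arr)] <= 0):
                raise ValueError("linear-scale present values must be strictly positive")

    @property
    def mask(self) -> pd.DataFrame:
        """True where the cell is missing (not quantified)."""
        return self.values.isna()

    @property
    def proteins(self) -> list[str]:
        return list(self.values.index)

    @property
    def experiments(self) -> list[str]:
        return list(self.values.columns)

    def subset_rows(self, proteins: Sequence[str]) -> "IntensityMatrix":
        return IntensityMatrix(self.values.loc[list(proteins)].copy(), self.layer, self.scale)

    def subset_columns(self, experiments: Sequence[str]) -> "IntensityMatrix":
        return IntensityMatrix(self.values[list(experiments)].copy(), self.layer, self.scale)

    def copy(self) -> "IntensityMatrix":
        return IntensityMatrix(self.values.copy(), self.layer, self.scale)


def _parse_flag(series: pd.Series) -> pd.Series:
    return series.fillna("").astype(str).str.strip() == "+"


def _parse_counts(cell: object) -> tuple[int, ...]:
    text = "" if cell is None or (isinstance(cell, float) and np.isnan(cell)) else str(cell)
    parts = [p for p in text.split(";") if p.strip() != ""]
    try:
        return tuple(int(float(p)) for p in parts)
    except ValueError as exc:
        raise ProteinGroupsError(f"unparseable peptide-count cell {cell!r}") from exc


def read_protein_groups(
    path: str | Path, design: ExperimentDesign
) -> tuple[list[ProteinRecord], IntensityMatrix, IntensityMatrix]:
    """Parse a proteinGroups-dialect table into records plus LFQ and iBAQ layers.

    Intensity 0 in the file is converted to missing (NaN) in both layers.
    Row order is shared between the two returned matrices.
    """
    table = pd.read_csv(path, sep="\t", dtype=str)
    return protein_groups_from_frame(table, design)


def protein_groups_from_frame(
    table: pd.DataFrame, design: ExperimentDesign
) -> tuple[list[ProteinRecord], IntensityMatrix, IntensityMatrix]:
    """In-memory counterpart of :func:`read_protein_groups`."""
    required = [
        "Majority protein IDs",
        "Gene names",
        "Peptide counts (razor + unique)",
        "Reverse",
        "Potential contaminant",
    ]
    missing_cols = [c for c in required if c not in table.columns]
    if missing_cols:
        raise ProteinGroupsError(f"protein-groups table missing column(s): {missing_cols}")

    records: list[ProteinRecord] = []
    for i, row in table.iterrows():
        accession = str(row["Majority protein IDs"]).split(";")[0].strip()
        gene = str(row["Gene names"]).split(";")[0].strip() if pd.notna(row["Gene names"]) else ""
        records.append(
            ProteinRecord(
                protein_id=accession,
                gene_symbol=gene,
                peptide_counts=_parse_counts(row["Peptide counts (razor + unique)"]),
                is_reverse=bool(_parse_flag(table["Reverse"]).iloc[i]),
                is_contaminant=bool(_parse_flag(table["Potential contaminant"]).iloc[i]),
            )
        )
    index = pd.Index([r.protein_id for r in records], name="protein_id")
    if index.duplicated().any():
        dups = sorted(set(index[index.duplicated()]))
        raise ProteinGroupsError(f"duplicate leader accession(s): {dups}")

    layers = {}
    for layer, prefix in (("LFQ", "LFQ intensity "), ("iBAQ", "iBAQ ")):
        cols = {}
        for exp_id in design.experiment_ids:
            col = prefix + exp_id
            if col not in table.columns:
                raise ProteinGroupsError(
                    f"design experiment {exp_id!r} has no {col!r} column in the table"
                )
            raw = table[col]
            try:
                if raw.dtype == object:
                    # float() is correctly rounded; pandas' fast parser is not
                    vals = raw.map(float)
                else:
                    vals = raw.astype(float)
            except (ValueError, TypeError) as exc:
                raise ProteinGroupsError(f"non-numeric intensity in column {col!r}") from exc
            cols[exp_id] = vals.where(vals > 0, np.nan).to_numpy(dtype=float)
        grid = pd.DataFrame(cols, index=index)
        layers[layer] = IntensityMatrix(grid, layer=layer, scale="linear")
    return records, layers["LFQ"], layers["iBAQ"]


def filter_records(
    records: Sequence[ProteinRecord],
    matrices: Sequence[IntensityMatrix],
    min_peptides: int = 2,
) -> tuple[list[ProteinRecord], list[IntensityMatrix], dict[str, int]]:
    """Drop decoy, contaminant, and under-evidenced groups from records and matrices.

    A group survives when neither flag is set and the *maximum* razor+unique
    peptide count over its members reaches ``min_peptides``. Returns the
    surviving records, row-filtered matrices (alignment preserved) and a drop
    log per reason.
    """
    keep: list[str] = []
    dropped = {"reverse": 0, "contaminant": 0, "low_peptides": 0}
    for rec in records:
        if rec.is_reverse:
            dropped["reverse"] += 1
        elif rec.is_contaminant:
            dropped["contaminant"] += 1
        elif rec.max_peptides < min_peptides:
            dropped["low_peptides"] += 1
        else:
            keep.append(rec.protein_id)
    kept_records = [r for r in records if r.protein_id in set(keep)]
    kept_matrices = [m.subset_rows(keep) for m in matrices]
    return kept_records, kept_matrices, dropped


def merge_homologs(
    matrices: Sequence[IntensityMatrix],
    groups: Mapping[str, Iterable[str]] = DEFAULT_MERGE_GROUPS,
    records: Sequence[ProteinRecord] | None = None,
) -> list[IntensityMatrix]:
    """Sum homolog groups row-wise on the linear scale.

    Members may be named by accession or gene symbol (resolved through
    ``records`` when given). Missing members contribute 0 to the sum; the
    merged cell is missing only where every member is missing. Members absent
    from the table trigger a warning and the merge proceeds over those present.
    """
    out: list[IntensityMatrix] = []
    symbol_to_acc: dict[str, str] = {}
    if records is not None:
        symbol_to_acc = {r.gene_symbol: r.protein_id for r in records if r.gene_symbol}
    for m in matrices:
        if m.scale != "linear":
            raise ValueError("merge_homologs requires linear-scale matrices")
        vals = m.values.copy()
        for merged_id, members in groups.items():
            rows = []
            for member in members:
                acc = symbol_to_acc.get(member, member)
                if acc in vals.index and acc not in rows:
                    rows.append(acc)
            if not rows:
                continue
            absent = [x for x in members if symbol_to_acc.get(x, x) not in vals.index and x not in vals.index]
            if absent:
                warnings.warn(
                    f"merge group {merged_id!r}: member(s) {absent} absent; merging over present rows",
                    stacklevel=2,
                )
            block = vals.loc[rows]
            merged = block.sum(axis=0, min_count=1)  # NaN only when every member is NaN
            vals = vals.drop(index=rows)
            vals.loc[merged_id] = merged
        out.append(IntensityMatrix(vals, m.layer, m.scale))
    return out
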