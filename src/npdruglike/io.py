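"""Readers, writers and shared record types.

Molecule structures are RDKit ``Mol`` objects parsed from SMILES or SDF.
Descriptor and endpoint tables are thin, validated wrappers around pandas
DataFrames so that downstream code can rely on their invariants (no missing
cells, unique ids, binary endpoints) without re-checking.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from rdkit import Chem
from rdkit import RDLogger

logger = logging.getLogger(__name__)

CATEGORIES = ("drug", "np", "toxin")

# RDKit is chatty about every parse failure; we count and report instead.
RDLogger.DisableLog("rdApp.error")


class ChemIOError(ValueError):
    """Raised for malformed molecule or table inputs."""


@dataclass
class MoleculeRecord:
    """One compound: identifier, structure, category label, optional name.

    ``structure`` may be ``None`` when only a descriptor row exists for the
    compound (e.g. descriptor tables supplied as CSV without structures).
    """

    id: str
    structure: Chem.Mol | None
    category: str
    name: str | None = None

    def __post_init__(self) -> None:
        if self.category not in CATEGORIES:
            raise ChemIOError(
                f"category {self.category!r} for {self.id!r} not one of {CATEGORIES}"
            )


@dataclass
class ParseReport:
    """Bookkeeping for a molecule-file parse: counts are conserved."""

    n_input: int = 0
    n_parsed: int = 0
    failures: list[str] = field(default_factory=list)

    @property
    def n_failed(self) -> int:
        return len(self.failures)


@dataclass
class DescriptorTable:
    """Molecules x continuous-descriptor matrix with category labels.

    ``values`` is indexed by molecule id with one column per descriptor;
    ``categories`` is an id-indexed Series of drug/np/toxin labels.
    """

    values: pd.DataFrame
    categories: pd.Series

    def __post_init__(self) -> None:
        if self.values.index.has_duplicates:
            dupes = self.values.index[self.values.index.duplicated()].unique().tolist()
            raise ChemIOError(f"duplicate molecule ids: {dupes}")
        if self.values.columns.has_duplicates:
            dupes = self.values.columns[self.values.columns.duplicated()].unique().tolist()
            raise ChemIOError(f"duplicate descriptor names: {dupes}")
        if self.values.isna().any().any():
            bad = self.values.index[self.values.isna().any(axis=1)].tolist()
            raise ChemIOError(f"missing descriptor cells for ids: {bad[:10]}")
        self.categories = self.categories.reindex(self.values.index)
        if self.categories.isna().any():
            bad = self.categories.index[self.categories.isna()].tolist()
            raise ChemIOError(f"missing category for ids: {bad[:10]}")
        unknown = set(self.categories.unique()) - set(CATEGORIES)
        if unknown:
            raise ChemIOError(f"unknown categories: {sorted(unknown)}")

    @property
    def ids(self) -> list[str]:
        return self.values.index.tolist()

    @property
    def variables(self) -> list[str]:
        return self.values.columns.tolist()

    def subset(self, category: str) -> pd.DataFrame:
        """Rows of ``values`` belonging to one category."""
        return self.values.loc[self.categories == category]


@dataclass
class EndpointTable:
    """Molecules x binary ADMET-endpoint matrix (1 beneficial, 0 harmful)."""

    values: pd.DataFrame
    categories: pd.Series | None = None

    def __post_init__(self) -> None:
        if self.values.columns.has_duplicates:
            raise ChemIOError("duplicate endpoint names")
        arr = self.values.to_numpy()
        if not np.isin(arr, (0, 1)).all():
            raise ChemIOError("endpoint values must be 0 or 1")
        self.values = self.values.astype(int)
        if self.categories is not None:
            self.categories = self.categories.reindex(self.values.index)

    @property
    def ids(self) -> list[str]:
        return self.values.index.tolist()

    @property
    def endpoints(self) -> list[str]:
        return self.values.columns.tolist()


def read_molecules(
    path: str | Path,
    format: str,
    category: str,
    strict: bool = False,
) -> tuple[list[MoleculeRecord], ParseReport]:
    """Read molecules from a SMILES or SDF file.

    SMILES files carry one molecule per line with an optional second
    whitespace-separated token used as the id; ids default to ``M<line>``.
    Unparseable entries are counted in the returned :class:`ParseReport`
    rather than silently dropped; ``strict=True`` aborts on the first
    failure instead.
    """
    path = Path(path)
    if not path.exists():
        raise ChemIOError(f"no such file: {path}")
    if format not in ("smiles", "sdf"):
        raise ChemIOError(f"format must be 'smiles' or 'sdf', got {format!r}")

    records: list[MoleculeRecord] = []
    report = ParseReport()

    if format == "smiles":
        lines = [
            ln for ln in path.read_text().splitlines() if ln.strip() and not ln.startswith("#")
        ]
        if not lines:
            raise ChemIOError(f"empty molecule file: {path}")
        for i, line in enumerate(lines, start=1):
            report.n_input += 1
            tokens = line.split()
            smi, mid = tokens[0], (tokens[1] if len(tokens) > 1 else f"M{i}")
            mol = Chem.MolFromSmiles(smi)
            if mol is None:
                if strict:
                    raise ChemIOError(f"unparseable SMILES at line {i}: {smi!r}")
                report.failures.append(mid)
                continue
            records.append(MoleculeRecord(id=mid, structure=mol, category=category))
            report.n_parsed += 1
    else:
        supplier = Chem.SDMolSupplier(str(path))
        n_entries = len(supplier)
        if n_entries == 0:
            raise ChemIOError(f"empty SDF file: {path}")
        for i, mol in enumerate(supplier, start=1):
            report.n_input += 1
            if mol is None:
                if strict:
                    raise ChemIOError(f"unparseable SDF entry {i} in {path}")
                report.failures.append(f"entry{i}")
                continue
            mid = mol.GetProp("_Name") if mol.HasProp("_Name") and mol.GetProp("_Name") else f"M{i}"
            name = mol.GetProp("name") if mol.HasProp("name") else None
            records.append(MoleculeRecord(id=mid, structure=mol, category=category, name=name))
            report.n_parsed += 1

    ids = [r.id for r in records]
    dupes = sorted({i for i in ids if ids.count(i) > 1})
    if dupes:
        raise ChemIOError(f"duplicate molecule ids: {dupes}")
    if report.n_failed:
        logger.warning("%d of %d entries in %s failed to parse", report.n_failed, report.n_input, path)
    return records, report


def read_descriptor_csv(
    path: str | Path,
    id_column: str = "id",
    category_column: str = "category",
) -> DescriptorTable:
    """Read a descriptor CSV: id column, category column, numeric descriptors.

    Numeric coercion is strict — any non-numeric or missing cell raises
    with its row and column named.
    """
    path = Path(path)
    if not path.exists():
        raise ChemIOError(f"no such file: {path}")
    df = pd.read_csv(path, dtype=str)
    if id_column not in df.columns:
        raise ChemIOError(f"missing id column {id_column!r}")
    if category_column not in df.columns:
        raise ChemIOError(f"missing category column {category_column!r}")
    df = df.set_index(id_column)
    categories = df.pop(category_column)
    values = pd.DataFrame(index=df.index)
    for col in df.columns:
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = coerced.isna()
        if bad.any():
            rid = df.index[bad][0]
            raise ChemIOError(
                f"non-numeric cell at row {rid!r}, column {col!r}: {df.loc[rid, col]!r}"
            )
        values[col] = coerced
    return DescriptorTable(values=values, categories=categories)


def write_descriptor_csv(table: DescriptorTable, path: str | Path) -> None:
    """Write a DescriptorTable in the layout ``read_descriptor_csv`` expects."""
    out = table.values.copy()
    out.insert(0, "category", table.categories)
    out.index.name = "id"
    out.to_csv(Path(path), float_format="%.12g")


def read_endpoint_csv(
    path: str | Path,
    id_column: str = "id",
    category_column: str | None = "category",
) -> EndpointTable:
    """Read a binary ADMET endpoint CSV (1 beneficial, 0 harmful)."""
    path = Path(path)
    if not path.exists():
        raise ChemIOError(f"no such file: {path}")
    df = pd.read_csv(path).set_index(id_column)
    categories = None
    if category_column and category_column in df.columns:
        categories = df.pop(category_column)
    return EndpointTable(values=df, categories=categories)


def write_endpoint_csv(table: EndpointTable, path: str | Path) -> None:
    out = table.values.copy()
    if table.categories is not None:
        out.insert(0, "category", table.categories)
    out.index.name = "id"
    out.to_csv(Path(path))


def write_scores_csv(profiles: Sequence | pd.DataFrame, path: str | Path) -> None:
    """Write per-molecule score rows (likeness profiles or composite scores).

    Accepts a DataFrame indexed by id, or a sequence of dataclass records
    with an ``id`` field. Column order follows the input and is stable.
    """
    if isinstance(profiles, pd.DataFrame):
        if profiles.empty:
            raise ChemIOError("no profiles to write")
        out = profiles.copy()
        out.index.name = "id"
        out.to_csv(Path(path), float_format="%.12g")
        return
    profiles = list(profiles)
    if not profiles:
        raise ChemIOError("no profiles to write")
    rows = [vars(p).copy() for p in profiles]
    df = pd.DataFrame(rows).set_index("id")
    df.index.name = "id"
    df.to_csv(Path(path), float_format="%.12g")


def read_scores_csv(path: str | Path) -> pd.DataFrame:
    """Read back a score table written by :func:`write_scores_csv`."""
    return pd.read_csv(Path(path), index_col="id")


def read_distance_csv(path: str | Path) -> tuple[np.ndarray, list[str]]:
    """Read a square distance matrix CSV with id header row and column."""
    df = pd.read_csv(Path(path), index_col=0)
    if list(df.index) != list(df.columns):
        raise ChemIOError("distance matrix row and column ids differ")
    return df.to_numpy(dtype=float), df.index.tolist()
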