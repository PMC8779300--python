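"""The eight molecular properties behind QED/RDL, and structural alerts.

Properties: molecular weight (MW, Da), atomic-contribution log P (ALOGP,
Crippen model), hydrogen-bond donors (HBD), hydrogen-bond acceptors (HBA,
Lipinski N+O convention), topological polar surface area (PSA, A^2),
rotatable bonds (ROTB, amide C-N excluded), aromatic rings (AROM, SSSR rings
whose bonds are all aromatic), and structural-alert matches (ALERTS, number
of distinct alert patterns with at least one match).
"""

from __future__ import annotations

import importlib.resources
import logging
from dataclasses import dataclass, fields
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from rdkit import Chem
from rdkit.Chem import Crippen, Descriptors, Lipinski

from .io import DescriptorTable, MoleculeRecord, read_descriptor_csv

logger = logging.getLogger(__name__)

PROPERTY_NAMES = ("MW", "ALOGP", "HBD", "HBA", "PSA", "ROTB", "AROM", "ALERTS")


class DescriptorError(ValueError):
    pass


@dataclass(frozen=True)
class PropertyVector:
    """The eight QED/RDL properties of one molecule."""

    MW: float
    ALOGP: float
    HBD: int
    HBA: int
    PSA: float
    ROTB: int
    AROM: int
    ALERTS: int

    def __post_init__(self) -> None:
        if self.MW <= 0:
            raise DescriptorError(f"MW must be positive, got {self.MW}")
        if self.PSA < 0:
            raise DescriptorError(f"PSA must be non-negative, got {self.PSA}")
        for name in ("HBD", "HBA", "ROTB", "AROM", "ALERTS"):
            v = getattr(self, name)
            if not (isinstance(v, (int,)) and v >= 0):
                raise DescriptorError(f"{name} must be a non-negative integer, got {v!r}")

    def as_dict(self) -> dict[str, float]:
        return {f.name: getattr(self, f.name) for f in fields(self)}


@dataclass(frozen=True)
class AlertPattern:
    smarts: str
    name: str
    query: Chem.Mol

    @classmethod
    def compile(cls, smarts: str, name: str) -> "AlertPattern":
        q = Chem.MolFromSmarts(smarts)
        if q is None:
            raise DescriptorError(f"invalid alert SMARTS {smarts!r} ({name})")
        return cls(smarts=smarts, name=name, query=q)


def alert_patterns(
    path: str | Path | None = None, source: str = "file"
) -> list[AlertPattern]:
    """Load structural-alert patterns.

    ``source="file"`` reads a SMARTS file (one ``pattern name`` pair per
    line, ``#`` comments); with no path, the curated default set shipped
    with the package is used. ``source="rdkit-brenk"`` builds the patterns
    from RDKit's Brenk filter catalog at run time.
    """
    if source == "rdkit-brenk":
        from rdkit.Chem import FilterCatalog

        params = FilterCatalog.FilterCatalogParams()
        params.AddCatalog(FilterCatalog.FilterCatalogParams.FilterCatalogs.BRENK)
        catalog = FilterCatalog.FilterCatalog(params)
        out = []
        for i in range(catalog.GetNumEntries()):
            entry = catalog.GetEntryWithIdx(i)
            out.append(
                AlertPattern(
                    smarts="<catalog>", name=entry.GetDescription(), query=entry
                )
            )
        return out
    if source != "file":
        raise DescriptorError(f"unknown alert source {source!r}")
    if path is None:
        ref = importlib.resources.files("npdruglike.data") / "alerts_curated_v1.smarts"
        text = ref.read_text()
    else:
        text = Path(path).read_text()
    patterns = []
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split()
        smarts = parts[0]
        name = parts[1] if len(parts) > 1 else smarts
        patterns.append(AlertPattern.compile(smarts, name))
    return patterns


def count_structural_alerts(
    structure: Chem.Mol, patterns: Sequence[AlertPattern]
) -> int:
    """Number of distinct alert patterns with >= 1 match (not total matches)."""
    n = 0
    for p in patterns:
        if hasattr(p.query, "HasFilterMatch"):  # FilterCatalog entry
            if p.query.HasFilterMatch(structure):
                n += 1
        elif structure.HasSubstructMatch(p.query):
            n += 1
    return n


def _aromatic_ring_count(mol: Chem.Mol) -> int:
    # SSSR rings whose bonds are all aromatic; deterministic for fused systems
    ri = mol.GetRingInfo()
    count = 0
    for ring_bonds in ri.BondRings():
        if all(mol.GetBondWithIdx(b).GetIsAromatic() for b in ring_bonds):
            count += 1
    return count


_DEFAULT_ALERTS: list[AlertPattern] | None = None


def _default_alerts() -> list[AlertPattern]:
    global _DEFAULT_ALERTS
    if _DEFAULT_ALERTS is None:
        _DEFAULT_ALERTS = alert_patterns()
    return _DEFAULT_ALERTS


def eight_properties(
    structure: Chem.Mol, alerts: Sequence[AlertPattern] | None = None
) -> PropertyVector:
    """Compute the eight QED/RDL properties for a sanitized structure.

    Deterministic for a given structure; raises if the molecule cannot be
    sanitized (invalid valences, aromaticity perception failure).
    """
    if structure is None:
        raise DescriptorError("structure is None")
    try:
        Chem.SanitizeMol(structure)
    except Exception as exc:  # pragma: no cover - rdkit raises various types
        name = structure.GetProp("_Name") if structure.HasProp("_Name") else "<unnamed>"
        raise DescriptorError(f"cannot sanitize molecule {name}: {exc}") from exc
    if alerts is None:
        alerts = _default_alerts()
    return PropertyVector(
        MW=Descriptors.MolWt(structure),
        ALOGP=Crippen.MolLogP(structure),
        HBD=int(Lipinski.NumHDonors(structure)),
        HBA=int(Lipinski.NOCount(structure)),
        PSA=Descriptors.TPSA(structure),
        ROTB=int(Lipinski.NumRotatableBonds(structure)),
        AROM=_aromatic_ring_count(structure),
        ALERTS=int(count_structural_alerts(structure, alerts)),
    )


def property_table(
    molecules: Iterable[MoleculeRecord],
    alerts: Sequence[AlertPattern] | None = None,
) -> pd.DataFrame:
    """Eight-property table (id-indexed) for molecules with structures."""
    rows, ids = [], []
    for rec in molecules:
        if rec.structure is None:
            raise DescriptorError(f"molecule {rec.id!r} has no structure")
        rows.append(eight_properties(rec.structure, alerts).as_dict())
        ids.append(rec.id)
    return pd.DataFrame(rows, index=pd.Index(ids, name="id"))


def build_descriptor_table(
    molecules: Sequence[MoleculeRecord],
    backend: str = "computed",
    alerts: Sequence[AlertPattern] | None = None,
) -> DescriptorTable:
    """Assemble a DescriptorTable for chemical-space analysis.

    ``backend="computed"`` computes the eight properties from structures;
    ``backend="csv:<path>"`` loads a descriptor CSV (a stand-in for richer
    commercial descriptor panels) and checks that its ids exactly match the
    molecule list.
    """
    categories = pd.Series(
        {m.id: m.category for m in molecules}, name="category"
    )
    if backend == "computed":
        values = property_table(molecules, alerts)
        return DescriptorTable(values=values, categories=categories.reindex(values.index))
    if backend.startswith("csv:"):
        table = read_descriptor_csv(backend[4:])
        mol_ids = {m.id for m in molecules}
        csv_ids = set(table.ids)
        if mol_ids != csv_ids:
            extra = sorted(csv_ids - mol_ids)[:10]
            missing = sorted(mol_ids - csv_ids)[:10]
            raise DescriptorError(
                f"id mismatch between molecules and CSV (extra in CSV: {extra}, "
                f"missing from CSV: {missing})"
            )
        return DescriptorTable(
            values=table.values, categories=categories.reindex(table.values.index)
        )
    raise DescriptorError(f"unknown backend {backend!r}")
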