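"""Input/output for compound libraries and descriptor tables.

Structures are read from SDF (V2000, 3D coordinates in Angstrom) or SMILES
lists into :class:`MoleculeRecord` objects that keep every SDF data item as a
verbatim text tag.  Precomputed descriptor values travel either as SDF tags
(imported through :func:`extract_descriptors` with a tag map that translates
tool-specific spellings to canonical names) or as delimited text tables.

Numeric tag parsing tolerates the Unicode minus sign and comma thousands
separators, since supplementary material often derives from typeset sources.
"""

from __future__ import annotations

import csv
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping

import numpy as np
import pandas as pd
from rdkit import Chem, RDLogger

logger = logging.getLogger(__name__)

# RDKit is chatty about malformed records; we log skips ourselves.
RDLogger.DisableLog("rdApp.error")
RDLogger.DisableLog("rdApp.warning")

#: Default translation from common tool-specific SDF tag spellings to the
#: canonical descriptor names used throughout the package.  Matching is
#: case-sensitive.
DEFAULT_TAG_MAP: dict[str, str] = {
    "mol MW": "MW",
    "MW": "MW",
    "QPlogPo/w": "logP",
    "logP": "logP",
    "accptHB": "HBA",
    "donorHB": "HBD",
    "#rotor": "NRB",
    "SASA": "S_mol",
    "FOSA": "S_mol_hfob",
    "FISA": "S_mol_fisa",
    "PISA": "S_mol_pisa",
    "WPSA": "S_mol_wpsa",
    "volume": "V_mol",
    "dipole": "dipole",
    "QPlogS": "logS_wat",
    "CIQPlogS": "CI_logS_wat",
    "QPlogKhsa": "logK_HSA",
    "QPlogBB": "logB_B",
    "QPPCaco": "BIP_caco2",
    "QPPMDCK": "MDCK",
    "QPpolrz": "QP_polrz",
    "QPlogHERG": "logHERG",
    "QPlogKp": "logK_p",
    "#metab": "metab",
    "CNS": "CNS",
    "Human Oral Absorption": "qualitative_oral_absorption",
    "Percent Human Oral Absorption": "percent_oral_absorption",
    "Jm": "J_m",
    "#stars": "stars",
}


def parse_numeric(text: str) -> float:
    """Parse a numeric tag value, tolerating typeset artifacts.

    Accepts the Unicode minus sign (U+2212) and comma thousands separators.
    Raises ``ValueError`` for anything that is not a number.
    """
    cleaned = text.strip().replace("−", "-").replace(",", "")
    if not cleaned:
        raise ValueError("empty numeric field")
    return float(cleaned)


@dataclass
class MoleculeRecord:
    """One compound: identifier, optional 3D structure, raw SDF tags."""

    id: str
    mol: Chem.Mol | None = None
    tags: dict[str, str] = field(default_factory=dict)

    @property
    def has_structure(self) -> bool:
        return self.mol is not None

    @property
    def has_coordinates(self) -> bool:
        return self.mol is not None and self.mol.GetNumConformers() > 0

    def numeric_tag(self, name: str) -> float | None:
        """Tag value as a float, or None if absent/unparseable."""
        raw = self.tags.get(name)
        if raw is None:
            return None
        try:
            return parse_numeric(raw)
        except ValueError:
            return None


@dataclass
class DescriptorTable:
    """Per-compound descriptor values with per-descriptor provenance.

    ``data`` is indexed by compound id with one column per canonical
    descriptor name; missing values are NaN, never silently zero.
    ``provenance`` maps each descriptor name to one of ``computed``,
    ``imported`` or ``model``.
    """

    data: pd.DataFrame
    provenance: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.data.index.has_duplicates:
            dup = self.data.index[self.data.index.duplicated()][0]
            raise ValueError(f"duplicate compound id: {dup!r}")

    @property
    def descriptor_names(self) -> list[str]:
        return list(self.data.columns)

    @property
    def ids(self) -> list[str]:
        return list(self.data.index)

    def __len__(self) -> int:
        return len(self.data)

    def rows(self) -> Iterator[tuple[str, "DescriptorVector"]]:
        """Iterate (compound id, DescriptorVector) with NaNs dropped."""
        from .descriptors import DescriptorVector

        for cid, row in self.data.iterrows():
            values = {k: float(v) for k, v in row.items() if not pd.isna(v)}
            prov = {k: self.provenance.get(k, "imported") for k in values}
            yield str(cid), DescriptorVector(values=values, provenance=prov)

    def vector(self, cid: str) -> "DescriptorVector":
        from .descriptors import DescriptorVector

        row = self.data.loc[cid]
        values = {k: float(v) for k, v in row.items() if not pd.isna(v)}
        prov = {k: self.provenance.get(k, "imported") for k in values}
        return DescriptorVector(values=values, provenance=prov)

    def subset(self, ids: Iterable[str]) -> "DescriptorTable":
        wanted = [i for i in ids if i in self.data.index]
        return DescriptorTable(self.data.loc[wanted], dict(self.provenance))

    def merged_with(self, other: "DescriptorTable") -> "DescriptorTable":
        """Combine two tables; where both define a value, ``other`` wins."""
        data = other.data.combine_first(self.data) if len(self.data) else other.data
        # combine_first reorders; keep union order with self first
        idx = list(self.data.index) + [i for i in other.data.index if i not in self.data.index]
        prov = {**self.provenance, **other.provenance}
        return DescriptorTable(data.loc[idx], prov)


class RecordList(list):
    """List of MoleculeRecord that remembers how many input blocks were skipped."""

    n_skipped: int = 0


def _dedup_id(base: str, seen: set[str]) -> str:
    if base not in seen:
        return base
    k = 1
    while f"{base}_{k}" in seen:
        k += 1
    return f"{base}_{k}"


def read_structures(path: str | Path, format: str | None = None) -> RecordList:
    """Read an SDF or SMILES file into a list of :class:`MoleculeRecord`.

    Record order is preserved and SDF data items are kept verbatim as text
    tags.  Malformed molecule blocks are skipped with a logged warning; the
    skip count is available on the returned list as ``.n_skipped``.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format is None:
        format = "smiles" if path.suffix.lower() in {".smi", ".smiles", ".txt"} else "sdf"
    if format not in {"sdf", "smiles"}:
        raise ValueError(f"unsupported format: {format!r}")
    records = RecordList()
    seen: set[str] = set()
    if format == "sdf":
        if path.stat().st_size == 0:
            return records
        supplier = Chem.SDMolSupplier(str(path), sanitize=True, removeHs=False)
        for i, mol in enumerate(supplier):
            if mol is None:
                records.n_skipped += 1
                logger.warning("skipped malformed molecule block %d in %s", i + 1, path.name)
                continue
            name = mol.GetProp("_Name").strip() if mol.HasProp("_Name") else ""
            cid = _dedup_id(name or f"mol{i + 1}", seen)
            seen.add(cid)
            tags = {pn: mol.GetProp(pn) for pn in mol.GetPropNames()}
            records.append(MoleculeRecord(id=cid, mol=mol, tags=tags))
    else:
        with open(path) as fh:
            lineno = 0
            for line in fh:
                line = line.strip()
                if not line:
                    continue
                lineno += 1
                parts = line.split(None, 1)
                smiles = parts[0]
                mol = Chem.MolFromSmiles(smiles)
                if mol is None:
                    records.n_skipped += 1
                    logger.warning("skipped unparseable SMILES line %d in %s", lineno, path.name)
                    continue
                base = parts[1].strip() if len(parts) > 1 else f"mol{lineno}"
                cid = _dedup_id(base, seen)
                seen.add(cid)
                records.append(MoleculeRecord(id=cid, mol=mol, tags={}))
    return records


def write_structures(records: Iterable[MoleculeRecord], path: str | Path) -> int:
    """Write records with their tags back to an SDF file; returns count written."""
    path = Path(path)
    writer = Chem.SDWriter(str(path))
    n = 0
    try:
        for rec in records:
            if rec.mol is None:
                logger.warning("record %s has no structure; not written", rec.id)
                continue
            mol = Chem.Mol(rec.mol)
            mol.SetProp("_Name", rec.id)
            for k, v in rec.tags.items():
                mol.SetProp(k, v)
            writer.write(mol)
            n += 1
    finally:
        writer.close()
    return n


def read_descriptor_table(path: str | Path, id_column: str = "id") -> DescriptorTable:
    """Read a delimited text descriptor table (delimiter sniffed from the header).

    Non-numeric cells in descriptor columns become missing values; a duplicate
    compound id raises ``ValueError`` naming it.
    """
    path = Path(path)
    with open(path) as fh:
        header = fh.readline()
    if not header:
        raise ValueError(f"{path}: empty file")
    try:
        dialect = csv.Sniffer().sniff(header, delimiters=",\t;")
        sep = dialect.delimiter
    except csv.Error:
        sep = ","
    df = pd.read_csv(path, sep=sep, dtype=str)
    if id_column not in df.columns:
        raise ValueError(f"{path}: id column {id_column!r} not in header {list(df.columns)}")
    ids = df[id_column].astype(str)
    if ids.duplicated().any():
        dup = ids[ids.duplicated()].iloc[0]
        raise ValueError(f"{path}: duplicate compound id: {dup!r}")
    data = df.drop(columns=[id_column])
    for col in data.columns:
        data[col] = data[col].map(
            lambda x: np.nan if pd.isna(x) else _numeric_or_nan(str(x))
        )
    data.index = pd.Index(ids, name="id")
    prov = {c: "imported" for c in data.columns}
    return DescriptorTable(data.astype(float), prov)


def _numeric_or_nan(text: str) -> float:
    try:
        return parse_numeric(text)
    except ValueError:
        return math.nan


def extract_descriptors(
    records: Iterable[MoleculeRecord],
    tag_map: Mapping[str, str] | None = None,
) -> DescriptorTable:
    """Import precomputed descriptors from SDF tags into a DescriptorTable.

    ``tag_map`` translates raw tag names to canonical descriptor names
    (:data:`DEFAULT_TAG_MAP` by default).  Untagged compounds yield rows of
    missing values; unparseable numerics become missing with one warning.
    """
    if tag_map is None:
        tag_map = DEFAULT_TAG_MAP
    rows: dict[str, dict[str, float]] = {}
    names: list[str] = []
    for rec in records:
        row: dict[str, float] = {}
        for tag, value in rec.tags.items():
            canon = tag_map.get(tag)
            if canon is None:
                continue
            if canon not in names:
                names.append(canon)
            try:
                row[canon] = parse_numeric(value)
            except ValueError:
                logger.warning(
                    "record %s: tag %r value %r is not numeric; marked missing",
                    rec.id, tag, value,
                )
        rows[rec.id] = row
    data = pd.DataFrame.from_dict(rows, orient="index", columns=names, dtype=float)
    data = data.reindex(list(rows))  # keep untagged compounds as all-missing rows
    data.index.name = "id"
    return DescriptorTable(data, {n: "imported" for n in names})
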