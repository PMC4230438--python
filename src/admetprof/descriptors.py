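"""Structure-based physicochemical descriptors.

Constitutional counts (MW, hydrogen-bond donors/acceptors, rotatable bonds)
and the Crippen atom-contribution logP estimate are delegated to RDKit, whose
conventions match the Lipinski-style counts the screening filters are defined
on: HBA = all N+O atoms, HBD = N-H/O-H hydrogens, rotatable bonds exclude
amide C-N.

Geometric descriptors are computed here from 3D coordinates:

* solvent-accessible surface area (``S_mol``) and its hydrophobic component
  (``S_mol_hfob``) by deterministic Shrake-Rupley sphere sampling with a
  Fibonacci-spiral point set (default 960 points/atom, probe radius 1.4 A,
  Bondi van der Waals radii);
* solvent-accessible volume (``V_mol``) by grid sampling of the union of
  probe-inflated atomic spheres;
* globularity ``Glob = 4*pi*r^2 / S_mol`` with ``r`` the radius of the sphere
  of volume ``V_mol`` (1 for a perfect sphere, smaller for elongated shapes);
* the solid-cohesion index ``Ind_coh = HBA*sqrt(HBD)/S_mol`` (the default of a
  pluggable formula; see docs/methods.md).

Hydrophobic atoms are, by default, saturated carbons, hydrogens attached to
them, and halogens; the class is configurable.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from importlib import resources
from typing import Callable, Iterable, Sequence

import numpy as np
import yaml
from rdkit import Chem
from rdkit.Chem import Crippen, Descriptors as RDDescriptors, Lipinski, rdMolDescriptors

from .chem_io import DescriptorTable, MoleculeRecord

logger = logging.getLogger(__name__)

DEFAULT_PROBE_RADIUS = 1.4  # Angstrom, water probe
DEFAULT_SASA_POINTS = 960
DEFAULT_GRID_RESOLUTION = 0.15  # Angstrom

_HALOGENS = {"F", "Cl", "Br", "I", "At"}


def _load_radii() -> tuple[dict[str, float], float]:
    text = resources.files("admetprof.data").joinpath("vdw_radii.yaml").read_text()
    doc = yaml.safe_load(text)
    return {k: float(v) for k, v in doc["radii"].items()}, float(doc["default"])


VDW_RADII, _DEFAULT_RADIUS = _load_radii()


def vdw_radius(element: str) -> float:
    """Bondi van der Waals radius in Angstrom (generic fallback with warning)."""
    r = VDW_RADII.get(element)
    if r is None:
        logger.warning("no vdW radius for element %r; using generic %.2f A", element, _DEFAULT_RADIUS)
        return _DEFAULT_RADIUS
    return r


@dataclass
class DescriptorVector:
    """Named descriptor values for one compound with per-value provenance.

    ``provenance[name]`` is ``computed`` (derived from the structure here),
    ``imported`` (read from tags/tables) or ``model`` (a QSPR layer output).
    """

    values: dict[str, float] = field(default_factory=dict)
    provenance: dict[str, str] = field(default_factory=dict)

    def get(self, name: str) -> float | None:
        return self.values.get(name)

    def set(self, name: str, value: float, provenance: str = "computed") -> None:
        self.values[name] = float(value)
        self.provenance[name] = provenance

    def update(self, other: "DescriptorVector") -> None:
        self.values.update(other.values)
        self.provenance.update(other.provenance)

    def __contains__(self, name: str) -> bool:
        return name in self.values

    def __len__(self) -> int:
        return len(self.values)


# ---------------------------------------------------------------------------
# constitutional counts and lipophilicity
# ---------------------------------------------------------------------------

def compute_constitutional(
    rec: MoleculeRecord, *, hba_exclude_donor_heteroatoms: bool = False
) -> DescriptorVector:
    """MW, HBD, HBA and rotatable-bond count from 2D connectivity.

    With ``hba_exclude_donor_heteroatoms`` the acceptor count drops N/O atoms
    that carry a donor hydrogen; the default counts all N+O, matching the
    Lipinski-style criteria the filters quote.  Records without a structure
    yield an empty vector (descriptors missing, never zero).
    """
    dv = DescriptorVector()
    if rec.mol is None:
        return dv
    # counts are defined on the heavy-atom graph: explicit hydrogens would
    # inflate the degree terms in the rotatable-bond definition
    mol = Chem.RemoveHs(rec.mol)
    dv.set("MW", RDDescriptors.MolWt(mol))
    dv.set("HBD", Lipinski.NHOHCount(mol))
    if hba_exclude_donor_heteroatoms:
        hba = sum(
            1
            for a in mol.GetAtoms()
            if a.GetAtomicNum() in (7, 8) and a.GetTotalNumHs() == 0
        )
    else:
        hba = Lipinski.NOCount(mol)
    dv.set("HBA", hba)
    dv.set("NRB", rdMolDescriptors.CalcNumRotatableBonds(mol))
    return dv


def estimate_logp(rec: MoleculeRecord) -> float:
    """Crippen atom-contribution estimate of the octanol/water log P."""
    if rec.mol is None:
        raise ValueError(f"record {rec.id} has no structure")
    return float(Crippen.MolLogP(rec.mol))


def crippen_contributions(rec: MoleculeRecord) -> list[float]:
    """Per-atom Crippen logP contributions (sums to :func:`estimate_logp`).

    Hydrogens are made explicit first so every typed atom, including the
    hydrogens the whole-molecule estimate folds in, contributes one term.
    """
    if rec.mol is None:
        raise ValueError(f"record {rec.id} has no structure")
    mol = Chem.AddHs(rec.mol)
    return [c[0] for c in rdMolDescriptors._CalcCrippenContribs(mol)]


# ---------------------------------------------------------------------------
# geometry: SASA, volume, globularity
# ---------------------------------------------------------------------------

def fibonacci_sphere(n: int) -> np.ndarray:
    """Deterministic quasi-uniform unit-sphere point set (n, 3)."""
    i = np.arange(n, dtype=float)
    phi = math.pi * (3.0 - math.sqrt(5.0)) * i  # golden-angle spiral
    z = 1.0 - (2.0 * i + 1.0) / n
    r = np.sqrt(np.maximum(0.0, 1.0 - z * z))
    return np.column_stack([r * np.cos(phi), r * np.sin(phi), z])


def hydrophobic_atom_mask(mol: Chem.Mol, hydrophobic_elements: set[str] | None = None) -> np.ndarray:
    """Boolean mask over atoms: saturated C, H attached to such C, halogens."""
    extra = _HALOGENS if hydrophobic_elements is None else hydrophobic_elements
    n = mol.GetNumAtoms()
    mask = np.zeros(n, dtype=bool)
    saturated_c = set()
    for atom in mol.GetAtoms():
        if atom.GetSymbol() == "C" and all(
            b.GetBondType() == Chem.BondType.SINGLE for b in atom.GetBonds()
        ):
            saturated_c.add(atom.GetIdx())
            mask[atom.GetIdx()] = True
        elif atom.GetSymbol() in extra:
            mask[atom.GetIdx()] = True
    for atom in mol.GetAtoms():
        if atom.GetSymbol() == "H":
            nbrs = atom.GetNeighbors()
            if nbrs and nbrs[0].GetIdx() in saturated_c:
                mask[atom.GetIdx()] = True
    return mask


def _coords_and_radii(rec: MoleculeRecord) -> tuple[np.ndarray, np.ndarray, Chem.Mol]:
    if rec.mol is None or rec.mol.GetNumConformers() == 0:
        raise ValueError(f"record {rec.id} has no 3D coordinates")
    mol = rec.mol
    conf = mol.GetConformer()
    coords = np.array(conf.GetPositions(), dtype=float)
    radii = np.array([vdw_radius(a.GetSymbol()) for a in mol.GetAtoms()])
    return coords, radii, mol


def shrake_rupley_areas(
    coords: np.ndarray,
    radii: np.ndarray,
    probe_radius: float = DEFAULT_PROBE_RADIUS,
    n_points: int = DEFAULT_SASA_POINTS,
) -> np.ndarray:
    """Per-atom solvent-accessible areas (A^2) by deterministic sphere sampling.

    Each atom's vdW sphere is inflated by the probe radius and sampled with a
    fixed Fibonacci point set; a point is accessible if it lies outside every
    other inflated sphere.  Exactly coincident duplicate atoms are tolerated
    (the duplicate contributes zero area).
    """
    coords = np.asarray(coords, dtype=float)
    radii = np.asarray(radii, dtype=float) + probe_radius
    n_atoms = len(coords)
    unit = fibonacci_sphere(n_points)
    areas = np.zeros(n_atoms)
    for i in range(n_atoms):
        pts = coords[i] + radii[i] * unit
        buried = np.zeros(n_points, dtype=bool)
        for j in range(n_atoms):
            if j == i:
                continue
            if np.allclose(coords[j], coords[i]) and radii[j] >= radii[i] and j < i:
                buried[:] = True  # exact duplicate: later copy owns no area
                break
            d2 = np.sum((pts - coords[j]) ** 2, axis=1)
            # small margin keeps exactly-touching surfaces accessible despite
            # floating-point jitter in the reconstructed distances
            buried |= d2 < radii[j] ** 2 - 1e-9
        areas[i] = 4.0 * math.pi * radii[i] ** 2 * (n_points - buried.sum()) / n_points
    return areas


def compute_sasa(
    rec: MoleculeRecord,
    probe_radius: float = DEFAULT_PROBE_RADIUS,
    n_points: int = DEFAULT_SASA_POINTS,
    hydrophobic_elements: set[str] | None = None,
) -> tuple[float, float]:
    """Total SASA and its hydrophobic component, both in A^2."""
    coords, radii, mol = _coords_and_radii(rec)
    areas = shrake_rupley_areas(coords, radii, probe_radius, n_points)
    mask = hydrophobic_atom_mask(mol, hydrophobic_elements)
    return float(areas.sum()), float(areas[mask].sum())


def compute_volume(
    rec: MoleculeRecord,
    probe_radius: float = DEFAULT_PROBE_RADIUS,
    resolution: float = DEFAULT_GRID_RESOLUTION,
) -> float:
    """Volume (A^3) of the union of probe-inflated atomic spheres, by grid count."""
    coords, radii, _ = _coords_and_radii(rec)
    return sphere_union_volume(coords, radii + probe_radius, resolution)


def sphere_union_volume(coords: np.ndarray, radii: np.ndarray, resolution: float) -> float:
    """Grid estimate of the volume of a union of spheres; converges as the
    grid spacing shrinks."""
    if resolution <= 0:
        raise ValueError("resolution must be positive")
    coords = np.asarray(coords, dtype=float)
    radii = np.asarray(radii, dtype=float)
    lo = (coords - radii[:, None]).min(axis=0) - resolution
    hi = (coords + radii[:, None]).max(axis=0) + resolution
    axes = [np.arange(lo[k] + resolution / 2, hi[k], resolution) for k in range(3)]
    gx, gy, gz = np.meshgrid(*axes, indexing="ij")
    pts = np.column_stack([gx.ravel(), gy.ravel(), gz.ravel()])
    inside = np.zeros(len(pts), dtype=bool)
    for c, r in zip(coords, radii):
        inside |= np.sum((pts - c) ** 2, axis=1) < r * r
    return float(inside.sum()) * resolution**3


def globularity(s_mol: float, v_mol: float) -> float:
    """Glob = 4*pi*r^2 / S_mol with r the radius of the equal-volume sphere."""
    if s_mol <= 0 or v_mol <= 0:
        raise ValueError("globularity requires positive surface and volume")
    r = (3.0 * v_mol / (4.0 * math.pi)) ** (1.0 / 3.0)
    return 4.0 * math.pi * r * r / s_mol


def cohesion_index(
    hba: float,
    hbd: float,
    s_mol: float,
    formula: Callable[[float, float, float], float] | None = None,
) -> float:
    """Solid-cohesion index from H-bond counts and SASA.

    Default form ``HBA*sqrt(HBD)/S_mol`` (0 when HBD = 0); an alternative
    callable ``formula(hba, hbd, s_mol)`` may be supplied.
    """
    if s_mol <= 0:
        raise ValueError("cohesion index requires positive surface area")
    if hba < 0 or hbd < 0:
        raise ValueError("H-bond counts must be non-negative")
    if formula is not None:
        return float(formula(hba, hbd, s_mol))
    return hba * math.sqrt(hbd) / s_mol


# ---------------------------------------------------------------------------
# batch driver
# ---------------------------------------------------------------------------

def compute_descriptors(
    records: Iterable[MoleculeRecord],
    *,
    geometry: bool = True,
    probe_radius: float = DEFAULT_PROBE_RADIUS,
    n_points: int = DEFAULT_SASA_POINTS,
    resolution: float = DEFAULT_GRID_RESOLUTION,
) -> DescriptorTable:
    """Compute all open-surrogate descriptors for a list of records.

    Geometric descriptors are filled only for records with 3D coordinates;
    everything a record cannot support is left missing.
    """
    import pandas as pd

    rows: dict[str, dict[str, float]] = {}
    for rec in records:
        dv = compute_constitutional(rec)
        if rec.has_structure:
            dv.set("logP", estimate_logp(rec))
        if geometry and rec.has_coordinates:
            s_mol, s_hfob = compute_sasa(rec, probe_radius, n_points)
            v_mol = compute_volume(rec, probe_radius, resolution)
            dv.set("S_mol", s_mol)
            dv.set("S_mol_hfob", s_hfob)
            dv.set("V_mol", v_mol)
            if s_mol > 0 and v_mol > 0:
                dv.set("Glob", globularity(s_mol, v_mol))
            if s_mol > 0:
                dv.set("Ind_coh", cohesion_index(dv.values["HBA"], dv.values["HBD"], s_mol))
        rows[rec.id] = dict(dv.values)
    names: list[str] = []
    for row in rows.values():
        for k in row:
            if k not in names:
                names.append(k)
    data = pd.DataFrame.from_dict(rows, orient="index", columns=names, dtype=float)
    data = data.reindex(list(rows))  # structureless records stay as missing rows
    data.index.name = "id"
    return DescriptorTable(data, {n: "computed" for n in names})
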