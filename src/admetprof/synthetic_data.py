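"""Synthetic descriptor tables and a toy molecule library with known truth.

Two generators make every pipeline stage testable without external data:

* :func:`generate_descriptor_table` builds a per-compound descriptor table
  from a :class:`SyntheticSpec`.  Each descriptor marginal is either
  *planted* (an exact in-range fraction: ``round(f * n)`` scored rows receive
  in-range values, the rest out-of-range values, assignment shuffled by the
  seed) or *distributional* (Gaussian around a stated mean; the dispersion
  may be given directly or solved so that the expected in-range mass hits a
  target fraction, falling back to a truncated-Gaussian mixture when no pure
  Gaussian at that mean can reach the target).  Ground-truth in-range flags,
  expected star counts and expected filter memberships are returned alongside
  and are computed by the generator's own arithmetic, independently of the
  compliance module.

* :func:`toy_library` returns 13 small real molecules (water, ethanol,
  benzene, hexane, a di-amide, ...) whose constitutional descriptors were
  derived by hand and frozen in :data:`TOY_FIXTURES`.  Helpers build bare
  single- and two-atom records whose solvent-accessible surface and volume
  have closed-form values.

:func:`study_spec` encodes the profiled natural-product library's study
conditions: 3,179 compounds of which 67 carry no descriptors, marginal means
at the published library averages, and in-range fractions at the published
per-descriptor compliance percentages.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from rdkit import Chem
from rdkit.Chem import AllChem
from rdkit.Geometry import Point3D
from scipy import optimize, stats

from .chem_io import DescriptorTable, MoleculeRecord
from .compliance import DescriptorRange, RangeRegistry

# ---------------------------------------------------------------------------
# toy library
# ---------------------------------------------------------------------------

TOY_SMILES: dict[str, str] = {
    "water": "O",
    "methane": "C",
    "ethane": "CC",
    "hexane": "CCCCCC",
    "benzene": "c1ccccc1",
    "toluene": "Cc1ccccc1",
    "phenol": "Oc1ccccc1",
    "ethanol": "CCO",
    "diethyl_ether": "CCOCC",
    "acetic_acid": "CC(=O)O",
    "acetamide": "CC(N)=O",
    "n_methylacetamide": "CC(=O)NC",
    "malonamide": "NC(=O)CC(N)=O",
}

#: Hand-derived constitutional descriptor values for the toy library.
#: MW from standard atomic masses; HBD = N-H/O-H hydrogens; HBA = N+O count;
#: NRB = acyclic single bonds between heavy atoms of degree >= 2, amide C-N
#: excluded.  A fixture may omit keys that are not hand-checkable.
TOY_FIXTURES: dict[str, dict[str, float]] = {
    "water": {"MW": 18.02, "HBD": 2, "HBA": 1, "NRB": 0},
    "methane": {"MW": 16.04, "HBD": 0, "HBA": 0, "NRB": 0},
    "ethane": {"MW": 30.07, "HBD": 0, "HBA": 0, "NRB": 0},
    "hexane": {"MW": 86.18, "HBD": 0, "HBA": 0, "NRB": 3},
    "benzene": {"MW": 78.11, "HBD": 0, "HBA": 0, "NRB": 0},
    "toluene": {"MW": 92.14, "HBD": 0, "HBA": 0, "NRB": 0},
    "phenol": {"MW": 94.11, "HBD": 1, "HBA": 1, "NRB": 0},
    "ethanol": {"MW": 46.07, "HBD": 1, "HBA": 1, "NRB": 0},
    "diethyl_ether": {"MW": 74.12, "HBD": 0, "HBA": 1, "NRB": 2},
    "acetic_acid": {"MW": 60.05, "HBD": 1, "HBA": 2, "NRB": 0},
    "acetamide": {"MW": 59.07, "HBD": 2, "HBA": 2, "NRB": 0},
    "n_methylacetamide": {"MW": 73.09, "HBD": 1, "HBA": 2, "NRB": 0},
    "malonamide": {"MW": 102.09, "HBD": 4, "HBA": 4, "NRB": 2},
}


def toy_library(embed_3d: bool = False, seed: int = 2013) -> list[MoleculeRecord]:
    """The fixed toy library; with ``embed_3d`` each molecule gets explicit
    hydrogens and a deterministic 3D conformer."""
    records = []
    for name, smi in TOY_SMILES.items():
        mol = Chem.MolFromSmiles(smi)
        if embed_3d:
            mol = Chem.AddHs(mol)
            AllChem.EmbedMolecule(mol, randomSeed=seed)
        records.append(MoleculeRecord(id=name, mol=mol, tags={}))
    return records


def _bare_record(cid: str, elements: Sequence[str], coords: Sequence[Sequence[float]]) -> MoleculeRecord:
    rw = Chem.RWMol()
    for el in elements:
        atom = Chem.Atom(el)
        atom.SetNoImplicit(True)
        rw.AddAtom(atom)
    mol = rw.GetMol()
    conf = Chem.Conformer(len(elements))
    for i, (x, y, z) in enumerate(coords):
        conf.SetAtomPosition(i, Point3D(float(x), float(y), float(z)))
    mol.AddConformer(conf)
    return MoleculeRecord(id=cid, mol=mol, tags={})


def single_atom_record(element: str = "C") -> MoleculeRecord:
    """A lone atom at the origin: SASA/volume have closed-form sphere values."""
    return _bare_record(f"atom_{element}", [element], [(0.0, 0.0, 0.0)])


def two_atom_record(element_a: str = "C", element_b: str = "C", distance: float = 10.0) -> MoleculeRecord:
    """Two unbonded atoms a fixed distance apart along x."""
    return _bare_record(
        f"pair_{element_a}{element_b}_{distance:g}",
        [element_a, element_b],
        [(0.0, 0.0, 0.0), (float(distance), 0.0, 0.0)],
    )


# ---------------------------------------------------------------------------
# synthetic descriptor tables
# ---------------------------------------------------------------------------

@dataclass
class SyntheticSpec:
    """Recipe for a synthetic descriptor table.

    ``marginals`` maps a canonical descriptor name to one of
    ``{"planted": f}`` (exact in-range fraction f),
    ``{"mean": m, "sigma": s}`` (plain Gaussian) or
    ``{"mean": m, "in_range": p}`` (Gaussian with dispersion solved for the
    target in-range mass, mixture fallback).  ``n_unscored`` rows are left
    entirely empty, emulating compounds a descriptor engine failed on.
    """

    n: int
    marginals: dict[str, Mapping[str, float]]
    seed: int = 0
    n_unscored: int = 0

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("n must be >= 1")
        if not 0 <= self.n_unscored <= self.n:
            raise ValueError("n_unscored must be in [0, n]")
        for name, spec in self.marginals.items():
            f = spec.get("planted")
            if f is not None and not 0.0 <= f <= 1.0:
                raise ValueError(f"{name}: planted fraction {f} outside [0, 1]")


@dataclass
class GroundTruth:
    """Construction-time truth for a generated table."""

    in_range: pd.DataFrame          # bool per (scored row, descriptor)
    expected_stars: pd.Series       # float (NaN for unscored rows)
    expected_filters: pd.DataFrame  # object: True/False/NA per published rule
    unscored_ids: list[str]
    meta: dict = field(default_factory=dict)


def _representative_values(rng_def: DescriptorRange) -> tuple[float, float, float]:
    """(in-range value, below-range value, above-range value); NaN where a
    side is unbounded."""
    lo, hi = rng_def.low, rng_def.high
    if math.isfinite(lo) and math.isfinite(hi):
        inside = 0.5 * (lo + hi)
        width = max(hi - lo, 1.0)
        below = lo - 0.5 * width
        above = hi + 0.5 * width
    elif math.isfinite(lo):
        inside, below, above = lo + 1.0, lo - 1.0, math.nan
    elif math.isfinite(hi):
        inside, below, above = hi - 1.0, math.nan, hi + 1.0
    else:
        raise ValueError(f"{rng_def.name}: cannot plant against an unbounded range")
    return inside, below, above


def _value_in_range(value: float, rng_def: DescriptorRange) -> bool:
    lo_ok = value > rng_def.low if rng_def.low_open else value >= rng_def.low
    hi_ok = value < rng_def.high if rng_def.high_open else value <= rng_def.high
    return lo_ok and hi_ok


def _solve_sigma(mean: float, target: float, rng_def: DescriptorRange) -> float | None:
    """Dispersion of a Gaussian at ``mean`` whose in-range mass equals
    ``target``, or None when unreachable."""
    lo, hi = rng_def.low, rng_def.high

    def mass(sigma: float) -> float:
        return float(stats.norm.cdf(hi, mean, sigma) - stats.norm.cdf(lo, mean, sigma))

    width = (hi - lo) if math.isfinite(hi - lo) else abs(mean) + 10.0
    sig_lo, sig_hi = 1e-9 * max(1.0, abs(mean)), 1e4 * max(width, 1.0)
    f_lo, f_hi = mass(sig_lo) - target, mass(sig_hi) - target
    if f_lo * f_hi > 0:
        return None
    return float(optimize.brentq(lambda s: mass(s) - target, sig_lo, sig_hi, xtol=1e-12))


def _sample_marginal(
    name: str,
    spec: Mapping[str, float],
    n: int,
    rng_def: DescriptorRange | None,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray | None]:
    """Values plus, in planted mode, the exact in-range mask (else None)."""
    if "planted" in spec:
        if rng_def is None:
            raise ValueError(f"{name}: planted marginal needs a registered range")
        f = float(spec["planted"])
        k_in = int(round(f * n))
        inside, below, above = _representative_values(rng_def)
        sides = [v for v in (below, above) if math.isfinite(v)]
        out_vals = rng.choice(sides, size=n - k_in)
        values = np.concatenate([np.full(k_in, inside), out_vals])
        mask = np.concatenate([np.ones(k_in, bool), np.zeros(n - k_in, bool)])
        perm = rng.permutation(n)
        return values[perm], mask[perm]
    mean = float(spec["mean"])
    if "sigma" in spec:
        values = rng.normal(mean, float(spec["sigma"]), size=n)
    else:
        target = float(spec["in_range"])
        if rng_def is None:
            raise ValueError(f"{name}: in_range target needs a registered range")
        sigma = _solve_sigma(mean, target, rng_def)
        if sigma is not None:
            values = rng.normal(mean, sigma, size=n)
        else:
            # mean sits outside (or too far from) the range for any pure
            # Gaussian: mix truncated Gaussians inside/outside the range
            values = _mixture_sample(mean, target, rng_def, n, rng)
    if spec.get("min") is not None:
        values = np.maximum(values, float(spec["min"]))
    return values, None


def _truncnorm(mean: float, sigma: float, lo: float, hi: float, size: int,
               rng: np.random.Generator) -> np.ndarray:
    a, b = (lo - mean) / sigma, (hi - mean) / sigma
    return stats.truncnorm.rvs(a, b, loc=mean, scale=sigma, size=size, random_state=rng)


def _mixture_sample(mean: float, target: float, rng_def: DescriptorRange, n: int,
                    rng: np.random.Generator) -> np.ndarray:
    lo, hi = rng_def.low, rng_def.high
    width = (hi - lo) if math.isfinite(hi - lo) else 2.0
    sigma = max(width / 4.0, 1e-6)
    inside_mask = rng.random(n) < target
    values = np.empty(n)
    n_in = int(inside_mask.sum())
    if n_in:
        c_lo = lo if math.isfinite(lo) else mean - 10 * sigma
        c_hi = hi if math.isfinite(hi) else mean + 10 * sigma
        values[inside_mask] = _truncnorm((c_lo + c_hi) / 2, sigma, c_lo, c_hi, n_in, rng)
    n_out = n - n_in
    if n_out:
        # place outside mass on the side of the stated mean
        if math.isfinite(hi) and mean > hi:
            values[~inside_mask] = _truncnorm(mean, abs(mean - hi) + sigma, hi + 1e-9, np.inf, n_out, rng)
        elif math.isfinite(lo) and mean < lo:
            values[~inside_mask] = _truncnorm(mean, abs(mean - lo) + sigma, -np.inf, lo - 1e-9, n_out, rng)
        else:
            values[~inside_mask] = _truncnorm(mean, sigma, hi + 1e-9, np.inf, n_out, rng)
    return values


#: published clause constants, re-stated here so the generator's filter truth
#: is computed independently of the compliance module
_TRUTH_FILTERS = {
    "druglike": lambda r: r["MW"] < 500 and r["logP"] < 5 and r["HBD"] <= 5 and r["HBA"] <= 10,
    "leadlike": lambda r: 150 <= r["MW"] <= 350 and r["logP"] <= 4 and r["HBD"] <= 3 and r["HBA"] <= 6,
    "fragmentlike": lambda r: (
        r["MW"] <= 250 and -2 <= r["logP"] <= 3 and r["HBD"] < 3 and r["HBA"] < 6 and r["NRB"] < 3
    ),
    "ro3": lambda r: r["logS_wat"] > -5.7 and r["BIP_caco2"] > 22 and r["metab"] < 7,
}

_FILTER_NEEDS = {
    "druglike": ("MW", "logP", "HBD", "HBA"),
    "leadlike": ("MW", "logP", "HBD", "HBA"),
    "fragmentlike": ("MW", "logP", "HBD", "HBA", "NRB"),
    "ro3": ("logS_wat", "BIP_caco2", "metab"),
}


def generate_descriptor_table(
    spec: SyntheticSpec,
    registry: RangeRegistry | None = None,
) -> tuple[DescriptorTable, GroundTruth]:
    """Generate a descriptor table plus construction-time ground truth.

    Deterministic under a fixed seed.  Expected star counts consider only
    generated descriptors that are in the registry's star set; unscored rows
    (all values missing) carry NaN expected stars.
    """
    if registry is None:
        registry = RangeRegistry.default()
    extra_ok = {"CNS", "percent_oral_absorption", "qualitative_oral_absorption", "J_m", "stars"}
    for name in spec.marginals:
        if name not in registry and name not in extra_ok:
            raise ValueError(f"unknown descriptor in spec: {name!r}")
    rng = np.random.default_rng(spec.seed)
    n_scored = spec.n - spec.n_unscored
    ids = [f"cmpd{i + 1:05d}" for i in range(spec.n)]
    unscored_ids = sorted(rng.choice(spec.n, size=spec.n_unscored, replace=False).tolist())
    unscored = [ids[i] for i in unscored_ids]
    scored = [i for i in ids if i not in set(unscored)]

    values: dict[str, np.ndarray] = {}
    flags: dict[str, np.ndarray] = {}
    for name in spec.marginals:
        rng_def = registry[name] if name in registry else None
        vals, mask = _sample_marginal(name, spec.marginals[name], n_scored, rng_def, rng)
        values[name] = vals
        if mask is None:
            if rng_def is not None:
                mask = np.array([_value_in_range(v, rng_def) for v in vals])
            else:
                mask = np.ones(n_scored, bool)
        flags[name] = mask

    data = pd.DataFrame(values, index=pd.Index(scored, name="id"))
    data = data.reindex(ids)  # unscored rows -> all NaN
    table = DescriptorTable(data, {n: "imported" for n in spec.marginals})

    in_range_df = pd.DataFrame(flags, index=pd.Index(scored, name="id"))
    star_names = [n for n in spec.marginals if n in set(registry.star_set)]
    stars_scored = (~in_range_df[star_names]).sum(axis=1) if star_names else pd.Series(0, index=scored)
    expected_stars = stars_scored.astype(float).reindex(ids)

    filt_truth = {}
    for fname, needs in _FILTER_NEEDS.items():
        if all(d in spec.marginals for d in needs):
            col = [
                _TRUTH_FILTERS[fname]({d: data.at[i, d] for d in needs}) if i in set(scored) else pd.NA
                for i in ids
            ]
            filt_truth[fname] = col
    expected_filters = pd.DataFrame(filt_truth, index=pd.Index(ids, name="id"), dtype=object)

    truth = GroundTruth(
        in_range=in_range_df,
        expected_stars=expected_stars,
        expected_filters=expected_filters,
        unscored_ids=unscored,
        meta={"seed": spec.seed, "n": spec.n, "n_unscored": spec.n_unscored},
    )
    return table, truth


def study_spec(seed: int = 0) -> SyntheticSpec:
    """Study-condition recipe: 3,179 compounds (67 unscored), marginal means
    at the published library averages and in-range masses at the published
    per-descriptor compliance percentages; descriptors without a published
    compliance figure get a plain Gaussian with a realistic dispersion."""
    marginals: dict[str, Mapping[str, float]] = {
        "MW": {"mean": 421.72, "sigma": 150.0, "min": 16.0},
        "logP": {"mean": 3.86, "sigma": 1.8},
        "HBA": {"mean": 6.54, "sigma": 2.5, "min": 0.0},
        "HBD": {"mean": 2.03, "sigma": 1.5, "min": 0.0},
        "NRB": {"mean": 7.46, "sigma": 4.0, "min": 0.0},
        "logB_B": {"mean": -1.23, "in_range": 0.8853},
        "BIP_caco2": {"mean": 1322.58, "in_range": 0.3728},
        "S_mol": {"mean": 696.98, "in_range": 0.9036},
        "S_mol_hfob": {"mean": 420.94, "in_range": 0.9132},
        "V_mol": {"mean": 1314.78, "in_range": 0.9103},
        "logS_wat": {"mean": -5.16, "in_range": 0.7246},
        "logK_HSA": {"mean": 0.52, "in_range": 0.8101},
        "MDCK": {"mean": 765.31, "in_range": 0.4714},
        "Ind_coh": {"mean": 0.013, "in_range": 0.9492},
        "Glob": {"mean": 0.84, "in_range": 0.8988},
        "QP_polrz": {"mean": 42.99, "sigma": 15.0, "min": 1.0},
        "logHERG": {"mean": -4.60, "in_range": 0.5835},
        "logK_p": {"mean": -2.99, "in_range": 0.9209},
        "metab": {"mean": 5.53, "in_range": 0.8152, "min": 0.0},
    }
    return SyntheticSpec(n=3179, marginals=marginals, seed=seed, n_unscored=67)
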