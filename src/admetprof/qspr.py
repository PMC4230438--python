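"""Closed-form predictive layers on top of imported/computed descriptors.

Three small models:

* :func:`similarity_adjusted_prediction` — a model prediction is blended
  toward the experimental value of the query's most similar training-set
  analogue once the similarity S reaches a threshold (default 0.9):
  ``P = S*P_exp + (1-S)*P_model``, so S = 1 returns the experimental value
  exactly and S below the threshold returns the raw model value.
* :func:`potts_guy_logkp` — the Potts-Guy QSPR for skin permeability,
  ``log Kp = 0.71 logP - 0.0061 MW - 6.3`` (Kp in cm/s; the cm/hr scale adds
  log10(3600)).
* :func:`transdermal_rate` — maximum steady-state transdermal flux
  ``J_m = Kp * C_sat`` with the saturated aqueous concentration
  ``C_sat = S_wat * MW * 1000`` in ug/cm^3, giving J_m in ug cm^-2 hr^-1 for
  Kp in cm/hr.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Sequence

from rdkit import Chem, DataStructs

from .chem_io import MoleculeRecord

#: Potts-Guy (1992) coefficients: logP weight, MW weight, intercept (cm/s).
POTTS_GUY_LOGP_COEF = 0.71
POTTS_GUY_MW_COEF = -0.0061
POTTS_GUY_INTERCEPT_CM_S = -6.3
_LOG10_S_PER_HR = math.log10(3600.0)


@dataclass
class TrainingSetEntry:
    """One experimental training-set compound for similarity adjustment."""

    id: str
    mol: Chem.Mol | None
    P_exp: float
    P_model: float | None = None

    def __post_init__(self) -> None:
        if not math.isfinite(self.P_exp):
            raise ValueError(f"training entry {self.id}: P_exp must be finite")


def tanimoto_similarity(a: Chem.Mol | MoleculeRecord, b: Chem.Mol | MoleculeRecord) -> float:
    """Tanimoto coefficient on hashed-substructure (RDKit path) fingerprints."""
    ma = a.mol if isinstance(a, MoleculeRecord) else a
    mb = b.mol if isinstance(b, MoleculeRecord) else b
    if ma is None or mb is None:
        raise ValueError("both molecules need structures for similarity")
    fa, fb = Chem.RDKFingerprint(ma), Chem.RDKFingerprint(mb)
    return float(DataStructs.TanimotoSimilarity(fa, fb))


def similarity_adjusted_prediction(
    P_model: float,
    query: MoleculeRecord | Chem.Mol,
    training_set: Sequence[TrainingSetEntry],
    similarity_fn: Callable[[object, object], float] = tanimoto_similarity,
    threshold: float = 0.9,
) -> float:
    """Blend a model prediction toward the nearest analogue's experimental value.

    Let S be the maximum similarity between the query and any training-set
    entry (ties broken by input order).  Below ``threshold`` the model value
    is returned unchanged; otherwise ``S*P_exp + (1-S)*P_model``, which equals
    P_exp exactly at S = 1.
    """
    if not training_set:
        raise ValueError("training set is empty")
    best_s = -1.0
    best_entry = training_set[0]
    for entry in training_set:
        s = float(similarity_fn(query, entry.mol))
        if not 0.0 <= s <= 1.0:
            raise ValueError(f"similarity {s} outside [0, 1]")
        if s > best_s:
            best_s, best_entry = s, entry
    if best_s < threshold:
        return float(P_model)
    return best_s * best_entry.P_exp + (1.0 - best_s) * float(P_model)


def potts_guy_logkp(logp: float, mw: float, scale: str = "cm_s") -> float:
    """Potts-Guy skin permeability, log Kp.

    ``scale='cm_s'`` returns the original cm/s value (intercept -6.3);
    ``scale='cm_hr'`` shifts by log10(3600) onto the cm/hr scale used by the
    -8..-1 compliance range.
    """
    if mw <= 0:
        raise ValueError("MW must be positive")
    logkp = POTTS_GUY_LOGP_COEF * logp + POTTS_GUY_MW_COEF * mw + POTTS_GUY_INTERCEPT_CM_S
    if scale == "cm_s":
        return logkp
    if scale == "cm_hr":
        return logkp + _LOG10_S_PER_HR
    raise ValueError(f"unknown scale {scale!r}")


def transdermal_rate(kp_cm_hr: float, s_wat_mol_l: float, mw: float) -> float:
    """Maximum transdermal transport rate J_m in ug cm^-2 hr^-1.

    ``J_m = Kp * C_sat`` with ``C_sat = S_wat * MW * 1000`` converting the
    saturated aqueous solubility from mol/L to ug/cm^3.  Zero iff Kp or S_wat
    is zero.
    """
    if kp_cm_hr < 0 or s_wat_mol_l < 0:
        raise ValueError("Kp and S_wat must be non-negative")
    if mw <= 0:
        raise ValueError("MW must be positive")
    return kp_cm_hr * (s_wat_mol_l * mw * 1000.0)
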