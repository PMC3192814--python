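"""Open-source polarity and solubility descriptors from SMILES.

The panel mirrors the descriptor families used in QSAR-style studies of
metabolite chemistry: a Crippen-type octanol/water partition coefficient
(logP), an ESOL-style aqueous solubility estimate (logS), the
charged-partial-surface-area (CPSA) family built from Gasteiger partial
charges and per-atom Labute accessible surface areas, and a handful of
substructure counts. Everything is computed from the 2D structure only —
no conformer generation — so every descriptor is deterministic.

CPSA definitions (charge-weighted variant):

* ``PPSA3 = sum(q_i * SA_i)`` over atoms with positive partial charge
* ``PNSA3 = sum(q_i * SA_i)`` over atoms with negative partial charge
* ``FPSA3 = PPSA3 / TMSA`` and ``FNSA3 = PNSA3 / TMSA`` where
  ``TMSA = sum(SA_i)`` is the total molecular surface area
* ``RPCG  = max(q_i > 0) / sum(q_i > 0)`` — relative positive charge;
  undefined (NaN) when no atom carries positive partial charge.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, NamedTuple, Sequence

import numpy as np
import pandas as pd
from rdkit import Chem
from rdkit.Chem import AllChem, Crippen, Descriptors, rdMolDescriptors

__all__ = [
    "DescriptorPanel",
    "StructureError",
    "PANEL_COLUMNS",
    "compute_logp",
    "compute_cpsa",
    "estimate_logs",
    "count_features",
    "compute_panel",
    "build_panel",
    "read_smiles_table",
    "write_panel_table",
    "cpsa_from_charges_areas",
]


class StructureError(ValueError):
    """SMILES could not be parsed or charges could not be assigned."""


class CpsaResult(NamedTuple):
    ppsa3: float
    pnsa3: float
    fpsa3: float
    fnsa3: float
    rpcg: float  # NaN when no positive partial charge exists


@dataclass(frozen=True)
class DescriptorPanel:
    """Per-metabolite descriptor vector."""

    id: str
    logp: float
    logs: float
    ppsa3: float
    pnsa3: float
    fpsa3: float
    fnsa3: float
    rpcg: float
    hbd_count: int
    n_count: int
    amide_count: int
    ring6_count: int
    hydrophobe_count: int
    lscore: float


PANEL_COLUMNS = [
    "id",
    "logp",
    "logs",
    "ppsa3",
    "pnsa3",
    "fpsa3",
    "fnsa3",
    "rpcg",
    "hbd_count",
    "n_count",
    "amide_count",
    "ring6_count",
    "hydrophobe_count",
    "lscore",
]

# Declared SMARTS. "Hydrophobe" = carbon bonded only to carbon/hydrogen
# (aromatic or aliphatic) or halogen; amide = N-C(=O).
_AMIDE = Chem.MolFromSmarts("[NX3][CX3](=[OX1])")
_HYDROPHOBE = Chem.MolFromSmarts("[$([#6;!$([#6]~[!#6;!#1])]),$([F,Cl,Br,I])]")

# ESOL coefficients (Delaney-type linear solubility model):
# logS = 0.16 - 0.63 logP - 0.0062 MW + 0.066 RB - 0.74 AP
ESOL_INTERCEPT = 0.16
ESOL_COEFFS = {"logp": -0.63, "mw": -0.0062, "rotatable_bonds": 0.066, "aromatic_proportion": -0.74}


def _mol_from_smiles(smiles: str) -> Chem.Mol:
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise StructureError(f"unparseable SMILES: {smiles!r}")
    return mol


def compute_logp(smiles: str) -> float:
    """Wildman–Crippen atomic-contribution octanol/water logP."""
    return float(Crippen.MolLogP(_mol_from_smiles(smiles)))


def cpsa_from_charges_areas(charges: Sequence[float], areas: Sequence[float]) -> CpsaResult:
    """CPSA sums from explicit per-atom charges and surface areas.

    Pure composition of the defining sums; exposed so the arithmetic can be
    checked against hand-evaluated atom sets independently of any molecule.
    """
    q = np.asarray(charges, dtype=float)
    sa = np.asarray(areas, dtype=float)
    if q.shape != sa.shape:
        raise ValueError("charges and areas must have equal length")
    tmsa = float(sa.sum())
    if tmsa <= 0:
        raise ValueError("total molecular surface area must be positive")
    pos = q > 0
    neg = q < 0
    ppsa3 = float((q[pos] * sa[pos]).sum())
    pnsa3 = float((q[neg] * sa[neg]).sum())
    rpcg = float(q[pos].max() / q[pos].sum()) if pos.any() else math.nan
    return CpsaResult(ppsa3, pnsa3, ppsa3 / tmsa, pnsa3 / tmsa, rpcg)


def _charges_and_areas(smiles: str) -> tuple[np.ndarray, np.ndarray]:
    mol = Chem.AddHs(_mol_from_smiles(smiles))
    AllChem.ComputeGasteigerCharges(mol)
    charges = np.array(
        [a.GetDoubleProp("_GasteigerCharge") for a in mol.GetAtoms()], dtype=float
    )
    if not np.isfinite(charges).all():
        raise StructureError(f"Gasteiger charge assignment failed for {smiles!r}")
    contribs, _ = rdMolDescriptors._CalcLabuteASAContribs(mol, includeHs=True)
    areas = np.array(list(contribs), dtype=float)
    return charges, areas


def compute_cpsa(smiles: str) -> CpsaResult:
    """Charge-weighted CPSA descriptors from Gasteiger charges and per-atom
    Labute accessible surface areas (hydrogens explicit)."""
    charges, areas = _charges_and_areas(smiles)
    return cpsa_from_charges_areas(charges, areas)


def estimate_logs(
    smiles: str | None = None,
    *,
    logp: float | None = None,
    mw: float | None = None,
    rotatable_bonds: float | None = None,
    aromatic_proportion: float | None = None,
) -> float:
    """ESOL-style log10 aqueous solubility (mol/L).

    Either pass a SMILES (inputs computed here) or the four model inputs
    explicitly — the latter lets the linear form be checked by hand.
    """
    if smiles is not None:
        mol = _mol_from_smiles(smiles)
        logp = float(Crippen.MolLogP(mol))
        mw = float(Descriptors.MolWt(mol))
        rotatable_bonds = float(rdMolDescriptors.CalcNumRotatableBonds(mol))
        heavy = mol.GetNumHeavyAtoms()
        aromatic = sum(1 for a in mol.GetAtoms() if a.GetIsAromatic())
        aromatic_proportion = aromatic / heavy if heavy else 0.0
    if None in (logp, mw, rotatable_bonds, aromatic_proportion):
        raise ValueError("provide a SMILES or all four model inputs")
    return float(
        ESOL_INTERCEPT
        + ESOL_COEFFS["logp"] * logp
        + ESOL_COEFFS["mw"] * mw
        + ESOL_COEFFS["rotatable_bonds"] * rotatable_bonds
        + ESOL_COEFFS["aromatic_proportion"] * aromatic_proportion
    )


def count_features(smiles: str) -> dict[str, float]:
    """Substructure counts plus the floating-point Lipinski score.

    ``lscore`` accumulates, for each Lipinski bound (MW 500, logP 5, HBD 5,
    HBA 10), the fractional excess over the bound: ``max(0, x/bound - 1)``
    summed over the four properties. Zero for any rule-of-five-compliant
    molecule, continuous beyond it.
    """
    mol = _mol_from_smiles(smiles)
    hbd = rdMolDescriptors.CalcNumHBD(mol)
    hba = rdMolDescriptors.CalcNumHBA(mol)
    mw = Descriptors.MolWt(mol)
    logp = Crippen.MolLogP(mol)
    lscore = sum(
        max(0.0, value / bound - 1.0)
        for value, bound in ((mw, 500.0), (logp, 5.0), (hbd, 5.0), (hba, 10.0))
    )
    ring6 = sum(1 for ring in mol.GetRingInfo().AtomRings() if len(ring) == 6)
    return {
        "hbd_count": int(hbd),
        "n_count": sum(1 for a in mol.GetAtoms() if a.GetAtomicNum() == 7),
        "amide_count": len(mol.GetSubstructMatches(_AMIDE)),
        "ring6_count": int(ring6),
        "hydrophobe_count": len(mol.GetSubstructMatches(_HYDROPHOBE)),
        "lscore": float(lscore),
    }


def compute_panel(met_id: str, smiles: str) -> DescriptorPanel:
    """Full descriptor panel for one metabolite."""
    logp = compute_logp(smiles)
    logs = estimate_logs(smiles)
    cpsa = compute_cpsa(smiles)
    counts = count_features(smiles)
    return DescriptorPanel(
        id=met_id,
        logp=logp,
        logs=logs,
        ppsa3=cpsa.ppsa3,
        pnsa3=cpsa.pnsa3,
        fpsa3=cpsa.fpsa3,
        fnsa3=cpsa.fnsa3,
        rpcg=cpsa.rpcg,
        **counts,
    )


def build_panel(
    smiles_table: Mapping[str, str],
) -> tuple[list[DescriptorPanel], dict[str, str]]:
    """Compute panels for an id -> SMILES table.

    Returns (panels, failures) where ``failures`` maps each failed id to the
    reason; failures are reported, never silently dropped.
    """
    if not smiles_table:
        raise ValueError("empty SMILES table")
    panels: list[DescriptorPanel] = []
    failures: dict[str, str] = {}
    for met_id, smi in smiles_table.items():
        try:
            panels.append(compute_panel(met_id, smi))
        except (StructureError, ValueError) as exc:
            failures[met_id] = str(exc)
    return panels, failures


def read_smiles_table(path: str | Path) -> dict[str, str]:
    """Read a .smi file: one ``id<whitespace>SMILES`` pair per line, or the
    reverse (``SMILES id``) if the first token parses as a molecule.

    Duplicate ids are an error.
    """
    table: dict[str, str] = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) != 2:
                raise ValueError(f"line {lineno}: expected two columns, got {len(parts)}")
            first, second = parts
            if Chem.MolFromSmiles(first) is not None and Chem.MolFromSmiles(second) is None:
                met_id, smi = second, first
            else:
                met_id, smi = first, second
            if met_id in table:
                raise ValueError(f"duplicate metabolite id {met_id!r} (line {lineno})")
            table[met_id] = smi
    return table


def panels_to_frame(panels: Sequence[DescriptorPanel]) -> pd.DataFrame:
    df = pd.DataFrame([vars(p) for p in panels], columns=PANEL_COLUMNS)
    return df


def write_panel_table(panels: Sequence[DescriptorPanel], path: str | Path) -> None:
    """TSV, fixed column order, missing values (undefined RPCG) as NA."""
    panels_to_frame(panels).to_csv(path, sep="\t", index=False, na_rep="NA")
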