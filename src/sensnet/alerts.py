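"""Electrophilic structural alerts for skin sensitization.

Skin sensitization is initiated by haptenation: an electrophilic chemical
covalently modifying skin proteins. Five mechanistic alerts cover the
classic electrophilic reaction domains — Michael-type addition (MA), Schiff
base formation (SB), acylation (AA), nucleophilic aromatic substitution
(SNAr) and second-order nucleophilic aliphatic substitution (SN2) — plus a
summary reactivity-domain (RD) alert that is true whenever any mechanism
alert fires.

The pattern lists below are a small, documented SMARTS rulebase, not a
reimplementation of any external expert system; analyses equally accept
precomputed flags supplied in the chemical table, so authoritative external
alert calls can be substituted without touching this module.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from rdkit import Chem

from .io_model import ALERT_NAMES, AlertFlags, ChemicalRecord
from .network import ModulePartition, UNDEFINED_MODULE

# Each mechanism is a list of SMARTS; the alert fires if any pattern matches.
ALERT_SMARTS: dict[str, tuple[str, ...]] = {
    # Michael acceptors: alpha,beta-unsaturated aldehyde/ketone/ester and
    # propiolate-type alkynes conjugated to a carbonyl
    "ma": (
        "[CX3]=[CX3][CX3]=[OX1]",
        "[CX2]#[CX2][CX3]=[OX1]",
        "[CX3]=[CX3][CX3](=[OX1])[OX2]",
    ),
    # Schiff base formers: aldehydes (incl. formaldehyde) and 1,2-diketones
    "sb": (
        "[CX3H1](=O)[#6]",
        "[CX3H2]=[OX1]",
        "[#6][CX3](=O)[CX3](=O)[#6]",
    ),
    # Acylating agents: acyl halides, anhydrides, sulfonyl halides, isocyanates
    "aa": (
        "[CX3](=[OX1])[F,Cl,Br,I]",
        "[CX3](=[OX1])[OX2][CX3](=[OX1])",
        "[SX4](=[OX1])(=[OX1])[F,Cl,Br,I]",
        "[NX2]=[CX2]=[OX1]",
    ),
    # SNAr: aryl halide activated by an ortho or para nitro group
    "snar": (
        "[F,Cl,Br,I]c1ccccc1[N+](=O)[O-]",
        "[F,Cl,Br,I]c1ccc([N+](=O)[O-])cc1",
    ),
    # SN2: primary/secondary aliphatic halide, sulfonate ester, epoxide
    "sn2": (
        "[CX4;H2,H3][Cl,Br,I]",
        "[CX4;H1]([#6])([#6])[Cl,Br,I]",
        "[CX4][OX2][SX4](=[OX1])(=[OX1])[#6]",
        "[CX4]1[OX2][CX4]1",
    ),
}

#: optional pro-Michael-acceptor pattern (allylic alcohols that become
#: Michael acceptors after oxidation); off by default
PRO_MA_SMARTS = ("[CX3]=[CX3][CX4;H1,H2][OX2H]",)

_COMPILED: dict[str, tuple[Chem.Mol, ...]] | None = None


def _compiled() -> dict[str, tuple[Chem.Mol, ...]]:
    global _COMPILED
    if _COMPILED is None:
        _COMPILED = {
            alert: tuple(Chem.MolFromSmarts(s) for s in patterns)
            for alert, patterns in ALERT_SMARTS.items()
        }
        _COMPILED["pro_ma"] = tuple(Chem.MolFromSmarts(s) for s in PRO_MA_SMARTS)
    return _COMPILED


def compute_alerts(structure: str, *, include_pro_ma: bool = False) -> AlertFlags:
    """Flag the five electrophilic mechanisms on a SMILES structure.

    ``include_pro_ma`` additionally counts allylic (pro-Michael) alcohols
    as MA. Unparsable SMILES raise; flags are never silently defaulted.
    """
    mol = Chem.MolFromSmiles(structure)
    if mol is None:
        raise ValueError(f"unparsable SMILES: {structure!r}")
    patterns = _compiled()
    hits = {alert: any(mol.HasSubstructMatch(p) for p in patterns[alert])
            for alert in ALERT_NAMES}
    if include_pro_ma and not hits["ma"]:
        hits["ma"] = any(mol.HasSubstructMatch(p) for p in patterns["pro_ma"])
    return AlertFlags(**hits).normalized()


def reactivity_domain(flags: AlertFlags) -> bool:
    """RD alert: true if any of the five mechanism alerts is true."""
    return flags.sn2 or flags.ma or flags.sb or flags.aa or flags.snar


def ensure_alert_flags(chems: Sequence[ChemicalRecord], *,
                       include_pro_ma: bool = False) -> None:
    """Fill missing alert flags in place from structures.

    Precomputed flags pass through untouched (they may come from an external
    expert system); chemicals with neither flags nor a structure raise.
    """
    for chem in chems:
        if chem.alert_flags is None:
            if chem.structure is None:
                raise ValueError(
                    f"chemical {chem.id!r} has neither alert flags nor a structure")
            chem.alert_flags = compute_alerts(chem.structure,
                                              include_pro_ma=include_pro_ma)


ALERT_TABLE_COLUMNS = ("SN2", "MA", "SB", "AA", "SNAr", "RD")
_COLUMN_TO_FIELD = {"SN2": "sn2", "MA": "ma", "SB": "sb", "AA": "aa",
                    "SNAr": "snar", "RD": "rd"}


def alert_prevalence(partition: ModulePartition,
                     chems: Sequence[ChemicalRecord]) -> pd.DataFrame:
    """Per-module structural-alert prevalence table.

    One row per module plus an ALL row (all chemicals) and an Undefined row
    (chemicals outside retained modules); columns are percent of module
    members flagged for each alert plus the member Count. Empty modules
    report n/a (NaN) prevalences.
    """
    missing = [c.id for c in chems if c.alert_flags is None]
    if missing:
        raise ValueError(f"chemicals without alert flags: {missing[:5]}")
    by_id = {c.id: c for c in chems}

    def row(members: list[str]) -> dict[str, float]:
        n = len(members)
        out: dict[str, float] = {}
        for col, fname in _COLUMN_TO_FIELD.items():
            if n == 0:
                out[col] = float("nan")
            else:
                flagged = sum(1 for cid in members
                              if by_id[cid].alert_flags.get(fname))
                out[col] = 100.0 * flagged / n
        out["Count"] = n
        return out

    module_rows: dict[str, dict[str, float]] = {}
    all_ids = [c.id for c in chems]
    module_rows["ALL"] = row(all_ids)
    module_rows["Undefined"] = row(
        [cid for cid in all_ids
         if partition.assignment.get(cid, UNDEFINED_MODULE) == UNDEFINED_MODULE])
    for mid in partition.module_ids:
        module_rows[str(mid)] = row([cid for cid in partition.members(mid)
                                     if cid in by_id])
    table = pd.DataFrame.from_dict(module_rows, orient="index")
    table.index.name = "Module"
    table["Count"] = table["Count"].astype(int)
    return table
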