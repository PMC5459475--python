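"""RECAP fragmentation and the activity-adjusted fragment frequency table.

Compounds are cleaved at the eleven retrosynthetically sensible bond types of
the RECAP scheme (amide, ester, amine, urea, ether, olefin, quaternary N,
aromatic N - aliphatic C, lactam N - aliphatic C, biaryl, sulfonamide); the
terminal fragments of each compound are then tallied across the library with
activity weights, yielding an activity-adjusted frequency (AAF) per fragment:

    AAF(f) = 100 * sum_m w(m) * I[f in frags(m)]
                 / sum_f' sum_m w(m) * I[f' in frags(m)]

with weights w = 1 for active, 0.5 for inconclusive and 0 for inactive
compounds, and per-compound 0/1 fragment incidence (multiplicity within one
compound is not counted).  Fragments whose weighted incidence is highest
among actives therefore rank first, which is what makes the table a
chemotype-priority readout rather than a plain frequency count.
"""

from __future__ import annotations

from typing import Sequence

import pandas as pd
from rdkit import Chem
from rdkit.Chem import Recap

from .chemspace import ACTIVE, INACTIVE, INCONCLUSIVE, CompoundLibrary, Molecule
from .errors import DegenerateInputError, InputError

DEFAULT_WEIGHTS = {ACTIVE: 1.0, INCONCLUSIVE: 0.5, INACTIVE: 0.0}


def recap_fragment(mol: Molecule | Chem.Mol) -> list[Chem.Mol]:
    """Terminal RECAP fragments of a molecule.

    Open valences at the cleavage points are capped with attachment-point
    dummy atoms (``*``).  A molecule with no cleavable bond is returned
    unchanged as its own single fragment, and terminal fragments are fixed
    points of the procedure (fragmenting them again returns them).
    """
    rdmol = mol.mol if isinstance(mol, Molecule) else mol
    if rdmol is None or rdmol.GetNumAtoms() == 0:
        raise InputError("cannot fragment an empty molecule")
    tree = Recap.RecapDecompose(rdmol)
    leaves = list(tree.GetLeaves().values())
    if not leaves:
        return [rdmol]
    return [leaf.mol for leaf in leaves]


def fragment_key(frag: Chem.Mol) -> str:
    """Canonical fragment identity with attachment points erased.

    Dummy atoms are replaced by hydrogens before canonicalization so that,
    e.g., an imidazolyl substituent is identified the same way regardless of
    which bond it was cleaved from.
    """
    edit = Chem.RWMol(frag)
    for atom in edit.GetAtoms():
        if atom.GetAtomicNum() == 0:
            atom.SetAtomicNum(1)
    out = edit.GetMol()
    Chem.SanitizeMol(out)
    return Chem.MolToSmiles(Chem.RemoveHs(out))


def activity_adjusted_frequency(library: CompoundLibrary,
                                weights: dict | None = None) -> pd.DataFrame:
    """Fragment table sorted by descending activity-adjusted frequency.

    Columns: ``fragment`` (canonical form), ``n_compounds`` (compounds
    containing it), ``n_active``, ``aaf_percent``.  The AAF column sums to
    100% over all fragments.  A library whose total activity weight is zero
    (e.g. all compounds inactive) has no defined table and raises.
    """
    w = dict(DEFAULT_WEIGHTS if weights is None else weights)
    rows: dict[str, dict] = {}
    total_weight = 0.0
    for molecule in library.molecules:
        label = molecule.label
        weight = w.get(label, 0.0)
        frag_keys = {fragment_key(f) for f in recap_fragment(molecule)}
        for key in frag_keys:
            rec = rows.setdefault(key, {"n_compounds": 0, "n_active": 0,
                                        "weighted": 0.0})
            rec["n_compounds"] += 1
            rec["n_active"] += int(label == ACTIVE)
            rec["weighted"] += weight
        total_weight += weight * len(frag_keys)
    if total_weight <= 0:
        raise DegenerateInputError(
            "zero total activity weight: no active or inconclusive compounds"
        )
    table = pd.DataFrame([
        {"fragment": k, "n_compounds": v["n_compounds"],
         "n_active": v["n_active"],
         "aaf_percent": 100.0 * v["weighted"] / total_weight}
        for k, v in rows.items()
    ])
    return (table.sort_values(["aaf_percent", "fragment"],
                              ascending=[False, True])
                 .reset_index(drop=True))
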