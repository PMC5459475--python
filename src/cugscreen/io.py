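"""File formats: SMILES/SDF libraries, PDB structures, snapshot CSV, OpenDX.

Small-molecule I/O goes through RDKit; PDB reading through Biopython.  The
PDB writer is a minimal fixed-width emitter for the point-atom structures
used here (one MODEL per conformer for ensembles).  The OpenDX writer emits
the standard regular-grid scalar format understood by VMD/PyMOL/Chimera.
"""

from __future__ import annotations

import json
import warnings
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from Bio.PDB import PDBParser
from rdkit import Chem

from .chemspace import CompoundLibrary, Molecule
from .ensemble import AtomicStructure, ConformerEnsemble
from .errors import InputError
from .synthetic import ProbeSnapshotSet

_MASSES = {
    "H": 1.008, "C": 12.011, "N": 14.007, "O": 15.999, "P": 30.974,
    "S": 32.06, "NA": 22.990, "MG": 24.305, "K": 39.098, "CL": 35.45,
}


# ---------------------------------------------------------------------------
# SMILES / SDF
# ---------------------------------------------------------------------------

def write_smi(library: CompoundLibrary, path: str | Path) -> None:
    """One record per line: SMILES<TAB>id<TAB>label."""
    with open(path, "w") as fh:
        for m in library.molecules:
            fh.write(f"{m.smiles}\t{m.id}\t{m.label or ''}\n")


def read_smi(path: str | Path) -> CompoundLibrary:
    molecules = []
    with open(path) as fh:
        for i, line in enumerate(fh):
            parts = line.rstrip("\n").split("\t")
            if not parts or not parts[0]:
                continue
            mol = Chem.MolFromSmiles(parts[0])
            if mol is None:
                raise InputError(f"line {i + 1}: invalid SMILES {parts[0]!r}")
            molecules.append(Molecule(
                mol=mol,
                id=parts[1] if len(parts) > 1 and parts[1] else f"CMPD{i:05d}",
                label=parts[2] if len(parts) > 2 and parts[2] else None,
            ))
    return CompoundLibrary(molecules=molecules,
                           provenance={"source": str(path)})


def write_sdf(library: CompoundLibrary, path: str | Path) -> None:
    writer = Chem.SDWriter(str(path))
    try:
        for m in library.molecules:
            mol = Chem.Mol(m.mol)
            mol.SetProp("_Name", m.id)
            if m.label is not None:
                mol.SetProp("label", m.label)
            if m.charges is not None:
                mol.SetProp("partial_charges",
                            " ".join(f"{q:.6f}" for q in m.charges))
            writer.write(mol)
    finally:
        writer.close()


def read_sdf(path: str | Path) -> CompoundLibrary:
    supplier = Chem.SDMolSupplier(str(path), removeHs=False)
    molecules = []
    for i, mol in enumerate(supplier):
        if mol is None:
            warnings.warn(f"record {i} in {path} could not be parsed; skipped")
            continue
        charges = None
        if mol.HasProp("partial_charges"):
            charges = np.array([float(x) for x in
                                mol.GetProp("partial_charges").split()])
        molecules.append(Molecule(
            mol=mol,
            id=mol.GetProp("_Name") if mol.HasProp("_Name") else f"CMPD{i:05d}",
            label=mol.GetProp("label") if mol.HasProp("label") else None,
            charges=charges,
        ))
    return CompoundLibrary(molecules=molecules,
                           provenance={"source": str(path)})


# ---------------------------------------------------------------------------
# PDB
# ---------------------------------------------------------------------------

def _pdb_atom_line(serial: int, name: str, resname: str, chain: str,
                   resseq: int, xyz: np.ndarray, element: str) -> str:
    return (f"ATOM  {serial:5d} {name:<4s}{resname:>4s} {chain:1s}"
            f"{resseq:4d}    {xyz[0]:8.3f}{xyz[1]:8.3f}{xyz[2]:8.3f}"
            f"{1.00:6.2f}{0.00:6.2f}          {element:>2s}\n")


def _structure_lines(structure: AtomicStructure,
                     coords: Optional[np.ndarray] = None) -> list[str]:
    coords = structure.coords if coords is None else coords
    lines, serial = [], 1
    per_res_counter: dict = {}
    for i in range(structure.n_atoms):
        key = (str(structure.chain[i]), int(structure.res_index[i]))
        per_res_counter[key] = per_res_counter.get(key, 0) + 1
        name = f"{structure.elements[i]}{per_res_counter[key]}"[:4]
        lines.append(_pdb_atom_line(
            serial, name, str(structure.res_name[i]), str(structure.chain[i]),
            int(structure.res_index[i]) + 1, coords[i],
            str(structure.elements[i]),
        ))
        serial += 1
    return lines


def write_pdb(structure: AtomicStructure, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.writelines(_structure_lines(structure))
        fh.write("END\n")


def write_ensemble_pdb(ensemble: ConformerEnsemble, path: str | Path) -> None:
    """Multi-MODEL PDB: one MODEL per conformer, reference topology."""
    with open(path, "w") as fh:
        for k, conf in enumerate(ensemble.conformers, start=1):
            fh.write(f"MODEL     {k:4d}\n")
            fh.writelines(_structure_lines(ensemble.reference, conf.coords))
            fh.write("ENDMDL\n")
        fh.write("END\n")


def write_ensemble_provenance(ensemble: ConformerEnsemble, path: str | Path
                              ) -> None:
    payload = {
        "target_mwrmsd": ensemble.target_mwrmsd,
        "conformers": [{
            "id": c.id, "mode_index": c.mode_index, "direction": c.direction,
            "achieved_mwrmsd": c.achieved_mwrmsd, "mode_source": c.mode_source,
        } for c in ensemble.conformers],
    }
    Path(path).write_text(json.dumps(payload, indent=2))


def read_pdb(path: str | Path, model: int = 0) -> AtomicStructure:
    """Read one model of a PDB file as a point-atom structure."""
    parser = PDBParser(QUIET=True)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        bio = parser.get_structure("s", str(path))
    models = list(bio.get_models())
    if not models:
        raise InputError(f"no models in {path}")
    coords, masses, elements = [], [], []
    res_index, res_name, chain = [], [], []
    for ch in models[model]:
        for residue in ch:
            for atom in residue:
                coords.append(atom.coord)
                el = (atom.element or atom.get_name()[0]).upper()
                elements.append(el.capitalize())
                masses.append(_MASSES.get(el, 12.011))
                res_index.append(residue.id[1] - 1)
                res_name.append(residue.get_resname().strip())
                chain.append(ch.id)
    return AtomicStructure(
        coords=np.asarray(coords, dtype=float), masses=np.asarray(masses),
        elements=np.asarray(elements), res_index=np.asarray(res_index),
        res_name=np.asarray(res_name), chain=np.asarray(chain),
        id=Path(path).stem,
    )


# ---------------------------------------------------------------------------
# probe snapshots
# ---------------------------------------------------------------------------

def write_snapshots_csv(snapshots: ProbeSnapshotSet, path: str | Path) -> None:
    snapshots.to_dataframe().to_csv(path, index=False)


def read_snapshots_csv(path: str | Path, box=None) -> ProbeSnapshotSet:
    df = pd.read_csv(path)
    required = {"frame", "probe_type", "x", "y", "z"}
    if not required.issubset(df.columns):
        raise InputError(f"snapshot CSV must have columns {sorted(required)}")
    xyz_all = df[["x", "y", "z"]].to_numpy(dtype=float)
    if box is None:
        box = np.stack([xyz_all.min(axis=0), xyz_all.max(axis=0)])
    frames = []
    for _, grp in df.groupby("frame", sort=True):
        frames.append((grp["probe_type"].to_numpy(),
                       grp[["x", "y", "z"]].to_numpy(dtype=float)))
    return ProbeSnapshotSet(box=np.asarray(box, dtype=float), frames=frames)


# ---------------------------------------------------------------------------
# OpenDX scalar grids
# ---------------------------------------------------------------------------

def write_dx(grid, path: str | Path, fill_value: float = 0.0) -> None:
    """Write a free-energy (or occupancy) grid as an OpenDX scalar field."""
    data = np.where(getattr(grid, "defined", np.ones(grid.shape, bool)),
                    getattr(grid, "dg", getattr(grid, "counts", None)),
                    fill_value)
    nx, ny, nz = grid.shape
    ox, oy, oz = grid.origin + grid.spacing / 2.0
    h = grid.spacing
    with open(path, "w") as fh:
        fh.write(f"object 1 class gridpositions counts {nx} {ny} {nz}\n")
        fh.write(f"origin {ox:.6f} {oy:.6f} {oz:.6f}\n")
        fh.write(f"delta {h:.6f} 0 0\ndelta 0 {h:.6f} 0\ndelta 0 0 {h:.6f}\n")
        fh.write(f"object 2 class gridconnections counts {nx} {ny} {nz}\n")
        fh.write(f"object 3 class array type double rank 0 items "
                 f"{nx * ny * nz} data follows\n")
        flat = data.ravel(order="C")
        for start in range(0, flat.size, 3):
            fh.write(" ".join(f"{v:.6e}" for v in flat[start:start + 3]) + "\n")
        fh.write('attribute "dep" string "positions"\n')
        fh.write('object "grid" class field\n')
        fh.write('component "positions" value 1\n')
        fh.write('component "connections" value 2\n')
        fh.write('component "data" value 3\n')


# ---------------------------------------------------------------------------
# model / selection JSON
# ---------------------------------------------------------------------------

def write_json(payload: dict, path: str | Path) -> None:
    def _default(o):
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        raise TypeError(f"not JSON-serializable: {type(o)}")
    Path(path).write_text(json.dumps(payload, indent=2, default=_default))
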