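"""Synthetic inputs for every pipeline stage.

Real inputs to the screen are a quantitative high-throughput screening
library with three-level activity calls, experimentally solved CUG-repeat
duplex structures, and probe-MD snapshot trajectories.  None of those are
required for testing: this module generates statistically controlled
stand-ins — a labeled compound library whose actives carry planted
"privileged" chemotypes (imidazole / benzimidazole / piperazine /
pyridopyrimidine cores), an idealized point-atom (CUG)_n duplex, probe
snapshots with planted Gaussian hotspots over a Poisson background, Gaussian
descriptor clouds, and a deterministic hash-scored stub docking engine.

All generators are pure functions of (parameters, seed).
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from rdkit import Chem
from rdkit import RDLogger

from .chemspace import (ACTIVE, INACTIVE, INCONCLUSIVE, CompoundLibrary,
                        Molecule)
from .docking import Pose
from .ensemble import AtomicStructure, Conformer
from .errors import InputError, ParameterError

RDLogger.DisableLog("rdApp.*")

# Planted "privileged" chemotype cores.  The substituent prefix is prepended
# directly to the template, e.g. "CC" + "c1ncc[nH]1" -> 2-ethylimidazole.
CHEMOTYPE_SMARTS = {
    "imidazole": "c1c[nH]cn1",
    "benzimidazole": "c1ccc2[nH]cnc2c1",
    "piperazine": "C1CNCCN1",
    "pyridopyrimidine": "c1cnc2ncncc2c1",
}

_ACTIVE_CORES = [
    "c1ncc[nH]1",              # imidazole (2-substituted)
    "c1nc2ccccc2[nH]1",        # benzimidazole (2-substituted)
    "N1CCNCC1",                # piperazine (N-substituted)
    "c1cnc2ncncc2c1",          # pyridopyrimidine-like bicyclic
    "Cc1ncc[nH]1",             # methylimidazole terminus
    "C(=O)Nc1ncc[nH]1",        # amide-linked imidazole
]

_DECOY_CORES = [
    "c1ccccc1",                # benzene
    "c1ccncc1",                # pyridine
    "C1CCCCC1",                # cyclohexane
    "C1CCOCC1",                # tetrahydropyran
    "N1CCOCC1",                # morpholine
    "OC(=O)c1ccccc1",          # benzoate
    "C(=O)NC",                 # simple amide terminus
    "C#N",                     # nitrile terminus
    "S(=O)(=O)N",              # sulfonamide terminus
    "CC(=O)OC",                # ester terminus
    "c1ccc2ccccc2c1",          # naphthalene
    "c1ccsc1",                 # thiophene
    "c1ccoc1",                 # furan
    "C1CCNCC1",                # piperidine (not piperazine)
    "CC(=O)c1ccccc1",          # acetophenone terminus
    "OCC(O)CO",                # glycerol-like polyol
]

# actives carry small decorations: the planted chemotypes dominate their
# fingerprints, emulating the tight clustering of the true positives
_ACTIVE_SUBSTITUENTS = ["", "C", "CC", "CO", "CN", "OC"]

# decoys range from tiny to large/branched/halogenated scaffolds, emulating
# the wide structural diversity of the screened negatives
_DECOY_SUBSTITUENTS = [
    "", "C", "CC", "CCC", "CCCC", "CCCCC", "CCCCCCC", "CCCCCCCCC",
    "CC(C)", "CC(C)(C)", "CO", "CCO", "CCCO", "CN", "CCN", "OC", "COC",
    "CCOCC", "C(c1ccccc1)", "C(c1ccccc1)C(c1ccccc1)", "CC(=O)N", "NC(=O)C",
    "FC(F)(F)", "ClCC", "BrCCC", "OCC(O)C", "C(=O)OCC", "S(=O)(=O)C",
    "C#CC", "C(C#N)C",
]


def _smiles_for(core: str, prefix: str) -> Optional[str]:
    smi = prefix + core
    mol = Chem.MolFromSmiles(smi)
    return Chem.MolToSmiles(mol) if mol is not None else None


def _chemotype_patterns() -> dict[str, Chem.Mol]:
    return {k: Chem.MolFromSmarts(v) for k, v in CHEMOTYPE_SMARTS.items()}


def has_planted_chemotype(mol: Chem.Mol | Molecule) -> bool:
    rdmol = mol.mol if isinstance(mol, Molecule) else mol
    return any(rdmol.HasSubstructMatch(p) for p in _chemotype_patterns().values())


def gen_compound_library(n: int, active_fraction: float, seed: int,
                         inconclusive_fraction: float = 0.1,
                         chemotype_rate: float = 0.95) -> CompoundLibrary:
    """Labeled compound library with chemotype-enriched actives.

    Label counts are forced by rounding: ``round(n * active_fraction)``
    actives, ``round(n * inconclusive_fraction)`` inconclusives, rest
    inactive.  Actives draw a planted-chemotype template with probability
    ``chemotype_rate`` (decoy otherwise); inconclusives are a 50/50 mixture;
    inactives are decoys only.  Same seed and parameters give a
    byte-identical library.
    """
    if n < 4:
        raise ParameterError("library size must be >= 4")
    if not 0 < active_fraction < 1:
        raise ParameterError("active_fraction must be in (0, 1)")
    if not 0 <= inconclusive_fraction < 1 - active_fraction:
        raise ParameterError("inconclusive_fraction out of range")
    rng = np.random.default_rng(seed)
    n_active = round(n * active_fraction)
    n_inconclusive = round(n * inconclusive_fraction)
    labels = ([ACTIVE] * n_active + [INCONCLUSIVE] * n_inconclusive
              + [INACTIVE] * (n - n_active - n_inconclusive))

    molecules = []
    for i, label in enumerate(labels):
        if label == ACTIVE:
            planted = rng.random() < chemotype_rate
        elif label == INCONCLUSIVE:
            planted = rng.random() < 0.5
        else:
            planted = False
        cores = _ACTIVE_CORES if planted else _DECOY_CORES
        subs = _ACTIVE_SUBSTITUENTS if planted else _DECOY_SUBSTITUENTS
        smi = None
        while smi is None:
            core = cores[rng.integers(len(cores))]
            prefix = subs[rng.integers(len(subs))]
            smi = _smiles_for(core, prefix)
        molecules.append(Molecule(mol=Chem.MolFromSmiles(smi),
                                  id=f"CMPD{i:05d}", label=label))
    return CompoundLibrary(molecules=molecules, provenance={
        "generator": "gen_compound_library", "n": n, "seed": seed,
        "active_fraction": active_fraction,
        "inconclusive_fraction": inconclusive_fraction,
        "chemotype_rate": chemotype_rate,
    })


# ---------------------------------------------------------------------------
# idealized (CUG)_n duplex
# ---------------------------------------------------------------------------

# Representative element/mass pattern for a coarse point-atom residue:
# phosphate P, bridging O, base N, two C, sugar O.
_RESIDUE_ELEMENTS = ["P", "O", "N", "C", "C", "O", "N", "C"]
_RESIDUE_MASSES = [30.974, 15.999, 14.007, 12.011, 12.011, 15.999,
                   14.007, 12.011]


@dataclass
class SyntheticRNASpec:
    """Parameters of the idealized A-form-like (CUG)_n duplex.

    Defaults follow canonical A-form helix geometry: 2.81 Å rise and 32.7°
    twist per residue, backbone radius 9.4 Å.
    """

    n_repeats: int = 3
    rise: float = 2.81           # Å per residue step
    twist: float = 32.7          # degrees per residue step
    groove_offset: float = 9.4   # helix radius, Å
    atoms_per_residue: int = 6
    masses: Optional[Sequence[float]] = None
    jitter: float = 0.15         # Å, seeded, centroid-preserving

    def __post_init__(self):
        if self.n_repeats < 2:
            raise ParameterError("n_repeats must be >= 2")
        if self.rise <= 0:
            raise ParameterError("rise must be positive")
        if not 1 <= self.atoms_per_residue <= len(_RESIDUE_ELEMENTS):
            raise ParameterError(
                f"atoms_per_residue must be in [1, {len(_RESIDUE_ELEMENTS)}]"
            )


def gen_rna_duplex(spec: SyntheticRNASpec = SyntheticRNASpec(), seed: int = 0
                   ) -> AtomicStructure:
    """Idealized two-strand point-atom CUG duplex.

    Residue anchors sit on two antiparallel helical backbone tracks of radius
    ``groove_offset`` (strand B rotated by 154° around the axis, giving
    distinct major/minor grooves).  Each residue's atoms run radially inward
    from the backbone toward the helix axis — phosphate outside, base-like
    atoms near the axis — so that the deepest atoms of paired residues
    approach each other like a base pair.  The local atom pattern is
    identical for every residue (in its rotated frame) and the seeded jitter
    is sum-zero, so the distance between consecutive same-strand residue
    centroids along the helix axis equals ``rise`` exactly.  The whole
    structure is centered at the origin.
    """
    rng = np.random.default_rng(seed)
    apr = spec.atoms_per_residue
    n_res = 3 * spec.n_repeats
    names = ["C", "U", "G"]
    masses = (np.asarray(spec.masses, dtype=float) if spec.masses is not None
              else np.asarray(_RESIDUE_MASSES[:apr]))
    if masses.shape[0] != apr:
        raise ParameterError("masses length must equal atoms_per_residue")
    elements = _RESIDUE_ELEMENTS[:apr]

    # radial depths: 0 (phosphate, backbone) .. 0.8*radius (base edge near
    # the axis); small tangential/axial spread breaks collinearity
    if apr > 1:
        depths = np.linspace(0.0, 0.8 * spec.groove_offset, apr)
    else:
        depths = np.zeros(1)
    phi = 2 * np.pi * np.arange(apr) / max(apr, 1)
    tangential = 0.8 * np.sin(phi)
    axial = 0.5 * np.cos(phi)

    coords, mass_list, elem_list = [], [], []
    res_index, res_name, chain = [], [], []
    twist = np.deg2rad(spec.twist)
    strand_b_shift = np.deg2rad(154.0)
    for strand, ch in enumerate("AB"):
        for i in range(n_res):
            if strand == 0:
                theta, z = i * twist, i * spec.rise
                name = names[i % 3]
            else:
                # 5'->3' of strand B runs against the axis; residue i of B
                # pairs with residue n_res-1-i of A at the same z level.
                pair = n_res - 1 - i
                theta, z = pair * twist + strand_b_shift, pair * spec.rise
                name = names[i % 3]
            u = np.array([np.cos(theta), np.sin(theta), 0.0])   # radial out
            v = np.array([-np.sin(theta), np.cos(theta), 0.0])  # tangential
            w = np.array([0.0, 0.0, 1.0])
            anchor = spec.groove_offset * u + z * w
            offsets = (-depths[:, None] * u + tangential[:, None] * v
                       + axial[:, None] * w)
            jit = rng.normal(0.0, spec.jitter, size=(apr, 3))
            jit -= jit.mean(axis=0)
            coords.append(anchor + offsets + jit)
            mass_list.append(masses)
            elem_list.extend(elements)
            res_index.extend([i] * apr)
            res_name.extend([name] * apr)
            chain.extend([ch] * apr)
    coords = np.concatenate(coords)
    coords -= coords.mean(axis=0)
    return AtomicStructure(
        coords=coords, masses=np.concatenate(mass_list),
        elements=np.asarray(elem_list), res_index=np.asarray(res_index),
        res_name=np.asarray(res_name), chain=np.asarray(chain),
        id=f"cug{spec.n_repeats}_seed{seed}",
    )


# ---------------------------------------------------------------------------
# probe snapshots
# ---------------------------------------------------------------------------

_BACKGROUND_PROBES = (("isopropanol", 0.7), ("acetamide", 0.1),
                      ("acetate", 0.1), ("isopropylamine", 0.1))


@dataclass
class PlantedHotspot:
    center: np.ndarray
    width: float          # Gaussian sigma, Å
    enrichment: float     # local density at center = (1+e) * bulk
    probe_type: str = "isopropanol"


@dataclass
class ProbeSnapshotSet:
    box: np.ndarray                     # (2, 3): min corner, max corner
    frames: list[tuple[np.ndarray, np.ndarray]]  # (types, (k,3) coords)
    hotspot_truth: list[PlantedHotspot] = field(default_factory=list)
    bulk_density: float = 0.0
    seed: int = 0

    @property
    def n_frames(self) -> int:
        return len(self.frames)

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for f, (types, xyz) in enumerate(self.frames):
            for t, (x, y, z) in zip(types, xyz):
                rows.append((f, t, x, y, z))
        return pd.DataFrame(rows, columns=["frame", "probe_type",
                                           "x", "y", "z"])


def gen_probe_snapshots(box, n_frames: int, bulk_density: float,
                        hotspots: Sequence[tuple] = (), seed: int = 0
                        ) -> ProbeSnapshotSet:
    """Probe-center snapshots: uniform Poisson background + Gaussian hotspots.

    Background probe counts per frame are Poisson with mean
    ``bulk_density * box volume`` and uniform positions; each hotspot
    ``(center, width, enrichment[, probe_type])`` contributes an independent
    Poisson number of probes (mean ``enrichment * bulk_density *
    (2*pi)^(3/2) * width^3`` per frame) at Gaussian-distributed positions, so
    the expected local density at the hotspot center is ``enrichment *
    bulk_density`` in excess of the background.
    """
    box = np.asarray(box, dtype=float).reshape(2, 3)
    if n_frames < 1:
        raise ParameterError("n_frames must be >= 1")
    if bulk_density <= 0:
        raise ParameterError("bulk_density must be positive")
    planted = []
    for h in hotspots:
        center = np.asarray(h[0], dtype=float)
        width, enrichment = float(h[1]), float(h[2])
        ptype = h[3] if len(h) > 3 else "isopropanol"
        if enrichment <= 0:
            raise ParameterError("hotspot enrichment must be positive")
        if ((center < box[0]) | (center > box[1])).any():
            raise ParameterError("hotspot center outside the box")
        planted.append(PlantedHotspot(center, width, enrichment, ptype))

    rng = np.random.default_rng(seed)
    side = box[1] - box[0]
    volume = float(np.prod(side))
    mean_bg = bulk_density * volume
    bg_types = np.array([t for t, _ in _BACKGROUND_PROBES])
    bg_probs = np.array([p for _, p in _BACKGROUND_PROBES])
    bg_probs = bg_probs / bg_probs.sum()

    frames = []
    for _ in range(n_frames):
        k = rng.poisson(mean_bg)
        xyz = box[0] + rng.random((k, 3)) * side
        types = bg_types[rng.choice(len(bg_types), size=k, p=bg_probs)]
        for h in planted:
            mean_h = (h.enrichment * bulk_density
                      * (2 * np.pi) ** 1.5 * h.width ** 3)
            kh = rng.poisson(mean_h)
            pts = np.empty((0, 3))
            while pts.shape[0] < kh:  # reject draws outside the box
                cand = rng.normal(h.center, h.width, size=(kh, 3))
                ok = ((cand >= box[0]) & (cand <= box[1])).all(axis=1)
                pts = np.concatenate([pts, cand[ok]])[:kh]
            xyz = np.concatenate([xyz, pts])
            types = np.concatenate([types, np.array([h.probe_type] * kh)])
        frames.append((types, xyz))
    return ProbeSnapshotSet(box=box, frames=frames, hotspot_truth=planted,
                            bulk_density=bulk_density, seed=seed)


# ---------------------------------------------------------------------------
# descriptor clouds
# ---------------------------------------------------------------------------

@dataclass
class DescriptorCloud:
    matrix: np.ndarray
    centers: np.ndarray
    assignments: np.ndarray
    ids: list[str]


def gen_descriptor_cloud(n: int, dim: int, n_clusters: int, seed: int = 0,
                         spread: float = 1.0, separation: float = 10.0
                         ) -> DescriptorCloud:
    """Gaussian blob descriptor matrix with recorded cluster centers."""
    if dim < 1:
        raise ParameterError("dim must be >= 1")
    if not 1 <= n_clusters <= n:
        raise ParameterError("need n >= n_clusters >= 1")
    rng = np.random.default_rng(seed)
    centers = rng.uniform(-separation, separation, size=(n_clusters, dim))
    assignments = rng.integers(n_clusters, size=n)
    matrix = centers[assignments] + rng.normal(0.0, spread, size=(n, dim))
    return DescriptorCloud(matrix=matrix, centers=centers,
                           assignments=assignments,
                           ids=[f"ROW{i:04d}" for i in range(n)])


# ---------------------------------------------------------------------------
# stub docking engine
# ---------------------------------------------------------------------------

def _hash_unit(parts: tuple) -> float:
    """Stable 64-bit hash of a tuple of strings/ints mapped to [0, 1)."""
    digest = hashlib.sha256("|".join(str(p) for p in parts).encode()).digest()
    return int.from_bytes(digest[:8], "big") / 2 ** 64


def stub_pose_engine(ligand: Molecule, receptor: Conformer, n_poses: int,
                     seed: int = 0) -> list[Pose]:
    """Deterministic stand-in for an external docking engine.

    Scores are a hash-derived function of (ligand id, conformer id, pose
    index, seed) mapped into a docking-like energy window [-12, -2]
    kcal/mol-ish, sorted ascending (best first) and reproducible across
    platforms and processes.
    """
    if n_poses < 1:
        raise ParameterError("n_poses must be >= 1")
    lig_id = ligand.id if isinstance(ligand, Molecule) else str(ligand)
    conf_id = receptor.id if isinstance(receptor, Conformer) else str(receptor)
    raw = sorted(
        -12.0 + 10.0 * _hash_unit((lig_id, conf_id, k, seed))
        for k in range(n_poses)
    )
    return [Pose(ligand_id=lig_id, conformer_id=conf_id, pose_index=k,
                 score=s) for k, s in enumerate(raw)]
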