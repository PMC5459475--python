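"""Radial-fingerprint chemical space: PCA model, property profiling, active region.

The ligand-based stage of the screen embeds a labeled compound library in a
low-dimensional chemical space built from hashed circular (Morgan/ECFP-style)
count fingerprints.  Active compounds cluster in that space, so a kernel
density fitted on the active projections defines an "active region" that can
be combined with Rule-of-Five filtering to pre-select candidates.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from rdkit import Chem
from rdkit.Chem import Descriptors, Lipinski, Crippen, rdMolDescriptors
from rdkit.Chem import rdFingerprintGenerator
from scipy.stats import gaussian_kde

from .errors import DegenerateInputError, InputError, ParameterError

ACTIVE = "active"
INCONCLUSIVE = "inconclusive"
INACTIVE = "inactive"
LABELS = (ACTIVE, INCONCLUSIVE, INACTIVE)


@dataclass
class Molecule:
    """A compound: an RDKit mol plus pipeline bookkeeping.

    3D coordinates, when present, live on the RDKit conformer; per-atom
    partial charges live in the ``_GasteigerCharge``/``partial_charge`` atom
    properties or the ``charges`` attribute set by the readers.
    """

    mol: Chem.Mol
    id: str
    label: Optional[str] = None
    charges: Optional[np.ndarray] = None

    @property
    def smiles(self) -> str:
        return Chem.MolToSmiles(self.mol)

    @property
    def coords(self) -> Optional[np.ndarray]:
        if self.mol.GetNumConformers() == 0:
            return None
        return np.asarray(self.mol.GetConformer().GetPositions(), dtype=float)


@dataclass
class CompoundLibrary:
    molecules: list[Molecule]
    provenance: dict = field(default_factory=dict)

    @property
    def labels(self) -> list[Optional[str]]:
        return [m.label for m in self.molecules]

    def __len__(self) -> int:
        return len(self.molecules)

    def __iter__(self):
        return iter(self.molecules)

    def subset(self, indices: Sequence[int]) -> "CompoundLibrary":
        return CompoundLibrary(
            molecules=[self.molecules[i] for i in indices],
            provenance={**self.provenance, "subset_of": len(self.molecules)},
        )


@dataclass
class FingerprintVector:
    counts: np.ndarray  # non-negative ints, fixed length
    radius: int
    length: int

    def __post_init__(self):
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.shape != (self.length,):
            raise InputError("fingerprint counts do not match declared length")
        if (self.counts < 0).any():
            raise InputError("fingerprint counts must be non-negative")


@dataclass
class PropertyProfile:
    mw: float          # molecular weight, u
    hba: int           # H-bond acceptors
    hbd: int           # H-bond donors
    formal_charge: int  # net formal charge, e
    tpsa: float        # topological polar surface area, Å^2
    xlogp: float       # atom-additive logP estimate
    rotatable_bonds: int


@dataclass
class ChemSpaceModel:
    mean: np.ndarray
    loadings: np.ndarray                 # (n_components, n_features), orthonormal rows
    explained_variance_fractions: np.ndarray
    fingerprint_radius: int
    fingerprint_length: int


@dataclass
class ActiveRegion:
    """Highest-density level set of a 2-D KDE fitted on active projections."""

    kde: gaussian_kde
    threshold: float
    level: float
    n_training: int

    def contains(self, points: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        dens = self.kde(pts.T)
        return dens >= self.threshold


_FP_GENERATORS: dict = {}


def _fp_generator(radius: int, length: int):
    key = (radius, length)
    if key not in _FP_GENERATORS:
        _FP_GENERATORS[key] = rdFingerprintGenerator.GetMorganGenerator(
            radius=radius, fpSize=length
        )
    return _FP_GENERATORS[key]


def compute_fingerprint(mol: Molecule | Chem.Mol, radius: int = 2,
                        length: int = 1024) -> FingerprintVector:
    """Hashed circular count fingerprint (radial/ECFP family).

    Counts atom-centered environments of topological radius 0..``radius``
    hashed into ``length`` positions.  Invariant to atom ordering because the
    environments are canonical graph invariants.
    """
    if radius < 0:
        raise ParameterError("radius must be >= 0")
    if length < 2 or (length & (length - 1)) != 0:
        raise ParameterError("fingerprint length must be a power of two")
    rdmol = mol.mol if isinstance(mol, Molecule) else mol
    if rdmol is None or rdmol.GetNumAtoms() == 0:
        raise InputError("cannot fingerprint an empty molecule")
    counts = _fp_generator(radius, length).GetCountFingerprintAsNumPy(rdmol)
    return FingerprintVector(counts=counts.astype(np.int64), radius=radius,
                             length=length)


def tanimoto(a: FingerprintVector, b: FingerprintVector) -> float:
    """Count-vector (MinMax) Tanimoto similarity."""
    if a.length != b.length:
        raise InputError("fingerprint lengths differ")
    mins = np.minimum(a.counts, b.counts).sum()
    maxs = np.maximum(a.counts, b.counts).sum()
    return float(mins / maxs) if maxs else 1.0


def compute_properties(mol: Molecule | Chem.Mol) -> PropertyProfile:
    """Physicochemical profile: MW, HBA/HBD, net charge, TPSA, xlogP, RotB.

    HBD counts N/O bearing at least one hydrogen; HBA counts N/O excluding
    pyrrole-type and amide nitrogens (the conventional Lipinski-style rules).
    xlogP is the Wildman–Crippen atom-additive estimate; TPSA the
    fragment-additive topological method.
    """
    rdmol = mol.mol if isinstance(mol, Molecule) else mol
    if rdmol is None or rdmol.GetNumAtoms() == 0:
        raise InputError("cannot profile an empty molecule")
    pt = Chem.GetPeriodicTable()
    for atom in rdmol.GetAtoms():
        if pt.GetAtomicWeight(atom.GetAtomicNum()) <= 0:
            raise InputError(f"unknown element {atom.GetSymbol()}")
    return PropertyProfile(
        mw=float(Descriptors.MolWt(rdmol)),
        hba=int(Lipinski.NumHAcceptors(rdmol)),
        hbd=int(Lipinski.NumHDonors(rdmol)),
        formal_charge=int(Chem.GetFormalCharge(rdmol)),
        tpsa=float(rdMolDescriptors.CalcTPSA(rdmol)),
        xlogp=float(Crippen.MolLogP(rdmol)),
        rotatable_bonds=int(Lipinski.NumRotatableBonds(rdmol)),
    )


def ro5_violations(profile: PropertyProfile) -> int:
    """Number of Rule-of-Five violations; "conforms" means at most one."""
    return int(
        (profile.mw > 500)
        + (profile.hbd > 5)
        + (profile.hba > 10)
        + (profile.xlogp > 5)
    )


def fit_chemspace(fps: Sequence[FingerprintVector]) -> ChemSpaceModel:
    """Mean-centered PCA of fingerprint count vectors.

    Components are sorted by decreasing variance; each eigenvector's sign is
    fixed so its largest-magnitude loading is positive, which removes the
    platform-dependent sign ambiguity of eigendecompositions.
    """
    if len(fps) < 3:
        raise InputError("need at least 3 fingerprints to fit a chemical space")
    lengths = {fp.length for fp in fps}
    if len(lengths) != 1:
        raise InputError("fingerprints have inconsistent lengths")
    X = np.stack([fp.counts for fp in fps]).astype(float)
    mean = X.mean(axis=0)
    Xc = X - mean
    total_var = float((Xc ** 2).sum()) / (X.shape[0] - 1)
    if total_var <= 1e-12:
        raise DegenerateInputError(
            "all fingerprints identical: zero variance, no principal axes"
        )
    # SVD of the centered matrix: right singular vectors are the loadings.
    _, s, vt = np.linalg.svd(Xc, full_matrices=False)
    var = s ** 2 / (X.shape[0] - 1)
    keep = var > 1e-12 * var[0]
    var, vt = var[keep], vt[keep]
    for i in range(vt.shape[0]):
        j = int(np.argmax(np.abs(vt[i])))
        if vt[i, j] < 0:
            vt[i] = -vt[i]
    return ChemSpaceModel(
        mean=mean,
        loadings=vt,
        explained_variance_fractions=var / var.sum(),
        fingerprint_radius=fps[0].radius,
        fingerprint_length=fps[0].length,
    )


def project(model: ChemSpaceModel, fp: FingerprintVector,
            n_components: int = 2) -> np.ndarray:
    """Project a fingerprint into the model's principal subspace."""
    if fp.length != model.mean.shape[0]:
        raise InputError("fingerprint length does not match the model")
    n = min(n_components, model.loadings.shape[0])
    return (fp.counts.astype(float) - model.mean) @ model.loadings[:n].T


def reconstruct(model: ChemSpaceModel, scores: np.ndarray) -> np.ndarray:
    """Inverse of :func:`project` using as many components as given scores."""
    scores = np.asarray(scores, dtype=float)
    return model.mean + scores @ model.loadings[: scores.shape[-1]]


def define_active_region(model: ChemSpaceModel,
                         active_fps: Sequence[FingerprintVector],
                         level: float = 0.90) -> ActiveRegion:
    """Fit a 2-D Gaussian KDE on active projections; keep the density level
    set that encloses at least ``level`` of the training actives.
    """
    if not 0 < level < 1:
        raise ParameterError("level must be in (0, 1)")
    if len(active_fps) < 5:
        raise InputError("need at least 5 active compounds to define a region")
    pts = np.stack([project(model, fp, 2) for fp in active_fps])
    try:
        kde = gaussian_kde(pts.T)  # Scott bandwidth
    except np.linalg.LinAlgError as exc:
        raise DegenerateInputError(f"active projections are degenerate: {exc}")
    dens = np.sort(kde(pts.T))
    n_out = int(np.floor((1.0 - level) * len(active_fps)))
    threshold = float(dens[n_out]) if n_out < len(dens) else float(dens[-1])
    return ActiveRegion(kde=kde, threshold=threshold, level=level,
                        n_training=len(active_fps))


def select_candidates(library: CompoundLibrary, model: ChemSpaceModel,
                      region: ActiveRegion, ro5_max: int = 1) -> CompoundLibrary:
    """Keep compounds projecting inside the active region that also pass the
    Rule-of-Five filter (at most ``ro5_max`` violations).  Input order kept.
    """
    chosen = []
    for i, molecule in enumerate(library.molecules):
        fp = compute_fingerprint(molecule, model.fingerprint_radius,
                                 model.fingerprint_length)
        if not region.contains(project(model, fp, 2))[0]:
            continue
        if ro5_violations(compute_properties(molecule)) > ro5_max:
            continue
        chosen.append(i)
    return library.subset(chosen)
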