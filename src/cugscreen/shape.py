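"""Gaussian-overlap shape and electrostatic similarity (scaffold hopping).

Each atom is represented by a spherical Gaussian whose width is tied to its
van der Waals radius by hard-sphere volume matching (the Grant–Pickup
parameterization with amplitude p = 2.7).  The overlap volume of two
molecules is then an analytic double sum,

    O_AB = sum_i sum_j w_i w_j (pi / (a_i + a_j))^(3/2)
                 * exp(-a_i a_j d_ij^2 / (a_i + a_j)),

with w_i = p for shape and w_i = q_i (partial charge) for electrostatics.
Shape similarity is the Tanimoto ST = O_AB / (O_AA + O_BB - O_AB) at the
shape-optimal rigid alignment; the electrostatic Tanimoto ET is the same
functional on charge-weighted Gaussians evaluated at that alignment (it may
be negative for anti-correlated charge distributions), and the combined score
is ST + ET.  A two-stage screen ranks a library by ST, keeps the top block,
and re-ranks it by the combined score — the usual shape-then-electrostatics
hit-hopping protocol around a query such as pentamidine.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from rdkit import Chem
from rdkit.Chem import AllChem
from scipy.optimize import minimize
from scipy.spatial.transform import Rotation

from .chemspace import CompoundLibrary, Molecule
from .errors import DegenerateInputError, InputError, ParameterError

#: Gaussian amplitude of the Grant–Pickup hard-sphere-matched atom density.
P_AMPLITUDE = 2.7
#: alpha_i = (KAPPA / r_vdw,i)^2 makes the Gaussian reproduce the hard-sphere
#: volume of an atom of radius r_vdw at amplitude p.
KAPPA = float(np.sqrt(np.pi * (3.0 * P_AMPLITUDE / (4.0 * np.pi)) ** (2.0 / 3.0)))

_PT = Chem.GetPeriodicTable()


@dataclass
class AlignmentTransform:
    rotation: np.ndarray      # (3, 3), orthonormal, det = +1
    translation: np.ndarray   # (3,), Å

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return coords @ self.rotation.T + self.translation

    @classmethod
    def identity(cls) -> "AlignmentTransform":
        return cls(rotation=np.eye(3), translation=np.zeros(3))


@dataclass
class SimilarityResult:
    candidate_id: str
    shape_tanimoto: float
    electrostatic_tanimoto: Optional[float]
    combo: Optional[float]
    transform: AlignmentTransform


def _coords(mol: Molecule) -> np.ndarray:
    c = mol.coords
    if c is None:
        raise InputError(f"molecule {mol.id} has no 3D coordinates")
    return c


def atom_alphas(mol: Molecule) -> np.ndarray:
    """Per-atom Gaussian exponents from van der Waals radii."""
    radii = np.array([_PT.GetRvdw(a.GetAtomicNum())
                      for a in mol.mol.GetAtoms()], dtype=float)
    return (KAPPA / radii) ** 2


def atom_charges(mol: Molecule) -> np.ndarray:
    """Partial charges: stored values if present, else Gasteiger assignment."""
    if mol.charges is not None:
        q = np.asarray(mol.charges, dtype=float)
        if q.shape[0] != mol.mol.GetNumAtoms():
            raise InputError("charge array does not match atom count")
        return q
    m = Chem.Mol(mol.mol)
    try:
        Chem.SanitizeMol(m)
        AllChem.ComputeGasteigerCharges(m)
        q = np.array([float(a.GetProp("_GasteigerCharge"))
                      for a in m.GetAtoms()])
    except Exception:
        return None
    if not np.isfinite(q).all():
        return None
    return q


def _pair_overlap(xa: np.ndarray, aa: np.ndarray, wa: np.ndarray,
                  xb: np.ndarray, ab: np.ndarray, wb: np.ndarray) -> float:
    d2 = ((xa[:, None, :] - xb[None, :, :]) ** 2).sum(axis=2)
    asum = aa[:, None] + ab[None, :]
    integrals = (np.pi / asum) ** 1.5 * np.exp(-aa[:, None] * ab[None, :]
                                               * d2 / asum)
    return float((wa[:, None] * wb[None, :] * integrals).sum())


def gaussian_overlap(a: Molecule, b: Molecule,
                     transform: Optional[AlignmentTransform] = None) -> float:
    """Shape overlap volume O_AB (Å^3); ``transform`` is applied to ``b``."""
    xa, xb = _coords(a), _coords(b)
    if transform is not None:
        xb = transform.apply(xb)
    aa, ab = atom_alphas(a), atom_alphas(b)
    return _pair_overlap(xa, aa, np.full(len(xa), P_AMPLITUDE),
                         xb, ab, np.full(len(xb), P_AMPLITUDE))


def charge_overlap(a: Molecule, b: Molecule,
                   transform: Optional[AlignmentTransform] = None
                   ) -> Optional[float]:
    """Charge-weighted Gaussian overlap; None when charges are unavailable."""
    qa, qb = atom_charges(a), atom_charges(b)
    if qa is None or qb is None:
        return None
    xa, xb = _coords(a), _coords(b)
    if transform is not None:
        xb = transform.apply(xb)
    return _pair_overlap(xa, atom_alphas(a), qa, xb, atom_alphas(b), qb)


def _principal_axes(coords: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    center = coords.mean(axis=0)
    centered = coords - center
    cov = centered.T @ centered
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1]
    axes = evecs[:, order]
    if np.linalg.det(axes) < 0:
        axes[:, 2] = -axes[:, 2]
    return center, axes


_FLIPS = [np.diag(f) for f in ((1, 1, 1), (1, -1, -1),
                               (-1, 1, -1), (-1, -1, 1))]


def align_pair(query: Molecule, candidate: Molecule,
               maxiter: int = 200) -> AlignmentTransform:
    """Rigid alignment of ``candidate`` onto ``query`` maximizing shape overlap.

    Four proper principal-axes orientations seed a derivative-free local
    optimization over rotation vector + translation; the best of the four
    refined poses is returned, so the result is never worse than the best
    rigid start.
    """
    xq, xc = _coords(query), _coords(candidate)
    for x, who in ((xq, query), (xc, candidate)):
        if x.shape[0] < 3 or np.linalg.matrix_rank(x - x.mean(axis=0),
                                                   tol=1e-8) < 2:
            raise DegenerateInputError(
                f"molecule {who.id}: need >= 3 non-collinear atoms to align"
            )
    cq, axes_q = _principal_axes(xq)
    cc, axes_c = _principal_axes(xc)
    aq, ac = atom_alphas(query), atom_alphas(candidate)
    wq = np.full(len(xq), P_AMPLITUDE)
    wc = np.full(len(xc), P_AMPLITUDE)

    def overlap_of(R: np.ndarray, t: np.ndarray) -> float:
        return _pair_overlap(xq, aq, wq, xc @ R.T + t, ac, wc)

    best_value, best_Rt = -np.inf, None
    for flip in _FLIPS:
        R0 = axes_q @ flip @ axes_c.T
        t0 = cq - R0 @ cc

        def negative_overlap(params, R0=R0, t0=t0):
            R = Rotation.from_rotvec(params[:3]).as_matrix() @ R0
            return -overlap_of(R, t0 + params[3:])

        res = minimize(negative_overlap, np.zeros(6), method="Powell",
                       options={"maxiter": maxiter, "xtol": 1e-6,
                                "ftol": 1e-10})
        params = res.x
        R = Rotation.from_rotvec(params[:3]).as_matrix() @ R0
        t = t0 + params[3:]
        value = overlap_of(R, t)
        # never return worse than the rigid start itself
        if overlap_of(R0, t0) > value:
            R, t, value = R0, t0, overlap_of(R0, t0)
        if value > best_value:
            best_value, best_Rt = value, (R, t)
    R, t = best_Rt
    return AlignmentTransform(rotation=R, translation=t)


def similarity_scores(query: Molecule, candidate: Molecule,
                      transform: Optional[AlignmentTransform] = None
                      ) -> SimilarityResult:
    """Shape and electrostatic Tanimoto at the (given or optimized) alignment.

    The electrostatic Tanimoto is evaluated at the shape-optimal pose rather
    than re-optimized; when charges cannot be assigned the electrostatic part
    is reported absent and the combined score undefined.
    """
    if transform is None:
        transform = align_pair(query, candidate)
    o_ab = gaussian_overlap(query, candidate, transform)
    o_aa = gaussian_overlap(query, query)
    o_bb = gaussian_overlap(candidate, candidate)
    st = o_ab / (o_aa + o_bb - o_ab)
    q_ab = charge_overlap(query, candidate, transform)
    if q_ab is None:
        et = combo = None
    else:
        q_aa = charge_overlap(query, query)
        q_bb = charge_overlap(candidate, candidate)
        et = q_ab / (q_aa + q_bb - q_ab)
        combo = st + et
    return SimilarityResult(candidate_id=candidate.id, shape_tanimoto=float(st),
                            electrostatic_tanimoto=et, combo=combo,
                            transform=transform)


def screen_library(query: Molecule, library: CompoundLibrary | Sequence[Molecule],
                   n_shape: int = 100, n_final: int = 50
                   ) -> list[SimilarityResult]:
    """Two-stage screen: rank all by shape Tanimoto, keep ``n_shape``, re-rank
    those by the combined shape+electrostatic score, return ``n_final``.
    Ties are broken by compound id.
    """
    if n_final > n_shape:
        raise ParameterError("n_final cannot exceed n_shape")
    molecules = list(library)
    results = [similarity_scores(query, m) for m in molecules]
    results.sort(key=lambda r: (-r.shape_tanimoto, r.candidate_id))
    shortlist = results[:n_shape]
    shortlist.sort(key=lambda r: (-(r.combo if r.combo is not None
                                    else -np.inf), r.candidate_id))
    return shortlist[:n_final]


def embed_3d(molecule: Molecule, seed: int = 0) -> Molecule:
    """Attach ETKDG 3D coordinates (hydrogens added then stripped back)."""
    m = Chem.AddHs(Chem.Mol(molecule.mol))
    if AllChem.EmbedMolecule(m, randomSeed=seed) != 0:
        raise InputError(f"embedding failed for {molecule.id}")
    m = Chem.RemoveHs(m)
    return Molecule(mol=m, id=molecule.id, label=molecule.label,
                    charges=molecule.charges)
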