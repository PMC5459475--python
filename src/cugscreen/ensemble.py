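"""Receptor conformational ensembles from essential dynamics / elastic networks.

The structure-based stage treats the RNA duplex as a set of mass points.  An
experimental (or synthetic) set of three-repeat duplex fragments is
superimposed, the soft collective motions are extracted either as principal
components of the mass-weighted coordinate covariance (essential dynamics,
EDA) or as low-frequency normal modes of an anisotropic elastic network
(ANM), and the reference structure is deformed along each mode in both
directions up to a fixed mass-weighted RMSD.  Docking against every deformed
conformer then realizes a conformational-selection screen.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.sparse.csgraph import connected_components
from scipy.spatial.distance import cdist

from .errors import (CorrespondenceError, DegenerateInputError,
                     DisconnectedNetworkError, InputError, ParameterError)


@dataclass
class AtomicStructure:
    """Point-atom structure: coordinates plus per-atom bookkeeping."""

    coords: np.ndarray        # (N, 3) Å
    masses: np.ndarray        # (N,) u
    elements: np.ndarray      # (N,) str
    res_index: np.ndarray     # (N,) int, residue serial within chain
    res_name: np.ndarray      # (N,) str
    chain: np.ndarray         # (N,) str
    id: str = "structure"

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=float)
        self.masses = np.asarray(self.masses, dtype=float)
        n = self.coords.shape[0]
        if self.coords.shape != (n, 3):
            raise InputError("coords must be (N, 3)")
        if not np.isfinite(self.coords).all():
            raise InputError("coordinates must be finite")
        if (self.masses <= 0).any():
            raise InputError("atomic masses must be positive")
        for name in ("elements", "res_index", "res_name", "chain"):
            arr = np.asarray(getattr(self, name))
            if arr.shape[0] != n:
                raise InputError(f"{name} length does not match atom count")
            setattr(self, name, arr)

    @property
    def n_atoms(self) -> int:
        return self.coords.shape[0]

    def with_coords(self, coords: np.ndarray, id: Optional[str] = None
                    ) -> "AtomicStructure":
        return AtomicStructure(
            coords=np.asarray(coords, dtype=float),
            masses=self.masses.copy(), elements=self.elements.copy(),
            res_index=self.res_index.copy(), res_name=self.res_name.copy(),
            chain=self.chain.copy(), id=id or self.id,
        )

    def residues(self) -> list[tuple[str, int, str, np.ndarray]]:
        """(chain, res_index, res_name, atom index array), in input order."""
        out, seen = [], {}
        for i in range(self.n_atoms):
            key = (str(self.chain[i]), int(self.res_index[i]))
            if key not in seen:
                seen[key] = len(out)
                out.append((key[0], key[1], str(self.res_name[i]), [i]))
            else:
                out[seen[key]][3].append(i)
        return [(c, r, n, np.asarray(ix)) for c, r, n, ix in out]


@dataclass
class StructuralEnsemble:
    members: list[AtomicStructure]
    reference_index: int = 0
    rmsds: Optional[np.ndarray] = None  # mass-weighted, to the reference

    @property
    def reference(self) -> AtomicStructure:
        return self.members[self.reference_index]

    def __len__(self) -> int:
        return len(self.members)


@dataclass
class ModeSet:
    """Orthonormal displacement modes in mass-weighted coordinate space."""

    modes: np.ndarray            # (n_modes, 3N), orthonormal rows
    scales: np.ndarray           # variance (EDA) or stiffness eigenvalue (ENM)
    sources: np.ndarray          # per-mode tag: "EDA" | "ENM"
    reference: AtomicStructure
    discarded_rigid: Optional[np.ndarray] = None  # near-zero ENM eigenvalues

    @property
    def n_modes(self) -> int:
        return self.modes.shape[0]


@dataclass
class Conformer:
    coords: np.ndarray
    mode_index: int
    direction: int
    achieved_mwrmsd: float
    mode_source: str = "EDA"
    id: str = ""


@dataclass
class ConformerEnsemble:
    conformers: list[Conformer]
    reference: AtomicStructure
    target_mwrmsd: float = 0.0

    def __len__(self) -> int:
        return len(self.conformers)


def mass_weighted_rmsd(a: np.ndarray, b: np.ndarray, masses: np.ndarray) -> float:
    """sqrt(sum_i m_i |a_i - b_i|^2 / sum_i m_i)."""
    d2 = ((np.asarray(a) - np.asarray(b)) ** 2).sum(axis=1)
    return float(np.sqrt((masses * d2).sum() / masses.sum()))


# ---------------------------------------------------------------------------
# repeat-window extraction
# ---------------------------------------------------------------------------

def _strand_repeats(res_names: Sequence[str]) -> int:
    """Number of complete consecutive C,U,G triples from the 5' end."""
    n = len(res_names)
    reps = 0
    while 3 * reps + 2 < n:
        a, b, c = res_names[3 * reps: 3 * reps + 3]
        if (a, b, c) != ("C", "U", "G"):
            break
        reps += 1
    return reps


def extract_repeat_windows(structure: AtomicStructure, n: int = 3
                           ) -> list[AtomicStructure]:
    """All contiguous ``n``-repeat windows of a CUG duplex.

    Each window keeps the ``n`` consecutive C,U,G triples of the first strand
    together with their base-paired partners on the second strand (pairing is
    antiparallel: residue ``i`` of strand one pairs with residue ``N-1-i`` of
    strand two).  A duplex with R repeats per strand yields R - n + 1 windows;
    fewer than ``n`` repeats yields an empty list.
    """
    if n < 1:
        raise ParameterError("window size must be >= 1")
    residues = structure.residues()
    chains = sorted({c for c, _, _, _ in residues})
    if len(chains) != 2:
        raise InputError("repeat-window extraction expects a two-chain duplex")
    by_chain = {c: [r for r in residues if r[0] == c] for c in chains}
    n_res = len(by_chain[chains[0]])
    if len(by_chain[chains[1]]) != n_res:
        raise CorrespondenceError("strands have unequal residue counts")
    reps = _strand_repeats([r[2] for r in by_chain[chains[0]]])
    if reps < n:
        return []
    windows = []
    for w in range(reps - n + 1):
        first = range(3 * w, 3 * w + 3 * n)
        partner = [n_res - 1 - i for i in reversed(first)]
        idx = []
        for i in first:
            idx.extend(by_chain[chains[0]][i][3])
        for j in partner:
            idx.extend(by_chain[chains[1]][j][3])
        idx = np.asarray(idx)
        windows.append(AtomicStructure(
            coords=structure.coords[idx], masses=structure.masses[idx],
            elements=structure.elements[idx], res_index=structure.res_index[idx],
            res_name=structure.res_name[idx], chain=structure.chain[idx],
            id=f"{structure.id}:w{w}",
        ))
    return windows


# ---------------------------------------------------------------------------
# superposition
# ---------------------------------------------------------------------------

def kabsch(mobile: np.ndarray, target: np.ndarray, weights: np.ndarray
           ) -> tuple[np.ndarray, np.ndarray]:
    """Weighted least-squares rigid fit of ``mobile`` onto ``target``.

    Returns (rotation, translation) such that mobile @ R.T + t is optimal.
    """
    w = np.asarray(weights, dtype=float)
    w = w / w.sum()
    cm = (w[:, None] * mobile).sum(axis=0)
    ct = (w[:, None] * target).sum(axis=0)
    A = (w[:, None] * (target - ct)).T @ (mobile - cm)
    U, _, Vt = np.linalg.svd(A)
    d = np.sign(np.linalg.det(U @ Vt))
    D = np.diag([1.0, 1.0, d])
    R = U @ D @ Vt
    t = ct - R @ cm
    return R, t


def superimpose_ensemble(structures: Sequence[AtomicStructure],
                         reference_index: int = 0) -> StructuralEnsemble:
    """Mass-weighted Kabsch superposition of every member onto the reference."""
    if len(structures) < 1:
        raise InputError("no structures to superimpose")
    counts = {s.n_atoms for s in structures}
    if len(counts) != 1:
        raise CorrespondenceError(
            f"atom counts differ across members: {sorted(counts)}"
        )
    ref = structures[reference_index]
    members, rmsds = [], []
    for s in structures:
        R, t = kabsch(s.coords, ref.coords, s.masses)
        fitted = s.coords @ R.T + t
        members.append(s.with_coords(fitted))
        rmsds.append(mass_weighted_rmsd(fitted, ref.coords, s.masses))
    return StructuralEnsemble(members=members, reference_index=reference_index,
                              rmsds=np.asarray(rmsds))


# ---------------------------------------------------------------------------
# essential dynamics (EDA)
# ---------------------------------------------------------------------------

def compute_eda_modes(ensemble: StructuralEnsemble, n_modes: int = 20,
                      anm_cutoff: float = 8.0) -> ModeSet:
    """Principal components of the mass-weighted coordinate covariance.

    At most min(members - 1, 3N - 6) nontrivial components exist; when the
    ensemble supplies fewer than ``n_modes`` the set is completed with elastic
    network modes of the reference, orthogonalized against the EDA modes and
    tagged by source.
    """
    if len(ensemble) < 3:
        raise InputError("essential dynamics needs at least 3 ensemble members")
    ref = ensemble.reference
    sqm = np.sqrt(np.repeat(ref.masses, 3))
    X = np.stack([m.coords.ravel() for m in ensemble.members]) * sqm
    Xc = X - X.mean(axis=0)
    if float((Xc ** 2).sum()) <= 1e-18:
        raise DegenerateInputError(
            "ensemble members are identical: zero coordinate covariance"
        )
    _, s, vt = np.linalg.svd(Xc, full_matrices=False)
    var = s ** 2 / (len(ensemble) - 1)
    keep = var > 1e-10 * var[0]
    modes, scales = vt[keep], var[keep]
    sources = ["EDA"] * modes.shape[0]
    if modes.shape[0] > n_modes:
        modes, scales = modes[:n_modes], scales[:n_modes]
        sources = sources[:n_modes]
    elif modes.shape[0] < n_modes:
        anm = build_anm_modes(ref, cutoff=anm_cutoff,
                              n_modes=n_modes)  # supplement
        for vec, lam in zip(anm.modes, anm.scales):
            if modes.shape[0] >= n_modes:
                break
            # Gram-Schmidt against everything accepted so far
            v = vec - modes.T @ (modes @ vec)
            nrm = np.linalg.norm(v)
            if nrm < 1e-6:
                continue
            modes = np.vstack([modes, v / nrm])
            scales = np.append(scales, lam)
            sources.append("ENM")
    return ModeSet(modes=modes, scales=scales, sources=np.asarray(sources),
                   reference=ref)


# ---------------------------------------------------------------------------
# anisotropic elastic network (ANM)
# ---------------------------------------------------------------------------

def anm_hessian(coords: np.ndarray, cutoff: float, gamma: float = 1.0
                ) -> np.ndarray:
    """Dense 3N x 3N ANM Hessian with unit spring constant within ``cutoff``."""
    n = coords.shape[0]
    H = np.zeros((3 * n, 3 * n))
    d = cdist(coords, coords)
    for i in range(n):
        for j in range(i + 1, n):
            if d[i, j] > cutoff or d[i, j] == 0.0:
                continue
            dr = coords[j] - coords[i]
            block = -gamma * np.outer(dr, dr) / d[i, j] ** 2
            H[3 * i: 3 * i + 3, 3 * j: 3 * j + 3] = block
            H[3 * j: 3 * j + 3, 3 * i: 3 * i + 3] = block
            H[3 * i: 3 * i + 3, 3 * i: 3 * i + 3] -= block
            H[3 * j: 3 * j + 3, 3 * j: 3 * j + 3] -= block
    return H


def build_anm_modes(structure: AtomicStructure, cutoff: float = 8.0,
                    n_modes: int = 20, gamma: float = 1.0) -> ModeSet:
    """Low-frequency normal modes of an all-atom anisotropic network model.

    The Hessian is mass-weighted (H' = M^-1/2 H M^-1/2) and diagonalized; the
    six near-zero rigid-body modes are discarded and recorded, and the
    ``n_modes`` lowest remaining eigenvectors are returned.
    """
    coords = structure.coords
    n = coords.shape[0]
    if n < 3:
        raise InputError("elastic network needs at least 3 atoms")
    adj = (cdist(coords, coords) <= cutoff) & ~np.eye(n, dtype=bool)
    n_comp, labels = connected_components(adj, directed=False)
    if n_comp > 1:
        sizes = np.bincount(labels)
        raise DisconnectedNetworkError(
            f"elastic network splits into {n_comp} components at cutoff "
            f"{cutoff} Å (sizes {sizes.tolist()})",
            components=[np.where(labels == k)[0] for k in range(n_comp)],
        )
    H = anm_hessian(coords, cutoff, gamma)
    inv_sqm = 1.0 / np.sqrt(np.repeat(structure.masses, 3))
    Hm = H * inv_sqm[:, None] * inv_sqm[None, :]
    evals, evecs = np.linalg.eigh(Hm)
    tol = 1e-8 * max(evals.max(), 1.0)
    near_zero = int((evals < tol).sum())
    if near_zero < 6:
        raise DegenerateInputError(
            f"expected >= 6 rigid-body modes, found {near_zero}"
        )
    rigid = evals[:near_zero]
    sel = slice(near_zero, near_zero + n_modes)
    return ModeSet(
        modes=evecs[:, sel].T.copy(),
        scales=evals[sel].copy(),
        sources=np.asarray(["ENM"] * evecs[:, sel].shape[1]),
        reference=structure,
        discarded_rigid=rigid,
    )


# ---------------------------------------------------------------------------
# mode deformation
# ---------------------------------------------------------------------------

def deform_along_mode(reference: AtomicStructure, mode: np.ndarray,
                      direction: int, target_mwrmsd: float,
                      mode_index: int = 0, mode_source: str = "EDA"
                      ) -> Conformer:
    """Displace the reference along a mass-weighted mode to an exact mwRMSD.

    x' = x + s * direction * M^-1/2 v with the closed-form amplitude
    s = target * sqrt(sum m) / |v|, which makes the mass-weighted RMSD of the
    deformed conformer equal to ``target_mwrmsd`` exactly (mwRMSD is linear
    in s for a fixed mode).
    """
    if direction not in (+1, -1):
        raise ParameterError("direction must be +1 or -1")
    if target_mwrmsd < 0:
        raise ParameterError("target mwRMSD must be >= 0")
    v = np.asarray(mode, dtype=float)
    if v.shape[0] != 3 * reference.n_atoms:
        raise InputError("mode dimension does not match the structure")
    nrm = np.linalg.norm(v)
    if nrm < 1e-12:
        raise DegenerateInputError("zero mode vector")
    sqm = np.sqrt(np.repeat(reference.masses, 3))
    disp = (v / nrm) / sqm                       # cartesian displacement shape
    s = target_mwrmsd * np.sqrt(reference.masses.sum())
    coords = reference.coords + direction * s * disp.reshape(-1, 3)
    achieved = mass_weighted_rmsd(coords, reference.coords, reference.masses)
    return Conformer(coords=coords, mode_index=mode_index, direction=direction,
                     achieved_mwrmsd=achieved, mode_source=mode_source,
                     id=f"m{mode_index:02d}{'p' if direction > 0 else 'n'}")


def build_ensemble(reference: AtomicStructure, modes: ModeSet,
                   per_mode: int = 2, target_mwrmsd: float = 2.0
                   ) -> ConformerEnsemble:
    """Deform the reference along every mode; two directions per mode.

    With 20 modes and two deformations per mode this yields the 40-conformer
    receptor ensemble used for conformational-selection docking.
    """
    if per_mode not in (1, 2):
        raise ParameterError("per_mode must be 1 or 2")
    if modes.n_modes == 0:
        raise InputError("empty mode set")
    directions = (+1,) if per_mode == 1 else (+1, -1)
    conformers = []
    for k in range(modes.n_modes):
        for direction in directions:
            conformers.append(deform_along_mode(
                reference, modes.modes[k], direction, target_mwrmsd,
                mode_index=k, mode_source=str(modes.sources[k]),
            ))
    return ConformerEnsemble(conformers=conformers, reference=reference,
                             target_mwrmsd=target_mwrmsd)
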