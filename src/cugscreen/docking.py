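"""Conformational-selection ensemble docking orchestration.

Every ligand is docked against every conformer of the receptor ensemble
through a pluggable pose-engine contract; poses are pooled, optionally
re-scored by a second (RNA-specific) scoring contract, and ligands are ranked
by their best pooled score.  With a 40-conformer ensemble and 50 poses per
run this yields the canonical 2000 candidate bindings per compound.

Engine contract:   engine(ligand, conformer, n_poses, seed) -> list[Pose]
Scorer contract:   scorer(pose) -> float  (lower is better)
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable, Optional, Sequence

import numpy as np
import pandas as pd

from .chemspace import Molecule
from .ensemble import Conformer, ConformerEnsemble
from .errors import InputError, ParameterError


@dataclass
class Pose:
    ligand_id: str
    conformer_id: str
    pose_index: int
    score: float
    rescore: Optional[float] = None
    coords: Optional[np.ndarray] = None

    @property
    def key(self) -> tuple:
        return (self.ligand_id, self.conformer_id, self.pose_index)


@dataclass
class LigandResult:
    ligand_id: str
    best_score: float
    best_conformer: str
    best_pose_index: int
    pose_count: int
    distinct_conformers_top10: int


@dataclass
class ScreenReport:
    ranking: list[LigandResult]
    excluded: list[str] = field(default_factory=list)
    failures: int = 0

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame([{
            "rank": i + 1,
            "ligand": r.ligand_id,
            "best_score": r.best_score,
            "best_conformer": r.best_conformer,
            "best_pose": r.best_pose_index,
            "poses": r.pose_count,
            "conformers_in_top10": r.distinct_conformers_top10,
        } for i, r in enumerate(self.ranking)])


def dock_ensemble(ligands: Sequence[Molecule], ensemble: ConformerEnsemble,
                  engine: Callable, n_poses_per_run: int, seed: int = 0
                  ) -> tuple[list[Pose], int]:
    """One engine call per (ligand, conformer); returns pooled poses.

    ``n_poses_per_run`` has no default on purpose: the per-run pose quota is a
    study design choice, not a property of the engine.  Engine failures on a
    single cell are tolerated; the run continues and the failure count is
    returned alongside the poses.
    """
    if n_poses_per_run < 1:
        raise ParameterError("n_poses_per_run must be >= 1")
    poses: list[Pose] = []
    failures = 0
    for lig in ligands:
        for conf in ensemble.conformers:
            try:
                emitted = engine(lig, conf, n_poses_per_run, seed)
            except Exception:
                failures += 1
                continue
            if len(emitted) > n_poses_per_run:
                raise InputError(
                    f"engine emitted {len(emitted)} poses, quota is "
                    f"{n_poses_per_run}"
                )
            poses.extend(emitted)
    return poses, failures


def passthrough_scorer(pose: Pose) -> float:
    """Keeps the engine score: used when no external re-scoring is available."""
    return pose.score


def rescore_poses(poses: Sequence[Pose], scorer: Callable = passthrough_scorer
                  ) -> tuple[list[Pose], int]:
    """Populate the rescore field; original engine scores are preserved.

    Poses on which the scorer raises are left unscored and counted; they are
    excluded from ranking downstream.
    """
    if not poses:
        raise InputError("no poses to rescore")
    out, unscored = [], 0
    for p in poses:
        try:
            out.append(replace(p, rescore=float(scorer(p))))
        except Exception:
            out.append(replace(p, rescore=None))
            unscored += 1
    return out, unscored


def rank_ligands(poses: Sequence[Pose]) -> ScreenReport:
    """Rank ligands by their best (minimum) rescore across all poses.

    Ties are broken by ligand id.  Per ligand the report records the conformer
    realizing the best pose and how many distinct receptor conformers appear
    among its ten best poses — the conformational-selection diagnostic: a
    ligand whose top poses spread over several conformers is recognizing more
    than one pre-existing receptor state.
    """
    if not poses:
        raise InputError("no poses to rank")
    by_ligand: dict[str, list[Pose]] = {}
    for p in poses:
        by_ligand.setdefault(p.ligand_id, []).append(p)
    results, excluded = [], []
    for lig, plist in by_ligand.items():
        scored = [p for p in plist if p.rescore is not None]
        if not scored:
            excluded.append(lig)
            continue
        scored.sort(key=lambda p: (p.rescore, p.conformer_id, p.pose_index))
        best = scored[0]
        top10 = scored[:10]
        results.append(LigandResult(
            ligand_id=lig,
            best_score=best.rescore,
            best_conformer=best.conformer_id,
            best_pose_index=best.pose_index,
            pose_count=len(plist),
            distinct_conformers_top10=len({p.conformer_id for p in top10}),
        ))
    results.sort(key=lambda r: (r.best_score, r.ligand_id))
    return ScreenReport(ranking=results, excluded=sorted(excluded))


def poses_to_dataframe(poses: Sequence[Pose]) -> pd.DataFrame:
    return pd.DataFrame([{
        "ligand": p.ligand_id, "conformer": p.conformer_id,
        "pose": p.pose_index, "score": p.score, "rescore": p.rescore,
    } for p in poses])
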