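"""Probe-density druggability maps: occupancy grids, hotspots, binding sites.

Probe-molecule snapshots from a (real or synthetic) co-solvent simulation are
binned onto a voxel grid.  Boltzmann inversion of the occupancy relative to a
uniform bulk expectation converts counts to per-voxel binding free energies,

    dG_v = -RT ln(n_v / n_expected),    R = 1.987e-3 kcal/(mol K),

so a voxel visited e-fold more often than bulk scores -RT ln(e).  Local
minima below a threshold are hotspots (with a minimum mutual separation);
single-linkage clustering of hotspots gives candidate binding sites whose
summed free energy translates into a maximal achievable dissociation
constant K_d = exp(dG_total / RT).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.ndimage import minimum_filter

from .errors import InputError, ParameterError
from .synthetic import ProbeSnapshotSet

#: Gas constant in kcal / (mol K)
R_KCAL = 1.987e-3


@dataclass
class OccupancyGrid:
    origin: np.ndarray            # (3,), Å
    spacing: float                # Å
    shape: tuple[int, int, int]
    counts: np.ndarray            # (nx, ny, nz) total probe counts
    counts_by_type: dict[str, np.ndarray]
    n_frames: int

    @property
    def n_voxels(self) -> int:
        return int(np.prod(self.shape))

    @property
    def bulk_expected(self) -> float:
        """Uniform reference: total observations spread over all voxels."""
        return float(self.counts.sum()) / self.n_voxels

    def voxel_centers(self) -> np.ndarray:
        grids = np.meshgrid(*[self.origin[d] + (np.arange(self.shape[d]) + 0.5)
                              * self.spacing for d in range(3)], indexing="ij")
        return np.stack([g.ravel() for g in grids], axis=1)


@dataclass
class FreeEnergyGrid:
    origin: np.ndarray
    spacing: float
    shape: tuple[int, int, int]
    dg: np.ndarray                 # kcal/mol; NaN where undefined
    defined: np.ndarray            # bool mask (count > 0)
    temperature: float
    counts_by_type: dict[str, np.ndarray] = field(default_factory=dict)


@dataclass
class Hotspot:
    center: np.ndarray
    dg: float                      # kcal/mol
    dominant_probe: str
    voxel: tuple[int, int, int]


@dataclass
class BindingSite:
    hotspots: list[Hotspot]
    dg_total: float
    kd: float                      # molar
    probe_fractions: dict[str, float]


def bin_occupancy(snapshots: ProbeSnapshotSet, spacing: float = 0.5
                  ) -> OccupancyGrid:
    """Histogram probe centers per voxel, split by probe type."""
    if spacing <= 0:
        raise ParameterError("spacing must be positive")
    if snapshots.n_frames < 1:
        raise InputError("empty snapshot set")
    box = snapshots.box
    shape = tuple(int(np.ceil((box[1][d] - box[0][d]) / spacing))
                  for d in range(3))
    edges = [box[0][d] + spacing * np.arange(shape[d] + 1) for d in range(3)]
    # extend the last edge to the box boundary so border probes are kept
    for d in range(3):
        edges[d][-1] = max(edges[d][-1], box[1][d])
    nonempty = [(t, x) for t, x in snapshots.frames if len(t)]
    counts = np.zeros(shape)
    by_type: dict[str, np.ndarray] = {}
    if nonempty:
        all_types = np.concatenate([t for t, _ in nonempty])
        all_xyz = np.concatenate([x for _, x in nonempty])
        for t in np.unique(all_types):
            h, _ = np.histogramdd(all_xyz[all_types == t], bins=edges)
            counts += h
            by_type[str(t)] = h
    return OccupancyGrid(origin=np.asarray(box[0], dtype=float),
                         spacing=spacing, shape=shape, counts=counts,
                         counts_by_type=by_type,
                         n_frames=snapshots.n_frames)


def free_energy_grid(grid: OccupancyGrid, temperature: float = 298.15
                     ) -> FreeEnergyGrid:
    """Boltzmann inversion of occupancy against the uniform bulk expectation.

    dG is a ratio of counts, so uniformly rescaling the number of frames
    leaves the grid unchanged.  Zero-count voxels have no defined free energy
    and are flagged.
    """
    if temperature <= 0:
        raise ParameterError("temperature must be positive")
    expected = grid.bulk_expected
    if expected <= 0:
        raise InputError("occupancy grid is empty")
    rt = R_KCAL * temperature
    defined = grid.counts > 0
    dg = np.full(grid.shape, np.nan)
    dg[defined] = -rt * np.log(grid.counts[defined] / expected)
    return FreeEnergyGrid(origin=grid.origin, spacing=grid.spacing,
                          shape=grid.shape, dg=dg, defined=defined,
                          temperature=temperature,
                          counts_by_type=grid.counts_by_type)


def detect_hotspots(fe: FreeEnergyGrid, threshold: float = -1.0,
                    min_separation: float = 1.5) -> list[Hotspot]:
    """Local minima of the free-energy grid below ``threshold``.

    Candidates are accepted greedily in ascending dG order (deepest first);
    a candidate closer than ``min_separation`` to an accepted hotspot is
    suppressed.
    """
    if threshold >= 0:
        raise ParameterError("hotspot threshold must be negative")
    filled = np.where(fe.defined, fe.dg, np.inf)
    local_min = (minimum_filter(filled, size=3, mode="constant", cval=np.inf)
                 == filled) & fe.defined & (filled < threshold)
    if not local_min.any():
        return []
    idx = np.argwhere(local_min)
    dgs = filled[local_min]
    order = np.argsort(dgs)
    accepted: list[Hotspot] = []
    for o in order:
        voxel = tuple(int(v) for v in idx[o])
        center = fe.origin + (np.asarray(voxel) + 0.5) * fe.spacing
        if any(np.linalg.norm(center - h.center) < min_separation
               for h in accepted):
            continue
        dominant = "unknown"
        if fe.counts_by_type:
            dominant = max(fe.counts_by_type,
                           key=lambda t: fe.counts_by_type[t][voxel])
        accepted.append(Hotspot(center=center, dg=float(dgs[o]),
                                dominant_probe=dominant, voxel=voxel))
    return accepted


def assemble_sites(hotspots: Sequence[Hotspot], merge_radius: float = 5.5,
                   temperature: float = 298.15,
                   counts_by_type: Optional[dict] = None) -> list[BindingSite]:
    """Single-linkage clustering of hotspots into binding sites.

    Per site the member free energies are summed and converted to a maximal
    achievable dissociation constant K_d = exp(dG_total / RT); sites are
    returned sorted by K_d ascending (tightest binding first).  Adding a
    negative-dG hotspot to a site can only decrease its K_d.
    """
    if merge_radius <= 0:
        raise ParameterError("merge_radius must be positive")
    hotspots = list(hotspots)
    if not hotspots:
        return []
    rt = R_KCAL * temperature
    centers = np.stack([h.center for h in hotspots])
    if len(hotspots) == 1:
        labels = np.array([1])
    else:
        Z = linkage(centers, method="single")
        labels = fcluster(Z, t=merge_radius, criterion="distance")
    sites = []
    for lab in np.unique(labels):
        members = [h for h, l in zip(hotspots, labels) if l == lab]
        dg_total = float(sum(h.dg for h in members))
        tallies: dict[str, float] = {}
        for h in members:
            tallies[h.dominant_probe] = tallies.get(h.dominant_probe, 0) + 1
        total = sum(tallies.values())
        sites.append(BindingSite(
            hotspots=members, dg_total=dg_total,
            kd=float(np.exp(dg_total / rt)),
            probe_fractions={t: c / total for t, c in tallies.items()},
        ))
    sites.sort(key=lambda s: s.kd)
    return sites
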