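"""Maximin diversity selection in descriptor space.

Given a standardized descriptor matrix, the task is to pick the k most
mutually dissimilar compounds: the subset maximizing the minimum pairwise
Euclidean distance (the maximin criterion).  The optimizer is a genetic
algorithm over fixed-size index subsets — tournament selection, uniform
crossover with duplicate repair, random-swap mutation and elitism — with an
exhaustive enumerator serving as the exact oracle on small instances.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from math import comb
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from rdkit.Chem import Crippen, Descriptors, Lipinski, rdMolDescriptors

from .chemspace import CompoundLibrary
from .errors import InputError, ParameterError


@dataclass
class DescriptorMatrix:
    matrix: np.ndarray                 # (n, d) standardized, no missing values
    ids: list[str]
    column_names: list[str]
    means: np.ndarray
    stds: np.ndarray
    dropped_columns: list[str] = field(default_factory=list)

    @property
    def n(self) -> int:
        return self.matrix.shape[0]


@dataclass
class SubsetSelection:
    indices: np.ndarray
    fitness: float                     # min pairwise Euclidean distance
    ga_trace: Optional[np.ndarray] = None  # best fitness per generation
    method: str = "ga"


def standardize_descriptors(raw, ids: Optional[Sequence[str]] = None,
                            column_names: Optional[Sequence[str]] = None
                            ) -> DescriptorMatrix:
    """Z-score columns; zero-variance columns are dropped and recorded."""
    if isinstance(raw, pd.DataFrame):
        column_names = list(raw.columns)
        ids = ids if ids is not None else [str(i) for i in raw.index]
        X = raw.to_numpy(dtype=float)
    else:
        X = np.asarray(raw, dtype=float)
        column_names = list(column_names or
                            [f"d{j}" for j in range(X.shape[1])])
        ids = list(ids or [str(i) for i in range(X.shape[0])])
    if X.ndim != 2 or X.shape[0] < 2:
        raise InputError("need a matrix with at least 2 rows")
    if not np.isfinite(X).all():
        raise InputError("descriptor matrix contains missing/non-finite values")
    means = X.mean(axis=0)
    stds = X.std(axis=0, ddof=0)
    keep = stds > 1e-12
    dropped = [c for c, k in zip(column_names, keep) if not k]
    Z = (X[:, keep] - means[keep]) / stds[keep]
    return DescriptorMatrix(matrix=Z, ids=list(ids),
                            column_names=[c for c, k in
                                          zip(column_names, keep) if k],
                            means=means[keep], stds=stds[keep],
                            dropped_columns=dropped)


def _distance_matrix(matrix: np.ndarray) -> np.ndarray:
    from scipy.spatial.distance import pdist, squareform
    return squareform(pdist(matrix))


def maximin_fitness(matrix: np.ndarray | DescriptorMatrix,
                    subset: Sequence[int]) -> float:
    """Minimum pairwise Euclidean distance within the subset."""
    X = matrix.matrix if isinstance(matrix, DescriptorMatrix) else \
        np.asarray(matrix, dtype=float)
    idx = np.asarray(list(subset), dtype=int)
    if idx.shape[0] < 2:
        raise ParameterError("subset must contain at least 2 indices")
    sub = X[idx]
    d2 = ((sub[:, None, :] - sub[None, :, :]) ** 2).sum(axis=2)
    iu = np.triu_indices(len(idx), k=1)
    return float(np.sqrt(d2[iu].min()))


def _subset_fitness(D: np.ndarray, idx: np.ndarray) -> float:
    sub = D[np.ix_(idx, idx)]
    iu = np.triu_indices(len(idx), k=1)
    return float(sub[iu].min())


def exhaustive_select(matrix: np.ndarray | DescriptorMatrix, k: int,
                      max_subsets: int = 10 ** 6) -> SubsetSelection:
    """True maximin optimum by enumeration (test oracle for the GA)."""
    X = matrix.matrix if isinstance(matrix, DescriptorMatrix) else \
        np.asarray(matrix, dtype=float)
    n = X.shape[0]
    if not 2 <= k <= n:
        raise ParameterError("need 2 <= k <= number of rows")
    n_subsets = comb(n, k)
    if n_subsets > max_subsets:
        raise ParameterError(
            f"C({n},{k}) = {n_subsets} subsets exceeds the enumeration bound "
            f"of {max_subsets}"
        )
    D = _distance_matrix(X)
    best_fit, best_idx = -np.inf, None
    for subset in combinations(range(n), k):
        idx = np.asarray(subset)
        fit = _subset_fitness(D, idx)
        if fit > best_fit:
            best_fit, best_idx = fit, idx
    return SubsetSelection(indices=best_idx, fitness=best_fit,
                           method="exhaustive")


def ga_select(matrix: np.ndarray | DescriptorMatrix, k: int,
              population: int = 100, generations: int = 500,
              mutation_rate: float = 0.1, tournament: int = 3,
              elitism: int = 1, seed: int = 0) -> SubsetSelection:
    """Genetic-algorithm maximin subset selection.

    Individuals are fixed-size index subsets.  Each generation applies
    tournament selection, uniform crossover (union of parents sampled back
    down to size k, repairing duplicates), random-swap mutation, and carries
    the elite through unchanged; the best-ever subset is returned and the
    per-generation best-fitness trace is non-decreasing by construction.
    """
    X = matrix.matrix if isinstance(matrix, DescriptorMatrix) else \
        np.asarray(matrix, dtype=float)
    n = X.shape[0]
    if not 2 <= k <= n:
        raise ParameterError("need 2 <= k <= number of rows")
    rng = np.random.default_rng(seed)
    D = _distance_matrix(X)

    if k == n:
        idx = np.arange(n)
        return SubsetSelection(indices=idx, fitness=_subset_fitness(D, idx),
                               ga_trace=np.asarray([_subset_fitness(D, idx)]))

    pop = np.stack([rng.choice(n, size=k, replace=False)
                    for _ in range(population)])
    fitness = np.array([_subset_fitness(D, ind) for ind in pop])
    best_idx = pop[fitness.argmax()].copy()
    best_fit = float(fitness.max())
    trace = [best_fit]

    for _ in range(generations):
        order = np.argsort(-fitness)
        new_pop = [pop[order[e]].copy() for e in range(elitism)]
        while len(new_pop) < population:
            parents = []
            for _ in range(2):
                contenders = rng.integers(population, size=tournament)
                parents.append(pop[contenders[fitness[contenders].argmax()]])
            pool = np.union1d(parents[0], parents[1])
            child = rng.choice(pool, size=min(k, len(pool)), replace=False)
            if len(child) < k:  # repair: top up with unused indices
                extra = np.setdiff1d(np.arange(n), child)
                child = np.concatenate([
                    child, rng.choice(extra, size=k - len(child),
                                      replace=False)])
            if rng.random() < mutation_rate:
                outside = np.setdiff1d(np.arange(n), child)
                if len(outside):
                    child[rng.integers(k)] = outside[rng.integers(len(outside))]
            new_pop.append(np.sort(child))
        pop = np.stack(new_pop)
        fitness = np.array([_subset_fitness(D, ind) for ind in pop])
        gen_best = float(fitness.max())
        if gen_best > best_fit:
            best_fit = gen_best
            best_idx = pop[fitness.argmax()].copy()
        trace.append(best_fit)

    return SubsetSelection(indices=np.sort(best_idx), fitness=best_fit,
                           ga_trace=np.asarray(trace))


# ---------------------------------------------------------------------------
# shipped descriptor set
# ---------------------------------------------------------------------------

_DESCRIPTOR_FUNCS = [
    ("mw", Descriptors.MolWt),
    ("heavy_atoms", Descriptors.HeavyAtomCount),
    ("hba", Lipinski.NumHAcceptors),
    ("hbd", Lipinski.NumHDonors),
    ("rotatable_bonds", Lipinski.NumRotatableBonds),
    ("rings", rdMolDescriptors.CalcNumRings),
    ("aromatic_rings", rdMolDescriptors.CalcNumAromaticRings),
    ("aliphatic_rings", rdMolDescriptors.CalcNumAliphaticRings),
    ("saturated_rings", rdMolDescriptors.CalcNumSaturatedRings),
    ("hetero_rings", rdMolDescriptors.CalcNumHeterocycles),
    ("tpsa", rdMolDescriptors.CalcTPSA),
    ("xlogp", Crippen.MolLogP),
    ("molar_refractivity", Crippen.MolMR),
    ("fraction_csp3", rdMolDescriptors.CalcFractionCSP3),
    ("n_count", lambda m: sum(a.GetAtomicNum() == 7 for a in m.GetAtoms())),
    ("o_count", lambda m: sum(a.GetAtomicNum() == 8 for a in m.GetAtoms())),
    ("s_count", lambda m: sum(a.GetAtomicNum() == 16 for a in m.GetAtoms())),
    ("halogen_count", lambda m: sum(a.GetAtomicNum() in (9, 17, 35, 53)
                                    for a in m.GetAtoms())),
    ("formal_charge", lambda m: sum(a.GetFormalCharge() for a in m.GetAtoms())),
    ("nhoh_count", Lipinski.NHOHCount),
    ("no_count", Lipinski.NOCount),
    ("balaban_j", Descriptors.BalabanJ),
    ("bertz_ct", Descriptors.BertzCT),
    ("chi0v", Descriptors.Chi0v),
    ("chi1v", Descriptors.Chi1v),
    ("chi2v", Descriptors.Chi2v),
    ("kappa1", Descriptors.Kappa1),
    ("kappa2", Descriptors.Kappa2),
    ("kappa3", Descriptors.Kappa3),
    ("labute_asa", Descriptors.LabuteASA),
    ("hall_kier_alpha", Descriptors.HallKierAlpha),
    ("fp_density", Descriptors.FpDensityMorgan2),
]


def compute_descriptor_matrix(library: CompoundLibrary) -> pd.DataFrame:
    """The shipped 32-descriptor profile (2-D structural + physicochemical).

    A compact, fully open descriptor set standing in for proprietary
    attribute collections; any user-supplied numeric matrix is equally
    accepted by the selection functions.
    """
    rows = {}
    for molecule in library.molecules:
        rows[molecule.id] = {name: float(func(molecule.mol))
                             for name, func in _DESCRIPTOR_FUNCS}
    return pd.DataFrame.from_dict(rows, orient="index")
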