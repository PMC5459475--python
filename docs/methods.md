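# Methods

This note records the models behind each pipeline stage, the tunable
parameters and their defaults, what the synthetic generators emulate, and the
design choices made where the published protocols leave the details open.

## Chemical space and the active region

Compounds are encoded as hashed circular count fingerprints (Morgan/ECFP
family; radius 2, 1024 positions by default — the length must be a power of
two). Circular environments are canonical graph invariants, so the vector is
independent of atom numbering. The chemical-space model is a mean-centered
PCA of the count vectors computed by SVD; components are sorted by variance
and each eigenvector's sign is fixed so its largest-magnitude loading is
positive, removing the platform-dependent sign ambiguity. A library of
identical fingerprints has no principal axes and raises a degenerate-input
error rather than returning arbitrary directions.

The *active region* is defined operationally rather than pictorially: a
Gaussian KDE (Scott bandwidth) is fitted on the 2-D projections of active
compounds only — inconclusive compounds are excluded from region training —
and the region is the KDE level set whose threshold is the ⌊(1−level)·n⌋-th
smallest training density, which guarantees at least `level` (default 0.90)
of the training actives are members. Candidate selection intersects region
membership with a Rule-of-Five filter (violations of MW ≤ 500, HBD ≤ 5,
HBA ≤ 10, xlogP ≤ 5; "conforming" means at most one violation).

Property definitions: HBD = N/O bearing ≥ 1 hydrogen; HBA = N/O excluding
pyrrole-type and amide nitrogens (conventional Lipinski-style rules as
implemented in RDKit); TPSA by the fragment-additive topological method;
xlogP by the Wildman–Crippen atom-additive scheme. These are open,
reproducible stand-ins for the proprietary property calculators often used
in published screens; absolute xlogP values can differ from other
implementations by a few tenths.

## Fragment statistics

RECAP fragmentation (RDKit implementation of the eleven retrosynthetic bond
rules) reduces each compound to terminal fragments; fragment identity is the
canonical SMILES with attachment points erased (dummy atoms → H), so the same
substituent is counted once regardless of which bond it was cleaved from.
The activity-adjusted frequency is

    AAF(f) = 100 · Σ_m w(m)·I[f ∈ frags(m)] / Σ_f' Σ_m w(m)·I[f' ∈ frags(m)]

with weights w = 1 (active), 0.5 (inconclusive), 0 (inactive), and
*per-compound 0/1 incidence*: a fragment occurring twice in one compound
counts once. Both the weighting and the incidence convention are design
choices of this package (the statistic is usually reported without a printed
formula); they make the table sum to exactly 100% and make inactive
compounds provably irrelevant to every AAF value. A library with zero total
weight (no active or inconclusive members) has no defined table and raises.

## Gaussian shape and electrostatic similarity

Atoms are spherical Gaussians p·exp(−α r²) with amplitude p = 2.7 and
α_i = (κ/r_vdw,i)², κ = √(π·(3p/4π)^(2/3)) ≈ 1.5312 — the hard-sphere
volume-matching (Grant–Pickup) parameterization. Molecular overlap is the
analytic double sum over atom pairs; first-order (pairwise) overlap only, no
higher-order inclusion–exclusion corrections. Alignment maximizes shape
overlap with a Powell search over rotation vector + translation from four
proper principal-axes starts (axis-flip degeneracy), and is guaranteed never
to return less overlap than the best rigid start. The electrostatic Tanimoto
uses the same Gaussian widths with partial charges as weights, evaluated at
the shape-optimal pose (not re-optimized) — it can be negative for
anti-correlated charge distributions. Charges come from the input SDF when
present, otherwise from Gasteiger iterative electronegativity equalization;
when neither is available the electrostatic term is reported absent and the
combined score undefined. The combined score is ST + ET, which is why
published similarity windows for this protocol exceed 1. One conformer per
molecule is scored; multi-conformer queries must be expanded upstream.

## Maximin diversity selection

Descriptors are z-scored; zero-variance columns are dropped and recorded.
The shipped descriptor set is 32 open 2-D structural/physicochemical RDKit
descriptors (counts, ring statistics, connectivity and shape indices,
property-profile values, fingerprint density); any numeric matrix is
accepted. The GA works on fixed-size index subsets with tournament selection
(size 3), uniform crossover (union of parents re-sampled to size k with
duplicate repair), random-swap mutation (rate 0.1), elitism 1, population
100, 500 generations. These defaults were validated against the exhaustive
enumerator (bound 10⁶ subsets) on small fixtures; the best-ever subset is
returned and the best-fitness trace is non-decreasing by construction. The
two-stage subset sizes used in published screens (50 most dissimilar, then
12, then a purchased handful) are left entirely to the caller — k is a
parameter with no fidelity claim.

## Receptor ensemble from essential dynamics / elastic networks

Structures are point atoms with masses; all structural operations need only
coordinates, masses, and residue bookkeeping. Three-repeat windows of longer
CUG duplexes are extracted with their antiparallel base-pairing partners
(residue i of strand one pairs with residue N−1−i of strand two); a duplex
with R repeats yields R−3+1 windows. Superposition is mass-weighted Kabsch.

Two mode sources are implemented and tagged per mode:

- **EDA** — principal components of the mass-weighted coordinate covariance
  across ensemble members (at most members−1 nontrivial components);
- **ENM/ANM** — an anisotropic elastic network over all atoms (unit spring
  constant, default cutoff 8 Å), mass-weighted Hessian, dense
  eigendecomposition; exactly six near-zero rigid-body modes are discarded
  and recorded, and a disconnected network at the chosen cutoff is an error
  that names the components.

When an ensemble supplies fewer EDA components than requested, the mode set
is completed with ENM modes Gram-Schmidt-orthogonalized against the EDA
modes, so the returned set is always orthonormal in mass-weighted space with
an auditable source tag per mode.

Deformation along a mode is exact: x′ = x + s·(±1)·M^(−1/2)v with
s = target·√(Σmᵢ)/|v|, so the mass-weighted RMSD of every emitted conformer
equals the target (default 2 Å) to machine precision — "up to 2 Å" is read
as the endpoint amplitude; intermediate amplitudes are available by passing
a smaller target. The standard protocol (20 modes × 2 directions) yields 40
conformers; +/− conformers of one mode average back to the reference by
linearity.

## Druggability maps

Probe centers are binned on a voxel grid (default spacing 0.5 Å). The bulk
reference is the uniform expectation — total observations divided by voxel
count — which is the simplest auditable null; it slightly inflates the
expectation when strong hotspots contribute a non-negligible fraction of all
observations (for the synthetic defaults below the resulting bias is
≈ 0.04–0.07 kcal/mol, well inside the 0.2 kcal/mol recovery tolerance used
in the tests). A solvent-shell reference would remove this bias and is a
known limitation. Boltzmann inversion uses R = 1.987×10⁻³ kcal/(mol·K) and
T = 298.15 K by default; zero-count voxels are flagged undefined, not
assigned a value. Hotspots are strict 26-neighbor local minima below a
threshold (default −1.0 kcal/mol), accepted deepest-first with an exclusion
radius (default 1.5 Å); a broad density peak can legitimately produce
several hotspots farther apart than the exclusion radius. Sites are
single-linkage clusters of hotspots at a merge radius (default 5.5 Å,
a drug-sized aggregation scale); the site free energy is the plain sum of
member hotspot energies and the maximal achievable affinity is
K_d = exp(ΔG_total/RT). Which hotspots should be summed into one "site" is
not standardized in the literature; the single-linkage rule is an explicit,
configurable stand-in.

## Ensemble docking orchestration

The pose engine and re-scorer are contracts, not implementations: the engine
is any callable (ligand, conformer, n_poses, seed) → poses that is
deterministic given its seed and respects the pose quota; the re-scorer is
any callable pose → float with lower = better (higher-is-better services
must be wrapped with a polarity flip in their adapter). `n_poses_per_run`
has **no default**: published descriptions of this protocol state both 20
and 50 poses per run in different places, so the quota is an explicit study
parameter; the canonical 2000-poses-per-ligand total corresponds to 40
conformers × 50 poses. Engine failures on single (ligand, conformer) cells
are tolerated and counted; scorer failures leave poses unscored and excluded
from ranking with a count. Ranking is by per-ligand minimum rescore, ties
broken by ligand id, and the report records the conformer hosting each
ligand's best pose plus the number of distinct conformers among its top ten
poses (the conformational-selection diagnostic).

## Synthetic data: what it emulates, and what it does not

- **Compound library**: actives carry one of four planted chemotype cores
  (imidazole, benzimidazole, piperazine, pyridopyrimidine) with probability
  0.95 and small decorations, emulating the observation that true positives
  cluster tightly in fingerprint space; inactives are drawn from a wide pool
  of decoy scaffolds and substituents (never containing a planted
  chemotype), emulating the structural diversity of screening negatives;
  inconclusives are a 50/50 mixture at weight 0.5. Label counts are forced
  by rounding. The library does *not* emulate assay noise, activity cliffs,
  tautomers or stereochemistry — a passing enrichment test shows the
  machinery works on separable data, not that real qHTS data are separable.
- **RNA duplex**: an idealized A-form-like point-atom duplex (rise 2.81 Å,
  twist 32.7°, backbone radius 9.4 Å, 154° inter-strand phase, 6 atoms per
  residue running radially inward from backbone to base positions, C/U/G
  cycling, exact antiparallel pairing). It has correct bookkeeping, masses
  and connectivity scale, but no sugar/base chemistry, so mode shapes are
  qualitatively helical, not chemically meaningful.
- **Probe snapshots**: uniform Poisson background (bulk density default
  0.016 probes/Å³, chosen so a 0.5 Å voxel accumulates ~10 expected counts
  in 5000 frames) plus Gaussian hotspots with expected center excess
  enrichment × bulk; the planted truth is stored for recovery tests. Real
  co-solvent MD has correlated frames, excluded volume and probe–probe
  interactions, none of which are modeled.
- **Stub engine**: SHA-256-derived scores in a docking-like window
  [−12, −2], sorted ascending, reproducible across platforms. It exercises
  the orchestration (counts, provenance, determinism, failure handling),
  not binding physics.

## Numerical conventions

Coordinates in Å, masses in u, energies in kcal/mol, temperatures in K,
K_d in molar. PCA/EDA sign fixed by largest-|loading| positive. Eigenvalue
cutoffs: rigid modes < 1e-8 × the largest Hessian eigenvalue; PCA components
kept above 1e-12 × the leading variance. Ties in screens and rankings are
broken by compound/ligand id for full determinism. All generators are pure
functions of (parameters, seed); the test suite and the acceptance script
run in a few minutes on one CPU with the problem sizes stated above
(108-atom duplex, 200–1000-compound libraries, 5000-frame probe sets, 12-row
diversity fixtures), which are the package's chosen desk-scale study
conditions.
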