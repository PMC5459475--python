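# cugscreen

A virtual-screening pipeline for small molecules that recognize CUG-repeat
RNA, the toxic transcript structure of myotonic dystrophy type 1 (DM1).
Expanded CUG repeats fold into double-helical hairpins with periodic U-U
mismatches that sequester the MBNL1 splicing regulator; the screening problem
is to find drug-like small molecules that bind those hairpins and free MBNL1.

`cugscreen` implements the two halves of that discovery workflow as a tested,
reusable Python library for computational chemists:

**Ligand-based enrichment**

- *Chemical space* (`cugscreen.chemspace`): hashed circular (Morgan/ECFP
  "radial") count fingerprints, mean-centered PCA, physicochemical profiling
  (MW, HBA/HBD, formal charge, TPSA, xlogP, rotatable bonds), Rule-of-Five
  counting, and an "active region" — the highest-density level set of a 2-D
  Gaussian KDE fitted on the projections of active compounds — used to
  pre-select candidates.
- *Fragment statistics* (`cugscreen.fragments`): RECAP retrosynthetic
  fragmentation and the activity-adjusted frequency
  AAF(f) = 100 · Σₘ w(m)·I[f ∈ frags(m)] / Σ_f′ Σₘ w(m)·I[f′ ∈ frags(m)],
  with weights 1 / 0.5 / 0 for active / inconclusive / inactive compounds.
- *Shape & electrostatics* (`cugscreen.shape`): Grant–Pickup Gaussian volume
  overlap, shape Tanimoto ST = O_AB/(O_AA+O_BB−O_AB), charge-weighted
  electrostatic Tanimoto at the shape-optimal alignment, and the two-stage
  screen (rank by ST, re-rank the top block by ST+ET).
- *Diversity selection* (`cugscreen.diversity`): maximin subset selection —
  maximize the minimum pairwise Euclidean distance in standardized descriptor
  space — by a genetic algorithm, with an exhaustive oracle for validation.

**Structure-based prioritization**

- *Conformational ensembles* (`cugscreen.ensemble`): extraction of
  three-repeat duplex windows, mass-weighted Kabsch superposition, essential
  dynamics (PCA of the mass-weighted coordinate covariance) and/or
  anisotropic elastic-network modes, and deformation of the reference along
  each mode to an exact mass-weighted RMSD:
  x′ = x + s·(±1)·M^(−1/2)v with s chosen in closed form so that
  mwRMSD(x′, x) = target. Twenty modes × two directions at 2 Å give the
  40-conformer receptor ensemble.
- *Druggability* (`cugscreen.druggability`): probe-occupancy voxel grids,
  Boltzmann inversion ΔG_v = −RT ln(n_v/n_expected), hotspot detection
  (local minima with an exclusion radius), and single-linkage assembly of
  hotspots into binding sites with K_d = exp(ΔG_total/RT).
- *Ensemble docking* (`cugscreen.docking`): conformational-selection
  orchestration — every ligand against every conformer through a pluggable
  pose-engine contract (40 conformers × 50 poses/run = 2000 candidate
  bindings per ligand), pooled re-scoring, and ranking by best pose.

Every input the pipeline needs can be generated synthetically
(`cugscreen.synthetic`): labeled compound libraries whose actives carry
planted chemotypes (imidazole, benzimidazole, piperazine, pyridopyrimidine),
an idealized point-atom (CUG)ₙ duplex, probe snapshots with planted Gaussian
hotspots, descriptor clouds, and a deterministic hash-scored stub docking
engine, so the whole workflow is testable without downloads or external
engines.

## Worked example

```python
from cugscreen import synthetic as syn, ensemble as ens, docking as dk

duplex = syn.gen_rna_duplex(seed=0)                    # 108-atom (CUG)3 duplex
modes = ens.build_anm_modes(duplex, cutoff=8.0, n_modes=20)
conformers = ens.build_ensemble(duplex, modes, per_mode=2, target_mwrmsd=2.0)
print(len(conformers))                                 # 40

ligands = syn.gen_compound_library(4, 0.5, seed=1).molecules[:2]
poses, failures = dk.dock_ensemble(ligands, conformers,
                                   syn.stub_pose_engine,
                                   n_poses_per_run=50, seed=0)
print(len(poses) // len(ligands))                      # 2000
report = dk.rank_ligands(dk.rescore_poses(poses)[0])
print(report.to_dataframe().head(2).to_string(index=False))
```

prints

```
40
2000
 rank    ligand  best_score best_conformer  best_pose  poses  conformers_in_top10
    1 CMPD00000  -11.999247           m05p          0   2000                    8
    2 CMPD00001  -11.998466           m08n          0   2000                   10
```

The 40 conformers are the receptor ensemble (each exactly 2 Å mass-weighted
RMSD from the reference along one soft mode); each ligand accumulates 2000
stub-engine poses across the ensemble and is ranked by its best pooled score.
`conformers_in_top10` is the conformational-selection diagnostic: how many
distinct receptor conformations host the ligand's ten best poses.

A command-line interface mirrors the library:

```bash
cugscreen simulate library --n 200 --seed 0 --out lib.smi
cugscreen chemspace --library lib.smi --out selected.smi
cugscreen ensemble --n-modes 20 --rmsd 2.0 --out ensemble.pdb
cugscreen dock --ligands selected.smi --poses-per-run 50 --out ranking.csv
```

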