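"""Gaussian overlap closed forms, alignment recovery, two-stage screening."""

import numpy as np
import pytest
from rdkit import Chem
from scipy.spatial.transform import Rotation

from conftest import molecule_from_smiles, single_atom_molecule
from cugscreen import shape as sh
from cugscreen.chemspace import CompoundLibrary, Molecule
from cugscreen.errors import DegenerateInputError, InputError, ParameterError


def carbon_alpha():
    r = Chem.GetPeriodicTable().GetRvdw(6)
    return (sh.KAPPA / r) ** 2


class TestClosedForms:
    def test_two_identical_atoms_at_zero_separation(self):
        a = single_atom_molecule("C", (0, 0, 0), "a")
        b = single_atom_molecule("C", (0, 0, 0), "b")
        alpha = carbon_alpha()
        expected = sh.P_AMPLITUDE ** 2 * (np.pi / (2 * alpha)) ** 1.5
        assert sh.gaussian_overlap(a, b) == pytest.approx(expected,
                                                          rel=1e-10)

    @pytest.mark.parametrize("d", [0.5, 1.0, 2.0, 3.7])
    def test_separation_damping_factor(self, d):
        a = single_atom_molecule("C", (0, 0, 0), "a")
        b = single_atom_molecule("C", (d, 0, 0), "b")
        alpha = carbon_alpha()
        expected = (sh.P_AMPLITUDE ** 2 * (np.pi / (2 * alpha)) ** 1.5
                    * np.exp(-alpha * d * d / 2))
        assert sh.gaussian_overlap(a, b) == pytest.approx(expected,
                                                          rel=1e-10)

    def test_overlap_symmetric(self):
        rng = np.random.default_rng(0)
        for _ in range(5):
            xa, xb = rng.normal(size=3), rng.normal(size=3)
            a = single_atom_molecule("N", xa, "a")
            b = single_atom_molecule("O", xb, "b")
            assert sh.gaussian_overlap(a, b) == pytest.approx(
                sh.gaussian_overlap(b, a), rel=1e-12)

    def test_monotone_decay_with_distance(self):
        values = [sh.gaussian_overlap(single_atom_molecule("C", (0, 0, 0)),
                                      single_atom_molecule("C", (d, 0, 0)))
                  for d in np.linspace(0, 6, 25)]
        assert (np.diff(values) <= 0).all()

    def test_missing_coordinates_rejected(self):
        a = molecule_from_smiles("CCO")
        b = single_atom_molecule("C", (0, 0, 0))
        with pytest.raises(InputError):
            sh.gaussian_overlap(a, b)


@pytest.fixture(scope="module")
def embedded_query():
    pentamidine = "NC(=N)c1ccc(OCCCCCOc2ccc(C(N)=N)cc2)cc1"
    return sh.embed_3d(Molecule(Chem.MolFromSmiles(pentamidine), "query"),
                       seed=1)


def rigidly_moved(molecule, rotvec, translation, new_id="moved"):
    R = Rotation.from_rotvec(rotvec).as_matrix()
    mol = Chem.Mol(molecule.mol)
    conf = mol.GetConformer()
    moved = np.asarray(conf.GetPositions()) @ R.T + np.asarray(translation)
    for i, p in enumerate(moved):
        conf.SetAtomPosition(i, p.tolist())
    return Molecule(mol=mol, id=new_id, charges=molecule.charges)


class TestAlignment:
    def test_rotated_copy_recovers_self_overlap(self, embedded_query):
        copy = rigidly_moved(embedded_query, [0.4, -0.3, 0.9], [3, -2, 5])
        transform = sh.align_pair(embedded_query, copy)
        self_overlap = sh.gaussian_overlap(embedded_query, embedded_query)
        recovered = sh.gaussian_overlap(embedded_query, copy, transform)
        assert recovered == pytest.approx(self_overlap, rel=1e-4)

    def test_translation_recovered(self, embedded_query):
        shift = np.array([4.0, 1.0, -2.5])
        copy = rigidly_moved(embedded_query, [0, 0, 0], shift)
        transform = sh.align_pair(embedded_query, copy)
        aligned = transform.apply(copy.coords)
        assert np.abs(aligned - embedded_query.coords).max() < 1e-3

    def test_rotation_is_proper(self, embedded_query):
        copy = rigidly_moved(embedded_query, [1.0, 0.2, -0.5], [1, 2, 3])
        t = sh.align_pair(embedded_query, copy)
        assert np.abs(t.rotation @ t.rotation.T - np.eye(3)).max() < 1e-8
        assert np.linalg.det(t.rotation) == pytest.approx(1.0, abs=1e-8)

    def test_collinear_candidate_rejected(self, embedded_query):
        mol = Chem.MolFromSmiles("C#N")
        m = sh.embed_3d(Molecule(mol, "linear"), seed=0)
        with pytest.raises(DegenerateInputError):
            sh.align_pair(embedded_query, m)


class TestSimilarity:
    def test_self_similarity_identity(self, embedded_query):
        res = sh.similarity_scores(embedded_query, embedded_query,
                                   transform=sh.AlignmentTransform.identity())
        assert res.shape_tanimoto == pytest.approx(1.0, abs=1e-12)
        assert res.electrostatic_tanimoto == pytest.approx(1.0, abs=1e-12)
        assert res.combo == pytest.approx(2.0, abs=1e-12)

    def test_opposite_charges_negative_electrostatics(self):
        tri = [(0, 0, 0), (1.5, 0, 0), (0, 1.5, 0)]
        a_mols, b_mols = [], []
        for q, mols in ((0.4, a_mols), (-0.4, b_mols)):
            mol = Chem.RWMol()
            for _ in tri:
                mol.AddAtom(Chem.Atom("C"))
            m = mol.GetMol()
            conf = Chem.Conformer(3)
            for i, p in enumerate(tri):
                conf.SetAtomPosition(i, [float(v) for v in p])
            m.AddConformer(conf)
            mols.append(Molecule(mol=m, id=f"q{q}",
                                 charges=np.full(3, q)))
        res = sh.similarity_scores(a_mols[0], b_mols[0],
                                   transform=sh.AlignmentTransform.identity())
        assert res.electrostatic_tanimoto < 0

    def test_substructure_candidate_below_one(self, embedded_query):
        # candidate = embedded subset of the query's atoms at identical coords
        mol = Chem.RWMol()
        keep = list(range(embedded_query.mol.GetNumAtoms() // 2))
        for i in keep:
            mol.AddAtom(Chem.Atom(
                embedded_query.mol.GetAtomWithIdx(i).GetAtomicNum()))
        m = mol.GetMol()
        conf = Chem.Conformer(len(keep))
        for j, i in enumerate(keep):
            conf.SetAtomPosition(j, embedded_query.coords[i].tolist())
        m.AddConformer(conf)
        res = sh.similarity_scores(embedded_query, Molecule(m, "sub"),
                                   transform=sh.AlignmentTransform.identity())
        assert 0 < res.shape_tanimoto < 1

    def test_joint_rigid_motion_invariance(self, embedded_query):
        candidate = rigidly_moved(embedded_query, [0.2, 0.1, -0.3], [1, 0, 2],
                                  "cand")
        st0 = sh.similarity_scores(
            embedded_query, candidate,
            transform=sh.AlignmentTransform.identity()).shape_tanimoto
        both_moved_q = rigidly_moved(embedded_query, [0.7, -0.2, 0.4],
                                     [5, 5, 5], "q2")
        both_moved_c = rigidly_moved(candidate, [0.7, -0.2, 0.4],
                                     [5, 5, 5], "c2")
        st1 = sh.similarity_scores(
            both_moved_q, both_moved_c,
            transform=sh.AlignmentTransform.identity()).shape_tanimoto
        assert st1 == pytest.approx(st0, rel=1e-10)


@pytest.fixture(scope="module")
def embedded_library(embedded_query):
    smiles = ["Cc1nc2ccccc2[nH]1", "CCN1CCNCC1", "CCCCO", "c1ccncc1",
              "CC(=O)Nc1ccccc1", "COc1ccccc1", "CCCCCCCC", "OCC1CCCCC1",
              "Nc1ncc[nH]1"]
    mols = [sh.embed_3d(Molecule(Chem.MolFromSmiles(s), f"L{i:02d}"), seed=i)
            for i, s in enumerate(smiles)]
    return CompoundLibrary(molecules=mols + [embedded_query])


class TestScreen:
    def test_query_in_library_ranks_first(self, embedded_query,
                                          embedded_library):
        results = sh.screen_library(embedded_query, embedded_library,
                                    n_shape=10, n_final=5)
        assert results[0].candidate_id == "query"
        assert results[0].combo == pytest.approx(2.0, abs=1e-6)

    def test_bad_stage_sizes_rejected(self, embedded_query, embedded_library):
        with pytest.raises(ParameterError):
            sh.screen_library(embedded_query, embedded_library,
                              n_shape=3, n_final=5)

    def test_two_stage_equals_manual_protocol(self, embedded_query,
                                              embedded_library):
        # exhaustive oracle: apply the two-stage protocol by hand
        scored = [sh.similarity_scores(embedded_query, m)
                  for m in embedded_library]
        by_shape = sorted(scored,
                          key=lambda r: (-r.shape_tanimoto, r.candidate_id))
        shortlist = by_shape[:6]
        manual = sorted(shortlist,
                        key=lambda r: (-r.combo, r.candidate_id))[:3]
        auto = sh.screen_library(embedded_query, embedded_library,
                                 n_shape=6, n_final=3)
        assert [r.candidate_id for r in auto] == \
            [r.candidate_id for r in manual]

    def test_degenerate_protocol_sorts_by_combo(self, embedded_query,
                                                embedded_library):
        n = len(embedded_library)
        results = sh.screen_library(embedded_query, embedded_library,
                                    n_shape=n, n_final=n)
        combos = [r.combo for r in results]
        assert combos == sorted(combos, reverse=True)
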