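"""Windows, superposition, EDA/ANM modes, and exact-amplitude deformation."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from cugscreen import ensemble as ens
from cugscreen.errors import (CorrespondenceError, DegenerateInputError,
                              DisconnectedNetworkError, InputError,
                              ParameterError)
from cugscreen.synthetic import SyntheticRNASpec, gen_rna_duplex


def point_structure(coords, masses=None, sid="toy"):
    coords = np.asarray(coords, dtype=float)
    n = len(coords)
    return ens.AtomicStructure(
        coords=coords,
        masses=np.ones(n) if masses is None else np.asarray(masses, float),
        elements=np.array(["C"] * n), res_index=np.arange(n),
        res_name=np.array(["C"] * n), chain=np.array(["A"] * n), id=sid)


class TestWindows:
    def test_six_repeats_give_four_windows(self, duplex6):
        windows = ens.extract_repeat_windows(duplex6, 3)
        assert len(windows) == 4
        assert all(w.n_atoms == duplex6.n_atoms * 3 // 6 for w in windows)

    def test_exactly_three_repeats_single_window(self, duplex):
        windows = ens.extract_repeat_windows(duplex, 3)
        assert len(windows) == 1
        assert windows[0].n_atoms == duplex.n_atoms

    def test_too_short_duplex_empty(self):
        short = gen_rna_duplex(SyntheticRNASpec(n_repeats=2), seed=0)
        assert ens.extract_repeat_windows(short, 3) == []

    def test_windows_keep_pairing(self, duplex6):
        w = ens.extract_repeat_windows(duplex6, 3)[0]
        names_a = [n for c, _, n, _ in w.residues() if c == "A"]
        names_b = [n for c, _, n, _ in w.residues() if c == "B"]
        assert names_a == ["C", "U", "G"] * 3
        assert len(names_b) == 9


class TestSuperposition:
    def test_rigid_copy_fits_exactly(self, duplex):
        R = Rotation.from_rotvec([0.3, -1.1, 0.5]).as_matrix()
        moved = duplex.with_coords(duplex.coords @ R.T + [5.0, -3.0, 2.0])
        sup = ens.superimpose_ensemble([duplex, moved])
        assert sup.rmsds[1] < 1e-6

    def test_never_worse_than_unaligned(self, duplex6):
        windows = ens.extract_repeat_windows(duplex6, 3)
        sup = ens.superimpose_ensemble(windows)
        for raw, member in zip(windows, sup.members):
            before = ens.mass_weighted_rmsd(raw.coords,
                                            windows[0].coords, raw.masses)
            after = ens.mass_weighted_rmsd(member.coords,
                                           windows[0].coords, raw.masses)
            assert after <= before + 1e-12

    def test_two_point_closed_form(self):
        # target: 2 unit-mass atoms on the x axis; mobile: same pair on the
        # y axis.  Optimal fit is the 90° rotation, residual exactly 0.
        target = point_structure([[-1, 0, 0], [1, 0, 0]])
        mobile = point_structure([[0, -1, 0], [0, 1, 0]])
        R, t = ens.kabsch(mobile.coords, target.coords, mobile.masses)
        fitted = mobile.coords @ R.T + t
        assert np.abs(fitted - target.coords).max() < 1e-8

    def test_atom_count_mismatch_rejected(self, duplex):
        other = point_structure(np.zeros((4, 3)))
        with pytest.raises(CorrespondenceError):
            ens.superimpose_ensemble([duplex, other])


class TestEda:
    def _displaced_members(self, base, vectors, amplitudes):
        sqm = np.sqrt(np.repeat(base.masses, 3))
        members = []
        for amps in amplitudes:
            disp = sum(a * (v / sqm) for a, v in zip(amps, vectors))
            members.append(base.with_coords(
                base.coords + disp.reshape(-1, 3)))
        return members

    def test_rank_one_ensemble_single_mode(self, duplex):
        rng = np.random.default_rng(0)
        v = rng.normal(size=3 * duplex.n_atoms)
        v /= np.linalg.norm(v)
        members = self._displaced_members(duplex, [v],
                                          [(0,), (1,), (2,), (-1,)])
        modes = ens.compute_eda_modes(
            ens.StructuralEnsemble(members=members), n_modes=1)
        assert modes.n_modes == 1
        assert str(modes.sources[0]) == "EDA"
        assert abs(abs(modes.modes[0] @ v) - 1) < 1e-8

    def test_planted_two_dim_subspace_recovered(self, duplex):
        rng = np.random.default_rng(1)
        v1 = rng.normal(size=3 * duplex.n_atoms)
        v1 /= np.linalg.norm(v1)
        v2 = rng.normal(size=3 * duplex.n_atoms)
        v2 -= (v2 @ v1) * v1
        v2 /= np.linalg.norm(v2)
        amps = [(0.0, 0.0), (1.0, 0.2), (-0.5, 1.0), (2.0, -1.0), (0.3, 0.7)]
        members = self._displaced_members(duplex, [v1, v2], amps)
        modes = ens.compute_eda_modes(
            ens.StructuralEnsemble(members=members), n_modes=2)
        # principal angles between recovered and planted subspaces
        s = np.linalg.svd(modes.modes @ np.stack([v1, v2]).T,
                          compute_uv=False)
        assert np.abs(s - 1).max() < 1e-6

    def test_orthonormal_and_enm_supplement(self, duplex6):
        windows = ens.extract_repeat_windows(duplex6, 3)
        sup = ens.superimpose_ensemble(windows)
        modes = ens.compute_eda_modes(sup, n_modes=20)
        assert modes.n_modes == 20
        gram = modes.modes @ modes.modes.T
        assert np.abs(gram - np.eye(20)).max() < 1e-8
        assert (modes.sources == "EDA").sum() == 3   # 4 members -> 3 PCs
        assert (modes.sources == "ENM").sum() == 17

    def test_identical_members_degenerate(self, duplex):
        members = [duplex.with_coords(duplex.coords) for _ in range(4)]
        with pytest.raises(DegenerateInputError):
            ens.compute_eda_modes(ens.StructuralEnsemble(members=members))

    def test_too_few_members_rejected(self, duplex):
        with pytest.raises(InputError):
            ens.compute_eda_modes(
                ens.StructuralEnsemble(members=[duplex, duplex]))


class TestAnm:
    def test_six_rigid_modes_discarded(self, duplex):
        modes = ens.build_anm_modes(duplex, cutoff=8.0, n_modes=20)
        assert len(modes.discarded_rigid) == 6
        assert modes.n_modes == 20
        assert (modes.scales >= -1e-10).all()

    def test_hessian_translational_invariance(self, duplex):
        H = ens.anm_hessian(duplex.coords[:20], cutoff=8.0)
        n = 20
        # row sums per coordinate block vanish: uniform translation costs 0
        for d in range(3):
            shift = np.zeros(3 * n)
            shift[d::3] = 1.0
            assert np.abs(H @ shift).max() < 1e-10

    def test_equilateral_triangle_matches_hand_hessian(self):
        side = 1.5
        coords = np.array([[0.0, 0, 0], [side, 0, 0],
                           [side / 2, side * np.sqrt(3) / 2, 0]])
        structure = point_structure(coords)
        modes = ens.build_anm_modes(structure, cutoff=2.0, n_modes=3)
        # independent 9x9 Hessian built directly from the spring formula
        H = np.zeros((9, 9))
        for i in range(3):
            for j in range(3):
                if i == j:
                    continue
                dr = coords[j] - coords[i]
                block = -np.outer(dr, dr) / (dr @ dr)
                H[3 * i:3 * i + 3, 3 * j:3 * j + 3] = block
                H[3 * i:3 * i + 3, 3 * i:3 * i + 3] -= block
        evals = np.linalg.eigvalsh(H)
        nonzero = evals[np.abs(evals) > 1e-8]
        assert np.allclose(np.sort(modes.scales), np.sort(nonzero),
                           atol=1e-10)

    def test_disconnected_network_reported(self):
        coords = np.vstack([np.random.default_rng(0).normal(size=(4, 3)),
                            np.random.default_rng(1).normal(size=(4, 3)) + 100])
        with pytest.raises(DisconnectedNetworkError) as err:
            ens.build_anm_modes(point_structure(coords), cutoff=8.0)
        assert len(err.value.components) == 2


class TestDeformation:
    def test_zero_target_identity(self, duplex):
        modes = ens.build_anm_modes(duplex, n_modes=1)
        conf = ens.deform_along_mode(duplex, modes.modes[0], +1, 0.0)
        assert np.array_equal(conf.coords, duplex.coords)

    def test_achieved_equals_target_for_random_modes(self, duplex):
        rng = np.random.default_rng(7)
        for target in (0.5, 2.0, 3.3):
            v = rng.normal(size=3 * duplex.n_atoms)
            conf = ens.deform_along_mode(duplex, v, -1, target)
            assert conf.achieved_mwrmsd == pytest.approx(target, abs=1e-8)

    def test_two_atom_hand_case(self):
        s = point_structure([[0.0, 0, 0], [3.0, 0, 0]])
        mode = np.array([1.0, 0, 0, -1.0, 0, 0]) / np.sqrt(2)
        conf = ens.deform_along_mode(s, mode, +1, 2.0)
        disp = conf.coords - s.coords
        assert np.abs(np.abs(disp[:, 0]) - 2.0).max() < 1e-12
        assert np.abs(disp[:, 1:]).max() == 0.0
        assert np.sign(disp[0, 0]) == -np.sign(disp[1, 0])

    def test_zero_mode_rejected(self, duplex):
        with pytest.raises(DegenerateInputError):
            ens.deform_along_mode(duplex, np.zeros(3 * duplex.n_atoms),
                                  +1, 2.0)


class TestBuildEnsemble:
    def test_twenty_modes_two_directions_forty_conformers(self, duplex):
        modes = ens.build_anm_modes(duplex, n_modes=20)
        e = ens.build_ensemble(duplex, modes, per_mode=2, target_mwrmsd=2.0)
        assert len(e) == 40

    def test_single_mode_single_direction(self, duplex):
        modes = ens.build_anm_modes(duplex, n_modes=1)
        e = ens.build_ensemble(duplex, modes, per_mode=1)
        assert len(e) == 1

    def test_mirror_deformations_average_to_reference(self, duplex):
        modes = ens.build_anm_modes(duplex, n_modes=3)
        e = ens.build_ensemble(duplex, modes, per_mode=2, target_mwrmsd=2.0)
        for k in range(3):
            plus = next(c for c in e.conformers
                        if c.mode_index == k and c.direction == 1)
            minus = next(c for c in e.conformers
                         if c.mode_index == k and c.direction == -1)
            mean = (plus.coords + minus.coords) / 2
            assert np.abs(mean - duplex.coords).max() < 1e-8

    def test_bad_per_mode_rejected(self, duplex):
        modes = ens.build_anm_modes(duplex, n_modes=2)
        with pytest.raises(ParameterError):
            ens.build_ensemble(duplex, modes, per_mode=3)

    def test_pipeline_deterministic_in_seed(self):
        def run():
            s = gen_rna_duplex(seed=9)
            m = ens.build_anm_modes(s, n_modes=5)
            return ens.build_ensemble(s, m, 2, 2.0)
        a, b = run(), run()
        for ca, cb in zip(a.conformers, b.conformers):
            assert np.array_equal(ca.coords, cb.coords)
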