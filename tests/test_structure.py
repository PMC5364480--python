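"""PDB round-trips, Kabsch superposition, trajectory RMSD, SASA, dihedrals."""

import io
import math

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from pinevol.structure import (
    Atom,
    Selection,
    Structure,
    backbone_dihedrals,
    kabsch_superpose,
    read_structure,
    read_trajectory,
    sasa,
    trajectory_rmsd,
    write_pdb,
)
from pinevol.synth import build_backbone_from_dihedrals, perturb_structure


def single_atom(element="C", name="X"):
    return Structure([Atom(name, element, "UNK", 1, "A")], np.zeros((1, 3)))


class TestPdbIO:
    def test_structure_round_trip_to_3_decimals(self, helix_structure, tmp_path):
        p = tmp_path / "helix.pdb"
        write_pdb(helix_structure, p)
        back = read_structure(p)
        assert [(a.name, a.res_name, a.res_id) for a in back.atoms] == [
            (a.name, a.res_name, a.res_id) for a in helix_structure.atoms
        ]
        assert np.allclose(back.coords, helix_structure.coords, atol=1.5e-3)

    def test_trajectory_round_trip(self, helix_structure, tmp_path):
        traj = perturb_structure(helix_structure, noise_sigma=0.3, n_frames=5, seed=1)
        p = tmp_path / "traj.pdb"
        write_pdb(traj, p)
        back = read_trajectory(p)
        assert back.n_frames == 5
        assert np.allclose(back.frames, traj.frames, atol=1.5e-3)

    def test_no_atoms_rejected(self):
        with pytest.raises(ValueError, match="no ATOM"):
            read_structure(io.StringIO("HEADER    EMPTY\nEND\n"))

    def test_model_atom_mismatch_rejected(self, tmp_path):
        text = (
            "MODEL        1\n"
            "ATOM      1  CA  ALA A   1       0.000   0.000   0.000  1.00  0.00           C\n"
            "ATOM      2  CB  ALA A   1       1.500   0.000   0.000  1.00  0.00           C\n"
            "ENDMDL\n"
            "MODEL        2\n"
            "ATOM      1  CA  ALA A   1       0.000   0.000   0.000  1.00  0.00           C\n"
            "ENDMDL\nEND\n"
        )
        with pytest.raises(ValueError, match="model 2"):
            read_trajectory(io.StringIO(text))


class TestKabsch:
    def test_rigid_copy_zero_rmsd(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=(10, 3))
        rot = Rotation.random(rng=rng).as_matrix()
        y = x @ rot.T + np.array([3.0, -1.0, 2.0])
        r, t, rmsd = kabsch_superpose(x, y)
        assert rmsd < 1e-9
        assert np.linalg.det(r) == pytest.approx(1.0, abs=1e-9)

    def test_identity_input(self):
        x = np.random.default_rng(1).normal(size=(5, 3))
        r, t, rmsd = kabsch_superpose(x, x)
        assert np.allclose(r, np.eye(3), atol=1e-9)
        assert np.allclose(t, 0.0, atol=1e-9)
        assert rmsd < 1e-12

    def test_agrees_with_scipy_align_vectors(self):
        """Independent oracle: scipy's align_vectors solves the same
        orthogonal Procrustes problem."""
        rng = np.random.default_rng(2)
        for _ in range(20):
            x = rng.normal(size=(12, 3))
            y = rng.normal(size=(12, 3))
            _, _, rmsd = kabsch_superpose(x, y)
            xc = x - x.mean(axis=0)
            yc = y - y.mean(axis=0)
            _, rssd = Rotation.align_vectors(yc, xc)
            assert rmsd == pytest.approx(rssd / math.sqrt(len(x)), rel=1e-9, abs=1e-12)

    def test_beats_random_rotations(self):
        rng = np.random.default_rng(3)
        x = rng.normal(size=(10, 3))
        y = rng.normal(size=(10, 3))
        _, _, best = kabsch_superpose(x, y)
        xc = x - x.mean(axis=0)
        yc = y - y.mean(axis=0)
        rots = Rotation.random(2000, rng=rng).as_matrix()
        cand = np.einsum("kij,nj->kni", rots, xc)
        rmsds = np.sqrt(np.mean(np.sum((cand - yc) ** 2, axis=2), axis=1))
        assert best <= rmsds.min() + 1e-12

    def test_degenerate_inputs_rejected(self):
        line = np.column_stack([np.arange(5.0), np.zeros(5), np.zeros(5)])
        with pytest.raises(ValueError, match="collinear"):
            kabsch_superpose(line, line)
        with pytest.raises(ValueError, match="3 atom"):
            kabsch_superpose(np.zeros((2, 3)), np.zeros((2, 3)))

    def test_rmsd_is_a_metric_on_sampled_triples(self):
        rng = np.random.default_rng(4)
        for _ in range(10):
            a, b, c = rng.normal(size=(3, 8, 3))
            _, _, rab = kabsch_superpose(a, b)
            _, _, rba = kabsch_superpose(b, a)
            _, _, rbc = kabsch_superpose(b, c)
            _, _, rac = kabsch_superpose(a, c)
            assert rab == pytest.approx(rba, rel=1e-9)
            assert rac <= rab + rbc + 1e-9


class TestTrajectoryRmsd:
    def test_static_trajectory_all_zero(self, helix_structure):
        traj = perturb_structure(helix_structure, n_frames=4)
        series = trajectory_rmsd(traj, 0)
        assert all(r < 1e-12 for _, r in series)

    def test_rigid_motion_zero_after_superposition(self, helix_structure):
        traj = perturb_structure(
            helix_structure, rotation=(40.0, 10.0, -25.0),
            translation=(1.0, 2.0, 3.0), n_frames=3,
        )
        series = trajectory_rmsd(traj, reference=helix_structure, superpose=True)
        assert all(r < 1e-9 for _, r in series)

    def test_ca_selection_restricts_atoms(self, helix_structure):
        traj = perturb_structure(helix_structure, noise_sigma=0.2, n_frames=3, seed=2)
        sel = Selection.ca(res_range=(3, 8))
        assert len(sel.indices(traj.topology)) == 6
        series = trajectory_rmsd(traj, 0, sel)
        assert len(series) == 3 and series[0][1] < 1e-12

    def test_empty_selection_rejected(self, helix_structure):
        traj = perturb_structure(helix_structure, n_frames=2)
        with pytest.raises(ValueError, match="selection"):
            trajectory_rmsd(traj, 0, Selection(chain="Z"))

    def test_times_propagate(self, helix_structure):
        traj = perturb_structure(helix_structure, n_frames=3, dt_ns=4.8)
        series = trajectory_rmsd(traj, 0)
        assert [t for t, _ in series] == [0.0, 4.8, 9.6]


class TestSasa:
    def test_isolated_sphere_analytic(self):
        total, per_res = sasa(single_atom(), probe_radius=1.4, n_points=960,
                              radii={"C": 1.6})
        analytic = 4.0 * math.pi * 3.0**2
        assert total == pytest.approx(analytic, rel=0.01)
        assert per_res[("A", 1)] == pytest.approx(total)

    def test_fully_overlapping_atoms_equal_one_sphere(self):
        s = Structure(
            [Atom("X", "C", "UNK", 1, "A"), Atom("Y", "C", "UNK", 2, "A")],
            np.zeros((2, 3)),
        )
        # Coincident spheres expose the surface of a single sphere.
        total, _ = sasa(s)
        single, _ = sasa(single_atom())
        assert total == pytest.approx(single, rel=1e-9)

    def test_distant_pair_equals_two_spheres(self):
        s = Structure(
            [Atom("X", "C", "UNK", 1, "A"), Atom("Y", "C", "UNK", 2, "A")],
            np.array([[0.0, 0.0, 0.0], [50.0, 0.0, 0.0]]),
        )
        total, _ = sasa(s)
        single, _ = sasa(single_atom())
        assert total == pytest.approx(2 * single, rel=1e-9)

    def test_burial_inequality_on_two_chain_contact(self, helix_structure):
        # Second copy translated to touch the first: complex SASA must not
        # exceed the sum of the isolated chains.
        atoms_b = [Atom(a.name, a.element, a.res_name, a.res_id, "B")
                   for a in helix_structure.atoms]
        offset = helix_structure.coords + np.array([4.0, 0.0, 0.0])
        complex_atoms = list(helix_structure.atoms) + atoms_b
        complex_coords = np.vstack([helix_structure.coords, offset])
        cplx = Structure(complex_atoms, complex_coords)
        total_ab, _ = sasa(cplx)
        total_a, _ = sasa(cplx.subset(Selection(chain="A")))
        total_b, _ = sasa(cplx.subset(Selection(chain="B")))
        assert total_ab < total_a + total_b

    def test_quadrature_converges(self, helix_structure):
        t1, _ = sasa(helix_structure, n_points=960)
        t2, _ = sasa(helix_structure, n_points=1920)
        assert abs(t1 - t2) / t2 < 0.01

    def test_matches_mdtraj_oracle(self, helix_structure, tmp_path):
        """Independent Shrake-Rupley implementation (mdtraj) agrees on a
        backbone fixture to within quadrature error."""
        md = pytest.importorskip("mdtraj")
        p = tmp_path / "helix.pdb"
        write_pdb(helix_structure, p)
        t = md.load(str(p))
        ref = md.shrake_rupley(t, probe_radius=0.14, n_sphere_points=960).sum() * 100.0
        ours, _ = sasa(helix_structure, probe_radius=1.4, n_points=960)
        assert ours == pytest.approx(float(ref), rel=0.02)

    def test_unknown_element_rejected(self):
        with pytest.raises(ValueError, match="radius"):
            sasa(single_atom(element="ZZ"))

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError, match="n_points"):
            sasa(single_atom(), n_points=50)


class TestBackboneDihedrals:
    def test_two_residue_chain_termini_undefined(self):
        s = build_backbone_from_dihedrals(
            [("ALA", -57.0, -47.0, 180.0), ("ALA", -57.0, -47.0, 180.0)]
        )
        torsions = backbone_dihedrals(s)
        assert torsions[1]["phi"] is None
        assert torsions[2]["psi"] is None
        assert torsions[2]["phi"] is not None

    def test_chain_gap_yields_absent_dihedrals(self, helix_structure):
        # Teleport the second half of the helix away: the broken peptide
        # bond must not produce interpolated dihedrals.
        coords = helix_structure.coords.copy()
        split = [i for i, a in enumerate(helix_structure.atoms) if a.res_id > 6]
        coords[split] += 100.0
        broken = helix_structure.with_coords(coords)
        torsions = backbone_dihedrals(broken)
        assert torsions[7]["phi"] is None and torsions[7]["omega"] is None
        assert torsions[6]["psi"] is None
        assert torsions[8]["phi"] is not None

    def test_multichain_requires_chain_argument(self, helix_structure):
        atoms_b = [Atom(a.name, a.element, a.res_name, a.res_id, "B")
                   for a in helix_structure.atoms]
        both = Structure(
            list(helix_structure.atoms) + atoms_b,
            np.vstack([helix_structure.coords, helix_structure.coords + 100.0]),
        )
        with pytest.raises(ValueError, match="chain"):
            backbone_dihedrals(both)
        torsions = backbone_dihedrals(both, chain="B")
        assert torsions[5]["phi"] == pytest.approx(-57.0, abs=1.0)
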