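"""Solvent density grids: superposition, binning, thresholds, XYZ/cube I/O."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from probekit import (
    IsoSpec,
    SolventMolecule,
    Trajectory,
    XYZParseError,
    check_containment,
    compute_sdf,
    gen_nanodroplet,
    read_cube,
    read_xyz_trajectory,
    superpose,
    threshold_region,
    write_cube,
    write_xyz_trajectory,
)
from probekit.synthetic_data import solute_template


def toy_trajectory(n_frames=3, solvent_offset=(5.0, 0.0, 0.0)):
    """Solute template plus one water fixed at a solute-relative site."""
    el, xyz = solute_template()
    water = np.array([[0.0, 0.0, 0.0], [0.9572, 0, 0], [-0.24, 0.927, 0]])
    coords = np.concatenate([xyz, water + np.asarray(solvent_offset)])
    frames = np.stack([coords] * n_frames)
    mols = (SolventMolecule(tuple(range(len(el), len(el) + 3)), ("O", "H", "H")),)
    return Trajectory(tuple(el) + ("O", "H", "H"), frames, tuple(range(len(el))), mols)


class TestSuperpose:
    def test_identity(self, rng):
        pts = rng.normal(size=(8, 3))
        rot, trans, rmsd = superpose(pts, pts)
        assert np.allclose(rot, np.eye(3), atol=1e-10)
        assert np.allclose(trans, 0, atol=1e-10)
        assert rmsd < 1e-12

    def test_recovers_known_rotation(self, rng):
        pts = rng.normal(size=(10, 3))
        true_rot = Rotation.random(rng=rng).as_matrix()
        moved = pts @ true_rot.T + np.array([1.0, -2.0, 0.5])
        rot, trans, rmsd = superpose(moved, pts)
        assert rmsd < 1e-9
        assert np.allclose(rot @ true_rot, np.eye(3), atol=1e-9)
        assert np.allclose(moved @ rot.T + trans, pts, atol=1e-9)

    def test_mirror_image_gets_proper_rotation(self, rng):
        pts = rng.normal(size=(10, 3))
        mirrored = pts * np.array([-1.0, 1.0, 1.0])
        rot, _, rmsd = superpose(mirrored, pts)
        assert np.linalg.det(rot) == pytest.approx(1.0, abs=1e-10)
        assert rmsd > 0.1

    def test_orthogonality_invariant(self, rng):
        for _ in range(5):
            a = rng.normal(size=(6, 3))
            b = rng.normal(size=(6, 3))
            rot, _, rmsd = superpose(a, b)
            assert np.allclose(rot @ rot.T, np.eye(3), atol=1e-10)
            assert np.linalg.det(rot) == pytest.approx(1.0, abs=1e-10)
            unaligned = float(
                np.sqrt((((a - a.mean(0)) - (b - b.mean(0))) ** 2).sum() / len(a))
            )
            assert rmsd <= unaligned + 1e-12

    def test_degenerate_rejected(self):
        line = np.stack([np.arange(5.0)] * 3, axis=1)  # collinear
        with pytest.raises(ValueError):
            superpose(line, line)
        with pytest.raises(ValueError):
            superpose(np.zeros((2, 3)), np.zeros((2, 3)))


class TestComputeSdf:
    def test_fixed_atom_single_voxel_density(self):
        traj = toy_trajectory()
        grid = compute_sdf(traj, "O", spacing=0.5)
        # one O per frame in one voxel: 1 / (0.5 Å)^3 = 8000 nm^-3
        assert grid.density.max() == pytest.approx(8000.0)
        assert np.count_nonzero(grid.density) == 1

    def test_count_conservation(self, small_droplet):
        grid = compute_sdf(small_droplet, "H", spacing=1.0, extent=50.0)
        total = grid.density.sum() * grid.voxel_volume_nm3
        n_h = small_droplet.solvent_atom_indices("H").size
        assert total == pytest.approx(n_h, abs=1e-9)

    def test_rigid_motion_invariance(self, rng):
        base = toy_trajectory(n_frames=2)
        rot = Rotation.random(rng=rng).as_matrix()
        shift = np.array([3.0, -1.0, 2.0])
        moved = Trajectory(
            base.elements,
            base.frames @ rot.T + shift,
            base.solute_atoms,
            base.solvent_molecules,
        )
        g0 = compute_sdf(base, "O", spacing=0.5)
        g1 = compute_sdf(moved, "O", spacing=0.5)
        assert np.allclose(g0.density, g1.density, atol=1e-6)

    def test_frame_duplication_leaves_sdf_unchanged(self, small_droplet):
        doubled = Trajectory(
            small_droplet.elements,
            np.concatenate([small_droplet.frames, small_droplet.frames]),
            small_droplet.solute_atoms,
            small_droplet.solvent_molecules,
        )
        g1 = compute_sdf(small_droplet, "O", spacing=1.0, extent=40.0)
        g2 = compute_sdf(doubled, "O", spacing=1.0, extent=40.0)
        assert np.allclose(g1.density, g2.density, atol=1e-12)

    def test_uniform_sphere_density(self):
        # solvent uniform in a sphere -> voxel densities ≈ N/V
        rng = np.random.default_rng(5)
        el, xyz = solute_template()
        n_mol, n_frames, radius = 200, 60, 12.0
        frames = []
        for _ in range(n_frames):
            centers = rng.normal(size=(n_mol, 3))
            centers *= radius * rng.random((n_mol, 1)) ** (1 / 3) / np.linalg.norm(
                centers, axis=1, keepdims=True
            )
            waters = np.concatenate(
                [c + np.array([[0, 0, 0], [0.96, 0, 0], [-0.24, 0.93, 0]]) for c in centers]
            )
            frames.append(np.concatenate([xyz, waters]))
        mols = tuple(
            SolventMolecule((len(el) + 3 * m, len(el) + 3 * m + 1, len(el) + 3 * m + 2),
                            ("O", "H", "H"))
            for m in range(n_mol)
        )
        traj = Trajectory(tuple(el) + ("O", "H", "H") * n_mol, np.stack(frames),
                          tuple(range(len(el))), mols)
        grid = compute_sdf(traj, "O", spacing=2.0, extent=16.0)
        expected = n_mol / (4 / 3 * np.pi * radius**3 * 1e-3)  # nm^-3
        # central voxels (fully inside the sphere) only, Monte-Carlo tolerance
        core = grid.density[3:5, 3:5, 3:5]
        assert core.mean() == pytest.approx(expected, rel=0.15)

    def test_empty_selection_and_bad_spacing(self, small_droplet):
        with pytest.raises(ValueError):
            compute_sdf(small_droplet, "Xx")
        with pytest.raises(ValueError):
            compute_sdf(small_droplet, "O", spacing=0.0)

    def test_octanol_carbon_class_aggregates(self):
        traj = gen_nanodroplet(n_frames=2, solvent="octanol", n_solvent=5, seed=3)
        assert traj.solvent_atom_indices("C").size == 5 * 8
        assert traj.solvent_atom_indices("C1").size == 5


class TestThresholdRegion:
    def test_below_threshold_empty(self, small_droplet):
        grid = compute_sdf(small_droplet, "O", spacing=2.0, extent=40.0)
        mask, vol = threshold_region(grid, IsoSpec(grid.density.max() + 1))
        assert not mask.any() and vol == 0.0

    def test_single_hot_voxel_volume(self):
        grid = compute_sdf(toy_trajectory(), "O", spacing=0.5)
        mask, vol = threshold_region(grid, IsoSpec(40.0))
        assert mask.sum() == 1
        assert vol == pytest.approx(1.25e-4)

    def test_matches_brute_force_scan(self, small_droplet):
        grid = compute_sdf(small_droplet, "H", spacing=1.5, extent=36.0)
        for thr in (5.0, 40.0, 100.0):
            mask, vol = threshold_region(grid, IsoSpec(thr))
            brute = np.zeros_like(mask)
            for idx in np.ndindex(*grid.shape):
                brute[idx] = grid.density[idx] >= thr
            assert np.array_equal(mask, brute)
            assert vol == pytest.approx(brute.sum() * grid.voxel_volume_nm3)


class TestContainment:
    def test_droplet_fully_contained(self, small_droplet):
        frac = check_containment(small_droplet, 15.0, tolerance=1.0)
        assert np.all(frac == 1.0)

    def test_half_outside(self):
        el, xyz = solute_template()
        water = np.array([[0, 0, 0], [0.96, 0, 0], [-0.24, 0.93, 0]])
        coords = np.concatenate([xyz, water + [5, 0, 0], water + [40, 0, 0]])
        mols = tuple(
            SolventMolecule(tuple(range(len(el) + 3 * m, len(el) + 3 * m + 3)),
                            ("O", "H", "H"))
            for m in range(2)
        )
        traj = Trajectory(tuple(el) + ("O", "H", "H") * 2, coords[None],
                          tuple(range(len(el))), mols)
        assert check_containment(traj, 15.0)[0] == pytest.approx(0.5)

    def test_agrees_with_direct_distances(self, small_droplet):
        frac = check_containment(small_droplet, 10.0)
        f0 = small_droplet.frames[0]
        solute_c = f0[list(small_droplet.solute_atoms)].mean(axis=0)
        inside = sum(
            np.linalg.norm(f0[list(m.indices)].mean(axis=0) - solute_c) <= 10.0
            for m in small_droplet.solvent_molecules
        )
        assert frac[0] == pytest.approx(inside / len(small_droplet.solvent_molecules))


class TestXyzIO:
    def test_round_trip(self, tmp_path, small_droplet):
        p = tmp_path / "droplet.xyz"
        write_xyz_trajectory(small_droplet, p)
        back = read_xyz_trajectory(p, len(small_droplet.solute_atoms), "water")
        assert back.n_frames == small_droplet.n_frames
        assert back.elements == small_droplet.elements
        assert np.allclose(back.frames, small_droplet.frames, atol=1e-6)
        assert len(back.solvent_molecules) == len(small_droplet.solvent_molecules)

    def test_basic_parse(self, tmp_path):
        p = tmp_path / "t.xyz"
        frames = "\n".join(
            f"4\nframe {i}\nC 0 0 0\nO 1 0 0\nH 1.5 0 0\nH 2 0 0" for i in range(3)
        )
        p.write_text(frames + "\n")
        traj = read_xyz_trajectory(p, 1, ("O", "H", "H"))
        assert traj.n_frames == 3 and len(traj.elements) == 4

    def test_truncated_frame_names_frame(self, tmp_path):
        p = tmp_path / "bad.xyz"
        p.write_text("2\nok\nC 0 0 0\nO 1 0 0\n2\nbad\nC 0 0 0\n")
        with pytest.raises(XYZParseError, match="frame 1"):
            read_xyz_trajectory(p, 1, ("O",))

    def test_unknown_element_rejected(self, tmp_path):
        p = tmp_path / "bad.xyz"
        p.write_text("1\nx\nQq 0 0 0\n")
        with pytest.raises(XYZParseError, match="Qq"):
            read_xyz_trajectory(p, 1, ())


class TestCubeIO:
    def test_round_trip(self, tmp_path, small_droplet):
        grid = compute_sdf(small_droplet, "O", spacing=2.0, extent=30.0)
        el = tuple(small_droplet.elements[i] for i in small_droplet.solute_atoms)
        p = tmp_path / "o.cube"
        write_cube(grid, el, small_droplet.solute_coords(0), p)
        back = read_cube(p)
        assert back.shape == grid.shape
        assert np.allclose(back.density, grid.density, atol=1e-5)
        assert np.allclose(back.origin, grid.origin, atol=1e-4)

    def test_small_grid_layout_z_fastest(self, tmp_path):
        from probekit import SDFGrid

        dens = np.arange(8.0).reshape(2, 2, 2)
        grid = SDFGrid(np.zeros(3), 1.0, (2, 2, 2), dens)
        p = tmp_path / "t.cube"
        write_cube(grid, ("C",), np.zeros((1, 3)), p)
        values = []
        lines = p.read_text().splitlines()
        for ln in lines[7:]:  # 6 header lines + 1 atom
            values.extend(float(v) for v in ln.split())
        assert values == [0.0, 1.0, 2.0, 3.0, 4.0, 5.0, 6.0, 7.0]

    def test_empty_solute_rejected(self, tmp_path, small_droplet):
        grid = compute_sdf(small_droplet, "O", spacing=2.0, extent=30.0)
        with pytest.raises(ValueError):
            write_cube(grid, (), np.zeros((0, 3)), tmp_path / "x.cube")
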