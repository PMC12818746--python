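"""Spatial distribution functions of solvent around a superposed solute.

A nanodroplet trajectory (solute plus explicit solvent within a ~15 Å
sphere) is reduced to a solute-fixed 3D number-density map: every frame's
solute is rigid-body superposed onto frame 0, the same transform is applied
to the solvent, and selected solvent atoms (oxygen, hydrogen or carbon
classes) are binned into a cubic voxel grid.  Densities are reported in
nm⁻³ — the convention in which hydration-shell features appear at tens of
nm⁻³ — and can be thresholded into isosurface regions or exported as
Gaussian cube files for visualization.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy.spatial.transform import Rotation

from .constants import ANG3_TO_NM3, BOHR_ANG

__all__ = [
    "SolventMolecule",
    "Trajectory",
    "SDFGrid",
    "IsoSpec",
    "XYZParseError",
    "canonical_pose",
    "WATER_ROLES",
    "OCTANOL_ROLES",
    "read_xyz_trajectory",
    "write_xyz_trajectory",
    "superpose",
    "compute_sdf",
    "threshold_region",
    "write_cube",
    "read_cube",
    "check_containment",
]

# fmt: off
_ELEMENTS = frozenset(
    "H He Li Be B C N O F Ne Na Mg Al Si P S Cl Ar K Ca Sc Ti V Cr Mn Fe Co "
    "Ni Cu Zn Ga Ge As Se Br Kr Rb Sr Y Zr Nb Mo Tc Ru Rh Pd Ag Cd In Sn Sb "
    "Te I Xe Cs Ba La Ce Pr Nd Pm Sm Eu Gd Tb Dy Ho Er Tm Yb Lu Hf Ta W Re "
    "Os Ir Pt Au Hg Tl Pb Bi Po At Rn Fr Ra Ac Th Pa U".split()
)
_ATOMIC_NUMBER = {
    "H": 1, "B": 5, "C": 6, "N": 7, "O": 8, "F": 9, "Na": 11, "P": 15,
    "S": 16, "Cl": 17, "K": 19, "Br": 35, "I": 53,
}
# fmt: on

#: Per-molecule atom roles of a 3-site water.
WATER_ROLES: tuple[str, ...] = ("O", "H", "H")
#: Hydroxyl O/H followed by the C1…C8 backbone of n-octanol.
OCTANOL_ROLES: tuple[str, ...] = ("O", "H", "C1", "C2", "C3", "C4", "C5", "C6", "C7", "C8")

_TEMPLATES = {"water": WATER_ROLES, "octanol": OCTANOL_ROLES}


class XYZParseError(ValueError):
    """Malformed multi-frame XYZ file (message names the frame)."""


@dataclass(frozen=True)
class SolventMolecule:
    """Atom indices of one solvent molecule with per-atom role labels."""

    indices: tuple[int, ...]
    roles: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.indices) != len(self.roles):
            raise ValueError("indices and roles must align")


@dataclass
class Trajectory:
    """Multi-frame coordinates (Å) with a solute/solvent partition."""

    elements: tuple[str, ...]
    frames: np.ndarray  # (n_frames, n_atoms, 3)
    solute_atoms: tuple[int, ...]
    solvent_molecules: tuple[SolventMolecule, ...]

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        if self.frames.ndim != 3 or self.frames.shape[2] != 3:
            raise ValueError("frames must have shape (n_frames, n_atoms, 3)")
        if self.frames.shape[1] != len(self.elements):
            raise ValueError("atom count mismatch between frames and elements")
        if not np.all(np.isfinite(self.frames)):
            raise ValueError("non-finite coordinates")
        solute = set(self.solute_atoms)
        solvent = {i for m in self.solvent_molecules for i in m.indices}
        if solute & solvent:
            raise ValueError("solute and solvent index sets must be disjoint")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    def solute_coords(self, frame: int) -> np.ndarray:
        return self.frames[frame][list(self.solute_atoms)]

    def solvent_atom_indices(self, atom_class: str) -> np.ndarray:
        """Indices of solvent atoms whose role matches ``atom_class``.

        ``"O"``/``"H"``/``"C"`` match by leading element letter (so ``"C"``
        aggregates C1…C8); any other string matches the role exactly.
        """
        picked = [
            i
            for mol in self.solvent_molecules
            for i, role in zip(mol.indices, mol.roles)
            if (role.rstrip("0123456789") == atom_class)
            or (role == atom_class)
        ]
        return np.asarray(picked, dtype=int)


@dataclass
class SDFGrid:
    """Cubic voxel grid of solvent number density (nm⁻³) around the solute."""

    origin: np.ndarray  # Å, corner of voxel (0,0,0)
    spacing: float  # Å
    shape: tuple[int, int, int]
    density: np.ndarray  # nm⁻³
    atom_class: str = ""

    def __post_init__(self) -> None:
        self.origin = np.asarray(self.origin, dtype=float)
        self.density = np.asarray(self.density, dtype=float)
        if self.density.shape != tuple(self.shape):
            raise ValueError("density shape must match grid shape")
        if np.any(self.density < 0):
            raise ValueError("densities must be non-negative")

    @property
    def voxel_volume_nm3(self) -> float:
        return self.spacing**3 * ANG3_TO_NM3


@dataclass(frozen=True)
class IsoSpec:
    """Isosurface threshold in nm⁻³ (40 is conventional for O/H, 15 for C)."""

    threshold: float = 40.0

    def __post_init__(self) -> None:
        if self.threshold <= 0:
            raise ValueError("threshold must be > 0")


# ---------------------------------------------------------------------------
# XYZ I/O


def read_xyz_trajectory(
    path: str | Path,
    solute_spec: int | tuple[int, int],
    solvent_template: str | Sequence[str],
) -> Trajectory:
    """Parse a multi-frame XYZ file and partition atoms into solute/solvent.

    ``solute_spec`` is either the number of leading solute atoms or a
    ``(start, stop)`` index range (stop exclusive); the remaining atoms are
    chunked into solvent molecules following ``solvent_template`` (a role
    tuple, or ``"water"`` / ``"octanol"``).
    """
    path = Path(path)
    lines = path.read_text().splitlines()
    frames: list[np.ndarray] = []
    elements: list[str] | None = None
    pos, frame_no = 0, 0
    while pos < len(lines):
        if not lines[pos].strip():
            pos += 1
            continue
        try:
            natoms = int(lines[pos].strip())
        except ValueError:
            raise XYZParseError(
                f"{path}: frame {frame_no}: expected atom count, got {lines[pos]!r}"
            ) from None
        block = lines[pos + 2 : pos + 2 + natoms]
        if len(block) < natoms:
            raise XYZParseError(f"{path}: frame {frame_no}: truncated ({len(block)}/{natoms} atom lines)")
        symbols, coords = [], []
        for ln in block:
            parts = ln.split()
            if len(parts) < 4:
                raise XYZParseError(f"{path}: frame {frame_no}: malformed atom line {ln!r}")
            sym = parts[0]
            if sym not in _ELEMENTS:
                raise XYZParseError(f"{path}: frame {frame_no}: unknown element symbol {sym!r}")
            try:
                coords.append([float(p) for p in parts[1:4]])
            except ValueError:
                raise XYZParseError(
                    f"{path}: frame {frame_no}: non-numeric coordinate in {ln!r}"
                ) from None
            symbols.append(sym)
        if elements is None:
            elements = symbols
        elif symbols != elements or natoms != len(elements):
            raise XYZParseError(f"{path}: frame {frame_no}: inconsistent atoms vs frame 0")
        frames.append(np.asarray(coords))
        pos += 2 + natoms
        frame_no += 1
    if not frames:
        raise XYZParseError(f"{path}: no frames found")
    assert elements is not None

    if isinstance(solute_spec, int):
        solute = tuple(range(solute_spec))
    else:
        solute = tuple(range(solute_spec[0], solute_spec[1]))
    roles = (
        _TEMPLATES[solvent_template]
        if isinstance(solvent_template, str)
        else tuple(solvent_template)
    )
    rest = [i for i in range(len(elements)) if i not in set(solute)]
    if len(rest) % len(roles):
        raise XYZParseError(
            f"{path}: {len(rest)} solvent atoms do not tile the {len(roles)}-atom template"
        )
    mols = tuple(
        SolventMolecule(tuple(rest[i : i + len(roles)]), roles)
        for i in range(0, len(rest), len(roles))
    )
    return Trajectory(tuple(elements), np.stack(frames), solute, mols)


def write_xyz_trajectory(traj: Trajectory, path: str | Path, comment: str = "") -> None:
    with open(path, "w") as fh:
        for frame in traj.frames:
            fh.write(f"{len(traj.elements)}\n{comment}\n")
            for sym, (x, y, z) in zip(traj.elements, frame):
                fh.write(f"{sym} {x:.8f} {y:.8f} {z:.8f}\n")


# ---------------------------------------------------------------------------
# Superposition and density


def superpose(
    mobile: np.ndarray, reference: np.ndarray
) -> tuple[np.ndarray, np.ndarray, float]:
    """Least-squares rigid superposition of ``mobile`` onto ``reference``.

    Returns ``(rotation, translation, rmsd)`` such that
    ``mobile @ rotation.T + translation`` best fits ``reference``; the
    rotation is always proper (det +1, mirror images are not reflected).
    """
    mobile = np.asarray(mobile, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if mobile.shape != reference.shape or mobile.ndim != 2 or mobile.shape[0] < 3:
        raise ValueError("need two equal (n≥3, 3) coordinate sets")
    mc, rc = mobile.mean(axis=0), reference.mean(axis=0)
    m0, r0 = mobile - mc, reference - rc
    if np.linalg.matrix_rank(m0, tol=1e-8) < 2:
        raise ValueError("degenerate (collinear) geometry")
    rot, _ = Rotation.align_vectors(r0, m0)
    matrix = rot.as_matrix()
    translation = rc - mc @ matrix.T
    diff = mobile @ matrix.T + translation - reference
    rmsd = float(np.sqrt((diff**2).sum() / mobile.shape[0]))
    return matrix, translation, rmsd


def canonical_pose(solute: np.ndarray) -> np.ndarray:
    """Express a solute geometry in its principal-axes frame.

    Centered at the centroid, axes ordered by descending gyration
    eigenvalue, signs fixed by the skewness of the atomic projections and
    handedness enforced by a cross product — so any globally rotated or
    translated copy of the same geometry maps to identical coordinates.
    Near-symmetric solutes (degenerate gyration eigenvalues) have no unique
    pose; the solutes used here are asymmetric.
    """
    x0 = solute - solute.mean(axis=0)
    _, evecs = np.linalg.eigh(x0.T @ x0)
    axes = evecs[:, ::-1]  # principal axis first
    for k in range(2):
        proj = x0 @ axes[:, k]
        skew = (proj**3).sum()
        if skew < 0 or (skew == 0 and proj.max() < -proj.min()):
            axes[:, k] = -axes[:, k]
    axes[:, 2] = np.cross(axes[:, 0], axes[:, 1])
    return x0 @ axes


def compute_sdf(
    trajectory: Trajectory,
    atom_class: str,
    spacing: float = 0.5,
    extent: float = 34.0,
) -> SDFGrid:
    """Bin solvent atoms of one class into a solute-fixed density grid.

    Every frame's solute is superposed onto frame 0's solute expressed in
    its principal-axes frame (a solute-intrinsic pose, which makes the
    resulting grid invariant under global rigid motions of the whole
    trajectory); the selected solvent atoms are transported by the same
    rigid transform and counted into cubic voxels of edge ``spacing`` (Å)
    in a cube of edge ``extent`` centered on the solute centroid.  Voxel
    density is the mean count per frame divided by the voxel volume, in
    nm⁻³.
    """
    if spacing <= 0:
        raise ValueError("spacing must be > 0")
    selected = trajectory.solvent_atom_indices(atom_class)
    if selected.size == 0:
        raise ValueError(f"no solvent atoms in class {atom_class!r}")
    ref = canonical_pose(trajectory.solute_coords(0))
    n_vox = max(int(round(extent / spacing)), 1)
    origin = np.zeros(3) - 0.5 * n_vox * spacing
    counts = np.zeros((n_vox, n_vox, n_vox), dtype=float)
    edges = [origin[d] + spacing * np.arange(n_vox + 1) for d in range(3)]
    for f in range(trajectory.n_frames):
        rot, trans, _ = superpose(trajectory.solute_coords(f), ref)
        pts = trajectory.frames[f][selected] @ rot.T + trans
        hist, _ = np.histogramdd(pts, bins=edges)
        counts += hist
    density = counts / trajectory.n_frames / (spacing**3 * ANG3_TO_NM3)
    return SDFGrid(origin, spacing, (n_vox, n_vox, n_vox), density, atom_class)


def threshold_region(grid: SDFGrid, iso: IsoSpec) -> tuple[np.ndarray, float]:
    """Voxel mask at/above the isosurface threshold and its volume in nm³."""
    mask = grid.density >= iso.threshold
    return mask, float(mask.sum()) * grid.voxel_volume_nm3


def check_containment(
    trajectory: Trajectory, radius: float, tolerance: float = 0.0
) -> np.ndarray:
    """Per-frame fraction of solvent centroids within ``radius + tolerance``
    of the solute centroid (a sanity check on droplet confinement)."""
    fractions = np.empty(trajectory.n_frames)
    for f in range(trajectory.n_frames):
        solute_centroid = trajectory.solute_coords(f).mean(axis=0)
        if not trajectory.solvent_molecules:
            fractions[f] = 1.0
            continue
        centroids = np.stack(
            [
                trajectory.frames[f][list(m.indices)].mean(axis=0)
                for m in trajectory.solvent_molecules
            ]
        )
        dist = np.linalg.norm(centroids - solute_centroid, axis=1)
        fractions[f] = float(np.mean(dist <= radius + tolerance))
    return fractions


# ---------------------------------------------------------------------------
# Cube export


def write_cube(
    grid: SDFGrid,
    solute_elements: Sequence[str],
    solute_coords: np.ndarray,
    path: str | Path,
) -> None:
    """Export the grid as a Gaussian cube file (lengths in Bohr, densities
    written z-fastest per the cube convention)."""
    solute_coords = np.asarray(solute_coords, dtype=float)
    if len(solute_elements) == 0 or solute_coords.shape != (len(solute_elements), 3):
        raise ValueError("solute elements/coordinates required")
    nx, ny, nz = grid.shape
    sp_b = grid.spacing / BOHR_ANG
    orig_b = grid.origin / BOHR_ANG
    with open(path, "w") as fh:
        fh.write("probekit solvent density\n")
        fh.write(f"SDF atom class {grid.atom_class or '?'} (nm^-3)\n")
        fh.write(
            f"{len(solute_elements):5d} {orig_b[0]:12.6f} {orig_b[1]:12.6f} {orig_b[2]:12.6f}\n"
        )
        fh.write(f"{nx:5d} {sp_b:12.6f} {0.0:12.6f} {0.0:12.6f}\n")
        fh.write(f"{ny:5d} {0.0:12.6f} {sp_b:12.6f} {0.0:12.6f}\n")
        fh.write(f"{nz:5d} {0.0:12.6f} {0.0:12.6f} {sp_b:12.6f}\n")
        for sym, (x, y, z) in zip(solute_elements, solute_coords):
            zn = _ATOMIC_NUMBER.get(sym, 0)
            fh.write(
                f"{zn:5d} {0.0:12.6f} {x / BOHR_ANG:12.6f} {y / BOHR_ANG:12.6f} {z / BOHR_ANG:12.6f}\n"
            )
        for row in grid.density.reshape(-1, nz):
            for start in range(0, nz, 6):
                fh.write(
                    " ".join(f"{v:13.5E}" for v in row[start : start + 6]) + "\n"
                )


def read_cube(path: str | Path) -> SDFGrid:
    """Read back a cube file written by :func:`write_cube`."""
    with open(path) as fh:
        fh.readline()
        fh.readline()
        parts = fh.readline().split()
        natoms = int(parts[0])
        origin = np.array([float(p) for p in parts[1:4]]) * BOHR_ANG
        dims, spacing = [], None
        for _ in range(3):
            parts = fh.readline().split()
            dims.append(int(parts[0]))
            vec = [float(p) for p in parts[1:4]]
            step = max(abs(v) for v in vec) * BOHR_ANG
            spacing = step if spacing is None else spacing
        for _ in range(natoms):
            fh.readline()
        values = np.fromstring(fh.read(), sep=" ")
    nx, ny, nz = dims
    if values.size != nx * ny * nz:
        raise ValueError(f"cube data size mismatch: {values.size} vs {nx * ny * nz}")
    return SDFGrid(origin, float(spacing), (nx, ny, nz), values.reshape(nx, ny, nz))
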