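"""Seeded generators for every input the analysis stages consume.

Each generator plants a known ground truth that the matching analysis
operation must recover, which makes the whole pipeline testable without
any deposited data:

* excitation tables with a dominant visible band, weaker UV bands and a
  thermal (≈kT) frame-energy spread;
* solvent nanodroplets (rigid solute at the origin, solvent packed inside
  a 15 Å sphere by rejection sampling, optional planted solvation hot
  spot, per-frame random rigid motions);
* sigmoidal pH titrations with Gaussian noise;
* three-channel cell images whose red/green puncta share signal with a
  controllable mixing correlation ρ (G = √ρ·S + √(1−ρ)·N);
* viability plates with control and blank wells.

All randomness flows through ``numpy.random.default_rng(seed)``; a fixed
seed gives byte-identical output.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy.spatial.transform import Rotation

from .constants import KB_KJ_PER_MOL_K
from .ensemble_spectra import FrameExcitations
from .imaging_assays import ChannelPair, ViabilityPlate
from .solvation_structure import (
    OCTANOL_ROLES,
    WATER_ROLES,
    SolventMolecule,
    Trajectory,
)
from .titration_analysis import DoseRespParams, TitrationPoint, doseresp_eval

__all__ = [
    "PackingError",
    "solute_template",
    "gen_excitations",
    "gen_nanodroplet",
    "gen_titration",
    "gen_cell_images",
    "gen_viability_plate",
]


class PackingError(RuntimeError):
    """Rejection sampling failed to place a solvent molecule."""


# ---------------------------------------------------------------------------
# Excitation tables


def gen_excitations(
    n_frames: int = 200,
    seed: int = 0,
    center_nm: float = 505.0,
    center_sigma_nm: float = 5.0,
    main_strength: float = 0.8,
    uv_bands: Sequence[tuple[float, float, float]] = ((350.0, 12.0, 0.15), (300.0, 8.0, 0.08)),
    energy_scale_kj: float = KB_KJ_PER_MOL_K * 300.0,
    base_energy_kj: float = 0.0,
) -> list[FrameExcitations]:
    """Emulated per-frame excitation tables.

    Each frame carries one dominant visible excitation jittered around
    ``center_nm`` plus weaker UV bands; frame energies are the base energy
    plus an exponential spread of scale ``energy_scale_kj`` (defaulting to
    kT at 300 K, the spread thermal sampling produces).
    """
    if n_frames < 1:
        raise ValueError("need ≥ 1 frame")
    rng = np.random.default_rng(seed)
    frames = []
    for i in range(n_frames):
        energy = base_energy_kj + rng.exponential(energy_scale_kj)
        exc = [
            (
                float(rng.normal(center_nm, center_sigma_nm)),
                float(abs(rng.normal(main_strength, 0.05 * main_strength))),
            )
        ]
        for c, s, amp in uv_bands:
            exc.append(
                (float(rng.normal(c, s)), float(abs(rng.normal(amp, 0.2 * amp))))
            )
        frames.append(FrameExcitations(i, float(energy), tuple(exc)))
    return frames


# ---------------------------------------------------------------------------
# Nanodroplets


def solute_template() -> tuple[tuple[str, ...], np.ndarray]:
    """A small rigid asymmetric solute (crude dipyrromethene-like skeleton).

    Only the geometric role matters: enough non-degenerate atoms for
    unambiguous rigid-body superposition.
    """
    ring = [
        (1.40 * math.cos(k * math.pi / 3), 1.40 * math.sin(k * math.pi / 3), 0.0)
        for k in range(6)
    ]
    extra = [
        (0.0, 0.0, 1.25),  # N above the ring plane
        (2.30, 0.00, 0.45),  # B
        (2.95, 0.85, 0.95),  # F
        (2.95, -0.85, 0.95),  # F
        (-2.10, 0.60, -0.40),  # N of the amino arm
        (-2.80, 1.45, 0.25),  # C
    ]
    elements = ("C",) * 6 + ("N", "B", "F", "F", "N", "C")
    return elements, np.array(ring + extra)


_WATER_GEOM = np.array(
    [
        [0.0, 0.0, 0.0],
        [0.9572, 0.0, 0.0],
        [-0.2399872, 0.9266272, 0.0],
    ]
)


def _octanol_geom() -> np.ndarray:
    # hydroxyl O-H then a C1..C8 zigzag backbone, 1.54 Å steps
    coords = [np.array([0.0, 0.0, 0.0]), np.array([-0.65, 0.65, 0.0])]
    x = 0.0
    for k in range(8):
        x += 1.30
        coords.append(np.array([x, 0.45 * ((-1) ** k), 0.0]))
    return np.stack(coords)


def gen_nanodroplet(
    n_frames: int = 20,
    solvent: str = "water",
    n_solvent: int = 90,
    radius: float = 15.0,
    seed: int = 0,
    min_dist: float = 1.8,
    hotspot_site: Sequence[float] | None = None,
    hotspot_fraction: float = 0.0,
    rigid_motion: bool = True,
    max_attempts: int = 20000,
) -> Trajectory:
    """Generate a nanodroplet trajectory by per-frame rejection packing.

    The rigid solute sits at the origin of every frame's internal
    coordinates; solvent molecules (defaults: 90 waters in a 15 Å sphere)
    are placed with random orientation and uniform centers, rejecting any
    placement closer than ``min_dist`` to an existing atom.  If
    ``hotspot_site`` is given, a fraction of frames pin the first solvent
    molecule exactly at that solute-relative site (a planted SDF feature).
    Finally an independent random global rotation+translation is applied to
    each frame, which the SDF alignment must undo.
    """
    if n_solvent < 0 or radius <= 0:
        raise ValueError("solvent count and radius must be positive")
    if solvent == "water":
        roles, geom = WATER_ROLES, _WATER_GEOM
        solvent_elements = ("O", "H", "H")
    elif solvent == "octanol":
        roles, geom = OCTANOL_ROLES, _octanol_geom()
        solvent_elements = ("O", "H") + ("C",) * 8
    else:
        raise ValueError(f"unknown solvent {solvent!r}")

    rng = np.random.default_rng(seed)
    solute_el, solute_xyz = solute_template()
    n_solute = len(solute_el)
    nat_mol = len(roles)
    elements = tuple(solute_el) + tuple(solvent_elements) * n_solvent

    hot_frames = (
        set(np.flatnonzero(rng.random(n_frames) < hotspot_fraction))
        if hotspot_site is not None
        else set()
    )
    if hotspot_site is not None and hotspot_fraction >= 1.0:
        hot_frames = set(range(n_frames))

    frames = []
    for f in range(n_frames):
        placed = [solute_xyz.copy()]
        for m in range(n_solvent):
            if m == 0 and f in hot_frames:
                mol = geom - geom.mean(axis=0) + np.asarray(hotspot_site, dtype=float)
                placed.append(mol)
                continue
            for attempt in range(max_attempts):
                center = rng.normal(size=3)
                center *= radius * rng.random() ** (1 / 3) / np.linalg.norm(center)
                rot = Rotation.random(rng=rng).as_matrix()
                mol = (geom - geom.mean(axis=0)) @ rot.T + center
                others = np.concatenate(placed)
                d2 = ((others[:, None, :] - mol[None, :, :]) ** 2).sum(-1)
                if d2.min() >= min_dist**2:
                    placed.append(mol)
                    break
            else:
                raise PackingError(
                    f"frame {f}: failed to place molecule {m} after {max_attempts} attempts"
                )
        coords = np.concatenate(placed)
        if rigid_motion:
            rot = Rotation.random(rng=rng).as_matrix()
            shift = rng.uniform(-5.0, 5.0, size=3)
            coords = coords @ rot.T + shift
        frames.append(coords)

    mols = tuple(
        SolventMolecule(
            tuple(range(n_solute + m * nat_mol, n_solute + (m + 1) * nat_mol)), roles
        )
        for m in range(n_solvent)
    )
    return Trajectory(elements, np.stack(frames), tuple(range(n_solute)), mols)


# ---------------------------------------------------------------------------
# Titrations and plates


def gen_titration(
    params: DoseRespParams,
    ph_start: float = 2.2,
    ph_stop: float = 8.7,
    ph_step: float = 0.05,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> list[TitrationPoint]:
    """Sigmoidal titration data from a known parameter set plus noise."""
    n = int(math.floor((ph_stop - ph_start) / ph_step + 1e-9)) + 1 if ph_stop >= ph_start else 0
    ph = ph_start + ph_step * np.arange(n)
    rng = np.random.default_rng(seed)
    y = doseresp_eval(params, ph) if n else np.array([])
    if noise_sd > 0 and n:
        y = y + rng.normal(0.0, noise_sd, size=n)
    return [TitrationPoint(float(p), float(v)) for p, v in zip(ph, y)]


def gen_viability_plate(
    true_viability: Mapping[str, float],
    n_replicates: int = 6,
    control_mean: float = 100.0,
    blank_mean: float = 10.0,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> ViabilityPlate:
    """Plate whose expected viability per condition equals the ground truth.

    Treated means are placed at blank + (control−blank)·v/100; Gaussian
    replicate noise of absolute scale ``noise_sd`` (reading units) is added
    to every well.
    """
    rng = np.random.default_rng(seed)

    def wells(mean: float) -> list[float]:
        return list(mean + rng.normal(0.0, noise_sd, size=n_replicates)) if noise_sd > 0 else [mean] * n_replicates

    span = control_mean - blank_mean
    treated = {
        cond: wells(blank_mean + span * v / 100.0)
        for cond, v in true_viability.items()
    }
    return ViabilityPlate(treated=treated, control=wells(control_mean), blank=wells(blank_mean))


# ---------------------------------------------------------------------------
# Cell images


def _texture(
    rng: np.random.Generator,
    shape: tuple[int, int],
    centers: np.ndarray | None,
    n_puncta: int,
    punctum_sigma: float,
    cell_radius: float,
    floor_sd: float,
) -> np.ndarray:
    """One puncta-plus-noise field: Gaussian spots over a Gaussian floor.

    Independently drawn fields are identically distributed, which makes the
    shared-signal mixing correlation exact.  When ``centers`` is given the
    puncta are confined to cell disks; note that confinement gives
    nominally independent fields a common spatial mean profile and hence a
    small positive correlation (see ``gen_cell_images``).
    """
    yy, xx = np.mgrid[0 : shape[0], 0 : shape[1]]
    img = rng.normal(0.0, floor_sd, size=shape)
    for _ in range(n_puncta):
        if centers is None:
            cy, cx = rng.uniform(0, shape[0]), rng.uniform(0, shape[1])
        else:
            cell = centers[rng.integers(len(centers))]
            ang = rng.uniform(0, 2 * math.pi)
            rad = cell_radius * 0.8 * math.sqrt(rng.random())
            cy, cx = cell[0] + rad * math.sin(ang), cell[1] + rad * math.cos(ang)
        amp = rng.uniform(0.8, 1.6)
        img += amp * np.exp(
            -((yy - cy) ** 2 + (xx - cx) ** 2) / (2 * punctum_sigma**2)
        )
    return img


def gen_cell_images(
    seed: int = 0,
    shape: tuple[int, int] = (512, 512),
    n_cells: int = 15,
    rho: float = 0.7,
    n_puncta_per_cell: int = 12,
    punctum_sigma: float = 2.5,
    cell_radius: float = 45.0,
    nucleus_radius: float = 16.0,
    floor_sd: float = 0.35,
    shot_noise_sd: float = 1.5,
    confine_puncta: bool = False,
) -> dict[str, object]:
    """Three-channel synthetic confocal field with known mixing correlation.

    Red and green are built from the shared-signal model
    ``G = √|ρ|·S + √(1−|ρ|)·N_g`` (similarly for red, with the sign of ρ on
    the shared term), where S, N_r, N_g are independent, identically
    distributed puncta textures — so the red/green Pearson correlation is ρ
    by construction.  The blue channel holds nucleus disks; cell disk masks
    are returned as a labeled image.  All channels are rescaled to 8 bit
    with a light shot-noise floor.

    By default puncta centers are uniform over the field: confining them to
    the cell disks (``confine_puncta=True``) is visually more cell-like but
    imprints the shared cell geometry on all three latent fields, which
    biases the realized red/green correlation above the planted ρ.

    Returns a dict with keys ``red``, ``green``, ``blue`` (uint8 arrays),
    ``labels`` (int cell masks), ``pair`` (a :class:`ChannelPair`) and
    ``rho`` (the planted ground truth).
    """
    if not -1.0 <= rho <= 1.0:
        raise ValueError("rho must lie in [-1, 1]")
    rng = np.random.default_rng(seed)
    h, w = shape
    # keep whole cells inside small fields
    cell_radius = min(cell_radius, min(h, w) / 4.0)
    nucleus_radius = min(nucleus_radius, cell_radius / 2.5)
    centers = np.stack(
        [
            rng.uniform(cell_radius, h - cell_radius, size=n_cells),
            rng.uniform(cell_radius, w - cell_radius, size=n_cells),
        ],
        axis=1,
    )
    yy, xx = np.mgrid[0:h, 0:w]
    labels = np.zeros(shape, dtype=np.int32)
    blue = rng.normal(12.0, 3.0, size=shape)
    for i, (cy, cx) in enumerate(centers, start=1):
        cell = (yy - cy) ** 2 + (xx - cx) ** 2 <= cell_radius**2
        labels[cell & (labels == 0)] = i
        nucleus = (yy - cy) ** 2 + (xx - cx) ** 2 <= nucleus_radius**2
        blue[nucleus] += 160.0

    n_puncta = n_puncta_per_cell * n_cells
    punc_centers = centers if confine_puncta else None
    args = (shape, punc_centers, n_puncta, punctum_sigma, cell_radius, floor_sd)
    shared = _texture(rng, *args)
    noise_r = _texture(rng, *args)
    noise_g = _texture(rng, *args)
    mag = abs(rho)
    sign = 1.0 if rho >= 0 else -1.0
    red_f = math.sqrt(mag) * shared + math.sqrt(1 - mag) * noise_r
    green_f = sign * math.sqrt(mag) * shared + math.sqrt(1 - mag) * noise_g

    def to_uint8(fld: np.ndarray) -> np.ndarray:
        z = (fld - fld.mean()) / fld.std()
        img = 100.0 + 20.0 * z
        if shot_noise_sd > 0:
            img = img + rng.normal(
                0.0, shot_noise_sd, size=fld.shape
            ) * np.sqrt(np.clip(img, 0, None) / 100.0)
        return np.clip(np.round(img), 0, 255).astype(np.uint8)

    red = to_uint8(red_f)
    green = to_uint8(green_f)
    blue8 = np.clip(np.round(blue), 0, 255).astype(np.uint8)
    return {
        "red": red,
        "green": green,
        "blue": blue8,
        "labels": labels,
        "pair": ChannelPair(red=red, green=green, masks=labels),
        "rho": rho,
    }
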