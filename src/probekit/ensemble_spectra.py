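"""Boltzmann-weighted ensemble absorption spectra from per-frame excitations.

A molecular-dynamics trajectory of a chromophore in an explicit solvent
nanodroplet yields one table of electronic excitations (wavelength,
oscillator strength) per sampled snapshot, together with the snapshot's
total energy.  The ensemble absorption spectrum is the Boltzmann-weighted
average of the per-frame spectra: each frame's stick excitations are
broadened with area-normalized Gaussians (FWHM in nm) and summed with
weight

    w_i = exp(-ΔE_i / kT) / Σ_j exp(-ΔE_j / kT)

where ΔE_i is the frame energy relative to the lowest-energy frame in the
set and T defaults to 300 K.  Two broadening widths are conventional: a
narrow 10 nm FWHM for analysis and a wide 55 nm FWHM that matches the
width of experimental bands for display; both are plain config options and
are applied per excitation (never as a second smoothing pass).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.special import softmax

from .constants import FWHM_TO_SIGMA, HARTREE_KJ_PER_MOL, KB_KJ_PER_MOL_K

__all__ = [
    "FrameExcitations",
    "EnsembleConfig",
    "EnsembleWeights",
    "Spectrum",
    "ExcitationTableError",
    "read_excitation_table",
    "write_excitation_table",
    "boltzmann_weights",
    "broaden",
    "ensemble_spectrum",
    "sample_frames",
    "lambda_max",
    "normalize_max",
    "write_spectrum",
    "read_spectrum",
]

_ENERGY_UNITS = {"kj/mol": 1.0, "kjmol": 1.0, "hartree": HARTREE_KJ_PER_MOL}


class ExcitationTableError(ValueError):
    """Malformed excitation table (message names the offending line)."""


@dataclass(frozen=True)
class FrameExcitations:
    """One snapshot's energy and electronic excitations.

    ``frame_energy`` is the total snapshot energy in kJ/mol (conversion from
    Hartree happens at read time); ``excitations`` is an ordered list of
    ``(wavelength_nm, oscillator_strength)`` pairs.
    """

    frame_id: int
    frame_energy: float
    excitations: tuple[tuple[float, float], ...]

    def __post_init__(self) -> None:
        if not math.isfinite(self.frame_energy):
            raise ValueError(f"frame {self.frame_id}: non-finite frame energy")
        for wl, f in self.excitations:
            if not (math.isfinite(wl) and wl > 0):
                raise ValueError(
                    f"frame {self.frame_id}: wavelength must be finite and > 0, got {wl}"
                )
            if not (math.isfinite(f) and f >= 0):
                raise ValueError(
                    f"frame {self.frame_id}: oscillator strength must be ≥ 0, got {f}"
                )


@dataclass
class EnsembleConfig:
    """Ensemble-averaging parameters.

    per_frame_fwhm is the narrow analysis broadening; display_fwhm matches
    experimental band widths.  The wavelength grid is inclusive of
    grid_start and runs in steps of grid_step up to grid_stop.
    """

    temperature: float = 300.0  # K
    per_frame_fwhm: float = 10.0  # nm
    display_fwhm: float = 55.0  # nm
    grid_start: float = 250.0  # nm
    grid_stop: float = 800.0  # nm
    grid_step: float = 1.0  # nm
    boltzmann_constant: float = KB_KJ_PER_MOL_K  # kJ/mol/K, fixed

    def __post_init__(self) -> None:
        if self.temperature <= 0:
            raise ValueError("temperature must be > 0")
        if self.per_frame_fwhm <= 0 or self.display_fwhm <= 0:
            raise ValueError("fwhm must be > 0")
        if not self.grid_start < self.grid_stop:
            raise ValueError("grid_start must be < grid_stop")
        if self.grid_step <= 0:
            raise ValueError("grid_step must be > 0")

    def wavelength_grid(self) -> np.ndarray:
        n = int(math.floor((self.grid_stop - self.grid_start) / self.grid_step)) + 1
        return float(self.grid_start) + float(self.grid_step) * np.arange(n, dtype=float)


@dataclass(frozen=True)
class EnsembleWeights:
    """Normalized Boltzmann weights aligned with ``frame_ids``."""

    frame_ids: tuple[int, ...]
    weights: np.ndarray

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        if np.any((w < 0) | (w > 1)) or abs(w.sum() - 1.0) > 1e-12:
            raise ValueError("weights must lie in [0,1] and sum to 1 within 1e-12")


@dataclass
class Spectrum:
    """Intensity on a strictly increasing wavelength grid (arbitrary units)."""

    wavelengths: np.ndarray
    intensities: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.wavelengths.shape != self.intensities.shape:
            raise ValueError("wavelengths and intensities must have equal length")
        if self.wavelengths.size and np.any(np.diff(self.wavelengths) <= 0):
            raise ValueError("wavelength grid must be strictly increasing")
        if np.any(self.intensities < 0):
            raise ValueError("intensities must be non-negative")


# ---------------------------------------------------------------------------
# I/O


def read_excitation_table(
    path: str | Path, energy_unit: str | None = None
) -> list[FrameExcitations]:
    """Read a per-frame excitation CSV into ``FrameExcitations`` records.

    Expected columns: ``frame_id, frame_energy, wavelength_nm, osc_strength``,
    one row per excitation; an optional ``energy_unit`` column (``hartree`` or
    ``kJ/mol``) overrides the ``energy_unit`` argument.  Energies are converted
    to kJ/mol internally.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, skip_blank_lines=True)
    except pd.errors.EmptyDataError:
        raise ExcitationTableError(f"{path}: empty file") from None
    if df.empty:
        raise ExcitationTableError(f"{path}: no data rows (line 2)")

    required = ["frame_id", "frame_energy", "wavelength_nm", "osc_strength"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ExcitationTableError(f"{path}: missing column(s) {missing} (line 1)")

    if "energy_unit" in df.columns:
        units = df["energy_unit"].astype(str).str.strip().str.lower()
    elif energy_unit is not None:
        units = pd.Series([energy_unit.strip().lower()] * len(df), index=df.index)
    else:
        raise ExcitationTableError(
            f"{path}: no energy_unit column and no energy_unit argument given"
        )

    for col in required:
        numeric = pd.to_numeric(df[col], errors="coerce")
        bad = numeric.isna() & df[col].notna() | df[col].isna()
        if bad.any():
            line = int(bad.idxmax()) + 2  # header is line 1
            raise ExcitationTableError(f"{path}: non-numeric or missing {col} (line {line})")
        df[col] = numeric

    frames: list[FrameExcitations] = []
    for fid, grp in df.groupby("frame_id", sort=True):
        unit_set = set(units.loc[grp.index])
        if len(unit_set) > 1:
            raise ExcitationTableError(
                f"{path}: conflicting energy units for frame {fid}: {sorted(unit_set)}"
            )
        unit = unit_set.pop()
        if unit not in _ENERGY_UNITS:
            raise ExcitationTableError(f"{path}: unknown energy unit {unit!r}")
        energies = grp["frame_energy"].unique()
        if len(energies) > 1:
            line = int(grp.index[1]) + 2
            raise ExcitationTableError(
                f"{path}: conflicting frame_energy values for frame {fid} (line {line})"
            )
        try:
            frames.append(
                FrameExcitations(
                    frame_id=int(fid),
                    frame_energy=float(energies[0]) * _ENERGY_UNITS[unit],
                    excitations=tuple(
                        (float(w), float(f))
                        for w, f in zip(grp["wavelength_nm"], grp["osc_strength"])
                    ),
                )
            )
        except ValueError as exc:
            line = int(grp.index[0]) + 2
            raise ExcitationTableError(f"{path}: {exc} (near line {line})") from None
    return frames


def write_excitation_table(
    frames: Sequence[FrameExcitations], path: str | Path, energy_unit: str = "kJ/mol"
) -> None:
    """Write frames back to the CSV schema ``read_excitation_table`` reads."""
    unit = energy_unit.strip().lower()
    if unit not in _ENERGY_UNITS:
        raise ValueError(f"unknown energy unit {energy_unit!r}")
    factor = _ENERGY_UNITS[unit]
    rows = [
        {
            "frame_id": fr.frame_id,
            "frame_energy": repr(fr.frame_energy / factor),
            "energy_unit": energy_unit,
            "wavelength_nm": repr(wl),
            "osc_strength": repr(f),
        }
        for fr in frames
        for wl, f in fr.excitations
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Core computation


def boltzmann_weights(
    frames: Sequence[FrameExcitations], config: EnsembleConfig | None = None
) -> EnsembleWeights:
    """Boltzmann weights of the sampled frames at ``config.temperature``.

    ΔE_i is referenced to the minimum energy in the set, so the result is
    invariant to uniform energy offsets and numerically stable for large
    spreads (computed via a shifted softmax).
    """
    config = config or EnsembleConfig()
    if len(frames) == 0:
        raise ValueError("at least one frame required")
    energies = np.array([f.frame_energy for f in frames], dtype=float)
    if not np.all(np.isfinite(energies)):
        raise ValueError("non-finite frame energy")
    kt = config.boltzmann_constant * config.temperature
    w = softmax(-(energies - energies.min()) / kt)
    w = w / w.sum()  # tighten normalization to the 1e-12 invariant
    return EnsembleWeights(
        frame_ids=tuple(f.frame_id for f in frames), weights=w
    )


def broaden(
    excitations: Sequence[tuple[float, float]],
    fwhm: float,
    grid: np.ndarray,
    label: str = "",
) -> Spectrum:
    """Gaussian-broaden stick excitations onto ``grid``.

    Each excitation contributes an area-normalized Gaussian (σ = FWHM /
    2√(2 ln 2)) scaled by its oscillator strength, so the integral of the
    band equals the total oscillator strength.  An empty excitation list
    gives an all-zero spectrum.
    """
    if fwhm <= 0:
        raise ValueError("fwhm must be > 0")
    grid = np.asarray(grid, dtype=float)
    if grid.size == 0:
        raise ValueError("empty wavelength grid")
    sigma = fwhm / FWHM_TO_SIGMA
    intensities = np.zeros_like(grid)
    for wl, f in excitations:
        intensities += (
            f / (sigma * math.sqrt(2 * math.pi))
        ) * np.exp(-0.5 * ((grid - wl) / sigma) ** 2)
    return Spectrum(grid, intensities, label=label)


def ensemble_spectrum(
    frames: Sequence[FrameExcitations],
    config: EnsembleConfig | None = None,
    fwhm: float | None = None,
    label: str = "",
) -> Spectrum:
    """Boltzmann-weighted sum of per-frame broadened spectra.

    The result is a pointwise convex combination of the per-frame spectra;
    ``fwhm`` defaults to ``config.per_frame_fwhm`` (pass
    ``config.display_fwhm`` for the wide display variant).
    """
    config = config or EnsembleConfig()
    weights = boltzmann_weights(frames, config)
    grid = config.wavelength_grid()
    fwhm = config.per_frame_fwhm if fwhm is None else fwhm
    total = np.zeros_like(grid)
    for w, fr in zip(weights.weights, frames):
        total += w * broaden(fr.excitations, fwhm, grid).intensities
    return Spectrum(grid, total, label=label)


def sample_frames(n_available: int, n_sample: int, seed: int) -> np.ndarray:
    """Uniformly sample ``n_sample`` distinct frame indices, sorted ascending."""
    if n_sample > n_available:
        raise ValueError(f"cannot sample {n_sample} from {n_available} frames")
    rng = np.random.default_rng(seed)
    return np.sort(rng.choice(n_available, size=n_sample, replace=False))


def lambda_max(
    spectrum: Spectrum, window: tuple[float, float] | None = None
) -> float:
    """Wavelength (nm) of the global intensity maximum.

    Ties break toward the shortest wavelength; an all-zero spectrum has no
    band and raises ``ValueError``.
    """
    wl, inten = spectrum.wavelengths, spectrum.intensities
    if wl.size == 0:
        raise ValueError("empty spectrum")
    if window is not None:
        lo, hi = window
        if lo < wl[0] or hi > wl[-1]:
            raise ValueError("window outside the spectrum grid")
        mask = (wl >= lo) & (wl <= hi)
        wl, inten = wl[mask], inten[mask]
    peak = inten.max()
    if peak <= 0:
        raise ValueError("no band: spectrum is all zero")
    return float(wl[np.flatnonzero(inten == peak)[0]])


def normalize_max(spectrum: Spectrum) -> Spectrum:
    """Scale a spectrum so its maximum intensity is 1 (for plotting)."""
    peak = spectrum.intensities.max()
    if peak <= 0:
        raise ValueError("cannot normalize an all-zero spectrum")
    return Spectrum(
        spectrum.wavelengths, spectrum.intensities / peak, label=spectrum.label
    )


def write_spectrum(spectrum: Spectrum, path: str | Path) -> None:
    """Write a spectrum as two-column TSV (wavelength_nm, intensity)."""
    pd.DataFrame(
        {"wavelength_nm": spectrum.wavelengths, "intensity": spectrum.intensities}
    ).to_csv(path, sep="\t", index=False)


def read_spectrum(path: str | Path, label: str = "") -> Spectrum:
    df = pd.read_csv(path, sep="\t")
    return Spectrum(df["wavelength_nm"].to_numpy(), df["intensity"].to_numpy(), label)
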