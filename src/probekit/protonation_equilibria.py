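"""Thermochemistry-based pKa calibration and pH speciation.

The pKa of a new compound can be estimated from the computed deprotonation
enthalpy ΔH (kJ/mol, 298 K) of its conjugate acid via an empirical linear
calibration pKa = slope·ΔH + intercept fitted, per chemical class (aromatic
amine vs benzimidazole), on reference compounds with known pKa.  With
stepwise macroscopic pKa values in hand, the fractional population of each
protonation microstate of a multi-site base follows from the standard
equilibrium relation: the relative abundance of a microstate is the product
over its bound protons of 10^(pKa_step − pH), normalized at each pH.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats

__all__ = [
    "CalibrationPoint",
    "CalibrationLine",
    "Microstate",
    "SpeciationProfile",
    "fit_calibration",
    "predict_pka",
    "microstates_from_enthalpies",
    "speciation",
    "dominant_species",
]


@dataclass(frozen=True)
class CalibrationPoint:
    """Reference compound: deprotonation enthalpy (kJ/mol, 298 K) and pKa."""

    compound_id: str
    delta_h: float
    pka: float
    chemical_class: str = "amine"

    def __post_init__(self) -> None:
        if not (math.isfinite(self.delta_h) and math.isfinite(self.pka)):
            raise ValueError(f"{self.compound_id}: non-finite calibration point")


@dataclass(frozen=True)
class CalibrationLine:
    """Fitted pKa = slope·ΔH + intercept for one chemical class."""

    slope: float  # per kJ/mol
    intercept: float
    n_points: int
    residual_sd: float
    chemical_class: str
    slope_se: float = float("nan")
    intercept_se: float = float("nan")

    def __post_init__(self) -> None:
        if self.n_points < 2:
            raise ValueError("a calibration line needs at least 2 points")


@dataclass(frozen=True)
class Microstate:
    """One protonation microstate.

    ``step_pkas`` lists the stepwise macroscopic pKa for each bound proton
    along the protonation path from the neutral form (length == n_protons);
    absolute energy (Hartree) and the deprotonation enthalpy to the neutral
    form are optional metadata only.
    """

    label: str
    n_protons: int
    step_pkas: tuple[float, ...] = ()
    energy: float | None = None
    deprotonation_enthalpy: float | None = None
    pka_estimate: float | None = None

    def __post_init__(self) -> None:
        if self.n_protons < 0:
            raise ValueError("n_protons must be ≥ 0")


@dataclass
class SpeciationProfile:
    """Per-microstate fractional populations over a pH grid."""

    ph_grid: np.ndarray
    fractions: dict[str, np.ndarray]
    n_protons: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.ph_grid = np.asarray(self.ph_grid, dtype=float)
        total = np.sum(list(self.fractions.values()), axis=0)
        if np.any(np.abs(total - 1.0) > 1e-10):
            raise ValueError("fractions must sum to 1 at every pH (1e-10)")


def fit_calibration(
    points: Sequence[CalibrationPoint], chemical_class: str
) -> CalibrationLine:
    """Ordinary least-squares pKa-vs-ΔH line over one chemical class.

    ``residual_sd`` is sqrt(SS_res / (n−2)) (0 by convention for an exact
    two-point fit).
    """
    sel = [p for p in points if p.chemical_class == chemical_class]
    if len(sel) < 2:
        raise ValueError(
            f"need ≥ 2 calibration points of class {chemical_class!r}, got {len(sel)}"
        )
    dh = np.array([p.delta_h for p in sel])
    pka = np.array([p.pka for p in sel])
    if np.ptp(dh) == 0:
        raise ValueError("all delta_h equal: calibration line undefined")
    res = stats.linregress(dh, pka)
    resid = pka - (res.slope * dh + res.intercept)
    dof = len(sel) - 2
    residual_sd = float(np.sqrt((resid**2).sum() / dof)) if dof > 0 else 0.0
    return CalibrationLine(
        slope=float(res.slope),
        intercept=float(res.intercept),
        n_points=len(sel),
        residual_sd=residual_sd,
        chemical_class=chemical_class,
        slope_se=float(res.stderr) if dof > 0 else 0.0,
        intercept_se=float(res.intercept_stderr) if dof > 0 else 0.0,
    )


def predict_pka(line: CalibrationLine, delta_h: float) -> float:
    """Evaluate the calibration line at a deprotonation enthalpy (kJ/mol)."""
    return line.slope * delta_h + line.intercept


def microstates_from_enthalpies(
    labels_protons_dh: Sequence[tuple[str, int, float | None]],
    line: CalibrationLine,
) -> tuple[Microstate, ...]:
    """Build microstates whose single-step pKa comes from the calibration.

    For singly protonated states the step pKa is predicted from ΔH; the
    neutral state passes ΔH ``None``.  Multi-proton states are not derivable
    from one enthalpy and must be constructed explicitly.
    """
    out = []
    for label, n, dh in labels_protons_dh:
        if n == 0:
            out.append(Microstate(label, 0))
        elif n == 1 and dh is not None:
            pka = predict_pka(line, dh)
            out.append(
                Microstate(label, 1, (pka,), deprotonation_enthalpy=dh, pka_estimate=pka)
            )
        else:
            raise ValueError(f"{label}: cannot derive {n}-proton state from one ΔH")
    return tuple(out)


def speciation(
    microstates: Sequence[Microstate], ph_grid: Sequence[float]
) -> SpeciationProfile:
    """Fractional population of each microstate across a pH grid.

    Relative abundance of a microstate is Π over its bound protons of
    10^(pKa_step − pH); populations are computed in log10 space and
    normalized per pH point, so arbitrarily extreme pKa/pH combinations do
    not overflow.
    """
    neutral = [m for m in microstates if m.n_protons == 0]
    if len(neutral) != 1:
        raise ValueError("exactly one neutral (0-proton) microstate required")
    for m in microstates:
        if len(m.step_pkas) != m.n_protons:
            raise ValueError(
                f"{m.label}: {m.n_protons} protons but {len(m.step_pkas)} stepwise pKa values"
            )
        if any(not math.isfinite(p) for p in m.step_pkas):
            raise ValueError(f"{m.label}: non-finite stepwise pKa")
    ph = np.asarray(ph_grid, dtype=float)
    # log10 relative abundance per state, shape (n_states, n_ph)
    log10_rel = np.stack(
        [
            np.full_like(ph, sum(m.step_pkas)) - m.n_protons * ph
            for m in microstates
        ]
    )
    log10_rel -= log10_rel.max(axis=0, keepdims=True)
    rel = 10.0**log10_rel
    frac = rel / rel.sum(axis=0, keepdims=True)
    return SpeciationProfile(
        ph_grid=ph,
        fractions={m.label: frac[i] for i, m in enumerate(microstates)},
        n_protons={m.label: m.n_protons for m in microstates},
    )


def dominant_species(profile: SpeciationProfile, ph: float) -> str:
    """Label of the most abundant microstate at the grid point nearest ``ph``
    (ties resolved toward the fewest bound protons)."""
    grid = profile.ph_grid
    if not grid.min() <= ph <= grid.max():
        raise ValueError(f"pH {ph} outside the profile grid [{grid.min()}, {grid.max()}]")
    idx = int(np.argmin(np.abs(grid - ph)))
    best = max(
        profile.fractions,
        key=lambda lab: (profile.fractions[lab][idx], -profile.n_protons.get(lab, 0)),
    )
    return best
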