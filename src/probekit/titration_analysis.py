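"""Four-parameter dose-response fitting of fluorescence pH titrations.

Plotting the fluorescence intensity of a pH-responsive probe against pH
gives a sigmoid fitted with the standard dose-response model

    y = A1 + (A2 − A1) / (1 + 10^((log x0 − x)·p))

where x is pH, A1 and A2 are the asymptotes, log x0 the midpoint and p the
slope factor.  The midpoint is read directly as the probe's apparent pKa.
The fit is unweighted nonlinear least squares (Levenberg-Marquardt via
lmfit), reporting per-parameter standard errors, reduced chi-square and
adjusted R².  The parameterization is degenerate under (A1, A2, p) →
(A2, A1, −p); fits are canonicalized to p < 0, which places A1 at the
high-pH asymptote (the convention for probes that light up in acid).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
from lmfit import Model

__all__ = [
    "TitrationPoint",
    "DoseRespParams",
    "PkaEstimate",
    "doseresp_eval",
    "fit_doseresp",
    "pka_from_fit",
    "fold_change",
]


@dataclass(frozen=True)
class TitrationPoint:
    """One (pH, fluorescence intensity) observation."""

    ph: float
    intensity: float

    def __post_init__(self) -> None:
        if not (math.isfinite(self.ph) and math.isfinite(self.intensity)):
            raise ValueError("pH and intensity must be finite")


@dataclass(frozen=True)
class DoseRespParams:
    """Fitted dose-response parameters with uncertainties and fit quality."""

    a1: float
    a2: float
    log_x0: float
    p: float
    a1_se: float = float("nan")
    a2_se: float = float("nan")
    log_x0_se: float = float("nan")
    p_se: float = float("nan")
    reduced_chisq: float = float("nan")
    adj_r_square: float = float("nan")
    n_points: int = 0


@dataclass(frozen=True)
class PkaEstimate:
    """Apparent pKa read from the sigmoid midpoint."""

    value: float
    stderr: float

    @property
    def display(self) -> str:
        """Two-decimal display convention for reporting."""
        return f"{self.value:.2f}"


def _doseresp(x, a1, a2, log_x0, p):
    return a1 + (a2 - a1) / (1.0 + 10.0 ** ((log_x0 - x) * p))


def doseresp_eval(
    params: DoseRespParams | Sequence[float], x: float | np.ndarray
) -> float | np.ndarray:
    """Evaluate the dose-response curve at pH ``x``."""
    if isinstance(params, DoseRespParams):
        a1, a2, log_x0, p = params.a1, params.a2, params.log_x0, params.p
    else:
        a1, a2, log_x0, p = params
    y = _doseresp(np.asarray(x, dtype=float), a1, a2, log_x0, p)
    return float(y) if np.isscalar(x) else y


def fit_doseresp(
    data: Sequence[TitrationPoint],
    normalize: bool = False,
    max_nfev: int = 10000,
) -> DoseRespParams:
    """Fit the four-parameter dose-response model to titration data.

    Starting values: A1 = min(y), A2 = max(y), log x0 = median pH, p of unit
    magnitude with sign taken from the empirical intensity-vs-pH slope.  If
    ``normalize``, intensities are divided by their maximum before fitting
    (asymptotes are then on a near-unity scale).  Raises ``ValueError`` on
    fewer than 5 points, fewer than 4 distinct pH values, zero intensity
    variance, or failure to converge.
    """
    if len(data) < 5:
        raise ValueError(f"need ≥ 5 titration points, got {len(data)}")
    x = np.array([d.ph for d in data], dtype=float)
    y = np.array([d.intensity for d in data], dtype=float)
    if len(np.unique(x)) < 4:
        raise ValueError("need ≥ 4 distinct pH values")
    if np.ptp(y) == 0:
        raise ValueError("constant intensity: transition not identifiable")
    if normalize:
        y = y / y.max()

    slope_sign = -1.0 if np.polyfit(x, y, 1)[0] < 0 else 1.0
    model = Model(_doseresp)
    params = model.make_params(
        a1=float(y.min()),
        a2=float(y.max()),
        log_x0=float(np.median(x)),
        p=slope_sign * 1.0,
    )
    result = model.fit(y, params, x=x, max_nfev=max_nfev)
    if not result.success:
        raise ValueError(f"dose-response fit did not converge: {result.message}")

    vals = {k: float(result.params[k].value) for k in ("a1", "a2", "log_x0", "p")}
    errs = {
        k: (float(result.params[k].stderr) if result.params[k].stderr is not None else float("nan"))
        for k in ("a1", "a2", "log_x0", "p")
    }
    n, k_par = len(y), 4
    ss_res = float(np.sum(result.residual**2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    adj_r2 = 1.0 - (ss_res / ss_tot) * (n - 1) / (n - k_par) if n > k_par else float("nan")
    fitted = DoseRespParams(
        a1=vals["a1"],
        a2=vals["a2"],
        log_x0=vals["log_x0"],
        p=vals["p"],
        a1_se=errs["a1"],
        a2_se=errs["a2"],
        log_x0_se=errs["log_x0"],
        p_se=errs["p"],
        reduced_chisq=float(result.redchi),
        adj_r_square=adj_r2,
        n_points=n,
    )
    if fitted.p > 0:  # canonicalize the (A1,A2,p)→(A2,A1,−p) degeneracy
        fitted = replace(
            fitted,
            a1=fitted.a2,
            a2=fitted.a1,
            a1_se=fitted.a2_se,
            a2_se=fitted.a1_se,
            p=-fitted.p,
        )
    return fitted


def pka_from_fit(params: DoseRespParams) -> PkaEstimate:
    """The apparent pKa: the fitted midpoint log x0 with its standard error."""
    return PkaEstimate(value=params.log_x0, stderr=params.log_x0_se)


def fold_change(params: DoseRespParams, ph_low: float, ph_high: float) -> float:
    """Model-based intensity ratio y(ph_low) / y(ph_high)."""
    denom = doseresp_eval(params, ph_high)
    if abs(denom) < 1e-12:
        raise ValueError("model intensity at ph_high is ~0; fold change undefined")
    return float(doseresp_eval(params, ph_low) / denom)
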