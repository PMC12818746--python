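"""Quantitative fluorescence-imaging and plate-reader statistics.

Four assay read-outs used to characterize an intracellular pH probe:

* **Viability** from a resazurin plate:
  ``100 × (mean treated − mean blank) / (mean control − mean blank)``,
  reported per condition as mean ± SEM over replicate wells.
* **Colocalization** of two 8-bit channels: the pixelwise Pearson
  correlation, plus the Costes automatic background threshold — the pair of
  channel intensities, taken along the inter-channel orthogonal regression,
  below which the residual correlation of "background" pixels is no longer
  positive.  The Pearson coefficient above both thresholds is reported
  alongside the whole-image value.
* **Per-cell intensity**: mean channel intensity within each labeled cell
  mask.
* **pH-dependent fluorescence gain**:
  ``100 × (F(pH 4.5) − F(pH 7)) / F(pH 7)``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage

__all__ = [
    "ViabilityPlate",
    "ViabilityResult",
    "ChannelPair",
    "ColocResult",
    "GainPair",
    "viability_percent",
    "pearson",
    "costes_thresholds",
    "colocalize",
    "per_cell_intensity",
    "fluorescence_gain",
    "read_channel",
]


@dataclass
class ViabilityPlate:
    """Plate-reader readings: treated wells per condition, untreated
    controls, and medium-only blanks."""

    treated: Mapping[str, Sequence[float]]
    control: Sequence[float]
    blank: Sequence[float]

    def __post_init__(self) -> None:
        if not len(self.control) or not len(self.blank):
            raise ValueError("control and blank groups need ≥ 1 reading")
        for cond, vals in self.treated.items():
            if not len(vals):
                raise ValueError(f"condition {cond!r} has no readings")


@dataclass(frozen=True)
class ViabilityResult:
    """Viability % for one condition; ``flagged`` marks values outside
    [0, 100] (reported as computed, never clipped)."""

    percent: float
    sem: float
    n: int
    flagged: bool


@dataclass
class ChannelPair:
    """Co-registered 8-bit red/green channels (optionally with cell masks)."""

    red: np.ndarray
    green: np.ndarray
    masks: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.red = np.asarray(self.red)
        self.green = np.asarray(self.green)
        if self.red.shape != self.green.shape:
            raise ValueError("channel shapes differ")
        for name, ch in (("red", self.red), ("green", self.green)):
            if ch.min() < 0 or ch.max() > 255:
                raise ValueError(f"{name} channel values outside [0, 255]")


@dataclass(frozen=True)
class ColocResult:
    pearson_r: float
    costes_threshold_red: float
    costes_threshold_green: float
    pearson_above_threshold: float
    n_pixels_used: int
    thresholds_defined: bool = True


@dataclass(frozen=True)
class GainPair:
    """Mean fluorescence at acidic (pH 4.5) and near-neutral (pH 7) clamp."""

    fluo_acid: float
    fluo_neutral: float


def viability_percent(plate: ViabilityPlate) -> dict[str, ViabilityResult]:
    """Viability % per treated condition, mean ± SEM over replicates.

    Per-replicate viability uses the group means of blank and control; the
    result is affine-invariant under a common shift of all readings.
    """
    control = np.asarray(plate.control, dtype=float)
    blank = np.asarray(plate.blank, dtype=float)
    denom = control.mean() - blank.mean()
    if denom == 0:
        raise ValueError("control mean equals blank mean: viability undefined")
    out: dict[str, ViabilityResult] = {}
    for cond, vals in plate.treated.items():
        v = 100.0 * (np.asarray(vals, dtype=float) - blank.mean()) / denom
        mean = float(v.mean())
        sem = float(v.std(ddof=1) / math.sqrt(len(v))) if len(v) > 1 else 0.0
        out[cond] = ViabilityResult(
            percent=mean, sem=sem, n=len(v), flagged=not (0.0 <= mean <= 100.0)
        )
    return out


def pearson(pair: ChannelPair, mask: np.ndarray | None = None) -> float:
    """Pixelwise Pearson correlation of the two channels (within ``mask``)."""
    r_px = pair.red.astype(float).ravel()
    g_px = pair.green.astype(float).ravel()
    if mask is not None:
        sel = np.asarray(mask).ravel().astype(bool)
        r_px, g_px = r_px[sel], g_px[sel]
    if r_px.size < 2:
        raise ValueError("need ≥ 2 pixels in scope")
    if np.ptp(r_px) == 0 or np.ptp(g_px) == 0:
        raise ValueError("zero variance in a channel: correlation undefined")
    rc = r_px - r_px.mean()
    gc = g_px - g_px.mean()
    return float((rc * gc).sum() / math.sqrt((rc**2).sum() * (gc**2).sum()))


def _orthogonal_regression(r_px: np.ndarray, g_px: np.ndarray) -> tuple[float, float]:
    """Total-least-squares line G = a·R + b via the covariance eigenvector."""
    cov = np.cov(np.stack([r_px, g_px]))
    evals, evecs = np.linalg.eigh(cov)
    major = evecs[:, np.argmax(evals)]
    if major[0] == 0:
        raise ValueError("vertical regression line: thresholds undefined")
    a = major[1] / major[0]
    b = g_px.mean() - a * r_px.mean()
    return float(a), float(b)


def costes_thresholds(pair: ChannelPair) -> ColocResult:
    """Costes automatic background thresholds for a channel pair.

    Fits the orthogonal regression G = a·R + b over all pixels, then scans
    candidate red thresholds T downward from 255 (green threshold a·T + b):
    the returned pair is the first (largest) T at which the Pearson
    correlation of pixels below *both* thresholds is ≤ 0.  If the
    whole-image correlation is ≤ 0 the thresholds are undefined and the
    result is flagged; if the scan exhausts all levels (perfect correlation)
    the thresholds fall to the channel minima.
    """
    r_px = pair.red.astype(float).ravel()
    g_px = pair.green.astype(float).ravel()
    r_full = pearson(pair)
    if r_full <= 0:
        return ColocResult(
            pearson_r=r_full,
            costes_threshold_red=float("nan"),
            costes_threshold_green=float("nan"),
            pearson_above_threshold=float("nan"),
            n_pixels_used=r_px.size,
            thresholds_defined=False,
        )
    a, b = _orthogonal_regression(r_px, g_px)
    t_red: float | None = None
    for t in range(255, -1, -1):
        below = (r_px < t) & (g_px < a * t + b)
        if below.sum() < 2:
            continue
        rb, gb = r_px[below], g_px[below]
        if np.ptp(rb) == 0 or np.ptp(gb) == 0:
            continue
        r_below = np.corrcoef(rb, gb)[0, 1]
        if r_below <= 0:
            t_red = float(t)
            break
    if t_red is None:  # never decorrelates: background indistinguishable
        t_red = float(r_px.min())
    t_green = float(np.clip(a * t_red + b, 0.0, 255.0))
    above = (r_px > t_red) & (g_px > t_green)
    if above.sum() >= 2 and np.ptp(r_px[above]) > 0 and np.ptp(g_px[above]) > 0:
        r_above = float(np.corrcoef(r_px[above], g_px[above])[0, 1])
    else:
        r_above = float("nan")
    return ColocResult(
        pearson_r=r_full,
        costes_threshold_red=t_red,
        costes_threshold_green=t_green,
        pearson_above_threshold=r_above,
        n_pixels_used=int(above.sum()),
    )


def colocalize(
    pair: ChannelPair,
    scatter_range: tuple[float, float] = (20.0, 255.0),
) -> tuple[ColocResult, pd.DataFrame]:
    """Full colocalization report plus an (R_i, G_i) scatter table.

    The scatter table keeps pixels whose red *and* green intensities both
    lie in ``scatter_range`` (default 20-255, suppressing the dark
    background for plotting).
    """
    result = costes_thresholds(pair)
    lo, hi = scatter_range
    r_px = pair.red.astype(float).ravel()
    g_px = pair.green.astype(float).ravel()
    sel = (r_px >= lo) & (r_px <= hi) & (g_px >= lo) & (g_px <= hi)
    scatter = pd.DataFrame({"R_i": r_px[sel], "G_i": g_px[sel]})
    return result, scatter


def per_cell_intensity(
    image: np.ndarray, cell_masks: np.ndarray
) -> dict[int, float]:
    """Mean pixel intensity within each labeled cell region (label > 0)."""
    image = np.asarray(image, dtype=float)
    labels = np.asarray(cell_masks)
    if labels.shape != image.shape:
        raise ValueError("mask shape must match image shape")
    ids = np.unique(labels)
    ids = ids[ids > 0]
    if ids.size == 0:
        raise ValueError("no labeled cells in mask")
    means = ndimage.mean(image, labels=labels, index=ids)
    return {int(i): float(m) for i, m in zip(ids, means)}


def fluorescence_gain(pair: GainPair) -> float:
    """Percent fluorescence gain of the acidic over the neutral condition."""
    if pair.fluo_neutral <= 0:
        raise ValueError("neutral-pH fluorescence must be > 0")
    return 100.0 * (pair.fluo_acid - pair.fluo_neutral) / pair.fluo_neutral


def read_channel(path: str | Path, page: int = 0) -> np.ndarray:
    """Read one 8-bit grayscale plane from a TIFF file."""
    import tifffile

    arr = tifffile.imread(path, key=page)
    if arr.ndim == 3:  # RGB page: caller should split; take first plane
        arr = arr[..., 0]
    if arr.dtype != np.uint8:
        raise ValueError(f"{path}: expected 8-bit image, got {arr.dtype}")
    return arr
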