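"""Cross-frequency power comodulation.

A comodulogram asks which rhythms wax and wane together: for every pair
of frequencies the power time courses (columns of a spectrogram) are
correlated across time, yielding a symmetric frequency x frequency
matrix of Pearson coefficients with unit diagonal.  Correlations are
computed on log10 power by default (power distributions are heavy
tailed).  Interaction strength is conventionally read as weak
(|r| < 0.2), moderate (0.2 <= |r| < 0.5) or high (|r| >= 0.5).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .multitaper import Spectrogram

__all__ = [
    "Comodulogram",
    "RegionSummary",
    "StrengthScale",
    "comodulogram",
    "region_summary",
    "classify_strength",
]

logger = logging.getLogger(__name__)


@dataclass
class Comodulogram:
    """Frequency x frequency correlation matrix of power time series.

    Cells involving a constant-power frequency row are NaN (undefined);
    elsewhere r is in [-1, 1], the matrix is symmetric and the diagonal
    is exactly 1.
    """

    freqs: np.ndarray
    r: np.ndarray
    window_count: int


@dataclass(frozen=True)
class RegionSummary:
    """Mean +/- SD and 95 % CI of r over a band x band rectangle."""

    band_x: tuple
    band_y: tuple
    mean: float
    sd: float
    ci95: tuple
    n_bins: int

    def __str__(self) -> str:
        return (
            f"{self.band_x[0]:g}-{self.band_x[1]:g} Hz x "
            f"{self.band_y[0]:g}-{self.band_y[1]:g} Hz: "
            f"{self.mean:.3f} ± {self.sd:.3f}, "
            f"95% CI = {self.ci95[0]:.3f}-{self.ci95[1]:.3f}"
        )


@dataclass(frozen=True)
class StrengthScale:
    """Comodulation strength thresholds: weak < ``weak_hi`` <= moderate
    < ``moderate_hi`` <= high <= 1."""

    weak_hi: float = 0.2
    moderate_hi: float = 0.5

    def __post_init__(self) -> None:
        if not 0.0 < self.weak_hi < self.moderate_hi <= 1.0:
            raise ValueError("require 0 < weak_hi < moderate_hi <= 1")


def comodulogram(spectrogram: Spectrogram, log_power: bool = True, eps: float = 1e-30) -> Comodulogram:
    """Pearson-correlate spectral power time series across frequencies.

    Uses the spectrogram's ``mean_power`` columns sampled every dt.
    Rows with zero variance (constant power) are flagged undefined
    (NaN) and logged rather than producing spurious correlations.
    """
    nt = spectrogram.times.size
    if nt < 10:
        raise ValueError(f"need at least 10 time samples, got {nt}")
    ts = spectrogram.mean_power  # (n_times, n_freqs)
    if log_power:
        ts = np.log10(np.maximum(ts, eps))
    sd = ts.std(axis=0)
    valid = sd > 0
    n_const = int((~valid).sum())
    if n_const:
        logger.info("comodulogram: %d constant-power frequency rows set undefined", n_const)
    nf = ts.shape[1]
    r = np.full((nf, nf), np.nan)
    if valid.any():
        sub = np.corrcoef(ts[:, valid].T)
        r[np.ix_(valid, valid)] = sub
        r[valid, valid] = 1.0
    return Comodulogram(spectrogram.freqs.copy(), r, window_count=nt)


def region_summary(comod: Comodulogram, band_x: tuple, band_y: tuple) -> RegionSummary:
    """Mean, SD and 95 % CI of r over a band x band rectangle.

    Main-diagonal cells (same frequency on both axes) are removed so
    the trivial r = 1 does not inflate the mean.  The CI is
    mean +/- t(0.975, n_bins - 1) x SD.
    """
    mx = (comod.freqs >= band_x[0] - 1e-9) & (comod.freqs < band_x[1] - 1e-9)
    my = (comod.freqs >= band_y[0] - 1e-9) & (comod.freqs < band_y[1] - 1e-9)
    if not mx.any() or not my.any():
        raise ValueError("band does not intersect the frequency grid")
    ix = np.where(mx)[0]
    iy = np.where(my)[0]
    cells = comod.r[np.ix_(ix, iy)].astype(float).copy()
    diag = ix[:, None] == iy[None, :]
    vals = cells[~diag]
    vals = vals[np.isfinite(vals)]
    if vals.size == 0:
        raise ValueError("region is empty after removing diagonal/undefined cells")
    mean = float(vals.mean())
    sd = float(vals.std(ddof=1)) if vals.size > 1 else 0.0
    if vals.size > 1:
        tq = float(stats.t.ppf(0.975, vals.size - 1))
        ci = (mean - tq * sd, mean + tq * sd)
    else:
        ci = (mean, mean)
    return RegionSummary(
        band_x=tuple(map(float, band_x)), band_y=tuple(map(float, band_y)),
        mean=mean, sd=sd, ci95=ci, n_bins=int(vals.size),
    )


def classify_strength(value: float, scale: StrengthScale = StrengthScale()) -> str:
    """Map |r| to ``"weak"``, ``"moderate"`` or ``"high"``."""
    if not np.isfinite(value):
        raise ValueError("comodulation value must be finite")
    v = abs(float(value))
    if v > 1.0:
        raise ValueError(f"|r| = {v} exceeds 1")
    if v < scale.weak_hi:
        return "weak"
    if v < scale.moderate_hi:
        return "moderate"
    return "high"
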