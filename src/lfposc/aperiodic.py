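"""Aperiodic (1/f^alpha) characterization of power spectra.

Neural power spectra ride on a broadband background P(f) = C / f^alpha.
On log-log axes this background is a straight line with slope -alpha and
intercept log10(C), so an ordinary least-squares fit of log10(power) on
log10(frequency) characterizes it.  Fits are typically run separately
below and above the line-noise notch (1-48 Hz and 52-150 Hz).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .spectra import PowerSpectrum, _included_mask

__all__ = ["AperiodicFit", "fit_loglog"]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class AperiodicFit:
    """Result of a log-log linear fit.

    ``slope`` equals -alpha of the power law; ``intercept`` is log10 of
    the scale C (in the units of the fitted spectrum); ``r_squared`` is
    the coefficient of determination of the fit.
    """

    slope: float
    intercept: float
    r_squared: float
    f_range: tuple
    n_points: int

    @property
    def exponent_alpha(self) -> float:
        """Power-law exponent alpha = -slope."""
        return -self.slope

    def summary(self) -> str:
        return (
            f"Y = {self.slope:+.4f} * X {self.intercept:+.4f}   "
            f"R2 = {self.r_squared:.4f}   "
            f"({self.n_points} points over {self.f_range[0]}-{self.f_range[1]} Hz)"
        )


def _ols_loglog(logf: np.ndarray, logp: np.ndarray) -> tuple:
    A = np.column_stack([logf, np.ones_like(logf)])
    coef, *_ = np.linalg.lstsq(A, logp, rcond=None)
    slope, intercept = float(coef[0]), float(coef[1])
    resid = logp - A @ coef
    ss_res = float(resid @ resid)
    ss_tot = float(((logp - logp.mean()) ** 2).sum())
    if ss_tot <= 1e-300:
        # flat data: zero explained variance by convention
        r2 = 1.0 if ss_res <= 1e-300 and abs(slope) > 0 else 0.0
    else:
        r2 = max(0.0, 1.0 - ss_res / ss_tot)
    return slope, intercept, r2


def fit_loglog(
    spectrum: PowerSpectrum,
    f_range: tuple = (1.0, 48.0),
    exclude: tuple = (),
    peak_exclude: bool = False,
) -> AperiodicFit:
    """OLS fit of log10(power) on log10(frequency) over ``f_range``.

    Bins with zero power are dropped (their count is logged).  With
    ``peak_exclude`` a single robust refinement is applied: bins whose
    residual exceeds two robust standard deviations (1.4826 x MAD) are
    dropped and the model refit once, de-weighting narrowband peaks that
    violate the power-law model.

    Raises
    ------
    ValueError
        If fewer than 3 strictly positive bins remain in the range.
    """
    mask = _included_mask(spectrum.freqs, f_range, exclude)
    mask &= spectrum.freqs > 0
    freqs = spectrum.freqs[mask]
    power = spectrum.power[mask]
    pos = power > 0
    n_zero = int((~pos).sum())
    if n_zero:
        logger.info("fit_loglog dropped %d zero-power bins", n_zero)
    freqs, power = freqs[pos], power[pos]
    if freqs.size < 3:
        raise ValueError(
            f"need at least 3 positive power bins in {f_range}, got {freqs.size}"
        )
    logf, logp = np.log10(freqs), np.log10(power)
    slope, intercept, r2 = _ols_loglog(logf, logp)
    n_used = logf.size
    if peak_exclude:
        resid = logp - (slope * logf + intercept)
        rsd = 1.4826 * np.median(np.abs(resid - np.median(resid)))
        if rsd > 0:
            keep = np.abs(resid - np.median(resid)) <= 2.0 * rsd
            if keep.sum() >= 3 and keep.sum() < n_used:
                slope, intercept, r2 = _ols_loglog(logf[keep], logp[keep])
                n_used = int(keep.sum())
    return AperiodicFit(slope, intercept, r2, tuple(f_range), n_used)
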