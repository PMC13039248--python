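"""Jackknife two-group comparison of spectrogram ensembles.

Each time-frequency bin of a multitaper spectrogram carries m = N_E x K
statistically independent (epoch, taper) power estimates.  Comparing two
ensembles bin-by-bin, the statistic is the difference of mean log10
powers; its standard error comes from delete-one jackknife variances of
each ensemble mean, summed across ensembles; the ratio is referred to a
t distribution with DOF = 2 N_E K (36 at the N_E = 6, K = 3 defaults).
Each bin is classified +1 (second ensemble significantly greater), -1
(significantly smaller) or 0 (no significant difference), and the
fractions of each type within a band summarize the map ("pie chart"
probability densities).

Per-bin tests are descriptive: overlapping time windows are correlated
in time, so no correction across bins is applied by default (an optional
Benjamini-Hochberg flag is available).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .multitaper import Spectrogram

__all__ = ["InferenceMap", "BandProbabilityDensity", "jackknife_compare", "band_probability_density"]

logger = logging.getLogger(__name__)


@dataclass
class InferenceMap:
    """Per-bin +1/0/-1 classification of a two-ensemble comparison.

    +1 means the second ensemble's power is significantly greater than
    the first's (E2nd >> E1st), -1 the reverse, 0 no significant
    difference at level ``alpha``.
    """

    times: np.ndarray
    freqs: np.ndarray
    types: np.ndarray  # int8, values in {-1, 0, +1}
    alpha: float
    dof: int

    def __post_init__(self) -> None:
        vals = np.unique(self.types)
        if not np.isin(vals, (-1, 0, 1)).all():
            raise ValueError("inference types must be -1, 0 or +1")


@dataclass(frozen=True)
class BandProbabilityDensity:
    """Fractions of each inference type within one frequency band."""

    band: tuple  # (low, high) Hz
    p_plus: float
    p_zero: float
    p_minus: float
    n_bins: int

    def __post_init__(self) -> None:
        total = self.p_plus + self.p_zero + self.p_minus
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"type fractions sum to {total}, expected 1")

    def as_dict(self) -> dict:
        return {
            "band_lo_hz": self.band[0],
            "band_hi_hz": self.band[1],
            "p_plus": self.p_plus,
            "p_zero": self.p_zero,
            "p_minus": self.p_minus,
            "n_bins": self.n_bins,
        }


def _jackknife_mean_var(values: np.ndarray) -> tuple:
    """Delete-one jackknife variance of the mean along axis 0.

    For sample v_1..v_m the leave-one-out means are
    theta_i = (S - v_i)/(m - 1); the jackknife variance of the mean is
    (m - 1)/m * sum_i (theta_i - mean(theta))^2.
    """
    m = values.shape[0]
    if m < 2:
        raise ValueError("jackknife needs at least 2 estimates per ensemble")
    s = values.sum(axis=0)
    loo = (s[None, ...] - values) / (m - 1)
    var = (m - 1) / m * ((loo - loo.mean(axis=0)) ** 2).sum(axis=0)
    return values.mean(axis=0), var


def jackknife_compare(
    first: Spectrogram,
    second: Spectrogram,
    alpha: float = 0.05,
    eps: float = 1e-30,
    dof: int | None = None,
    fdr: bool = False,
) -> InferenceMap:
    """Classify every bin of ``second`` vs ``first`` as +1, 0 or -1.

    The per-bin statistic is the difference of mean log10 power; its
    standard error is the square root of the summed jackknife variances
    of the two ensemble means; the two-sided test uses a t reference
    with ``dof`` degrees of freedom (default 2 N_E K when both ensembles
    share N_E and K, else m1 + m2).  Power estimates are floored at
    ``eps`` before taking logs.

    With ``fdr`` the per-bin p-values are Benjamini-Hochberg adjusted
    across the whole map before thresholding at ``alpha``.
    """
    if first.times.shape != second.times.shape or not np.allclose(first.times, second.times):
        raise ValueError("time grids differ between the spectrograms")
    if first.freqs.shape != second.freqs.shape or not np.allclose(first.freqs, second.freqs):
        raise ValueError("frequency grids differ between the spectrograms")
    if first.m < 2 or second.m < 2:
        raise ValueError("each ensemble needs at least 2 (epoch, taper) estimates")

    n_floored = int((first.stack < eps).sum() + (second.stack < eps).sum())
    if n_floored:
        logger.info("floored %d zero/negative power estimates at eps=%g", n_floored, eps)
    v1 = np.log10(np.maximum(first.stack, eps))
    v2 = np.log10(np.maximum(second.stack, eps))
    m1, var1 = _jackknife_mean_var(v1)
    m2, var2 = _jackknife_mean_var(v2)
    delta = m2 - m1
    se = np.sqrt(var1 + var2)

    if dof is None:
        same = first.n_epochs == second.n_epochs and first.params.n_tapers == second.params.n_tapers
        dof = 2 * first.n_epochs * first.params.n_tapers if same else first.m + second.m

    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, delta / np.where(se > 0, se, 1.0), 0.0)
    if fdr:
        p = 2.0 * stats.t.sf(np.abs(t), dof)
        order = np.argsort(p, axis=None)
        n = p.size
        ranked = p.flatten()[order]
        adj = np.minimum.accumulate((ranked * n / np.arange(1, n + 1))[::-1])[::-1]
        p_adj = np.empty(n)
        p_adj[order] = np.minimum(adj, 1.0)
        sig = p_adj.reshape(p.shape) < alpha
    else:
        crit = stats.t.ppf(1.0 - alpha / 2.0, dof)
        sig = np.abs(t) > crit
    types = (np.sign(delta) * sig).astype(np.int8)
    return InferenceMap(first.times.copy(), first.freqs.copy(), types, alpha, int(dof))


def band_probability_density(imap: InferenceMap, band: tuple) -> BandProbabilityDensity:
    """Fractions of +1/0/-1 bins with frequency in [low, high)."""
    lo, hi = band
    mask = (imap.freqs >= lo - 1e-9) & (imap.freqs < hi - 1e-9)
    if not mask.any():
        raise ValueError(f"band [{lo}, {hi}) Hz does not intersect the frequency grid")
    sub = imap.types[:, mask]
    n = sub.size
    return BandProbabilityDensity(
        band=(float(lo), float(hi)),
        p_plus=float((sub == 1).sum() / n),
        p_zero=float((sub == 0).sum() / n),
        p_minus=float((sub == -1).sum() / n),
        n_bins=int(n),
    )
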