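"""FFT power spectra, averaging, dual normalization and band powers.

Per-epoch spectra are one-sided periodograms on the epoch's native grid
(0.1-Hz bins for 10-s epochs), mean-removed and tapered with a
power-normalized window so the white-noise level is unbiased and total
spectral power matches time-domain variance (Parseval).  Two
normalizations mirror standard LFP practice: percent of total power
(removes absolute power differences between groups) and percent of each
subject's own pre-treatment baseline session (set to 100 %).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import signal as sps

__all__ = [
    "PowerSpectrum",
    "Band",
    "BandScheme",
    "default_bands",
    "epoch_spectrum",
    "average_spectrum",
    "normalize_to_total",
    "band_powers",
    "baseline_normalize",
]

_FTOL = 1e-9  # Hz tolerance for band-edge membership

#: canonical normalization range: the analysed bands span 1-150 Hz and the
#: 48-52 Hz notch bins are meaningless after line-noise filtering
DEFAULT_TOTAL_RANGE = (1.0, 150.0)
DEFAULT_EXCLUDE = ((48.0, 52.0),)


@dataclass
class PowerSpectrum:
    """One-sided power spectrum (power per frequency bin).

    ``units`` is one of ``"raw"`` or ``"percent_of_total"``.
    ``n_averaged`` counts the epochs that went into the estimate.
    """

    freqs: np.ndarray
    power: np.ndarray
    units: str = "raw"
    n_averaged: int = 1

    def __post_init__(self) -> None:
        self.freqs = np.asarray(self.freqs, dtype=np.float64)
        self.power = np.asarray(self.power, dtype=np.float64)
        if self.freqs.shape != self.power.shape:
            raise ValueError("freqs and power must have identical shape")
        if self.freqs.size > 1 and not np.all(np.diff(self.freqs) > 0):
            raise ValueError("frequency grid must be strictly increasing")
        if np.any(self.power < 0):
            raise ValueError("spectral power must be non-negative")

    @property
    def df(self) -> float:
        """Frequency bin spacing in Hz."""
        return float(self.freqs[1] - self.freqs[0]) if self.freqs.size > 1 else np.nan


@dataclass(frozen=True)
class Band:
    """Half-open frequency band [low, high); set ``closed_high`` to
    include the upper edge (used for the topmost band)."""

    label: str
    low: float
    high: float
    closed_high: bool = False

    def __post_init__(self) -> None:
        if not self.low < self.high:
            raise ValueError(f"band {self.label!r}: require low < high")

    def mask(self, freqs: np.ndarray) -> np.ndarray:
        hi = freqs <= self.high + _FTOL if self.closed_high else freqs < self.high - _FTOL
        return (freqs >= self.low - _FTOL) & hi


@dataclass(frozen=True)
class BandScheme:
    """Ordered, non-overlapping set of frequency bands."""

    bands: tuple

    def __post_init__(self) -> None:
        labels = [b.label for b in self.bands]
        if len(set(labels)) != len(labels):
            raise ValueError("duplicate band labels")
        ordered = sorted(self.bands, key=lambda b: b.low)
        for a, b in zip(ordered, ordered[1:]):
            if b.low < a.high - _FTOL:
                raise ValueError(f"bands {a.label!r} and {b.label!r} overlap")

    def __iter__(self):
        return iter(self.bands)

    def __getitem__(self, label: str) -> Band:
        for b in self.bands:
            if b.label == label:
                return b
        raise KeyError(label)

    @property
    def labels(self) -> list:
        return [b.label for b in self.bands]


def default_bands() -> BandScheme:
    """Canonical rodent LFP bands: delta 1-4, theta 4-12, beta 12-30,
    low gamma 30-48 and high gamma 52-150 Hz (upper edge inclusive).

    Edges are half-open so the 4-Hz bin belongs to theta, not delta; the
    48-52 Hz notch gap between the gamma bands is never assigned.
    """
    return BandScheme(
        (
            Band("delta", 1.0, 4.0),
            Band("theta", 4.0, 12.0),
            Band("beta", 12.0, 30.0),
            Band("low_gamma", 30.0, 48.0),
            Band("high_gamma", 52.0, 150.0, closed_high=True),
        )
    )


def epoch_spectrum(epoch: np.ndarray, fs: float, taper: str = "hann") -> PowerSpectrum:
    """One-sided power spectrum of a single epoch.

    The epoch mean is removed, the taper is applied with RMS
    normalization (``mean(w**2) == 1``) so broadband power is unbiased,
    and the result is expressed as power per bin: summing over all bins
    recovers the (windowed) time-domain variance.
    """
    epoch = np.asarray(epoch, dtype=np.float64)
    if epoch.ndim != 1 or epoch.size < 2:
        raise ValueError("epoch must be a 1-D array of at least 2 samples")
    n = epoch.size
    w = sps.get_window(taper, n, fftbins=True).astype(np.float64)
    w /= np.sqrt(np.mean(w**2))
    x = (epoch - epoch.mean()) * w
    X = np.fft.rfft(x)
    power = (np.abs(X) ** 2) / n**2
    power[1:] *= 2.0
    if n % 2 == 0:
        power[-1] /= 2.0  # Nyquist bin is not duplicated
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    return PowerSpectrum(freqs, power, units="raw", n_averaged=1)


def average_spectrum(spectra: list) -> PowerSpectrum:
    """Arithmetic per-bin mean of spectra on identical grids and units.

    ``n_averaged`` of the result is the sum of the inputs' counts, so
    averaging 18 epochs from each of 10 mice reports 180.
    """
    if not spectra:
        raise ValueError("need at least one spectrum")
    ref = spectra[0]
    for s in spectra[1:]:
        if s.freqs.shape != ref.freqs.shape or not np.allclose(s.freqs, ref.freqs):
            raise ValueError("spectra are on different frequency grids")
        if s.units != ref.units:
            raise ValueError(f"mixed units: {s.units!r} vs {ref.units!r}")
    power = np.mean([s.power for s in spectra], axis=0)
    return PowerSpectrum(
        ref.freqs.copy(), power, units=ref.units,
        n_averaged=int(sum(s.n_averaged for s in spectra)),
    )


def _included_mask(freqs, f_range, exclude):
    lo, hi = f_range
    mask = (freqs >= lo - _FTOL) & (freqs <= hi + _FTOL)
    for xlo, xhi in exclude:
        mask &= ~((freqs >= xlo - _FTOL) & (freqs <= xhi + _FTOL))
    return mask


def normalize_to_total(
    spectrum: PowerSpectrum,
    f_range: tuple = DEFAULT_TOTAL_RANGE,
    exclude: tuple = DEFAULT_EXCLUDE,
) -> PowerSpectrum:
    """Express each bin as percent of total power over ``f_range``.

    The notch band (48-52 Hz by default) is excluded from the total so
    filtered-out bins do not dilute the normalization.  The returned
    spectrum sums to exactly 100 over the included range.
    """
    if spectrum.units != "raw":
        raise ValueError("normalize_to_total expects a raw spectrum")
    mask = _included_mask(spectrum.freqs, f_range, exclude)
    total = spectrum.power[mask].sum()
    if total <= 0:
        raise ZeroDivisionError("total power over the normalization range is zero")
    return PowerSpectrum(
        spectrum.freqs.copy(), 100.0 * spectrum.power / total,
        units="percent_of_total", n_averaged=spectrum.n_averaged,
    )


def band_powers(spectrum: PowerSpectrum, scheme: BandScheme | None = None) -> dict:
    """Sum bin powers per band (bin centre in [low, high)).

    Returns ``{band label: power}`` in the spectrum's units.
    """
    scheme = scheme or default_bands()
    out = {}
    for band in scheme:
        if band.low < spectrum.freqs[0] - _FTOL or band.high > spectrum.freqs[-1] + _FTOL:
            raise ValueError(
                f"band {band.label!r} [{band.low}, {band.high}] outside the "
                f"spectrum grid [{spectrum.freqs[0]}, {spectrum.freqs[-1]}]"
            )
        out[band.label] = float(spectrum.power[band.mask(spectrum.freqs)].sum())
    return out


def baseline_normalize(table: pd.DataFrame, baseline_session: str) -> pd.DataFrame:
    """Express band powers as percent of each subject's baseline session.

    ``table`` is long-format with columns (group, mouse, session, band,
    value, units).  Every (group, mouse, band) must have a strictly
    positive value in ``baseline_session``; baseline rows become exactly
    100 and units become ``percent_of_baseline``.
    """
    required = {"group", "mouse", "session", "band", "value"}
    if not required.issubset(table.columns):
        raise ValueError(f"table must have columns {sorted(required)}")
    base = table[table["session"] == baseline_session]
    key = ["group", "mouse", "band"]
    base_map = base.set_index(key)["value"]
    dup = base_map.index.duplicated()
    if dup.any():
        raise ValueError("multiple baseline rows for the same (group, mouse, band)")
    out = table.copy()
    idx = pd.MultiIndex.from_frame(out[key])
    missing = ~idx.isin(base_map.index)
    if missing.any():
        bad = out.loc[missing, key].drop_duplicates().itertuples(index=False)
        raise ValueError(
            "missing baseline for: " + ", ".join(f"({g}, {m}, {b})" for g, m, b in bad)
        )
    denom = base_map.reindex(idx).to_numpy()
    nonpos = denom <= 0
    if nonpos.any():
        bad = out.loc[nonpos, key].drop_duplicates().itertuples(index=False)
        raise ValueError(
            "zero baseline power for: " + ", ".join(f"({g}, {m}, {b})" for g, m, b in bad)
        )
    out["value"] = 100.0 * out["value"].to_numpy() / denom
    # baseline rows are exactly 100 by construction; enforce bitwise
    out.loc[out["session"] == baseline_session, "value"] = 100.0
    out["units"] = "percent_of_baseline"
    return out
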