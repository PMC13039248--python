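"""Multitaper (Slepian-taper) time-frequency spectrograms.

A window of length T seconds and half-bandwidth W Hz admits K = 2TW - 1
discrete prolate spheroidal sequences (DPSS, "Slepian tapers") that are
mutually orthogonal and optimally energy-concentrated in [-W, W].
Because the tapers are orthogonal and epochs are interchangeable trials,
the m = N_E x K tapered power estimates at each time-frequency bin are
statistically independent; their mean is the spectrogram and the full
stack is retained for resampling (jackknife) inference downstream.

Defaults follow common LFP practice: T = 2 s, W = 1 Hz (hence K = 3),
windows stepped by dt = 0.5 s, native Rayleigh grid dF = 1/T = 0.5 Hz.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import windows as spw

from .core import EpochSet

__all__ = ["MultitaperParams", "Spectrogram", "dpss_family", "mt_spectrogram"]


@dataclass(frozen=True)
class MultitaperParams:
    """Multitaper spectrogram parameters.

    ``T``: window length (s). ``W``: half-bandwidth (Hz). ``K``: taper
    count, defaulting to the full useful family 2TW - 1. ``dt``: window
    step (s).  The frequency grid is the window's native Rayleigh grid,
    spacing ``dF = 1/T``, truncated to [``fmin``, ``fmax``] for storage.
    """

    T: float = 2.0
    W: float = 1.0
    K: int | None = None
    dt: float = 0.5
    fmin: float = 0.5
    fmax: float = 150.0

    def __post_init__(self) -> None:
        if self.T <= 0 or self.W <= 0:
            raise ValueError("T and W must be positive")
        if self.T * self.W < 1:
            raise ValueError(
                f"time-bandwidth product T*W = {self.T * self.W} < 1: no valid taper"
            )
        if self.dt <= 0 or self.dt > self.T:
            raise ValueError("require 0 < dt <= T")
        k = self.n_tapers
        if k < 1:
            raise ValueError("taper count must be at least 1")

    @property
    def n_tapers(self) -> int:
        """K = 2TW - 1 unless overridden."""
        return int(self.K) if self.K is not None else int(round(2 * self.T * self.W - 1))

    @property
    def dF(self) -> float:
        """Native frequency grid spacing (Rayleigh limit), Hz."""
        return 1.0 / self.T


@dataclass
class Spectrogram:
    """Time-frequency power with the per-(epoch, taper) estimate stack.

    ``stack`` has shape (m, n_times, n_freqs) with m = N_E x K;
    ``mean_power`` is its mean over the first axis.
    """

    times: np.ndarray
    freqs: np.ndarray
    stack: np.ndarray
    params: MultitaperParams
    n_epochs: int
    mean_power: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        if self.stack.shape[0] != self.n_epochs * self.params.n_tapers:
            raise ValueError("stack depth must equal N_E * K")
        self.mean_power = self.stack.mean(axis=0)

    @property
    def m(self) -> int:
        """Number of independent (epoch, taper) estimates per bin."""
        return self.stack.shape[0]


def dpss_family(T: float, W: float, fs: float, K: int | None = None) -> np.ndarray:
    """The first K = 2TW - 1 Slepian tapers for a T-second window.

    Returns an array of shape (K, round(T*fs)) of unit-norm, mutually
    orthogonal sequences ordered by energy concentration in [-W, W].
    """
    if T * W < 1:
        raise ValueError(f"time-bandwidth product T*W = {T * W} < 1: no valid taper")
    n = int(round(T * fs))
    k = int(K) if K is not None else int(round(2 * T * W - 1))
    tapers = spw.dpss(n, NW=T * W, Kmax=k, norm=2)
    return np.atleast_2d(tapers)


def mt_spectrogram(epochs: EpochSet, params: MultitaperParams = MultitaperParams()) -> Spectrogram:
    """Multitaper spectrogram of an epoch ensemble.

    For every window start (stepping by ``dt``) and every epoch, K
    tapered one-sided power estimates are computed on the native dF
    grid; the per-bin mean over all N_E x K estimates is ``mean_power``
    and the full stack is retained.  Each window is mean-removed before
    tapering.  Times are window centres.
    """
    if epochs.n_epochs == 0:
        raise ValueError("epoch set is empty")
    fs = epochs.fs
    win = int(round(params.T * fs))
    n_samp = epochs.epochs.shape[1]
    if n_samp < win:
        raise ValueError(
            f"epochs of {n_samp / fs:.3f} s are shorter than the window T = {params.T} s"
        )
    step = int(round(params.dt * fs))
    starts = np.arange(0, n_samp - win + 1, step)
    times = (starts + win / 2.0) / fs
    tapers = dpss_family(params.T, params.W, fs, K=params.n_tapers)
    k = tapers.shape[0]

    freqs_full = np.fft.rfftfreq(win, d=1.0 / fs)
    fmask = (freqs_full >= params.fmin - 1e-9) & (freqs_full <= params.fmax + 1e-9)
    freqs = freqs_full[fmask]
    one_sided = np.full(freqs_full.size, 2.0)
    one_sided[0] = 1.0
    if win % 2 == 0:
        one_sided[-1] = 1.0
    one_sided = one_sided[fmask]

    n_e = epochs.n_epochs
    stack = np.empty((n_e * k, times.size, freqs.size))
    idx = starts[:, None] + np.arange(win)[None, :]
    for e in range(n_e):
        segs = epochs.epochs[e][idx]  # (n_times, win)
        segs = segs - segs.mean(axis=1, keepdims=True)
        for j in range(k):
            X = np.fft.rfft(segs * tapers[j], axis=1)
            # tapers are unit-norm, so |X|^2 is a PSD-scale power estimate
            stack[e * k + j] = (np.abs(X[:, fmask]) ** 2) * one_sided / fs
    return Spectrogram(times, freqs, stack, params, n_epochs=n_e)
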