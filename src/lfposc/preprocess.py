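"""Notch filtering, epoch segmentation and automated artifact screening.

The line-noise filter is a band-stop IIR (notch) design with cutoff
frequencies at 48 and 52 Hz by default, applied forward-backward so the
net phase distortion is zero.  Epoching cuts non-overlapping fixed-length
segments; artifact screening replaces the manual "artifact-free segment"
selection of typical LFP workflows with a reproducible rule based on the
scaled median absolute deviation of the whole recording.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from .core import EpochSet, Signal

__all__ = [
    "FilterSpec",
    "notch_filter",
    "segment_epochs",
    "screen_artifacts",
    "NoAnalyzableDataError",
]

logger = logging.getLogger(__name__)


class NoAnalyzableDataError(RuntimeError):
    """Raised when artifact screening rejects every epoch of a session."""


@dataclass(frozen=True)
class FilterSpec:
    """Band-stop IIR filter specification.

    ``stop_lo``/``stop_hi`` are the cutoff frequencies in Hz (defaults
    48 and 52, bracketing 50-Hz mains interference); ``order`` is the
    analogue prototype order of the Butterworth band-stop design.
    """

    stop_lo: float = 48.0
    stop_hi: float = 52.0
    order: int = 4
    design: str = "butter"

    def __post_init__(self) -> None:
        if not 0 < self.stop_lo < self.stop_hi:
            raise ValueError("require 0 < stop_lo < stop_hi")
        if self.design != "butter":
            raise ValueError(f"unsupported band-stop design {self.design!r}")


def notch_filter(signal: Signal, spec: FilterSpec = FilterSpec()) -> Signal:
    """Remove line interference with a zero-phase band-stop IIR filter.

    The filter is applied forward and backward (``sosfiltfilt``), which
    squares the magnitude response and cancels phase distortion, so
    oscillation timing is preserved for later time-frequency analysis.

    Returns a new :class:`Signal` of identical length and sampling rate.
    """
    nyq = signal.fs / 2.0
    if spec.stop_hi >= nyq:
        raise ValueError(
            f"stop band edge {spec.stop_hi} Hz reaches Nyquist ({nyq} Hz)"
        )
    if signal.n_samples == 0:
        return Signal(signal.samples.copy(), signal.fs, signal.t0, dict(signal.meta))
    sos = sps.butter(
        spec.order, [spec.stop_lo, spec.stop_hi], btype="bandstop", fs=signal.fs, output="sos"
    )
    # a narrow notch rings for ~1/bandwidth seconds; generous reflect
    # padding keeps that edge transient out of the returned samples
    padlen = int(min(signal.n_samples - 1, round(signal.fs)))
    filtered = sps.sosfiltfilt(sos, signal.samples, padlen=padlen)
    return Signal(filtered, signal.fs, signal.t0, dict(signal.meta))


def segment_epochs(
    signal: Signal,
    epoch_len: float,
    max_epochs: int | None = None,
    policy: str = "contiguous-from-start",
) -> EpochSet:
    """Cut non-overlapping, equal-length epochs from a signal.

    The epoch count is ``floor(duration / epoch_len)``, capped at
    ``max_epochs``; any trailing remainder is discarded.  With policy
    ``"contiguous-from-start"`` the retained epochs tile the start of the
    recording; with ``"evenly-spaced"`` the capped epochs are drawn at
    evenly spaced positions among the available ones.
    """
    if epoch_len <= 0:
        raise ValueError("epoch_len must be positive")
    if policy not in ("contiguous-from-start", "evenly-spaced"):
        raise ValueError(f"unknown epoching policy {policy!r}")
    n_samp = int(round(epoch_len * signal.fs))
    n_avail = signal.n_samples // n_samp if n_samp else 0
    if n_avail == 0:
        logger.warning(
            "signal of %.3f s too short for any %.3f-s epoch (%s)",
            signal.duration,
            epoch_len,
            signal.meta or "unnamed",
        )
        return EpochSet(
            np.empty((0, n_samp)), epoch_len, signal.fs,
            rejected_mask=np.zeros(0, dtype=bool), reasons=[],
        )
    n_take = n_avail if max_epochs is None else min(n_avail, int(max_epochs))
    if policy == "contiguous-from-start" or n_take == n_avail:
        starts = np.arange(n_take) * n_samp
    else:  # evenly-spaced among available slots
        slots = np.linspace(0, n_avail - 1, n_take).round().astype(int)
        starts = slots * n_samp
    epochs = np.stack([signal.samples[s : s + n_samp] for s in starts])
    return EpochSet(epochs, epoch_len, signal.fs)


def screen_artifacts(
    epochs: EpochSet,
    k_mad: float = 8.0,
    flat_tol: float = 1e-9,
    session: str = "",
) -> EpochSet:
    """Reject epochs containing amplitude artifacts or flat-lines.

    An epoch is rejected with reason ``"amplitude"`` if any sample
    deviates from the epoch median by more than ``k_mad`` times the
    scaled median absolute deviation (MAD x 1.4826) of the whole
    recording, and with reason ``"flat"`` if its peak-to-peak range is
    below ``flat_tol``.  Retained epochs are passed through unchanged.

    Raises
    ------
    NoAnalyzableDataError
        If every epoch is rejected (names the offending session).
    """
    if not k_mad > 0:
        raise ValueError("k_mad must be positive")
    n = epochs.n_epochs
    if n == 0:
        return epochs
    allsamp = epochs.epochs.ravel()
    mad = 1.4826 * np.median(np.abs(allsamp - np.median(allsamp)))
    keep = np.ones(n, dtype=bool)
    reasons: list = [None] * n
    for i, ep in enumerate(epochs.epochs):
        if np.ptp(ep) < flat_tol:
            keep[i] = False
            reasons[i] = "flat"
        elif mad > 0 and np.max(np.abs(ep - np.median(ep))) > k_mad * mad:
            keep[i] = False
            reasons[i] = "amplitude"
    if not keep.any():
        raise NoAnalyzableDataError(
            f"all {n} epochs rejected by artifact screening"
            + (f" in session {session!r}" if session else "")
        )
    n_rej = int((~keep).sum())
    if n_rej:
        logger.info("artifact screening rejected %d/%d epochs", n_rej, n)
    return EpochSet(
        epochs.epochs[keep], epochs.epoch_len, epochs.fs,
        rejected_mask=~keep, reasons=reasons,
    )
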