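"""Core containers: voltage signals and epoch collections.

A :class:`Signal` is one subject-session voltage trace with its sampling
rate and identifying metadata.  An :class:`EpochSet` is a stack of
equal-length segments cut from one or more signals, together with the
bookkeeping of which candidate segments were rejected during artifact
screening and why.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["Signal", "EpochSet"]


@dataclass
class Signal:
    """A continuous voltage time series.

    Parameters
    ----------
    samples : array_like
        Voltage samples (arbitrary units).
    fs : float
        Sampling rate in Hz.
    t0 : float
        Start time in seconds (default 0).
    meta : dict
        Identifying metadata, typically ``group``, ``mouse``, ``session``.
    """

    samples: np.ndarray
    fs: float
    t0: float = 0.0
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=np.float64)
        if self.samples.ndim != 1:
            raise ValueError("Signal samples must be one-dimensional")
        if not self.fs > 0:
            raise ValueError(f"sampling rate must be positive, got {self.fs}")
        if self.samples.size and not np.all(np.isfinite(self.samples)):
            raise ValueError("Signal contains non-finite samples")

    @property
    def n_samples(self) -> int:
        return self.samples.size

    @property
    def duration(self) -> float:
        """Signal duration in seconds."""
        return self.n_samples / self.fs

    def crop(self, t_start: float, t_stop: float) -> "Signal":
        """Return the sub-signal covering ``[t_start, t_stop)`` seconds."""
        i0 = int(round(t_start * self.fs))
        i1 = int(round(t_stop * self.fs))
        if not 0 <= i0 <= i1 <= self.n_samples:
            raise ValueError(
                f"crop window [{t_start}, {t_stop}) s outside signal of "
                f"{self.duration:.3f} s"
            )
        return Signal(self.samples[i0:i1], self.fs, t0=self.t0 + t_start, meta=dict(self.meta))


@dataclass
class EpochSet:
    """Equal-length segments of a recording.

    ``epochs`` holds the retained segments only.  ``rejected_mask`` and
    ``reasons`` are aligned with the original candidate segments: entry
    ``i`` describes candidate ``i``, with ``reasons[i]`` a short code
    (``"amplitude"``, ``"flat"``) or ``None`` when retained.
    """

    epochs: np.ndarray  # (n_epochs, n_samples_per_epoch)
    epoch_len: float  # seconds
    fs: float
    rejected_mask: np.ndarray = None  # bool per candidate
    reasons: list = None

    def __post_init__(self) -> None:
        self.epochs = np.atleast_2d(np.asarray(self.epochs, dtype=np.float64))
        if self.epochs.size == 0:
            self.epochs = self.epochs.reshape(0, int(round(self.epoch_len * self.fs)))
        n_samp = int(round(self.epoch_len * self.fs))
        if abs(self.epoch_len * self.fs - n_samp) > 1e-6:
            raise ValueError("epoch_len times fs must be an integer sample count")
        if self.epochs.shape[0] and self.epochs.shape[1] != n_samp:
            raise ValueError(
                f"epochs have {self.epochs.shape[1]} samples, expected {n_samp}"
            )
        if self.rejected_mask is None:
            self.rejected_mask = np.zeros(self.epochs.shape[0], dtype=bool)
        self.rejected_mask = np.asarray(self.rejected_mask, dtype=bool)
        if self.reasons is None:
            self.reasons = [None] * self.rejected_mask.size

    @property
    def n_epochs(self) -> int:
        """Number of retained epochs (N_E)."""
        return self.epochs.shape[0]

    @property
    def n_candidates(self) -> int:
        return self.rejected_mask.size
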