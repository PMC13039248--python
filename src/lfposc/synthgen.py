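"""Synthetic LFP cohort generation with planted, recoverable structure.

Real LFP-like traces are emulated as the sum of

* a 1/f^alpha aperiodic background, synthesized by shaping the amplitude
  spectrum of white noise in the frequency domain (the planted exponent
  is therefore exact in expectation, which is what recovery tests need);
* band-limited oscillatory components (delta, theta, beta, gamma ...)
  realized as white noise shaped by a zero-phase Gaussian band-pass
  centred on each component's frequency, so the theta peak is broad as
  in real recordings rather than a spectral line;
* 50-Hz line interference as a pure sinusoid;
* optionally, a shared slow log-normal amplitude envelope across flagged
  components (for cross-frequency comodulation tests) and injectable
  high-amplitude transients (for artifact-screening tests).

A cohort is a set of such signals indexed by (group, mouse, session);
group x session x band amplitude multipliers plant effects whose ground
truth (expected band-power percentage of the first session) is returned
alongside the data.  Per-mouse seeds are derived from a stable hash so
adding a mouse never changes any other mouse's samples.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .core import Signal

__all__ = [
    "OscComponent",
    "AperiodicSpec",
    "LineNoiseSpec",
    "SharedEnvelopeSpec",
    "EffectSchedule",
    "CohortConfig",
    "CohortDataset",
    "synth_signal",
    "synth_cohort",
    "inject_transient",
    "paper_emulation",
]


@dataclass(frozen=True)
class OscComponent:
    """A band-limited oscillatory component.

    ``bandwidth`` is the half-power (FWHM) width of the Gaussian
    band-pass, ``amplitude`` the RMS contribution in signal units.
    ``label`` names the band the component represents (effect
    multipliers are keyed by it); ``shared_envelope`` opts the component
    into the cohort's common slow amplitude envelope.
    """

    center_freq: float
    bandwidth: float
    amplitude: float
    label: str = ""
    shared_envelope: bool = False

    def __post_init__(self) -> None:
        if not self.center_freq > 0:
            raise ValueError("center_freq must be positive")
        if not self.bandwidth > 0:
            raise ValueError("bandwidth must be positive")
        if self.amplitude < 0:
            raise ValueError("amplitude must be non-negative")


@dataclass(frozen=True)
class AperiodicSpec:
    """1/f^alpha background: one-sided PSD(f) = scale_C / f**exponent_alpha
    in (signal units)^2 per Hz, so scale_C is the PSD at 1 Hz.

    Below ``plateau_hz`` the target spectrum is held at its
    ``plateau_hz`` value so steep exponents do not put unbounded
    variance into sub-analysis-range drift; the 1-150 Hz analysis range
    is unaffected at the 0.5-Hz default.
    """

    exponent_alpha: float = 0.5
    scale_C: float = 1.0
    plateau_hz: float = 0.5

    def __post_init__(self) -> None:
        if self.exponent_alpha < 0:
            raise ValueError("exponent_alpha must be non-negative")
        if self.scale_C < 0:
            raise ValueError("scale_C must be non-negative")


@dataclass(frozen=True)
class LineNoiseSpec:
    """Mains interference: a sinusoid at ``freq`` (50 Hz by default)."""

    freq: float = 50.0
    amplitude: float = 0.0

    def __post_init__(self) -> None:
        if not self.freq > 0:
            raise ValueError("line frequency must be positive")


@dataclass(frozen=True)
class SharedEnvelopeSpec:
    """Common slow log-normal amplitude envelope for flagged components.

    ``cutoff_hz`` limits the envelope's bandwidth; ``sigma`` is the
    standard deviation of its log (modulation depth).
    """

    cutoff_hz: float = 0.2
    sigma: float = 0.5


@dataclass(frozen=True)
class EffectSchedule:
    """(group, session, band label) -> positive amplitude multiplier.

    Missing entries default to 1 (no planted effect).
    """

    multipliers: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for key, mult in self.multipliers.items():
            if not mult > 0:
                raise ValueError(f"multiplier for {key} must be positive, got {mult}")

    def get(self, group: str, session: str, label: str) -> float:
        return float(self.multipliers.get((group, session, label), 1.0))


@dataclass
class CohortConfig:
    """Full description of a synthetic cohort."""

    n_mice_per_group: int = 10
    group_labels: tuple = ("vehicle", "treated")
    session_labels: tuple = ("PRE", "D-1", "D-3", "D-12")
    fs: float = 5000.0
    duration: float = 300.0
    aperiodic: AperiodicSpec = field(default_factory=AperiodicSpec)
    components: tuple = ()
    line_noise: LineNoiseSpec = field(default_factory=LineNoiseSpec)
    effects: EffectSchedule = field(default_factory=EffectSchedule)
    envelope: SharedEnvelopeSpec | None = None
    base_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_mice_per_group < 1:
            raise ValueError("n_mice_per_group must be at least 1")
        if not self.group_labels:
            raise ValueError("group_labels must be non-empty")
        if not self.session_labels:
            raise ValueError("session_labels must be non-empty")
        n = self.duration * self.fs
        if abs(n - round(n)) > 1e-6:
            raise ValueError("duration x fs must be an integer sample count")
        fmax = max((c.center_freq + c.bandwidth / 2 for c in self.components), default=0.0)
        if self.components and self.fs <= 2 * fmax:
            raise ValueError(
                f"fs = {self.fs} Hz cannot represent components up to {fmax} Hz"
            )


@dataclass
class CohortDataset:
    """Signals keyed by (group, mouse index, session) plus planted truth.

    ``truth`` is a long-format table with one row per (group, band,
    session): the expected band-power percentage of the first session
    implied by the planted amplitude multipliers (power scales as
    amplitude squared).
    """

    signals: dict
    truth: pd.DataFrame
    config: CohortConfig

    @property
    def fs(self) -> float:
        return self.config.fs

    def __len__(self) -> int:
        return len(self.signals)


def _draw_spectrum(rng: np.random.Generator, gain: np.ndarray, idx=None, n_bins=None) -> np.ndarray:
    """Random rFFT coefficients of shaped Gaussian noise.

    Coefficients are drawn directly in the frequency domain with the
    same distribution as the rFFT of unit white noise of length n
    (E|X_k|^2 = n) scaled by ``gain``; restricting to ``idx`` draws
    only the bins where the gain is non-negligible.
    """
    if idx is None:
        m = gain.size
        z = rng.standard_normal(2 * m).reshape(2, m)
        X = (z[0] + 1j * z[1]) / np.sqrt(2.0)
        X *= gain
        X[0] = 0.0  # mean-free
        return X
    m = idx.size
    z = rng.standard_normal(2 * m).reshape(2, m)
    X = np.zeros(n_bins, dtype=complex)
    X[idx] = (z[0] + 1j * z[1]) / np.sqrt(2.0) * gain
    X[0] = 0.0
    return X


def _spectrum_power(X: np.ndarray, n: int) -> float:
    """Time-domain mean square of ``irfft(X, n)`` via Parseval."""
    w = np.full(X.size, 2.0)
    w[0] = 1.0
    if n % 2 == 0:
        w[-1] = 1.0
    return float((w * np.abs(X) ** 2).sum()) / n**2


def _component_gain(comp: OscComponent, freqs: np.ndarray) -> np.ndarray:
    """Zero-phase Gaussian band-pass amplitude gain whose power response
    has half-power (FWHM) width ``comp.bandwidth`` centred on
    ``comp.center_freq``."""
    sigma_f = comp.bandwidth / (2.0 * np.sqrt(2.0 * np.log(2.0)))
    return np.exp(-((freqs - comp.center_freq) ** 2) / (4.0 * sigma_f**2))


def synth_signal(
    aperiodic: AperiodicSpec,
    components,
    line_noise: LineNoiseSpec,
    duration: float,
    fs: float,
    seed: int,
    envelope: SharedEnvelopeSpec | None = None,
) -> Signal:
    """Synthesize one LFP-like trace.

    The expected power spectrum is the sum of the aperiodic power law,
    the Gaussian-band component spectra and a line at the mains
    frequency.  Identical seeds produce identical samples.
    """
    if duration <= 0:
        raise ValueError("duration must be positive")
    if fs <= 0:
        raise ValueError("fs must be positive")
    fmax = max((c.center_freq + c.bandwidth / 2 for c in components), default=0.0)
    fmax = max(fmax, line_noise.freq if line_noise.amplitude > 0 else 0.0)
    if fmax and fs <= 2 * fmax:
        raise ValueError(f"fs = {fs} Hz cannot represent content up to {fmax} Hz (aliasing)")
    n = int(round(duration * fs))
    rng = np.random.default_rng(int(seed))
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    n_bins = freqs.size
    total_X = np.zeros(n_bins, dtype=complex)  # accumulated rFFT, single inverse below
    x_extra = np.zeros(0)  # time-domain parts (envelope-modulated components)

    # aperiodic 1/f^alpha background, plateaued below plateau_hz;
    # gain calibrated so the one-sided PSD is exactly scale_C * f**-alpha
    if aperiodic.scale_C > 0:
        gain = np.zeros(n_bins)
        nz = freqs > 0
        f_eff = np.maximum(freqs[nz], aperiodic.plateau_hz)
        gain[nz] = np.sqrt(aperiodic.scale_C * fs * n / 2.0) * f_eff ** (
            -aperiodic.exponent_alpha / 2.0
        )
        total_X += _draw_spectrum(rng, gain)

    # common slow log-normal envelope for flagged components
    env = None
    if envelope is not None and any(c.shared_envelope and c.amplitude > 0 for c in components):
        idx = np.nonzero((freqs > 0) & (freqs <= envelope.cutoff_hz))[0]
        if idx.size:
            z = np.fft.irfft(
                _draw_spectrum(rng, np.full(idx.size, np.sqrt(n)), idx=idx, n_bins=n_bins), n=n
            )
            sd = z.std()
            if sd > 0:
                z *= envelope.sigma / sd
            env = np.exp(z - z.mean())

    for comp in components:
        gain_full = _component_gain(comp, freqs)
        idx = np.nonzero(gain_full > 1e-8)[0]
        if idx.size == 0:
            continue
        # draw unconditionally so the stream position per component is stable
        X = _draw_spectrum(rng, gain_full[idx] * np.sqrt(n), idx=idx, n_bins=n_bins)
        if comp.amplitude == 0:
            continue
        if env is not None and comp.shared_envelope:
            y = np.fft.irfft(X, n=n) * env
            rms = np.sqrt(np.mean(y**2))
            if rms > 0:
                if x_extra.size == 0:
                    x_extra = np.zeros(n)
                x_extra += y * (comp.amplitude / rms)
        else:
            ms = _spectrum_power(X, n)
            if ms > 0:
                total_X += X * (comp.amplitude / np.sqrt(ms))

    x = np.fft.irfft(total_X, n=n)
    if x_extra.size:
        x = x + x_extra

    if line_noise.amplitude > 0:
        phase = rng.uniform(0.0, 2.0 * np.pi)
        t = np.arange(n) / fs
        x += line_noise.amplitude * np.sqrt(2.0) * np.sin(2.0 * np.pi * line_noise.freq * t + phase)

    return Signal(x, fs, meta={"seed": int(seed)})


def mouse_seed(base_seed: int, group: str, mouse: int, session: str) -> int:
    """Deterministic per-signal seed from a stable hash of its key.

    XOR with a CRC-32 of the key keeps seeds independent of iteration
    order, so adding a mouse or session never changes other signals.
    """
    h = zlib.crc32(f"{group}|{mouse:04d}|{session}".encode())
    return (int(base_seed) ^ h) & 0x7FFFFFFF


def synth_cohort(config: CohortConfig) -> CohortDataset:
    """Generate one Signal per (group, mouse, session) plus ground truth.

    Effect multipliers scale component amplitudes before synthesis.  The
    truth table gives, per (group, band, session), the expected band
    power as a percentage of the first session (multiplier ratio
    squared, times 100).
    """
    signals = {}
    for group in config.group_labels:
        for mouse in range(config.n_mice_per_group):
            for session in config.session_labels:
                comps = tuple(
                    replace(c, amplitude=c.amplitude * config.effects.get(group, session, c.label))
                    for c in config.components
                )
                seed = mouse_seed(config.base_seed, group, mouse, session)
                sig = synth_signal(
                    config.aperiodic, comps, config.line_noise,
                    config.duration, config.fs, seed, envelope=config.envelope,
                )
                sig.meta.update({"group": group, "mouse": mouse, "session": session})
                signals[(group, mouse, session)] = sig

    rows = []
    first = config.session_labels[0]
    for group in config.group_labels:
        for comp in config.components:
            if not comp.label:
                continue
            m0 = config.effects.get(group, first, comp.label)
            for session in config.session_labels:
                m = config.effects.get(group, session, comp.label)
                rows.append(
                    {
                        "group": group,
                        "band": comp.label,
                        "session": session,
                        "amplitude_multiplier": m,
                        "expected_pct_of_first": 100.0 * (m / m0) ** 2,
                    }
                )
    truth = pd.DataFrame(rows, columns=["group", "band", "session", "amplitude_multiplier", "expected_pct_of_first"])
    return CohortDataset(signals=signals, truth=truth, config=config)


def inject_transient(
    signal: Signal, t_center: float, amplitude: float, width: float = 0.02
) -> Signal:
    """Add a Gaussian-shaped high-amplitude transient (test artifact)."""
    if not 0 <= t_center <= signal.duration:
        raise ValueError("transient centre outside the signal")
    t = np.arange(signal.n_samples) / signal.fs
    pulse = amplitude * np.exp(-((t - t_center) ** 2) / (2.0 * width**2))
    return Signal(signal.samples + pulse, signal.fs, signal.t0, dict(signal.meta))


def paper_emulation(
    n_mice_per_group: int = 10,
    duration: float = 300.0,
    fs: float = 5000.0,
    base_seed: int = 0,
) -> CohortConfig:
    """Default two-group, four-session cortical cohort preset.

    Vehicle and treated groups across sessions PRE, D-1, D-3, D-12; a
    1/f^0.5 background; a dominant theta component centred at 8 Hz plus
    delta, beta and gamma components; 50-Hz line contamination.  Planted
    theta dynamics: both groups drop on D-1; the vehicle group drifts
    back toward baseline while the treated group overshoots above
    baseline on D-3 and D-12 (gamma joins by D-12).  Multiplier values
    are configuration, chosen to give the qualitative pattern a clear
    sign at this cohort size, not quantitative claims about any dataset.
    """
    components = (
        OscComponent(1.5, 1.5, 0.6, label="delta"),
        OscComponent(8.0, 2.0, 1.0, label="theta"),
        OscComponent(20.0, 8.0, 0.5, label="beta"),
        OscComponent(40.0, 10.0, 0.45, label="low_gamma"),
        OscComponent(80.0, 30.0, 0.8, label="high_gamma"),
    )
    effects = EffectSchedule(
        {
            ("vehicle", "D-1", "theta"): 0.80,
            ("vehicle", "D-3", "theta"): 0.85,
            ("treated", "D-1", "theta"): 0.70,
            ("treated", "D-3", "theta"): 1.30,
            ("treated", "D-12", "theta"): 1.50,
            ("treated", "D-3", "delta"): 1.20,
            ("treated", "D-12", "low_gamma"): 1.30,
            ("treated", "D-12", "high_gamma"): 1.30,
        }
    )
    return CohortConfig(
        n_mice_per_group=n_mice_per_group,
        group_labels=("vehicle", "treated"),
        session_labels=("PRE", "D-1", "D-3", "D-12"),
        fs=fs,
        duration=duration,
        aperiodic=AperiodicSpec(exponent_alpha=0.5, scale_C=0.05),
        components=components,
        line_noise=LineNoiseSpec(50.0, 0.5),
        effects=effects,
        base_seed=base_seed,
    )
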