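"""End-to-end cohort analysis orchestration.

Given a cohort of (group, mouse, session) signals, the pipeline runs the
full spectral workflow deterministically:

1. zero-phase notch filtering (48-52 Hz band-stop);
2. FFT arm — 10-s epochs over a 3-min window, artifact screening,
   per-epoch spectra, per-mouse and group averages, percent-of-total
   normalization, band powers and percent-of-baseline tables;
3. aperiodic log-log fits over 1-48 and 52-150 Hz at group and mouse
   level;
4. mTFT arm — per group x session multitaper spectrograms built from
   one 300-s segment per mouse (N_E = number of mice used, K = 3);
5. ordered-day jackknife inference maps with theta-band probability
   densities;
6. comodulograms with band x band region summaries.

Identical inputs and configuration produce byte-identical CSV/JSON
outputs; a manifest records the configuration hash and library versions.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .aperiodic import fit_loglog
from .comodulation import classify_strength, comodulogram, region_summary
from .core import Signal
from .inference import band_probability_density, jackknife_compare
from .multitaper import MultitaperParams, mt_spectrogram
from .preprocess import FilterSpec, NoAnalyzableDataError, notch_filter, screen_artifacts, segment_epochs
from .core import EpochSet
from .spectra import (
    BandScheme,
    average_spectrum,
    band_powers,
    baseline_normalize,
    default_bands,
    epoch_spectrum,
    normalize_to_total,
)
from .synthgen import CohortDataset

__all__ = ["AnalysisConfig", "AnalysisResult", "run_cohort_analysis"]

logger = logging.getLogger(__name__)

#: default band x band rectangles summarized on each comodulogram
DEFAULT_COMOD_REGIONS = (
    ((4.0, 8.0), (12.0, 30.0)),   # low theta x beta
    ((1.0, 4.0), (12.0, 30.0)),   # delta x beta
    ((6.0, 8.0), (18.0, 30.0)),   # low theta x high beta
    ((4.0, 12.0), (30.0, 48.0)),  # theta x low gamma
)


@dataclass
class AnalysisConfig:
    """All tunable parameters of a cohort analysis run."""

    bands: BandScheme = field(default_factory=default_bands)
    notch: FilterSpec = field(default_factory=FilterSpec)
    mt_params: MultitaperParams = field(default_factory=MultitaperParams)
    fft_epoch_len: float = 10.0
    fft_window_s: float = 180.0
    fft_max_epochs: int = 18
    mtft_epoch_len: float = 300.0
    mtft_n_mice: int = 6
    baseline_session: str | None = None  # default: first session label seen
    alpha: float = 0.05
    focus_band: tuple = (4.0, 12.0)  # theta, for probability densities
    comparisons: tuple | None = None  # ((first, second), ...); default: ordered-day plan
    comod_regions: tuple = DEFAULT_COMOD_REGIONS
    aperiodic_ranges: tuple = ((1.0, 48.0), (52.0, 150.0))
    k_mad: float = 8.0
    flat_tol: float = 1e-9
    taper: str = "hann"

    def comparison_plan(self, sessions) -> tuple:
        """Default ordered comparison plan: the first post-baseline
        session against baseline and against every later session
        (e.g. D-1 vs PRE, D-1 vs D-3, D-1 vs D-12)."""
        if self.comparisons is not None:
            return tuple(self.comparisons)
        sessions = list(sessions)
        if len(sessions) < 2:
            return ()
        s1 = sessions[1]
        return tuple([(s1, sessions[0])] + [(s1, s) for s in sessions[2:]])


@dataclass
class AnalysisResult:
    """Bundle of all per-cohort outputs."""

    band_table_raw: pd.DataFrame
    band_table_pct_total: pd.DataFrame
    band_table_pct_baseline: pd.DataFrame
    group_spectra: dict        # (group, session) -> percent_of_total PowerSpectrum
    aperiodic_fits: pd.DataFrame
    spectrograms: dict         # (group, session) -> Spectrogram
    inference_maps: dict       # (group, first, second) -> InferenceMap
    densities: pd.DataFrame    # one row per (group, first, second) focus-band density
    comodulograms: dict        # (group, session) -> Comodulogram
    region_summaries: pd.DataFrame
    skipped: list
    manifest: dict

    def write(self, out_dir, include_stacks: bool = False) -> None:
        """Write tables, spectra, maps and the manifest under ``out_dir``."""
        from . import io as lio

        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.band_table_raw.to_csv(out / "band_powers_raw.csv", index=False)
        self.band_table_pct_total.to_csv(out / "band_powers_pct_total.csv", index=False)
        self.band_table_pct_baseline.to_csv(out / "band_powers_pct_baseline.csv", index=False)
        self.aperiodic_fits.to_csv(out / "aperiodic_fits.csv", index=False)
        self.densities.to_csv(out / "inference_densities.csv", index=False)
        self.region_summaries.to_csv(out / "comodulation_regions.csv", index=False)
        spec_dir = out / "spectra"
        spec_dir.mkdir(exist_ok=True)
        for (group, session), ps in sorted(self.group_spectra.items()):
            pd.DataFrame({"freq_hz": ps.freqs, "power": ps.power}).to_csv(
                spec_dir / f"{_safe(group)}_{_safe(session)}.csv", index=False
            )
        sg_dir = out / "spectrograms"
        sg_dir.mkdir(exist_ok=True)
        for (group, session), sg in sorted(self.spectrograms.items()):
            lio.write_spectrogram(
                sg, sg_dir / f"{_safe(group)}_{_safe(session)}.h5", include_stack=include_stacks
            )
        im_dir = out / "inference"
        im_dir.mkdir(exist_ok=True)
        for (group, first, second), imap in sorted(self.inference_maps.items()):
            lio.write_inference_map(
                imap, im_dir / f"{_safe(group)}_{_safe(first)}_vs_{_safe(second)}.h5"
            )
        (out / "inference_densities.json").write_text(
            self.densities.to_json(orient="records", indent=2)
        )
        (out / "manifest.json").write_text(json.dumps(self.manifest, indent=2, sort_keys=True))


def _safe(label: str) -> str:
    return str(label).replace("/", "-").replace(" ", "_")


def _config_hash(config: AnalysisConfig) -> str:
    def default(o):
        if dataclasses.is_dataclass(o) and not isinstance(o, type):
            return dataclasses.asdict(o)
        if isinstance(o, (np.floating, np.integer)):
            return o.item()
        return str(o)

    blob = json.dumps(dataclasses.asdict(config), default=default, sort_keys=True)
    return hashlib.sha256(blob.encode()).hexdigest()[:16]


def run_cohort_analysis(
    dataset: CohortDataset | dict,
    config: AnalysisConfig = None,
) -> AnalysisResult:
    """Run the full spectral analysis over a cohort.

    ``dataset`` is a :class:`CohortDataset` or a plain mapping
    ``{(group, mouse, session): Signal}``.  Returns an
    :class:`AnalysisResult`; call its ``write`` method to materialize
    the output files.
    """
    config = config or AnalysisConfig()
    signals = dataset.signals if isinstance(dataset, CohortDataset) else dict(dataset)
    if not signals:
        raise ValueError("empty cohort")
    fs_values = {sig.fs for sig in signals.values()}
    if len(fs_values) != 1:
        raise ValueError(f"signals must share one sampling rate, got {sorted(fs_values)}")
    fs = float(next(iter(fs_values)))

    groups = sorted({k[0] for k in signals})
    sessions = _session_order(signals, dataset)
    baseline = config.baseline_session or sessions[0]
    if baseline not in sessions:
        raise ValueError(f"baseline session {baseline!r} absent from the cohort ({sessions})")

    skipped: list = []
    rows_raw, rows_total = [], []
    mouse_spectra: dict = {}

    for (group, mouse, session), sig in sorted(signals.items()):
        filtered = notch_filter(sig, config.notch)
        window = filtered.crop(0.0, min(config.fft_window_s, filtered.duration))
        epochs = segment_epochs(window, config.fft_epoch_len, max_epochs=config.fft_max_epochs)
        try:
            epochs = screen_artifacts(
                epochs, k_mad=config.k_mad, flat_tol=config.flat_tol,
                session=f"{group}/{mouse}/{session}",
            )
        except NoAnalyzableDataError as err:
            logger.warning("skipping %s/%s/%s: %s", group, mouse, session, err)
            skipped.append((group, mouse, session, str(err)))
            continue
        if epochs.n_epochs == 0:
            skipped.append((group, mouse, session, "no epochs"))
            continue
        per_epoch = [epoch_spectrum(e, filtered.fs, taper=config.taper) for e in epochs.epochs]
        mouse_raw = average_spectrum(per_epoch)
        mouse_spectra[(group, mouse, session)] = mouse_raw
        mouse_total = normalize_to_total(mouse_raw)
        for band, val in band_powers(mouse_raw, config.bands).items():
            rows_raw.append(
                {"group": group, "mouse": mouse, "session": session, "band": band,
                 "value": val, "units": "raw", "n_epochs": epochs.n_epochs}
            )
        for band, val in band_powers(mouse_total, config.bands).items():
            rows_total.append(
                {"group": group, "mouse": mouse, "session": session, "band": band,
                 "value": val, "units": "percent_of_total", "n_epochs": epochs.n_epochs}
            )

    cols = ["group", "mouse", "session", "band", "value", "units", "n_epochs"]
    table_raw = pd.DataFrame(rows_raw, columns=cols)
    table_total = pd.DataFrame(rows_total, columns=cols)
    table_baseline = baseline_normalize(table_raw.drop(columns=["n_epochs"]), baseline)

    # group-average spectra (mouse spectra averaged, then normalized) and fits
    group_spectra: dict = {}
    fit_rows = []
    for group in groups:
        for session in sessions:
            per_mouse = [
                ps for (g, m, s), ps in mouse_spectra.items() if g == group and s == session
            ]
            if not per_mouse:
                continue
            grp_raw = average_spectrum(per_mouse)
            grp_total = normalize_to_total(grp_raw)
            group_spectra[(group, session)] = grp_total
            for f_range in config.aperiodic_ranges:
                fit = fit_loglog(grp_total, f_range=f_range)
                fit_rows.append(
                    {"group": group, "mouse": "all", "session": session,
                     "f_lo": f_range[0], "f_hi": f_range[1], "slope": fit.slope,
                     "intercept": fit.intercept, "r_squared": fit.r_squared,
                     "n_points": fit.n_points}
                )
    for (group, mouse, session), ps in sorted(mouse_spectra.items()):
        for f_range in config.aperiodic_ranges:
            fit = fit_loglog(normalize_to_total(ps), f_range=f_range)
            fit_rows.append(
                {"group": group, "mouse": mouse, "session": session,
                 "f_lo": f_range[0], "f_hi": f_range[1], "slope": fit.slope,
                 "intercept": fit.intercept, "r_squared": fit.r_squared,
                 "n_points": fit.n_points}
            )
    aperiodic_fits = pd.DataFrame(
        fit_rows,
        columns=["group", "mouse", "session", "f_lo", "f_hi", "slope", "intercept",
                 "r_squared", "n_points"],
    )

    # mTFT arm: one long segment per mouse as the epoch ensemble
    spectrograms: dict = {}
    for group in groups:
        mice = sorted({m for (g, m, s) in signals if g == group})[: config.mtft_n_mice]
        for session in sessions:
            segs = []
            for mouse in mice:
                sig = signals.get((group, mouse, session))
                if sig is None or sig.duration < config.mtft_epoch_len - 1e-9:
                    continue
                filtered = notch_filter(sig, config.notch)
                segs.append(filtered.crop(0.0, config.mtft_epoch_len).samples)
            if len(segs) < 2:
                logger.warning(
                    "mTFT: fewer than 2 usable segments for %s/%s; skipping spectrogram",
                    group, session,
                )
                continue
            eset = EpochSet(np.stack(segs), config.mtft_epoch_len, fs)
            spectrograms[(group, session)] = mt_spectrogram(eset, config.mt_params)

    # ordered-day inference maps and focus-band densities
    inference_maps: dict = {}
    dens_rows = []
    for group in groups:
        for first, second in config.comparison_plan(sessions):
            sg1 = spectrograms.get((group, first))
            sg2 = spectrograms.get((group, second))
            if sg1 is None or sg2 is None:
                continue
            imap = jackknife_compare(sg1, sg2, alpha=config.alpha)
            inference_maps[(group, first, second)] = imap
            dens = band_probability_density(imap, config.focus_band)
            dens_rows.append(
                {"group": group, "first": first, "second": second, **dens.as_dict(),
                 "alpha": config.alpha, "dof": imap.dof}
            )
    densities = pd.DataFrame(
        dens_rows,
        columns=["group", "first", "second", "band_lo_hz", "band_hi_hz",
                 "p_plus", "p_zero", "p_minus", "n_bins", "alpha", "dof"],
    )

    # comodulograms and region summaries
    comodulograms: dict = {}
    region_rows = []
    for (group, session), sg in sorted(spectrograms.items()):
        com = comodulogram(sg)
        comodulograms[(group, session)] = com
        for band_x, band_y in config.comod_regions:
            summ = region_summary(com, band_x, band_y)
            region_rows.append(
                {"group": group, "session": session,
                 "band_x_lo": band_x[0], "band_x_hi": band_x[1],
                 "band_y_lo": band_y[0], "band_y_hi": band_y[1],
                 "mean": summ.mean, "sd": summ.sd,
                 "ci_lo": summ.ci95[0], "ci_hi": summ.ci95[1],
                 "n_bins": summ.n_bins, "label": classify_strength(min(abs(summ.mean), 1.0))}
            )
    region_summaries = pd.DataFrame(
        region_rows,
        columns=["group", "session", "band_x_lo", "band_x_hi", "band_y_lo", "band_y_hi",
                 "mean", "sd", "ci_lo", "ci_hi", "n_bins", "label"],
    )

    manifest = {
        "lfposc_version": __version__,
        "numpy_version": np.__version__,
        "config_hash": _config_hash(config),
        "baseline_session": baseline,
        "groups": groups,
        "sessions": sessions,
        "n_signals": len(signals),
        "n_skipped": len(skipped),
    }
    if isinstance(dataset, CohortDataset):
        manifest["generator_seed"] = dataset.config.base_seed

    return AnalysisResult(
        band_table_raw=table_raw,
        band_table_pct_total=table_total,
        band_table_pct_baseline=table_baseline,
        group_spectra=group_spectra,
        aperiodic_fits=aperiodic_fits,
        spectrograms=spectrograms,
        inference_maps=inference_maps,
        densities=densities,
        comodulograms=comodulograms,
        region_summaries=region_summaries,
        skipped=skipped,
        manifest=manifest,
    )


def _session_order(signals: dict, dataset) -> list:
    """Session labels in cohort order when known, else first-seen order."""
    if isinstance(dataset, CohortDataset):
        return [s for s in dataset.config.session_labels]
    seen = []
    for (_, _, session) in signals:
        if session not in seen:
            seen.append(session)
    return seen
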