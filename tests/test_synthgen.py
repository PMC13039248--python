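"""Generator contracts: determinism, planted spectra, cohort plumbing."""

import numpy as np
import pytest

import lfposc as L

FS = 5000.0
NO_LINE = L.LineNoiseSpec(50.0, 0.0)


def _avg_spectrum(sig, epoch_len):
    es = L.segment_epochs(sig, epoch_len)
    return L.average_spectrum([L.epoch_spectrum(e, sig.fs) for e in es.epochs])


class TestSynthSignal:
    def test_zero_config_gives_zero_signal(self):
        sig = L.synth_signal(
            L.AperiodicSpec(0.5, 0.0),
            (L.OscComponent(8, 2, 0.0),),
            NO_LINE, 2.0, FS, seed=0,
        )
        assert sig.n_samples == int(2.0 * FS)
        assert np.allclose(sig.samples, 0.0)

    def test_sample_count_is_rounded_duration_times_fs(self):
        sig = L.synth_signal(L.AperiodicSpec(0.5, 1.0), (), NO_LINE, 1.5, 1000.0, seed=1)
        assert sig.n_samples == 1500

    def test_single_component_peaks_at_center(self):
        sig = L.synth_signal(
            L.AperiodicSpec(0, 0), (L.OscComponent(8.0, 2.0, 1.0),), NO_LINE, 10.0, FS, seed=2
        )
        ps = _avg_spectrum(sig, 10.0)
        assert abs(ps.freqs[np.argmax(ps.power)] - 8.0) <= 1.0

    def test_identical_seed_identical_samples(self):
        args = (
            L.AperiodicSpec(0.5, 0.05),
            (L.OscComponent(8, 2, 1.0, "theta"), L.OscComponent(20, 8, 0.5, "beta")),
            L.LineNoiseSpec(50.0, 0.5), 5.0, FS,
        )
        a = L.synth_signal(*args, seed=7)
        b = L.synth_signal(*args, seed=7)
        assert np.array_equal(a.samples, b.samples)
        c = L.synth_signal(*args, seed=8)
        assert not np.array_equal(a.samples, c.samples)

    def test_aliasing_and_argument_errors(self):
        with pytest.raises(ValueError, match="aliasing|represent"):
            L.synth_signal(L.AperiodicSpec(0, 0), (L.OscComponent(600.0, 10, 1.0),), NO_LINE, 1.0, 1000.0, seed=0)
        with pytest.raises(ValueError, match="duration"):
            L.synth_signal(L.AperiodicSpec(0, 0), (), NO_LINE, -1.0, FS, seed=0)

    def test_component_rms_matches_amplitude(self):
        sig = L.synth_signal(
            L.AperiodicSpec(0, 0), (L.OscComponent(8.0, 2.0, 2.5),), NO_LINE, 20.0, FS, seed=3
        )
        assert sig.samples.std() == pytest.approx(2.5, rel=1e-6)

    @pytest.mark.parametrize("alpha", [0.5, 1.0, 1.5])
    def test_aperiodic_exponent_recovered_by_independent_ols(self, alpha):
        """64 averaged 10-s epochs of a pure 1/f^alpha background fit by
        plain numpy OLS on log10-log10 axes recover slope -alpha."""
        sig = L.synth_signal(L.AperiodicSpec(alpha, 1.0), (), NO_LINE, 640.0, FS, seed=4)
        ps = _avg_spectrum(sig, 10.0)
        m = (ps.freqs >= 1.0) & (ps.freqs <= 48.0)
        slope = np.polyfit(np.log10(ps.freqs[m]), np.log10(ps.power[m]), 1)[0]
        assert slope == pytest.approx(-alpha, abs=0.05)

    def test_aperiodic_psd_calibration(self):
        """alpha=0, scale_C=2 is white noise of one-sided PSD 2: 10-s
        epoch bins (0.1 Hz wide) hold 0.2 power units each."""
        sig = L.synth_signal(L.AperiodicSpec(0.0, 2.0), (), NO_LINE, 320.0, FS, seed=5)
        ps = _avg_spectrum(sig, 10.0)
        m = (ps.freqs >= 10) & (ps.freqs <= 100)
        assert ps.power[m].mean() == pytest.approx(0.2, rel=0.05)

    @pytest.mark.parametrize("center,bw", [(3.0, 1.0), (8.0, 2.0), (12.5, 1.5)])
    def test_spectral_fidelity_peak_within_one_bin(self, center, bw):
        """Averaged spectra localize a planted component to within one
        0.5-Hz bin of its centre frequency."""
        sig = L.synth_signal(
            L.AperiodicSpec(0, 0), (L.OscComponent(center, bw, 1.0),), NO_LINE, 512.0, 1000.0, seed=6
        )
        ps = _avg_spectrum(sig, 2.0)
        assert abs(ps.freqs[np.argmax(ps.power)] - center) <= ps.df + 1e-9

    def test_wideband_component_peaks_within_half_bandwidth(self):
        comp = L.OscComponent(20.0, 8.0, 1.0)
        sig = L.synth_signal(L.AperiodicSpec(0, 0), (comp,), NO_LINE, 256.0, 1000.0, seed=7)
        ps = _avg_spectrum(sig, 2.0)
        assert abs(ps.freqs[np.argmax(ps.power)] - 20.0) <= 4.0

    def test_line_noise_power_at_line_frequency(self):
        sig = L.synth_signal(L.AperiodicSpec(0, 0), (), L.LineNoiseSpec(50.0, 1.0), 10.0, FS, seed=8)
        ps = _avg_spectrum(sig, 10.0)
        assert ps.freqs[np.argmax(ps.power)] == pytest.approx(50.0)
        assert ps.power.sum() == pytest.approx(1.0, rel=0.05)  # RMS amplitude contract


class TestCohort:
    def test_cohort_size_and_truth_table(self):
        cfg = L.CohortConfig(
            n_mice_per_group=10, group_labels=("a", "b"),
            session_labels=("PRE", "D-1", "D-3", "D-12"),
            fs=1000.0, duration=2.0,
            aperiodic=L.AperiodicSpec(0.5, 0.1),
            components=(L.OscComponent(8, 2, 1.0, "theta"),),
            effects=L.EffectSchedule({("a", "D-1", "theta"): 0.5}),
            base_seed=1,
        )
        ds = L.synth_cohort(cfg)
        assert len(ds) == 10 * 2 * 4
        row = ds.truth.set_index(["group", "session", "band"]).loc[("a", "D-1", "theta")]
        assert row["expected_pct_of_first"] == pytest.approx(25.0)

    def test_cohort_determinism(self):
        cfg = L.CohortConfig(
            n_mice_per_group=2, group_labels=("g",), session_labels=("s1", "s2"),
            fs=1000.0, duration=2.0, components=(L.OscComponent(8, 2, 1.0, "theta"),),
            base_seed=9,
        )
        d1, d2 = L.synth_cohort(cfg), L.synth_cohort(cfg)
        for key in d1.signals:
            assert np.array_equal(d1.signals[key].samples, d2.signals[key].samples)

    def test_adding_a_mouse_leaves_other_mice_unchanged(self):
        base = dict(
            group_labels=("g",), session_labels=("s1",), fs=1000.0, duration=2.0,
            components=(L.OscComponent(8, 2, 1.0, "theta"),), base_seed=9,
        )
        small = L.synth_cohort(L.CohortConfig(n_mice_per_group=2, **base))
        big = L.synth_cohort(L.CohortConfig(n_mice_per_group=3, **base))
        for key, sig in small.signals.items():
            assert np.array_equal(sig.samples, big.signals[key].samples)

    def test_empty_groups_rejected(self):
        with pytest.raises(ValueError):
            L.CohortConfig(group_labels=(), duration=1.0, fs=100.0)
        with pytest.raises(ValueError):
            L.CohortConfig(session_labels=(), duration=1.0, fs=100.0)

    def test_halved_theta_multiplier_quarters_band_power(self):
        """Amplitude multiplier 0.5 planted on one session yields ~25 %
        of baseline theta power through the full FFT pipeline."""
        cfg = L.CohortConfig(
            n_mice_per_group=3, group_labels=("vehicle",), session_labels=("PRE", "D-1"),
            fs=FS, duration=180.0,
            aperiodic=L.AperiodicSpec(0, 0),
            components=(L.OscComponent(8.0, 2.0, 1.0, label="theta"),),
            effects=L.EffectSchedule({("vehicle", "D-1", "theta"): 0.5}),
            base_seed=5,
        )
        ds = L.synth_cohort(cfg)
        res = L.run_cohort_analysis(ds, L.AnalysisConfig(mtft_n_mice=0))
        tb = res.band_table_pct_baseline
        rec = tb[(tb.band == "theta") & (tb.session == "D-1")]["value"].mean()
        assert rec == pytest.approx(25.0, abs=3.0)


class TestTransient:
    def test_injected_transient_location_and_amplitude(self):
        sig = L.Signal(np.zeros(int(2 * FS)), FS)
        out = L.inject_transient(sig, t_center=1.0, amplitude=5.0, width=0.01)
        assert out.samples.max() == pytest.approx(5.0)
        assert abs(np.argmax(out.samples) / FS - 1.0) < 0.01
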