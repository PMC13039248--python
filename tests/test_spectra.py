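"""FFT spectrum estimation, averaging, normalization and band powers."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import lfposc as L

FS = 5000.0


class TestEpochSpectrum:
    def test_sinusoid_peaks_at_its_frequency(self, theta_sinusoid):
        ps = L.epoch_spectrum(theta_sinusoid.samples, FS)
        assert ps.freqs[np.argmax(ps.power)] == pytest.approx(8.0)
        assert ps.df == pytest.approx(0.1)  # native grid of a 10-s epoch

    def test_zero_epoch_gives_zero_spectrum(self):
        ps = L.epoch_spectrum(np.zeros(1000), FS)
        assert np.allclose(ps.power, 0.0)

    def test_parseval_white_noise(self):
        x = np.random.default_rng(0).standard_normal(int(10 * FS))
        ps = L.epoch_spectrum(x, FS)
        assert ps.power.sum() == pytest.approx(x.var(), rel=0.05)

    def test_parseval_sinusoid(self, theta_sinusoid):
        x = theta_sinusoid.samples
        ps = L.epoch_spectrum(x, FS)
        assert ps.power.sum() == pytest.approx(x.var(), rel=0.05)

    def test_mean_removed_before_transform(self):
        """A large DC offset leaves the spectrum unchanged."""
        x = np.random.default_rng(1).standard_normal(5000)
        a = L.epoch_spectrum(x, FS)
        b = L.epoch_spectrum(x + 100.0, FS)
        assert np.allclose(a.power, b.power, rtol=1e-9, atol=1e-12)

    def test_too_short_epoch_rejected(self):
        with pytest.raises(ValueError):
            L.epoch_spectrum(np.ones(1), FS)


class TestAverageSpectrum:
    def test_idempotent_on_identical_spectra(self, theta_sinusoid):
        ps = L.epoch_spectrum(theta_sinusoid.samples, FS)
        avg = L.average_spectrum([ps, ps])
        assert np.allclose(avg.power, ps.power)
        assert avg.n_averaged == 2

    def test_n_averaged_accumulates(self, theta_sinusoid):
        ps = L.epoch_spectrum(theta_sinusoid.samples, FS)
        mice = [L.average_spectrum([ps] * 18) for _ in range(10)]
        assert L.average_spectrum(mice).n_averaged == 180

    def test_variance_shrinks_with_epoch_count(self):
        """Per-bin variance of averaged white-noise spectra scales as
        1/N_E (checked at N_E = 1, 4, 16)."""
        rng = np.random.default_rng(2)
        fs, n = 1000.0, 1000

        def avg_var(n_e, reps=60):
            vals = []
            for _ in range(reps):
                specs = [L.epoch_spectrum(rng.standard_normal(n), fs) for _ in range(n_e)]
                vals.append(L.average_spectrum(specs).power[50:300])
            return np.var(np.array(vals), axis=0).mean()

        v1, v4, v16 = avg_var(1), avg_var(4), avg_var(16)
        assert v1 / v4 == pytest.approx(4.0, rel=0.35)
        assert v1 / v16 == pytest.approx(16.0, rel=0.35)

    def test_mixed_grids_rejected(self):
        a = L.epoch_spectrum(np.ones(1000), 1000.0)
        b = L.epoch_spectrum(np.ones(500), 1000.0)
        with pytest.raises(ValueError, match="grid"):
            L.average_spectrum([a, b])

    def test_mixed_units_rejected(self):
        x = np.random.default_rng(3).standard_normal(1000)
        a = L.epoch_spectrum(x, 1000.0)
        b = L.normalize_to_total(L.epoch_spectrum(x, 1000.0), f_range=(1, 400))
        with pytest.raises(ValueError, match="units"):
            L.average_spectrum([a, b])


class TestNormalizeToTotal:
    def _flat_spectrum(self):
        freqs = np.round(np.arange(0, 2001) * 0.1, 10)
        return L.PowerSpectrum(freqs, np.ones_like(freqs))

    def test_sums_to_100_over_included_range(self, theta_sinusoid):
        ps = L.epoch_spectrum(theta_sinusoid.samples, FS)
        norm = L.normalize_to_total(ps)
        mask = (norm.freqs >= 1) & (norm.freqs <= 150)
        mask &= ~((norm.freqs >= 48) & (norm.freqs <= 52))
        assert norm.power[mask].sum() == pytest.approx(100.0, abs=1e-6)

    def test_flat_spectrum_theta_fraction(self):
        """Flat power on [1, 150] with the notch excluded: theta holds
        8/145 of the total, about 5.517 %."""
        norm = L.normalize_to_total(self._flat_spectrum())
        theta = L.band_powers(norm)["theta"]
        assert theta == pytest.approx(100.0 * 8.0 / 145.0, rel=1e-6)

    def test_power_confined_to_theta(self):
        freqs = np.round(np.arange(0, 2001) * 0.1, 10)
        power = np.where((freqs >= 5) & (freqs < 11), 1.0, 0.0)
        norm = L.normalize_to_total(L.PowerSpectrum(freqs, power))
        bands = L.band_powers(norm)
        assert bands["theta"] == pytest.approx(100.0)
        assert all(v == 0 for k, v in bands.items() if k != "theta")

    def test_zero_total_power_raises(self):
        freqs = np.arange(0, 200.0)
        with pytest.raises(ZeroDivisionError):
            L.normalize_to_total(L.PowerSpectrum(freqs, np.zeros_like(freqs)))

    def test_double_normalization_rejected(self):
        norm = L.normalize_to_total(self._flat_spectrum())
        with pytest.raises(ValueError):
            L.normalize_to_total(norm)

    @given(scale=st.floats(1e-6, 1e6))
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_scale_invariance(self, scale):
        ps = self._flat_spectrum()
        ps.power = ps.power * np.linspace(1, 3, ps.power.size)
        a = L.normalize_to_total(ps)
        b = L.normalize_to_total(L.PowerSpectrum(ps.freqs, ps.power * scale))
        assert np.allclose(a.power, b.power, atol=1e-6)


class TestBandPowers:
    def test_flat_spectrum_delta_beta_ratio(self):
        freqs = np.round(np.arange(0, 2001) * 0.1, 10)
        ps = L.PowerSpectrum(freqs, np.ones_like(freqs))
        bands = L.band_powers(ps)
        assert bands["delta"] / bands["beta"] == pytest.approx(3.0 / 18.0, rel=1e-6)

    def test_pure_theta_component_dominates(self, theta_sinusoid):
        ps = L.epoch_spectrum(theta_sinusoid.samples, FS)
        bands = L.band_powers(ps)
        assert all(bands["theta"] > v for k, v in bands.items() if k != "theta")

    def test_zero_spectrum_zero_bands(self):
        freqs = np.arange(0, 200.0)
        bands = L.band_powers(L.PowerSpectrum(freqs, np.zeros_like(freqs)))
        assert all(v == 0.0 for v in bands.values())

    def test_band_outside_grid_rejected(self):
        ps = L.PowerSpectrum(np.arange(0, 100.0), np.ones(100))
        with pytest.raises(ValueError, match="outside"):
            L.band_powers(ps)  # high gamma reaches 150 Hz

    def test_band_widening_is_monotone(self):
        rng = np.random.default_rng(4)
        freqs = np.arange(0.0, 200.0)
        ps = L.PowerSpectrum(freqs, rng.uniform(0, 1, freqs.size))
        narrow = L.BandScheme((L.Band("x", 4.0, 12.0),))
        wide = L.BandScheme((L.Band("x", 2.0, 20.0),))
        assert L.band_powers(ps, wide)["x"] >= L.band_powers(ps, narrow)["x"]

    def test_edge_bin_belongs_to_upper_band(self):
        freqs = np.round(np.arange(0, 2001) * 0.1, 10)
        power = np.where(np.isclose(freqs, 4.0), 1.0, 0.0)
        bands = L.band_powers(L.PowerSpectrum(freqs, power))
        assert bands["theta"] == pytest.approx(1.0)
        assert bands["delta"] == 0.0

    def test_high_gamma_includes_its_upper_edge(self):
        freqs = np.round(np.arange(0, 2001) * 0.1, 10)
        power = np.where(np.isclose(freqs, 150.0), 1.0, 0.0)
        assert L.band_powers(L.PowerSpectrum(freqs, power))["high_gamma"] == pytest.approx(1.0)


class TestBaselineNormalize:
    def _table(self):
        rows = []
        for mouse in (0, 1):
            for session, val in (("PRE", 2.0), ("D-1", 4.0)):
                rows.append({"group": "g", "mouse": mouse, "session": session,
                             "band": "theta", "value": val, "units": "raw"})
        return pd.DataFrame(rows)

    def test_baseline_rows_become_exactly_100(self):
        out = L.baseline_normalize(self._table(), "PRE")
        assert (out[out.session == "PRE"]["value"] == 100.0).all()

    def test_doubled_power_reads_200(self):
        out = L.baseline_normalize(self._table(), "PRE")
        assert np.allclose(out[out.session == "D-1"]["value"], 200.0)

    def test_missing_baseline_names_offender(self):
        table = self._table()
        table = table[~((table.mouse == 1) & (table.session == "PRE"))]
        with pytest.raises(ValueError, match="1, theta"):
            L.baseline_normalize(table, "PRE")

    def test_zero_baseline_names_offender(self):
        table = self._table()
        table.loc[(table.mouse == 0) & (table.session == "PRE"), "value"] = 0.0
        with pytest.raises(ValueError, match="zero baseline"):
            L.baseline_normalize(table, "PRE")

    def test_scale_invariance_of_baseline_table(self):
        table = self._table()
        out1 = L.baseline_normalize(table, "PRE")
        table2 = table.copy()
        table2["value"] *= 7.3
        out2 = L.baseline_normalize(table2, "PRE")
        assert np.allclose(out1["value"], out2["value"], atol=1e-6)
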