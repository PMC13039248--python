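import numpy as np
import pytest

import lfposc as L

FS = 5000.0


@pytest.fixture(scope="session")
def fs():
    return FS


@pytest.fixture(scope="session")
def theta_sinusoid():
    """Unit-amplitude 8-Hz sinusoid, 10 s at 5 kHz."""
    t = np.arange(int(10 * FS)) / FS
    return L.Signal(np.sin(2 * np.pi * 8.0 * t), FS)


@pytest.fixture(scope="session")
def small_cohort():
    """Tiny two-group cohort used by pipeline tests: 2 mice, 2 sessions,
    40-s signals with a planted theta drop on the second session."""
    cfg = L.CohortConfig(
        n_mice_per_group=2,
        group_labels=("vehicle", "treated"),
        session_labels=("PRE", "D-1"),
        fs=FS,
        duration=40.0,
        aperiodic=L.AperiodicSpec(0.5, 0.05),
        components=(
            L.OscComponent(8.0, 2.0, 1.0, label="theta"),
            L.OscComponent(20.0, 8.0, 0.5, label="beta"),
        ),
        line_noise=L.LineNoiseSpec(50.0, 0.5),
        effects=L.EffectSchedule({("treated", "D-1", "theta"): 0.5}),
        base_seed=123,
    )
    return L.synth_cohort(cfg)


@pytest.fixture(scope="session")
def small_analysis(small_cohort):
    """Analysis of the tiny cohort: 10-s FFT epochs over the whole 40 s,
    20-s mTFT segments so every stage runs quickly."""
    config = L.AnalysisConfig(
        fft_window_s=40.0, fft_max_epochs=4, mtft_epoch_len=20.0, mtft_n_mice=2
    )
    return L.run_cohort_analysis(small_cohort, config), small_cohort
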