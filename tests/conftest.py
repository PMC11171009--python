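import numpy as np
import pytest

from rtstress import synth
from rtstress.types import NNSeries


@pytest.fixture(scope="session")
def default_spec():
    return synth.TachogramSpec(
        mean_hr=60, sdnn_target=40, lf_hf_target=1.0, duration=300
    )


@pytest.fixture(scope="session")
def nn_series(default_spec):
    return synth.generate_nn_series(default_spec, seed=3)


@pytest.fixture(scope="session")
def clean_ppg(nn_series):
    """300 s clean synthetic PPG at 100 Hz with ground-truth beats."""
    return synth.synthesize_ppg(nn_series, fs=100, noise_sd=0.02, seed=1)


@pytest.fixture(scope="session")
def small_cohort():
    """40 patients x 3 days, moderate stress probability."""
    cfg = synth.CohortConfig(
        n_patients=40, days_per_patient=(3, 3), p_stress=0.75, seed=7
    )
    return synth.generate_cohort(cfg)


def tone_tachogram(freqs_amps, duration=300.0, mean_rr=1000.0, phases=None):
    """Tachogram whose RR modulation is a sum of pure tones.

    ``freqs_amps`` is a list of (freq_hz, amplitude_ms) pairs; returns an
    NNSeries built by walking beat times through the continuous RR curve.
    """
    phases = phases or [0.0] * len(freqs_amps)
    t = [0.0]
    while t[-1] < duration:
        rr = mean_rr + sum(
            a * np.sin(2 * np.pi * f * t[-1] + ph)
            for (f, a), ph in zip(freqs_amps, phases)
        )
        t.append(t[-1] + rr / 1000.0)
    bt = np.array(t)
    return NNSeries(beat_times=bt, nn_ms=np.diff(bt) * 1000.0)
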