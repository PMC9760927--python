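import numpy as np
import pytest

from fibervitals import (CouplerParams, PhysioParams, SamplingSpec,
                         make_coupler_record, make_phase_signal)


@pytest.fixture
def sampling():
    return SamplingSpec(fs=250.0, duration_s=180.0)


@pytest.fixture
def clean_physio():
    """Noise-free default physiology: breathing 77/min, heart 158/min."""
    return PhysioParams(rr_bpm=77.0, hr_bpm=158.0, noise_sd_rad=0.0)


@pytest.fixture
def clean_phase(clean_physio, sampling):
    return make_phase_signal(clean_physio, sampling, seed=0)


@pytest.fixture
def clean_record(clean_phase):
    return make_coupler_record(clean_phase, CouplerParams(), seed=0)


def breathing_only(rr_bpm: float, duration_s: float = 60.0, fs: float = 250.0):
    """Phase signal containing only the breathing fundamental."""
    p = PhysioParams(rr_bpm=rr_bpm, hr_bpm=max(2 * rr_bpm, rr_bpm + 40),
                     breath_harmonics=(), cardiac_amp_rad=0.0,
                     drift_amp_rad=0.0, noise_sd_rad=0.0)
    return make_phase_signal(p, SamplingSpec(fs=fs, duration_s=duration_s), seed=0)


def ideal_phase_grid(n: int = 6000) -> np.ndarray:
    """Phase ramp over exactly one turn whose grid hits every multiple of
    pi/3, so each coupler channel attains exactly +/-1."""
    assert n % 6 == 0
    return 2 * np.pi * np.arange(n) / n
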