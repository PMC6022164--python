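import numpy as np
import pytest

from facepulse.ppg import bandpass_filter
from facepulse.synthetic import (
    PulseScenario,
    constant_hr,
    generate_ppg_waveform,
    generate_validation_study,
)


@pytest.fixture(scope="session")
def pulse_72() -> tuple:
    """A clean 60 s, 72 BPM recording: (trace, truth)."""
    scen = PulseScenario(
        duration_s=60.0, hr_trajectory=constant_hr(72.0), noise_sd=0.1, seed=7
    )
    return generate_ppg_waveform(scen)


@pytest.fixture(scope="session")
def filtered_72(pulse_72):
    trace, _ = pulse_72
    return bandpass_filter(trace)


@pytest.fixture(scope="session")
def small_study():
    """A reduced validation study (6 subjects, 45 s) for fast pipeline tests."""
    return generate_validation_study(seed=3, n_subjects=6, duration_s=45.0)


def brute_force_dft_modulus(x: np.ndarray, nfft: int) -> np.ndarray:
    """O(N^2) one-sided DFT modulus; the independent spectrum oracle."""
    x = np.asarray(x, dtype=float)
    n_bins = nfft // 2 + 1
    k = np.arange(n_bins)[:, None]
    t = np.arange(len(x))[None, :]
    ang = -2.0 * np.pi * k * t / nfft
    re = (x * np.cos(ang)).sum(axis=1)
    im = (x * np.sin(ang)).sum(axis=1)
    return np.sqrt(re**2 + im**2)


def brute_force_peaks(
    x: np.ndarray, prominence: float, distance: int
) -> np.ndarray:
    """Independent local-maximum scan with prominence and separation rules.

    Mirrors the documented behaviour: candidate peaks are strict local
    maxima; prominence is the height above the highest of the two minima
    between the peak and its nearest higher neighbours (or signal edge);
    the separation rule keeps higher peaks first.
    """
    n = len(x)
    cand = [i for i in range(1, n - 1) if x[i] > x[i - 1] and x[i] > x[i + 1]]
    keep = []
    for i in cand:
        j, left_min = i - 1, x[i]
        while j >= 0 and x[j] <= x[i]:
            left_min = min(left_min, x[j])
            j -= 1
        j, right_min = i + 1, x[i]
        while j < n and x[j] <= x[i]:
            right_min = min(right_min, x[j])
            j += 1
        if x[i] - max(left_min, right_min) >= prominence:
            keep.append(i)
    keep.sort(key=lambda i: -x[i])
    selected: list[int] = []
    for i in keep:
        if all(abs(i - j) >= distance for j in selected):
            selected.append(i)
    return np.array(sorted(selected), dtype=int)
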