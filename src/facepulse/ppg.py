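"""Pulse-signal processing: bandpass filtering, spectra, HR series, peaks.

The luminosity trace of a skin ROI carries the cardiac pulse as a narrowband
oscillation.  The processing chain is:

1. discard the first ``cut_start_s`` seconds of the raw trace;
2. apply a zero-phase second-order Butterworth bandpass (defaults 50-190 BPM,
   i.e. 0.83-3.17 Hz);
3. exclude a further ``stabilization_s`` seconds of filtered output from all
   downstream estimates (filter transient settling);
4. estimate HR from the in-band maximum of the FFT magnitude on sliding
   windows advanced every 0.5 s, and detect individual beats as signal peaks.

An optional piecewise correction shifts estimates by -15/0/+15 BPM depending
on the heart-rate band (low < 76, mid 76-90, high > 90 BPM).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from .errors import (
    ConfigurationError,
    InsufficientDataError,
    NoSignalError,
    RangeError,
)
from .video import ChannelTrace

#: Cadence of the sliding HR estimator, seconds.
HR_STEP_S = 0.5

#: Default sliding analysis window, seconds.  At 15 fps a raw 10 s window has
#: 0.1 Hz (6 BPM) bins; zero-padding plus quadratic peak interpolation brings
#: the effective resolution below 1 BPM.
DEFAULT_WINDOW_S = 10.0


@dataclass(frozen=True)
class BandpassSpec:
    """Butterworth bandpass parameters, stated in BPM and derived in Hz."""

    low_bpm: float = 50.0
    high_bpm: float = 190.0
    order: int = 2

    def __post_init__(self) -> None:
        if not 0 < self.low_bpm < self.high_bpm:
            raise ConfigurationError(
                f"need 0 < low < high BPM; got {self.low_bpm}, {self.high_bpm}"
            )

    @property
    def low_hz(self) -> float:
        return self.low_bpm / 60.0

    @property
    def high_hz(self) -> float:
        return self.high_bpm / 60.0


@dataclass(frozen=True)
class FilteredSignal:
    """Bandpassed luminosity signal with transient-exclusion bookkeeping.

    ``values[i]`` is the filtered sample at absolute time
    ``start_s + i / fps`` of the source trace; the first ``stabilization_s``
    seconds of ``values`` are excluded from every downstream estimate.
    """

    values: np.ndarray
    fps: float
    start_s: float = 1.0  # cut_start_s: raw seconds dropped before filtering
    stabilization_s: float = 3.0

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "values", np.asarray(self.values, dtype=float)
        )

    @property
    def retained_start_s(self) -> float:
        """Absolute time at which estimates may begin."""
        return self.start_s + self.stabilization_s

    @property
    def end_s(self) -> float:
        return self.start_s + len(self.values) / self.fps

    def retained(self) -> np.ndarray:
        """Samples past the stabilization span."""
        skip = int(round(self.stabilization_s * self.fps))
        return self.values[skip:]

    def slice_window(self, t0: float, t1: float) -> np.ndarray:
        """Samples covering absolute times [t0, t1); window must be retained."""
        if t0 < self.retained_start_s - 1e-9 or t1 > self.end_s + 1e-9:
            raise RangeError(
                f"window [{t0}, {t1}] outside retained span "
                f"[{self.retained_start_s}, {self.end_s}]"
            )
        i0 = int(round((t0 - self.start_s) * self.fps))
        i1 = int(round((t1 - self.start_s) * self.fps))
        return self.values[i0:i1]


@dataclass(frozen=True)
class Spectrum:
    """One-sided FFT magnitude on a strictly increasing frequency grid."""

    freqs_hz: np.ndarray
    magnitudes: np.ndarray

    def __post_init__(self) -> None:
        f = np.asarray(self.freqs_hz, dtype=float)
        m = np.asarray(self.magnitudes, dtype=float)
        if f.shape != m.shape:
            raise ValueError("freqs and magnitudes must be the same length")
        object.__setattr__(self, "freqs_hz", f)
        object.__setattr__(self, "magnitudes", m)


@dataclass(frozen=True)
class HRSeries:
    """Timestamped HR estimates at a fixed cadence (default 0.5 s)."""

    times_s: np.ndarray
    hr_bpm: np.ndarray
    step_s: float = HR_STEP_S

    def __post_init__(self) -> None:
        object.__setattr__(self, "times_s", np.asarray(self.times_s, float))
        object.__setattr__(self, "hr_bpm", np.asarray(self.hr_bpm, float))

    def __len__(self) -> int:
        return len(self.times_s)

    def resample_1s(self) -> "HRSeries":
        """Keep every 2nd value: the 1 s cadence consumed by the
        time-series model."""
        return HRSeries(
            times_s=self.times_s[::2], hr_bpm=self.hr_bpm[::2], step_s=1.0
        )


@dataclass(frozen=True)
class PeakSet:
    """Detected signal peaks: times, amplitudes, inter-peak intervals."""

    peak_times_s: np.ndarray
    amplitudes: np.ndarray
    distances_s: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "peak_times_s", np.asarray(self.peak_times_s, float)
        )
        object.__setattr__(
            self, "amplitudes", np.asarray(self.amplitudes, float)
        )
        object.__setattr__(
            self, "distances_s", np.asarray(self.distances_s, float)
        )

    @property
    def n_peaks(self) -> int:
        return len(self.peak_times_s)


def butter_sos(spec: BandpassSpec, fps: float):
    """Second-order-sections Butterworth bandpass for the given band."""
    nyq = fps / 2.0
    if spec.high_hz >= nyq:
        raise ConfigurationError(
            f"high cutoff {spec.high_hz:.2f} Hz >= Nyquist {nyq:.2f} Hz"
        )
    return sps.butter(
        spec.order, [spec.low_hz, spec.high_hz], btype="bandpass", fs=fps,
        output="sos",
    )


def bandpass_filter(
    trace: ChannelTrace,
    spec: BandpassSpec | None = None,
    cut_start_s: float = 1.0,
    stabilization_s: float = 3.0,
) -> FilteredSignal:
    """Zero-phase Butterworth bandpass of a luminosity trace.

    The first ``cut_start_s`` seconds of the raw trace are discarded before
    filtering; the next ``stabilization_s`` seconds of filtered output are
    flagged for exclusion.  Filtering is forward-backward (``sosfiltfilt``),
    preserving peak timing for the beat statistics.  The output is de-meaned
    over the retained span.
    """
    spec = spec or BandpassSpec()
    fps = trace.fps
    n_cut = int(round(cut_start_s * fps))
    n_stab = int(round(stabilization_s * fps))
    kept = np.asarray(trace.values, dtype=float)[n_cut:]
    min_len = max(n_stab + int(fps), 3 * int(fps), 15)
    if len(kept) < min_len:
        raise InsufficientDataError(
            f"trace has {len(kept)} samples after the cut; "
            f"need at least {min_len}"
        )
    sos = butter_sos(spec, fps)
    filtered = sps.sosfiltfilt(sos, kept - kept.mean())
    filtered = filtered - filtered[n_stab:].mean()
    return FilteredSignal(
        values=filtered,
        fps=fps,
        start_s=cut_start_s,
        stabilization_s=stabilization_s,
    )


def _nfft_for_resolution(n: int, fps: float, df_hz: float = 1.0 / 60.0) -> int:
    """Zero-padded FFT length giving grid spacing <= df_hz (1 BPM)."""
    nfft = max(n, int(np.ceil(fps / df_hz)))
    return 1 << int(np.ceil(np.log2(nfft)))


def compute_spectrum(
    sig: FilteredSignal,
    window: tuple[float, float] | None = None,
) -> Spectrum:
    """One-sided DFT modulus of a retained-span window.

    The window is de-meaned (DC removal) and zero-padded so the frequency
    grid spacing is at most 1 BPM (0.0167 Hz).
    """
    if window is None:
        window = (sig.retained_start_s, sig.end_s)
    t0, t1 = window
    x = sig.slice_window(t0, t1)
    if len(x) < 4 * sig.fps:
        raise InsufficientDataError(
            f"window [{t0}, {t1}] has {len(x)} samples; need >= 4 s"
        )
    x = x - x.mean()
    nfft = _nfft_for_resolution(len(x), sig.fps)
    mags = np.abs(np.fft.rfft(x, n=nfft))
    freqs = np.fft.rfftfreq(nfft, d=1.0 / sig.fps)
    return Spectrum(freqs_hz=freqs, magnitudes=mags)


def dominant_hr(
    spectrum: Spectrum,
    band: BandpassSpec | None = None,
    noise_floor: float = 1e-12,
) -> float:
    """HR in BPM from the in-band magnitude maximum.

    The argmax over ``[low_hz, high_hz]`` is refined by quadratic
    interpolation through the three bins around the maximum, then converted
    to BPM and clamped to the band.

    Because the bandpass attenuates frequencies near the low cutoff, a slow
    pulse's second harmonic can narrowly exceed its fundamental in finely
    resolved spectra.  A subharmonic check guards against this: if an
    in-band line near half the peak frequency carries at least 40% of the
    peak magnitude, that line is taken as the pulse fundamental (a pure tone
    has no subharmonic energy, so the check never fires spuriously).
    """
    band = band or BandpassSpec()
    freqs, mags = spectrum.freqs_hz, spectrum.magnitudes
    mask = (freqs >= band.low_hz) & (freqs <= band.high_hz)
    if not mask.any():
        raise NoSignalError("spectrum does not cover the analysis band")
    in_band = mags[mask]
    if in_band.max() <= noise_floor:
        raise NoSignalError("no in-band spectral energy above the noise floor")
    idx = np.flatnonzero(mask)[np.argmax(in_band)]
    half = freqs[idx] / 2.0
    if half >= band.low_hz:
        grid = freqs[1] - freqs[0] if len(freqs) > 1 else 0.0
        tol = max(2.0 * grid, 0.03 * half)
        near = mask & (freqs >= half - tol) & (freqs <= half + tol)
        if near.any() and mags[near].max() >= 0.4 * mags[idx]:
            idx = np.flatnonzero(near)[np.argmax(mags[near])]
    freq = _quadratic_peak(freqs, mags, idx)
    return float(np.clip(freq * 60.0, band.low_bpm, band.high_bpm))


def _quadratic_peak(freqs: np.ndarray, mags: np.ndarray, idx: int) -> float:
    """Vertex of the parabola through (idx-1, idx, idx+1); falls back to the
    bin center at grid edges."""
    if idx == 0 or idx == len(mags) - 1:
        return float(freqs[idx])
    y0, y1, y2 = mags[idx - 1 : idx + 2]
    denom = y0 - 2.0 * y1 + y2
    if abs(denom) < 1e-30:
        return float(freqs[idx])
    delta = 0.5 * (y0 - y2) / denom
    delta = float(np.clip(delta, -0.5, 0.5))
    df = freqs[idx + 1] - freqs[idx]
    return float(freqs[idx] + delta * df)


def sliding_hr(
    sig: FilteredSignal,
    band: BandpassSpec | None = None,
    window_s: float = DEFAULT_WINDOW_S,
    step_s: float = HR_STEP_S,
) -> HRSeries:
    """HR estimates every ``step_s`` seconds from a sliding spectral window.

    Each output at time ``t`` is ``dominant_hr`` of the window
    ``[t - window_s, t]``; the first output lands at
    ``cut_start_s + stabilization_s + window_s``.
    """
    band = band or BandpassSpec()
    first_t = sig.retained_start_s + window_s
    if first_t > sig.end_s + 1e-9:
        raise InsufficientDataError(
            f"signal ends at {sig.end_s:.2f} s; need at least "
            f"{first_t:.2f} s for one {window_s:.0f} s window"
        )
    n_steps = int(np.floor((sig.end_s - first_t) / step_s + 1e-9)) + 1
    times = first_t + step_s * np.arange(n_steps)
    hrs = np.empty(n_steps)
    for i, t in enumerate(times):
        spec = compute_spectrum(sig, (t - window_s, t))
        hrs[i] = dominant_hr(spec, band)
    return HRSeries(times_s=times, hr_bpm=hrs, step_s=step_s)


def detect_peaks(
    sig: FilteredSignal,
    band: BandpassSpec | None = None,
    prominence_factor: float = 0.5,
    min_separation_s: float | None = None,
) -> PeakSet:
    """Individual beats as local maxima of the filtered signal.

    A peak must have prominence >= ``prominence_factor`` times the
    retained-span standard deviation and be separated from its neighbours by
    at least ``min_separation_s``.  By default the separation adapts to the
    signal: 0.6 of the beat period at the spectrally estimated dominant rate,
    which rejects the dicrotic bump (offset ~0.3 period after the systolic
    peak) at every heart rate while never merging true beats; if no dominant
    rate can be estimated it falls back to one period at the band's fastest
    rate (``60 / high_bpm`` seconds).  An empty result is not an error.
    """
    band = band or BandpassSpec()
    x = sig.retained()
    if len(x) < 2 * sig.fps * 60.0 / band.high_bpm:
        raise InsufficientDataError(
            "retained span shorter than two beat periods"
        )
    sd = x.std()
    if min_separation_s is None:
        min_separation_s = 60.0 / band.high_bpm
        if sd > 0 and len(x) >= 4 * sig.fps:
            try:
                hr_est = dominant_hr(compute_spectrum(sig), band)
                min_separation_s = 0.6 * 60.0 / hr_est
            except NoSignalError:
                pass
    distance = max(1, int(round(sig.fps * min_separation_s)))
    if sd == 0:
        idx = np.array([], dtype=int)
    else:
        idx, _ = sps.find_peaks(
            x, prominence=prominence_factor * sd, distance=distance
        )
    times = sig.retained_start_s + idx / sig.fps
    return PeakSet(
        peak_times_s=times,
        amplitudes=x[idx],
        distances_s=np.diff(times),
    )


def apply_correction(
    hr_raw: float, reference_hr: float | None = None
) -> float:
    """Piecewise HR correction: -15 below 76 BPM, none in 76-90, +15 above 90.

    The band is chosen from ``reference_hr`` when a contact-device reading is
    available, otherwise from the raw video estimate itself.
    """
    band_hr = hr_raw if reference_hr is None else reference_hr
    if band_hr < 76.0:
        return hr_raw - 15.0
    if band_hr <= 90.0:
        return hr_raw
    return hr_raw + 15.0
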