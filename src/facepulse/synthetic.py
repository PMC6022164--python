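"""Ground-truthed synthetic inputs: PPG waveforms, pulse videos, study tables.

Every pipeline stage is testable offline against these generators, which are
pure functions of (scenario, seed).

The beat waveform is a minimal PPG morphology: a systolic Gaussian peak plus
a dicrotic-notch Gaussian at 40% amplitude offset by 0.3 of the beat period.
Per-channel pulse amplitudes default to the ratio G:R:B = 1.0:0.5:0.3 — the
green channel carries the strongest pulsatile signal because oxy- and
deoxyhemoglobin absorb green light most strongly, which is also why green
performs best in practice.

The validation-study generator emulates a protocol of 15 subjects, each
recorded in three states (rest, post-exercise, recovery; post-exercise HR >
recovery HR > rest HR), with three cuff-style reference HR/BP triplets per
recording (start, middle, end) and a continuous 1 Hz finger-sensor-style HR
series.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import BoundsError, ScenarioError
from .features import FEATURE_COLUMNS, TARGET_COLUMNS
from .ppg import HRSeries
from .video import ChannelTrace, FrameSequence, Region, ROIRectangle

__all__ = [
    "PulseScenario",
    "SubjectProfile",
    "Recording",
    "ValidationStudy",
    "constant_hr",
    "linear_hr",
    "step_hr",
    "beat_template",
    "generate_ppg_waveform",
    "generate_pulse_video",
    "default_roi_layout",
    "generate_validation_study",
    "generate_model1_dataset",
    "generate_narx_benchmark",
]

#: Default per-channel pulse amplitudes (8-bit intensity units).
DEFAULT_AMPLITUDES = {"G": 2.0, "R": 1.0, "B": 0.6}

#: Default skin-like base color (R, G, B).
DEFAULT_BASE_COLOR = (180.0, 140.0, 120.0)

#: Blood-pressure generative link used by the study and dataset generators:
#: sp = SP_SLOPE * hr + SP_INTERCEPT (+ noise), dp likewise.  Documented
#: constants chosen to give plausible mmHg values over the 50-190 BPM range;
#: they exist to make model recovery testable, not to model physiology.
SP_SLOPE, SP_INTERCEPT = 0.6, 70.0
DP_SLOPE, DP_INTERCEPT = 0.4, 45.0


def constant_hr(bpm: float) -> Callable[[np.ndarray], np.ndarray]:
    return lambda t: np.full_like(np.asarray(t, float), bpm)


def linear_hr(bpm0: float, bpm1: float, duration_s: float):
    """HR drifting linearly from bpm0 to bpm1 over the recording."""
    return lambda t: bpm0 + (bpm1 - bpm0) * np.asarray(t, float) / duration_s


def step_hr(bpm0: float, bpm1: float, switch_s: float):
    """HR stepping from bpm0 to bpm1 at ``switch_s``."""
    return lambda t: np.where(np.asarray(t, float) < switch_s, bpm0, bpm1)


@dataclass(frozen=True)
class PulseScenario:
    """Parameters of one synthetic pulse recording.

    ``hr_trajectory`` is BPM as a function of time (seconds); it must stay
    within [50, 190] BPM and below half the frame rate.
    """

    duration_s: float = 120.0
    fps: float = 15.0
    hr_trajectory: Callable[[np.ndarray], np.ndarray] = field(
        default_factory=lambda: constant_hr(72.0)
    )
    pulse_amplitude: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_AMPLITUDES)
    )
    base_color: tuple[float, float, float] = DEFAULT_BASE_COLOR
    noise_sd: float = 0.1
    drift_amplitude: float = 0.5
    drift_period_s: float = 30.0
    seed: int = 0

    def validate(self) -> None:
        t = np.linspace(0.0, self.duration_s, 512)
        hr = np.asarray(self.hr_trajectory(t), dtype=float)
        if hr.min() < 50.0 or hr.max() > 190.0:
            raise ScenarioError(
                f"HR trajectory spans [{hr.min():.0f}, {hr.max():.0f}] BPM; "
                "must stay within [50, 190]"
            )
        if self.fps <= 2.0 * hr.max() / 60.0:
            raise ScenarioError("fps must exceed twice the maximum pulse rate")


_TEMPLATE_GRID = np.linspace(0.0, 1.0, 2048, endpoint=False)


def beat_template(phase_frac: np.ndarray) -> np.ndarray:
    """Zero-mean, unit-peak beat shape as a function of phase in [0, 1).

    Systolic Gaussian at phase 0.25 (sd 0.06) plus a dicrotic component at
    40% amplitude offset by 0.3 of the period (phase 0.55, sd 0.09).
    """
    u = np.mod(np.asarray(phase_frac, float), 1.0)

    def _raw(v):
        return np.exp(-0.5 * ((v - 0.25) / 0.06) ** 2) + 0.4 * np.exp(
            -0.5 * ((v - 0.55) / 0.09) ** 2
        )

    raw = _raw(u)
    mean = _raw(_TEMPLATE_GRID).mean()
    return raw - mean


def _pulse_phase(scenario: PulseScenario, times: np.ndarray) -> np.ndarray:
    """Accumulated beat phase: integral of instantaneous rate hr/60."""
    rate_hz = np.asarray(scenario.hr_trajectory(times), float) / 60.0
    dt = 1.0 / scenario.fps
    return np.concatenate([[0.0], np.cumsum(rate_hz[:-1] * dt)])


def generate_ppg_waveform(
    scenario: PulseScenario,
    channel: str = "G",
    region: Region | str = Region.FOREHEAD,
) -> tuple[ChannelTrace, HRSeries]:
    """One channel's luminosity trace plus the injected ground-truth HR.

    Trace = base color + amplitude x beat template(phase) + sinusoidal
    illumination drift + white noise, clipped to [0, 255].  Ground truth is
    the HR trajectory sampled every 0.5 s.
    """
    scenario.validate()
    rng = np.random.default_rng(scenario.seed)
    n = int(round(scenario.duration_s * scenario.fps))
    times = np.arange(n) / scenario.fps
    phase = _pulse_phase(scenario, times)
    amp = scenario.pulse_amplitude.get(channel, 0.0)
    base = scenario.base_color[("R", "G", "B").index(channel)]
    drift = scenario.drift_amplitude * np.sin(
        2.0 * np.pi * times / scenario.drift_period_s
    )
    noise = rng.normal(0.0, scenario.noise_sd, n) if scenario.noise_sd else 0.0
    values = np.clip(base + amp * beat_template(phase) + drift + noise, 0, 255)
    trace = ChannelTrace(
        values=values, channel=channel, region=region, fps=scenario.fps
    )
    truth_t = np.arange(0.0, scenario.duration_s, 0.5)
    truth = HRSeries(
        times_s=truth_t,
        hr_bpm=np.asarray(scenario.hr_trajectory(truth_t), float),
        step_s=0.5,
    )
    return trace, truth


def default_roi_layout(
    width: int = 160, height: int = 120
) -> dict[Region, ROIRectangle]:
    """Desk-scale ROI layout for small synthetic frames (proportional to a
    forehead-plus-cheeks arrangement on a full-resolution face)."""
    return {
        Region.FOREHEAD: ROIRectangle(Region.FOREHEAD, width // 2 - 20, 8, 40, 16),
        Region.RIGHT_CHEEK: ROIRectangle(
            Region.RIGHT_CHEEK, width // 2 + 16, height // 2, 24, 24
        ),
        Region.LEFT_CHEEK: ROIRectangle(
            Region.LEFT_CHEEK, width // 2 - 40, height // 2, 24, 24
        ),
    }


def generate_pulse_video(
    scenario: PulseScenario,
    roi_layout: Mapping[Region, ROIRectangle] | None = None,
    frame_size: tuple[int, int] = (120, 160),
) -> tuple[FrameSequence, HRSeries]:
    """Synthetic face video: each ROI's pixels pulse around the base color.

    A static sub-integer dither field (per-pixel offsets in [-0.5, 0.5],
    drawn once from the seed, emulating sensor fixed-pattern noise) lets ROI
    averaging recover sub-integer modulation after 8-bit quantization;
    ``noise_sd`` adds white pixel noise independent per frame.
    """
    scenario.validate()
    height, width = frame_size
    layout = roi_layout or default_roi_layout(width, height)
    for roi in layout.values():
        if roi.x + roi.width > width or roi.y + roi.height > height:
            raise BoundsError(
                f"ROI {roi.region.value} exceeds frame {width}x{height}"
            )
    rng = np.random.default_rng(scenario.seed)
    n = int(round(scenario.duration_s * scenario.fps))
    times = np.arange(n) / scenario.fps
    phase = _pulse_phase(scenario, times)
    pulse = beat_template(phase)  # (n,)
    drift = scenario.drift_amplitude * np.sin(
        2.0 * np.pi * times / scenario.drift_period_s
    )
    base = np.array(scenario.base_color, dtype=float)
    amps = np.array(
        [scenario.pulse_amplitude.get(c, 0.0) for c in ("R", "G", "B")]
    )
    dither = rng.uniform(-0.5, 0.5, (height, width, 3))
    frames = np.empty((n, height, width, 3), dtype=np.uint8)
    for i in range(n):
        frame = np.tile(base + drift[i], (height, width, 1))
        for roi in layout.values():
            frame[
                roi.y : roi.y + roi.height, roi.x : roi.x + roi.width, :
            ] += amps * pulse[i]
        frame += dither
        if scenario.noise_sd:
            frame += rng.normal(0.0, scenario.noise_sd, frame.shape)
        frames[i] = np.clip(np.rint(frame), 0, 255).astype(np.uint8)
    truth_t = np.arange(0.0, scenario.duration_s, 0.5)
    truth = HRSeries(
        times_s=truth_t,
        hr_bpm=np.asarray(scenario.hr_trajectory(truth_t), float),
        step_s=0.5,
    )
    return FrameSequence(frames=frames, fps=scenario.fps), truth


# ---------------------------------------------------------------------------
# Study-level generators
# ---------------------------------------------------------------------------

STATES = ("rest", "post_exercise", "recovery")


@dataclass(frozen=True)
class SubjectProfile:
    """Per-subject true physiology for the three recording states."""

    subject_id: int
    hr_by_state: dict[str, float]
    sp_by_state: dict[str, float]
    dp_by_state: dict[str, float]

    def __post_init__(self) -> None:
        hr = self.hr_by_state
        if not (hr["post_exercise"] > hr["recovery"] > hr["rest"]):
            raise ScenarioError(
                "state ordering violated: need post_exercise > recovery > rest"
            )


@dataclass(frozen=True)
class Recording:
    """One synthetic recording: traces per (region, channel) + references."""

    subject_id: int
    state: str
    true_hr: float
    sp: float
    dp: float
    traces: dict[tuple[Region, str], ChannelTrace]
    reference_triplets: pd.DataFrame  # columns: position, hr, sp, dp
    finger_hr: HRSeries  # continuous 1 s cadence reference


@dataclass(frozen=True)
class ValidationStudy:
    recordings: list[Recording]

    def reference_table(self) -> pd.DataFrame:
        """Tidy per-recording truth: subject, state, hr, sp, dp."""
        return pd.DataFrame(
            [
                {
                    "subject": r.subject_id,
                    "state": r.state,
                    "hr": r.true_hr,
                    "sp": r.sp,
                    "dp": r.dp,
                }
                for r in self.recordings
            ]
        )


def _subject_profiles(rng: np.random.Generator, n_subjects: int):
    profiles = []
    for sid in range(n_subjects):
        rest = float(np.clip(rng.normal(68.0, 5.0), 55.0, 85.0))
        post = rest + float(np.clip(rng.normal(32.0, 8.0), 15.0, 60.0))
        post = min(post, 185.0)
        recovery = rest + float(np.clip(rng.normal(12.0, 4.0), 3.0, 25.0))
        recovery = min(recovery, post - 2.0)
        hr = {"rest": rest, "post_exercise": post, "recovery": recovery}
        sp = {
            s: SP_SLOPE * h + SP_INTERCEPT + rng.normal(0.0, 2.0)
            for s, h in hr.items()
        }
        dp = {
            s: DP_SLOPE * h + DP_INTERCEPT + rng.normal(0.0, 2.0)
            for s, h in hr.items()
        }
        profiles.append(
            SubjectProfile(
                subject_id=sid, hr_by_state=hr, sp_by_state=sp, dp_by_state=dp
            )
        )
    return profiles


def generate_validation_study(
    seed: int,
    n_subjects: int = 15,
    duration_s: float = 90.0,
    fps: float = 15.0,
    noise_sd: float = 1.0,
    channels: Sequence[str] = ("R", "G", "B"),
) -> ValidationStudy:
    """The full synthetic validation study: 15 subjects x 3 states.

    Each of the 45 recordings carries one luminosity trace per (region,
    channel) with G-dominant pulse amplitudes and shared white noise level
    ``noise_sd``, three reference HR/BP triplets (start, middle, end), and a
    continuous 1 Hz finger-sensor-style HR series.  Durations default to
    90 s (within the 1.5-3 min protocol range) at 15 fps.
    """
    rng = np.random.default_rng(seed)
    recordings: list[Recording] = []
    for profile in _subject_profiles(rng, n_subjects):
        for state in STATES:
            hr_true = profile.hr_by_state[state]
            drift_bpm = float(rng.uniform(-2.0, 2.0))
            traj = linear_hr(hr_true - drift_bpm / 2, hr_true + drift_bpm / 2,
                             duration_s)
            traces: dict[tuple[Region, str], ChannelTrace] = {}
            for region in Region:
                scen = PulseScenario(
                    duration_s=duration_s,
                    fps=fps,
                    hr_trajectory=traj,
                    noise_sd=noise_sd,
                    seed=int(rng.integers(0, 2**31 - 1)),
                )
                for channel in channels:
                    trace, _ = generate_ppg_waveform(
                        replace(scen, seed=int(rng.integers(0, 2**31 - 1))),
                        channel=channel,
                        region=region,
                    )
                    traces[(region, channel)] = trace
            triplets = pd.DataFrame(
                {
                    "position": ["start", "middle", "end"],
                    "hr": [
                        float(traj(np.array([t]))[0] + rng.normal(0.0, 1.0))
                        for t in (0.0, duration_s / 2, duration_s - 1.0)
                    ],
                    "sp": profile.sp_by_state[state] + rng.normal(0.0, 1.0, 3),
                    "dp": profile.dp_by_state[state] + rng.normal(0.0, 1.0, 3),
                }
            )
            finger_t = np.arange(0.0, duration_s, 1.0)
            finger = HRSeries(
                times_s=finger_t,
                hr_bpm=np.asarray(traj(finger_t), float)
                + rng.normal(0.0, 0.5, len(finger_t)),
                step_s=1.0,
            )
            recordings.append(
                Recording(
                    subject_id=profile.subject_id,
                    state=state,
                    true_hr=hr_true,
                    sp=float(profile.sp_by_state[state]),
                    dp=float(profile.dp_by_state[state]),
                    traces=traces,
                    reference_triplets=triplets,
                    finger_hr=finger,
                )
            )
    return ValidationStudy(recordings=recordings)


def generate_model1_dataset(
    n: int, seed: int, noise_frac: float = 0.0
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-video feature/target tables for regression-model recovery tests.

    Features are the 18 per-region summaries drawn around a per-sample true
    HR in [55, 180] BPM; targets follow the documented linear links
    (hr = mean of the three regional HR means; sp/dp linear in hr) with
    optional Gaussian noise of SD ``noise_frac`` x SD(noiseless target).
    """
    if n < 50:
        raise ValueError(f"need n >= 50; got {n}")
    rng = np.random.default_rng(seed)
    hr_true = rng.uniform(55.0, 180.0, n)
    rows = {}
    hr_means = []
    for region in ("forehead", "right_cheek", "left_cheek"):
        hr_mean = hr_true + rng.normal(0.0, 1.5, n)
        amp_mean = rng.uniform(0.8, 3.0, n)
        rows[f"{region}_hr_mean"] = hr_mean
        rows[f"{region}_hr_sd"] = np.abs(rng.normal(1.5, 0.5, n))
        rows[f"{region}_amp_mean"] = amp_mean
        rows[f"{region}_amp_sd"] = 0.1 * amp_mean * np.abs(
            rng.normal(1.0, 0.3, n)
        )
        rows[f"{region}_dist_mean"] = 60.0 / hr_mean + rng.normal(0.0, 0.005, n)
        rows[f"{region}_dist_sd"] = np.abs(rng.normal(0.03, 0.01, n))
        hr_means.append(hr_mean)
    features = pd.DataFrame(rows)[list(FEATURE_COLUMNS)]
    hr_target = np.mean(hr_means, axis=0)
    targets_clean = pd.DataFrame(
        {
            "hr": hr_target,
            "sp": SP_SLOPE * hr_target + SP_INTERCEPT,
            "dp": DP_SLOPE * hr_target + DP_INTERCEPT,
        }
    )[list(TARGET_COLUMNS)]
    if noise_frac > 0:
        noise = rng.normal(0.0, 1.0, targets_clean.shape) * (
            noise_frac * targets_clean.std(ddof=1).to_numpy()
        )
        targets = targets_clean + noise
    else:
        targets = targets_clean
    return features, targets


def generate_narx_benchmark(
    n_seconds: int = 2000,
    seed: int = 0,
    noise_sd: float = 0.02,
    n_hidden: int = 5,
    delays: int = 2,
    n_inputs: int = 9,
    n_outputs: int = 2,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Time series from a known random NARX teacher network.

    Exogenous inputs are smooth AR(1) series; targets are generated by
    iterating a randomly weighted tanh network of the stated topology on the
    lagged inputs and its own past outputs, plus white observation noise.
    Returns (inputs, targets) as per-second DataFrames.
    """
    rng = np.random.default_rng(seed)
    # smooth exogenous drivers
    X = np.zeros((n_seconds, n_inputs))
    eps = rng.normal(0.0, 1.0, (n_seconds, n_inputs))
    for t in range(1, n_seconds):
        X[t] = 0.9 * X[t - 1] + 0.3 * eps[t]
    width = delays * (n_inputs + n_outputs)
    w1 = rng.normal(0.0, 1.0, (n_hidden, width)) / np.sqrt(width)
    b1 = rng.normal(0.0, 0.1, n_hidden)
    w2 = rng.normal(0.0, 1.0, (n_outputs, n_hidden))
    b2 = np.zeros(n_outputs)
    Y = np.zeros((n_seconds, n_outputs))
    for t in range(delays, n_seconds):
        reg = np.concatenate(
            [X[t - k] for k in range(1, delays + 1)]
            + [Y[t - k] for k in range(1, delays + 1)]
        )
        Y[t] = w2 @ np.tanh(w1 @ reg + b1) + b2 + rng.normal(
            0.0, noise_sd, n_outputs
        )
    cols_x = [f"x{i}" for i in range(n_inputs)]
    cols_y = [f"y{i}" for i in range(n_outputs)]
    return pd.DataFrame(X, columns=cols_x), pd.DataFrame(Y, columns=cols_y)
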