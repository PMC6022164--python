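"""End-to-end orchestration: trace -> HR series -> features -> predictions.

This module chains the signal stages into per-recording and per-study
analyses and exposes :func:`run_pipeline`, the config-driven entry point the
command line wraps.  Every run writes a manifest (command, config snapshot,
seeds, input checksums) so deterministic paths reproduce bit-identically.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from . import __version__
from .errors import ConfigurationError
from .features import (
    FEATURE_COLUMNS,
    TARGET_COLUMNS,
    RegionFeatures,
    assemble_features,
    summarize_region,
)
from .models import FeedforwardRegressor
from .ppg import (
    BandpassSpec,
    FilteredSignal,
    HRSeries,
    PeakSet,
    apply_correction,
    bandpass_filter,
    detect_peaks,
    sliding_hr,
)
from .stats import method_comparison_table
from .synthetic import Recording, ValidationStudy, generate_validation_study
from .video import ChannelTrace, Region, extract_channel_trace, crop_region, load_video, read_roi_config


@dataclass(frozen=True)
class TraceAnalysis:
    """All signal-stage outputs for one luminosity trace."""

    filtered: FilteredSignal
    hr_series: HRSeries
    peaks: PeakSet
    hr_mean: float


def analyze_trace(
    trace: ChannelTrace,
    band: BandpassSpec | None = None,
    window_s: float = 10.0,
    step_s: float = 0.5,
) -> TraceAnalysis:
    """Filter a trace, estimate sliding HR, and detect beats."""
    band = band or BandpassSpec()
    filtered = bandpass_filter(trace, band)
    hr = sliding_hr(filtered, band, window_s=window_s, step_s=step_s)
    peaks = detect_peaks(filtered, band)
    return TraceAnalysis(
        filtered=filtered,
        hr_series=hr,
        peaks=peaks,
        hr_mean=float(np.mean(hr.hr_bpm)),
    )


def recording_features(
    recording: Recording,
    channel: str = "G",
    band: BandpassSpec | None = None,
) -> np.ndarray:
    """The 18-input feature vector of one recording (one channel)."""
    per_region: dict[Region, RegionFeatures] = {}
    for region in Region:
        analysis = analyze_trace(recording.traces[(region, channel)], band)
        per_region[region] = summarize_region(analysis.hr_series, analysis.peaks)
    return assemble_features(per_region)


def study_hr_estimates(
    study: ValidationStudy,
    band: BandpassSpec | None = None,
    correction: str = "off",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-video HR estimates for every (channel, region) plus the reference.

    Returns ``(estimates, reference)`` ready for
    :func:`facepulse.stats.method_comparison_table`.  ``correction`` is
    ``"off"``, ``"auto"`` (band from the raw estimate) or ``"reference"``
    (band from the contact-device HR).
    """
    if correction not in ("off", "auto", "reference"):
        raise ConfigurationError(f"unknown correction mode: {correction!r}")
    est_rows, ref_rows = [], []
    for idx, rec in enumerate(study.recordings):
        video_id = f"s{rec.subject_id:02d}_{rec.state}"
        ref_rows.append({"video": video_id, "hr_bpm": rec.true_hr})
        for (region, channel), trace in rec.traces.items():
            analysis = analyze_trace(trace, band)
            hr = analysis.hr_mean
            if correction == "auto":
                hr = apply_correction(hr)
            elif correction == "reference":
                hr = apply_correction(hr, reference_hr=rec.true_hr)
            est_rows.append(
                {
                    "video": video_id,
                    "channel": channel,
                    "region": region.value,
                    "hr_bpm": hr,
                }
            )
    return pd.DataFrame(est_rows), pd.DataFrame(ref_rows)


def study_feature_table(
    study: ValidationStudy,
    channel: str = "G",
    band: BandpassSpec | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-recording 18-feature table and reference HR/SP/DP targets."""
    feats, targs = [], []
    for rec in study.recordings:
        feats.append(recording_features(rec, channel, band))
        ref = rec.reference_triplets[["hr", "sp", "dp"]].mean()
        targs.append(ref.to_numpy())
    features = pd.DataFrame(feats, columns=list(FEATURE_COLUMNS))
    targets = pd.DataFrame(targs, columns=list(TARGET_COLUMNS))
    return features, targets


# ---------------------------------------------------------------------------
# Config-driven pipeline
# ---------------------------------------------------------------------------

_TOP_KEYS = {
    "seed", "out_dir", "study", "videos", "roi", "channel", "band",
    "window_s", "step_s", "correction", "train_model1",
}


def _validate_config(config: Mapping) -> dict:
    cfg = dict(config)
    unknown = set(cfg) - _TOP_KEYS
    if unknown:
        raise ConfigurationError(f"unknown config key(s): {sorted(unknown)}")
    for key in ("seed", "out_dir"):
        if key not in cfg:
            raise ConfigurationError(f"missing required config key: {key}")
    if "study" not in cfg and "videos" not in cfg:
        raise ConfigurationError(
            "config must request either `study` (synthetic) or `videos`"
        )
    if "videos" in cfg and "roi" not in cfg:
        raise ConfigurationError(
            "config key `roi` is required for video analysis"
        )
    cfg.setdefault("channel", "G")
    cfg.setdefault("window_s", 10.0)
    cfg.setdefault("step_s", 0.5)
    cfg.setdefault("correction", "off")
    cfg.setdefault("train_model1", True)
    return cfg


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(config: Mapping | str | Path) -> dict[str, Path]:
    """Execute analyze -> features -> model stages per a validated config.

    ``config`` is a mapping or a YAML file path.  Artifacts written to
    ``out_dir``: ``hr_estimates.csv``, ``comparison.csv``, ``features.csv``,
    ``targets.csv``, ``predictions.csv`` (when ``train_model1``), and
    ``manifest.json``.  Returns the artifact paths.
    """
    if isinstance(config, (str, Path)):
        import yaml

        config = yaml.safe_load(Path(config).read_text())
    cfg = _validate_config(config)
    out_dir = Path(cfg["out_dir"])
    out_dir.mkdir(parents=True, exist_ok=True)
    seed = int(cfg["seed"])
    band = BandpassSpec(**cfg.get("band", {}))
    artifacts: dict[str, Path] = {}
    checksums: dict[str, str] = {}

    if "study" in cfg:
        study_cfg = dict(cfg["study"] or {})
        study = generate_validation_study(seed=seed, **study_cfg)
        estimates, reference = study_hr_estimates(
            study, band, correction=cfg["correction"]
        )
        comparison = method_comparison_table(estimates, reference)
        features, targets = study_feature_table(study, cfg["channel"], band)
        reference_full = study.reference_table()
    else:
        rois = cfg["roi"]
        if isinstance(rois, (str, Path)):
            rois = read_roi_config(rois)
        est_rows, feat_rows = [], []
        for vid_path in cfg["videos"]:
            vid_path = Path(vid_path)
            checksums[vid_path.name] = _sha256(vid_path) if vid_path.is_file() else "dir"
            seq = load_video(vid_path, fps=cfg.get("fps"))
            per_region: dict[Region, RegionFeatures] = {}
            for region, roi in rois.items():
                trace = extract_channel_trace(
                    crop_region(seq, roi), cfg["channel"], region
                )
                analysis = analyze_trace(
                    trace, band, cfg["window_s"], cfg["step_s"]
                )
                per_region[Region(region)] = summarize_region(
                    analysis.hr_series, analysis.peaks
                )
                est_rows.append(
                    {
                        "video": vid_path.name,
                        "channel": cfg["channel"],
                        "region": Region(region).value,
                        "hr_bpm": analysis.hr_mean,
                    }
                )
            feat_rows.append(assemble_features(per_region))
        estimates = pd.DataFrame(est_rows)
        comparison = None
        features = pd.DataFrame(feat_rows, columns=list(FEATURE_COLUMNS))
        targets = None
        reference_full = None

    artifacts["hr_estimates"] = out_dir / "hr_estimates.csv"
    estimates.to_csv(artifacts["hr_estimates"], index=False)
    artifacts["features"] = out_dir / "features.csv"
    features.to_csv(artifacts["features"], index=False)
    if comparison is not None:
        artifacts["comparison"] = out_dir / "comparison.csv"
        comparison.to_csv(artifacts["comparison"], index=False)
    if targets is not None:
        artifacts["targets"] = out_dir / "targets.csv"
        targets.to_csv(artifacts["targets"], index=False)
    if reference_full is not None:
        artifacts["reference"] = out_dir / "reference.csv"
        reference_full.to_csv(artifacts["reference"], index=False)

    if cfg["train_model1"] and targets is not None:
        model = FeedforwardRegressor(random_state=seed)
        model.fit(features.to_numpy(), targets.to_numpy())
        pred = model.predict(features.to_numpy())
        predictions = pd.DataFrame(
            pred, columns=[f"pred_{c}" for c in TARGET_COLUMNS]
        )
        artifacts["predictions"] = out_dir / "predictions.csv"
        predictions.to_csv(artifacts["predictions"], index=False)

    manifest = {
        "command": "run_pipeline",
        "package_version": __version__,
        "config": {k: v for k, v in cfg.items() if k != "out_dir"},
        "seed": seed,
        "input_checksums": checksums,
        "artifacts": {k: p.name for k, p in artifacts.items()},
        "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
    }
    manifest_path = out_dir / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, default=str))
    artifacts["manifest"] = manifest_path
    return artifacts
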