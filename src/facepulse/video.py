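"""Frame-sequence I/O, face-region cropping, and per-channel luminosity traces.

The pulse signal recoverable from skin video is a sub-integer modulation of
the mean pixel intensity over a region of interest (ROI).  This module reduces
an RGB frame sequence to one scalar per frame per channel: the arithmetic mean
of that channel over the ROI, computed in floating point (the pulsatile
amplitude is far below one 8-bit step, so means must never be rounded).

Channel order is fixed to R, G, B at the API boundary; readers convert from
container-native order.  Pixel coordinates are 0-based with a top-left origin
and half-open extents ``[x, x + width) x [y, y + height)``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from enum import Enum
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import (
    BoundsError,
    ConfigurationError,
    DecodeError,
    EmptyInputError,
)

CHANNELS = ("R", "G", "B")

_FRAME_SUFFIXES = (".png", ".tif", ".tiff", ".bmp", ".jpg", ".jpeg")


class Region(str, Enum):
    """The three face regions with high surface blood flow."""

    FOREHEAD = "forehead"
    RIGHT_CHEEK = "right_cheek"
    LEFT_CHEEK = "left_cheek"


@dataclass(frozen=True)
class FrameSequence:
    """An ordered stack of RGB frames with a fixed frame rate.

    Attributes
    ----------
    frames : ndarray of shape (n_frames, height, width, 3), uint8
        Channel order R, G, B.
    fps : float
        Frames per second; must be positive.
    """

    frames: np.ndarray
    fps: float

    def __post_init__(self) -> None:
        frames = np.asarray(self.frames)
        if frames.ndim != 4 or frames.shape[-1] != 3:
            raise ValueError(
                f"frames must have shape (n, H, W, 3); got {frames.shape}"
            )
        if self.fps <= 0:
            raise ValueError(f"fps must be positive; got {self.fps}")
        object.__setattr__(self, "frames", frames)

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def height(self) -> int:
        return self.frames.shape[1]

    @property
    def width(self) -> int:
        return self.frames.shape[2]

    @property
    def duration_s(self) -> float:
        return self.n_frames / self.fps


@dataclass(frozen=True)
class ROIRectangle:
    """A rectangular ROI: 0-based top-left corner plus extents in pixels."""

    region: Region
    x: int
    y: int
    width: int
    height: int

    def __post_init__(self) -> None:
        object.__setattr__(self, "region", Region(self.region))
        if self.width < 8 or self.height < 8:
            raise ValueError("ROI extents must be at least 8x8 pixels")
        if self.x < 0 or self.y < 0:
            raise ValueError("ROI origin must be non-negative")


@dataclass(frozen=True)
class ChannelTrace:
    """Per-frame mean intensity of one RGB channel over one face region."""

    values: np.ndarray
    channel: str
    region: Region
    fps: float

    def __post_init__(self) -> None:
        if self.channel not in CHANNELS:
            raise ValueError(f"channel must be one of {CHANNELS}")
        object.__setattr__(self, "region", Region(self.region))
        object.__setattr__(
            self, "values", np.asarray(self.values, dtype=float)
        )

    def __len__(self) -> int:
        return len(self.values)

    @property
    def times_s(self) -> np.ndarray:
        return np.arange(len(self.values)) / self.fps

    def to_frame(self) -> pd.DataFrame:
        """Tidy representation: columns time_s, region, channel, value."""
        return pd.DataFrame(
            {
                "time_s": self.times_s,
                "region": self.region.value,
                "channel": self.channel,
                "value": self.values,
            }
        )


def load_video(path: str | Path, fps: float | None = None) -> FrameSequence:
    """Read a frame sequence from disk.

    Supported layouts, tried in order:

    * a directory of per-frame images (sorted by filename) — the lossless
      fixture format, free of codec quantization;
    * a multi-page TIFF stack;
    * a ``.npy`` array of shape (n, H, W, 3);
    * any container imageio can decode (MP4/AVI), when a codec plugin is
      installed.

    The frame rate is read from a JSON sidecar (``<path>.json`` or
    ``meta.json`` inside a frame directory, key ``"fps"``) unless ``fps``
    overrides it.

    Raises
    ------
    DecodeError
        Unreadable or empty input, or fewer than 2 frames.
    ConfigurationError
        No fps metadata found and no override given.
    """
    path = Path(path)
    if not path.exists():
        raise DecodeError(f"no such file or directory: {path}")

    frames = _read_frames(path)
    if frames.shape[0] < 2:
        raise DecodeError(f"{path}: fewer than 2 frames")
    if frames.ndim == 3:  # grayscale stack -> replicate to RGB
        frames = np.repeat(frames[..., None], 3, axis=-1)
    if frames.shape[-1] == 4:  # drop alpha
        frames = frames[..., :3]

    if fps is None:
        fps = _sidecar_fps(path)
    if fps is None:
        raise ConfigurationError(
            f"{path}: no fps metadata; pass fps= or provide a JSON sidecar"
        )
    return FrameSequence(frames=frames, fps=float(fps))


def _read_frames(path: Path) -> np.ndarray:
    import imageio.v3 as iio

    try:
        if path.is_dir():
            files = sorted(
                p for p in path.iterdir() if p.suffix.lower() in _FRAME_SUFFIXES
            )
            if not files:
                raise DecodeError(f"{path}: no frame images found")
            return np.stack([iio.imread(f) for f in files])
        if path.suffix.lower() == ".npy":
            return np.load(path)
        if path.suffix.lower() in (".tif", ".tiff"):
            import tifffile

            return np.asarray(tifffile.imread(path))
        return np.asarray(iio.imread(path))
    except DecodeError:
        raise
    except Exception as exc:  # codec/IO failures surface as DecodeError
        raise DecodeError(f"could not decode {path}: {exc}") from exc


def _sidecar_fps(path: Path) -> float | None:
    candidates = [path.with_suffix(path.suffix + ".json")]
    if path.is_dir():
        candidates.append(path / "meta.json")
    for cand in candidates:
        if cand.exists():
            meta = json.loads(cand.read_text())
            if "fps" in meta:
                return float(meta["fps"])
    try:
        import imageio.v3 as iio

        meta = iio.immeta(path)
        if meta.get("fps"):
            return float(meta["fps"])
    except Exception:
        pass
    return None


def write_frames(seq: FrameSequence, path: str | Path) -> Path:
    """Write a frame sequence as a lossless PNG stack with an fps sidecar."""
    import imageio.v3 as iio

    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    for i, frame in enumerate(seq.frames):
        iio.imwrite(path / f"frame_{i:06d}.png", frame)
    (path / "meta.json").write_text(json.dumps({"fps": seq.fps}))
    return path


def crop_region(seq: FrameSequence, roi: ROIRectangle) -> FrameSequence:
    """Crop every frame to the ROI rectangle; fps and frame count unchanged."""
    if roi.x + roi.width > seq.width or roi.y + roi.height > seq.height:
        raise BoundsError(
            f"ROI {roi.region.value} [{roi.x}:{roi.x + roi.width}, "
            f"{roi.y}:{roi.y + roi.height}] exceeds frame "
            f"{seq.width}x{seq.height}"
        )
    cropped = seq.frames[:, roi.y : roi.y + roi.height, roi.x : roi.x + roi.width, :]
    return FrameSequence(frames=cropped, fps=seq.fps)


def extract_channel_trace(
    seq: FrameSequence,
    channel: str,
    region: Region | str = Region.FOREHEAD,
) -> ChannelTrace:
    """Reduce each frame to the floating-point mean of one channel.

    ``values[t]`` is the arithmetic mean of the chosen channel over all
    pixels of frame ``t``.
    """
    if channel not in CHANNELS:
        raise ValueError(f"channel must be one of {CHANNELS}; got {channel!r}")
    if seq.n_frames == 0:
        raise EmptyInputError("cannot extract a trace from an empty sequence")
    idx = CHANNELS.index(channel)
    values = seq.frames[..., idx].astype(np.float64).mean(axis=(1, 2))
    return ChannelTrace(values=values, channel=channel, region=region, fps=seq.fps)


def read_roi_config(path: str | Path) -> dict[Region, ROIRectangle]:
    """Parse a plain-text ROI config: one ``region x y width height`` per line.

    Lines starting with ``#`` are comments; a header line is tolerated.
    """
    rois: dict[Region, ROIRectangle] = {}
    for raw in Path(path).read_text().splitlines():
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.replace(",", " ").split()
        if parts[0].lower() == "region":
            continue
        if len(parts) != 5:
            raise ConfigurationError(f"bad ROI line: {raw!r}")
        region = Region(parts[0])
        x, y, w, h = (int(p) for p in parts[1:])
        rois[region] = ROIRectangle(region=region, x=x, y=y, width=w, height=h)
    if not rois:
        raise ConfigurationError(f"{path}: no ROI definitions found")
    return rois
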