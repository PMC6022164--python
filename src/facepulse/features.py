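"""Feature summarization, [-1, 1] normalization, and data division.

Each face region contributes six summary features (mean and sample SD of the
sliding HR estimates, of the detected peak amplitudes, and of the inter-peak
distances); the three regions concatenate to the 18-input vector consumed by
the regression model.  Variables are normalized linearly onto [-1, 1] with
recoverable per-variable (min, max) settings, and samples are divided
70/15/15 into training/validation/test by a seeded random permutation.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_array, check_is_fitted

from .errors import (
    AlignmentError,
    DegenerateRangeError,
    InsufficientDataError,
    InsufficientSamplesError,
    MissingRegionError,
)
from .ppg import HRSeries, PeakSet
from .video import Region

#: Per-region feature names, in fixed order.
REGION_FEATURE_NAMES = (
    "hr_mean",
    "hr_sd",
    "amp_mean",
    "amp_sd",
    "dist_mean",
    "dist_sd",
)

#: Region order in the 18-input vector.
REGION_ORDER = (Region.FOREHEAD, Region.RIGHT_CHEEK, Region.LEFT_CHEEK)

#: Column names of the assembled 18-input feature vector.
FEATURE_COLUMNS = tuple(
    f"{region.value}_{name}"
    for region in REGION_ORDER
    for name in REGION_FEATURE_NAMES
)

#: Column names of the reference targets.
TARGET_COLUMNS = ("hr", "sp", "dp")


@dataclass(frozen=True)
class RegionFeatures:
    """Six summary statistics of one region's HR series and beat peaks."""

    hr_mean: float
    hr_sd: float
    amp_mean: float
    amp_sd: float
    dist_mean: float
    dist_sd: float

    def as_array(self) -> np.ndarray:
        return np.array(
            [getattr(self, name) for name in REGION_FEATURE_NAMES]
        )


@dataclass(frozen=True)
class TargetsHRBP:
    """Reference triplet from the contact device: HR (BPM), SP/DP (mmHg)."""

    hr: float
    sp: float
    dp: float

    def __post_init__(self) -> None:
        if not (self.sp > self.dp > 0):
            raise ValueError(f"need sp > dp > 0; got sp={self.sp}, dp={self.dp}")
        if not (30.0 <= self.hr <= 220.0):
            raise ValueError(f"hr {self.hr} outside plausible range [30, 220]")

    def as_array(self) -> np.ndarray:
        return np.array([self.hr, self.sp, self.dp])


def summarize_region(hr: HRSeries, peaks: PeakSet) -> RegionFeatures:
    """Means and sample (n-1) standard deviations of HR, amplitudes, distances.

    Requires at least 2 HR estimates and 3 peaks (2 inter-peak distances).
    """
    if len(hr) < 2:
        raise InsufficientDataError("need >= 2 HR estimates to summarize")
    if peaks.n_peaks < 3:
        raise InsufficientDataError("need >= 3 detected peaks to summarize")
    return RegionFeatures(
        hr_mean=float(np.mean(hr.hr_bpm)),
        hr_sd=float(np.std(hr.hr_bpm, ddof=1)),
        amp_mean=float(np.mean(peaks.amplitudes)),
        amp_sd=float(np.std(peaks.amplitudes, ddof=1)),
        dist_mean=float(np.mean(peaks.distances_s)),
        dist_sd=float(np.std(peaks.distances_s, ddof=1)),
    )


def assemble_features(
    region_features: dict[Region | str, RegionFeatures],
) -> np.ndarray:
    """Concatenate the three regions' features into the fixed-order 18-vector.

    Order: (forehead, right_cheek, left_cheek) x (hr_mean, hr_sd, amp_mean,
    amp_sd, dist_mean, dist_sd).
    """
    normalized = {Region(k): v for k, v in region_features.items()}
    missing = [r.value for r in REGION_ORDER if r not in normalized]
    if missing:
        raise MissingRegionError(f"missing region(s): {', '.join(missing)}")
    return np.concatenate([normalized[r].as_array() for r in REGION_ORDER])


class SymmetricMinMaxScaler(TransformerMixin, BaseEstimator):
    """Linear per-variable map of [min, max] onto [-1, 1], invertible.

    The fitted (min, max) pairs are the recoverable normalization settings
    that let model outputs be mapped back to physical units.  Values outside
    the fitted range extrapolate linearly (beyond +/-1).

    Attributes
    ----------
    data_min_, data_max_ : ndarray of shape (n_features,)
        Per-variable raw range observed during :meth:`fit`.
    """

    def fit(self, X, y=None):
        X = check_array(X, dtype=float, ensure_min_samples=2)
        self.data_min_ = X.min(axis=0)
        self.data_max_ = X.max(axis=0)
        degenerate = np.flatnonzero(self.data_max_ <= self.data_min_)
        if degenerate.size:
            raise DegenerateRangeError(
                f"constant column(s) {degenerate.tolist()}: "
                "the [-1, 1] map is undefined"
            )
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X):
        check_is_fitted(self)
        X = check_array(X, dtype=float)
        span = self.data_max_ - self.data_min_
        return 2.0 * (X - self.data_min_) / span - 1.0

    def inverse_transform(self, X):
        check_is_fitted(self)
        X = check_array(X, dtype=float)
        span = self.data_max_ - self.data_min_
        return (X + 1.0) / 2.0 * span + self.data_min_

    # -- JSON round-trip of the settings ---------------------------------
    def to_dict(self) -> dict:
        check_is_fitted(self)
        return {
            "data_min": self.data_min_.tolist(),
            "data_max": self.data_max_.tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SymmetricMinMaxScaler":
        obj = cls()
        obj.data_min_ = np.asarray(d["data_min"], dtype=float)
        obj.data_max_ = np.asarray(d["data_max"], dtype=float)
        obj.n_features_in_ = len(obj.data_min_)
        return obj

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict()))

    @classmethod
    def load(cls, path: str | Path) -> "SymmetricMinMaxScaler":
        return cls.from_dict(json.loads(Path(path).read_text()))


def fit_normalization(table: np.ndarray) -> SymmetricMinMaxScaler:
    """Fit [-1, 1] normalization settings on a samples-by-variables table."""
    return SymmetricMinMaxScaler().fit(np.asarray(table, dtype=float))


def split_counts(n: int, ratios: tuple[float, float, float] = (0.70, 0.15, 0.15)):
    """Training/validation/test sample counts for the random data division.

    The validation and test partitions each get ``round(0.15 * n)`` samples;
    training takes the remainder, so the three counts always sum to ``n``
    (e.g. 45 -> 31/7/7 and 10984 -> 7688/1648/1648).
    """
    if n < 10:
        raise InsufficientSamplesError(f"need n >= 10 for a 70/15/15 split; got {n}")
    val = int(round(n * ratios[1]))
    test = int(round(n * ratios[2]))
    train = n - val - test
    return train, val, test


def split_indices(n: int, rng: np.random.Generator | int | None = None):
    """Seeded random permutation partitioned per :func:`split_counts`.

    Returns (train_idx, val_idx, test_idx) index arrays.
    """
    train, val, test = split_counts(n)
    rng = np.random.default_rng(rng)
    perm = rng.permutation(n)
    return perm[:train], perm[train : train + val], perm[train + val :]


def build_secondwise_inputs(
    hr: dict[Region | str, HRSeries],
    magnitude: dict[Region | str, np.ndarray],
    luminosity: dict[Region | str, np.ndarray],
) -> pd.DataFrame:
    """Per-second rows of (hr, magnitude, luminosity) x 3 regions (9 columns).

    HR series at 0.5 s cadence are resampled to 1 s by keeping every 2nd
    value; all three per-region series must then agree in length.
    """
    cols: dict[str, np.ndarray] = {}
    n_rows: int | None = None
    for region in REGION_ORDER:
        series = _get(hr, region)
        if series.step_s == 0.5:
            series = series.resample_1s()
        mag = np.asarray(_get(magnitude, region), dtype=float)
        lum = np.asarray(_get(luminosity, region), dtype=float)
        m = min(len(series), len(mag), len(lum))
        if n_rows is None:
            n_rows = m
        elif m != n_rows:
            raise AlignmentError(
                f"region {region.value} has {m} usable rows; expected {n_rows}"
            )
        cols[f"{region.value}_hr"] = series.hr_bpm[:m]
        cols[f"{region.value}_magnitude"] = mag[:m]
        cols[f"{region.value}_luminosity"] = lum[:m]
    return pd.DataFrame(cols)


def _get(mapping, region: Region):
    normalized = {Region(k): v for k, v in mapping.items()}
    if region not in normalized:
        raise MissingRegionError(f"missing region: {region.value}")
    return normalized[region]
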