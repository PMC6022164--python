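"""Validation statistics: Pearson linear fits and correlation matrices.

Agreement between the video-derived HR and a contact reference is judged by
the Pearson linear fit y = ax + b, reported as R^2, RMSE of the residuals,
and a two-sided p-value for slope != 0 (t statistic, n - 2 degrees of
freedom).  Per-channel x per-region comparison tables and significance-
masked correlation matrices (alpha = 0.05, no multiple-testing correction by
default, optional Benjamini-Hochberg) support study-level reporting.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sstats

from .errors import DegenerateFitError
from .video import Region

__all__ = [
    "FitStatistics",
    "CorrelationMatrix",
    "pearson_fit",
    "method_comparison_table",
    "correlation_matrix",
]


@dataclass(frozen=True)
class FitStatistics:
    """Pearson linear fit y = ax + b with its quality diagnostics."""

    slope: float
    intercept: float
    r_squared: float
    rmse: float
    p_value: float
    n: int


def pearson_fit(x, y) -> FitStatistics:
    """Least-squares line y = ax + b with R^2, residual RMSE and slope p.

    Requires n >= 3 aligned points and non-constant x.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError(f"x and y lengths differ: {x.shape} vs {y.shape}")
    if len(x) < 3:
        raise ValueError(f"need >= 3 points for a linear fit; got {len(x)}")
    if np.std(x) == 0:
        raise DegenerateFitError("x has zero variance; the fit is undefined")
    res = sstats.linregress(x, y)
    residuals = y - (res.slope * x + res.intercept)
    return FitStatistics(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue**2),
        rmse=float(np.sqrt(np.mean(residuals**2))),
        p_value=float(res.pvalue),
        n=len(x),
    )


def method_comparison_table(
    estimates: pd.DataFrame, reference: pd.DataFrame
) -> pd.DataFrame:
    """Per-(channel, region) linear fits of video HR against reference HR.

    Parameters
    ----------
    estimates : DataFrame with columns ``video``, ``channel``, ``region``,
        ``hr_bpm`` — one row per analyzed video per channel per region.
    reference : DataFrame with columns ``video``, ``hr_bpm`` — the contact-
        device HR per video.

    Returns a tidy table with one row per (channel, region) cell (9 cells
    for 3 channels x 3 regions) carrying the :class:`FitStatistics` fields;
    cells with fewer than 3 paired videos are reported with NaN statistics
    rather than failing.
    """
    ref = reference.set_index("video")["hr_bpm"]
    rows = []
    for channel in ("R", "G", "B"):
        for region in Region:
            cell = estimates[
                (estimates["channel"] == channel)
                & (estimates["region"] == region.value)
            ]
            paired = cell.set_index("video")["hr_bpm"].to_frame("est")
            paired["ref"] = ref
            paired = paired.dropna()
            row: dict = {"channel": channel, "region": region.value}
            if len(paired) >= 3 and np.std(paired["ref"]) > 0:
                fit = pearson_fit(paired["ref"], paired["est"])
                row.update(
                    slope=fit.slope,
                    intercept=fit.intercept,
                    r_squared=fit.r_squared,
                    rmse=fit.rmse,
                    p_value=fit.p_value,
                    n=fit.n,
                )
            else:
                row.update(
                    slope=np.nan, intercept=np.nan, r_squared=np.nan,
                    rmse=np.nan, p_value=np.nan, n=len(paired),
                )
            rows.append(row)
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class CorrelationMatrix:
    """Pairwise Pearson correlations with a significance mask."""

    variables: tuple[str, ...]
    r: pd.DataFrame
    p: pd.DataFrame
    significant: pd.DataFrame
    alpha: float


def correlation_matrix(
    table: pd.DataFrame,
    alpha: float = 0.05,
    bh_correction: bool = False,
) -> CorrelationMatrix:
    """Pairwise Pearson r and p over named columns, masked at ``alpha``.

    Rows with missing values are dropped pairwise.  Constant columns yield
    NaN in their row/column (with a warning) rather than failing.  When
    ``bh_correction`` is set, the off-diagonal p-values are
    Benjamini-Hochberg adjusted before masking; the default is the raw
    per-pair test.
    """
    if table.shape[0] < 4:
        raise ValueError(f"need >= 4 rows; got {table.shape[0]}")
    if table.shape[1] < 2:
        raise ValueError(f"need >= 2 columns; got {table.shape[1]}")
    cols = tuple(table.columns)
    k = len(cols)
    r = np.eye(k)
    p = np.zeros((k, k))
    import warnings

    for i in range(k):
        for j in range(i + 1, k):
            pair = table.iloc[:, [i, j]].dropna()
            x, y = pair.iloc[:, 0].to_numpy(float), pair.iloc[:, 1].to_numpy(float)
            if len(pair) < 3 or np.std(x) == 0 or np.std(y) == 0:
                warnings.warn(
                    f"correlation undefined for ({cols[i]}, {cols[j]})"
                )
                r[i, j] = r[j, i] = np.nan
                p[i, j] = p[j, i] = np.nan
                continue
            res = sstats.pearsonr(x, y)
            r[i, j] = r[j, i] = res.statistic
            p[i, j] = p[j, i] = res.pvalue
    if bh_correction:
        iu = np.triu_indices(k, 1)
        pvals = p[iu]
        finite = np.isfinite(pvals)
        adj = np.full_like(pvals, np.nan)
        if finite.any():
            adj[finite] = _benjamini_hochberg(pvals[finite])
        p_adj = np.eye(k) * 0.0
        p_adj[iu] = adj
        p_adj = p_adj + p_adj.T
        np.fill_diagonal(p_adj, 0.0)
        p = p_adj
    r_df = pd.DataFrame(r, index=cols, columns=cols)
    p_df = pd.DataFrame(p, index=cols, columns=cols)
    with np.errstate(invalid="ignore"):
        mask = p_df < alpha
    np.fill_diagonal(mask.values, True)
    return CorrelationMatrix(
        variables=cols, r=r_df, p=p_df, significant=mask, alpha=alpha
    )


def _benjamini_hochberg(pvals: np.ndarray) -> np.ndarray:
    order = np.argsort(pvals)
    m = len(pvals)
    adj = np.empty(m)
    running = 1.0
    for rank_idx in range(m - 1, -1, -1):
        i = order[rank_idx]
        running = min(running, pvals[i] * m / (rank_idx + 1))
        adj[i] = running
    return adj
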