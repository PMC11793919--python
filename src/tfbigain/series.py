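"""Data model for incomplete, irregularly sampled multivariate time series.

A sequence is a features-by-time value matrix (D x T) with NaN marking missing
entries, a binary mask (1 = observed), and a strictly increasing timestamp
vector starting at 0. Because sampling is irregular, the elapsed time since
the most recent observation of each feature (and, running time backwards,
until the next one) carries real information; the forward/backward time-lag
matrices record it and drive the decay mechanism of the GRUI cell.

Time-lag recursions, per feature d (1-based time index i):

    forward:  d[d,1] = 0;  d[d,i] = t_i - t_{i-1}            if feature d was
                                                              observed at i-1,
                           d[d,i] = d[d,i-1] + t_i - t_{i-1}  otherwise.
    backward: mirror image anchored at i = T.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "IncompleteSeries",
    "TimeLagPair",
    "SeriesScaler",
    "build_mask",
    "forward_time_lag",
    "backward_time_lag",
    "time_lags",
    "reverse_time",
    "standardize",
    "as_series_list",
    "read_series_csv",
    "write_series_csv",
    "read_dataset",
    "write_dataset",
]

TIME_COLUMN = "time"
SEQUENCE_COLUMN = "sequence_id"


def _validate_timestamps(timestamps: np.ndarray, n_timesteps: int) -> np.ndarray:
    t = np.asarray(timestamps, dtype=float).ravel()
    if t.shape[0] != n_timesteps:
        raise ValueError(
            f"timestamp length {t.shape[0]} does not match T={n_timesteps}"
        )
    if t[0] != 0.0:
        raise ValueError("timestamps must start at 0 (re-zero before building)")
    if n_timesteps > 1 and not np.all(np.diff(t) > 0):
        raise ValueError("timestamps must be strictly increasing")
    return t


def build_mask(values) -> np.ndarray:
    """Binary observation mask: 1 where finite, 0 where missing (NaN)."""
    values = np.asarray(values, dtype=float)
    if values.ndim != 2 or values.size == 0:
        raise ValueError("values must be a non-empty D x T matrix")
    return np.isfinite(values).astype(np.int8)


@dataclass
class IncompleteSeries:
    """One multivariate sequence with missing entries.

    Attributes
    ----------
    values : (D, T) float array, NaN at missing positions.
    mask : (D, T) int array, 1 = observed.
    timestamps : (T,) float array, strictly increasing, first element 0.
    feature_names : optional list of D names.
    """

    values: np.ndarray
    mask: np.ndarray = None
    timestamps: np.ndarray = None
    feature_names: list | None = None

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.size == 0:
            raise ValueError("values must be a non-empty D x T matrix")
        D, T = self.values.shape
        if self.mask is None:
            self.mask = build_mask(self.values)
        self.mask = np.asarray(self.mask, dtype=np.int8)
        if self.mask.shape != (D, T):
            raise ValueError("mask shape must equal values shape")
        expected = build_mask(self.values)
        if not np.array_equal(self.mask, expected):
            raise ValueError("mask inconsistent with NaN pattern of values")
        if self.timestamps is None:
            self.timestamps = np.arange(T, dtype=float)
        self.timestamps = _validate_timestamps(self.timestamps, T)
        if self.feature_names is not None and len(self.feature_names) != D:
            raise ValueError("feature_names length must equal D")

    @property
    def n_features(self) -> int:
        return self.values.shape[0]

    @property
    def n_timesteps(self) -> int:
        return self.values.shape[1]

    def lags(self) -> "TimeLagPair":
        return time_lags(self.mask, self.timestamps)

    def copy(self) -> "IncompleteSeries":
        return IncompleteSeries(
            self.values.copy(),
            self.mask.copy(),
            self.timestamps.copy(),
            None if self.feature_names is None else list(self.feature_names),
        )


@dataclass
class TimeLagPair:
    """Forward (since last observation) and backward (until next) lag matrices."""

    delta_f: np.ndarray
    delta_b: np.ndarray

    def __post_init__(self):
        self.delta_f = np.asarray(self.delta_f, dtype=float)
        self.delta_b = np.asarray(self.delta_b, dtype=float)
        if self.delta_f.shape != self.delta_b.shape:
            raise ValueError("delta_f and delta_b must share a shape")
        if (self.delta_f < 0).any() or (self.delta_b < 0).any():
            raise ValueError("time lags must be nonnegative")


def _check_lag_inputs(mask, timestamps):
    mask = np.asarray(mask)
    if mask.ndim != 2 or mask.size == 0:
        raise ValueError("mask must be a non-empty D x T matrix")
    t = _validate_timestamps(timestamps, mask.shape[1])
    return mask, t


def forward_time_lag(mask, timestamps) -> np.ndarray:
    """Elapsed time since the previous observation of each feature."""
    mask, t = _check_lag_inputs(mask, timestamps)
    D, T = mask.shape
    delta = np.zeros((D, T), dtype=float)
    for i in range(1, T):
        gap = t[i] - t[i - 1]
        delta[:, i] = np.where(mask[:, i - 1] == 1, gap, delta[:, i - 1] + gap)
    return delta


def backward_time_lag(mask, timestamps) -> np.ndarray:
    """Elapsed time until the next observation of each feature."""
    mask, t = _check_lag_inputs(mask, timestamps)
    D, T = mask.shape
    delta = np.zeros((D, T), dtype=float)
    for i in range(T - 2, -1, -1):
        gap = t[i + 1] - t[i]
        delta[:, i] = np.where(mask[:, i + 1] == 1, gap, delta[:, i + 1] + gap)
    return delta


def time_lags(mask, timestamps) -> TimeLagPair:
    return TimeLagPair(
        forward_time_lag(mask, timestamps), backward_time_lag(mask, timestamps)
    )


def reverse_time(series: IncompleteSeries) -> IncompleteSeries:
    """Reflect a series in time: columns reversed, timestamps re-anchored at 0."""
    t = series.timestamps
    new_t = t[-1] - t[::-1]
    return IncompleteSeries(
        series.values[:, ::-1].copy(),
        series.mask[:, ::-1].copy(),
        new_t.copy(),
        series.feature_names,
    )


class SeriesScaler:
    """Per-feature z-scoring over observed entries of a dataset.

    Follows the fit/transform/inverse_transform convention; statistics are
    pooled across sequences, features with zero spread get unit scale so the
    transform is always invertible.
    """

    def fit(self, dataset: Sequence[IncompleteSeries]) -> "SeriesScaler":
        dataset = list(dataset)
        if not dataset:
            raise ValueError("cannot fit scaler on an empty dataset")
        D = dataset[0].n_features
        sums = np.zeros(D)
        sqsums = np.zeros(D)
        counts = np.zeros(D)
        for s in dataset:
            if s.n_features != D:
                raise ValueError("all sequences must share the feature set")
            obs = s.mask == 1
            vals = np.where(obs, s.values, 0.0)
            sums += vals.sum(axis=1)
            sqsums += (vals**2).sum(axis=1)
            counts += obs.sum(axis=1)
        empty = np.flatnonzero(counts == 0)
        if empty.size:
            names = (
                [dataset[0].feature_names[i] for i in empty]
                if dataset[0].feature_names is not None
                else list(empty)
            )
            raise ValueError(f"features with no observed entries: {names}")
        self.means_ = sums / counts
        var = sqsums / counts - self.means_**2
        scales = np.sqrt(np.maximum(var, 0.0))
        self.scales_ = np.where(scales > 0, scales, 1.0)
        self.n_features_in_ = D
        return self

    def _check(self, series: IncompleteSeries):
        if not hasattr(self, "means_"):
            raise ValueError("scaler is not fitted")
        if series.n_features != self.n_features_in_:
            raise ValueError("feature count differs from the fitted dataset")

    def transform(self, series: IncompleteSeries) -> IncompleteSeries:
        self._check(series)
        vals = (series.values - self.means_[:, None]) / self.scales_[:, None]
        vals[series.mask == 0] = np.nan
        return IncompleteSeries(
            vals, series.mask.copy(), series.timestamps.copy(), series.feature_names
        )

    def transform_dataset(self, dataset) -> list:
        return [self.transform(s) for s in dataset]

    def inverse_transform_values(self, values: np.ndarray) -> np.ndarray:
        """Map a (D, T) matrix in standardized units back to original units."""
        if not hasattr(self, "means_"):
            raise ValueError("scaler is not fitted")
        return values * self.scales_[:, None] + self.means_[:, None]


def standardize(dataset: Iterable[IncompleteSeries]):
    """Z-score observed entries per feature; returns (dataset, fitted scaler)."""
    dataset = list(dataset)
    scaler = SeriesScaler().fit(dataset)
    return scaler.transform_dataset(dataset), scaler


def as_series_list(X, timestamps=None) -> list:
    """Coerce estimator input into a list of IncompleteSeries.

    Accepts a list of IncompleteSeries, a list of (D, T) arrays with NaN for
    missing, or one 3-D array of shape (n_sequences, D, T). `timestamps` may
    be a single shared vector or a per-sequence list.
    """
    if isinstance(X, IncompleteSeries):
        X = [X]
    if isinstance(X, np.ndarray):
        if X.ndim != 3:
            raise ValueError("array input must be 3-D (n_sequences, D, T)")
        X = list(X)
    out = []
    for i, item in enumerate(X):
        if isinstance(item, IncompleteSeries):
            out.append(item)
            continue
        ts = None
        if timestamps is not None:
            ts = (
                timestamps[i]
                if isinstance(timestamps, (list, tuple))
                else timestamps
            )
        out.append(IncompleteSeries(np.asarray(item, dtype=float), timestamps=ts))
    if not out:
        raise ValueError("empty dataset")
    return out


# ---- wide-CSV interchange ------------------------------------------------
#
# One sequence = one wide CSV: one row per timestamp, an optional leading
# "time" column, one column per feature, empty cells meaning missing.
# Multi-sequence datasets are either a directory of such files or a single
# long CSV carrying a "sequence_id" column.


def _frame_to_series(df: pd.DataFrame) -> IncompleteSeries:
    if TIME_COLUMN in df.columns:
        t = df[TIME_COLUMN].to_numpy(dtype=float)
        t = t - t[0]  # re-anchor so the first observation is time 0
        df = df.drop(columns=[TIME_COLUMN])
    else:
        t = None
    values = df.to_numpy(dtype=float).T  # wide rows are timestamps -> D x T
    return IncompleteSeries(values, timestamps=t, feature_names=list(df.columns))


def read_series_csv(path) -> IncompleteSeries:
    return _frame_to_series(pd.read_csv(path))


def write_series_csv(series: IncompleteSeries, path) -> None:
    names = series.feature_names or [f"f{i}" for i in range(series.n_features)]
    df = pd.DataFrame(series.values.T, columns=names)
    df.insert(0, TIME_COLUMN, series.timestamps)
    df.to_csv(path, index=False)


def read_dataset(path) -> list:
    """Read a dataset from a directory of wide CSVs or one long CSV."""
    path = Path(path)
    if path.is_dir():
        files = sorted(path.glob("*.csv"))
        if not files:
            raise ValueError(f"no .csv files under {path}")
        return [read_series_csv(f) for f in files]
    df = pd.read_csv(path)
    if SEQUENCE_COLUMN not in df.columns:
        return [_frame_to_series(df)]
    out = []
    for _, group in df.groupby(SEQUENCE_COLUMN, sort=True):
        out.append(_frame_to_series(group.drop(columns=[SEQUENCE_COLUMN]).reset_index(drop=True)))
    return out


def write_dataset(dataset: Sequence[IncompleteSeries], path, long_format=False) -> None:
    path = Path(path)
    if long_format or path.suffix == ".csv":
        frames = []
        for i, s in enumerate(dataset):
            names = s.feature_names or [f"f{j}" for j in range(s.n_features)]
            df = pd.DataFrame(s.values.T, columns=names)
            df.insert(0, TIME_COLUMN, s.timestamps)
            df.insert(0, SEQUENCE_COLUMN, i)
            frames.append(df)
        pd.concat(frames, ignore_index=True).to_csv(path, index=False)
    else:
        path.mkdir(parents=True, exist_ok=True)
        width = len(str(max(len(dataset) - 1, 1)))
        for i, s in enumerate(dataset):
            write_series_csv(s, path / f"seq_{i:0{width}d}.csv")
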