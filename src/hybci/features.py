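"""Per-channel trial statistics and feature-table assembly.

Seven statistics are computed per channel per trial: mean, maximum, slope,
variance, skewness, kurtosis, and median.  Conventions:

* variance uses the N-1 denominator;
* skewness and kurtosis are the third and fourth standardized moments with
  the population (biased) standard deviation in the denominator, and the
  kurtosis is NOT excess (no -3);
* slope is the least-squares linear-fit slope over the full epoch, in
  amplitude units per second (a windowed variant - the mean of per-window
  regression slopes - is available via ``slope_window``);
* a constant channel yields skewness = kurtosis = 0 with a warning rather
  than an error, so degenerate all-zero channels do not abort a run.

Tables are assembled channel-major (all 7 features of channel 1, then
channel 2, ...), one row per trial, with the class label kept alongside.
With the reference geometry this gives 36*7 = 252 feature columns for HbO
or HbR, 32*7 = 224 for EEG, 476 for EEG+HbO / EEG+HbR and 504 for HbO+HbR.
"""

from __future__ import annotations

import dataclasses
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .epochs import EpochSet
from .errors import ShapeError

__all__ = [
    "FEATURE_NAMES",
    "FeatureTable",
    "channel_features",
    "build_table",
    "combine_tables",
]

FEATURE_NAMES = ("mean", "max", "slope", "var", "skew", "kurt", "median")


@dataclass
class FeatureTable:
    """Observations x features matrix with per-row class labels."""

    X: np.ndarray
    y: np.ndarray
    names: list[str]
    name: str = ""

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.y = np.asarray(self.y, dtype=int)
        if self.X.ndim != 2:
            raise ShapeError("X must be 2-D")
        if self.X.shape[0] != len(self.y):
            raise ShapeError("one label per row required")
        if self.X.shape[1] != len(self.names):
            raise ShapeError("one name per feature column required")

    @property
    def n_obs(self) -> int:
        return self.X.shape[0]

    @property
    def n_features(self) -> int:
        return self.X.shape[1]

    def replace(self, **kw) -> "FeatureTable":
        return dataclasses.replace(self, **kw)

    def subset(self, idx) -> "FeatureTable":
        return self.replace(X=self.X[idx], y=self.y[idx])

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(self.X, columns=self.names)
        df["label"] = self.y
        return df

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, name: str = "") -> "FeatureTable":
        if "label" not in df.columns:
            raise ShapeError('feature table requires a "label" column')
        names = [c for c in df.columns if c != "label"]
        return cls(X=df[names].to_numpy(float), y=df["label"].to_numpy(int),
                   names=names, name=name)

    @classmethod
    def vstack(cls, tables) -> "FeatureTable":
        tables = list(tables)
        first = tables[0]
        for t in tables[1:]:
            if t.names != first.names:
                raise ShapeError("cannot stack tables with different features")
        return cls(
            X=np.vstack([t.X for t in tables]),
            y=np.concatenate([t.y for t in tables]),
            names=list(first.names), name=first.name,
        )


def _moments(data: np.ndarray, fs: float, slope_window: float | None):
    """Feature block for a trials x channels x samples array.

    Returns an array of shape ``(trials, channels, 7)`` in the canonical
    feature order.
    """
    n = data.shape[-1]
    mean = data.mean(axis=-1)
    mx = data.max(axis=-1)
    med = np.median(data, axis=-1)
    var = data.var(axis=-1, ddof=1)
    centered = data - mean[..., None]
    m2 = (centered ** 2).mean(axis=-1)
    m3 = (centered ** 3).mean(axis=-1)
    m4 = (centered ** 4).mean(axis=-1)
    degenerate = m2 == 0
    if np.any(degenerate):
        warnings.warn(
            "constant channel(s) encountered; skewness/kurtosis set to 0",
            RuntimeWarning, stacklevel=3,
        )
    safe_m2 = np.where(degenerate, 1.0, m2)
    skew = np.where(degenerate, 0.0, m3 / safe_m2 ** 1.5)
    kurt = np.where(degenerate, 0.0, m4 / safe_m2 ** 2)
    slope = _slope(data, centered, fs, slope_window)
    return np.stack([mean, mx, slope, var, skew, kurt, med], axis=-1)


def _regression_slope(centered: np.ndarray, fs: float) -> np.ndarray:
    n = centered.shape[-1]
    t = np.arange(n) / fs
    tc = t - t.mean()
    denom = (tc ** 2).sum()
    return (centered * tc).sum(axis=-1) / denom


def _slope(data, centered, fs, slope_window):
    if slope_window is None:
        return _regression_slope(centered, fs)
    w = round(slope_window * fs)
    if w < 2:
        raise ShapeError(f"slope window {slope_window}s too short at fs={fs}")
    n = data.shape[-1]
    slopes = []
    for start in range(0, n - w + 1, w):
        seg = data[..., start:start + w]
        slopes.append(_regression_slope(seg - seg.mean(-1, keepdims=True), fs))
    return np.mean(slopes, axis=0)


def channel_features(x, fs: float = 1.0,
                     slope_window: float | None = None) -> np.ndarray:
    """The 7-vector (mean, max, slope, var, skew, kurt, median) of a series."""
    x = np.asarray(x, dtype=float)
    if x.ndim != 1 or len(x) < 3:
        raise ShapeError("channel_features requires a 1-D series of length >= 3")
    return _moments(x[None, None, :], fs, slope_window)[0, 0]


def build_table(epochs: EpochSet, name: str | None = None,
                slope_window: float | None = None) -> FeatureTable:
    """Assemble the channel-major feature table of an epoch set.

    One row per trial; columns ``ch{c}_{feature}`` with all seven features
    of channel 1 first, then channel 2, and so on.
    """
    if epochs.n_trials == 0:
        raise ShapeError("cannot build a feature table from an empty EpochSet")
    if epochs.n_samples < 3:
        raise ShapeError("epochs must have at least 3 samples")
    block = _moments(epochs.data, epochs.fs, slope_window)  # (T, C, 7)
    X = block.reshape(epochs.n_trials, epochs.n_channels * len(FEATURE_NAMES))
    names = [f"ch{c + 1}_{f}" for c in range(epochs.n_channels)
             for f in FEATURE_NAMES]
    return FeatureTable(X=X, y=epochs.labels.copy(), names=names,
                        name=name if name is not None else epochs.modality)


def combine_tables(a: FeatureTable, b: FeatureTable) -> FeatureTable:
    """Horizontally concatenate two feature tables over the same trials.

    Row counts, label vectors, and hence trial ordering must match exactly;
    a mismatch signals a trial-alignment bug upstream.  Column names are
    prefixed with each source's provenance tag to stay unique.
    """
    if b.n_features == 0:
        return a.replace()
    if a.n_features == 0:
        return b.replace()
    if a.n_obs != b.n_obs:
        raise ShapeError(f"row counts differ: {a.n_obs} vs {b.n_obs}")
    if not np.array_equal(a.y, b.y):
        raise ShapeError(
            "label vectors differ between tables; trial ordering is broken"
        )
    tag_a = a.name or "a"
    tag_b = b.name or "b"
    return FeatureTable(
        X=np.hstack([a.X, b.X]),
        y=a.y.copy(),
        names=[f"{tag_a}_{n}" for n in a.names] + [f"{tag_b}_{n}" for n in b.names],
        name=f"{tag_a}+{tag_b}",
    )
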