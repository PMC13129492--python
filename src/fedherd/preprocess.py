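"""Sensor-stream preprocessing: filling, screening, scaling, features, labels, windows.

The pipeline an edge client applies to its raw table, in order:

1. :func:`fill_missing` — per-animal forward fill then backward fill of
   the physiological channels (values carried verbatim, never
   interpolated).
2. :func:`remove_outliers` — drop whole rows whose heart rate, body
   temperature or activity sits more than ``z_max`` (default 3)
   population standard deviations from the table mean.
3. :func:`generate_labels` — proxy stress label from raw units:
   ``is_stressed = 1`` iff heart_rate > 100 bpm OR body_temp > 39.5 °C
   (strict). Thresholds are only meaningful before scaling, so this must
   run on raw values; a guard trips if it sees already-normalized data.
4. :func:`add_rolling_features` — trailing (causal) 30-minute rolling
   mean of heart rate and temperature and rolling population variance of
   activity, per animal.
5. :func:`normalize_minmax` — min–max scale the model-input features to
   [0, 1]; bounds are learned on training data, frozen, and re-applied
   (with clipping) at inference.
6. :func:`make_windows` — fixed-length sliding windows per animal; the
   window label is its final row's label.

GPS coordinates are carried through but excluded from the model-input
feature set.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConfigError, DataError, GuardError
from .synthetic import PHYSIO_FEATURES

logger = logging.getLogger("fedherd.preprocess")

__all__ = [
    "MODEL_FEATURES",
    "ROLLING_FEATURES",
    "PreprocessConfig",
    "FeatureBounds",
    "WindowedDataset",
    "fill_missing",
    "remove_outliers",
    "generate_labels",
    "normalize_minmax",
    "add_rolling_features",
    "make_windows",
    "preprocess_table",
]

#: Rolling-feature columns appended by :func:`add_rolling_features`.
ROLLING_FEATURES = ["hr_roll_mean", "temp_roll_mean", "activity_roll_var"]

#: Default model-input feature set (GPS excluded).
MODEL_FEATURES = [
    "heart_rate",
    "body_temp",
    "activity_level",
    "ambient_temp",
    "humidity",
] + ROLLING_FEATURES


@dataclass
class PreprocessConfig:
    z_max: float = 3.0
    hr_threshold: float = 100.0        # bpm
    temp_threshold: float = 39.5       # °C
    rolling_window_minutes: float = 30.0
    outlier_features: tuple[str, ...] = tuple(PHYSIO_FEATURES)

    def validate(self) -> None:
        if self.z_max <= 0:
            raise ConfigError("z_max must be > 0")
        if self.hr_threshold <= 0 or self.temp_threshold <= 0:
            raise ConfigError("stress thresholds must be positive")
        if self.rolling_window_minutes <= 0:
            raise ConfigError("rolling_window_minutes must be > 0")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["outlier_features"] = list(self.outlier_features)
        return d


class FeatureBounds:
    """Frozen per-feature (min, max) used by min–max scaling.

    Learned on training data only and shipped with the model; inference
    values outside the bounds are clipped into [0, 1].
    """

    def __init__(self, bounds: dict[str, tuple[float, float]]):
        for name, (lo, hi) in bounds.items():
            if hi < lo:
                raise ConfigError(f"feature bounds for {name!r} have max < min")
        self.bounds = {k: (float(lo), float(hi)) for k, (lo, hi) in bounds.items()}

    def __getitem__(self, name: str) -> tuple[float, float]:
        return self.bounds[name]

    def __contains__(self, name: str) -> bool:
        return name in self.bounds

    def __eq__(self, other) -> bool:
        return isinstance(other, FeatureBounds) and self.bounds == other.bounds

    def to_json(self) -> str:
        return json.dumps(
            {k: {"min": lo, "max": hi} for k, (lo, hi) in self.bounds.items()},
            indent=2, sort_keys=True,
        )

    @classmethod
    def from_json(cls, text: str) -> "FeatureBounds":
        raw = json.loads(text)
        return cls({k: (v["min"], v["max"]) for k, v in raw.items()})

    def save(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(self.to_json())

    @classmethod
    def load(cls, path) -> "FeatureBounds":
        with open(path) as fh:
            return cls.from_json(fh.read())


def fill_missing(table: pd.DataFrame) -> pd.DataFrame:
    """Forward- then backward-fill physiological gaps, per animal.

    Values are carried verbatim, never interpolated. An animal with zero
    observations for a feature cannot be filled and raises a
    :class:`DataError` naming the animal and feature.
    """
    out = table.copy()
    for feat in PHYSIO_FEATURES:
        if feat not in out.columns:
            continue
        filled = out.groupby("cattle_id", sort=False)[feat].transform(
            lambda s: s.ffill().bfill()
        )
        if filled.isna().any():
            bad = out.loc[filled.isna(), "cattle_id"].iloc[0]
            raise DataError(f"animal {bad!r} has no observed values for {feat!r}")
        out[feat] = filled
    return out


def remove_outliers(
    table: pd.DataFrame, cfg: PreprocessConfig | None = None
) -> tuple[pd.DataFrame, int]:
    """Drop rows where any screened feature has |z| > z_max.

    Mean and SD (population, ddof=0) are computed over the whole table,
    across its animals. Features with zero SD flag nothing. Returns the
    surviving rows and the number of rows dropped.
    """
    cfg = cfg or PreprocessConfig()
    cfg.validate()
    if len(table) == 0:
        return table.copy(), 0
    drop = np.zeros(len(table), dtype=bool)
    for feat in cfg.outlier_features:
        vals = table[feat].to_numpy(dtype=float)
        if np.isnan(vals).any():
            raise DataError(f"remove_outliers requires no missing values in {feat!r}; run fill_missing first")
        mu = vals.mean()
        sd = vals.std()  # ddof=0
        if sd == 0.0:
            continue
        drop |= np.abs(vals - mu) / sd > cfg.z_max
    kept = table.loc[~drop].reset_index(drop=True)
    return kept, int(drop.sum())


def generate_labels(
    table: pd.DataFrame, cfg: PreprocessConfig | None = None
) -> pd.DataFrame:
    """Proxy stress label: 1 iff heart_rate > 100 bpm OR body_temp > 39.5 °C.

    Strict inequalities; idempotent. Must be called on RAW physiological
    units — if every heart rate is <= 1.0 the table has evidently been
    min–max scaled already and a :class:`GuardError` is raised.
    """
    cfg = cfg or PreprocessConfig()
    cfg.validate()
    out = table.copy()
    if len(out) == 0:
        return out
    hr = out["heart_rate"].to_numpy(dtype=float)
    temp = out["body_temp"].to_numpy(dtype=float)
    if np.nanmax(hr) <= 1.0:
        raise GuardError(
            "heart_rate values are all <= 1.0: generate_labels must run on raw "
            "(pre-normalization) units"
        )
    out["is_stressed"] = ((hr > cfg.hr_threshold) | (temp > cfg.temp_threshold)).astype(np.int64)
    return out


def normalize_minmax(
    table: pd.DataFrame,
    bounds: FeatureBounds | None = None,
    feature_cols: list[str] | None = None,
) -> tuple[pd.DataFrame, FeatureBounds]:
    """Min–max scale features into [0, 1]; returns the bounds used.

    If ``bounds`` is None they are learned from the table (training
    mode). Degenerate features (max == min) map to 0. With supplied
    bounds, out-of-range values are clipped into [0, 1] (inference mode).
    """
    out = table.copy()
    if feature_cols is None:
        feature_cols = [c for c in MODEL_FEATURES if c in out.columns]
    learn = bounds is None
    if learn:
        learned = {}
        for feat in feature_cols:
            vals = out[feat].to_numpy(dtype=float)
            if np.isnan(vals).any():
                raise DataError(f"normalize_minmax requires no missing values in {feat!r}")
            learned[feat] = (float(vals.min()), float(vals.max())) if len(vals) else (0.0, 0.0)
        bounds = FeatureBounds(learned)
    for feat in feature_cols:
        if feat not in bounds:
            raise ConfigError(f"no bounds supplied for feature {feat!r}")
        lo, hi = bounds[feat]
        vals = out[feat].to_numpy(dtype=float)
        if hi == lo:
            out[feat] = 0.0
        else:
            scaled = (vals - lo) / (hi - lo)
            out[feat] = scaled if learn else np.clip(scaled, 0.0, 1.0)
    return out, bounds


def add_rolling_features(
    table: pd.DataFrame, cfg: PreprocessConfig | None = None
) -> pd.DataFrame:
    """Append trailing time-window features per animal.

    Causal windows of ``rolling_window_minutes`` ending at (and
    including) the current sample: rolling mean of heart rate and body
    temperature, rolling population variance (ddof=0) of activity. A
    single-sample window has variance 0.
    """
    cfg = cfg or PreprocessConfig()
    cfg.validate()
    if len(table) == 0:
        out = table.copy()
        for c in ROLLING_FEATURES:
            out[c] = pd.Series(dtype=float)
        return out
    window = pd.Timedelta(minutes=cfg.rolling_window_minutes)
    pieces = []
    for cid, grp in table.groupby("cattle_id", sort=False):
        ts = grp["timestamp"]
        if not ts.is_monotonic_increasing:
            raise DataError(f"timestamps for animal {cid!r} are not sorted")
        roll = grp.rolling(window, on="timestamp")
        pieces.append(grp.assign(
            hr_roll_mean=roll["heart_rate"].mean().to_numpy(),
            temp_roll_mean=roll["body_temp"].mean().to_numpy(),
            activity_roll_var=roll["activity_level"].var(ddof=0).to_numpy(),
        ))
    return pd.concat(pieces).loc[table.index].reset_index(drop=True)


@dataclass
class WindowedDataset:
    """Fixed-length feature windows with binary labels — the training unit.

    ``X`` has shape (n_windows, window_len, n_features) with values in
    [0, 1]; every window comes from a single animal's contiguous samples
    and carries the label of its final row.
    """

    X: np.ndarray
    y: np.ndarray
    cattle_id: np.ndarray
    end_timestamp: np.ndarray
    feature_names: tuple[str, ...]
    window_len: int
    stride: int

    def __len__(self) -> int:
        return self.X.shape[0]

    @property
    def n_samples(self) -> int:
        return self.X.shape[0]

    def subset(self, idx) -> "WindowedDataset":
        return WindowedDataset(
            X=self.X[idx], y=self.y[idx],
            cattle_id=self.cattle_id[idx], end_timestamp=self.end_timestamp[idx],
            feature_names=self.feature_names,
            window_len=self.window_len, stride=self.stride,
        )

    @classmethod
    def concat(cls, parts: list["WindowedDataset"]) -> "WindowedDataset":
        if not parts:
            raise DataError("cannot concatenate zero datasets")
        first = parts[0]
        for p in parts[1:]:
            if p.feature_names != first.feature_names or p.window_len != first.window_len:
                raise DataError("incompatible WindowedDatasets")
        return cls(
            X=np.concatenate([p.X for p in parts]),
            y=np.concatenate([p.y for p in parts]),
            cattle_id=np.concatenate([p.cattle_id for p in parts]),
            end_timestamp=np.concatenate([p.end_timestamp for p in parts]),
            feature_names=first.feature_names,
            window_len=first.window_len,
            stride=first.stride,
        )


def make_windows(
    table: pd.DataFrame,
    window_len: int,
    stride: int = 1,
    feature_cols: list[str] | None = None,
) -> WindowedDataset:
    """Slide fixed-length windows over each animal's contiguous samples.

    Per animal with n samples the window count is
    floor((n - window_len)/stride) + 1 for n >= window_len, else 0
    (short animals are logged and skipped). The window label is the
    ``is_stressed`` value of its last row.
    """
    if window_len < 1 or stride < 1:
        raise ConfigError("window_len and stride must be >= 1")
    if feature_cols is None:
        feature_cols = [c for c in MODEL_FEATURES if c in table.columns]
    Xs, ys, cids, ends = [], [], [], []
    for cid, grp in table.groupby("cattle_id", sort=False):
        n = len(grp)
        if n < window_len:
            logger.info("animal %s has %d < %d samples; yields no windows", cid, n, window_len)
            continue
        feats = grp[feature_cols].to_numpy(dtype=float)
        labels = grp["is_stressed"].to_numpy()
        if pd.isna(labels).any():
            raise DataError(f"animal {cid!r} has unset is_stressed labels")
        times = grp["timestamp"].to_numpy()
        starts = np.arange(0, n - window_len + 1, stride)
        for s in starts:
            Xs.append(feats[s:s + window_len])
            ys.append(int(labels[s + window_len - 1]))
            cids.append(cid)
            ends.append(times[s + window_len - 1])
    if Xs:
        X = np.stack(Xs)
        end_ts = np.array(ends)
    else:
        X = np.zeros((0, window_len, len(feature_cols)))
        end_ts = np.array([], dtype="datetime64[ns]")
    return WindowedDataset(
        X=X,
        y=np.asarray(ys, dtype=np.int64),
        cattle_id=np.asarray(cids, dtype=object),
        end_timestamp=end_ts,
        feature_names=tuple(feature_cols),
        window_len=window_len,
        stride=stride,
    )


def preprocess_table(
    table: pd.DataFrame,
    cfg: PreprocessConfig | None = None,
    bounds: FeatureBounds | None = None,
) -> tuple[pd.DataFrame, FeatureBounds, int]:
    """Run fill → outlier screen → labels → rolling features → scaling.

    Labels are computed from raw heart rate / body temperature before
    scaling (the 100 bpm / 39.5 °C thresholds only exist in raw units);
    the scaled copy keeps those labels. Returns
    ``(processed, bounds, dropped_rows)``.
    """
    cfg = cfg or PreprocessConfig()
    out = fill_missing(table)
    out, dropped = remove_outliers(out, cfg)
    out = generate_labels(out, cfg)
    out = add_rolling_features(out, cfg)
    out, bounds = normalize_minmax(out, bounds)
    return out, bounds, dropped
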