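"""Synthetic multi-animal sensor streams in the MmCows-style schema.

Generates seeded heart-rate / body-temperature / activity / environment
time series for a herd of dairy cattle, with per-animal baseline
heterogeneity, a sinusoidal diurnal ambient cycle, Poisson-arrival stress
episodes that elevate heart rate and body temperature, and optional
sensor faults (dropout runs and spike outliers). Also partitions a herd
into disjoint per-animal client tables, the non-IID setting used by the
federated simulation.

Generative model
----------------
* Each animal draws a baseline (heart rate, temperature, activity) once
  from the configured population mean/sd — this is what makes per-animal
  partitions non-IID.
* Stress episodes arrive per animal as a Poisson process (episodes per
  animal-day) with a fixed duration; inside an episode heart rate and
  temperature receive additive boosts and activity is perturbed.
* Ambient temperature is shared herd-wide: daily mean plus a sinusoid
  peaking mid-afternoon, plus noise. Humidity is noisy around its mean.
* GPS coordinates follow a per-animal Gaussian random walk from a common
  origin (no behavioural model).

The generator never writes stress labels itself: ``is_stressed`` is left
unset and is filled later by thresholding (see :mod:`fedherd.preprocess`).
Ground-truth episode intervals are returned alongside the table so tests
can compare labels against the latent state.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConfigError, PartitionError
from .seeding import derive_seed

__all__ = [
    "SCHEMA_COLUMNS",
    "PHYSIO_FEATURES",
    "HerdSimConfig",
    "FaultConfig",
    "simulate_herd",
    "inject_faults",
    "partition_by_animal",
    "train_test_split_by_animal",
    "write_sensor_csv",
    "read_sensor_csv",
    "write_episodes_csv",
    "read_episodes_csv",
]

#: Exact column order of the sensor CSV dialect.
SCHEMA_COLUMNS = [
    "timestamp",
    "cattle_id",
    "heart_rate",
    "body_temp",
    "activity_level",
    "ambient_temp",
    "humidity",
    "location_lat",
    "location_long",
    "is_stressed",
]

#: Wearable-sensor channels subject to dropout/outlier faults and filling.
PHYSIO_FEATURES = ["heart_rate", "body_temp", "activity_level"]


@dataclass
class HerdSimConfig:
    """Parameters of the herd simulator.

    Baseline means must leave an unstressed animal below the stress
    thresholds (heart rate < 100 bpm, body temperature < 39.5 °C) so that
    proxy labels are driven by episodes, not by baseline drift.
    """

    n_animals: int = 20
    duration_hours: float = 168.0          # 7 days
    sampling_interval_minutes: float = 15.0
    hr_baseline_mean: float = 70.0         # bpm
    hr_baseline_sd: float = 5.0
    hr_noise_sd: float = 3.0               # per-sample measurement noise
    temp_baseline_mean: float = 38.5       # °C
    temp_baseline_sd: float = 0.2
    temp_noise_sd: float = 0.15
    activity_baseline_mean: float = 0.3    # unitless movement index >= 0
    activity_baseline_sd: float = 0.1
    activity_noise_sd: float = 0.08
    activity_diurnal_amplitude: float = 0.1
    ambient_profile: tuple[float, float] = (20.0, 6.0)  # (daily mean °C, diurnal amplitude °C)
    ambient_noise_sd: float = 0.5
    humidity_profile: tuple[float, float] = (60.0, 10.0)  # (mean %, sd %)
    stress_episode_rate: float = 2.0       # episodes per animal-day
    stress_episode_duration_minutes: float = 60.0
    stress_hr_boost: float = 35.0          # bpm
    stress_temp_boost: float = 1.2         # °C
    stress_activity_shift: float = 0.15    # magnitude of per-episode activity perturbation
    gps_origin: tuple[float, float] = (42.44, -76.47)   # (lat, long) degrees
    gps_step_sd: float = 1e-4              # degrees per step
    start_time: str = "2024-06-01T00:00:00"
    seed: int = 0

    def validate(self) -> None:
        if self.n_animals < 0:
            raise ConfigError("n_animals must be >= 0")
        if self.duration_hours <= 0:
            raise ConfigError("duration_hours must be > 0")
        if self.sampling_interval_minutes <= 0:
            raise ConfigError("sampling_interval_minutes must be > 0")
        if self.stress_episode_rate < 0:
            raise ConfigError("stress_episode_rate must be >= 0")
        if self.stress_episode_duration_minutes <= 0:
            raise ConfigError("stress_episode_duration_minutes must be > 0")
        if self.stress_hr_boost <= 0:
            raise ConfigError("stress_hr_boost must be > 0")
        if self.stress_temp_boost <= 0:
            raise ConfigError("stress_temp_boost must be > 0")
        if self.hr_baseline_mean >= 100.0:
            raise ConfigError("hr_baseline_mean must keep unstressed heart_rate below 100 bpm")
        if self.temp_baseline_mean >= 39.5:
            raise ConfigError("temp_baseline_mean must keep unstressed body_temp below 39.5 degC")
        for name in ("hr_baseline_sd", "temp_baseline_sd", "activity_baseline_sd",
                     "hr_noise_sd", "temp_noise_sd", "activity_noise_sd", "gps_step_sd"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be >= 0")
        if self.activity_baseline_mean < 0:
            raise ConfigError("activity_baseline_mean must be >= 0")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["ambient_profile"] = list(self.ambient_profile)
        d["humidity_profile"] = list(self.humidity_profile)
        d["gps_origin"] = list(self.gps_origin)
        return d


@dataclass
class FaultConfig:
    """Sensor-fault injection: dropout runs and spike outliers.

    ``outlier_magnitude_sd_multiplier`` must exceed 3 so injected spikes
    stay removable by the z > 3 screening rule downstream.
    """

    missing_rate: float = 0.05             # probability per physiological cell
    missing_run_length_mean: float = 3.0   # samples (geometric run lengths)
    outlier_rate: float = 0.01             # probability per physiological cell
    outlier_magnitude_sd_multiplier: float = 6.0
    seed: int = 0

    def validate(self) -> None:
        for name in ("missing_rate", "outlier_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name} must be in [0, 1]")
        if self.missing_run_length_mean < 1.0:
            raise ConfigError("missing_run_length_mean must be >= 1 sample")
        if self.outlier_magnitude_sd_multiplier <= 3.0:
            raise ConfigError("outlier_magnitude_sd_multiplier must be > 3")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def _animal_id(i: int, n_total: int) -> str:
    width = max(3, len(str(max(n_total - 1, 0))))
    return f"cow_{i:0{width}d}"


def simulate_herd(config: HerdSimConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate a herd; return ``(table, episodes)``.

    ``table`` has the exact schema of :data:`SCHEMA_COLUMNS`, sorted by
    (cattle_id, timestamp) with equally spaced timestamps per animal.
    ``is_stressed`` is left unset. ``episodes`` holds the ground-truth
    stress intervals as (cattle_id, start_timestamp, end_timestamp),
    clipped to the simulated span.
    """
    config.validate()

    step = pd.Timedelta(minutes=config.sampling_interval_minutes)
    n_ticks = int(round(config.duration_hours * 60.0 / config.sampling_interval_minutes))
    start = pd.Timestamp(config.start_time)
    times = start + step * np.arange(n_ticks)
    t_minutes = np.arange(n_ticks) * config.sampling_interval_minutes
    tod_hours = (t_minutes / 60.0 + start.hour + start.minute / 60.0) % 24.0
    # Sinusoid peaking at 15:00 local time.
    diurnal = np.sin(2.0 * np.pi * (tod_hours - 9.0) / 24.0)

    if config.n_animals == 0:
        empty = pd.DataFrame({c: pd.Series(dtype=d) for c, d in zip(
            SCHEMA_COLUMNS,
            ["datetime64[ns]", "object", "float64", "float64", "float64",
             "float64", "float64", "float64", "float64", "float64"],
        )})
        episodes = pd.DataFrame(columns=["cattle_id", "start_timestamp", "end_timestamp"])
        return empty, episodes

    env_rng = np.random.default_rng(derive_seed(config.seed, "herd", "environment"))
    amb_mean, amb_amp = config.ambient_profile
    ambient = amb_mean + amb_amp * diurnal + env_rng.normal(0.0, config.ambient_noise_sd, n_ticks)
    hum_mean, hum_sd = config.humidity_profile
    humidity = np.clip(hum_mean + env_rng.normal(0.0, hum_sd, n_ticks), 0.0, 100.0)

    duration_days = config.duration_hours / 24.0
    total_minutes = n_ticks * config.sampling_interval_minutes
    frames = []
    episode_rows = []
    end_time = times[-1] if n_ticks else start
    for i in range(config.n_animals):
        cid = _animal_id(i, config.n_animals)
        rng = np.random.default_rng(derive_seed(config.seed, "herd", "animal", i))
        base_hr = rng.normal(config.hr_baseline_mean, config.hr_baseline_sd)
        base_temp = rng.normal(config.temp_baseline_mean, config.temp_baseline_sd)
        base_act = max(0.05, rng.normal(config.activity_baseline_mean, config.activity_baseline_sd))

        n_ep = rng.poisson(config.stress_episode_rate * duration_days)
        starts = np.sort(rng.uniform(0.0, total_minutes, n_ep))
        in_episode = np.zeros(n_ticks, dtype=bool)
        act_shift = np.zeros(n_ticks)
        for s in starts:
            e = s + config.stress_episode_duration_minutes
            mask = (t_minutes >= s) & (t_minutes < e)
            if not mask.any():
                continue
            in_episode |= mask
            sign = 1.0 if rng.random() < 0.5 else -1.0
            act_shift[mask] += sign * config.stress_activity_shift
            episode_rows.append((
                cid,
                start + pd.Timedelta(minutes=float(s)),
                min(start + pd.Timedelta(minutes=float(e)), end_time + step),
            ))

        hr = base_hr + rng.normal(0.0, config.hr_noise_sd, n_ticks) \
            + config.stress_hr_boost * in_episode
        temp = base_temp + rng.normal(0.0, config.temp_noise_sd, n_ticks) \
            + config.stress_temp_boost * in_episode
        act = np.clip(
            base_act
            + config.activity_diurnal_amplitude * diurnal
            + rng.normal(0.0, config.activity_noise_sd, n_ticks)
            + act_shift,
            0.0, None,
        )
        lat = config.gps_origin[0] + np.cumsum(rng.normal(0.0, config.gps_step_sd, n_ticks))
        lon = config.gps_origin[1] + np.cumsum(rng.normal(0.0, config.gps_step_sd, n_ticks))

        frames.append(pd.DataFrame({
            "timestamp": times,
            "cattle_id": cid,
            "heart_rate": hr,
            "body_temp": temp,
            "activity_level": act,
            "ambient_temp": ambient,
            "humidity": humidity,
            "location_lat": lat,
            "location_long": lon,
            "is_stressed": np.nan,
        }))

    table = pd.concat(frames, ignore_index=True)
    table = table.sort_values(["cattle_id", "timestamp"], kind="stable").reset_index(drop=True)
    episodes = pd.DataFrame(episode_rows, columns=["cattle_id", "start_timestamp", "end_timestamp"])
    episodes = episodes.sort_values(["cattle_id", "start_timestamp"]).reset_index(drop=True)
    return table, episodes


def _missing_mask(rng: np.random.Generator, n: int, rate: float, run_mean: float) -> np.ndarray:
    """Geometric-run dropout mask with expected per-cell rate ~= rate."""
    if rate <= 0.0 or n == 0:
        return np.zeros(n, dtype=bool)
    if rate >= 1.0:
        return np.ones(n, dtype=bool)
    if run_mean <= 1.0:
        return rng.random(n) < rate
    p_start = min(1.0, rate / run_mean)
    starts = np.flatnonzero(rng.random(n) < p_start)
    mask = np.zeros(n, dtype=bool)
    for s in starts:
        run = rng.geometric(1.0 / run_mean)
        mask[s:s + run] = True
    return mask


def inject_faults(
    table: pd.DataFrame, fault_cfg: FaultConfig
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Corrupt physiological cells with dropout runs and spike outliers.

    Returns ``(corrupted_table, fault_log)`` where the log records
    (cattle_id, timestamp, feature, kind) for every injected fault.
    Environmental and identity columns are never touched. Outlier cells
    are displaced by at least ``outlier_magnitude_sd_multiplier`` feature
    standard deviations (population SD over the clean table).
    """
    fault_cfg.validate()
    out = table.copy()
    log_rows: list[tuple] = []
    if len(out) == 0:
        return out, pd.DataFrame(columns=["cattle_id", "timestamp", "feature", "kind"])

    rng = np.random.default_rng(derive_seed(fault_cfg.seed, "faults"))
    feature_sd = {f: float(np.std(out[f].to_numpy(dtype=float))) for f in PHYSIO_FEATURES}

    for feat in PHYSIO_FEATURES:
        col = out[feat].to_numpy(dtype=float).copy()
        # Spike outliers first (on observed values), dropout may then hide some.
        if fault_cfg.outlier_rate > 0.0:
            hit = rng.random(len(col)) < fault_cfg.outlier_rate
            if hit.any():
                sd = feature_sd[feat] if feature_sd[feat] > 0 else 1.0
                signs = np.where(rng.random(hit.sum()) < 0.5, -1.0, 1.0)
                mags = fault_cfg.outlier_magnitude_sd_multiplier + np.abs(rng.standard_normal(hit.sum()))
                col[hit] = col[hit] + signs * mags * sd
                for idx in np.flatnonzero(hit):
                    log_rows.append((out.at[idx, "cattle_id"], out.at[idx, "timestamp"], feat, "outlier"))

        missing = np.zeros(len(col), dtype=bool)
        for _, grp in out.groupby("cattle_id", sort=False):
            gidx = grp.index.to_numpy()
            m = _missing_mask(rng, len(gidx), fault_cfg.missing_rate, fault_cfg.missing_run_length_mean)
            missing[gidx] = m
        col[missing] = np.nan
        for idx in np.flatnonzero(missing):
            log_rows.append((out.at[idx, "cattle_id"], out.at[idx, "timestamp"], feat, "missing"))
        out[feat] = col

    log = pd.DataFrame(log_rows, columns=["cattle_id", "timestamp", "feature", "kind"])
    return out, log


def partition_by_animal(table: pd.DataFrame, n_clients: int, seed: int) -> list[pd.DataFrame]:
    """Split a herd into ``n_clients`` disjoint per-animal tables.

    Animals are shuffled by ``seed`` and split as evenly as possible
    (group sizes differ by at most one). The union of the client tables
    equals the input row-for-row and no animal appears on two clients.
    """
    if n_clients < 1:
        raise ConfigError("n_clients must be >= 1")
    animals = sorted(table["cattle_id"].unique())
    if n_clients > len(animals):
        raise PartitionError(
            f"cannot split {len(animals)} animals across {n_clients} clients"
        )
    rng = np.random.default_rng(derive_seed(seed, "partition"))
    order = [animals[i] for i in rng.permutation(len(animals))]
    groups = [list(g) for g in np.array_split(np.array(order, dtype=object), n_clients)]
    return [
        table[table["cattle_id"].isin(set(g))].reset_index(drop=True) for g in groups
    ]


def train_test_split_by_animal(
    table: pd.DataFrame, test_fraction: float, seed: int
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Hold out a fraction of animals (at least one) as a global test set."""
    if not 0.0 < test_fraction < 1.0:
        raise ConfigError("test_fraction must be in (0, 1)")
    animals = sorted(table["cattle_id"].unique())
    if len(animals) < 2:
        raise ConfigError("need at least 2 animals to hold out a test set")
    n_test = min(len(animals) - 1, max(1, int(round(test_fraction * len(animals)))))
    rng = np.random.default_rng(derive_seed(seed, "test-split"))
    order = [animals[i] for i in rng.permutation(len(animals))]
    test_set = set(order[:n_test])
    train = table[~table["cattle_id"].isin(test_set)].reset_index(drop=True)
    test = table[table["cattle_id"].isin(test_set)].reset_index(drop=True)
    return train, test


# ---------------------------------------------------------------------------
# CSV dialect
# ---------------------------------------------------------------------------

def write_sensor_csv(table: pd.DataFrame, path, float_format: str | None = "%.6f") -> None:
    """Write a sensor table with the exact schema header; missing cells empty.

    Timestamps are ISO-8601; ``is_stressed`` is written as a bare integer
    when present and an empty field when unset. Fixed float formatting
    makes equal (config, seed) pairs produce byte-identical files.
    """
    out = table.copy()
    cols = [c for c in SCHEMA_COLUMNS if c in out.columns]
    extra = [c for c in out.columns if c not in SCHEMA_COLUMNS]
    out = out[cols + extra]
    if "is_stressed" in out.columns:
        out["is_stressed"] = out["is_stressed"].astype("Int64")
    out.to_csv(path, index=False, float_format=float_format,
               date_format="%Y-%m-%dT%H:%M:%S")


def read_sensor_csv(path) -> pd.DataFrame:
    table = pd.read_csv(path, parse_dates=["timestamp"], dtype={"cattle_id": str})
    if "is_stressed" in table.columns:
        table["is_stressed"] = table["is_stressed"].astype("float64")
    return table


def write_episodes_csv(episodes: pd.DataFrame, path) -> None:
    episodes.to_csv(path, index=False, date_format="%Y-%m-%dT%H:%M:%S")


def read_episodes_csv(path) -> pd.DataFrame:
    return pd.read_csv(path, parse_dates=["start_timestamp", "end_timestamp"],
                       dtype={"cattle_id": str})
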