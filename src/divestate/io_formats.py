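"""Reading and writing of logger, GPS and result files.

The canonical in-memory data model is :class:`RawDeployment`: a multi-rate
record holding the 25 Hz tri-axial acceleration channels (surge/sway/heave)
together with the 1 Hz pressure/temperature channel, both on a common clock
expressed in seconds since deployment start.  Acceleration is canonicalized
to m/s² on ingest (loggers commonly report g); pressure stays in millibar
until the feature stage converts it to depth.

File dialects are deliberately plain: a single accelerometer CSV in which
the 1 Hz environmental channels appear on every 25th row (blank elsewhere),
a three-column GPS CSV, a per-sample state table CSV and a model-parameter
JSON document.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from .errors import ContractError, DataError, FormatError

STANDARD_GRAVITY = 9.80665  # m/s² per unit g

DEFAULT_COLUMNS: Mapping[str, str] = {
    "time": "time",
    "ax": "ax",          # surge
    "ay": "ay",          # sway
    "az": "az",          # heave
    "pressure": "pressure_mbar",
    "temperature": "temp_c",
}


@dataclass(frozen=True)
class IngestConfig:
    """Declares the accelerometer CSV layout and units.

    The logger's acceleration unit is not self-describing, so it must be
    declared here; ``g`` inputs are multiplied by standard gravity
    (9.80665 m/s²) on ingest.
    """

    columns: Mapping[str, str] = field(default_factory=lambda: dict(DEFAULT_COLUMNS))
    accel_units: str = "g"            # "g" or "ms2"
    f_acc: float = 25.0               # nominal acceleration rate, Hz
    f_env: float = 1.0                # nominal pressure/temperature rate, Hz
    latitude_colony: float = 57.0     # degrees, used downstream for depth

    def __post_init__(self) -> None:
        if self.accel_units not in ("g", "ms2"):
            raise FormatError(f"unknown acceleration unit {self.accel_units!r}")
        if self.f_acc <= 0 or self.f_env <= 0:
            raise FormatError("sampling rates must be positive")


@dataclass
class RawDeployment:
    """Multi-rate logger record (25 Hz acceleration + 1 Hz environment)."""

    deployment_id: str
    accel_time: np.ndarray          # s since deployment start, strictly increasing
    A_h: np.ndarray                 # surge, m/s²
    A_l: np.ndarray                 # sway, m/s²
    A_v: np.ndarray                 # heave, m/s²
    env_time: np.ndarray            # s, strictly increasing, nominal 1 Hz
    pressure_mbar: np.ndarray
    temperature_c: np.ndarray
    latitude_colony: float
    f_acc: float = 25.0
    f_env: float = 1.0
    gap_mask: np.ndarray | None = None   # True where sample follows a gap > 2 intervals
    n_flagged: int = 0                   # rows dropped on ingest (NaN acceleration)

    def __post_init__(self) -> None:
        for name in ("accel_time", "A_h", "A_l", "A_v"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=float))
        for name in ("env_time", "pressure_mbar", "temperature_c"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=float))
        if self.gap_mask is None:
            self.gap_mask = self._compute_gap_mask()
        else:
            self.gap_mask = np.asarray(self.gap_mask, dtype=bool)
        self.validate()

    def _compute_gap_mask(self) -> np.ndarray:
        gap = np.zeros(self.accel_time.shape, dtype=bool)
        if self.accel_time.size > 1:
            dt = np.diff(self.accel_time)
            gap[1:] = dt > 2.0 / self.f_acc
        return gap

    def validate(self) -> None:
        if self.f_acc <= 0 or self.f_env <= 0:
            raise DataError("sampling rates must be positive")
        for name in ("accel_time", "env_time"):
            t = getattr(self, name)
            if t.size > 1 and not np.all(np.diff(t) > 0):
                idx = int(np.argmin(np.diff(t) > 0)) + 1
                raise DataError(f"{name} not strictly increasing at row {idx}")
        n = self.accel_time.size
        for name in ("A_h", "A_l", "A_v", "gap_mask"):
            if getattr(self, name).size != n:
                raise DataError(f"{name} length mismatch with accel_time")
        m = self.env_time.size
        for name in ("pressure_mbar", "temperature_c"):
            if getattr(self, name).size != m:
                raise DataError(f"{name} length mismatch with env_time")
        if n and m:
            if self.env_time[0] < self.accel_time[0] - 1e-9 or self.env_time[-1] > self.accel_time[-1] + 1e-9:
                raise DataError("env_time extends beyond the acceleration record")

    @property
    def duration_s(self) -> float:
        if self.accel_time.size == 0:
            return 0.0
        return float(self.accel_time[-1] - self.accel_time[0])


@dataclass
class GPSTrack:
    """GPS fixes (nominally one per ~100 s)."""

    fix_time: np.ndarray
    lat: np.ndarray
    lon: np.ndarray
    distance_to_colony: np.ndarray | None = None  # filled by the behavior module

    def __post_init__(self) -> None:
        self.fix_time = np.asarray(self.fix_time, dtype=float)
        self.lat = np.asarray(self.lat, dtype=float)
        self.lon = np.asarray(self.lon, dtype=float)
        if np.any(np.abs(self.lat) > 90):
            raise DataError("latitude out of [-90, 90]")
        if np.any(np.abs(self.lon) > 180):
            raise DataError("longitude out of [-180, 180]")
        if self.fix_time.size > 1 and not np.all(np.diff(self.fix_time) > 0):
            raise DataError("fix_time not strictly increasing")

    def __len__(self) -> int:
        return self.fix_time.size


def read_accelerometer_csv(path, config: IngestConfig | None = None,
                           deployment_id: str | None = None) -> RawDeployment:
    """Read a logger CSV into a :class:`RawDeployment`.

    The file carries one row per 25 Hz acceleration sample; pressure and
    temperature cells are populated only on the 1 Hz rows and blank
    elsewhere.  Rows with missing acceleration values are dropped and
    counted in ``n_flagged`` (never silently: n_in = n_out + n_flagged).
    """
    config = config or IngestConfig()
    df = pd.read_csv(path)
    cols = config.columns
    for key in ("time", "ax", "ay", "az", "pressure"):
        if cols[key] not in df.columns:
            raise FormatError(f"missing mandatory column {cols[key]!r}")
    has_temp = cols.get("temperature") in df.columns

    t = df[cols["time"]].to_numpy(dtype=float)
    if t.size > 1:
        bad = np.nonzero(np.diff(t) <= 0)[0]
        if bad.size:
            raise DataError(f"timestamps not strictly increasing at row {int(bad[0]) + 1}")

    acc = df[[cols["ax"], cols["ay"], cols["az"]]].to_numpy(dtype=float)
    keep = np.all(np.isfinite(acc), axis=1)
    n_flagged = int((~keep).sum())
    scale = STANDARD_GRAVITY if config.accel_units == "g" else 1.0

    p = df[cols["pressure"]].to_numpy(dtype=float)
    env_rows = np.isfinite(p) & keep
    temp = (df[cols["temperature"]].to_numpy(dtype=float)[env_rows]
            if has_temp else np.zeros(int(env_rows.sum())))

    t0 = t[keep][0] if keep.any() else 0.0
    return RawDeployment(
        deployment_id=deployment_id or str(path),
        accel_time=t[keep] - t0,
        A_h=acc[keep, 0] * scale,
        A_l=acc[keep, 1] * scale,
        A_v=acc[keep, 2] * scale,
        env_time=t[env_rows] - t0,
        pressure_mbar=p[env_rows],
        temperature_c=temp,
        latitude_colony=config.latitude_colony,
        f_acc=config.f_acc,
        f_env=config.f_env,
        n_flagged=n_flagged,
    )


def write_accelerometer_csv(dep: RawDeployment, path, units: str = "g",
                            columns: Mapping[str, str] | None = None) -> None:
    """Write a deployment back to the single-file CSV dialect."""
    if units not in ("g", "ms2"):
        raise FormatError(f"unknown acceleration unit {units!r}")
    cols = columns or DEFAULT_COLUMNS
    scale = 1.0 / STANDARD_GRAVITY if units == "g" else 1.0
    n = dep.accel_time.size
    p = np.full(n, np.nan)
    temp = np.full(n, np.nan)
    idx = np.searchsorted(dep.accel_time, dep.env_time)
    idx = np.clip(idx, 0, max(n - 1, 0))
    p[idx] = dep.pressure_mbar
    temp[idx] = dep.temperature_c
    pd.DataFrame({
        cols["time"]: dep.accel_time,
        cols["ax"]: dep.A_h * scale,
        cols["ay"]: dep.A_l * scale,
        cols["az"]: dep.A_v * scale,
        cols["pressure"]: p,
        cols["temperature"]: temp,
    }).to_csv(path, index=False)


def read_gps_csv(path) -> GPSTrack:
    """Read a time/lat/lon CSV, sorting by time and collapsing duplicate
    timestamps to their first occurrence."""
    df = pd.read_csv(path)
    for col in ("time", "lat", "lon"):
        if col not in df.columns:
            raise FormatError(f"missing mandatory column {col!r}")
    df = df.sort_values("time", kind="stable").drop_duplicates("time", keep="first")
    return GPSTrack(
        fix_time=df["time"].to_numpy(dtype=float),
        lat=df["lat"].to_numpy(dtype=float),
        lon=df["lon"].to_numpy(dtype=float),
    )


def write_gps_csv(track: GPSTrack, path) -> None:
    pd.DataFrame({"time": track.fix_time, "lat": track.lat, "lon": track.lon}).to_csv(
        path, index=False)


# ---------------------------------------------------------------------------
# State table (per-sample classification result)
# ---------------------------------------------------------------------------

_STATE_FEATURE_COLS = ("Depth", "B", "V_s", "Amp_v", "B_var")


def write_state_table(seq, features, path) -> None:
    """Write one row per sample: time, key features, wet/gap flags, raw and
    smoothed labels, and per-state posterior responsibilities.

    ``seq`` is a ``gmm_em.StateSequence``; ``features`` a
    ``signal_features.FeatureTable`` on the same sample grid (``seq`` may
    cover a subset of the grid, matched on time).
    """
    n = seq.time.size
    data = features.data
    if n:
        pos = np.searchsorted(data["time"].to_numpy(), seq.time)
        if pos.max(initial=0) >= len(data) or not np.allclose(
                data["time"].to_numpy()[pos], seq.time):
            raise ContractError("state sequence and feature table grids differ")
    else:
        pos = np.array([], dtype=int)
    out = {"time": seq.time}
    for col in _STATE_FEATURE_COLS:
        out[col] = data[col].to_numpy()[pos]
    out["wet"] = data["wet"].to_numpy()[pos]
    out["gap"] = data["gap"].to_numpy()[pos]
    out["label"] = seq.labels
    out["smoothed_label"] = (seq.smoothed_labels if seq.smoothed_labels is not None
                             else seq.labels)
    for k in range(seq.K):
        out[f"p_{k + 1}"] = seq.responsibilities[:, k] if n else np.array([])
    pd.DataFrame(out).to_csv(path, index=False)


def read_state_table(path) -> pd.DataFrame:
    """Companion reader for :func:`write_state_table` (lossless round trip)."""
    df = pd.read_csv(path)
    for col in ("time", "label", "smoothed_label"):
        if col not in df.columns:
            raise FormatError(f"missing mandatory column {col!r}")
    return df


# ---------------------------------------------------------------------------
# Model parameters as JSON
# ---------------------------------------------------------------------------

def config_hash(config) -> str:
    """Stable short hash of any YAML-serializable configuration object."""
    text = yaml.safe_dump(config, sort_keys=True, default_flow_style=True)
    return hashlib.sha1(text.encode()).hexdigest()[:12]


def write_model_json(model, path, config=None) -> None:
    doc = {
        "K": model.K,
        "weights": model.weights.tolist(),
        "means": model.means.tolist(),
        "covariances": model.covariances.tolist(),
        "loglik_trace": list(model.loglik_trace),
        "converged": bool(model.converged),
        "seed": model.seed,
        "n_params": model.n_params,
        "bic": model.bic,
        "channels": list(model.channels) if model.channels else None,
        "config_hash": config_hash(config) if config is not None else None,
    }
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=1)


def read_model_json(path):
    from .gmm_em import MixtureModel

    with open(path) as fh:
        doc = json.load(fh)
    return MixtureModel(
        K=doc["K"],
        weights=np.asarray(doc["weights"]),
        means=np.asarray(doc["means"]),
        covariances=np.asarray(doc["covariances"]),
        loglik_trace=list(doc["loglik_trace"]),
        converged=doc["converged"],
        seed=doc["seed"],
        bic=doc["bic"],
        channels=doc.get("channels"),
    )
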