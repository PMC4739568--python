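"""Derived variables from the raw multi-rate logger record.

The chain, in the order it runs:

1. pressure (millibar) → surface-offset removal → decibar → depth (m) via
   the UNESCO seawater formula with latitude-dependent gravity;
2. vertical speed V_s as the per-second change in depth (positive = deeper);
3. static acceleration S per axis as a centered running mean of A (the
   gravity component, encoding body orientation), dynamic acceleration
   D = A − S (movement effort);
4. pitch B = atan(S_h / sqrt(S_l² + S_v²)) in degrees, corrected by the
   median pitch observed while the bird rests quietly at the sea surface
   (imperfect device-mounting offset);
5. heave amplitude Amp_v as a rolling SD of D_v, pitch variability B_var as
   a rolling SD of the first-differenced pitch;
6. standardized (z-scored) copies of the channels used for clustering.

Everything lands on the 25 Hz acceleration grid; depth and V_s are linearly
interpolated up from the 1 Hz environmental grid.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import (CalibrationError, ConfigError, ContractError, DomainError,
                     StandardizationError)
from .io_formats import RawDeployment

# ---------------------------------------------------------------------------
# Depth from pressure (UNESCO seawater formula; t = 0 °C, s = 35 PSU assumed)
# ---------------------------------------------------------------------------

DEG_PER_RAD = 57.29578  # the formula's printed degree→radian constant


def gravity(latitude: float, p) -> np.ndarray | float:
    """Local gravity (m/s²) as a function of latitude (degrees) and pressure
    (decibar).

    g = 9.780318·[1 + (5.2788e-3 + 2.36e-5·x)·x] + 1.092e-6·p with
    x = sin²(latitude/57.29578).  Increasing in |latitude| at fixed p.
    """
    p = np.asarray(p, dtype=float)
    if np.any(p < 0):
        raise DomainError("pressure must be non-negative (decibar)")
    x = np.sin(latitude / DEG_PER_RAD) ** 2
    g = 9.780318 * (1.0 + (5.2788e-3 + 2.36e-5 * x) * x) + 1.092e-6 * p
    return g if g.ndim else float(g)


def pressure_to_depth(p, latitude: float) -> np.ndarray | float:
    """Depth (m) from sea pressure (decibar) at the given latitude.

    Depth = [(((−1.82e−15·p + 2.279e−10)·p − 2.2512e−5)·p + 9.72659)·p] / g.
    The caller must already have removed the atmospheric offset and
    converted millibar → decibar (1 decibar = 100 millibar).
    """
    p = np.asarray(p, dtype=float)
    if np.any(p < 0):
        raise DomainError("pressure must be non-negative (decibar)")
    g = gravity(latitude, p)
    depth = ((((-1.82e-15 * p + 2.279e-10) * p - 2.2512e-5) * p + 9.72659) * p) / g
    return depth if depth.ndim else float(depth)


def estimate_surface_pressure(pressure_mbar, window_mbar: float = 2.0) -> float:
    """Atmospheric (surface) pressure estimate in millibar.

    Median of the samples within ``window_mbar`` of the 1st percentile —
    i.e. of the lowest-pressure cluster, which a diving logger records
    whenever the animal is at or above the surface.  Assumes at least ~1 %
    of the record is spent at the surface.
    """
    p = np.asarray(pressure_mbar, dtype=float)
    p = p[np.isfinite(p)]
    if p.size == 0:
        raise ContractError("empty pressure series")
    lo = np.quantile(p, 0.01)
    return float(np.median(p[p <= lo + window_mbar]))


# ---------------------------------------------------------------------------
# Windowed statistics
# ---------------------------------------------------------------------------

def _window_bounds(n: int, half: int, symmetric: bool):
    i = np.arange(n)
    if symmetric:
        m = np.minimum(half, np.minimum(i, n - 1 - i))
        return i - m, i + m
    return np.maximum(0, i - half), np.minimum(n - 1, i + half)


def _half_width(window_s: float, rate: float) -> int:
    return int(round(window_s * rate / 2.0))


def running_mean(x, half: int, valid=None, symmetric: bool = True) -> np.ndarray:
    """Centered running mean with half-width ``half`` samples.

    With ``symmetric=True`` the window shrinks symmetrically at the edges
    (preserves the mean's phase); otherwise it is clipped to the bounds.
    Samples where ``valid`` is False (gaps) are excluded from every window;
    windows with no valid sample yield NaN.
    """
    x = np.asarray(x, dtype=float)
    n = x.size
    if n == 0:
        raise ContractError("empty series")
    if valid is None:
        valid = np.isfinite(x)
    else:
        valid = np.asarray(valid, dtype=bool) & np.isfinite(x)
    if half == 0:                      # one-sample window: exact identity
        return np.where(valid, x, np.nan)
    lo, hi = _window_bounds(n, half, symmetric)
    cs = np.concatenate(([0.0], np.cumsum(np.where(valid, x, 0.0))))
    cn = np.concatenate(([0], np.cumsum(valid.astype(np.int64))))
    s = cs[hi + 1] - cs[lo]
    c = cn[hi + 1] - cn[lo]
    with np.errstate(invalid="ignore", divide="ignore"):
        out = s / c
    out[c == 0] = np.nan
    return out


def static_acceleration(a, window_s: float, rate: float, valid=None) -> np.ndarray:
    """Gravity (static) component: centered running mean of a raw channel.

    ``window_s·rate`` must be ≥ 1; a one-sample window is the identity.
    """
    a = np.asarray(a, dtype=float)
    if a.size == 0:
        raise ContractError("empty series")
    if window_s * rate < 1:
        raise ContractError("window must span at least one sample")
    return running_mean(a, _half_width(window_s, rate), valid=valid, symmetric=True)


def dynamic_acceleration(a, s) -> np.ndarray:
    """Movement (dynamic) component D = A − S, elementwise."""
    a = np.asarray(a, dtype=float)
    s = np.asarray(s, dtype=float)
    if a.shape != s.shape:
        raise ContractError("length mismatch between raw and static series")
    return a - s


def rolling_sd(x, window_s: float, rate: float, valid=None) -> np.ndarray:
    """Centered rolling sample standard deviation (denominator n−1).

    Edge windows are clipped to the series bounds; windows with fewer than
    two valid samples yield 0.  Non-negative everywhere.
    """
    x = np.asarray(x, dtype=float)
    n = x.size
    if n == 0:
        raise ContractError("empty series")
    if window_s * rate < 2:
        raise ContractError("window must span at least two samples")
    if valid is None:
        valid = np.isfinite(x)
    else:
        valid = np.asarray(valid, dtype=bool) & np.isfinite(x)
    # center globally before accumulating to keep the sums well conditioned
    mu = np.mean(x[valid]) if valid.any() else 0.0
    xc = np.where(valid, x - mu, 0.0)
    lo, hi = _window_bounds(n, _half_width(window_s, rate), symmetric=False)
    cs1 = np.concatenate(([0.0], np.cumsum(xc)))
    cs2 = np.concatenate(([0.0], np.cumsum(xc * xc)))
    cn = np.concatenate(([0], np.cumsum(valid.astype(np.int64))))
    s1 = cs1[hi + 1] - cs1[lo]
    s2 = cs2[hi + 1] - cs2[lo]
    c = (cn[hi + 1] - cn[lo]).astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        var = (s2 - s1 * s1 / c) / (c - 1.0)
    var = np.where(c >= 2, np.maximum(var, 0.0), 0.0)
    return np.sqrt(var)


def sd_of_running_mean(x, window_s: float, rate: float, valid=None) -> np.ndarray:
    """Alternative amplitude reading: rolling SD *of* the running mean."""
    rm = running_mean(x, _half_width(window_s, rate), valid=valid, symmetric=False)
    return rolling_sd(rm, window_s, rate, valid=valid)


# ---------------------------------------------------------------------------
# Orientation
# ---------------------------------------------------------------------------

def pitch(S_h, S_l, S_v) -> np.ndarray | float:
    """Body pitch B = atan(S_h / sqrt(S_l² + S_v²)) in degrees ∈ [−90, 90].

    Zero when S_h = 0; sign follows S_h; ±90 in the arctangent limit when
    the lateral plane carries no gravity (S_l = S_v = 0).  An all-zero
    static vector has no defined orientation: scalars raise, arrays get NaN.
    """
    scalar = np.isscalar(S_h) and np.isscalar(S_l) and np.isscalar(S_v)
    S_h = np.asarray(S_h, dtype=float)
    denom = np.hypot(np.asarray(S_l, dtype=float), np.asarray(S_v, dtype=float))
    undefined = (denom == 0) & (S_h == 0)
    if scalar and undefined:
        raise DomainError("all-zero static vector: orientation undefined")
    b = np.degrees(np.arctan2(S_h, denom))
    b = np.where(undefined, np.nan, b)
    return float(b) if scalar else b


def vertical_speed(depth) -> np.ndarray:
    """Per-second change in depth on the 1 Hz grid (positive = descending).

    The first sample is assigned 0.
    """
    depth = np.asarray(depth, dtype=float)
    if depth.size < 2:
        raise ContractError("need at least two depth samples")
    return np.concatenate(([0.0], np.diff(depth)))


def standardize(x, valid=None, name: str = "channel") -> np.ndarray:
    """(x − mean)/SD over the valid samples (sample SD, n−1).

    Idempotent to floating precision; raises on zero variance.
    """
    x = np.asarray(x, dtype=float)
    if valid is None:
        valid = np.isfinite(x)
    else:
        valid = np.asarray(valid, dtype=bool) & np.isfinite(x)
    if valid.sum() < 2:
        raise StandardizationError(f"{name}: too few valid samples")
    mu = float(np.mean(x[valid]))
    sd = float(np.std(x[valid], ddof=1))
    if sd == 0.0:
        raise StandardizationError(f"{name}: zero variance")
    return (x - mu) / sd


# ---------------------------------------------------------------------------
# Feature table assembly
# ---------------------------------------------------------------------------

#: windows exactly as printed for the two study species:
#: razorbill — 1 s static running mean, 10 s amplitude window;
#: guillemot — 2 s static running mean, 5 s amplitude window.
SPECIES_PRESETS = {
    "razorbill": {"static_window_s": 1.0, "amp_window_s": 10.0},
    "guillemot": {"static_window_s": 2.0, "amp_window_s": 5.0},
}

#: channels the clustering stage consumes
UNDERWATER_CHANNELS = ["Amp_v", "B_var", "z_V_s", "z_D_h", "z_D_l", "z_D_v", "z_B"]
ABOVEWATER_CHANNELS = ["Amp_v", "z_D_h", "z_D_l", "z_D_v", "z_B"]
_Z_SOURCES = {"z_V_s": "V_s", "z_D_h": "D_h", "z_D_l": "D_l", "z_D_v": "D_v", "z_B": "B"}


@dataclass(frozen=True)
class FeatureConfig:
    """Tunable windows and thresholds for the feature chain."""

    static_window_s: float = 1.0       # running-mean width for S (s)
    amp_window_s: float = 10.0         # rolling-SD width for Amp_v / B_var (s)
    latitude: float = 57.0             # degrees, for the gravity term
    surface_threshold_m: float = 0.2   # submerged ⇔ Depth > threshold
    standardization_scope: str = "per-deployment"   # or "pooled"
    amp_mode: str = "rolling_sd"       # or "sd_of_running_mean"
    pitch_offset_deg: float | None = None   # None → estimate from resting samples
    surface_pressure_mbar: float | None = None  # None → estimate from the record

    def __post_init__(self) -> None:
        if self.static_window_s <= 0 or self.amp_window_s <= 0:
            raise ConfigError("window widths must be positive")
        if not (0 < self.surface_threshold_m < 1):
            raise ConfigError("surface_threshold_m must be in (0, 1) m")
        if self.amp_mode not in ("rolling_sd", "sd_of_running_mean"):
            raise ConfigError(f"unknown amp_mode {self.amp_mode!r}")
        if self.standardization_scope not in ("per-deployment", "pooled"):
            raise ConfigError("standardization_scope must be per-deployment or pooled")

    @classmethod
    def for_species(cls, species: str, **kw) -> "FeatureConfig":
        if species not in SPECIES_PRESETS:
            raise ConfigError(f"unknown species preset {species!r}")
        return cls(**{**SPECIES_PRESETS[species], **kw})

    @classmethod
    def from_yaml(cls, path) -> "FeatureConfig":
        import yaml
        with open(path) as fh:
            doc = yaml.safe_load(fh) or {}
        species = doc.pop("species", None)
        return cls.for_species(species, **doc) if species else cls(**doc)


@dataclass
class FeatureTable:
    """Per-sample derived variables on the 25 Hz grid.

    ``data`` columns: time, A_*, S_*, D_*, B_raw, B, Depth, V_s, Amp_v,
    B_var, z_* copies, wet, gap.  ``env`` holds the companion 1 Hz table
    (time, pressure_mbar, Depth, V_s) used by the dive module.
    """

    data: pd.DataFrame
    env: pd.DataFrame
    rate_hz: float
    deployment_id: str
    pitch_offset_deg: float
    surface_pressure_mbar: float
    config: FeatureConfig = field(default_factory=FeatureConfig)

    def __len__(self) -> int:
        return len(self.data)

    @property
    def wet(self) -> np.ndarray:
        return self.data["wet"].to_numpy()

    @property
    def gap(self) -> np.ndarray:
        return self.data["gap"].to_numpy()

    def matrix(self, channels: Sequence[str]) -> np.ndarray:
        missing = [c for c in channels if c not in self.data.columns]
        if missing:
            raise ContractError(f"channels not in feature table: {missing}")
        return self.data[list(channels)].to_numpy(dtype=float)

    def to_csv(self, path) -> None:
        self.data.to_csv(path, index=False)


def estimate_pitch_offset(features: FeatureTable) -> float:
    """Device-mounting pitch offset: the median raw pitch over quiet
    surface samples (Depth below the surface threshold and Amp_v at or
    below its 25th percentile among those samples).

    A bird resting on the sea surface is level, so this median is the
    orientation error of the logger; the caller subtracts it from B.
    """
    d = features.data
    b = d["B_raw"].to_numpy() if "B_raw" in d.columns else d["B"].to_numpy()
    return _pitch_offset(b, d["Depth"].to_numpy(), d["Amp_v"].to_numpy(),
                         features.gap, features.config.surface_threshold_m)


def _pitch_offset(b_raw, depth, amp_v, gap, surface_threshold_m: float) -> float:
    surface = (depth < surface_threshold_m) & ~gap & np.isfinite(b_raw)
    if not surface.any():
        raise CalibrationError(
            "no surface samples for pitch calibration; supply pitch_offset_deg manually")
    q25 = np.quantile(amp_v[surface], 0.25)
    resting = surface & (amp_v <= q25)
    if not resting.any():
        raise CalibrationError(
            "no quiet surface-resting samples; supply pitch_offset_deg manually")
    return float(np.median(b_raw[resting]))


def build_feature_table(dep: RawDeployment, cfg: FeatureConfig | None = None) -> FeatureTable:
    """Run the full feature chain on a deployment.

    Depth and V_s are computed on the 1 Hz grid and linearly interpolated
    onto the 25 Hz acceleration grid; the wet flag is Depth > threshold.
    A = S + D holds exactly on every sample by construction.
    """
    cfg = cfg or FeatureConfig()
    t = dep.accel_time
    if t.size == 0:
        raise ContractError("empty deployment")
    gap = dep.gap_mask.copy()
    valid = ~gap

    # --- 1 Hz chain: pressure → depth → vertical speed
    p_surf = (cfg.surface_pressure_mbar if cfg.surface_pressure_mbar is not None
              else estimate_surface_pressure(dep.pressure_mbar))
    p_db = np.maximum(dep.pressure_mbar - p_surf, 0.0) / 100.0
    depth_env = pressure_to_depth(p_db, cfg.latitude)
    v_s_env = vertical_speed(depth_env) if depth_env.size >= 2 else np.zeros_like(depth_env)
    env = pd.DataFrame({
        "time": dep.env_time,
        "pressure_mbar": dep.pressure_mbar,
        "Depth": depth_env,
        "V_s": v_s_env,
        "temperature_c": dep.temperature_c,
    })

    depth = np.interp(t, dep.env_time, depth_env)
    v_s = np.interp(t, dep.env_time, v_s_env)

    # --- static / dynamic decomposition and orientation
    rate = dep.f_acc
    cols: dict[str, np.ndarray] = {"time": t}
    for axis, raw in (("h", dep.A_h), ("l", dep.A_l), ("v", dep.A_v)):
        s = static_acceleration(raw, cfg.static_window_s, rate, valid=valid)
        s = np.where(np.isfinite(s), s, raw)  # gap samples: no smoothing
        cols[f"A_{axis}"] = raw
        cols[f"S_{axis}"] = s
        cols[f"D_{axis}"] = dynamic_acceleration(raw, s)

    b_raw = pitch(cols["S_h"], cols["S_l"], cols["S_v"])

    amp_fn = rolling_sd if cfg.amp_mode == "rolling_sd" else sd_of_running_mean
    amp_v = amp_fn(cols["D_v"], cfg.amp_window_s, rate, valid=valid)

    if cfg.pitch_offset_deg is not None:
        offset = cfg.pitch_offset_deg
    else:
        offset = _pitch_offset(b_raw, depth, amp_v, gap, cfg.surface_threshold_m)
    b = b_raw - offset

    db = np.concatenate(([0.0], np.diff(b)))
    b_var = amp_fn(db, cfg.amp_window_s, rate, valid=valid)

    cols.update(B_raw=b_raw, B=b, Depth=depth, V_s=v_s, Amp_v=amp_v, B_var=b_var)

    # --- standardized copies (per-deployment scope)
    for zname, src in _Z_SOURCES.items():
        try:
            cols[zname] = standardize(cols[src], valid=valid, name=src)
        except StandardizationError:
            warnings.warn(f"channel {src} has zero variance; z-copy set to 0",
                          stacklevel=2)
            cols[zname] = np.zeros_like(cols[src])

    cols["wet"] = depth > cfg.surface_threshold_m
    cols["gap"] = gap
    return FeatureTable(
        data=pd.DataFrame(cols),
        env=env,
        rate_hz=rate,
        deployment_id=dep.deployment_id,
        pitch_offset_deg=float(offset),
        surface_pressure_mbar=float(p_surf),
        config=cfg,
    )
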