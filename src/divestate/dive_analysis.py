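"""Wet/dry segmentation, dive detection and dive summary statistics.

All operations work on the 1 Hz depth series.  A dive is a maximal
submerged interval (depth above the surface threshold) whose maximum depth
reaches at least 1 m; shallower splashes are discarded, as are submerged
excursions shorter than a minimum duration (default 3 s, disable with
``min_duration_s=None``).  The bottom phase — the interval between the end
of descent and the start of ascent — is delimited by the smoothed vertical
speed approaching zero relative to the dive's peak descent/ascent rates
(the depth profile's inflection region); a pure V-shaped dive has none.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import ContractError
from .signal_features import FeatureTable, running_mean


@dataclass
class DiveRecord:
    """One detected dive."""

    dive_index: int
    start_time: float
    end_time: float
    max_depth: float
    bottom_start: float | None = None
    bottom_end: float | None = None

    @property
    def duration(self) -> float:
        return self.end_time - self.start_time

    def __post_init__(self) -> None:
        if not self.start_time < self.end_time:
            raise ContractError("dive start must precede its end")
        if (self.bottom_start is None) != (self.bottom_end is None):
            raise ContractError("bottom interval must be fully present or absent")
        if self.bottom_start is not None:
            if not (self.start_time <= self.bottom_start < self.bottom_end <= self.end_time):
                raise ContractError("bottom interval must nest inside the dive")


@dataclass(frozen=True)
class WetDryInterval:
    start: int        # index of first sample
    stop: int         # one past the last sample
    submerged: bool


def segment_wet_dry(depth, surface_threshold_m: float = 0.2) -> list[WetDryInterval]:
    """Maximal contiguous intervals labeled submerged / surface.

    Intervals tile the record with no overlap; an empty series yields an
    empty list.
    """
    depth = np.asarray(depth, dtype=float)
    n = depth.size
    if n == 0:
        return []
    sub = depth > surface_threshold_m
    change = np.nonzero(np.diff(sub))[0] + 1
    bounds = np.concatenate(([0], change, [n]))
    return [WetDryInterval(int(a), int(b), bool(sub[a]))
            for a, b in zip(bounds[:-1], bounds[1:])]


def detect_dives(time, depth, min_depth_m: float = 1.0,
                 surface_threshold_m: float = 0.2,
                 min_duration_s: float | None = 3.0,
                 bottom_q: float = 0.25) -> list[DiveRecord]:
    """One DiveRecord per submerged interval with max depth ≥ ``min_depth_m``.

    ``min_duration_s`` suppresses splash artifacts; pass None to disable.
    """
    time = np.asarray(time, dtype=float)
    depth = np.asarray(depth, dtype=float)
    if time.size != depth.size:
        raise ContractError("time and depth length mismatch")
    dives: list[DiveRecord] = []
    for iv in segment_wet_dry(depth, surface_threshold_m):
        if not iv.submerged:
            continue
        seg_t = time[iv.start:iv.stop]
        seg_d = depth[iv.start:iv.stop]
        if float(seg_d.max()) < min_depth_m:
            continue
        duration = float(seg_t[-1] - seg_t[0])
        if min_duration_s is not None and duration < min_duration_s:
            continue
        bottom = bottom_phase(seg_t, seg_d, q=bottom_q)
        dives.append(DiveRecord(
            dive_index=len(dives),
            start_time=float(seg_t[0]),
            end_time=float(seg_t[-1]),
            max_depth=float(seg_d.max()),
            bottom_start=None if bottom is None else bottom[0],
            bottom_end=None if bottom is None else bottom[1],
        ))
    return dives


def bottom_phase(time, depth, q: float = 0.25, smooth_s: float = 3.0,
                 min_bottom_s: float = 4.0) -> tuple[float, float] | None:
    """Bottom interval of one dive from the inflection of its depth profile.

    The smoothed vertical speed is compared with the dive's peak descent
    and ascent rates: the bottom starts where it first falls below
    ``q``·peak-descent (after the descent peak) and ends where it last
    exceeds −``q``·peak-ascent (before the ascent trough).  Returns None
    (a V-shaped dive) when no interval of at least ``min_bottom_s`` exists.
    """
    time = np.asarray(time, dtype=float)
    depth = np.asarray(depth, dtype=float)
    if time.size < 5:
        return None
    vs = np.gradient(depth, time)
    dt = float(np.median(np.diff(time)))
    half = max(int(round(smooth_s / dt / 2.0)), 1)
    vs = running_mean(vs, half, symmetric=True)
    peak_desc = float(vs.max())
    peak_asc = float(-vs.min())
    if peak_desc <= 0 or peak_asc <= 0:
        return None
    i_d = int(np.argmax(vs))
    i_a = int(np.argmin(vs))
    if i_d >= i_a:
        return None
    below = np.nonzero(vs[i_d:i_a + 1] < q * peak_desc)[0]
    above = np.nonzero(vs[i_d:i_a + 1] > -q * peak_asc)[0]
    if below.size == 0 or above.size == 0:
        return None
    bs = i_d + int(below[0])
    be = i_d + int(above[-1])
    if bs >= be or time[be] - time[bs] < min_bottom_s:
        return None
    return float(time[bs]), float(time[be])


@dataclass
class DiveSummary:
    n: int
    depth_mean: float | None
    depth_sd: float | None
    duration_mean: float | None
    duration_sd: float | None
    dives_per_hour: float


def dive_summary(dives: Sequence[DiveRecord], recorded_hours: float) -> DiveSummary:
    """Mean/SD of max depth and duration (sample SD), plus dives per hour."""
    if recorded_hours <= 0:
        raise ContractError("recorded_hours must be positive")
    n = len(dives)
    if n == 0:
        return DiveSummary(0, None, None, None, None, 0.0)
    depths = np.array([d.max_depth for d in dives])
    durs = np.array([d.duration for d in dives])
    sd = (lambda x: float(np.std(x, ddof=1))) if n > 1 else (lambda x: None)
    return DiveSummary(
        n=n,
        depth_mean=float(depths.mean()),
        depth_sd=sd(depths),
        duration_mean=float(durs.mean()),
        duration_sd=sd(durs),
        dives_per_hour=n / recorded_hours,
    )


def dives_from_features(features: FeatureTable, **kw) -> list[DiveRecord]:
    """Run dive detection on a feature table's 1 Hz depth channel."""
    kw.setdefault("surface_threshold_m", features.config.surface_threshold_m)
    return detect_dives(features.env["time"].to_numpy(),
                        features.env["Depth"].to_numpy(), **kw)


def dives_to_frame(dives: Sequence[DiveRecord]) -> pd.DataFrame:
    return pd.DataFrame([{
        "dive_index": d.dive_index,
        "start": d.start_time,
        "end": d.end_time,
        "duration": d.duration,
        "max_depth": d.max_depth,
        "bottom_start": d.bottom_start,
        "bottom_end": d.bottom_end,
    } for d in dives], columns=["dive_index", "start", "end", "duration",
                                "max_depth", "bottom_start", "bottom_end"])


def write_dive_table(dives: Sequence[DiveRecord], path) -> None:
    dives_to_frame(dives).to_csv(path, index=False)
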