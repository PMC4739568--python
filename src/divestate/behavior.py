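"""Temporal smoothing, transition matrices, per-state summaries and GPS.

A behavior is only deemed to occur when consistent for at least one
second, so hard labels are smoothed before any sequence analysis: the
posterior responsibility matrix is run through a centered 1 s running
mean and re-argmaxed (a majority-vote mode filter is available as an
alternative — a "running mean" of a categorical partition is not
computable literally on labels).

Transition probabilities Pr(Z_t = j | Z_{t-1} = i) are estimated on a
1 Hz label grid (per-second majority of the smoothed labels) from counts
of consecutive pairs; sequence breaks — data gaps and wet/dry scope
boundaries — contribute no transitions, and pooling across individuals
sums counts before normalizing.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import ContractError
from .gmm_em import StateSequence
from .io_formats import GPSTrack
from .signal_features import FeatureTable, running_mean

EARTH_RADIUS_M = 6_371_000.0


# ---------------------------------------------------------------------------
# Label smoothing
# ---------------------------------------------------------------------------

def smooth_states(seq: StateSequence, window_s: float = 1.0, rate: float = 25.0,
                  method: str = "mean") -> StateSequence:
    """Fill ``smoothed_labels`` by temporally smoothing the partition.

    ``method="mean"`` (primary): argmax of the centered running mean of
    the responsibilities; ``method="mode"``: centered majority vote on the
    hard labels.  Raw labels are preserved.
    """
    if window_s * rate < 1:
        raise ContractError("window must span at least one sample")
    n = len(seq)
    if n == 0:
        return replace(seq, smoothed_labels=seq.labels.copy())
    half = int(round(window_s * rate / 2.0))
    if method == "mean":
        sm = np.column_stack([
            running_mean(seq.responsibilities[:, k], half, symmetric=False)
            for k in range(seq.K)])
        smoothed = np.argmax(sm, axis=1) + 1
    elif method == "mode":
        onehot = np.equal.outer(seq.labels, np.arange(1, seq.K + 1)).astype(float)
        sm = np.column_stack([running_mean(onehot[:, k], half, symmetric=False)
                              for k in range(seq.K)])
        smoothed = np.argmax(sm, axis=1) + 1
    else:
        raise ContractError(f"unknown smoothing method {method!r}")
    return replace(seq, smoothed_labels=smoothed)


def labels_to_1hz(time, labels) -> tuple[np.ndarray, np.ndarray]:
    """Downsample labels to a 1 Hz grid by per-second majority.

    Returns (second stamps, labels); ties break toward the smaller label.
    """
    time = np.asarray(time, dtype=float)
    labels = np.asarray(labels)
    if time.size == 0:
        return np.array([]), np.array([], dtype=int)
    sec = np.floor(time).astype(int)
    out_sec, out_lab = [], []
    for s in np.unique(sec):
        vals, counts = np.unique(labels[sec == s], return_counts=True)
        out_sec.append(s)
        out_lab.append(int(vals[np.argmax(counts)]))
    return np.asarray(out_sec, dtype=float), np.asarray(out_lab, dtype=int)


# ---------------------------------------------------------------------------
# Transition matrices
# ---------------------------------------------------------------------------

@dataclass
class TransitionMatrix:
    """Row-stochastic matrix P[i, j] = Pr(Z_t = j | Z_{t-1} = i)."""

    counts: np.ndarray               # (K, K) integer transition counts
    probabilities: np.ndarray        # rows sum to 1 where defined, else NaN
    states: np.ndarray               # 1-based state ids, row/column order
    row_defined: np.ndarray          # False where a state was never left

    @property
    def K(self) -> int:
        return self.counts.shape[0]


def transition_matrix(labels, K: int | None = None) -> TransitionMatrix:
    """Estimate P from one label sequence or a list of label segments.

    Each segment contributes its consecutive pairs only — segment breaks
    (gaps, scope boundaries) never span a transition.  Rows with zero
    outgoing counts are flagged undefined (NaN), not fabricated.
    """
    if isinstance(labels, (list, tuple)) and labels and not np.isscalar(labels[0]):
        segments = [np.asarray(s, dtype=int) for s in labels]
    else:
        segments = [np.asarray(labels, dtype=int)]
    total = sum(s.size for s in segments)
    if total < 2:
        raise ContractError("need at least two labels to count transitions")
    if K is None:
        K = int(max(s.max() for s in segments if s.size))
    counts = np.zeros((K, K), dtype=np.int64)
    for s in segments:
        if s.size < 2:
            continue
        if s.min() < 1 or s.max() > K:
            raise ContractError("labels must lie in {1..K}")
        np.add.at(counts, (s[:-1] - 1, s[1:] - 1), 1)
    row_tot = counts.sum(axis=1)
    defined = row_tot > 0
    probs = np.full((K, K), np.nan)
    probs[defined] = counts[defined] / row_tot[defined, None]
    return TransitionMatrix(
        counts=counts,
        probabilities=probs,
        states=np.arange(1, K + 1),
        row_defined=defined,
    )


def pool_transition_matrices(matrices: Sequence[TransitionMatrix]) -> TransitionMatrix:
    """Species-level pooling: sum counts across individuals, then normalize."""
    if not matrices:
        raise ContractError("nothing to pool")
    K = matrices[0].K
    if any(m.K != K for m in matrices):
        raise ContractError("cannot pool matrices of different K")
    counts = np.sum([m.counts for m in matrices], axis=0)
    row_tot = counts.sum(axis=1)
    defined = row_tot > 0
    probs = np.full((K, K), np.nan)
    probs[defined] = counts[defined] / row_tot[defined, None]
    return TransitionMatrix(counts, probs, np.arange(1, K + 1), defined)


def write_transition_csv(tm: TransitionMatrix, path) -> None:
    """Counts and probabilities side by side, one row per origin state."""
    rows = []
    for i, s in enumerate(tm.states):
        row = {"state": int(s), "defined": bool(tm.row_defined[i])}
        for j, t in enumerate(tm.states):
            row[f"n_to_{int(t)}"] = int(tm.counts[i, j])
            row[f"p_to_{int(t)}"] = tm.probabilities[i, j]
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Per-state feature summaries
# ---------------------------------------------------------------------------

def per_state_summary(features: FeatureTable, labels,
                      channels: Sequence[str] = ("B", "D_v"),
                      mask=None) -> pd.DataFrame:
    """Mean and SD of each requested channel per state, with n per state.

    ``labels`` must align with the feature rows selected by ``mask``
    (default: all rows).  States absent from the data get an n = 0 row
    only if present in ``labels``' 1..max range.
    """
    d = features.data if mask is None else features.data[np.asarray(mask, bool)]
    labels = np.asarray(labels, dtype=int)
    if len(d) != labels.size:
        raise ContractError("labels do not align with the selected feature rows")
    rows = []
    for s in range(1, labels.max(initial=0) + 1):
        sel = labels == s
        row = {"state": s, "n": int(sel.sum())}
        for ch in channels:
            x = d[ch].to_numpy()[sel]
            x = x[np.isfinite(x)]
            row[f"{ch}_mean"] = float(x.mean()) if x.size else np.nan
            row[f"{ch}_sd"] = float(np.std(x, ddof=1)) if x.size > 1 else np.nan
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# GPS joining and colony distance
# ---------------------------------------------------------------------------

def haversine_m(lat1, lon1, lat2, lon2) -> np.ndarray | float:
    """Great-circle distance in meters (Earth radius 6,371,000 m)."""
    lat1, lon1, lat2, lon2 = map(np.radians, (np.asarray(lat1, float),
                                              np.asarray(lon1, float),
                                              np.asarray(lat2, float),
                                              np.asarray(lon2, float)))
    a = (np.sin((lat2 - lat1) / 2) ** 2
         + np.cos(lat1) * np.cos(lat2) * np.sin((lon2 - lon1) / 2) ** 2)
    d = 2 * EARTH_RADIUS_M * np.arcsin(np.sqrt(a))
    return float(d) if d.ndim == 0 else d


def distance_to_colony(track: GPSTrack) -> np.ndarray:
    """Distance of every fix from the colony, taken as the first fix.

    Also fills ``track.distance_to_colony``.
    """
    if len(track) == 0:
        raise ContractError("empty GPS track")
    d = haversine_m(track.lat, track.lon, track.lat[0], track.lon[0])
    d = np.atleast_1d(d)
    track.distance_to_colony = d
    return d


def join_gps(seq: StateSequence, track: GPSTrack,
             tolerance_s: float = 100.0) -> pd.DataFrame:
    """Annotate each sample with the nearest-in-time fix within tolerance.

    Samples with no fix within ``tolerance_s`` get NaN annotations; fully
    disjoint time ranges raise a warning and return an all-absent table.
    """
    if len(track) == 0:
        raise ContractError("empty GPS track")
    t = seq.time
    ft = track.fix_time
    idx = np.clip(np.searchsorted(ft, t), 1, max(len(ft) - 1, 1)) if len(ft) > 1 \
        else np.zeros(t.size, dtype=int)
    if len(ft) > 1:
        left = idx - 1
        idx = np.where(np.abs(ft[idx] - t) < np.abs(ft[left] - t), idx, left)
    dt = np.abs(ft[idx] - t) if t.size else np.array([])
    within = dt <= tolerance_s
    if t.size and not within.any():
        warnings.warn("state sequence and GPS track do not overlap in time",
                      stacklevel=2)
    dist = (track.distance_to_colony if track.distance_to_colony is not None
            else distance_to_colony(track))
    out = pd.DataFrame({
        "time": t,
        "fix_time": np.where(within, ft[idx], np.nan),
        "lat": np.where(within, track.lat[idx], np.nan),
        "lon": np.where(within, track.lon[idx], np.nan),
        "dt": np.where(within, dt, np.nan),
        "distance_to_colony": np.where(within, dist[idx], np.nan),
    })
    if seq.smoothed_labels is not None:
        out["smoothed_label"] = seq.smoothed_labels
    out["label"] = seq.labels
    return out
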