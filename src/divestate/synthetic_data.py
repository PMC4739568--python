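"""Simulated multi-rate biologging deployments with known ground truth.

A deployment is driven by a 1 Hz Markov chain over named behavioral states
(e.g. flight, float, rest, descent, chase, ascent).  Each state carries an
emission model: a mean body pitch with jitter, per-axis dynamic-acceleration
noise, an optional flapping oscillation on the heave axis (a sinusoid plus
noise — a stand-in for the constant wing-beat signal of flying auks), and a
depth rate.  Depth integrates the state rates at 1 Hz with a reflecting
floor just below the surface; dives end by a chain transition out of a
designated exit state (the ascent), never by the depth trajectory itself.
That matters statistically: because every realized underwater transition —
including the exit — is drawn from the scenario's transition matrix, the
empirical underwater transition matrix of the truth labels is an unbiased
estimate of the generator's (renormalized) underwater block, which is what
the recovery experiment measures convergence against.  A depth-terminated
design would instead censor ascent transitions near the surface and bias
the process away from its own generator.

The 25 Hz accelerometer signal is built as A = S + D with
S = g·(sin B, 0, cos B) for the (jittered) state pitch B plus a constant
device-mounting offset, and D the state's dynamic noise.  Pressure is the
exact inverse of the package's own depth conversion plus surface pressure
and sensor noise, so the feature chain can reconstruct depth to millimeters.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.optimize import linear_sum_assignment

from . import behavior, dive_analysis, gmm_em
from .errors import ConfigError
from .io_formats import GPSTrack, RawDeployment
from .signal_features import (UNDERWATER_CHANNELS, FeatureConfig,
                              build_feature_table, gravity, pressure_to_depth)


@dataclass(frozen=True)
class StateSpec:
    """Emission and dynamics parameters of one behavioral state."""

    name: str
    wet: bool = False
    pitch_deg: float = 0.0
    pitch_jitter_deg: float = 4.0        # sd of white pitch noise before smoothing
    dyn_sd: tuple[float, float, float] = (0.1, 0.1, 0.1)   # surge/sway/heave, m/s²
    depth_rate: float = 0.0              # m/s, positive = descending
    depth_rate_sd: float = 0.0
    flap_amp: float = 0.0                # sinusoid amplitude on heave, m/s²
    flap_freq_hz: float = 8.0
    dive_entry: bool = False             # may be entered directly from a dry state
    dive_exit: bool = False              # may transition back to a dry state


@dataclass
class Scenario:
    """A complete simulated-trip specification."""

    states: Sequence[StateSpec]
    transition: np.ndarray               # (S, S) row-stochastic, 1 Hz
    duration_h: float = 2.0
    f_acc: float = 25.0
    f_env: float = 1.0
    latitude: float = 57.0
    surface_pressure_mbar: float = 1013.0
    pressure_noise_mbar: float = 0.5
    temperature_c: float = 8.0
    mount_offset_deg: float = 0.0        # imperfect device orientation
    min_submerged_m: float = 1.2         # depth floor while submerged
    static_window_s: float = 1.0         # matched analysis windows
    amp_window_s: float = 10.0

    def __post_init__(self) -> None:
        self.transition = np.asarray(self.transition, dtype=float)
        self.validate()

    @property
    def wet_indices(self) -> list[int]:
        return [i for i, s in enumerate(self.states) if s.wet]

    @property
    def dry_indices(self) -> list[int]:
        return [i for i, s in enumerate(self.states) if not s.wet]

    def validate(self) -> None:
        S = len(self.states)
        P = self.transition
        if P.shape != (S, S):
            raise ConfigError("transition matrix shape must match state count")
        if np.any(P < 0) or not np.allclose(P.sum(axis=1), 1.0, atol=1e-9):
            raise ConfigError("transition rows must be non-negative and sum to 1")
        if self.duration_h <= 0:
            raise ConfigError("duration must be positive")
        if not self.dry_indices:
            raise ConfigError("at least one dry (surface) state is required")
        for i in self.dry_indices:
            for j in self.wet_indices:
                if P[i, j] > 0 and not self.states[j].dive_entry:
                    raise ConfigError(
                        f"dry state {self.states[i].name!r} may only enter the water "
                        f"via a dive-entry state, not {self.states[j].name!r}")
        for i in self.wet_indices:
            for j in self.dry_indices:
                if P[i, j] > 0 and not self.states[i].dive_exit:
                    raise ConfigError(
                        "underwater states may only surface via a dive-exit state "
                        f"({self.states[i].name!r} → {self.states[j].name!r})")

    def feature_config(self, **kw) -> FeatureConfig:
        return FeatureConfig(static_window_s=self.static_window_s,
                             amp_window_s=self.amp_window_s,
                             latitude=self.latitude, **kw)


@dataclass
class SimulationTruth:
    """Ground truth accompanying a simulated deployment."""

    state_env: np.ndarray            # (T,) state indices on the 1 Hz grid
    state_acc: np.ndarray            # (T·f_acc,) indices on the 25 Hz grid
    depth_env: np.ndarray            # (T,) true depth, m
    pitch_acc: np.ndarray            # (n,) true pitch (no mount offset), degrees
    static_acc: np.ndarray           # (n, 3) true static acceleration
    dives: list                      # DiveRecord list from the true depth
    wet_state_indices: list[int]     # scenario indices of the underwater states
    scenario: Scenario = None

    def underwater_labels_env(self) -> np.ndarray:
        """1-based underwater labels on the 1 Hz grid; 0 where dry."""
        lab = np.zeros(self.state_env.size, dtype=int)
        for rank, idx in enumerate(self.wet_state_indices, start=1):
            lab[self.state_env == idx] = rank
        return lab


def _pressure_from_depth(depth, latitude: float) -> np.ndarray:
    """Invert the UNESCO depth conversion (fixed point; exact to ~1e-10 m)."""
    depth = np.asarray(depth, dtype=float)
    p = depth * gravity(latitude, 0.0) / 9.72659
    for _ in range(4):
        d_hat = np.asarray(pressure_to_depth(p, latitude))
        with np.errstate(invalid="ignore", divide="ignore"):
            ratio = np.where(d_hat > 0, depth / np.where(d_hat > 0, d_hat, 1.0), 1.0)
        p = p * ratio
    return p


def simulate_deployment(scenario: Scenario, seed: int
                        ) -> tuple[RawDeployment, SimulationTruth]:
    """Simulate one deployment; bit-identical for identical seeds."""
    rng = np.random.default_rng(seed)
    T = int(round(scenario.duration_h * 3600))
    S = len(scenario.states)
    P = scenario.transition

    # --- 1 Hz latent chain; depth integrates state rates with a floor
    state = np.empty(T, dtype=int)
    depth = np.zeros(T)
    state[0] = scenario.dry_indices[0]
    for t in range(1, T):
        s = int(rng.choice(S, p=P[state[t - 1]]))
        state[t] = s
        spec = scenario.states[s]
        if spec.wet:
            d = depth[t - 1] + spec.depth_rate + (
                rng.normal(0.0, spec.depth_rate_sd) if spec.depth_rate_sd else 0.0)
            depth[t] = max(d, scenario.min_submerged_m)
        else:
            depth[t] = 0.0

    # --- 25 Hz emissions
    sps = int(round(scenario.f_acc))
    n = T * sps
    state_acc = np.repeat(state, sps)
    acc_time = np.arange(n) / scenario.f_acc

    pitch_mean = np.array([s.pitch_deg for s in scenario.states])[state_acc]
    jitter_sd = np.array([s.pitch_jitter_deg for s in scenario.states])[state_acc]
    noise = rng.normal(0.0, 1.0, n) * jitter_sd
    half = max(int(round(0.5 * scenario.f_acc / 2)), 1)     # 0.5 s smoothing
    kernel = np.ones(2 * half + 1) / (2 * half + 1)
    pitch_true = pitch_mean + np.convolve(noise, kernel, mode="same")

    g = gravity(scenario.latitude, 0.0)
    b = np.radians(pitch_true + scenario.mount_offset_deg)
    static = np.column_stack((g * np.sin(b), np.zeros(n), g * np.cos(b)))

    dyn_sd = np.array([s.dyn_sd for s in scenario.states])[state_acc]
    dynamic = rng.normal(0.0, 1.0, (n, 3)) * dyn_sd
    flap_amp = np.array([s.flap_amp for s in scenario.states])[state_acc]
    flap_freq = np.array([s.flap_freq_hz for s in scenario.states])[state_acc]
    dynamic[:, 2] += flap_amp * np.sin(2 * np.pi * flap_freq * acc_time)
    accel = static + dynamic

    # --- 1 Hz pressure channel (exact inverse of the depth conversion)
    p_db = _pressure_from_depth(depth, scenario.latitude)
    pressure = (scenario.surface_pressure_mbar + 100.0 * p_db
                + rng.normal(0.0, scenario.pressure_noise_mbar, T))
    temperature = scenario.temperature_c + rng.normal(0.0, 0.1, T)

    dep = RawDeployment(
        deployment_id=f"sim-{seed}",
        accel_time=acc_time,
        A_h=accel[:, 0], A_l=accel[:, 1], A_v=accel[:, 2],
        env_time=np.arange(T, dtype=float),
        pressure_mbar=pressure,
        temperature_c=temperature,
        latitude_colony=scenario.latitude,
        f_acc=scenario.f_acc,
        f_env=scenario.f_env,
    )
    dives = dive_analysis.detect_dives(
        np.arange(T, dtype=float), depth,
        min_depth_m=1.0, surface_threshold_m=scenario.min_submerged_m / 2.0,
        min_duration_s=3.0)
    truth = SimulationTruth(
        state_env=state,
        state_acc=state_acc,
        depth_env=depth,
        pitch_acc=pitch_true,
        static_acc=static,
        dives=dives,
        wet_state_indices=scenario.wet_indices,
        scenario=scenario,
    )
    return dep, truth


def simulate_gps_track(duration_s: float, seed: int,
                       colony: tuple[float, float] = (59.382, -1.807),
                       fix_interval_s: float = 100.0,
                       speed_ms: float = 8.0) -> GPSTrack:
    """Simple colony-out-and-back track for join tests (first fix = colony)."""
    rng = np.random.default_rng(seed)
    t = np.arange(0.0, duration_s, fix_interval_s)
    leg = np.minimum(t, duration_s - t) * speed_ms          # out then back, m
    bearing = rng.uniform(0, 2 * np.pi)
    dlat = leg * np.cos(bearing) / 111_320.0
    dlon = leg * np.sin(bearing) / (111_320.0 * np.cos(np.radians(colony[0])))
    return GPSTrack(fix_time=t, lat=colony[0] + dlat, lon=colony[1] + dlon)


# ---------------------------------------------------------------------------
# Shipped presets (parameter values inspired by shallow- and deep-diving auks)
# ---------------------------------------------------------------------------

def razorbill_like(duration_h: float = 2.0) -> Scenario:
    """Shallow diver: 3 underwater states, dives a few meters deep,
    1 s static / 10 s amplitude analysis windows."""
    states = [
        StateSpec("flight", wet=False, pitch_deg=0, pitch_jitter_deg=6,
                  dyn_sd=(0.8, 0.8, 1.0), flap_amp=6.0, flap_freq_hz=8.0),
        StateSpec("float", wet=False, pitch_deg=0, pitch_jitter_deg=4,
                  dyn_sd=(0.08, 0.08, 0.10)),
        StateSpec("rest", wet=False, pitch_deg=0, pitch_jitter_deg=1.5,
                  dyn_sd=(0.02, 0.02, 0.03)),
        StateSpec("descent", wet=True, pitch_deg=-40, pitch_jitter_deg=5,
                  dyn_sd=(0.20, 0.20, 0.30), depth_rate=0.8, depth_rate_sd=0.08,
                  dive_entry=True),
        StateSpec("chase", wet=True, pitch_deg=0, pitch_jitter_deg=25,
                  dyn_sd=(0.50, 0.50, 0.80), depth_rate=0.0, depth_rate_sd=0.12),
        StateSpec("ascent", wet=True, pitch_deg=40, pitch_jitter_deg=5,
                  dyn_sd=(0.05, 0.05, 0.07), depth_rate=-0.9, depth_rate_sd=0.05,
                  dive_exit=True),
    ]
    P = np.array([
        # flight float  rest   desc   chase  asc
        [0.970, 0.030, 0.000, 0.000, 0.000, 0.000],
        [0.010, 0.920, 0.005, 0.065, 0.000, 0.000],
        [0.005, 0.015, 0.980, 0.000, 0.000, 0.000],
        [0.000, 0.000, 0.000, 0.820, 0.150, 0.030],
        [0.000, 0.000, 0.000, 0.030, 0.850, 0.120],
        [0.000, 0.200, 0.000, 0.020, 0.060, 0.720],
    ])
    return Scenario(states=states, transition=P, duration_h=duration_h,
                    latitude=59.382, mount_offset_deg=4.0,
                    static_window_s=1.0, amp_window_s=10.0)


def guillemot_like(duration_h: float = 3.0) -> Scenario:
    """Deep diver: 4 underwater states including a low-variance deep-search
    state, dives tens of meters, 2 s static / 5 s amplitude windows."""
    states = [
        StateSpec("flight", wet=False, pitch_deg=0, pitch_jitter_deg=6,
                  dyn_sd=(0.8, 0.8, 1.0), flap_amp=6.0, flap_freq_hz=8.0),
        StateSpec("float", wet=False, pitch_deg=0, pitch_jitter_deg=4,
                  dyn_sd=(0.08, 0.08, 0.10)),
        StateSpec("rest", wet=False, pitch_deg=0, pitch_jitter_deg=1.5,
                  dyn_sd=(0.02, 0.02, 0.03)),
        StateSpec("descent", wet=True, pitch_deg=-38, pitch_jitter_deg=6,
                  dyn_sd=(0.20, 0.20, 0.35), depth_rate=1.2, depth_rate_sd=0.08,
                  dive_entry=True),
        StateSpec("search", wet=True, pitch_deg=4, pitch_jitter_deg=3,
                  dyn_sd=(0.10, 0.10, 0.12), depth_rate=0.0, depth_rate_sd=0.10),
        StateSpec("chase", wet=True, pitch_deg=0, pitch_jitter_deg=25,
                  dyn_sd=(0.45, 0.45, 0.65), depth_rate=0.0, depth_rate_sd=0.20),
        StateSpec("ascent", wet=True, pitch_deg=40, pitch_jitter_deg=6,
                  dyn_sd=(0.05, 0.05, 0.08), depth_rate=-1.3, depth_rate_sd=0.08,
                  dive_exit=True),
    ]
    P = np.array([
        # flight float  rest   desc   search chase  asc
        [0.970, 0.030, 0.000, 0.000, 0.000, 0.000, 0.000],
        [0.008, 0.950, 0.005, 0.037, 0.000, 0.000, 0.000],
        [0.005, 0.015, 0.980, 0.000, 0.000, 0.000, 0.000],
        [0.000, 0.000, 0.000, 0.960, 0.030, 0.008, 0.002],
        [0.000, 0.000, 0.000, 0.005, 0.935, 0.050, 0.010],
        [0.000, 0.000, 0.000, 0.002, 0.080, 0.838, 0.080],
        [0.000, 0.035, 0.000, 0.002, 0.018, 0.020, 0.925],
    ])
    return Scenario(states=states, transition=P, duration_h=duration_h,
                    latitude=56.065, mount_offset_deg=4.0,
                    static_window_s=2.0, amp_window_s=5.0)


PRESETS = {"razorbill": razorbill_like, "guillemot": guillemot_like}


# ---------------------------------------------------------------------------
# End-to-end recovery experiment
# ---------------------------------------------------------------------------

@dataclass
class RecoveryReport:
    """Parameter/state recovery of the full pipeline on one simulation."""

    label_agreement: float               # best-permutation, 1 Hz underwater grid
    transition_error_max: float          # vs the generator's underwater block
    dive_count_truth: int
    dive_count_detected: int
    n_underwater_seconds: int
    mean_abs_mean_error: float           # component means vs truth-class means
    permutation: np.ndarray              # est component k ↦ truth state perm[k]
    model: gmm_em.MixtureModel
    transition_estimated: behavior.TransitionMatrix
    transition_generator: np.ndarray


def generator_underwater_matrix(scenario: Scenario) -> np.ndarray:
    """The generator's transition block over underwater states (renormalized)."""
    idx = scenario.wet_indices
    P = scenario.transition[np.ix_(idx, idx)]
    return P / P.sum(axis=1, keepdims=True)


def recovery_experiment(scenario: Scenario, seed: int, *, K: int | None = None,
                        decimate: int = 1, n_starts: int = 4,
                        max_iter: int = 300,
                        smoothing_window_s: float = 1.0) -> RecoveryReport:
    """Run features → wet split → EM → smoothing → transitions against truth.

    Agreement and transitions are evaluated on the 1 Hz behavioral grid
    (per-second majority labels), over seconds that are underwater in both
    the pipeline's segmentation and the simulator's truth; component/state
    matching uses the best permutation (Hungarian assignment on the
    confusion matrix).
    """
    dep, truth = simulate_deployment(scenario, seed)
    cfg = scenario.feature_config()
    ft = build_feature_table(dep, cfg)

    dives_detected = dive_analysis.dives_from_features(ft)

    channels = UNDERWATER_CHANNELS
    mask = ft.wet & ~ft.gap & np.all(np.isfinite(ft.matrix(channels)), axis=1)
    X = ft.matrix(channels)[mask]
    t_wet = ft.data["time"].to_numpy()[mask]
    K_true = len(truth.wet_state_indices)
    K_fit = K if K is not None else K_true

    model = fit_gmm_for_recovery(X[::decimate], K_fit, seed, n_starts, max_iter,
                                 channels)
    seq = gmm_em.predict_sequence(model, X, t_wet)
    seq = behavior.smooth_states(seq, window_s=smoothing_window_s,
                                 rate=scenario.f_acc)

    sec, est_lab = behavior.labels_to_1hz(seq.time, seq.smoothed_labels)
    sec = sec.astype(int)
    truth_uw = truth.underwater_labels_env()
    in_truth = truth_uw[sec] > 0
    sec_m, est_m = sec[in_truth], est_lab[in_truth]
    tru_m = truth_uw[sec_m]

    # best permutation: estimated component -> truth state
    conf = np.zeros((K_fit, K_true), dtype=np.int64)
    np.add.at(conf, (est_m - 1, tru_m - 1), 1)
    rows, cols = linear_sum_assignment(-conf)
    perm = np.arange(max(K_fit, K_true))
    perm[rows] = cols
    agreement = float(conf[rows, cols].sum() / conf.sum()) if conf.sum() else 0.0

    # transitions on contiguous underwater 1 Hz segments, in truth-state order
    mapped = perm[est_m - 1] + 1
    breaks = np.nonzero(np.diff(sec_m) != 1)[0] + 1
    segments = np.split(mapped, breaks)
    tm = behavior.transition_matrix([s for s in segments if s.size >= 2], K=K_true)
    P_gen = generator_underwater_matrix(scenario)
    both = tm.row_defined[:, None] & np.isfinite(tm.probabilities)
    terr = float(np.nanmax(np.abs(tm.probabilities - P_gen)[both])) if both.any() else np.nan

    # component means vs empirical truth-class means in feature space
    truth_acc_uw = np.zeros(truth.state_acc.size, dtype=int)
    for rank, idx in enumerate(truth.wet_state_indices, start=1):
        truth_acc_uw[truth.state_acc == idx] = rank
    lab_acc = truth_acc_uw[mask]
    errs = []
    for k in range(K_fit):
        sel = lab_acc == perm[k] + 1
        if sel.any():
            errs.append(np.abs(model.means[k] - X[sel].mean(axis=0)))
    mean_err = float(np.mean(errs)) if errs else np.nan

    return RecoveryReport(
        label_agreement=agreement,
        transition_error_max=terr,
        dive_count_truth=len(truth.dives),
        dive_count_detected=len(dives_detected),
        n_underwater_seconds=int(sec_m.size),
        mean_abs_mean_error=mean_err,
        permutation=perm[:K_fit],
        model=model,
        transition_estimated=tm,
        transition_generator=P_gen,
    )


def fit_gmm_for_recovery(X, K, seed, n_starts, max_iter, channels):
    return gmm_em.fit_gmm(X, K, seed=seed, n_starts=n_starts,
                          max_iter=max_iter, channels=channels)
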