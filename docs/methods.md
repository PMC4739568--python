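# Methods

This note documents the models and numerical choices behind divestate: the
feature chain, the dive rules, the mixture model, the behavioral
summaries, and what the built-in simulator does and does not emulate.

## Data model

A deployment is multi-rate: tri-axial acceleration (surge `A_h`, sway
`A_l`, heave `A_v`) at a nominal 25 Hz, and pressure (millibar) plus
temperature at 1 Hz, all on one clock normalized to seconds since
deployment start. Acceleration input units are declared at ingest
(default g, multiplied by 9.80665 m/s²) so that reported heave values are
in m/s². Rows with missing acceleration are counted, never silently
dropped; timestamps gaps larger than two sample intervals are flagged and
excluded from every windowed statistic rather than interpolated — a
rolling SD spanning a gap is meaningless.

## Depth from pressure

Sea pressure is obtained by subtracting an estimated surface
(atmospheric) pressure from the logger's absolute pressure. The estimate
is the median of samples within 2 mbar of the record's 1st percentile —
the low-pressure cluster a diving logger records at the surface. This
assumes at least ~1 % of the record is spent at or above the surface;
without the offset, depth at the surface would read about 10 m. The
offset can be overridden in `FeatureConfig` when barometric data exist.

Millibar are divided by 100 to decibar and converted with the UNESCO
seawater formula (0 °C, 35 PSU water column assumed):

    g = 9.780318·[1 + (5.2788e−3 + 2.36e−5·x)·x] + 1.092e−6·p,
        x = sin²(latitude/57.29578)
    depth = [(((−1.82e−15·p + 2.279e−10)·p − 2.2512e−5)·p + 9.72659)·p]/g

with latitude taken as the colony's. Negative sea pressures after offset
removal (sensor noise at the surface) are clipped to zero.

## Feature chain

* **Static acceleration** `S` — centered running mean of each raw axis.
  Window: 1 s for razorbill-type, 2 s for guillemot-type deployments
  (species presets ship exactly these). Windows shrink symmetrically at
  the record edges, preserving the phase of events; a one-sample window
  is the identity.
* **Dynamic acceleration** `D = A − S` elementwise, so `A = S + D`
  reconstructs to one ulp.
* **Pitch** `B = atan(S_h/√(S_l²+S_v²))` in degrees, positive head-up,
  ±90° in the degenerate limit `S_l = S_v = 0`, undefined for an all-zero
  static vector. Device-mounting error is removed by subtracting the
  median raw pitch over quiet surface samples — depth below the surface
  threshold and `Amp_v` at or below its 25th percentile among those
  samples — on the assumption that a bird resting on the sea surface is
  level. If a deployment has no such samples the offset must be supplied
  manually (`FeatureConfig.pitch_offset_deg`). Note the resting samples
  are *surface* samples; the submerged (`wet`) flag itself is
  `Depth > surface_threshold` (default 0.2 m).
* **Vertical speed** `V_s` — first difference of the 1 Hz depth, m/s,
  positive descending, first sample 0.
* **Amplitude channels** — `Amp_v` is the centered rolling sample SD
  (n−1) of `D_v`; `B_var` the rolling SD of the first-differenced pitch.
  Window: 10 s (razorbill preset) or 5 s (guillemot preset). Edge windows
  are clipped. The phrase "SD over a running mean" admits a second
  reading — the SD *of* the running mean — which is available as
  `amp_mode="sd_of_running_mean"`; the rolling-SD reading is the default.
  The pitch offset, being a constant, does not affect `B_var`.
* **Standardization** — z-scores (sample SD) per deployment over non-gap
  samples. For group runs channels are standardized per individual before
  pooling, which keeps inter-individual gain differences from dominating
  the clusters. A zero-variance channel (possible in degenerate simulated
  records) yields a zero z-channel with a warning rather than an error.

Depth and `V_s` are linearly interpolated from the 1 Hz grid onto the
25 Hz feature grid; all clustering runs on the 25 Hz grid by default with
an integer decimation flag for speed.

### Numerical choices

Running means and rolling SDs are computed with cumulative sums (the
rolling variance is accumulated about the global mean to avoid
cancellation). They agree with naive per-window loops to ~1e-12 absolute;
tests assert 1e-8. Identities stated as "exact" (e.g. `A = S + D`) hold
to one ulp of the values involved.

## Dive analysis

The 1 Hz depth partitions the record into maximal surface/submerged
intervals at a configurable surface threshold (default 0.2 m — the
boundary between "wet at the surface" and "diving"; the dive definition
itself only fixes the ≥ 1 m max-depth rule, not start/end depths). A
submerged interval is a dive when its maximum depth is ≥ 1 m; excursions
shorter than 3 s are suppressed as splash artifacts (disable with
`min_duration_s=None`).

Bottom phase is delimited by the inflection region of the depth profile,
operationalized on the smoothed (3 s running mean) vertical speed: the
bottom starts where the speed first falls below a fraction q = 0.25 of
the dive's peak descent rate (after that peak) and ends where it last
exceeds −q times the peak ascent rate (before that trough). Intervals
shorter than 4 s are treated as absent — a V-shaped dive. The q-fraction
rule is this package's stated stand-in for proprietary dive-software
inflection detection, not a reconstruction of it.

## Gaussian mixture EM

The mixture `p(x) = Σ_k π_k N(x|μ_k, Σ_k)` with full per-component
covariances (diagonal available by flag) is fitted by EM:

* **E step** in log space via Cholesky factorizations and log-sum-exp;
  responsibilities are exact posteriors.
* **M step**: `π_k = N_k/n`, weighted means, weighted scatter plus
  `ε·I` with `ε = 1e−6 · trace(global covariance)/d`.
* **Initialization**: means seeded from data points with probability
  proportional to squared distance from the current seed set; covariances
  start at the (regularized) global covariance, weights uniform. Default
  10 restarts, best final log likelihood wins. EM is initialization-
  sensitive; on features with heavy-tailed amplitude channels a handful
  of restarts can land in a merged-state optimum, so restarts should not
  be reduced aggressively for underwater runs.
* **Convergence**: relative log-likelihood change < 1e−8 or 500
  iterations. Every iteration is non-decreasing in log likelihood up to a
  −1e−8 numerical floor (asserted in tests).
* **Collapse handling**: a component whose effective count drops below
  d+1 is reseeded once from a random data point (the monotone trace
  restarts); a second collapse aborts that start, and a fit error is
  raised only if every start aborts.
* **Model scoring**: BIC = −2·loglik + n_params·log n with
  n_params = (K−1) + K·d + K·d(d+1)/2 for full covariances. The
  ecological choice of K cannot be automated; `run_design` sweeps a K
  range and reports BIC per K, leaving the choice to the user. The
  above-water design is fixed at K = 3 (high activity flying/flapping,
  medium activity floating or walking, null activity resting).

Run designs select the channel sets listed in the README, restrict to
submerged (or dry) non-gap samples, and at group level pool one
contiguous, seeded, equal-duration block per animal (quota hours, e.g.
15 h or 22 h per individual on multi-day field deployments) before
fitting; per-animal state sequences are then decoded over each full
deployment.

## Behavioral summaries

A behavior is deemed to occur only when consistent for ≥ 1 s, so the
partition is smoothed before sequence analysis. A running mean of a
categorical partition is not computable literally, so the primary
smoother is the centered 1 s running mean of the *responsibility* matrix
followed by argmax; a majority-vote mode filter is the alternative. Raw
labels are always preserved alongside.

Transition matrices are estimated on a 1 Hz label grid (per-second
majority of smoothed labels, ties toward the smaller label) from counts
of consecutive pairs. Sequence breaks — data gaps and wet/dry scope
boundaries — contribute no transitions; in particular the matrices are
computed within contiguous same-scope segments, not across dives and
surface pauses. Rows never left are flagged undefined rather than
normalized. Species-level pooling sums counts across individuals before
normalizing.

GPS fixes (nominally every 100 s) are joined to samples by nearest time
within a tolerance (default 100 s); the colony is taken as the first fix
of the track and distances are great-circle (haversine, Earth radius
6 371 000 m).

## The simulator

`synthetic_data` drives a 1 Hz Markov chain over named states with
per-state emissions: mean pitch with smoothed jitter, per-axis dynamic
noise, an optional 8 Hz flapping sinusoid on heave (a stand-in for the
wing-beat signal — no biomechanical stroke model is attempted), and a
depth rate. Structural rules are validated: the water can only be
entered through a dive-entry state (descent) and left through a
dive-exit state (ascent).

Depth integrates the state rates with a floor of 1.2 m while submerged.
Two consequences are deliberate:

* **Dive termination is chain-driven, not depth-driven.** Each dive ends
  with a drawn ascent→surface transition; the depth then drops from its
  residual value to zero. Because every realized underwater transition,
  including the exit, is a draw from the transition matrix, the
  empirical underwater transition matrix of the truth labels is an
  unbiased estimate of the generator's renormalized underwater block.
  (An earlier depth-terminated design was measurably biased ~0.04 in
  max-entry error at 10⁴ steps, because surfacing censored late-ascent
  draws.)
* **The submerged floor keeps every wet excursion unambiguously above
  the 1 m dive rule**, so truth and detected dive counts can be compared
  exactly instead of flipping on sensor noise at the 1 m boundary.

Pressure is generated by numerically inverting the package's own depth
conversion (fixed point, exact to ~1e−10 m) plus surface pressure
(1013 mbar) and Gaussian sensor noise of 0.5 mbar — the stated accuracy
class of this kind of logger. Identical seeds give bit-identical output.

Two presets ship. `razorbill` (shallow diver): three underwater states —
descent (pitch −40°, 0.8 m/s), chase (level, high pitch jitter and
dynamic noise), ascent (pitch +40°, −0.9 m/s, very low heave dynamics) —
plus flight/float/rest above water; dives average ~4–5 m and ~20 s.
`guillemot` (deep diver): adds a low-variance deep-search state; descent
1.2 m/s sustained ~25 s, dives tens of meters. Emission contrasts are
chosen so that the windowed features separate the states by several
within-state SDs; transition stickiness keeps state runs long relative
to the amplitude windows. Dive *rates* are higher than field-typical so
short simulations carry enough dives for stable statistics.

**What passing recovery tests do and do not show.** The simulator's
emissions are Gaussian given the state and its states are Markov at 1 Hz.
Real accelerometry has autocorrelated, non-Gaussian dynamics, buoyancy
that changes with depth, stroke-and-glide gaits, and behaviors outside
the state repertoire. High recovery on simulations therefore validates
the *pipeline* — feature derivation, surface splitting, EM fitting,
smoothing and transition estimation compose correctly and recover a
known latent structure — not classification accuracy on field data.

## Recovery experiment and problem sizes

`recovery_experiment` runs the full pipeline on one simulated deployment
and reports: best-permutation (Hungarian assignment on the confusion
matrix) label agreement on the 1 Hz underwater grid; the max-entry error
of the estimated underwater transition matrix against the generator
block; truth vs detected dive counts; and the mean absolute error of the
fitted component means against the empirical truth-class means.

The shipped checks use a 2 h shallow-diver deployment at the full 25 Hz
grid for agreement and dive counts, and an 8 h deployment (decimation 5
for the EM input) for the transition comparison, which needs ≥ 10⁴
underwater 1 Hz steps for sampling error to sit well inside the 0.05
band. Residual transition error (~0.03) is dominated by the 1 s
smoothing suppressing rare one-second direct descent→ascent switches — a
property of the behavioral-granularity convention, not of the estimator.

## Known limitations

* Wet/dry state is inferred from depth alone; a bird floating on the
  surface is "dry" to the pipeline. Above-water states therefore mix
  surface floating with true dry land unless GPS distances are used.
* The seawater conversion fixes 0 °C / 35 PSU; no temperature- or
  salinity-dependent density refinement.
* Roll and yaw are not estimated; the pitch formula assumes the sway
  axis carries negligible gravity at rest.
* K selection remains a human, ecological judgement; BIC is reported as
  an aid only.
* The bottom-phase rule is a declared operationalization of "inflection
  points", with two tunables (q, minimum bottom duration).
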