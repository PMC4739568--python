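# divestate

Unsupervised behavioral-state classification for diving-seabird biologging
data: tri-axial accelerometry (25 Hz) combined with a 1 Hz pressure/
temperature channel, optionally matched to GPS fixes.

## Who this is for

Movement ecologists who deploy accelerometer + depth loggers on diving
birds (razorbills, guillemots and similar wing-propelled divers) and want
to discover behavioral modes — descending, searching, prey chasing,
ascending, flying, floating, resting — *without* a labeled training set or
species-specific thresholds. The latent states are found by clustering
derived movement variables with a Gaussian mixture model fitted by
Expectation–Maximization, written from scratch in this package.

## The method

1. **Depth.** Logger pressure (millibar) is offset-corrected to sea
   pressure, converted to decibar and mapped to depth with the UNESCO
   seawater formula, using latitude-dependent gravity
   `g = 9.780318·[1 + (5.2788e−3 + 2.36e−5·x)·x] + 1.092e−6·p`,
   `x = sin²(lat/57.29578)`.
2. **Feature set.** Static acceleration `S` (centered running mean of each
   axis; 1 s for razorbill-type, 2 s for guillemot-type deployments),
   dynamic acceleration `D = A − S`, body pitch
   `B = atan(S_h/√(S_l²+S_v²))·180/π` corrected for device-mounting offset,
   vertical speed `V_s` (change in depth per second), heave amplitude
   `Amp_v` and pitch variability `B_var` (rolling SDs over 10 s / 5 s), and
   standardized (z-scored) copies of the clustering channels.
3. **Surface split and dives.** The record is segmented at the water
   surface from the depth channel; a dive is any submerged excursion with
   maximum depth ≥ 1 m; bottom phase comes from the inflection of the
   depth profile.
4. **Latent states.** A K-component full-covariance Gaussian mixture is
   fitted by EM (log-sum-exp E step; weighted M step; covariance
   regularization; distance-weighted restarts; BIC reported across K).
   Underwater runs use `Amp_v, B_var, z(V_s), z(D_h), z(D_l), z(D_v), z(B)`;
   above-water runs use `Amp_v, z(D_h), z(D_l), z(D_v), z(B)` with K = 3
   (high / medium / null activity).
5. **Behavior summaries.** Posterior responsibilities are smoothed with a
   1 s running mean before re-labeling, labels are reduced to a 1 Hz grid,
   and transition probability matrices
   `P[i,j] = Pr(Z_t = j | Z_{t−1} = i)` are counted within contiguous
   same-scope segments (pooling across animals sums counts).

A built-in simulator (`divestate.synthetic_data`) generates multi-rate
deployments from a latent 1 Hz Markov process with per-state emission
models, so the whole pipeline is testable end to end against known truth.

## Worked example

Simulate a one-hour shallow-diver trip, detect its dives, and run the full
recovery pipeline (features → surface split → EM at K = 3 → smoothing →
transition matrix) against the simulator's truth:

```bash
$ divestate simulate --preset razorbill --hours 1 --seed 4 --out demo
simulated 1.0 h (razorbill); 96 dives; wrote demo_accel.csv and demo_gps.csv

$ divestate dives --accel demo_accel.csv --out demo_dives.csv
96 dives (96.0/h) → demo_dives.csv

$ divestate recover --preset razorbill --hours 1 --seed 4 --decimate 5
{
 "label_agreement": 0.9641,
 "transition_error_max": 0.0325,
 "dive_count_truth": 96,
 "dive_count_detected": 96,
 "n_underwater_seconds": 1837,
 "mean_abs_mean_error": 0.0709
}
```

Reading the report: 96.4 % of underwater seconds receive the correct
latent state after smoothing (best permutation of mixture components);
every simulated dive is found by the ≥ 1 m rule; the estimated underwater
transition matrix is within 0.033 (max entry) of the generator's; the
fitted component means sit within 0.07 (z-scored units) of the true
per-state feature means.

The same stages are available as library calls
(`build_feature_table`, `detect_dives`, `fit_gmm`, `run_design`,
`smooth_states`, `transition_matrix`, `join_gps`) — see `docs/methods.md`
for the modeling details and parameter guidance.

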