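"""Depth conversion, static/dynamic decomposition, pitch and windowed stats.

Windowed statistics are checked against naive per-window loop oracles;
the depth conversion against an independently coded evaluation of the
seawater formula.
"""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import divestate as ds
from divestate.signal_features import (_half_width, running_mean,
                                       sd_of_running_mean)

# ---------------------------------------------------------------------------
# Independent oracles
# ---------------------------------------------------------------------------

def gravity_oracle(lat_deg, p_db):
    x = np.sin(lat_deg / 57.29578) ** 2
    poly = 1.0 + 5.2788e-3 * x + 2.36e-5 * x * x
    return 9.780318 * poly + 1.092e-6 * p_db


def depth_oracle(p_db, lat_deg):
    num = (9.72659 * p_db - 2.2512e-5 * p_db ** 2
           + 2.279e-10 * p_db ** 3 - 1.82e-15 * p_db ** 4)
    return num / gravity_oracle(lat_deg, p_db)


def loop_running_mean(x, half, symmetric=True):
    n = len(x)
    out = np.empty(n)
    for i in range(n):
        m = min(half, i, n - 1 - i) if symmetric else half
        lo, hi = max(0, i - m), min(n - 1, i + m)
        out[i] = np.mean(x[lo:hi + 1])
    return out


def loop_rolling_sd(x, half):
    n = len(x)
    out = np.empty(n)
    for i in range(n):
        lo, hi = max(0, i - half), min(n - 1, i + half)
        w = x[lo:hi + 1]
        out[i] = np.std(w, ddof=1) if w.size > 1 else 0.0
    return out


# ---------------------------------------------------------------------------
# Gravity and depth
# ---------------------------------------------------------------------------

class TestGravity:
    def test_equator_surface_value_is_leading_constant(self):
        assert ds.gravity(0.0, 0.0) == 9.780318

    def test_pole_matches_direct_formula_evaluation(self):
        assert ds.gravity(90.0, 0.0) == pytest.approx(gravity_oracle(90.0, 0.0),
                                                      rel=1e-12)
        assert 9.83 < ds.gravity(90.0, 0.0) < 9.834

    def test_linear_in_pressure(self):
        assert (ds.gravity(0.0, 1000.0) - ds.gravity(0.0, 0.0)
                == pytest.approx(1.092e-6 * 1000.0, rel=1e-12))

    def test_increasing_in_absolute_latitude(self):
        lats = np.linspace(0, 90, 19)
        g = np.array([ds.gravity(l, 0.0) for l in lats])
        assert np.all(np.diff(g) > 0)

    def test_negative_pressure_rejected(self):
        with pytest.raises(ds.DomainError):
            ds.gravity(0.0, -1.0)


class TestPressureToDepth:
    def test_zero_pressure_is_zero_depth(self):
        for lat in (0.0, 45.0, 90.0):
            assert ds.pressure_to_depth(0.0, lat) == 0.0

    def test_fair_isle_100_decibar_matches_oracle(self):
        d = ds.pressure_to_depth(100.0, 59.382)
        assert d == pytest.approx(depth_oracle(100.0, 59.382), rel=1e-12)
        assert 98.0 < d < 100.0

    def test_oracle_agreement_over_domain_grid(self):
        p = np.linspace(0.0, 6000.0, 241)
        for lat in np.linspace(0.0, 90.0, 10):
            np.testing.assert_allclose(ds.pressure_to_depth(p, lat),
                                       depth_oracle(p, lat),
                                       rtol=1e-9, atol=1e-12)

    def test_strictly_increasing_in_pressure(self):
        p = np.linspace(0.0, 6000.0, 601)
        d = ds.pressure_to_depth(p, 45.0)
        assert np.all(np.diff(d) > 0)

    def test_negative_pressure_rejected(self):
        with pytest.raises(ds.DomainError):
            ds.pressure_to_depth(-5.0, 0.0)


# ---------------------------------------------------------------------------
# Windowed statistics
# ---------------------------------------------------------------------------

class TestStaticAcceleration:
    def test_constant_series_is_fixed_point(self):
        x = np.full(100, 3.7)
        np.testing.assert_allclose(ds.static_acceleration(x, 1.0, 25.0), x,
                                   atol=1e-12)

    def test_alternating_signal_interior_mean(self):
        x = np.tile([1.0, -1.0], 200)
        out = ds.static_acceleration(x, 1.0, 25.0)   # 25-sample window
        np.testing.assert_allclose(np.abs(out[12:-12]), 1.0 / 25.0, atol=1e-12)

    def test_single_sample_window_is_identity(self):
        x = np.array([1.0, 5.0, -2.0])
        np.testing.assert_array_equal(ds.static_acceleration(x, 0.04, 25.0), x)

    def test_matches_loop_oracle(self, rng):
        x = rng.normal(size=2000)
        out = ds.static_acceleration(x, 1.0, 25.0)
        np.testing.assert_allclose(out, loop_running_mean(x, 12), atol=1e-8)

    def test_empty_series_rejected(self):
        with pytest.raises(ds.ContractError):
            ds.static_acceleration(np.array([]), 1.0, 25.0)

    def test_gap_samples_excluded_from_windows(self):
        x = np.ones(50)
        x[20] = 1e6
        valid = np.ones(50, dtype=bool)
        valid[20] = False
        out = running_mean(x, 5, valid=valid)
        np.testing.assert_allclose(np.delete(out, 20), 1.0)


class TestDynamicAcceleration:
    def test_raw_equals_static_gives_zero(self):
        a = np.array([1.0, 2.0, 3.0])
        np.testing.assert_array_equal(ds.dynamic_acceleration(a, a), 0.0 * a)

    def test_elementwise_difference(self):
        out = ds.dynamic_acceleration(np.array([1.0, 2.0, 3.0]),
                                      np.array([2.0, 2.0, 2.0]))
        np.testing.assert_array_equal(out, [-1.0, 0.0, 1.0])

    def test_length_mismatch_rejected(self):
        with pytest.raises(ds.ContractError):
            ds.dynamic_acceleration(np.zeros(3), np.zeros(4))

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.integers(0, 2 ** 31 - 1))
    def test_reconstruction_exact(self, seed):
        r = np.random.default_rng(seed)
        a = r.normal(size=300)
        s = ds.static_acceleration(a, 1.0, 25.0)
        d = ds.dynamic_acceleration(a, s)
        assert np.max(np.abs(a - (s + d))) < 1e-12   # one ulp on O(1) values


class TestRollingSD:
    def test_constant_series_zero(self):
        np.testing.assert_array_equal(
            ds.rolling_sd(np.full(50, 2.5), 1.0, 25.0), np.zeros(50))

    def test_two_sample_full_span(self):
        out = ds.rolling_sd(np.array([0.0, 2.0]), 2.0, 1.0)
        np.testing.assert_allclose(out, np.sqrt(2.0), atol=1e-12)

    def test_matches_loop_oracle(self, rng):
        x = rng.normal(size=1500) * 3.0 + 1.0
        out = ds.rolling_sd(x, 1.0, 25.0)
        np.testing.assert_allclose(out, loop_rolling_sd(x, 12), atol=1e-8)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.floats(0.1, 100.0), st.integers(0, 2 ** 31 - 1))
    def test_scale_equivariance(self, c, seed):
        x = np.random.default_rng(seed).normal(size=200)
        np.testing.assert_allclose(ds.rolling_sd(c * x, 0.4, 25.0),
                                   c * ds.rolling_sd(x, 0.4, 25.0),
                                   rtol=1e-9, atol=1e-12)

    def test_window_below_two_samples_rejected(self):
        with pytest.raises(ds.ContractError):
            ds.rolling_sd(np.ones(10), 0.04, 25.0)

    def test_alternative_amplitude_reading_differs(self, rng):
        x = rng.normal(size=500)
        a = ds.rolling_sd(x, 0.4, 25.0)
        b = sd_of_running_mean(x, 0.4, 25.0)
        assert not np.allclose(a, b)


# ---------------------------------------------------------------------------
# Orientation
# ---------------------------------------------------------------------------

class TestPitch:
    @pytest.mark.parametrize("shlv,expected", [
        ((0.0, 0.3, 0.95), 0.0),
        ((1.0, 0.0, 1.0), 45.0),
        ((1.0, 0.0, 0.0), 90.0),
        ((-1.0, 0.0, 0.0), -90.0),
    ])
    def test_reference_angles(self, shlv, expected):
        assert ds.pitch(*shlv) == pytest.approx(expected, abs=1e-12)

    def test_all_zero_vector_rejected(self):
        with pytest.raises(ds.DomainError):
            ds.pitch(0.0, 0.0, 0.0)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.floats(-89.9, 89.9))
    def test_tilted_gravity_vector_recovers_angle(self, theta):
        g = 9.81
        b = np.radians(theta)
        recovered = ds.pitch(g * np.sin(b), 0.0, g * np.cos(b))
        assert recovered == pytest.approx(theta, abs=1e-6)

    def test_sign_follows_surge(self):
        assert ds.pitch(0.5, 0.1, 0.8) > 0
        assert ds.pitch(-0.5, 0.1, 0.8) < 0


class TestVerticalSpeed:
    def test_constant_depth_is_zero(self):
        np.testing.assert_array_equal(ds.vertical_speed(np.full(5, 3.0)),
                                      np.zeros(5))

    def test_descent_positive(self):
        np.testing.assert_array_equal(ds.vertical_speed([0.0, 1.0, 3.0]),
                                      [0.0, 1.0, 2.0])

    def test_ascent_negative(self):
        np.testing.assert_array_equal(ds.vertical_speed([10.0, 8.0]),
                                      [0.0, -2.0])

    def test_too_short_rejected(self):
        with pytest.raises(ds.ContractError):
            ds.vertical_speed([1.0])


class TestStandardize:
    def test_zero_mean_unit_sd(self):
        z = ds.standardize([1.0, 2.0, 3.0])
        assert np.mean(z) == pytest.approx(0.0, abs=1e-12)
        assert np.std(z, ddof=1) == pytest.approx(1.0, abs=1e-12)

    def test_constant_channel_rejected_by_name(self):
        with pytest.raises(ds.StandardizationError, match="heave"):
            ds.standardize(np.ones(10), name="heave")

    def test_idempotent(self, rng):
        x = rng.normal(3.0, 7.0, size=500)
        once = ds.standardize(x)
        np.testing.assert_allclose(ds.standardize(once), once, atol=1e-12)


class TestPitchOffset:
    def test_constant_resting_pitch_is_recovered_and_removed(self, short_scenario):
        import dataclasses
        sc = dataclasses.replace(short_scenario, mount_offset_deg=7.0)
        dep, _ = ds.simulate_deployment(sc, seed=3)
        ft = ds.build_feature_table(dep, sc.feature_config())
        assert ft.pitch_offset_deg == pytest.approx(7.0, abs=1.0)
        # corrected resting pitch centered on zero
        rest = (~ft.wet) & (ft.data["Amp_v"].to_numpy()
                            < np.quantile(ft.data["Amp_v"], 0.25))
        assert abs(np.median(ft.data["B"].to_numpy()[rest])) < 1.0

    def test_median_of_discrete_resting_pitches(self, short_features):
        # feature-table path: estimate equals the median over resting samples
        off = ds.estimate_pitch_offset(short_features)
        assert np.isfinite(off)

    def test_no_surface_samples_is_calibration_error(self, short_features):
        import copy
        ft = copy.deepcopy(short_features)
        ft.data["Depth"] += 10.0   # permanently submerged record
        with pytest.raises(ds.CalibrationError):
            ds.estimate_pitch_offset(ft)


# ---------------------------------------------------------------------------
# Full table
# ---------------------------------------------------------------------------

class TestBuildFeatureTable:
    def test_invariants_on_simulated_deployment(self, short_features):
        d = short_features.data
        for ax in "hlv":
            resid = d[f"A_{ax}"] - (d[f"S_{ax}"] + d[f"D_{ax}"])
            assert np.max(np.abs(resid.to_numpy())) < 1e-12
        assert d["B_raw"].between(-90, 90).all()
        assert (d["Amp_v"] >= 0).all()
        assert (d["B_var"] >= 0).all()
        ok = ~d["gap"]
        for z in ("z_B", "z_V_s", "z_D_h", "z_D_l", "z_D_v"):
            assert np.mean(d[z][ok]) == pytest.approx(0.0, abs=1e-9)
            assert np.std(d[z][ok], ddof=1) == pytest.approx(1.0, abs=1e-9)

    def test_depth_reconstruction_close_to_truth(self, short_deployment,
                                                 short_scenario, short_features):
        _, truth = short_deployment
        recon = short_features.env["Depth"].to_numpy()
        assert np.max(np.abs(recon - truth.depth_env)) < 0.05

    def test_surface_pressure_estimate(self, short_features, short_scenario):
        assert short_features.surface_pressure_mbar == pytest.approx(
            short_scenario.surface_pressure_mbar, abs=0.5)

    def test_still_deployment_has_near_zero_amplitude(self):
        sc = ds.Scenario(
            states=[ds.StateSpec("float", wet=False, pitch_deg=0.0,
                                 pitch_jitter_deg=2.0,
                                 dyn_sd=(0.05, 0.05, 0.05))],
            transition=np.array([[1.0]]), duration_h=0.1,
            pressure_noise_mbar=0.0, mount_offset_deg=7.0)
        dep, _ = ds.simulate_deployment(sc, seed=0)
        with pytest.warns(UserWarning):   # V_s has zero variance here
            ft = ds.build_feature_table(dep, sc.feature_config())
        assert np.all(ft.env["Depth"].to_numpy() < 0.05)
        assert np.median(ft.data["Amp_v"]) < 0.1
        assert abs(np.median(ft.data["B"])) < 1.0   # offset removed

    def test_species_presets_match_published_windows(self):
        razorbill = ds.FeatureConfig.for_species("razorbill")
        guillemot = ds.FeatureConfig.for_species("guillemot")
        assert (razorbill.static_window_s, razorbill.amp_window_s) == (1.0, 10.0)
        assert (guillemot.static_window_s, guillemot.amp_window_s) == (2.0, 5.0)
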