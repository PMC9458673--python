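"""The season generator: envelope identities, determinism, schedule shape."""

import dataclasses

import numpy as np
import pytest

from avprofiler import (
    GroundTruthProfile,
    SeasonConfig,
    simulate_bout,
    simulate_season,
    simulate_session,
    summarise_session,
)
from avprofiler.profile import bin_max_acceleration, compute_acceleration, lowpass_filter
from avprofiler.synthetic import SessionTrace, build_schedule, draw_player_profiles

from conftest import make_session


class TestSimulateBout:
    def test_tracks_ode_closed_form_with_first_order_step_error(self, ref_profile):
        """v(t) follows V0*(1 - exp(-A0 t / V0)) up to O(1/omega)."""
        for omega, tol in ((10.0, 0.15), (100.0, 0.015)):
            v = simulate_bout(ref_profile, 1.0, 0.0, 0.97 * ref_profile.V0, omega)
            t = np.arange(v.size) / omega
            exact = ref_profile.V0 * (1.0 - np.exp(-ref_profile.A0 * t / ref_profile.V0))
            assert np.max(np.abs(v - exact)) < tol

    def test_every_sample_difference_sits_on_the_envelope(self, ref_profile):
        for effort in (1.0, 0.6):
            v = simulate_bout(ref_profile, effort, 1.0, 8.0)
            a = np.diff(v) * 10.0
            expected = effort * ref_profile.A0 * (1.0 - v[1:] / ref_profile.V0)
            np.testing.assert_allclose(a, expected, atol=1e-9)

    def test_regression_on_maximal_segment_recovers_truth(self, ref_profile):
        """Finite-difference accelerations vs velocity lie on the true line."""
        from scipy.stats import linregress

        v = simulate_bout(ref_profile, 1.0, 3.0, 8.5)
        res = linregress(v[1:], np.diff(v) * 10.0)
        assert res.slope == pytest.approx(-4.72 / 8.86, abs=1e-9)
        assert res.intercept == pytest.approx(4.72, abs=1e-9)

    def test_target_above_v0_rejected(self, ref_profile):
        with pytest.raises(ValueError, match="V0"):
            simulate_bout(ref_profile, 1.0, 0.0, ref_profile.V0 + 0.1)

    def test_bad_effort_and_start_rejected(self, ref_profile):
        with pytest.raises(ValueError):
            simulate_bout(ref_profile, 0.0, 0.0, 5.0)
        with pytest.raises(ValueError):
            simulate_bout(ref_profile, 1.0, 6.0, 5.0)


class TestSimulateSession:
    def test_sample_count_matches_duration(self, ref_profile):
        tr = make_session(ref_profile, seed=0, duration_s=5400.0)
        assert tr.v.size == 54_000
        assert tr.t.size == 54_000

    def test_fixed_seed_gives_byte_identical_trace(self, ref_profile):
        a = make_session(ref_profile, seed=42)
        b = make_session(ref_profile, seed=42)
        assert a.v.tobytes() == b.v.tobytes()
        assert a.t.tobytes() == b.t.tobytes()

    def test_noise_free_bin_maxima_touch_the_envelope(self, ref_profile):
        """Per 0.1 m/s bin, the max finite-difference acceleration equals the
        envelope at some velocity inside the bin (Euler-exact construction)."""
        tr = make_session(ref_profile, seed=1, noise_sd=0.0)
        a = np.diff(tr.v) * tr.sampling_rate
        binned = bin_max_acceleration(tr.v[1:], a, 0.1)
        sel = binned[(binned.bin_center > 3.0) & (binned.bin_center < 0.9 * ref_profile.V0)]
        env = ref_profile.envelope(sel.bin_center.to_numpy())
        # envelope varies by A0*w/V0 ~ 0.053 across a bin
        assert np.max(np.abs(sel.a_max.to_numpy() - env)) < 0.06

    def test_velocities_non_negative_and_duration_too_short_errors(self, ref_profile):
        tr = make_session(ref_profile, seed=3)
        assert tr.v.min() >= 0.0
        cfg = SeasonConfig()
        with pytest.raises(ValueError, match="too short"):
            simulate_session(ref_profile, "game", 30.0, cfg, np.random.default_rng(0))


class TestSummarise:
    def _const_trace(self, v, n=1000):
        return SessionTrace(
            player_id="p", session_id="s", date=None, kind="training",
            sampling_rate=10.0, t=np.arange(n) / 10.0,
            v=np.full(n, float(v)),
        )

    def test_constant_velocity_gives_distance_and_no_counts(self):
        s = summarise_session(self._const_trace(2.0, 1000))
        assert s["total_distance_m"] == pytest.approx(200.0)
        assert s["accel_count_2"] == 0 and s["decel_count_2"] == 0
        assert s["max_speed_mps"] == pytest.approx(2.0)

    def test_zero_velocity_gives_all_zero(self):
        s = summarise_session(self._const_trace(0.0, 1000))
        assert s["total_distance_m"] == 0.0
        assert s["max_speed_mps"] == 0.0
        assert s["sprint_count"] == 0
        assert s["mean_moving_speed_mps"] == 0.0

    def test_zone_distances_sum_to_total(self, ref_profile):
        tr = make_session(ref_profile, seed=5)
        s = summarise_session(tr)
        zones = sum(s[f"dist_zone{i}_m"] for i in range(1, 6))
        assert zones == pytest.approx(s["total_distance_m"], abs=1e-6)

    def test_peak_filtered_acceleration_matches_envelope_at_argmax(self, ref_profile):
        # the filtered peak sits just after a maximal-bout onset, where the
        # two-sided first-order kernel still mixes in pre-bout zeros while
        # the true acceleration decays with time constant V0/A0; for a 1 Hz
        # cutoff at these parameters the deficit is a stable ~5.9%
        tr = make_session(ref_profile, seed=7, noise_sd=0.0, duration_s=5400.0)
        a_f = lowpass_filter(compute_acceleration(tr.v, 10.0), 10.0)
        i = int(np.argmax(a_f))
        env = ref_profile.envelope(np.array([tr.v[i + 1]]))[0]
        assert summarise_session(tr)["peak_filtered_accel_mps2"] == pytest.approx(
            env, rel=0.08
        )


class TestSeason:
    def test_schedule_counts_and_training_before_game(self):
        cfg = SeasonConfig(n_players=2, n_games=4, n_trainings=10,
                           game_duration_s=600, training_duration_s=600)
        ds = simulate_season(cfg, with_summaries=False)
        assert len(ds.schedule) == 14
        assert len(ds.truth) == 28  # player-sessions
        kinds = ds.schedule["kind"].tolist()
        assert kinds.count("game") == 4
        first_game = kinds.index("game")
        assert "training" in kinds[:first_game]

    def test_zero_drift_keeps_ground_truth_constant(self):
        cfg = SeasonConfig(n_players=2, n_games=4, n_trainings=10,
                           game_duration_s=600, training_duration_s=600,
                           acute_sd=0.0)
        profiles = [
            GroundTruthProfile("P00", drift_sd=0.0),
            GroundTruthProfile("P01", A0=5.0, V0=9.0, drift_sd=0.0),
        ]
        ds = simulate_season(cfg, profiles=profiles, with_summaries=False)
        for pid, g in ds.truth.groupby("player_id"):
            assert g["intercept_true"].nunique() == 1
            assert g["slope_true"].nunique() == 1

    def test_season_determinism(self, tiny_config):
        a = simulate_season(tiny_config)
        b = simulate_season(tiny_config)
        assert a.summaries.equals(b.summaries)
        assert a.truth.equals(b.truth)
        ta = a.trace("P00", "S003")
        tb = b.trace("P00", "S003")
        assert ta.v.tobytes() == tb.v.tobytes()

    def test_population_draw_centres_on_reported_means(self):
        rng = np.random.default_rng(123)
        profs = draw_player_profiles(42, rng)
        intercepts = np.array([p.intercept_true for p in profs])
        slopes = np.array([p.slope_true for p in profs])
        assert abs(intercepts.mean() - 4.721) < 0.483
        assert abs(slopes.mean() - (-0.533)) < 0.078

    def test_roundtrip_write(self, tiny_season, tmp_path):
        tiny_season.write(tmp_path / "out")
        assert (tmp_path / "out" / "schedule.json").exists()
        assert (tmp_path / "out" / "summaries.json").exists()
        assert (tmp_path / "out" / "ground_truth" / "truth.json").exists()
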