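"""Generator contracts: track geometry, head model, ratings, full cohorts."""

import json

import numpy as np
import pytest

from vrheadmotion.errors import ConfigurationError
from vrheadmotion.io_formats import trial_records_frame
from vrheadmotion.study_design import EXPERIMENT_2, build_session_schedule, enumerate_orders
from vrheadmotion.synthetic_cohort import (
    Cohort,
    CohortConfig,
    HeadModelParams,
    HeadPopulation,
    RatingModel,
    TrackConfig,
    default_study_configs,
    generate_cohort,
    generate_vehicle_trace,
    simulate_head_trace,
    simulate_ratings,
    write_cohort,
)


class TestVehicleTrace:
    def test_zero_amplitude_track_is_identically_zero(self):
        track = TrackConfig(turn_amplitude=0.0)
        trace = generate_vehicle_trace(track, "fast", seed=0)
        assert np.all(trace.yaw == 0.0)

    def test_zero_turns_with_amplitude_rejected(self):
        with pytest.raises(ConfigurationError, match="zero turns"):
            generate_vehicle_trace(TrackConfig(n_turns=0, turn_amplitude=3.0), "fast", 0)

    def test_slow_is_time_dilated_fast(self):
        track = TrackConfig()
        fast = generate_vehicle_trace(track, "fast", seed=1)
        slow = generate_vehicle_trace(track, "slow", seed=1)
        # slow(t) == fast(t/2): sample pairs on the shared grid
        np.testing.assert_allclose(slow.yaw[::2], fast.yaw[: 2700], atol=1e-9)
        assert slow.n_samples == fast.n_samples == 5400

    def test_turn_count_matches_peak_oracle(self):
        # count extrema exceeding half the maximum excursion
        track = TrackConfig(n_turns=6, amplitude_jitter=0.0, spacing_jitter=0.0,
                            duration_jitter=0.0)
        trace = generate_vehicle_trace(track, "fast", seed=2)
        y = np.abs(trace.yaw)
        peaks = 0
        for i in range(1, len(y) - 1):
            if y[i] >= y[i - 1] and y[i] > y[i + 1] and y[i] > y.max() / 2:
                peaks += 1
        assert peaks == 6

    def test_non_integer_grid_rejected(self):
        with pytest.raises(ConfigurationError, match="integer sample count"):
            TrackConfig(lap_duration=60.005).n_samples()


class TestHeadTrace:
    def test_identity_limit(self):
        vehicle = generate_vehicle_trace(TrackConfig(), "fast", seed=3)
        params = HeadModelParams(gain=1.0, lead_ms=0.0, noise_sd=0.0, drift_sd=0.0)
        head = simulate_head_trace(vehicle, params, seed=0)
        np.testing.assert_allclose(head.yaw, vehicle.yaw, atol=1e-9)

    def test_zero_gain_no_noise_is_flat(self):
        vehicle = generate_vehicle_trace(TrackConfig(), "fast", seed=3)
        params = HeadModelParams(gain=0.0, lead_ms=500.0, noise_sd=0.0, drift_sd=0.0)
        head = simulate_head_trace(vehicle, params, seed=0)
        for axis in ("pitch", "yaw", "roll"):
            assert np.all(head.channel(axis) == 0.0)

    def test_seeded_determinism_and_seed_sensitivity(self):
        vehicle = generate_vehicle_trace(TrackConfig(), "fast", seed=3)
        params = HeadModelParams()
        a = simulate_head_trace(vehicle, params, seed=5)
        b = simulate_head_trace(vehicle, params, seed=5)
        c = simulate_head_trace(vehicle, params, seed=6)
        np.testing.assert_array_equal(a.yaw, b.yaw)
        assert np.abs(a.yaw - c.yaw).max() > 0.01

    def test_negative_noise_sd_rejected(self):
        vehicle = generate_vehicle_trace(TrackConfig(), "fast", seed=3)
        with pytest.raises(ConfigurationError, match=">= 0"):
            simulate_head_trace(vehicle, HeadModelParams(noise_sd=-1.0), seed=0)

    def test_lead_shift_holds_boundary_values(self):
        vehicle = generate_vehicle_trace(TrackConfig(), "fast", seed=3)
        params = HeadModelParams(gain=1.0, lead_ms=2000.0, noise_sd=0.0, drift_sd=0.0)
        head = simulate_head_trace(vehicle, params, seed=0)
        assert head.yaw[-1] == pytest.approx(vehicle.yaw[-1])


class TestRatings:
    def _schedule(self):
        return build_session_schedule(EXPERIMENT_2, enumerate_orders(EXPERIMENT_2)[0])

    def test_deterministic_latent_with_all_zero_coefficients(self):
        model = RatingModel(
            intercepts={"vection": 10.0, "sickness": 10.0, "presence": 10.0},
            speed={m: {"stationary": 0.0, "slow": 0.0, "fast": 0.0}
                   for m in ("vection", "sickness", "presence")},
            direction={m: {"forward": 0.0, "reverse": 0.0, "lateral": 0.0}
                       for m in ("vection", "sickness", "presence")},
            trait_loading={"vection": 0.0, "sickness": 0.0, "presence": 0.0},
            residual_sd=0.0,
        )
        records = simulate_ratings(self._schedule(), {}, model, seed=0, experiment=2)
        assert all(r.vection_magnitude == 10 for r in records)
        assert all(r.sickness == 10 and r.presence == 10 for r in records)

    def test_magnitude_one_has_no_onset(self):
        model = RatingModel(
            intercepts={"vection": 1.0, "sickness": 3.0, "presence": 3.0},
            speed={m: {"stationary": 0.0, "slow": 0.0, "fast": 0.0}
                   for m in ("vection", "sickness", "presence")},
            direction={m: {"forward": 0.0, "reverse": 0.0, "lateral": 0.0}
                       for m in ("vection", "sickness", "presence")},
            trait_loading={"vection": 0.0, "sickness": 0.0, "presence": 0.0},
            residual_sd=0.0,
        )
        records = simulate_ratings(self._schedule(), {}, model, seed=0, experiment=2)
        assert all(r.vection_magnitude == 1 for r in records)
        assert all(r.vection_onset is None and r.vection_duration is None for r in records)

    def test_onset_duration_fit_within_lap(self):
        records = simulate_ratings(
            self._schedule(), {}, RatingModel(), seed=3, experiment=2
        )
        for r in records:
            if r.vection_magnitude >= 2:
                assert r.vection_onset + r.vection_duration <= 60.0 + 1e-9

    def test_missing_coefficient_rejected(self):
        model = RatingModel(direction={"vection": {"forward": 0.0},
                                       "sickness": {"forward": 0.0},
                                       "presence": {"forward": 0.0}})
        schedule = build_session_schedule(EXPERIMENT_2, enumerate_orders(EXPERIMENT_2)[-1])
        with pytest.raises(ConfigurationError, match="coefficient"):
            simulate_ratings(schedule, {}, model, seed=0, experiment=2)

    def test_speed_effect_direction_in_small_cohorts(self):
        # planted positive fast coefficient shows up in cohort means
        wins = 0
        for seed in range(10):
            cohort = generate_cohort(
                CohortConfig(experiment=2, n_participants=12, seed=seed,
                             ratings=RatingModel())
            )
            frame = trial_records_frame(cohort.records)
            laps = frame[frame.speed.isin(["slow", "fast"])]
            means = laps.groupby("speed").vection_magnitude.mean()
            wins += means["fast"] > means["slow"]
        assert wins >= 9


class TestGenerateCohort:
    def test_noise_free_homogeneous_cohort_is_identical(self):
        config = CohortConfig(
            experiment=2,
            n_participants=4,
            seed=0,
            track=TrackConfig(n_turns=2),
            head=HeadPopulation(gain_sd=0.0, lead_ms_sd=0.0, noise_sd=0.0,
                                noise_log_sd=0.0, drift_sd=0.0),
            ratings=RatingModel(),
        )
        cohort = generate_cohort(config)
        traces = cohort.analysis_traces("fast")
        assert len(traces) == 4
        for other in traces[1:]:
            np.testing.assert_allclose(other.yaw, traces[0].yaw, atol=1e-12)
            assert np.corrcoef(other.yaw, traces[0].yaw)[0, 1] == pytest.approx(1.0)

    def test_pure_function_of_config_and_seed(self):
        config = CohortConfig(experiment=2, n_participants=5, seed=9)
        a, b = generate_cohort(config), generate_cohort(config)
        assert trial_records_frame(a.records).equals(trial_records_frame(b.records))
        for key in a.head_traces:
            np.testing.assert_array_equal(a.head_traces[key].yaw, b.head_traces[key].yaw)

    def test_adding_participants_preserves_earlier_ones(self):
        small = generate_cohort(CohortConfig(experiment=2, n_participants=4, seed=9))
        large = generate_cohort(CohortConfig(experiment=2, n_participants=8, seed=9))
        gt_small = small.ground_truth.per_participant.set_index("participant_id")
        gt_large = large.ground_truth.per_participant.set_index("participant_id")
        for pid in gt_small.index:
            assert gt_small.loc[pid, "gain"] == gt_large.loc[pid, "gain"]
        for key, trace in small.head_traces.items():
            np.testing.assert_array_equal(trace.yaw, large.head_traces[key].yaw)

    def test_default_study_is_88_participants(self):
        c1, c2 = default_study_configs(0)
        assert c1.n_participants + c2.n_participants == 88
        assert c1.track_seed == c2.track_seed

    def test_roundtrip_through_disk_layout(self, tmp_path):
        from vrheadmotion.reporting import StudyData

        cohort = generate_cohort(CohortConfig(experiment=2, n_participants=4, seed=2))
        write_cohort(cohort, tmp_path)
        study = StudyData.from_dir(tmp_path)
        assert len(study.traces) == len(cohort.head_traces)
        key = sorted(cohort.head_traces)[0]
        np.testing.assert_allclose(
            study.traces[key].yaw, cohort.head_traces[key].yaw, atol=1e-9
        )
        truth = json.loads((tmp_path / "ground_truth.json").read_text())
        assert "per_participant" in truth

    def test_ground_truth_never_read_by_analysis(self, tmp_path):
        # the leakage firewall: delete the sidecar, analysis is unaffected
        from vrheadmotion.reporting import StudyData

        cohort = generate_cohort(CohortConfig(experiment=2, n_participants=4, seed=2))
        write_cohort(cohort, tmp_path)
        study_with = StudyData.from_dir(tmp_path)
        (tmp_path / "ground_truth.json").unlink()
        study_without = StudyData.from_dir(tmp_path)
        assert study_with.records.equals(study_without.records)
        for key in study_with.traces:
            np.testing.assert_array_equal(
                study_with.traces[key].yaw, study_without.traces[key].yaw
            )
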