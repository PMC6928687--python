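"""Simulator contracts: determinism, protocol bookkeeping, gait structure,
and recoverability of the angle-to-voltage mapping."""

import numpy as np
import pytest
from dataclasses import replace

from gaitstrain import (
    CHANNEL_NAMES,
    ProtocolSpec,
    SensorModel,
    generate_cohort,
    simulate_joint_angles,
    simulate_marker_grid,
    simulate_sensor_voltages,
)
from gaitstrain.synthetic import stride_frequency


class TestProtocol:
    def test_default_protocol_matches_study_design(self):
        p = ProtocolSpec()
        assert p.speeds == (8.0, 9.0, 10.0, 11.0, 12.0)
        assert p.n_trials == 15
        assert p.frames_per_trial == 6000

    @pytest.mark.parametrize("bad", [
        dict(trial_duration=0.0),
        dict(sample_rate=-1.0),
        dict(repeats=0),
        dict(speeds=()),
    ])
    def test_invalid_config_rejected(self, bad):
        with pytest.raises(ValueError):
            ProtocolSpec(**bad)


class TestGenerateCohort:
    def test_trial_count_and_frames(self, short_protocol):
        cohort = generate_cohort(1, short_protocol, seed=7)
        assert len(cohort.trials) == short_protocol.n_trials
        assert all(t.angles.n_frames == 500 for t in cohort.trials)
        assert all(t.sensors.v.shape == (500, 9) for t in cohort.trials)

    def test_deterministic_given_seed(self, short_protocol):
        a = generate_cohort(2, short_protocol, seed=7)
        b = generate_cohort(2, short_protocol, seed=7)
        for ta, tb in zip(a.trials, b.trials):
            np.testing.assert_array_equal(ta.angles.angles, tb.angles.angles)
            np.testing.assert_array_equal(ta.sensors.v, tb.sensors.v)

    def test_different_seeds_differ(self, short_protocol):
        a = generate_cohort(1, short_protocol, seed=7)
        b = generate_cohort(1, short_protocol, seed=8)
        assert not np.array_equal(a.trials[0].sensors.v, b.trials[0].sensors.v)

    def test_full_protocol_frame_budget(self):
        # 15 one-minute trials at 100 Hz = 90,000 samples per participant
        protocol = ProtocolSpec()
        per_participant = protocol.n_trials * protocol.frames_per_trial
        assert per_participant == 90_000

    def test_voltages_positive(self, small_cohort):
        assert all(t.sensors.v.min() > 0 for t in small_cohort.trials)


class TestJointAngles:
    def test_sagittal_ranges_dominate(self, angle_trial):
        rom = np.ptp(angle_trial.angles, axis=0)
        sag = rom[[0, 3, 4]]
        nonsag = rom[[1, 2, 5]]
        assert sag.min() > nonsag.max()

    def test_cadence_increases_with_speed(self, profile):
        freqs = [stride_frequency(profile, s) for s in (8, 9, 10, 11, 12)]
        assert all(b > a for a, b in zip(freqs, freqs[1:]))

    def test_autocorrelation_peaks_at_stride_period(self, profile, short_protocol):
        ja = simulate_joint_angles(
            profile, 10.0, 0, short_protocol, np.random.default_rng(0)
        )
        x = ja.angles[:, 0] - ja.angles[:, 0].mean()
        ac = np.correlate(x, x, mode="full")[x.size - 1 :]
        period = short_protocol.sample_rate / stride_frequency(profile, 10.0)
        lo, hi = int(0.5 * period), int(1.5 * period)
        peak_lag = lo + int(np.argmax(ac[lo:hi]))
        assert abs(peak_lag - period) <= 1.0


class TestSensorVoltages:
    def test_constant_angles_give_baseline(self, profile, short_protocol):
        flat = replace(
            profile,
            amplitude_scale=np.full(6, 1e-12),
            sensor_noise_sd=0.0,
        )
        ja = simulate_joint_angles(
            flat, 10.0, 0, short_protocol, np.random.default_rng(0),
            butterworth=False,
        )
        sv = simulate_sensor_voltages(ja, flat, 0, SensorModel(saturation="linear"))
        np.testing.assert_allclose(sv.v, np.tile(sv.v0, (ja.n_frames, 1)), atol=1e-9)

    def test_noiseless_linear_map_recovers_angles(self, profile, angle_trial,
                                                  linear_sensor_model):
        quiet = replace(profile, sensor_noise_sd=0.0)
        sv = simulate_sensor_voltages(angle_trial, quiet, 0, linear_sensor_model)
        # least-squares from the 9 voltages back to the 6 angles
        design = np.column_stack([np.ones(sv.v.shape[0]), sv.v])
        beta, *_ = np.linalg.lstsq(design, angle_trial.angles, rcond=None)
        pred = design @ beta
        ss_res = ((angle_trial.angles - pred) ** 2).sum(axis=0)
        ss_tot = ((angle_trial.angles - angle_trial.angles.mean(axis=0)) ** 2).sum(axis=0)
        assert np.all(1.0 - ss_res / ss_tot > 0.999999)

    def test_linear_regime_scales_with_amplitude(self, profile, short_protocol,
                                                 linear_sensor_model):
        quiet = replace(profile, sensor_noise_sd=0.0,
                        amplitude_scale=np.full(6, 0.5))
        doubled = replace(quiet, amplitude_scale=np.full(6, 1.0))
        ja1 = simulate_joint_angles(quiet, 10.0, 0, short_protocol,
                                    np.random.default_rng(5), butterworth=False)
        ja2 = simulate_joint_angles(doubled, 10.0, 0, short_protocol,
                                    np.random.default_rng(5), butterworth=False)
        v1 = simulate_sensor_voltages(ja1, quiet, 0, linear_sensor_model).v
        v2 = simulate_sensor_voltages(ja2, doubled, 0, linear_sensor_model).v
        exc1 = v1 - v1.mean(axis=0)
        exc2 = v2 - v2.mean(axis=0)
        np.testing.assert_allclose(exc2, 2.0 * exc1, atol=1e-8)

    def test_frame_mismatch_rejected(self, profile, angle_trial):
        bad = replace(angle_trial, angles=angle_trial.angles[:, :5])
        with pytest.raises(ValueError):
            simulate_sensor_voltages(bad, profile, 0)


class TestMarkerGrid:
    def test_static_angles_keep_neutral_distances(self, profile, short_protocol,
                                                  grid_model):
        flat = replace(profile, amplitude_scale=np.full(6, 1e-12))
        ja = simulate_joint_angles(flat, 10.0, 0, short_protocol,
                                   np.random.default_rng(0), butterworth=False)
        gm = replace(grid_model, background_amp=0.0, marker_noise_sd=0.0,
                     peak_strain=0.0)
        grid = simulate_marker_grid(ja, gm, seed=0)
        d0 = np.linalg.norm(
            grid.neutral_positions[None, :, :] - grid.positions, axis=2
        )
        assert np.abs(d0).max() < 1e-12

    def test_informative_strain_affine_in_drive(self, angle_trial, grid_model):
        gm = replace(grid_model, background_amp=0.0, marker_noise_sd=0.0)
        grid = simulate_marker_grid(angle_trial, gm, seed=0)
        a, b = grid.informative_pairs[0]  # pure hip-sagittal mix
        dist = np.linalg.norm(grid.positions[:, a] - grid.positions[:, b], axis=1)
        strain = (dist - gm.spacing) / gm.spacing
        hip_sag = angle_trial.angles[:, 0]
        design = np.column_stack([np.ones(hip_sag.size), hip_sag])
        beta, *_ = np.linalg.lstsq(design, strain, rcond=None)
        resid = strain - design @ beta
        assert np.abs(resid).max() < 1e-6

    def test_invalid_grid_rejected(self, angle_trial):
        from gaitstrain import GridModel

        with pytest.raises(ValueError):
            simulate_marker_grid(angle_trial, GridModel(grid_rows=1), seed=0)

    def test_channel_names_aligned(self):
        assert len(CHANNEL_NAMES) == 6
        assert CHANNEL_NAMES[0] == "hip_sag" and CHANNEL_NAMES[3] == "knee_sag"
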