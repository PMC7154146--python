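"""Synthetic cohort generator: determinism, ground truth, signal model."""

import numpy as np
import pytest

from sstkit import (ConfigurationError, RecordingConfig, SyntheticParams,
                    cohort_seeds, cosine_smooth, generate_cohort,
                    generate_participant, generate_participant_series,
                    ground_truth_phase, participant_average_from_series,
                    single_cycle_coefficients, smoothing_window)


def test_generator_is_deterministic(schedule, two_channel_config, stimulus):
    p = SyntheticParams()
    a = generate_participant(p, schedule, two_channel_config, stimulus, 11)
    b = generate_participant(p, schedule, two_channel_config, stimulus, 11)
    np.testing.assert_array_equal(a.samples, b.samples)
    c = generate_participant(p, schedule, two_channel_config, stimulus, 12)
    assert not np.array_equal(a.samples, c.samples)


def test_degenerate_case_is_pure_cosine(noiseless_params, schedule,
                                        two_channel_config, stimulus):
    rec = generate_participant(noiseless_params, schedule, two_channel_config,
                               stimulus, 3)
    t = np.arange(rec.samples.shape[1]) / rec.sampling_rate
    expected = noiseless_params.ssvep_amplitude * np.cos(
        2 * np.pi * stimulus.frequency * t)
    np.testing.assert_allclose(rec.samples[1], expected, atol=1e-12)  # C3: no dip


def test_ground_truth_phase_closed_forms(schedule, two_channel_config):
    flat = SyntheticParams(carrier_phase=0.4)
    assert ground_truth_phase(flat, schedule, "C3", 5, 12.0,
                              two_channel_config) == pytest.approx(0.4)
    dip = SyntheticParams(carrier_phase=0.4, dip_channels={"FC5": 0.3},
                          dip_width=1.0, participant_depth_sd=0.0)
    center = schedule.test_offset  # dip centre within every room
    assert ground_truth_phase(dip, schedule, "FC5", 5, center,
                              two_channel_config) == pytest.approx(0.4 - 0.3)
    # three dip widths out, the Gaussian tail leaves ~1.1% of the depth
    val = ground_truth_phase(dip, schedule, "FC5", 5, center - 3.0,
                             two_channel_config)
    assert val == pytest.approx(0.4 - 0.3 * np.exp(-4.5), abs=1e-12)
    with pytest.raises(KeyError):
        ground_truth_phase(dip, schedule, "Oz", 5, 12.0, two_channel_config)
    with pytest.raises(ValueError):
        ground_truth_phase(dip, schedule, "FC5", 5, 1e6, two_channel_config)


def test_demod_tracks_truth_convolved_with_window(dip_params, dip_series,
                                                  schedule, two_channel_config):
    """Noiseless demodulated phase = ground truth ⊛ smoothing window (<0.01 rad)."""
    w = smoothing_window(10)
    truth = ground_truth_phase(dip_params, schedule, "FC5", 7,
                               dip_series.cycle_centers, two_channel_config)
    expected = np.convolve(truth, w, mode="same")
    got = np.angle(dip_series.coefficients[0])
    err = np.abs(got - expected)[dip_series.edge_valid]
    assert err.max() < 0.01


def test_global_phase_offset_shifts_demodulated_phase(schedule,
                                                      two_channel_config,
                                                      stimulus):
    base = SyntheticParams(noise_pink_amplitude=0.0, alpha_amplitude=0.0,
                           carrier_phase=0.0, dip_channels={"FC5": 0.2})
    shifted = SyntheticParams(noise_pink_amplitude=0.0, alpha_amplitude=0.0,
                              carrier_phase=0.7, dip_channels={"FC5": 0.2})
    series = []
    for p in (base, shifted):
        rec = generate_participant(p, schedule, two_channel_config, stimulus, 4)
        series.append(cosine_smooth(single_cycle_coefficients(rec, stimulus)))
    diff = np.angle(series[1].coefficients * np.conj(series[0].coefficients))
    assert np.allclose(diff[:, series[0].edge_valid], 0.7, atol=5e-3)


def test_cohort_size_duration_and_montage(schedule, montage, stimulus,
                                          noiseless_params):
    cohort = generate_cohort(noiseless_params, schedule, montage, stimulus,
                             n_participants=50, seed=1)
    assert len(cohort) == 50
    assert all(r.duration >= 380.0 for r in cohort)
    assert all(r.samples.shape[0] == 20 for r in cohort)


def test_cohort_seeding(schedule, two_channel_config, stimulus):
    p = SyntheticParams()
    one = generate_cohort(p, schedule, two_channel_config, stimulus, 1, seed=5)
    assert len(one) == 1
    a = generate_cohort(p, schedule, two_channel_config, stimulus, 2, seed=5)
    b = generate_cohort(p, schedule, two_channel_config, stimulus, 2, seed=5)
    for ra, rb in zip(a, b):
        np.testing.assert_array_equal(ra.samples, rb.samples)
    c = generate_cohort(p, schedule, two_channel_config, stimulus, 2, seed=6)
    assert not np.array_equal(a[0].samples, c[0].samples)
    # carrier phases independent across participants
    phases = [ground_truth_phase(p, schedule, "FC5", int(s), 0.0,
                                 two_channel_config)
              for s in cohort_seeds(5, 4)]
    assert len(set(np.round(phases, 6))) == 4
    with pytest.raises(ConfigurationError):
        cohort_seeds(5, 0)


def test_fast_path_shares_ground_truth_with_raw_path(dip_params, schedule,
                                                     two_channel_config,
                                                     stimulus):
    series = generate_participant_series(dip_params, schedule,
                                         two_channel_config, stimulus, 9)
    truth = ground_truth_phase(dip_params, schedule, "FC5", 9,
                               series.cycle_centers, two_channel_config)
    np.testing.assert_allclose(np.angle(series.coefficients[0]), truth,
                               atol=1e-12)


def test_fast_path_matches_raw_pipeline_statistics(schedule, two_channel_config,
                                                   stimulus):
    """The calibrated cycle-level route reproduces the raw route's test-point
    phase scatter to within sampling error."""
    p = SyntheticParams()
    def deltas(fast, n):
        out = []
        for seed in range(n):
            if fast:
                c = generate_participant_series(p, schedule, two_channel_config,
                                                stimulus, seed)
            else:
                rec = generate_participant(p, schedule, two_channel_config,
                                           stimulus, seed)
                c = single_cycle_coefficients(rec, stimulus)
            avg = participant_average_from_series(cosine_smooth(c), schedule)
            out.append(np.angle(avg.series[0, schedule.test_cycle(13.0)]))
        return np.asarray(out)
    sd_raw = deltas(False, 30).std()
    sd_fast = deltas(True, 120).std()
    assert sd_fast == pytest.approx(sd_raw, rel=0.45)  # both ≈ 0.24 rad


def test_invalid_configurations_raise():
    with pytest.raises(ConfigurationError):
        SyntheticParams(dip_channels={"FC5": -0.1})
    with pytest.raises(ConfigurationError):
        SyntheticParams(dip_width=0.0)
    with pytest.raises(ConfigurationError):
        SyntheticParams(noise_pink_amplitude=-1.0)
    with pytest.raises(ConfigurationError):
        RecordingConfig(channel_labels=("FC5", "FC5"))
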