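"""Event-locked epoching, baseline phase zeroing, and pooling."""

import numpy as np
import pytest

from sstkit import (EventSchedule, ParticipantAverage, SyntheticParams,
                    baseline_normalize_and_average, cosine_smooth,
                    extract_epochs, generate_participant_series,
                    ground_truth_phase, participant_average_from_series,
                    pool_participants, smoothing_window)
from sstkit.demod import SSVEPSeries
from sstkit.epoching import EpochingError


def _series(values: np.ndarray, cycle_rate: float = 13.0) -> SSVEPSeries:
    v = np.atleast_2d(values).astype(complex)
    return SSVEPSeries(coefficients=v, cycle_rate=cycle_rate, t0=0.0,
                       channel_labels=tuple(f"ch{i}" for i in range(v.shape[0])),
                       smoothing_width=10,
                       edge_valid=np.ones(v.shape[1], dtype=bool))


def _avg(series: np.ndarray, schedule: EventSchedule,
         pid: str = "p") -> ParticipantAverage:
    s = np.atleast_2d(series).astype(complex)
    return ParticipantAverage(series=s, schedule=schedule, cycle_rate=13.0,
                              channel_labels=tuple(f"ch{i}"
                                                   for i in range(s.shape[0])),
                              participant_id=pid,
                              edge_valid=np.ones(s.shape[1], dtype=bool))


class TestExtractEpochs:
    def test_default_geometry_is_10_rooms_by_455_cycles(self, dip_series,
                                                        schedule):
        es = extract_epochs(dip_series, schedule)
        assert es.epochs.shape == (10, 2, 455)
        # epoch 0 cycle 0 aligns with room entry (t = 0)
        np.testing.assert_array_equal(es.epochs[0, :, :20],
                                      dip_series.coefficients[:, :20])

    def test_zero_rooms_gives_empty_set(self, dip_series):
        sched = EventSchedule(n_rooms=0)
        es = extract_epochs(dip_series, sched)
        assert es.epochs.shape == (0, 2, 455)

    def test_room_past_end_raises_naming_the_room(self, schedule):
        short = _series(np.ones(1000))
        with pytest.raises(EpochingError, match="room 2"):
            extract_epochs(short, schedule)


class TestBaselineNormalization:
    def test_constant_phase_zeroes_out(self, schedule):
        series = _series(np.exp(1.1j) * np.ones(4940))
        es = extract_epochs(series, schedule)
        avg = baseline_normalize_and_average(es, cycle_rate=13.0)
        np.testing.assert_allclose(np.angle(avg.series), 0.0, atol=1e-12)

    def test_idempotent_on_zero_baseline_series(self, schedule):
        rng = np.random.default_rng(0)
        vals = np.exp(1j * rng.normal(0, 0.1, 4940))
        es = extract_epochs(_series(vals), schedule)
        once = baseline_normalize_and_average(es, cycle_rate=13.0)
        es2 = extract_epochs(_series(np.tile(once.series[0], 11)[:4940]),
                             schedule)
        # feeding an already-zero-baseline room pattern changes nothing
        b = once.series[0, once.baseline_cycles].mean()
        assert np.angle(b) == pytest.approx(0.0, abs=1e-9)

    def test_degenerate_baseline_raises(self, schedule):
        vals = np.ones(4940, dtype=complex)
        vals[:65] = np.resize([1.0, -1.0], 65)
        vals[64] = 0.0  # 32 cancelling pairs + one zero → zero resultant
        es = extract_epochs(_series(np.tile(vals[:455], 11)[:4940]), schedule)
        with pytest.raises(EpochingError, match="baseline"):
            baseline_normalize_and_average(es, cycle_rate=13.0)

    def test_known_dip_recovered_to_window_convolved_truth(
            self, dip_params, dip_series, schedule, two_channel_config):
        """After room averaging and baseline zeroing, the normalized FC5
        phase equals the ground-truth dip convolved with the smoothing
        window (baseline contribution of the dip at 0–5 s is nil)."""
        avg = participant_average_from_series(dip_series, schedule)
        w = smoothing_window(10)
        tau = (np.arange(455) + 0.5) / 13.0
        truth = -0.3 * np.exp(-0.5 * (tau - schedule.test_offset) ** 2)
        expected = np.convolve(truth, w, mode="same")
        got = np.angle(avg.series[0])
        mask = avg.edge_valid
        assert np.abs(got - expected)[mask].max() < 0.01
        tc = schedule.test_cycle(13.0)
        assert got[tc] == pytest.approx(-0.3 * 0.985, abs=0.01)


class TestPooling:
    def test_single_participant_pools_to_itself(self, schedule):
        rng = np.random.default_rng(1)
        a = _avg(np.exp(1j * rng.normal(0, 0.3, 455)), schedule)
        pooled = pool_participants([a])
        np.testing.assert_allclose(pooled.phase_deg,
                                   np.degrees(np.angle(a.series)), atol=1e-9)

    def test_symmetric_phases_cancel(self, schedule):
        x = 0.4 * np.sin(np.linspace(0, 3, 455))
        a = _avg(np.exp(1j * x), schedule, "a")
        b = _avg(np.exp(-1j * x), schedule, "b")
        pooled = pool_participants([a, b])
        np.testing.assert_allclose(pooled.phase_deg, 0.0, atol=1e-9)

    def test_unit_weighting_ignores_amplitude(self, schedule):
        a = _avg(100.0 * np.exp(0.2j) * np.ones(455), schedule, "a")
        b = _avg(np.exp(-0.4j) * np.ones(455), schedule, "b")
        pooled = pool_participants([a, b], weighting="unit")
        np.testing.assert_allclose(np.radians(pooled.phase_deg), -0.1,
                                   atol=1e-9)
        heavy = pool_participants([a, b], weighting="amplitude")
        assert np.all(np.radians(heavy.phase_deg) > 0.15)

    def test_mismatched_geometry_raises(self, schedule):
        a = _avg(np.ones(455), schedule)
        b = _avg(np.ones(400), schedule)
        with pytest.raises(EpochingError):
            pool_participants([a, b])
        with pytest.raises(EpochingError):
            pool_participants([])

    def test_pooled_phases_are_principal_values(self, schedule):
        rng = np.random.default_rng(2)
        avgs = [_avg(np.exp(1j * rng.uniform(-np.pi, np.pi, 455)), schedule,
                     str(i)) for i in range(5)]
        pooled = pool_participants(avgs)
        assert np.all(pooled.phase_deg > -180.0) and np.all(pooled.phase_deg <= 180.0)


class TestInvariances:
    def test_global_phase_offset_leaves_average_unchanged(self, dip_series,
                                                          schedule):
        avg0 = participant_average_from_series(dip_series, schedule)
        rotated = SSVEPSeries(coefficients=dip_series.coefficients * np.exp(0.9j),
                              cycle_rate=dip_series.cycle_rate, t0=0.0,
                              channel_labels=dip_series.channel_labels,
                              smoothing_width=dip_series.smoothing_width,
                              edge_valid=dip_series.edge_valid)
        avg1 = participant_average_from_series(rotated, schedule)
        np.testing.assert_allclose(avg0.series, avg1.series, atol=1e-9)

    def test_room_order_does_not_matter(self, dip_series, schedule):
        es = extract_epochs(dip_series, schedule)
        avg0 = baseline_normalize_and_average(es, cycle_rate=13.0)
        perm = np.random.default_rng(0).permutation(10)
        shuffled = type(es)(epochs=es.epochs[perm], schedule=es.schedule,
                            channel_labels=es.channel_labels,
                            participant_id=es.participant_id,
                            edge_valid=es.edge_valid[perm])
        avg1 = baseline_normalize_and_average(shuffled, cycle_rate=13.0)
        np.testing.assert_allclose(avg0.series, avg1.series, atol=1e-12)

    def test_null_cohorts_pool_to_zero_at_the_test_cycle(
            self, schedule, two_channel_config, stimulus):
        """Monte Carlo null: across 60 dip-free cohorts the pooled phase at
        the event-boundary cycle is centred on zero (within 3 SE)."""
        tc = schedule.test_cycle(13.0)
        params = SyntheticParams()  # no dip channels
        vals = []
        seeds = iter(range(10_000))
        for _ in range(60):
            avgs = [participant_average_from_series(
                cosine_smooth(generate_participant_series(
                    params, schedule, two_channel_config, stimulus,
                    next(seeds))), schedule) for _ in range(6)]
            pooled = pool_participants(avgs)
            vals.append(np.radians(pooled.phase_deg[0, tc]))
        vals = np.asarray(vals)
        se = vals.std(ddof=1) / np.sqrt(len(vals))
        assert abs(vals.mean()) < 3 * se + 1e-12
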