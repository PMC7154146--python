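"""Event-locked epoching, per-participant averaging, baseline phase zeroing, pooling.

This is the averaging pipeline behind the pooled phase time-series: the
35 s epoch following each room entry is cut out of the smoothed cycle
series, averaged across the 10 rooms as complex numbers (real and
imaginary parts separately), rotated so the mean phase over the first
5 s baseline is zero, and finally pooled across participants with a
circular mean.

Phases are carried as complex numbers end to end; angles are
materialized only at the pooling/reporting boundary. Differences are
always formed as ``arg(z1 * conj(z2))``, never by subtracting angles.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .config import EventSchedule
from .demod import SSVEPSeries


class EpochingError(ValueError):
    pass


@dataclass(frozen=True)
class EpochSet:
    """Room-locked complex epochs: (n_rooms, n_channels, cycles_per_room)."""

    epochs: np.ndarray
    schedule: EventSchedule
    channel_labels: tuple[str, ...]
    participant_id: str
    edge_valid: np.ndarray  # (n_rooms, cycles_per_room) bool

    @property
    def n_rooms(self) -> int:
        return self.epochs.shape[0]


@dataclass(frozen=True)
class ParticipantAverage:
    """Room-averaged, baseline-zeroed complex series per channel.

    Invariant: the argument of the mean complex value over the baseline
    cycles is zero (to numerical precision) on every channel.
    """

    series: np.ndarray  # (n_channels, cycles_per_room) complex
    schedule: EventSchedule
    cycle_rate: float
    channel_labels: tuple[str, ...]
    participant_id: str
    edge_valid: np.ndarray  # (cycles_per_room,) bool

    @property
    def baseline_cycles(self) -> slice:
        return self.schedule.baseline_cycles(self.cycle_rate)

    def index_of(self, channel: str) -> int:
        try:
            return self.channel_labels.index(channel)
        except ValueError:
            raise KeyError(f"unknown channel {channel!r}") from None


@dataclass(frozen=True)
class PooledSeries:
    """Cross-participant pooled phase per channel, in degrees.

    Positive values are phase advance (earlier response, read as
    increased activity); negative values phase lag.
    """

    phase_deg: np.ndarray  # (n_channels, cycles_per_room)
    resultant_length: np.ndarray  # (n_channels, cycles_per_room), in [0, 1]
    n_participants: int
    schedule: EventSchedule
    cycle_rate: float
    channel_labels: tuple[str, ...]

    @property
    def times(self) -> np.ndarray:
        """Time within the room, seconds, at cycle starts."""
        return np.arange(self.phase_deg.shape[1]) / self.cycle_rate


def extract_epochs(series: SSVEPSeries, schedule: EventSchedule,
                   participant_id: str = "") -> EpochSet:
    """Cut the per-room epochs out of a smoothed cycle series.

    Room onsets are rounded to the nearest stimulus cycle; each epoch
    covers ``round(room_duration * f)`` cycles from room entry (455 at
    13 Hz / 35 s). An epoch running past the end of the series raises,
    naming the offending room.
    """
    f = series.cycle_rate
    cpr = schedule.cycles_per_room(f)
    onsets = np.round(schedule.room_onsets() * f).astype(int)
    n = series.n_cycles
    epochs = np.empty((schedule.n_rooms, len(series.channel_labels), cpr),
                      dtype=complex)
    valid = np.empty((schedule.n_rooms, cpr), dtype=bool)
    for r, start in enumerate(onsets):
        if start < 0 or start + cpr > n:
            raise EpochingError(
                f"room {r} epoch (cycles {start}..{start + cpr}) extends "
                f"past the series of {n} cycles")
        epochs[r] = series.coefficients[:, start:start + cpr]
        valid[r] = series.edge_valid[start:start + cpr]
    return EpochSet(epochs=epochs, schedule=schedule,
                    channel_labels=series.channel_labels,
                    participant_id=participant_id or "unknown",
                    edge_valid=valid)


def baseline_normalize_and_average(epochs: EpochSet,
                                   cycle_rate: float | None = None,
                                   order: str = "average_then_rotate") -> ParticipantAverage:
    """Average epochs across rooms and zero the baseline phase.

    Default order averages the complex epochs across rooms first, then
    rotates the averaged series by the conjugate unit phasor of its
    baseline mean. ``order="rotate_then_average"`` zeroes each room's
    own baseline before averaging instead (the two readings of the
    procedure; see the methods note).
    """
    if epochs.n_rooms == 0:
        raise EpochingError("cannot average an empty epoch set")
    f = cycle_rate if cycle_rate is not None else (
        epochs.epochs.shape[2] / epochs.schedule.room_duration)
    base = epochs.schedule.baseline_cycles(f)
    if base.stop <= base.start:
        raise EpochingError("baseline window is empty at this cycle rate")

    def _rotate(series: np.ndarray) -> np.ndarray:
        b = series[..., base].mean(axis=-1, keepdims=True)
        mag = np.abs(b)
        if np.any(mag == 0):
            raise EpochingError("degenerate baseline: zero complex resultant")
        return series * (np.conj(b) / mag)

    if order == "average_then_rotate":
        avg = _rotate(epochs.epochs.mean(axis=0))
    elif order == "rotate_then_average":
        avg = _rotate(np.stack([_rotate(room) for room in epochs.epochs]).mean(axis=0))
    else:
        raise EpochingError(f"unknown baseline order {order!r}")
    return ParticipantAverage(series=avg, schedule=epochs.schedule,
                              cycle_rate=f, channel_labels=epochs.channel_labels,
                              participant_id=epochs.participant_id,
                              edge_valid=epochs.edge_valid.all(axis=0))


def pool_participants(averages: list[ParticipantAverage],
                      weighting: str = "unit") -> PooledSeries:
    """Circular mean of participant phase series, reported in degrees.

    ``unit`` weighting (default) normalizes every participant's complex
    value to unit modulus before averaging, so the pooled phase is the
    circular mean of phases and high-amplitude participants carry no
    extra weight; ``amplitude`` averages the raw complex values.
    """
    if not averages:
        raise EpochingError("need at least one participant to pool")
    ref = averages[0]
    shape = ref.series.shape
    for a in averages[1:]:
        if a.series.shape != shape or a.channel_labels != ref.channel_labels:
            raise EpochingError("participants have mismatched epoch geometry")
    stack = np.stack([a.series for a in averages])  # (n_p, n_ch, n_cyc)
    if weighting == "unit":
        mag = np.abs(stack)
        mag[mag == 0] = 1.0
        stack = stack / mag
    elif weighting != "amplitude":
        raise EpochingError(f"unknown pooling weighting {weighting!r}")
    resultant = stack.mean(axis=0)
    return PooledSeries(phase_deg=np.degrees(np.angle(resultant)),
                        resultant_length=np.abs(resultant) /
                        (np.abs(stack).mean(axis=0) if weighting == "amplitude" else 1.0),
                        n_participants=len(averages), schedule=ref.schedule,
                        cycle_rate=ref.cycle_rate, channel_labels=ref.channel_labels)
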