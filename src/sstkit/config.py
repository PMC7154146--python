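"""Experiment configuration: stimulus, event schedule, recording montage.

Defaults describe the virtual-gallery paradigm this package models: a
13 Hz sinusoidal flicker superimposed on a first-person walk through ten
35 s gallery rooms (380 s total), with the exit door — the event
boundary — appearing 30 s after room entry. EEG is sampled at 400 Hz
from 20 scalp sites of the 10-10 system.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

#: The 20-site 10-10 montage used throughout; FC5/FC6 overlie the
#: left/right ventrolateral prefrontal cortex.
DEFAULT_CHANNELS: tuple[str, ...] = (
    "Fp1", "Fp2", "F3", "Fz", "F4", "FC5", "FC6", "T7", "T8", "C3",
    "Cz", "C4", "P3", "Pz", "P4", "PO7", "PO8", "O1", "Oz", "O2",
)


class ConfigurationError(ValueError):
    """Raised when a configuration object violates its invariants."""


@dataclass(frozen=True)
class StimulusSpec:
    """Flicker stimulus evoking the steady-state visual evoked potential.

    Parameters
    ----------
    frequency : float
        Flicker frequency in Hz. The SSVEP is demodulated at exactly
        this frequency, one complex coefficient per stimulus cycle.
    modulation_depth : float
        Luminance modulation depth (fraction). Metadata only: the
        recorded response amplitude, not the stimulus, is simulated.
    """

    frequency: float = 13.0
    modulation_depth: float = 0.45

    def __post_init__(self) -> None:
        if self.frequency <= 0:
            raise ConfigurationError("stimulus frequency must be positive")


@dataclass(frozen=True)
class EventSchedule:
    """Timing of the repeated room epochs and the event-boundary test point.

    ``test_offset`` is the within-room time of the event boundary (door
    appearance); ``baseline_window`` is the within-room interval whose
    mean SSVEP phase defines each participant's zero reference.
    """

    n_rooms: int = 10
    room_duration: float = 35.0
    test_offset: float = 30.0
    baseline_window: tuple[float, float] = (0.0, 5.0)
    total_duration: float = 380.0

    def __post_init__(self) -> None:
        if self.n_rooms < 0:
            raise ConfigurationError("n_rooms must be non-negative")
        if self.room_duration <= 0 or self.total_duration <= 0:
            raise ConfigurationError("durations must be positive")
        if not (0 < self.test_offset < self.room_duration):
            raise ConfigurationError(
                "test_offset must fall strictly inside a room epoch")
        lo, hi = self.baseline_window
        if not (0 <= lo < hi <= self.room_duration):
            raise ConfigurationError(
                "baseline_window must be a non-empty interval within the room")
        if self.n_rooms * self.room_duration > self.total_duration + 1e-9:
            raise ConfigurationError(
                "rooms do not fit inside total_duration")

    def room_onsets(self) -> np.ndarray:
        """Room-entry times in seconds (rooms are contiguous from t=0)."""
        return np.arange(self.n_rooms) * self.room_duration

    def cycles_per_room(self, frequency: float) -> int:
        return int(round(self.room_duration * frequency))

    def test_cycle(self, frequency: float) -> int:
        """Within-room cycle index of the event-boundary test point."""
        return int(round(self.test_offset * frequency))

    def baseline_cycles(self, frequency: float) -> slice:
        lo, hi = self.baseline_window
        return slice(int(round(lo * frequency)), int(round(hi * frequency)))

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2) + "\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "EventSchedule":
        d = json.loads(Path(path).read_text())
        d["baseline_window"] = tuple(d["baseline_window"])
        return cls(**d)


@dataclass(frozen=True)
class RecordingConfig:
    """EEG digitization parameters and channel montage."""

    sampling_rate: float = 400.0
    channel_labels: tuple[str, ...] = DEFAULT_CHANNELS

    def __post_init__(self) -> None:
        if self.sampling_rate <= 0:
            raise ConfigurationError("sampling_rate must be positive")
        if len(set(self.channel_labels)) != len(self.channel_labels):
            raise ConfigurationError("channel labels must be unique")

    def validate_against(self, stimulus: StimulusSpec) -> None:
        if self.sampling_rate <= 2 * stimulus.frequency:
            raise ConfigurationError(
                "sampling_rate must exceed twice the stimulus frequency")

    def index_of(self, channel: str) -> int:
        try:
            return self.channel_labels.index(channel)
        except ValueError:
            raise KeyError(f"unknown channel {channel!r}") from None


@dataclass(frozen=True)
class SyntheticParams:
    """Ground-truth parameters for the synthetic SSVEP cohort generator.

    The generated signal per channel is
    ``A * cos(2*pi*f*t + phi_p + dphi_ch(t)) + pink noise + alpha rhythm``
    where ``phi_p`` is a participant-specific carrier phase and
    ``dphi_ch`` a Gaussian-profile phase lag of depth ``dip_channels[ch]``
    (radians) and SD ``dip_width`` (s), centred ``dip_center`` seconds
    after every room entry. Per-participant dip depths are drawn from
    ``Normal(depth, participant_depth_sd)`` truncated at zero.

    ``cycle_noise_sd`` drives the cycle-level fast path
    (:func:`sstkit.synth.generate_participant_series`): complex Gaussian
    noise per component, in µV, calibrated so the fast path reproduces
    the raw path's single-cycle coefficient noise under the default
    noise amplitudes.
    """

    ssvep_amplitude: float = 1.5
    carrier_phase: float | None = None  # None: uniform(-pi, pi] per participant
    dip_channels: dict[str, float] = field(default_factory=dict)
    dip_width: float = 1.0
    dip_center: float | None = None  # None: schedule.test_offset
    participant_depth_sd: float = 0.05
    noise_pink_amplitude: float = 10.0
    noise_pink_exponent: float = 1.0
    alpha_amplitude: float = 3.0
    alpha_freq: float = 10.0
    cycle_noise_sd: float = 2.9
    amplitude_dip_depth: float = 0.0  # fractional amplitude drop, robustness only
    quantize_16bit: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.ssvep_amplitude < 0 or self.noise_pink_amplitude < 0 \
                or self.alpha_amplitude < 0 or self.cycle_noise_sd < 0:
            raise ConfigurationError("amplitudes must be non-negative")
        if any(d < 0 for d in self.dip_channels.values()):
            raise ConfigurationError("dip depths must be non-negative")
        if self.dip_width <= 0:
            raise ConfigurationError("dip_width must be positive")
        if self.participant_depth_sd < 0:
            raise ConfigurationError("participant_depth_sd must be non-negative")
        if not 0 <= self.amplitude_dip_depth < 1:
            raise ConfigurationError("amplitude_dip_depth must lie in [0, 1)")


@dataclass(frozen=True)
class RawRecording:
    """Multichannel sampled EEG voltages in µV."""

    samples: np.ndarray  # (n_channels, n_samples), float64, µV
    sampling_rate: float
    channel_labels: tuple[str, ...]
    participant_id: str

    def __post_init__(self) -> None:
        if self.samples.ndim != 2 or self.samples.shape[0] != len(self.channel_labels):
            raise ConfigurationError("samples must be (n_channels, n_samples)")
        if not np.all(np.isfinite(self.samples)):
            raise ConfigurationError("samples contain non-finite values")

    @property
    def duration(self) -> float:
        return self.samples.shape[1] / self.sampling_rate

    def index_of(self, channel: str) -> int:
        try:
            return self.channel_labels.index(channel)
        except ValueError:
            raise KeyError(f"unknown channel {channel!r}") from None
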