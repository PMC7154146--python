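"""Single-cycle Fourier demodulation of the SSVEP with cosine-weighted smoothing.

The steady-state response is reduced to one complex coefficient per
stimulus cycle: the projection of that cycle's samples onto the stimulus
frequency, scaled so a unit-amplitude cosine at the stimulus frequency
yields ``1 + 0j``. A sliding cosine-weighted window (default 10 cycles,
hop 1 cycle) then smooths the coefficient sequence, trading temporal
resolution (~half the window width) for phase stability.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as _signal

from .config import RawRecording, StimulusSpec


class DemodulationError(ValueError):
    pass


@dataclass(frozen=True)
class CycleCoefficients:
    """One complex SSVEP coefficient per stimulus cycle per channel.

    ``coefficients[ch, k]`` has the amplitude (µV) and phase (radians)
    of the response during cycle ``k``; ``cycle_rate`` equals the
    stimulus frequency, so cycle ``k`` starts at ``t0 + k / cycle_rate``.
    """

    coefficients: np.ndarray  # (n_channels, n_cycles) complex
    cycle_rate: float
    t0: float
    channel_labels: tuple[str, ...]

    @property
    def n_cycles(self) -> int:
        return self.coefficients.shape[1]

    @property
    def times(self) -> np.ndarray:
        """Cycle start times in seconds."""
        return self.t0 + np.arange(self.n_cycles) / self.cycle_rate

    @property
    def cycle_centers(self) -> np.ndarray:
        """Cycle midpoint times; phase estimates refer to these."""
        return self.t0 + (np.arange(self.n_cycles) + 0.5) / self.cycle_rate

    def index_of(self, channel: str) -> int:
        try:
            return self.channel_labels.index(channel)
        except ValueError:
            raise KeyError(f"unknown channel {channel!r}") from None


@dataclass(frozen=True)
class SSVEPSeries(CycleCoefficients):
    """Smoothed per-cycle SSVEP series.

    ``edge_valid[k]`` is False within half a window of either end, where
    the smoothing kernel was renormalized over the available cycles.
    """

    smoothing_width: int = 10
    edge_valid: np.ndarray = None  # (n_cycles,) bool

    @property
    def phase(self) -> np.ndarray:
        return np.angle(self.coefficients)

    @property
    def amplitude(self) -> np.ndarray:
        return np.abs(self.coefficients)


def cycle_boundaries(n_samples: int, sampling_rate: float, frequency: float) -> np.ndarray:
    """Sample indices delimiting whole stimulus cycles.

    Boundaries sit at ``floor(k * fs / f)`` so that non-integer
    samples-per-cycle (400/13 ≈ 30.77) never accumulates drift over a
    long recording.
    """
    n_cycles = int(np.floor(n_samples * frequency / sampling_rate))
    k = np.arange(n_cycles + 1)
    return np.floor(k * sampling_rate / frequency).astype(np.intp)


def single_cycle_coefficients(recording: RawRecording,
                              stimulus: StimulusSpec) -> CycleCoefficients:
    """Project each stimulus cycle onto the stimulus frequency.

    For cycle ``k`` spanning samples ``i in [floor(k*fs/f), floor((k+1)*fs/f))``
    the coefficient is ``(2/n_k) * sum_i x[i] * exp(-2j*pi*f*t_i)`` with
    ``t_i = i / fs`` the exact sample time, so ``x(t) = cos(2*pi*f*t)``
    maps to ``1 + 0j`` up to the ripple of the non-integer cycle length.
    """
    fs, f = recording.sampling_rate, stimulus.frequency
    if fs <= 2 * f:
        raise DemodulationError("sampling rate must exceed twice the stimulus frequency")
    x = recording.samples
    bounds = cycle_boundaries(x.shape[1], fs, f)
    if len(bounds) < 2:
        raise DemodulationError("recording shorter than one stimulus cycle")
    t = np.arange(x.shape[1]) / fs
    basis = np.exp(-2j * np.pi * f * t)
    prod = x * basis  # (n_ch, n_samples)
    sums = np.add.reduceat(prod, bounds[:-1], axis=1)
    counts = np.diff(bounds)
    coeffs = 2.0 * sums / counts
    return CycleCoefficients(coefficients=coeffs, cycle_rate=f, t0=0.0,
                             channel_labels=recording.channel_labels)


def smoothing_window(width: int = 10, taper: str = "cosine") -> np.ndarray:
    """Symmetric smoothing kernel over ``width + 1`` cycle taps, unit sum.

    ``cosine`` (default): ``w_j = cos(pi * j / width)`` for
    ``j in [-width/2, width/2]`` — the half-cosine taper whose end taps
    vanish. ``hann`` is the squared-cosine alternative.
    """
    if width < 2:
        raise DemodulationError("smoothing width must be at least 2 cycles")
    h = width // 2
    j = np.arange(-h, h + 1)
    if taper == "cosine":
        w = np.cos(np.pi * j / width)
        w[np.abs(w) < 1e-15] = 0.0  # exact zero at j = ±width/2
    elif taper == "hann":
        w = np.cos(np.pi * j / width) ** 2
    else:
        raise DemodulationError(f"unknown taper {taper!r}")
    return w / w.sum()


def cosine_smooth(coeffs: CycleCoefficients, width: int = 10,
                  taper: str = "cosine") -> SSVEPSeries:
    """Slide the cosine-weighted window over the cycle series (hop = 1 cycle).

    Interior output ``k`` is ``sum_j w_j c_{k+j}`` with unit-sum weights;
    within ``width/2`` cycles of either end the kernel is renormalized
    over the cycles actually present and the output flagged
    ``edge_valid = False``. No extrapolation is ever performed, so the
    early baseline cycles stay usable.
    """
    c = coeffs.coefficients
    n = c.shape[1]
    if n < width:
        raise DemodulationError(
            f"series of {n} cycles is shorter than the {width}-cycle window")
    w = smoothing_window(width, taper)
    num = _signal.convolve(c, w[np.newaxis, :], mode="same")
    den = np.convolve(np.ones(n), w, mode="same")
    smoothed = num / den
    h = width // 2
    edge_valid = np.ones(n, dtype=bool)
    edge_valid[:h] = False
    edge_valid[n - h:] = False
    return SSVEPSeries(coefficients=smoothed, cycle_rate=coeffs.cycle_rate,
                       t0=coeffs.t0, channel_labels=coeffs.channel_labels,
                       smoothing_width=width, edge_valid=edge_valid)


def demodulate(recording: RawRecording, stimulus: StimulusSpec,
               width: int = 10, taper: str = "cosine") -> SSVEPSeries:
    """Raw recording → smoothed per-cycle SSVEP series (both demod stages)."""
    return cosine_smooth(single_cycle_coefficients(recording, stimulus),
                         width=width, taper=taper)


def phase_to_latency(delta_phase: float | np.ndarray, frequency: float) -> float | np.ndarray:
    """Convert an SSVEP phase shift (radians) to a latency change (seconds).

    Positive phase advance means the response arrives earlier, i.e. a
    negative latency change: ``-delta_phase / (2*pi*frequency)``.
    """
    if frequency <= 0:
        raise DemodulationError("frequency must be positive")
    return -np.asarray(delta_phase) / (2 * np.pi * frequency)
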