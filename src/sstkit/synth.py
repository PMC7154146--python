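"""Synthetic SSVEP cohort generator.

Emulates the gallery paradigm at the signal level so every downstream
stage can be tested against known ground truth: each channel carries a
13 Hz SSVEP of fixed amplitude and participant-specific carrier phase,
with a Gaussian-profile transient phase lag (the event-boundary effect)
injected at the same within-room time in every room on designated
channels, on top of 1/f^a pink noise and a 10 Hz alpha rhythm.

Two routes produce the same ground-truth phase trajectory:

* :func:`generate_participant` synthesizes the raw 400 Hz voltage trace
  (the full pipeline input, writable as EDF);
* :func:`generate_participant_series` synthesizes the per-cycle complex
  coefficients directly — statistically matched, orders of magnitude
  cheaper, intended for large simulation studies (null calibration,
  power) where resynthesizing and demodulating raw voltages per cohort
  would dominate the runtime.
"""

from __future__ import annotations

import numpy as np
from scipy import stats as _sstats

from .config import (ConfigurationError, EventSchedule, RawRecording,
                     RecordingConfig, StimulusSpec, SyntheticParams)
from .demod import CycleCoefficients


def pink_noise(n_samples: int, exponent: float, rng: np.random.Generator) -> np.ndarray:
    """Unit-RMS 1/f^exponent noise via spectral shaping of white noise."""
    white = rng.standard_normal(n_samples)
    spec = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n_samples)
    scale = np.ones_like(freqs)
    nz = freqs > 0
    scale[nz] = freqs[nz] ** (-exponent / 2.0)
    scale[0] = 0.0  # no DC
    y = np.fft.irfft(spec * scale, n=n_samples)
    return y / y.std()


def _streams(participant_seed: int) -> tuple[np.random.Generator, np.random.Generator]:
    """Split a participant seed into (ground-truth draws, noise draws).

    Separate streams guarantee that the deterministic part of the signal
    — carrier phase and dip depths — does not depend on how much noise
    is drawn, so :func:`ground_truth_phase` stays exact for both the raw
    and the cycle-level route.
    """
    truth_ss, noise_ss = np.random.SeedSequence(participant_seed).spawn(2)
    return np.random.default_rng(truth_ss), np.random.default_rng(noise_ss)


def _participant_truth(params: SyntheticParams,
                       rng: np.random.Generator) -> tuple[float, dict[str, float]]:
    """Draw carrier phase and per-channel dip depths for one participant.

    Depths come from Normal(depth, participant_depth_sd) truncated at
    zero (inverse-CDF sampling, one uniform draw per channel so the
    stream layout is fixed); channels are visited in sorted label order.
    """
    if params.carrier_phase is None:
        phi_p = float(rng.uniform(-np.pi, np.pi))
    else:
        phi_p = float(params.carrier_phase)
    depths: dict[str, float] = {}
    for label in sorted(params.dip_channels):
        mean = params.dip_channels[label]
        u = float(rng.uniform())
        sd = params.participant_depth_sd
        if sd == 0:
            depths[label] = mean
        else:
            a = -mean / sd  # truncate at zero
            depths[label] = float(_sstats.truncnorm.ppf(u, a, np.inf,
                                                        loc=mean, scale=sd))
    return phi_p, depths


def _dip_profile(t: np.ndarray, schedule: EventSchedule, depth: float,
                 width: float, center: float) -> np.ndarray:
    """Phase offset Δφ(t): −depth·Gaussian(τ − center) within each room, else 0."""
    t = np.asarray(t, dtype=float)
    room = np.floor_divide(t, schedule.room_duration).astype(int)
    in_room = (t >= 0) & (room < schedule.n_rooms)
    tau = t - np.clip(room, 0, max(schedule.n_rooms - 1, 0)) * schedule.room_duration
    prof = np.exp(-0.5 * ((tau - center) / width) ** 2)
    return np.where(in_room, -depth * prof, 0.0)


def ground_truth_phase(params: SyntheticParams, schedule: EventSchedule,
                       channel: str, participant_seed: int,
                       t: float | np.ndarray,
                       config: RecordingConfig | None = None) -> float | np.ndarray:
    """Instantaneous SSVEP phase φ_p + Δφ_ch(t) exactly as generated.

    The oracle counterpart of :func:`generate_participant`: tests compare
    demodulated phase against this trajectory (convolved with the
    smoothing window) without re-running any pipeline stage.
    """
    config = config or RecordingConfig()
    config.index_of(channel)  # KeyError on unknown channel
    t_arr = np.asarray(t, dtype=float)
    if np.any(t_arr < 0) or np.any(t_arr > schedule.total_duration):
        raise ValueError("t outside the recording")
    truth_rng, _ = _streams(participant_seed)
    phi_p, depths = _participant_truth(params, truth_rng)
    center = params.dip_center if params.dip_center is not None else schedule.test_offset
    out = phi_p + _dip_profile(t_arr, schedule, depths.get(channel, 0.0),
                               params.dip_width, center)
    return float(out) if np.isscalar(t) or np.ndim(t) == 0 else out


def generate_participant(params: SyntheticParams, schedule: EventSchedule,
                         config: RecordingConfig, stimulus: StimulusSpec,
                         participant_seed: int,
                         participant_id: str | None = None) -> RawRecording:
    """Synthesize one participant's raw multichannel EEG trace.

    Per channel: ``A·cos(2πf·t + φ_p + Δφ_ch(t))`` plus pink noise
    (independent per channel) and a shared alpha sinusoid with a random
    per-participant phase. Bit-identical for identical seeds.
    """
    config.validate_against(stimulus)
    fs, f = config.sampling_rate, stimulus.frequency
    n = int(round(schedule.total_duration * fs))
    t = np.arange(n) / fs
    truth_rng, noise_rng = _streams(participant_seed)
    phi_p, depths = _participant_truth(params, truth_rng)
    center = params.dip_center if params.dip_center is not None else schedule.test_offset
    alpha_phase = noise_rng.uniform(0, 2 * np.pi)
    alpha = params.alpha_amplitude * np.cos(2 * np.pi * params.alpha_freq * t + alpha_phase)

    samples = np.empty((len(config.channel_labels), n))
    for i, label in enumerate(config.channel_labels):
        dphi = _dip_profile(t, schedule, depths.get(label, 0.0),
                            params.dip_width, center)
        amp = params.ssvep_amplitude
        if params.amplitude_dip_depth > 0 and label in depths:
            amp = amp * (1.0 + params.amplitude_dip_depth * dphi
                         / max(depths[label], np.finfo(float).tiny))
        carrier = amp * np.cos(2 * np.pi * f * t + phi_p + dphi)
        if params.noise_pink_amplitude > 0:
            noise = params.noise_pink_amplitude * pink_noise(
                n, params.noise_pink_exponent, noise_rng)
        else:
            noise = 0.0
        samples[i] = carrier + noise + alpha
    if params.quantize_16bit:
        lsb = 1000.0 / 65536.0  # ±500 µV physical range
        samples = np.round(samples / lsb) * lsb
    return RawRecording(samples=samples, sampling_rate=fs,
                        channel_labels=tuple(config.channel_labels),
                        participant_id=participant_id or f"sub-{participant_seed}")


def generate_participant_series(params: SyntheticParams, schedule: EventSchedule,
                                config: RecordingConfig, stimulus: StimulusSpec,
                                participant_seed: int) -> CycleCoefficients:
    """Cycle-level fast path: synthesize single-cycle coefficients directly.

    The carrier contributes ``A·exp(i(φ_p + Δφ_ch))`` evaluated at cycle
    midpoints; measurement noise enters as i.i.d. complex Gaussian with
    per-component SD ``params.cycle_noise_sd`` (µV), calibrated against
    the raw route's empirical coefficient noise. Ground-truth draws use
    the same stream as :func:`generate_participant`, so
    :func:`ground_truth_phase` applies unchanged.
    """
    f = stimulus.frequency
    n_cycles = int(np.floor(schedule.total_duration * f))
    truth_rng, noise_rng = _streams(participant_seed)
    phi_p, depths = _participant_truth(params, truth_rng)
    center = params.dip_center if params.dip_center is not None else schedule.test_offset
    tc = (np.arange(n_cycles) + 0.5) / f
    n_ch = len(config.channel_labels)
    coeffs = np.empty((n_ch, n_cycles), dtype=complex)
    for i, label in enumerate(config.channel_labels):
        dphi = _dip_profile(tc, schedule, depths.get(label, 0.0),
                            params.dip_width, center)
        coeffs[i] = params.ssvep_amplitude * np.exp(1j * (phi_p + dphi))
    if params.cycle_noise_sd > 0:
        eps = noise_rng.standard_normal((2, n_ch, n_cycles))
        coeffs = coeffs + params.cycle_noise_sd * (eps[0] + 1j * eps[1])
    return CycleCoefficients(coefficients=coeffs, cycle_rate=f, t0=0.0,
                             channel_labels=tuple(config.channel_labels))


def cohort_seeds(seed: int, n_participants: int) -> np.ndarray:
    """Deterministic per-participant seeds derived from one cohort seed."""
    if n_participants < 1:
        raise ConfigurationError("n_participants must be at least 1")
    return np.random.SeedSequence(seed).generate_state(n_participants).astype(np.int64)


def generate_cohort(params: SyntheticParams, schedule: EventSchedule,
                    config: RecordingConfig, stimulus: StimulusSpec,
                    n_participants: int, seed: int) -> list[RawRecording]:
    """Raw recordings for a cohort; carrier phases independent across participants."""
    seeds = cohort_seeds(seed, n_participants)
    return [generate_participant(params, schedule, config, stimulus, int(s),
                                 participant_id=f"sub-{p:03d}")
            for p, s in enumerate(seeds)]
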