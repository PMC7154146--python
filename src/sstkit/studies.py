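"""Simulation studies over the pipeline: fidelity, calibration, power.

Each function runs a self-contained study at a configurable problem
size and returns plain numbers, so the same code backs the analysis
drivers, the test suite and the acceptance script. All randomness is
seeded; cohort seeds derive from the study seed through independent
``SeedSequence`` streams.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .config import (EventSchedule, RawRecording, RecordingConfig,
                     StimulusSpec, SyntheticParams)
from .demod import cosine_smooth, single_cycle_coefficients, smoothing_window
from .epoching import pool_participants
from .pipeline import participant_average_from_series
from .stats import PhaseDeltaVector, enumerate_exact_p, permutation_test, phase_delta_at
from .synth import cohort_seeds, generate_participant_series


def demod_phase_fidelity(n_phases: int = 100, duration: float = 5.0,
                         seed: int = 0) -> float:
    """Worst-case phase error recovering a noiseless carrier.

    Demodulates ``cos(2*pi*13*t + phi)`` for ``n_phases`` random phases
    and returns the largest absolute interior-cycle error (radians) of
    the smoothed series.
    """
    rng = np.random.default_rng(seed)
    stim = StimulusSpec()
    fs = 400.0
    t = np.arange(int(duration * fs)) / fs
    worst = 0.0
    for phi in rng.uniform(-np.pi, np.pi, n_phases):
        rec = RawRecording(samples=np.cos(2 * np.pi * stim.frequency * t
                                          + phi)[np.newaxis, :],
                           sampling_rate=fs, channel_labels=("probe",),
                           participant_id="fidelity")
        s = cosine_smooth(single_cycle_coefficients(rec, stim))
        err = np.abs(np.angle(s.coefficients[0, s.edge_valid]
                              * np.exp(-1j * phi)))
        worst = max(worst, float(err.max()))
    return worst


def mc_enumeration_agreement(n_vectors: int = 50, n: int = 12,
                             n_permutations: int = 100_000,
                             seed: int = 0) -> tuple[float, float]:
    """Monte Carlo vs exact enumeration on random delta vectors.

    Returns ``(max_abs_diff, max_allowed)`` where the allowance is the
    three-sigma binomial band ``3*sqrt(p*(1-p)/N)`` of the worst case.
    """
    rng = np.random.default_rng(seed)
    worst = (-np.inf, 0.0, 0.0)  # (diff/allow, diff, allow)
    for k in range(n_vectors):
        d = np.clip(rng.normal(-0.1, 0.3, n), -np.pi + 1e-9, np.pi)
        exact = enumerate_exact_p(d)
        mc = permutation_test(PhaseDeltaVector(d), n_permutations,
                              seed=int(rng.integers(2**31)))
        diff = abs(mc.p - exact)
        allow = 3 * np.sqrt(max(exact * (1 - exact), 1e-9) / n_permutations)
        if diff / allow > worst[0]:
            worst = (diff / allow, diff, allow)
    return worst[1], worst[2]


def _cohort_deltas(params: SyntheticParams, schedule: EventSchedule,
                   config: RecordingConfig, stimulus: StimulusSpec,
                   channel: str, n_participants: int,
                   cohort_seed: int) -> np.ndarray:
    out = np.empty(n_participants)
    for i, s in enumerate(cohort_seeds(cohort_seed, n_participants)):
        series = cosine_smooth(generate_participant_series(
            params, schedule, config, stimulus, int(s)))
        avg = participant_average_from_series(series, schedule)
        out[i] = phase_delta_at(avg, schedule, channel)
    return out


def type_i_error_rate(n_cohorts: int = 200, n_participants: int = 20,
                      alpha: float = 0.05, n_permutations: int = 100_000,
                      seed: int = 0) -> float:
    """Rejection rate of the permutation test on dip-free cohorts.

    Simulates ``n_cohorts`` null cohorts on a two-channel montage with
    the default noise model (cycle-level route) and tests FC5 at the
    event-boundary cycle; returns the fraction with ``p <= alpha``.
    """
    params = SyntheticParams()  # no dip anywhere
    schedule, stim = EventSchedule(), StimulusSpec()
    config = RecordingConfig(channel_labels=("FC5", "C3"))
    root = np.random.SeedSequence(seed)
    c_seeds = root.generate_state(n_cohorts).astype(np.int64)
    p_seeds = np.random.SeedSequence([seed, 1]).generate_state(n_cohorts)
    rejections = 0
    for c in range(n_cohorts):
        deltas = _cohort_deltas(params, schedule, config, stim, "FC5",
                                n_participants, int(c_seeds[c]))
        res = permutation_test(PhaseDeltaVector(deltas), n_permutations,
                               seed=int(p_seeds[c]))
        rejections += res.p <= alpha
    return rejections / n_cohorts


def window_attenuation(dip_width: float = 1.0, width: int = 10,
                       frequency: float = 13.0,
                       schedule: EventSchedule | None = None) -> float:
    """Fraction of a Gaussian phase dip surviving the smoothing window.

    Convolves a unit-depth dip profile (sampled at cycle midpoints)
    with the normalized window and reads the test cycle.
    """
    schedule = schedule or EventSchedule()
    cpr = schedule.cycles_per_room(frequency)
    tau = (np.arange(cpr) + 0.5) / frequency
    profile = np.exp(-0.5 * ((tau - schedule.test_offset) / dip_width) ** 2)
    smoothed = np.convolve(profile, smoothing_window(width), mode="same")
    return float(smoothed[schedule.test_cycle(frequency)])


@dataclass(frozen=True)
class RecoveryResult:
    mean_recovered_depth: float  # radians, attenuation-corrected
    true_depth: float
    detection_rate: float  # fraction of cohorts with p below threshold
    attenuation: float


def dip_recovery_study(n_cohorts: int = 20, n_participants: int = 50,
                       depth: float = 0.3, dip_width: float = 1.0,
                       p_threshold: float = 0.01,
                       n_permutations: int = 100_000,
                       seed: int = 0) -> RecoveryResult:
    """Recover an injected FC5 dip from full cohorts under default noise.

    Per cohort: simulate, pool, read the pooled phase at the test cycle,
    correct for the smoothing-window attenuation, and run the sign-flip
    test. Returns the across-cohort mean recovered depth and the
    fraction of cohorts detected at ``p_threshold``.
    """
    params = SyntheticParams(dip_channels={"FC5": depth}, dip_width=dip_width)
    schedule, stim = EventSchedule(), StimulusSpec()
    config = RecordingConfig(channel_labels=("FC5", "C3"))
    atten = window_attenuation(dip_width, frequency=stim.frequency,
                               schedule=schedule)
    tc = schedule.test_cycle(stim.frequency)
    c_seeds = np.random.SeedSequence(seed).generate_state(n_cohorts).astype(np.int64)
    p_seeds = np.random.SeedSequence([seed, 1]).generate_state(n_cohorts)
    recovered, detected = [], 0
    for c in range(n_cohorts):
        avgs = []
        deltas = np.empty(n_participants)
        for i, s in enumerate(cohort_seeds(int(c_seeds[c]), n_participants)):
            series = cosine_smooth(generate_participant_series(
                params, schedule, config, stim, int(s)))
            avg = participant_average_from_series(series, schedule)
            avgs.append(avg)
            deltas[i] = phase_delta_at(avg, schedule, "FC5")
        pooled = pool_participants(avgs)
        recovered.append(-np.radians(pooled.phase_deg[0, tc]) / atten)
        res = permutation_test(PhaseDeltaVector(deltas), n_permutations,
                               seed=int(p_seeds[c]))
        detected += res.p < p_threshold
    return RecoveryResult(mean_recovered_depth=float(np.mean(recovered)),
                          true_depth=depth,
                          detection_rate=detected / n_cohorts,
                          attenuation=atten)


def step_half_rise_cycles(width: int = 10, step: float = 0.4) -> int:
    """Cycles from first window contact to half amplitude of a phase step."""
    n, at = 80, 40
    c = np.ones(n, dtype=complex)
    c[at:] = np.exp(1j * step)
    from .demod import CycleCoefficients
    s = cosine_smooth(CycleCoefficients(
        coefficients=c[np.newaxis, :], cycle_rate=13.0, t0=0.0,
        channel_labels=("probe",)), width=width)
    phase = np.angle(s.coefficients[0])
    half_idx = int(np.argmax(phase >= step / 2))
    onset = at - width // 2
    return half_idx - onset
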