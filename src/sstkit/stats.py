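"""Inference at the event-boundary time point.

One scalar per participant — the baseline-referenced SSVEP phase at the
test cycle — enters a one-sample sign-flip permutation test: under the
null the phase is as likely above the baseline reference as below it,
so flipping the sign of a random subset of participants leaves the
distribution of the group mean unchanged. The lower-tail count across
resamples (or across all 2^n sign patterns) gives the exact one-sided
p-value, Bonferroni-corrected across the 20 scalp sites, with the
t-quantile r_equivalent as effect size.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as _sstats

from .config import EventSchedule
from .epoching import ParticipantAverage

_TIE_EPS = 1e-12  # ties with the observed statistic count as extreme


class StatsError(ValueError):
    pass


@dataclass(frozen=True)
class PhaseDeltaVector:
    """Per-participant phase differences (radians) at the test cycle."""

    deltas: np.ndarray
    channel: str = ""

    def __post_init__(self) -> None:
        d = np.asarray(self.deltas, dtype=float)
        object.__setattr__(self, "deltas", d)
        if d.ndim != 1 or d.size < 1:
            raise StatsError("deltas must be a non-empty 1-d vector")
        if not np.all(np.isfinite(d)):
            raise StatsError("deltas must be finite")
        if np.any(d <= -np.pi - 1e-9) or np.any(d > np.pi + 1e-9):
            raise StatsError("phase deltas must lie in (-pi, pi]")

    @property
    def n(self) -> int:
        return self.deltas.size


@dataclass(frozen=True)
class PermutationResult:
    observed: float  # group mean delta, radians
    n_permutations: int
    n_at_or_below: int
    p: float
    mode: str  # "monte_carlo" | "enumerate"
    seed: int | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.p <= 1.0:
            raise StatsError("p must lie in [0, 1]")


def phase_delta_at(avg: ParticipantAverage, schedule: EventSchedule,
                   channel: str) -> float:
    """Baseline-referenced phase (radians) at the event-boundary cycle.

    Reads the argument of the normalized series at cycle
    ``round(test_offset * f)`` (390 for 30 s at 13 Hz); negative values
    are phase lag relative to the zeroed baseline. Refuses cycles inside
    the smoothing edge region.
    """
    cyc = schedule.test_cycle(avg.cycle_rate)
    if not 0 <= cyc < avg.series.shape[1]:
        raise StatsError(f"test cycle {cyc} outside the epoch")
    if not avg.edge_valid[cyc]:
        raise StatsError(f"test cycle {cyc} lies in the smoothing edge region")
    return float(np.angle(avg.series[avg.index_of(channel), cyc]))


def _lower_tail_count(means: np.ndarray, observed: float) -> int:
    return int(np.count_nonzero(means <= observed + _TIE_EPS))


def enumerate_exact_p(deltas: PhaseDeltaVector | np.ndarray) -> float:
    """Exact lower-tail probability over all 2^n sign-flip patterns.

    Feasible up to n = 20 (about a million patterns); beyond that the
    Monte Carlo mode of :func:`permutation_test` is the tool.
    """
    d = deltas.deltas if isinstance(deltas, PhaseDeltaVector) else \
        PhaseDeltaVector(np.asarray(deltas)).deltas
    n = d.size
    if n > 20:
        raise StatsError(
            f"n={n} gives 2^{n} patterns; use permutation_test(mode='monte_carlo')")
    sums = np.zeros(1)
    for x in d:  # doubling construction: all signed sums
        sums = np.concatenate([sums + x, sums - x])
    return _lower_tail_count(sums, float(d.sum())) / sums.size


def permutation_test(deltas: PhaseDeltaVector, n_permutations: int = 100_000,
                     seed: int | None = None, mode: str = "monte_carlo",
                     add_one: bool = False) -> PermutationResult:
    """One-sample sign-flip permutation test (lower tail).

    Each resample multiplies an independently chosen random subset of
    participants' deltas by −1 and recomputes the group mean; ``p`` is
    the fraction of resamples whose mean is at or below the observed
    mean. ``mode="enumerate"`` replaces sampling with the full 2^n
    enumeration (exact, seedless). ``add_one`` applies the
    (count+1)/(N+1) guard against reporting p = 0; off by default.
    """
    d = deltas.deltas
    observed = float(d.mean())
    if mode == "enumerate":
        p = enumerate_exact_p(deltas)
        total = 2 ** deltas.n
        return PermutationResult(observed=observed, n_permutations=total,
                                 n_at_or_below=int(round(p * total)), p=p,
                                 mode=mode, seed=None)
    if mode != "monte_carlo":
        raise StatsError(f"unknown mode {mode!r}")
    if n_permutations < 1:
        raise StatsError("n_permutations must be at least 1")
    if seed is None:
        raise StatsError("monte_carlo mode requires a seed")
    rng = np.random.default_rng(seed)
    count = 0
    chunk = 20_000
    for start in range(0, n_permutations, chunk):
        m = min(chunk, n_permutations - start)
        signs = rng.integers(0, 2, size=(m, deltas.n)) * 2 - 1
        count += _lower_tail_count(signs @ d / deltas.n, observed)
    if add_one:
        p = (count + 1) / (n_permutations + 1)
    else:
        p = count / n_permutations
    return PermutationResult(observed=observed, n_permutations=n_permutations,
                             n_at_or_below=count, p=p, mode=mode, seed=seed)


def r_equivalent(p: float, n: int) -> float:
    """Effect-size correlation recovered from a one-sided p and sample size.

    ``t`` is the Student-t quantile at ``1 − p`` with ``n − 1`` degrees
    of freedom and ``r = t / sqrt(t² + df)``; monotone decreasing in p.
    """
    if not 0.0 < p < 1.0:
        raise StatsError("p must lie strictly in (0, 1)")
    if n < 3:
        raise StatsError("need n >= 3")
    df = n - 1
    t = _sstats.t.ppf(1.0 - p, df)
    return float(t / np.sqrt(t * t + df))


@dataclass(frozen=True)
class SignificanceTable:
    """Per-channel p-values with Bonferroni flags and effect sizes."""

    table: pd.DataFrame  # electrode, p, sig_* columns, r_equivalent
    m: int
    alphas: tuple[float, ...]

    def significant(self, alpha: float) -> list[str]:
        col = f"sig_{alpha:g}"
        if col not in self.table:
            raise StatsError(f"alpha {alpha} not in table")
        return list(self.table.loc[self.table[col], "electrode"])

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)


def bonferroni_table(p_by_channel: dict[str, float], m: int = 20,
                     alphas: tuple[float, ...] = (0.01, 0.05),
                     n: int | None = None) -> SignificanceTable:
    """Bonferroni correction over ``m`` comparisons at each experiment-wide α.

    A channel is flagged at level α iff ``p ≤ α / m``. When ``n`` is
    given, :func:`r_equivalent` is tabulated alongside (NaN where p is
    degenerate).
    """
    if m < len(p_by_channel):
        raise StatsError("m must cover all channels tested")
    rows = []
    for ch, p in p_by_channel.items():
        if not 0.0 <= p <= 1.0:
            raise StatsError(f"p for {ch} outside [0, 1]")
        row: dict[str, object] = {"electrode": ch, "p": p}
        for a in alphas:
            row[f"sig_{a:g}"] = bool(p <= a / m)
        if n is not None:
            row["r_equivalent"] = r_equivalent(p, n) if 0 < p < 1 else np.nan
        rows.append(row)
    return SignificanceTable(table=pd.DataFrame(rows), m=m, alphas=tuple(alphas))


def cohort_phase_deltas(averages: list[ParticipantAverage],
                        schedule: EventSchedule, channel: str,
                        wrap: bool = True) -> PhaseDeltaVector:
    """Collect each participant's test-cycle phase delta for one channel."""
    vals = np.array([phase_delta_at(a, schedule, channel) for a in averages])
    if wrap:  # angles are already principal values; keep the exact bound
        vals = np.angle(np.exp(1j * vals))
    return PhaseDeltaVector(deltas=vals, channel=channel)
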