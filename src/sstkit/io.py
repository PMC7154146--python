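"""Plain-text (CSV/JSON) serialization of pipeline products."""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .config import EventSchedule
from .demod import SSVEPSeries
from .epoching import ParticipantAverage, PooledSeries


def ssvep_to_csv(series: SSVEPSeries, path: str | Path) -> Path:
    """Long-format per-cycle series: one row per (channel, cycle)."""
    n_ch, n_cyc = series.coefficients.shape
    frames = []
    for i, ch in enumerate(series.channel_labels):
        c = series.coefficients[i]
        frames.append(pd.DataFrame({
            "channel": ch,
            "cycle_index": np.arange(n_cyc),
            "time_s": series.times,
            "real": c.real,
            "imag": c.imag,
            "amplitude": np.abs(c),
            "phase_rad": np.angle(c),
            "edge_valid": series.edge_valid,
        }))
    path = Path(path)
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)
    return path


def ssvep_from_csv(path: str | Path) -> SSVEPSeries:
    """Inverse of :func:`ssvep_to_csv`.

    The cycle rate is recovered from the time column and the smoothing
    width from the leading run of edge-invalid cycles.
    """
    df = pd.read_csv(path)
    channels = tuple(df["channel"].unique())
    first = df[df["channel"] == channels[0]].sort_values("cycle_index")
    dt = float(np.median(np.diff(first["time_s"].to_numpy())))
    cycle_rate = round(1.0 / dt, 9)
    edge_valid = first["edge_valid"].to_numpy(dtype=bool)
    half = int(np.argmax(edge_valid)) if edge_valid.any() else 0
    coeffs = np.stack([
        (g := df[df["channel"] == ch].sort_values("cycle_index"))["real"].to_numpy()
        + 1j * g["imag"].to_numpy()
        for ch in channels])
    return SSVEPSeries(coefficients=coeffs, cycle_rate=cycle_rate,
                       t0=float(first["time_s"].iloc[0]),
                       channel_labels=channels,
                       smoothing_width=2 * half if half else 0,
                       edge_valid=edge_valid)


def participant_average_to_csv(avg: ParticipantAverage, path: str | Path) -> Path:
    n_ch, n_cyc = avg.series.shape
    frames = []
    for i, ch in enumerate(avg.channel_labels):
        c = avg.series[i]
        frames.append(pd.DataFrame({
            "channel": ch,
            "cycle_index": np.arange(n_cyc),
            "time_in_room_s": np.arange(n_cyc) / avg.cycle_rate,
            "real": c.real,
            "imag": c.imag,
            "phase_deg": np.degrees(np.angle(c)),
            "edge_valid": avg.edge_valid,
        }))
    path = Path(path)
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)
    return path


def pooled_to_csv(pooled: PooledSeries, path: str | Path) -> Path:
    """Wide-format pooled phase: cycle rows, one phase column per channel."""
    n_cyc = pooled.phase_deg.shape[1]
    data: dict[str, np.ndarray] = {
        "cycle_index": np.arange(n_cyc),
        "time_in_room_s": pooled.times,
    }
    for i, ch in enumerate(pooled.channel_labels):
        data[f"phase_deg_{ch}"] = pooled.phase_deg[i]
    path = Path(path)
    pd.DataFrame(data).to_csv(path, index=False)
    return path


def pooled_from_csv(path: str | Path, schedule: EventSchedule | None = None,
                    n_participants: int = 0) -> PooledSeries:
    df = pd.read_csv(path)
    channels = tuple(c.removeprefix("phase_deg_") for c in df.columns
                     if c.startswith("phase_deg_"))
    phase = np.stack([df[f"phase_deg_{ch}"].to_numpy() for ch in channels])
    t = df["time_in_room_s"].to_numpy()
    cycle_rate = round(1.0 / float(np.median(np.diff(t))), 9)
    return PooledSeries(phase_deg=phase, resultant_length=np.ones_like(phase),
                        n_participants=n_participants,
                        schedule=schedule or EventSchedule(),
                        cycle_rate=cycle_rate, channel_labels=channels)
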