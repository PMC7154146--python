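"""Reading and writing raw recordings as European Data Format (EDF).

Writing uses a small self-contained EDF encoder (ASCII header, 16-bit
little-endian samples, one-second data records, physical units µV) —
sufficient for continuous single-session EEG. Reading goes through
MNE's EDF reader, which also serves as the independent check on the
writer in the test suite.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

from .config import RawRecording

_DIG_MIN, _DIG_MAX = -32767, 32767


def _field(value: str, width: int) -> bytes:
    s = str(value)[:width]
    return s.ljust(width).encode("ascii")


def write_edf(recording: RawRecording, path: str | Path) -> Path:
    """Write a recording to EDF with 16-bit sample encoding.

    The trace is zero-padded to a whole number of one-second records.
    Each channel gets a symmetric physical range just covering its data,
    so quantization error is at most range/2^16.
    """
    path = Path(path)
    fs = recording.sampling_rate
    spr = int(round(fs))
    if abs(spr - fs) > 1e-9:
        raise ValueError("EDF writer requires an integer sampling rate")
    x = recording.samples
    n_ch, n_samp = x.shape
    n_rec = int(np.ceil(n_samp / spr))
    if n_rec * spr != n_samp:
        x = np.pad(x, ((0, 0), (0, n_rec * spr - n_samp)))

    phys_max = np.maximum(np.abs(x).max(axis=1), 1e-3)
    phys_max = np.array([float(f"{v:.6g}") * 1.000001 for v in phys_max])
    digital = np.round(x / phys_max[:, None] * _DIG_MAX).astype("<i2")

    header = [
        _field("0", 8), _field(recording.participant_id, 80),
        _field("Startdate 01-JAN-2000", 80),
        _field("01.01.00", 8), _field("00.00.00", 8),
        _field(str(256 * (1 + n_ch)), 8), _field("", 44),
        _field(str(n_rec), 8), _field("1", 8), _field(str(n_ch), 4),
    ]
    labels = recording.channel_labels
    for width, values in [
        (16, labels), (80, ["AgAgCl electrode"] * n_ch), (8, ["uV"] * n_ch),
        (8, [f"{-v:.6g}" for v in phys_max]), (8, [f"{v:.6g}" for v in phys_max]),
        (8, [str(_DIG_MIN)] * n_ch), (8, [str(_DIG_MAX)] * n_ch),
        (80, [""] * n_ch), (8, [str(spr)] * n_ch), (32, [""] * n_ch),
    ]:
        header.extend(_field(v, width) for v in values)

    with open(path, "wb") as fh:
        fh.write(b"".join(header))
        # record-major, signal-minor layout
        fh.write(np.ascontiguousarray(
            digital.reshape(n_ch, n_rec, spr).transpose(1, 0, 2)).tobytes())
    return path


def read_edf(path: str | Path, participant_id: str | None = None) -> RawRecording:
    """Read an EDF file into a RawRecording (µV) via MNE."""
    import mne

    raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    return RawRecording(samples=raw.get_data() * 1e6,
                        sampling_rate=float(raw.info["sfreq"]),
                        channel_labels=tuple(raw.ch_names),
                        participant_id=participant_id or Path(path).stem)
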