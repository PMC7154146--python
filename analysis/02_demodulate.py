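#!/usr/bin/env python
"""Demodulate the cohort's EDF recordings into per-cycle SSVEP series.

Each recording is reduced to one complex 13 Hz coefficient per stimulus
cycle per channel, smoothed with the 10-cycle cosine-weighted window
(hop one cycle), and written as a long-format CSV.
"""

import argparse
from pathlib import Path

import numpy as np

from sstkit import StimulusSpec, cosine_smooth, read_edf, single_cycle_coefficients
from sstkit.io import ssvep_to_csv


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--cohort", type=Path, default=Path("results/cohort"))
    args = ap.parse_args()

    stimulus = StimulusSpec()
    out = args.cohort / "ssvep"
    out.mkdir(parents=True, exist_ok=True)
    paths = sorted((args.cohort / "edf").glob("*.edf"))
    if not paths:
        raise SystemExit(f"no EDF files under {args.cohort / 'edf'}; "
                         "run 01_simulate_cohort.py first")
    for p in paths:
        rec = read_edf(p)
        series = cosine_smooth(single_cycle_coefficients(rec, stimulus))
        ssvep_to_csv(series, out / f"{p.stem}_ssvep.csv")
        amp = np.median(series.amplitude[:, series.edge_valid])
        print(f"{p.stem}: {series.n_cycles} cycles, "
              f"median SSVEP amplitude {amp:.2f} uV")
    print(f"\n{len(paths)} per-cycle series under {out}")


if __name__ == "__main__":
    main()
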