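# sstkit

Steady-state topography (SST) analysis of event-boundary-locked EEG.

When a continuous experience crosses an event boundary — here, the
door between rooms of a virtual art gallery coming into view — frontal
brain activity transiently drops. `sstkit` implements the signal path
and inference used to measure that effect with the steady-state visual
evoked potential (SSVEP): a diffuse 13 Hz flicker entrains an
oscillatory response whose *phase* at each of 20 scalp sites tracks
regional activity (phase advance = shorter latency = more activity).
The package provides

- a **synthetic cohort generator** (raw 400 Hz EEG or per-cycle
  coefficients) with a known Gaussian phase-lag transient injected at
  the event boundary, pink-noise + alpha background, and exact
  ground-truth oracles — the original recordings are unavailable, so
  every stage is validated against simulation;
- **single-cycle Fourier demodulation**: one complex coefficient per
  stimulus cycle, `c_k = (2/n_k)·Σ x[i]·e^{−2πi f t_i}`, smoothed by a
  10-cycle cosine-weighted sliding window (hop 1 cycle, ≈385 ms
  temporal resolution);
- **event-locked averaging**: the 35 s epoch after each room entry,
  averaged over 10 rooms as complex numbers, baseline phase (first 5 s)
  rotated to zero, pooled across participants by circular mean;
- **inference**: one-sample sign-flip permutation test of the phase at
  the 30 s boundary cycle (100,000 resamples, or exact 2^n enumeration
  for n ≤ 20), Bonferroni correction over the 20 sites, and the
  `r_equivalent = t/√(t²+df)` effect size.

EDF is read via MNE and written by a built-in 16-bit encoder; all
derived products are CSV/JSON.

## Worked example

The numbered drivers under `analysis/` run the whole study on a
synthetic cohort (n = 12, dips of 0.3 rad at FC5/C3 and 0.2 rad at P3):

```bash
python analysis/01_simulate_cohort.py --seed 1   # EDFs + ground truth
python analysis/02_demodulate.py                 # per-cycle SSVEP CSVs
python analysis/03_event_locked_analysis.py      # pooling + permutation test
python analysis/04_simulation_studies.py         # calibration & power
```

Step 03 prints the pooled boundary-cycle phase per site and the
corrected significance sets (abridged):

```
pooled over n=12; phase at the 30 s boundary cycle (deg, + = advance):
  FC5   -27.32 <-- lag
  C3    -15.28 <-- lag
  P3    -18.71 <-- lag
  Oz     +1.43
  ...
significant after Bonferroni (m=20): p<0.01 -> ['FC5']; p<0.05 -> ['FC5', 'C3']
```

The injected left fronto-central lag is recovered (negative pooled
phase ≈ −27° ≈ −0.48 rad at FC5 for this cohort's drawn depths) and
survives Bonferroni correction, while no-dip sites hover near zero.
Step 04 reports the pipeline's calibration:

```
demodulator fidelity: worst interior phase error 1.04e-03 rad
type-I error on 200 null cohorts at alpha=0.05: 0.035 (binomial 95% band around 0.05: [0.02, 0.09])
0.3 rad FC5 dip over 20 cohorts of n=50: recovered 0.316 rad after /0.986 window correction; detected at p<0.01 in 100% of cohorts
published table: corrected p<0.01 -> ['FC5', 'C3'], p<0.05 -> ['FC5', 'C3', 'P3']; r_equivalent(p=2e-4, n=50) = 0.477
```

The same steps are available as a CLI (`sst simulate|demod|analyze|
report|all`) with a JSON config file and flag overrides; see
`sst --help`.

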