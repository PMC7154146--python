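# Methods

## The measurement model

A spatially diffuse 13 Hz sinusoidal flicker superimposed on the visual
field entrains a steady-state visual evoked potential (SSVEP) in the
EEG. `sstkit` tracks the *phase* of that response cycle by cycle: a
phase advance at a scalp site is read as a latency decrease of the
evoked response and hence increased regional activity; a phase lag as
reduced activity. The paradigm modelled here is a first-person walk
through ten identical 35 s gallery rooms (380 s total, 400 Hz
digitization, 20 sites of the 10-10 montage). The exit door — an event
boundary — appears 30 s after each room entry; the hypothesis under
test is a transient phase lag, maximal at left fronto-central sites
(FC5, C3), time-locked to that boundary.

## Demodulation

For stimulus frequency `f` and sampling rate `fs`, cycle `k` spans
samples `i ∈ [floor(k·fs/f), floor((k+1)·fs/f))`. Its complex
coefficient is

    c_k = (2 / n_k) · Σ_i x[i] · exp(−2πi·f·t_i),   t_i = i / fs,

so a unit cosine at `f` maps to `1 + 0i`. Cycle boundaries are floored
per cycle rather than accumulated, so the non-integer samples-per-cycle
ratio (400/13 ≈ 30.77) causes bounded ripple (< 0.03 in amplitude) and
no phase drift over the 380 s recording.

The coefficient sequence is smoothed with a sliding cosine-weighted
window of `width = 10` cycles, hop one cycle:

    w_j = cos(π·j / width),   j = −width/2 … width/2,

normalized to unit sum; the end taps vanish, giving an 11-tap symmetric
kernel. A Hann (squared-cosine) taper is selectable. At the edges the
kernel is renormalized over the cycles actually present and the output
flagged `edge_valid = False`; nothing is extrapolated, so the early
baseline cycles remain usable. The smoothed step response reaches half
amplitude five cycles (≈ 385 ms at 13 Hz) after the window first
touches the step — the method's effective temporal resolution. The
window attenuates a Gaussian phase dip of SD 1 s by a factor 0.986
(computed by convolving the unit dip with the kernel), which the
recovery study divides out.

Phase is carried as complex numbers end to end; angles are materialized
only for statistics and display. Phase differences are formed as
`arg(z₁·conj(z₂))`, never by subtracting angles, so wrapping is never
an issue. `phase_to_latency` converts a phase shift to a latency
change, `Δt = −Δφ/(2πf)`: +0.1 rad at 13 Hz is −1.224 ms.

## Event-locked averaging

The 455-cycle (35 s) epoch following each room entry (onsets rounded to
the nearest cycle) is averaged across the ten rooms as complex numbers.
The averaged series is then rotated so that the argument of its mean
complex value over the first 5 s (cycles 0–64) is exactly zero — a
wrap-safe circular baseline. The amplifier's bandpass phase response
makes absolute phase arbitrary, which is precisely why only
baseline-referenced phase is interpreted. Whether each room is rotated
before averaging or the room average rotated once is not uniquely
determined by the procedure's description; both orders are implemented
(`baseline_order`), the default rotating the room average, which uses
the better-estimated (10-room) baseline. Pooling across participants
takes the circular mean of unit-normalized complex values, so
high-amplitude participants carry no extra weight; amplitude-weighted
pooling is available as a config flag.

## Inference

Per participant and channel the statistic is the baseline-referenced
phase at cycle `round(30 s × 13 Hz) = 390` — only the door-appearance
time point is tested. Under the null (phase equally likely above or
below the baseline reference) each participant's delta is
sign-symmetric, so the one-sample sign-flip permutation test applies:
each of 100,000 resamples flips the sign of an independently chosen
random subset of participants and recomputes the group mean; the
one-sided p is the fraction of resamples at or below the observed mean,
with ties counted as extreme and `p = count / N` exactly (an optional
`(count+1)/(N+1)` guard is off by default). For `n ≤ 20` the full `2^n`
enumeration is available and exact. p-values are Bonferroni-corrected
for the 20 sites; the effect size is

    r_equivalent = t / sqrt(t² + df),   t = t-quantile(1 − p, df = n − 1).

Note the df = n−1 one-sample convention: at the strongest reported
operating point (p = 2×10⁻⁴, n = 50) it gives r = 0.477, whereas the
source study prints r = 0.52 without stating its df/p convention; the
value is computed, not tuned.

## The synthetic cohort

Because the original 50-participant recordings are unavailable, every
stage is validated against a generator with known ground truth. Per
channel the raw trace is

    A · cos(2πf·t + φ_p + Δφ_ch(t)) + pink + alpha,

with `φ_p` a participant-specific carrier phase (uniform unless fixed)
and, within each room, `Δφ_ch(τ) = −d_ch(p) · exp(−(τ − 30)²/(2·w²))` —
a Gaussian phase lag (depth `d`, SD `w = 1 s`) centred on the boundary,
identical in every room. Gaussian was chosen as the minimal smooth
transient; the effect lives in phase only (the test statistic is phase),
with an optional amplitude-dip parameter for robustness checks.
Per-participant depths are drawn from `Normal(d, 0.05)` truncated at
zero via inverse-CDF sampling, so the draw count per participant is
fixed and `ground_truth_phase` reproduces the trajectory exactly from
the participant seed. Cohort seeds expand to participant seeds through
a `SeedSequence`; ground-truth and noise draws use separate child
streams.

Background noise is `1/f` pink noise (FFT spectral shaping, RMS 10 µV)
plus a shared 10 µV-band alpha sinusoid (10 Hz, 3 µV, random phase per
participant) — the dominant constituents of resting EEG background.
The SSVEP amplitude default is 1.5 µV. No study states these
amplitudes; they were fixed once so that the per-participant test-point
phase SD is ≈ 0.235 rad, comfortably consistent with the
signal-to-noise implied by the reported n = 50, p = 2×10⁻⁴ effect, and
not revisited. The generator does not model blinks, EMG, eye movement
or volume conduction, and 16-bit quantization is off by default
(negligible at these amplitudes; a flag enables it) — so passing tests
demonstrate correctness of the signal path and calibration of the
statistics under this idealized background, not robustness to
structured artifacts.

### Cycle-level fast path

Large simulation studies synthesize the per-cycle coefficients
directly: `A·exp(i(φ_p + Δφ))` at cycle midpoints plus i.i.d. complex
Gaussian noise of per-component SD 2.9 µV. That SD was calibrated to
match the raw route's *test-point phase SD* rather than its per-cycle
coefficient SD: pink noise is correlated across cycles and averages
less effectively than white noise, so matching the inferential quantity
is the honest equivalence (both routes give SD ≈ 0.235 rad; the test
suite checks the agreement). Both routes share the ground-truth stream,
so the same oracle applies.

## Study sizes and numerical choices

- Demodulator fidelity: 100 random carrier phases, 5 s traces;
  worst interior error ≈ 1×10⁻³ rad (limit 0.05).
- Monte Carlo vs enumeration: 50 random n = 12 vectors, 100,000
  resamples against the full 4096-pattern enumeration, three-sigma
  binomial agreement.
- Type-I calibration: 200 dip-free cohorts of n = 20 on a two-channel
  montage via the fast path; rejection at α = 0.05 must stay in the
  binomial 95% band [0.02, 0.09].
- Recovery/power: 20 cohorts of n = 50 with a 0.3 rad FC5 dip; the
  pooled, attenuation-corrected depth must land within ±20% of truth
  and p < 0.01 in ≥ 90% of cohorts.
- The worked-example cohort in `analysis/` uses n = 12 raw-path
  participants with dips FC5/C3 0.3 rad and P3 0.2 rad: large enough
  that the exact enumeration's p floor (2⁻¹² ≈ 2.4×10⁻⁴) can clear the
  corrected 0.01 threshold, small enough to run in seconds.
- Ties in the permutation count use an absolute tolerance of 1e-12;
  the baseline rotation raises on an exactly zero complex resultant;
  epoch extraction raises (naming the room) rather than truncate.

## Known limitations

- Absolute phase is meaningless by construction; all conclusions are
  within-recording, baseline-referenced.
- Only the 30 s point is tested; no whole-curve scan or max-statistic
  correction is implemented, mirroring the single-point hypothesis.
- The EDF writer covers continuous single-session recordings
  (integer sampling rates, one-second records); it is not a general
  EDF+ implementation.
- The r = 0.52 discrepancy above is documented, not resolved.
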