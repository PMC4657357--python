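# Methods

This note documents the models, parameter choices and numerical decisions
behind `callid`, and what the synthetic validation does and does not show
about real recordings.

## The measurement problem

Five belugas share an acoustically connected pool complex; one animal (or a
mother–calf pair) is isolated at a time. Two hydrophones 7.5 m apart at 1 m
depth record at 500 kHz/16 bit. The analysis asks whether the stereotyped
broadband pulsed contact call type (PS1) carries caller identity: calls are
detected, attributed to the isolated animal by inter-channel arrival-time
difference (TDOA), reduced to nine temporal/spectral descriptors, screened,
and classified back to individuals by quadratic discriminant analysis (QDA)
with leave-one-out cross-validation (LOOCV). The potential-for-individual-
coding statistic PIC = CVb / mean(CVw) summarizes, per descriptor, whether
between-individual variation exceeds within-individual variation (CVw uses
the small-sample correction `1 + 1/(4n)`).

No recordings from the study system are public, so the package ships a
generator that renders ground-truthed sessions from parametric caller
profiles; all acceptance properties are measured against that truth.

## Synthetic caller model

**IPI contour.** A call is a pulse train whose inter-pulse intervals follow
a piecewise-linear template: a level `initial_ipi_ms` held through interval
`transition_onset − 1`, then a linear ramp at `slope_ms_per_pulse` that
saturates at `terminal_ipi_ms`. Three stochastic terms sit on top of it:

* a call-level offset (`ipi_call_sd`, Gaussian, clipped to the caller's
  observed level range `ipi_level_min/max_ms`) — between-call
  within-individual variation, the component that gives CVw its size;
* i.i.d. per-interval jitter (`ipi_jitter_sd`);
* for the calf only, a bounded random walk (`ipi_walk_sd`, reflected into
  ±40 % of the template) — a caller with no stereotyped repetition pattern.

IPIs are floored at 0.1 ms. Template levels and per-call spreads of the
five default profiles are set from the published per-animal summary table
(initial level = mean of the 11–20 block, terminal level = mean of the
last block, pulse-count mean/SD/min/max); they are simulation fixtures, not
measurements. With all scales zero the draw is the deterministic template,
which is what the sample-exact fidelity tests use.

**Pulse waveform.** Each pulse is designed in the frequency domain with
zero phase: a sharp Gaussian (σ = 4 kHz) at the caller's peak frequency on
a broad Gaussian pedestal (σ = `spectral_bw`, −2.5 dB), plus the ~6 kHz
low-band energy peak common to all callers (−8 dB), high-passed at 1 kHz,
inverse-transformed into a 256-sample (0.51 ms) transient and Tukey-
tapered. The sharp-plus-pedestal composition is deliberate: measured
burst-pulse spectra combine a well-defined peak with a 10 dB bandwidth of
60–130 kHz, and a single Gaussian wide enough for such a bandwidth is so
flat near its maximum that its peak frequency would be unmeasurable. With
the −2.5 dB pedestal the 10 dB bandwidth is ≈1.55 σ, which is how the
default widths were derived from the published bandwidths. Zero phase puts
the envelope maximum exactly at the centre sample, so pulse-peak truth is
sample-exact. The adult male additionally carries a continuous ~13 kHz
tonal component at −44 dB (audible in long-window spectra, negligible in
the 1.5 ms pulse windows). The pulse atom is short (±0.26 ms) so that even
the male's fastest contours (IPIs down to ~1.4 ms) do not overlap
neighbouring atoms — overlapping tails would interfere and modulate
envelope peak heights.

**Sessions, geometry, noise.** Callers hold fixed 3-D positions; the
isolated animal sits on the channel-1 side (TDOA ≈ +4.7 ms), the group on
the far side (−4.5 to −4.9 ms). Propagation is straight-path delay and 1/r
spreading only — no multipath (a single synthetic echo is available in
`render_call` to exercise the detector's reflection rejection) and no
absorption. Noise is white Gaussian plus a low-passed component that
raises the *spectral* floor below 5 kHz by 10 dB (per unit bandwidth) —
the persistent low-frequency pool noise that motivates the 6 kHz analysis
floor. `snr_db` (default 20) is defined as peak in-band (6–170 kHz)
envelope of the call over the white component's RMS: the level an analyst
reads off a detector display. Defining SNR on the raw waveform instead
would make it depend on how much of a pulse's energy falls outside the
band, i.e. on the caller's spectrum. The schedule budgets one generous
slot per call (maximum plausible pulse count × slowest plausible IPI), so
default sessions contain no overlaps; overlapping schedules are allowed
and flagged in the truth.

## Detector

The front end is the analytic-signal magnitude after a 4th-order 6–170 kHz
Butterworth band-pass (zero-phase). Three thresholds derive from the noise
level (median envelope of a caller-free window):

* *onset*: first crossing of `3 × noise` by the envelope averaged over
  20 µs. The averaging matters: at 500 kHz a raw single-sample test against
  3× the Rayleigh median (≈3.5 σ of the envelope) fires on the noise's own
  upper tail within milliseconds.
* *segmentation*: supra-threshold runs at `5 × noise`, merged across gaps
  shorter than 50 ms (a call ends at the last supra-threshold sample
  followed by ≥ 50 ms of silence), minimum duration 10 ms.
* *pulse peaks*: envelope maxima above `3 × noise` with a 1 ms refractory
  spacing form candidates; the working threshold is then raised to 0.65 ×
  the call's own typical pulse amplitude (median of candidates within 6 dB
  of the strongest) when that is stricter. The signal-relative threshold is
  what makes exact pulse counting possible: a millisecond gap holds
  thousands of envelope samples, so the threshold must clear ≈6 σ of the
  noise envelope, which a noise-multiple alone cannot guarantee across
  callers with different in-band levels.

Two deterministic rules replace the manual pulse-count corrections a human
analyst performs: candidates 0.1–1.0 ms after a stronger pulse and below
0.7 of its amplitude are discarded as reflections; gaps longer than 1.6 ×
the local median IPI are re-scanned at 0.3 × the working threshold, floored
at `4 × noise`, for low-amplitude direct pulses. The noise floor on the
recovery pass means deep fades (more than ~12 dB below the working
threshold at 20 dB SNR) are left missing rather than confabulated from
noise peaks.

At the default pack's conditions (20 dB SNR) the pulse count is exact for
≈99 % of calls; the residual errors are single false/missed peaks in the
adult male's long wideband calls, whose in-band envelope sits lowest.

## TDOA attribution

Envelopes of both channels are baseline-clipped at 3× their median (so the
sparse pulse peaks, not the noise floor, carry the correlation),
cross-correlated within ±1.2× the geometric bound `spacing / c = 5 ms`,
and the peak refined by 3-point parabolic interpolation; an onset-based
estimator is provided as an alternative. Two gates mark an estimate
ambiguous: a normalized correlation peak below 0.3, and *coverage* below
0.75 — the fraction of channel-2 pulse energy within ±0.3 ms of aligned
channel-1 pulse support. The coverage gate is what catches simultaneous
calls from opposite sides, where the correlation peak alone would happily
pick the louder source. Verdicts (isolated / other / ambiguous) follow the
zone interval with a ±0.2 ms tolerance band at the decision edge;
ambiguous calls are counted but excluded from per-individual analysis.
Periodic pulse trains put large sidelobes at lags offset by one IPI, but
these lie well outside the tolerance and do not flip verdicts at this
geometry (the two sides differ by ~9 ms of TDOA).

## Features

IPI indexing: interval *i* (1-based) is led by pulse *i*; "pulses 11–20"
selects the ten intervals with leading indices 11–20, and the mirrored
block the leading indices *n*−20…*n*−11. Trains of 12–20 pulses average
the available subset and are flagged truncated; below 12 the block
averages are undefined while duration and PRR (pulse count / duration, so
PRR × duration = count exactly) are still reported. The three
representative pulses are (3, ⌈n/2⌉, n−2), taking the earlier pulse as the
middle at even counts.

Pulse spectra: 256-sample Hamming frames at 50 % overlap tiling the 1.5 ms
window around a peak; power-averaged, 5-point moving-average smoothed,
in dB re the 6–170 kHz band maximum. At 500 kHz this is 1953 Hz × 0.512 ms
resolution. Spectral parameters are read in 11–170 kHz (above the common
6 kHz peak): peak = first maximal bin; the 10 dB edges are found by
scanning outward from the peak while the level stays within 10 dB — the
contiguous supra-cut region, so a disjoint distant lobe does not stretch
the bandwidth. A flat spectrum is flagged degenerate.

Call typing is a fixed rule over measured descriptors (two concurrent
non-overlapping components → C1; broadband pulsed ≥ 150 ms → PS1; tonal
< 150 ms → S; tonal ≥ 150 ms → W; else O), with a spectral-peak-energy
tonality score (threshold 0.6) standing in for aural judgement.

## Statistics

Sample SDs use the n−1 denominator throughout. Kruskal–Wallis (tie
corrected) serves the temporal parameters, one-way ANOVA the spectral
ones. VIF screening removes the largest-VIF feature iteratively until all
fall below 20. Before QDA, features constant within any class are dropped:
a 10 dB band edge pinned at the analysis-band limit for a wideband caller
makes that class's covariance singular, and on the default pack this step
leaves exactly the five features the screening narrative expects (the two
IPI averages, duration, PRR, peak frequency). Robust outliers are flagged
(never dropped) by MCD Mahalanobis distances against the χ² 0.975
quantile; on the synthetic pack, as in mixed-caller data generally, a
large fraction of a distinctive caller's calls is flagged — the flags are
diagnostics, not a filter. Box's M (chi-square approximation) tests
covariance homogeneity; multivariate normality uses Mardia's skewness and
kurtosis on class-centred residuals (the assumption QDA actually makes).
Class balancing subsamples classes above a cap (default: the second-largest
class size) without replacement, deterministically per seed.

QDA is authored in-package: per-class mean and covariance (n−1), classify
by maximal prior-weighted Gaussian log-density; priors default to class
proportions ("equal sample size" priors), with uniform or explicit priors
available. LOOCV refits every fold; scikit-learn's per-fold QDA serves as
an independent oracle in the tests, never as the implementation. Stepwise
ranking is forward selection on LOOCV correctness with a 0.05 minimum
improvement (the first feature is always accepted; candidates singular in
any fold are skipped).

Reported tables round CVs and PIC to 2 decimals and rates to 1 decimal.
Integer category shares round half-up by default, which keeps shares
summing to 100 within k/2 points; a truncation mode reproduces the
published formatting of the worked example (38 % from 2633/6817).

## Problem sizes and determinism

Validation runs use 30 calls per caller at 20 dB SNR for the feature/PIC/
DFA properties (150 calls; LOOCV ≈ 93 % against a ≈20 % permutation null),
two to four 25-call sessions for attribution (≥ 95 % correct verdicts, no
wrong-side assignments), and 12–15 calls per session for the end-to-end
pipeline runs. All randomness flows through `numpy.random.SeedSequence`
from a single seed; identical configurations produce byte-identical report
bundles, and the acceptance script derives every stream from its `--seed`.

## What the synthetic validation does not show

The generator's callers are stationary point sources with fixed spectra;
real calls vary with the caller's orientation (burst pulses are
directional), the pool adds multipath beyond the single optional echo, and
the profile pack's parameter values are plausible fixtures, not estimates
of any real animal. Passing tests therefore demonstrate that the
measurement chain recovers known structure under the stated noise model —
not that real beluga calls are this separable; classification rates on
real recordings should be expected to fall below the synthetic pack's,
because directivity and propagation add within-caller variance the
generator does not model.
Calls shorter than 150 ms are typed S/O and leave the PS1 analysis, and
callers are only separable by TDOA when isolated on the far side of the
array — both mirror the study design rather than limitations of the code.
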