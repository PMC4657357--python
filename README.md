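# callid

Individuality analysis of odontocete pulsed contact calls.

Captive belugas separated from their group produce a stereotyped broadband
pulsed contact call (here called the *PS1* type). The biological question is
whether these calls carry caller identity — the pulsed analogue of the
bottlenose dolphin's signature whistle. `callid` implements the complete
measurement and analysis chain for that question on a two-hydrophone array,
together with a ground-truthed synthetic data generator, so every stage is
testable end to end without access to any recordings:

1. **Synthesis** (`callid.synth`) — parametric caller profiles (piecewise
   IPI-contour templates, per-pulse spectral envelopes, an optional ~13 kHz
   tonal component, source levels) rendered into two-channel 500 kHz
   sessions with straight-path delays, 1/r spreading and configurable noise.
2. **Detection** (`callid.detect`) — band-limited (6–170 kHz) envelope
   detection of call onsets and pulse peaks, with deterministic echo
   rejection and low-amplitude recovery rules, and inter-pulse-interval
   (IPI) extraction.
3. **Attribution** (`callid.tdoa`) — signed time-difference-of-arrival
   between the two channels assigns each call to the isolated animal's side
   or the group's side; borderline or mixed-source calls are counted but
   excluded as ambiguous.
4. **Features** (`callid.features`) — the nine per-call descriptors: average
   IPI of intervals led by pulses 11–20, the mirrored average over the last
   such block, duration, pulse count, pulse repetition rate (PRR), and — from
   256-point Hamming spectra of the middle pulse — peak frequency, the 10 dB
   bandwidth and its lower/upper edges. Plus a rule-based call-type
   categorizer (PS1 / C1 / S / W / O).
5. **Statistics** (`callid.stats`) — the potential-for-individual-coding
   statistic,

   ```
   CVb  = 100 · SD/mean                     (all calls pooled)
   CVw  = 100 · (SD/mean) · (1 + 1/(4n))    (per individual, small-n corrected)
   PIC  = CVb / mean(CVw)
   ```

   with PIC > 1 marking a candidate identity cue; Kruskal–Wallis and one-way
   ANOVA group tests; VIF multicollinearity screening; robust-Mahalanobis
   (MCD) outlier flagging; Box's M and Mardia diagnostics; random class-size
   balancing; quadratic discriminant analysis scored by jack-knife
   leave-one-out cross-validation; and forward stepwise feature ranking.
6. **Pipeline** (`callid.pipeline`, CLI `callid`) — orchestrates one
   simulated isolation session per caller, analyzes them, and emits the
   report bundle (feature CSV, assignment CSV, PIC table, DFA/screening
   JSON, summary JSON).

## Worked example

```python
import numpy as np
from callid import (default_profiles, render_call, add_noise,
                    estimate_noise_level, detect_pulses, extract_ipis,
                    temporal_features, select_pulse_locations,
                    pulse_spectrum, spectral_features)

fs = 500e3
prof = default_profiles()["H"]                   # the adult male
wave, truth = render_call(prof, fs, rng_seed=4)
x = np.concatenate([np.zeros(int(0.45 * fs)), wave])
x = add_noise(x, fs, snr_db=20.0, rng_seed=1)

noise = estimate_noise_level(x, fs, (0.0, 0.4))
train = detect_pulses(x, fs, (0.445, len(x) / fs), noise)
tf = temporal_features(extract_ipis(train), train)
_, mid, _ = select_pulse_locations(train.n_pulses)
sf = spectral_features(pulse_spectrum(x, train.peak_times[mid - 1], fs))

print(f"pulses {train.n_pulses} (true {truth.n_pulses})")
print(f"avg IPI 11-20      {tf.avg_ipi_11_20_ms:.2f} ms")
print(f"avg IPI last block {tf.avg_ipi_11_20_last_ms:.2f} ms")
print(f"duration {tf.duration_s:.3f} s, PRR {tf.prr_pps:.1f} pulses/s")
print(f"peak frequency {sf.peak_freq_hz/1e3:.1f} kHz")
```

prints

```
pulses 113 (true 113)
avg IPI 11-20      2.65 ms
avg IPI last block 7.69 ms
duration 0.560 s, PRR 201.9 pulses/s
peak frequency 113.3 kHz
```

— the detector recovered every pulse; the early-contour IPI average (~2.7 ms)
is far below the late average (~7.7 ms), the rising contour this caller's
profile encodes, and the spectral peak lands within one 1953 Hz bin of the
profile's 113 kHz setting.

The full pipeline on five simulated isolation sessions:

```bash
callid full --out out --seed 21 --n-calls 15
# wrote report bundle to out
# overall leave-one-out correct classification: 73.3 %
```

`out/summary.json` then holds the per-type call counts, attribution
accounting, PIC table location and the stepwise ranking (the initial-block
IPI average ranks first, as expected from the contour construction).

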