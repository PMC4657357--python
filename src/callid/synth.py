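"""Ground-truthed synthesis of pulse-train contact calls and array sessions.

Every downstream stage of the package (pulse detection, TDOA attribution,
feature extraction, individuality statistics) is validated against synthetic
recordings produced here, because the study system — belugas producing
stereotyped broadband pulsed contact calls ("PS1"-type calls) in an isolation
pool monitored by two hydrophones — has no public recordings.

A caller is described by an :class:`IndividualProfile`: a piecewise-linear
inter-pulse-interval (IPI) contour template with jitter terms, a Gaussian
spectral envelope for the individual pulses, a common low-frequency energy
peak near 6 kHz, an optional narrowband tonal component (observed around
13 kHz in the adult male), and a source level.  :func:`default_profiles`
provides a five-animal pack (one adult male ``H``, two adult females ``T``
and ``G``, one sub-adult female ``N``, one calf ``M``) whose parameters are
fixtures emulating the published group, not claims about any real animal.

Sessions place callers in 3-D around a two-hydrophone pair (default 7.5 m
apart at 1 m depth, 500 kHz sampling) and model straight-path delay and
spherical (1/r) spreading only.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import yaml
from scipy.io import wavfile
from scipy.signal import butter, hilbert, sosfilt, sosfiltfilt
from scipy.signal.windows import tukey

__all__ = [
    "IndividualProfile",
    "SessionScene",
    "CallTruth",
    "CallRecord",
    "SessionTruth",
    "ipi_contour_template",
    "design_pulse",
    "render_call",
    "add_noise",
    "render_session",
    "default_profiles",
    "default_scene",
    "write_wav",
    "read_wav",
]

#: lower edge of the recording chain's useful band (analog high-pass), Hz
_MIN_FREQ_HZ = 1000.0
#: hard floor for any synthesized IPI, ms
_MIN_IPI_MS = 0.1


@dataclass
class IndividualProfile:
    """Parametric template of one caller.

    The IPI contour template is piecewise linear in interval index ``i``
    (1-based; interval ``i`` spans pulse ``i`` to pulse ``i+1``): it holds
    ``initial_ipi_ms`` through interval ``transition_onset - 1``, then ramps
    at ``slope_ms_per_pulse`` per interval until it reaches
    ``terminal_ipi_ms``, where it saturates.

    Per-call variability has three components: a call-level offset of the
    whole template (``ipi_call_sd``, between-call within-individual), an
    independent per-interval jitter (``ipi_jitter_sd``), and an optional
    bounded random walk (``ipi_walk_sd``) used for callers with no
    stereotyped repetition pattern (the calf profile).

    Spectrally, a pulse has a Gaussian magnitude envelope centred at
    ``spectral_peak`` (per-call jittered by ``spectral_peak_call_sd``)
    riding on a broad pedestal of width ``spectral_bw`` (10 dB bandwidth
    ~1.55 × that width), plus a common low-band energy peak
    at ``low_band_peak``.  ``tonal_freq``, if set, adds a continuous
    narrowband component spanning the call.
    """

    label: str
    initial_ipi_ms: float = 5.0
    plateau_pulses: int = 20
    transition_onset: int = 25
    slope_ms_per_pulse: float = 0.05
    terminal_ipi_ms: float = 7.5
    ipi_jitter_sd: float = 0.0
    ipi_call_sd: float = 0.0
    ipi_level_min_ms: float | None = None
    ipi_level_max_ms: float | None = None
    ipi_walk_sd: float = 0.0
    n_pulses_mean: float = 100.0
    n_pulses_sd: float = 0.0
    n_pulses_min: int = 2
    n_pulses_max: int | None = None
    spectral_peak: float = 110e3
    spectral_bw: float = 30e3
    spectral_peak_call_sd: float = 0.0
    low_band_peak: float = 6e3
    low_band_level_db: float = -8.0
    low_band_bw: float = 2e3
    tonal_freq: float | None = None
    tonal_level_db: float = -44.0
    source_level_db: float = 0.0
    amp_jitter_db: float = 0.5

    def validate(self) -> None:
        if self.initial_ipi_ms <= 0 or self.terminal_ipi_ms <= 0:
            raise ValueError("initial and terminal IPIs must be positive")
        if self.n_pulses_mean < 2:
            raise ValueError("n_pulses_mean must be at least 2")
        if not (6e3 < self.spectral_peak <= 170e3):
            raise ValueError("spectral_peak must lie in (6 kHz, 170 kHz]")
        if min(self.ipi_jitter_sd, self.ipi_call_sd, self.ipi_walk_sd) < 0:
            raise ValueError("jitter scales must be non-negative")

    def template(self, n_pulses: int) -> np.ndarray:
        """Deterministic IPI template (ms) for a call of ``n_pulses`` pulses."""
        if n_pulses < 2:
            raise ValueError("a pulse train needs at least 2 pulses")
        idx = np.arange(1, n_pulses)  # 1-based interval index
        ramp = self.slope_ms_per_pulse * np.maximum(
            idx - self.transition_onset + 1, 0
        )
        ipis = self.initial_ipi_ms + ramp
        lo = min(self.initial_ipi_ms, self.terminal_ipi_ms)
        hi = max(self.initial_ipi_ms, self.terminal_ipi_ms)
        return np.clip(ipis, lo, hi)


def ipi_contour_template(
    profile: IndividualProfile, n_pulses: int, rng_seed=None
) -> np.ndarray:
    """Draw one IPI contour (ms, length ``n_pulses - 1``) from a profile.

    With all jitter scales zero the output is the deterministic piecewise
    template.  Jitter is additive Gaussian; the optional random walk is
    reflected into a ±40 % band around the template so a non-stereotyped
    contour still wanders near its nominal level.  All IPIs are floored at
    0.1 ms.
    """
    profile.validate()
    if n_pulses < 2:
        raise ValueError("a pulse train needs at least 2 pulses")
    rng = np.random.default_rng(rng_seed)
    ipis = profile.template(n_pulses).astype(float)
    if profile.ipi_call_sd > 0:
        offset = rng.normal(0.0, profile.ipi_call_sd)
        # keep the call's template level inside the caller's observed range
        lo = profile.ipi_level_min_ms
        hi = profile.ipi_level_max_ms
        if lo is not None:
            offset = max(offset, lo - profile.initial_ipi_ms)
        if hi is not None:
            offset = min(offset, hi - profile.initial_ipi_ms)
        ipis = ipis + offset
    if profile.ipi_walk_sd > 0:
        steps = rng.normal(0.0, profile.ipi_walk_sd, size=ipis.size)
        walk = np.cumsum(steps)
        bound = 0.4 * ipis
        # reflect the walk into [-bound, bound]
        walk = np.abs((walk + bound) % (4 * bound) - 2 * bound) - bound
        ipis = ipis + walk
    if profile.ipi_jitter_sd > 0:
        ipis = ipis + rng.normal(0.0, profile.ipi_jitter_sd, size=ipis.size)
    return np.maximum(ipis, _MIN_IPI_MS)


def design_pulse(
    fs: float,
    peak_hz: float,
    sigma_hz: float,
    low_band_hz: float = 6e3,
    low_band_level_db: float = -8.0,
    low_band_sigma_hz: float = 2e3,
    sharp_sigma_hz: float = 4e3,
    pedestal_level_db: float = -2.5,
    n: int = 256,
) -> np.ndarray:
    """Band-limited transient with a prescribed magnitude spectrum.

    The magnitude envelope is a *sharp* Gaussian (width ``sharp_sigma_hz``)
    at ``peak_hz`` riding on a *broad* Gaussian pedestal (width
    ``sigma_hz``, ``pedestal_level_db`` below the sharp component): real
    burst-pulse spectra combine a well-defined peak frequency with a 10 dB
    bandwidth of tens of kilohertz, which a single Gaussian cannot do —
    it would be too flat near its maximum for the peak to be measurable.
    With the default pedestal level the 10 dB bandwidth is ~1.55 ×
    ``sigma_hz``.

    The pulse is designed in the frequency domain (zero phase), so its
    envelope peaks exactly at the centre sample ``n // 2``.  Content below
    1 kHz is removed to mimic the analog high-pass of a recording chain; a
    Tukey window tapers the residual ringing.  Peak amplitude is
    normalized to 1.
    """
    if fs < 2 * (peak_hz + sigma_hz):
        raise ValueError(
            f"fs={fs:g} violates Nyquist for peak {peak_hz:g} + bw {sigma_hz:g}"
        )
    f = np.fft.rfftfreq(n, 1.0 / fs)
    mag = np.exp(-0.5 * ((f - peak_hz) / sharp_sigma_hz) ** 2)
    mag = mag + 10 ** (pedestal_level_db / 20.0) * np.exp(
        -0.5 * ((f - peak_hz) / sigma_hz) ** 2
    )
    mag = mag + 10 ** (low_band_level_db / 20.0) * np.exp(
        -0.5 * ((f - low_band_hz) / low_band_sigma_hz) ** 2
    )
    mag[f < _MIN_FREQ_HZ] = 0.0
    pulse = np.fft.fftshift(np.fft.irfft(mag, n))
    pulse *= tukey(n, 0.5)
    peak = np.abs(pulse).max()
    if peak > 0:
        pulse /= peak
    return pulse


@dataclass
class CallTruth:
    """Ground truth for one rendered single-channel call."""

    label: str
    fs: float
    peak_indices: np.ndarray  # exact sample index of each pulse peak
    peak_times_s: np.ndarray
    peak_amplitudes: np.ndarray
    ipis_ms: np.ndarray  # quantized to the sample grid, matches peak times
    ipis_drawn_ms: np.ndarray  # pre-quantization draw from the template
    n_pulses: int
    peak_hz: float


def render_call(
    profile: IndividualProfile,
    fs: float,
    rng_seed=None,
    n_pulses: int | None = None,
    pad_s: float = 0.005,
    echo: tuple[float, float] | None = None,
) -> tuple[np.ndarray, CallTruth]:
    """Render one call as a single-channel waveform plus per-pulse truth.

    Pulse centres are placed on the sample grid (cumulative template times
    rounded to the nearest sample), and the returned truth lists the exact
    peak sample indices, so detector accuracy can be scored to the sample.

    Parameters
    ----------
    echo
        Optional ``(delay_s, gain)`` single surface reflection: a scaled
        copy of the pulse train added at a fixed lag, used to exercise the
        detector's reflection rejection.
    """
    profile.validate()
    rng = np.random.default_rng(rng_seed)
    if fs < 2 * (profile.spectral_peak + profile.spectral_bw):
        raise ValueError("sampling rate violates Nyquist for this profile")
    if n_pulses is None:
        n_pulses = int(round(rng.normal(profile.n_pulses_mean, profile.n_pulses_sd)))
        n_pulses = max(n_pulses, profile.n_pulses_min, 2)
        if profile.n_pulses_max is not None:
            n_pulses = min(n_pulses, profile.n_pulses_max)
    ipis = ipi_contour_template(profile, n_pulses, rng)

    peak_hz = profile.spectral_peak
    if profile.spectral_peak_call_sd > 0:
        peak_hz = float(
            np.clip(
                rng.normal(peak_hz, profile.spectral_peak_call_sd),
                12e3,
                min(168e3, fs / 2 - profile.spectral_bw),
            )
        )
    pulse = design_pulse(
        fs,
        peak_hz,
        profile.spectral_bw,
        low_band_hz=profile.low_band_peak,
        low_band_level_db=profile.low_band_level_db,
        low_band_sigma_hz=profile.low_band_bw,
    )
    half = pulse.size // 2

    pad = int(round(pad_s * fs))
    times_s = np.concatenate([[0.0], np.cumsum(ipis) / 1e3])
    peak_indices = pad + np.round(times_s * fs).astype(np.int64)
    n_samples = int(peak_indices[-1] + pad + half + 1)
    wave = np.zeros(n_samples)

    if np.isneginf(profile.source_level_db):
        amps = np.zeros(n_pulses)
    else:
        level = 10 ** (profile.source_level_db / 20.0)
        db_jit = rng.normal(0.0, profile.amp_jitter_db, size=n_pulses)
        amps = level * 10 ** (db_jit / 20.0)

    for idx, amp in zip(peak_indices, amps):
        lo, hi = idx - half, idx - half + pulse.size
        wave[lo:hi] += amp * pulse

    if echo is not None and not np.isneginf(profile.source_level_db):
        delay_s, gain = echo
        lag = int(round(delay_s * fs))
        for idx, amp in zip(peak_indices, amps):
            lo, hi = idx + lag - half, idx + lag - half + pulse.size
            if hi <= n_samples:
                wave[lo:hi] += gain * amp * pulse

    if profile.tonal_freq is not None and not np.isneginf(profile.source_level_db):
        a = 10 ** ((profile.source_level_db + profile.tonal_level_db) / 20.0)
        lo = max(peak_indices[0] - pad // 2, 0)
        hi = min(peak_indices[-1] + pad // 2, n_samples)
        t = np.arange(lo, hi) / fs
        seg = a * np.sin(2 * np.pi * profile.tonal_freq * t)
        ramp = min(int(0.005 * fs), seg.size // 4)
        if ramp > 0:
            env = np.ones(seg.size)
            env[:ramp] = 0.5 * (1 - np.cos(np.pi * np.arange(ramp) / ramp))
            env[-ramp:] = env[:ramp][::-1]
            seg *= env
        wave[lo:hi] += seg

    peak_times = peak_indices / fs
    truth = CallTruth(
        label=profile.label,
        fs=fs,
        peak_indices=peak_indices,
        peak_times_s=peak_times,
        peak_amplitudes=amps,
        ipis_ms=np.diff(peak_times) * 1e3,
        ipis_drawn_ms=ipis,
        n_pulses=n_pulses,
        peak_hz=peak_hz,
    )
    return wave, truth


def _inband_peak(wave: np.ndarray, fs: float, band=(6e3, 170e3)) -> float:
    """Peak of the band-limited analytic envelope (signal level for SNR)."""
    x = np.asarray(wave, dtype=np.float64)
    if not np.any(x):
        return 0.0
    hi = min(band[1], 0.98 * fs / 2)
    sos = butter(4, (band[0], hi), btype="band", fs=fs, output="sos")
    return float(np.abs(hilbert(sosfiltfilt(sos, x))).max())


def add_noise(
    wave: np.ndarray,
    fs: float,
    snr_db: float,
    rng_seed=None,
    low_boost_db: float = 10.0,
    low_cut_hz: float = 5e3,
) -> np.ndarray:
    """Add broadband Gaussian noise with an elevated low-frequency floor.

    ``snr_db`` is the ratio of the waveform's in-band (6–170 kHz) envelope
    peak — the signal level an analyst reads off a detector display — to
    the white component's RMS.  A low-pass filtered component raises the
    *spectral* floor below ``low_cut_hz`` by ``low_boost_db`` (its RMS is
    scaled by the band-fraction ``sqrt(low_cut / (fs/2))`` so the boost is
    per unit bandwidth), emulating the persistent low-frequency pool noise
    that motivates restricting spectral analysis to frequencies above
    ~6 kHz.
    """
    rng = np.random.default_rng(rng_seed)
    peak = _inband_peak(wave, fs)
    sigma = peak / 10 ** (snr_db / 20.0) if peak > 0 else 10 ** (-snr_db / 20.0)
    noise = rng.normal(0.0, sigma, size=wave.shape)
    sos = butter(4, low_cut_hz, btype="low", fs=fs, output="sos")
    low = sosfilt(sos, rng.normal(0.0, 1.0, size=wave.shape), axis=0)
    rms = np.sqrt(np.mean(low**2))
    if rms > 0:
        target = sigma * 10 ** (low_boost_db / 20.0) * np.sqrt(low_cut_hz / (fs / 2))
        low *= target / rms
    return wave + noise + low


# ---------------------------------------------------------------------------
# sessions


@dataclass
class SessionScene:
    """Geometry, schedule and noise configuration for one recording session.

    ``profiles`` maps caller labels to profiles; ``positions`` gives each
    caller's fixed 3-D position (m).  Exactly two hydrophones are supported
    (default: 7.5 m apart at 1 m depth).  ``snr_db`` sets the white-noise
    floor relative to the mean received pulse peak across scheduled calls.
    """

    profiles: dict[str, IndividualProfile]
    positions: dict[str, tuple[float, float, float]]
    call_schedule: list[tuple[str, float]]
    duration_s: float
    seed: int
    hydrophones: tuple[tuple[float, float, float], tuple[float, float, float]] = (
        (-3.75, 0.0, -1.0),
        (3.75, 0.0, -1.0),
    )
    sound_speed: float = 1500.0
    fs: float = 500e3
    snr_db: float = 20.0
    noise_low_boost_db: float = 10.0

    def validate(self) -> None:
        if len(self.hydrophones) != 2:
            raise ValueError("exactly two hydrophones are required")
        fmax = max(
            p.spectral_peak + p.spectral_bw for p in self.profiles.values()
        )
        if self.fs < 2 * fmax:
            raise ValueError("fs violates Nyquist for the loudest profile")
        for label, onset in self.call_schedule:
            if label not in self.profiles:
                raise ValueError(f"scheduled caller {label!r} has no profile")
            if label not in self.positions:
                raise ValueError(f"scheduled caller {label!r} has no position")
            if not (0 <= onset < self.duration_s):
                raise ValueError("call onsets must lie within [0, duration)")

    @property
    def spacing(self) -> float:
        h1, h2 = (np.asarray(h, float) for h in self.hydrophones)
        return float(np.linalg.norm(h1 - h2))

    @property
    def tdoa_bound_s(self) -> float:
        """Geometric bound |TDOA| <= hydrophone spacing / sound speed."""
        return self.spacing / self.sound_speed

    def true_tdoa(self, label: str) -> float:
        """Signed TDOA (s) for a caller; positive = arrives at channel 1 first."""
        src = np.asarray(self.positions[label], float)
        r1 = float(np.linalg.norm(src - np.asarray(self.hydrophones[0], float)))
        r2 = float(np.linalg.norm(src - np.asarray(self.hydrophones[1], float)))
        return (r2 - r1) / self.sound_speed

    def to_yaml(self, path) -> None:
        d = {
            "profiles": {k: asdict(p) for k, p in self.profiles.items()},
            "positions": {k: list(v) for k, v in self.positions.items()},
            "call_schedule": [[l, float(t)] for l, t in self.call_schedule],
            "duration_s": self.duration_s,
            "seed": self.seed,
            "hydrophones": [list(h) for h in self.hydrophones],
            "sound_speed": self.sound_speed,
            "fs": self.fs,
            "snr_db": self.snr_db,
            "noise_low_boost_db": self.noise_low_boost_db,
        }
        Path(path).write_text(yaml.safe_dump(d, sort_keys=True))

    @classmethod
    def from_yaml(cls, path) -> "SessionScene":
        d = yaml.safe_load(Path(path).read_text())
        profiles = {
            k: IndividualProfile(**v) for k, v in d["profiles"].items()
        }
        return cls(
            profiles=profiles,
            positions={k: tuple(v) for k, v in d["positions"].items()},
            call_schedule=[(l, float(t)) for l, t in d["call_schedule"]],
            duration_s=float(d["duration_s"]),
            seed=int(d["seed"]),
            hydrophones=tuple(tuple(h) for h in d["hydrophones"]),
            sound_speed=float(d["sound_speed"]),
            fs=float(d["fs"]),
            snr_db=float(d["snr_db"]),
            noise_low_boost_db=float(d.get("noise_low_boost_db", 10.0)),
        )


@dataclass
class CallRecord:
    """Per-call ground truth inside a session."""

    call_id: str
    label: str
    onset_s: float
    tdoa_s: float  # exact geometric value; positive = channel 1 first
    peak_times_ch1: np.ndarray
    peak_times_ch2: np.ndarray
    ipis_ms: np.ndarray
    n_pulses: int
    peak_hz: float
    overlap: bool
    position: tuple[float, float, float]


@dataclass
class SessionTruth:
    fs: float
    sound_speed: float
    hydrophones: tuple
    calls: list[CallRecord] = field(default_factory=list)

    def to_json(self, path) -> None:
        d = {
            "fs": self.fs,
            "sound_speed": self.sound_speed,
            "hydrophones": [list(h) for h in self.hydrophones],
            "calls": [
                {
                    "call_id": c.call_id,
                    "label": c.label,
                    "onset_s": c.onset_s,
                    "tdoa_s": c.tdoa_s,
                    "peak_times_ch1": c.peak_times_ch1.tolist(),
                    "peak_times_ch2": c.peak_times_ch2.tolist(),
                    "ipis_ms": c.ipis_ms.tolist(),
                    "n_pulses": c.n_pulses,
                    "peak_hz": c.peak_hz,
                    "overlap": c.overlap,
                    "position": list(c.position),
                }
                for c in self.calls
            ],
        }
        Path(path).write_text(json.dumps(d, sort_keys=True, indent=1))

    @classmethod
    def from_json(cls, path) -> "SessionTruth":
        d = json.loads(Path(path).read_text())
        calls = [
            CallRecord(
                call_id=c["call_id"],
                label=c["label"],
                onset_s=c["onset_s"],
                tdoa_s=c["tdoa_s"],
                peak_times_ch1=np.asarray(c["peak_times_ch1"]),
                peak_times_ch2=np.asarray(c["peak_times_ch2"]),
                ipis_ms=np.asarray(c["ipis_ms"]),
                n_pulses=c["n_pulses"],
                peak_hz=c["peak_hz"],
                overlap=c["overlap"],
                position=tuple(c["position"]),
            )
            for c in d["calls"]
        ]
        return cls(
            fs=d["fs"],
            sound_speed=d["sound_speed"],
            hydrophones=tuple(tuple(h) for h in d["hydrophones"]),
            calls=calls,
        )


def render_session(scene: SessionScene) -> tuple[np.ndarray, SessionTruth]:
    """Render a full two-channel session.

    Each scheduled call is rendered once and inserted on both channels with
    straight-path delay (distance / sound speed) and 1/r spreading loss.
    The recorded truth carries the exact geometric TDOA and the per-channel
    pulse-peak times as placed on the sample grid.  Identical scenes
    (including the seed) yield bit-identical audio and truth.
    """
    scene.validate()
    fs = scene.fs
    n = int(round(scene.duration_s * fs))
    audio = np.zeros((n, 2), dtype=np.float64)
    hyd = [np.asarray(h, float) for h in scene.hydrophones]

    root = np.random.SeedSequence(scene.seed)
    call_seeds = root.spawn(len(scene.call_schedule) + 1)
    truth = SessionTruth(
        fs=fs, sound_speed=scene.sound_speed, hydrophones=scene.hydrophones
    )
    received_peaks = []
    intervals = []
    for k, (label, onset) in enumerate(scene.call_schedule):
        profile = scene.profiles[label]
        wave, call_truth = render_call(profile, fs, rng_seed=call_seeds[k])
        src = np.asarray(scene.positions[label], float)
        dists = [float(np.linalg.norm(src - h)) for h in hyd]
        peak_times = []
        for ch, r in enumerate(dists):
            if r <= 0:
                raise ValueError("source coincides with a hydrophone")
            gain = 1.0 / r
            i0 = int(round((onset + r / scene.sound_speed) * fs))
            start = i0 - int(call_truth.peak_indices[0])
            lo, hi = max(start, 0), min(start + wave.size, n)
            if hi <= lo:
                raise ValueError("scheduled call falls outside the session")
            audio[lo:hi, ch] += gain * wave[lo - start : hi - start]
            peak_times.append((start + call_truth.peak_indices) / fs)
        received_peaks.append(_inband_peak(wave, fs) / max(dists))
        tdoa_s = (dists[1] - dists[0]) / scene.sound_speed
        span = (
            onset + call_truth.peak_times_s[0] - 0.01,
            onset + call_truth.peak_times_s[-1] + 0.01,
        )
        overlap = any(span[0] < b and a < span[1] for a, b in intervals)
        if overlap:  # mark the earlier partner too
            for rec, (a, b) in zip(truth.calls, intervals):
                if span[0] < b and a < span[1]:
                    rec.overlap = True
        intervals.append(span)
        truth.calls.append(
            CallRecord(
                call_id=f"call{k:04d}",
                label=label,
                onset_s=onset,
                tdoa_s=tdoa_s,
                peak_times_ch1=peak_times[0],
                peak_times_ch2=peak_times[1],
                ipis_ms=call_truth.ipis_ms,
                n_pulses=call_truth.n_pulses,
                peak_hz=call_truth.peak_hz,
                overlap=overlap,
                position=tuple(scene.positions[label]),
            )
        )

    noise_rng = np.random.default_rng(call_seeds[-1])
    ref = float(np.mean(received_peaks)) if received_peaks else 1.0
    sigma = ref / 10 ** (scene.snr_db / 20.0)
    audio += noise_rng.normal(0.0, sigma, size=audio.shape)
    sos = butter(4, 5e3, btype="low", fs=fs, output="sos")
    low = sosfilt(sos, noise_rng.normal(0.0, 1.0, size=audio.shape), axis=0)
    rms = np.sqrt(np.mean(low**2))
    target = sigma * 10 ** (scene.noise_low_boost_db / 20.0) * np.sqrt(5e3 / (fs / 2))
    audio += low * (target / rms)
    return audio, truth


# ---------------------------------------------------------------------------
# default profile pack and scene


def default_profiles() -> dict[str, IndividualProfile]:
    """Five-caller pack emulating the published group.

    Template levels (initial / terminal IPI), pulse counts and per-call
    spreads follow the published temporal summary table; per-pulse spectral
    peaks follow the middle-pulse column of the spectral table.  The adult
    male ``H`` carries the ~13 kHz tonal component; the calf ``M`` has no
    stereotyped contour (high jitter plus a bounded random walk).  These
    defaults are simulation fixtures, not measurements.
    """
    return {
        "H": IndividualProfile(
            label="H",
            initial_ipi_ms=2.92,
            plateau_pulses=25,
            transition_onset=30,
            slope_ms_per_pulse=0.08,
            terminal_ipi_ms=7.76,
            ipi_jitter_sd=0.3,
            ipi_call_sd=1.25,
            ipi_level_min_ms=2.05,
            ipi_level_max_ms=6.96,
            n_pulses_mean=144.2,
            n_pulses_sd=48.4,
            n_pulses_min=64,
            n_pulses_max=234,
            spectral_peak=113e3,
            spectral_bw=81e3,
            spectral_peak_call_sd=8e3,
            tonal_freq=13e3,
        ),
        "T": IndividualProfile(
            label="T",
            initial_ipi_ms=5.69,
            plateau_pulses=25,
            transition_onset=30,
            slope_ms_per_pulse=0.05,
            terminal_ipi_ms=7.12,
            ipi_jitter_sd=0.3,
            ipi_call_sd=1.5,
            ipi_level_min_ms=4.48,
            ipi_level_max_ms=10.0,
            n_pulses_mean=83.5,
            n_pulses_sd=31.9,
            n_pulses_min=19,
            n_pulses_max=154,
            spectral_peak=29e3,
            spectral_bw=72e3,
            spectral_peak_call_sd=8e3,
        ),
        "G": IndividualProfile(
            label="G",
            initial_ipi_ms=5.67,
            plateau_pulses=20,
            transition_onset=25,
            slope_ms_per_pulse=0.09,
            terminal_ipi_ms=7.91,
            ipi_jitter_sd=0.3,
            ipi_call_sd=0.35,
            ipi_level_min_ms=4.92,
            ipi_level_max_ms=6.4,
            n_pulses_mean=100.5,
            n_pulses_sd=23.0,
            n_pulses_min=46,
            n_pulses_max=145,
            spectral_peak=117e3,
            spectral_bw=45e3,
            spectral_peak_call_sd=8e3,
        ),
        "N": IndividualProfile(
            label="N",
            initial_ipi_ms=5.96,
            plateau_pulses=18,
            transition_onset=21,
            slope_ms_per_pulse=0.08,
            terminal_ipi_ms=7.60,
            ipi_jitter_sd=0.3,
            ipi_call_sd=0.22,
            ipi_level_min_ms=5.48,
            ipi_level_max_ms=6.53,
            n_pulses_mean=82.6,
            n_pulses_sd=40.3,
            n_pulses_min=32,
            n_pulses_max=144,
            spectral_peak=107e3,
            spectral_bw=53e3,
            spectral_peak_call_sd=8e3,
        ),
        "M": IndividualProfile(
            label="M",
            initial_ipi_ms=6.85,
            plateau_pulses=15,
            transition_onset=20,
            slope_ms_per_pulse=0.05,
            terminal_ipi_ms=8.24,
            ipi_jitter_sd=1.0,
            ipi_call_sd=1.0,
            ipi_level_min_ms=4.96,
            ipi_level_max_ms=10.8,
            ipi_walk_sd=0.5,
            n_pulses_mean=80.2,
            n_pulses_sd=26.0,
            n_pulses_min=43,
            n_pulses_max=180,
            spectral_peak=117e3,
            spectral_bw=41e3,
            spectral_peak_call_sd=8e3,
        ),
    }


#: default caller positions: the isolated animal sits on the channel-1 side
#: of the array (positive TDOA), the rest of the group on the far side.
_DEFAULT_GROUP_POSITIONS = {
    "H": (6.0, 1.5, -2.0),
    "T": (7.0, -1.0, -1.5),
    "G": (6.0, -2.0, -2.0),
    "N": (8.0, 2.0, -1.0),
    "M": (5.5, 0.5, -1.5),
}
_DEFAULT_ISOLATED_POSITION = (-7.0, 2.0, -1.5)


def default_scene(
    seed: int,
    n_calls: int = 25,
    isolated_label: str = "T",
    snr_db: float = 20.0,
    gap_s: float = 0.3,
    start_s: float = 0.5,
    isolated_fraction: float | None = None,
) -> SessionScene:
    """Build a session: one isolated caller, the rest grouped opposite.

    With ``isolated_fraction=None`` calls cycle evenly through the five
    callers; otherwise that fraction of the schedule goes to the isolated
    caller (isolated animals call far more often than the group), spread
    evenly, with the remaining slots cycling through the others.  The
    schedule leaves ``start_s`` of caller-free noise for noise-floor
    estimation and spaces calls by each caller's expected duration plus
    ``gap_s`` (no overlaps by default).
    """
    profiles = default_profiles()
    positions = dict(_DEFAULT_GROUP_POSITIONS)
    positions[isolated_label] = _DEFAULT_ISOLATED_POSITION
    labels = list(profiles)
    others = [l for l in labels if l != isolated_label]
    if isolated_fraction is None:
        order = [labels[k % len(labels)] for k in range(n_calls)]
    else:
        n_iso = int(round(isolated_fraction * n_calls))
        order = []
        j = 0
        for k in range(n_calls):
            iso_due = ((k + 1) * n_iso) // n_calls > (k * n_iso) // n_calls
            if iso_due:
                order.append(isolated_label)
            else:
                order.append(others[j % len(others)])
                j += 1
    schedule = []
    t = start_s
    for label in order:
        p = profiles[label]
        schedule.append((label, t))
        # budget a slot covering the longest plausible call: max pulse count
        # at the slowest template level, plus call-level offset and walk
        n_hi = p.n_pulses_max or (p.n_pulses_mean + 3 * p.n_pulses_sd)
        ipi_hi = max(p.initial_ipi_ms, p.terminal_ipi_ms)
        if p.ipi_walk_sd > 0:
            ipi_hi *= 1.4
        ipi_hi += 3 * p.ipi_call_sd
        t += n_hi * ipi_hi / 1e3 + gap_s
    return SessionScene(
        profiles=profiles,
        positions=positions,
        call_schedule=schedule,
        duration_s=t + 0.5,
        seed=seed,
        snr_db=snr_db,
    )


# ---------------------------------------------------------------------------
# WAV I/O


def write_wav(path, audio: np.ndarray, fs: float, peak_dbfs: float = -6.0) -> float:
    """Write float audio as 16-bit PCM WAV, peak-normalized to ``peak_dbfs``.

    Returns the scale factor applied (useful for mapping levels back).
    """
    audio = np.atleast_2d(np.asarray(audio, dtype=np.float64))
    if audio.shape[0] < audio.shape[1]:
        audio = audio.T
    peak = np.abs(audio).max()
    scale = (10 ** (peak_dbfs / 20.0)) / peak if peak > 0 else 1.0
    pcm = np.round(audio * scale * 32767.0).astype(np.int16)
    wavfile.write(str(path), int(fs), pcm)
    return scale


def read_wav(path) -> tuple[np.ndarray, float]:
    """Read a WAV file to float64 in [-1, 1]; returns (audio, fs)."""
    fs, data = wavfile.read(str(path))
    data = np.asarray(data)
    if data.dtype == np.int16:
        data = data.astype(np.float64) / 32768.0
    elif data.dtype == np.int32:
        data = data.astype(np.float64) / 2147483648.0
    else:
        data = data.astype(np.float64)
    if data.ndim == 1:
        data = data[:, None]
    return data, float(fs)
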