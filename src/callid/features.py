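"""Per-call temporal and spectral descriptors, and call-type categorization.

Nine parameters are measured per pulsed call — five temporal (average IPI of
intervals led by pulses 11–20, the mirrored average over the last such
block, duration, pulse count, pulse repetition rate) and four spectral
(peak frequency, the 10 dB bandwidth, and its lower and upper edges),
measured on short power spectra of individual pulses.

Spectra use 256-point FFTs of Hamming-windowed frames tiling a 1.5 ms
window around a pulse peak (at 500 kHz this gives 1953 Hz frequency and
0.512 ms time resolution), are 5-point smoothed, and are expressed in dB
relative to the band maximum (0 dB at the strongest bin in 6–170 kHz).
Spectral parameters are then read in the 11–170 kHz analysis band, above
the common ~6 kHz energy peak shared by all callers.

IPI indexing convention: interval ``i`` (1-based) is led by pulse ``i``;
"pulses 11–20" therefore selects the ten intervals led by those pulses, and
the mirrored block selects leading pulses ``n−20 … n−11``.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import ceil

import numpy as np
from scipy.signal import find_peaks
from scipy.signal.windows import hamming

from callid.detect import IPIContour, PulseTrain

__all__ = [
    "TemporalFeatures",
    "Spectrum",
    "SpectralFeatures",
    "CallFeatures",
    "temporal_features",
    "pulse_spectrum",
    "select_pulse_locations",
    "spectral_features",
    "categorize_call",
    "tonality_score",
    "FEATURE_COLUMNS",
]

#: canonical order of the nine candidate parameters
FEATURE_COLUMNS = [
    "avg_ipi_11_20_ms",
    "avg_ipi_11_20_last_ms",
    "duration_s",
    "n_pulses",
    "prr_pps",
    "peak_freq_hz",
    "bw10_hz",
    "lower10_hz",
    "upper10_hz",
]


@dataclass
class TemporalFeatures:
    avg_ipi_11_20_ms: float | None
    avg_ipi_11_20_last_ms: float | None
    duration_s: float
    n_pulses: int
    prr_pps: float
    truncated: bool  # averages computed on fewer than 10 intervals


@dataclass
class Spectrum:
    """Relative power spectrum of one pulse (band max = 0 dB)."""

    freqs_hz: np.ndarray
    level_db: np.ndarray
    band_hz: tuple[float, float]
    pulse_location: str  # "third" | "middle" | "third_from_last" | other tag

    @property
    def bin_width_hz(self) -> float:
        return float(self.freqs_hz[1] - self.freqs_hz[0])


@dataclass
class SpectralFeatures:
    peak_freq_hz: float
    bw10_hz: float
    lower10_hz: float
    upper10_hz: float
    degenerate: bool = False


@dataclass
class CallFeatures:
    """The nine-parameter descriptor vector of one call."""

    call_id: str
    individual: str | None
    temporal: TemporalFeatures
    spectral: SpectralFeatures
    low_snr: bool = False

    def as_row(self) -> dict:
        t, s = self.temporal, self.spectral
        return {
            "call_id": self.call_id,
            "individual": self.individual,
            "avg_ipi_11_20_ms": t.avg_ipi_11_20_ms,
            "avg_ipi_11_20_last_ms": t.avg_ipi_11_20_last_ms,
            "duration_s": t.duration_s,
            "n_pulses": t.n_pulses,
            "prr_pps": t.prr_pps,
            "peak_freq_hz": s.peak_freq_hz,
            "bw10_hz": s.bw10_hz,
            "lower10_hz": s.lower10_hz,
            "upper10_hz": s.upper10_hz,
            "truncated": t.truncated,
            "low_snr": self.low_snr,
        }


def temporal_features(contour: IPIContour, train: PulseTrain) -> TemporalFeatures:
    """Five temporal descriptors from a pulse train and its IPI contour.

    Duration runs from the first to the last pulse peak; PRR is the pulse
    count divided by that duration, so ``prr × duration = n_pulses`` holds
    exactly.  For trains of 12–20 pulses the two block averages use the
    available intervals and are flagged truncated; below 12 pulses they are
    undefined (``None``) while duration and PRR are still returned.
    """
    n = train.n_pulses
    if n < 2:
        raise ValueError("temporal features need at least 2 pulses")
    if contour.ipis.size != n - 1:
        raise ValueError("contour length does not match the pulse train")
    duration = float(train.peak_times[-1] - train.peak_times[0])
    if duration <= 0:
        raise ValueError("pulse times must be strictly increasing")
    prr = n / duration

    # 0-based slices: leading pulses 11..20 -> ipis[10:20];
    # leading pulses (n-20)..(n-11) -> ipis[n-21:n-11]
    front = contour.ipis[10 : min(20, n - 1)]
    back = contour.ipis[max(0, n - 21) : n - 11]
    truncated = False
    if n >= 21:
        avg_front = float(front.mean())
        avg_back = float(back.mean())
    elif n >= 12:
        avg_front = float(front.mean())
        avg_back = float(back.mean())
        truncated = True
    else:
        avg_front = avg_back = None
    return TemporalFeatures(
        avg_ipi_11_20_ms=avg_front,
        avg_ipi_11_20_last_ms=avg_back,
        duration_s=duration,
        n_pulses=n,
        prr_pps=prr,
        truncated=truncated,
    )


def pulse_spectrum(
    waveform: np.ndarray,
    peak_time: float,
    fs: float,
    band_hz: tuple[float, float] = (6e3, 170e3),
    nfft: int = 256,
    window_ms: float = 1.5,
    pulse_location: str = "middle",
) -> Spectrum:
    """Relative power spectrum of the 1.5 ms of data containing one pulse.

    Hamming-windowed ``nfft``-sample frames at 50 % overlap tile the
    window; their power spectra are averaged, 5-point moving-average
    smoothed, converted to dB and shifted so the maximum inside ``band_hz``
    is 0 dB.
    """
    waveform = np.asarray(waveform, dtype=np.float64)
    half = int(round(window_ms / 2e3 * fs))
    c = int(round(peak_time * fs))
    i0, i1 = c - half, c + half
    if i0 < 0 or i1 > len(waveform):
        raise ValueError("analysis window exceeds the recording")
    seg = waveform[i0:i1]
    win = hamming(nfft, sym=False)
    hop = nfft // 2
    starts = range(0, len(seg) - nfft + 1, hop)
    if not starts:
        raise ValueError("analysis window shorter than one FFT frame")
    power = np.zeros(nfft // 2 + 1)
    for s in starts:
        spec = np.fft.rfft(seg[s : s + nfft] * win)
        power += np.abs(spec) ** 2
    power /= len(list(starts))
    # 5-point moving average on the power spectrum
    kernel = np.ones(5) / 5.0
    smoothed = np.convolve(power, kernel, mode="same")
    freqs = np.fft.rfftfreq(nfft, 1.0 / fs)
    tiny = np.finfo(float).tiny
    level = 10 * np.log10(np.maximum(smoothed, tiny))
    in_band = (freqs >= band_hz[0]) & (freqs <= band_hz[1])
    if not in_band.any():
        raise ValueError("normalization band contains no FFT bins")
    level -= level[in_band].max()
    return Spectrum(
        freqs_hz=freqs, level_db=level, band_hz=band_hz, pulse_location=pulse_location
    )


def select_pulse_locations(n_pulses: int) -> tuple[int, int, int]:
    """The three representative pulses: third, middle, third from last.

    Returns 1-based indices ``(3, ceil(n/2), n - 2)``; the earlier pulse is
    taken as the middle one for even counts.  Needs at least 5 pulses.
    """
    if n_pulses < 5:
        raise ValueError("pulse-location selection needs at least 5 pulses")
    return 3, ceil(n_pulses / 2), n_pulses - 2


def spectral_features(
    spec: Spectrum, analysis_band_hz: tuple[float, float] = (11e3, 170e3)
) -> SpectralFeatures:
    """Peak frequency and 10 dB bandwidth within the analysis band.

    The peak is the first maximal bin; the 10 dB band edges are found by
    scanning outward from the peak while the level stays within 10 dB of
    it (the contiguous supra−10 dB region around the peak), clipped to the
    analysis band.  A flat spectrum is flagged degenerate with the peak at
    the lowest bin.
    """
    mask = (spec.freqs_hz >= analysis_band_hz[0]) & (
        spec.freqs_hz <= analysis_band_hz[1]
    )
    if not mask.any():
        raise ValueError("spectrum does not cover the analysis band")
    freqs = spec.freqs_hz[mask]
    level = spec.level_db[mask]
    degenerate = bool(np.allclose(level, level[0]))
    k = int(np.argmax(level))  # argmax returns the first maximal bin
    peak_level = level[k]
    cut = peak_level - 10.0
    lo = k
    while lo > 0 and level[lo - 1] >= cut:
        lo -= 1
    hi = k
    while hi < len(level) - 1 and level[hi + 1] >= cut:
        hi += 1
    return SpectralFeatures(
        peak_freq_hz=float(freqs[k]),
        bw10_hz=float(freqs[hi] - freqs[lo]),
        lower10_hz=float(freqs[lo]),
        upper10_hz=float(freqs[hi]),
        degenerate=degenerate,
    )


def tonality_score(waveform: np.ndarray, fs: float, n_peaks: int = 5) -> float:
    """Fraction of spectral energy in the top narrowband peaks.

    A surrogate for aural/visual tonality judgement: the power spectrum is
    lightly smoothed, its ``n_peaks`` largest local maxima are located, and
    the energy within ±2 bins of each is divided by the total.  Tonal calls
    concentrate energy in a few harmonics and score high; broadband pulsed
    calls spread energy and score low.  Scores are in [0, 1].
    """
    waveform = np.asarray(waveform, dtype=np.float64)
    nfft = min(8192, 2 ** int(np.ceil(np.log2(max(len(waveform), 16)))))
    power = np.abs(np.fft.rfft(waveform, nfft)) ** 2
    smoothed = np.convolve(power, np.ones(3) / 3.0, mode="same")
    total = smoothed.sum()
    if total <= 0:
        return 0.0
    peaks, props = find_peaks(smoothed, height=0)
    if len(peaks) == 0:
        return 0.0
    top = peaks[np.argsort(props["peak_heights"])[-n_peaks:]]
    energy = 0.0
    for p in top:
        energy += smoothed[max(p - 2, 0) : p + 3].sum()
    return float(min(energy / total, 1.0))


def categorize_call(
    duration_s: float,
    tonality: float,
    band_coverage: float,
    component_count: int = 1,
    tonality_threshold: float = 0.6,
    long_call_s: float = 0.150,
    broadband_coverage: float = 0.5,
) -> str:
    """Rule-based call typing into {PS1, C1, S, W, O}.

    * two concurrent non-overlapping components → ``C1`` (combined call);
    * broadband pulsed call lasting ≥ 150 ms → ``PS1``;
    * tonal call shorter than 150 ms → ``S``; tonal and ≥ 150 ms → ``W``;
    * anything unresolved → ``O``.

    ``band_coverage`` is the fraction of the analysis band with appreciable
    energy (broadband calls cover most of it); ``tonality`` comes from
    :func:`tonality_score` or an equivalent judgement.
    """
    if component_count >= 2:
        return "C1"
    tonal = tonality >= tonality_threshold
    if tonal:
        return "S" if duration_s < long_call_s else "W"
    if band_coverage >= broadband_coverage and duration_s >= long_call_s:
        return "PS1"
    return "O"
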