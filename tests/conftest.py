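"""Shared fixtures: synthetic calls, the default-pack feature table, sessions.

The expensive fixtures (150-call feature pack, attribution sessions) are
session-scoped and shared between the statistical tests and the acceptance
suite.  All randomness is seeded, so the suite is deterministic.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
import pytest

from callid import detect, features as feat, synth

FS = 500e3
PAD_S = 0.45  # leading caller-free noise used for the noise-floor estimate


def clean_profile(**overrides) -> synth.IndividualProfile:
    """A deterministic profile: no jitter, fixed pulse count and spectrum."""
    base = dict(
        label="X",
        initial_ipi_ms=5.0,
        terminal_ipi_ms=5.0,
        n_pulses_mean=50,
        spectral_peak=110e3,
        spectral_bw=30e3,
        amp_jitter_db=0.0,
    )
    base.update(overrides)
    return synth.IndividualProfile(**base)


def noisy_call(profile, seed, snr_db=20.0, n_pulses=None, echo=None):
    """Render one call with a leading quiet segment and additive noise.

    Returns ``(waveform, truth, noise_level, call_start_s)`` where the
    truth peak times are already offset to the padded timeline.
    """
    w, truth = synth.render_call(
        profile, FS, rng_seed=np.random.SeedSequence([int(seed), 1]),
        n_pulses=n_pulses, echo=echo,
    )
    pad = int(PAD_S * FS)
    x = np.zeros(pad + len(w))
    x[pad:] = w
    if snr_db is not None:
        x = synth.add_noise(
            x, FS, snr_db, rng_seed=np.random.SeedSequence([int(seed), 2])
        )
    noise_level = detect.estimate_noise_level(x, FS, (0.0, 0.4))
    truth = dataclasses.replace(
        truth,
        peak_indices=truth.peak_indices + pad,
        peak_times_s=truth.peak_times_s + PAD_S,
    )
    return x, truth, noise_level, PAD_S - 0.005


def extract_call_features(x, train):
    """Nine-parameter row from a detected train inside a padded waveform."""
    contour = detect.extract_ipis(train)
    tf = feat.temporal_features(contour, train)
    _, mid, _ = feat.select_pulse_locations(train.n_pulses)
    spec = feat.pulse_spectrum(x, float(train.peak_times[mid - 1]), FS)
    sf = feat.spectral_features(spec)
    return {
        "avg_ipi_11_20_ms": tf.avg_ipi_11_20_ms,
        "avg_ipi_11_20_last_ms": tf.avg_ipi_11_20_last_ms,
        "duration_s": tf.duration_s,
        "n_pulses": tf.n_pulses,
        "prr_pps": tf.prr_pps,
        "peak_freq_hz": sf.peak_freq_hz,
        "bw10_hz": sf.bw10_hz,
        "lower10_hz": sf.lower10_hz,
        "upper10_hz": sf.upper10_hz,
    }, spec


@pytest.fixture(scope="session")
def feature_pack():
    """Detected features for 30 calls per caller of the default pack, SNR 20.

    Columns: the nine descriptors, ``individual`` and ``count_err``
    (detected minus true pulse count).
    """
    rows = []
    k = 0
    for lab, prof in synth.default_profiles().items():
        for _ in range(30):
            w, truth = synth.render_call(
                prof, FS, rng_seed=np.random.SeedSequence([42, k])
            )
            k += 1
            pad = int(PAD_S * FS)
            x = np.zeros(pad + len(w))
            x[pad:] = w
            x = synth.add_noise(x, FS, 20.0, rng_seed=np.random.SeedSequence([43, k]))
            nl = detect.estimate_noise_level(x, FS, (0.0, 0.4))
            train = detect.detect_pulses(
                x, FS, (PAD_S - 0.005, len(x) / FS), nl, call_id=f"{lab}{k}"
            )
            row, _ = extract_call_features(x, train)
            row["individual"] = lab
            row["count_err"] = train.n_pulses - truth.n_pulses
            rows.append(row)
    return pd.DataFrame(rows)


@pytest.fixture(scope="session")
def attribution_runs():
    """Verdicts for 50 scheduled calls across two isolation sessions.

    Each record holds the true caller, whether it was the isolated animal,
    the assigned verdict, and the true and estimated TDOA.
    """
    import callid.tdoa as td
    from callid.pipeline import RunConfig

    records = []
    config = RunConfig(mode="full", seed=0)
    for sess, (seed, iso) in enumerate([(11, "T"), (12, "G")]):
        scene = synth.default_scene(
            seed=seed, n_calls=25, isolated_label=iso, isolated_fraction=0.6
        )
        audio, truth = synth.render_session(scene)
        zone = td.IsolationZone.from_scene(scene)
        noise = [
            detect.estimate_noise_level(audio[:, ch], scene.fs, (0.0, 0.4))
            for ch in range(2)
        ]
        for rec in truth.calls:
            a = float(rec.peak_times_ch1[0]) - 0.005
            b = float(rec.peak_times_ch1[-1]) + 0.005
            i0, i1 = int(a * scene.fs), int(b * scene.fs)
            est = td.estimate_tdoa(
                audio[i0:i1], scene.fs, max_lag_s=zone.bound_s * 1.2
            )
            asg = td.assign_caller(est.tdoa_s, zone, config.tdoa_tolerance_s)
            records.append(
                {
                    "label": rec.label,
                    "is_isolated": rec.label == iso,
                    "verdict": asg.verdict,
                    "tdoa_true_s": rec.tdoa_s,
                    "tdoa_est_s": est.tdoa_s,
                    "overlap": rec.overlap,
                }
            )
    return pd.DataFrame(records)
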