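"""End-to-end orchestration: simulate, detect, attribute, featurize, report.

``run_pipeline`` mirrors the workflow of an isolation study: each animal is
isolated in turn (one simulated session per caller), calls are detected on
both channels, attributed to the isolated animal or the rest of the group
by TDOA, categorized, and the attributed pulsed calls are carried into the
individuality analysis (PIC table, univariate tests, VIF screening, robust
outlier flags, class balancing, quadratic DFA with leave-one-out CV, and
stepwise feature ranking).

Every stage logs call counts in and out of its filters, so "counted but
excluded" accounting is auditable in the summary.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

import callid.tdoa as tdoa_mod
from callid import detect, features as feat, stats, synth

__all__ = [
    "RunConfig",
    "PipelineError",
    "share_percentages",
    "analyze_session",
    "report_from_features",
    "run_pipeline",
]

log = logging.getLogger("callid.pipeline")


class PipelineError(RuntimeError):
    """Stage-tagged pipeline failure (``stage`` drives the CLI exit code)."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


@dataclass
class RunConfig:
    """Configuration of a pipeline run.

    ``mode`` is one of ``simulate`` (render sessions only), ``analyze``
    (detect/attribute/featurize existing audio) or ``full`` (simulate five
    isolation sessions — one per caller — analyze them and produce the
    statistical report).  ``balance_cap`` caps class sizes before DFA; the
    default ``"second_largest"`` reduces the biggest class to the size of
    the runner-up, mirroring how a dominant caller is down-sampled.
    """

    mode: str = "full"
    out_dir: str | Path = "callid_out"
    seed: int = 0
    scene_path: str | Path | None = None
    n_calls_per_session: int = 25
    isolated_fraction: float = 0.6
    snr_db: float = 20.0
    detect_params: detect.DetectParams = field(default_factory=detect.DetectParams)
    analysis_band_hz: tuple[float, float] = (11e3, 170e3)
    priors: str = "proportional"
    improvement_min: float = 0.05
    balance_cap: int | str | None = "second_largest"
    tdoa_tolerance_s: float = 0.2e-3
    quiet_window_s: tuple[float, float] = (0.0, 0.4)

    def validate(self) -> None:
        if self.mode not in {"simulate", "analyze", "full"}:
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.mode in {"simulate", "full"} and self.seed is None:
            raise ValueError("a seed is mandatory in simulate/full modes")


def share_percentages(counts: dict, method: str = "round") -> dict:
    """Integer percentage shares of category counts.

    ``method="round"`` rounds half up; ``method="trunc"`` truncates toward
    zero, which is how at least one published share (38 % from 2633/6817)
    was evidently formatted.  Rounded shares sum to 100 within k/2 points
    for k categories; truncated shares may fall short of 100.
    """
    total = sum(counts.values())
    if total <= 0:
        raise ValueError("category counts sum to zero")
    out = {}
    for k, v in counts.items():
        x = 100.0 * v / total
        out[k] = int(math.floor(x + 0.5)) if method == "round" else int(math.floor(x))
    return out


def _session_seeds(seed: int, n: int) -> list[int]:
    state = np.random.SeedSequence(seed).generate_state(n, dtype=np.uint32)
    return [int(s % (2**31)) for s in state]


def analyze_session(
    audio: np.ndarray,
    fs: float,
    zone: tdoa_mod.IsolationZone,
    config: RunConfig,
    isolated_label: str | None = None,
    session_id: str = "s0",
) -> pd.DataFrame:
    """Detect, attribute and featurize every call in a two-channel session.

    Returns one row per detected call interval with the nine descriptor
    columns, the TDOA verdict, the rule-based call type, and (when the
    verdict is *isolated* and the session's isolated caller is known) the
    attributed individual label.
    """
    params = config.detect_params
    noise = [
        detect.estimate_noise_level(audio[:, ch], fs, config.quiet_window_s, params.band_hz)
        for ch in range(2)
    ]
    intervals: list[tuple[float, float]] = []
    for ch in range(2):
        intervals.extend(detect.find_calls(audio[:, ch], fs, noise[ch], params))
    intervals.sort()
    merged: list[list[float]] = []
    for a, b in intervals:
        if merged and a <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], b)
        else:
            merged.append([a, b])
    log.info("%s: %d call intervals after channel merge", session_id, len(merged))

    rows = []
    for k, (a, b) in enumerate(merged):
        call_id = f"{session_id}_call{k:04d}"
        trains = [
            detect.detect_pulses(
                audio[:, ch], fs, (a, b), noise[ch], params, call_id, ch
            )
            for ch in range(2)
        ]
        snrs = [
            (np.median(t.peak_amplitudes) / noise[t.channel]) if t.n_pulses else 0.0
            for t in trains
        ]
        best = int(np.argmax(snrs))
        train = trains[best]
        if train.n_pulses < 2:
            continue

        i0, i1 = int(a * fs), int(b * fs)
        est = tdoa_mod.estimate_tdoa(
            audio[i0:i1], fs, max_lag_s=zone.bound_s * 1.2, band_hz=params.band_hz
        )
        assignment = tdoa_mod.assign_caller(
            est.tdoa_s, zone, config.tdoa_tolerance_s, call_id
        )

        contour = detect.extract_ipis(train)
        temporal = feat.temporal_features(contour, train)
        spectral = None
        coverage = 0.0
        if train.n_pulses >= 5:
            _, mid, _ = feat.select_pulse_locations(train.n_pulses)
            try:
                spec = feat.pulse_spectrum(
                    audio[:, best], float(train.peak_times[mid - 1]), fs
                )
            except ValueError:
                spec = None
            if spec is not None:
                spectral = feat.spectral_features(spec, config.analysis_band_hz)
                in_band = (spec.freqs_hz >= 6e3) & (spec.freqs_hz <= 170e3)
                coverage = float(np.mean(spec.level_db[in_band] >= -30.0))
        tonality = feat.tonality_score(audio[i0:i1, best], fs)
        call_type = feat.categorize_call(temporal.duration_s, tonality, coverage)

        individual = (
            isolated_label
            if (assignment.verdict == "isolated" and isolated_label is not None)
            else None
        )
        row = {
            "session_id": session_id,
            "call_id": call_id,
            "individual": individual,
            "verdict": assignment.verdict,
            "tdoa_ms": None if est.tdoa_s is None else est.tdoa_s * 1e3,
            "call_type": call_type,
            "avg_ipi_11_20_ms": temporal.avg_ipi_11_20_ms,
            "avg_ipi_11_20_last_ms": temporal.avg_ipi_11_20_last_ms,
            "duration_s": temporal.duration_s,
            "n_pulses": temporal.n_pulses,
            "prr_pps": temporal.prr_pps,
            "peak_freq_hz": spectral.peak_freq_hz if spectral else None,
            "bw10_hz": spectral.bw10_hz if spectral else None,
            "lower10_hz": spectral.lower10_hz if spectral else None,
            "upper10_hz": spectral.upper10_hz if spectral else None,
            "truncated": temporal.truncated,
        }
        rows.append(row)
    return pd.DataFrame(rows)


def report_from_features(df: pd.DataFrame, config: RunConfig, out_dir: Path) -> dict:
    """Statistical report from an attributed per-call feature table.

    Uses the pulsed calls attributed to a known individual.  Emits the PIC
    table, univariate test results, the screening report, the
    leave-one-out DFA result and the stepwise ranking; returns the summary
    dictionary (also written as ``summary.json``).
    """
    out_dir.mkdir(parents=True, exist_ok=True)
    temporal_params = ["avg_ipi_11_20_ms", "avg_ipi_11_20_last_ms", "duration_s", "n_pulses", "prr_pps"]
    spectral_params = ["peak_freq_hz", "bw10_hz", "lower10_hz", "upper10_hz"]
    all_params = feat.FEATURE_COLUMNS

    attributed = df[df["individual"].notna()].copy()
    if attributed["individual"].nunique() < 2:
        raise PipelineError("stats", "need calls from >= 2 individuals")

    table = stats.pic_table(attributed, all_params)
    table.to_csv(out_dir / "pic_table.csv")

    tests = {}
    by_ind = {
        lab: grp for lab, grp in attributed.groupby("individual")
    }
    for p in temporal_params:
        groups = [g[p].dropna().to_numpy() for g in by_ind.values()]
        h, dfree, pval = stats.kruskal_wallis(groups)
        tests[p] = {"test": "kruskal_wallis", "stat": h, "df": dfree, "p": pval}
    for p in spectral_params:
        groups = [g[p].dropna().to_numpy() for g in by_ind.values()]
        f, df1, df2, pval = stats.one_way_anova(groups)
        tests[p] = {"test": "anova", "F": f, "df1": df1, "df2": df2, "p": pval}

    complete = attributed.dropna(subset=all_params)
    screening = stats.vif_screen(complete[all_params])
    retained = stats.drop_degenerate_within(
        complete[screening.retained], complete["individual"]
    )
    try:
        flags, dists = stats.robust_outliers(complete[retained].to_numpy())
        screening.outlier_flags, screening.outlier_distances = flags, dists
        n_outliers = int(flags.sum())
    except ValueError:
        n_outliers = None

    cap = config.balance_cap
    sizes = complete["individual"].value_counts()
    if cap == "second_largest":
        cap = int(sizes.sort_values().iloc[-2]) if len(sizes) >= 2 else None
    balanced = (
        stats.balance_classes(complete, "individual", cap, config.seed)
        if cap
        else complete
    )
    log.info(
        "DFA sample: %d calls (%d before balancing), features %s",
        len(balanced), len(complete), retained,
    )

    dfa = stats.qda_loocv(
        balanced[retained], balanced["individual"].to_numpy(), priors=config.priors
    )
    stepwise = stats.stepwise_select(
        balanced[retained],
        balanced["individual"].to_numpy(),
        improvement_min=config.improvement_min,
        priors=config.priors,
    )
    diagnostics = stats.covariance_diagnostics(
        balanced[retained], balanced["individual"].to_numpy()
    )

    dfa_payload = dfa.to_json_dict()
    dfa_payload["stepwise_order"] = stepwise.order
    dfa_payload["stepwise_accuracy_trace"] = [round(a, 4) for a in stepwise.accuracy_trace]
    (out_dir / "dfa.json").write_text(json.dumps(dfa_payload, sort_keys=True, indent=1))

    screening_payload = {
        "vif_initial": {k: _json_num(v) for k, v in screening.vif_initial.items()},
        "vif_final": {k: _json_num(v) for k, v in screening.vif.items()},
        "removed": screening.removed,
        "retained": retained,
        "n_outlier_flags": n_outliers,
        "diagnostics": diagnostics,
    }
    (out_dir / "screening.json").write_text(
        json.dumps(screening_payload, sort_keys=True, indent=1)
    )

    cat_counts = df["call_type"].value_counts().to_dict()
    verdict_counts = df["verdict"].value_counts().to_dict()
    per_ind = attributed["individual"].value_counts().to_dict()
    summary = {
        "n_calls_detected": int(len(df)),
        "call_type_counts": {k: int(v) for k, v in sorted(cat_counts.items())},
        "call_type_pct": share_percentages(cat_counts),
        "verdict_counts": {k: int(v) for k, v in sorted(verdict_counts.items())},
        "attributed_counts": {k: int(v) for k, v in sorted(per_ind.items())},
        "attributed_total": int(sum(per_ind.values())),
        "analyzed_total": int(len(complete)),
        "dfa_sample": int(len(balanced)),
        "overall_loocv_rate_pct": round(dfa.overall_rate_pct, 1),
        "stepwise_first": stepwise.order[0] if stepwise.order else None,
        "univariate_tests": {
            k: {kk: _json_num(vv) for kk, vv in v.items()} for k, v in tests.items()
        },
    }
    (out_dir / "summary.json").write_text(json.dumps(summary, sort_keys=True, indent=1))
    return summary


def _json_num(v):
    if isinstance(v, (np.floating, float)):
        if np.isnan(v):
            return None
        if np.isinf(v):
            return "inf"
        return round(float(v), 6)
    if isinstance(v, (np.integer,)):
        return int(v)
    return v


def run_pipeline(config: RunConfig) -> dict:
    """Run the configured pipeline and write the report bundle.

    In ``full`` mode, five sessions are simulated — each caller isolated in
    turn at the isolation-side position — then analyzed and reported.  The
    bundle (features CSV, assignments CSV, PIC table CSV, DFA and screening
    JSON, summary JSON, plus per-session WAV/truth in simulate/full modes)
    is byte-identical across runs with the same configuration and seed.
    """
    config.validate()
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    if config.mode == "simulate":
        scene = _load_or_default_scene(config, isolated_label="T", seed=config.seed)
        _simulate_one(scene, out_dir, "session")
        return {"mode": "simulate", "out_dir": str(out_dir)}

    if config.mode == "analyze":
        if config.scene_path is None:
            raise PipelineError("analyze", "analyze mode needs a scene config")
        scene = synth.SessionScene.from_yaml(config.scene_path)
        audio, fs = synth.read_wav(out_dir / "session.wav")
        zone = tdoa_mod.IsolationZone.from_scene(scene)
        df = analyze_session(audio, fs, zone, config, session_id="session")
        df.to_csv(out_dir / "features.csv", index=False)
        return {"mode": "analyze", "n_calls": int(len(df))}

    # full mode
    labels = sorted(synth.default_profiles())
    seeds = _session_seeds(config.seed, len(labels))
    frames = []
    for label, seed in zip(labels, seeds):
        scene = _load_or_default_scene(config, isolated_label=label, seed=seed)
        try:
            audio, truth = synth.render_session(scene)
        except ValueError as exc:
            raise PipelineError("simulate", str(exc)) from exc
        synth.write_wav(out_dir / f"session_{label}.wav", audio, scene.fs)
        truth.to_json(out_dir / f"truth_{label}.json")
        scene.to_yaml(out_dir / f"scene_{label}.yaml")
        zone = tdoa_mod.IsolationZone.from_scene(scene)
        try:
            df = analyze_session(
                audio, scene.fs, zone, config,
                isolated_label=label, session_id=f"s{label}",
            )
        except ValueError as exc:
            raise PipelineError("detect", str(exc)) from exc
        frames.append(df)
    df = pd.concat(frames, ignore_index=True)
    df.to_csv(out_dir / "features.csv", index=False)
    df[["call_id", "tdoa_ms", "verdict"]].to_csv(
        out_dir / "assignments.csv", index=False
    )
    try:
        summary = report_from_features(df, config, out_dir)
    except PipelineError:
        raise
    except ValueError as exc:
        raise PipelineError("stats", str(exc)) from exc
    return summary


def _load_or_default_scene(config: RunConfig, isolated_label: str, seed: int):
    if config.scene_path is not None:
        scene = synth.SessionScene.from_yaml(config.scene_path)
        scene.seed = seed
        return scene
    return synth.default_scene(
        seed=seed,
        n_calls=config.n_calls_per_session,
        isolated_label=isolated_label,
        snr_db=config.snr_db,
        isolated_fraction=config.isolated_fraction,
    )


def _simulate_one(scene, out_dir: Path, name: str) -> None:
    try:
        audio, truth = synth.render_session(scene)
    except ValueError as exc:
        raise PipelineError("simulate", str(exc)) from exc
    synth.write_wav(out_dir / f"{name}.wav", audio, scene.fs)
    truth.to_json(out_dir / f"{name}_truth.json")
    scene.to_yaml(out_dir / f"{name}_scene.yaml")
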