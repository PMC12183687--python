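"""End-to-end driver: simulate -> chemometrics -> electrophysiology -> align.

A single config dict (YAML-friendly, flat keys per stage) governs every
stage; ``run_pipeline`` executes them in order, writes plain-text tables and
a machine-readable metrics file, and — because the session is synthetic —
scores the analysis against ground truth (concentration recovery, reward
effect signs on dopamine and beta power, spike detection F1).

All randomness derives from ``config['seed']``; identical (config, seed)
pairs give identical outputs.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from . import __version__
from . import align as _align
from . import ephys as _ephys
from . import fscv as _fscv
from . import synth as _synth
from .session_io import SessionBundle, write_session

__all__ = ["DEFAULT_CONFIG", "run_pipeline", "PipelineStageError"]


DEFAULT_CONFIG = {
    "task": "shape",
    "n_trials": 20,
    "n_sessions": 1,
    "seed": 0,
    # simulation
    "fs": 30_000.0,
    "noise_nA": 0.5,
    "drift_linear_nA_s": 0.02,
    "drift_step_nA": 0.05,
    "movement_prob": 0.01,
    "spike_rate_hz": 10.0,
    "artifact_amp_uV": 250.0,
    # analysis
    "alpha": 0.05,
    "r_threshold": 0.8,
    "beta_band": [13.0, 28.0],
    "beta_smooth_s": 0.25,
    "epoch_window": [-2.0, 6.0],
    "postcue_window": [0.2, 2.0],
    "successful_forced_only": True,
    "write_session": False,
}


class PipelineStageError(RuntimeError):
    """A pipeline stage failed; carries the partial-output manifest."""

    def __init__(self, stage: str, manifest: dict, cause: BaseException):
        super().__init__(f"pipeline stage '{stage}' failed: {cause}")
        self.stage = stage
        self.manifest = dict(manifest)


def _config_hash(config: dict) -> str:
    return hashlib.sha256(
        json.dumps(config, sort_keys=True, default=str).encode()).hexdigest()[:12]


def _postcue_mean(rel, row_matrix, labels, window):
    sel = (rel >= window[0]) & (rel <= window[1])
    out = {}
    for cond in ("large", "small"):
        rows = row_matrix[np.asarray(labels) == cond]
        if rows.size == 0:
            out[cond] = np.nan
            continue
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            out[cond] = float(np.nanmean(rows[:, sel]))
    return out


def _match_spikes(detected: np.ndarray, truth: np.ndarray,
                  tolerance_s: float = 0.5e-3):
    """Greedy one-to-one matching of detected to true spike times."""
    used = np.zeros(truth.size, dtype=bool)
    tp = 0
    for t in detected:
        i = np.searchsorted(truth, t)
        best, best_d = -1, tolerance_s
        for j in (i - 1, i):
            if 0 <= j < truth.size and not used[j]:
                d = abs(truth[j] - t)
                if d <= best_d:
                    best, best_d = j, d
        if best >= 0:
            used[best] = True
            tp += 1
    fp = detected.size - tp
    fn = truth.size - tp
    precision = tp / max(tp + fp, 1)
    recall = tp / max(tp + fn, 1)
    f1 = 2 * precision * recall / max(precision + recall, 1e-12)
    return {"tp": tp, "fp": fp, "fn": fn, "precision": precision,
            "recall": recall, "f1": f1}


def _run_one_session(config: dict, seed: int, out: Optional[Path], manifest: dict):
    stage = "simulate"
    try:
        trials = _synth.simulate_trials(config["task"], config["n_trials"],
                                        seed=seed)
        wf = _synth.generate_waveform()
        templates = _synth.make_templates(wf)
        cp, truth_f = _synth.simulate_fscv_session(
            trials, templates, noise_nA=config["noise_nA"],
            drift_linear_nA_s=config["drift_linear_nA_s"],
            drift_step_nA=config["drift_step_nA"],
            movement_prob=config["movement_prob"], seed=seed)
        trace, truth_e = _synth.simulate_ephys_session(
            trials, fs=config["fs"], spike_rate_hz=config["spike_rate_hz"],
            artifact_amp_uV=config["artifact_amp_uV"], seed=seed)
        if config.get("write_session") and out is not None:
            bundle = SessionBundle(colorplot=cp, ephys={trace.channel: trace},
                                   events=cp.events, ground_truth=truth_f,
                                   config=config, seed=seed,
                                   checksums={})
            write_session(bundle, out / f"session_{seed}")
            manifest[f"session_{seed}"] = "written"

        sel = trials
        if config["successful_forced_only"] and config["task"] == "shape":
            sel = trials[(trials["trial_type"] == "forced") & trials["success"]]
        cue_times = sel["t_value_cue"].to_numpy()
        reward = sel["reward"].to_numpy()

        stage = "fscv-analyze"
        # bank noise matches the differential (background-subtracted) frames
        standards, conc, movement = _fscv.make_training_bank(
            templates, noise_nA=max(np.sqrt(2.0) * config["noise_nA"], 1e-3))
        model = _fscv.fit_pcr(standards, conc, analytes=_fscv.BANK_ANALYTES,
                              alpha=config["alpha"],
                              movement_standards=movement)
        rel_f, mat_f = _fscv.trial_chem_matrix(
            cp, model, cue_times, tuple(config["epoch_window"]),
            r_threshold=config["r_threshold"])
        da_avg = _align.average_trial_matrix(mat_f, rel_f, reward)
        da_eff = _postcue_mean(rel_f, mat_f, reward,
                               tuple(config["postcue_window"]))

        # ground-truth reward effect on the same trials/window
        rel_t, mat_t = _epoch_series(truth_f.frame_times, truth_f.da_nM,
                                     cue_times, tuple(config["epoch_window"]),
                                     reference_event=True)
        truth_eff = _postcue_mean(rel_t, mat_t, reward,
                                  tuple(config["postcue_window"]))

        stage = "ephys-analyze"
        cleaned = _ephys.remove_artifacts_spectral(trace)
        env = _ephys.beta_power(cleaned, tuple(config["beta_band"]),
                                config["beta_smooth_s"])
        beta_avg = _align.epoch_and_average(env.times, env.power, cue_times,
                                            tuple(config["epoch_window"]),
                                            reward)
        rel_b, mat_b = _epoch_series(env.times, env.power, cue_times,
                                     tuple(config["epoch_window"]))
        beta_eff = _postcue_mean(rel_b, mat_b, reward,
                                 tuple(config["postcue_window"]))
        rel_bt, mat_bt = _epoch_series(truth_e.beta_env_times, truth_e.beta_env,
                                       cue_times, tuple(config["epoch_window"]))
        beta_truth_eff = _postcue_mean(rel_bt, mat_bt, reward,
                                       tuple(config["postcue_window"]))

        spike_metrics = None
        if config["spike_rate_hz"] > 0 and config["fs"] >= 10_000:
            t_clean = _ephys.remove_artifacts_time(trace, truth_e.artifact_times)
            excised = [(t - 1e-3, t + 8.5e-3 + 2e-3)
                       for t in truth_e.artifact_times]
            spikes = _ephys.detect_spikes(t_clean, exclude_intervals=excised)
            recoverable = _recoverable_spikes(truth_e.spike_times,
                                              truth_e.artifact_times)
            spike_metrics = _match_spikes(spikes.times, recoverable)

        stage = "align"
        clock = _align.sync_streams(cp.events, trace.events,
                                    code=_synth.EVENT_CODES["trial_start"])

        # per-trial recovery against truth (value-cue-referenced epochs)
        both = ~(np.isnan(mat_f) | np.isnan(mat_t))
        rmse = (float(np.sqrt(np.mean((mat_f[both] - mat_t[both]) ** 2)))
                if both.any() else np.nan)

        def _sign_match(a, b):
            if np.isnan(a) or np.isnan(b):
                return None
            return bool(np.sign(a) == np.sign(b))

        da_delta = da_eff["large"] - da_eff["small"]
        da_truth_delta = truth_eff["large"] - truth_eff["small"]
        beta_delta = beta_eff["large"] - beta_eff["small"]
        beta_truth_delta = beta_truth_eff["large"] - beta_truth_eff["small"]
        return {
            "seed": seed,
            "clock_slope": clock.slope, "clock_offset": clock.offset,
            "da_rmse_nM": rmse,
            "null_fraction": float(np.isnan(mat_f).mean()) if mat_f.size else np.nan,
            "da_effect_large_minus_small_nM": da_delta,
            "da_truth_effect_nM": da_truth_delta,
            "da_sign_match": _sign_match(da_delta, da_truth_delta),
            "beta_effect_large_minus_small_uV2": beta_delta,
            "beta_truth_effect_uV2": beta_truth_delta,
            "beta_sign_match": _sign_match(beta_delta, beta_truth_delta),
            "spikes": spike_metrics,
        }, da_avg, beta_avg
    except Exception as e:                                  # noqa: BLE001
        raise PipelineStageError(stage, manifest, e) from e


def _recoverable_spikes(spike_times: np.ndarray, artifact_times: np.ndarray,
                        window_pre: float = 1e-3, window_post: float = 2e-3,
                        scan_duration: float = 8.5e-3) -> np.ndarray:
    """True spikes whose trough lies outside the excised artifact windows."""
    keep = np.ones(spike_times.size, dtype=bool)
    for t in artifact_times:
        keep &= ~((spike_times >= t - window_pre)
                  & (spike_times <= t + scan_duration + window_post))
    return spike_times[keep]


def _epoch_series(times, values, event_times, window, reference_event=False):
    """Trial matrix of a uniform series around events; optionally subtract the
    value at the event frame (mirrors per-trial background referencing)."""
    times = np.asarray(times, float)
    values = np.asarray(values, float)
    dt = float(np.median(np.diff(times)))
    lo, hi = int(round(window[0] / dt)), int(round(window[1] / dt))
    rel = np.arange(lo, hi + 1) * dt
    rows = []
    for t_ev in event_times:
        # nearest frame at or before the event, matching ColorPlot.frame_at
        i0 = int(np.floor((t_ev - times[0]) / dt + 1e-9))
        if i0 + lo < 0 or i0 + hi >= times.size:
            rows.append(np.full(rel.size, np.nan))
            continue
        seg = values[i0 + lo: i0 + hi + 1].copy()
        if reference_event:
            seg -= values[i0]
        rows.append(seg)
    return rel, np.asarray(rows)


def _rate(flags) -> Optional[float]:
    known = [f for f in flags if f is not None]
    return float(np.mean(known)) if known else None


def _avg_table(avg, value_name: str) -> pd.DataFrame:
    rows = []
    for cond in avg.mean:
        for i, t in enumerate(avg.time):
            rows.append((t, cond, avg.mean[cond][i], avg.se[cond][i],
                         int(avg.n[cond][i])))
    return pd.DataFrame(rows, columns=["time_s", "condition", value_name,
                                       "se", "n"])


def run_pipeline(config: Optional[dict] = None, out_dir=None) -> dict:
    """Run the full synthetic-session analysis; returns the metrics report.

    When ``out_dir`` is given, writes ``metrics.json`` plus trial-average
    tables (``da_trial_average.tsv``, ``beta_trial_average.tsv``) there.
    """
    cfg = dict(DEFAULT_CONFIG)
    if config:
        cfg.update(config)
    out = Path(out_dir) if out_dir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {}

    sessions = []
    da_avg = beta_avg = None
    for i in range(int(cfg["n_sessions"])):
        res, da_avg, beta_avg = _run_one_session(cfg, int(cfg["seed"]) + i,
                                                 out, manifest)
        sessions.append(res)

    report = {
        "package_version": __version__,
        "config_hash": _config_hash(cfg),
        "seed": int(cfg["seed"]),
        "n_sessions": len(sessions),
        "sessions": sessions,
        "da_sign_recovery_rate": _rate([s["da_sign_match"] for s in sessions]),
        "erd_sign_recovery_rate": _rate([s["beta_sign_match"] for s in sessions]),
        "mean_da_rmse_nM": float(np.mean([s["da_rmse_nM"] for s in sessions])),
    }
    f1s = [s["spikes"]["f1"] for s in sessions if s["spikes"] is not None]
    if f1s:
        report["mean_spike_f1"] = float(np.mean(f1s))

    if out is not None:
        (out / "metrics.json").write_text(json.dumps(report, indent=1))
        manifest["metrics.json"] = "written"
        if da_avg is not None:
            _avg_table(da_avg, "dDA_nM").to_csv(out / "da_trial_average.tsv",
                                                sep="\t", index=False)
            _avg_table(beta_avg, "beta_power_uV2").to_csv(
                out / "beta_trial_average.tsv", sep="\t", index=False)
    return report
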