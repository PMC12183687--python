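"""Session file formats: flat binaries with JSON sidecars and checksums.

A session directory holds
  colorplot.f32 / colorplot.json   frames x samples float32 current matrix
  ephys_<ch>.i16 / ephys_<ch>.json int16 voltage trace with gain sidecar
  events.tsv                       timestamp_s <tab> code <tab> label [trial]
  ground_truth.json                optional known truth for synthetic sessions
  session.json                     config snapshot + seed + file manifest

Writes are round-trip faithful: reading a written session and re-writing it
reproduces every byte.  EPhys samples are quantized to int16 at a recorded
gain (uV per LSB); the stored representation — not the pre-quantization float
trace — is the session of record.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .fscv import ColorPlot
from .synth import EPhysTrace, GroundTruth, ScanWaveform

__all__ = ["SessionBundle", "write_session", "read_session",
           "ChecksumError", "MissingSidecarError", "DimensionError",
           "write_events", "read_events"]


class ChecksumError(IOError):
    """Stored checksum does not match file contents."""


class MissingSidecarError(IOError):
    """A required sidecar or data file is absent."""


class DimensionError(IOError):
    """Binary payload size disagrees with its sidecar metadata."""


@dataclass
class SessionBundle:
    """In-memory session: color plot, ephys traces, events, optional truth."""

    colorplot: Optional[ColorPlot]
    ephys: dict                     # channel -> EPhysTrace
    events: Optional[pd.DataFrame]
    ground_truth: Optional[GroundTruth]
    config: dict
    seed: Optional[int]
    checksums: dict


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def write_events(events: pd.DataFrame, path: Path) -> None:
    events.to_csv(path, sep="\t", index=False, float_format="%.6f")


def read_events(path: Path) -> pd.DataFrame:
    ev = pd.read_csv(path, sep="\t")
    if "timestamp_s" not in ev.columns or "code" not in ev.columns:
        raise MissingSidecarError(f"{path} lacks timestamp_s/code columns")
    return ev


def _truth_to_json(gt: GroundTruth) -> dict:
    out = {}
    for k, v in asdict(gt).items():
        out[k] = v.tolist() if isinstance(v, np.ndarray) else v
    return out


def _truth_from_json(d: dict) -> GroundTruth:
    arrays = {"frame_times", "da_nM", "ph", "movement_frames", "beta_env_times",
              "beta_env", "erd_profile", "spike_times", "artifact_times"}
    kw = {}
    for k, v in d.items():
        kw[k] = np.asarray(v) if (k in arrays and v is not None) else v
    return GroundTruth(**kw)


def write_session(bundle: SessionBundle, directory) -> dict:
    """Write a session directory; returns the manifest with checksums."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    manifest = {}

    if bundle.colorplot is not None:
        cp = bundle.colorplot
        data = cp.currents.astype("<f4")
        fpath = directory / "colorplot.f32"
        fpath.write_bytes(data.tobytes())
        wf = cp.waveform
        sidecar = {
            "shape": list(data.shape), "dtype": "<f4",
            "frame_rate_hz": wf.frame_rate,
            "t0_s": float(cp.frame_times[0]),
            "waveform": {"v_start": wf.v_start, "v_peak": wf.v_peak,
                         "scan_rate": wf.scan_rate,
                         "repetition_interval": wf.repetition_interval,
                         "adc_rate": wf.adc_rate},
            "sha256": _sha256(fpath),
        }
        (directory / "colorplot.json").write_text(json.dumps(sidecar, indent=1))
        manifest["colorplot.f32"] = sidecar["sha256"]

    for ch, tr in bundle.ephys.items():
        gain = max(np.max(np.abs(tr.samples)), 1e-9) / 32000.0
        q = np.round(tr.samples / gain).astype("<i2")
        fpath = directory / f"ephys_{ch}.i16"
        fpath.write_bytes(q.tobytes())
        sidecar = {"n_samples": int(q.size), "dtype": "<i2",
                   "fs_hz": tr.fs, "gain_uV_per_lsb": gain,
                   "channel": tr.channel, "reference": list(tr.reference),
                   "sha256": _sha256(fpath)}
        (directory / f"ephys_{ch}.json").write_text(json.dumps(sidecar, indent=1))
        manifest[f"ephys_{ch}.i16"] = sidecar["sha256"]

    events = bundle.events
    if events is None and bundle.colorplot is not None:
        events = bundle.colorplot.events
    if events is not None:
        write_events(events, directory / "events.tsv")
        manifest["events.tsv"] = _sha256(directory / "events.tsv")

    if bundle.ground_truth is not None:
        (directory / "ground_truth.json").write_text(
            json.dumps(_truth_to_json(bundle.ground_truth)))
        manifest["ground_truth.json"] = _sha256(directory / "ground_truth.json")

    session = {"config": bundle.config, "seed": bundle.seed, "files": manifest}
    (directory / "session.json").write_text(json.dumps(session, indent=1))
    return manifest


def read_session(directory) -> SessionBundle:
    """Load and validate a session directory (checksums, dimensions)."""
    directory = Path(directory)
    spath = directory / "session.json"
    if not spath.exists():
        raise MissingSidecarError(f"missing {spath}")
    session = json.loads(spath.read_text())
    manifest = session.get("files", {})

    for fname, digest in manifest.items():
        fpath = directory / fname
        if not fpath.exists():
            raise MissingSidecarError(f"manifest names missing file {fname}")
        if _sha256(fpath) != digest:
            raise ChecksumError(f"checksum mismatch for {fname}")

    colorplot = None
    if (directory / "colorplot.f32").exists():
        side_path = directory / "colorplot.json"
        if not side_path.exists():
            raise MissingSidecarError("colorplot.f32 present without sidecar")
        side = json.loads(side_path.read_text())
        raw = np.frombuffer((directory / "colorplot.f32").read_bytes(),
                            dtype=side["dtype"])
        shape = tuple(side["shape"])
        if raw.size != shape[0] * shape[1]:
            raise DimensionError(
                f"colorplot.f32 holds {raw.size} values, sidecar shape {shape}")
        wfp = side["waveform"]
        from .synth import generate_waveform
        wf = generate_waveform(**wfp)
        if wf.n_samples != shape[1]:
            raise DimensionError(
                f"sidecar field 'waveform' implies {wf.n_samples} samples/scan "
                f"but shape says {shape[1]}")
        if abs(wf.frame_rate - side["frame_rate_hz"]) > 1e-9:
            raise DimensionError(
                "sidecar field 'frame_rate_hz' disagrees with the waveform "
                "repetition interval")
        frame_times = side["t0_s"] + np.arange(shape[0]) / side["frame_rate_hz"]
        events = (read_events(directory / "events.tsv")
                  if (directory / "events.tsv").exists() else None)
        colorplot = ColorPlot(currents=raw.reshape(shape).astype(float),
                              frame_times=frame_times, waveform=wf,
                              events=events)

    ephys = {}
    for side_path in sorted(directory.glob("ephys_*.json")):
        side = json.loads(side_path.read_text())
        fpath = side_path.with_suffix(".i16")
        if not fpath.exists():
            raise MissingSidecarError(f"sidecar {side_path.name} without binary")
        raw = np.frombuffer(fpath.read_bytes(), dtype=side["dtype"])
        if raw.size != side["n_samples"]:
            raise DimensionError(
                f"{fpath.name} holds {raw.size} samples, sidecar says "
                f"{side['n_samples']}")
        events = (read_events(directory / "events.tsv")
                  if (directory / "events.tsv").exists() else None)
        ephys[side["channel"]] = EPhysTrace(
            samples=raw.astype(float) * side["gain_uV_per_lsb"],
            fs=side["fs_hz"], channel=side["channel"],
            reference=tuple(side["reference"]), events=events)

    events = (read_events(directory / "events.tsv")
              if (directory / "events.tsv").exists() else None)
    truth = None
    if (directory / "ground_truth.json").exists():
        truth = _truth_from_json(json.loads(
            (directory / "ground_truth.json").read_text()))

    return SessionBundle(colorplot=colorplot, ephys=ephys, events=events,
                         ground_truth=truth, config=session.get("config", {}),
                         seed=session.get("seed"), checksums=manifest)
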