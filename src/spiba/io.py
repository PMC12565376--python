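"""Readers/writers for the supported dialects plus session orchestration.

Readers validate rather than coerce: non-monotone time columns, missing
landmark columns, or more than 1% missing samples are rejected with a
diagnostic.  All JSON outputs carry a schema version and the fully resolved
parameter set for provenance.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.io import wavfile

from . import cardiac, face, kinematics, voice
from .core import UniformSeries
from .errors import InvalidInputError, SchemaError, SpibaError
from .face import FaceGrid, N_LANDMARKS, RegionMap
from .kinematics import TriaxialSeries

__all__ = [
    "SCHEMA_VERSION",
    "read_sensor_csv",
    "write_sensor_csv",
    "read_triaxial_csv",
    "write_triaxial_csv",
    "read_openface_csv",
    "read_wav",
    "write_wav",
    "SessionConfig",
    "run_session",
]

SCHEMA_VERSION = "1.0"


def _validated_series(time: np.ndarray, path, epoch_ms: bool):
    t = np.asarray(time, dtype=float)
    if epoch_ms:
        t = (t - t[0]) / 1000.0
    if t.size < 2:
        raise SchemaError(f"{path}: need at least 2 rows")
    dt = np.diff(t)
    if np.any(dt <= 0):
        bad = int(np.argmax(dt <= 0)) + 2
        raise SchemaError(f"{path}: time column not strictly increasing at line {bad}")
    step = float(np.median(dt))
    n_missing = int(np.sum(np.round(dt / step) - 1))
    if n_missing > 0.01 * t.size:
        raise SchemaError(
            f"{path}: {n_missing} missing samples (> 1% of {t.size}); rejecting"
        )
    if np.max(np.abs(dt - step)) > 1e-6 * step:
        raise SchemaError(f"{path}: time column not uniform within 1e-6 relative")
    gap_report = {"n_missing": n_missing, "step": step}
    return t[0], 1.0 / step, gap_report


def _read_csv(path):
    df = pd.read_csv(path, float_precision="round_trip")
    df.columns = [str(c).strip() for c in df.columns]
    return df


def read_sensor_csv(path, time_column: str = "time", value_column: str = "value",
                    units: str = "", epoch_ms: bool = False) -> UniformSeries:
    """Read a single-channel ``time,value`` CSV into a UniformSeries."""
    df = _read_csv(path)
    for col in (time_column, value_column):
        if col not in df.columns:
            raise SchemaError(f"{path}: missing column {col!r} (have {list(df.columns)})")
    t0, fs, _ = _validated_series(df[time_column].to_numpy(), path, epoch_ms)
    return UniformSeries.from_rate(df[value_column].to_numpy(dtype=float), fs, t0, units)


def write_sensor_csv(series: UniformSeries, path, value_column: str = "value"):
    pd.DataFrame({"time": series.timestamps, value_column: series.values}).to_csv(
        path, index=False
    )


def read_triaxial_csv(path, meta: dict, epoch_ms: bool = False) -> TriaxialSeries:
    """Read a ``time,x,y,z`` CSV; ``meta`` supplies location/task/participant."""
    df = _read_csv(path)
    for col in ("time", "x", "y", "z"):
        if col not in df.columns:
            raise SchemaError(f"{path}: missing column {col!r}")
    t0, fs, _ = _validated_series(df["time"].to_numpy(), path, epoch_ms)
    n = len(df)
    ts = t0 + np.arange(n) / fs
    return TriaxialSeries(
        ts, df["x"].to_numpy(float), df["y"].to_numpy(float), df["z"].to_numpy(float),
        meta.get("location", "pectoralis"), meta.get("task", "resting"),
        meta.get("participant", ""), fs,
    )


def write_triaxial_csv(tri: TriaxialSeries, path):
    pd.DataFrame({"time": tri.timestamps, "x": tri.x, "y": tri.y, "z": tri.z}).to_csv(
        path, index=False
    )


def read_openface_csv(path, min_confidence: float = 0.75,
                      frame_rate: float = 30.0) -> FaceGrid:
    """Read landmark trajectories in the OpenFace CSV dialect.

    Requires columns ``x_0..x_67`` and ``y_0..y_67`` (whitespace around
    header names is tolerated).  Frames are ordered by the ``frame`` column
    when present; rows with ``confidence`` below ``min_confidence`` are
    dropped; the frame rate is inferred from a ``timestamp`` column when
    available.
    """
    df = _read_csv(path)
    missing = [f"{ax}_{i}" for ax in ("x", "y") for i in range(N_LANDMARKS)
               if f"{ax}_{i}" not in df.columns]
    if missing:
        raise SchemaError(
            f"{path}: missing {len(missing)} landmark columns (first: {missing[0]})"
        )
    if "frame" in df.columns:
        df = df.sort_values("frame")
    if "confidence" in df.columns:
        df = df[df["confidence"] >= min_confidence]
    if not len(df):
        raise SchemaError(f"{path}: no frames left after confidence filtering")
    if "timestamp" in df.columns and len(df) > 1:
        dt = float(np.median(np.diff(df["timestamp"].to_numpy(float))))
        if dt > 0:
            frame_rate = 1.0 / dt
    xs = df[[f"x_{i}" for i in range(N_LANDMARKS)]].to_numpy(float)
    ys = df[[f"y_{i}" for i in range(N_LANDMARKS)]].to_numpy(float)
    return FaceGrid(np.stack([xs, ys], axis=-1), frame_rate)


def read_wav(path, channel: int = None) -> UniformSeries:
    """Read a mono WAV into a float series in [-1, 1].

    Multichannel files require an explicit ``channel`` selection.  Integer
    PCM is rescaled by its type range; float data passes through.
    """
    fs, data = wavfile.read(path)
    if data.ndim > 1:
        if channel is None:
            raise InvalidInputError(
                f"{path}: {data.shape[1]} channels; select one with channel="
            )
        data = data[:, channel]
    if np.issubdtype(data.dtype, np.integer):
        info = np.iinfo(data.dtype)
        data = data.astype(float) / max(abs(info.min), info.max)
    else:
        data = data.astype(float)
    return UniformSeries.from_rate(data, float(fs))


def write_wav(path, series: UniformSeries):
    wavfile.write(path, int(round(series.sampling_rate)),
                  series.values.astype(np.float32))


# --------------------------------------------------------------------------
# session orchestration
# --------------------------------------------------------------------------

@dataclass
class SessionConfig:
    """Paths and parameters for one participant session.

    Any modality path may be None; failures in one modality are isolated and
    reported without aborting the rest of the run.
    """

    participant: str = ""
    output_dir: str = "."
    ecg_path: str = None
    imu_path: str = None
    imu_meta: dict = field(default_factory=dict)
    face_path: str = None
    voice_path: str = None
    voice_band: int = 8
    region_map: dict = None
    params: dict = field(default_factory=dict)


def _ecg_result(cfg: SessionConfig) -> dict:
    raw = read_sensor_csv(cfg.ecg_path, value_column=cfg.params.get("ecg_value_column", "mv"),
                          units="mV")
    filtered = cardiac.preprocess_ecg(raw)
    ibi = cardiac.detect_rpeaks(filtered)
    out = {"n_beats": int(ibi.beat_times.size)}
    pc = cardiac.poincare(ibi)
    out["poincare"] = {"sd1": pc.sd1, "sd2": pc.sd2, "ratio_sd2_sd1": pc.ratio_sd2_sd1}
    sp = cardiac.spectral(ibi)
    out["spectral"] = {"lf_power": sp.lf_power, "hf_power": sp.hf_power,
                       "lf_hf_ratio": sp.lf_hf_ratio,
                       "lf_resolution_warning": sp.lf_resolution_warning}
    _, sig = cardiac.cardiac_gamma(ibi)
    out["gamma"] = sig.to_dict()
    out["windows"] = cardiac.windowed_rr(ibi).to_dict(orient="records")
    return out


def _imu_result(cfg: SessionConfig) -> dict:
    tri = read_triaxial_csv(cfg.imu_path, cfg.imu_meta)
    sig = kinematics.imu_signature(tri)
    return {
        "location": sig.location, "task": sig.task,
        "gamma": sig.gamma.to_dict(),
        "center_of_position": list(sig.center_of_position),
        "norm_mean": sig.norm_mean,
    }


def _face_result(cfg: SessionConfig) -> dict:
    grid = read_openface_csv(cfg.face_path)
    rmap = (RegionMap.from_json_dict(cfg.region_map) if cfg.region_map
            else RegionMap.default())
    norm = face.normalize_face(grid)
    speeds = face.landmark_speeds(norm)
    sigs = {}
    for region, idx in rmap.regions.items():
        rs = face.region_signature(speeds[:, list(idx)], region,
                                   frame_rate=grid.frame_rate)
        sigs[region] = (rs.gamma.to_dict() if rs.gamma is not None
                        else {"insufficient": True, "n_spikes": rs.n_spikes})
    out = {"regions": sigs}
    full = [face.region_signature(speeds[:, list(rmap.regions[r])], r,
                                  frame_rate=grid.frame_rate)
            for r in ("V1", "V2", "V3") if r in rmap.regions]
    if len(full) == 3 and all(s.gamma is not None for s in full):
        out["triangle_area"] = face.triangle(*full).area
    return out


def _voice_result(cfg: SessionConfig) -> dict:
    audio = read_wav(cfg.voice_path)
    env = voice.gammatone_envelope(audio, band=cfg.voice_band)
    sig = voice.voice_signature(env)
    return {
        "band": env.band_index, "band_center": env.band_center,
        "gamma_nsr_attack": sig.gamma_nsr_attack,
        "gamma_nsr_decay": sig.gamma_nsr_decay,
        "median_auc_attack": sig.median_auc_attack,
        "median_auc_decay": sig.median_auc_decay,
        "n_cycles": sig.n_cycles, "low_confidence": sig.low_confidence,
    }


def run_session(config: SessionConfig) -> dict:
    """Run every configured modality, isolating per-modality failures.

    Writes one ``<modality>.json`` per modality plus a combined
    ``session_report.json`` to the output directory and returns the report.
    """
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    runners = {
        "ecg": (config.ecg_path, _ecg_result),
        "imu": (config.imu_path, _imu_result),
        "face": (config.face_path, _face_result),
        "voice": (config.voice_path, _voice_result),
    }
    report = {
        "schema_version": SCHEMA_VERSION,
        "participant": config.participant,
        "params": {**config.params, "voice_band": config.voice_band},
        "modalities": {},
    }
    for name, (path, fn) in runners.items():
        if path is None:
            continue
        try:
            result = fn(config)
            status = {"status": "ok", "result": result}
        except (SpibaError, OSError) as exc:
            status = {"status": "failed", "error": f"{type(exc).__name__}: {exc}"}
        report["modalities"][name] = status
        with open(outdir / f"{name}.json", "w") as fh:
            json.dump({"schema_version": SCHEMA_VERSION, **status}, fh, indent=2)
    with open(outdir / "session_report.json", "w") as fh:
        json.dump(report, fh, indent=2)
    return report
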