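"""File-format plumbing: CSV series, PNG frame stacks, WAV stimuli, JSON sidecars.

CSV dialect: comma-separated, header row, UTF-8, '.' decimal.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
from scipy.io import wavfile

from .errors import InvalidParameterError
from .synthetic import ForcingSignal
from .tracking import PositionSeries


def write_series_csv(path: str | Path, t: np.ndarray, value: np.ndarray) -> None:
    pd.DataFrame({"t_s": t, "value": value}).to_csv(path, index=False)


def read_series_csv(path: str | Path) -> tuple[np.ndarray, np.ndarray, float]:
    """Read a (t_s, value) CSV; returns (t, value, fs)."""
    df = pd.read_csv(path)
    for col in ("t_s", "value"):
        if col not in df.columns:
            raise InvalidParameterError(f"{path}: missing column {col!r}")
    t = df["t_s"].to_numpy(dtype=float)
    if len(t) < 2:
        raise InvalidParameterError(f"{path}: need >= 2 samples")
    dt = np.diff(t)
    if not np.allclose(dt, dt[0], rtol=1e-6, atol=1e-9):
        raise InvalidParameterError(f"{path}: non-uniform time grid")
    return t, df["value"].to_numpy(dtype=float), 1.0 / dt[0]


def write_forcing_csv(path: str | Path, forcing: ForcingSignal) -> None:
    write_series_csv(path, forcing.t, forcing.u)


def read_forcing_csv(path: str | Path, kind: str = "external") -> ForcingSignal:
    t, u, fs = read_series_csv(path)
    return ForcingSignal(t=t, u=u, fs=fs, kind=kind)


def write_forcing_wav(path: str | Path, forcing: ForcingSignal) -> None:
    """Write an audio-rate stimulus as 32-bit float WAV, peak-normalized."""
    peak = np.max(np.abs(forcing.u)) or 1.0
    wavfile.write(path, int(round(forcing.fs)),
                  (forcing.u / peak).astype(np.float32))


def write_position_csv(path: str | Path, series: PositionSeries) -> None:
    pd.DataFrame({
        "t_s": series.t, "x_px": series.x, "y_px": series.y,
        "object_id": series.object_id,
    }).to_csv(path, index=False)


def read_position_csv(path: str | Path) -> PositionSeries:
    df = pd.read_csv(path)
    for col in ("t_s", "x_px", "y_px"):
        if col not in df.columns:
            raise InvalidParameterError(f"{path}: missing column {col!r}")
    t = df["t_s"].to_numpy(dtype=float)
    dt = np.diff(t)
    if len(t) < 2 or not np.allclose(dt, dt[0], rtol=1e-6, atol=1e-9):
        raise InvalidParameterError(f"{path}: non-uniform or too-short time grid")
    oid = str(df["object_id"].iloc[0]) if "object_id" in df.columns else Path(path).stem
    return PositionSeries(
        t=t, x=df["x_px"].to_numpy(dtype=float), y=df["y_px"].to_numpy(dtype=float),
        object_id=oid, fs=1.0 / dt[0],
    )


def write_frames_png(out_dir: str | Path, frames: np.ndarray, prefix: str = "frame") -> list[Path]:
    """Write a float [0,1] frame stack as numbered 8-bit PNGs."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = []
    for i, frame in enumerate(frames):
        p = out_dir / f"{prefix}_{i:06d}.png"
        iio.imwrite(p, (np.clip(frame, 0, 1) * 255).astype(np.uint8))
        paths.append(p)
    return paths


def read_frames(source: str | Path) -> np.ndarray:
    """Read a directory of numbered PNG/TIFF frames into a float [0,1] stack."""
    source = Path(source)
    if source.is_dir():
        files = sorted(p for p in source.iterdir()
                       if p.suffix.lower() in (".png", ".tif", ".tiff"))
        if not files:
            raise InvalidParameterError(f"no PNG/TIFF frames in {source}")
        frames = np.stack([iio.imread(p) for p in files])
    else:
        frames = iio.imread(source)
        if frames.ndim == 2:
            frames = frames[None]
    frames = frames.astype(float)
    if frames.max() > 1.0:
        frames /= 255.0
    return frames


def write_json(path: str | Path, obj: dict) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True, default=_json_default))


def read_json(path: str | Path) -> dict:
    return json.loads(Path(path).read_text())


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON serializable: {type(o)}")


def config_hash(obj: dict) -> str:
    """Stable short hash of a configuration mapping, for provenance stamps."""
    blob = json.dumps(obj, sort_keys=True, default=_json_default).encode()
    return hashlib.sha256(blob).hexdigest()[:12]
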