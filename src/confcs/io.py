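"""Plain-text file formats and run manifests.

Traces, ACF curves and sedimentation profiles are stored as CSV with
``# key = value`` metadata headers; every CLI run can emit a JSON manifest
recording the command, configuration, seeds, package version and file
digests, so that any stochastic result is re-runnable.
"""

from __future__ import annotations

import hashlib
import json
from datetime import datetime, timezone
from pathlib import Path

import numpy as np

from .acf import ACFCurve
from .scaling import load_construct_table as read_table
from .sedimentation import DensityProfile
from .simulate import IntensityTrace

__all__ = [
    "read_trace",
    "write_trace",
    "read_acf",
    "write_acf",
    "read_profile",
    "write_profile",
    "read_table",
    "write_manifest",
]


def _parse_header(path: Path) -> tuple[dict, int]:
    meta: dict = {}
    n_header = 0
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            n_header += 1
            body = line[1:].strip()
            if "=" in body:
                key, _, val = body.partition("=")
                key = key.strip()
                val = val.strip()
                try:
                    meta[key] = json.loads(val)
                except json.JSONDecodeError:
                    meta[key] = val
    return meta, n_header


def _load_columns(path: Path, n_cols_min: int, n_cols_max: int):
    meta, n_header = _parse_header(path)
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if lineno <= n_header:
                continue
            stripped = line.strip()
            if not stripped:
                continue
            if lineno == n_header + 1 and any(c.isalpha() for c in stripped.split(",")[0]):
                continue  # column-name row
            parts = stripped.split(",")
            if not n_cols_min <= len(parts) <= n_cols_max:
                raise ValueError(f"{path}:{lineno}: expected {n_cols_min}-{n_cols_max} columns")
            try:
                rows.append([float(x) for x in parts])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: malformed numeric row") from exc
    if not rows:
        raise ValueError(f"{path}: no data rows")
    width = max(len(r) for r in rows)
    if any(len(r) != width for r in rows):
        raise ValueError(f"{path}: inconsistent column counts")
    return meta, np.asarray(rows, dtype=float)


def write_trace(path: str | Path, trace: IntensityTrace) -> None:
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(f"# dt_sample = {trace.dt_sample!r}\n")
        fh.write(f"# t_start = {trace.t_start!r}\n")
        for key in ("seed", "config_hash"):
            if key in trace.meta:
                fh.write(f"# {key} = {json.dumps(trace.meta[key])}\n")
        fh.write("time_s,intensity\n")
        np.savetxt(fh, np.column_stack([trace.times, trace.values]), fmt="%.17g", delimiter=",")


def read_trace(path: str | Path) -> IntensityTrace:
    path = Path(path)
    meta, data = _load_columns(path, 2, 2)
    dt_sample = float(meta.get("dt_sample", data[1, 0] - data[0, 0] if data.shape[0] > 1 else 1.0))
    return IntensityTrace(
        dt_sample=dt_sample,
        values=data[:, 1],
        t_start=float(meta.get("t_start", data[0, 0])),
        meta={k: v for k, v in meta.items() if k not in ("dt_sample", "t_start")} | {"source": str(path)},
    )


def write_acf(path: str | Path, acf: ACFCurve) -> None:
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(f"# min_lag = {acf.min_lag!r}\n")
        for key, val in acf.meta.items():
            fh.write(f"# {key} = {json.dumps(val)}\n")
        if acf.sem is None:
            fh.write("lag_s,G\n")
            np.savetxt(fh, np.column_stack([acf.lags, acf.values]), fmt="%.17g", delimiter=",")
        else:
            fh.write("lag_s,G,sem\n")
            np.savetxt(
                fh, np.column_stack([acf.lags, acf.values, acf.sem]), fmt="%.17g", delimiter=","
            )


def read_acf(path: str | Path) -> ACFCurve:
    path = Path(path)
    meta, data = _load_columns(path, 2, 3)
    sem = data[:, 2] if data.shape[1] == 3 else None
    return ACFCurve(
        lags=data[:, 0],
        values=data[:, 1],
        sem=sem,
        min_lag=float(meta.get("min_lag", 0.0)),
        meta={k: v for k, v in meta.items() if k != "min_lag"} | {"source": str(path)},
    )


def write_profile(path: str | Path, profile: DensityProfile) -> None:
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(f"# channel_height = {profile.channel_height!r}\n")
        fh.write("z_um,count\n")
        np.savetxt(fh, np.column_stack([profile.z, profile.counts]), fmt="%.17g", delimiter=",")


def read_profile(path: str | Path) -> DensityProfile:
    path = Path(path)
    meta, data = _load_columns(path, 2, 2)
    return DensityProfile(
        z=data[:, 0], counts=data[:, 1], channel_height=float(meta.get("channel_height", 50.0))
    )


def _digest(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def write_manifest(
    path: str | Path,
    command: str,
    config: dict,
    seeds: list[int] | int | None = None,
    inputs: list[str | Path] = (),
    outputs: list[str | Path] = (),
) -> dict:
    """Write a JSON run manifest with config snapshot and file digests."""
    from . import __version__

    manifest = {
        "command": command,
        "config": config,
        "seeds": seeds,
        "version": __version__,
        "timestamp": datetime.now(timezone.utc).isoformat(),
        "inputs": {str(p): _digest(Path(p)) for p in inputs},
        "outputs": {str(p): _digest(Path(p)) for p in outputs},
    }
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
        fh.write("\n")
    return manifest
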