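"""Delimited-text I/O for recordings, trajectories and result tables.

Recordings are stored as tab-separated tables (column 1: time in seconds,
columns 2-5: the SUM, MS, DG, CA1 channels) with ``# key: value`` metadata
header lines; the float format round-trips IEEE doubles exactly.  An
optional EDF import maps scrambled channel labels back to the canonical
order (requires ``mne``, which is not a package dependency).
"""

from __future__ import annotations

import hashlib
import os
from typing import Optional

import numpy as np
import pandas as pd

from .errors import SchemaError
from .simdata import CHANNELS, MultiSiteRecording, PoolGeometry, SwimTrajectory

_META_INT = {"day", "trial"}
_META_FLOAT = {"fs", "f0", "search_duration", "latency", "bias_gain", "start_angle"}
_META_BOOL = {"probe", "guided"}


def _format_meta(meta: dict) -> list:
    lines = []
    for k, v in meta.items():
        if isinstance(v, (str, int, float, bool, np.integer, np.floating)):
            lines.append(f"# {k}: {v!r}" if isinstance(v, str) else f"# {k}: {v}")
    return lines


def _parse_meta(lines: list) -> dict:
    meta = {}
    for line in lines:
        body = line.lstrip("#").strip()
        if ":" not in body:
            continue
        k, v = body.split(":", 1)
        k, v = k.strip(), v.strip()
        if k in _META_BOOL:
            meta[k] = v == "True"
        elif k in _META_INT:
            meta[k] = int(v)
        elif k in _META_FLOAT:
            meta[k] = float(v) if v not in ("None", "") else None
        else:
            meta[k] = v.strip("'\"")
    return meta


def write_recording(rec: MultiSiteRecording, path: str) -> None:
    t = np.arange(rec.samples.shape[0]) / rec.fs
    header = _format_meta({"fs": rec.fs, **rec.meta})
    header.append("time\t" + "\t".join(rec.channel_labels))
    data = np.column_stack([t, rec.samples])
    np.savetxt(path, data, fmt="%.17g", delimiter="\t", header="\n".join(header), comments="")


def read_recording(path: str) -> MultiSiteRecording:
    """Read a delimited EEG table, validating schema (channel count/labels,
    monotone time, finite samples) with row numbers in error messages."""
    meta_lines, header = [], None
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith("#"):
                meta_lines.append(line)
            else:
                header = line
                break
    if header is None:
        raise SchemaError(f"{path}: no column header found")
    cols = header.split("\t")
    if cols[0] != "time" or len(cols) != 5:
        raise SchemaError(
            f"{path}: expected columns time + 4 channels, got {len(cols) - 1} channels"
        )
    labels = tuple(cols[1:])
    if sorted(labels) != sorted(CHANNELS):
        raise SchemaError(f"{path}: channel labels {labels} do not match {CHANNELS}")
    data = np.loadtxt(path, delimiter="\t", skiprows=len(meta_lines) + 1)
    if data.ndim == 1:
        data = data[None, :]
    meta = _parse_meta(meta_lines)
    fs = meta.pop("fs", None)
    t = data[:, 0]
    dts = np.diff(t)
    bad = np.flatnonzero(dts <= 0)
    if bad.size:
        raise SchemaError(f"{path}: non-monotone time at data row {int(bad[0]) + 1}")
    if fs is None:
        fs = 1.0 / float(np.median(dts))
    samples = data[:, 1:]
    nan_rows = np.flatnonzero(~np.all(np.isfinite(samples), axis=1))
    if nan_rows.size:
        raise SchemaError(f"{path}: non-finite samples at data rows {nan_rows[:5].tolist()}")
    # reorder scrambled channel columns back to canonical order
    order = [labels.index(ch) for ch in CHANNELS]
    return MultiSiteRecording(samples=samples[:, order], fs=float(fs), meta=meta)


def write_trajectory(traj: SwimTrajectory, path: str) -> None:
    header = _format_meta(
        {"pool_radius": traj.pool.radius,
         "platform_x": traj.pool.platform_center[0],
         "platform_y": traj.pool.platform_center[1],
         "platform_radius": traj.pool.platform_radius,
         **traj.meta}
    )
    header.append("t\tx\ty")
    np.savetxt(path, traj.points, fmt="%.17g", delimiter="\t",
               header="\n".join(header), comments="")


def read_trajectory(path: str) -> SwimTrajectory:
    meta_lines = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#"):
                meta_lines.append(line.rstrip("\n"))
            else:
                break
    meta = _parse_meta(meta_lines)
    pool = PoolGeometry(
        radius=float(meta.pop("pool_radius", 0.75)),
        platform_center=(
            float(meta.pop("platform_x", 0.0)),
            float(meta.pop("platform_y", 0.375)),
        ),
        platform_radius=float(meta.pop("platform_radius", 0.045)),
    )
    pts = np.loadtxt(path, delimiter="\t", skiprows=len(meta_lines) + 1)
    if pts.ndim == 1:
        pts = pts[None, :]
    return SwimTrajectory(points=pts, pool=pool, meta=meta)


def read_recording_edf(path: str) -> MultiSiteRecording:  # pragma: no cover - optional
    """EDF import through ``mne`` (optional dependency); channels are mapped
    to the canonical SUM/MS/DG/CA1 order by label."""
    try:
        import mne
    except ImportError as exc:
        raise SchemaError("EDF import requires the optional 'mne' package") from exc
    raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    picks = []
    for ch in CHANNELS:
        if ch not in raw.ch_names:
            raise SchemaError(f"{path}: EDF missing channel {ch}")
        picks.append(raw.ch_names.index(ch))
    samples = raw.get_data()[picks].T
    return MultiSiteRecording(samples=samples, fs=float(raw.info["sfreq"]), meta={})


def write_table(df: pd.DataFrame, path: str) -> None:
    df.to_csv(path, sep="\t", index=False)


def file_checksum(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def ensure_dir(path: str) -> str:
    os.makedirs(path, exist_ok=True)
    return path
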