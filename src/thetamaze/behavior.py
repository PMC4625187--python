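"""Water-maze performance metrics from swim trajectories.

Escape latency (time to first platform entry, capped at the 60 s trial
limit), path length (polyline length of the tracked positions), mean swim
velocity, and per-quadrant distances for the probe trial.  Quadrants are
the four 90-degree sectors whose bisectors point N/E/S/W (boundaries at 45,
135, 225 and 315 degrees from east); a point exactly on a boundary belongs
to the counterclockwise sector, and each path segment is assigned to the
quadrant containing its midpoint so the quadrant distances sum exactly to
the total path length.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Tuple

import numpy as np

from .errors import DegenerateDataError, ParameterError, SchemaError
from .simdata import PoolGeometry, SwimTrajectory

QUADRANTS: Tuple[str, str, str, str] = ("N", "S", "E", "W")
_SECTOR_ORDER = ("E", "N", "W", "S")  # counterclockwise from east


@dataclass
class TrialMetrics:
    """Per-trial summary: latency [s], path length [m], velocity [m/s]."""

    latency: float
    path_length: float
    mean_velocity: float
    guided: bool


@dataclass
class QuadrantDistances:
    """Distance swum per quadrant [m]; values sum to the total path length."""

    distances: Dict[str, float]
    total: float


def path_length(traj: SwimTrajectory) -> float:
    """Sum of Euclidean segment lengths of the tracked path."""
    xy = traj.xy
    if xy.shape[0] < 2:
        raise DegenerateDataError("path length needs at least 2 trajectory points")
    return float(np.sum(np.hypot(*np.diff(xy, axis=0).T)))


def escape_latency(traj: SwimTrajectory, max_latency: float = 60.0) -> TrialMetrics:
    """Latency to first platform entry; timeout trials get ``max_latency``
    with the ``guided`` flag set.

    The path (and hence length and velocity) is truncated at platform entry.
    """
    if traj.meta.get("probe"):
        raise ParameterError("probe trajectories have no platform; use quadrant_distances")
    if traj.points.shape[0] < 2:
        raise DegenerateDataError("trajectory needs at least 2 points")
    pool = traj.pool
    d = np.hypot(
        traj.xy[:, 0] - pool.platform_center[0], traj.xy[:, 1] - pool.platform_center[1]
    )
    inside = np.flatnonzero(d <= pool.platform_radius)
    if inside.size:
        k = int(inside[0])
        if k == 0:
            # released on the platform: credit the first positive timestamp
            k = 1
        latency = float(traj.t[k] - traj.t[0])
        guided = False
        sub = SwimTrajectory(points=traj.points[: k + 1], pool=pool, meta=dict(traj.meta))
        length = path_length(sub)
    else:
        latency = float(max_latency)
        guided = True
        length = path_length(traj)
    return TrialMetrics(
        latency=latency,
        path_length=length,
        mean_velocity=length / latency,
        guided=guided,
    )


def quadrant_of(point: Tuple[float, float], pool: PoolGeometry) -> str:
    """Quadrant label of a point; boundary points go to the counterclockwise
    sector (e.g. the 45-degree ray belongs to N, not E)."""
    x, y = point
    if x * x + y * y > pool.radius**2 * (1 + 1e-9):
        raise ParameterError(f"point {point} lies outside the pool")
    ang = np.degrees(np.arctan2(y, x)) % 360.0
    idx = int(np.floor((ang + 45.0) / 90.0)) % 4
    return _SECTOR_ORDER[idx]


def quadrant_distances(traj: SwimTrajectory) -> QuadrantDistances:
    """Per-quadrant path length via midpoint assignment of each segment."""
    xy = traj.xy
    if xy.shape[0] < 2:
        raise DegenerateDataError("quadrant distances need at least 2 trajectory points")
    seg = np.diff(xy, axis=0)
    lengths = np.hypot(seg[:, 0], seg[:, 1])
    mid = 0.5 * (xy[:-1] + xy[1:])
    dist = {q: 0.0 for q in QUADRANTS}
    for m, ln in zip(mid, lengths):
        dist[quadrant_of((m[0], m[1]), traj.pool)] += float(ln)
    return QuadrantDistances(distances=dist, total=float(lengths.sum()))
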