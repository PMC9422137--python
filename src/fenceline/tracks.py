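"""GPS track ingestion, fix-schedule regularization, and step construction.

Relocations arrive as Movebank-style CSV (animal id, UTC timestamp, projected
x/y in meters, movement tactic). Steps connect consecutive relocations one fix
interval apart; turning angles are signed (counterclockwise positive) relative
to the previous step's heading.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import Enum
from pathlib import Path

import numpy as np
import pandas as pd


class Tactic(str, Enum):
    migrant = "migrant"
    resident = "resident"


@dataclass(frozen=True)
class TrackPoint:
    animal_id: str
    timestamp: pd.Timestamp
    x: float
    y: float
    tactic: Tactic


@dataclass(frozen=True)
class Step:
    animal_id: str
    start: TrackPoint
    end: TrackPoint
    duration_h: float
    step_length: float
    heading: float  # radians, atan2 convention
    turning_angle: float | None  # None for an animal's first step


DEFAULT_COLUMN_MAP = {
    "animal_id": "animal_id",
    "timestamp": "timestamp",
    "x": "x",
    "y": "y",
    "tactic": "tactic",
}

#: Movebank-style column names accepted out of the box.
MOVEBANK_COLUMN_MAP = {
    "animal_id": "individual-local-identifier",
    "timestamp": "timestamp",
    "x": "utm-easting",
    "y": "utm-northing",
    "tactic": "tactic",
}


def read_tracks(
    path: str | Path, column_map: dict[str, str] | None = None
) -> list[TrackPoint]:
    """Read relocations from CSV, sorted by animal then time.

    Duplicate (animal, timestamp) rows and unparseable timestamps are
    reported as errors naming the offending animal/row.
    """
    cmap = dict(DEFAULT_COLUMN_MAP)
    if column_map:
        cmap.update(column_map)
    df = pd.read_csv(path, float_precision="round_trip")
    missing = [v for k, v in cmap.items() if v not in df.columns and k != "tactic"]
    if missing:
        raise ValueError(f"{path}: missing required column(s) {missing}")
    ts = pd.to_datetime(df[cmap["timestamp"]], utc=True, errors="coerce")
    if ts.isna().any():
        bad = int(np.flatnonzero(ts.isna().to_numpy())[0])
        raise ValueError(
            f"{path}: unparseable timestamp at data row {bad + 1}: "
            f"{df[cmap['timestamp']].iloc[bad]!r}"
        )
    out = pd.DataFrame(
        {
            "animal_id": df[cmap["animal_id"]].astype(str),
            "timestamp": ts,
            "x": df[cmap["x"]].astype(float),
            "y": df[cmap["y"]].astype(float),
        }
    )
    if cmap["tactic"] in df.columns:
        out["tactic"] = df[cmap["tactic"]].astype(str)
    else:
        out["tactic"] = Tactic.resident.value
    dup = out.duplicated(subset=["animal_id", "timestamp"], keep=False)
    if dup.any():
        first = out[dup].iloc[0]
        raise ValueError(
            f"{path}: duplicate timestamp {first['timestamp']} for animal "
            f"{first['animal_id']}"
        )
    out = out.sort_values(["animal_id", "timestamp"], kind="mergesort")
    return [
        TrackPoint(r.animal_id, r.timestamp, r.x, r.y, Tactic(r.tactic))
        for r in out.itertuples(index=False)
    ]


def write_tracks(path: str | Path, points: list[TrackPoint]) -> None:
    """Write relocations as CSV (inverse of :func:`read_tracks` defaults)."""
    pd.DataFrame(
        {
            "animal_id": [p.animal_id for p in points],
            "timestamp": [p.timestamp.isoformat() for p in points],
            "x": [p.x for p in points],
            "y": [p.y for p in points],
            "tactic": [p.tactic.value for p in points],
        }
    ).to_csv(path, index=False, float_format="%.17g")  # exact float round-trip


def group_by_animal(points: list[TrackPoint]) -> dict[str, list[TrackPoint]]:
    groups: dict[str, list[TrackPoint]] = {}
    for p in points:
        groups.setdefault(p.animal_id, []).append(p)
    for pts in groups.values():
        pts.sort(key=lambda p: p.timestamp)
    return groups


def regularize(
    points: list[TrackPoint], interval_h: float = 4.0, tolerance_min: float = 15.0
) -> list[TrackPoint]:
    """Drop relocations isolated on the fix schedule.

    A point is kept when it has a neighboring relocation one fix interval
    (within tolerance) away on at least one side; points with neither a
    conforming predecessor nor successor cannot anchor or terminate any step
    and are removed. The operation is idempotent: every kept point's
    certifying neighbor is itself kept.
    """
    if interval_h <= 0:
        raise ValueError("interval_h must be positive")
    tol = pd.Timedelta(minutes=tolerance_min)
    target = pd.Timedelta(hours=interval_h)
    kept: list[TrackPoint] = []
    for pts in group_by_animal(points).values():
        times = [p.timestamp for p in pts]
        for i, p in enumerate(pts):
            before = i > 0 and abs((times[i] - times[i - 1]) - target) <= tol
            after = i + 1 < len(pts) and abs((times[i + 1] - times[i]) - target) <= tol
            if before or after:
                kept.append(p)
    kept.sort(key=lambda p: (p.animal_id, p.timestamp))
    return kept


def build_steps(
    points: list[TrackPoint], interval_h: float = 4.0, tolerance_min: float = 15.0
) -> list[Step]:
    """Build steps between consecutive points one fix interval apart.

    Points must belong to a single animal. Gaps longer than the interval
    break the chain (no step, and the following step has no turning angle).
    """
    if len({p.animal_id for p in points}) > 1:
        raise ValueError("build_steps expects points from a single animal")
    pts = sorted(points, key=lambda p: p.timestamp)
    tol = pd.Timedelta(minutes=tolerance_min)
    target = pd.Timedelta(hours=interval_h)
    steps: list[Step] = []
    prev_heading: float | None = None
    for a, b in zip(pts[:-1], pts[1:]):
        dt = b.timestamp - a.timestamp
        if abs(dt - target) > tol:
            prev_heading = None
            continue
        dx, dy = b.x - a.x, b.y - a.y
        heading = math.atan2(dy, dx)
        turn = None
        if prev_heading is not None:
            turn = _wrap_angle(heading - prev_heading)
        steps.append(
            Step(
                animal_id=a.animal_id,
                start=a,
                end=b,
                duration_h=dt / pd.Timedelta(hours=1),
                step_length=math.hypot(dx, dy),
                heading=heading,
                turning_angle=turn,
            )
        )
        prev_heading = heading
    return steps


def _wrap_angle(theta: float) -> float:
    """Wrap an angle to (-pi, pi]."""
    theta = (theta + math.pi) % (2 * math.pi) - math.pi
    if theta == -math.pi:
        theta = math.pi
    return theta


def filter_min_relocations(
    groups: dict[str, list[TrackPoint]], minimum: int = 500
) -> dict[str, list[TrackPoint]]:
    """Retain animals with at least ``minimum`` relocations (inclusive)."""
    if minimum < 1:
        raise ValueError("minimum must be >= 1")
    return {aid: pts for aid, pts in groups.items() if len(pts) >= minimum}


def points_in_area(points: list[TrackPoint], bounds: tuple[float, float, float, float]) -> list[TrackPoint]:
    """Relocations inside a rectangular study area (xmin, ymin, xmax, ymax)."""
    xmin, ymin, xmax, ymax = bounds
    return [p for p in points if xmin <= p.x <= xmax and ymin <= p.y <= ymax]
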