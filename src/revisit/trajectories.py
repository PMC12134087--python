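"""Trajectory data model and delimited-text I/O.

Fixes are (id, timestamp, x, y) rows in a projected, metre-unit coordinate
system.  Coordinates must already be projected: geographic longitude /
latitude input is rejected rather than silently reprojected, because every
distance and radius downstream is metric.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "Fix",
    "Trajectory",
    "TrajectorySet",
    "read_trajectories",
    "write_trajectories",
    "tracking_span",
]


@dataclass(frozen=True)
class Fix:
    """One GPS fix: an individual at (x, y) metres at time t (UTC)."""

    individual_id: str
    t: pd.Timestamp
    x: float
    y: float

    def __post_init__(self):
        if not (np.isfinite(self.x) and np.isfinite(self.y)):
            raise ValueError(f"non-finite coordinates for {self.individual_id} at {self.t}")
        if pd.isna(self.t):
            raise ValueError(f"missing timestamp for {self.individual_id}")


@dataclass
class Trajectory:
    """Time-ordered fixes for one individual.

    Arrays are the working representation (``t`` as float seconds since the
    Unix epoch, ``x``/``y`` in metres); :class:`Fix` objects are a
    convenience view.
    """

    individual_id: str
    t: np.ndarray          # float64 seconds since epoch, strictly increasing
    x: np.ndarray
    y: np.ndarray
    sex: str | None = None  # "bull" | "cow" | None

    def __post_init__(self):
        self.t = np.asarray(self.t, dtype=float)
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if not (len(self.t) == len(self.x) == len(self.y)):
            raise ValueError("t, x, y must have equal length")
        if len(self.t) == 0:
            raise ValueError(f"empty trajectory for {self.individual_id}")
        if np.any(np.diff(self.t) <= 0):
            raise ValueError(f"fix times not strictly increasing for {self.individual_id}")
        if not (np.all(np.isfinite(self.t)) and np.all(np.isfinite(self.x)) and np.all(np.isfinite(self.y))):
            raise ValueError(f"non-finite fix data for {self.individual_id}")

    def __len__(self) -> int:
        return len(self.t)

    @property
    def timestamps(self) -> pd.DatetimeIndex:
        return pd.to_datetime((self.t * 1e9).astype("int64"), utc=True)

    @property
    def span(self) -> tuple[pd.Timestamp, pd.Timestamp]:
        ts = self.timestamps
        return ts[0], ts[-1]

    def fixes(self) -> list[Fix]:
        ts = self.timestamps
        return [Fix(self.individual_id, ts[i], self.x[i], self.y[i]) for i in range(len(self))]

    @classmethod
    def from_frame(cls, individual_id: str, df: pd.DataFrame, sex: str | None = None) -> "Trajectory":
        t = pd.to_datetime(df["timestamp"], utc=True).astype("int64").to_numpy() / 1e9
        return cls(individual_id, t, df["x"].to_numpy(float), df["y"].to_numpy(float), sex=sex)


@dataclass
class TrajectorySet:
    """Trajectories keyed by individual id, sharing one projected CRS."""

    trajectories: dict[str, Trajectory] = field(default_factory=dict)
    crs: str = "projected-metres"

    def __len__(self) -> int:
        return len(self.trajectories)

    def __getitem__(self, key: str) -> Trajectory:
        return self.trajectories[key]

    def __iter__(self):
        return iter(self.trajectories.values())

    def ids(self) -> list[str]:
        return list(self.trajectories)

    def add(self, traj: Trajectory) -> None:
        if traj.individual_id in self.trajectories:
            raise ValueError(f"duplicate individual id {traj.individual_id!r}")
        self.trajectories[traj.individual_id] = traj


def _looks_geographic(x: np.ndarray, y: np.ndarray) -> bool:
    """Heuristic for lon/lat degrees masquerading as metres.

    Degree-valued tracking data sits inside +-180/+-90, has fractional
    values, and spans far less than two degrees; a metre-valued track with
    all three properties would cover under two metres, which no real
    trajectory does.
    """
    if len(x) == 0:
        return False
    in_bounds = float(np.max(np.abs(x))) <= 180.0 and float(np.max(np.abs(y))) <= 90.0
    fractional = bool(np.any(x != np.round(x)) or np.any(y != np.round(y)))
    tiny_span = (np.ptp(x) < 2.0) and (np.ptp(y) < 2.0)
    return in_bounds and fractional and tiny_span


def read_trajectories(path, crs: str = "projected-metres") -> TrajectorySet:
    """Read a delimited fix table into a :class:`TrajectorySet`.

    The file must have a header ``id,timestamp,x,y`` (optionally ``sex``),
    comma or tab delimited, with ISO-8601 timestamps.  Rows are sorted by
    time per individual; duplicate (id, timestamp) pairs are a validation
    error.  Coordinates that all fall inside lon/lat bounds are rejected as
    un-projected.

    Parameters
    ----------
    path : str or file-like
        Delimited text source.
    crs : str
        Free-text descriptor of the projected CRS the coordinates are in.
    """
    df = pd.read_csv(path, sep=None, engine="python")
    required = {"id", "timestamp", "x", "y"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"missing required column(s): {sorted(missing)}")

    ts = pd.to_datetime(df["timestamp"], utc=True, errors="coerce", format="ISO8601")
    bad = ts.isna()
    if bad.any():
        lines = (df.index[bad] + 2).tolist()  # header is line 1
        raise ValueError(f"unparseable timestamp(s) at line(s) {lines[:10]}")
    df = df.assign(timestamp=ts)

    dup = df.duplicated(subset=["id", "timestamp"], keep=False)
    if dup.any():
        first = df.loc[dup].iloc[0]
        raise ValueError(
            f"duplicate (id, timestamp) pair: id={first['id']!r} t={first['timestamp'].isoformat()}"
        )

    if _looks_geographic(df["x"].to_numpy(float), df["y"].to_numpy(float)):
        raise ValueError(
            "coordinates look like geographic lon/lat degrees; project to a metre-unit CRS first"
        )

    out = TrajectorySet(crs=crs)
    for ind, sub in df.sort_values(["id", "timestamp"]).groupby("id", sort=True):
        sex = None
        if "sex" in sub.columns:
            vals = sub["sex"].dropna().unique()
            if len(vals):
                sex = str(vals[0])
        out.add(Trajectory.from_frame(str(ind), sub, sex=sex))
    logger.info("read %d fixes, %d individuals", len(df), len(out))
    return out


def write_trajectories(trajset: TrajectorySet, path) -> None:
    """Write fixes back to CSV with the canonical column order."""
    frames = []
    for traj in trajset:
        frame = pd.DataFrame(
            {
                "id": traj.individual_id,
                "timestamp": traj.timestamps.strftime("%Y-%m-%dT%H:%M:%S.%f%z"),
                "x": traj.x,
                "y": traj.y,
            }
        )
        if traj.sex is not None:
            frame["sex"] = traj.sex
        frames.append(frame)
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def tracking_span(traj: Trajectory) -> tuple[pd.Timestamp, pd.Timestamp]:
    """First and last fix time of a trajectory.

    Individuals differ in the length of their tracking period; the span is
    the denominator input when raw visit counts are rescaled to per-season
    revisitation rates.
    """
    return traj.span
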