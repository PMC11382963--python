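"""Reading, validating and normalising check-in trajectories.

A *check-in* is one timestamped visit of a user to a named location (venue),
optionally tagged with a venue category.  Trajectories are per-user,
chronologically sorted sequences of check-ins over a finite location
alphabet; the analysis modules treat the location ids as opaque symbols and
use the coordinates only for the radius of gyration.

Supported dialects
------------------
``snap_tsv``
    Headerless tab-separated files in the style of the SNAP check-in dumps
    (Brightkite/Gowalla): user, ISO-8601 time, latitude, longitude,
    location id.
``weeplaces_csv``
    CSV with a header including a venue ``category`` column (the Weeplaces
    export style): userid, placeid, datetime, lat, lon, city, category.
``generic_csv``
    Any CSV; column names are resolved through ``column_map``.

Timestamps are treated as already local to the user unless
``localize_by_longitude`` is set, in which case a crude fixed offset of
``round(lon / 15)`` hours is applied — hour-of-week analysis is meaningless
across mixed timezones, so the assumption is explicit and overridable.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "WEEPLACES_CATEGORIES",
    "CheckIn",
    "Trajectory",
    "Dataset",
    "read_checkins",
    "write_checkins",
    "dataset_from_frame",
    "slot_index",
    "slot_indices",
    "to_symbol_sequence",
]

#: The eight standard Weeplaces venue tags, used as the default category set.
WEEPLACES_CATEGORIES: tuple[str, ...] = (
    "Home/Work",
    "Education",
    "Entertainment",
    "Food",
    "Travel",
    "Shops",
    "Outdoors",
    "Nightlife",
)

_WEEKDAYS = ("monday", "tuesday", "wednesday", "thursday", "friday", "saturday", "sunday")

_CANONICAL_COLUMNS = ["user_id", "timestamp", "lat", "lon", "location_id", "category"]

_DIALECT_COLUMNS: dict[str, Mapping[str, str]] = {
    # SNAP check-in dumps are headerless; positional names are assigned below.
    "snap_tsv": {
        "user": "user_id",
        "checkin_time": "timestamp",
        "latitude": "lat",
        "longitude": "lon",
        "location_id": "location_id",
    },
    "weeplaces_csv": {
        "userid": "user_id",
        "placeid": "location_id",
        "datetime": "timestamp",
        "lat": "lat",
        "lon": "lon",
        "category": "category",
    },
}


@dataclass(frozen=True)
class CheckIn:
    """One timestamped visit to a venue."""

    user_id: str
    timestamp: pd.Timestamp
    lat: float
    lon: float
    location_id: str
    category: Optional[str] = None


@dataclass
class Trajectory:
    """One user's time-ordered visitation sequence.

    The check-ins are stored as a DataFrame with canonical columns
    (timestamp, lat, lon, location_id, category), sorted by timestamp with
    ties kept in file order.
    """

    user_id: str
    df: pd.DataFrame

    def __post_init__(self) -> None:
        # parsed trajectories always have T >= 1; an empty frame is only
        # produced by category filtering and is allowed to flow through
        ts = self.df["timestamp"]
        if not ts.is_monotonic_increasing:
            raise ValueError(f"trajectory for {self.user_id!r} is not time-sorted")

    def __len__(self) -> int:
        return len(self.df)

    @property
    def alphabet(self) -> set[str]:
        """Set of distinct location ids visited (the alphabet V)."""
        return set(self.df["location_id"])

    @property
    def checkins(self) -> list[CheckIn]:
        return [
            CheckIn(
                user_id=self.user_id,
                timestamp=row.timestamp,
                lat=row.lat,
                lon=row.lon,
                location_id=row.location_id,
                category=row.category if isinstance(row.category, str) else None,
            )
            for row in self.df.itertuples(index=False)
        ]

    def symbols(self) -> list[str]:
        """The ordered location-id sequence X = {x(1), ..., x(T)}."""
        return list(self.df["location_id"])

    def slots(self, week_start: str = "monday") -> np.ndarray:
        """Hour-of-week slot index (0..167) of every check-in."""
        return slot_indices(self.df["timestamp"], week_start=week_start)


@dataclass
class Dataset:
    """A collection of per-user trajectories with provenance metadata."""

    trajectories: dict[str, Trajectory]
    provenance: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.trajectories)

    def __iter__(self) -> Iterable[Trajectory]:
        return iter(self.trajectories.values())

    @property
    def n_records(self) -> int:
        return sum(len(t) for t in self.trajectories.values())

    def to_frame(self) -> pd.DataFrame:
        """All check-ins as one canonical DataFrame (user_id first column)."""
        frames = []
        for uid, traj in self.trajectories.items():
            df = traj.df.copy()
            df.insert(0, "user_id", uid)
            frames.append(df)
        return pd.concat(frames, ignore_index=True)


def slot_index(timestamp, week_start: str = "monday") -> int:
    """Hour-of-week slot in [0, 167]: ``24 * day_offset + hour``.

    Slots are half-open hourly intervals [h, h+1) starting at 00:00 of
    ``week_start``.
    """
    ts = pd.Timestamp(timestamp)
    start = _WEEKDAYS.index(week_start.lower())
    return 24 * ((ts.weekday() - start) % 7) + ts.hour


def slot_indices(timestamps, week_start: str = "monday") -> np.ndarray:
    """Vectorised :func:`slot_index` over a timestamp series."""
    ts = pd.DatetimeIndex(timestamps)
    start = _WEEKDAYS.index(week_start.lower())
    return (24 * ((ts.weekday - start) % 7) + ts.hour).to_numpy()


def to_symbol_sequence(trajectory: Trajectory) -> list[str]:
    """Ordered location-id sequence of a trajectory (length preserved)."""
    return trajectory.symbols()


def _resolve_columns(
    df: pd.DataFrame, dialect: str, column_map: Optional[Mapping[str, str]]
) -> pd.DataFrame:
    if dialect == "generic_csv":
        if column_map is None:
            # assume canonical names already
            mapping = {c: c for c in _CANONICAL_COLUMNS if c in df.columns}
        else:
            mapping = dict(column_map)
    else:
        mapping = dict(_DIALECT_COLUMNS[dialect])
        if column_map:
            mapping.update(column_map)
    missing = [src for src in mapping if src not in df.columns]
    if missing:
        raise ValueError(f"columns {missing} not found in input (have {list(df.columns)})")
    out = df[list(mapping)].rename(columns=mapping)
    for col in _CANONICAL_COLUMNS:
        if col not in out.columns:
            out[col] = np.nan if col in ("lat", "lon") else None
    return out[_CANONICAL_COLUMNS]


def read_checkins(
    path,
    dialect: str = "generic_csv",
    column_map: Optional[Mapping[str, str]] = None,
    *,
    localize_by_longitude: bool = False,
    source_name: Optional[str] = None,
    errors: str = "drop",
) -> Dataset:
    """Read a check-in file into per-user, chronologically sorted trajectories.

    Malformed rows (unparseable timestamp, missing/empty location id,
    coordinates out of range) are dropped and counted; if more than half of
    the rows are malformed, or the file is unreadable, the read fails.
    Duplicate (user, timestamp) rows are kept in file order.

    Parameters
    ----------
    path : path-like
    dialect : {"snap_tsv", "weeplaces_csv", "generic_csv"}
    column_map : mapping of input column -> canonical column, for
        ``generic_csv`` (or to override a dialect's defaults).
    localize_by_longitude : apply a ``round(lon/15)``-hour offset to convert
        nominally-UTC stamps to approximate local time.
    errors : "drop" (default) to drop malformed rows, "raise" to fail on any.
    """
    path = Path(path)
    if dialect not in ("snap_tsv", "weeplaces_csv", "generic_csv"):
        raise ValueError(f"unknown dialect {dialect!r}")
    if not path.exists():
        raise FileNotFoundError(path)

    if dialect == "snap_tsv":
        raw = pd.read_csv(
            path,
            sep="\t",
            header=None,
            names=list(_DIALECT_COLUMNS["snap_tsv"]),
            dtype=str,
            on_bad_lines="skip",
        )
    else:
        raw = pd.read_csv(path, dtype=str, on_bad_lines="skip")
    n_raw = len(raw)
    if n_raw == 0:
        raise ValueError(f"{path}: no rows")

    df = _resolve_columns(raw, dialect, column_map)
    df["timestamp"] = pd.to_datetime(df["timestamp"], errors="coerce", utc=True).dt.tz_localize(
        None
    )
    df["lat"] = pd.to_numeric(df["lat"], errors="coerce")
    df["lon"] = pd.to_numeric(df["lon"], errors="coerce")

    bad = (
        df["timestamp"].isna()
        | df["user_id"].isna()
        | df["location_id"].isna()
        | (df["location_id"].astype(str).str.len() == 0)
        | df["lat"].isna()
        | df["lon"].isna()
        | (df["lat"].abs() > 90)
        | (df["lon"].abs() > 180)
    )
    n_bad = int(bad.sum())
    if errors == "raise" and n_bad:
        raise ValueError(f"{path}: {n_bad} malformed rows")
    if n_bad > 0.5 * n_raw:
        raise ValueError(f"{path}: {n_bad}/{n_raw} rows malformed; refusing to continue")
    if n_bad:
        logger.warning("%s: dropped %d malformed rows of %d", path, n_bad, n_raw)
    df = df[~bad].reset_index(drop=True)

    if localize_by_longitude:
        offset_h = np.round(df["lon"].to_numpy() / 15.0).astype(int)
        df["timestamp"] = df["timestamp"] + pd.to_timedelta(offset_h, unit="h")

    ds = dataset_from_frame(df)
    ds.provenance = {
        "source": source_name or path.name,
        "dialect": dialect,
        "n_raw_rows": n_raw,
        "n_dropped": n_bad,
        "n_records": ds.n_records,
        "time_span": [
            str(df["timestamp"].min()),
            str(df["timestamp"].max()),
        ],
    }
    return ds


def dataset_from_frame(df: pd.DataFrame, provenance: Optional[dict] = None) -> Dataset:
    """Build a Dataset from a canonical-column DataFrame.

    Rows are sorted per user by timestamp (stable, so equal stamps keep
    their input order).
    """
    trajs: dict[str, Trajectory] = {}
    for uid, g in df.groupby("user_id", sort=True):
        g = g.sort_values("timestamp", kind="stable").reset_index(drop=True)
        trajs[str(uid)] = Trajectory(
            user_id=str(uid), df=g[["timestamp", "lat", "lon", "location_id", "category"]]
        )
    return Dataset(trajectories=trajs, provenance=provenance or {})


def write_checkins(dataset: Dataset, path, *, week_start: str = "monday") -> None:
    """Write a Dataset in the generic_csv dialect plus a JSON provenance sidecar.

    One row per check-in: user_id, timestamp, slot, lat, lon, location_id,
    category.  Re-reading the CSV with ``dialect="generic_csv"`` reproduces
    the sequences, timestamps and categories exactly.
    """
    path = Path(path)
    df = dataset.to_frame()
    out = df.copy()
    out.insert(2, "slot", slot_indices(df["timestamp"], week_start=week_start))
    out["timestamp"] = out["timestamp"].dt.strftime("%Y-%m-%dT%H:%M:%S")
    out.to_csv(path, index=False)
    sidecar = path.with_suffix(path.suffix + ".provenance.json")
    meta = dict(dataset.provenance)
    meta.setdefault("n_records", dataset.n_records)
    meta.setdefault("n_users", len(dataset))
    sidecar.write_text(json.dumps(meta, indent=2, default=str))
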