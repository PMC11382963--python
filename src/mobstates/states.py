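"""Time-dependent predictability: hour-of-week profiles, windows, strata.

A user's check-ins are pooled across weeks into hour-of-week slots (168 =
24 h x 7 days), and the uncorrelated predictability Pi_u is computed within
each slot from the slot's own visitation frequencies.  Because single-hour
slot subsequences are short, temporal correlations contribute little there
and only the frequency-based (uncorrelated) bound is used; whole-trajectory
baselines use the same pipeline on the full sequence.

The module also provides coarser window sizes (w-hour bins tiling the week),
per-user activity metrics (distinct locations S, radius of gyration r_g,
monthly check-in rate f_c), population profiles and activity-stratified
profiles.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence, Union

import numpy as np

from .entropy import fano_predictability, shannon_entropy
from .io import Dataset, Trajectory

__all__ = [
    "SlotProfile",
    "ActivityMetrics",
    "slot_predictability",
    "binned_predictability",
    "windowed_predictability",
    "population_profile",
    "activity_metrics",
    "stratified_profiles",
    "distribution_mode",
    "DEFAULT_STRATA",
]

N_SLOTS = 168

#: Default stratum edges per activity metric (half-open [lo, hi) bins); the
#: bands include the commonly discussed ranges: 10-20 and >60 distinct
#: locations, <10 km and >100 km radius of gyration.
DEFAULT_STRATA: dict[str, list[float]] = {
    "S": [1, 10, 20, 60, math.inf],
    "r_g": [0, 10, 100, math.inf],
    "f_c": [0, 10, 50, math.inf],
}

EARTH_RADIUS_KM = 6371.0088
DAYS_PER_MONTH = 30.44


@dataclass
class SlotProfile:
    """Population per-slot predictability summary.

    ``mean``/``sd``/``count`` are length-168 arrays; slots with no observing
    user are NaN (never zero-filled).  ``sd`` is the population standard
    deviation over users with data in the slot.
    """

    mean: np.ndarray
    sd: np.ndarray
    count: np.ndarray
    n_users: int
    label: Optional[str] = None


@dataclass(frozen=True)
class ActivityMetrics:
    """Per-user activity level: diversity, spatial coverage, intensity."""

    S: int
    r_g: float  # km; NaN when coordinates are unavailable
    f_c: float  # mean check-ins per month (30.44-day months)


def _pi_u(symbols: Sequence[str]) -> float:
    res = shannon_entropy(symbols)
    if res.S == 1:
        return 1.0
    return fano_predictability(res.H_u, res.S).Pi


def binned_predictability(
    trajectory: Trajectory, w: int, *, week_start: str = "monday"
) -> np.ndarray:
    """Per-bin uncorrelated predictability for w-hour bins tiling the week.

    The weekly cycle is partitioned into ``ceil(168 / w)`` half-open bins;
    check-ins from all weeks are pooled per bin, and Pi_u is computed from
    each bin's visitation frequencies.  Empty bins are NaN.
    """
    if not (1 <= w <= N_SLOTS):
        raise ValueError("window size must be in 1..168 hours")
    n_bins = math.ceil(N_SLOTS / w)
    slots = trajectory.slots(week_start=week_start)
    bins = slots // w
    symbols = trajectory.symbols()
    out = np.full(n_bins, np.nan)
    order = np.argsort(bins, kind="stable")
    sorted_bins = bins[order]
    boundaries = np.searchsorted(sorted_bins, np.arange(n_bins + 1))
    for b in range(n_bins):
        lo, hi = boundaries[b], boundaries[b + 1]
        if hi > lo:
            out[b] = _pi_u([symbols[i] for i in order[lo:hi]])
    return out


def slot_predictability(trajectory: Trajectory, *, week_start: str = "monday") -> np.ndarray:
    """Hour-of-week profile: Pi_u per slot 0..167 (NaN where unobserved)."""
    return binned_predictability(trajectory, 1, week_start=week_start)


def windowed_predictability(
    trajectory: Trajectory, w: Union[int, str], *, week_start: str = "monday"
) -> float:
    """Mean per-bin Pi_u of one user at window size ``w`` hours.

    ``w="full"`` returns the whole-trajectory baseline Pi_u (no windowing).
    ``w=168`` pools everything into one weekly bin and therefore equals the
    baseline exactly.
    """
    if w == "full":
        return _pi_u(trajectory.symbols())
    vals = binned_predictability(trajectory, int(w), week_start=week_start)
    return float(np.nanmean(vals))


def _haversine_km(lat1, lon1, lat2, lon2) -> np.ndarray:
    """Great-circle distance in km between coordinate arrays, in degrees."""
    p1, p2 = np.radians(lat1), np.radians(lat2)
    dphi = p2 - p1
    dlmb = np.radians(lon2) - np.radians(lon1)
    a = np.sin(dphi / 2) ** 2 + np.cos(p1) * np.cos(p2) * np.sin(dlmb / 2) ** 2
    return 2 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(a, 0, 1)))


def activity_metrics(trajectory: Trajectory) -> ActivityMetrics:
    """Distinct locations S, radius of gyration r_g (km), monthly rate f_c.

    The radius of gyration is the root-mean-square great-circle distance of
    the check-ins from their centre of mass (3-D Cartesian centroid projected
    back to the sphere).  The monthly rate divides the record count by the
    observation span in 30.44-day months, with a one-day floor on the span.
    """
    df = trajectory.df
    s = len(set(df["location_id"]))

    lat = df["lat"].to_numpy(dtype=float)
    lon = df["lon"].to_numpy(dtype=float)
    if np.isnan(lat).any() or np.isnan(lon).any():
        r_g = float("nan")
    else:
        phi, lmb = np.radians(lat), np.radians(lon)
        xyz = np.stack(
            [np.cos(phi) * np.cos(lmb), np.cos(phi) * np.sin(lmb), np.sin(phi)], axis=1
        )
        c = xyz.mean(axis=0)
        norm = np.linalg.norm(c)
        if norm < 1e-12:  # degenerate antipodal centroid
            r_g = float("nan")
        else:
            c = c / norm
            clat = math.degrees(math.asin(np.clip(c[2], -1, 1)))
            clon = math.degrees(math.atan2(c[1], c[0]))
            d = _haversine_km(lat, lon, clat, clon)
            r_g = float(np.sqrt(np.mean(d**2)))

    ts = df["timestamp"]
    span_days = max(1.0, (ts.iloc[-1] - ts.iloc[0]).total_seconds() / 86400.0)
    f_c = len(df) / (span_days / DAYS_PER_MONTH)
    return ActivityMetrics(S=s, r_g=r_g, f_c=float(f_c))


def population_profile(
    dataset: Dataset, *, week_start: str = "monday", label: Optional[str] = None
) -> SlotProfile:
    """Per-slot mean and spread of Pi_u over users with data in the slot.

    The standard deviation uses the population convention (ddof=0); slots
    nobody observed are NaN with count 0.
    """
    users = list(dataset.trajectories.values())
    if not users:
        return SlotProfile(
            mean=np.full(N_SLOTS, np.nan),
            sd=np.full(N_SLOTS, np.nan),
            count=np.zeros(N_SLOTS, dtype=int),
            n_users=0,
            label=label,
        )
    mat = np.vstack([slot_predictability(t, week_start=week_start) for t in users])
    present = ~np.isnan(mat)
    count = present.sum(axis=0)
    denom = np.maximum(count, 1)
    filled = np.where(present, mat, 0.0)
    mean = np.where(count > 0, filled.sum(axis=0) / denom, np.nan)
    var = np.where(count > 0, (np.where(present, (mat - mean) ** 2, 0.0)).sum(axis=0) / denom, np.nan)
    sd = np.sqrt(var)
    return SlotProfile(mean=mean, sd=sd, count=count, n_users=len(users), label=label)


def stratified_profiles(
    dataset: Dataset,
    metric: str,
    bin_edges: Optional[Sequence[float]] = None,
    *,
    week_start: str = "monday",
) -> dict[str, SlotProfile]:
    """Population profiles stratified by an activity metric.

    Users are assigned to half-open strata ``[edge_i, edge_{i+1})`` of the
    chosen metric (``"S"``, ``"r_g"`` or ``"f_c"``); users whose metric is
    undefined (NaN) or falls outside the edges are excluded.  Empty strata
    yield an all-missing profile with zero users.
    """
    if metric not in DEFAULT_STRATA:
        raise ValueError(f"metric must be one of {sorted(DEFAULT_STRATA)}")
    edges = list(DEFAULT_STRATA[metric] if bin_edges is None else bin_edges)
    if len(edges) < 2 or any(a >= b for a, b in zip(edges, edges[1:])):
        raise ValueError("bin_edges must be strictly increasing with >= 2 entries")

    assignments: dict[int, dict[str, Trajectory]] = {i: {} for i in range(len(edges) - 1)}
    for uid, traj in dataset.trajectories.items():
        m = getattr(activity_metrics(traj), metric)
        if m is None or (isinstance(m, float) and math.isnan(m)):
            continue
        for i in range(len(edges) - 1):
            if edges[i] <= m < edges[i + 1]:
                assignments[i][uid] = traj
                break

    out: dict[str, SlotProfile] = {}
    for i in range(len(edges) - 1):
        name = f"{metric}=[{edges[i]:g},{edges[i + 1]:g})"
        out[name] = population_profile(
            Dataset(trajectories=assignments[i]), week_start=week_start, label=name
        )
    return out


def distribution_mode(values: Sequence[float], bin_width: float = 0.02) -> float:
    """Modal value of a sample on [0, 1] via a fixed-width histogram.

    Returns the midpoint of the highest-count bin; ties are broken toward
    the higher-valued bin.
    """
    vals = np.asarray([v for v in values if not math.isnan(v)], dtype=float)
    if vals.size == 0:
        raise ValueError("no finite values")
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    n_bins = int(math.ceil(1.0 / bin_width - 1e-9))
    edges = np.minimum(np.arange(n_bins + 1) * bin_width, 1.0)
    counts, _ = np.histogram(vals, bins=edges)
    idx = len(counts) - 1 - int(np.argmax(counts[::-1]))  # ties -> higher bin
    return float((edges[idx] + edges[idx + 1]) / 2)
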