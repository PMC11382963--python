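"""Synthetic check-in cohorts with known ground truth.

Every analysis stage in this package is exercised against generated data
whose structure is known by construction:

* :func:`gen_markov_sequence` — stationary 2+-state Markov chains with the
  closed-form entropy rate, the oracle for the Lempel–Ziv estimator;
* :func:`gen_schedule_user` / :func:`gen_cohort` — schedule-driven users on
  an hourly check-in lattice: home at night, work on weekday daytimes,
  Zipf-popular leisure venues otherwise, with the probability of following
  the routine modulated by 24 / 12 / 6 h harmonics.  Cohorts draw venue-pool
  size, spatial spread and attendance rate from log-normal distributions,
  reproducing the right-skewed heavy-tailed activity metrics seen in
  check-in services;
* :func:`gen_periodic_series` — sinusoid-plus-noise hourly series for the
  wavelet module;
* :func:`gen_regression_cohort` — users whose measured correlated
  predictability is, by a one-off empirical calibration, a designed linear
  function of their category visit frequencies plus Gaussian noise, so that
  coefficient recovery by the context model is a genuine end-to-end test.

All generators are pure functions of their parameters and seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .entropy import fano_predictability, lz_entropy_rate
from .io import WEEPLACES_CATEGORIES, Dataset, Trajectory, dataset_from_frame

__all__ = [
    "CohortSpec",
    "GroundTruth",
    "gen_markov_sequence",
    "gen_schedule_user",
    "gen_cohort",
    "gen_periodic_series",
    "gen_regression_cohort",
]

#: Category weights for leisure venues (Home/Work is assigned structurally).
LEISURE_CATEGORY_WEIGHTS = {
    "Food": 0.25,
    "Shops": 0.18,
    "Entertainment": 0.15,
    "Nightlife": 0.12,
    "Outdoors": 0.12,
    "Travel": 0.10,
    "Education": 0.08,
}

_EPOCH = pd.Timestamp("2012-01-02 00:00:00")  # a Monday


@dataclass
class CohortSpec:
    """Parameters of a schedule-driven synthetic cohort.

    Amplitudes ``a24/a12/a6`` modulate the probability of following the
    daily routine around ``routine_base``; the dominant designed period per
    user is chosen according to ``mode_fractions`` (shares of 24 h-, 12 h-
    and 6 h-dominant users) by making that harmonic's amplitude the major
    one.  Heterogeneity across users (venue-pool size, spatial spread in
    km, hourly attendance rate) is log-normal.
    """

    n_users: int = 100
    weeks: int = 16
    seed: int = 0
    a24: float = 0.35
    a12: float = 0.06
    a6: float = 0.02
    routine_base: float = 0.55
    amp_major: float = 0.35
    amp_minor: float = 0.06
    mode_fractions: tuple[float, float, float] = (1.0, 0.0, 0.0)
    attendance: float = 0.35
    attendance_sigma: float = 0.45
    n_leisure_median: float = 20.0
    n_leisure_sigma: float = 0.7
    zipf_exponent: float = 1.2
    spread_km_median: float = 3.0
    spread_km_sigma: float = 0.8
    noise: float = 0.05

    def __post_init__(self) -> None:
        for name in ("a24", "a12", "a6", "amp_major", "amp_minor"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if self.n_users < 1:
            raise ValueError("n_users must be >= 1")
        if abs(sum(self.mode_fractions) - 1.0) > 1e-9:
            raise ValueError("mode_fractions must sum to 1")


@dataclass
class GroundTruth:
    """What the generator designed, recorded next to every cohort."""

    designed_mode: dict[str, str] = field(default_factory=dict)  # user -> "24h"/"12h"/"6h"
    user_params: dict[str, dict] = field(default_factory=dict)
    beta: Optional[dict[str, float]] = None
    noise_sd: Optional[float] = None
    designed_r2: Optional[float] = None
    targets: Optional[dict[str, float]] = None
    calibration: Optional[dict] = None
    analytic_entropy_rate: Optional[float] = None


def _stationary_distribution(P: np.ndarray) -> np.ndarray:
    w, v = np.linalg.eig(P.T)
    i = int(np.argmin(np.abs(w - 1.0)))
    pi = np.real(v[:, i])
    pi = np.abs(pi)
    return pi / pi.sum()


def gen_markov_sequence(
    P: Sequence[Sequence[float]], N: int, seed: int
) -> tuple[list[str], float]:
    """Sample a stationary Markov chain and return its analytic entropy rate.

    The rate is ``sum_i pi_i sum_j P_ij (-log2 P_ij)`` with ``pi`` the
    stationary distribution; symbols are "s0", "s1", ...
    """
    P = np.asarray(P, dtype=float)
    if P.ndim != 2 or P.shape[0] != P.shape[1]:
        raise ValueError("P must be square")
    if (P < 0).any() or not np.allclose(P.sum(axis=1), 1.0, atol=1e-9):
        raise ValueError("P must be row-stochastic")
    k = P.shape[0]
    pi = _stationary_distribution(P)
    with np.errstate(divide="ignore", invalid="ignore"):
        logp = np.where(P > 0, np.log2(np.where(P > 0, P, 1.0)), 0.0)
    rate = float(-(pi[:, None] * P * logp).sum())

    rng = np.random.default_rng(seed)
    states = np.empty(N, dtype=np.int64)
    states[0] = rng.choice(k, p=pi)
    # row-wise inverse-CDF sampling
    cum = np.cumsum(P, axis=1)
    u = rng.random(N)
    for t in range(1, N):
        states[t] = np.searchsorted(cum[states[t - 1]], u[t])
    return [f"s{i}" for i in states], rate


def _km_offsets_to_latlon(lat0: float, lon0: float, dx_km, dy_km):
    lat = lat0 + np.asarray(dy_km) / 111.32
    lon = lon0 + np.asarray(dx_km) / (111.32 * math.cos(math.radians(lat0)))
    return lat, lon


def gen_schedule_user(
    user_id: str,
    seed,
    *,
    weeks: int = 16,
    attendance: float = 0.35,
    n_leisure: int = 20,
    zipf_exponent: float = 1.2,
    spread_km: float = 3.0,
    routine_base: float = 0.55,
    a24: float = 0.35,
    a12: float = 0.06,
    a6: float = 0.02,
    noise: float = 0.05,
    center: tuple[float, float] = (40.0, -75.0),
    daily_only: bool = False,
) -> pd.DataFrame:
    """One schedule-driven user's check-ins as a canonical DataFrame.

    Check-ins sit on an hourly lattice (at most one per hour).  At each
    attended hour the user follows the routine with probability
    ``base + a24 cos(2 pi (h - 4)/24) + a12 cos(2 pi (h - 4)/12) +
    a6 cos(2 pi (h - 4)/6)`` (clipped to [0, 1]; peak at 04:00): routine
    means home at night/weekends and the workplace on weekday daytimes.
    Otherwise a leisure venue is drawn with Zipf-distributed popularity,
    or — with probability ``noise`` — uniformly from the whole pool.
    """
    rng = np.random.default_rng(seed)
    total_h = weeks * 168
    hourly = np.arange(total_h)
    hod = hourly % 24
    dow = (hourly // 24) % 7

    attend = rng.random(total_h) < attendance
    idx = np.flatnonzero(attend)
    if idx.size == 0:
        idx = np.array([9])  # guarantee T >= 1
    h, d = hod[idx], dow[idx]
    if daily_only:  # every day identical: no weekend, no weekday rotation
        d = np.zeros_like(d)

    phase = 2 * np.pi * (h - 4)
    p_routine = np.clip(
        routine_base
        + a24 * np.cos(phase / 24)
        + a12 * np.cos(phase / 12)
        + a6 * np.cos(phase / 6),
        0.0,
        1.0,
    )
    routine = rng.random(idx.size) < p_routine
    at_work = routine & (d < 5) & (h >= 9) & (h < 17)
    # weekend daytime is an outing drawn from the leisure pool either way
    # (check-in services log little at-home daytime activity)
    weekend_day = (d >= 5) & (h >= 10) & (h < 21)
    at_home = routine & ~at_work & ~weekend_day

    # venue pool: home, work, and Zipf-popular leisure venues
    ranks = np.arange(1, n_leisure + 1)
    w = ranks ** (-float(zipf_exponent))
    w /= w.sum()
    # popularity ranking rotates with the day of week (gym on Mondays, bar
    # on Fridays): within-day concentration is unchanged but pooling
    # several days mixes differently ranked venues
    leisure_choice = (rng.choice(n_leisure, size=idx.size, p=w) + d * max(1, n_leisure // 7)) % n_leisure
    uniform_mask = rng.random(idx.size) < noise
    n_pool = n_leisure + 2
    uniform_choice = rng.integers(0, n_pool, size=idx.size)

    # venue codes: 0 = home, 1 = work, 2.. = leisure
    venue = np.where(at_home, 0, np.where(at_work, 1, leisure_choice + 2))
    venue = np.where(uniform_mask & ~routine, uniform_choice, venue)

    # fixed venue geometry: home/work near the centre, leisure scattered
    dx = np.concatenate([[0.0, 1.5], rng.normal(0, spread_km, n_leisure)])
    dy = np.concatenate([[0.0, 0.8], rng.normal(0, spread_km, n_leisure)])
    vlat, vlon = _km_offsets_to_latlon(center[0], center[1], dx, dy)
    cat_names = list(LEISURE_CATEGORY_WEIGHTS)
    cat_w = np.array(list(LEISURE_CATEGORY_WEIGHTS.values()))
    leis_cats = rng.choice(cat_names, size=n_leisure, p=cat_w / cat_w.sum())
    vcat = np.concatenate([["Home/Work", "Home/Work"], leis_cats])
    vid = np.array(
        [f"{user_id}_home", f"{user_id}_work"] + [f"{user_id}_L{r}" for r in range(n_leisure)]
    )

    return pd.DataFrame(
        {
            "user_id": user_id,
            "timestamp": _EPOCH + pd.to_timedelta(idx, unit="h"),
            "lat": vlat[venue],
            "lon": vlon[venue],
            "location_id": vid[venue],
            "category": vcat[venue],
        }
    )


def gen_cohort(spec: CohortSpec) -> tuple[Dataset, GroundTruth]:
    """A heterogeneous cohort of schedule-driven users plus its ground truth.

    Per-user venue-pool size, spatial spread and attendance rate are
    log-normal (right-skewed, heavy-tailed); designed dominant periods are
    assigned deterministically by ``mode_fractions`` (largest-remainder
    apportionment, so the designed shares are exact).
    """
    root = np.random.default_rng(spec.seed)
    child_seeds = np.random.SeedSequence(spec.seed).spawn(spec.n_users)

    n = spec.n_users
    counts = _apportion(np.asarray(spec.mode_fractions, dtype=float), n)
    modes = np.repeat(["24h", "12h", "6h"], counts)

    n_leis = np.maximum(
        3, np.round(np.exp(root.normal(math.log(spec.n_leisure_median), spec.n_leisure_sigma, n)))
    ).astype(int)
    spread = np.exp(root.normal(math.log(spec.spread_km_median), spec.spread_km_sigma, n))
    att = np.clip(
        spec.attendance * np.exp(root.normal(0, spec.attendance_sigma, n)), 0.03, 0.9
    )
    centers = np.stack(
        [root.uniform(30, 48, n), root.uniform(-120, -75, n)], axis=1
    )

    truth = GroundTruth()
    frames = []
    for i in range(n):
        uid = f"u{i:04d}"
        amps = {"a24": spec.amp_minor, "a12": spec.amp_minor / 2, "a6": spec.amp_minor / 3}
        amps[f"a{modes[i][:-1]}"] = spec.amp_major
        frames.append(
            gen_schedule_user(
                uid,
                child_seeds[i],
                weeks=spec.weeks,
                attendance=float(att[i]),
                n_leisure=int(n_leis[i]),
                zipf_exponent=spec.zipf_exponent,
                spread_km=float(spread[i]),
                routine_base=spec.routine_base,
                noise=spec.noise,
                center=(float(centers[i, 0]), float(centers[i, 1])),
                **amps,
            )
        )
        truth.designed_mode[uid] = modes[i]
        truth.user_params[uid] = {
            "n_leisure": int(n_leis[i]),
            "spread_km": float(spread[i]),
            "attendance": float(att[i]),
            **amps,
        }

    df = pd.concat(frames, ignore_index=True)
    ds = dataset_from_frame(
        df, provenance={"source": "synthetic_schedule_cohort", "seed": spec.seed}
    )
    return ds, truth


def _apportion(fractions: np.ndarray, n: int) -> np.ndarray:
    """Largest-remainder apportionment of n users to designed shares."""
    raw = fractions * n
    counts = np.floor(raw).astype(int)
    rem = raw - counts
    deficit = int(n - counts.sum())
    if deficit > 0:
        for j in np.argsort(-rem)[:deficit]:
            counts[j] += 1
    elif deficit < 0:  # float round-off pushed a floor too high
        for j in np.argsort(rem)[: -deficit]:
            counts[j] -= 1
    return counts


def gen_periodic_series(
    periods: Sequence[float],
    amplitudes: Sequence[float],
    noise_sd: float,
    length_h: int,
    seed: int,
) -> np.ndarray:
    """Sum of sinusoids plus Gaussian noise, sampled hourly."""
    periods = np.asarray(periods, dtype=float)
    amplitudes = np.asarray(amplitudes, dtype=float)
    if (periods <= 2).any():
        raise ValueError("periods must exceed 2 h (the Nyquist limit of hourly sampling)")
    if periods.size and length_h < 2 * periods.max():
        raise ValueError("series must cover at least two cycles of the longest period")
    t = np.arange(length_h, dtype=float)
    x = np.zeros(length_h)
    for p, a in zip(periods, amplitudes):
        x += a * np.cos(2 * np.pi * t / p)
    rng = np.random.default_rng(seed)
    if noise_sd > 0:
        x += rng.normal(0, noise_sd, length_h)
    return x


# ---------------------------------------------------------------------------
# regression cohort: measured Pi_c designed to be linear in category mixture
# ---------------------------------------------------------------------------

#: Designed per-category predictability levels: routine-bound categories
#: (Home/Work, Travel, Shops) high, leisure categories (Food, Entertainment,
#: Nightlife) low, mirroring how venue-revisit concentration differs by
#: activity type.
DEFAULT_BETA: dict[str, float] = {
    "Home/Work": 0.88,
    "Travel": 0.78,
    "Shops": 0.72,
    "Education": 0.62,
    "Outdoors": 0.58,
    "Entertainment": 0.50,
    "Food": 0.45,
    "Nightlife": 0.38,
}


def _run_lengths(n_total: int, n_runs: int) -> np.ndarray:
    """Deterministic run lengths summing exactly to ``n_total`` (Bresenham)."""
    edges = np.round(np.arange(n_runs + 1) * (n_total / n_runs)).astype(int)
    return np.maximum(np.diff(edges), 1)


def _run_sequence(
    rng: np.random.Generator, f: np.ndarray, n_total: int, m: int, n_runs: int
) -> tuple[np.ndarray, np.ndarray]:
    """Symbol codes (cat * m + venue) of a run-structured sequence.

    The sequence concatenates ``n_runs`` runs summing to exactly
    ``n_total`` symbols; each run repeats a freshly drawn (category, venue)
    pair, categories following the largest-remainder composition of ``f``
    in random order, venues uniform within category.  Returns
    (codes, category codes).
    """
    counts = _apportion(np.asarray(f, dtype=float), n_runs)
    cats = np.repeat(np.arange(len(counts)), counts)
    rng.shuffle(cats)
    venues = rng.integers(0, m, size=n_runs)
    codes = cats * m + venues
    lengths = _run_lengths(n_total, n_runs)
    seq = np.repeat(codes, lengths)
    seq_cats = np.repeat(cats, lengths)
    return seq, seq_cats


def _binary_entropy_arr(x: np.ndarray) -> np.ndarray:
    x = np.clip(np.asarray(x, dtype=float), 1e-12, 1 - 1e-12)
    return -x * np.log2(x) - (1 - x) * np.log2(1 - x)


def _measure_pi_c(seq_codes: np.ndarray) -> tuple[float, float, int]:
    s = len(set(seq_codes.tolist()))
    hc = lz_entropy_rate(seq_codes.tolist())
    return fano_predictability(hc, s, kind="correlated").Pi, hc, s


def _calibrate(
    rng: np.random.Generator,
    runs_grid: np.ndarray,
    m: int,
    n_total: int,
    n_cats: int,
    reps: int,
) -> tuple[np.ndarray, float]:
    """Empirical map n_runs -> E[measured Pi_c] at the uniform mixture.

    The sequence length is held at ``n_total`` for every grid point (the
    Lempel–Ziv estimator's bias depends on the sample size, so the
    calibration must vary only the revisit structure).  Returns the per-grid
    mean measured Pi_c (non-increasing in ``n_runs``), the mean measured
    entropy rate (non-decreasing), and the pooled within-grid variance of
    the Pi_c measurement.
    """
    f0 = np.full(n_cats, 1.0 / n_cats)
    pi_means = np.empty(runs_grid.size)
    h_means = np.empty(runs_grid.size)
    wvar = np.empty(runs_grid.size)
    for i, r in enumerate(runs_grid):
        vals = [
            _measure_pi_c(_run_sequence(rng, f0, n_total, m, int(r))[0]) for _ in range(reps)
        ]
        pi_means[i] = np.mean([v[0] for v in vals])
        h_means[i] = np.mean([v[1] for v in vals])
        wvar[i] = np.var([v[0] for v in vals], ddof=1)
    # fewer runs = longer revisit runs = more predictable, lower entropy rate
    pi_means = np.minimum.accumulate(pi_means)
    h_means = np.maximum.accumulate(h_means)
    return pi_means, h_means, float(np.mean(wvar))


def gen_regression_cohort(
    n_users: int = 2000,
    seed: int = 0,
    *,
    beta: Optional[dict[str, float]] = None,
    designed_r2: float = 0.42,
    n_checkins: int = 720,
    venues_per_category: int = 6,
    dirichlet_alpha: float = 2.0,
    calibration_points: int = 28,
    calibration_reps: int = 8,
) -> tuple[Dataset, GroundTruth]:
    """Cohort whose measured Pi_c is a designed linear function of category mix.

    Per user, a Dirichlet category mixture ``f`` is drawn and a target
    ``Pi* = sum_k beta_k f_k + eps`` set, with ``eps`` Gaussian and its
    variance chosen so the population R-squared equals ``designed_r2``
    (after subtracting the measurement variance of the Pi_c estimator,
    estimated during calibration).  The target is then realised by tuning
    the user's venue-revisit concentration — the number of revisit runs the
    fixed-length sequence is divided into — through a monotone calibration
    lookup built once per cohort.  Every sequence has exactly
    ``n_checkins`` symbols so the Lempel–Ziv small-sample bias is common to
    calibration and cohort.  The lookup is built at the uniform mixture and
    corrected per user for their own mixture entropy: the entropy rate of
    the run process is ``(H(f) + log2 m) * n_runs / N``, so
    ``n_runs_u = n_runs_cal * (H(f0) + log2 m) / (H(f_u) + log2 m)``.

    Sequences are laid on an hourly lattice; venues are global per
    (category, index) with fixed coordinates.  GroundTruth records beta,
    the noise level, the targets and the calibration table.
    """
    cats = list(WEEPLACES_CATEGORIES)
    k = len(cats)
    beta = dict(DEFAULT_BETA) if beta is None else dict(beta)
    bvec = np.array([beta[c] for c in cats])
    m = venues_per_category
    h_venue = math.log2(m)
    h_f0 = math.log2(k)

    rng = np.random.default_rng(seed)
    runs_grid = np.unique(
        np.round(np.geomspace(n_checkins // 40, n_checkins, calibration_points))
    ).astype(int)
    pi_cal, h_cal, meas_var = _calibrate(rng, runs_grid, m, n_checkins, k, calibration_reps)

    f = rng.dirichlet(np.full(k, dirichlet_alpha), size=n_users)
    lin = f @ bvec

    var_lin = float(np.var(lin))
    total_noise = var_lin * (1 - designed_r2) / designed_r2
    eps_sd = math.sqrt(max(total_noise - meas_var, 1e-8))
    eps = rng.normal(0, eps_sd, n_users)
    lo, hi = pi_cal[-1] + 0.01, pi_cal[0] - 0.005  # pi_cal decreases with n_runs
    targets = np.clip(lin + eps, lo, hi)
    n_clipped = int(((lin + eps) < lo).sum() + ((lin + eps) > hi).sum())

    # Invert the calibration per user.  The measured Pi_c depends on the
    # measured entropy rate and the realised alphabet size S, and S shrinks
    # when the mixture is concentrated; so the target Pi is first converted
    # to a target entropy rate through Fano's identity at the user's own
    # expected S, the (increasing) rate calibration is inverted in log
    # n_runs, and finally the run count is scaled so the user's process
    # entropy rate, (H(f) + log2 m) * n_runs / N, matches the calibrated one.
    with np.errstate(divide="ignore", invalid="ignore"):
        h_f = np.array([-np.sum(fi[fi > 0] * np.log2(fi[fi > 0])) for fi in f])
    runs_u = np.round(np.exp(np.interp(targets, pi_cal[::-1], np.log(runs_grid[::-1].astype(float))))).astype(int)
    for _ in range(2):  # expected S depends on the run count: iterate
        exp_s = np.array(
            [
                (m * (1 - (1 - 1 / m) ** _apportion(fi, int(r)))).sum()
                for fi, r in zip(f, np.maximum(runs_u, 8))
            ]
        )
        h_target = _binary_entropy_arr(targets) + (1 - targets) * np.log2(
            np.maximum(exp_s - 1, 1.001)
        )
        log_runs_cal = np.interp(h_target, h_cal, np.log(runs_grid.astype(float)))
        runs_u = np.clip(
            np.round(np.exp(log_runs_cal) * (h_f0 + h_venue) / (h_f + h_venue)),
            8,
            n_checkins,
        ).astype(int)

    # global venue geometry: one cluster per category around a city centre
    lat0, lon0 = 40.0, -75.0
    vdx = rng.normal(0, 5.0, (k, m))
    vdy = rng.normal(0, 5.0, (k, m))
    vlat, vlon = _km_offsets_to_latlon(lat0, lon0, vdx, vdy)
    vid = np.array([[f"c{i}_v{j}" for j in range(m)] for i in range(k)])

    frames = []
    truth_targets: dict[str, float] = {}
    for u in range(n_users):
        uid = f"r{u:05d}"
        seq, seq_cats = _run_sequence(rng, f[u], n_checkins, m, int(runs_u[u]))
        venue_idx = seq % m
        frames.append(
            pd.DataFrame(
                {
                    "user_id": uid,
                    "timestamp": _EPOCH + pd.to_timedelta(np.arange(seq.size), unit="h"),
                    "lat": vlat[seq_cats, venue_idx],
                    "lon": vlon[seq_cats, venue_idx],
                    "location_id": vid[seq_cats, venue_idx],
                    "category": np.array(cats)[seq_cats],
                }
            )
        )
        truth_targets[uid] = float(targets[u])

    df = pd.concat(frames, ignore_index=True)
    ds = dataset_from_frame(
        df, provenance={"source": "synthetic_regression_cohort", "seed": seed}
    )
    truth = GroundTruth(
        beta=beta,
        noise_sd=eps_sd,
        designed_r2=designed_r2,
        targets=truth_targets,
        calibration={
            "runs_grid": runs_grid.tolist(),
            "pi_mean": pi_cal.tolist(),
            "measurement_variance": meas_var,
            "n_clipped_targets": n_clipped,
        },
    )
    return ds, truth
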