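"""Wavelet decomposition of predictability time series.

Hour-of-week predictability profiles carry periodic structure — circadian
(~24 h), circasemidian (~12 h) and, weakly, ~6 h components.  This module
estimates those modes with a continuous Morlet wavelet transform:

* :func:`cwt_power` — the wavelet power ``|W(s, t)|^2`` on a geometric scale
  grid (12 sub-octaves per octave, periods from 2 h up to half the series
  length), computed in the Fourier domain with the standard normalisation
  so that unit-variance white noise has expected power 1 at every scale;
* :func:`global_spectrum` — the time-averaged power per period, excluding
  points inside the cone of influence where zero-padding edge effects
  dominate;
* :func:`rednoise_threshold` — a chi-square significance level against an
  AR(1) ("red noise") background fitted from the series' lag-1
  autocorrelation, with the reduced degrees of freedom appropriate for
  time-averaged wavelet power;
* :func:`dominant_mode` — per-user classification of the strongest spectral
  component into 24 h / 12 h / 6 h / other.

The input series is mean-removed and variance-normalised before the
transform, so power is in units of the series variance and the mode labels
are invariant to positive rescaling.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy.stats import chi2

from .io import Dataset, Trajectory
from .states import slot_predictability

logger = logging.getLogger(__name__)

__all__ = [
    "SpectrumResult",
    "ModeLabel",
    "cwt_power",
    "global_spectrum",
    "rednoise_threshold",
    "dominant_mode",
    "mode_shares",
    "profile_series",
]

OMEGA0 = 6.0
DJ = 1.0 / 12.0  # 12 sub-octaves per octave
MIN_PERIOD_H = 2.0
#: Fourier wavelength of a Morlet wavelet of scale 1 (omega0 = 6): ~1.033.
FOURIER_FACTOR = 4 * np.pi / (OMEGA0 + np.sqrt(2 + OMEGA0**2))
#: Decorrelation factor gamma for the Morlet degrees-of-freedom reduction.
GAMMA_MORLET = 2.32

NOMINAL_PERIODS_H = (24.0, 12.0, 6.0)
MODE_MAX_PERIOD_H = 42.0
MODE_REL_TOL = 0.20


@dataclass
class SpectrumResult:
    """Global wavelet power spectrum with optional significance threshold."""

    periods: np.ndarray  # hours, strictly increasing
    power: np.ndarray  # time-averaged |W|^2 per period, variance units
    threshold: Optional[np.ndarray] = None  # red-noise significance level
    alpha: Optional[float] = None
    coi_fraction: Optional[np.ndarray] = None  # fraction of times outside the COI

    @property
    def peak_period(self) -> float:
        return float(self.periods[int(np.argmax(self.power))])


@dataclass(frozen=True)
class ModeLabel:
    """Dominant spectral mode of one user's predictability profile."""

    user_id: str
    label: str  # "24h", "12h", "6h" or "other"
    peak_period: float
    peak_power: float


def _prepare(series: Sequence[float], max_missing_frac: float = 0.2) -> np.ndarray:
    x = np.asarray(series, dtype=float)
    if x.ndim != 1:
        raise ValueError("series must be one-dimensional")
    if len(x) < 48:
        raise ValueError(f"series too short for wavelet analysis ({len(x)} < 48 points)")
    missing = np.isnan(x)
    if missing.any():
        if missing.mean() > max_missing_frac:
            raise ValueError(
                f"{missing.mean():.0%} of the series is missing (limit {max_missing_frac:.0%})"
            )
        idx = np.arange(len(x))
        x = x.copy()
        x[missing] = np.interp(idx[missing], idx[~missing], x[~missing])
    return x


def cwt_power(
    series: Sequence[float],
    *,
    omega0: float = OMEGA0,
    dt: float = 1.0,
    max_period: Optional[float] = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Morlet continuous-wavelet power of an hourly series.

    Returns ``(periods, power, coi)`` where ``power[j, t] = |W(s_j, t)|^2``
    in units of the series variance, ``periods`` is the equivalent Fourier
    period (hours) of each scale, and ``coi[t]`` is the cone-of-influence
    period above which the power at time ``t`` is affected by edge padding.

    The series is mean-removed and variance-normalised; short internal gaps
    (NaN) are linearly interpolated, and series with more than 20% missing
    are rejected.
    """
    x = _prepare(series)
    n = len(x)
    sd = x.std()
    if sd > 0:
        x = (x - x.mean()) / sd
    else:
        x = x - x.mean()  # constant series -> all-zero power

    # zero-pad to the next power of two to limit wrap-around
    n_pad = int(2 ** np.ceil(np.log2(n)))
    xp = np.zeros(n_pad)
    xp[:n] = x
    xf = np.fft.fft(xp)
    omega = 2 * np.pi * np.fft.fftfreq(n_pad, d=dt)

    ff = 4 * np.pi / (omega0 + np.sqrt(2 + omega0**2))
    if max_period is None:
        max_period = n * dt / 2.0
    s0 = MIN_PERIOD_H / ff
    j_max = max(0, int(np.floor(np.log2((max_period / ff) / s0) / DJ)))
    scales = s0 * 2 ** (DJ * np.arange(j_max + 1))
    periods = scales * ff

    # Morlet daughter in the Fourier domain, analytic (positive freqs only)
    pos = omega > 0
    W = np.empty((len(scales), n), dtype=complex)
    norm_const = np.pi**-0.25
    for j, s in enumerate(scales):
        psi_hat = np.zeros(n_pad)
        psi_hat[pos] = (
            norm_const * np.sqrt(2 * np.pi * s / dt) * np.exp(-0.5 * (s * omega[pos] - omega0) ** 2)
        )
        W[j] = np.fft.ifft(xf * psi_hat)[:n]

    power = np.abs(W) ** 2
    # cone of influence: e-folding time sqrt(2)*s, expressed as a period
    t_edge = np.minimum(np.arange(n), np.arange(n)[::-1]) * dt
    coi = ff / np.sqrt(2.0) * np.maximum(t_edge, 1e-8)
    return periods, power, coi


def global_spectrum(
    series: Sequence[float],
    *,
    omega0: float = OMEGA0,
    dt: float = 1.0,
    max_period: Optional[float] = None,
    alpha: Optional[float] = None,
) -> SpectrumResult:
    """Time-averaged wavelet power per period, outside the cone of influence.

    For scales so large that every time point lies inside the cone of
    influence, the average falls back to all time points (these periods are
    edge-dominated; ``coi_fraction`` records the share of usable points per
    period).  If ``alpha`` is given, a red-noise significance threshold is
    attached (see :func:`rednoise_threshold`).
    """
    periods, power, coi = cwt_power(series, omega0=omega0, dt=dt, max_period=max_period)
    valid = periods[:, None] <= coi[None, :]
    n_valid = valid.sum(axis=1)
    sums = np.where(valid, power, 0.0).sum(axis=1)
    gp = np.where(n_valid > 0, sums / np.maximum(n_valid, 1), power.mean(axis=1))
    result = SpectrumResult(
        periods=periods,
        power=gp,
        coi_fraction=n_valid / power.shape[1],
    )
    if alpha is not None:
        result.threshold = rednoise_threshold(
            series, alpha=alpha, omega0=omega0, dt=dt, max_period=max_period
        )
        result.alpha = alpha
    return result


def _lag1_autocorr(x: np.ndarray) -> float:
    x = x - x.mean()
    denom = float(np.dot(x, x))
    if denom == 0:
        return 0.0
    return float(np.dot(x[:-1], x[1:]) / denom)


def rednoise_threshold(
    series: Sequence[float],
    alpha: float = 0.05,
    *,
    omega0: float = OMEGA0,
    dt: float = 1.0,
    max_period: Optional[float] = None,
) -> np.ndarray:
    """Red-noise significance level for the global wavelet spectrum.

    Fits an AR(1) background from the series' lag-1 autocorrelation ``a``;
    the background spectrum at period ``P`` is
    ``(1 - a^2) / (1 + a^2 - 2 a cos(2 pi dt / P))`` (variance units).  The
    time-averaged power of such noise follows a scaled chi-square whose
    degrees of freedom grow with the number of independent wavelet samples
    in the average, ``nu = 2 sqrt(1 + (n_a dt / (gamma s))^2)``; the
    threshold is ``background * chi2_{1 - alpha, nu} / nu``.
    """
    x = _prepare(series)
    a = _lag1_autocorr(x)
    if a >= 1.0:
        raise ValueError("degenerate series: lag-1 autocorrelation >= 1")
    a = max(a, 0.0)  # negative lag-1 -> treat as white

    periods, power, coi = cwt_power(series, omega0=omega0, dt=dt, max_period=max_period)
    n = power.shape[1]
    scales = periods / FOURIER_FACTOR
    background = (1 - a**2) / (1 + a**2 - 2 * a * np.cos(2 * np.pi * dt / periods))

    valid = periods[:, None] <= coi[None, :]
    n_avg = np.maximum(valid.sum(axis=1), 1)
    dof = 2 * np.sqrt(1 + (n_avg * dt / (GAMMA_MORLET * scales)) ** 2)
    return background * chi2.ppf(1 - alpha, dof) / dof


def profile_series(
    trajectory: Trajectory, *, max_gap_h: int = 3, week_start: str = "monday"
) -> Optional[np.ndarray]:
    """168-point hour-of-week Pi_u series of one user, gap-filled.

    Runs of missing slots no longer than ``max_gap_h`` hours are linearly
    interpolated (circularly across the week boundary); users with longer
    gaps or an entirely missing profile return ``None``.
    """
    prof = slot_predictability(trajectory, week_start=week_start)
    missing = np.isnan(prof)
    if not missing.any():
        return prof
    if missing.all():
        return None
    # longest circular run of missing slots
    m2 = np.concatenate([missing, missing])
    run, longest = 0, 0
    for flag in m2:
        run = run + 1 if flag else 0
        longest = max(longest, run)
    if longest > min(max_gap_h, len(prof) - 1):
        return None
    idx = np.arange(len(prof))
    good = idx[~missing]
    filled = prof.copy()
    filled[missing] = np.interp(idx[missing], good, prof[good], period=len(prof))
    return filled


def dominant_mode(
    user_series: Sequence[float],
    user_id: str = "",
    *,
    max_period: float = MODE_MAX_PERIOD_H,
    rel_tol: float = MODE_REL_TOL,
) -> ModeLabel:
    """Classify the strongest spectral component of a user series.

    The global-spectrum maximum is located over periods up to ``max_period``
    hours; the user is labelled "24h", "12h" or "6h" when the peak lies
    within ``rel_tol`` (default 20%) of the nominal period, else "other".
    """
    spec = global_spectrum(user_series, max_period=max_period)
    mask = spec.periods <= max_period
    powers = spec.power[mask]
    periods = spec.periods[mask]
    k = int(np.argmax(powers))
    peak_period = float(periods[k])
    label = "other"
    for nominal in NOMINAL_PERIODS_H:
        if abs(peak_period - nominal) <= rel_tol * nominal:
            label = f"{int(nominal)}h"
            break
    return ModeLabel(
        user_id=user_id, label=label, peak_period=peak_period, peak_power=float(powers[k])
    )


def mode_shares(
    dataset: Dataset, *, max_gap_h: int = 3, week_start: str = "monday"
) -> tuple[dict[str, float], list[ModeLabel]]:
    """Fraction of users per dominant-mode label, with per-user labels.

    Users whose hour-of-week profile cannot be constructed (too sparse) are
    skipped with a logged reason and excluded from the shares, which sum
    to 1 over the labelled users.
    """
    labels: list[ModeLabel] = []
    for uid, traj in dataset.trajectories.items():
        series = profile_series(traj, max_gap_h=max_gap_h, week_start=week_start)
        if series is None:
            logger.info("user %s skipped: hour-of-week profile too sparse", uid)
            continue
        labels.append(dominant_mode(series, user_id=uid))
    if not labels:
        raise ValueError("no user had sufficient slot coverage")
    shares: dict[str, float] = {}
    for lab in labels:
        shares[lab.label] = shares.get(lab.label, 0.0) + 1.0
    total = sum(shares.values())
    return {k: v / total for k, v in sorted(shares.items())}, labels
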