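"""Location-context predictability and the category-frequency linear model.

Venues carry coarse category tags (Home/Work, Food, Nightlife, ...).  Two
analyses use them:

* *category-restricted predictability*: a user's trajectory is filtered to
  one category and scored with the same entropy pipeline as the full
  trajectory, giving per-category distributions of Pi_u and Pi_c to compare
  against the whole-trajectory baseline;
* the *context model*: ordinary least squares of the whole-trajectory
  correlated predictability Pi_c on the user's relative category visit
  frequencies.  The frequencies sum to one, so one reference category is
  dropped and an intercept included — predictions are invariant to which
  category is dropped.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .entropy import sequence_predictability
from .io import WEEPLACES_CATEGORIES, Dataset, Trajectory

__all__ = [
    "CategoryFrequencies",
    "ContextModel",
    "filter_by_category",
    "category_frequencies",
    "category_predictability",
    "fit_context_model",
    "residual_diagnostics",
]


@dataclass(frozen=True)
class CategoryFrequencies:
    """Relative visit frequency per category for one user.

    ``frequencies`` sums to 1 over the categorised check-ins; ``coverage``
    is the fraction of the user's check-ins that carry a category at all.
    """

    user_id: str
    frequencies: dict[str, float]
    coverage: float


@dataclass
class ContextModel:
    """Fitted linear model of Pi_c on category visit frequencies."""

    categories: list[str]
    reference: str
    coefficients: dict[str, float]  # per non-reference category (contrasts)
    intercept: float
    std_errors: dict[str, float]
    r_squared: float
    fitted: pd.Series  # predicted Pi_c per user_id
    residuals: pd.Series
    n: int
    _sm_result: object = field(default=None, repr=False)

    def predict(self, frequencies: dict[str, float]) -> float:
        """Predicted Pi_c for a category-frequency vector (sums to 1)."""
        return self.intercept + sum(
            self.coefficients[c] * frequencies.get(c, 0.0) for c in self.coefficients
        )


def filter_by_category(trajectory: Trajectory, category: str) -> Trajectory:
    """Order-preserving sub-trajectory of check-ins in one category.

    Unknown category names raise with the list of valid categories; a known
    category that the user never visits yields an empty sub-trajectory.
    """
    present = sorted({c for c in trajectory.df["category"].dropna().unique()})
    valid = set(present) | set(WEEPLACES_CATEGORIES)
    if category not in valid:
        raise ValueError(f"unknown category {category!r}; valid categories: {sorted(valid)}")
    sub = trajectory.df[trajectory.df["category"] == category].reset_index(drop=True)
    return Trajectory(user_id=trajectory.user_id, df=sub)


def category_frequencies(
    trajectory: Trajectory, categories: Sequence[str] = WEEPLACES_CATEGORIES
) -> Optional[CategoryFrequencies]:
    """Relative category visit frequencies of one user (None if uncategorised)."""
    cats = trajectory.df["category"]
    counted = cats.dropna()
    if len(counted) == 0:
        return None
    counts = counted.value_counts()
    total = counts.sum()
    freqs = {c: float(counts.get(c, 0)) / total for c in categories}
    return CategoryFrequencies(
        user_id=trajectory.user_id,
        frequencies=freqs,
        coverage=len(counted) / len(cats),
    )


def category_predictability(
    dataset: Dataset,
    categories: Sequence[str] = WEEPLACES_CATEGORIES,
    *,
    min_length: int = 10,
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Per-user Pi_u / Pi_c on category-restricted and full trajectories.

    Returns a tidy frame with columns (user_id, category, N, S, Pi_u, Pi_c)
    where category "baseline" scores the full trajectory, plus a count of
    users excluded per category for having fewer than ``min_length``
    check-ins in it.
    """
    rows = []
    excluded: dict[str, int] = {c: 0 for c in categories}
    for uid, traj in dataset.trajectories.items():
        res, pi_u, pi_c = sequence_predictability(traj.symbols())
        rows.append(
            {
                "user_id": uid,
                "category": "baseline",
                "N": res.N,
                "S": res.S,
                "Pi_u": pi_u.Pi,
                "Pi_c": pi_c.Pi if pi_c else np.nan,
            }
        )
        for cat in categories:
            sub = traj.df[traj.df["category"] == cat]
            if len(sub) < min_length:
                excluded[cat] += 1
                continue
            res, pi_u, pi_c = sequence_predictability(list(sub["location_id"]))
            rows.append(
                {
                    "user_id": uid,
                    "category": cat,
                    "N": res.N,
                    "S": res.S,
                    "Pi_u": pi_u.Pi,
                    "Pi_c": pi_c.Pi if pi_c else np.nan,
                }
            )
    return pd.DataFrame(rows), excluded


def fit_context_model(
    dataset: Dataset,
    categories: Sequence[str] = WEEPLACES_CATEGORIES,
    *,
    reference: Optional[str] = None,
    target: Optional[pd.Series] = None,
) -> ContextModel:
    """OLS of whole-trajectory Pi_c on relative category visit frequencies.

    One reference category (default: the first) is dropped because the
    frequencies sum to one; an intercept is included.  ``target`` may
    supply precomputed per-user Pi_c values (indexed by user id) to avoid
    rescoring.  Raises if the design is rank-deficient, naming the
    collinear columns.
    """
    categories = list(categories)
    reference = reference or categories[0]
    if reference not in categories:
        raise ValueError(f"reference {reference!r} not in categories")

    records = []
    for uid, traj in dataset.trajectories.items():
        cf = category_frequencies(traj, categories)
        if cf is None:
            continue
        if target is not None:
            if uid not in target.index or np.isnan(target.loc[uid]):
                continue
            pi_c_val = float(target.loc[uid])
        else:
            res, _, pi_c = sequence_predictability(traj.symbols())
            if pi_c is None:
                continue
            pi_c_val = pi_c.Pi
        records.append({"user_id": uid, "Pi_c": pi_c_val, **cf.frequencies})
    frame = pd.DataFrame(records)
    regressors = [c for c in categories if c != reference]
    if len(frame) < len(regressors) + 2:
        raise ValueError(
            f"need at least {len(regressors) + 2} users with categories and Pi_c, "
            f"got {len(frame)}"
        )
    frame = frame.set_index("user_id")
    X = sm.add_constant(frame[regressors])
    rank = np.linalg.matrix_rank(X.to_numpy())
    if rank < X.shape[1]:
        corr = frame[regressors].corr().abs()
        np.fill_diagonal(corr.values, 0)
        worst = corr.stack().idxmax()
        raise ValueError(
            f"rank-deficient design (rank {rank} < {X.shape[1]}); "
            f"most collinear columns: {worst}"
        )
    fit = sm.OLS(frame["Pi_c"], X).fit()
    return ContextModel(
        categories=categories,
        reference=reference,
        coefficients={c: float(fit.params[c]) for c in regressors},
        intercept=float(fit.params["const"]),
        std_errors={c: float(fit.bse[c]) for c in regressors},
        r_squared=float(fit.rsquared),
        fitted=pd.Series(fit.fittedvalues, index=frame.index, name="Pi_c_hat"),
        residuals=pd.Series(fit.resid, index=frame.index, name="residual"),
        n=len(frame),
        _sm_result=fit,
    )


def residual_diagnostics(model: ContextModel) -> dict[str, float]:
    """Moment and normality summary of the model residuals.

    Reports mean, standard deviation, skewness, excess kurtosis and the
    D'Agostino–Pearson normality statistic with its p-value.
    """
    r = model.residuals.to_numpy()
    stat, pval = stats.normaltest(r)
    return {
        "mean": float(r.mean()),
        "sd": float(r.std(ddof=1)),
        "skewness": float(stats.skew(r)),
        "excess_kurtosis": float(stats.kurtosis(r)),
        "normality_stat": float(stat),
        "normality_pvalue": float(pval),
    }
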