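"""Shared fixtures: small synthetic cohorts and the brute-force LZ oracle."""

import numpy as np
import pytest

from mobstates.synthetic import CohortSpec, gen_cohort


def brute_lambda(sequence):
    """Brute-force shortest-unseen-substring lengths.

    Enumerates, for each 1-based position i, all substrings of the history
    (positions 1..i-1) to find the shortest substring starting at i not
    contained in it; saturates at (N - i + 1) + 1 when every substring to
    the sequence end has been seen.  Reference oracle only: quadratic-to-
    cubic cost.
    """
    s = list(sequence)
    n = len(s)
    out = []
    for i in range(n):
        hist = s[:i]

        def contains(sub):
            L = len(sub)
            return any(hist[j : j + L] == sub for j in range(len(hist) - L + 1))

        lam = None
        for k in range(1, n - i + 1):
            if not contains(s[i : i + k]):
                lam = k
                break
        out.append(lam if lam is not None else (n - i) + 1)
    return out


@pytest.fixture(scope="session")
def small_cohort():
    """30 schedule-driven users, 16 weeks, defaults (24 h-dominant)."""
    ds, truth = gen_cohort(CohortSpec(n_users=30, weeks=16, seed=1))
    return ds, truth


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240901)
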