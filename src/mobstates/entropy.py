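"""Entropy and predictability of symbolic visitation sequences.

Two entropy measures are computed for a user's location sequence:

* the *uncorrelated* entropy ``H_u`` — the Shannon entropy of the empirical
  visitation frequencies, which ignores the order of visits; and
* the *entropy rate* ``H_c`` — a nonparametric Lempel–Ziv-type estimate of the
  per-symbol uncertainty that accounts for temporal order, built from the
  lengths of the shortest substrings not previously seen.

Either entropy is converted to a *predictability* bound ``Pi`` by inverting
Fano's inequality: ``Pi`` is the maximum success rate any next-location
predictor can achieve given the measured entropy and the number of distinct
locations ``S``.

All logarithms are base 2; entropies are in bits.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Hashable, Optional, Sequence

import numpy as np
from scipy.optimize import brentq

__all__ = [
    "EntropyResult",
    "PredictabilityBound",
    "shannon_entropy",
    "lambda_lengths",
    "lz_entropy_rate",
    "fano_predictability",
    "sequence_predictability",
]


@dataclass(frozen=True)
class EntropyResult:
    """Entropy summary of one symbol sequence.

    Attributes
    ----------
    H_u : float
        Uncorrelated (Shannon) entropy in bits, or NaN if not computed.
    H_c : float
        Lempel–Ziv entropy rate in bits per symbol, or NaN if not computed.
    S : int
        Number of distinct symbols in the sequence.
    N : int
        Sequence length (number of recorded moves).
    lambdas : numpy array or None
        The shortest-unseen-substring lengths, kept for audit when requested.
    """

    H_u: float
    H_c: float
    S: int
    N: int
    lambdas: Optional[np.ndarray] = None


@dataclass(frozen=True)
class PredictabilityBound:
    """Fano upper bound on next-symbol prediction accuracy."""

    Pi: float
    kind: str  # "uncorrelated" or "correlated"
    S: int
    H: float


def shannon_entropy(sequence: Sequence[Hashable]) -> EntropyResult:
    """Shannon entropy of the empirical symbol frequencies, in bits.

    ``H_u = -sum_x p(x) log2 p(x)`` with ``p(x)`` the fraction of visits to
    location ``x``; the convention ``0 log 0 = 0`` applies. Temporal order is
    ignored.
    """
    counts = Counter(sequence)
    n = sum(counts.values())
    if n == 0:
        raise ValueError("cannot compute entropy of an empty sequence")
    p = np.array(list(counts.values()), dtype=float) / n
    h = float(-(p * np.log2(p)).sum())
    # guard against -0.0 from a single-symbol sequence
    return EntropyResult(H_u=max(h, 0.0), H_c=float("nan"), S=len(counts), N=n)


class _SuffixAutomaton:
    """Incremental suffix automaton over integer symbols.

    Supports extending by one symbol and querying the longest prefix of a
    pattern that occurs as a substring of the text added so far.  Linear in
    the text length; queries cost one transition per matched symbol.
    """

    __slots__ = ("next", "link", "length", "last")

    def __init__(self) -> None:
        self.next: list[dict[int, int]] = [{}]
        self.link: list[int] = [-1]
        self.length: list[int] = [0]
        self.last = 0

    def extend(self, c: int) -> None:
        nxt, link, length = self.next, self.link, self.length
        cur = len(nxt)
        nxt.append({})
        length.append(length[self.last] + 1)
        link.append(-1)
        p = self.last
        while p != -1 and c not in nxt[p]:
            nxt[p][c] = cur
            p = link[p]
        if p == -1:
            link[cur] = 0
        else:
            q = nxt[p][c]
            if length[p] + 1 == length[q]:
                link[cur] = q
            else:
                clone = len(nxt)
                nxt.append(dict(nxt[q]))
                length.append(length[p] + 1)
                link.append(link[q])
                while p != -1 and nxt[p].get(c) == q:
                    nxt[p][c] = clone
                    p = link[p]
                link[q] = clone
                link[cur] = clone
        self.last = cur


def lambda_lengths(sequence: Sequence[Hashable]) -> np.ndarray:
    """Shortest-unseen-substring lengths ``Lambda_i`` for each position.

    For 1-based position ``i``, ``Lambda_i`` is the length of the shortest
    substring starting at ``i`` that does not occur as a contiguous substring
    anywhere within positions ``1..i-1`` (the growing history).  If every
    substring from ``i`` to the end of the sequence occurs in the history,
    the value saturates at ``(N - i + 1) + 1``.  ``Lambda_1 = 1``.

    Implemented with an incremental suffix automaton so that the total cost
    is the sum of match lengths (near-linear for typical sequences), rather
    than the cubic cost of naive substring scanning.
    """
    seq = list(sequence)
    n = len(seq)
    if n == 0:
        raise ValueError("empty sequence")
    codes: dict[Hashable, int] = {}
    s = [codes.setdefault(x, len(codes)) for x in seq]

    sa = _SuffixAutomaton()
    lam = np.empty(n, dtype=np.int64)
    for j in range(n):
        # longest prefix of s[j:] occurring inside the history s[:j]
        state = 0
        matched = 0
        trans = sa.next
        for k in range(j, n):
            nxt = trans[state].get(s[k])
            if nxt is None:
                break
            state = nxt
            matched += 1
        lam[j] = matched + 1  # saturates naturally at (n - j) + 1
        sa.extend(s[j])
    return lam


def lz_entropy_rate(
    sequence: Sequence[Hashable], *, return_lambdas: bool = False
) -> float | tuple[float, np.ndarray]:
    """Lempel–Ziv estimate of the entropy rate, in bits per symbol.

    ``H_c = N log2(N) / sum_i Lambda_i`` where ``N`` is the number of moves.
    For a sequence of all-distinct symbols every ``Lambda_i`` is 1 and the
    estimate equals ``log2 N``; structure (repetition) inflates the match
    lengths and drives the estimate toward zero.
    """
    n = len(sequence)
    if n < 2:
        raise ValueError("entropy rate needs at least 2 observations")
    lam = lambda_lengths(sequence)
    h = n * np.log2(n) / float(lam.sum())
    if return_lambdas:
        return float(h), lam
    return float(h)


def _binary_entropy(x: np.ndarray | float) -> np.ndarray | float:
    x = np.asarray(x, dtype=float)
    out = np.zeros_like(x)
    inner = (x > 0) & (x < 1)
    xi = x[inner]
    out[inner] = -xi * np.log2(xi) - (1 - xi) * np.log2(1 - xi)
    return out if out.ndim else float(out)


def fano_predictability(H: float, S: int, *, kind: str = "uncorrelated") -> PredictabilityBound:
    """Invert Fano's inequality for the maximum predictability ``Pi``.

    Solves ``H = B(Pi) + (1 - Pi) log2(S - 1)`` for the unique root on the
    decreasing branch ``Pi in [1/S, 1]``, where ``B`` is the binary entropy
    function.  Degenerate cases: a single distinct location (``S = 1``) or
    zero entropy give ``Pi = 1``; an entropy at or above ``log2 S`` (no
    structure at all) clamps to the uniform guess rate ``Pi = 1/S``.
    """
    if S < 1:
        raise ValueError("S must be >= 1")
    if not np.isfinite(H) or H < 0:
        raise ValueError(f"entropy must be finite and non-negative, got {H!r}")
    if S == 1 or H == 0:
        return PredictabilityBound(Pi=1.0, kind=kind, S=S, H=H)
    log2s = np.log2(S)
    if H >= log2s:
        return PredictabilityBound(Pi=1.0 / S, kind=kind, S=S, H=H)
    log_sm1 = np.log2(S - 1)

    def f(pi: float) -> float:
        return float(_binary_entropy(pi) + (1.0 - pi) * log_sm1 - H)

    # f(1/S) = log2(S) - H > 0 and f(1) = -H < 0: bracketed root.
    pi = brentq(f, 1.0 / S, 1.0, xtol=1e-14, rtol=8.9e-16)
    return PredictabilityBound(Pi=float(pi), kind=kind, S=S, H=H)


def sequence_predictability(
    sequence: Sequence[Hashable], *, correlated: bool = True
) -> tuple[EntropyResult, PredictabilityBound, Optional[PredictabilityBound]]:
    """Full entropy/predictability summary of one sequence.

    Returns the entropy result together with the uncorrelated bound ``Pi_u``
    and, when ``correlated`` and the sequence has at least two moves, the
    correlated bound ``Pi_c`` from the entropy rate.  ``S`` is always the
    number of distinct symbols in the exact sequence being scored.
    """
    res = shannon_entropy(sequence)
    pi_u = fano_predictability(res.H_u, res.S, kind="uncorrelated")
    pi_c = None
    if correlated and res.N >= 2:
        hc, lam = lz_entropy_rate(sequence, return_lambdas=True)
        res = EntropyResult(H_u=res.H_u, H_c=hc, S=res.S, N=res.N, lambdas=lam)
        pi_c = fano_predictability(hc, res.S, kind="correlated")
    return res, pi_u, pi_c
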