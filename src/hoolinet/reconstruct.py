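"""Recover integer per-match incident counts from printed (mean, SD) pairs.

Published incident tables report only the mean and sample standard deviation
of each pair's per-match counts.  Because counts are small non-negative
integers, an exhaustive search over sample sizes and non-decreasing integer
vectors usually pins down the underlying sample — often uniquely — which
makes the printed rows fully re-testable.

Matching conventions: a printed value constrains the true value either
exactly (``mode="exact"``), to round-half-away-from-zero at its printed
decimals (``mode="round"``), or to truncation at its printed decimals
(``mode="trunc"``; some published tables truncate rather than round).
"""

from __future__ import annotations

from dataclasses import dataclass
from math import ceil, floor, isqrt, sqrt
from typing import Iterator, Literal

MatchMode = Literal["exact", "round", "trunc"]


@dataclass(frozen=True)
class ReconstructionResult:
    """Outcome of the search at the minimal admissible sample size."""

    found: bool
    counts: tuple[int, ...]  # canonical (lexicographically smallest) solution
    n: int
    achieved_mean: float
    achieved_sd: float
    unique_at_n: bool
    solutions: tuple[tuple[int, ...], ...]  # all solutions at minimal n

    @classmethod
    def unreconstructable(cls) -> "ReconstructionResult":
        return cls(False, (), 0, float("nan"), float("nan"), False, ())


def _interval(value: float, digits: int | None, mode: MatchMode) -> tuple[float, float]:
    """Half-open interval [lo, hi) of true values matching a printed one."""
    if mode == "exact" or digits is None:
        eps = 1e-9
        return value - eps, value + eps
    step = 10.0**-digits
    if mode == "round":
        # round-half-away-from-zero for non-negative values
        return value - step / 2, value + step / 2
    if mode == "trunc":
        return value, value + step
    raise ValueError(f"unknown match mode {mode!r}")


def _vectors(
    k: int, s: int, q: int, min_val: int, count_max: int
) -> Iterator[tuple[int, ...]]:
    """Non-decreasing integer vectors of length k, sum s, sum of squares q."""
    if k == 0:
        if s == 0 and q == 0:
            yield ()
        return
    # pruning bounds: remaining sum and sum of squares must stay feasible
    if s < min_val * k or s > count_max * k:
        return
    if q < s * s / k - 1e-9 or q < s or q > s * count_max:
        return
    hi = min(count_max, s, isqrt(q) if q >= 0 else 0)
    for v in range(min_val, hi + 1):
        for rest in _vectors(k - 1, s - v, q - v * v, v, count_max):
            yield (v,) + rest


def reconstruct_counts(
    printed_mean: float,
    printed_sd: float,
    mean_digits: int | None = None,
    sd_digits: int | None = 6,
    mean_mode: MatchMode = "round",
    sd_mode: MatchMode = "round",
    n_max: int = 40,
    count_max: int = 40,
) -> ReconstructionResult:
    """Exhaustively search for the smallest integer sample matching a row.

    For each candidate sample size n (from 2, where a sample SD first
    exists, up to ``n_max``), the printed mean constrains the integer sum S
    to a short interval and the printed SD then constrains the integer sum
    of squares Q; a backtracking enumeration checks whether a non-decreasing
    vector with entries in [0, ``count_max``] realises (n, S, Q).  The first
    n with any solution is returned with all solutions at that n and the
    lexicographically smallest as canonical (only (n, mean, sd) matter
    downstream, so the choice among ties is immaterial).

    ``mean_digits``/``sd_digits`` are the printed decimal counts; with
    ``mean_mode="exact"`` the printed mean is treated as the true value
    (appropriate when a table prints "1" or "2.75" for an exact mean).
    """
    if printed_sd < 0:
        raise ValueError("printed_sd must be >= 0")
    if n_max < 2:
        raise ValueError("n_max must be >= 2")
    if count_max < 1:
        raise ValueError("count_max must be >= 1")
    m_lo, m_hi = _interval(printed_mean, mean_digits, mean_mode)
    sd_lo, sd_hi = _interval(printed_sd, sd_digits, sd_mode)
    sd_lo = max(sd_lo, 0.0)
    for n in range(2, n_max + 1):
        solutions: list[tuple[int, ...]] = []
        # S/n in [m_lo, m_hi)
        s_min = max(0, ceil(m_lo * n - 1e-12))
        s_max = floor(m_hi * n - 1e-12)
        for s in range(s_min, s_max + 1):
            if not (m_lo - 1e-12 <= s / n < m_hi):
                continue
            q_lo = (n - 1) * sd_lo**2 + s * s / n
            q_hi = (n - 1) * sd_hi**2 + s * s / n
            for q in range(ceil(q_lo - 1e-9), floor(q_hi + 1e-9) + 1):
                var = (q - s * s / n) / (n - 1)
                if var < -1e-12:
                    continue
                sd = sqrt(max(var, 0.0))
                if not (sd_lo - 1e-12 <= sd < sd_hi):
                    continue
                solutions.extend(_vectors(n, s, q, 0, count_max))
        if solutions:
            solutions = sorted(set(solutions))
            canonical = solutions[0]
            mean = sum(canonical) / n
            var = (
                sum(x * x for x in canonical) - sum(canonical) ** 2 / n
            ) / (n - 1)
            return ReconstructionResult(
                found=True,
                counts=canonical,
                n=n,
                achieved_mean=mean,
                achieved_sd=sqrt(max(var, 0.0)),
                unique_at_n=len(solutions) == 1,
                solutions=tuple(solutions),
            )
    return ReconstructionResult.unreconstructable()
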