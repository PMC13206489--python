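"""Poisson false-positive accounting for multi-comparison database searches.

A search performs T pairwise comparisons (T = N_profiles for a stain search,
N(N−1)/2 for a full database self-comparison).  With a per-comparison
false-positive rate α the number of false positives X is, for small α, well
approximated by a Poisson distribution with mean μ = α·T.  A laboratory can
therefore specify its risk either directly as μ, or as an upper bound U on
the false-positive count together with a confidence β that the bound holds;
the two are linked through the Poisson CDF F(U; μ) = Σ_{k≤U} e^{−μ} μ^k/k!,
which is inverted for μ when (U, β) is given.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal, Optional

from scipy.optimize import brentq
from scipy.special import gammaincc

SearchMode = Literal["stain", "db"]


def comparisons_count(n_profiles: int, mode: SearchMode) -> int:
    """Pairwise comparisons in one search: N for stain mode, N(N−1)/2 for db."""
    if n_profiles < 1:
        raise ValueError("n_profiles must be at least 1")
    if mode == "stain":
        return n_profiles
    if mode == "db":
        t = n_profiles * (n_profiles - 1) // 2
        if t < 1:
            raise ValueError(
                "a database-to-database search needs at least 2 profiles"
            )
        return t
    raise ValueError(f"unknown search mode {mode!r}")


def poisson_cdf(u: int, mu: float) -> float:
    """P(X ≤ u) for X ~ Poisson(mu).

    Evaluated through the regularised upper incomplete gamma function,
    which stays accurate for means far beyond what naive term-by-term
    summation of e^{−μ} μ^k / k! can handle.
    """
    if u < 0:
        return 0.0
    if mu < 0:
        raise ValueError("mu must be nonnegative")
    if mu == 0:
        return 1.0
    return float(gammaincc(u + 1, mu))


def upper_bound(mu: float, beta: float) -> int:
    """Smallest integer U with P(X ≤ U) ≥ β for X ~ Poisson(mu)."""
    if not 0.0 < beta < 1.0:
        raise ValueError("beta must be in (0, 1)")
    if mu < 0:
        raise ValueError("mu must be nonnegative")
    if mu == 0:
        return 0
    lo, hi = 0, max(1, int(mu))
    while poisson_cdf(hi, mu) < beta:
        lo, hi = hi + 1, hi * 2
    while lo < hi:
        mid = (lo + hi) // 2
        if poisson_cdf(mid, mu) >= beta:
            hi = mid
        else:
            lo = mid + 1
    return lo


def lower_bound(mu: float, gamma: float) -> int:
    """Largest integer L with P(X < L) ≤ gamma; 0 when no positive L works."""
    if not 0.0 < gamma < 1.0:
        raise ValueError("gamma must be in (0, 1)")
    l = 0
    while poisson_cdf(l, mu) <= gamma:
        l += 1
    return l


def poisson_band(mu: float, level: float = 0.95) -> tuple[int, int]:
    """Two-sided Poisson interval [L, U] holding at least ``level`` mass.

    Equal-tailed convention: L is the largest integer with
    P(X < L) ≤ (1−level)/2 and U the smallest with P(X ≤ U) ≥ 1−(1−level)/2.
    """
    tail = (1.0 - level) / 2.0
    return lower_bound(mu, tail), upper_bound(mu, 1.0 - tail)


def mu_from_upper_bound(u: int, beta: float) -> float:
    """Invert β = F(U; μ) for μ: the expected count whose Poisson CDF at U is β.

    F(U; ·) is continuous and strictly decreasing in μ, so the root is found
    by bracketed bisection (Brent) on a generous interval.
    """
    if u < 0:
        raise ValueError("U must be nonnegative")
    if not 0.0 < beta < 1.0:
        raise ValueError("beta must be in (0, 1)")
    if u == 0:
        return -math.log(beta)
    hi = u + 20.0 * math.sqrt(u + 1.0) + 20.0
    return float(brentq(lambda m: poisson_cdf(u, m) - beta, 0.0, hi, xtol=1e-12))


def per_comparison_alpha(mu: float, t: int) -> float:
    """Per-comparison false-positive rate α = μ / T."""
    if t < 1:
        raise ValueError("comparison count T must be at least 1")
    if mu < 0:
        raise ValueError("mu must be nonnegative")
    return mu / t


def prob_at_least_one(mu: float) -> float:
    """P(X ≥ 1) = 1 − e^{−μ}: the chance a search yields any false positive."""
    if mu < 0:
        raise ValueError("mu must be nonnegative")
    return -math.expm1(-mu)


@dataclass(frozen=True)
class RiskSpec:
    """A laboratory's risk specification for one search.

    Either ``mu`` (expected false positives) or the pair ``(u, beta)``
    (upper bound at confidence) must be given.  :meth:`resolve` turns the
    spec into the comparison count T, the working μ and the per-comparison
    rate α for a database of ``n_profiles``.
    """

    mode: SearchMode
    n_profiles: int
    mu: Optional[float] = None
    u: Optional[int] = None
    beta: Optional[float] = None

    def __post_init__(self) -> None:
        if self.mu is None and (self.u is None or self.beta is None):
            raise ValueError("specify either mu or both u and beta")
        if self.mu is not None and self.u is not None:
            raise ValueError("specify mu or (u, beta), not both")

    @property
    def t(self) -> int:
        return comparisons_count(self.n_profiles, self.mode)

    def resolve(self) -> "ResolvedRisk":
        mu = self.mu
        if mu is None:
            mu = mu_from_upper_bound(self.u, self.beta)
        t = self.t
        return ResolvedRisk(t=t, mu=mu, alpha=per_comparison_alpha(mu, t))


@dataclass(frozen=True)
class ResolvedRisk:
    t: int
    mu: float
    alpha: float
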