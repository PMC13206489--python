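"""Discretised log10LR probability mass functions and their convolution.

The chance that two unrelated people share a genotype g at one locus is
P(g|g,H0)·P(g); summing that mass at the genotype's log10LR places a
*sub*-probability mass function on a uniform grid of bin width Δ (index n
stands for log10LR = n·Δ).  The total mass is the per-locus probability of
any exact genotype match, so it is below one.  For a set of loci M, the PMF
of the total log10LR of a fully matching pair is the convolution of the
single-locus PMFs, computed here by FFT (forward transforms, point-wise
product, inverse transform) with a direct-summation implementation kept as
an independent oracle.  Tail sums of the multi-locus PMF convert a log10LR
threshold into a per-comparison false-positive rate α and back.

Defaults are Δ = 0.001 and an array length of 2^16 = 65,536 bins, enough
head-room for a 24-locus total log10LR near 40 without circular-convolution
aliasing.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import scipy.fft

from .bn_model import (
    Genotype,
    ThetaModel,
    conditional_match_probability,
    genotype_probability,
    locus_genotype_arrays,
)
from .frequencies import AlleleFrequencyTable

DEFAULT_DELTA = 0.001
DEFAULT_LENGTH = 2**16

#: FFT round-off below this magnitude is clamped to zero; anything more
#: negative indicates a real inconsistency and raises.
_NEGATIVE_MASS_TOL = 1e-12


class GridError(ValueError):
    """PMFs on incompatible (Δ, length) grids were combined."""


class AliasingError(ValueError):
    """The log10LR support does not fit the grid (circular wrap-around)."""


def bin_index(x, delta: float = DEFAULT_DELTA):
    """Map log10LR values to grid bins: round-half-away-from-zero of x/Δ.

    A 1e-12 pre-snap absorbs float noise so values that are analytically on
    a bin centre land there on every platform.  Only nonnegative x occur
    here (LRE ≥ 1).
    """
    t = np.asarray(x, dtype=float) / delta
    n = np.floor(t + 0.5 + 1e-12).astype(np.int64)
    if n.ndim == 0:
        return int(n)
    return n


@dataclass(frozen=True)
class DiscretePMF:
    """Sub-probability mass on a uniform log10LR grid.

    ``mass[n]`` is the probability that a fully matching unrelated pair
    attains total log10LR = n·Δ over the loci in ``loci``.
    """

    delta: float
    mass: np.ndarray
    loci: frozenset[str]

    def __post_init__(self) -> None:
        object.__setattr__(self, "mass", np.asarray(self.mass, dtype=float))
        object.__setattr__(self, "loci", frozenset(self.loci))
        if np.any(self.mass < 0):
            raise ValueError("PMF mass must be nonnegative")

    @property
    def length(self) -> int:
        return len(self.mass)

    @property
    def total_mass(self) -> float:
        return float(self.mass.sum())

    @property
    def support_max_bin(self) -> int:
        """Index of the last nonzero bin; -1 for an all-zero PMF."""
        nz = np.nonzero(self.mass)[0]
        return int(nz[-1]) if nz.size else -1

    @property
    def grid(self) -> np.ndarray:
        """log10LR value of each bin centre."""
        return np.arange(self.length) * self.delta

    def conditional_moments(self) -> tuple[float, float, float]:
        """Mean, variance and skewness of the PMF renormalised to mass 1."""
        total = self.total_mass
        if total <= 0:
            raise ValueError("empty PMF has no moments")
        w = self.mass / total
        x = self.grid
        mean = float(np.dot(w, x))
        var = float(np.dot(w, (x - mean) ** 2))
        if var > 0:
            skew = float(np.dot(w, (x - mean) ** 3)) / var**1.5
        else:
            skew = float("nan")
        return mean, var, skew

    def to_frame(self):
        """Two-column (log10_lr, mass) frame of the nonzero bins."""
        import pandas as pd

        nz = np.nonzero(self.mass)[0]
        return pd.DataFrame(
            {"log10_lr": nz * self.delta, "mass": self.mass[nz]}
        )


def equal_genotype_mass(
    g: Genotype, table: AlleleFrequencyTable, model: ThetaModel
) -> float:
    """Probability that two unrelated random persons both carry genotype g."""
    return conditional_match_probability(g, table, model) * genotype_probability(
        g, table, model
    )


def single_locus_pmf(
    locus: str,
    table: AlleleFrequencyTable,
    model: ThetaModel,
    delta: float = DEFAULT_DELTA,
    length: int = DEFAULT_LENGTH,
) -> DiscretePMF:
    """Discretised PMF of the single-locus log10LR of a matching pair.

    Every genotype of the locus contributes its equal-genotype mass at the
    bin of its log10 LRE; distinct genotypes whose log10LRs fall in the same
    bin are summed ("clumping").
    """
    arrays = locus_genotype_arrays(locus, table, model)
    bins = bin_index(arrays["log10_lre"], delta)
    if np.any(bins >= length):
        raise AliasingError(
            f"{locus}: log10LR support exceeds the grid "
            f"(needs bin {int(bins.max())}, length {length})"
        )
    mass = np.zeros(length)
    np.add.at(mass, bins, arrays["cond"] * arrays["prob"])
    return DiscretePMF(delta=delta, mass=mass, loci=frozenset({locus}))


def _check_grids(pmfs: Sequence[DiscretePMF]) -> None:
    deltas = {p.delta for p in pmfs}
    lengths = {p.length for p in pmfs}
    if len(deltas) > 1 or len(lengths) > 1:
        raise GridError("all PMFs must share the same bin width and length")


def _check_aliasing(pmfs: Sequence[DiscretePMF]) -> None:
    need = sum(max(p.support_max_bin, 0) for p in pmfs)
    if need >= pmfs[0].length:
        raise AliasingError(
            f"combined support needs {need + 1} bins but the grid has "
            f"{pmfs[0].length}; enlarge the array length"
        )


def convolve_fft(
    pmfs: Sequence[DiscretePMF],
    delta: float = DEFAULT_DELTA,
    length: int = DEFAULT_LENGTH,
) -> DiscretePMF:
    """Convolve single-locus PMFs by FFT into the multi-locus log10LR PMF.

    Transforms each PMF, multiplies point-wise in the frequency domain and
    inverts.  Tiny negative round-off is clamped to zero; a genuinely
    negative value raises, as it would indicate an internal inconsistency.
    """
    pmfs = list(pmfs)
    if not pmfs:
        mass = np.zeros(length)
        mass[0] = 1.0
        return DiscretePMF(delta=delta, mass=mass, loci=frozenset())
    if len(pmfs) == 1:
        return pmfs[0]
    _check_grids(pmfs)
    _check_aliasing(pmfs)
    n = pmfs[0].length
    spectrum = scipy.fft.rfft(pmfs[0].mass)
    for p in pmfs[1:]:
        spectrum *= scipy.fft.rfft(p.mass)
    mass = scipy.fft.irfft(spectrum, n=n)
    low = mass.min()
    if low < -_NEGATIVE_MASS_TOL:
        raise FloatingPointError(
            f"FFT convolution produced mass {low}, beyond round-off"
        )
    np.clip(mass, 0.0, None, out=mass)
    loci = frozenset().union(*(p.loci for p in pmfs))
    return DiscretePMF(delta=pmfs[0].delta, mass=mass, loci=loci)


def convolve_direct(
    pmfs: Sequence[DiscretePMF],
    delta: float = DEFAULT_DELTA,
    length: int = DEFAULT_LENGTH,
) -> DiscretePMF:
    """Direct-summation convolution; the oracle for :func:`convolve_fft`.

    Works on the trimmed supports with ``np.convolve`` (plain multiply–add,
    no transforms), so it is exact up to float arithmetic but only practical
    for a handful of small loci.
    """
    pmfs = list(pmfs)
    if not pmfs:
        mass = np.zeros(length)
        mass[0] = 1.0
        return DiscretePMF(delta=delta, mass=mass, loci=frozenset())
    if len(pmfs) == 1:
        return pmfs[0]
    _check_grids(pmfs)
    _check_aliasing(pmfs)
    n = pmfs[0].length
    acc = pmfs[0].mass[: pmfs[0].support_max_bin + 1]
    for p in pmfs[1:]:
        acc = np.convolve(acc, p.mass[: p.support_max_bin + 1])
    mass = np.zeros(n)
    mass[: len(acc)] = acc
    loci = frozenset().union(*(p.loci for p in pmfs))
    return DiscretePMF(delta=pmfs[0].delta, mass=mass, loci=loci)


def alpha_from_threshold(pmf: DiscretePMF, log_lr_threshold: float) -> float:
    """Expected per-comparison FPR: tail mass at and above the threshold bin."""
    if log_lr_threshold < 0:
        raise ValueError("log10LR threshold must be nonnegative")
    k = bin_index(log_lr_threshold, pmf.delta)
    if k >= pmf.length:
        return 0.0
    return float(pmf.mass[k:].sum())


def threshold_from_alpha(pmf: DiscretePMF, alpha: float) -> float:
    """Smallest grid threshold whose tail mass does not exceed alpha.

    Returns Δ·k* for the smallest bin k* with tail(k*) ≤ alpha, so the
    round-trip guarantee alpha_from_threshold(pmf, result) ≤ alpha holds.
    If alpha already covers the whole sub-distribution the threshold is 0.
    """
    if alpha <= 0:
        raise ValueError("alpha must be positive")
    tail = np.cumsum(pmf.mass[::-1])[::-1]
    if tail[0] <= alpha:
        return 0.0
    # tail is nonincreasing; first index where tail <= alpha
    k = int(np.argmax(tail <= alpha))
    if tail[k] > alpha:  # no bin qualifies within the array: beyond support
        k = pmf.support_max_bin + 1
    return k * pmf.delta


class PMFCache:
    """Memoised multi-locus PMFs and thresholds for one (table, θ, grid).

    The convolution for a loci set M only needs to run once per distinct M;
    repeated queries — the common case in a database search, where many
    pairs share the same overlapping loci — are served from the cache.
    """

    def __init__(
        self,
        table: AlleleFrequencyTable,
        model: ThetaModel,
        delta: float = DEFAULT_DELTA,
        length: int = DEFAULT_LENGTH,
    ) -> None:
        self.table = table
        self.model = model
        self.delta = delta
        self.length = length
        self._single: dict[str, DiscretePMF] = {}
        self._multi: dict[tuple[str, ...], DiscretePMF] = {}
        self._thresholds: dict[tuple[tuple[str, ...], float], float] = {}
        self.hits = 0
        self.misses = 0

    def _key(self, loci: Iterable[str]) -> tuple[str, ...]:
        return tuple(sorted(loci))

    def single(self, locus: str) -> DiscretePMF:
        if locus not in self._single:
            self._single[locus] = single_locus_pmf(
                locus, self.table, self.model, self.delta, self.length
            )
        return self._single[locus]

    def pmf(self, loci: Iterable[str]) -> DiscretePMF:
        key = self._key(loci)
        if not key:
            raise ValueError("loci set must be non-empty")
        if key in self._multi:
            self.hits += 1
            return self._multi[key]
        self.misses += 1
        result = convolve_fft(
            [self.single(l) for l in key], self.delta, self.length
        )
        self._multi[key] = result
        return result

    def threshold(self, loci: Iterable[str], alpha: float) -> float:
        key = (self._key(loci), alpha)
        if key not in self._thresholds:
            self._thresholds[key] = threshold_from_alpha(
                self.pmf(key[0]), alpha
            )
        return self._thresholds[key]

    @property
    def stats(self) -> dict[str, int]:
        return {
            "hits": self.hits,
            "misses": self.misses,
            "cached_sets": len(self._multi),
        }


def n_genotypes(n_alleles: int) -> int:
    """Number of unordered genotypes a ladder of n alleles can form."""
    return n_alleles * (n_alleles + 1) // 2


def count_loci_subsets(n_loci: int, min_size: int, max_size: int) -> int:
    """Number of loci subsets with sizes in [min_size, max_size]."""
    import math

    return sum(math.comb(n_loci, k) for k in range(min_size, max_size + 1))
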