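"""Balding–Nichols single-locus genotype probabilities and match LRs.

The coancestry coefficient θ models population substructure: two "unrelated"
members of the same subpopulation share more alleles than Hardy–Weinberg
equilibrium predicts.  Under the model, the probability that a random person
carries genotype g is

    homozygote (a_i, a_i):   θ p_i + (1 − θ) p_i²
    heterozygote (a_i, a_j): 2 (1 − θ) p_i p_j

and the probability that a *second* unrelated person carries g given that one
person was already seen with g (the NRC II Recommendation 4.10 match
probability) is

    homozygote:   (3θ + (1−θ)p_i)(2θ + (1−θ)p_i) / ((1+θ)(1+2θ))
    heterozygote: 2(θ + (1−θ)p_i)(θ + (1−θ)p_j) / ((1+θ)(1+2θ))

The equal-genotype likelihood ratio LRE(g) is the reciprocal of that
conditional match probability; its log10 is the per-locus evidential weight
of an exact genotype match.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .frequencies import AlleleFrequencyTable


@dataclass(frozen=True)
class ThetaModel:
    """Coancestry coefficient θ ∈ [0, 1) of the Balding–Nichols model."""

    theta: float = 0.01

    def __post_init__(self) -> None:
        if not 0.0 <= self.theta < 1.0:
            raise ValueError(f"theta must be in [0, 1), got {self.theta}")


@dataclass(frozen=True)
class Genotype:
    """Unordered pair of allele labels at one locus, stored canonically.

    Use :func:`genotype` to build one; it orders the alleles by their ladder
    index so that (a, b) and (b, a) compare equal.
    """

    locus: str
    alleles: tuple[str, str]

    @property
    def is_homozygous(self) -> bool:
        return self.alleles[0] == self.alleles[1]


def genotype(
    locus: str, a1: str, a2: str, table: AlleleFrequencyTable
) -> Genotype:
    """Build a canonically ordered genotype, validating against the ladder."""
    lf = table[locus]
    i, j = lf.index_of(a1), lf.index_of(a2)
    if i > j:
        a1, a2 = a2, a1
    return Genotype(locus=locus, alleles=(a1, a2))


def _allele_freqs(g: Genotype, table: AlleleFrequencyTable) -> tuple[float, float]:
    lf = table[g.locus]
    a1, a2 = g.alleles
    return lf.frequencies[lf.index_of(a1)], lf.frequencies[lf.index_of(a2)]


def genotype_probability(
    g: Genotype, table: AlleleFrequencyTable, model: ThetaModel
) -> float:
    """Probability that a random unrelated person carries genotype g."""
    p, q = _allele_freqs(g, table)
    th = model.theta
    if g.is_homozygous:
        return th * p + (1.0 - th) * p * p
    return 2.0 * (1.0 - th) * p * q


def conditional_match_probability(
    g: Genotype, table: AlleleFrequencyTable, model: ThetaModel
) -> float:
    """P(a second unrelated person has g | one person was seen with g)."""
    p, q = _allele_freqs(g, table)
    th = model.theta
    denom = (1.0 + th) * (1.0 + 2.0 * th)
    if g.is_homozygous:
        return (3.0 * th + (1.0 - th) * p) * (2.0 * th + (1.0 - th) * p) / denom
    return 2.0 * (th + (1.0 - th) * p) * (th + (1.0 - th) * q) / denom


def lre(g: Genotype, table: AlleleFrequencyTable, model: ThetaModel) -> float:
    """Equal-genotype likelihood ratio, 1 / conditional match probability."""
    return 1.0 / conditional_match_probability(g, table, model)


def log10_lre(g: Genotype, table: AlleleFrequencyTable, model: ThetaModel) -> float:
    """log10 of the equal-genotype LR; the per-locus log10LR of a match."""
    return math.log10(lre(g, table, model))


def locus_genotype_arrays(
    locus: str, table: AlleleFrequencyTable, model: ThetaModel
) -> dict[str, np.ndarray]:
    """Vectorised Balding–Nichols quantities over all genotypes of a locus.

    Enumerates the K(K+1)/2 unordered genotypes (i ≤ j by ladder index) and
    returns aligned arrays: allele indices ``i``/``j``, genotype probability
    ``prob``, conditional match probability ``cond``, and ``log10_lre``.
    """
    lf = table[locus]
    p = lf.frequencies
    th = model.theta
    i, j = np.triu_indices(lf.n_alleles)
    pi, pj = p[i], p[j]
    hom = i == j
    prob = np.where(
        hom, th * pi + (1.0 - th) * pi * pi, 2.0 * (1.0 - th) * pi * pj
    )
    denom = (1.0 + th) * (1.0 + 2.0 * th)
    cond = np.where(
        hom,
        (3.0 * th + (1.0 - th) * pi) * (2.0 * th + (1.0 - th) * pi) / denom,
        2.0 * (th + (1.0 - th) * pi) * (th + (1.0 - th) * pj) / denom,
    )
    return {
        "i": i,
        "j": j,
        "prob": prob,
        "cond": cond,
        "log10_lre": -np.log10(cond),
    }
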