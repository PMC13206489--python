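"""Pairwise profile comparison and thresholded database search.

Two profiles are compared on the loci typed in both (the overlapping set M);
they are a full match when the unordered genotypes agree at every locus of
M.  For a full match the total log10LR is the sum of the per-locus log10
equal-genotype LRs over M.  Three filtering methods decide whether a match
is worth human review:

* ``locus-count`` — review when |M| ≥ k (the conventional static rule);
* ``static-lr``   — review when log10LR ≥ a fixed cutoff;
* ``dynamic-lr``  — review when log10LR ≥ the threshold that caps the
  expected false positives of the whole search, computed per loci set M
  from the tail of the convolved PMF at the per-comparison rate α.

Wildcard / near-match searching (one allowed mismatch) is out of scope:
matching is exact genotype equality.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Optional, Sequence

from .bn_model import ThetaModel, log10_lre
from .frequencies import AlleleFrequencyTable
from .pmf_engine import PMFCache
from .popsim import Profile

Method = Literal["dynamic-lr", "static-lr", "locus-count"]


class MatchContractError(ValueError):
    """An LR was requested for a pair that is not a full match."""


@dataclass(frozen=True)
class MatchResult:
    """Outcome of one stain-vs-candidate comparison that fully matched."""

    stain_id: str
    candidate_id: str
    shared_loci: frozenset[str]
    is_full_match: bool
    log10_lr: float
    threshold: Optional[float]
    decision: Literal["review", "reject"]
    method: Method

    @property
    def n_shared_loci(self) -> int:
        return len(self.shared_loci)


def compare(a: Profile, b: Profile) -> tuple[frozenset[str], bool]:
    """Overlapping loci set M and whether all shared genotypes are equal.

    An empty M means the profiles cannot match at all.
    """
    shared = a.loci & b.loci
    if not shared:
        return frozenset(), False
    full = all(a.genotypes[l] == b.genotypes[l] for l in shared)
    return shared, full


def total_log10_lr(
    a: Profile,
    b: Profile,
    table: AlleleFrequencyTable,
    model: ThetaModel,
) -> float:
    """Total log10LR of a full match: Σ over M of log10 LRE per locus."""
    shared, full = compare(a, b)
    if not shared or not full:
        raise MatchContractError(
            "total_log10_lr requires a full match on a non-empty loci set"
        )
    return sum(log10_lre(a.genotypes[l], table, model) for l in shared)


def search(
    stain: Profile,
    database: Sequence[Profile],
    table: AlleleFrequencyTable,
    model: ThetaModel,
    method: Method,
    *,
    alpha: Optional[float] = None,
    static_log10_lr: Optional[float] = None,
    min_loci: Optional[int] = None,
    cache: Optional[PMFCache] = None,
) -> list[MatchResult]:
    """Search one stain against a database and filter the full matches.

    ``alpha`` is the per-comparison false-positive rate already resolved
    from the laboratory's risk specification (see :mod:`dynlr.risk`); it is
    required for ``dynamic-lr``, as is a :class:`PMFCache` (one is created
    on the fly if omitted).  ``static-lr`` needs ``static_log10_lr`` and
    ``locus-count`` needs ``min_loci``.  Thresholds are computed once per
    distinct overlapping loci set.  Results are sorted by log10LR,
    descending.
    """
    if method == "dynamic-lr":
        if alpha is None:
            raise ValueError("dynamic-lr requires alpha")
        if cache is None:
            cache = PMFCache(table, model)
    elif method == "static-lr":
        if static_log10_lr is None:
            raise ValueError("static-lr requires static_log10_lr")
    elif method == "locus-count":
        if min_loci is None:
            raise ValueError("locus-count requires min_loci")
    else:
        raise ValueError(f"unknown method {method!r}")

    results = []
    for candidate in database:
        shared, full = compare(stain, candidate)
        if not shared or not full:
            continue
        lr = total_log10_lr(stain, candidate, table, model)
        if method == "dynamic-lr":
            threshold = cache.threshold(shared, alpha)
            decision = "review" if lr >= threshold else "reject"
        elif method == "static-lr":
            threshold = static_log10_lr
            decision = "review" if lr >= threshold else "reject"
        else:
            threshold = None
            decision = "review" if len(shared) >= min_loci else "reject"
        results.append(
            MatchResult(
                stain_id=stain.sample_id,
                candidate_id=candidate.sample_id,
                shared_loci=shared,
                is_full_match=True,
                log10_lr=lr,
                threshold=threshold,
                decision=decision,
                method=method,
            )
        )
    results.sort(key=lambda r: r.log10_lr, reverse=True)
    return results
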