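"""Validation analyses for the dynamic-threshold framework, at desk scale.

Everything here is a pure function of (seed, config, table):

* :func:`run_calibration` — searches batches of synthetic stains against
  synthetic databases drawn from a shared Dirichlet subpopulation and checks
  that the observed false-positive counts track the targeted Poisson mean
  and its 95% band.
* :func:`run_roc` — compares the three filtering methods (locus count,
  static LR, dynamic LR) on planted-donor searches with degraded stains.
* :func:`mc_convergence` — Monte-Carlo cross-check of the FFT-convolved
  log10LR distribution, scored with a normalised Wasserstein distance.
* :func:`gap_analysis` / :func:`gaussian_tail_comparison` — structure of
  the discrete PMFs: zero-probability gaps, skewness, and how badly a
  moment-matched Gaussian underestimates the right tail.
* :func:`relatives_passthrough` — how often parent/child and full-sibling
  profiles survive a threshold calibrated for unrelated false positives.

The scan engines work on integer genotype codes (ladder index pair i·K+j)
so that a stain can be compared against a whole database with a few array
operations; they implement the same exact-match rule as
:func:`dynlr.matcher.search`, which the test suite cross-checks.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import scipy.stats

from .bn_model import ThetaModel, locus_genotype_arrays
from .frequencies import AlleleFrequencyTable, ValidationError
from .pmf_engine import (
    DEFAULT_DELTA,
    DEFAULT_LENGTH,
    DiscretePMF,
    PMFCache,
    bin_index,
    convolve_fft,
    single_locus_pmf,
)
from .popsim import dirichlet_subpop_frequencies, sample_allele_indices
from .risk import poisson_band

# ---------------------------------------------------------------------------
# coded-genotype helpers


def _lre_lookup(table: AlleleFrequencyTable, model: ThetaModel) -> dict[str, np.ndarray]:
    """Per locus, log10 LRE indexed by genotype code i·K+j (i ≤ j)."""
    lookup = {}
    for locus in table.loci:
        arrays = locus_genotype_arrays(locus, table, model)
        k = table[locus].n_alleles
        values = np.full(k * k, np.nan)
        values[arrays["i"] * k + arrays["j"]] = arrays["log10_lre"]
        lookup[locus] = values
    return lookup


def _sample_codes(
    freqs: AlleleFrequencyTable, loci: Sequence[str], n: int, rng: np.random.Generator
) -> dict[str, np.ndarray]:
    """n HWE genotype codes per locus, drawn from ``freqs``."""
    codes = {}
    for locus in loci:
        lf = freqs[locus]
        a = sample_allele_indices(lf.frequencies, n, rng)
        b = sample_allele_indices(lf.frequencies, n, rng)
        codes[locus] = np.minimum(a, b) * lf.n_alleles + np.maximum(a, b)
    return codes


# ---------------------------------------------------------------------------
# calibration against the Poisson model


@dataclass(frozen=True)
class CalibrationConfig:
    """Batched stain-vs-database searches at fixed expected-FP targets."""

    mu_targets: tuple[float, ...] = (1.0, 5.0, 10.0)
    db_size: int = 5000
    n_stains: int = 1000
    n_batches: int = 50
    stain_loci: int = 4
    theta: float = 0.01
    seed: int = 0
    delta: float = DEFAULT_DELTA
    length: int = DEFAULT_LENGTH
    band_level: float = 0.95


@dataclass(frozen=True)
class CalibrationReport:
    """Observed false-positive counts per batch, against Poisson bands."""

    config: CalibrationConfig
    observed: dict[float, np.ndarray]
    bands: dict[float, tuple[int, int]]

    def mean_observed(self, mu: float) -> float:
        return float(self.observed[mu].mean())

    def coverage(self, mu: float) -> float:
        lo, hi = self.bands[mu]
        x = self.observed[mu]
        return float(np.mean((x >= lo) & (x <= hi)))

    @property
    def overall_coverage(self) -> float:
        inside = total = 0
        for mu, x in self.observed.items():
            lo, hi = self.bands[mu]
            inside += int(np.sum((x >= lo) & (x <= hi)))
            total += len(x)
        return inside / total

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for mu, x in self.observed.items():
            lo, hi = self.bands[mu]
            for batch, obs in enumerate(x):
                rows.append((mu, batch, int(obs), lo, hi))
        return pd.DataFrame(
            rows, columns=["mu_target", "batch", "observed_fp", "band_lo", "band_hi"]
        )


def run_calibration(
    config: CalibrationConfig, table: AlleleFrequencyTable
) -> CalibrationReport:
    """Count false positives cleared by dynamic thresholds, batch by batch.

    Each batch draws a fresh shared subpopulation (one Dirichlet draw per
    locus), a fresh database and fresh stain donors from it; stains carry
    ``stain_loci`` randomly chosen loci.  Stain donors are not database
    members, so every full match that clears its dynamic threshold is a
    false positive.  Thresholds are computed from the *base* table — the
    framework never sees the subpopulation draw — at α = μ / (stains · db).
    """
    model = ThetaModel(config.theta)
    cache = PMFCache(table, model, config.delta, config.length)
    lookup = _lre_lookup(table, model)
    loci = list(table.loci)
    n_loci = len(loci)
    t_comparisons = config.n_stains * config.db_size

    ss = np.random.SeedSequence(config.seed)
    observed: dict[float, np.ndarray] = {}
    bands: dict[float, tuple[int, int]] = {}
    for mu in config.mu_targets:
        alpha = mu / t_comparisons
        bands[mu] = poisson_band(mu, config.band_level)
        counts = np.zeros(config.n_batches, dtype=np.int64)
        if alpha == 0.0:  # an infinite threshold: nothing can pass
            observed[mu] = counts
            continue
        for batch in range(config.n_batches):
            rng = np.random.default_rng(ss.spawn(1)[0])
            subpop = dirichlet_subpop_frequencies(table, model, rng)
            db = _sample_codes(subpop, loci, config.db_size, rng)
            stain_pool = _sample_codes(subpop, loci, config.n_stains, rng)
            fp = 0
            for s in range(config.n_stains):
                chosen = rng.choice(n_loci, size=config.stain_loci, replace=False)
                chosen_loci = [loci[c] for c in chosen]
                mask = db[chosen_loci[0]] == stain_pool[chosen_loci[0]][s]
                for locus in chosen_loci[1:]:
                    mask &= db[locus] == stain_pool[locus][s]
                n_match = int(np.count_nonzero(mask))
                if n_match == 0:
                    continue
                lr = sum(
                    lookup[locus][stain_pool[locus][s]] for locus in chosen_loci
                )
                if lr >= cache.threshold(chosen_loci, alpha):
                    fp += n_match
            counts[batch] = fp
        observed[mu] = counts
    return CalibrationReport(config=config, observed=observed, bands=bands)


# ---------------------------------------------------------------------------
# ROC comparison of the three filtering methods


@dataclass(frozen=True)
class RocConfig:
    db_size: int = 20000
    stains_per_count: int = 200
    locus_counts: tuple[int, ...] = (3, 4, 5, 6, 7)
    theta: float = 0.01
    seed: int = 0
    delta: float = DEFAULT_DELTA
    length: int = DEFAULT_LENGTH
    #: sweep grid for the dynamic method's per-comparison rate α
    alpha_grid: tuple[float, ...] = tuple(np.logspace(-12, -2, 101))
    #: sweep grid for the static log10LR threshold
    static_grid: tuple[float, ...] = tuple(np.arange(0.0, 40.0, 0.1))


@dataclass(frozen=True)
class RocCurve:
    fpr: np.ndarray
    tpr: np.ndarray
    auc: float


@dataclass(frozen=True)
class RocReport:
    curves: dict[str, RocCurve]
    n_true: int
    n_false: int

    def auc(self, method: str) -> float:
        return self.curves[method].auc


def sweep_curve(
    pos_scores: np.ndarray,
    neg_scores: np.ndarray,
    thresholds: np.ndarray,
    neg_weights: Optional[np.ndarray] = None,
) -> RocCurve:
    """ROC curve for the rule "accept when score ≥ threshold".

    ``neg_weights`` lets one negative score stand for several adventitious
    matches (a stain's coincidental matches all share the stain's score).
    The curve is evaluated at the union of the sweep grid and the observed
    scores, so the trapezoid AUC is exact for the sample, including the
    half-credit that tied scores earn.
    """
    if neg_weights is None:
        neg_weights = np.ones_like(neg_scores)
    thresholds = np.union1d(thresholds, np.union1d(pos_scores, neg_scores))
    tpr = (pos_scores[None, :] >= thresholds[:, None]).mean(axis=1)
    total_neg = neg_weights.sum()
    fpr = (
        (neg_scores[None, :] >= thresholds[:, None]) * neg_weights[None, :]
    ).sum(axis=1) / max(total_neg, 1)
    fpr = np.concatenate([[0.0], fpr[::-1], [1.0]])
    tpr = np.concatenate([[0.0], tpr[::-1], [1.0]])
    order = np.lexsort((tpr, fpr))
    fpr, tpr = fpr[order], tpr[order]
    return RocCurve(fpr=fpr, tpr=tpr, auc=float(np.trapezoid(tpr, fpr)))


def run_roc(config: RocConfig, table: AlleleFrequencyTable) -> RocReport:
    """ROC curves and AUCs of locus-count, static-LR and dynamic-LR filters.

    One shared subpopulation draw produces the database; each stain is a
    database member truncated to k loci (its donor is the planted true
    match) and is scanned against the whole database.  The three methods
    are swept over their control parameter: minimum locus count k, static
    log10LR cutoff, and per-comparison rate α (a pair passes at level α
    when the tail probability of its loci set's PMF at the pair's log10LR
    is at most α — equivalent to log10LR clearing the dynamic threshold).
    """
    model = ThetaModel(config.theta)
    cache = PMFCache(table, model, config.delta, config.length)
    lookup = _lre_lookup(table, model)
    loci = list(table.loci)
    n_loci = len(loci)
    rng = np.random.default_rng(config.seed)
    subpop = dirichlet_subpop_frequencies(table, model, rng)
    db = _sample_codes(subpop, loci, config.db_size, rng)

    n_stains = config.stains_per_count * len(config.locus_counts)
    donor_idx = rng.integers(config.db_size, size=n_stains)
    stain_k = np.repeat(config.locus_counts, config.stains_per_count)

    lr_scores = np.zeros(n_stains)
    tail_scores = np.zeros(n_stains)
    fp_counts = np.zeros(n_stains)
    for s in range(n_stains):
        chosen = rng.choice(n_loci, size=int(stain_k[s]), replace=False)
        chosen_loci = [loci[c] for c in chosen]
        codes = {locus: db[locus][donor_idx[s]] for locus in chosen_loci}
        mask = db[chosen_loci[0]] == codes[chosen_loci[0]]
        for locus in chosen_loci[1:]:
            mask &= db[locus] == codes[locus]
        fp_counts[s] = np.count_nonzero(mask) - 1  # donor always matches
        lr = sum(lookup[locus][codes[locus]] for locus in chosen_loci)
        lr_scores[s] = lr
        pmf = cache.pmf(chosen_loci)
        tail_scores[s] = float(
            pmf.mass[bin_index(max(lr, 0.0), pmf.delta):].sum()
        )

    # smaller tail probability = stronger evidence; sweep on -log10(tail)
    with np.errstate(divide="ignore"):
        dyn_scores = -np.log10(tail_scores)
    alpha_grid = np.asarray(config.alpha_grid, dtype=float)
    with np.errstate(divide="ignore"):
        dyn_thresholds = -np.log10(alpha_grid)

    k_scores = stain_k.astype(float)
    curves = {
        "locus-count": sweep_curve(
            k_scores,
            k_scores,
            np.arange(0, max(config.locus_counts) + 2, dtype=float),
            fp_counts,
        ),
        "static-lr": sweep_curve(
            lr_scores,
            lr_scores,
            np.asarray(config.static_grid, dtype=float),
            fp_counts,
        ),
        "dynamic-lr": sweep_curve(
            dyn_scores, dyn_scores, dyn_thresholds, fp_counts
        ),
    }
    return RocReport(
        curves=curves, n_true=n_stains, n_false=int(fp_counts.sum())
    )


# ---------------------------------------------------------------------------
# Monte-Carlo convergence of the FFT PMF


def _bn_matching_pair_values(
    freqs: np.ndarray,
    theta: float,
    values_by_code: np.ndarray,
    n: int,
    rng: np.random.Generator,
    accept_estimate: float,
) -> np.ndarray:
    """n per-locus log10LR draws conditional on two BN genotypes matching.

    Four alleles are drawn sequentially with the Pólya-urn form of the
    Balding–Nichols model: allele m+1 copies a uniformly chosen previous
    allele with probability mθ/(1+(m−1)θ) and is a fresh draw from the base
    frequencies otherwise.  Alleles 1–2 form one genotype, alleles 3–4 the
    other; unequal pairs are rejected.
    """
    k = len(freqs)
    out: list[np.ndarray] = []
    got = 0
    while got < n:
        m = int((n - got) / max(accept_estimate, 1e-6) * 1.2) + 1000
        a1 = sample_allele_indices(freqs, m, rng)
        copy = rng.random(m) < theta
        a2 = np.where(copy, a1, sample_allele_indices(freqs, m, rng))
        copy = rng.random(m) < 2.0 * theta / (1.0 + theta)
        prev = np.where(rng.integers(2, size=m) == 0, a1, a2)
        a3 = np.where(copy, prev, sample_allele_indices(freqs, m, rng))
        copy = rng.random(m) < 3.0 * theta / (1.0 + 2.0 * theta)
        pick = rng.integers(3, size=m)
        prev = np.select([pick == 0, pick == 1], [a1, a2], a3)
        a4 = np.where(copy, prev, sample_allele_indices(freqs, m, rng))
        g1 = np.minimum(a1, a2) * k + np.maximum(a1, a2)
        g2 = np.minimum(a3, a4) * k + np.maximum(a3, a4)
        equal = g1 == g2
        vals = values_by_code[g1[equal]]
        out.append(vals)
        got += len(vals)
    return np.concatenate(out)[:n]


@dataclass(frozen=True)
class McReport:
    loci: tuple[str, ...]
    n_trials: int
    fft_mean: float
    fft_std: float
    mc_mean: float
    mc_std: float
    norm_wasserstein: float


def mc_convergence(
    loci: Sequence[str],
    table: AlleleFrequencyTable,
    model: ThetaModel,
    n_trials: int,
    rng: np.random.Generator,
    delta: float = DEFAULT_DELTA,
    length: int = DEFAULT_LENGTH,
) -> McReport:
    """Monte-Carlo vs FFT distribution of the total log10LR of matching pairs.

    The sampler draws genotype pairs per locus under the Balding–Nichols
    null and keeps only matching pairs; because loci are independent, the
    per-locus conditional draws sum to a draw of the total log10LR
    conditional on a full match.  The FFT PMF is renormalised by its total
    mass for the comparison.  The Wasserstein-1 distance between the two is
    reported normalised by the FFT distribution's standard deviation.
    """
    loci = list(loci)
    if not loci:
        raise ValidationError("loci set must be non-empty")
    model_singles = []
    sums = np.zeros(n_trials)
    for locus in loci:
        lf = table[locus]
        arrays = locus_genotype_arrays(locus, table, model)
        values = np.full(lf.n_alleles * lf.n_alleles, np.nan)
        values[arrays["i"] * lf.n_alleles + arrays["j"]] = arrays["log10_lre"]
        single = single_locus_pmf(locus, table, model, delta, length)
        model_singles.append(single)
        sums += _bn_matching_pair_values(
            lf.frequencies,
            model.theta,
            values,
            n_trials,
            rng,
            accept_estimate=single.total_mass,
        )
    pmf = convolve_fft(model_singles, delta, length)
    mean, var, _ = pmf.conditional_moments()
    std = float(np.sqrt(var))
    nz = np.nonzero(pmf.mass)[0]
    wd = scipy.stats.wasserstein_distance(
        sums, nz * delta, v_weights=pmf.mass[nz]
    )
    return McReport(
        loci=tuple(loci),
        n_trials=n_trials,
        fft_mean=mean,
        fft_std=std,
        mc_mean=float(sums.mean()),
        mc_std=float(sums.std(ddof=1)),
        norm_wasserstein=float(wd / std),
    )


# ---------------------------------------------------------------------------
# discreteness diagnostics


def gap_analysis(
    pmf: DiscretePMF, min_gap: float = 0.04
) -> list[tuple[float, float]]:
    """Zero-probability intervals wider than ``min_gap`` inside the support.

    Returns (start, end) log10LR intervals for every maximal run of
    zero-mass bins strictly between the first and last nonzero bin whose
    width (run length · Δ) exceeds ``min_gap``.
    """
    if min_gap < pmf.delta:
        raise ValidationError("min_gap must be at least one bin width")
    nz = np.nonzero(pmf.mass)[0]
    if nz.size == 0:
        raise ValidationError("empty PMF has no support")
    gaps = []
    for left, right in zip(nz[:-1], nz[1:]):
        width = (right - left - 1) * pmf.delta
        if width > min_gap:
            gaps.append(((left + 1) * pmf.delta, right * pmf.delta))
    return gaps


@dataclass(frozen=True)
class GaussianTailReport:
    mean: float
    std: float
    skewness: float
    #: thresholds mean + k·σ for k = 1..4
    thresholds: np.ndarray
    discrete_tail: np.ndarray
    gaussian_tail: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "k_sigma": np.arange(1, len(self.thresholds) + 1),
                "threshold": self.thresholds,
                "discrete_tail": self.discrete_tail,
                "gaussian_tail": self.gaussian_tail,
            }
        )


def gaussian_tail_comparison(pmf: DiscretePMF) -> GaussianTailReport:
    """Discrete vs moment-matched Gaussian tail mass at mean + kσ, k = 1..4.

    The Gaussian baseline has the PMF's conditional mean and variance and is
    scaled to the same total mass.  A heavy (right-skewed) discrete tail
    shows up as discrete tail mass exceeding the Gaussian tail at high k —
    the regime where operational thresholds live.
    """
    if pmf.total_mass <= 0:
        raise ValidationError("empty PMF")
    mean, var, skew = pmf.conditional_moments()
    if var <= 0:
        raise ValidationError("zero-variance PMF has no tail comparison")
    std = float(np.sqrt(var))
    ks = np.arange(1, 5)
    thresholds = mean + ks * std
    discrete = np.array(
        [
            float(pmf.mass[bin_index(t, pmf.delta):].sum())
            if bin_index(t, pmf.delta) < pmf.length
            else 0.0
            for t in thresholds
        ]
    )
    gaussian = pmf.total_mass * scipy.stats.norm.sf(ks)
    return GaussianTailReport(
        mean=mean,
        std=std,
        skewness=skew,
        thresholds=thresholds,
        discrete_tail=discrete,
        gaussian_tail=gaussian,
    )


# ---------------------------------------------------------------------------
# relatives against a threshold calibrated for unrelated false positives


@dataclass(frozen=True)
class RelativesConfig:
    db_size: int = 5000
    n_stains: int = 2000
    locus_counts: tuple[int, ...] = (3, 4, 5, 6)
    theta: float = 0.01
    mu: float = 1.0
    seed: int = 0
    n_batches: int = 1
    delta: float = DEFAULT_DELTA
    length: int = DEFAULT_LENGTH


def _relative_codes(
    donor_codes: dict[str, np.ndarray],
    relationship: str,
    freqs: AlleleFrequencyTable,
    rng: np.random.Generator,
) -> dict[str, np.ndarray]:
    """Vectorised relative simulation over a column of donors, per locus."""
    out = {}
    n = len(next(iter(donor_codes.values())))
    for locus, codes in donor_codes.items():
        lf = freqs[locus]
        k = lf.n_alleles
        da, db_ = codes // k, codes % k
        if relationship == "parent-child":
            ibd = np.ones(n, dtype=np.int64)
        else:
            ibd = rng.choice(3, size=n, p=(0.25, 0.5, 0.25))
        shared = np.where(rng.integers(2, size=n) == 0, da, db_)
        fresh1 = sample_allele_indices(lf.frequencies, n, rng)
        fresh2 = sample_allele_indices(lf.frequencies, n, rng)
        a = np.select([ibd == 2, ibd == 1], [da, shared], fresh1)
        b = np.select([ibd == 2], [db_], fresh2)
        out[locus] = np.minimum(a, b) * k + np.maximum(a, b)
    return out


def relatives_passthrough(
    config: RelativesConfig, table: AlleleFrequencyTable
) -> pd.DataFrame:
    """Detected vs reviewed match counts by relationship and locus count.

    Stain donors (not in the database) each get a simulated parent/child
    and full sibling.  For every locus count the stains are scanned against
    an unrelated database, and compared directly with their two relatives,
    under the dynamic threshold that targets ``mu`` expected *unrelated*
    false positives per batch (α = μ / (stains · db)).  Counts are averaged
    over batches.
    """
    model = ThetaModel(config.theta)
    cache = PMFCache(table, model, config.delta, config.length)
    lookup = _lre_lookup(table, model)
    loci = list(table.loci)
    n_loci = len(loci)
    alpha_t = config.n_stains * config.db_size

    ss = np.random.SeedSequence(config.seed)
    acc: dict[tuple[str, int], np.ndarray] = {}
    for batch in range(config.n_batches):
        rng = np.random.default_rng(ss.spawn(1)[0])
        subpop = dirichlet_subpop_frequencies(table, model, rng)
        db = _sample_codes(subpop, loci, config.db_size, rng)
        donors = _sample_codes(subpop, loci, config.n_stains, rng)
        parents = _relative_codes(donors, "parent-child", subpop, rng)
        siblings = _relative_codes(donors, "full-sibling", subpop, rng)

        alpha = config.mu / alpha_t
        for k_loci in config.locus_counts:
            counts = {
                rel: np.zeros(2) for rel in ("unrelated", "parent-child", "full-sibling")
            }
            for s in range(config.n_stains):
                chosen = rng.choice(n_loci, size=k_loci, replace=False)
                chosen_loci = [loci[c] for c in chosen]
                thr = cache.threshold(chosen_loci, alpha)
                lr = sum(lookup[locus][donors[locus][s]] for locus in chosen_loci)
                passes = lr >= thr

                mask = db[chosen_loci[0]] == donors[chosen_loci[0]][s]
                for locus in chosen_loci[1:]:
                    mask &= db[locus] == donors[locus][s]
                n_match = int(np.count_nonzero(mask))
                counts["unrelated"] += (n_match, n_match * passes)

                for rel, codes in (
                    ("parent-child", parents),
                    ("full-sibling", siblings),
                ):
                    if all(
                        codes[locus][s] == donors[locus][s]
                        for locus in chosen_loci
                    ):
                        counts[rel] += (1, passes)
            for rel, (detected, reviewed) in counts.items():
                key = (rel, k_loci)
                acc.setdefault(key, np.zeros(2))
                acc[key] += (detected, reviewed)

    rows = [
        (rel, k_loci, det / config.n_batches, rev / config.n_batches)
        for (rel, k_loci), (det, rev) in sorted(acc.items())
    ]
    return pd.DataFrame(
        rows, columns=["relationship", "n_loci", "detected", "reviewed"]
    )
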