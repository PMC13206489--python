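"""Synthetic populations: structured frequencies, profiles, stains, relatives.

Generating profiles straight from published allele frequencies under
Hardy–Weinberg equilibrium overstates population diversity and therefore
understates coincidental match rates.  To emulate the substructure the
Balding–Nichols LR model assumes, each study first draws one set of
*subpopulation* frequencies per locus from a Dirichlet distribution whose
mean is the published frequencies and whose concentration, (1−θ)/θ, is the
stationary Balding–Nichols parameterisation; database and stain donors are
then sampled in Hardy–Weinberg equilibrium within that shared subpopulation.

Degraded crime stains are modelled by uniformly random locus dropout down to
a target locus count.  Relatives are simulated locus-by-locus from
identity-by-descent states: a parent or child shares exactly one allele per
locus, full siblings share 2/1/0 alleles with probability 1/4, 1/2, 1/4;
alleles not shared by descent are drawn from the subpopulation frequencies.
All generation is a pure function of (seed, config, table).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Literal, Optional, Sequence

import numpy as np
import pandas as pd

from .bn_model import Genotype, ThetaModel
from .frequencies import (
    AlleleFrequencyTable,
    LocusFrequencies,
    ValidationError,
    apply_pmin,
)

Relationship = Literal["parent-child", "full-sibling"]
PROFILE_COLUMNS = ("sample_id", "locus", "allele1", "allele2")


@dataclass(frozen=True)
class Profile:
    """One typed individual: a mapping locus → genotype plus provenance."""

    sample_id: str
    genotypes: dict[str, Genotype]
    origin: str = "unrelated"
    donor_id: Optional[str] = None

    @property
    def loci(self) -> frozenset[str]:
        return frozenset(self.genotypes)

    def __len__(self) -> int:
        return len(self.genotypes)


@dataclass(frozen=True)
class SimConfig:
    """Reproducible study layout; identical seeds give identical output."""

    seed: int
    db_size: int
    n_stains: int
    stain_loci_range: tuple[int, int] = (3, 9)
    theta: float = 0.01
    #: relationships simulated for each stain donor
    relatives: tuple[Relationship, ...] = ()
    #: if True, each stain donor is also a database member (guaranteed match)
    stains_in_database: bool = True


@dataclass(frozen=True)
class Study:
    """Output of :func:`generate_study`."""

    frequencies: AlleleFrequencyTable  # the shared subpopulation draw
    database: tuple[Profile, ...]
    stains: tuple[Profile, ...]
    relatives: tuple[Profile, ...]
    manifest: dict


# ---------------------------------------------------------------------------
# frequency generation


def synthetic_frequency_table(
    n_loci: int = 10,
    seed: int | np.random.Generator = 0,
    allele_range: tuple[int, int] = (4, 14),
    n_typed: int = 800,
    concentration: float = 1.0,
) -> AlleleFrequencyTable:
    """Generate a p_min-corrected synthetic frequency table.

    Ladder sizes are drawn uniformly from ``allele_range``, giving the
    heterogeneous locus diversity (low-diversity TPOX-like loci next to
    SE33-like highly polymorphic ones) that real multiplexes show.
    Frequencies come from a flat Dirichlet, so a share of alleles lands
    below p_min = 5/(2N) and exercises the rare-allele correction.
    """
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    loci_data: dict[str, LocusFrequencies] = {}
    for idx in range(n_loci):
        k = int(rng.integers(allele_range[0], allele_range[1] + 1))
        freqs = rng.dirichlet(np.full(k, concentration))
        name = f"L{idx + 1:02d}"
        first = int(rng.integers(5, 12))
        loci_data[name] = LocusFrequencies(
            name=name,
            ladder=tuple(str(first + a) for a in range(k)),
            frequencies=freqs,
            n_typed=n_typed,
        )
    return apply_pmin(AlleleFrequencyTable(loci_data=loci_data))


def dirichlet_subpop_frequencies(
    table: AlleleFrequencyTable,
    model: ThetaModel,
    rng: np.random.Generator,
) -> AlleleFrequencyTable:
    """Draw skewed subpopulation frequencies around the base table.

    Per locus the draw is Dirichlet with concentration α_i = p_i (1−θ)/θ —
    the stationary distribution of subpopulation frequencies under the
    Balding–Nichols model, so E[q_i] = p_i and Var[q_i] ≈ θ p_i (1−p_i).
    θ = 0 means no structuring and returns the table unchanged.
    """
    if model.theta == 0.0:
        return table
    scale = (1.0 - model.theta) / model.theta
    loci_data = {}
    for name, lf in table.loci_data.items():
        q = rng.dirichlet(lf.frequencies * scale)
        loci_data[name] = replace(lf, frequencies=q)
    return AlleleFrequencyTable(loci_data=loci_data, corrected=table.corrected)


# ---------------------------------------------------------------------------
# vectorised sampling primitives (profile objects are built on top of these)


def sample_allele_indices(
    freqs: np.ndarray, n: int, rng: np.random.Generator
) -> np.ndarray:
    """n i.i.d. allele (ladder-index) draws from a frequency vector."""
    cdf = np.cumsum(freqs)
    cdf[-1] = 1.0
    return np.searchsorted(cdf, rng.random(n), side="right").astype(np.int64)


def sample_genotype_index_pairs(
    freqs: np.ndarray, n: int, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """n unordered genotype draws (i ≤ j) under HWE within the population."""
    a = sample_allele_indices(freqs, n, rng)
    b = sample_allele_indices(freqs, n, rng)
    return np.minimum(a, b), np.maximum(a, b)


def sample_profile(
    freqs: AlleleFrequencyTable,
    loci: Sequence[str],
    rng: np.random.Generator,
    sample_id: str = "S1",
    origin: str = "unrelated",
    donor_id: Optional[str] = None,
) -> Profile:
    """Draw one profile: two independent alleles per locus (HWE)."""
    if not loci:
        raise ValidationError("loci set must be non-empty")
    genotypes = {}
    for locus in loci:
        lf = freqs[locus]
        i, j = sample_genotype_index_pairs(lf.frequencies, 1, rng)
        genotypes[locus] = Genotype(
            locus=locus, alleles=(lf.ladder[int(i[0])], lf.ladder[int(j[0])])
        )
    return Profile(
        sample_id=sample_id, genotypes=genotypes, origin=origin, donor_id=donor_id
    )


def degrade_profile(
    profile: Profile, target_loci: int, rng: np.random.Generator
) -> Profile:
    """Random locus dropout: keep a uniformly random subset of target size."""
    if target_loci < 1:
        raise ValidationError("target_loci must be at least 1")
    loci = sorted(profile.genotypes)
    if target_loci > len(loci):
        raise ValidationError(
            f"cannot keep {target_loci} loci of a {len(loci)}-locus profile"
        )
    if target_loci == len(loci):
        return profile
    keep = rng.choice(len(loci), size=target_loci, replace=False)
    kept = {loci[k]: profile.genotypes[loci[k]] for k in sorted(keep)}
    return Profile(
        sample_id=profile.sample_id,
        genotypes=kept,
        origin=profile.origin,
        donor_id=profile.donor_id,
    )


def simulate_relative(
    donor: Profile,
    relationship: Relationship,
    freqs: AlleleFrequencyTable,
    rng: np.random.Generator,
    sample_id: Optional[str] = None,
) -> Profile:
    """Simulate a relative of the donor locus-by-locus from IBD states.

    parent-child: exactly one allele identical by descent at every locus
    (the shared donor allele chosen uniformly, the other drawn from the
    frequency pool).  full-sibling: IBD state 2/1/0 with probability
    1/4, 1/2, 1/4; IBD alleles are copied, the rest drawn independently.
    """
    if relationship not in ("parent-child", "full-sibling"):
        raise ValidationError(f"unknown relationship {relationship!r}")
    genotypes = {}
    for locus, g in donor.genotypes.items():
        lf = freqs[locus]
        donor_alleles = g.alleles
        if relationship == "parent-child":
            ibd = 1
        else:
            ibd = int(rng.choice(3, p=(0.25, 0.5, 0.25)))
        if ibd == 2:
            alleles = donor_alleles
        else:
            shared = (
                [donor_alleles[int(rng.integers(2))]] if ibd == 1 else []
            )
            fresh = [
                lf.ladder[int(k)]
                for k in sample_allele_indices(lf.frequencies, 2 - ibd, rng)
            ]
            alleles = tuple(shared + fresh)
        i, j = lf.index_of(alleles[0]), lf.index_of(alleles[1])
        if i > j:
            alleles = (alleles[1], alleles[0])
        genotypes[locus] = Genotype(locus=locus, alleles=tuple(alleles))
    return Profile(
        sample_id=sample_id or f"{donor.sample_id}-{relationship}",
        genotypes=genotypes,
        origin=relationship,
        donor_id=donor.sample_id,
    )


def generate_study(config: SimConfig, table: AlleleFrequencyTable) -> Study:
    """Build a full in-silico study from one shared subpopulation draw.

    One Dirichlet draw structures both the database and the stain donors.
    Stain donors are database members when ``stains_in_database`` (planted
    true matches) or separate individuals otherwise; stains are degraded to
    a uniform target length in ``stain_loci_range``; relatives are built
    from the *full* donor profile before degradation.
    """
    rng = np.random.default_rng(config.seed)
    model = ThetaModel(config.theta)
    subpop = dirichlet_subpop_frequencies(table, model, rng)
    loci = list(table.loci)

    database = tuple(
        sample_profile(subpop, loci, rng, sample_id=f"DB{i:06d}")
        for i in range(config.db_size)
    )

    lo, hi = config.stain_loci_range
    stains = []
    relatives = []
    for s in range(config.n_stains):
        if config.stains_in_database:
            donor_idx = int(rng.integers(config.db_size))
            donor = database[donor_idx]
        else:
            donor = sample_profile(
                subpop, loci, rng, sample_id=f"DONOR{s:05d}"
            )
        target = int(rng.integers(lo, hi + 1))
        stain = degrade_profile(
            Profile(
                sample_id=f"STAIN{s:05d}",
                genotypes=dict(donor.genotypes),
                origin="stain-donor",
                donor_id=donor.sample_id,
            ),
            target,
            rng,
        )
        stains.append(stain)
        for rel in config.relatives:
            relatives.append(
                simulate_relative(
                    donor, rel, subpop, rng,
                    sample_id=f"REL{s:05d}-{rel}",
                )
            )

    manifest = {
        "seed": config.seed,
        "theta": config.theta,
        "db_size": config.db_size,
        "n_stains": config.n_stains,
        "stain_loci_range": list(config.stain_loci_range),
        "relatives": list(config.relatives),
        "stains_in_database": config.stains_in_database,
        "loci": loci,
    }
    return Study(
        frequencies=subpop,
        database=database,
        stains=tuple(stains),
        relatives=tuple(relatives),
        manifest=manifest,
    )


# ---------------------------------------------------------------------------
# profile CSV dialect


def profiles_to_frame(profiles: Sequence[Profile]) -> pd.DataFrame:
    rows = [
        (p.sample_id, locus, g.alleles[0], g.alleles[1])
        for p in profiles
        for locus, g in sorted(p.genotypes.items())
    ]
    return pd.DataFrame(rows, columns=list(PROFILE_COLUMNS))


def write_profiles_csv(profiles: Sequence[Profile], path) -> None:
    profiles_to_frame(profiles).to_csv(path, index=False)


def load_profiles_csv(path, table: AlleleFrequencyTable) -> list[Profile]:
    """Read profiles (``sample_id,locus,allele1,allele2``), validating
    loci and alleles against the table and canonicalising allele order."""
    df = pd.read_csv(
        path, dtype={"sample_id": str, "locus": str, "allele1": str, "allele2": str}
    )
    missing = [c for c in PROFILE_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"{path}: missing column(s) {', '.join(missing)}")
    profiles = []
    for sample_id, sub in df.groupby("sample_id", sort=False):
        genotypes = {}
        for _, row in sub.iterrows():
            locus = row["locus"]
            if locus in genotypes:
                raise ValidationError(
                    f"{sample_id}: locus {locus} appears more than once"
                )
            lf = table[locus]
            a1, a2 = row["allele1"], row["allele2"]
            i, j = lf.index_of(a1), lf.index_of(a2)
            if i > j:
                a1, a2 = a2, a1
            genotypes[locus] = Genotype(locus=locus, alleles=(a1, a2))
        profiles.append(Profile(sample_id=str(sample_id), genotypes=genotypes))
    return profiles
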