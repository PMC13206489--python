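"""Allele-frequency tables for forensic STR loci.

A table holds, per locus, an ordered allele *ladder* (opaque string labels,
so microvariants like ``"9.3"`` survive round-trips), the frequencies aligned
to that ladder, and the number of typed individuals ``N`` from which the
frequencies were estimated.  The minimum allele frequency ``p_min = 5/(2N)``
guards against alleles that are rare in the reference sample: before any
probability calculation every frequency is floored at ``p_min`` and the locus
is renormalised so the frequencies form a proper distribution.

The canonical on-disk dialect is a long-format CSV with one row per allele
and columns ``locus,allele,frequency,n_typed``.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterator, Mapping

import numpy as np
import pandas as pd

REQUIRED_COLUMNS = ("locus", "allele", "frequency", "n_typed")


class FrequencyTableError(ValueError):
    """Base class for frequency-table problems."""


class FormatError(FrequencyTableError):
    """The CSV file does not have the expected shape."""


class ValidationError(FrequencyTableError):
    """The file parsed but its contents are not a valid frequency table."""


@dataclass(frozen=True)
class LocusFrequencies:
    """Allele ladder and frequencies for a single STR locus."""

    name: str
    ladder: tuple[str, ...]
    frequencies: np.ndarray
    n_typed: int
    corrected: bool = False
    #: number of alleles that were below p_min before correction
    n_rare: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "frequencies", np.asarray(self.frequencies, dtype=float)
        )
        if len(self.ladder) != len(self.frequencies):
            raise ValidationError(
                f"{self.name}: ladder and frequencies differ in length"
            )
        if len(self.ladder) < 2:
            raise ValidationError(
                f"{self.name}: a locus needs at least 2 alleles"
            )
        if len(set(self.ladder)) != len(self.ladder):
            raise ValidationError(f"{self.name}: duplicate allele labels")
        if self.n_typed <= 0:
            raise ValidationError(f"{self.name}: n_typed must be positive")
        freqs = self.frequencies
        if np.any(freqs < 0) or np.any(freqs > 1):
            raise ValidationError(
                f"{self.name}: frequencies must lie in [0, 1]"
            )

    @property
    def p_min(self) -> float:
        """Minimum allele frequency, the conservative ``5/(2N)`` rule."""
        return 5.0 / (2.0 * self.n_typed)

    @property
    def n_alleles(self) -> int:
        return len(self.ladder)

    def index_of(self, allele: str) -> int:
        try:
            return self.ladder.index(allele)
        except ValueError:
            raise KeyError(
                f"allele {allele!r} not in ladder of locus {self.name}"
            ) from None


@dataclass(frozen=True)
class AlleleFrequencyTable:
    """Per-locus allele ladders and frequencies for a reference population."""

    loci_data: Mapping[str, LocusFrequencies]
    corrected: bool = False

    @property
    def loci(self) -> tuple[str, ...]:
        return tuple(self.loci_data)

    def __getitem__(self, locus: str) -> LocusFrequencies:
        try:
            return self.loci_data[locus]
        except KeyError:
            raise KeyError(f"locus {locus!r} not in table") from None

    def __contains__(self, locus: str) -> bool:
        return locus in self.loci_data

    def __iter__(self) -> Iterator[str]:
        return iter(self.loci_data)

    def __len__(self) -> int:
        return len(self.loci_data)

    @property
    def rare_allele_counts(self) -> dict[str, int]:
        """Per-locus count of alleles floored at p_min by :func:`apply_pmin`."""
        return {name: lf.n_rare for name, lf in self.loci_data.items()}

    @property
    def n_rare_alleles(self) -> int:
        return sum(self.rare_allele_counts.values())

    def to_frame(self) -> pd.DataFrame:
        rows = [
            (lf.name, allele, freq, lf.n_typed)
            for lf in self.loci_data.values()
            for allele, freq in zip(lf.ladder, lf.frequencies)
        ]
        return pd.DataFrame(rows, columns=list(REQUIRED_COLUMNS))

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def load_frequency_table(path) -> AlleleFrequencyTable:
    """Read a long-format frequency CSV (``locus,allele,frequency,n_typed``).

    Frequencies are returned exactly as stored: no flooring and no silent
    renormalisation happens at load time (that is :func:`apply_pmin`'s job),
    so a locus whose raw frequencies sum to 0.98 is accepted here.
    """
    try:
        df = pd.read_csv(path, dtype={"locus": str, "allele": str})
    except (pd.errors.ParserError, pd.errors.EmptyDataError) as exc:
        raise FormatError(f"cannot parse {path}: {exc}") from exc
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing column(s) {', '.join(missing)}")

    if df.duplicated(subset=["locus", "allele"]).any():
        dup = df[df.duplicated(subset=["locus", "allele"])].iloc[0]
        raise ValidationError(
            f"duplicate entry for ({dup['locus']}, {dup['allele']})"
        )

    loci_data: dict[str, LocusFrequencies] = {}
    for locus, sub in df.groupby("locus", sort=False):
        n_typed_vals = sub["n_typed"].unique()
        if len(n_typed_vals) != 1:
            raise ValidationError(f"{locus}: n_typed varies within the locus")
        freqs = sub["frequency"].to_numpy(dtype=float)
        if np.any(~np.isfinite(freqs)):
            raise ValidationError(f"{locus}: non-finite frequency")
        loci_data[str(locus)] = LocusFrequencies(
            name=str(locus),
            ladder=tuple(sub["allele"].astype(str)),
            frequencies=freqs,
            n_typed=int(n_typed_vals[0]),
        )
    if not loci_data:
        raise ValidationError(f"{path}: no loci found")
    return AlleleFrequencyTable(loci_data=loci_data)


def _floor_and_renormalise(freqs: np.ndarray, p_min: float) -> np.ndarray:
    """Floor frequencies at p_min and renormalise to a proper distribution.

    Renormalising after flooring can push a borderline frequency back under
    p_min, so the clamped set is grown until the result is a fixed point:
    clamped alleles sit exactly at p_min and the rest are scaled by a common
    factor.  This keeps both guarantees downstream code relies on: the
    frequencies sum to one, and none is below p_min (up to float round-off).
    """
    if p_min * len(freqs) >= 1.0:
        raise ValidationError(
            "p_min correction infeasible: p_min * n_alleles >= 1"
        )
    clamped = freqs < p_min
    while True:
        free_sum = freqs[~clamped].sum()
        scale = (1.0 - p_min * clamped.sum()) / free_sum
        out = np.where(clamped, p_min, scale * freqs)
        newly = (~clamped) & (out < p_min * (1.0 - 1e-12))
        if not newly.any():
            return out
        clamped |= newly


def apply_pmin(table: AlleleFrequencyTable) -> AlleleFrequencyTable:
    """Apply the ``5/(2N)`` minimum-frequency correction to every locus.

    Frequencies below p_min are raised to p_min and each locus is then
    renormalised to sum to one.  The operation is idempotent, and the number
    of corrected ("rare") alleles is recorded per locus.
    """
    loci_data: dict[str, LocusFrequencies] = {}
    for name, lf in table.loci_data.items():
        p_min = lf.p_min
        below = lf.frequencies < p_min * (1.0 - 1e-12)
        n_rare = lf.n_rare if lf.corrected else int(below.sum())
        if below.any():
            freqs = _floor_and_renormalise(lf.frequencies, p_min)
        else:
            freqs = lf.frequencies
        loci_data[name] = replace(
            lf, frequencies=freqs, corrected=True, n_rare=n_rare
        )
    return AlleleFrequencyTable(loci_data=loci_data, corrected=True)
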