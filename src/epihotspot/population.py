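"""Population allele-frequency tables and frequency-weighted hotspot burden.

Frequencies are allele frequencies on the 2n-alleles basis, as reported by
the Allele Frequency Net Database, in decimal form in [0, 1].  No
Hardy-Weinberg phenotype conversion is applied.  A blank cell means the
allele was not typed in that population — distinct from an observed
frequency of 0 — and is kept as missing (NaN): absent alleles are excluded
from burden sums and reported, never silently treated as zero.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence, Set

import numpy as np
import pandas as pd

from .errors import ValidationError


@dataclass(frozen=True)
class AlleleFrequencyTable:
    """Allele x population frequency matrix with optional sample sizes.

    ``frequencies`` is indexed by allele name with one column per
    population; missing entries are NaN.  ``sample_sizes`` maps population
    name to the number of individuals typed (frequencies are per 2n
    chromosomes).
    """

    frequencies: pd.DataFrame
    sample_sizes: Mapping[str, int] | None = None

    def __post_init__(self) -> None:
        if self.frequencies.index.has_duplicates:
            dupes = self.frequencies.index[self.frequencies.index.duplicated()].tolist()
            raise ValidationError(f"duplicate allele rows: {dupes}")
        if self.frequencies.columns.has_duplicates:
            raise ValidationError("population column names must be unique")
        values = self.frequencies.to_numpy(dtype=float)
        with np.errstate(invalid="ignore"):
            bad = (values < 0) | (values > 1)
        if np.any(bad & ~np.isnan(values)):
            rows, cols = np.nonzero(bad & ~np.isnan(values))
            allele = self.frequencies.index[rows[0]]
            pop = self.frequencies.columns[cols[0]]
            raise ValidationError(
                f"frequency outside [0, 1] at allele {allele!r}, "
                f"population {pop!r}: {values[rows[0], cols[0]]}"
            )

    @property
    def populations(self) -> list[str]:
        return list(self.frequencies.columns)

    @property
    def alleles(self) -> list[str]:
        return list(self.frequencies.index)

    def frequency(self, allele: str, population: str) -> float:
        """Frequency of an allele in a population (NaN if not typed)."""
        self._check_population(population)
        if allele not in self.frequencies.index:
            raise ValidationError(f"unknown allele {allele!r}")
        return float(self.frequencies.loc[allele, population])

    def _check_population(self, population: str) -> None:
        if population not in self.frequencies.columns:
            raise ValidationError(
                f"unknown population {population!r}; available: {self.populations}"
            )

    def all_absent_populations(self) -> list[str]:
        """Populations with no typed allele at all (entire column missing)."""
        return [p for p in self.populations if self.frequencies[p].isna().all()]


def read_frequency_table(path: str | Path) -> AlleleFrequencyTable:
    """Read an AFND-style CSV: first column ``allele``, one column per
    population, optional ``n_<population>`` sample-size columns.

    Blank cells load as missing (NaN), distinct from 0.
    """
    df = pd.read_csv(Path(path), dtype={0: str})
    if df.columns[0] != "allele":
        raise ValidationError(
            f"first CSV column must be 'allele', got {df.columns[0]!r}"
        )
    df = df.set_index("allele")
    size_cols = [c for c in df.columns if c.startswith("n_")]
    sample_sizes = None
    if size_cols:
        sample_sizes = {}
        for c in size_cols:
            col = df[c].dropna()
            if not col.empty:
                sample_sizes[c[2:]] = int(col.iloc[0])
        df = df.drop(columns=size_cols)
    df = df.astype(float)
    table = AlleleFrequencyTable(frequencies=df, sample_sizes=sample_sizes)
    absent = table.all_absent_populations()
    if absent:
        warnings.warn(f"populations with no typed alleles: {absent}", stacklevel=2)
    return table


def filter_by_frequency(
    table: AlleleFrequencyTable,
    population: str,
    min_freq: float,
    inclusive: bool = False,
) -> list[str]:
    """Alleles whose frequency in a population exceeds ``min_freq``.

    The comparison is strict ('>') by default; pass ``inclusive=True`` for
    '>='.  Untyped (missing) alleles never pass.  Results are sorted by
    descending frequency, ties broken by allele name.
    """
    table._check_population(population)
    col = table.frequencies[population]
    if inclusive:
        mask = col >= min_freq
    else:
        mask = col > min_freq
    passing = col[mask & col.notna()]
    return sorted(passing.index, key=lambda a: (-passing[a], a))


@dataclass(frozen=True)
class PopulationBurden:
    """Frequency-weighted strong-binder burden per hotspot start.

    ``burden[p]`` is the sum over panel alleles of the allele's frequency in
    the population times an indicator that the allele binds the core at
    start p strongly.  It approximates, position by position, how much of
    the population carries an HLA allele for which that core is a hotspot
    (upper-bounded by the summed panel frequencies).
    """

    population: str
    burden: pd.Series
    skipped_alleles: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if (self.burden < 0).any():
            raise ValidationError("burden entries must be non-negative")


def weighted_hotspot_burden(
    per_allele_hotspots: Mapping[str, Set[int]],
    table: AlleleFrequencyTable,
    population: str,
) -> PopulationBurden:
    """Aggregate per-allele SB start sets into a frequency-weighted burden.

    Alleles missing from the table, or untyped in the population, are
    skipped with a warning and reported in ``skipped_alleles``.
    """
    table._check_population(population)
    totals: dict[int, float] = {}
    skipped: list[str] = []
    for allele, starts in per_allele_hotspots.items():
        if allele not in table.frequencies.index:
            skipped.append(allele)
            continue
        freq = table.frequencies.loc[allele, population]
        if pd.isna(freq):
            skipped.append(allele)
            continue
        for start in starts:
            totals[start] = totals.get(start, 0.0) + float(freq)
    if skipped:
        warnings.warn(
            f"alleles without a frequency in {population!r} skipped: {sorted(skipped)}",
            stacklevel=2,
        )
    burden = pd.Series(totals, dtype=float).sort_index()
    burden.index.name = "start"
    burden.name = "burden"
    return PopulationBurden(
        population=population, burden=burden, skipped_alleles=tuple(sorted(skipped))
    )


def write_burden_tsv(burden: PopulationBurden, path: str | Path) -> None:
    """Write a burden vector as TSV (position, burden); 1-based positions."""
    path = Path(path)
    with path.open("w") as fh:
        fh.write(f"# frequency-weighted SB burden, population={burden.population}; "
                 "position is 1-based core start\n")
        fh.write("position\tburden\n")
        for pos, value in burden.burden.items():
            fh.write(f"{pos}\t{value:.6g}\n")
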