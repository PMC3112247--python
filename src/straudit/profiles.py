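"""Genotype profile containers and tabular I/O.

A profile is one individual's unordered allele-length pair at each
microsatellite locus, plus the catch year, genotyping laboratory and the
multiplex assay each locus was amplified in.  Profiles are exchanged as
tab-separated tables with one row per individual x locus:

    individual_id  year  lab  locus  allele1  allele2  multiplex

Allele pairs are phase-free: storage and output are canonicalized with the
smaller length first, and readers accept either order.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

from . import nmdr

PROFILE_COLUMNS = ["individual_id", "year", "lab", "locus",
                   "allele1", "allele2", "multiplex"]


class ProfileFormatError(ValueError):
    """A profile table is malformed (missing columns, bad values)."""


class ProfileIntegrityError(ValueError):
    """A profile table is internally inconsistent (conflicting duplicates)."""


@dataclasses.dataclass(frozen=True)
class GenotypeProfile:
    """One individual's multilocus microsatellite genotype.

    Parameters
    ----------
    individual_id
        Opaque sample identifier.
    year
        Calendar catch year.
    lab
        Genotyping laboratory factor level (e.g. ``"Lab1"``).
    genotypes
        Mapping locus name -> unordered pair of allele lengths in bp,
        stored sorted ascending.  A homozygote has two equal lengths.
    multiplex_of
        Mapping locus name -> multiplex assay id; must cover exactly the
        loci present in ``genotypes``.
    """

    individual_id: str
    year: int
    lab: str
    genotypes: dict[str, tuple[int, int]]
    multiplex_of: dict[str, str]

    def __post_init__(self):
        canon = {}
        for locus, pair in self.genotypes.items():
            if len(pair) != 2:
                raise ProfileFormatError(
                    f"{self.individual_id}/{locus}: genotype must have 2 alleles")
            a, b = int(pair[0]), int(pair[1])
            if a <= 0 or b <= 0:
                raise ProfileFormatError(
                    f"{self.individual_id}/{locus}: allele lengths must be positive")
            canon[locus] = (a, b) if a <= b else (b, a)
        object.__setattr__(self, "genotypes", canon)
        if set(self.multiplex_of) != set(self.genotypes):
            raise ProfileFormatError(
                f"{self.individual_id}: multiplex map must cover exactly the "
                f"genotyped loci")

    @property
    def loci(self) -> list[str]:
        return sorted(self.genotypes)


@dataclasses.dataclass
class AuditConfig:
    """Tunable knobs shared across pipeline stages.

    ``n_draws`` is the Monte-Carlo sample size used to average
    individual-specific error probabilities over the random-effect
    distribution; ``n_boot`` the number of cluster-bootstrap replicates;
    ``center_year`` the constant subtracted from the calendar year so that
    the YEAR covariate is 0 mid-study.
    """

    loci: list[str] = dataclasses.field(default_factory=lambda: list(nmdr.LOCI))
    multiplex_of: dict[str, str] = dataclasses.field(
        default_factory=lambda: dict(nmdr.MULTIPLEXES))
    center_year: int = nmdr.CENTER_YEAR
    n_draws: int = 1_000_000
    n_boot: int = 500
    quad_order: int = 20
    seed: int = 0

    def __post_init__(self):
        if self.n_draws < 1:
            raise ValueError("n_draws must be >= 1")
        if self.n_boot < 1:
            raise ValueError("n_boot must be >= 1")
        years = sorted(nmdr.YEARS)
        if not (years[0] <= self.center_year <= years[-1]):
            raise ValueError("center_year must lie within the study period")


def profiles_to_frame(profiles: Iterable[GenotypeProfile]) -> pd.DataFrame:
    """Canonical long-format table: sorted by individual then locus,
    alleles min-first."""
    rows = []
    for p in profiles:
        for locus in sorted(p.genotypes):
            a1, a2 = p.genotypes[locus]
            rows.append((p.individual_id, p.year, p.lab, locus, a1, a2,
                         p.multiplex_of[locus]))
    frame = pd.DataFrame(rows, columns=PROFILE_COLUMNS)
    return frame.sort_values(["individual_id", "locus"], kind="mergesort",
                             ignore_index=True)


def frame_to_profiles(frame: pd.DataFrame) -> list[GenotypeProfile]:
    missing = [c for c in PROFILE_COLUMNS if c not in frame.columns]
    if missing:
        raise ProfileFormatError(f"missing column(s): {', '.join(missing)}")
    profiles = []
    for ind, grp in frame.groupby("individual_id", sort=True):
        genotypes: dict[str, tuple[int, int]] = {}
        multiplex: dict[str, str] = {}
        years = grp["year"].unique()
        labs = grp["lab"].unique()
        if len(years) != 1 or len(labs) != 1:
            raise ProfileIntegrityError(
                f"{ind}: inconsistent year/lab across rows")
        for row in grp.itertuples(index=False):
            pair = tuple(sorted((int(row.allele1), int(row.allele2))))
            if row.locus in genotypes:
                if genotypes[row.locus] != pair:
                    raise ProfileIntegrityError(
                        f"{ind}/{row.locus}: duplicate rows with conflicting alleles")
                continue
            genotypes[row.locus] = pair
            multiplex[row.locus] = str(row.multiplex)
        profiles.append(GenotypeProfile(str(ind), int(years[0]), str(labs[0]),
                                        genotypes, multiplex))
    return profiles


def read_profiles(path: str | Path, sep: str = "\t") -> list[GenotypeProfile]:
    """Read a delimited profile table; one profile per distinct individual.

    Rows may appear in any order and alleles in either order; the result is
    canonical.  Duplicate (individual, locus) rows must agree.
    """
    frame = pd.read_csv(path, sep=sep)
    return frame_to_profiles(frame)


def write_profiles(profiles: Iterable[GenotypeProfile], path: str | Path,
                   sep: str = "\t") -> None:
    """Write the canonical sorted table (alleles min-first, UTF-8)."""
    profiles_to_frame(profiles).to_csv(path, sep=sep, index=False)
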