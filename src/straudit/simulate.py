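"""Synthetic DNA-register generator.

The real register profiles are not public, so every downstream stage is
exercised on simulated data carrying the same statistical structure: true
genotypes drawn from Hardy--Weinberg pairs of per-locus allele-frequency
spectra; binary error events from the mixed logistic model (individual
and multiplex-within-individual Gaussian random intercepts on the logit
scale); and, conditional on an error, one of the four observable error
categories realized by mutating allele lengths.

Mutation semantics (the audit reports outcomes, not mechanisms; these
choices reproduce exactly the four observable categories):

* single false allele — one allele of a heterozygote is shifted;
* double false allele — both alleles are shifted independently;
* false homozygote    — one allele of a heterozygote is overwritten by
  the other;
* false heterozygote  — one allele of a homozygote is shifted.

Shift magnitudes are 1 bp with probability ``p_shift_1bp`` and otherwise
one repeat unit (2 or 4 bp depending on the locus), with a random sign.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
from scipy.special import expit

from . import nmdr
from .profiles import GenotypeProfile


@dataclasses.dataclass
class SimulationDesign:
    """Sampling frame of the synthetic register audit."""

    samples_per_year: dict[int, int] = dataclasses.field(
        default_factory=lambda: dict(nmdr.SAMPLES_PER_YEAR))
    lab_of_year: dict[int, str] = dataclasses.field(
        default_factory=lambda: dict(nmdr.LAB_OF_YEAR))
    loci: list[str] = dataclasses.field(default_factory=lambda: list(nmdr.LOCI))
    multiplex_of: dict[str, str] = dataclasses.field(
        default_factory=lambda: dict(nmdr.MULTIPLEXES))
    allele_freqs: dict[str, tuple[np.ndarray, np.ndarray]] | None = None

    def __post_init__(self):
        missing = set(self.samples_per_year) - set(self.lab_of_year)
        if missing:
            raise ValueError(f"lab schedule does not cover year(s) {sorted(missing)}")
        if set(self.multiplex_of) < set(self.loci):
            raise ValueError("multiplex map must cover all loci")
        if self.allele_freqs is not None:
            for locus, (lengths, probs) in self.allele_freqs.items():
                if not np.isclose(np.sum(probs), 1.0):
                    raise ValueError(f"{locus}: allele frequencies must sum to 1")

    @classmethod
    def default(cls, seed: int = 0) -> "SimulationDesign":
        design = cls()
        design.allele_freqs = default_allele_frequencies(design.loci, seed)
        return design

    @property
    def n_individuals(self) -> int:
        return sum(self.samples_per_year.values())


# Default error-type mixture: the audit's 31 classified errors
# (12 single / 6 double false allele sizes, 10 false homozygotes,
# 3 false heterozygotes).
DEFAULT_MIXTURE: dict[str, float] = {
    "single_false_allele": 12 / 31,
    "double_false_allele": 6 / 31,
    "false_homozygote": 10 / 31,
    "false_heterozygote": 3 / 31,
}

_HET_CLASSES = ["single_false_allele", "double_false_allele", "false_homozygote"]
_HOM_CLASSES = ["false_heterozygote"]


@dataclasses.dataclass
class TrueModelParams:
    """Generative parameters of the error process (logit scale).

    ``locus_coefs`` lists offsets for error-prone loci; loci named in
    ``error_free_loci`` never err (emulating a locus with no observed
    errors).  The error-type ``mixture`` is renormalized within genotype
    class: a heterozygote can yield single/double false alleles or a false
    homozygote, a homozygote only a false heterozygote (shifting one
    allele of a homozygote *is* the false-heterozygote outcome) or a
    double false allele.
    """

    intercept: float = nmdr.M1_INTERCEPT
    locus_coefs: dict[str, float] = dataclasses.field(
        default_factory=lambda: dict(nmdr.M1_LOCUS_COEF))
    year_slope: float = nmdr.M1_YEAR_SLOPE
    lab_coefs: dict[str, float] = dataclasses.field(default_factory=dict)
    sigma_ind: float = float(np.sqrt(nmdr.M1_VAR_IND))
    sigma_mp: float = 0.0
    mixture: dict[str, float] = dataclasses.field(
        default_factory=lambda: dict(DEFAULT_MIXTURE))
    p_shift_1bp: float = 0.45
    center_year: int = nmdr.CENTER_YEAR
    error_free_loci: list[str] = dataclasses.field(
        default_factory=lambda: list(nmdr.ERROR_FREE_LOCI))

    def __post_init__(self):
        if self.sigma_ind < 0 or self.sigma_mp < 0:
            raise ValueError("random-effect SDs must be non-negative")
        tot = sum(self.mixture.values())
        if not np.isclose(tot, 1.0):
            raise ValueError("error-type mixture must sum to 1")

    def linear_predictor(self, locus: str, year: int, lab: str) -> float:
        eta = self.intercept + self.locus_coefs.get(locus, 0.0)
        eta += self.year_slope * (year - self.center_year)
        eta += self.lab_coefs.get(lab, 0.0)
        return eta


def default_allele_frequencies(loci: Sequence[str], seed: int = 0,
                               ranges: Mapping[str, tuple[int, int]] | None = None,
                               concentration: float = 1.0
                               ) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    """Dirichlet-drawn allele-frequency spectra on each locus's repeat ladder.

    The support steps through the locus's observed length range by its
    repeat unit (4 bp for tetranucleotide GATA markers, 2 bp otherwise).
    The true spectra of the register population are unpublished; these are
    synthetic placeholders with realistic support.
    """
    if ranges is None:
        ranges = nmdr.ALLELE_RANGES
    rng = np.random.default_rng(seed)
    out = {}
    for locus in loci:
        lo, hi = ranges[locus]
        step = nmdr.REPEAT_UNIT.get(locus, 2)
        lengths = np.arange(lo, hi + 1, step)
        probs = rng.dirichlet(np.full(len(lengths), concentration))
        out[locus] = (lengths, probs)
    return out


def _renormalized_mixture(mixture: Mapping[str, float], is_het: bool
                          ) -> tuple[list[str], np.ndarray]:
    classes = _HET_CLASSES if is_het else _HOM_CLASSES
    weights = np.array([mixture.get(c, 0.0) for c in classes], float)
    if weights.sum() <= 0:
        raise ValueError("error-type mixture incompatible with genotype class")
    return classes, weights / weights.sum()


def _draw_shift(rng: np.random.Generator, repeat: int, p1: float) -> int:
    mag = 1 if rng.random() < p1 else repeat
    return mag if rng.random() < 0.5 else -mag


def _mutate(rng: np.random.Generator, true_gt: tuple[int, int], cls: str,
            repeat: int, p1: float) -> tuple[int, int]:
    """Apply one error class to a genotype, guaranteeing the observed pair
    realizes exactly that class when re-classified."""
    a, b = true_gt
    for _ in range(100):
        if cls == "single_false_allele":
            # shift one allele of a het, avoiding collision with its partner
            if rng.random() < 0.5:
                new = a + _draw_shift(rng, repeat, p1)
                obs = (new, b)
            else:
                new = b + _draw_shift(rng, repeat, p1)
                obs = (a, new)
            if new > 0 and new not in (a, b):
                return tuple(sorted(obs))
        elif cls == "double_false_allele":
            na = a + _draw_shift(rng, repeat, p1)
            nb = b + _draw_shift(rng, repeat, p1)
            if na > 0 and nb > 0 and na != nb \
                    and na not in (a, b) and nb not in (a, b):
                return tuple(sorted((na, nb)))
        elif cls == "false_homozygote":
            keep = a if rng.random() < 0.5 else b
            return (keep, keep)
        elif cls == "false_heterozygote":
            new = a + _draw_shift(rng, repeat, p1)
            if new > 0 and new != a:
                return tuple(sorted((a, new)))
        else:
            raise ValueError(f"unknown error class {cls!r}")
    raise RuntimeError(f"could not realize error class {cls} at genotype {true_gt}")


def simulate_register(design: SimulationDesign, params: TrueModelParams,
                      seed: int = 0
                      ) -> tuple[list[GenotypeProfile], list[GenotypeProfile]]:
    """Generate paired (true, observed-register) profile sets.

    True genotypes are Hardy--Weinberg draws from the design's allele
    spectra.  Per individual a random intercept ``b_i ~ N(0, sigma_ind^2)``
    and per multiplex block ``b_im ~ N(0, sigma_mp^2)`` are drawn; an error
    occurs at locus ``l`` with probability ``logistic(eta_il)``, in which
    case an error type is drawn from the genotype-class-renormalized
    mixture and the observed genotype is mutated accordingly.  Error-free
    loci and non-error loci are copied verbatim into the register set.
    """
    rng = np.random.default_rng(seed)
    freqs = design.allele_freqs
    if freqs is None:
        freqs = default_allele_frequencies(design.loci,
                                           seed=int(rng.integers(2 ** 31)))
    true_profiles: list[GenotypeProfile] = []
    obs_profiles: list[GenotypeProfile] = []
    mp_ids = sorted({design.multiplex_of[l] for l in design.loci})
    counter = 0
    for year in sorted(design.samples_per_year):
        lab = design.lab_of_year[year]
        for _ in range(design.samples_per_year[year]):
            ind = f"ind{counter:05d}"
            counter += 1
            b_i = rng.normal(0.0, params.sigma_ind) if params.sigma_ind > 0 else 0.0
            b_im = {mp: (rng.normal(0.0, params.sigma_mp)
                         if params.sigma_mp > 0 else 0.0) for mp in mp_ids}
            true_gts: dict[str, tuple[int, int]] = {}
            obs_gts: dict[str, tuple[int, int]] = {}
            mp_map = {l: design.multiplex_of[l] for l in design.loci}
            for locus in design.loci:
                lengths, probs = freqs[locus]
                pair = rng.choice(lengths, size=2, p=probs)
                gt = tuple(sorted(int(x) for x in pair))
                true_gts[locus] = gt
                if locus in params.error_free_loci:
                    obs_gts[locus] = gt
                    continue
                eta = params.linear_predictor(locus, year, lab) \
                    + b_i + b_im[mp_map[locus]]
                if rng.random() < expit(eta):
                    is_het = gt[0] != gt[1]
                    classes, w = _renormalized_mixture(params.mixture, is_het)
                    cls = classes[rng.choice(len(classes), p=w)]
                    obs_gts[locus] = _mutate(rng, gt, cls,
                                             nmdr.REPEAT_UNIT.get(locus, 2),
                                             params.p_shift_1bp)
                else:
                    obs_gts[locus] = gt
            true_profiles.append(GenotypeProfile(ind, year, lab, true_gts, mp_map))
            obs_profiles.append(GenotypeProfile(ind, year, lab, obs_gts,
                                                dict(mp_map)))
    return true_profiles, obs_profiles


def write_sidecar(path: str | Path, params: TrueModelParams, seed: int,
                  design: SimulationDesign) -> None:
    """Record generative parameters and seed next to emitted profile tables."""
    doc = {
        "seed": seed,
        "intercept": params.intercept,
        "locus_coefs": params.locus_coefs,
        "year_slope": params.year_slope,
        "lab_coefs": params.lab_coefs,
        "sigma_ind": params.sigma_ind,
        "sigma_mpind": params.sigma_mp,
        "mixture": params.mixture,
        "p_shift_1bp": params.p_shift_1bp,
        "center_year": params.center_year,
        "error_free_loci": params.error_free_loci,
        "n_individuals": design.n_individuals,
        "samples_per_year": design.samples_per_year,
    }
    Path(path).write_text(json.dumps(doc, indent=2, sort_keys=True))
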