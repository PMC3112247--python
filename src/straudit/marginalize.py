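"""Population-averaged error rates and multilocus (profile-match) summaries.

Under the mixed model an individual's per-locus error probability is
``logistic(mu_l + eta)`` with ``eta`` the individual's Gaussian random
effect.  The population-averaged (marginal) rate is the expectation of
that probability over ``eta ~ N(0, sigma^2)``, estimated here by plain
Monte Carlo.

For profile matching against a register what matters is the distribution
of ``E``, the number of loci in a profile with at least one error.  With
per-individual probabilities ``p_il``:

    P_i(E > 0) = 1 - prod_l (1 - p_il)
    P_i(E = 1) = sum_l p_il * prod_{k != l} (1 - p_ik)

Averaging these over the random effect ("dependence" scenario) captures
the within-individual correlation of errors; substituting the marginal
rates ``p_l`` directly ("independence" scenario) ignores it.  The shared
random effect concentrates errors in few individuals, so the conditional
probability of a second error given a first, P(E>1 | E>0), is markedly
larger under dependence.
"""

from __future__ import annotations

import dataclasses
from typing import Mapping, Sequence

import numpy as np
from scipy.special import expit
from scipy.stats import norm

from .glmm import FitResult


@dataclasses.dataclass
class MarginalRates:
    """Per-locus population-averaged rates at one calendar year."""

    year: int
    rates: dict[str, float]
    mc_se: dict[str, float]

    @property
    def across_locus_mean(self) -> float:
        return float(np.mean(list(self.rates.values())))


@dataclasses.dataclass
class MultilocusSummary:
    """Distribution summary of the multilocus error count E (fractions).

    ``p_any`` = P(E>0), ``p_one`` = P(E=1), ``p_multi`` = P(E>1) and
    ``p_multi_given_any`` = P(E>1 | E>0); ``scenario`` records whether the
    numbers come from the dependence (shared random effect) or the
    independence computation.
    """

    scenario: str
    p_any: float
    p_one: float
    p_multi: float

    @property
    def p_multi_given_any(self) -> float:
        return self.p_multi / self.p_any if self.p_any > 0 else 0.0

    def percent(self) -> dict[str, float]:
        return {
            "P(E>0)": 100.0 * self.p_any,
            "P(E=1)": 100.0 * self.p_one,
            "P(E>1)": 100.0 * self.p_multi,
            "P(E>1|E>0)": 100.0 * self.p_multi_given_any,
        }


def mc_marginal_rate(mu: float, sigma: float, n_draws: int = 1_000_000,
                     seed: int | np.random.Generator = 0) -> tuple[float, float]:
    """Monte-Carlo marginal rate E[logistic(mu + eta)], eta ~ N(0, sigma^2).

    Returns ``(rate, mc_standard_error)``; with sigma = 0 the rate is
    exactly ``logistic(mu)`` and the SE is 0.
    """
    if n_draws < 1:
        raise ValueError("n_draws must be >= 1")
    if sigma < 0:
        raise ValueError("sigma must be non-negative")
    if sigma == 0.0:
        return float(expit(mu)), 0.0
    rng = seed if isinstance(seed, np.random.Generator) \
        else np.random.default_rng(seed)
    p = expit(mu + rng.normal(0.0, sigma, n_draws))
    return float(p.mean()), float(p.std(ddof=1) / np.sqrt(n_draws))


def predictors_from_fit(fit: FitResult, year: int) -> dict[str, float]:
    """Per-locus linear predictors (fixed part) at a calendar year.

    For YEAR models the slope is applied to ``year - center_year``; for
    LAB models the lab serving that year must be resolvable from the
    study's lab schedule.  Loci dropped from the fit (zero observed
    errors) are omitted; they are reported as zero-rate downstream.
    """
    beta = fit.beta
    mu0 = beta["Intercept"]
    if "YEAR" in beta:
        mu0 += beta["YEAR"] * (year - fit.center_year)
    elif any(name.startswith("LAB[") for name in beta):
        from . import nmdr
        lab = nmdr.LAB_OF_YEAR.get(year)
        if lab is None:
            raise ValueError(f"no laboratory on record for year {year}")
        mu0 += beta.get(f"LAB[{lab}]", 0.0)
    out = {}
    for locus in fit.locus_levels:
        out[locus] = mu0 + fit.beta.get(f"LOCUS[{locus}]", 0.0)
    if not any(name.startswith("LOCUS[") for name in beta) and not fit.locus_levels:
        raise ValueError("fit carries no locus levels to project")
    return out


def marginal_rate_table(fit_or_predictors: FitResult | Mapping[str, float],
                        year: int, sigma: float | None = None,
                        n_draws: int = 1_000_000, seed: int = 0,
                        zero_rate_loci: Sequence[str] = ()) -> MarginalRates:
    """Population-averaged per-locus rates at one year.

    Accepts either a :class:`FitResult` (predictors and sigma are derived
    from it; its dropped loci are reported as exactly 0) or a ready-made
    mapping locus -> linear predictor together with an explicit ``sigma``.
    The same random draws are reused across loci, mirroring the shared
    random effect.
    """
    if isinstance(fit_or_predictors, FitResult):
        fit = fit_or_predictors
        from . import nmdr
        if not (min(nmdr.YEARS) <= year <= max(nmdr.YEARS)):
            import warnings
            warnings.warn(f"year {year} lies outside the study period; "
                          "projection is an extrapolation", RuntimeWarning)
        predictors = predictors_from_fit(fit, year)
        if sigma is None:
            sigma = fit.sigma_ind if fit.sigma_ind > 0 else fit.sigma_mp
        zero_rate_loci = tuple(fit.dropped_loci) if not zero_rate_loci \
            else tuple(zero_rate_loci)
    else:
        predictors = dict(fit_or_predictors)
        if sigma is None:
            raise ValueError("sigma is required with explicit predictors")
    rng = np.random.default_rng(seed)
    loci = list(predictors)
    if sigma == 0.0:
        rates = {l: float(expit(predictors[l])) for l in loci}
        ses = {l: 0.0 for l in loci}
    else:
        eta = rng.normal(0.0, sigma, n_draws)
        rates, ses = {}, {}
        for l in loci:
            p = expit(predictors[l] + eta)
            rates[l] = float(p.mean())
            ses[l] = float(p.std(ddof=1) / np.sqrt(n_draws))
    for l in zero_rate_loci:
        rates[l] = 0.0
        ses[l] = 0.0
    return MarginalRates(year, rates, ses)


def multilocus_independent(rates: Sequence[float] | Mapping[str, float]
                           ) -> MultilocusSummary:
    """Closed-form multilocus summary assuming independent loci.

    ``P(E>0) = 1 - prod(1-p_l)`` and ``P(E=1) = sum_l p_l prod_{k!=l}
    (1-p_k)`` evaluated from the supplied per-locus rates.
    """
    p = np.asarray(list(rates.values()) if isinstance(rates, Mapping)
                   else rates, float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("rates must lie in [0, 1]")
    q = 1.0 - p
    prod_q = q.prod()
    p_any = 1.0 - prod_q
    # sum_l p_l * prod_{k != l} q_k, robust to q_l = 0
    p_one = 0.0
    for l in range(len(p)):
        others = np.delete(q, l).prod()
        p_one += p[l] * others
    # p_one is computed directly and can exceed p_any by float rounding
    return MultilocusSummary("independence", float(p_any), float(p_one),
                             max(0.0, float(p_any - p_one)))


def multilocus_dependent(predictors: Sequence[float] | Mapping[str, float],
                         sigma: float, n_draws: int = 1_000_000,
                         seed: int = 0, batch: int = 200_000
                         ) -> MultilocusSummary:
    """Monte-Carlo multilocus summary under a shared random effect.

    Draws ``eta ~ N(0, sigma^2)`` once per simulated individual, computes
    the conditional profile probabilities from ``p_il = logistic(mu_l +
    eta)`` jointly over all loci, and averages.  Loci with zero rate
    (e.g. excluded error-free loci) may simply be omitted: they contribute
    p = 0 and do not change the summary.
    """
    mus = np.asarray(list(predictors.values())
                     if isinstance(predictors, Mapping) else predictors, float)
    if n_draws < 1:
        raise ValueError("n_draws must be >= 1")
    rng = np.random.default_rng(seed)
    tot_any = 0.0
    tot_one = 0.0
    done = 0
    while done < n_draws:
        m = min(batch, n_draws - done)
        eta = rng.normal(0.0, sigma, m) if sigma > 0 else np.zeros(m)
        p = expit(mus[None, :] + eta[:, None])
        q = 1.0 - p
        prod_q = q.prod(axis=1)
        p_any_i = 1.0 - prod_q
        with np.errstate(divide="ignore", invalid="ignore"):
            ratio = np.where(q > 0, p / q, 0.0)
        p_one_i = prod_q * ratio.sum(axis=1)
        tot_any += p_any_i.sum()
        tot_one += p_one_i.sum()
        done += m
    p_any = tot_any / n_draws
    p_one = tot_one / n_draws
    return MultilocusSummary("dependence", float(p_any), float(p_one),
                             max(0.0, float(p_any - p_one)))


def density_of_rates(mu: float, sigma: float,
                     grid: Sequence[float]) -> np.ndarray:
    """Density of the individual-specific rate p = logistic(mu + eta).

    Change of variables from eta ~ N(0, sigma^2):
    ``f(p) = phi(logit(p) - mu; 0, sigma) / (p (1 - p))`` on (0, 1).
    For the fitted spread the density is unimodal but right-skewed;
    inflating sigma pushes mass toward p > 0.5 and eventually makes the
    population bimodal (near-error-free vs error-prone individuals).
    """
    g = np.asarray(grid, float)
    if np.any((g <= 0) | (g >= 1)):
        raise ValueError("grid must lie strictly inside (0, 1)")
    if sigma <= 0:
        raise ValueError("sigma must be positive for a continuous density")
    logit = np.log(g / (1.0 - g))
    return norm.pdf(logit - mu, scale=sigma) / (g * (1.0 - g))
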