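"""Synthetic register generator: determinism, limits and error mechanics."""

import numpy as np
import pytest
from numpy.polynomial.hermite import hermgauss
from scipy.special import expit
from scipy.stats import chisquare

import straudit as sa
from straudit.simulate import DEFAULT_MIXTURE


def test_default_allele_frequencies_are_valid_and_deterministic():
    f1 = sa.default_allele_frequencies(sa.nmdr.LOCI, seed=7)
    f2 = sa.default_allele_frequencies(sa.nmdr.LOCI, seed=7)
    for locus in sa.nmdr.LOCI:
        lengths, probs = f1[locus]
        lo, hi = sa.nmdr.ALLELE_RANGES[locus]
        assert lengths.min() >= lo and lengths.max() <= hi
        assert np.diff(lengths).min() == sa.nmdr.REPEAT_UNIT[locus]
        assert probs.sum() == pytest.approx(1.0)
        assert np.array_equal(probs, f2[locus][1])
    lengths, _ = f1["GATA417"]
    assert lengths.min() >= 223 and lengths.max() <= 252


def test_same_seed_reproduces_register(small_register):
    design, params, true_p, obs_p = small_register
    t2, o2 = sa.simulate_register(design, params, seed=11)
    assert [p.genotypes for p in t2] == [p.genotypes for p in true_p]
    assert [p.genotypes for p in o2] == [p.genotypes for p in obs_p]


def test_very_negative_intercept_gives_error_free_register():
    design = sa.SimulationDesign.default(seed=0)
    params = sa.TrueModelParams(intercept=-50.0)
    true_p, obs_p = sa.simulate_register(design, params, seed=3)
    recs = sa.compare_profiles(obs_p, true_p)
    assert sum(r.is_error for r in recs) == 0


def test_forced_half_rate_without_random_effects():
    # logistic(eta) = 0.5 everywhere: mismatch fraction ~ 0.5
    design = sa.SimulationDesign.default(seed=0)
    params = sa.TrueModelParams(
        intercept=0.0, locus_coefs={}, year_slope=0.0,
        sigma_ind=0.0, sigma_mp=0.0, error_free_loci=[])
    true_p, obs_p = sa.simulate_register(design, params, seed=4)
    recs = sa.compare_profiles(obs_p, true_p)
    frac = np.mean([r.is_error for r in recs])
    n = len(recs)
    assert abs(frac - 0.5) < 3 * np.sqrt(0.25 / n)


def test_error_type_mixture_reproduced_conditionally():
    """Across seeds, heterozygote errors follow the renormalized mixture and
    every homozygote error is a false heterozygote (chi-square GOF)."""
    design = sa.SimulationDesign.default(seed=0)
    # crank the rate up so counts are informative
    params = sa.TrueModelParams(intercept=-1.5, locus_coefs={},
                                year_slope=0.0, sigma_ind=0.0,
                                error_free_loci=[])
    het = {"single_false_allele": 0, "double_false_allele": 0,
           "false_homozygote": 0}
    n_hom_errors = 0
    n_hom_false_het = 0
    for seed in range(10):
        true_p, obs_p = sa.simulate_register(design, params, seed=seed)
        truth = {p.individual_id: p for p in true_p}
        for r in sa.compare_profiles(obs_p, true_p):
            if not r.is_error:
                continue
            tg = truth[r.individual_id].genotypes[r.locus]
            if tg[0] == tg[1]:
                n_hom_errors += 1
                n_hom_false_het += r.error_class == "false_heterozygote"
            else:
                het[r.error_class] += 1
    assert n_hom_errors > 0 and n_hom_false_het == n_hom_errors
    w = np.array([DEFAULT_MIXTURE[c] for c in het])
    w = w / w.sum()
    observed = np.array(list(het.values()), float)
    _, p = chisquare(observed, observed.sum() * w)
    assert p > 0.01


def test_errors_independent_across_loci_without_random_effects():
    """With sigma = 0 the error indicators of two loci are uncorrelated
    across individuals."""
    design = sa.SimulationDesign.default(seed=0)
    design.samples_per_year = {2001: 5000}
    design.lab_of_year = {2001: "Lab1"}
    params = sa.TrueModelParams(intercept=-2.0, locus_coefs={},
                                year_slope=0.0, sigma_ind=0.0,
                                error_free_loci=[])
    true_p, obs_p = sa.simulate_register(design, params, seed=8)
    recs = sa.compare_profiles(obs_p, true_p)
    ind = sorted({r.individual_id for r in recs})
    idx = {w: i for i, w in enumerate(ind)}
    loci = sa.nmdr.LOCI
    mat = np.zeros((len(ind), len(loci)))
    lidx = {l: j for j, l in enumerate(loci)}
    for r in recs:
        mat[idx[r.individual_id], lidx[r.locus]] = r.is_error
    corr = np.corrcoef(mat.T)
    off = corr[~np.eye(len(loci), dtype=bool)]
    assert np.abs(off).max() < 4 / np.sqrt(len(ind))


def test_overall_error_rate_matches_model_implied_expectation(small_records,
                                                              small_register):
    """The simulated per-locus error rate over the error-prone loci agrees
    with the generative model's design-averaged marginal rate, computed by
    an independent Gauss-Hermite oracle."""
    design, params, _, _ = small_register
    nodes, wts = hermgauss(64)
    eta_nodes = np.sqrt(2.0) * params.sigma_ind * nodes
    expected = []
    for year, n in design.samples_per_year.items():
        for locus, coef in params.locus_coefs.items():
            mu = params.intercept + coef + params.year_slope * (year - 2001)
            marg = (wts * expit(mu + eta_nodes)).sum() / np.sqrt(np.pi)
            expected.append((n, marg))
    counts = np.array([n for n, _ in expected], float)
    rate_exp = float(np.average([m for _, m in expected], weights=counts))
    err_loci = set(params.locus_coefs)
    sub = [r for r in small_records if r.locus in err_loci]
    rate_obs = np.mean([r.is_error for r in sub])
    se = np.sqrt(rate_exp * (1 - rate_exp) / len(sub))
    assert abs(rate_obs - rate_exp) < 3 * se


def test_mixture_must_sum_to_one():
    with pytest.raises(ValueError):
        sa.TrueModelParams(mixture={"single_false_allele": 0.5})
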