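"""Mixed logistic model: design building, AGHQ likelihood, fitting, AIC."""

import numpy as np
import pytest
from scipy.special import expit, logit, logsumexp

import straudit as sa


def mc_marginal_loglik(beta, data, sigma, n_draws=400_000, seed=99):
    """Brute-force MC integration of the marginal likelihood, with MC SEs
    of each per-individual log-likelihood (delta method)."""
    rng = np.random.default_rng(seed)
    b = rng.normal(0.0, sigma, n_draws)
    eta0 = data.X @ beta
    lls, ses = [], []
    for g in range(data.n_ind):
        rows = data.ind_codes == g
        e0, yy = eta0[rows], data.y[rows]
        ll_m = (yy[None, :] * (e0[None, :] + b[:, None])
                - np.logaddexp(0, e0[None, :] + b[:, None])).sum(axis=1)
        log_mean = logsumexp(ll_m) - np.log(n_draws)
        w = np.exp(ll_m - log_mean)          # relative weights, mean 1
        ses.append(w.std(ddof=1) / np.sqrt(n_draws))
        lls.append(log_mean)
    return np.array(lls), np.array(ses)


# --- design -----------------------------------------------------------------

def test_design_group_counts_match_audit_shape(tally_records, m1_spec):
    data = sa.build_design(tally_records, m1_spec)
    assert data.n_ind == 215           # 234 individuals minus error-free lab
    assert data.n_mp == 645            # 3 multiplexes per retained individual
    assert data.n_rows == 215 * 9      # 1935: error-free locus dropped
    assert data.dropped_loci == ["EV001"]
    assert data.dropped_labs == ["Lab3"]


def test_design_without_random_terms_has_no_grouping(tally_records):
    spec = sa.ModelSpec(frozenset({"YEAR"}), frozenset())
    data = sa.build_design(tally_records, spec)
    assert data.ind_codes is None and data.mp_codes is None


def test_year_lab_confounding_rejected():
    with pytest.raises(ValueError):
        sa.ModelSpec(frozenset({"YEAR", "LAB"}), frozenset())


def test_candidate_set_has_18_models():
    specs = sa.candidate_specs()
    assert len(specs) == 18
    assert len(set(specs)) == 18
    assert all(not ({"YEAR", "LAB"} <= s.fixed) for s in specs)
    assert all(len(s.random) <= 1 for s in specs)


# --- marginal likelihood ----------------------------------------------------

def test_sigma_zero_reduces_to_plain_logistic(tally_records, m1_spec):
    data = sa.build_design(tally_records, m1_spec)
    rng = np.random.default_rng(0)
    beta = rng.normal(-2, 0.5, data.X.shape[1])
    eta = data.X @ beta
    plain = float((data.y * eta - np.logaddexp(0, eta)).sum())
    assert sa.marginal_loglik(beta, data, 0.0, 0.0) == pytest.approx(
        plain, abs=1e-10)


def test_aghq_matches_monte_carlo_integration(m1_spec):
    """Quadrature equals brute-force MC integration on a small dataset,
    per individual, within 3 MC standard errors."""
    design = sa.SimulationDesign.default(seed=5)
    design.samples_per_year = {2000: 3, 2003: 2}
    true_p, obs_p = sa.simulate_register(
        design, sa.TrueModelParams(intercept=-1.0), seed=21)
    recs = sa.compare_profiles(obs_p, true_p)
    data = sa.build_design(recs, m1_spec, drop_zero_levels=False)
    rng = np.random.default_rng(1)
    beta = np.concatenate([[-1.2], rng.normal(0, 0.3, data.X.shape[1] - 1)])
    sigma = 1.2
    nodes, ses = mc_marginal_loglik(beta, data, sigma)
    quad = []
    from straudit.glmm import _aghq_group_logliks
    lls, _ = _aghq_group_logliks(data.X @ beta, data.y, data.ind_codes,
                                 data.n_ind, sigma, order=20)
    for g in range(data.n_ind):
        assert abs(lls[g] - nodes[g]) < 3 * ses[g] + 1e-8
    assert sa.marginal_loglik(beta, data, sigma, 0.0) == pytest.approx(
        float(lls.sum()))


def test_quadrature_order_refinement_is_negligible(m1_fit):
    data, res = m1_fit
    beta = np.array([res.beta[c] for c in data.colnames])
    l20 = sa.marginal_loglik(beta, data, res.sigma_ind, 0.0, order=20)
    l40 = sa.marginal_loglik(beta, data, res.sigma_ind, 0.0, order=40)
    assert abs(l20 - l40) < 5e-5
    assert abs(l20 - l40) / abs(l20) < 1e-6


def test_marginal_loglik_invariant_to_individual_relabeling(small_records,
                                                            m1_spec):
    import dataclasses
    data = sa.build_design(small_records, m1_spec)
    rng = np.random.default_rng(2)
    beta = rng.normal(-2, 0.3, data.X.shape[1])
    base = sa.marginal_loglik(beta, data, 1.1, 0.0)
    names = sorted({r.individual_id for r in small_records})
    perm = dict(zip(names, rng.permutation(names)))
    relabeled = [dataclasses.replace(r, individual_id=perm[r.individual_id])
                 for r in small_records]
    data2 = sa.build_design(relabeled, m1_spec)
    assert sa.marginal_loglik(beta, data2, 1.1, 0.0) == pytest.approx(base)


def test_clustering_favours_random_effect_for_all_or_nothing_data():
    """When errors concentrate in a few individuals, a large random-effect
    SD yields a higher marginal likelihood than independence."""
    recs = []
    for i in range(40):
        err = i < 4                     # 4 individuals carry all errors
        for j, locus in enumerate(sa.nmdr.LOCI):
            gt = (150, 154)
            og = (150, 155) if err else gt
            recs.append(sa.ComparisonRecord(
                f"w{i}", 2001, "Lab1", locus, sa.nmdr.MULTIPLEXES[locus],
                og, gt, err, "single_false_allele" if err else "none",
                int(err), "eq_1bp" if err else "not_applicable"))
    spec = sa.ModelSpec(frozenset(), frozenset({"IND"}))
    data = sa.build_design(recs, spec, drop_zero_levels=False)
    frac = np.mean(data.y)
    beta = np.array([logit(frac)])
    ll_indep = sa.marginal_loglik(beta, data, 0.0, 0.0)
    ll_mixed = sa.marginal_loglik(np.array([-8.0]), data, 6.0, 0.0)
    assert ll_mixed > ll_indep


# --- fitting ----------------------------------------------------------------

def test_intercept_only_logistic_fit_is_logit_of_error_fraction(tally_records):
    spec = sa.ModelSpec(frozenset(), frozenset())
    data = sa.build_design(tally_records, spec)
    res = sa.fit(data)
    frac = data.y.mean()
    assert res.beta["Intercept"] == pytest.approx(logit(frac), abs=1e-6)
    assert res.converged and res.k == 1


def test_sigma_zero_truth_recovered_at_boundary():
    design = sa.SimulationDesign.default(seed=3)
    params = sa.TrueModelParams(intercept=-3.0, locus_coefs={},
                                year_slope=0.0, sigma_ind=0.0,
                                error_free_loci=[])
    true_p, obs_p = sa.simulate_register(design, params, seed=17)
    recs = sa.compare_profiles(obs_p, true_p)
    spec = sa.ModelSpec(frozenset(), frozenset({"IND"}))
    data = sa.build_design(recs, spec, drop_zero_levels=False)
    res = sa.fit(data, order=20)
    plain = sa.fit(sa.build_design(recs, sa.ModelSpec(frozenset(), frozenset()),
                                   drop_zero_levels=False))
    assert res.sigma_ind < 0.35
    assert abs(res.loglik - plain.loglik) < 0.6


def test_m1_fit_on_synthetic_register_is_sane(m1_fit):
    data, res = m1_fit
    assert res.converged
    assert res.k == data.X.shape[1] + 1
    assert 0.3 < res.sigma_ind < 3.0
    assert res.aic == pytest.approx(-2 * res.loglik + 2 * res.k)


# --- model selection --------------------------------------------------------

def test_akaike_weights_reproduce_published_selection():
    aics = [a for *_, a in sa.nmdr.CANDIDATE_AICS]
    w = sa.akaike_weights(aics)
    assert w[0] == pytest.approx(0.576, abs=1e-3)
    assert w[1] == pytest.approx(0.234, abs=1e-3)
    assert w.sum() == pytest.approx(1.0, abs=1e-12)
    year_w = sum(wk for (name, fx, rd, a), wk in
                 zip(sa.nmdr.CANDIDATE_AICS, w) if "YEAR" in fx)
    ind_w = sum(wk for (name, fx, rd, a), wk in
                zip(sa.nmdr.CANDIDATE_AICS, w) if "IND" in rd)
    assert year_w == pytest.approx(0.86, abs=0.01)
    assert ind_w == pytest.approx(0.95, abs=0.01)


def test_akaike_weight_edge_cases():
    assert np.allclose(sa.akaike_weights([10.0, 10.0, 10.0]), 1 / 3)
    w = sa.akaike_weights([100.0, 102.0])
    assert w[0] == pytest.approx(1 / (1 + np.exp(-1.0)), abs=1e-12)
    with pytest.raises(ValueError):
        sa.akaike_weights([np.inf, np.inf])
    w = sa.akaike_weights([5.0, np.inf])
    assert w.tolist() == [1.0, 0.0]


def test_weight_order_is_inverse_aic_order():
    rng = np.random.default_rng(12)
    aics = rng.uniform(100, 150, 10)
    w = sa.akaike_weights(aics)
    assert np.array_equal(np.argsort(aics), np.argsort(-w))


def test_selection_table_and_combined_weight():
    labels, fixed, random, aics = zip(*[(n, f, r, a) for n, f, r, a in
                                        sa.nmdr.CANDIDATE_AICS])
    table = sa.selection_table(labels, fixed, random, aics)
    assert table.loc[0, "model"] == "M1"
    assert table.loc[0, "delta"] == 0.0
    assert table["weight"].sum() == pytest.approx(1.0)
    assert sa.combined_weight(table, "YEAR") == pytest.approx(0.86, abs=0.01)
    assert sa.combined_weight(table, "IND") == pytest.approx(0.95, abs=0.01)


def test_nested_quadrature_matches_mc_integration():
    """The nested IND + MP:IND likelihood equals brute-force double MC
    integration on a small dataset."""
    design = sa.SimulationDesign.default(seed=123)
    design.samples_per_year = {2000: 4, 2004: 3}
    tp, op = sa.simulate_register(
        design, sa.TrueModelParams(intercept=-1.0, sigma_mp=0.8), seed=3)
    recs = sa.compare_profiles(op, tp)
    spec = sa.ModelSpec(frozenset({"YEAR"}), frozenset({"IND", "MP:IND"}))
    data = sa.build_design(recs, spec, drop_zero_levels=False)
    beta = np.array([-1.0, 0.1])
    s_ind, s_mp = 1.0, 0.8
    ll = sa.marginal_loglik(beta, data, s_ind, s_mp, order=15)
    rng = np.random.default_rng(0)
    M = 200_000
    eta0 = data.X @ beta
    total, var = 0.0, 0.0
    for g in range(data.n_ind):
        rows = np.where(data.ind_codes == g)[0]
        mps = data.mp_codes[rows]
        umps = np.unique(mps)
        cmap = {m: i for i, m in enumerate(umps)}
        eta = (eta0[rows][None, :] + rng.normal(0, s_ind, M)[:, None]
               + rng.normal(0, s_mp, (M, len(umps)))[:, [cmap[m] for m in mps]])
        ll_m = (data.y[rows][None, :] * eta - np.logaddexp(0, eta)).sum(axis=1)
        log_mean = logsumexp(ll_m) - np.log(M)
        total += log_mean
        var += (np.exp(ll_m - log_mean).std(ddof=1) / np.sqrt(M)) ** 2
    assert abs(ll - total) < 3 * np.sqrt(var)


def test_candidate_set_fit_selects_generative_structure(small_records):
    """Fitting all 18 candidates to a register simulated with locus, year
    and individual effects ranks a model with all three on top."""
    table, fits = sa.fit_candidate_set(small_records, order=12)
    assert len(table) == 18
    assert table["weight"].sum() == pytest.approx(1.0, abs=1e-12)
    assert (table["aic"].diff().dropna() >= 0).all()
    assert table.loc[0, "delta"] == 0.0
    assert fits[0].spec.label == table.loc[0, "model"]
    best = fits[0].spec
    assert "IND" in best.random and {"LOCUS"} <= best.fixed


def test_locus_effects_detected_by_aic():
    """With strong locus effects, the LOCUS model beats the intercept-only
    model by AIC in every seed (selection consistency, distilled to the
    decisive pair)."""
    wins = 0
    for seed in range(10):
        design = sa.SimulationDesign.default(seed=1)
        params = sa.TrueModelParams(
            intercept=-3.5,
            locus_coefs={"GATA417": 2.5, "GT509": -0.5, "GT310": -0.5,
                         "GT211": 0.0, "GT023": 0.0, "GT575": 0.0,
                         "GATA098": 0.0, "GATA028": 1.5, "EV037": 0.0},
            year_slope=0.0, sigma_ind=1.0)
        true_p, obs_p = sa.simulate_register(design, params, seed=100 + seed)
        recs = sa.compare_profiles(obs_p, true_p)
        with_locus = sa.fit(sa.build_design(
            recs, sa.ModelSpec(frozenset({"LOCUS"}), frozenset({"IND"}))),
            compute_se=False)
        without = sa.fit(sa.build_design(
            recs, sa.ModelSpec(frozenset(), frozenset({"IND"}))),
            compute_se=False)
        wins += with_locus.aic < without.aic
    assert wins >= 9
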