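"""Mixed logistic regression for per-locus genotyping-error indicators.

The response is the binary error indicator of one individual x locus
observation.  The linear predictor combines fixed effects — LOCUS and
either YEAR (centered calendar year, a proxy for steadily improving
technology) or LAB (the genotyping laboratory; confounded with YEAR, the
two never co-occur) — with Gaussian random intercepts: IND, one per
individual (sample quality), and/or MP:IND, one per multiplex assay within
an individual (assay handling).

The marginal likelihood integrates the conditional Bernoulli likelihood
over the random effects by adaptive Gauss--Hermite quadrature: per group
the integrand is re-centered at its conditional mode and scaled by the
Laplace curvature before applying the Hermite rule, which keeps a 20-node
rule accurate even for large random-effect variances.  Models with both
random effects use a nested rule (outer over IND, inner over each MP:IND
block).  Model comparison uses AIC and Akaike weights
``w_k = exp(-Delta_k/2) / sum_j exp(-Delta_j/2)``.
"""

from __future__ import annotations

import dataclasses
import itertools
import warnings
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from numpy.polynomial.hermite import hermgauss
from scipy.special import expit, logsumexp

from .audit import ComparisonRecord

FIXED_TERMS = ("LOCUS", "YEAR", "LAB")
RANDOM_TERMS = ("IND", "MP:IND")

_SIGMA_FLOOR = 1e-8          # sigma below this is treated as exactly 0
_MIN_LOG_SIGMA = -10.0


@dataclasses.dataclass(frozen=True)
class ModelSpec:
    """A candidate model: fixed-effect terms and random intercepts."""

    fixed: frozenset = frozenset()
    random: frozenset = frozenset()

    def __post_init__(self):
        fixed = frozenset(self.fixed)
        random = frozenset(self.random)
        if not fixed <= set(FIXED_TERMS):
            raise ValueError(f"unknown fixed term(s) {fixed - set(FIXED_TERMS)}")
        if not random <= set(RANDOM_TERMS):
            raise ValueError(f"unknown random term(s) {random - set(RANDOM_TERMS)}")
        if {"YEAR", "LAB"} <= fixed:
            raise ValueError("YEAR and LAB are confounded and cannot co-occur")
        object.__setattr__(self, "fixed", fixed)
        object.__setattr__(self, "random", random)

    @property
    def label(self) -> str:
        fx = " + ".join(sorted(self.fixed)) or "1"
        rd = " + ".join(sorted(self.random)) or "-"
        return f"{fx} | {rd}"


def candidate_specs(include_both_random: bool = False) -> list[ModelSpec]:
    """The canonical 18-model candidate set (6 fixed structures x 3 random
    structures).  Models with both random intercepts can be appended for
    completeness but are excluded by default."""
    fixed_sets = [{"LOCUS", "YEAR"}, {"YEAR"}, {"LAB", "LOCUS"}, {"LAB"},
                  {"LOCUS"}, set()]
    random_sets: list[set] = [{"IND"}, {"MP:IND"}, set()]
    if include_both_random:
        random_sets = [{"IND", "MP:IND"}] + random_sets
    return [ModelSpec(frozenset(f), frozenset(r))
            for f, r in itertools.product(fixed_sets, random_sets)]


@dataclasses.dataclass
class ModelData:
    """Design matrix plus grouping structure for one ModelSpec."""

    spec: ModelSpec
    X: np.ndarray
    y: np.ndarray
    colnames: list[str]
    ind_codes: np.ndarray | None
    mp_codes: np.ndarray | None
    mp_to_ind: np.ndarray | None        # individual index of each mp block
    n_ind: int
    n_mp: int
    center_year: int
    locus_levels: list[str]
    lab_levels: list[str]
    ref_locus: str | None
    ref_lab: str | None
    dropped_loci: list[str]
    dropped_labs: list[str]

    @property
    def n_rows(self) -> int:
        return len(self.y)


def build_design(records: Iterable[ComparisonRecord], spec: ModelSpec,
                 center_year: int = 2001, drop_zero_levels: bool = True,
                 ref_locus: str | None = None,
                 ref_lab: str | None = None) -> ModelData:
    """Assemble response, treatment-coded design matrix and grouping indices.

    Factor levels (loci, labs) whose observations contain no errors carry
    no information about the remaining parameters and make the MLE of
    their own offset diverge; by default their rows are removed before
    fitting, and the removed levels are reported as zero-rate downstream.
    YEAR enters as calendar year minus ``center_year``.
    """
    recs = list(records)
    df = pd.DataFrame({
        "individual_id": [r.individual_id for r in recs],
        "year": [r.year for r in recs],
        "lab": [r.lab for r in recs],
        "locus": [r.locus for r in recs],
        "multiplex": [r.multiplex for r in recs],
        "y": [int(r.is_error) for r in recs],
    })
    dropped_loci: list[str] = []
    dropped_labs: list[str] = []
    if drop_zero_levels:
        locus_errs = df.groupby("locus")["y"].sum()
        lab_errs = df.groupby("lab")["y"].sum()
        dropped_loci = sorted(locus_errs.index[locus_errs == 0])
        dropped_labs = sorted(lab_errs.index[lab_errs == 0])
        df = df[~df["locus"].isin(dropped_loci) & ~df["lab"].isin(dropped_labs)]
        df = df.reset_index(drop=True)
    if df.empty:
        raise ValueError("no rows left after dropping zero-error levels")

    locus_levels = sorted(df["locus"].unique())
    lab_levels = sorted(df["lab"].unique())
    cols = [np.ones(len(df))]
    names = ["Intercept"]
    if "LOCUS" in spec.fixed:
        ref = ref_locus if ref_locus is not None else locus_levels[0]
        if ref not in locus_levels:
            raise ValueError(f"reference locus {ref!r} not among retained levels")
        for lv in locus_levels:
            if lv == ref:
                continue
            cols.append((df["locus"] == lv).to_numpy(float))
            names.append(f"LOCUS[{lv}]")
        ref_locus = ref
    else:
        ref_locus = None
    if "YEAR" in spec.fixed:
        cols.append((df["year"] - center_year).to_numpy(float))
        names.append("YEAR")
    if "LAB" in spec.fixed:
        ref = ref_lab if ref_lab is not None else lab_levels[0]
        if ref not in lab_levels:
            raise ValueError(f"reference lab {ref!r} not among retained levels")
        for lv in lab_levels:
            if lv == ref:
                continue
            cols.append((df["lab"] == lv).to_numpy(float))
            names.append(f"LAB[{lv}]")
        ref_lab = ref
    else:
        ref_lab = None
    X = np.column_stack(cols)
    y = df["y"].to_numpy(float)

    # perfect-separation hazard: a retained factor level with no events
    for name, col in zip(names[1:], X.T[1:]):
        if name.startswith(("LOCUS[", "LAB[")) and y[col == 1].sum() == 0:
            warnings.warn(f"factor level {name} has all-zero responses "
                          "(perfect-separation hazard)", RuntimeWarning)

    ind_codes = mp_codes = mp_to_ind = None
    n_ind = n_mp = 0
    if spec.random:
        ind_codes, ind_levels = pd.factorize(df["individual_id"], sort=True)
        n_ind = len(ind_levels)
        mp_key = df["individual_id"].astype(str) + "\x00" + df["multiplex"].astype(str)
        mp_codes, mp_levels = pd.factorize(mp_key, sort=True)
        n_mp = len(mp_levels)
        first_row = np.zeros(n_mp, dtype=int)
        first_row[mp_codes[::-1]] = np.arange(len(df))[::-1]
        mp_to_ind = ind_codes[first_row]
    return ModelData(spec, X, y, names, ind_codes, mp_codes, mp_to_ind,
                     n_ind, n_mp, center_year, locus_levels, lab_levels,
                     ref_locus, ref_lab, dropped_loci, dropped_labs)


# ---------------------------------------------------------------------------
# marginal likelihood
# ---------------------------------------------------------------------------

def _row_loglik(eta: np.ndarray, y: np.ndarray) -> np.ndarray:
    return y * eta - np.logaddexp(0.0, eta)


def _plain_loglik(beta: np.ndarray, data: ModelData) -> float:
    return float(_row_loglik(data.X @ beta, data.y).sum())


def _group_modes(eta0, y, codes, n_groups, sigma, b0=None, tol=1e-10,
                 max_iter=100):
    """Vectorized Newton search for the conditional mode of each group's
    log-integrand; returns (mode, curvature -h'')."""
    b = np.zeros(n_groups) if b0 is None else b0.copy()
    inv_var = 1.0 / sigma ** 2
    for _ in range(max_iter):
        p = expit(eta0 + b[codes])
        g = np.bincount(codes, weights=y - p, minlength=n_groups) - b * inv_var
        h = -np.bincount(codes, weights=p * (1 - p), minlength=n_groups) - inv_var
        step = g / h
        np.clip(step, -5.0, 5.0, out=step)
        b -= step
        if np.max(np.abs(g)) < tol:
            break
    p = expit(eta0 + b[codes])
    curv = np.bincount(codes, weights=p * (1 - p), minlength=n_groups) + inv_var
    return b, curv


def _aghq_group_logliks(eta0, y, codes, n_groups, sigma, order, b0=None):
    """Per-group log marginal likelihood, one Gaussian random intercept."""
    nodes, wts = hermgauss(order)
    bhat, curv = _group_modes(eta0, y, codes, n_groups, sigma, b0=b0)
    tau = 1.0 / np.sqrt(curv)
    log_prior_norm = -0.5 * np.log(2 * np.pi) - np.log(sigma)
    vals = np.empty((order, n_groups))
    for k, z in enumerate(nodes):
        b_k = bhat + np.sqrt(2.0) * tau * z
        ll = np.bincount(codes, weights=_row_loglik(eta0 + b_k[codes], y),
                         minlength=n_groups)
        h = ll - 0.5 * (b_k / sigma) ** 2 + log_prior_norm
        vals[k] = np.log(wts[k]) + z * z + h
    return np.log(np.sqrt(2.0) * tau) + logsumexp(vals, axis=0), bhat


def marginal_loglik(beta: np.ndarray, data: ModelData,
                    sigma_ind: float = 0.0, sigma_mp: float = 0.0,
                    order: int = 20,
                    _mode_cache: dict | None = None) -> float:
    """Log marginal likelihood of the mixed logistic model.

    Integrates over the IND and/or MP:IND Gaussian random intercepts by
    adaptive Gauss--Hermite quadrature of the given ``order``; with no
    random effect (or sigma = 0) this is exactly the ordinary logistic
    log-likelihood.
    """
    if order < 1:
        raise ValueError("quadrature order must be >= 1")
    beta = np.asarray(beta, float)
    if not np.all(np.isfinite(beta)) or not np.isfinite(sigma_ind) \
            or not np.isfinite(sigma_mp):
        raise ValueError("non-finite parameters")
    if sigma_ind < 0 or sigma_mp < 0:
        raise ValueError("sigma must be non-negative")
    use_ind = "IND" in data.spec.random and sigma_ind > _SIGMA_FLOOR
    use_mp = "MP:IND" in data.spec.random and sigma_mp > _SIGMA_FLOOR
    eta0 = data.X @ beta
    y = data.y
    if not use_ind and not use_mp:
        return float(_row_loglik(eta0, y).sum())
    cache = _mode_cache if _mode_cache is not None else {}
    if use_ind and not use_mp:
        lls, bhat = _aghq_group_logliks(eta0, y, data.ind_codes, data.n_ind,
                                        sigma_ind, order, b0=cache.get("ind"))
        cache["ind"] = bhat
        return float(lls.sum())
    if use_mp and not use_ind:
        lls, bhat = _aghq_group_logliks(eta0, y, data.mp_codes, data.n_mp,
                                        sigma_mp, order, b0=cache.get("mp"))
        cache["mp"] = bhat
        return float(lls.sum())
    return _nested_loglik(eta0, y, data, sigma_ind, sigma_mp, order)


def _nested_loglik(eta0, y, data: ModelData, sigma_ind, sigma_mp, order):
    """Nested quadrature: outer over IND, inner over MP:IND blocks.

    The outer integrand per individual, g_i(b) = log N(b; 0, sigma_ind^2) +
    sum over the individual's multiplex blocks of the inner AGHQ marginal,
    is maximized by a derivative-free Newton scheme (finite differences of
    the smooth scalar function) before applying the Hermite rule.
    """
    n_ind, n_mp = data.n_ind, data.n_mp
    mp_to_ind = data.mp_to_ind

    def g(b_ind: np.ndarray) -> np.ndarray:
        offset = b_ind[data.ind_codes]
        mp_lls, _ = _aghq_group_logliks(eta0 + offset, y, data.mp_codes,
                                        n_mp, sigma_mp, order)
        per_ind = np.bincount(mp_to_ind, weights=mp_lls, minlength=n_ind)
        return per_ind - 0.5 * (b_ind / sigma_ind) ** 2 \
            - 0.5 * np.log(2 * np.pi) - np.log(sigma_ind)

    b = np.zeros(n_ind)
    h = 1e-4
    for _ in range(50):
        g0, gp, gm = g(b), g(b + h), g(b - h)
        d1 = (gp - gm) / (2 * h)
        d2 = (gp - 2 * g0 + gm) / h ** 2
        d2 = np.minimum(d2, -1.0 / sigma_ind ** 2)   # keep concave
        step = np.clip(d1 / d2, -5.0, 5.0)
        b -= step
        if np.max(np.abs(d1)) < 1e-8:
            break
    g0, gp, gm = g(b), g(b + h), g(b - h)
    d2 = np.minimum((gp - 2 * g0 + gm) / h ** 2, -1.0 / sigma_ind ** 2)
    tau = 1.0 / np.sqrt(-d2)
    nodes, wts = hermgauss(order)
    vals = np.empty((order, n_ind))
    for k, z in enumerate(nodes):
        vals[k] = np.log(wts[k]) + z * z + g(b + np.sqrt(2.0) * tau * z)
    return float((np.log(np.sqrt(2.0) * tau) + logsumexp(vals, axis=0)).sum())


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class FitResult:
    """Maximum-likelihood fit of one candidate model."""

    spec: ModelSpec
    beta: dict[str, float]
    sigma_ind: float
    sigma_mp: float
    loglik: float
    k: int
    converged: bool
    se: dict[str, float] = dataclasses.field(default_factory=dict)
    cov: np.ndarray | None = None
    param_names: list[str] = dataclasses.field(default_factory=list)
    center_year: int = 2001
    locus_levels: list[str] = dataclasses.field(default_factory=list)
    lab_levels: list[str] = dataclasses.field(default_factory=list)
    ref_locus: str | None = None
    ref_lab: str | None = None
    dropped_loci: list[str] = dataclasses.field(default_factory=list)
    dropped_labs: list[str] = dataclasses.field(default_factory=list)

    @property
    def aic(self) -> float:
        return -2.0 * self.loglik + 2.0 * self.k

    def to_dict(self) -> dict:
        return {
            "model": self.spec.label,
            "beta": self.beta,
            "sigma_ind": self.sigma_ind,
            "sigma_mpind": self.sigma_mp,
            "loglik": self.loglik,
            "k": self.k,
            "aic": self.aic,
            "converged": self.converged,
            "se": self.se,
            "center_year": self.center_year,
            "locus_levels": self.locus_levels,
            "lab_levels": self.lab_levels,
            "ref_locus": self.ref_locus,
            "ref_lab": self.ref_lab,
            "dropped_loci": self.dropped_loci,
            "dropped_labs": self.dropped_labs,
        }


def _pack(beta, log_sigmas):
    return np.concatenate([beta, log_sigmas])


def _finite_diff_grad(f, x, h=1e-5):
    g = np.zeros_like(x)
    for i in range(len(x)):
        e = np.zeros_like(x)
        e[i] = h
        g[i] = (f(x + e) - f(x - e)) / (2 * h)
    return g


def _finite_diff_hess(f, x, h=1e-4):
    n = len(x)
    H = np.zeros((n, n))
    f0 = f(x)
    for i in range(n):
        for j in range(i, n):
            ei = np.zeros(n); ei[i] = h
            ej = np.zeros(n); ej[j] = h
            if i == j:
                H[i, i] = (f(x + ei) - 2 * f0 + f(x - ei)) / h ** 2
            else:
                H[i, j] = H[j, i] = (
                    f(x + ei + ej) - f(x + ei - ej)
                    - f(x - ei + ej) + f(x - ei - ej)) / (4 * h ** 2)
    return H


def fit(data: ModelData, order: int = 20,
        sigma_starts: Sequence[float] = (0.1, 1.0),
        compute_se: bool = True) -> FitResult:
    """Maximize the marginal likelihood over (beta, log sigma).

    Starts from the ordinary-logistic solution; random-effect SDs are
    optimized on the log scale from multiple starting values.  The
    convergence flag requires a small finite-difference gradient and a
    positive-definite Hessian; a failed fit is returned flagged, not
    raised, so that bootstrap replicates can account for it.
    """
    from scipy.optimize import minimize

    spec = data.spec
    glm = sm.GLM(data.y, data.X, family=sm.families.Binomial()).fit()
    beta0 = np.asarray(glm.params, float)
    names = list(data.colnames)
    n_rand = len(spec.random)
    k = data.X.shape[1] + n_rand

    if n_rand == 0:
        ll = _plain_loglik(beta0, data)
        se = dict(zip(names, np.asarray(glm.bse, float)))
        return FitResult(spec, dict(zip(names, beta0)), 0.0, 0.0, ll, k,
                         True, se, np.asarray(glm.cov_params(), float),
                         names, data.center_year, data.locus_levels,
                         data.lab_levels, data.ref_locus, data.ref_lab,
                         data.dropped_loci, data.dropped_labs)

    has_ind = "IND" in spec.random
    has_mp = "MP:IND" in spec.random
    cache: dict = {}

    def unpack(theta):
        beta = theta[:len(beta0)]
        logs = theta[len(beta0):]
        i = 0
        s_ind = s_mp = 0.0
        if has_ind:
            s_ind = float(np.exp(logs[i])); i += 1
        if has_mp:
            s_mp = float(np.exp(logs[i]))
        return beta, s_ind, s_mp

    def negll(theta):
        beta, s_ind, s_mp = unpack(theta)
        return -marginal_loglik(beta, data, s_ind, s_mp, order,
                                _mode_cache=cache)

    best = None
    for s0 in sigma_starts:
        x0 = _pack(beta0, np.full(n_rand, np.log(s0)))
        bounds = [(None, None)] * len(beta0) + [(_MIN_LOG_SIGMA, 5.0)] * n_rand
        res = minimize(negll, x0, method="L-BFGS-B", bounds=bounds,
                       options={"maxiter": 500, "ftol": 1e-12, "gtol": 1e-7})
        if best is None or res.fun < best.fun:
            best = res
    theta = best.x
    ll = -best.fun
    grad = _finite_diff_grad(negll, theta)
    at_boundary = np.any(theta[len(beta0):] <= _MIN_LOG_SIGMA + 1e-6)
    # scale-aware first-order criterion: finite-difference gradients cannot
    # resolve below ~1e-5 in absolute terms, and the meaningful scale of the
    # score is set by the log-likelihood magnitude
    gtol = 1e-5 * max(100.0, abs(ll))
    grad_ok = np.max(np.abs(grad if not at_boundary else grad[:len(beta0)])) < gtol

    se: dict[str, float] = {}
    cov = None
    hess_ok = True
    param_names = names + (["log_sigma_ind"] if has_ind else []) \
        + (["log_sigma_mpind"] if has_mp else [])
    if compute_se:
        H = _finite_diff_hess(negll, theta)
        try:
            evals = np.linalg.eigvalsh(H)
            hess_ok = bool(evals.min() > 0)
            cov = np.linalg.inv(H)
            se = dict(zip(param_names, np.sqrt(np.maximum(np.diag(cov), 0.0))))
        except np.linalg.LinAlgError:
            hess_ok = False
    converged = bool(best.success and grad_ok and (hess_ok or at_boundary))

    beta, s_ind, s_mp = unpack(theta)
    return FitResult(spec, dict(zip(names, beta)), s_ind, s_mp, ll, k,
                     converged, se, cov, param_names, data.center_year,
                     data.locus_levels, data.lab_levels, data.ref_locus,
                     data.ref_lab, data.dropped_loci, data.dropped_labs)


# ---------------------------------------------------------------------------
# model selection
# ---------------------------------------------------------------------------

def akaike_weights(aics: Sequence[float]) -> np.ndarray:
    """Akaike weights exp(-Delta/2), normalized to sum to one."""
    a = np.asarray(aics, float)
    finite = np.isfinite(a)
    if not finite.any():
        raise ValueError("need at least one finite AIC")
    w = np.zeros_like(a)
    d = a[finite] - a[finite].min()
    w[finite] = np.exp(-d / 2.0)
    return w / w.sum()


def selection_table(labels: Sequence[str], fixed: Sequence[frozenset],
                    random: Sequence[frozenset], aics: Sequence[float],
                    sigmas: Sequence[float] | None = None) -> pd.DataFrame:
    """AIC ranking with Delta-AIC and Akaike weights, best model first."""
    w = akaike_weights(aics)
    a = np.asarray(aics, float)
    df = pd.DataFrame({
        "model": list(labels),
        "fixed": [" + ".join(sorted(f)) or "-" for f in fixed],
        "random": [" + ".join(sorted(r)) or "-" for r in random],
        "sigma": sigmas if sigmas is not None else np.nan,
        "aic": a,
        "delta": a - a[np.isfinite(a)].min(),
        "weight": w,
    })
    return df.sort_values("aic", ignore_index=True)


def combined_weight(table: pd.DataFrame, term: str) -> float:
    """Summed Akaike weight of models whose fixed or random part contains
    ``term`` (e.g. "YEAR", "IND")."""
    mask = table.apply(
        lambda row: term in str(row["fixed"]).split(" + ")
        or term in str(row["random"]).split(" + "), axis=1)
    return float(table.loc[mask, "weight"].sum())


def fit_candidate_set(records: Iterable[ComparisonRecord],
                      center_year: int = 2001, order: int = 20,
                      include_both_random: bool = False,
                      compute_se: bool = False
                      ) -> tuple[pd.DataFrame, list[FitResult]]:
    """Fit every candidate model and rank by AIC.

    Returns the selection table (sorted by AIC) and the fits in table
    order.  Per-model convergence failures are propagated as flags.
    """
    recs = list(records)
    fits = []
    for spec in candidate_specs(include_both_random):
        data = build_design(recs, spec, center_year=center_year)
        fits.append(fit(data, order=order, compute_se=compute_se))
    sigmas = [f.sigma_ind if "IND" in f.spec.random else
              (f.sigma_mp if "MP:IND" in f.spec.random else np.nan)
              for f in fits]
    table = selection_table([f.spec.label for f in fits],
                            [f.spec.fixed for f in fits],
                            [f.spec.random for f in fits],
                            [f.aic for f in fits], sigmas)
    labels = [f.spec.label for f in fits]
    order_idx = [labels.index(m) for m in table["model"]]
    table["converged"] = [fits[i].converged for i in order_idx]
    fits_sorted = [fits[i] for i in order_idx]
    return table, fits_sorted
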