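# Methods

## The problem

A wildlife DNA register stores one multilocus microsatellite profile per
individual and identifies recaptured or traded individuals by exact (or
near-exact) profile matching. Genotyping errors — a recorded allele length
differing from the true length — degrade that matching. `straudit`
implements the statistical machinery for auditing such a register against
re-genotyped reference profiles: empirical error rates, a mixed logistic
regression for the error process, AIC-based model selection, and the
population-averaged per-locus and whole-profile error probabilities that
matter for identification. The default design constants describe the
Norwegian minke whale DNA register (NMDR): 10 loci in 3 multiplexes, four
laboratories over 1997–2008, and 234 analyzable re-genotyped samples.

## Error model

For individual *i* and locus *l*, let `y_il = 1` if the register genotype
differs from the true genotype (as unordered allele pairs). The model is

    y_il ~ Bernoulli(p_il),  logit(p_il) = eta_il
    eta_il = beta0 + LOCUS_l + YEAR_i (or LAB_i) + b_i + b_im

with `b_i ~ N(0, sigma_IND^2)` shared by all loci of an individual
(sample quality) and `b_im ~ N(0, sigma_MPIND^2)` shared by the loci of
one multiplex assay within an individual (assay handling). YEAR enters as
calendar year minus a centering constant (default 2001, the middle of the
study period; this coding makes the published coefficients reproduce the
published 2001 marginal rates, which we verified with the Monte-Carlo
machinery before freezing the default). YEAR and LAB are confounded —
each laboratory served a contiguous block of years — and never co-occur.
The candidate set crosses 6 fixed structures with {IND, MP:IND, none},
giving 18 models; fits with both random effects are supported but excluded
from the default candidate table because the multiplex variance collapses
to zero whenever the individual effect is present.

Factor levels observed with zero errors (in the NMDR: locus EV001 and
Lab 3) are dropped before fitting: they are perfectly separated, their
offsets have no finite MLE, and they carry no information about the other
parameters. They re-enter downstream reporting with rate exactly 0.

## Marginal likelihood and fitting

The likelihood marginalizes the random effects by adaptive Gauss–Hermite
quadrature: per group the integrand is re-centered at its conditional mode
(found by a damped, vectorized Newton iteration on the strictly concave
per-group objective) and scaled by the Laplace curvature, then integrated
with a 20-node Hermite rule (configurable; order 20 vs 40 changes the
log-likelihood of a typical fit by ~1e-5 absolute, ~1e-7 relative).
Models with both random effects use a nested rule — outer over the
individual effect, inner over each multiplex block — with the outer mode
located by finite-difference Newton on the smooth scalar outer integrand.
With an empty random structure (or a variance of zero) the code reduces
exactly to the ordinary logistic log-likelihood. The implementation was
validated against brute-force Monte-Carlo integration of the same
integrals (the test suite keeps this oracle).

Maximization runs over `(beta, log sigma)` with L-BFGS-B from the
ordinary-logistic solution, multi-started at sigma ∈ {0.1, 1.0}. AIC
counts every fixed coefficient plus one per random-effect SD. The
convergence flag requires optimizer success, a positive-definite
finite-difference Hessian, and a small score: `max|grad| <
1e-5 * max(100, |loglik|)`. The scale-aware form is deliberate — an
absolute cutoff near the finite-difference noise floor flags genuinely
converged optima on larger datasets. Wald standard errors come from the
inverse finite-difference Hessian; intervals for the variance are formed
on the log-SD scale and transformed.

## Population-averaged rates and multilocus summaries

The marginal (population-averaged) per-locus rate at year *t* is
`E[logistic(mu_l + eta)]` with `eta ~ N(0, sigma^2)`, estimated by plain
Monte Carlo with N = 10^6 draws by default (MC standard errors are
reported; they scale as 1/sqrt(N)). For profile matching, with `E` the
number of erroneous loci in a profile:

    P_i(E>0) = 1 - prod_l (1 - p_il)
    P_i(E=1) = sum_l p_il prod_{k != l} (1 - p_ik)

The dependence scenario draws one shared `eta` per simulated individual,
evaluates these conditionally and averages; the independence scenario
plugs the marginal rates into the same formulas in closed form. Because
the shared effect concentrates errors in few individuals, the dependence
scenario yields a *smaller* P(E>0) but a much larger P(E>1 | E>0) — the
register-audit headline that near-miss matching rules must account for.
Excluded zero-rate loci contribute p = 0 and may simply be omitted.

## Bootstrap

Standard deviations of fitted quantities come from a nonparametric
cluster bootstrap: individuals (complete locus sets) are resampled with
replacement to the original count; duplicated individuals get fresh
identities so each copy receives its own random intercept. Replicates
whose refit fails the convergence flag — or whose resample carries no
errors at all — are counted as warnings; the primary SD uses converged
replicates, and a warnings-as-zero variant (estimates of warned
replicates set to 0) bounds the impact of non-convergence from above.
Default B = 500 replicates.

## Synthetic register generator

The generator emulates the audit's sampling frame: 20 samples per year
minus the historical exclusions (per-year counts 16/20/.../19 giving the
per-lab totals 116/60/19/39; the audit reports only three of the six
excluded samples' years, so the remaining exclusions were assigned to
1997 and 2008), the lab schedule, and a fixed 3-way multiplex partition
(the true assay composition is not recoverable from the audit summary).
True genotypes are Hardy–Weinberg draws from Dirichlet-generated spectra
on each locus's repeat ladder spanning its observed length range — the
register's real allele frequencies are unpublished, so the spectra are
synthetic placeholders and nothing downstream depends on them.

Error events follow the mixed model above with the published selected-
model coefficients as defaults (intercept −4.74, year slope −0.36,
VAR(IND) = 1.81, per-locus offsets; EV001 error-free). On an error, the
category is drawn from the audit's empirical mixture (12:6:10:3 for
single/double false allele, false homozygote, false heterozygote),
renormalized within genotype class: a heterozygote can realize a
single/double false allele or a false homozygote; a homozygote realizes a
false heterozygote (shifting one of its alleles) — a lone shifted allele
of a homozygote *is* the false-heterozygote outcome, so the mixture
cannot be applied unconditionally. Shifts are ±1 bp with probability
0.45, otherwise ± one repeat unit, re-drawn when a collision would change
the category (e.g. a "single false allele" landing on the partner allele
would silently become a false homozygote). Error-free loci are copied
verbatim.

What the generator does *not* emulate: amplification failure and missing
data (the register is complete by mandate), null alleles and allelic
dropout biochemistry beyond the four observed categories, systematic
inter-laboratory calibration shifts, and microsatellite mutation. Passing
tests therefore demonstrate correctness of the estimation machinery under
the model's own assumptions, not robustness to real-data pathologies
outside them.

A note on the generator's implied totals: the published coefficients are
conditional-model ML estimates; averaged over the full 1997–2008 design
they imply an overall per-locus error rate near 0.025, noticeably above
the audit's raw empirical 0.016. This is a property of the published fit
(marginal means of a nonlinear mixed model need not match raw rates),
so the generator's self-consistency test compares simulated totals
against the model-implied expectation computed by an independent
quadrature oracle, not against the raw rate.

## Numerical and design choices

- Allele pairs are unordered multisets stored min-first; allele error
  counts minimize substitutions over the two pairings (the only
  convention that reproduces the published per-allele counts).
- Classification is exclusive and exhaustive: genotype-class transitions
  (het↔hom) take precedence, then the number of shifted alleles. A true
  heterozygote recorded as a homozygote of a *novel* allele is classed
  false homozygote with 2 allele errors and flagged — a corner the audit
  never observed.
- Treatment contrasts use the alphabetically first retained level as
  reference (configurable). Marginal rates, the quantities compared
  against published values, are contrast-invariant.
- Problem sizes in the test suite (register-size fits, 20-seed recovery
  at n ≈ 2000, 10^6-draw Monte Carlo) were chosen to keep each check's
  sampling error well inside its assertion tolerance.
- Bootstrap resampling, simulation and Monte Carlo all take explicit
  seeds; identical seeds give bit-identical results.

## Known limitations

- The nested (two-random-effect) likelihood is accurate but slow on
  large registers; it exists for completeness, matching its marginal role
  in the analysis.
- Wald intervals for variance components degrade near the sigma = 0
  boundary (the fit reports a boundary flag instead of pretending
  otherwise).
- The empirical rate table treats groups with no observations as
  undefined rather than zero.
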