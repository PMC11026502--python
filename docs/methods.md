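# Methods

## The model

`qxgfrailty` fits a parametric proportional-hazards model with an
unobserved multiplicative random effect ("frailty") on the hazard of each
subject:

    lambda(t | z_i, x_i) = z_i * lambda0(t) * exp(x_i' beta),   z_i > 0.

The frailty z captures heterogeneity that the covariates miss: subjects
with z > 1 are at elevated risk, z < 1 at reduced risk. Integrating z out
gives the population ("marginal") survival as the Laplace transform of the
frailty law evaluated at the cumulative hazard times the risk score,
S(t|x) = L(Lambda0(t) e^{x'beta}), and the marginal hazard as
-(log S)'.

The frailty law here is the quasi-xgamma (QXg) distribution, the
two-component mixture

    f(z) = theta/(1+zeta) e^{-theta z} (zeta + theta^2 z^2 / 2)
         = w * Exponential(theta) + (1-w) * Gamma(3, theta),
    w = zeta/(1+zeta).

Because a frailty scale is not identifiable next to the baseline hazard,
the law is pinned to unit mean by theta = (3+zeta)/(1+zeta). Its variance,

    sigma^2 = (zeta^2 + 8 zeta + 3) / (3+zeta)^2,

is the heterogeneity parameter practitioners read: it ranges over
(1/3, 13/12], rises from 1/3 at zeta=0 (pure Gamma(3) frailty) to a
maximum 13/12 at zeta=9, then falls back towards 1 (the exponential-frailty
limit). The map zeta -> sigma^2 is therefore two-to-one above sigma^2 = 1;
`zeta_from_variance` exposes both algebraic branches

    zeta = (4 - 3 sigma^2 -+ sqrt(C)) / (sigma^2 - 1),   C = 13 - 12 sigma^2,

defaulting to the lower branch (zeta <= 9), which is the only one that
exists for sigma^2 < 1. The sigma^2 = 1 point is handled as the continuity
limit zeta = 3. Internally *everything* is parameterized by zeta — it
indexes the law uniquely, is unbounded above, and yields the compact
marginal forms (with D = (3+zeta) + Lambda0(t) e^{x'beta} (1+zeta)):

    S(t|x)      = (3+zeta)(zeta D^2 + (3+zeta)^2) / ((1+zeta) D^3)
    lambda(t|x) = lambda0 e^{x'beta} (1+zeta)/D
                  * (zeta D^2 + 3(3+zeta)^2)/(zeta D^2 + (3+zeta)^2).

These were derived from the mixture Laplace transform
L(s) = [zeta r + r^3]/(1+zeta), r = theta/(theta+s), and are verified in
the test suite against direct quadrature of the mixing integral. The
sigma^2-parameterized entry points are thin wrappers through the branch
map.

Two baselines are supported: Weibull, Lambda0 = (t/rho)^kappa, and
Gompertz, Lambda0 = (rho1/kappa1)(e^{kappa1 t} - 1) with kappa1 > 0 (the
kappa1 < 0 regime has a bounded cumulative hazard, hence a cure fraction,
and is out of scope; near kappa1 = 0 the exponential limit rho1*t is used
with expm1/log1p for stability). Covariates enter with no intercept — the
baseline absorbs scale.

## Estimation

The right-censored log likelihood is assembled as the composition

    log L = sum_i [ delta_i log lambda(t_i|x_i) + log S(t_i|x_i) ],

never as a transcribed expansion, so it is correct by construction for
both baselines and is audited in tests against quadrature-based marginal
functions. Optimization is quasi-Newton (BFGS) on the unconstrained scale
(log kappa, log rho, log zeta, beta), with a Nelder-Mead polish fallback.
The likelihood carries a genuine ridge along which a larger baseline shape
trades off against a larger frailty shape (both govern late-time hazard
deceleration), and a secondary mode can appear on the other side of it;
`fit()` therefore multi-starts (default 3) from a moment-style start plus
structured restarts that straddle the auto point in (shape, zeta).
Standard errors come from the numeric Hessian at the optimum; the frailty
variance's SE uses the delta method through sigma^2(zeta). Parameter
points outside the domain score -inf; non-convergence raises an explicit
`ConvergenceError`, never a silent answer.

For uncensored univariate samples, five estimators of (zeta, theta) are
provided — maximum likelihood, ordinary and weighted least squares on the
probability plot (weights (n+1)^2(n+2)/(i(n-i+1))), Cramer-von Mises, and
Anderson-Darling — all minimized over (log zeta, log theta) from a
moment-matching start (the ratio E[Z^2]/E[Z]^2 pins zeta inside (4/3, 2)).
The "AnDE" label used in parts of the actuarial literature is accepted as
an alias for Anderson-Darling; tables that print "CVM" get that criterion.

## Goodness of fit

**Complete data (Rao-Robson-Nikulin).** Y^2 = X^2 on b equiprobable cells
(boundaries at fitted quantiles j/b) plus the correction
(1/n) l'(I-J)^{-1} l that restores the chi-squared_{b-1} limit when the
parameters were estimated from the ungrouped sample. Cell-probability
derivatives are central finite differences (step 1e-5 * max(1,|u|)) taken
on the log-parameter scale: the quadratic form is invariant under smooth
reparameterization, and the log scale keeps the stencil inside the domain
however close an estimate is to a boundary. I is the *expected*
per-observation information, computed by 300-node Gauss-Legendre
quadrature of E[score score']: I - J is nearly singular for this family
(smallest eigenvalue a few percent of the largest), and an empirical
outer-product estimate of I injects enough noise into the correction to
visibly over-reject; with the expected information the simulated null
level is within Monte-Carlo error of nominal from n = 150 up.

**Censored data (Bagdonavicius-Nikulin).** The time axis is cut into r
intervals with equal expected failure counts e_j = E/r under the fitted
marginal cumulative hazard (E = sum_i Lambda(t_i|x_i); boundaries found by
monotone root-finding). The statistic adds sum_j (W_j - e_j)^2 / W_j and
the quadratic form V'G^{-1}V built from the per-event log-hazard scores.
G = i - M B^{-1} M' is numerically rank-deficient here (the grouped scores
absorb nearly all event information; median eigenvalue ratio ~2e-4), so it
is inverted through an eigenvalue floor at 1% of its leading eigenvalue.
The calibration is insensitive to the floor over 0.5%-2%; without any
floor the correction explodes along the null direction and the statistic
loses its chi-squared shape. With the floor, the simulated null
distribution at n = 1000 matches chi-squared with r-1 degrees of freedom
(mean 4.05, variance 8.2 at r=5), which is the convention used throughout
(the worked-application critical value chi2_{0.05}(4) = 9.488);
`df_convention="intervals"` is available because parts of the literature
quote r df. Intervals left with zero events are merged into a neighbor,
reducing the df. Known limitation: below n ~ 300 the censored test is
mildly anticonservative (level ~0.92-0.94 at nominal 0.95).

## Risk indicators

For a QXg loss Z at level q: VaR is the quantile (bracketed root-finding
on the closed-form CDF, tolerance 1e-10 on the CDF scale); TVaR, tail
variance, tail mean-variance and mean excess come from the closed-form
upper partial moments

    E[Z^k 1{Z>u}] = [zeta Gu(k+1, theta u) + Gu(k+3, theta u)/2]
                    / ((1+zeta) theta^k),

with Gu the upper incomplete gamma function; adaptive quadrature is kept
as the test oracle. The tail mean-variance weight defaults to pi = 0.5:
the printed reference tables satisfy TMV = TVaR + 0.5 * TV exactly
(e.g. 7.9207537 + 0.5*8.1291089 = 11.9853081), so the weight is inferred
and overridable. VaR and TVaR increase in q; tail variance and mean excess
decrease in q in the moderate-zeta regime all fitted tables occupy —
as zeta grows the law approaches the exponential, whose mean excess is
flat, so these monotonicities are not family-wide properties.

## Synthetic data

`simulate_survival_dataset` draws the frailty exactly from the
Exponential/Gamma(3) mixture, a single covariate x ~ Bernoulli(0.5)
(matching the single regression coefficient of the reference designs), and
inverts the conditional survival: T = Lambda0^{-1}(-log U / (z e^{x beta})).
Right censoring is an independent Uniform(0, c) time; c is calibrated by
bisection against a pilot sample of latent event times using the exact
conditional censoring probability min(T/c, 1), hitting the target fraction
within 0.5%. The two study designs shipped as module constants are
(kappa=0.8, rho=0.9, sigma^2=0.6, beta=0.5; Weibull) and (kappa1=1.07,
rho1=0.5, sigma^2=0.7, beta=0.3; Gompertz), with censoring targets 0-50%.

What the generator does *not* emulate: real covariate structure (several
correlated continuous clinical covariates rather than one balanced binary
one), informative or administrative censoring, ties, and measurement
error. Passing tests therefore certify the estimators and tests under the
model's own data-generating process, not robustness to misspecification.

## Study sizes and numerical choices

Monte-Carlo studies run at desk scale: empirical-level studies use 2000
replicates at n = 1000 (binomial 3-SE tolerance ~0.015 around 0.95);
estimator-recovery studies use 300 replicates at n in {20, 1000} with
three optimizer starts per fit. Reported level/recovery values are
reproducible from the seeds recorded in the drivers. Quantile inversion
brackets [0, mean + 50/theta] and doubles as needed; sampling, simulation
and fitting accept explicit seeds end to end; identical seeds give
bit-identical datasets and tables. Degenerate inputs (samples with fewer
than three distinct points, datasets without events, single records) fail
loudly with domain errors rather than returning boundary estimates.
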