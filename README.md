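# qxgfrailty

Parametric survival modelling with **quasi-xgamma frailty**: unobserved
heterogeneity in time-to-event data, modified chi-squared goodness-of-fit
testing for fitted models, and actuarial tail-risk analysis of
QXg-distributed losses.

## Who this is for

Biostatisticians and reliability/actuarial analysts working with
right-censored time-to-event data in which subjects sharing the same
covariates still differ systematically in risk — genetic background,
unmeasured comorbidity, driver behaviour. Ignoring that heterogeneity
biases hazard estimates downward over time; frailty models absorb it into
an unobserved multiplicative random effect.

## The model

Each subject's hazard is

```
lambda(t | z, x) = z * lambda0(t) * exp(x' beta)
```

where `lambda0` is a Weibull (`(kappa/rho)(t/rho)^(kappa-1)`) or Gompertz
(`rho1 * exp(kappa1 t)`) baseline and the frailty `z` follows the
quasi-xgamma distribution — a mixture of an Exponential(theta) and a
Gamma(3, theta) with weights `zeta/(1+zeta)` and `1/(1+zeta)` — rescaled
to unit mean. The population-level survival is the frailty's Laplace
transform at the cumulative hazard,
`S(t|x) = L(Lambda0(t) exp(x'beta))`, available in closed form; the
frailty variance `sigma^2 = (zeta^2+8zeta+3)/(3+zeta)^2 in (1/3, 13/12]`
measures the heterogeneity. Estimation is maximum likelihood on
right-censored data; model adequacy is checked with the
Nikulin–Rao–Robson statistic (complete data) or the
Bagdonavicius–Nikulin statistic (censored data), both asymptotically
chi-squared after correcting for estimated parameters. For loss analysis
the package computes VaR, tail value-at-risk, tail variance, tail
mean-variance and mean excess loss in closed form under five estimators
(MLE, OLS, weighted LS, Cramér–von Mises, Anderson–Darling).

See `docs/methods.md` for formulas, numerical choices, and limitations.

## Worked example

Simulate a heterogeneous cohort (Weibull baseline `kappa=0.8, rho=0.9`,
frailty variance 0.6, one binary covariate with `beta=0.5`, 30% censoring),
fit, and test the fit:

```python
import numpy as np
from qxgfrailty import (QXgFrailtyModel, SimulationDesign,
                        simulate_survival_dataset, bagdonavicius_nikulin_test)

design = SimulationDesign(n=500, shape=0.8, scale=0.9, sigma2=0.6,
                          beta=(0.5,), censor_fraction=0.3, seed=42)
data = simulate_survival_dataset(design, np.random.default_rng(42))
res = QXgFrailtyModel.from_dataframe(data).fit(seed=0)
print(res.summary())
```

```
QXg frailty proportional-hazards model
baseline: weibull   n = 500   events = 344
log-likelihood = -351.548083   converged = True   iterations = 44   seed = 0

     param       estimate      std err
     kappa      0.7997044     0.071855
       rho      0.9013581      0.20052
      zeta      0.7140571      0.81964
        x1      0.4396976      0.15634
    sigma2      0.6685651      0.26512
```

All four generating values sit well within a standard error: the baseline
shape/scale near (0.8, 0.9), the covariate effect near 0.5, and a frailty
variance near 0.6 — i.e. substantial unobserved heterogeneity, correctly
recovered. The censored-data goodness-of-fit test does not reject:

```python
print(bagdonavicius_nikulin_test(QXgFrailtyModel.from_dataframe(data), res, intervals=5))
# statistic = 2.085073 (pearson 1.60973 + correction 0.4753432), df = 4, p-value = 0.7201153
```

Risk indicators at a fixed parameter point (here the MLE of a reference
loss table):

```python
from qxgfrailty import kri_table
print(kri_table(params=(0.14107, 0.52017), q_levels=[0.5, 0.9, 0.99]))
```

```
method      zeta     theta    q        var       tvar  tail_variance  tail_mean_variance  mean_excess
 fixed 0.1410700 0.5201700 0.50  4.6982373  7.9207668      8.1291196          11.9853265    3.2225295
 fixed 0.1410700 0.5201700 0.90  9.8829701 12.5095586      6.2864769          15.6527970    2.6265885
 fixed 0.1410700 0.5201700 0.99 15.8459743 18.2226119      5.4063254          20.9257746    2.3766376
```

Read: half of losses exceed 4.70; the mean loss beyond the 99% quantile
(15.85) is 18.22. VaR and TVaR rise with the confidence level while the
mean excess shrinks — the distribution's tail thins relative to its
threshold.

A command-line interface mirrors the library:

```sh
qxgfrailty fit data.csv --baseline weibull --seed 0 --out fit.txt
qxgfrailty gof data.csv --test bnik --cells 5
qxgfrailty risk --zeta 0.14107 --theta 0.52017 --q-levels 0.5,0.99
qxgfrailty simulate --config design.yaml --seed 1 --out sim.csv
```

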