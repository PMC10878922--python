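# naptplx

Heavy-tailed lifetime modelling with the **alpha-power transformed Power
Lomax** family — a four-parameter distribution for survival and reliability
data with extreme observations, plus the full inferential toolkit around it:
classical and Bayesian fitting, competitor models, goodness-of-fit model
selection, and Monte-Carlo estimator studies.

It is written for biostatisticians and reliability analysts who need a
flexible parametric lifetime model (decreasing, L-shaped or unimodal hazards
from one family) and a reproducible pipeline from raw lifetimes to a model
comparison table.

## The model

The baseline Power Lomax cdf is

```
G(x; θ, β, λ) = 1 − λ^θ (λ + x^β)^(−θ),   x > 0,   θ, β, λ > 0,
```

and the alpha-power transform turns it into the four-parameter family

```
F(x) = G(x) · α^(G(x) − 1),        f(x) = g(x) · α^(G(x)−1) · (1 + log(α) G(x)),
```

with α = 1 recovering the baseline exactly.  The transform defines a proper
distribution for α ≥ e⁻¹; the package enforces this.  Raw moments of order
r exist iff r < θβ and are computed by a beta-function series cross-checked
against quadrature.  Everything is evaluated in log space, so fits with
α in the thousands are routine.

Two classic benchmark datasets ship with the package (`bundled:bladder`,
remission times of 128 bladder-cancer patients, and `bundled:income_tax`,
59 monthly Egyptian income-tax figures).

## Worked example

Fit the four-parameter model to the bladder-cancer data and print the
quartile table for two parameter rows:

```
$ naptplx --log-level WARNING fit --data bundled:bladder --model NAPTPLx --starts 25 --seed 1
{
  "model": "NAPTPLx",
  "n": 128,
  "estimates": {
    "theta": 2.9524957524094577,
    "beta": 1.0120220628037628,
    "lam": 9.629911753887809,
    "alpha": 7.504093985771625
  },
  "ses": {
    "theta": 3.178310257851542,
    "beta": 0.5668057416466781,
    "lam": 6.549030532198629,
    "alpha": 18.76240795200912
  },
  "nll": 409.40040164316633,
  "aic": 826.8008032863327,
  "bic": 838.2089243420112,
  "converged": true,
  "n_starts_used": 25
}

$ naptplx --log-level WARNING props --params "0.5,0.5,0.5,0.5;1,2,0.5,20"
   theta     beta      lam     alpha       Q1   median       Q3
0.500000 0.500000 0.500000  0.500000 0.029628 0.302408 3.810631
1.000000 2.000000 0.500000 20.000000 1.008958 1.565673 2.551431
```

The fit lands on an interior maximum-likelihood optimum with NLL 409.40;
β̂ ≈ 1.01 says the hazard is nearly Lomax-shaped (finite intercept, then
decreasing after an early peak), and the large SEs on α̂ and λ̂ reflect the
genuine ridge between the scale and transform-shape parameters.  The
quartile rows reproduce the family's published quartile table.

The same operations are available as library calls:

```python
import naptplx as nx

sample = nx.load_bundled("bladder")
report = nx.comparison_table(sample.values,
                             ("Lx", "PLx", "MOLx", "MOPLx", "NAPTPLx"),
                             n_starts=25, seed=1)
print(report.table[["ks", "ad", "cvm", "nll", "aic", "bic"]])
print(report.ranking("nll"))   # NAPTPLx first on the bladder data
```

Other subcommands: `compare` (full goodness-of-fit table plus TTT/PP/fitted
curve CSVs), `simulate` (bias/MSE study of the ML estimators), `bayes`
(random-walk Metropolis with HPD intervals and Geweke diagnostics).  All
stochastic commands are bit-reproducible under `--seed`.

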