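# tweediecost

Tweedie compound Poisson–Gamma GLMs for semicontinuous health-care cost
data, with the standard competitor models and the comparison machinery to
judge them.

## The problem

Per-person health-care costs over a period are non-negative, right-skewed,
and pile up at exactly zero for non-users.  The usual fixes are a two-part
model (a logistic regression for "any cost?" times a continuous model for
positive costs) or a Tobit censored regression — both of which complicate
interpretation.  A Tweedie GLM with mean–variance power `p ∈ (1, 2)` models
zeros and positive costs with a *single* distribution: the outcome is a
Poisson number `M ~ Pois(λ)` of utilization events, each carrying an iid
Gamma(α, β) cost,

    Z = X₁ + … + X_M,     Pr(Z = 0) = exp(−λ),
    E(Z|x) = μ = exp(x'β),    Var(Z|x) = φ μᵖ,
    λ = μ^(2−p)/(φ(2−p)),  α = (2−p)/(p−1),  β = φ(p−1)μ^(p−1).

`tweediecost` implements this model (exact series log-likelihood, profile
likelihood over `(φ, p)`), the four standard competitors (two-part
Binomial/Gamma and Binomial/generalized-Gamma, Tobit, Poisson), marginal
effects at the covariate means with delta-method standard errors, AIC and
5-fold cross-validated RMSE comparison with rank sums, distributional
diagnostics (mean–variance bins, model-implied quantiles), and a Monte
Carlo study generator covering low/high correlation between users and
non-users across zero proportions.  See `docs/methods.md` for the
methodology in full.

Intended users: health economists and biostatisticians comparing cost
models, and anyone needing a well-tested compound Poisson–Gamma kernel.

## Worked example

```python
import numpy as np
from tweediecost import core, fit_tweedie_glm, compare_models

rng = np.random.default_rng(42)
n = 3000
X = np.column_stack([rng.uniform(2, 8, n), rng.uniform(-10, 1, n),
                     rng.uniform(-2, 0, n)])
mu = np.exp(X @ [0.35, 0.05, -0.3])          # mean costs ~ a few dollars
y = core.sample_glm(mu, phi=2.0, p=1.6, rng=rng)   # ~8% exact zeros

fit = fit_tweedie_glm(X, y)
print(f"p_hat={fit.aux['p']:.3f}  phi_hat={fit.aux['phi']:.3f}")
print(fit.coef.round(3).to_dict())

report = compare_models((X, y), seed=3)
for m, v in report.per_model.items():
    print(f"{m:18s} aic={v['aic']:9.1f} cv_rmse={v['cv_rmse']:6.2f} "
          f"rank_aic={report.ranks_aic[m]}")
```

prints (exactly, for this seed):

```
p_hat=1.594  phi_hat=1.966
{'const': -0.05, 'x1': 0.353, 'x2': 0.046, 'x3': -0.333}
tweedie            aic=  17790.8 cv_rmse=  7.93 rank_aic=1
twopart_gamma      aic=  17893.2 cv_rmse=  7.93 rank_aic=3
twopart_gengamma   aic=  17846.6 cv_rmse=  7.93 rank_aic=2
tobit              aic=  20083.6 cv_rmse=  8.10 rank_aic=4
poisson            aic=  27424.4 cv_rmse=  7.94 rank_aic=5
```

The generating power 1.6 and dispersion 2.0 are recovered (1.594, 1.966),
the slopes match to a few hundredths, and on data truly drawn from a
Tweedie GLM the Tweedie model attains the lowest AIC of the five, while
cross-validated RMSE — which only sees the conditional mean — barely
separates the well-specified mean models.

## Command line

The same pipeline is scriptable:

```sh
tweediecost simulate --scenario high_corr --zero-prop 0.1 --n 2000 \
    --n-replicates 20 --seed 7 --out report.json
tweediecost fit data.csv --model tweedie --me-out effects.csv
tweediecost compare data.csv --seed 1 --out comparison.json
tweediecost qq data.csv --model tweedie --out qq.csv
tweediecost meanvar data.csv --out meanvar.csv
```

The full-scale replication of the simulation study (100 replicates of
N=5000 for each of seven zero proportions in both correlation scenarios)
is a CLI loop — several hours on one core:

```sh
for s in low_corr high_corr; do
  for z in 0.05 0.1 0.15 0.2 0.3 0.5 0.7; do
    tweediecost simulate --scenario $s --zero-prop $z \
        --n 5000 --n-replicates 100 --seed 1 \
        --out study_${s}_${z}.json --records-out study_${s}_${z}.csv
  done
done
```

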