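# cohosem

Bayesian structural equation modeling of the link between landscape
urbanization and coho salmon (*Oncorhynchus kisutch*) pre-spawn
mortality.

Adult coho returning to spawn in urban streams die at high rates before
egg deposition, a syndrome tied to toxic stormwater runoff. Quantifying
that risk across a region is hard because the candidate landscape
predictors — road densities, traffic, impervious cover, development
classes, population density — are strongly collinear. `cohosem` takes
the supervised-dimension-reduction route: a latent factor analysis
compresses the indicator panel into a single "urbanization" score per
subbasin, and that score simultaneously drives a hierarchical binomial
model of observed spawner mortality, so the ordination is weighted by
its ability to predict the response. The package is aimed at
quantitative ecologists who want to fit, compare, and predict from this
model family on their own monitoring data, or to study its behavior on
synthetic data.

## The model

For indicator *j* in subbasin *s* (D indicators, latent score
*z_s* ~ N(0,1)):

    g(μ_sj) = a0_j + a_j z_s
    x_sj ~ logistic-normal(μ_sj, σ_j)        (area fractions, logit link)
    x_sj ~ Gamma(mean μ_sj, shape φ_j)       (nonnegative skewed, log link)

For the mortality surveys (y egg-retaining females of n sampled in
subbasin *s*, year *i*, with standardized precipitation anomalies):

    y_is ~ Binomial(n_is, p_is)
    logit p_is = β0(s) + β1(s)·ppt_su,is + β2(s)·ppt_fa,is + δ_is
    β_k(s) = γ_k0 + γ_k1 z_s + ν_ks,  ν_ks ~ N(0, σ_βk),  δ_is ~ N(0, σ_δ)

Each β_k may be dropped, estimated as a hyper-mean with subbasin random
effects, or allowed to vary with urbanization — an 18-candidate grid
scored by WAIC, PSIS-LOO, and grouped K-fold cross-validation on the
δ-marginalized mortality likelihood. Posterior sampling uses the
package's own No-U-Turn sampler with analytic gradients (numba-compiled
hot path). See `docs/methods.md` for assumptions, priors, and numerical
choices.

## Worked example

```python
import numpy as np
from cohosem import make_fixture, fit, McmcConfig, check_convergence
from cohosem.synthetic_data import FULL_STRUCTURE
from cohosem.prediction import predict_risk, band_summary

ds = make_fixture("study_scale", seed=1)   # 51 monitored + 51 unmonitored subbasins
post = fit(ds, FULL_STRUCTURE,
           mcmc=McmcConfig(chains=2, warmup=400, draws=500, seed=1))
rep = check_convergence(post, rhat_max=1.05, ess_min=50)
print(f"max R-hat {rep.max_rhat:.3f}, min bulk ESS {rep.min_ess:.0f}")

g01 = post.stacked("gamma_z")[:, 0, 0]     # urbanization -> mortality main effect
print(f"gamma_01 mean {g01.mean():.2f}, 95% CI "
      f"({np.quantile(g01, 0.025):.2f}, {np.quantile(g01, 0.975):.2f})")

records = predict_risk(post, seed=1)       # baseline climate, all 102 subbasins
print({k: round(v, 2) for k, v in band_summary(records).items()})
```

Output from this exact script (about a minute on one CPU):

```
max R-hat 1.059, min bulk ESS 28
gamma_01 mean 1.52, 95% CI (1.24, 1.88)
{'<10%': 0.34, '10-40%': 0.53, '>40%': 0.13}
```

The fitted urbanization effect is positive and near the generating value
for this scenario (1.4 up to the latent-scale factor discussed in
`docs/methods.md`), and baseline risk splits the 102 subbasins into the
<10%, 10–40% and >40% predicted-mortality bands. A few measurement-model
intercepts mix slowly at this short demonstration budget — the
production default is 4 chains × 1000 warmup + 1000 draws, under which
the R-hat 1.01 bar applies.

The same pipeline is scriptable from the shell:

```sh
cohosem simulate --scenario tiny --seed 7 --out data/
cohosem fit      --data data/ --structure z/z/z --seed 7 --out fit/
cohosem select   --data data/ --models core4 --seed 7 --out sel/
cohosem crossval --data data/ --scheme by_subbasin --folds 5 --seed 7 --out cv/
cohosem predict  --posterior fit/posterior.npz --seed 7 --out pred/
cohosem report   --data data/ --posterior fit/posterior.npz --seed 7 --out rep/
```

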