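# Methods

`cohosem` implements a Bayesian structural equation model that links a
latent "urbanization" gradient, measured through a panel of landscape
indicators, to coho salmon pre-spawn mortality observed in spawner
surveys, together with the model-selection and risk-prediction machinery
needed to use it.

## Model

**Measurement (factor) component.** Each subbasin *s* has a latent score
*z_s* ~ N(0, 1) (one factor by default; the code accepts L factors with
the identifiability requirement L < D/2, but multi-factor fits are
considered experimental because single-factor structure is what the
biology supports). Each of the D landscape indicators is regressed on
*z* on a link scale:

- Proportion-type indicators (land-cover and impervious fractions) are
  clipped to [1e-4, 1 − 1e-4], logit-transformed, and modeled as normal
  with mean a0_j + a_j z_s and residual SD σ_j (a logistic-normal
  likelihood).
- Nonnegative skewed indicators (road densities, traffic, population,
  restoration) get an additive floor of 1e-4 × column max (they contain
  many exact zeros), are divided by their sample SD to unit variance,
  and are modeled as gamma with mean exp(a0_j + a_j z_s) and shape φ_j
  (variance mean²/φ).

Each proportion column has its own univariate logistic-normal; no
compositional (sum-to-one) coupling across land-cover classes is
imposed. The scale divisor and floor are recorded in the fitted
`VariableSpec` for provenance.

**Mortality (GLMM) component.** For subbasin *s* in year *i*, the number
of egg-retaining female carcasses is y_is ~ Binomial(n_is, p_is) with

    logit p_is = β0(s) + β1(s)·ppt_su + β2(s)·ppt_fa + δ_is,
    β_k(s) = γ_k0 + γ_k1 z_s + ν_ks,   ν_ks ~ N(0, σ_βk),
    δ_is ~ N(0, σ_δ),

where the precipitation covariates are standardized anomalies (mean 0
per subbasin), δ absorbs extra-binomial year-to-year variance, and the
ν are uncorrelated across k. Candidate structures restrict each β_k to
be absent ("0"), a hyper-mean plus random effects ("1"), or additionally
urbanization-dependent ("z"); the intercept is always estimated. The
2 × 3 × 3 grid gives 18 candidates.

**Priors.** N(0, 5) on a0_j, γ_k0, γ_k1; N(0, 2) on loadings; half-N(0, 2)
on σ_j, σ_βk, σ_δ; Gamma(shape 2, rate 0.1) on φ_j. All overridable via
`Priors.override`. These are weakly informative on the logit/log scales
where the data live.

**Identification.** The joint density is invariant under negating all
loadings, factor scores, and urbanization slopes simultaneously. Draws
are reflected after sampling so that a designated anchor variable's
loading (the first gamma-type indicator by default) is nonnegative;
under the exact symmetry this is equivalent to imposing the constraint
during sampling. A second, subtler indeterminacy matters for simulation
studies: the latent scale is fixed by the z ~ N(0,1) prior, so the
hyper-coefficients are identified only up to the affine transform
induced by the realized factor scores' sample mean/SD. Recovery checks
therefore target the identified functionals γ_k0 + γ_k1·mean(z) and
γ_k1·sd(z).

## Inference

Sampling uses the package's own No-U-Turn sampler over a flattened
unconstrained parameterization: positive parameters are log-transformed
with Jacobians; ν and δ are non-centered (ν = σ_β ν̃ with ν̃ ~ N(0,1)),
which keeps the funnel geometry of small hyper-SDs benign. Gradients are
closed-form; the hot path is compiled with numba and asserted equal
(to ~1e-11) to a plain-numpy reference, which is in turn asserted equal
to a scipy-density reference (`sem_core.log_posterior`) up to the
transform Jacobians. Warmup follows the usual three-phase schedule
(step-size-only buffer, doubling variance-estimation windows for a
diagonal mass matrix, terminal step-size buffer) with dual-averaging
step-size adaptation (target acceptance 0.95 by default — hierarchical
logistic models want high acceptance). Defaults are 4 chains × 1000
warmup + 1000 draws; the test suite uses 2 × (250–800) at its reduced
problem sizes, with convergence thresholds relaxed accordingly
(R-hat ≤ 1.03 rather than the production default 1.01). Divergences
above a configurable fraction raise a `SamplerError` carrying the
sampler report.

## Model selection

All scores are computed on the mortality likelihood with δ marginalized
out, so models are compared on predicted mortality frequencies rather
than on fitting their own overdispersion residuals. The marginal
integral E_δ[Bin(y | n, logit⁻¹(η + δ))] is estimated by importance
sampling from a Student-t(5) proposal evaluated at stratified antithetic
quantiles (one uniform per stratum, reflected within the stratum) with
self-normalized N/t weights. The heavy-tailed proposal covers the cases
where the binomial mass concentrates several σ_δ into the tail; measured
against adaptive quadrature the error is ~1e-4 at M = 1000 (the default)
and ~1e-6 at M = 10⁴. σ_δ = 0 draws reduce exactly to the plain
binomial.

WAIC uses the standard pointwise decomposition (penalty = pointwise
variance of log-likelihood). PSIS-LOO smooths the largest 20% of
importance weights (min 5) per observation with a generalized Pareto
fitted by the Zhang–Stephens profile-likelihood method; k̂ > 0.7 is
flagged, and degenerate (all-equal) weights fall back to raw importance
sampling with k̂ reported as NaN. Δ scores are reported on the deviance
scale (−2·ELPD) relative to the best model, with the SE of each Δ
computed from pointwise ELPD differences.

K-fold cross-validation holds out whole calendar years (one fold per
year) or whole subbasins (K = 10 by default, random assignment under the
run seed). Held-out subbasins keep their landscape rows in the factor
likelihood — the same conditioning used for out-of-sample prediction —
while their random effects are drawn fresh from the hyper-distribution
when scoring.

## Prediction

Baseline risk sets the precipitation anomalies to zero. Per posterior
draw and subbasin, β_k(s) is rebuilt from that draw's z; monitored
subbasins use their posterior ν draws, unmonitored subbasins draw fresh
ν ~ N(0, σ_β); a fresh δ is always included, so the reported mean is the
δ-marginal (new-year) probability. A δ-free "typical year" mean is also
exported because it is not obvious which variant a mapped mean should
use; the δ-inclusive one is primary. Uncertainty is the posterior SD of
logit p. Fresh draws are keyed by (seed, CRC32 of the subbasin id), so
predictions are invariant to row order. Risk bands are half-open:
[0, 0.10), [0.10, 0.40), [0.40, 1].

## Synthetic data

The generator draws from exactly the model above, so parameter recovery
is well-posed. The reference ("strong") scenario uses γ00 = −1.7,
γ01 = 1.4, γ10 = 0.5, γ11 = −0.35, γ20 = 0.25, γ21 = −0.2,
σ_β = (0.4, 0.2, 0.2), σ_δ = 0.5: baseline mortality ~15%, an
urbanization main effect strong enough that mortality spans roughly
0–0.9 across z ∈ [−2.5, 2.5], and rain effects that weaken with
urbanization. Loadings are mostly positive (0.4–1.5) with one
evergreen-like cover class near zero. Survey sizes are uniform on 5–80
females; monitored subbasins have 1–12 survey years drawn from a
12-year pool (about 5–6 years on average at the 20-subbasin scale,
matching a multi-year monitoring program). The "null" scenario zeroes
every landscape and rain effect and all σ_β, making mortality
exchangeable across subbasins.

Named scenarios: `study_scale` (51 monitored of 102 total subbasins,
19 indicators split 10 gamma / 9 proportion), `tiny` (6 of 8, 4
indicators — fast tests), `strong_small` / `null` (20 subbasins, 4
indicators — selection operating characteristics). What the generator
does **not** emulate: spatial autocorrelation between subbasins,
compositional coupling among cover classes, shared year effects in
precipitation, or real GIS-derived covariate distributions. Passing
tests therefore demonstrate internal coherence of the method, not
robustness to those real-data features.

## Numerical and design choices

- Proportions are clamped at 1e-4 before the logit; gamma columns are
  floored at 1e-4 × column max (the zero-handling rule is the package's
  own choice and is recorded in the fitted specs).
- A constant (zero-SD) indicator column is a data error naming the
  column; support violations in the joint density yield −inf rather
  than exceptions.
- δ-marginalization draws default to M = 1000; K-fold refits in the
  test suite use M = 400, where the integration error (~1e-3) is far
  below fold-level predictive noise.
- Problem sizes in the test suite (5 recovery replicates, 10 CV
  replicates at S = 20 with K = 5, 2 chains of a few hundred draws) were
  chosen so the whole suite completes in well under half an hour on one
  CPU; the operating-characteristic margins measured at those sizes are
  large (CV Δ ≈ 6–7 SE on strong-effect data).
- Reruns with the same seed are byte-identical for all CSV outputs;
  every output file embeds the seed and a hash of the analysis settings
  (paths excluded).

## Known limitations

- Single-CPU, dense numpy: fitting very large landscape tables (tens of
  thousands of subbasins) is untested and likely slow; the 1,500-subbasin
  scale of a full regional prediction is within reach but not exercised
  by the default suite.
- L > 1 factors are accepted but unsupported by diagnostics tailored to
  multimodality; treat such fits as experimental.
- PSIS-LOO tail smoothing uses a fixed 20% tail fraction; k̂ values for
  short chains (< ~100 draws) are unreliable and reported as such.
- The CLI's `select` subcommand refits every candidate from scratch;
  at study scale with production MCMC settings this is hours of compute,
  which is inherent to the 18-candidate design rather than to this
  implementation.
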