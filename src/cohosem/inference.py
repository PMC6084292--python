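"""Posterior sampling for the SEM and convergence diagnostics.

Sampling uses the package's own NUTS implementation (:mod:`cohosem._hmc`)
over the analytic-gradient packed posterior.  The reflection
non-identifiability of the factor model (negating all loadings, factor
scores and urbanization slopes leaves the posterior unchanged) is
resolved after sampling by reflecting each draw so that a designated
anchor variable's loading is nonnegative; under the exact symmetry this
is equivalent to imposing the constraint during sampling.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._hmc import nuts_sample
from ._packed import PackedSem
from .sem_core import GAMMA, ModelStructure, Priors, SemDataset

__all__ = ["McmcConfig", "PosteriorDraws", "SamplerError", "fit", "check_convergence"]


class SamplerError(RuntimeError):
    """Raised when adaptation or sampling fails; carries the sampler report."""

    def __init__(self, message: str, report: dict | None = None):
        super().__init__(message)
        self.report = report or {}


@dataclass(frozen=True)
class McmcConfig:
    """Sampler settings.

    Defaults (4 chains x 1000 warmup + 1000 draws, target acceptance
    0.95) suit hierarchical logistic models; tests use smaller budgets.
    """

    chains: int = 4
    warmup: int = 1000
    draws: int = 1000
    seed: int = 0
    target_accept: float = 0.95
    max_treedepth: int = 10

    def __post_init__(self) -> None:
        if self.chains < 2:
            raise ValueError("need >= 2 chains for convergence diagnostics")
        if self.draws < 1 or self.warmup < 0:
            raise ValueError("draws >= 1 and warmup >= 0 required")
        if not 0.0 < self.target_accept < 1.0:
            raise ValueError("target_accept must be in (0, 1)")


@dataclass
class PosteriorDraws:
    """Labeled posterior draws for one candidate structure.

    Every array in ``posterior`` has leading dims (chain, draw).  ``v``
    and ``gamma*`` are stored dense over k in {0,1,2} with zeros for
    coefficients the structure excludes.
    """

    posterior: dict[str, np.ndarray]
    structure: ModelStructure
    specs: list
    landscape_ids: np.ndarray
    survey_subbasins: np.ndarray
    sample_stats: dict[str, np.ndarray]
    seed: int
    priors: Priors

    @property
    def n_chains(self) -> int:
        return self.posterior["gamma0"].shape[0]

    @property
    def n_draws(self) -> int:
        return self.posterior["gamma0"].shape[1]

    @property
    def n_samples(self) -> int:
        return self.n_chains * self.n_draws

    def stacked(self, name: str) -> np.ndarray:
        """Draws of one variable flattened over chains: (chain*draw, ...)."""
        arr = self.posterior[name]
        return arr.reshape(-1, *arr.shape[2:])

    def to_inference_data(self):
        import arviz as az

        return az.from_dict(posterior=self.posterior, sample_stats=self.sample_stats)

    MONITORED = (
        "a0", "loadings", "sigma", "shape", "z",
        "gamma0", "gamma_z", "sigma_beta", "sigma_delta",
    )

    def monitored_posterior(self) -> dict[str, np.ndarray]:
        return {k: v for k, v in self.posterior.items() if k in self.MONITORED and v.size}


def fit(
    dataset: SemDataset,
    structure: ModelStructure,
    priors: Priors = Priors(),
    mcmc: McmcConfig = McmcConfig(),
    anchor: int | None = None,
    max_divergence_frac: float = 0.5,
) -> PosteriorDraws:
    """Draw from the joint posterior of ``structure`` fitted to ``dataset``.

    ``anchor`` is the landscape-variable index whose loading is
    constrained nonnegative (default: the first gamma-type variable).
    Deterministic for a fixed seed.
    """
    model = PackedSem(dataset, structure, priors)
    if anchor is None:
        anchor = next(
            (j for j, sp in enumerate(model.specs) if sp.family == GAMMA), 0
        )
    seeds = np.random.SeedSequence(mcmc.seed).spawn(mcmc.chains)
    all_draws = np.empty((mcmc.chains, mcmc.draws, model.dim))
    stats_list = []
    for c in range(mcmc.chains):
        rng = np.random.default_rng(seeds[c])
        theta0 = model.initial_theta(rng)
        try:
            draws, stats = nuts_sample(
                model.logp_grad, theta0, mcmc.warmup, mcmc.draws, rng,
                target_accept=mcmc.target_accept, max_treedepth=mcmc.max_treedepth,
            )
        except ValueError as e:
            raise SamplerError(f"chain {c} failed: {e}") from e
        all_draws[c] = draws
        stats_list.append(stats)

    div_frac = float(np.mean([s.divergent.mean() for s in stats_list]))
    if div_frac > max_divergence_frac:
        raise SamplerError(
            f"{div_frac:.0%} divergent transitions; adaptation failed",
            report={"divergent_frac": div_frac,
                    "step_size": [s.step_size for s in stats_list]},
        )
    if not np.all(np.isfinite(all_draws)):
        raise SamplerError("non-finite draws encountered")

    sl = model.slices
    L = model.L
    cd = (mcmc.chains, mcmc.draws)

    def block(key, *shape):
        return all_draws[:, :, sl[key]].reshape(*cd, *shape) if sl[key].stop > sl[key].start \
            else np.zeros((*cd, *shape))

    post: dict[str, np.ndarray] = {}
    post["a0"] = block("a0", model.D)
    post["loadings"] = block("a", model.D, L)
    post["sigma"] = np.exp(block("t_sigma", model.Dp)) if model.Dp else np.zeros((*cd, 0))
    post["shape"] = np.exp(block("t_phi", model.Dg)) if model.Dg else np.zeros((*cd, 0))
    post["z"] = block("z", model.S, L)

    gamma0 = np.zeros((*cd, 3))
    gamma_z = np.zeros((*cd, 3, L))
    sigma_beta = np.zeros((*cd, 3))
    v = np.zeros((*cd, 3, model.S_mon))
    g0 = block("gamma0", len(model.active))
    sb = np.exp(block("t_sigma_beta", len(model.active)))
    vr = block("v_raw", len(model.active), model.S_mon)
    for i, k in enumerate(model.active):
        gamma0[..., k] = g0[..., i]
        sigma_beta[..., k] = sb[..., i]
        v[..., k, :] = sb[..., i, None] * vr[..., i, :]
    gz = block("gamma_z", len(model.with_z), L)
    for iz, k in enumerate(model.with_z):
        gamma_z[..., k, :] = gz[..., iz, :]
    post["gamma0"] = gamma0
    post["gamma_z"] = gamma_z
    post["sigma_beta"] = sigma_beta
    post["v"] = v
    if model.N:
        post["sigma_delta"] = np.exp(block("t_sigma_delta", 1))[..., 0]
        post["delta"] = post["sigma_delta"][..., None] * block("delta_raw", model.N)
    else:
        post["sigma_delta"] = np.zeros(cd)
        post["delta"] = np.zeros((*cd, 0))

    # reflect draws so the anchor loading is nonnegative in every draw
    sign = np.where(post["loadings"][:, :, anchor, :] < 0, -1.0, 1.0)  # (c, d, L)
    post["loadings"] = post["loadings"] * sign[:, :, None, :]
    post["z"] = post["z"] * sign[:, :, None, :]
    post["gamma_z"] = post["gamma_z"] * sign[:, :, None, :]

    sample_stats = {
        "accept_prob": np.stack([s.accept_prob for s in stats_list]),
        "n_leapfrog": np.stack([s.n_leapfrog for s in stats_list]),
        "diverging": np.stack([s.divergent for s in stats_list]),
        "energy": np.stack([s.energy for s in stats_list]),
        "step_size": np.array([s.step_size for s in stats_list]),
    }
    return PosteriorDraws(
        posterior=post,
        structure=structure,
        specs=model.specs,
        landscape_ids=np.asarray(dataset.landscape.index),
        survey_subbasins=np.asarray(dataset.survey_subbasins),
        sample_stats=sample_stats,
        seed=mcmc.seed,
        priors=priors,
    )


@dataclass
class ConvergenceReport:
    passed: bool
    offenders: list[str]
    max_rhat: float
    min_ess: float

    def __bool__(self) -> bool:  # pragma: no cover - convenience
        return self.passed


def check_convergence(
    post: PosteriorDraws,
    rhat_max: float = 1.01,
    ess_min: float = 100.0,
) -> ConvergenceReport:
    """Split-R-hat / bulk-ESS check over the monitored parameters.

    Fails (with an offender list naming parameters) if any monitored
    parameter has R-hat above ``rhat_max`` or bulk ESS below ``ess_min``.
    Local parameters (per-observation delta, per-subbasin v) are not
    monitored by default.
    """
    import arviz as az

    data = az.from_dict(posterior=post.monitored_posterior())
    rhat = az.rhat(data)
    ess = az.ess(data)
    offenders: list[str] = []
    max_rhat, min_ess = 0.0, np.inf
    for name in rhat.data_vars:
        r = np.asarray(rhat[name]).ravel()
        e = np.asarray(ess[name]).ravel()
        finite = np.isfinite(r)
        if finite.any():
            max_rhat = max(max_rhat, float(np.nanmax(r[finite])))
        if e.size:
            min_ess = min(min_ess, float(np.nanmin(e)))
        bad = np.where((finite & (r > rhat_max)) | (e < ess_min))[0]
        offenders.extend(f"{name}[{i}]" for i in bad)
    return ConvergenceReport(
        passed=not offenders, offenders=offenders,
        max_rhat=max_rhat, min_ess=min_ess,
    )
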