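"""Synthetic landscape and spawner-survey generator.

Emulates the structure of the motivating study system: ~51 monitored
subbasins embedded in a larger pool of unmonitored ones, 19 landscape
indicators split between gamma-type (road densities, traffic, population,
restoration) and proportion-type (land-cover / impervious fractions)
families, 1-12 survey years per subbasin, and pre-spawn mortality
fractions spanning roughly 0-0.9.

Everything is drawn from the model's own generative process with known
parameters, so recovery of those parameters by the inference machinery is
a well-posed test.  Precipitation covariates are generated directly as
standardized anomalies (mean 0, SD ``ppt_sd``), the scale on which the
model predicts.  No spatial autocorrelation between subbasins is
simulated, and proportion columns are generated independently of one
another (no compositional sum-to-one coupling).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .sem_core import (
    GAMMA,
    PROPORTION,
    FactorParams,
    GlmmParams,
    ModelStructure,
    SemDataset,
    SemParams,
    VariableSpec,
)

FULL_STRUCTURE = ModelStructure("z", "z", "z")

_GAMMA_NAMES = [
    "road_local_density", "road_arterial_density", "road_interstate_density",
    "traffic_volume", "pop_density", "restoration_density", "stream_crossings",
    "culvert_density", "bridge_density", "rail_density",
]
_PROP_NAMES = [
    "dev_low_cover", "dev_med_cover", "dev_high_cover", "impervious_cover",
    "evergreen_cover", "deciduous_cover", "grass_cover", "wetland_cover",
    "agriculture_cover",
]

_YEAR_POOL_START = 2000


@dataclass
class ScenarioConfig:
    """Generator settings for one synthetic scenario.

    ``true_params`` holds the hyper-parameters of the generative model;
    its factor scores / random effects / overdispersion residuals are
    filled in during generation and returned as the dataset's truth.
    """

    S_monitored: int
    S_total: int
    D_gamma: int
    D_prop: int
    years_per_subbasin: tuple[int, int]
    n_range: tuple[int, int]
    true_params: SemParams
    ppt_sd: float = 1.0
    seed: int = 0
    year_pool: int = 12

    def __post_init__(self) -> None:
        if not self.S_total >= self.S_monitored >= 2:
            raise ValueError("need S_total >= S_monitored >= 2")
        if self.D_gamma + self.D_prop < 3:
            raise ValueError("need at least 3 indicators")
        if min(self.D_gamma, self.D_prop, self.S_monitored) <= 0:
            raise ValueError("all counts must be positive")
        lo, hi = self.years_per_subbasin
        if not 1 <= lo <= hi <= self.year_pool:
            raise ValueError("empty or invalid year range")
        nlo, nhi = self.n_range
        if not 1 <= nlo <= nhi:
            raise ValueError("invalid n_range")

    @property
    def D(self) -> int:
        return self.D_gamma + self.D_prop

    @property
    def specs(self) -> list[VariableSpec]:
        names_g = (_GAMMA_NAMES * ((self.D_gamma // len(_GAMMA_NAMES)) + 1))[: self.D_gamma]
        names_p = (_PROP_NAMES * ((self.D_prop // len(_PROP_NAMES)) + 1))[: self.D_prop]
        names_g = [n if names_g.count(n) == 1 else f"{n}_{i}" for i, n in enumerate(names_g)]
        names_p = [n if names_p.count(n) == 1 else f"{n}_{i}" for i, n in enumerate(names_p)]
        return [VariableSpec(n, GAMMA) for n in names_g] + [
            VariableSpec(n, PROPORTION) for n in names_p
        ]


@dataclass
class SurveyObservation:
    """One subbasin-year spawner survey record."""

    subbasin_id: str
    year: int
    n_females: int
    y_prespawn_dead: int
    ppt_summer: float
    ppt_fall: float


@dataclass
class SyntheticDataset(SemDataset):
    """A generated dataset plus the true parameters that produced it."""

    truth: SemParams = None
    config: ScenarioConfig = None

    @property
    def survey_observations(self) -> list[SurveyObservation]:
        return [
            SurveyObservation(
                str(r.subbasin_id), int(r.year), int(r.n_females),
                int(r.y_prespawn_dead), float(r.ppt_summer), float(r.ppt_fall),
            )
            for r in self.surveys.itertuples(index=False)
        ]


def default_true_params(
    D_gamma: int,
    D_prop: int,
    effect: str = "strong",
) -> SemParams:
    """Reference hyper-parameters for the generative model.

    ``effect="strong"`` gives a clear urbanization gradient: mostly
    positive loadings (one cover class, the evergreen-like column, loads
    slightly negatively), a positive main effect of urbanization on
    mortality (gamma_01 = 1) and rain effects that weaken with
    urbanization (negative gamma_11, gamma_21).  ``effect="null"`` zeroes
    every landscape and rain effect so mortality is exchangeable across
    subbasins.
    """
    D = D_gamma + D_prop
    a0 = np.concatenate([np.full(D_gamma, 0.3), np.full(D_prop, -1.5)])
    loadings = np.concatenate(
        [
            0.5 + 0.5 * np.linspace(0, 1, D_gamma),
            0.4 + 0.4 * np.linspace(0, 1, D_prop),
        ]
    )
    if D_prop >= 5:
        loadings[D_gamma + 4] = -0.1  # evergreen-like column: near-zero loading
    sigma = np.full(D_prop, 0.8)
    shape = np.full(D_gamma, 2.0)
    if effect == "strong":
        # baseline ~15% mortality, urbanization main effect strong enough
        # that p spans ~0.005-0.9 over z in [-2.5, 2.5] (the observed span)
        gamma0 = np.array([-1.7, 0.5, 0.25])
        gamma_z = np.array([[1.4], [-0.35], [-0.2]])
        sigma_beta = np.array([0.4, 0.2, 0.2])
        sigma_delta = 0.5
    elif effect == "null":
        gamma0 = np.array([-1.7, 0.0, 0.0])
        gamma_z = np.zeros((3, 1))
        sigma_beta = np.zeros(3)
        sigma_delta = 0.3
    else:
        raise ValueError(f"unknown effect scenario {effect!r}")
    factor = FactorParams(
        a0=a0, loadings=loadings.reshape(D, 1), sigma=sigma, shape=shape,
        z=np.zeros((0, 1)),
    )
    glmm = GlmmParams(
        gamma0=gamma0, gamma_z=gamma_z, sigma_beta=sigma_beta,
        v=np.zeros((3, 0)), sigma_delta=sigma_delta, delta=np.zeros(0),
    )
    return SemParams(factor=factor, glmm=glmm)


def generate_landscape(
    config: ScenarioConfig, rng: np.random.Generator | None = None
) -> tuple[pd.DataFrame, np.ndarray]:
    """Draw the landscape attribute table and the true factor scores.

    For each subbasin, z_s ~ N(0, 1).  Proportion-type columns are
    logistic-normal (normal on the logit scale with mean a0_j + a_j z_s
    and SD sigma_j); gamma-type columns are gamma with mean
    exp(a0_j + a_j z_s) and shape phi_j.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    f = config.true_params.factor
    L = f.loadings.shape[1]
    if f.a0.size != config.D:
        raise ValueError("true_params dimensioned for a different D")
    z = rng.standard_normal((config.S_total, L))
    eta = f.a0[None, :] + z @ f.loadings.T
    cols = {}
    specs = config.specs
    ig = ip = 0
    for j, spec in enumerate(specs):
        if spec.family == GAMMA:
            phi = f.shape[ig]
            ig += 1
            mean = np.exp(eta[:, j])
            cols[spec.name] = rng.gamma(shape=phi, scale=mean / phi)
        else:
            s = f.sigma[ip]
            ip += 1
            from scipy.special import expit

            cols[spec.name] = expit(eta[:, j] + s * rng.standard_normal(config.S_total))
    ids = [f"sb{i:04d}" for i in range(config.S_total)]
    return pd.DataFrame(cols, index=pd.Index(ids, name="subbasin_id")), z


def generate_surveys(
    config: ScenarioConfig,
    z: np.ndarray,
    rng: np.random.Generator | None = None,
) -> tuple[pd.DataFrame, np.ndarray, np.ndarray]:
    """Draw subbasin-year mortality surveys given factor scores.

    Returns (survey table, realized random effects v (3, S_monitored),
    realized overdispersion residuals delta).  Subbasin coefficients
    follow the varying-intercept, varying-slopes model; per-observation
    precipitation anomalies are N(0, ppt_sd); y ~ Binomial(n, p) with
    logit p = beta0 + beta1 ppt_su + beta2 ppt_fa + delta.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed + 1)
    from scipy.special import expit

    g = config.true_params.glmm
    if np.any(g.sigma_beta < 0) or g.sigma_delta < 0:
        raise ValueError("hyper-SDs must be nonnegative")
    S = config.S_monitored
    if z.shape[0] < S:
        raise ValueError("factor scores missing for some monitored subbasins")
    z_mon = np.atleast_2d(z)[:S]
    v = g.sigma_beta[:, None] * rng.standard_normal((3, S))
    betas = g.gamma0[:, None] + (g.gamma_z @ z_mon.T) + v  # (3, S)

    lo, hi = config.years_per_subbasin
    nlo, nhi = config.n_range
    years_all = np.arange(_YEAR_POOL_START, _YEAR_POOL_START + config.year_pool)
    rows = []
    deltas = []
    for s in range(S):
        n_years = int(rng.integers(lo, hi + 1))
        years = np.sort(rng.choice(years_all, size=n_years, replace=False))
        for year in years:
            n = int(rng.integers(nlo, nhi + 1))
            ppt_su = config.ppt_sd * rng.standard_normal()
            ppt_fa = config.ppt_sd * rng.standard_normal()
            d = g.sigma_delta * rng.standard_normal()
            eta = betas[0, s] + betas[1, s] * ppt_su + betas[2, s] * ppt_fa + d
            y = int(rng.binomial(n, expit(eta)))
            rows.append((f"sb{s:04d}", int(year), n, y, ppt_su, ppt_fa))
            deltas.append(d)
    surveys = pd.DataFrame(
        rows,
        columns=["subbasin_id", "year", "n_females", "y_prespawn_dead", "ppt_summer", "ppt_fall"],
    )
    return surveys, v, np.asarray(deltas)


def generate_dataset(config: ScenarioConfig) -> SyntheticDataset:
    """Full generative draw: landscape + surveys + truth, seeded."""
    rng = np.random.default_rng(config.seed)
    landscape, z = generate_landscape(config, rng)
    surveys, v, delta = generate_surveys(config, z, rng)
    t = config.true_params
    truth = SemParams(
        factor=FactorParams(
            a0=t.factor.a0.copy(), loadings=t.factor.loadings.copy(),
            sigma=t.factor.sigma.copy(), shape=t.factor.shape.copy(), z=z,
        ),
        glmm=GlmmParams(
            gamma0=t.glmm.gamma0.copy(), gamma_z=t.glmm.gamma_z.copy(),
            sigma_beta=t.glmm.sigma_beta.copy(), v=v,
            sigma_delta=t.glmm.sigma_delta, delta=delta,
        ),
    )
    return SyntheticDataset(
        landscape=landscape, specs=config.specs, surveys=surveys,
        truth=truth, config=config,
    )


_FIXTURES = {
    "study_scale": lambda seed: ScenarioConfig(
        S_monitored=51, S_total=102, D_gamma=10, D_prop=9,
        years_per_subbasin=(1, 12), n_range=(5, 80),
        true_params=default_true_params(10, 9, "strong"), seed=seed,
    ),
    "tiny": lambda seed: ScenarioConfig(
        S_monitored=6, S_total=8, D_gamma=2, D_prop=2,
        years_per_subbasin=(2, 4), n_range=(10, 40),
        true_params=default_true_params(2, 2, "strong"), seed=seed,
    ),
    "strong_small": lambda seed: ScenarioConfig(
        S_monitored=20, S_total=20, D_gamma=2, D_prop=2,
        years_per_subbasin=(3, 8), n_range=(20, 60),
        true_params=default_true_params(2, 2, "strong"), seed=seed,
    ),
    "null": lambda seed: ScenarioConfig(
        S_monitored=20, S_total=20, D_gamma=2, D_prop=2,
        years_per_subbasin=(3, 8), n_range=(20, 60),
        true_params=default_true_params(2, 2, "null"), seed=seed,
    ),
}

FIXTURE_NAMES = tuple(_FIXTURES)


def make_fixture(name: str, seed: int = 0) -> SyntheticDataset:
    """Named, seeded scenario: one of ``study_scale``, ``tiny``,
    ``strong_small``, ``null``.

    ``study_scale`` mirrors the study dimensions (51 monitored subbasins
    among 102 total, 19 indicators); ``tiny`` is a fast test scenario
    (6 monitored, 4 indicators); ``strong_small``/``null`` are 20-subbasin
    scenarios with and without landscape/rain effects.
    """
    try:
        cfg = _FIXTURES[name](seed)
    except KeyError:
        raise KeyError(f"unknown fixture {name!r}; choose from {FIXTURE_NAMES}") from None
    return generate_dataset(cfg)
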