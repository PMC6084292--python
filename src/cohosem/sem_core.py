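"""Core structural equation model: types, transforms, likelihoods, priors.

The model couples a factor analysis for landscape indicators to a
hierarchical binomial GLMM for pre-spawn mortality:

* Each of D landscape indicators x_sj (one per subbasin s) is regressed on
  L latent factor scores z_sl ~ N(0, 1) on a link scale:
  g(mu_sj) = a0_j + sum_l a_jl z_sl.  Proportion-type indicators are
  logit-transformed and modeled as normal (logistic-normal); nonnegative
  skewed indicators are modeled as gamma with log link, parameterized by
  mean m and shape phi (variance m^2 / phi).
* Mortality counts y_is ~ Binomial(n_is, p_is) with
  logit p_is = beta0(s) + beta1(s) ppt_su + beta2(s) ppt_fa + delta_is,
  delta_is ~ N(0, sigma_delta) absorbing extra-binomial variance.
* The subbasin coefficients follow a varying-intercept, varying-slopes
  model beta_k(s) = gamma_k0 + sum_l gamma_kl z_sl + nu_ks,
  nu_ks ~ N(0, sigma_beta_k), with uncorrelated random effects.

Candidate model structures restrict each beta_k to be absent (slopes
only), a hyper-mean with random effects, or additionally urbanization
(z) dependent.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import gammaln, logit

PROPORTION = "proportion"
GAMMA = "gamma"

_MODE_CODE = {"zero": "0", "mean": "1", "z": "z"}
_CODE_MODE = {v: k for k, v in _MODE_CODE.items()}


class DataError(ValueError):
    """Raised when input data violate a declared domain."""


class ShapeError(ValueError):
    """Raised on dimension mismatches between data and parameters."""


@dataclass(frozen=True)
class VariableSpec:
    """Declaration of one landscape indicator column.

    Parameters
    ----------
    name : column label in the landscape table.
    family : ``"proportion"`` for (0,1) area fractions (logistic-normal
        likelihood) or ``"gamma"`` for nonnegative continuous variables
        (mean-shape gamma likelihood with log link).
    clamp : increment used to bound proportions away from {0, 1}; for
        gamma variables the additive floor is ``clamp * column max``.
    scale : divisor applied to gamma-type variables so the transformed
        column has unit variance.  Filled in by :func:`transform_landscape`.
    """

    name: str
    family: str
    clamp: float = 1e-4
    scale: float = 1.0

    def __post_init__(self) -> None:
        if self.family not in (PROPORTION, GAMMA):
            raise ValueError(f"unknown family {self.family!r} for {self.name!r}")
        if not 0.0 < self.clamp <= 0.01:
            raise ValueError(f"clamp must be in (0, 0.01], got {self.clamp}")
        if self.scale <= 0:
            raise ValueError("scale must be positive")


@dataclass
class FactorParams:
    """Parameters of the latent-factor measurement model.

    ``a0`` and ``loadings`` are per-variable intercepts and slopes on the
    link scale; ``sigma`` holds residual SDs of the logistic-normal
    (proportion) variables, ``shape`` the gamma shapes, each ordered as
    the variables of that family appear in the spec list.  ``z`` is the
    (S, L) matrix of factor scores.
    """

    a0: np.ndarray
    loadings: np.ndarray  # (D, L)
    sigma: np.ndarray  # per proportion-type variable
    shape: np.ndarray  # per gamma-type variable
    z: np.ndarray  # (S, L)

    def __post_init__(self) -> None:
        self.a0 = np.asarray(self.a0, float)
        self.loadings = np.atleast_2d(np.asarray(self.loadings, float))
        if self.loadings.shape[0] != self.a0.size:
            self.loadings = self.loadings.reshape(self.a0.size, -1)
        self.sigma = np.asarray(self.sigma, float)
        self.shape = np.asarray(self.shape, float)
        self.z = np.atleast_2d(np.asarray(self.z, float))
        if self.z.shape[1] != self.loadings.shape[1]:
            self.z = self.z.reshape(-1, self.loadings.shape[1])
        if np.any(self.sigma <= 0):
            raise ValueError("residual SDs sigma_j must be positive")
        if np.any(self.shape <= 0):
            raise ValueError("gamma shapes phi_j must be positive")
        D, L = self.loadings.shape
        if not L < D / 2:
            raise ValueError(f"identifiability requires L < D/2 (got L={L}, D={D})")


@dataclass
class GlmmParams:
    """Parameters of the mortality GLMM.

    The subbasin coefficients beta_k(s) are always derived from these via
    :func:`build_betas`; they are never stored.  ``v`` is (3, S) of
    subbasin random effects, ``delta`` the per-observation overdispersion
    residuals aligned with the survey table.
    """

    gamma0: np.ndarray  # (3,)
    gamma_z: np.ndarray  # (3, L)
    sigma_beta: np.ndarray  # (3,)
    v: np.ndarray  # (3, S)
    sigma_delta: float
    delta: np.ndarray  # (N_obs,)

    def __post_init__(self) -> None:
        self.gamma0 = np.asarray(self.gamma0, float)
        self.gamma_z = np.atleast_2d(np.asarray(self.gamma_z, float))
        if self.gamma_z.shape[0] != 3:
            self.gamma_z = self.gamma_z.reshape(3, -1)
        self.sigma_beta = np.asarray(self.sigma_beta, float)
        self.v = np.atleast_2d(np.asarray(self.v, float))
        self.delta = np.asarray(self.delta, float)
        self.sigma_delta = float(self.sigma_delta)
        if np.any(self.sigma_beta < 0) or self.sigma_delta < 0:
            raise ValueError("hyper-SDs must be nonnegative")


@dataclass
class SemParams:
    """Full parameter set: factor model coupled to the mortality GLMM."""

    factor: FactorParams
    glmm: GlmmParams

    def __post_init__(self) -> None:
        if self.glmm.v.shape[1] > self.factor.z.shape[0]:
            raise ValueError(
                "GLMM random effects refer to more subbasins than have factor scores"
            )


@dataclass(frozen=True)
class ModelStructure:
    """One candidate structure for the mortality GLMM.

    Each coefficient beta_k may be fixed at zero (slopes only), estimated
    with a hyper-mean plus subbasin random effects (``"mean"``), or
    additionally allowed to vary with the latent urbanization factor
    (``"z"``).  The intercept is always estimated.
    """

    intercept_mode: str = "z"
    summer_mode: str = "z"
    fall_mode: str = "z"
    L: int = 1

    def __post_init__(self) -> None:
        if self.intercept_mode not in ("mean", "z"):
            raise ValueError("intercept_mode must be 'mean' or 'z' (always estimated)")
        for m in (self.summer_mode, self.fall_mode):
            if m not in ("zero", "mean", "z"):
                raise ValueError(f"invalid slope mode {m!r}")
        if self.L < 1:
            raise ValueError("L must be >= 1")

    @property
    def modes(self) -> tuple[str, str, str]:
        return (self.intercept_mode, self.summer_mode, self.fall_mode)

    def active(self, k: int) -> bool:
        """Whether beta_k is estimated at all (with random effects)."""
        return self.modes[k] != "zero"

    def has_z(self, k: int) -> bool:
        """Whether beta_k varies with the latent factor."""
        return self.modes[k] == "z"

    @property
    def code(self) -> str:
        """Compact code, e.g. ``"z/z/1"`` (intercept/summer/fall)."""
        return "/".join(_MODE_CODE[m] for m in self.modes)

    @classmethod
    def from_code(cls, code: str, L: int = 1) -> "ModelStructure":
        parts = code.split("/")
        if len(parts) != 3 or any(p not in _CODE_MODE for p in parts):
            raise ValueError(f"bad structure code {code!r}")
        return cls(*(_CODE_MODE[p] for p in parts), L=L)


@dataclass(frozen=True)
class Priors:
    """Weakly informative default priors, overridable per field.

    Normal(0, sd) on intercepts/loadings/hyper-coefficients, half-Normal
    on all SDs, Gamma(shape, rate) on the gamma dispersions phi_j.
    """

    a0_sd: float = 5.0
    loading_sd: float = 2.0
    gamma_sd: float = 5.0
    sigma_hn: float = 2.0
    sigma_beta_hn: float = 2.0
    sigma_delta_hn: float = 2.0
    phi_shape: float = 2.0
    phi_rate: float = 0.1

    def override(self, **kw: float) -> "Priors":
        return replace(self, **kw)


@dataclass
class SemDataset:
    """Landscape table + declared specs + mortality surveys.

    The landscape table is indexed by subbasin_id and may contain more
    subbasins than are surveyed (their indicators still inform the factor
    model).  On construction, surveyed subbasins are moved to the front of
    the table, in first-appearance order, so that factor-score rows
    ``z[:S_monitored]`` always align with the random-effect columns.
    """

    landscape: pd.DataFrame
    specs: list[VariableSpec]
    surveys: pd.DataFrame

    def __post_init__(self) -> None:
        if len(self.surveys):
            sid = self.surveys["subbasin_id"].to_numpy()
            monitored = pd.unique(sid)
            missing = set(monitored) - set(self.landscape.index)
            if missing:
                raise DataError(f"surveyed subbasins missing landscape rows: {sorted(missing)}")
            rest = [i for i in self.landscape.index if i not in set(monitored)]
            self.landscape = self.landscape.loc[list(monitored) + rest]

    @property
    def survey_subbasins(self) -> np.ndarray:
        """Surveyed subbasin ids, in the row order of the landscape table."""
        if not len(self.surveys):
            return np.asarray([])
        return pd.unique(self.surveys["subbasin_id"].to_numpy())

    @property
    def n_monitored(self) -> int:
        return len(self.survey_subbasins)

    def subset_surveys(self, mask: np.ndarray) -> "SemDataset":
        """Dataset with a row-subset of surveys; landscape table unchanged."""
        return SemDataset(self.landscape.copy(), list(self.specs), self.surveys[mask].reset_index(drop=True))


# ---------------------------------------------------------------------------
# data transforms
# ---------------------------------------------------------------------------

def transform_landscape(
    raw: pd.DataFrame, specs: Sequence[VariableSpec]
) -> tuple[pd.DataFrame, list[VariableSpec]]:
    """Map a raw landscape table onto the model's likelihood scale.

    Proportion-type columns are clipped to [clamp, 1-clamp] and
    logit-transformed.  Gamma-type columns get an additive floor of
    ``clamp * column max`` (bounding the many exact zeros away from the
    gamma support boundary) and are divided by their sample SD so every
    column enters the likelihood with unit variance.

    Returns the transformed table and the specs with fitted ``scale``
    recorded for inversion/provenance.
    """
    out = {}
    fitted: list[VariableSpec] = []
    for spec in specs:
        if spec.name not in raw.columns:
            raise DataError(f"landscape table missing declared column {spec.name!r}")
        x = raw[spec.name].to_numpy(float)
        if spec.family == PROPORTION:
            out[spec.name] = logit(np.clip(x, spec.clamp, 1.0 - spec.clamp))
            fitted.append(spec)
        else:
            shifted = x + spec.clamp * np.max(x)
            sd = float(np.std(shifted, ddof=1))
            if not np.isfinite(sd) or sd <= 1e-10 * float(np.mean(np.abs(shifted))):
                raise DataError(f"gamma-type column {spec.name!r} is constant (zero SD)")
            out[spec.name] = shifted / sd
            fitted.append(replace(spec, scale=sd))
    return pd.DataFrame(out, index=raw.index), fitted


# ---------------------------------------------------------------------------
# densities
# ---------------------------------------------------------------------------

def gamma_meanshape_logpdf(x, mean, shape):
    """Log-density of a gamma with mean ``mean`` and shape ``shape``.

    Variance is mean^2 / shape; this is Gamma(shape, rate=shape/mean).
    """
    x = np.asarray(x, float)
    mean = np.asarray(mean, float)
    shape = np.asarray(shape, float)
    return (
        shape * (np.log(shape) - np.log(mean))
        - gammaln(shape)
        + (shape - 1.0) * np.log(x)
        - shape * x / mean
    )


def logistic_normal_logpdf(x, mu, sigma):
    """Log-density on (0,1) of a variable whose logit is N(mu, sigma)."""
    x = np.asarray(x, float)
    lp = stats.norm.logpdf(logit(x), mu, sigma)
    return lp - np.log(x) - np.log1p(-x)


def binomial_logit_logpmf(y, n, eta):
    """Binomial log-mass at y with logit(p) = eta, stable for large |eta|."""
    y = np.asarray(y, float)
    n = np.asarray(n, float)
    eta = np.asarray(eta, float)
    return (
        gammaln(n + 1) - gammaln(y + 1) - gammaln(n - y + 1)
        + y * eta
        - n * np.logaddexp(0.0, eta)
    )


def loglik_factor(
    table: pd.DataFrame | np.ndarray,
    specs: Sequence[VariableSpec],
    params: FactorParams,
) -> np.ndarray:
    """Per-entry log-density matrix (S, D) of the factor measurement model.

    ``table`` must already be transformed (logit / unit-variance scale).
    Logistic-normal entries are scored on the logit scale under
    N(a0_j + a_j . z_s, sigma_j); gamma entries under the mean-shape gamma
    with mean exp(a0_j + a_j . z_s).
    """
    x = table.to_numpy(float) if isinstance(table, pd.DataFrame) else np.asarray(table, float)
    D = len(specs)
    if x.ndim != 2 or x.shape[1] != D or params.a0.size != D:
        raise ShapeError(
            f"table has shape {x.shape}, expected (S, {D}) matching specs/params"
        )
    if params.z.shape[0] != x.shape[0]:
        raise ShapeError("factor scores z do not match the table's subbasin count")
    eta = params.a0[None, :] + params.z @ params.loadings.T  # (S, D)
    ll = np.empty_like(eta)
    ip = ig = 0
    for j, spec in enumerate(specs):
        if spec.family == PROPORTION:
            s = params.sigma[ip]
            ip += 1
            r = (x[:, j] - eta[:, j]) / s
            ll[:, j] = -0.5 * r * r - 0.5 * np.log(2.0 * np.pi) - np.log(s)
        else:
            phi = params.shape[ig]
            ig += 1
            ll[:, j] = gamma_meanshape_logpdf(x[:, j], np.exp(eta[:, j]), phi)
    return ll


def build_betas(params: SemParams, structure: ModelStructure) -> np.ndarray:
    """Subbasin regression coefficients beta_k(s), shape (3, S).

    beta_k(s) = gamma_k0 + gamma_k. z_s + nu_ks when the structure allows
    it; urbanization slopes and/or the whole coefficient are zeroed out
    according to the structure.  Only the first ``v.shape[1]`` subbasins
    (those with survey data) get random effects.
    """
    z = params.factor.z
    g = params.glmm
    S = g.v.shape[1]
    betas = np.zeros((3, S))
    for k in range(3):
        if not structure.active(k):
            continue
        betas[k] = g.gamma0[k] + g.v[k]
        if structure.has_z(k):
            betas[k] += z[:S] @ g.gamma_z[k]
    return betas


def loglik_mortality(
    surveys: pd.DataFrame,
    params: SemParams,
    structure: ModelStructure,
    subbasin_order: Sequence | None = None,
) -> np.ndarray:
    """Per-observation binomial log-mass vector for the survey table.

    ``surveys`` needs columns subbasin_id, n_females, y_prespawn_dead,
    ppt_summer, ppt_fall.  ``subbasin_order`` gives the subbasin ids
    corresponding to rows of z / columns of v (defaults to first
    appearance order in the survey table).
    """
    y = surveys["y_prespawn_dead"].to_numpy(float)
    n = surveys["n_females"].to_numpy(float)
    if np.any(y > n) or np.any(y < 0) or np.any(n <= 0):
        raise DataError("survey counts must satisfy 0 <= y <= n, n > 0")
    sid = surveys["subbasin_id"].to_numpy()
    if subbasin_order is None:
        subbasin_order = pd.unique(sid)
    index = pd.Index(subbasin_order)
    s_idx = index.get_indexer(sid)
    if np.any(s_idx < 0):
        raise DataError("survey refers to a subbasin absent from the parameter set")
    betas = build_betas(params, structure)
    eta = (
        betas[0, s_idx]
        + betas[1, s_idx] * surveys["ppt_summer"].to_numpy(float)
        + betas[2, s_idx] * surveys["ppt_fall"].to_numpy(float)
        + params.glmm.delta
    )
    return binomial_logit_logpmf(y, n, eta)


def _halfnormal_logpdf(x, sd):
    x = np.asarray(x, float)
    return np.where(
        x >= 0,
        0.5 * np.log(2.0 / np.pi) - np.log(sd) - 0.5 * (x / sd) ** 2,
        -np.inf,
    )


def log_posterior(
    dataset,
    params: SemParams,
    structure: ModelStructure,
    priors: Priors = Priors(),
) -> float:
    """Joint log-posterior density (unnormalized) at ``params``.

    Sums the factor likelihood over the transformed landscape table, the
    binomial mortality likelihood, standard-normal priors on z, the
    random-effect densities (nu under sigma_beta, delta under sigma_delta)
    and the hyper-priors.  Returns -inf (never raises) when a parameter
    is outside its support.

    ``dataset`` is any object with ``landscape`` (raw table), ``specs``
    and ``surveys`` attributes; this function is deliberately written as
    a plain sum of scipy densities so it can serve as a readable
    reference against faster code paths.
    """
    f, g = params.factor, params.glmm
    try:
        table, specs = transform_landscape(dataset.landscape, dataset.specs)
    except DataError:
        return -np.inf
    if np.any(f.sigma <= 0) or np.any(f.shape <= 0) or g.sigma_delta < 0:
        return -np.inf

    lp = float(np.sum(loglik_factor(table, specs, f)))
    surveys = dataset.surveys
    if len(surveys):
        order = getattr(dataset, "survey_subbasins", None)
        lp += float(np.sum(loglik_mortality(surveys, params, structure, order)))

    lp += float(np.sum(stats.norm.logpdf(f.z)))
    for k in range(3):
        if structure.active(k):
            sb = g.sigma_beta[k]
            if sb < 0:
                return -np.inf
            if sb == 0.0:
                # degenerate limit: nu is a point mass at zero
                if np.any(g.v[k] != 0.0):
                    return -np.inf
            else:
                lp += float(np.sum(stats.norm.logpdf(g.v[k], 0.0, sb)))
            lp += float(_halfnormal_logpdf(sb, priors.sigma_beta_hn))
            lp += float(stats.norm.logpdf(g.gamma0[k], 0.0, priors.gamma_sd))
            if structure.has_z(k):
                lp += float(np.sum(stats.norm.logpdf(g.gamma_z[k], 0.0, priors.gamma_sd)))
    if len(surveys):
        if g.sigma_delta < 0:
            return -np.inf
        if g.sigma_delta == 0.0:
            if np.any(g.delta != 0.0):
                return -np.inf
        else:
            lp += float(np.sum(stats.norm.logpdf(g.delta, 0.0, g.sigma_delta)))
    lp += float(_halfnormal_logpdf(g.sigma_delta, priors.sigma_delta_hn))

    lp += float(np.sum(stats.norm.logpdf(f.a0, 0.0, priors.a0_sd)))
    lp += float(np.sum(stats.norm.logpdf(f.loadings, 0.0, priors.loading_sd)))
    lp += float(np.sum(_halfnormal_logpdf(f.sigma, priors.sigma_hn)))
    lp += float(
        np.sum(stats.gamma.logpdf(f.shape, priors.phi_shape, scale=1.0 / priors.phi_rate))
    )
    if not np.isfinite(lp):
        return -np.inf
    return lp
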