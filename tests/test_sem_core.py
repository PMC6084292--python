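"""Transforms, likelihood terms and the joint posterior density."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import integrate, stats
from scipy.special import expit, logit

from cohosem.sem_core import (
    DataError,
    FactorParams,
    GlmmParams,
    ModelStructure,
    SemParams,
    ShapeError,
    VariableSpec,
    binomial_logit_logpmf,
    build_betas,
    gamma_meanshape_logpdf,
    log_posterior,
    logistic_normal_logpdf,
    loglik_factor,
    loglik_mortality,
    transform_landscape,
)
from cohosem.synthetic_data import FULL_STRUCTURE, make_fixture


def _specs():
    return [
        VariableSpec("roads", "gamma"),
        VariableSpec("cover", "proportion"),
        VariableSpec("wetland", "proportion"),
    ]


class TestTransformLandscape:
    def test_proportion_zero_clamped_to_logit_of_clamp(self):
        raw = pd.DataFrame({"roads": [1.0, 2.0], "cover": [0.0, 0.5], "wetland": [0.2, 0.4]})
        out, _ = transform_landscape(raw, _specs())
        assert out["cover"].iloc[0] == pytest.approx(logit(1e-4))
        assert out["cover"].iloc[0] == pytest.approx(-9.2102, abs=1e-3)

    def test_proportion_midpoint_maps_to_zero(self):
        raw = pd.DataFrame({"roads": [1.0, 2.0], "cover": [0.5, 0.7], "wetland": [0.2, 0.4]})
        out, _ = transform_landscape(raw, _specs())
        assert out["cover"].iloc[0] == 0.0

    def test_gamma_column_scaled_to_unit_variance(self):
        raw = pd.DataFrame({"roads": [2.0, 4.0, 6.0], "cover": [0.1, 0.2, 0.3], "wetland": [0.2, 0.3, 0.4]})
        out, fitted = transform_landscape(raw, _specs())
        # oracle: SD computed independently of the implementation
        shifted = np.array([2.0, 4.0, 6.0]) + 1e-4 * 6.0
        assert np.std(out["roads"], ddof=1) == pytest.approx(1.0)
        assert fitted[0].scale == pytest.approx(np.std(shifted, ddof=1))

    def test_constant_gamma_column_rejected_by_name(self):
        raw = pd.DataFrame({"roads": [3.0, 3.0, 3.0], "cover": [0.1, 0.2, 0.3], "wetland": [0.2, 0.3, 0.4]})
        with pytest.raises(DataError, match="roads"):
            transform_landscape(raw, _specs())


def _factor_params(S=3, a0=(0.0, 0.0, 0.0), a=(0.0, 0.0, 0.0), sigma=(1.0, 1.0),
                   shape=1.0, z=None):
    if z is None:
        z = np.zeros((S, 1))
    return FactorParams(
        a0=np.array(a0), loadings=np.array(a).reshape(3, 1),
        sigma=np.array(sigma), shape=np.array([shape]), z=np.asarray(z),
    )


class TestLoglikFactor:
    def test_logit_value_at_mean_is_standard_normal_mode(self):
        specs = _specs()
        params = _factor_params(S=1)
        table = np.array([[1.0, 0.0, 0.3]])  # gamma scaled value, prop cols on logit scale
        ll = loglik_factor(table, specs, params)
        assert ll[0, 1] == pytest.approx(-0.5 * math.log(2 * math.pi), abs=1e-12)

    def test_shape_one_gamma_is_exponential(self):
        specs = _specs()
        params = _factor_params(S=1, a0=(math.log(2.0), 0.0, 0.0), shape=1.0)
        table = np.array([[0.7, 0.3, -0.1]])
        ll = loglik_factor(table, specs, params)
        assert ll[0, 0] == pytest.approx(stats.expon.logpdf(0.7, scale=2.0), abs=1e-12)

    def test_dimension_mismatch_raises(self):
        with pytest.raises(ShapeError):
            loglik_factor(np.zeros((3, 4)), _specs(), _factor_params())

    def test_reflection_symmetry_exact(self):
        rng = np.random.default_rng(5)
        specs = _specs()
        z = rng.standard_normal((4, 1))
        p1 = _factor_params(S=4, a0=(0.2, -0.4, 0.1), a=(0.8, -0.6, 0.3),
                            sigma=(0.7, 1.2), shape=2.5, z=z)
        p2 = _factor_params(S=4, a0=(0.2, -0.4, 0.1), a=(-0.8, 0.6, -0.3),
                            sigma=(0.7, 1.2), shape=2.5, z=-z)
        table = np.column_stack(
            [rng.gamma(2.0, 1.0, 4), rng.normal(0, 1, 4), rng.normal(0, 1, 4)]
        )
        ll1 = loglik_factor(table, specs, p1)
        ll2 = loglik_factor(table, specs, p2)
        np.testing.assert_array_equal(ll1, ll2)


class TestDensityNormalization:
    """Every per-entry density integrates/sums to one over its domain."""

    @pytest.mark.parametrize("mean,shape", [(1.0, 0.7), (2.5, 3.0), (0.4, 1.0)])
    def test_gamma_meanshape_normalizes(self, mean, shape):
        val, _ = integrate.quad(
            lambda x: np.exp(gamma_meanshape_logpdf(x, mean, shape)),
            0, np.inf, limit=200,
        )
        assert val == pytest.approx(1.0, abs=1e-6)

    @pytest.mark.parametrize("mu,sigma", [(0.0, 1.0), (-1.5, 0.6), (2.0, 1.8)])
    def test_logistic_normal_normalizes(self, mu, sigma):
        val, _ = integrate.quad(
            lambda x: np.exp(logistic_normal_logpdf(x, mu, sigma)),
            0, 1, limit=200,
        )
        assert val == pytest.approx(1.0, abs=1e-6)

    @pytest.mark.parametrize("n,eta", [(7, 0.0), (30, -2.2), (12, 1.7)])
    def test_binomial_logit_sums_to_one(self, n, eta):
        y = np.arange(n + 1)
        total = np.exp(binomial_logit_logpmf(y, n, eta)).sum()
        assert total == pytest.approx(1.0, abs=1e-12)


def _glmm_params(S=2, N=2, **kw):
    defaults = dict(
        gamma0=np.zeros(3), gamma_z=np.zeros((3, 1)), sigma_beta=np.zeros(3),
        v=np.zeros((3, S)), sigma_delta=0.0, delta=np.zeros(N),
    )
    defaults.update(kw)
    return GlmmParams(**defaults)


def _surveys(rows):
    return pd.DataFrame(
        rows,
        columns=["subbasin_id", "year", "n_females", "y_prespawn_dead",
                 "ppt_summer", "ppt_fall"],
    )


class TestLoglikMortality:
    def test_symmetric_binomial_at_zero_params(self):
        surveys = _surveys([("a", 2000, 2, 1, 0.3, -0.2)])
        params = SemParams(_factor_params(S=1), _glmm_params(S=1, N=1))
        ll = loglik_mortality(surveys, params, FULL_STRUCTURE)
        assert ll[0] == pytest.approx(math.log(0.5), abs=1e-12)

    def test_dropped_summer_coefficient_ignores_covariate(self):
        rng = np.random.default_rng(0)
        rows = [("a", 2000 + i, 20, 5, rng.normal(), rng.normal()) for i in range(4)]
        surveys = _surveys(rows)
        params = SemParams(
            _factor_params(S=1),
            _glmm_params(S=1, N=4, gamma0=np.array([-0.5, 9.9, 0.3]),
                         sigma_delta=1.0, delta=rng.normal(0, 1, 4)),
        )
        struct = ModelStructure("mean", "zero", "mean")
        ll1 = loglik_mortality(surveys, params, struct)
        surveys2 = surveys.assign(ppt_summer=rng.normal(size=4))
        ll2 = loglik_mortality(surveys2, params, struct)
        np.testing.assert_array_equal(ll1, ll2)

    def test_matches_direct_binomial_formula(self):
        # brute-force oracle: independent direct implementation
        rng = np.random.default_rng(3)
        S, N = 3, 8
        z = rng.standard_normal((S, 1))
        factor = _factor_params(S=S, a0=(0.1, -0.2, 0.3), a=(0.9, 0.4, -0.2), z=z)
        glmm = _glmm_params(
            S=S, N=N,
            gamma0=np.array([-1.0, 0.4, 0.2]), gamma_z=np.array([[1.2], [-0.3], [0.1]]),
            sigma_beta=np.array([0.5, 0.2, 0.1]),
            v=rng.normal(0, 0.3, (3, S)), sigma_delta=0.4, delta=rng.normal(0, 0.4, N),
        )
        params = SemParams(factor, glmm)
        sids = ["a", "b", "c"]
        rows = []
        for i in range(N):
            s = i % S
            rows.append((sids[s], 2000 + i, int(rng.integers(5, 30)),
                         0, rng.normal(), rng.normal()))
        surveys = _surveys(rows)
        surveys["y_prespawn_dead"] = [
            int(rng.integers(0, n + 1)) for n in surveys["n_females"]
        ]
        ll = loglik_mortality(surveys, params, FULL_STRUCTURE, subbasin_order=sids)
        betas = build_betas(params, FULL_STRUCTURE)
        for i, r in surveys.iterrows():
            s = sids.index(r.subbasin_id)
            eta = (betas[0, s] + betas[1, s] * r.ppt_summer
                   + betas[2, s] * r.ppt_fall + glmm.delta[i])
            p = 1.0 / (1.0 + math.exp(-eta))
            expected = (
                math.lgamma(r.n_females + 1) - math.lgamma(r.y_prespawn_dead + 1)
                - math.lgamma(r.n_females - r.y_prespawn_dead + 1)
                + r.y_prespawn_dead * math.log(p)
                + (r.n_females - r.y_prespawn_dead) * math.log1p(-p)
            )
            assert ll[i] == pytest.approx(expected, abs=1e-9)

    def test_y_above_n_rejected(self):
        surveys = _surveys([("a", 2000, 2, 3, 0.0, 0.0)])
        params = SemParams(_factor_params(S=1), _glmm_params(S=1, N=1))
        with pytest.raises(DataError):
            loglik_mortality(surveys, params, FULL_STRUCTURE)

    def test_monotone_in_z_when_observed_exceeds_predicted(self):
        # increasing z raises p toward y/n, hence the log-mass, when gamma_01 > 0
        surveys = _surveys([("a", 2000, 20, 18, 0.0, 0.0)])
        lls = []
        for zval in np.linspace(-1.5, 1.5, 7):
            factor = _factor_params(S=1, z=np.array([[zval]]))
            glmm = _glmm_params(S=1, N=1, gamma_z=np.array([[1.0], [0.0], [0.0]]))
            ll = loglik_mortality(surveys, SemParams(factor, glmm), FULL_STRUCTURE)
            lls.append(ll[0])
        assert np.all(np.diff(lls) > 0)


class TestLogPosterior:
    def test_finite_at_generator_truth(self):
        ds = make_fixture("tiny", seed=2)
        lp = log_posterior(ds, ds.truth, FULL_STRUCTURE)
        assert np.isfinite(lp)

    def test_doubling_surveys_doubles_mortality_loglik(self):
        ds = make_fixture("tiny", seed=4)
        doubled = ds.surveys.loc[ds.surveys.index.repeat(2)].reset_index(drop=True)
        truth2 = SemParams(
            ds.truth.factor,
            GlmmParams(
                gamma0=ds.truth.glmm.gamma0, gamma_z=ds.truth.glmm.gamma_z,
                sigma_beta=ds.truth.glmm.sigma_beta, v=ds.truth.glmm.v,
                sigma_delta=ds.truth.glmm.sigma_delta,
                delta=np.repeat(ds.truth.glmm.delta, 2),
            ),
        )
        ll1 = loglik_mortality(ds.surveys, ds.truth, FULL_STRUCTURE,
                               ds.survey_subbasins).sum()
        ll2 = loglik_mortality(doubled, truth2, FULL_STRUCTURE,
                               ds.survey_subbasins).sum()
        assert ll2 == pytest.approx(2 * ll1, rel=1e-12)

    def test_invalid_support_gives_minus_inf_not_exception(self):
        ds = make_fixture("tiny", seed=4)
        bad = SemParams(
            ds.truth.factor,
            GlmmParams(
                gamma0=ds.truth.glmm.gamma0, gamma_z=ds.truth.glmm.gamma_z,
                sigma_beta=np.array([0.0, 0.1, 0.1]), v=ds.truth.glmm.v,
                sigma_delta=ds.truth.glmm.sigma_delta, delta=ds.truth.glmm.delta,
            ),
        )
        assert log_posterior(ds, bad, FULL_STRUCTURE) == -np.inf

    def test_matches_independent_density_sum(self):
        """Independent oracle: every term re-derived with raw scipy calls."""
        ds = make_fixture("tiny", seed=9)
        params, struct = ds.truth, FULL_STRUCTURE
        table, fitted = transform_landscape(ds.landscape, ds.specs)
        x = table.to_numpy()
        f, g = params.factor, params.glmm
        eta = f.a0 + f.z @ f.loadings.T
        lp = 0.0
        ig = ip = 0
        for j, spec in enumerate(fitted):
            if spec.family == "proportion":
                lp += stats.norm.logpdf(x[:, j], eta[:, j], f.sigma[ip]).sum()
                ip += 1
            else:
                lp += stats.gamma.logpdf(
                    x[:, j], f.shape[ig], scale=np.exp(eta[:, j]) / f.shape[ig]
                ).sum()
                ig += 1
        order = list(ds.survey_subbasins)
        betas = g.gamma0[:, None] + g.gamma_z @ f.z[: len(order)].T + g.v
        for i, r in ds.surveys.iterrows():
            s = order.index(r.subbasin_id)
            lin = (betas[0, s] + betas[1, s] * r.ppt_summer
                   + betas[2, s] * r.ppt_fall + g.delta[i])
            lp += stats.binom.logpmf(r.y_prespawn_dead, r.n_females, expit(lin))
        lp += stats.norm.logpdf(f.z).sum()
        for k in range(3):
            lp += stats.norm.logpdf(g.v[k], 0, g.sigma_beta[k]).sum()
            lp += stats.halfnorm.logpdf(g.sigma_beta[k], scale=2.0)
            lp += stats.norm.logpdf(g.gamma0[k], 0, 5.0)
            lp += stats.norm.logpdf(g.gamma_z[k], 0, 5.0).sum()
        lp += stats.norm.logpdf(g.delta, 0, g.sigma_delta).sum()
        lp += stats.halfnorm.logpdf(g.sigma_delta, scale=2.0)
        lp += stats.norm.logpdf(f.a0, 0, 5.0).sum()
        lp += stats.norm.logpdf(f.loadings, 0, 2.0).sum()
        lp += stats.halfnorm.logpdf(f.sigma, scale=2.0).sum()
        lp += stats.gamma.logpdf(f.shape, 2.0, scale=10.0).sum()
        assert log_posterior(ds, params, struct) == pytest.approx(lp, abs=1e-8)


class TestModelStructure:
    def test_codes_round_trip(self):
        for code in ["z/z/z", "1/z/0", "1/0/0", "z/1/1"]:
            assert ModelStructure.from_code(code).code == code

    def test_intercept_cannot_be_dropped(self):
        with pytest.raises(ValueError):
            ModelStructure("zero", "mean", "mean")

    def test_identifiability_limit_enforced(self):
        with pytest.raises(ValueError, match="identifiability"):
            FactorParams(
                a0=np.zeros(2), loadings=np.zeros((2, 1)),
                sigma=np.array([1.0]), shape=np.array([1.0]), z=np.zeros((3, 1)),
            )
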