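"""Flattened parameterization of the SEM posterior with analytic gradients.

The sampler works on a single unconstrained vector theta.  Positive
parameters (sigma_j, phi_j, sigma_beta_k, sigma_delta) are log-transformed
with the Jacobian included; subbasin random effects and overdispersion
residuals are non-centered (v = sigma_beta * v_raw, delta = sigma_delta *
delta_raw with standard-normal raws), which keeps the posterior geometry
benign when the hyper-SDs are small.

All gradient formulas are closed-form; ``tests`` verify them against
finite differences and the scipy-based reference density in
:mod:`cohosem.sem_core`.
"""

from __future__ import annotations

import numpy as np
from scipy.special import expit, gammaln, digamma

from .sem_core import (
    GAMMA,
    PROPORTION,
    FactorParams,
    GlmmParams,
    ModelStructure,
    Priors,
    SemDataset,
    SemParams,
    transform_landscape,
)

_LOG2PI = float(np.log(2.0 * np.pi))
_HN_CONST = 0.5 * float(np.log(2.0 / np.pi))


class PackedSem:
    """Joint log-posterior of one candidate structure as f: R^dim -> R."""

    def __init__(
        self,
        dataset: SemDataset,
        structure: ModelStructure,
        priors: Priors = Priors(),
    ):
        self.structure = structure
        self.priors = priors
        self.L = structure.L

        table, fitted = transform_landscape(dataset.landscape, dataset.specs)
        self.specs = fitted
        self.x = np.ascontiguousarray(table.to_numpy(float))
        self.S, self.D = self.x.shape
        self.idx_prop = np.array(
            [j for j, sp in enumerate(fitted) if sp.family == PROPORTION], int
        )
        self.idx_gam = np.array(
            [j for j, sp in enumerate(fitted) if sp.family == GAMMA], int
        )
        self.Dp, self.Dg = len(self.idx_prop), len(self.idx_gam)
        self.u_prop = self.x[:, self.idx_prop]
        self.w_gam = self.x[:, self.idx_gam]
        self.log_w = np.log(self.w_gam)

        surveys = dataset.surveys
        self.N = len(surveys)
        order = dataset.survey_subbasins
        self.S_mon = len(order)
        if self.N:
            import pandas as pd

            s_idx = pd.Index(order).get_indexer(surveys["subbasin_id"].to_numpy())
            self.s_idx = np.ascontiguousarray(s_idx)
            self.y = surveys["y_prespawn_dead"].to_numpy(float)
            self.n = surveys["n_females"].to_numpy(float)
            self.xsu = surveys["ppt_summer"].to_numpy(float)
            self.xfa = surveys["ppt_fall"].to_numpy(float)
            self.log_choose = (
                gammaln(self.n + 1) - gammaln(self.y + 1) - gammaln(self.n - self.y + 1)
            )
        else:
            self.s_idx = np.zeros(0, int)
            self.y = self.n = self.xsu = self.xfa = np.zeros(0)
            self.log_choose = np.zeros(0)
        self.covs = (np.ones(self.N), self.xsu, self.xfa)

        self.active = [k for k in range(3) if structure.active(k)]
        self.with_z = [k for k in range(3) if structure.has_z(k)]

        # --- vector layout ---
        L = self.L
        sizes = {
            "a0": self.D,
            "a": self.D * L,
            "t_sigma": self.Dp,
            "t_phi": self.Dg,
            "z": self.S * L,
            "gamma0": len(self.active),
            "gamma_z": len(self.with_z) * L,
            "t_sigma_beta": len(self.active),
            "v_raw": len(self.active) * self.S_mon,
            "t_sigma_delta": 1 if self.N else 0,
            "delta_raw": self.N,
        }
        self.slices = {}
        off = 0
        for k, sz in sizes.items():
            self.slices[k] = slice(off, off + sz)
            off += sz
        self.dim = off

    # ------------------------------------------------------------------
    def _get(self, theta: np.ndarray, key: str) -> np.ndarray:
        return theta[self.slices[key]]

    def logp_grad(self, theta: np.ndarray) -> tuple[float, np.ndarray]:
        """Joint unconstrained log-density and its gradient (compiled core)."""
        from ._fastcore import logp_grad_core

        if not hasattr(self, "_core_args"):
            order = [
                "a0", "a", "t_sigma", "t_phi", "z", "gamma0", "gamma_z",
                "t_sigma_beta", "v_raw", "t_sigma_delta", "delta_raw",
            ]
            offsets = np.array([self.slices[k].start for k in order], np.int64)
            pr = self.priors
            self._core_args = (
                offsets,
                self.D, self.L, self.S, self.S_mon, self.N, self.Dp, self.Dg,
                self.idx_prop.astype(np.int64), self.idx_gam.astype(np.int64),
                np.ascontiguousarray(self.u_prop), np.ascontiguousarray(self.w_gam),
                np.ascontiguousarray(self.log_w),
                self.s_idx.astype(np.int64), self.y, self.n, self.xsu, self.xfa,
                self.log_choose,
                np.array(self.active, np.int64), np.array(self.with_z, np.int64),
                pr.a0_sd, pr.loading_sd, pr.gamma_sd, pr.sigma_hn,
                pr.sigma_beta_hn, pr.sigma_delta_hn, pr.phi_shape, pr.phi_rate,
            )
        grad = np.zeros_like(theta)
        lp = logp_grad_core(theta, grad, *self._core_args)
        return lp, grad

    def logp_grad_numpy(self, theta: np.ndarray) -> tuple[float, np.ndarray]:
        """Joint unconstrained log-density and its gradient."""
        pr = self.priors
        L = self.L
        grad = np.zeros_like(theta)

        a0 = self._get(theta, "a0")
        a = self._get(theta, "a").reshape(self.D, L)
        t_sig = self._get(theta, "t_sigma")
        t_phi = self._get(theta, "t_phi")
        z = self._get(theta, "z").reshape(self.S, L)
        sig = np.exp(t_sig)
        phi = np.exp(t_phi)

        g_a0 = grad[self.slices["a0"]]
        g_a = grad[self.slices["a"]].reshape(self.D, L)
        g_tsig = grad[self.slices["t_sigma"]]
        g_tphi = grad[self.slices["t_phi"]]
        g_z = grad[self.slices["z"]].reshape(self.S, L)

        eta = a0[None, :] + z @ a.T  # (S, D)
        d_eta = np.empty_like(eta)
        lp = 0.0

        # logistic-normal columns: u ~ N(eta, sigma)
        if self.Dp:
            eta_p = eta[:, self.idx_prop]
            r = (self.u_prop - eta_p) / sig[None, :]
            lp += float(
                -0.5 * np.sum(r * r)
                - self.S * np.sum(t_sig)
                - 0.5 * self.S * self.Dp * _LOG2PI
            )
            d_eta[:, self.idx_prop] = r / sig[None, :]
            g_tsig[:] = np.sum(r * r, axis=0) - self.S

        # gamma columns: w ~ Gamma(mean=exp(eta), shape=phi)
        if self.Dg:
            eta_g = eta[:, self.idx_gam]
            w_rel = self.w_gam * np.exp(-eta_g)  # w / mean
            lp += float(
                np.sum(
                    phi[None, :] * (t_phi[None, :] - eta_g + self.log_w - w_rel)
                    - self.log_w
                )
                - self.S * np.sum(gammaln(phi))
            )
            d_eta[:, self.idx_gam] = phi[None, :] * (w_rel - 1.0)
            dphi = np.sum(
                t_phi[None, :] + 1.0 - eta_g - digamma(phi)[None, :] + self.log_w - w_rel,
                axis=0,
            )
            g_tphi[:] = phi * dphi

        g_a0[:] = np.sum(d_eta, axis=0)
        g_a[:] = d_eta.T @ z
        g_z[:] = d_eta @ a

        # z ~ N(0, 1)
        lp += float(-0.5 * np.sum(z * z) - 0.5 * z.size * _LOG2PI)
        g_z -= z

        # priors on measurement parameters (with log-scale Jacobians)
        lp += float(
            -0.5 * np.sum((a0 / pr.a0_sd) ** 2)
            - self.D * (0.5 * _LOG2PI + np.log(pr.a0_sd))
        )
        g_a0 -= a0 / pr.a0_sd**2
        lp += float(
            -0.5 * np.sum((a / pr.loading_sd) ** 2)
            - a.size * (0.5 * _LOG2PI + np.log(pr.loading_sd))
        )
        g_a -= a / pr.loading_sd**2
        if self.Dp:
            lp += float(
                np.sum(-0.5 * (sig / pr.sigma_hn) ** 2 + t_sig)
                + self.Dp * (_HN_CONST - np.log(pr.sigma_hn))
            )
            g_tsig += 1.0 - (sig / pr.sigma_hn) ** 2
        if self.Dg:
            lp += float(
                np.sum(pr.phi_shape * t_phi - pr.phi_rate * phi)
                + self.Dg * (pr.phi_shape * np.log(pr.phi_rate) - gammaln(pr.phi_shape))
            )
            g_tphi += pr.phi_shape - pr.phi_rate * phi

        # ---------------- GLMM ----------------
        gamma0 = self._get(theta, "gamma0")
        gamma_z = self._get(theta, "gamma_z").reshape(len(self.with_z), L)
        t_sb = self._get(theta, "t_sigma_beta")
        sb = np.exp(t_sb)
        v_raw = self._get(theta, "v_raw").reshape(len(self.active), self.S_mon)

        g_gamma0 = grad[self.slices["gamma0"]]
        g_gamma_z = grad[self.slices["gamma_z"]].reshape(len(self.with_z), L)
        g_tsb = grad[self.slices["t_sigma_beta"]]
        g_vraw = grad[self.slices["v_raw"]].reshape(len(self.active), self.S_mon)

        z_mon = z[: self.S_mon]
        if self.N:
            t_sd = self._get(theta, "t_sigma_delta")
            sd_delta = float(np.exp(t_sd[0]))
            d_raw = self._get(theta, "delta_raw")

            lin = sd_delta * d_raw
            betas = {}
            for i, k in enumerate(self.active):
                beta_k = gamma0[i] + sb[i] * v_raw[i]
                if k in self.with_z:
                    beta_k = beta_k + z_mon @ gamma_z[self.with_z.index(k)]
                betas[k] = beta_k
                lin = lin + beta_k[self.s_idx] * self.covs[k]

            p = expit(lin)
            lp += float(
                np.sum(self.log_choose + self.y * lin - self.n * np.logaddexp(0.0, lin))
            )
            dlin = self.y - self.n * p

            for i, k in enumerate(self.active):
                wk = dlin * self.covs[k]
                Bk = np.bincount(self.s_idx, weights=wk, minlength=self.S_mon)
                g_gamma0[i] = np.sum(wk)
                g_vraw[i] = sb[i] * Bk
                g_tsb[i] = sb[i] * float(Bk @ v_raw[i])
                if k in self.with_z:
                    iz = self.with_z.index(k)
                    g_gamma_z[iz] = Bk @ z_mon
                    g_z[: self.S_mon] += Bk[:, None] * gamma_z[iz][None, :]

            # delta_raw ~ N(0, 1); sigma_delta half-normal
            lp += float(-0.5 * np.sum(d_raw * d_raw) - 0.5 * self.N * _LOG2PI)
            grad[self.slices["delta_raw"]] = sd_delta * dlin - d_raw
            g_tsd = sd_delta * float(dlin @ d_raw)
            lp += float(
                -0.5 * (sd_delta / pr.sigma_delta_hn) ** 2
                + t_sd[0]
                + _HN_CONST
                - np.log(pr.sigma_delta_hn)
            )
            g_tsd += 1.0 - (sd_delta / pr.sigma_delta_hn) ** 2
            grad[self.slices["t_sigma_delta"]] = g_tsd

        # v_raw ~ N(0, 1); hyper-priors on gamma and sigma_beta
        lp += float(-0.5 * np.sum(v_raw * v_raw) - 0.5 * v_raw.size * _LOG2PI)
        g_vraw -= v_raw
        lp += float(
            -0.5 * np.sum((gamma0 / pr.gamma_sd) ** 2)
            - gamma0.size * (0.5 * _LOG2PI + np.log(pr.gamma_sd))
        )
        g_gamma0 -= gamma0 / pr.gamma_sd**2
        if gamma_z.size:
            lp += float(
                -0.5 * np.sum((gamma_z / pr.gamma_sd) ** 2)
                - gamma_z.size * (0.5 * _LOG2PI + np.log(pr.gamma_sd))
            )
            g_gamma_z -= gamma_z / pr.gamma_sd**2
        lp += float(
            np.sum(-0.5 * (sb / pr.sigma_beta_hn) ** 2 + t_sb)
            + sb.size * (_HN_CONST - np.log(pr.sigma_beta_hn))
        )
        g_tsb += 1.0 - (sb / pr.sigma_beta_hn) ** 2

        return lp, grad

    def logp(self, theta: np.ndarray) -> float:
        return self.logp_grad(theta)[0]

    # ------------------------------------------------------------------
    def unpack(self, theta: np.ndarray) -> SemParams:
        """Natural-scale SemParams for one theta vector."""
        L = self.L
        sig = np.exp(self._get(theta, "t_sigma"))
        phi = np.exp(self._get(theta, "t_phi"))
        factor = FactorParams(
            a0=self._get(theta, "a0").copy(),
            loadings=self._get(theta, "a").reshape(self.D, L).copy(),
            sigma=sig if self.Dp else np.ones(0),
            shape=phi if self.Dg else np.ones(0),
            z=self._get(theta, "z").reshape(self.S, L).copy(),
        )
        gamma0 = np.zeros(3)
        gamma_z = np.zeros((3, L))
        sigma_beta = np.zeros(3)
        v = np.zeros((3, self.S_mon))
        sb = np.exp(self._get(theta, "t_sigma_beta"))
        v_raw = self._get(theta, "v_raw").reshape(len(self.active), self.S_mon)
        for i, k in enumerate(self.active):
            gamma0[k] = self._get(theta, "gamma0")[i]
            sigma_beta[k] = sb[i]
            v[k] = sb[i] * v_raw[i]
        gz = self._get(theta, "gamma_z").reshape(len(self.with_z), L)
        for iz, k in enumerate(self.with_z):
            gamma_z[k] = gz[iz]
        if self.N:
            sd_delta = float(np.exp(self._get(theta, "t_sigma_delta")[0]))
            delta = sd_delta * self._get(theta, "delta_raw")
        else:
            sd_delta, delta = 1.0, np.zeros(0)
        glmm = GlmmParams(
            gamma0=gamma0,
            gamma_z=gamma_z,
            sigma_beta=sigma_beta,
            v=v,
            sigma_delta=sd_delta,
            delta=delta,
        )
        return SemParams(factor=factor, glmm=glmm)

    def log_transform_adjustment(self, theta: np.ndarray) -> float:
        """Difference between the packed density and the natural-scale one.

        Accounts for the log transforms of positive parameters and the
        non-centered reparameterization of v and delta.
        """
        adj = float(
            np.sum(self._get(theta, "t_sigma"))
            + np.sum(self._get(theta, "t_phi"))
            + np.sum(self._get(theta, "t_sigma_beta"))
        )
        adj += self.S_mon * float(np.sum(self._get(theta, "t_sigma_beta")))
        if self.N:
            t_sd = float(self._get(theta, "t_sigma_delta")[0])
            adj += t_sd + self.N * t_sd
        return adj

    def initial_theta(self, rng: np.random.Generator, scale: float = 0.5) -> np.ndarray:
        theta = scale * rng.uniform(-1.0, 1.0, self.dim)
        return theta
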