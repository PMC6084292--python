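"""Posterior-predictive mortality risk at baseline climate.

Baseline predictions set the precipitation anomalies to zero (an
average-rainfall year).  For every subbasin with a factor-score draw in
the posterior — monitored or not — the subbasin coefficients are rebuilt
per draw; monitored subbasins use their posterior random-effect draws
while unmonitored ones get fresh nu ~ N(0, sigma_beta).  A fresh
overdispersion deviate delta ~ N(0, sigma_delta) is included in each
predictive draw, so the reported mean is the delta-marginal (new-year)
mortality probability; a delta-free "typical year" mean is also
reported.  Risk bands follow the <10% / 10-40% / >40% convention.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import expit

from .inference import PosteriorDraws
from .sem_core import DataError

__all__ = ["RiskRecord", "predict_risk", "band_summary", "risk_table", "RISK_BANDS"]

RISK_BANDS = ("<10%", "10-40%", ">40%")
_THRESHOLDS = (0.10, 0.40)


@dataclass
class RiskRecord:
    """Predicted mortality risk for one subbasin at baseline climate."""

    subbasin_id: str
    mean_prob: float  # delta-marginal posterior mean mortality probability
    mean_prob_typical: float  # delta excluded ("typical year")
    se_logit: float  # posterior SD of logit(p)
    lo95: float
    hi95: float
    band: str
    monitored: bool

    def __post_init__(self) -> None:
        if not 0.0 < self.mean_prob < 1.0:
            raise ValueError("mean probability must lie in (0, 1)")
        if self.band != band_of(self.mean_prob):
            raise ValueError("risk band inconsistent with mean probability")


def band_of(p: float) -> str:
    """Risk band of a mean probability; bands are [0,0.1), [0.1,0.4), [0.4,1]."""
    if p < _THRESHOLDS[0]:
        return RISK_BANDS[0]
    if p < _THRESHOLDS[1]:
        return RISK_BANDS[1]
    return RISK_BANDS[2]


def predict_risk(
    post: PosteriorDraws,
    subbasin_ids: np.ndarray | None = None,
    baseline: tuple[float, float] = (0.0, 0.0),
    seed: int = 0,
) -> list[RiskRecord]:
    """Posterior-predictive risk records for the requested subbasins.

    ``post`` must come from a fit whose landscape table contained every
    requested subbasin (their factor scores inform the prediction even
    without survey data).  ``baseline`` gives the summer/fall
    precipitation anomalies, zero by default.  Fresh random draws (nu for
    unmonitored subbasins, delta for everyone) are keyed by ``seed`` and
    the subbasin id, so predictions do not depend on row order.
    """
    land_index = pd.Index(post.landscape_ids)
    if subbasin_ids is None:
        subbasin_ids = np.asarray(post.landscape_ids)
    idx = land_index.get_indexer(np.asarray(subbasin_ids))
    if np.any(idx < 0):
        missing = list(np.asarray(subbasin_ids)[idx < 0])
        raise DataError(
            f"subbasins {missing} have no factor-score draws; refit jointly "
            "with their landscape rows included"
        )
    mon_index = pd.Index(post.survey_subbasins)
    v_idx = mon_index.get_indexer(np.asarray(subbasin_ids))

    z = post.stacked("z")[:, idx, :]  # (n, U, L)
    gamma0 = post.stacked("gamma0")
    gamma_z = post.stacked("gamma_z")
    sigma_beta = post.stacked("sigma_beta")
    v = post.stacked("v")
    sigma_delta = post.stacked("sigma_delta")
    n_samp = z.shape[0]

    beta = gamma0[:, :, None] + np.einsum("nkl,nul->nku", gamma_z, z)
    in_fit = v_idx >= 0
    if in_fit.any():
        beta[:, :, in_fit] += v[:, :, v_idx[in_fit]]
    su, fa = baseline
    eta_typical = beta[:, 0, :] + beta[:, 1, :] * su + beta[:, 2, :] * fa
    eta = np.empty_like(eta_typical)
    from zlib import crc32

    for j, sid in enumerate(np.asarray(subbasin_ids)):
        rng_j = np.random.default_rng([seed, crc32(str(sid).encode())])
        if not in_fit[j]:
            nu = sigma_beta * rng_j.standard_normal((n_samp, 3))
            eta_typical[:, j] += nu[:, 0] + nu[:, 1] * su + nu[:, 2] * fa
        eta[:, j] = eta_typical[:, j] + sigma_delta * rng_j.standard_normal(n_samp)

    p = expit(eta)
    mean_p = p.mean(axis=0)
    mean_p_typ = expit(eta_typical).mean(axis=0)
    se_logit = eta.std(axis=0, ddof=1)
    lo, hi = np.quantile(p, [0.025, 0.975], axis=0)

    records = []
    for j, sid in enumerate(np.asarray(subbasin_ids)):
        records.append(
            RiskRecord(
                subbasin_id=str(sid),
                mean_prob=float(mean_p[j]),
                mean_prob_typical=float(mean_p_typ[j]),
                se_logit=float(se_logit[j]),
                lo95=float(lo[j]),
                hi95=float(hi[j]),
                band=band_of(float(mean_p[j])),
                monitored=bool(in_fit[j]),
            )
        )
    return records


def band_summary(
    records: list[RiskRecord],
    weights: np.ndarray | None = None,
) -> dict[str, float]:
    """Fraction of subbasins (or of supplied area weights) in each band."""
    if not records:
        raise ValueError("no risk records supplied")
    if weights is None:
        w = np.ones(len(records))
    else:
        w = np.asarray(weights, float)
        if w.size != len(records):
            raise DataError("weights length does not match records")
        if np.any(w < 0):
            raise DataError("weights must be nonnegative")
    total = float(w.sum())
    out = {}
    for band in RISK_BANDS:
        mask = np.array([r.band == band for r in records])
        out[band] = float(w[mask].sum()) / total
    return out


def risk_table(records: list[RiskRecord]) -> pd.DataFrame:
    """One RiskRecord per row, ready for CSV export / user joins."""
    return pd.DataFrame(
        [
            {
                "subbasin_id": r.subbasin_id,
                "mean_prob": r.mean_prob,
                "mean_prob_typical": r.mean_prob_typical,
                "se_logit": r.se_logit,
                "lo95": r.lo95,
                "hi95": r.hi95,
                "band": r.band,
                "monitored": r.monitored,
            }
            for r in records
        ]
    )
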