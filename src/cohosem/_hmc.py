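"""No-U-Turn sampler with dual-averaging step size and diagonal mass
matrix adaptation.

A compact, dependency-free implementation of the slice-variable NUTS
transition (Hoffman & Gelman 2014, Alg. 6) with a warmup schedule in the
usual three phases: an initial fast interval adapting only the step
size, a sequence of doubling windows that estimate the posterior
variances for the diagonal mass matrix, and a terminal fast interval
that re-settles the step size.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np

__all__ = ["nuts_sample", "NutsStats"]

_MAX_DELTA_H = 1000.0  # divergence threshold on the Hamiltonian error


@dataclass
class NutsStats:
    step_size: float
    inv_mass: np.ndarray
    accept_prob: np.ndarray  # per kept draw
    n_leapfrog: np.ndarray
    divergent: np.ndarray
    energy: np.ndarray


def _leapfrog(logp_grad, theta, r, grad, eps, inv_mass):
    r = r + 0.5 * eps * grad
    theta = theta + eps * inv_mass * r
    lp, grad = logp_grad(theta)
    r = r + 0.5 * eps * grad
    return theta, r, lp, grad


def _kinetic(r, inv_mass):
    with np.errstate(over="ignore", invalid="ignore"):
        return 0.5 * float(np.dot(r * inv_mass, r))


class _Tree:
    __slots__ = (
        "theta_m", "r_m", "grad_m", "theta_p", "r_p", "grad_p",
        "theta_prop", "lp_prop", "grad_prop", "n", "stop", "div", "alpha", "n_alpha",
    )


def _build_tree(logp_grad, theta, r, grad, log_u, v, depth, eps, inv_mass, H0, rng):
    t = _Tree()
    if depth == 0:
        theta1, r1, lp1, grad1 = _leapfrog(logp_grad, theta, r, grad, v * eps, inv_mass)
        H1 = lp1 - _kinetic(r1, inv_mass) if np.isfinite(lp1) else -np.inf
        t.theta_m = t.theta_p = t.theta_prop = theta1
        t.r_m = t.r_p = r1
        t.grad_m = t.grad_p = t.grad_prop = grad1
        t.lp_prop = lp1
        t.n = int(log_u <= H1)
        t.div = (H1 - H0) < -_MAX_DELTA_H  # divergence
        t.stop = t.div
        t.alpha = min(1.0, float(np.exp(min(0.0, H1 - H0))))
        t.n_alpha = 1
        return t
    t = _build_tree(logp_grad, theta, r, grad, log_u, v, depth - 1, eps, inv_mass, H0, rng)
    if not t.stop:
        if v == -1:
            t2 = _build_tree(
                logp_grad, t.theta_m, t.r_m, t.grad_m, log_u, v, depth - 1, eps, inv_mass, H0, rng
            )
            t.theta_m, t.r_m, t.grad_m = t2.theta_m, t2.r_m, t2.grad_m
        else:
            t2 = _build_tree(
                logp_grad, t.theta_p, t.r_p, t.grad_p, log_u, v, depth - 1, eps, inv_mass, H0, rng
            )
            t.theta_p, t.r_p, t.grad_p = t2.theta_p, t2.r_p, t2.grad_p
        if t2.n > 0 and rng.random() < t2.n / max(t.n + t2.n, 1):
            t.theta_prop, t.lp_prop, t.grad_prop = t2.theta_prop, t2.lp_prop, t2.grad_prop
        t.n += t2.n
        dtheta = t.theta_p - t.theta_m
        t.div = t.div or t2.div
        t.stop = (
            t2.stop
            or float(np.dot(dtheta, inv_mass * t.r_m)) < 0
            or float(np.dot(dtheta, inv_mass * t.r_p)) < 0
        )
        t.alpha += t2.alpha
        t.n_alpha += t2.n_alpha
    return t


def _nuts_step(logp_grad, theta, lp, grad, eps, inv_mass, max_depth, rng):
    sqrt_mass = 1.0 / np.sqrt(inv_mass)
    r0 = rng.standard_normal(theta.size) * sqrt_mass
    H0 = lp - _kinetic(r0, inv_mass)
    log_u = H0 + np.log(rng.random())
    theta_m = theta_p = theta
    r_m = r_p = r0
    grad_m = grad_p = grad
    n = 1
    depth = 0
    alpha_sum, n_alpha = 0.0, 0
    n_leap = 0
    divergent = False
    while depth < max_depth:
        v = -1 if rng.random() < 0.5 else 1
        if v == -1:
            t = _build_tree(logp_grad, theta_m, r_m, grad_m, log_u, v, depth, eps, inv_mass, H0, rng)
            theta_m, r_m, grad_m = t.theta_m, t.r_m, t.grad_m
        else:
            t = _build_tree(logp_grad, theta_p, r_p, grad_p, log_u, v, depth, eps, inv_mass, H0, rng)
            theta_p, r_p, grad_p = t.theta_p, t.r_p, t.grad_p
        n_leap += 2**depth
        alpha_sum += t.alpha
        n_alpha += t.n_alpha
        divergent = divergent or t.div
        if t.stop:
            break
        if t.n > 0 and rng.random() < min(1.0, t.n / n):
            theta, lp, grad = t.theta_prop, t.lp_prop, t.grad_prop
        n += t.n
        dtheta = theta_p - theta_m
        if (
            float(np.dot(dtheta, inv_mass * r_m)) < 0
            or float(np.dot(dtheta, inv_mass * r_p)) < 0
        ):
            break
        depth += 1
    accept = alpha_sum / max(n_alpha, 1)
    energy = -(lp - _kinetic(r0, inv_mass))
    return theta, lp, grad, accept, n_leap, divergent, energy


def _find_initial_step(logp_grad, theta, lp, grad, inv_mass, rng):
    eps = 1.0
    r0 = rng.standard_normal(theta.size) / np.sqrt(inv_mass)
    H0 = lp - _kinetic(r0, inv_mass)
    _, r1, lp1, _ = _leapfrog(logp_grad, theta, r0, grad, eps, inv_mass)
    H1 = lp1 - _kinetic(r1, inv_mass) if np.isfinite(lp1) else -np.inf
    direction = 1.0 if (H1 - H0) > np.log(0.5) else -1.0
    for _ in range(100):
        eps *= 2.0**direction
        _, r1, lp1, _ = _leapfrog(logp_grad, theta, r0, grad, eps, inv_mass)
        H1 = lp1 - _kinetic(r1, inv_mass) if np.isfinite(lp1) else -np.inf
        if direction == 1.0 and (H1 - H0) <= np.log(0.5):
            break
        if direction == -1.0 and (H1 - H0) > np.log(0.5):
            break
    return max(eps, 1e-10)


def _adapt_schedule(n_warmup: int) -> tuple[int, int, list[int]]:
    """(init_buffer, term_buffer, window ends) on the warmup iteration axis."""
    init = max(10, int(0.15 * n_warmup))
    term = max(10, int(0.10 * n_warmup))
    middle = n_warmup - init - term
    if middle < 20:
        init = max(5, n_warmup // 4)
        term = max(5, n_warmup // 10)
        middle = n_warmup - init - term
    ends = []
    size = max(25, middle // 8)
    pos = init
    while pos + size < init + middle:
        ends.append(pos + size)
        pos += size
        size *= 2
    ends.append(init + middle)
    return init, term, ends


def nuts_sample(
    logp_grad: Callable[[np.ndarray], tuple[float, np.ndarray]],
    theta0: np.ndarray,
    n_warmup: int,
    n_draws: int,
    rng: np.random.Generator,
    target_accept: float = 0.95,
    max_treedepth: int = 10,
) -> tuple[np.ndarray, NutsStats]:
    """Run one NUTS chain; returns (draws, stats) with warmup discarded."""
    theta = np.array(theta0, float)
    lp, grad = logp_grad(theta)
    if not np.isfinite(lp):
        raise ValueError("initial point has non-finite log-density")
    dim = theta.size
    inv_mass = np.ones(dim)

    eps = _find_initial_step(logp_grad, theta, lp, grad, inv_mass, rng)
    mu = np.log(10.0 * eps)
    log_eps_bar, h_bar = 0.0, 0.0
    gamma_da, t0, kappa = 0.05, 10.0, 0.75
    da_count = 0

    init_buf, term_buf, win_ends = _adapt_schedule(n_warmup)
    welford_n = 0
    welford_mean = np.zeros(dim)
    welford_m2 = np.zeros(dim)

    draws = np.empty((n_draws, dim))
    accepts = np.empty(n_draws)
    leaps = np.empty(n_draws, int)
    divs = np.zeros(n_draws, bool)
    energies = np.empty(n_draws)

    total = n_warmup + n_draws
    for it in range(total):
        theta, lp, grad, accept, n_leap, div, energy = _nuts_step(
            logp_grad, theta, lp, grad, eps, inv_mass, max_treedepth, rng
        )
        if it < n_warmup:
            # dual averaging
            da_count += 1
            frac = 1.0 / (da_count + t0)
            h_bar = (1.0 - frac) * h_bar + frac * (target_accept - accept)
            log_eps = mu - np.sqrt(da_count) / gamma_da * h_bar
            w = da_count**-kappa
            log_eps_bar = w * log_eps + (1.0 - w) * log_eps_bar
            eps = float(np.exp(log_eps))
            in_window = init_buf <= it < n_warmup - term_buf
            if in_window:
                welford_n += 1
                d = theta - welford_mean
                welford_mean += d / welford_n
                welford_m2 += d * (theta - welford_mean)
                if (it + 1) in win_ends and welford_n >= 10:
                    var = welford_m2 / (welford_n - 1)
                    inv_mass = var * welford_n / (welford_n + 5.0) + 1e-3 * (
                        5.0 / (welford_n + 5.0)
                    )
                    welford_n = 0
                    welford_mean[:] = 0.0
                    welford_m2[:] = 0.0
                    # restart step-size adaptation around the current value
                    eps = _find_initial_step(logp_grad, theta, lp, grad, inv_mass, rng)
                    mu = np.log(10.0 * eps)
                    log_eps_bar, h_bar, da_count = 0.0, 0.0, 0
            if it == n_warmup - 1:
                eps = float(np.exp(log_eps_bar))
        else:
            j = it - n_warmup
            draws[j] = theta
            accepts[j] = accept
            leaps[j] = n_leap
            divs[j] = div
            energies[j] = energy

    stats = NutsStats(
        step_size=eps,
        inv_mass=inv_mass,
        accept_prob=accepts,
        n_leapfrog=leaps,
        divergent=divs,
        energy=energies,
    )
    return draws, stats
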