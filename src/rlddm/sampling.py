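"""Adaptive Hamiltonian Monte Carlo.

A compact gradient-based sampler driving the hierarchical posterior: leapfrog
integration with a jittered number of steps (guarding against resonant
trajectory lengths), dual-averaging step-size adaptation toward a target
acceptance rate, and windowed diagonal mass-matrix estimation from warmup
draws.  Divergent transitions (energy error above a fixed threshold) are
rejected and counted.

The sampler is deterministic given (data, seed) on a fixed platform.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["HMCStats", "hmc_sample", "sample_chains"]

_DIVERGENCE_ENERGY = 500.0


@dataclass
class HMCStats:
    accept_rate: float
    step_size: float
    n_divergent: int
    energies: np.ndarray = field(repr=False)


def _leapfrog(logp_grad, x, p, eps, n_steps, inv_mass):
    lp, g = logp_grad(x)
    for _ in range(n_steps):
        p = p + 0.5 * eps * g
        x = x + eps * inv_mass * p
        lp, g = logp_grad(x)
        if not np.isfinite(lp):
            return x, p, lp, g
        p = p + 0.5 * eps * g
    return x, p, lp, g


def _find_initial_step(logp_grad, x0, inv_mass, rng):
    """Crude doubling/halving heuristic for a sane starting step size."""
    eps = 0.1
    lp0, g0 = logp_grad(x0)
    p0 = rng.standard_normal(x0.size) / np.sqrt(inv_mass)
    h0 = -lp0 + 0.5 * np.sum(inv_mass * p0 * p0)
    def accept_ratio(eps_try):
        _, p1, lp1, _ = _leapfrog(logp_grad, x0, p0, eps_try, 1, inv_mass)
        if not np.isfinite(lp1):
            return 0.0
        h1 = -lp1 + 0.5 * np.sum(inv_mass * p1 * p1)
        return float(np.exp(min(h0 - h1, 0.0)))

    ratio = accept_ratio(eps)
    direction = 1 if ratio > 0.5 else -1
    for _ in range(30):
        eps *= 2.0**direction
        ratio = accept_ratio(eps)
        if (direction == 1 and ratio <= 0.5) or (direction == -1 and ratio >= 0.5):
            break
    return eps


def hmc_sample(
    logp_grad,
    x0: np.ndarray,
    n_iter: int = 800,
    n_warmup: int = 400,
    seed: int = 0,
    target_accept: float = 0.85,
    max_leapfrog: int = 32,
):
    """One HMC chain; returns (draws after warmup, HMCStats).

    ``logp_grad(x) -> (logp, grad)`` must return ``-inf`` (any gradient) for
    invalid states.  Warmup splits into three windows: step-size tuning with
    unit mass (20%), mass estimation (60%), final step-size tuning under the
    estimated mass (20%).
    """
    rng = np.random.default_rng(seed)
    x = np.asarray(x0, dtype=float).copy()
    dim = x.size
    inv_mass = np.ones(dim)

    w1 = max(int(0.2 * n_warmup), 10)
    w2 = max(int(0.8 * n_warmup), w1 + 10)
    draws = np.empty((n_iter - n_warmup, dim))
    energies = np.empty(n_iter)
    warm_buf = []

    eps = _find_initial_step(logp_grad, x, inv_mass, rng)
    mu_da = np.log(10.0 * eps)
    log_eps_bar, h_bar = 0.0, 0.0
    gamma, t0, kappa = 0.05, 10.0, 0.75
    da_iter = 0

    n_accept = 0
    n_div = 0
    lp, _ = logp_grad(x)
    if not np.isfinite(lp):
        raise ValueError("initial point has zero posterior density")

    for it in range(n_iter):
        p0 = rng.standard_normal(dim) / np.sqrt(inv_mass)
        h0 = -lp + 0.5 * np.sum(inv_mass * p0 * p0)
        n_steps = int(rng.integers(1, max_leapfrog + 1))
        x1, p1, lp1, _ = _leapfrog(logp_grad, x, p0, eps, n_steps, inv_mass)
        if np.isfinite(lp1):
            h1 = -lp1 + 0.5 * np.sum(inv_mass * p1 * p1)
            d_h = h0 - h1
        else:
            d_h = -np.inf
        if d_h < -_DIVERGENCE_ENERGY and it >= n_warmup:
            n_div += 1
        accept_prob = min(1.0, np.exp(min(d_h, 0.0)))
        if np.isfinite(d_h) and rng.random() < accept_prob:
            x, lp = x1, lp1
            n_accept += 1
        energies[it] = h0

        if it < n_warmup:
            da_iter += 1
            h_bar = (1.0 - 1.0 / (da_iter + t0)) * h_bar + (
                target_accept - accept_prob
            ) / (da_iter + t0)
            log_eps = mu_da - np.sqrt(da_iter) / gamma * h_bar
            w = da_iter ** (-kappa)
            log_eps_bar = w * log_eps + (1.0 - w) * log_eps_bar
            eps = float(np.exp(log_eps))
            if w1 <= it < w2:
                warm_buf.append(x.copy())
            if it + 1 == w2 and len(warm_buf) > 10:
                var = np.var(np.asarray(warm_buf), axis=0)
                inv_mass = 0.9 * var + 0.1 * np.ones(dim)
                eps = _find_initial_step(logp_grad, x, inv_mass, rng)
                mu_da = np.log(10.0 * eps)
                log_eps_bar, h_bar, da_iter = 0.0, 0.0, 0
            if it + 1 == n_warmup:
                eps = float(np.exp(log_eps_bar))
        else:
            draws[it - n_warmup] = x

    stats = HMCStats(
        accept_rate=n_accept / n_iter,
        step_size=eps,
        n_divergent=n_div,
        energies=energies,
    )
    return draws, stats


def sample_chains(
    logp_grad,
    init_points,
    n_iter: int = 800,
    n_warmup: int = 400,
    seed: int = 0,
    target_accept: float = 0.85,
    max_leapfrog: int = 32,
):
    """Run several chains sequentially; returns (chains, draws, dim) + stats."""
    all_draws = []
    all_stats = []
    for c, x0 in enumerate(init_points):
        d, s = hmc_sample(
            logp_grad,
            x0,
            n_iter=n_iter,
            n_warmup=n_warmup,
            seed=seed + 1000 * c,
            target_accept=target_accept,
            max_leapfrog=max_leapfrog,
        )
        all_draws.append(d)
        all_stats.append(s)
    return np.stack(all_draws), all_stats
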