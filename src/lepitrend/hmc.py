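"""Adaptive Hamiltonian Monte Carlo on an unconstrained parameter vector.

A standard HMC implementation: leapfrog integration with a jittered number
of steps, dual-averaging step-size adaptation towards a target acceptance
rate during warmup, and a diagonal mass matrix estimated from the middle
warmup window.  All randomness flows from a single integer seed per chain,
so runs are reproducible draw-for-draw.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass
class ChainResult:
    draws: np.ndarray          # (n_kept, d)
    accept_rate: float
    step_size: float
    n_divergent: int


def _leapfrog(logp_grad, q, p, eps, n_steps, inv_mass):
    lp, grad = logp_grad(q)
    for _ in range(n_steps):
        p = p + 0.5 * eps * grad
        q = q + eps * p * inv_mass
        lp, grad = logp_grad(q)
        if not np.isfinite(lp):
            return q, p, lp, grad
        p = p + 0.5 * eps * grad
    return q, p, lp, grad


def run_chain(
    logp_grad,
    init: np.ndarray,
    n_iter: int,
    n_warmup: int,
    seed,
    target_accept: float = 0.8,
    max_leapfrog: int = 16,
    init_step: float = 0.1,
) -> ChainResult:
    """Run one HMC chain; returns post-warmup draws."""
    rng = np.random.default_rng(seed)
    d = len(init)
    q = np.asarray(init, dtype=float).copy()
    lp, grad = logp_grad(q)
    if not np.isfinite(lp):
        raise ValueError("non-finite log-posterior at initialization")

    mass = np.ones(d)
    inv_mass = np.ones(d)
    eps = init_step
    # dual averaging state
    mu = np.log(10.0 * eps)
    log_eps_bar = 0.0
    h_bar = 0.0
    gamma, t0, kappa = 0.05, 10.0, 0.75

    # mass-estimation windows inside warmup (draws accumulate between
    # checkpoints; at each checkpoint the metric is refreshed and
    # step-size adaptation restarts)
    checkpoints = {int(0.4 * n_warmup), int(0.8 * n_warmup)}
    w_lo = int(0.1 * n_warmup)
    window: list[np.ndarray] = []

    kept = np.empty((n_iter - n_warmup, d))
    n_accept = 0
    n_div = 0
    da_iter = 0

    for it in range(n_iter):
        p0 = rng.normal(0.0, 1.0, d) * np.sqrt(mass)
        n_steps = int(rng.integers(max(1, max_leapfrog // 2), max_leapfrog + 1))
        lp0, _ = logp_grad(q)
        h0 = lp0 - 0.5 * np.sum(p0 * p0 * inv_mass)
        q1, p1, lp1, _ = _leapfrog(logp_grad, q.copy(), p0.copy(), eps, n_steps, inv_mass)
        if np.isfinite(lp1):
            h1 = lp1 - 0.5 * np.sum(p1 * p1 * inv_mass)
            log_ratio = h1 - h0
        else:
            log_ratio = -np.inf
        if log_ratio < -1000.0:
            n_div += 1
        alpha = min(1.0, np.exp(min(log_ratio, 0.0)))
        if np.log(rng.random()) < log_ratio:
            q = q1
            if it >= n_warmup:
                n_accept += 1

        if it < n_warmup:
            da_iter += 1
            h_bar = (1 - 1 / (da_iter + t0)) * h_bar + (target_accept - alpha) / (da_iter + t0)
            log_eps = mu - np.sqrt(da_iter) / gamma * h_bar
            w = da_iter ** (-kappa)
            log_eps_bar = w * log_eps + (1 - w) * log_eps_bar
            eps = float(np.exp(log_eps))
            if it >= w_lo:
                window.append(q.copy())
            if it in checkpoints and len(window) >= 10:
                var = np.var(np.asarray(window), axis=0)
                var = np.where(var > 1e-10, var, 1.0)
                inv_mass = var
                mass = 1.0 / var
                window = []
                # restart step-size adaptation under the new metric
                mu = np.log(10.0 * eps)
                h_bar = 0.0
                log_eps_bar = np.log(eps)
                da_iter = 0
            if it == n_warmup - 1:
                eps = float(np.exp(log_eps_bar))
        else:
            kept[it - n_warmup] = q

    n_kept = max(n_iter - n_warmup, 1)
    return ChainResult(kept, n_accept / n_kept, eps, n_div)


def sample(
    logp_grad,
    init: np.ndarray,
    chains: int,
    n_iter: int,
    n_warmup: int,
    seed: int,
    jitter: float = 0.5,
    **kwargs,
) -> tuple[np.ndarray, list[ChainResult]]:
    """Run ``chains`` independent chains; returns draws of shape
    ``(chains, n_iter - n_warmup, d)``.  Chain c uses rng seed ``[seed, c]``
    and a jittered copy of ``init``."""
    results = []
    all_draws = []
    for c in range(chains):
        rng = np.random.default_rng([int(seed), c])
        q0 = np.asarray(init, dtype=float) + jitter * rng.normal(0.0, 0.1, len(init))
        res = run_chain(logp_grad, q0, n_iter, n_warmup, seed=[int(seed), c, 1], **kwargs)
        results.append(res)
        all_draws.append(res.draws)
    return np.stack(all_draws), results
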