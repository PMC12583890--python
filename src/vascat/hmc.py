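"""Hamiltonian Monte Carlo with analytic gradients.

A compact, general-purpose HMC engine used to sample the hierarchical
psychometric posterior: multiple chains, dual-averaging step-size adaptation
toward a target acceptance rate, windowed diagonal-metric (mass matrix)
adaptation from warmup draws, jittered trajectory lengths, and divergence
tracking.  The target density is supplied as a callable returning the log
density and its gradient, so the engine knows nothing about the model.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np

LogpGrad = Callable[[np.ndarray], tuple[float, np.ndarray]]


@dataclass
class HMCSample:
    """Posterior draws and sampler telemetry.

    ``draws`` has shape (n_chains, n_draws, dim); ``accept_rate`` and
    ``divergences`` are per-chain; ``step_size`` and ``inv_metric`` are the
    adapted values used for the sampling phase.
    """

    draws: np.ndarray
    accept_rate: np.ndarray
    divergences: np.ndarray
    step_size: np.ndarray
    inv_metric: np.ndarray


def _leapfrog(logp_grad, x, p, grad, eps, n_steps, inv_metric):
    for _ in range(n_steps):
        p = p + 0.5 * eps * grad
        x = x + eps * inv_metric * p
        lp, grad = logp_grad(x)
        if not np.isfinite(lp):
            return x, p, lp, grad
        p = p + 0.5 * eps * grad
    return x, p, lp, grad


def _find_initial_step(logp_grad, x0, inv_metric, rng):
    """Heuristic doubling/halving to land near 50% acceptance."""
    eps = 0.1
    lp0, grad0 = logp_grad(x0)
    p = rng.standard_normal(x0.size) / np.sqrt(inv_metric)
    h0 = lp0 - 0.5 * np.sum(inv_metric * p * p)
    x1, p1, lp1, _ = _leapfrog(logp_grad, x0, p, grad0, eps, 1, inv_metric)
    h1 = lp1 - 0.5 * np.sum(inv_metric * p1 * p1) if np.isfinite(lp1) else -np.inf
    direction = 1.0 if (h1 - h0) > np.log(0.5) else -1.0
    for _ in range(50):
        eps = eps * (2.0 ** direction)
        x1, p1, lp1, _ = _leapfrog(logp_grad, x0, p, grad0, eps, 1, inv_metric)
        h1 = lp1 - 0.5 * np.sum(inv_metric * p1 * p1) if np.isfinite(lp1) else -np.inf
        if direction > 0 and (h1 - h0) <= np.log(0.5):
            return eps / 2.0
        if direction < 0 and (h1 - h0) > np.log(0.5):
            return eps
    return max(eps, 1e-6)


def sample_hmc(
    logp_grad: LogpGrad,
    x0: np.ndarray,
    *,
    n_chains: int = 4,
    n_warmup: int = 1000,
    n_draws: int = 1000,
    seed: int = 0,
    max_leapfrog: int = 24,
    target_accept: float = 0.8,
    init_inv_metric: np.ndarray | None = None,
    adapt_metric: bool = True,
) -> HMCSample:
    """Run HMC chains and return draws on the unconstrained scale.

    ``x0`` is either one starting point (dim,) used for every chain after
    jittering, or per-chain starts (n_chains, dim).  Warmup adapts the step
    size throughout (dual averaging) and re-estimates a diagonal metric from
    the middle warmup window; warmup draws are discarded.
    """
    x0 = np.atleast_2d(np.asarray(x0, dtype=float))
    dim = x0.shape[1]
    if x0.shape[0] == 1:
        x0 = np.repeat(x0, n_chains, axis=0)
    inv0 = (
        np.ones(dim) if init_inv_metric is None
        else np.asarray(init_inv_metric, dtype=float).copy()
    )

    ss = np.random.SeedSequence(seed)
    chain_seeds = ss.spawn(n_chains)
    draws = np.empty((n_chains, n_draws, dim))
    accept = np.zeros(n_chains)
    diverg = np.zeros(n_chains, dtype=int)
    eps_out = np.zeros(n_chains)
    inv_out = np.empty((n_chains, dim))

    win_lo, win_hi = int(0.25 * n_warmup), int(0.80 * n_warmup)

    for ci in range(n_chains):
        rng = np.random.default_rng(chain_seeds[ci])
        x = x0[ci].copy()
        inv_metric = inv0.copy()
        lp, grad = logp_grad(x)
        if not np.isfinite(lp):
            raise ValueError("non-finite log density at the initial point")

        eps = _find_initial_step(logp_grad, x, inv_metric, rng)
        # dual averaging state
        mu = np.log(10.0 * eps)
        log_eps_bar, h_bar, da_m = 0.0, 0.0, 0
        gamma, t0, kappa = 0.05, 10.0, 0.75
        window: list[np.ndarray] = []

        n_total = n_warmup + n_draws
        acc_count = 0
        for it in range(n_total):
            warming = it < n_warmup
            p = rng.standard_normal(dim) / np.sqrt(inv_metric)
            h_cur = lp - 0.5 * np.sum(inv_metric * p * p)
            n_steps = int(rng.integers(max(1, max_leapfrog // 2), max_leapfrog + 1))
            x_new, p_new, lp_new, grad_new = _leapfrog(
                logp_grad, x, p, grad, eps, n_steps, inv_metric
            )
            if np.isfinite(lp_new):
                h_new = lp_new - 0.5 * np.sum(inv_metric * p_new * p_new)
                delta = h_new - h_cur
            else:
                delta = -np.inf
            alpha = min(1.0, np.exp(min(delta, 0.0)))
            if delta < -1000.0:
                if not warming:
                    diverg[ci] += 1
            if np.log(rng.random()) < delta:
                x, lp, grad = x_new, lp_new, grad_new
                if not warming:
                    acc_count += 1

            if warming:
                da_m += 1
                h_bar = (1 - 1 / (da_m + t0)) * h_bar + (target_accept - alpha) / (da_m + t0)
                log_eps = mu - np.sqrt(da_m) / gamma * h_bar
                w = da_m ** (-kappa)
                log_eps_bar = w * log_eps + (1 - w) * log_eps_bar
                eps = np.exp(log_eps)
                if adapt_metric and win_lo <= it < win_hi:
                    window.append(x.copy())
                if adapt_metric and it == win_hi - 1 and len(window) >= 10:
                    arr = np.asarray(window)
                    n = arr.shape[0]
                    var = arr.var(axis=0, ddof=1)
                    inv_metric = (n / (n + 5.0)) * var + (5.0 / (n + 5.0)) * 1e-3
                    inv_metric = np.clip(inv_metric, 1e-8, None)
                    # restart step-size adaptation around the current value
                    eps = _find_initial_step(logp_grad, x, inv_metric, rng)
                    mu = np.log(10.0 * eps)
                    log_eps_bar, h_bar, da_m = 0.0, 0.0, 0
                if it == n_warmup - 1:
                    eps = np.exp(log_eps_bar)
            else:
                draws[ci, it - n_warmup] = x

        accept[ci] = acc_count / n_draws
        eps_out[ci] = eps
        inv_out[ci] = inv_metric

    return HMCSample(
        draws=draws,
        accept_rate=accept,
        divergences=diverg,
        step_size=eps_out,
        inv_metric=inv_out,
    )
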