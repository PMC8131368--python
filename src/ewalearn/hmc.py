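"""Hamiltonian Monte Carlo with dual-averaging step size and diagonal metric.

A compact, dependency-free HMC in the style of Stan's static engine:

* leapfrog integration with a diagonal mass matrix, adapted during warmup
  from the sample variance of the unconstrained draws (expanding memory
  windows, Stan-like schedule);
* dual-averaging step-size adaptation toward a target acceptance rate;
* jittered path lengths (the number of leapfrog steps is drawn uniformly up
  to ``max_leapfrog`` each iteration) to avoid periodicity pathologies;
* an energy-error divergence check (|dH| > 1000), with divergences counted
  and reported.

The sampler is deterministic given its ``numpy`` Generator.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np

LogpGrad = Callable[[np.ndarray], tuple[float, np.ndarray]]


@dataclass
class ChainResult:
    draws: np.ndarray  # [n_draws, dim]
    logp: np.ndarray  # [n_draws]
    accept_rate: float
    step_size: float
    divergences: int


def _leapfrog(
    logp_grad: LogpGrad,
    q: np.ndarray,
    p: np.ndarray,
    grad: np.ndarray,
    eps: float,
    n_steps: int,
    inv_mass: np.ndarray,
) -> tuple[np.ndarray, np.ndarray, float, np.ndarray, bool]:
    q = q.copy()
    p = p + 0.5 * eps * grad
    for step in range(n_steps):
        q += eps * inv_mass * p
        lp, grad = logp_grad(q)
        if not np.isfinite(lp):
            return q, p, -np.inf, grad, False
        if step != n_steps - 1:
            p += eps * grad
    p += 0.5 * eps * grad
    return q, p, lp, grad, True


def sample_chain(
    logp_grad: LogpGrad,
    x0: np.ndarray,
    n_warmup: int,
    n_draws: int,
    rng: np.random.Generator,
    target_accept: float = 0.85,
    max_leapfrog: int = 48,
    init_step: float = 0.05,
) -> ChainResult:
    dim = len(x0)
    q = np.asarray(x0, dtype=float).copy()
    lp, grad = logp_grad(q)
    if not np.isfinite(lp):
        raise FloatingPointError("non-finite log-density at the initial point")

    inv_mass = np.ones(dim)
    eps = init_step
    # dual averaging state (Hoffman & Gelman defaults)
    mu = np.log(10.0 * eps)
    log_eps_bar = 0.0
    H_bar = 0.0
    gamma_da, t0, kappa = 0.05, 10.0, 0.75

    # metric adaptation windows: a Stan-like 15% / growing windows / 10% split
    init_buf = max(1, int(0.15 * n_warmup))
    term_buf = max(1, int(0.10 * n_warmup))
    window_samples: list[np.ndarray] = []
    window_end = init_buf + max(25, int(0.25 * (n_warmup - init_buf - term_buf)))

    draws = np.empty((n_draws, dim))
    logps = np.empty(n_draws)
    n_accept = 0
    n_total = 0
    divergences = 0

    for it in range(n_warmup + n_draws):
        warm = it < n_warmup
        p0 = rng.standard_normal(dim) / np.sqrt(inv_mass)
        n_steps = int(rng.integers(1, max_leapfrog + 1))
        H0 = -lp + 0.5 * np.sum(inv_mass * p0**2)
        q_new, p_new, lp_new, grad_new, ok = _leapfrog(logp_grad, q, p0, grad, eps, n_steps, inv_mass)
        if ok:
            H1 = -lp_new + 0.5 * np.sum(inv_mass * p_new**2)
            dH = H1 - H0
            if not np.isfinite(dH) or dH > 1000.0:
                accept_prob = 0.0
                if not warm:
                    divergences += 1
            else:
                accept_prob = min(1.0, np.exp(-dH))
        else:
            accept_prob = 0.0
            if not warm:
                divergences += 1
        if rng.random() < accept_prob:
            q, lp, grad = q_new, lp_new, grad_new
            if not warm:
                n_accept += 1
        if not warm:
            n_total += 1

        if warm:
            # dual averaging
            m = it + 1
            H_bar = (1 - 1 / (m + t0)) * H_bar + (target_accept - accept_prob) / (m + t0)
            log_eps = mu - np.sqrt(m) / gamma_da * H_bar
            w = m**-kappa
            log_eps_bar = w * log_eps + (1 - w) * log_eps_bar
            eps = float(np.exp(log_eps))
            # metric windows
            if init_buf <= it < n_warmup - term_buf:
                window_samples.append(q.copy())
                if it + 1 >= window_end:
                    arr = np.asarray(window_samples)
                    if len(arr) >= 10:
                        var = arr.var(axis=0, ddof=1)
                        n = len(arr)
                        # regularise toward unit metric (Stan-style shrinkage)
                        inv_mass = (n / (n + 5.0)) * var + (5.0 / (n + 5.0)) * 1e-3
                        inv_mass = np.maximum(inv_mass, 1e-8)
                    window_samples = []
                    remaining = n_warmup - term_buf - (it + 1)
                    window_end = it + 1 + max(25, remaining if remaining < 50 else int(remaining * 0.5))
                    # restart step-size adaptation for the new metric
                    mu = np.log(10.0 * eps)
                    H_bar = 0.0
                    log_eps_bar = np.log(eps)
            if it == n_warmup - 1:
                eps = float(np.exp(log_eps_bar))
        else:
            draws[it - n_warmup] = q
            logps[it - n_warmup] = lp

    return ChainResult(
        draws=draws,
        logp=logps,
        accept_rate=n_accept / max(n_total, 1),
        step_size=eps,
        divergences=divergences,
    )


__all__ = ["ChainResult", "sample_chain"]
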