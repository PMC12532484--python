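"""A compact Hamiltonian Monte Carlo sampler with warmup adaptation.

Static-trajectory HMC with dual-averaging step-size adaptation and a
diagonal mass matrix estimated during warmup, in the style of Stan's
windowed adaptation (simplified to a single variance window).  The target
density is supplied as a callable returning the log density and its
gradient on an unconstrained parameter vector; hierarchical models should
hand over a non-centered parameterization so the posterior geometry stays
close to unit scale.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Tuple

import numpy as np

__all__ = ["HMCResult", "sample_hmc"]

LogpGrad = Callable[[np.ndarray], Tuple[float, np.ndarray]]


@dataclass
class HMCResult:
    """Draws and per-draw sampler statistics for one chain."""

    samples: np.ndarray        # (n_samples, dim)
    accept_prob: np.ndarray    # (n_samples,)
    divergent: np.ndarray      # (n_samples,) bool
    step_size: float
    inv_mass: np.ndarray       # (dim,)


def _leapfrog(logp_grad: LogpGrad, x, p, grad, eps, inv_mass, n_steps):
    x, p, grad = x.copy(), p.copy(), grad
    lp = -np.inf
    for _ in range(n_steps):
        p = p + 0.5 * eps * grad
        x = x + eps * inv_mass * p
        lp, grad = logp_grad(x)
        if not np.isfinite(lp):
            return x, p, grad, lp
        p = p + 0.5 * eps * grad
    return x, p, grad, lp


def _find_initial_step(logp_grad: LogpGrad, x0, inv_mass, rng) -> float:
    """Heuristic: double / halve eps until one leapfrog step has accept ~ 0.5."""
    eps = 0.1
    lp0, grad0 = logp_grad(x0)
    p0 = rng.standard_normal(x0.size) / np.sqrt(inv_mass)
    h0 = lp0 - 0.5 * np.sum(inv_mass * p0**2)
    _, p1, _, lp1 = _leapfrog(logp_grad, x0, p0, grad0, eps, inv_mass, 1)
    h1 = lp1 - 0.5 * np.sum(inv_mass * p1**2) if np.isfinite(lp1) else -np.inf
    direction = 1 if (h1 - h0) > math.log(0.5) else -1
    for _ in range(50):
        eps *= 2.0**direction
        _, p1, _, lp1 = _leapfrog(logp_grad, x0, p0, grad0, eps, inv_mass, 1)
        h1 = lp1 - 0.5 * np.sum(inv_mass * p1**2) if np.isfinite(lp1) else -np.inf
        if direction == 1 and (h1 - h0) <= math.log(0.5):
            break
        if direction == -1 and (h1 - h0) >= math.log(0.5):
            break
    return float(np.clip(eps, 1e-6, 10.0))


def sample_hmc(
    logp_grad: LogpGrad,
    x0: np.ndarray,
    n_warmup: int,
    n_samples: int,
    seed: int,
    target_accept: float = 0.85,
    trajectory_length: float = 1.8,
    max_leapfrog: int = 96,
) -> HMCResult:
    """Run one HMC chain.

    The number of leapfrog steps per iteration is ``trajectory_length / eps``
    (capped), jittered by +-25% to decorrelate trajectory endpoints.
    Iterations whose Hamiltonian error exceeds 1000 are flagged divergent and
    rejected.
    """
    rng = np.random.default_rng(seed)
    x = np.asarray(x0, dtype=float).copy()
    dim = x.size
    inv_mass = np.ones(dim)

    eps = _find_initial_step(logp_grad, x, inv_mass, rng)
    # dual averaging state
    mu_da = math.log(10.0 * eps)
    log_eps_bar, h_bar = 0.0, 0.0
    gamma_da, t0_da, kappa_da = 0.05, 10.0, 0.75

    # variance-estimation window: the middle 50% of warmup
    win_lo, win_hi = int(0.25 * n_warmup), int(0.75 * n_warmup)
    window: list[np.ndarray] = []

    lp, grad = logp_grad(x)
    samples = np.empty((n_samples, dim))
    accepts = np.empty(n_samples)
    divs = np.zeros(n_samples, dtype=bool)

    total = n_warmup + n_samples
    for it in range(total):
        warming = it < n_warmup
        p0 = rng.standard_normal(dim) / np.sqrt(inv_mass)
        h0 = lp - 0.5 * np.sum(inv_mass * p0**2)
        n_steps = int(np.clip(round(trajectory_length / eps), 1, max_leapfrog))
        n_steps = max(1, int(round(n_steps * rng.uniform(0.75, 1.25))))
        x_new, p_new, grad_new, lp_new = _leapfrog(logp_grad, x, p0, grad, eps, inv_mass, n_steps)
        if np.isfinite(lp_new):
            h1 = lp_new - 0.5 * np.sum(inv_mass * p_new**2)
            delta_h = h1 - h0
        else:
            delta_h = -np.inf
        divergent = not np.isfinite(delta_h) or delta_h < -1000.0
        alpha = 0.0 if divergent else min(1.0, math.exp(min(delta_h, 0.0)))
        if not divergent and rng.random() < alpha:
            x, lp, grad = x_new, lp_new, grad_new

        if warming:
            # dual averaging toward the target acceptance rate
            m = it + 1
            h_bar = (1 - 1 / (m + t0_da)) * h_bar + (target_accept - alpha) / (m + t0_da)
            log_eps = mu_da - math.sqrt(m) / gamma_da * h_bar
            w = m**-kappa_da
            log_eps_bar = w * log_eps + (1 - w) * log_eps_bar
            eps = float(np.clip(math.exp(log_eps), 1e-7, 10.0))
            if win_lo <= it < win_hi:
                window.append(x.copy())
            if it == win_hi - 1 and len(window) >= 10:
                var = np.var(np.asarray(window), axis=0)
                inv_mass = np.clip(var, 1e-6, 1e6)
                # re-tune the step size for the new metric
                eps = _find_initial_step(logp_grad, x, inv_mass, rng)
                mu_da = math.log(10.0 * eps)
                log_eps_bar, h_bar = math.log(eps), 0.0
            if it == n_warmup - 1:
                eps = float(np.clip(math.exp(log_eps_bar), 1e-7, 10.0))
        else:
            j = it - n_warmup
            samples[j] = x
            accepts[j] = alpha
            divs[j] = divergent

    return HMCResult(samples, accepts, divs, eps, inv_mass)
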