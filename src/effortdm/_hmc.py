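"""Adaptive Hamiltonian Monte Carlo on an unconstrained parameter vector.

A compact HMC implementation used by :mod:`effortdm.inference`: leapfrog
integration with a diagonal mass matrix, dual-averaging step-size
adaptation during warmup (target acceptance 0.8), one mass re-estimation
from the first warmup half, and a jittered number of leapfrog steps per
iteration to decorrelate trajectories. The target density is supplied as a
callable returning the joint log-density and its gradient, so the same
sampler serves the hierarchical choice models and any toy target used to
probe the convergence diagnostics.
"""

from __future__ import annotations

import math
from typing import Callable, Tuple

import numpy as np

__all__ = ["sample_hmc"]

LogpGrad = Callable[[np.ndarray], Tuple[float, np.ndarray]]


class _DualAveraging:
    """Nesterov dual averaging of log step size (Stan's defaults)."""

    def __init__(self, eps0: float, target: float = 0.8):
        self.mu = math.log(10 * eps0)
        self.target = target
        self.log_eps = math.log(eps0)
        self.log_eps_bar = 0.0
        self.h_bar = 0.0
        self.gamma, self.t0, self.kappa = 0.05, 10.0, 0.75
        self.count = 0

    def update(self, accept_stat: float) -> float:
        self.count += 1
        m = self.count
        eta = 1.0 / (m + self.t0)
        self.h_bar = (1 - eta) * self.h_bar + eta * (self.target - accept_stat)
        self.log_eps = self.mu - math.sqrt(m) / self.gamma * self.h_bar
        w = m ** (-self.kappa)
        self.log_eps_bar = w * self.log_eps + (1 - w) * self.log_eps_bar
        return math.exp(self.log_eps)


def _find_initial_step(logp_grad: LogpGrad, x: np.ndarray, inv_mass: np.ndarray,
                       rng: np.random.Generator) -> float:
    """Coarse step-size heuristic: double/halve until acceptance crosses 0.5."""
    eps = 0.1
    lp0, g0 = logp_grad(x)
    p = rng.standard_normal(x.size) / np.sqrt(inv_mass)
    h0 = lp0 - 0.5 * np.sum(inv_mass * p**2)

    def joint(eps):
        p1 = p + 0.5 * eps * g0
        x1 = x + eps * inv_mass * p1
        lp1, g1 = logp_grad(x1)
        p1 = p1 + 0.5 * eps * g1
        return lp1 - 0.5 * np.sum(inv_mass * p1**2)

    h = joint(eps)
    if not np.isfinite(h):
        direction = -1
    else:
        direction = 1 if (h - h0) > math.log(0.5) else -1
    for _ in range(50):
        eps *= 2.0**direction
        h = joint(eps)
        ok = np.isfinite(h) and (h - h0) > math.log(0.5)
        if (direction == 1) != ok:
            break
    return max(eps, 1e-8)


def _leapfrog(logp_grad: LogpGrad, x, p, g, eps, inv_mass, n_steps):
    for _ in range(n_steps):
        p = p + 0.5 * eps * g
        x = x + eps * inv_mass * p
        lp, g = logp_grad(x)
        if not np.all(np.isfinite(g)):
            return x, p, g, -np.inf
        p = p + 0.5 * eps * g
    return x, p, g, lp


def _run_chain(logp_grad, x0, n_warmup, n_samples, rng, target_accept,
               max_leapfrog, traj_jitter, n_leap_base):
    dim = x0.size
    x = np.asarray(x0, dtype=float).copy()
    lp, g = logp_grad(x)
    if not np.isfinite(lp):
        raise ValueError("initial point has non-finite log density")
    inv_mass = np.ones(dim)
    eps = _find_initial_step(logp_grad, x, inv_mass, rng)
    da = _DualAveraging(eps, target=target_accept)
    draws = np.empty((n_samples, dim))
    accepts = 0
    mass_window: list[np.ndarray] = []
    w1 = n_warmup // 2
    w2 = int(0.85 * n_warmup)  # second, cleaner mass window: [w1, w2)

    for it in range(n_warmup + n_samples):
        warming = it < n_warmup
        lo = max(1, int(n_leap_base * (1 - traj_jitter)))
        hi = max(lo + 1, int(n_leap_base * (1 + traj_jitter)) + 1)
        n_leap = min(int(rng.integers(lo, hi)), max_leapfrog)
        p0 = rng.standard_normal(dim) / np.sqrt(inv_mass)
        h0 = lp - 0.5 * np.sum(inv_mass * p0**2)
        x1, p1, g1, lp1 = _leapfrog(logp_grad, x, p0, g, eps, inv_mass, n_leap)
        if np.isfinite(lp1):
            h1 = lp1 - 0.5 * np.sum(inv_mass * p1**2)
            log_ratio = h1 - h0
            accept_stat = min(1.0, math.exp(min(0.0, log_ratio)))
        else:
            log_ratio, accept_stat = -np.inf, 0.0
        if math.log(rng.random()) < log_ratio:
            x, lp, g = x1, lp1, g1
            if not warming:
                accepts += 1
        if warming:
            eps = da.update(accept_stat)
            if w1 // 2 <= it < w2:
                mass_window.append(x.copy())
            if it in (w1 - 1, w2 - 1) and len(mass_window) >= 10:
                var = np.var(np.asarray(mass_window), axis=0)
                n = len(mass_window)
                # regularize toward unit scale (Stan-style shrinkage)
                inv_mass = (n / (n + 5.0)) * var + 1e-3 * (5.0 / (n + 5.0))
                inv_mass = np.maximum(inv_mass, 1e-8)
                eps0 = math.exp(da.log_eps_bar)
                da = _DualAveraging(eps0, target=target_accept)
                eps = eps0
                mass_window = []
            if it == n_warmup - 1:
                eps = math.exp(da.log_eps_bar)
        else:
            draws[it - n_warmup] = x
    return draws, {"step_size": eps, "accept_rate": accepts / max(1, n_samples)}


def sample_hmc(logp_grad: LogpGrad, init: np.ndarray, *, n_warmup: int = 500,
               n_samples: int = 500, n_chains: int = 4, seed=None,
               target_accept: float = 0.8, max_leapfrog: int = 128,
               traj_jitter: float = 0.5, init_jitter: float = 0.5,
               n_leap_base: int = 32, chain_inits=None):
    """Run ``n_chains`` independent adaptive HMC chains.

    Parameters
    ----------
    logp_grad
        Callable mapping a parameter vector to ``(log_density, gradient)``.
    init
        Central initial point; each chain starts from a jittered copy
        unless ``chain_inits`` (one vector per chain) is given.

    Returns
    -------
    draws : ndarray of shape (n_chains, n_samples, dim)
    stats : list of per-chain dicts (step size, acceptance rate)
    """
    init = np.asarray(init, dtype=float)
    ss = np.random.SeedSequence(seed)
    child_seeds = ss.spawn(n_chains)
    all_draws = np.empty((n_chains, n_samples, init.size))
    stats = []
    for c in range(n_chains):
        rng = np.random.default_rng(child_seeds[c])
        if chain_inits is not None:
            x0 = np.asarray(chain_inits[c], dtype=float)
        else:
            x0 = init + init_jitter * rng.standard_normal(init.size)
        draws, st = _run_chain(logp_grad, x0, n_warmup, n_samples, rng,
                               target_accept, max_leapfrog, traj_jitter,
                               n_leap_base)
        all_draws[c] = draws
        stats.append(st)
    return all_draws, stats
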