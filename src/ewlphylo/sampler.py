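"""A compact Hamiltonian Monte Carlo engine.

Static HMC with jittered path length, dual-averaging step-size adaptation
toward a target acceptance rate, and a diagonal mass matrix re-estimated
midway through warmup.  The target supplies the log density and its
gradient on an unconstrained scale; transforms and Jacobians belong to the
caller.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np

LogpGrad = Callable[[np.ndarray], tuple[float, np.ndarray]]


@dataclass
class ChainResult:
    draws: np.ndarray  # (n_samples, dim)
    accept_rate: float
    divergences: int
    step_size: float
    mass_diag: np.ndarray
    logp: np.ndarray = field(default=None)


def _leapfrog(
    logp_grad: LogpGrad,
    x: np.ndarray,
    p: np.ndarray,
    step: float,
    n_steps: int,
    inv_mass: np.ndarray,
    grad: np.ndarray,
) -> tuple[np.ndarray, np.ndarray, float, np.ndarray]:
    p = p + 0.5 * step * grad
    for i in range(n_steps):
        x = x + step * inv_mass * p
        lp, grad = logp_grad(x)
        if not np.isfinite(lp):
            return x, p, -np.inf, grad
        p = p + (step if i < n_steps - 1 else 0.5 * step) * grad
    return x, p, lp, grad


def _find_initial_step(
    logp_grad: LogpGrad, x0: np.ndarray, inv_mass: np.ndarray, rng: np.random.Generator
) -> float:
    """Double/halve until the one-step acceptance probability crosses 0.5."""
    step = 0.1
    lp0, grad0 = logp_grad(x0)
    p0 = rng.standard_normal(x0.size) / np.sqrt(inv_mass)
    h0 = lp0 - 0.5 * np.sum(inv_mass * p0**2)
    _, p1, lp1, _ = _leapfrog(logp_grad, x0.copy(), p0.copy(), step, 1, inv_mass, grad0)
    h1 = lp1 - 0.5 * np.sum(inv_mass * p1**2) if np.isfinite(lp1) else -np.inf
    direction = 1.0 if (h1 - h0) > np.log(0.5) else -1.0
    for _ in range(50):
        step *= 2.0**direction
        _, p1, lp1, _ = _leapfrog(
            logp_grad, x0.copy(), p0.copy(), step, 1, inv_mass, grad0
        )
        h1 = lp1 - 0.5 * np.sum(inv_mass * p1**2) if np.isfinite(lp1) else -np.inf
        if direction * (h1 - h0) < direction * np.log(0.5):
            break
    return step


def hmc_chain(
    logp_grad: LogpGrad,
    x0: np.ndarray,
    n_warmup: int,
    n_samples: int,
    rng: np.random.Generator,
    max_leapfrog: int = 16,
    target_accept: float = 0.8,
    mass_diag: np.ndarray | None = None,
    divergence_threshold: float = 1000.0,
) -> ChainResult:
    """Run one HMC chain and return post-warmup draws.

    The number of leapfrog steps per iteration is drawn uniformly from
    1..max_leapfrog, which breaks resonances without tuning a trajectory
    length.  Warmup splits in two windows: step size adapts throughout; the
    diagonal mass matrix is re-estimated from the first window's draws.
    """
    x = np.array(x0, dtype=float)
    dim = x.size
    mass = np.ones(dim) if mass_diag is None else np.asarray(mass_diag, float).copy()
    inv_mass = 1.0 / mass

    step = _find_initial_step(logp_grad, x, inv_mass, rng)
    # dual averaging state (Hoffman & Gelman defaults)
    mu = np.log(10.0 * step)
    log_step_bar, h_bar = 0.0, 0.0
    gamma, t0, kappa = 0.05, 10.0, 0.75

    lp, grad = logp_grad(x)
    draws = np.empty((n_samples, dim))
    logps = np.empty(n_samples)
    n_accept = 0
    n_total = 0
    divergences = 0
    window_draws: list[np.ndarray] = []
    switch = n_warmup // 2
    adapt_iter = 0

    for it in range(n_warmup + n_samples):
        warming = it < n_warmup
        p0 = rng.standard_normal(dim) * np.sqrt(mass)
        h0 = lp - 0.5 * np.sum(inv_mass * p0**2)
        n_steps = int(rng.integers(1, max_leapfrog + 1))
        x1, p1, lp1, grad1 = _leapfrog(
            logp_grad, x.copy(), p0.copy(), step, n_steps, inv_mass, grad.copy()
        )
        h1 = lp1 - 0.5 * np.sum(inv_mass * p1**2) if np.isfinite(lp1) else -np.inf
        delta = h1 - h0
        if delta < -divergence_threshold or not np.isfinite(h1):
            accept_prob = 0.0
            if not warming:
                divergences += 1
        else:
            accept_prob = min(1.0, float(np.exp(min(delta, 0.0))))
        if rng.random() < accept_prob:
            x, lp, grad = x1, lp1, grad1
            if not warming:
                n_accept += 1
        if not warming:
            n_total += 1
            draws[it - n_warmup] = x
            logps[it - n_warmup] = lp
        else:
            adapt_iter += 1
            frac = 1.0 / (adapt_iter + t0)
            h_bar = (1 - frac) * h_bar + frac * (target_accept - accept_prob)
            log_step = mu - np.sqrt(adapt_iter) / gamma * h_bar
            eta = adapt_iter ** (-kappa)
            log_step_bar = eta * log_step + (1 - eta) * log_step_bar
            step = float(np.exp(log_step))
            if it < switch:
                window_draws.append(x.copy())
            elif it == switch and len(window_draws) > 10:
                var = np.var(np.array(window_draws), axis=0)
                var = np.where(var > 1e-12, var, 1.0)
                mass = 1.0 / var
                inv_mass = var
                step = _find_initial_step(logp_grad, x, inv_mass, rng)
                mu = np.log(10.0 * step)
                log_step_bar, h_bar, adapt_iter = 0.0, 0.0, 0
            if it == n_warmup - 1:
                step = float(np.exp(log_step_bar)) if adapt_iter > 0 else step

    return ChainResult(
        draws=draws,
        accept_rate=n_accept / max(n_total, 1),
        divergences=divergences,
        step_size=step,
        mass_diag=mass,
        logp=logps,
    )


def run_chains(
    logp_grad: LogpGrad,
    x0s: list[np.ndarray],
    n_warmup: int,
    n_samples: int,
    seed: int,
    **kwargs,
) -> list[ChainResult]:
    """Run independent chains from the given start points, with per-chain
    RNG streams spawned from one seed."""
    seqs = np.random.SeedSequence(seed).spawn(len(x0s))
    return [
        hmc_chain(
            logp_grad,
            x0,
            n_warmup,
            n_samples,
            np.random.default_rng(seq),
            **kwargs,
        )
        for x0, seq in zip(x0s, seqs)
    ]
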