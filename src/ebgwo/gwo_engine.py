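"""Continuous grey wolf optimization with Levy-flight exploration.

The pack follows its three best members (alpha, beta, delta).  Each
iteration every wolf encircles each leader with stochastic coefficients
A = 2a*r1 - a and C = 2*r2, where the control scalar ``a`` decays
linearly from 2 to 0 over the run, and moves to the mean of the three
candidate points.  Heavy-tailed Levy steps, generated by the Mantegna
construction u / |v|^(1/beta), inject occasional long jumps around the
current best to keep exploration alive late in the schedule.

RNG discipline: one seeded ``numpy.random.Generator`` per run, consumed
in a fixed documented order — pack initialization, then per wolf per
iteration the leader coefficients (r1 then r2 for alpha, beta, delta in
turn), then the Levy acceptance draw and, if accepted, the Levy normals.
Record-and-replay oracles rely on that order.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

__all__ = [
    "GWOConfig",
    "WolfPack",
    "a_schedule",
    "coefficients",
    "encircle",
    "leader_guided_position",
    "mantegna_sigma_u",
    "levy_sample",
    "levy_perturb",
    "minimize",
]


@dataclass
class GWOConfig:
    """Run parameters for the wolf pack.

    ``levy_alpha`` is the Levy step size (0.1), ``levy_beta`` the tail
    index of the step distribution (0.5, heavier than Cauchy), and
    ``levy_prob`` the per-wolf chance of taking a Levy jump after the
    leader-guided move.  ``explore_prob`` is consumed by the binary
    selection layer (random-triplet exploration) and ignored by the
    continuous minimizer.
    """

    dim: int = 1
    pack_size: int = 10
    max_iter: int = 1000
    a_initial: float = 2.0
    levy_beta: float = 0.5
    levy_alpha: float = 0.1
    levy_prob: float = 0.5
    explore_prob: float = 0.2
    seed: int = 0
    bounds: tuple[float, float] = (0.0, 1.0)

    def __post_init__(self) -> None:
        if self.pack_size < 4:
            raise ValueError("pack_size must be >= 4 (three leaders plus one omega)")
        if self.max_iter < 1:
            raise ValueError("max_iter must be >= 1")
        if self.dim < 1:
            raise ValueError("dim must be >= 1")
        if not 0.0 < self.levy_beta <= 2.0:
            raise ValueError("levy_beta must lie in (0, 2]")
        if self.levy_alpha <= 0:
            raise ValueError("levy_alpha must be positive")
        if not 0.0 <= self.levy_prob <= 1.0:
            raise ValueError("levy_prob must lie in [0, 1]")
        if not 0.0 <= self.explore_prob <= 1.0:
            raise ValueError("explore_prob must lie in [0, 1]")
        lo, hi = self.bounds
        if not lo < hi:
            raise ValueError("bounds must be a non-empty interval")


@dataclass
class WolfPack:
    """Pack state: positions, fitnesses, and the sorted leader triple."""

    positions: np.ndarray
    fitnesses: np.ndarray
    leader_positions: np.ndarray = field(default=None)  # type: ignore[assignment]
    leader_fitnesses: np.ndarray = field(default=None)  # type: ignore[assignment]

    def update_leaders(self) -> None:
        """Merge current wolves into the best-so-far alpha/beta/delta triple."""
        pos, fit = self.positions, self.fitnesses
        if self.leader_positions is not None:
            pos = np.vstack([self.leader_positions, pos])
            fit = np.concatenate([self.leader_fitnesses, fit])
        order = np.argsort(fit, kind="stable")[:3]
        self.leader_positions = pos[order].copy()
        self.leader_fitnesses = fit[order].copy()


def a_schedule(t: int, T: int) -> float:
    """Linear decay of the encircling control scalar: a = 2 - 2 t / T."""
    if T < 1:
        raise ValueError("T must be >= 1")
    if not 0 <= t <= T:
        raise ValueError(f"iteration t={t} outside [0, {T}]")
    return 2.0 - 2.0 * t / T


def coefficients(
    a: float, rng: np.random.Generator, dim: int
) -> tuple[np.ndarray, np.ndarray]:
    """Draw the stochastic encircling coefficients A = 2a r1 - a, C = 2 r2."""
    r1 = rng.random(dim)
    r2 = rng.random(dim)
    return 2.0 * a * r1 - a, 2.0 * r2


def encircle(
    X: np.ndarray,
    X_p: np.ndarray,
    A: np.ndarray,
    C: np.ndarray,
    bounds: tuple[float, float] = (0.0, 1.0),
) -> np.ndarray:
    """One encircling step toward a target: X' = X_p - A * |C*X_p - X|, clipped."""
    X, X_p, A, C = map(np.asarray, (X, X_p, A, C))
    if not X.shape == X_p.shape == A.shape == C.shape:
        raise ValueError("encircle operands must share one dimension")
    D = np.abs(C * X_p - X)
    return np.clip(X_p - A * D, *bounds)


def leader_guided_position(
    X: np.ndarray,
    leaders: Sequence[np.ndarray],
    a: float,
    rng: np.random.Generator,
    bounds: tuple[float, float] = (0.0, 1.0),
) -> np.ndarray:
    """Mean of the encircling moves toward alpha, beta and delta, each with
    fresh coefficient draws."""
    X = np.asarray(X)
    if len(leaders) != 3:
        raise ValueError("exactly three leader positions required")
    candidates = []
    for leader in leaders:
        A, C = coefficients(a, rng, X.shape[0])
        candidates.append(encircle(X, np.asarray(leader), A, C, bounds))
    return np.clip(np.mean(candidates, axis=0), *bounds)


def mantegna_sigma_u(beta: float) -> float:
    """Scale of the Gaussian numerator in the Mantegna Levy-step construction.

    sigma_u = { Gamma(1+b) sin(pi b / 2) / [ Gamma((1+b)/2) b 2^((b-1)/2) ] }^(1/b)
    """
    if not 0.0 < beta <= 2.0:
        raise ValueError("beta must lie in (0, 2]")
    num = math.gamma(1.0 + beta) * math.sin(math.pi * beta / 2.0)
    den = math.gamma((1.0 + beta) / 2.0) * beta * 2.0 ** ((beta - 1.0) / 2.0)
    return (num / den) ** (1.0 / beta)


def levy_sample(beta: float, dim: int, rng: np.random.Generator) -> np.ndarray:
    """Heavy-tailed step vector: u / |v|^(1/beta) with u ~ N(0, sigma_u^2),
    v ~ N(0, 1) per dimension."""
    sigma_u = mantegna_sigma_u(beta)
    u = rng.normal(0.0, sigma_u, dim)
    v = rng.normal(0.0, 1.0, dim)
    return u / np.abs(v) ** (1.0 / beta)


def levy_perturb(
    Y: np.ndarray,
    Y_best: np.ndarray,
    alpha_step: float,
    beta: float,
    rng: np.random.Generator,
    bounds: tuple[float, float] = (0.0, 1.0),
) -> np.ndarray:
    """Levy jump around the current best: Y' = Y_best + alpha_step * Levy(beta)."""
    Y, Y_best = np.asarray(Y), np.asarray(Y_best)
    if Y.shape != Y_best.shape:
        raise ValueError("position dimensions must match")
    if alpha_step <= 0:
        raise ValueError("alpha_step must be positive")
    step = levy_sample(beta, Y_best.shape[0], rng)
    return np.clip(Y_best + alpha_step * step, *bounds)


def _evaluate(
    objective: Callable[[np.ndarray], float], positions: np.ndarray
) -> np.ndarray:
    out = np.empty(positions.shape[0])
    for i, x in enumerate(positions):
        val = float(objective(x))
        if not math.isfinite(val):
            raise ValueError(f"objective returned a non-finite value at {x!r}")
        out[i] = val
    return out


def minimize(
    objective: Callable[[np.ndarray], float], config: GWOConfig
) -> tuple[np.ndarray, float, np.ndarray]:
    """Minimize a box-bounded objective with the Levy-enhanced wolf pack.

    Returns the best-ever position, its value, and the per-iteration
    best-so-far trace (length ``max_iter``, monotone non-increasing).
    """
    rng = np.random.default_rng(config.seed)
    lo, hi = config.bounds
    pack = WolfPack(
        positions=rng.uniform(lo, hi, (config.pack_size, config.dim)),
        fitnesses=None,  # type: ignore[arg-type]
    )
    pack.fitnesses = _evaluate(objective, pack.positions)
    pack.update_leaders()
    best_pos = pack.leader_positions[0].copy()
    best_val = float(pack.leader_fitnesses[0])

    trace = np.empty(config.max_iter)
    for t in range(config.max_iter):
        a = a_schedule(t, config.max_iter)
        for i in range(config.pack_size):
            x = leader_guided_position(
                pack.positions[i], pack.leader_positions, a, rng, config.bounds
            )
            if rng.random() < config.levy_prob:
                x = levy_perturb(
                    x,
                    pack.leader_positions[0],
                    config.levy_alpha,
                    config.levy_beta,
                    rng,
                    config.bounds,
                )
            pack.positions[i] = x
        pack.fitnesses = _evaluate(objective, pack.positions)
        pack.update_leaders()
        if pack.leader_fitnesses[0] < best_val:
            best_val = float(pack.leader_fitnesses[0])
            best_pos = pack.leader_positions[0].copy()
        trace[t] = best_val
    return best_pos, best_val, trace
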