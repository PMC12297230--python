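"""Particle Swarm Optimization, real-valued and binary.

A swarm of candidate solutions moves through the parameter space guided by
each particle's own best position (pbest) and the swarm's best (gbest):

    v <- w*v + c1*r1*(pbest - x) + c2*r2*(gbest - x),  clamped to [-vmax, vmax]
    x <- x + v

The inertia weight w is either fixed (0.9) or decays linearly from 0.9 to
0.4 over the run. The binary variant replaces the position update with a
probabilistic rule: coordinate d becomes 1 with probability sigmoid(v_d).

Training stops at ``max_epochs`` or when a monitored loss has not improved
for ``patience`` consecutive epochs.
"""

from __future__ import annotations

import csv
import warnings
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy.special import expit as sigmoid

from .network import FitnessConfig, NetworkSpec, nll_l2_fitness, sample_dropout_mask

IMPROVEMENT_TOL = 1e-6  # monitored-loss decrease that counts as progress


@dataclass
class PSOConfig:
    """Swarm hyperparameters (defaults are the study's settings)."""

    n_particles: int = 100
    w_mode: str = "fixed"  # {"fixed", "linear_decay"}
    w_fixed: float = 0.9
    w_start: float = 0.9
    w_end: float = 0.4
    c1: float = 0.5
    c2: float = 0.3
    v_max: float = 0.2
    init_low: float = 0.0
    init_high: float = 1.0
    max_epochs: int = 1000
    patience: int = 10
    seed: int = 0
    per_coordinate_r: bool = False  # draw r1, r2 per coordinate instead of per particle

    def __post_init__(self) -> None:
        if self.n_particles < 2:
            raise ValueError("need at least 2 particles")
        if self.v_max <= 0:
            raise ValueError("v_max must be positive")
        if not 0.0 <= self.w_end <= self.w_start:
            raise ValueError("need 0 <= w_end <= w_start")
        if self.patience < 1:
            raise ValueError("patience must be >= 1")
        if self.w_mode not in ("fixed", "linear_decay"):
            raise ValueError(f"unknown w_mode {self.w_mode!r}")


@dataclass
class Particle:
    position: np.ndarray
    velocity: np.ndarray
    pbest_position: np.ndarray
    pbest_fitness: float


@dataclass
class SwarmState:
    """Full optimizer state; histories allow byte-identical replay checks."""

    particles: list[Particle]
    gbest_position: np.ndarray
    gbest_fitness: float
    epoch: int = 0
    stagnation_counter: int = 0
    history: list[dict] = field(default_factory=list)
    stop_reason: str = ""
    rng: np.random.Generator | None = field(default=None, repr=False)

    def history_rows(self) -> list[tuple]:
        return [
            (h["epoch"], h["w"], h["gbest_fitness"], h["monitored_loss"])
            for h in self.history
        ]

    def save_history(self, path) -> None:
        with open(path, "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(["epoch", "w", "gbest_train_fitness", "monitored_loss"])
            writer.writerows(self.history_rows())


def inertia_weight(epoch: int, cfg: PSOConfig) -> float:
    """Inertia at a given epoch: fixed, or linear decay w_start -> w_end."""
    if cfg.w_mode == "fixed":
        return cfg.w_fixed
    t_max = cfg.max_epochs
    return ((t_max - epoch) * (cfg.w_start - cfg.w_end) / t_max) + cfg.w_end


def _safe_fitness(fitness: Callable[[np.ndarray], float], x: np.ndarray) -> float:
    value = fitness(x)
    if not np.isfinite(value):
        warnings.warn(
            "non-finite fitness; particle penalised with +inf", stacklevel=2
        )
        return np.inf
    return float(value)


def init_swarm(
    dim: int, cfg: PSOConfig, fitness: Callable[[np.ndarray], float]
) -> SwarmState:
    """Uniform positions in [init_low, init_high], velocities in [-vmax, vmax]."""
    if dim < 1:
        raise ValueError("dimension must be >= 1")
    rng = np.random.default_rng(cfg.seed)
    particles = []
    for _ in range(cfg.n_particles):
        x = rng.uniform(cfg.init_low, cfg.init_high, size=dim)
        v = rng.uniform(-cfg.v_max, cfg.v_max, size=dim)
        f = _safe_fitness(fitness, x)
        particles.append(Particle(x, v, x.copy(), f))
    best = min(particles, key=lambda p: p.pbest_fitness)
    return SwarmState(
        particles=particles,
        gbest_position=best.pbest_position.copy(),
        gbest_fitness=best.pbest_fitness,
        rng=rng,
    )


def update_velocity(
    p: Particle,
    gbest: np.ndarray,
    w: float,
    cfg: PSOConfig,
    r1: float | np.ndarray,
    r2: float | np.ndarray,
) -> np.ndarray:
    """Velocity recursion with symmetric clamping."""
    v = (
        w * p.velocity
        + cfg.c1 * r1 * (p.pbest_position - p.position)
        + cfg.c2 * r2 * (gbest - p.position)
    )
    return np.clip(v, -cfg.v_max, cfg.v_max)


def update_position(p: Particle) -> np.ndarray:
    """x <- x + v; positions are unconstrained (the init range is not a box)."""
    return p.position + p.velocity


def binary_position_update(v: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Probabilistic bit update: coordinate d is 1 with probability sigmoid(v_d)."""
    v = np.asarray(v, dtype=float)
    r = rng.uniform(size=v.shape)
    return (r < sigmoid(v)).astype(int)


def pso_minimize(
    fitness: Callable[[np.ndarray], float],
    dim: int,
    cfg: PSOConfig,
    monitor: Callable[[np.ndarray], float] | None = None,
    binary: bool = False,
) -> tuple[np.ndarray, SwarmState]:
    """Core swarm loop minimising an arbitrary scalar fitness.

    ``monitor`` maps the incumbent gbest to the loss used for early
    stopping; by default the training fitness itself is monitored. pbest
    and gbest update immediately after each particle moves, so later
    particles in an epoch see improvements from earlier ones.
    """
    state = init_swarm(dim, cfg, fitness)
    rng = state.rng
    if binary:
        for p in state.particles:
            p.position = binary_position_update(p.velocity, rng).astype(float)
            p.pbest_position = p.position.copy()
            p.pbest_fitness = _safe_fitness(fitness, p.position)
        best = min(state.particles, key=lambda q: q.pbest_fitness)
        state.gbest_position = best.pbest_position.copy()
        state.gbest_fitness = best.pbest_fitness
    monitor = monitor or fitness
    best_monitored = np.inf
    for epoch in range(1, cfg.max_epochs + 1):
        w = inertia_weight(epoch, cfg)
        for p in state.particles:
            if cfg.per_coordinate_r:
                r1 = rng.uniform(size=dim)
                r2 = rng.uniform(size=dim)
            else:
                r1 = rng.uniform()
                r2 = rng.uniform()
            p.velocity = update_velocity(p, state.gbest_position, w, cfg, r1, r2)
            if binary:
                p.position = binary_position_update(p.velocity, rng).astype(float)
            else:
                p.position = update_position(p)
            f = _safe_fitness(fitness, p.position)
            if f < p.pbest_fitness:
                p.pbest_fitness = f
                p.pbest_position = p.position.copy()
                if f < state.gbest_fitness:
                    state.gbest_fitness = f
                    state.gbest_position = p.position.copy()
        monitored = _safe_fitness(monitor, state.gbest_position)
        state.epoch = epoch
        state.history.append(
            {
                "epoch": epoch,
                "w": w,
                "gbest_fitness": state.gbest_fitness,
                "monitored_loss": monitored,
            }
        )
        if monitored < best_monitored - IMPROVEMENT_TOL:
            best_monitored = monitored
            state.stagnation_counter = 0
        else:
            state.stagnation_counter += 1
        if state.stagnation_counter >= cfg.patience:
            state.stop_reason = f"no monitored improvement for {cfg.patience} epochs"
            break
    else:
        state.stop_reason = f"reached max_epochs ({cfg.max_epochs})"
    return state.gbest_position.copy(), state


def pso_train(
    train: tuple[np.ndarray, np.ndarray],
    monitor: tuple[np.ndarray, np.ndarray],
    net_spec: NetworkSpec,
    fit_cfg: FitnessConfig,
    cfg: PSOConfig,
) -> tuple[np.ndarray, SwarmState]:
    """Train the classifier by swarm search over its flat parameter vector.

    ``train`` drives the fitness (NLL + L2 on the training fold); ``monitor``
    drives early stopping (unpenalised NLL). With dropout_mode
    ``fixed_mask_per_epoch`` a single seeded keep-mask is shared by every
    fitness evaluation, keeping the objective identical across particles.
    """
    X_tr, y_tr = train
    X_mon, y_mon = monitor
    if X_tr.shape[1] != net_spec.n_input or X_mon.shape[1] != net_spec.n_input:
        raise ValueError("feature count does not match the network spec")
    mask = None
    if fit_cfg.dropout_mode == "fixed_mask_per_epoch":
        mask_rng = np.random.default_rng(fit_cfg.rng_seed)
        mask = sample_dropout_mask(net_spec, mask_rng)

    def fitness(params: np.ndarray) -> float:
        return nll_l2_fitness(params, X_tr, y_tr, fit_cfg, net_spec, dropout_mask=mask)

    no_penalty = FitnessConfig(l2_lambda=0.0, dropout_mode="off")

    def monitored(params: np.ndarray) -> float:
        return nll_l2_fitness(params, X_mon, y_mon, no_penalty, net_spec)

    return pso_minimize(fitness, net_spec.n_parameters, cfg, monitor=monitored)


def carve_validation(
    X: np.ndarray,
    y: np.ndarray,
    fraction: float = 0.2,
    seed: int = 0,
) -> tuple[tuple[np.ndarray, np.ndarray], tuple[np.ndarray, np.ndarray]]:
    """Split a training fold into (train, validation) for early stopping.

    Monitoring a slice of the training data avoids leaking the held-out
    test fold into the stopping rule.
    """
    rng = np.random.default_rng(seed)
    n = len(y)
    idx = rng.permutation(n)
    n_val = max(1, int(round(fraction * n)))
    val, tr = idx[:n_val], idx[n_val:]
    return (X[tr], y[tr]), (X[val], y[val])
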