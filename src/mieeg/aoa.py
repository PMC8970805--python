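"""Arithmetic Optimization Algorithm (AOA).

A population metaheuristic whose position updates use the four elementary
arithmetic operators.  Two schedules drive the search over iterations
t = 1..Mt:

* MOA(t) = min + t * (max - min) / Mt       — the phase gate: a dimension
  explores when a uniform draw r1 exceeds MOA(t), otherwise it exploits, so
  late iterations exploit more;
* MOP(t) = 1 - t^(1/alpha) / Mt^(1/alpha)   — the step magnitude, decreasing.

Exploration moves a dimension j to  X_b,j / (MOP + eps) * ((UB_j - LB_j) * mu
+ LB_j)  (division, r2 < 0.5) or the multiplicative mirror; exploitation uses
X_b,j -/+ MOP * ((UB_j - LB_j) * mu + LB_j) (subtraction / addition, gated by
r3).  Replacement is greedy (elitist): a candidate replaces an agent only when
its fitness improves, which makes the best-so-far trace monotone.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Dict, List, Optional, Sequence, Tuple, Union

import numpy as np

from .errors import ConfigError, OptimizationError


@dataclass
class SearchSpace:
    lb: np.ndarray
    ub: np.ndarray
    names: Optional[Sequence[str]] = None
    scale: Optional[Sequence[str]] = None  # per-dim "linear" or "log10"

    def __post_init__(self) -> None:
        self.lb = np.atleast_1d(np.asarray(self.lb, dtype=float))
        self.ub = np.atleast_1d(np.asarray(self.ub, dtype=float))
        if self.lb.shape != self.ub.shape:
            raise ConfigError("lb and ub must have the same length")
        if np.any(self.lb > self.ub):
            raise ConfigError("every lb_j must be <= ub_j")
        n = self.lb.size
        if self.names is None:
            self.names = [f"x{j}" for j in range(n)]
        if self.scale is None:
            self.scale = ["linear"] * n
        for s in self.scale:
            if s not in ("linear", "log10"):
                raise ConfigError(f"unknown scale {s!r}")

    @property
    def n_dims(self) -> int:
        return self.lb.size

    def decode(self, x: np.ndarray) -> Dict[str, float]:
        """Map an internal position to named values (undoing log10 dims)."""
        out = {}
        for j, name in enumerate(self.names):
            v = float(x[j])
            out[name] = 10.0 ** v if self.scale[j] == "log10" else v
        return out


@dataclass
class AOAConfig:
    N: int = 20
    Mt: int = 100
    min_moa: float = 0.2
    max_moa: float = 0.9
    mu: float = 0.5
    alpha: float = 5.0
    epsilon: float = 2.2e-16
    seed: int = 0

    def validate(self) -> None:
        if self.N < 2:
            raise ConfigError(f"population size N must be >= 2, got {self.N}")
        if self.Mt < 1:
            raise ConfigError(f"Mt must be >= 1, got {self.Mt}")
        if not 0 <= self.min_moa < self.max_moa <= 1:
            raise ConfigError(
                f"need 0 <= min_moa < max_moa <= 1, got "
                f"({self.min_moa}, {self.max_moa})")
        if self.epsilon <= 0:
            raise ConfigError("epsilon must be positive")


@dataclass
class AOAState:
    X: np.ndarray          # N x n positions
    fitness: np.ndarray    # length N
    best_x: np.ndarray
    best_f: float
    t: int = 0


def moa(t: float, cfg: AOAConfig) -> float:
    """Math-optimizer-accelerated schedule, linear from min_moa to max_moa."""
    if not 0 <= t <= cfg.Mt:
        raise ConfigError(f"t={t} outside [0, {cfg.Mt}]")
    return cfg.min_moa + t * (cfg.max_moa - cfg.min_moa) / cfg.Mt


def mop(t: float, cfg: AOAConfig) -> float:
    """Math-optimizer probability, 1 - t^(1/alpha) / Mt^(1/alpha)."""
    if not 0 <= t <= cfg.Mt:
        raise ConfigError(f"t={t} outside [0, {cfg.Mt}]")
    return 1.0 - t ** (1.0 / cfg.alpha) / cfg.Mt ** (1.0 / cfg.alpha)


def _evaluate(objective, X: np.ndarray) -> np.ndarray:
    vals = np.empty(X.shape[0])
    for i in range(X.shape[0]):
        try:
            vals[i] = float(objective(X[i]))
        except Exception:
            vals[i] = np.nan
        if not np.isfinite(vals[i]):
            vals[i] = np.nan
    return vals


def init_population(objective: Callable[[np.ndarray], float],
                    space: SearchSpace, cfg: AOAConfig,
                    rng: Optional[np.random.Generator] = None) -> AOAState:
    """Uniform positions inside the box, fitness evaluated, best recorded."""
    cfg.validate()
    rng = rng or np.random.default_rng(cfg.seed)
    X = rng.uniform(size=(cfg.N, space.n_dims)) * (space.ub - space.lb) + space.lb
    fitness = _evaluate(objective, X)
    if np.all(np.isnan(fitness)):
        raise OptimizationError("objective returned non-finite for every agent")
    if np.any(np.isnan(fitness)):
        warnings.warn("objective returned non-finite values; agents penalized")
        fitness = np.where(np.isnan(fitness), np.inf, fitness)
    b = int(np.argmin(fitness))
    return AOAState(X=X, fitness=fitness, best_x=X[b].copy(),
                    best_f=float(fitness[b]), t=0)


def explore_step(x_i: np.ndarray, best_x: np.ndarray, mop_val: float,
                 space: SearchSpace, cfg: AOAConfig,
                 rng: np.random.Generator) -> np.ndarray:
    """Division/multiplication move toward the best solution, then clipped."""
    span = (space.ub - space.lb) * cfg.mu + space.lb
    r2 = rng.uniform(size=space.n_dims)
    div = best_x / (mop_val + cfg.epsilon) * span
    mul = best_x * mop_val * span
    return np.clip(np.where(r2 < 0.5, div, mul), space.lb, space.ub)


def exploit_step(x_i: np.ndarray, best_x: np.ndarray, mop_val: float,
                 space: SearchSpace, cfg: AOAConfig,
                 rng: np.random.Generator) -> np.ndarray:
    """Subtraction/addition move around the best solution, then clipped."""
    span = (space.ub - space.lb) * cfg.mu + space.lb
    r3 = rng.uniform(size=space.n_dims)
    sub = best_x - mop_val * span
    add = best_x + mop_val * span
    return np.clip(np.where(r3 < 0.5, sub, add), space.lb, space.ub)


def aoa_optimize(objective: Callable[[np.ndarray], float],
                 space: SearchSpace, cfg: AOAConfig | None = None,
                 callback: Optional[Callable[[AOAState], None]] = None
                 ) -> Tuple[np.ndarray, float, List[float]]:
    """Minimize ``objective`` over the box; returns (best_x, best_f, trace).

    ``trace[t]`` is the best-so-far fitness after iteration t (element 0 is
    the post-initialization best); it is non-increasing by construction.
    Exactly N * (Mt + 1) objective evaluations are performed.
    """
    cfg = cfg or AOAConfig()
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    state = init_population(objective, space, cfg, rng)
    trace = [state.best_f]

    for t in range(1, cfg.Mt + 1):
        moa_t = moa(t, cfg)
        mop_t = mop(t, cfg)
        for i in range(cfg.N):
            r1 = rng.uniform(size=space.n_dims)
            explored = explore_step(state.X[i], state.best_x, mop_t, space, cfg, rng)
            exploited = exploit_step(state.X[i], state.best_x, mop_t, space, cfg, rng)
            candidate = np.where(r1 > moa_t, explored, exploited)
            f = _evaluate(objective, candidate[None])[0]
            if np.isnan(f):
                warnings.warn(f"non-finite objective at iteration {t}, agent {i}; skipped")
                continue
            if f < state.fitness[i]:
                state.X[i] = candidate
                state.fitness[i] = f
            if f < state.best_f:
                state.best_f = float(f)
                state.best_x = candidate.copy()
        state.t = t
        trace.append(state.best_f)
        if callback is not None:
            callback(state)
    return state.best_x, state.best_f, trace


def tune_hyperparameters(train_eval: Callable[[Dict[str, float]], float],
                         space: SearchSpace, cfg: AOAConfig | None = None
                         ) -> Tuple[Dict[str, float], float, List[Dict]]:
    """Maximize validation accuracy by minimizing (1 - accuracy) with AOA.

    ``train_eval`` maps a named hyperparameter dict (log10 dimensions already
    decoded) to an accuracy in [0, 1].  Failures are penalized with fitness 1.
    Returns (best config, best accuracy, evaluation log).
    """
    cfg = cfg or AOAConfig(N=5, Mt=10)
    log: List[Dict] = []

    def objective(x: np.ndarray) -> float:
        params = space.decode(x)
        try:
            acc = float(train_eval(params))
        except Exception as exc:
            log.append({"params": params, "accuracy": None, "error": str(exc)})
            return 1.0
        log.append({"params": params, "accuracy": acc, "error": None})
        return 1.0 - acc

    best_x, best_f, _trace = aoa_optimize(objective, space, cfg)
    return space.decode(best_x), 1.0 - best_f, log


__all__ = ["SearchSpace", "AOAConfig", "AOAState", "moa", "mop",
           "init_population", "explore_step", "exploit_step",
           "aoa_optimize", "tune_hyperparameters"]
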