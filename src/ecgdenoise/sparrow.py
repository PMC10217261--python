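"""Sparrow search algorithm (SSA) and the envelope-entropy fitness used to
pick VMD's mode count K and penalty alpha.

SSA is a population metaheuristic with three roles: producers lead the
search (shrinking exponential moves while the alarm is low, Gaussian steps
otherwise), scroungers follow the best producer or flee the worst position,
and a scout fraction is relocated each iteration as an anti-predation
reaction. The canonical update equations of the originating formulation are
used; the defaults for the ECG use case are a population of 30 and
15 iterations over the integer box K in [2, 15], alpha in [500, 5000].

The fitness is the minimum, across modes, of the Shannon entropy of each
mode's normalised analytic-signal envelope: structured components have
sparse envelopes (low entropy), noise-like components flat ones (high
entropy), so minimising the smallest per-mode entropy rewards parameter
combinations that isolate at least one clean, coherent component.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
from scipy.signal import hilbert

from .core import Signal
from .vmd import VMDParams, vmd_decompose

__all__ = ["SSAConfig", "SSAResult", "envelope_entropy", "vmd_fitness",
           "ssa_minimize", "optimize_vmd_params", "VMD_PARAM_BOUNDS"]

#: search box for [K, alpha]
VMD_PARAM_BOUNDS = ((2, 15), (500, 5000))


@dataclass(frozen=True)
class SSAConfig:
    """Sparrow-search controls.

    ``producer_fraction``/``scout_fraction``/``safety_threshold`` are the
    conventional 0.2 / 0.1 / 0.8 of the originating formulation.
    """

    bounds: tuple[tuple[float, float], ...]
    pop_size: int = 30
    max_iter: int = 15
    producer_fraction: float = 0.2
    scout_fraction: float = 0.1
    safety_threshold: float = 0.8
    integer_dims: frozenset[int] = frozenset()
    seed: int = 0

    def __post_init__(self) -> None:
        if self.pop_size < 2:
            raise ValueError(f"pop_size must be >= 2, got {self.pop_size}")
        if self.max_iter < 1:
            raise ValueError(f"max_iter must be >= 1, got {self.max_iter}")
        for lo, hi in self.bounds:
            if not lo < hi:
                raise ValueError(f"invalid bound ({lo}, {hi}): low must be < high")
        for frac in (self.producer_fraction, self.scout_fraction):
            if not 0.0 < frac < 1.0:
                raise ValueError(f"fractions must lie in (0, 1), got {frac}")
        object.__setattr__(self, "integer_dims", frozenset(self.integer_dims))


@dataclass(frozen=True)
class SSAResult:
    best_position: np.ndarray
    best_fitness: float
    convergence: np.ndarray  # best-so-far fitness per iteration (non-increasing)
    evaluations: int


def envelope_entropy(samples: Sequence[float]) -> float:
    """Shannon entropy (nats) of the normalised analytic-signal envelope.

    The envelope a_i = |hilbert(x)_i| is normalised to a probability vector
    p_i = a_i / sum(a); the entropy -sum p_i ln p_i is maximal (ln N) for a
    constant envelope and small for an impulsive one.
    """
    x = np.asarray(samples, dtype=float)
    if x.size < 4:
        raise ValueError(f"need at least 4 samples, got {x.size}")
    if not np.any(x):
        raise ValueError("envelope entropy is undefined for an all-zero signal")
    env = np.abs(hilbert(x))
    p = env / env.sum()
    nz = p[p > 0]
    return float(-(nz * np.log(nz)).sum())


def vmd_fitness(signal: Signal, K: int, alpha: float,
                aggregate: str = "min") -> float:
    """Envelope-entropy fitness of decomposing ``signal`` with (K, alpha).

    ``aggregate="min"`` (the local-minimum convention) scores the sparsest
    mode; ``"mean"`` is available as an alternative reading.
    """
    modeset = vmd_decompose(signal, VMDParams(K=int(K), alpha=float(alpha)))
    ents = []
    for mode in modeset.modes:
        if np.any(mode):
            ents.append(envelope_entropy(mode))
    if not ents:
        raise ValueError("decomposition produced only zero modes")
    if aggregate == "min":
        return min(ents)
    if aggregate == "mean":
        return float(np.mean(ents))
    raise ValueError(f"unknown aggregate {aggregate!r}")


def _clamp_round(X: np.ndarray, lo: np.ndarray, hi: np.ndarray,
                 int_dims: Sequence[int]) -> np.ndarray:
    X = np.clip(X, lo, hi)
    for d in int_dims:
        X[..., d] = np.round(X[..., d])
    return X


def ssa_minimize(objective: Callable[[np.ndarray], float],
                 config: SSAConfig) -> SSAResult:
    """Minimise ``objective`` over the bounded box with the sparrow search.

    The recorded convergence curve tracks the global best and is therefore
    non-increasing; the whole run is a pure function of ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    lo = np.array([b[0] for b in config.bounds], dtype=float)
    hi = np.array([b[1] for b in config.bounds], dtype=float)
    d = lo.size
    n = config.pop_size
    int_dims = sorted(config.integer_dims)
    n_eval = 0

    def evaluate(pos: np.ndarray) -> float:
        nonlocal n_eval
        val = float(objective(pos))
        n_eval += 1
        if not np.isfinite(val):
            raise ValueError(f"objective returned non-finite value {val} at {pos}")
        return val

    X = _clamp_round(lo + rng.random((n, d)) * (hi - lo), lo, hi, int_dims)
    F = np.array([evaluate(x) for x in X])
    gi = int(np.argmin(F))
    gbest_x, gbest_f = X[gi].copy(), float(F[gi])

    n_prod = max(1, int(round(config.producer_fraction * n)))
    n_scout = max(1, int(round(config.scout_fraction * n)))
    convergence = np.empty(config.max_iter)

    for it in range(config.max_iter):
        order = np.argsort(F, kind="stable")
        X, F = X[order], F[order]
        worst_x = X[-1].copy()
        f_worst = float(F[-1])

        # producers
        alarm = rng.random()
        for i in range(n_prod):
            if alarm < config.safety_threshold:
                r = rng.random()
                X[i] = X[i] * np.exp(-(i + 1) / (max(r, 1e-12) * config.max_iter))
            else:
                X[i] = X[i] + rng.standard_normal() * np.ones(d)
        best_prod = X[0].copy()

        # scroungers
        for i in range(n_prod, n):
            if i + 1 > n / 2:
                q = rng.standard_normal()
                X[i] = q * np.exp((worst_x - X[i]) / (i + 1) ** 2)
            else:
                a = rng.choice([-1.0, 1.0], size=d)
                step = float(np.abs(X[i] - best_prod) @ a) / d
                X[i] = best_prod + step
        X = _clamp_round(X, lo, hi, int_dims)
        F = np.array([evaluate(x) for x in X])

        # scouts: a random fraction reacts to danger
        scouts = rng.choice(n, size=n_scout, replace=False)
        for i in scouts:
            if F[i] > gbest_f:
                X[i] = gbest_x + rng.standard_normal(d) * np.abs(X[i] - gbest_x)
            else:
                k_step = rng.uniform(-1.0, 1.0)
                denom = (F[i] - f_worst) + 1e-50
                X[i] = X[i] + k_step * (np.abs(X[i] - worst_x) / denom)
            X[i] = _clamp_round(X[i], lo, hi, int_dims)
            F[i] = evaluate(X[i])

        ci = int(np.argmin(F))
        if F[ci] < gbest_f:  # strict: ties keep the earlier position
            gbest_f = float(F[ci])
            gbest_x = X[ci].copy()
        convergence[it] = gbest_f

    return SSAResult(best_position=gbest_x, best_fitness=gbest_f,
                     convergence=convergence, evaluations=n_eval)


def optimize_vmd_params(signal: Signal, config: SSAConfig | None = None,
                        seed: int = 0,
                        aggregate: str = "min") -> tuple[int, int, SSAResult]:
    """Select VMD's (K, alpha) for ``signal`` by sparrow search.

    Returns ``(K, alpha, result)``; both parameters are integers inside the
    search box. Fitness values are memoised per integer grid point, so
    revisited positions cost nothing.
    """
    if config is None:
        config = SSAConfig(bounds=VMD_PARAM_BOUNDS, integer_dims=frozenset({0, 1}),
                           seed=seed)
    cache: dict[tuple[int, int], float] = {}

    def objective(pos: np.ndarray) -> float:
        key = (int(round(pos[0])), int(round(pos[1])))
        if key not in cache:
            cache[key] = vmd_fitness(signal, key[0], key[1], aggregate=aggregate)
        return cache[key]

    result = ssa_minimize(objective, config)
    K = int(round(result.best_position[0]))
    alpha = int(round(result.best_position[1]))
    return K, alpha, result
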