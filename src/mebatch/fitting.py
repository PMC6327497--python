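"""Calibration of keff parameters by list-based threshold accepting (LTA).

The objective -- sum of squared errors between measured and simulated
extracellular concentration profiles as a function of keff multipliers --
is expensive, noisy-free but non-smooth (phase boundaries shift with the
parameters), so a gradient-free metaheuristic is used.  List-based
threshold accepting keeps a list of the L largest relative worsenings
seen during a random-walk warm-up; a candidate move is accepted when its
relative worsening (Z_new - Z_cur)/Z_cur stays below the current list
maximum T_max, and every accepted worsening replaces T_max with the
(smaller) realized value, so the acceptance threshold anneals toward
greedy search without a hand-tuned schedule.

A multi-walker mode runs several LTA trajectories with a synchronization
contract: walker 0 is "local" and never restarts; the remaining walkers
may restart from the global best at sync points (every ``restart_period``
iterations).  The schedule is executed serially and is bitwise
reproducible; a concurrent executor honoring the same sync points would
produce identical results.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "LTAConfig",
    "FitResult",
    "make_objective",
    "lta_optimize",
    "run_walkers",
]

_EPS = 1e-300


@dataclass
class LTAConfig:
    list_size: int = 8           # thresholds kept (L)
    max_iter: int = 500          # main-loop iterations per walker
    neighborhood_scale: float = 2.0  # max multiplicative step per move
    n_walkers: int = 1
    restart_period: int = 50     # iterations between sync points (R)
    restart: bool = True         # non-local walkers restart from global best
    warmup_per_threshold: int = 5  # warm-up moves = 5 * L
    seed: int = 0

    def __post_init__(self) -> None:
        if self.list_size < 1:
            raise ValueError("list_size must be >= 1")
        if not self.neighborhood_scale > 1:
            raise ValueError("neighborhood_scale must be > 1")
        if self.n_walkers < 1:
            raise ValueError("n_walkers must be >= 1")


@dataclass
class FitResult:
    x_best: np.ndarray
    z_best: float
    trace: pd.DataFrame          # iteration, walker, z, accepted, t_max
    n_evals: int
    thresholds: list[float] = field(default_factory=list)


def make_objective(model, measured: pd.DataFrame, config, init,
                   targets: Sequence[tuple[str, str]],
                   species: Sequence[str] | None = None,
                   ) -> Callable[[np.ndarray], float]:
    """Objective over keff multiplier vectors.

    Applies the multipliers to the target couplings, runs a batch
    simulation, and scores the simulated extracellular concentration
    profiles against ``measured`` (SSE).  A failed simulation returns
    +inf so the move is rejected rather than crashing the search.
    Evaluations are memoized on the rounded multiplier vector.
    """
    from .dynamics import simulate_batch
    from .ensemble import score_fit

    targets = [tuple(t) for t in targets]
    if not targets:
        raise ValueError("targets must be non-empty")
    cache: dict[tuple, float] = {}

    def objective(x: np.ndarray) -> float:
        x = np.asarray(x, dtype=float)
        key = tuple(np.round(np.log(np.maximum(x, _EPS)), 10))
        if key in cache:
            return cache[key]
        try:
            perturbed = model.with_keff_factors(dict(zip(targets, x)))
            tc = simulate_batch(perturbed, init, config)
            if tc.error is not None:
                raise RuntimeError(tc.error)
            val = score_fit(tc.concentrations, measured, species)
        except Exception:
            val = math.inf
        cache[key] = val
        return val

    objective.cache = cache  # type: ignore[attr-defined]
    return objective


def _propose(x: np.ndarray, lb: np.ndarray, ub: np.ndarray,
             scale: float, rng: np.random.Generator) -> np.ndarray:
    """Perturb one coordinate; log-space with reflection where possible."""
    y = x.copy()
    i = int(rng.integers(len(x)))
    if lb[i] > 0:
        lo, hi = math.log(lb[i]), math.log(ub[i])
        step = rng.uniform(-math.log(scale), math.log(scale))
        v = math.log(y[i]) + step
    else:
        span = (ub[i] - lb[i])
        lo, hi = lb[i], ub[i]
        step = rng.uniform(-1.0, 1.0) * (scale - 1.0) * span / 10.0
        v = y[i] + step
    # reflect into [lo, hi]
    width = hi - lo
    if width <= 0:
        v = lo
    else:
        v = (v - lo) % (2 * width)
        v = lo + (v if v <= width else 2 * width - v)
    y[i] = math.exp(v) if lb[i] > 0 else v
    return y


class _Walker:
    """One LTA trajectory with its own RNG and threshold list."""

    def __init__(self, objective, x0, lb, ub, config: LTAConfig,
                 rng: np.random.Generator, walker_id: int = 0):
        self.objective = objective
        self.lb, self.ub = lb, ub
        self.config = config
        self.rng = rng
        self.id = walker_id
        self.x = np.asarray(x0, dtype=float)
        self.z = objective(self.x)
        self.x_best, self.z_best = self.x.copy(), self.z
        self.n_evals = 1
        self.rows: list[dict] = []
        self.iteration = 0
        self._warmup()

    def _rel_worsening(self, z_new: float) -> float:
        return (z_new - self.z) / max(abs(self.z), 1e-12)

    def _warmup(self) -> None:
        cfg = self.config
        worsenings: list[float] = []
        for _ in range(cfg.warmup_per_threshold * cfg.list_size):
            y = _propose(self.x, self.lb, self.ub,
                         cfg.neighborhood_scale, self.rng)
            zy = self.objective(y)
            self.n_evals += 1
            w = self._rel_worsening(zy)
            if w > 0 and math.isfinite(w):
                worsenings.append(w)
            # random walk: always move (finite objective permitting)
            if math.isfinite(zy):
                self.x, self.z = y, zy
                if zy < self.z_best:
                    self.x_best, self.z_best = y.copy(), zy
        worsenings.sort(reverse=True)
        self.thresholds = worsenings[: cfg.list_size]
        if not self.thresholds:
            self.thresholds = [0.0]
        # resume the main search from the best point seen so far
        self.x, self.z = self.x_best.copy(), self.z_best

    def step(self) -> None:
        cfg = self.config
        self.iteration += 1
        y = _propose(self.x, self.lb, self.ub,
                     cfg.neighborhood_scale, self.rng)
        zy = self.objective(y)
        self.n_evals += 1
        w = self._rel_worsening(zy)
        t_max = max(self.thresholds)
        accepted = math.isfinite(zy) and w < t_max
        if accepted:
            if w > 0:
                # replace the list maximum with the smaller realized worsening
                self.thresholds[self.thresholds.index(t_max)] = w
            self.x, self.z = y, zy
            if zy < self.z_best:
                self.x_best, self.z_best = y.copy(), zy
        self.rows.append({"iteration": self.iteration, "walker": self.id,
                          "proposal": ";".join(f"{v:.10g}" for v in y),
                          "z": zy, "accepted": accepted,
                          "t_max": max(self.thresholds),
                          "z_best": self.z_best})

    def restart_from(self, x: np.ndarray, z: float) -> None:
        self.x, self.z = x.copy(), z


def lta_optimize(objective: Callable[[np.ndarray], float],
                 x0: Sequence[float],
                 bounds: Sequence[tuple[float, float]],
                 config: LTAConfig | None = None) -> FitResult:
    """Single-trajectory list-based threshold accepting."""
    config = config or LTAConfig()
    lb = np.array([b[0] for b in bounds], dtype=float)
    ub = np.array([b[1] for b in bounds], dtype=float)
    x0 = np.asarray(x0, dtype=float)
    if len(x0) != len(lb) or np.any(x0 < lb) or np.any(x0 > ub):
        raise ValueError("x0 must lie within bounds")
    rng = np.random.default_rng(config.seed)
    w = _Walker(objective, x0, lb, ub, config, rng)
    for _ in range(config.max_iter):
        w.step()
    return FitResult(x_best=w.x_best, z_best=w.z_best,
                     trace=pd.DataFrame(w.rows), n_evals=w.n_evals,
                     thresholds=list(w.thresholds))


def run_walkers(objective: Callable[[np.ndarray], float],
                x0: Sequence[float],
                bounds: Sequence[tuple[float, float]],
                config: LTAConfig | None = None) -> FitResult:
    """Multi-walker LTA with sync-point best-solution exchange.

    Walker 0 follows its local trajectory; walkers 1..W-1 restart from
    the global best at every sync point (when ``config.restart`` is set
    and their current point is worse).  With one walker this reduces
    exactly to :func:`lta_optimize`.
    """
    config = config or LTAConfig()
    if config.n_walkers == 1:
        return lta_optimize(objective, x0, bounds, config)
    lb = np.array([b[0] for b in bounds], dtype=float)
    ub = np.array([b[1] for b in bounds], dtype=float)
    x0 = np.asarray(x0, dtype=float)
    if len(x0) != len(lb) or np.any(x0 < lb) or np.any(x0 > ub):
        raise ValueError("x0 must lie within bounds")

    seeds = np.random.SeedSequence(config.seed).spawn(config.n_walkers)
    walkers = [_Walker(objective, x0, lb, ub, config,
                       np.random.default_rng(s), walker_id=i)
               for i, s in enumerate(seeds)]
    done = 0
    while done < config.max_iter:
        chunk = min(config.restart_period, config.max_iter - done)
        for w in walkers:
            for _ in range(chunk):
                w.step()
        done += chunk
        best = min(walkers, key=lambda w: w.z_best)
        if config.restart and done < config.max_iter:
            for w in walkers[1:]:
                if w.z > best.z_best:
                    w.restart_from(best.x_best, best.z_best)
    best = min(walkers, key=lambda w: w.z_best)
    rows = [row for w in walkers for row in w.rows]
    trace = pd.DataFrame(rows).sort_values(["iteration", "walker"],
                                           kind="stable")
    return FitResult(x_best=best.x_best, z_best=best.z_best,
                     trace=trace.reset_index(drop=True),
                     n_evals=sum(w.n_evals for w in walkers),
                     thresholds=list(best.thresholds))
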