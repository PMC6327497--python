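"""Batch time-course simulation driven by growth-maximizing ME solves.

The batch culture is advanced on small time steps.  In the base
(event-driven) mode the ME optimization runs only when substrate
availability changes -- a depletion, a feed-window boundary, or a
secreted metabolite becoming available -- because flux bounds depend on
availability only (0 when absent, a finite default when present), not on
concentration.  Between solves the last exchange fluxes and growth rate
propagate the extracellular state.  In the protein-inertia mode the
optimization re-runs at every step, carrying the complex concentrations
``p`` forward by the realized ``delta * dt``.

Integration rule: biomass updates exponentially, X' = X*exp(mu*dt)
(exact for constant mu); concentrations update forward-Euler with the
start-of-step biomass, c' = c + v_ex*X*dt (+ feed).  A variable-step
safeguard (:func:`min_time_step`) shortens any step that would drive a
concentration (or, in inertia mode, a complex concentration) negative,
so the limiting species lands exactly at zero.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .memodel import MEModel, ModelError
from .solver import (DEFAULT_MU_TOL, GrowthSolution, InertiaState,
                     maximize_growth, maximize_growth_inertia)

__all__ = [
    "BatchState",
    "Feed",
    "SimulationConfig",
    "TimeCourse",
    "detect_environment_change",
    "step_update",
    "min_time_step",
    "simulate_batch",
    "simulate_batch_inertia",
]

DEPLETION_THRESHOLD = 1e-9  # mmol/L below which a substrate counts as depleted
_MAX_STEPS = 200_000


@dataclass
class Feed:
    """Constant-rate feed of one metabolite over a time window."""

    start: float
    end: float
    metabolite: str
    rate: float  # mmol/L/h


@dataclass
class BatchState:
    """Extracellular state of the culture at one instant."""

    t: float
    c: dict[str, float]        # mmol/L per extracellular metabolite
    X: float                   # biomass, gDW/L

    def availability(self, feeds: Iterable[Feed] = (),
                     threshold: float = DEPLETION_THRESHOLD) -> frozenset[str]:
        avail = {m for m, v in self.c.items() if v > threshold}
        for f in feeds:
            if f.start <= self.t < f.end:
                avail.add(f.metabolite)
        return frozenset(avail)


@dataclass
class SimulationConfig:
    dt0: float = 0.1           # default time step, h
    t_batch: float = 10.0      # total batch time, h
    horizon: float = 2.0       # inertia planning horizon H, h
    solver_tol: float = DEFAULT_MU_TOL
    uptake_lb: float = -1000.0  # exchange lower bound when available
    fixed_bounds: dict[str, tuple[float | None, float | None]] = \
        field(default_factory=dict)  # e.g. oxygen-style global caps
    feeds: tuple[Feed, ...] = ()
    depletion_threshold: float = DEPLETION_THRESHOLD

    def __post_init__(self) -> None:
        if not (self.dt0 > 0 and self.t_batch > 0 and self.horizon > 0):
            raise ValueError("dt0, t_batch and horizon must all be > 0")


@dataclass
class TimeCourse:
    """Trajectories of a batch simulation on a shared time grid."""

    time: np.ndarray
    concentrations: pd.DataFrame   # time x extracellular metabolite, mmol/L
    biomass: pd.Series             # gDW/L
    mu: pd.Series                  # 1/h, value active over [t_k, t_{k+1})
    fluxes: pd.DataFrame           # time x reaction, mmol/gDW/h
    proteome: pd.DataFrame         # translation fluxes (base) or p (inertia)
    events: list[dict]             # solve-event log: {"t", "trigger", "mu"}
    mode: str = "base"
    error: str | None = None

    def exchange_fluxes(self, model: MEModel) -> pd.DataFrame:
        cols = {m: self.fluxes[r] for m, r in model.exchanges.items()
                if r in self.fluxes.columns}
        return pd.DataFrame(cols, index=self.fluxes.index)

    def mass_fractions(self, model: MEModel) -> pd.DataFrame:
        """Per-protein mass fractions along the trajectory.

        Uses translation fluxes (base mode) or complex concentrations
        (inertia mode) weighted by molecular weight.  Time points with an
        all-zero proteome (e.g. after total substrate exhaustion, when no
        synthesis flux exists) inherit the previous composition.
        """
        w = {p.id: p.weight_kda for p in model.proteins}
        cols = [c for c in self.proteome.columns if c in w]
        mass = self.proteome[cols] * pd.Series({c: w[c] for c in cols})
        total = mass.sum(axis=1)
        frac = mass.div(total.where(total > 0), axis=0)
        frac = frac.ffill()
        return frac.fillna(1.0 / max(len(cols), 1))

    # -- CSV round trip -------------------------------------------------
    def write_dir(self, path: str) -> None:
        os.makedirs(path, exist_ok=True)

        def _dump(df: pd.DataFrame, name: str) -> None:
            out = df.copy()
            out.insert(0, "time_h", self.time)
            out.to_csv(os.path.join(path, name), index=False)

        _dump(self.concentrations, "concentrations.csv")
        _dump(self.fluxes, "fluxes.csv")
        _dump(self.proteome, "proteome.csv")
        _dump(pd.DataFrame({"biomass_gdw_l": self.biomass,
                            "mu_per_h": self.mu}), "scalars.csv")
        with open(os.path.join(path, "events.jsonl"), "w") as fh:
            for ev in self.events:
                fh.write(json.dumps(ev) + "\n")
        with open(os.path.join(path, "meta.json"), "w") as fh:
            json.dump({"mode": self.mode, "error": self.error}, fh)

    @classmethod
    def read_dir(cls, path: str) -> "TimeCourse":
        def _load(name: str) -> pd.DataFrame:
            df = pd.read_csv(os.path.join(path, name))
            return df.set_index("time_h")

        conc = _load("concentrations.csv")
        fluxes = _load("fluxes.csv")
        proteome = _load("proteome.csv")
        scalars = _load("scalars.csv")
        events = []
        with open(os.path.join(path, "events.jsonl")) as fh:
            for line in fh:
                if line.strip():
                    events.append(json.loads(line))
        meta = {"mode": "base", "error": None}
        meta_path = os.path.join(path, "meta.json")
        if os.path.exists(meta_path):
            with open(meta_path) as fh:
                meta = json.load(fh)
        time = conc.index.to_numpy(dtype=float)
        return cls(time=time, concentrations=conc,
                   biomass=scalars["biomass_gdw_l"], mu=scalars["mu_per_h"],
                   fluxes=fluxes, proteome=proteome, events=events,
                   mode=meta.get("mode", "base"), error=meta.get("error"))


# ---------------------------------------------------------------------------
# elementary operations
# ---------------------------------------------------------------------------

def detect_environment_change(
    prev_availability: frozenset[str] | set[str],
    state: BatchState,
    feeds: Iterable[Feed] = (),
    threshold: float = DEPLETION_THRESHOLD,
) -> tuple[bool, dict[str, set[str]]]:
    """Has the set of available substrates changed since the last solve?

    Fires on depletion, on a feed window making a metabolite available,
    and on secretion pushing a metabolite above the availability
    threshold (enabling byproduct re-consumption phases).
    """
    now = state.availability(feeds, threshold)
    prev = frozenset(prev_availability)
    diff = {"added": set(now - prev), "removed": set(prev - now)}
    return now != prev, diff


def _feed_rates(feeds: Iterable[Feed], t: float) -> dict[str, float]:
    rates: dict[str, float] = {}
    for f in feeds:
        if f.start <= t < f.end:
            rates[f.metabolite] = rates.get(f.metabolite, 0.0) + f.rate
    return rates


def step_update(state: BatchState, v_ex: Mapping[str, float], mu: float,
                dt: float, feeds: Iterable[Feed] = ()) -> BatchState:
    """Advance the extracellular state by one step.

    X' = X*exp(mu*dt); c'_i = c_i + v_ex_i*X*dt + feed_i*dt.  Negative
    results beyond round-off indicate a missed :func:`min_time_step` call
    and raise; sub-threshold values clamp to exactly 0.
    """
    if not dt > 0:
        raise ValueError(f"dt must be > 0, got {dt}")
    rates = _feed_rates(feeds, state.t)
    c_new: dict[str, float] = {}
    for met, c in state.c.items():
        val = c + (v_ex.get(met, 0.0) * state.X + rates.get(met, 0.0)) * dt
        if val < -1e-6:
            raise RuntimeError(
                f"concentration of {met!r} went to {val:.3e} at "
                f"t={state.t + dt:.4f}: min_time_step was not applied")
        c_new[met] = 0.0 if val < DEPLETION_THRESHOLD else val
    return BatchState(t=state.t + dt, c=c_new,
                      X=state.X * float(np.exp(mu * dt)))


def min_time_step(state: BatchState, v_ex: Mapping[str, float],
                  p: Mapping[str, float] | None,
                  delta: Mapping[str, float] | None,
                  dt0: float, feeds: Iterable[Feed] = ()) -> float:
    """Variable-step safeguard.

    dt = min(dt0, dt_new_M, dt_new_P) where dt_new_M = min c_i/(-r_i)
    over species whose net consumption rate r_i = v_ex_i*X + feed_i would
    drive c_i negative within dt0, and dt_new_P = min p_i/(-delta_i) over
    complexes that would be depleted within dt0 (the protein term is
    skipped when p/delta are absent).
    """
    if not dt0 > 0:
        raise ValueError(f"dt0 must be > 0, got {dt0}")
    dt = dt0
    rates = _feed_rates(feeds, state.t)
    for met, c in state.c.items():
        r = v_ex.get(met, 0.0) * state.X + rates.get(met, 0.0)
        if r < 0 and c + r * dt0 < 0:
            cand = c / (-r)
            if cand > 1e-12:
                dt = min(dt, cand)
    if p is not None and delta is not None:
        for cid, d in delta.items():
            if d < 0 and p.get(cid, 0.0) + d * dt0 < 0:
                cand = p.get(cid, 0.0) / (-d)
                if cand > 1e-12:
                    dt = min(dt, cand)
    return dt


# ---------------------------------------------------------------------------
# simulation loops
# ---------------------------------------------------------------------------

def _exchange_overrides(model: MEModel, avail: frozenset[str],
                        config: SimulationConfig) -> dict:
    overrides: dict[str, tuple[float | None, float | None]] = {}
    for met, rxn in model.exchanges.items():
        lo = config.uptake_lb if met in avail else 0.0
        overrides[rxn] = (lo, None)
    for rxn, (lo, hi) in config.fixed_bounds.items():
        overrides[rxn] = (lo, hi)
    return overrides


def _next_boundary(feeds: Iterable[Feed], t: float, t_batch: float) -> float:
    nxt = t_batch
    for f in feeds:
        for edge in (f.start, f.end):
            if t + 1e-12 < edge < nxt:
                nxt = edge
    return nxt


def _v_ex(model: MEModel, sol: GrowthSolution) -> dict[str, float]:
    return {met: sol.v.get(rxn, 0.0) for met, rxn in model.exchanges.items()}


class _Recorder:
    def __init__(self, model: MEModel, mode: str):
        self.model = model
        self.mode = mode
        self.rows: list[dict] = []

    def add(self, state: BatchState, sol: GrowthSolution,
            p: Mapping[str, float] | None = None) -> None:
        row = {"t": state.t, "X": state.X, "mu": sol.mu_opt}
        row["c"] = dict(state.c)
        row["v"] = dict(sol.v)
        if self.mode == "inertia":
            row["prot"] = dict(p) if p is not None else {}
        else:
            row["prot"] = {pr.id: sol.v.get(pr.translation_rxn, 0.0)
                           for pr in self.model.proteins}
        self.rows.append(row)

    def build(self, events: list[dict], error: str | None) -> TimeCourse:
        time = np.array([r["t"] for r in self.rows])
        conc = pd.DataFrame([r["c"] for r in self.rows], index=time)
        fluxes = pd.DataFrame([r["v"] for r in self.rows], index=time).fillna(0.0)
        prot = pd.DataFrame([r["prot"] for r in self.rows], index=time)
        return TimeCourse(
            time=time, concentrations=conc,
            biomass=pd.Series([r["X"] for r in self.rows], index=time),
            mu=pd.Series([r["mu"] for r in self.rows], index=time),
            fluxes=fluxes, proteome=prot, events=events,
            mode=self.mode, error=error)


def simulate_batch(model: MEModel, init: BatchState,
                   config: SimulationConfig) -> TimeCourse:
    """Event-driven batch simulation (free proteome re-allocation).

    The ME optimization runs at t=0 and thereafter only when substrate
    availability changes or a feed window opens/closes; between solves
    the last exchange fluxes and growth rate propagate the state.
    """
    state = BatchState(t=float(init.t), c=dict(init.c), X=float(init.X))
    rec = _Recorder(model, "base")
    events: list[dict] = []
    error: str | None = None

    avail = state.availability(config.feeds, config.depletion_threshold)
    sol = maximize_growth(model, config.solver_tol,
                          _exchange_overrides(model, avail, config))
    if not sol.ok:
        return rec.build(events, f"solver status {sol.status} at t={state.t}")
    events.append({"t": state.t, "trigger": "initial", "mu": sol.mu_opt})
    rec.add(state, sol)

    steps = 0
    while state.t < config.t_batch - 1e-12:
        steps += 1
        if steps > _MAX_STEPS:
            error = "step limit exceeded"
            break
        boundary = _next_boundary(config.feeds, state.t, config.t_batch)
        dt_cap = min(config.dt0, config.t_batch - state.t,
                     boundary - state.t)
        v_ex = _v_ex(model, sol)
        dt = min_time_step(state, v_ex, None, None, dt_cap, config.feeds)
        state = step_update(state, v_ex, sol.mu_opt, dt, config.feeds)

        changed, diff = detect_environment_change(
            avail, state, config.feeds, config.depletion_threshold)
        at_boundary = abs(state.t - boundary) < 1e-12 and boundary < config.t_batch
        if changed or at_boundary:
            avail = state.availability(config.feeds, config.depletion_threshold)
            sol = maximize_growth(model, config.solver_tol,
                                  _exchange_overrides(model, avail, config))
            if not sol.ok:
                error = f"solver status {sol.status} at t={state.t}"
                rec.add(state, GrowthSolution(0.0, {}, sol.status))
                break
            trigger = "availability_change" if changed else "feed_boundary"
            events.append({"t": state.t, "trigger": trigger, "mu": sol.mu_opt,
                           "added": sorted(diff["added"]),
                           "removed": sorted(diff["removed"])})
        rec.add(state, sol)
    return rec.build(events, error)


def simulate_batch_inertia(model: MEModel, init: BatchState,
                           p_init: Mapping[str, float],
                           config: SimulationConfig) -> TimeCourse:
    """Batch simulation under protein-inertia constraints.

    The inertia optimization runs at every step with p0 set to the
    current complex concentrations; afterwards p advances by the realized
    delta*dt (the optimization itself anticipates over the horizon H,
    which is independent of the step size).
    """
    for c in model.complexes:
        if c.id not in p_init:
            raise ModelError(f"p_init missing complex {c.id!r}")
    state = BatchState(t=float(init.t), c=dict(init.c), X=float(init.X))
    p = {cid: float(val) for cid, val in p_init.items()}
    rec = _Recorder(model, "inertia")
    events: list[dict] = []
    error: str | None = None

    avail = state.availability(config.feeds, config.depletion_threshold)
    trigger = "initial"
    steps = 0
    while True:
        sol = maximize_growth_inertia(
            model, InertiaState(p, config.horizon), config.solver_tol,
            _exchange_overrides(model, avail, config))
        if not sol.ok:
            error = f"solver status {sol.status} at t={state.t}"
            rec.add(state, GrowthSolution(0.0, {}, sol.status), p)
            break
        events.append({"t": state.t, "trigger": trigger, "mu": sol.mu_opt})
        rec.add(state, sol, p)
        if state.t >= config.t_batch - 1e-12:
            break
        steps += 1
        if steps > _MAX_STEPS:
            error = "step limit exceeded"
            break

        boundary = _next_boundary(config.feeds, state.t, config.t_batch)
        dt_cap = min(config.dt0, config.t_batch - state.t,
                     boundary - state.t)
        v_ex = _v_ex(model, sol)
        dt = min_time_step(state, v_ex, p, sol.delta, dt_cap, config.feeds)
        p = {cid: max(0.0, p[cid] + sol.delta[cid] * dt) for cid in p}
        state = step_update(state, v_ex, sol.mu_opt, dt, config.feeds)

        changed, _diff = detect_environment_change(
            avail, state, config.feeds, config.depletion_threshold)
        if changed:
            avail = state.availability(config.feeds,
                                       config.depletion_threshold)
            trigger = "availability_change"
        else:
            trigger = "step"
    return rec.build(events, error)
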