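"""Shared fixtures: toy models, canonical batch runs, and independent oracles."""

from __future__ import annotations

import numpy as np
import pytest

from mebatch import (SimulationConfig, initial_state, simulate_batch,
                     toy1, toy2, toy5)
from mebatch.memodel import evaluate_at_mu
from mebatch.solver import solve_lp


# ---------------------------------------------------------------------------
# independent oracles
# ---------------------------------------------------------------------------

def grid_scan_mu(model, tol: float = 1e-6, bound_overrides=None,
                 stages=(1e-2, 1e-4, 1e-6)) -> float | None:
    """Brute-force staged feasibility scan over a mu grid.

    Walks upward from 0 in progressively finer steps (down to ``tol``),
    keeping the last feasible mu.  Independent of the bisection code
    path: it only calls the fixed-mu LP feasibility oracle.
    """
    def feasible(mu: float) -> bool:
        status, _ = solve_lp(evaluate_at_mu(model, mu, bound_overrides))
        return status == "optimal"

    if not feasible(0.0):
        return None
    lo = 0.0
    for step in stages:
        mu = lo + step
        while mu <= model.mu_max + 1e-12 and feasible(mu):
            lo = mu
            mu += step
        if step <= tol:
            break
    return lo


@pytest.fixture(scope="session")
def scan_oracle():
    return grid_scan_mu


# ---------------------------------------------------------------------------
# toy models
# ---------------------------------------------------------------------------

@pytest.fixture(scope="session")
def toy1_fix():
    model, spec = toy1()
    return model, spec


@pytest.fixture(scope="session")
def toy2_fix():
    model, spec = toy2()
    return model, spec


@pytest.fixture(scope="session")
def toy5_fix():
    model, spec = toy5()
    return model, spec


# ---------------------------------------------------------------------------
# canonical batch runs (computed once per session)
# ---------------------------------------------------------------------------

@pytest.fixture(scope="session")
def toy2_run(toy2_fix):
    model, spec = toy2_fix
    cfg = SimulationConfig(dt0=0.1, t_batch=10.0)
    return simulate_batch(model, initial_state(spec), cfg), cfg


@pytest.fixture(scope="session")
def toy5_run(toy5_fix):
    model, spec = toy5_fix
    cfg = SimulationConfig(dt0=0.1, t_batch=10.0)
    return simulate_batch(model, initial_state(spec), cfg), cfg
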