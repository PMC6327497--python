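"""Growth-rate maximization over fixed-mu linear programs.

The growth-maximization problem (max mu s.t. S(mu)v=0, l(mu)<=v<=u(mu))
is quasi-convex in mu: the set of feasible growth rates is an interval
[0, mu*].  The global optimum is therefore found by bisection on the
feasibility of the fixed-mu LP.  Two formulations are supported:

- the base formulation, where enzyme amounts are implicit (dilution
  coupling rows synthesized by :func:`mebatch.memodel.evaluate_at_mu`);
- the protein-inertia formulation, where complex concentrations ``p``
  and their rates of change ``delta`` are explicit variables tied to the
  previous time step's concentrations ``p0`` over a planning horizon
  ``H``: v_form_i - mu*p_i = delta_i, sum_j v_j/keff_ij <= p_i, and
  p_i = p0_i + delta_i*H, with the complex mass-balance rows removed.

Double precision with a 1e-9 feasibility tolerance is used throughout;
desk-scale models are well-conditioned, unlike genome-scale ME
reconstructions which require quad-precision solvers.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
from scipy.optimize import linprog

from .memodel import (DomainError, LinearProblem, MEModel, ModelError,
                      evaluate_at_mu)

__all__ = [
    "GrowthSolution",
    "InertiaState",
    "solve_lp",
    "maximize_growth",
    "build_inertia_problem",
    "maximize_growth_inertia",
]

FEASIBILITY_TOL = 1e-9
DEFAULT_MU_TOL = 1e-6  # bisection to six decimal points


@dataclass
class GrowthSolution:
    """Optimal growth rate and a feasible flux vector at that rate."""

    mu_opt: float
    v: dict[str, float]
    status: str  # "optimal" or "infeasible-at-zero"
    p: dict[str, float] | None = None
    delta: dict[str, float] | None = None

    @property
    def ok(self) -> bool:
        return self.status == "optimal"


@dataclass
class InertiaState:
    """Previous-step complex concentrations and the planning horizon."""

    p0: Mapping[str, float]
    horizon: float = 2.0  # hours

    def __post_init__(self) -> None:
        if not self.horizon > 0:
            raise DomainError(f"horizon must be > 0, got {self.horizon}")
        for cid, val in self.p0.items():
            if val < 0:
                raise DomainError(f"p0[{cid!r}] must be >= 0, got {val}")


def solve_lp(
    problem: LinearProblem,
    objective: Mapping[str, float] | None = None,
    sense: str = "min",
) -> tuple[str, np.ndarray | None]:
    """Solve an LP with the HiGHS backend.

    ``objective`` maps variable ids to cost coefficients (missing ids get
    0); ``None`` means a pure feasibility solve.  Returns a status string
    ("optimal", "infeasible", or "unbounded") and the optimal point.
    """
    n = len(problem.var_ids)
    c = np.zeros(n)
    if objective:
        idx = {v: j for j, v in enumerate(problem.var_ids)}
        for var, coef in objective.items():
            c[idx[var]] = coef
    if sense == "max":
        c = -c
    elif sense != "min":
        raise ValueError(f"sense must be 'min' or 'max', got {sense!r}")

    res = linprog(
        c,
        A_eq=problem.A_eq if problem.A_eq is not None and problem.A_eq.size else None,
        b_eq=problem.b_eq if problem.A_eq is not None and problem.A_eq.size else None,
        A_ub=problem.A_ub, b_ub=problem.b_ub,
        bounds=list(zip(problem.lb, problem.ub)),
        method="highs",
    )
    if res.status == 0:
        return "optimal", res.x
    if res.status == 3:
        return "unbounded", None
    return "infeasible", None


def check_solution(problem: LinearProblem, x: np.ndarray,
                   tol: float = 1e-8) -> float:
    """Max constraint violation of x against the problem (independent check)."""
    viol = 0.0
    if problem.A_eq is not None and problem.A_eq.size:
        viol = max(viol, float(np.max(np.abs(problem.A_eq @ x - problem.b_eq))))
    if problem.A_ub is not None and problem.A_ub.size:
        viol = max(viol, float(np.max(problem.A_ub @ x - problem.b_ub, initial=0.0)))
    viol = max(viol, float(np.max(problem.lb - x, initial=0.0)))
    viol = max(viol, float(np.max(x - problem.ub, initial=0.0)))
    return viol


def _bisect_mu(feasible, mu_max: float, tol: float):
    """Bisect sup{mu in [0, mu_max] : feasible(mu)}.

    ``feasible(mu)`` returns (is_feasible, point).  Returns
    (mu_opt, point) or (None, None) when infeasible at mu=0.
    """
    ok, x = feasible(0.0)
    if not ok:
        return None, None
    lo, x_lo = 0.0, x
    ok, x = feasible(mu_max)
    if ok:
        return mu_max, x
    hi = mu_max
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        ok, x = feasible(mid)
        if ok:
            lo, x_lo = mid, x
        else:
            hi = mid
    return lo, x_lo


def _parsimonious(problem: LinearProblem, objective: dict[str, float]):
    """Re-solve at fixed mu minimizing a secondary objective.

    Keeps the returned flux vector a deterministic vertex (e.g. zero
    uptake of substrates that carry a higher enzyme cost).  Falls back to
    a plain feasibility point if the secondary LP fails.
    """
    status, x = solve_lp(problem, objective, sense="min")
    if status == "optimal":
        return x
    status, x = solve_lp(problem)
    return x if status == "optimal" else None


def maximize_growth(
    model: MEModel,
    tol: float = DEFAULT_MU_TOL,
    bound_overrides: Mapping[str, tuple[float | None, float | None]] | None = None,
) -> GrowthSolution:
    """Maximize growth rate of the base formulation by bisection.

    Returns mu within ``tol`` of the supremum of feasible growth rates.
    A model feasible at mu=0 but at no mu>0 yields status "optimal" with
    mu_opt=0 (a consistent non-growing state); "infeasible-at-zero" is
    reserved for truly inconsistent constraints.
    """
    if not tol > 0:
        raise DomainError(f"tol must be > 0, got {tol}")

    def feas(mu: float):
        prob = evaluate_at_mu(model, mu, bound_overrides)
        status, x = solve_lp(prob)
        return status == "optimal", x

    mu_opt, x = _bisect_mu(feas, model.mu_max, tol)
    if mu_opt is None:
        return GrowthSolution(0.0, {}, "infeasible-at-zero")

    prob = evaluate_at_mu(model, mu_opt, bound_overrides)
    obj = {c.formation_rxn: 1.0 for c in model.complexes}
    x2 = _parsimonious(prob, obj) if obj else None
    if x2 is not None:
        x = x2
    v = dict(zip(prob.var_ids, map(float, x)))
    return GrowthSolution(mu_opt, v, "optimal")


def build_inertia_problem(
    model: MEModel,
    state: InertiaState,
    mu: float,
    bound_overrides: Mapping[str, tuple[float | None, float | None]] | None = None,
) -> LinearProblem:
    """Fixed-mu LP of the protein-inertia formulation.

    Variables are (v, p, delta).  The synthesized complex dilution rows of
    the base formulation are replaced by

        v_form_i - mu*p_i = delta_i
        p_i - delta_i*H   = p0_i
        sum_{j in CAT(i)} v_j / keff_ij <= p_i

    with v_form_i >= 0 and p_i >= 0, while all ordinary metabolite mass
    balances and the mu-dependent flux bounds are retained.
    """
    for c in model.complexes:
        if c.id not in state.p0:
            raise ModelError(f"missing p0 entry for complex {c.id!r}")
    if not state.horizon > 0:
        raise DomainError("horizon must be > 0")

    base = evaluate_at_mu(model, mu, bound_overrides)
    n = len(model.reactions)
    k = len(model.complexes)
    n_met = len(model.metabolites)
    rxn_index = {r: j for j, r in enumerate(model.reactions)}

    nv = n + 2 * k  # v, p, delta
    var_ids = (list(model.reactions)
               + [f"p:{c.id}" for c in model.complexes]
               + [f"delta:{c.id}" for c in model.complexes])

    # equalities: metabolite balances (complex rows dropped) + 2k inertia rows
    A_eq = np.zeros((n_met + 2 * k, nv))
    b_eq = np.zeros(n_met + 2 * k)
    A_eq[:n_met, :n] = base.A_eq[:n_met, :]
    row_ids = list(base.row_ids[:n_met])
    for i, c in enumerate(model.complexes):
        r1 = n_met + i          # v_form - mu*p - delta = 0
        A_eq[r1, rxn_index[c.formation_rxn]] = 1.0
        A_eq[r1, n + i] = -mu
        A_eq[r1, n + k + i] = -1.0
        row_ids.append(f"inertia:{c.id}")
        r2 = n_met + k + i      # p - delta*H = p0
        A_eq[r2, n + i] = 1.0
        A_eq[r2, n + k + i] = -state.horizon
        b_eq[r2] = float(state.p0[c.id])
        row_ids.append(f"horizon:{c.id}")

    # inequalities: enzyme capacity per complex (+ optional proteome cap)
    n_ub = k + (1 if model.enzyme_budget is not None else 0)
    A_ub = np.zeros((n_ub, nv))
    b_ub = np.zeros(n_ub)
    ub_row_ids = []
    for i, c in enumerate(model.complexes):
        for rxn, keff in c.keff.items():
            A_ub[i, rxn_index[rxn]] = 1.0 / keff
        A_ub[i, n + i] = -1.0
        ub_row_ids.append(f"capacity:{c.id}")
    if model.enzyme_budget is not None:
        A_ub[k, n:n + k] = 1.0   # sum_i p_i <= enzyme budget
        b_ub[k] = model.enzyme_budget
        ub_row_ids.append("enzyme_budget")

    lb = np.concatenate([base.lb, np.zeros(k), np.full(k, -np.inf)])
    ub = np.concatenate([base.ub, np.full(2 * k, np.inf)])
    for c in model.complexes:
        j = rxn_index[c.formation_rxn]
        lb[j] = max(lb[j], 0.0)  # v_form >= 0 (no active degradation)

    return LinearProblem(A_eq=A_eq, b_eq=b_eq, A_ub=A_ub, b_ub=b_ub,
                         lb=lb, ub=ub, var_ids=var_ids, row_ids=row_ids,
                         ub_row_ids=ub_row_ids)


def maximize_growth_inertia(
    model: MEModel,
    state: InertiaState,
    tol: float = DEFAULT_MU_TOL,
    bound_overrides: Mapping[str, tuple[float | None, float | None]] | None = None,
) -> GrowthSolution:
    """Bisection over the protein-inertia formulation.

    The solution carries the complex concentrations ``p`` and their rates
    of change ``delta``; delta_i < 0 arises only when dilution exceeds
    complex formation (mu*p_i > v_form_i) since formation flux is
    non-negative.
    """
    if not tol > 0:
        raise DomainError(f"tol must be > 0, got {tol}")

    def feas(mu: float):
        prob = build_inertia_problem(model, state, mu, bound_overrides)
        status, x = solve_lp(prob)
        return status == "optimal", x

    mu_opt, x = _bisect_mu(feas, model.mu_max, tol)
    if mu_opt is None:
        return GrowthSolution(0.0, {}, "infeasible-at-zero")

    prob = build_inertia_problem(model, state, mu_opt, bound_overrides)
    obj = {f"p:{c.id}": 1.0 for c in model.complexes}
    x2 = _parsimonious(prob, obj) if obj else None
    if x2 is not None:
        x = x2

    n = len(model.reactions)
    k = len(model.complexes)
    v = dict(zip(model.reactions, map(float, x[:n])))
    p = {c.id: float(x[n + i]) for i, c in enumerate(model.complexes)}
    delta = {c.id: float(x[n + k + i]) for i, c in enumerate(model.complexes)}
    return GrowthSolution(mu_opt, v, "optimal", p=p, delta=delta)
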