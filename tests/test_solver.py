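"""Growth maximization by bisection, base and protein-inertia formulations."""

import numpy as np
import pytest

from mebatch import (InertiaState, build_inertia_problem, maximize_growth,
                     maximize_growth_inertia, make_toy_model, solve_lp, toy1,
                     toy_inertia_mu_star, toy_mu_star)
from mebatch.fixtures import SubstrateSpec, ToySpec
from mebatch.memodel import DomainError, LinearProblem, ModelError, \
    evaluate_at_mu
from mebatch.solver import check_solution

TOL = 1e-6


class TestSolveLP:
    def test_simple_max(self):
        prob = LinearProblem(A_eq=np.zeros((0, 1)), b_eq=np.zeros(0),
                             A_ub=None, b_ub=None, lb=np.array([0.0]),
                             ub=np.array([3.0]), var_ids=["x"], row_ids=[])
        status, x = solve_lp(prob, {"x": 1.0}, sense="max")
        assert status == "optimal" and x[0] == pytest.approx(3.0)

    def test_infeasible_box(self):
        prob = LinearProblem(A_eq=np.zeros((0, 1)), b_eq=np.zeros(0),
                             A_ub=np.array([[-1.0], [1.0]]),
                             b_ub=np.array([-1.0, 0.0]),  # x >= 1 and x <= 0
                             lb=np.array([-10.0]), ub=np.array([10.0]),
                             var_ids=["x"], row_ids=[])
        status, _ = solve_lp(prob)
        assert status == "infeasible"

    def test_unbounded_distinct_from_infeasible(self):
        prob = LinearProblem(A_eq=np.zeros((0, 1)), b_eq=np.zeros(0),
                             A_ub=None, b_ub=None, lb=np.array([0.0]),
                             ub=np.array([np.inf]), var_ids=["x"], row_ids=[])
        status, _ = solve_lp(prob, {"x": 1.0}, sense="max")
        assert status == "unbounded"

    def test_toy1_feasible_at_analytic_mu(self, toy1_fix):
        model, _ = toy1_fix
        status, _ = solve_lp(evaluate_at_mu(model, 1.0 / 110.0 - 1e-9))
        assert status == "optimal"


class TestMaximizeGrowth:
    def test_toy1_closed_form(self, toy1_fix):
        model, spec = toy1_fix
        sol = maximize_growth(model, tol=TOL)
        assert sol.status == "optimal"
        assert sol.mu_opt == pytest.approx(1.0 / 110.0, abs=1e-6)
        assert sol.mu_opt == pytest.approx(toy_mu_star(spec), abs=1e-6)

    def test_toy1_doubled_budget(self):
        model, spec = toy1(e_max=0.02)
        sol = maximize_growth(model, tol=TOL)
        assert sol.mu_opt == pytest.approx(1.0 / 60.0, abs=1e-6)

    def test_no_substrate_means_no_growth(self, toy1_fix):
        """With all uptake closed the only consistent state is mu = 0."""
        model, _ = toy1_fix
        sol = maximize_growth(model, bound_overrides={"EX_glc": (0.0, 0.0)})
        assert sol.status == "optimal" and sol.mu_opt == pytest.approx(0.0, abs=TOL)

    def test_solution_feasibility_recheck(self, toy1_fix):
        """Returned flux vector satisfies the fixed-mu LP independently."""
        model, _ = toy1_fix
        sol = maximize_growth(model, tol=TOL)
        prob = evaluate_at_mu(model, sol.mu_opt)
        x = np.array([sol.v[r] for r in prob.var_ids])
        assert check_solution(prob, x) <= 1e-8

    @pytest.mark.parametrize("alpha", [1.0, 1.5, 4.0])
    def test_keff_monotonicity(self, toy1_fix, alpha):
        """Scaling every keff up never decreases the optimal growth rate."""
        model, _ = toy1_fix
        base = maximize_growth(model, tol=TOL).mu_opt
        scaled = model.with_keff_factors(
            {c: alpha for c in model.couplings()})
        assert maximize_growth(scaled, tol=TOL).mu_opt >= base - TOL

    def test_oracle_equivalence_canonical(self, toy1_fix, toy2_fix,
                                          scan_oracle):
        """Bisection optimum equals the brute-force grid-scan supremum."""
        for model, _ in (toy1_fix, toy2_fix):
            mu_scan = scan_oracle(model, tol=TOL)
            mu_bis = maximize_growth(model, tol=TOL).mu_opt
            assert mu_bis == pytest.approx(mu_scan, abs=2 * TOL)

    def test_oracle_equivalence_random_reparameterizations(self, scan_oracle):
        """Bisection equals grid scan and closed form on random re-scalings."""
        rng = np.random.default_rng(42)
        for _ in range(5):
            f = np.exp(rng.uniform(np.log(0.5), np.log(2.0), size=4))
            spec = ToySpec(
                substrates=(SubstrateSpec("glc", 10.0 * f[0]),),
                biomass_cost=10.0 * f[1], enzyme_cost=100.0 * f[2],
                e_max=0.01 * f[3], initial_conc={"glc": 10.0})
            model = make_toy_model(spec)
            mu_bis = maximize_growth(model, tol=TOL).mu_opt
            assert mu_bis == pytest.approx(scan_oracle(model, tol=TOL),
                                           abs=2 * TOL)
            assert mu_bis == pytest.approx(toy_mu_star(spec), abs=2 * TOL)


class TestInertia:
    def test_problem_shape_and_feasibility_boundary(self, toy1_fix):
        """p0=0, H=20: feasible at mu=0.004, infeasible at mu=0.005."""
        model, _ = toy1_fix
        state = InertiaState({"E_glc": 0.0}, horizon=20.0)
        assert solve_lp(build_inertia_problem(model, state, 0.004))[0] == \
            "optimal"
        assert solve_lp(build_inertia_problem(model, state, 0.005))[0] == \
            "infeasible"

    def test_missing_p0_and_bad_horizon(self, toy1_fix):
        model, _ = toy1_fix
        with pytest.raises(ModelError):
            build_inertia_problem(model, InertiaState({}, 2.0), 0.001)
        with pytest.raises(DomainError):
            InertiaState({"E_glc": 0.0}, horizon=0.0)
        with pytest.raises(DomainError):
            InertiaState({"E_glc": -0.1}, horizon=2.0)

    @pytest.mark.parametrize("H", [20.0, 50.0, 1e6])
    def test_closed_form_from_empty_proteome(self, toy1_fix, H):
        """mu*(H) = (0.01 - 0.1/H)/1.1 starting from p0 = 0."""
        model, spec = toy1_fix
        sol = maximize_growth_inertia(model, InertiaState({"E_glc": 0.0}, H),
                                      tol=TOL)
        assert sol.mu_opt == pytest.approx((0.01 - 0.1 / H) / 1.1, abs=1e-5)
        assert sol.mu_opt == pytest.approx(
            toy_inertia_mu_star(spec, H, 0.0), abs=1e-5)

    def test_short_horizon_gives_zero_growth(self, toy1_fix):
        """From p0=0 with H=2 the closed form is negative: growth impossible."""
        model, _ = toy1_fix
        sol = maximize_growth_inertia(model, InertiaState({"E_glc": 0.0}, 2.0),
                                      tol=TOL)
        assert sol.status == "optimal"
        assert sol.mu_opt == pytest.approx(0.0, abs=TOL)

    def test_transient_overshoot_from_steady_state(self, toy1_fix):
        """At p0 = p* with a short horizon the optimum exceeds the base rate.

        Shutting formation off (v_form = 0, delta < 0) lets the cell
        spend the saved enzyme-synthesis substrate on growth, so the
        planned rate transiently exceeds the sustainable 1/110; the
        closed form is the overshoot branch of the analytic oracle.
        """
        model, spec = toy1_fix
        sol = maximize_growth_inertia(model,
                                      InertiaState({"E_glc": 0.01}, 2.0),
                                      tol=TOL)
        oracle = toy_inertia_mu_star(spec, 2.0, 0.01)
        assert oracle > 1.0 / 110.0
        assert sol.mu_opt == pytest.approx(oracle, abs=1e-5)
        assert sol.delta["E_glc"] < 0  # dilution exceeds formation

    def test_horizon_monotonicity(self, toy1_fix):
        model, _ = toy1_fix
        mus = [maximize_growth_inertia(
            model, InertiaState({"E_glc": 0.0}, H), tol=TOL).mu_opt
            for H in (15.0, 30.0, 60.0, 120.0)]
        assert all(b >= a - TOL for a, b in zip(mus, mus[1:]))

    def test_infinite_horizon_limit_matches_base(self, toy1_fix):
        """As H -> inf the inertia optimum converges to the base optimum."""
        model, _ = toy1_fix
        base = maximize_growth(model, tol=TOL).mu_opt
        for p0 in (0.0, 0.005, 0.01):  # any p0 within the proteome budget
            sol = maximize_growth_inertia(
                model, InertiaState({"E_glc": p0}, 1e6), tol=TOL)
            assert sol.mu_opt == pytest.approx(base, abs=1e-5)

    def test_solution_invariants(self, toy1_fix):
        """p >= 0, v_form >= 0, and v_form - mu*p = delta per complex."""
        model, _ = toy1_fix
        state = InertiaState({"E_glc": 0.002}, 30.0)
        sol = maximize_growth_inertia(model, state, tol=TOL)
        p, d = sol.p["E_glc"], sol.delta["E_glc"]
        vform = sol.v["FORM_E_glc"]
        assert p >= -1e-9 and vform >= -1e-9
        assert vform - sol.mu_opt * p == pytest.approx(d, abs=1e-8)
        assert p == pytest.approx(0.002 + d * 30.0, abs=1e-8)
        prob = build_inertia_problem(model, state, sol.mu_opt)
        x = np.array([sol.v[v] if v in sol.v
                      else (sol.p[v[2:]] if v.startswith("p:")
                            else sol.delta[v[6:]])
                      for v in prob.var_ids])
        assert check_solution(prob, x) <= 1e-8
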