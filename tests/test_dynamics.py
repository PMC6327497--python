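"""Batch simulation: event-driven loop, variable steps, conservation."""

import numpy as np
import pandas as pd
import pytest

from mebatch import (BatchState, SimulationConfig, TimeCourse,
                     detect_environment_change, initial_state, min_time_step,
                     simulate_batch, simulate_batch_inertia, step_update)
from mebatch.dynamics import Feed


def carbon_defect(tc, spec):
    """Carbon bookkeeping gap of a toy run (independent audit).

    All substrate carbon passes through the internal pool m, which is
    split between growth (biomass_cost per unit growth flux) and enzyme
    formation (enzyme_cost per complex).  The uptake and formation sides
    integrate exactly under the forward-Euler update, so the residual
    isolates the O(dt) mismatch between the exponential biomass update
    and the left-Riemann growth integral.
    """
    t = tc.time
    dt = np.diff(t)
    X = tc.biomass.to_numpy()[:-1]
    mu = tc.mu.to_numpy()[:-1]
    yields = {s.id: s.m_yield for s in spec.substrates}
    consumed_m = 0.0
    for met, y in yields.items():
        dc = tc.concentrations[met].iloc[0] - tc.concentrations[met].iloc[-1]
        consumed_m += y * dc
    # m released by re-consumed byproducts is already counted via yields
    # (byproducts are SubstrateSpec entries too in the toys)
    form_cols = [c for c in tc.fluxes.columns if c.startswith("FORM_")]
    v_form = tc.fluxes[form_cols].to_numpy()[:-1].sum(axis=1)
    formed = float((v_form * X * dt).sum())
    grown = spec.biomass_cost * (tc.biomass.iloc[-1] - tc.biomass.iloc[0])
    # secreted byproduct mass that was not re-consumed is not m-carbon
    return abs(consumed_m - grown - spec.enzyme_cost * formed)


class TestElementaryOps:
    def test_step_update_arithmetic(self):
        state = BatchState(0.0, {"glc": 10.0}, 0.1)
        new = step_update(state, {"glc": -0.1}, 1.0 / 110.0, 0.1)
        assert new.c["glc"] == pytest.approx(9.999)
        assert new.X == pytest.approx(0.1 * np.exp(0.1 / 110.0))
        assert new.t == pytest.approx(0.1)

    def test_step_update_identity_cases(self):
        state = BatchState(2.0, {"glc": 1.0, "ac": 0.5}, 0.2)
        no_flux = step_update(state, {}, 0.3, 0.5)
        assert no_flux.c == state.c
        assert no_flux.X == pytest.approx(0.2 * np.exp(0.15))
        frozen = step_update(state, {}, 0.0, 0.5)
        assert frozen.c == state.c and frozen.X == state.X
        assert frozen.t == pytest.approx(2.5)

    def test_step_update_guards_missed_min_step(self):
        state = BatchState(0.0, {"glc": 0.001}, 1.0)
        with pytest.raises(RuntimeError):
            step_update(state, {"glc": -1.0}, 0.0, 1.0)

    def test_feed_contribution(self):
        state = BatchState(1.0, {"glc": 0.0}, 0.1)
        feed = Feed(0.5, 2.0, "glc", rate=0.2)
        new = step_update(state, {}, 0.0, 0.5, feeds=[feed])
        assert new.c["glc"] == pytest.approx(0.1)

    @pytest.mark.parametrize(
        "c, v, X, dt0, expected",
        [
            (0.004, -0.1, 0.2, 0.5, 0.2),    # 0.004/(0.1*0.2)
            (1.0, -0.1, 0.1, 0.5, 0.5),      # no depletion threatened
            (0.05, -1.0, 1.0, 0.5, 0.05),
        ],
    )
    def test_min_time_step_metabolite_term(self, c, v, X, dt0, expected):
        state = BatchState(0.0, {"a": c}, X)
        assert min_time_step(state, {"a": v}, None, None, dt0) == \
            pytest.approx(expected)

    def test_min_time_step_protein_term(self):
        state = BatchState(0.0, {}, 0.1)
        dt = min_time_step(state, {}, {"E": 0.001}, {"E": -0.01}, 0.5)
        assert dt == pytest.approx(0.1)
        # protein term skipped when p/delta absent
        assert min_time_step(state, {}, None, None, 0.5) == 0.5

    def test_detect_change_cases(self):
        st = BatchState(0.0, {"glc": 0.0, "ac": 0.5}, 0.1)
        changed, diff = detect_environment_change({"glc"}, st)
        assert changed and diff == {"added": {"ac"}, "removed": {"glc"}}
        st2 = BatchState(0.0, {"glc": 3.2}, 0.1)
        assert not detect_environment_change({"glc"}, st2)[0]
        # secretion crossing the availability threshold
        st3 = BatchState(0.0, {"glc": 3.2, "ac": 1e-4}, 0.1)
        changed, diff = detect_environment_change({"glc"}, st3)
        assert changed and diff["added"] == {"ac"}


class TestEventDrivenRuns:
    def test_toy1_single_solve(self, toy1_fix):
        """No availability change in the batch: exactly one optimization."""
        model, spec = toy1_fix
        tc = simulate_batch(model, initial_state(spec), SimulationConfig())
        assert tc.error is None
        assert len(tc.events) == 1 and tc.events[0]["trigger"] == "initial"
        assert np.allclose(tc.mu, 1.0 / 110.0, atol=1e-5)

    def test_toy2_diauxie(self, toy2_run):
        """Two solves; the cheap-enzyme substrate is consumed first, alone."""
        tc, _ = toy2_run
        assert tc.error is None
        assert len(tc.events) == 2
        t_dep = tc.events[1]["t"]
        assert tc.events[1]["removed"] == ["glc_a"]
        pre = tc.fluxes.loc[tc.fluxes.index < t_dep]
        assert np.all(np.abs(pre["UP_glc_b"]) < 1e-9)
        assert np.all(np.abs(pre["EX_glc_b"]) < 1e-9)
        # after depletion the slower substrate carries growth
        post = tc.fluxes.loc[tc.fluxes.index > t_dep]
        assert post["UP_glc_b"].max() > 1e-4

    def test_toy5_phase_ordering(self, toy5_run):
        """Single substrate -> mixed utilization -> byproduct reuse."""
        tc, _ = toy5_run
        assert tc.error is None
        ev = tc.events
        assert len(ev) == 1 + sum(e["trigger"] == "availability_change"
                                  for e in ev)
        f = tc.fluxes
        t_s1_gone = next(e["t"] for e in ev if "s1" in e.get("removed", []))
        phase1 = f.loc[f.index < t_s1_gone]
        assert np.all(phase1[["UP_s2", "UP_s3", "UP_s4", "UP_s5",
                              "UP_ac"]].to_numpy() < 1e-9)
        assert phase1["UP_s1"].min() > 1e-3
        # byproduct secreted during phase 1, became available
        assert any("ac" in e.get("added", []) for e in ev)
        mixed = f.loc[(f.index > t_s1_gone + 0.05)].iloc[0]
        assert sum(mixed[f"UP_s{i}"] > 1e-6 for i in (2, 3, 4, 5)) >= 2
        # byproduct is consumed only in the final phase
        t_ac = f.index[f["UP_ac"] > 1e-6]
        assert len(t_ac) and t_ac[0] > t_s1_gone
        ac = tc.concentrations["ac"]
        assert ac.iloc[-1] < ac.max() - 1e-4  # net reconsumption happened

    def test_event_driven_equivalence_under_refinement(self, toy1_fix):
        """Without availability changes, halving dt leaves mu identical and
        changes concentrations only by integration error."""
        model, spec = toy1_fix
        init = initial_state(spec)
        cfg1 = SimulationConfig(dt0=0.2, t_batch=4.0)
        cfg2 = SimulationConfig(dt0=0.1, t_batch=4.0)
        a = simulate_batch(model, init, cfg1)
        b = simulate_batch(model, init, cfg2)
        assert len(a.events) == len(b.events) == 1
        assert a.mu.iloc[0] == b.mu.iloc[0]
        ca = a.concentrations["glc"].iloc[-1]
        cb = b.concentrations["glc"].iloc[-1]
        assert ca == pytest.approx(cb, abs=5e-4)

    def test_feed_window_triggers_resolve(self, toy2_fix):
        model, spec = toy2_fix
        init = initial_state(spec)
        feed = Feed(1.0, 2.0, "glc_a", rate=0.05)
        cfg = SimulationConfig(dt0=0.1, t_batch=3.0, feeds=(feed,))
        tc = simulate_batch(model, init, cfg)
        assert tc.error is None
        kinds = {e["trigger"] for e in tc.events}
        assert "feed_boundary" in kinds or "availability_change" in kinds
        assert any(abs(e["t"] - 1.0) < 1e-9 for e in tc.events[1:])


class TestConservationAndSteps:
    def test_carbon_defect_halves_with_dt(self, toy2_fix):
        """The integration defect is O(dt): halving dt halves it."""
        model, spec = toy2_fix
        init = initial_state(spec)
        d = {}
        for dt0 in (0.1, 0.05):
            tc = simulate_batch(model, init,
                                SimulationConfig(dt0=dt0, t_batch=10.0))
            d[dt0] = carbon_defect(tc, spec)
        assert d[0.1] > 0
        assert 1.8 <= d[0.1] / d[0.05] <= 2.2

    @pytest.mark.parametrize("dt0", [0.3, 0.7, 1.3])
    def test_nonnegativity_adversarial_steps(self, toy2_fix, dt0):
        """Huge requested steps never push any concentration negative."""
        model, spec = toy2_fix
        tc = simulate_batch(model, initial_state(spec),
                            SimulationConfig(dt0=dt0, t_batch=10.0))
        assert tc.error is None
        assert tc.concentrations.to_numpy().min() >= -1e-9

    def test_shortened_step_lands_on_zero(self, toy2_fix):
        """Whenever dt < dt0, the limiting species ends the step at 0."""
        model, spec = toy2_fix
        cfg = SimulationConfig(dt0=0.5, t_batch=10.0)
        tc = simulate_batch(model, initial_state(spec), cfg)
        t = tc.time
        dts = np.diff(t)
        shortened = [k for k, dt in enumerate(dts)
                     if dt < cfg.dt0 - 1e-9
                     and abs(t[k + 1] - cfg.t_batch) > 1e-9]
        assert shortened, "expected at least one MinTimeStep-shortened step"
        for k in shortened:
            assert tc.concentrations.iloc[k + 1].min() <= 1e-9


class TestInertiaRuns:
    def test_fixed_point_matches_base(self, toy1_fix):
        """Starting at the steady-state proteome with a long horizon, the
        inertia trajectories coincide with the event-driven ones."""
        model, spec = toy1_fix
        init = initial_state(spec)
        cfg = SimulationConfig(dt0=0.1, t_batch=2.0, horizon=1e6)
        base = simulate_batch(model, init, cfg)
        inert = simulate_batch_inertia(model, init, {"E_glc": 0.01}, cfg)
        assert inert.error is None
        assert np.allclose(base.mu, inert.mu, rtol=1e-6, atol=1e-12)
        assert np.allclose(base.biomass, inert.biomass, rtol=1e-6)
        assert np.allclose(base.concentrations["glc"],
                           inert.concentrations["glc"], rtol=1e-6)
        assert np.abs(np.array([sol for sol in inert.proteome["E_glc"]])
                      - 0.01).max() < 1e-6

    def test_short_horizon_empty_proteome_no_growth(self, toy1_fix):
        """p0=0 with H=2: no growth state is reachable within the horizon."""
        model, spec = toy1_fix
        cfg = SimulationConfig(dt0=0.1, t_batch=1.0, horizon=2.0)
        tc = simulate_batch_inertia(model, initial_state(spec),
                                    {"E_glc": 0.0}, cfg)
        assert tc.error is None
        assert tc.mu.max() == pytest.approx(0.0, abs=1e-6)
        assert tc.proteome["E_glc"].max() == pytest.approx(0.0, abs=1e-9)

    def test_growth_rampup_from_partial_proteome(self, toy1_fix):
        """From a depleted proteome with a permissive horizon, the complex
        is rebuilt over time and growth accelerates monotonically."""
        model, spec = toy1_fix
        cfg = SimulationConfig(dt0=0.2, t_batch=4.0, horizon=50.0)
        tc = simulate_batch_inertia(model, initial_state(spec),
                                    {"E_glc": 0.001}, cfg)
        assert tc.error is None
        p = tc.proteome["E_glc"].to_numpy()
        assert p.min() >= -1e-9
        assert p[-1] > p[0]
        assert tc.concentrations.to_numpy().min() >= -1e-9
        # every solve is logged
        assert len(tc.events) == len(tc.time)

    def test_inertia_records_p_not_fluxes(self, toy1_fix):
        model, spec = toy1_fix
        cfg = SimulationConfig(dt0=0.5, t_batch=1.0, horizon=1e6)
        tc = simulate_batch_inertia(model, initial_state(spec),
                                    {"E_glc": 0.01}, cfg)
        assert tc.mode == "inertia"
        assert list(tc.proteome.columns) == ["E_glc"]


class TestTimeCourseIO:
    def test_csv_roundtrip(self, tmp_path, toy2_run):
        tc, _ = toy2_run
        tc.write_dir(str(tmp_path / "run"))
        back = TimeCourse.read_dir(str(tmp_path / "run"))
        assert np.allclose(back.time, tc.time)
        pd.testing.assert_frame_equal(back.concentrations, tc.concentrations,
                                      check_names=False)
        assert len(back.events) == len(tc.events)
        assert back.mode == tc.mode
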