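"""Deterministic toy ME models with pencil-and-paper optima.

These desk-scale fixtures stand in for a genome-scale reconstruction:
they are small enough that the optimal growth rate has a closed form,
which serves as an analytic oracle independent of the LP solver.

Toy architecture
----------------
A single internal currency metabolite ``m`` feeds both growth and enzyme
synthesis.  For each substrate ``s`` there is

- an exchange reaction  ``EX_s``:  s_ext ->        (flux < 0 is uptake),
- an uptake reaction    ``UP_s``:  s_ext -> y*m (+ byproducts), catalyzed
  by a dedicated complex ``E_s`` with rate constant keff_s, optionally
  capped by a transporter limit,
- a formation reaction  ``FORM_E_s``:  w_c * m -> E_s  (enzyme cost w_c,
  the complex production itself is synthesized by the model assembler).

Growth is a reaction ``GROWTH`` consuming ``g`` units of ``m`` whose flux
is pinned to mu through linear bounds (lower = upper = mu).  The model's
``enzyme_budget`` caps the total enzyme concentration at e_max:
sum_s v_UP_s / keff_s <= e_max in the base mode (enzyme amounts implied
by fluxes) and sum_s p_s <= e_max in the inertia mode, so keff
perturbations propagate into the capacity constraint.

Closed forms (single substrate, keff k, budget E, biomass cost g,
enzyme cost w):

- base optimum (enzyme implicitly diluted at rate mu):
      mu* = k*E / (g + w*E)
  TOY1 (k=10, E=0.01, g=10, w=100):  mu* = 0.1/11 = 1/110.
- inertia optimum for previous concentration p0 and horizon H is the
  larger of two vertices of the fixed-mu feasibility region:
    sustained branch (p = E, capacity saturated):
      mu_s = (k*E - w*(E - p0)/H) / (g + w*E)
    overshoot branch (v_form = 0, the complex dilutes; only pays off for
    p0 > 0):  g*mu*(1 + mu*H) = k*p0  =>
      mu_o = (-1 + sqrt(1 + 4*H*k*p0/g)) / (2*H)
  and mu*(H, p0) = max(0, mu_s, mu_o).
  TOY1 with p0=0:  mu*(H) = (k*E - w*E/H)/(g + w*E) = (0.01 - 0.1/H)/1.1.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .memodel import (EnzymeComplex, MEModel, Metabolite, MuExpression,
                      ModelError, Protein, StoichEntry)

__all__ = [
    "SubstrateSpec",
    "ToySpec",
    "make_toy_model",
    "toy1",
    "toy2",
    "toy5",
    "toy_mu_star",
    "toy_inertia_mu_star",
    "synth_measurements",
]


@dataclass(frozen=True)
class SubstrateSpec:
    """One consumable carbon source of a toy model."""

    id: str
    keff: float                      # 1/h, flux per unit enzyme
    uptake_cap: float | None = None  # transporter limit on UP flux (mmol/gDW/h)
    m_yield: float = 1.0             # units of m per unit substrate taken up
    secretes: dict[str, float] = field(default_factory=dict)
    # extracellular byproducts co-produced per unit uptake flux


@dataclass(frozen=True)
class ToySpec:
    substrates: tuple[SubstrateSpec, ...]
    biomass_cost: float = 10.0   # mmol m per unit growth flux (g)
    enzyme_cost: float = 100.0   # mmol m per mmol complex (w_c)
    e_max: float = 0.01          # proteome budget, mmol/gDW
    initial_conc: dict[str, float] = field(default_factory=dict)  # mmol/L
    x0: float = 0.1              # gDW/L
    mu_max: float = 2.0

    def __post_init__(self) -> None:
        if not (self.biomass_cost > 0 and self.enzyme_cost > 0
                and self.e_max > 0):
            raise ModelError("toy costs and e_max must be > 0")
        for s in self.substrates:
            if not s.keff > 0:
                raise ModelError(f"substrate {s.id}: keff must be > 0")


def make_toy_model(spec: ToySpec) -> MEModel:
    """Assemble a valid :class:`MEModel` from a :class:`ToySpec`."""
    if not spec.substrates:
        raise ModelError("toy spec needs at least one substrate")

    mets = [Metabolite("m")]
    reactions: list[str] = []
    stoich: list[StoichEntry] = []
    bounds: dict[str, tuple[MuExpression, MuExpression]] = {}
    complexes: list[EnzymeComplex] = []
    proteins: list[Protein] = []
    exchanges: dict[str, str] = {}

    ext_ids = {s.id for s in spec.substrates}
    for s in spec.substrates:
        ext_ids.update(s.secretes)
    for i, ext in enumerate(sorted(ext_ids)):
        mets.append(Metabolite(ext, extracellular=True))
        ex = f"EX_{ext}"
        reactions.append(ex)
        stoich.append(StoichEntry(ext, ex, MuExpression.const(-1.0)))
        bounds[ex] = (MuExpression.const(-1000.0), MuExpression.const(1000.0))
        exchanges[ext] = ex

    for i, s in enumerate(spec.substrates):
        up, form, enz = f"UP_{s.id}", f"FORM_E_{s.id}", f"E_{s.id}"
        reactions += [up, form]
        stoich += [
            StoichEntry(s.id, up, MuExpression.const(-1.0)),
            StoichEntry("m", up, MuExpression.const(s.m_yield)),
        ]
        for prod, coef in sorted(s.secretes.items()):
            stoich.append(StoichEntry(prod, up, MuExpression.const(coef)))
        stoich.append(StoichEntry("m", form, MuExpression.const(-spec.enzyme_cost)))
        cap = s.uptake_cap if s.uptake_cap is not None else 1000.0
        bounds[up] = (MuExpression.const(0.0), MuExpression.const(cap))
        bounds[form] = (MuExpression.const(0.0), MuExpression.const(1000.0))
        weight = 30.0 + 10.0 * i  # kDa, distinct per enzyme
        complexes.append(EnzymeComplex(enz, form, weight, {up: s.keff}))
        proteins.append(Protein(enz, form, weight))

    reactions.append("GROWTH")
    stoich.append(StoichEntry("m", "GROWTH",
                              MuExpression.const(-spec.biomass_cost)))
    bounds["GROWTH"] = (MuExpression.linear(0.0, 1.0),
                        MuExpression.linear(0.0, 1.0))

    return MEModel(metabolites=mets, reactions=reactions,
                   stoichiometry=stoich, bounds=bounds, complexes=complexes,
                   proteins=proteins, exchanges=exchanges, mu_max=spec.mu_max,
                   enzyme_budget=spec.e_max)


# ---------------------------------------------------------------------------
# canonical fixtures
# ---------------------------------------------------------------------------

def toy1(keff: float = 10.0, e_max: float = 0.01, biomass_cost: float = 10.0,
         enzyme_cost: float = 100.0, c0: float = 10.0,
         x0: float = 0.1) -> tuple[MEModel, ToySpec]:
    """Single-substrate toy; mu* = keff*e_max/(biomass_cost+enzyme_cost*e_max).

    Defaults give mu* = 1/110; the substrate pool is large enough that it
    never depletes within a default 10-h batch.
    """
    spec = ToySpec(substrates=(SubstrateSpec("glc", keff),),
                   biomass_cost=biomass_cost, enzyme_cost=enzyme_cost,
                   e_max=e_max, initial_conc={"glc": c0}, x0=x0)
    return make_toy_model(spec), spec


def toy2(keff_a: float = 10.0, keff_b: float = 2.0,
         c0_a: float = 0.03, c0_b: float = 0.05,
         x0: float = 0.1) -> tuple[MEModel, ToySpec]:
    """Two substrates sharing one proteome budget.

    Substrate A (keff 10) is five-fold cheaper per unit flux than B
    (keff 2), so the optimum consumes A exclusively while available:
    a desk-scale diauxie.  c0_a is sized to deplete mid-batch
    (uptake ~ keff*e_max*X = 0.01 mmol/L/h => ~3 h).
    """
    spec = ToySpec(substrates=(SubstrateSpec("glc_a", keff_a),
                               SubstrateSpec("glc_b", keff_b)),
                   initial_conc={"glc_a": c0_a, "glc_b": c0_b}, x0=x0)
    return make_toy_model(spec), spec


def toy5(x0: float = 0.1) -> tuple[MEModel, ToySpec]:
    """Five staggered substrates plus a secreted, re-consumable byproduct.

    The preferred substrate s1 overflows part of its carbon to ``ac``
    (an acetate-like byproduct).  Transporter caps on s2..s5 force a
    mixed-utilization phase once s1 is gone, and ``ac`` (worst keff) is
    consumed last: a single -> mixed -> byproduct-reuse phase sequence.
    """
    spec = ToySpec(
        substrates=(
            SubstrateSpec("s1", 10.0, m_yield=0.8, secretes={"ac": 0.4}),
            SubstrateSpec("s2", 6.0, uptake_cap=0.01),
            SubstrateSpec("s3", 4.0, uptake_cap=0.01),
            SubstrateSpec("s4", 3.0, uptake_cap=0.01),
            SubstrateSpec("s5", 2.0, uptake_cap=0.01),
            SubstrateSpec("ac", 1.0),
        ),
        initial_conc={"s1": 0.03, "s2": 0.004, "s3": 0.004, "s4": 0.004,
                      "s5": 0.002, "ac": 0.0},
        x0=x0,
    )
    return make_toy_model(spec), spec


# ---------------------------------------------------------------------------
# analytic oracles (independent of the LP solver)
# ---------------------------------------------------------------------------

def toy_mu_star(spec: ToySpec, substrate: str | None = None) -> float:
    """Closed-form base optimum when growth runs on a single substrate.

    mu* = y*k*E / (g + w*E) with the whole budget on that substrate
    (valid when no transporter cap binds).
    """
    subs = {s.id: s for s in spec.substrates}
    if substrate is None:
        s = max(subs.values(), key=lambda s: s.m_yield * s.keff)
    else:
        s = subs[substrate]
    return (s.m_yield * s.keff * spec.e_max
            / (spec.biomass_cost + spec.enzyme_cost * spec.e_max))


def toy_inertia_mu_star(spec: ToySpec, horizon: float, p0: float,
                        substrate: str | None = None) -> float:
    """Closed-form inertia optimum for a single-substrate toy.

    Maximum of the sustained branch (capacity saturated at the budget)
    and the overshoot branch (formation shut off, the complex dilutes),
    clipped at zero; see the module docstring for the derivation.
    """
    subs = {s.id: s for s in spec.substrates}
    if substrate is None:
        (s,) = subs.values()
    else:
        s = subs[substrate]
    g, w, E, k, y = (spec.biomass_cost, spec.enzyme_cost, spec.e_max,
                     s.keff, s.m_yield)
    mu_sustained = (y * k * E - w * (E - p0) / horizon) / (g + w * E)
    mu_overshoot = (-1.0 + math.sqrt(1.0 + 4.0 * horizon * y * k * p0 / g)) \
        / (2.0 * horizon)
    return max(0.0, mu_sustained, mu_overshoot)


# ---------------------------------------------------------------------------
# synthetic measurements
# ---------------------------------------------------------------------------

def initial_state(spec: ToySpec):
    """Batch starting point (t=0) encoded in a :class:`ToySpec`."""
    from .dynamics import BatchState
    c = {s.id: 0.0 for s in spec.substrates}
    for s in spec.substrates:
        c.update({k: c.get(k, 0.0) for k in s.secretes})
    c.update(spec.initial_conc)
    return BatchState(t=0.0, c=c, X=spec.x0)


def synth_measurements(model: MEModel, config, init, sigma: float = 0.1,
                       lag: float = 0.0,
                       seed: int = 0) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate the model and emit noisy, lag-shifted "measured" tables.

    Emulates batch-culture measurements: extracellular concentration
    profiles plus log2 expression (protein mass fraction) profiles.  Each
    profile is shifted by ``lag`` hours (measured(t) = simulated(t-lag),
    edge-held), then i.i.d. Gaussian noise of standard deviation ``sigma``
    is added; concentrations are clamped at zero.  Reproducible under a
    fixed seed.

    Returns ``(concentrations, log2_expression)`` DataFrames indexed by
    time (h).
    """
    from .dynamics import simulate_batch
    from .validation import log2_expression

    if abs(lag) > 2.0:
        raise ValueError("lag must be within +/-2 h")
    if sigma < 0:
        raise ValueError("sigma must be >= 0")

    tc = simulate_batch(model, init, config)
    rng = np.random.default_rng(seed)

    def _shift(df: pd.DataFrame) -> pd.DataFrame:
        t = df.index.to_numpy(dtype=float)
        src = np.clip(t - lag, t[0], t[-1])
        out = {c: np.interp(src, t, df[c].to_numpy(dtype=float))
               for c in df.columns}
        return pd.DataFrame(out, index=df.index)

    conc = _shift(tc.concentrations)
    if sigma > 0:
        conc = conc + rng.normal(0.0, sigma, conc.shape)
    conc = conc.clip(lower=0.0)

    expr = log2_expression(_shift(tc.mass_fractions(model)))
    if sigma > 0:
        expr = expr + rng.normal(0.0, sigma, expr.shape)
    return conc, expr
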