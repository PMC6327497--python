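"""Growth-rate-dependent metabolism-and-expression (ME) model data structures.

A ME model couples metabolic fluxes to the expression machinery that
produces the catalyzing enzymes.  Its stoichiometric matrix ``S(mu)`` and
flux bounds ``l(mu)``, ``u(mu)`` depend on the growth rate ``mu`` (1/h):
dilution of macromolecules scales linearly with ``mu`` and translation
capacity follows a hyperbolic saturation in ``mu``.  For any fixed ``mu``
the constraints become an ordinary linear program, which is the basis of
growth maximization by bisection (see :mod:`mebatch.solver`).

Units throughout the package: fluxes mmol/gDW/h, extracellular
concentrations mmol/L, intracellular complex concentrations mmol/gDW,
biomass gDW/L, growth rate 1/h, molecular weights kDa.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping

import numpy as np

__all__ = [
    "DomainError",
    "ModelError",
    "MuExpression",
    "Metabolite",
    "StoichEntry",
    "EnzymeComplex",
    "Protein",
    "LinearProblem",
    "MEModel",
    "evaluate_at_mu",
    "validate_model",
]


class DomainError(ValueError):
    """An argument lies outside its documented domain (e.g. mu < 0)."""


class ModelError(ValueError):
    """The model is structurally inconsistent for the requested operation."""


_FORMS = ("constant", "linear", "hyperbolic")


@dataclass(frozen=True)
class MuExpression:
    """A growth-rate-dependent coefficient.

    Supported forms:

    - ``constant``:   a
    - ``linear``:     a + b*mu      (e.g. dilution terms, -mu/keff couplings)
    - ``hyperbolic``: a*mu/(b+mu)   with b > 0 (translation-rate saturation)
    """

    form: str = "constant"
    a: float = 0.0
    b: float = 0.0

    def __post_init__(self) -> None:
        if self.form not in _FORMS:
            raise ModelError(f"unknown MuExpression form {self.form!r}")
        if self.form == "hyperbolic" and not self.b > 0:
            raise ModelError("hyperbolic MuExpression requires b > 0")

    def evaluate(self, mu: float) -> float:
        if self.form == "constant":
            return float(self.a)
        if self.form == "linear":
            return float(self.a + self.b * mu)
        return float(self.a * mu / (self.b + mu))

    # -- serialization -------------------------------------------------
    def to_dict(self) -> dict:
        return {"form": self.form, "a": self.a, "b": self.b}

    @classmethod
    def from_dict(cls, d: Mapping) -> "MuExpression":
        return cls(form=d.get("form", "constant"),
                   a=float(d.get("a", 0.0)), b=float(d.get("b", 0.0)))

    @classmethod
    def const(cls, a: float) -> "MuExpression":
        return cls("constant", float(a), 0.0)

    @classmethod
    def linear(cls, a: float, b: float) -> "MuExpression":
        return cls("linear", float(a), float(b))


@dataclass(frozen=True)
class Metabolite:
    id: str
    extracellular: bool = False


@dataclass(frozen=True)
class StoichEntry:
    met: str
    rxn: str
    expr: MuExpression


@dataclass(frozen=True)
class EnzymeComplex:
    """A catalytic protein complex with its effective rate constants.

    ``keff`` maps each catalyzed reaction j to the rate constant (1/h)
    linking flux to enzyme concentration, v_j = keff_j * e.  The set of
    keys is CAT(i).  ``formation_rxn`` is the reaction assembling the
    complex; it must *not* list the complex itself in its stoichiometry --
    the +1 production (and the -mu/keff dilution coupling on catalyzed
    reactions) is synthesized by :func:`evaluate_at_mu`.
    """

    id: str
    formation_rxn: str
    weight_kda: float
    keff: Mapping[str, float] = field(default_factory=dict)


@dataclass(frozen=True)
class Protein:
    id: str
    translation_rxn: str
    weight_kda: float


@dataclass
class LinearProblem:
    """A numeric LP: A_eq x = b_eq, A_ub x <= b_ub, lb <= x <= ub."""

    A_eq: np.ndarray
    b_eq: np.ndarray
    A_ub: np.ndarray | None
    b_ub: np.ndarray | None
    lb: np.ndarray
    ub: np.ndarray
    var_ids: list[str]
    row_ids: list[str]
    ub_row_ids: list[str] = field(default_factory=list)

    def var_index(self, var_id: str) -> int:
        return self.var_ids.index(var_id)


DEFAULT_LOWER = MuExpression.const(-1000.0)
DEFAULT_UPPER = MuExpression.const(1000.0)


@dataclass
class MEModel:
    """A mu-parameterized stoichiometric network with enzyme couplings."""

    metabolites: list[Metabolite]
    reactions: list[str]
    stoichiometry: list[StoichEntry]
    bounds: dict[str, tuple[MuExpression, MuExpression]]
    complexes: list[EnzymeComplex]
    proteins: list[Protein]
    exchanges: dict[str, str]
    mu_max: float = 2.0
    enzyme_budget: float | None = None
    # optional total proteome cap (mmol/gDW): sum_i e_i <= enzyme_budget,
    # where e_i = sum_{j in CAT(i)} v_j/keff_ij is the enzyme concentration
    # implied by the fluxes (in inertia mode the cap applies to p directly)

    # -- convenience look-ups ------------------------------------------
    @property
    def metabolite_ids(self) -> list[str]:
        return [m.id for m in self.metabolites]

    @property
    def extracellular_ids(self) -> list[str]:
        return [m.id for m in self.metabolites if m.extracellular]

    def complex_by_id(self, cid: str) -> EnzymeComplex:
        for c in self.complexes:
            if c.id == cid:
                return c
        raise ModelError(f"unknown complex {cid!r}")

    def couplings(self) -> list[tuple[str, str]]:
        """All (complex id, reaction id) pairs carrying a keff."""
        return [(c.id, r) for c in self.complexes for r in sorted(c.keff)]

    def bounds_for(self, rxn: str) -> tuple[MuExpression, MuExpression]:
        return self.bounds.get(rxn, (DEFAULT_LOWER, DEFAULT_UPPER))

    def copy(self) -> "MEModel":
        return MEModel(
            metabolites=list(self.metabolites),
            reactions=list(self.reactions),
            stoichiometry=list(self.stoichiometry),
            bounds=dict(self.bounds),
            complexes=list(self.complexes),
            proteins=list(self.proteins),
            exchanges=dict(self.exchanges),
            mu_max=self.mu_max,
            enzyme_budget=self.enzyme_budget,
        )

    def with_keff_factors(self, factors: Mapping[tuple[str, str], float]) -> "MEModel":
        """Return a copy with keff values multiplied by the given factors.

        ``factors`` maps (complex id, reaction id) to a multiplicative
        factor.  Unknown couplings raise :class:`ModelError`.
        """
        known = set(self.couplings())
        for key in factors:
            if tuple(key) not in known:
                raise ModelError(f"unknown keff coupling {key!r}")
        new_complexes = []
        for c in self.complexes:
            keff = dict(c.keff)
            for (cid, rxn), f in factors.items():
                if cid == c.id:
                    keff[rxn] = keff[rxn] * float(f)
            new_complexes.append(replace(c, keff=keff))
        model = self.copy()
        model.complexes = new_complexes
        return model

    # -- JSON round-trip -----------------------------------------------
    def to_json(self, path=None) -> str:
        doc = {
            "metabolites": [{"id": m.id, "extracellular": m.extracellular}
                            for m in self.metabolites],
            "reactions": [{"id": r} for r in self.reactions],
            "stoichiometry": [{"met": s.met, "rxn": s.rxn,
                               "expr": s.expr.to_dict()}
                              for s in self.stoichiometry],
            "bounds": [{"rxn": r, "lower": lo.to_dict(), "upper": hi.to_dict()}
                       for r, (lo, hi) in self.bounds.items()],
            "complexes": [{"id": c.id, "formation_rxn": c.formation_rxn,
                           "weight_kda": c.weight_kda,
                           "keff": dict(c.keff)}
                          for c in self.complexes],
            "proteins": [{"id": p.id, "translation_rxn": p.translation_rxn,
                          "weight_kda": p.weight_kda}
                         for p in self.proteins],
            "exchanges": dict(self.exchanges),
            "mu_max": self.mu_max,
        }
        if self.enzyme_budget is not None:
            doc["enzyme_budget"] = self.enzyme_budget
        text = json.dumps(doc, indent=1, sort_keys=True)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_json(cls, source) -> "MEModel":
        """Load a model from a JSON string, dict, or file path."""
        if isinstance(source, Mapping):
            doc = source
        else:
            text = str(source)
            if text.lstrip().startswith("{"):
                doc = json.loads(text)
            else:
                with open(text) as fh:
                    doc = json.load(fh)
        try:
            return cls(
                metabolites=[Metabolite(m["id"], bool(m.get("extracellular", False)))
                             for m in doc["metabolites"]],
                reactions=[r["id"] for r in doc["reactions"]],
                stoichiometry=[StoichEntry(s["met"], s["rxn"],
                                           MuExpression.from_dict(s["expr"]))
                               for s in doc["stoichiometry"]],
                bounds={b["rxn"]: (MuExpression.from_dict(b["lower"]),
                                   MuExpression.from_dict(b["upper"]))
                        for b in doc["bounds"]},
                complexes=[EnzymeComplex(c["id"], c["formation_rxn"],
                                         float(c["weight_kda"]),
                                         {k: float(v) for k, v in c["keff"].items()})
                           for c in doc["complexes"]],
                proteins=[Protein(p["id"], p["translation_rxn"],
                                  float(p["weight_kda"]))
                          for p in doc["proteins"]],
                exchanges=dict(doc["exchanges"]),
                mu_max=float(doc.get("mu_max", 2.0)),
                enzyme_budget=(None if doc.get("enzyme_budget") is None
                               else float(doc["enzyme_budget"])),
            )
        except (KeyError, TypeError) as exc:
            raise ModelError(f"malformed model JSON: {exc}") from exc


def validate_model(model: MEModel) -> list[str]:
    """Diagnose violations of the MEModel invariants.

    Returns a list of human-readable violations; an empty list means the
    model is well-formed.  This never raises: it is a diagnostics report.
    """
    issues: list[str] = []
    met_ids = model.metabolite_ids
    if len(set(met_ids)) != len(met_ids):
        issues.append("duplicate metabolite ids")
    rxn_set = set(model.reactions)
    if len(rxn_set) != len(model.reactions):
        issues.append("duplicate reaction ids")
    if not model.mu_max > 0:
        issues.append(f"mu_max must be > 0, got {model.mu_max}")
    if model.enzyme_budget is not None and not model.enzyme_budget > 0:
        issues.append(f"enzyme_budget must be > 0, got {model.enzyme_budget}")

    met_set = set(met_ids)
    for s in model.stoichiometry:
        if s.met not in met_set:
            issues.append(f"stoichiometry references unknown metabolite {s.met!r}")
        if s.rxn not in rxn_set:
            issues.append(f"stoichiometry references unknown reaction {s.rxn!r}")
    for rxn in model.bounds:
        if rxn not in rxn_set:
            issues.append(f"bounds reference unknown reaction {rxn!r}")

    # every MuExpression finite on [0, mu_max]
    mus = (0.0, 0.5 * model.mu_max, model.mu_max) if model.mu_max > 0 else (0.0,)
    def _check_expr(expr: MuExpression, where: str) -> None:
        try:
            vals = [expr.evaluate(m) for m in mus]
        except Exception as exc:  # pragma: no cover - defensive
            issues.append(f"{where}: expression not evaluable ({exc})")
            return
        if not all(np.isfinite(vals)):
            issues.append(f"{where}: non-finite value on [0, mu_max]")

    for s in model.stoichiometry:
        _check_expr(s.expr, f"stoichiometry ({s.met}, {s.rxn})")
    for rxn, (lo, hi) in model.bounds.items():
        _check_expr(lo, f"lower bound of {rxn}")
        _check_expr(hi, f"upper bound of {rxn}")

    seen_cplx: set[str] = set()
    for c in model.complexes:
        if c.id in seen_cplx:
            issues.append(f"duplicate complex id {c.id!r}")
        seen_cplx.add(c.id)
        if c.formation_rxn not in rxn_set:
            issues.append(f"complex {c.id}: formation reaction "
                          f"{c.formation_rxn!r} not in reactions")
        if not c.keff:
            issues.append(f"complex {c.id}: CAT(i) is empty (no keff couplings)")
        for rxn, k in c.keff.items():
            if rxn not in rxn_set:
                issues.append(f"complex {c.id}: keff reaction {rxn!r} unknown")
            if not k > 0:
                issues.append(f"complex {c.id}: keff for {rxn!r} must be > 0, "
                              f"got {k}")
        if not c.weight_kda > 0:
            issues.append(f"complex {c.id}: weight must be > 0")

    for p in model.proteins:
        if p.translation_rxn not in rxn_set:
            issues.append(f"protein {p.id}: translation reaction "
                          f"{p.translation_rxn!r} not in reactions")
        if not p.weight_kda > 0:
            issues.append(f"protein {p.id}: weight must be > 0")

    ext = set(model.extracellular_ids)
    for met in ext:
        if met not in model.exchanges:
            issues.append(f"extracellular metabolite {met!r} has no exchange "
                          f"reaction")
    for met, rxn in model.exchanges.items():
        if met not in met_set:
            issues.append(f"exchange references unknown metabolite {met!r}")
        elif met not in ext:
            issues.append(f"exchange metabolite {met!r} is not extracellular")
        if rxn not in rxn_set:
            issues.append(f"exchange reaction {rxn!r} not in reactions")
    return issues


def evaluate_at_mu(
    model: MEModel,
    mu: float,
    bound_overrides: Mapping[str, tuple[float | None, float | None]] | None = None,
) -> LinearProblem:
    """Instantiate the fixed-mu linear problem S(mu) v = 0, l(mu) <= v <= u(mu).

    Enzyme-use coupling is encoded on a synthesized constraint row per
    complex i: +1 on the formation reaction and -mu/keff_ij on each
    catalyzed reaction j, i.e. complex production must balance growth
    dilution of the enzyme demanded by its catalyzed fluxes.

    ``bound_overrides`` maps reaction id -> (lower, upper) numeric
    overrides applied after evaluating the mu-dependent bounds; ``None``
    entries leave that side untouched.  This is how the dynamic layer
    opens/closes exchange reactions.
    """
    if not (0.0 <= mu <= model.mu_max):
        raise DomainError(f"mu={mu} outside [0, {model.mu_max}]")

    n = len(model.reactions)
    rxn_index = {r: j for j, r in enumerate(model.reactions)}
    met_index = {m: i for i, m in enumerate(model.metabolite_ids)}
    n_rows = len(model.metabolites) + len(model.complexes)
    A = np.zeros((n_rows, n))
    row_ids = list(model.metabolite_ids)

    for s in model.stoichiometry:
        coef = s.expr.evaluate(mu)
        if not np.isfinite(coef):
            raise ModelError(f"non-finite coefficient for ({s.met}, {s.rxn}) "
                             f"at mu={mu}")
        A[met_index[s.met], rxn_index[s.rxn]] += coef

    for i, c in enumerate(model.complexes):
        row = len(model.metabolites) + i
        row_ids.append(f"complex:{c.id}")
        if c.formation_rxn not in rxn_index:
            raise ModelError(f"complex {c.id}: unknown formation reaction "
                             f"{c.formation_rxn!r}")
        A[row, rxn_index[c.formation_rxn]] += 1.0
        for rxn, keff in c.keff.items():
            if not keff > 0:
                raise ModelError(f"complex {c.id}: keff for {rxn!r} must be > 0")
            A[row, rxn_index[rxn]] += -mu / keff

    lb = np.empty(n)
    ub = np.empty(n)
    for r, j in rxn_index.items():
        lo_e, hi_e = model.bounds_for(r)
        lo, hi = lo_e.evaluate(mu), hi_e.evaluate(mu)
        if not (np.isfinite(lo) and np.isfinite(hi)):
            raise ModelError(f"non-finite bound for reaction {r!r} at mu={mu}")
        lb[j], ub[j] = lo, hi
    if bound_overrides:
        for r, (lo, hi) in bound_overrides.items():
            j = rxn_index.get(r)
            if j is None:
                raise ModelError(f"bound override for unknown reaction {r!r}")
            if lo is not None:
                lb[j] = lo
            if hi is not None:
                ub[j] = hi

    A_ub = b_ub = None
    ub_row_ids: list[str] = []
    if model.enzyme_budget is not None and model.complexes:
        # total implied enzyme concentration: sum_i sum_j v_j/keff_ij <= E
        A_ub = np.zeros((1, n))
        for c in model.complexes:
            for rxn, keff in c.keff.items():
                A_ub[0, rxn_index[rxn]] += 1.0 / keff
        b_ub = np.array([model.enzyme_budget])
        ub_row_ids = ["enzyme_budget"]

    return LinearProblem(
        A_eq=A, b_eq=np.zeros(n_rows), A_ub=A_ub, b_ub=b_ub,
        lb=lb, ub=ub, var_ids=list(model.reactions), row_ids=row_ids,
        ub_row_ids=ub_row_ids,
    )
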