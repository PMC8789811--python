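"""Event-B model objects and their generation from reaction networks.

Three generators are provided:

* :func:`gen_abstract_model` — the classic encoding: one natural-number
  variable per species, one event per reaction with "enough reactants"
  guards and delta actions, typing plus conservation invariants.
* :func:`gen_expanded_model` — the same encoding applied to an expanded
  refined network (model size grows with the combinatorics).
* :func:`gen_compact_model` — the size-preserving data refinement: each
  refined species family becomes a single function variable on a carrier
  set partitioned into singleton variant constants; each abstract reaction
  stays a single event, with parameters selecting variants, partition and
  availability guards, label-arithmetic linking guards, and
  function-override actions.  Gluing invariants ``A = rA(A_0) + ... +
  rA(A_l)`` tie the two state spaces together.

Models are plain dataclasses with a lossless dict/JSON round-trip and a
deterministic textual Event-B export (:func:`emit_text`).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple, Union

from .network import ConservationLaw, NetworkError, ReactionNetwork
from .refine import CompactModelPlan, RefinedNetwork, RefinementMap

__all__ = [
    "EBContext",
    "EBMachine",
    "EBModel",
    "CarrierSet",
    "LabelFunc",
    "Variable",
    "Invariant",
    "Guard",
    "Action",
    "Parameter",
    "Event",
    "ModelError",
    "sanitize_ids",
    "gen_abstract_model",
    "gen_expanded_model",
    "gen_compact_model",
    "default_refined_init",
    "emit_text",
]


class ModelError(ValueError):
    pass


def sanitize_ids(ids: Sequence[str]) -> Dict[str, str]:
    """Map species ids to Event-B identifiers (``:`` is not allowed there).

    Deterministic and collision-free: ``hsf3:hse -> hsf3_hse``; if that name
    is already taken a numeric suffix disambiguates.
    """
    out: Dict[str, str] = {}
    taken: set = set()
    for sid in ids:
        base = sid.replace(":", "_")
        name = base
        k = 2
        while name in taken:
            name = f"{base}_{k}"
            k += 1
        out[sid] = name
        taken.add(name)
    return out


# ---------------------------------------------------------------------------
# Model dataclasses
# ---------------------------------------------------------------------------

@dataclass
class CarrierSet:
    name: str
    constants: List[str]  # partitioned into singletons, one per variant


@dataclass
class LabelFunc:
    """Context constant function: variant constant -> attribute label level."""

    name: str
    set_name: str
    attr: str
    values: Dict[str, int]


@dataclass
class EBContext:
    name: str
    sets: List[CarrierSet] = field(default_factory=list)
    label_funcs: List[LabelFunc] = field(default_factory=list)

    def __post_init__(self):
        self._labels: Dict[str, Dict[str, int]] = {}
        for lf in self.label_funcs:
            for const, lvl in lf.values.items():
                self._labels.setdefault(const, {})[lf.attr] = lvl

    def label(self, const: str, attr: str) -> int:
        return self._labels.get(const, {}).get(attr, 0)

    def set_by_name(self, name: str) -> CarrierSet:
        for s in self.sets:
            if s.name == name:
                return s
        raise KeyError(name)

    def to_dict(self) -> Dict:
        return {
            "name": self.name,
            "sets": [{"name": s.name, "constants": s.constants} for s in self.sets],
            "label_funcs": [
                {"name": f.name, "set_name": f.set_name, "attr": f.attr, "values": f.values}
                for f in self.label_funcs
            ],
        }

    @classmethod
    def from_dict(cls, d: Dict) -> "EBContext":
        return cls(
            d["name"],
            [CarrierSet(s["name"], list(s["constants"])) for s in d["sets"]],
            [LabelFunc(f["name"], f["set_name"], f["attr"], dict(f["values"])) for f in d["label_funcs"]],
        )


@dataclass
class Variable:
    """A state variable: a natural scalar or a function on a variant domain."""

    name: str
    species: str  # the (abstract or refined) species it models
    kind: str = "scalar"  # "scalar" | "function"
    set_name: Optional[str] = None
    domain: List[str] = field(default_factory=list)  # constant names
    domain_species: List[str] = field(default_factory=list)  # refined species ids

    def to_dict(self) -> Dict:
        return {
            "name": self.name, "species": self.species, "kind": self.kind,
            "set_name": self.set_name, "domain": self.domain,
            "domain_species": self.domain_species,
        }

    @classmethod
    def from_dict(cls, d: Dict) -> "Variable":
        return cls(d["name"], d["species"], d["kind"], d["set_name"],
                   list(d["domain"]), list(d["domain_species"]))


@dataclass
class Invariant:
    """Typing, conservation or gluing invariant (structured, linear)."""

    label: str
    kind: str  # "typing" | "conservation" | "gluing"
    var: Optional[str] = None  # typing: the variable; gluing: concrete function
    coeffs: Dict[str, int] = field(default_factory=dict)  # conservation: var -> coeff
    constant: int = 0  # conservation right-hand side
    abstract_var: Optional[str] = None  # gluing

    def to_dict(self) -> Dict:
        return {"label": self.label, "kind": self.kind, "var": self.var,
                "coeffs": self.coeffs, "constant": self.constant,
                "abstract_var": self.abstract_var}

    @classmethod
    def from_dict(cls, d: Dict) -> "Invariant":
        return cls(d["label"], d["kind"], d.get("var"), dict(d.get("coeffs", {})),
                   d.get("constant", 0), d.get("abstract_var"))


@dataclass
class Guard:
    """Structured guard.

    kinds:
      ``member``       — parameter ``params[0]`` ranges over ``set_name``;
      ``avail_scalar`` — ``var >= amount``;
      ``avail_func``   — for every value v, ``var(v) >= #{p in params
                         assigned v}`` (coincidence-aware demand);
      ``linking``      — per-attribute label arithmetic:
                         sum of labels of ``lhs_params`` = sum over
                         ``rhs_params`` (state-independent).
    """

    label: str
    kind: str
    var: Optional[str] = None
    amount: int = 0
    params: List[str] = field(default_factory=list)
    set_name: Optional[str] = None
    attr: Optional[str] = None
    lhs_params: List[str] = field(default_factory=list)
    rhs_params: List[str] = field(default_factory=list)

    def to_dict(self) -> Dict:
        return {"label": self.label, "kind": self.kind, "var": self.var,
                "amount": self.amount, "params": self.params,
                "set_name": self.set_name, "attr": self.attr,
                "lhs_params": self.lhs_params, "rhs_params": self.rhs_params}

    @classmethod
    def from_dict(cls, d: Dict) -> "Guard":
        return cls(d["label"], d["kind"], d.get("var"), d.get("amount", 0),
                   list(d.get("params", [])), d.get("set_name"), d.get("attr"),
                   list(d.get("lhs_params", [])), list(d.get("rhs_params", [])))


@dataclass
class Action:
    """Delta assignment: scalar ``X := X + delta`` or accumulated function
    override ``rX := rX <+ {sigma(p) |-> rX(sigma(p)) + sum of deltas}``
    (deltas of coincident parameters add up)."""

    label: str
    kind: str  # "scalar" | "func"
    var: str
    delta: int = 0
    updates: List[Tuple[str, int]] = field(default_factory=list)  # (param, delta)

    def to_dict(self) -> Dict:
        return {"label": self.label, "kind": self.kind, "var": self.var,
                "delta": self.delta, "updates": [list(u) for u in self.updates]}

    @classmethod
    def from_dict(cls, d: Dict) -> "Action":
        return cls(d["label"], d["kind"], d["var"], d.get("delta", 0),
                   [tuple(u) for u in d.get("updates", [])])


@dataclass
class Parameter:
    name: str
    set_name: str
    domain: List[str]  # constant names

    def to_dict(self) -> Dict:
        return {"name": self.name, "set_name": self.set_name, "domain": self.domain}

    @classmethod
    def from_dict(cls, d: Dict) -> "Parameter":
        return cls(d["name"], d["set_name"], list(d["domain"]))


@dataclass
class Event:
    name: str
    params: List[Parameter] = field(default_factory=list)
    guards: List[Guard] = field(default_factory=list)
    actions: List[Action] = field(default_factory=list)
    source_reaction: Optional[str] = None

    def to_dict(self) -> Dict:
        return {"name": self.name,
                "params": [p.to_dict() for p in self.params],
                "guards": [g.to_dict() for g in self.guards],
                "actions": [a.to_dict() for a in self.actions],
                "source_reaction": self.source_reaction}

    @classmethod
    def from_dict(cls, d: Dict) -> "Event":
        return cls(d["name"], [Parameter.from_dict(p) for p in d["params"]],
                   [Guard.from_dict(g) for g in d["guards"]],
                   [Action.from_dict(a) for a in d["actions"]],
                   d.get("source_reaction"))


InitValue = Union[int, Dict[str, int]]


@dataclass
class EBMachine:
    name: str
    sees: List[str] = field(default_factory=list)
    refines: Optional[str] = None
    variables: List[Variable] = field(default_factory=list)
    invariants: List[Invariant] = field(default_factory=list)
    events: List[Event] = field(default_factory=list)
    init: Dict[str, InitValue] = field(default_factory=dict)

    def var_by_name(self, name: str) -> Variable:
        for v in self.variables:
            if v.name == name:
                return v
        raise KeyError(name)

    def event_by_name(self, name: str) -> Event:
        for e in self.events:
            if e.name == name:
                return e
        raise KeyError(name)

    def var_of_species(self, species: str) -> Variable:
        for v in self.variables:
            if v.species == species:
                return v
        raise KeyError(species)

    def to_dict(self) -> Dict:
        return {
            "name": self.name, "sees": self.sees, "refines": self.refines,
            "variables": [v.to_dict() for v in self.variables],
            "invariants": [i.to_dict() for i in self.invariants],
            "events": [e.to_dict() for e in self.events],
            "init": self.init,
        }

    @classmethod
    def from_dict(cls, d: Dict) -> "EBMachine":
        return cls(d["name"], list(d.get("sees", [])), d.get("refines"),
                   [Variable.from_dict(v) for v in d["variables"]],
                   [Invariant.from_dict(i) for i in d["invariants"]],
                   [Event.from_dict(e) for e in d["events"]],
                   {k: (v if isinstance(v, int) else dict(v)) for k, v in d["init"].items()})


@dataclass
class EBModel:
    """A machine together with the context it sees."""

    context: EBContext
    machine: EBMachine

    def to_dict(self) -> Dict:
        return {"context": self.context.to_dict(), "machine": self.machine.to_dict()}

    @classmethod
    def from_dict(cls, d: Dict) -> "EBModel":
        return cls(EBContext.from_dict(d["context"]), EBMachine.from_dict(d["machine"]))


# ---------------------------------------------------------------------------
# Generators
# ---------------------------------------------------------------------------

def _check_init(init: Mapping[str, int], species_ids: Sequence[str],
                laws: Sequence[ConservationLaw],
                expected_totals: Optional[Mapping[str, int]] = None) -> Dict[str, int]:
    full = {}
    for sid in species_ids:
        v = int(init.get(sid, 0))
        if v < 0:
            raise ModelError(f"initial value of {sid} is negative")
        full[sid] = v
    unknown = set(init) - set(species_ids)
    if unknown:
        raise ModelError(f"init mentions unknown species: {', '.join(sorted(unknown))}")
    if expected_totals:
        for law in laws:
            if law.description in expected_totals:
                got = law.value(full)
                want = int(expected_totals[law.description])
                if got != want:
                    raise ModelError(
                        f"init violates conservation law {law.description}: "
                        f"total {got} != required {want}"
                    )
    return full


def gen_abstract_model(net: ReactionNetwork, laws: Sequence[ConservationLaw],
                       init: Mapping[str, int], name: str = "M0",
                       context_name: str = "C0",
                       expected_totals: Optional[Mapping[str, int]] = None) -> EBModel:
    """Classic encoding: variable per species, event per reaction.

    Guards demand the full reactant multiplicities (so a catalyst needs to be
    present even when its net change is zero); actions apply the net deltas.
    Invariants: one typing invariant per variable plus one conservation
    equality per law, with the conserved total fixed by ``init``.
    """
    if not net.is_normalized:
        raise NetworkError("network must be normalized")
    init_full = _check_init(init, net.species_ids, laws, expected_totals)
    san = sanitize_ids(net.species_ids)
    ctx = EBContext(context_name)
    variables = [Variable(san[s.id], s.id, "scalar") for s in net.species]
    invariants: List[Invariant] = []
    n = 0
    for v in variables:
        n += 1
        invariants.append(Invariant(f"inv{n}", "typing", var=v.name))
    for law in laws:
        n += 1
        coeffs = {san[s]: c for s, c in sorted(law.coefficients.items())}
        invariants.append(Invariant(f"inv{n}", "conservation", coeffs=coeffs,
                                    constant=law.value(init_full)))
    events = []
    for r in net.reactions:
        guards = []
        g = 0
        for sid in sorted(r.reactants):
            g += 1
            guards.append(Guard(f"grd{g}", "avail_scalar", var=san[sid],
                                amount=r.reactants[sid]))
        actions = []
        a = 0
        for sid in sorted(set(r.reactants) | set(r.products)):
            d = r.products.get(sid, 0) - r.reactants.get(sid, 0)
            if d != 0:
                a += 1
                actions.append(Action(f"act{a}", "scalar", san[sid], delta=d))
        events.append(Event(r.id, [], guards, actions, source_reaction=r.id))
    machine = EBMachine(name, [context_name], None, variables, invariants, events,
                        {san[sid]: init_full[sid] for sid in net.species_ids})
    return EBModel(ctx, machine)


def default_refined_init(rmap: RefinementMap, abstract_init: Mapping[str, int]) -> Dict[str, int]:
    """Place all abstract mass in the all-level-zero variant of each family."""
    out: Dict[str, int] = {}
    for abs_id, fam in rmap.partition.items():
        zero = min(fam.variants, key=lambda v: sorted(v.labels))
        for v in fam.variants:
            out[v.id] = int(abstract_init.get(abs_id, 0)) if v.id == zero.id else 0
    return out


def gen_expanded_model(ref: RefinedNetwork, init: Mapping[str, int],
                       name: str = "M1exp", context_name: str = "C1exp",
                       laws: Optional[Sequence[ConservationLaw]] = None,
                       expected_totals: Optional[Mapping[str, int]] = None) -> EBModel:
    """Classic encoding of the expanded refined network.

    Conservation laws are recomputed on the refined stoichiometry unless
    given; the per-attribute label moiety shows up here as an extra law.
    """
    from .network import conservation_basis, stoichiometric_delta

    net = ref.network
    if laws is None:
        laws = conservation_basis(stoichiometric_delta(net), net.species_ids)
    return gen_abstract_model(net, laws, init, name=name, context_name=context_name,
                              expected_totals=expected_totals)


def gen_compact_model(plan: CompactModelPlan, rmap: RefinementMap,
                      laws: Sequence[ConservationLaw], init: Mapping[str, int],
                      abstract: EBModel, name: str = "M1", context_name: str = "C1",
                      symmetry_breaking: bool = False) -> EBModel:
    """Size-preserving refined machine: same variable and event counts as the
    abstract machine.

    Each refined abstract species X becomes a function ``rX`` on a carrier
    set partitioned into singleton variant constants; each abstract reaction
    stays one event whose parameters pick the variants, with partition
    membership guards, coincidence-aware availability guards, label-linking
    guards and override actions.  ``init`` gives refined-species counts and
    must project onto the abstract machine's init through the gluing sums.

    ``symmetry_breaking`` adds label-ordering guards over interchangeable
    identical-reactant parameters; it changes neither reachability nor the
    projected transition relation and is off by default.
    """
    net = plan.abstract
    abs_machine = abstract.machine
    san = sanitize_ids(net.species_ids)
    # refined species ids across all families, for init validation
    refined_ids = [v.id for fam in rmap.partition.values() for v in fam.variants]
    init_full = _check_init(init, refined_ids, [])

    # projection check: concrete init must glue onto abstract init
    for abs_id, fam in rmap.partition.items():
        glued = sum(init_full[v.id] for v in fam.variants)
        abs_val = abs_machine.init.get(san[abs_id], 0)
        if glued != abs_val:
            raise ModelError(
                f"concrete init for {abs_id} sums to {glued}, abstract init is {abs_val}"
            )

    variant_ids = [v.id for abs_id in net.species_ids
                   for v in rmap.family(abs_id).variants
                   if not rmap.family(abs_id).is_identity]
    vsan = sanitize_ids(variant_ids)

    sets: List[CarrierSet] = []
    label_funcs: List[LabelFunc] = []
    variables: List[Variable] = []
    for sp in net.species:
        fam = rmap.family(sp.id)
        if fam.is_identity:
            variables.append(Variable(san[sp.id], sp.id, "scalar"))
        else:
            set_name = f"S_{san[sp.id]}"
            consts = [vsan[v.id] for v in fam.variants]
            sets.append(CarrierSet(set_name, consts))
            for attr in sorted(fam.dims):
                label_funcs.append(LabelFunc(
                    f"lab_{attr}_{san[sp.id]}", set_name, attr,
                    {vsan[v.id]: v.label(attr) for v in fam.variants}))
            variables.append(Variable(f"r{san[sp.id]}", sp.id, "function", set_name,
                                      consts, [v.id for v in fam.variants]))
    ctx = EBContext(context_name, sets, label_funcs)

    invariants: List[Invariant] = []
    n = 0
    for v in variables:
        n += 1
        invariants.append(Invariant(f"inv{n}", "typing", var=v.name))
    by_species = {v.species: v for v in variables}
    for law in laws:
        n += 1
        coeffs = {by_species[s].name: c for s, c in sorted(law.coefficients.items())}
        const = sum(c * sum(init_full[v.id] for v in rmap.family(s).variants)
                    for s, c in law.coefficients.items())
        invariants.append(Invariant(f"inv{n}", "conservation", coeffs=coeffs, constant=const))
    for sp in net.species:
        fam = rmap.family(sp.id)
        if not fam.is_identity:
            n += 1
            invariants.append(Invariant(f"inv{n}", "gluing", var=f"r{san[sp.id]}",
                                        abstract_var=san[sp.id]))

    events: List[Event] = []
    for entry in plan.entries:
        params: List[Parameter] = []
        guards: List[Guard] = []
        actions: List[Action] = []
        g = a = 0
        slot_param: Dict[str, Parameter] = {}
        for slot in entry.params:
            fam = rmap.family(slot.abstract_id)
            set_name = f"S_{san[slot.abstract_id]}"
            p = Parameter(slot.name, set_name, [vsan[v.id] for v in fam.variants])
            params.append(p)
            slot_param[slot.name] = p
            g += 1
            guards.append(Guard(f"grd{g}", "member", params=[slot.name], set_name=set_name))
        for sid in sorted(entry.scalar_reactants):
            g += 1
            guards.append(Guard(f"grd{g}", "avail_scalar", var=san[sid],
                                amount=entry.scalar_reactants[sid]))
        # availability on functions: one guard per consumed function variable,
        # demand = number of consuming parameters assigned each argument
        consuming: Dict[str, List[str]] = {}
        for slot in entry.consuming_params():
            consuming.setdefault(slot.abstract_id, []).append(slot.name)
        for abs_id in sorted(consuming):
            g += 1
            guards.append(Guard(f"grd{g}", "avail_func", var=f"r{san[abs_id]}",
                                params=sorted(consuming[abs_id])))
        for attr in entry.attrs:
            lhs = [s.name for s in entry.params if s.side == "lhs"]
            rhs = [s.name for s in entry.params if s.side == "rhs"]
            g += 1
            guards.append(Guard(f"grd{g}", "linking", attr=attr,
                                lhs_params=lhs, rhs_params=rhs))
        if symmetry_breaking:
            by_side_species: Dict[Tuple[str, str], List[str]] = {}
            for slot in entry.params:
                by_side_species.setdefault((slot.side, slot.abstract_id), []).append(slot.name)
            for (side, abs_id), names in sorted(by_side_species.items()):
                for attr in sorted(rmap.family(abs_id).dims):
                    for p1, p2 in zip(names, names[1:]):
                        g += 1
                        guards.append(Guard(f"grd{g}", "ordering", attr=attr,
                                            lhs_params=[p1], rhs_params=[p2]))
        # actions
        touched_scalars = sorted(set(entry.scalar_reactants) | set(entry.scalar_products))
        for sid in touched_scalars:
            d = entry.scalar_products.get(sid, 0) - entry.scalar_reactants.get(sid, 0)
            if d != 0:
                a += 1
                actions.append(Action(f"act{a}", "scalar", san[sid], delta=d))
        func_updates: Dict[str, List[Tuple[str, int]]] = {}
        for slot in entry.params:
            var = f"r{san[slot.abstract_id]}"
            func_updates.setdefault(var, []).append(
                (slot.name, -1 if slot.side == "lhs" else 1))
        for var in sorted(func_updates):
            a += 1
            actions.append(Action(f"act{a}", "func", var, updates=func_updates[var]))
        events.append(Event(entry.reaction_id, params, guards, actions,
                            source_reaction=entry.reaction_id))

    init_m: Dict[str, InitValue] = {}
    for v in variables:
        if v.kind == "scalar":
            init_m[v.name] = init_full[v.species]
        else:
            init_m[v.name] = {const: init_full[sid]
                              for const, sid in zip(v.domain, v.domain_species)}
    machine = EBMachine(name, [context_name], abs_machine.name, variables,
                        invariants, events, init_m)
    return EBModel(ctx, machine)


# ---------------------------------------------------------------------------
# Textual emission
# ---------------------------------------------------------------------------

def _eq_cases_text(var: str, params: List[str]) -> str:
    """Availability predicate with coincidence-aware demands.

    For one parameter this is a plain application; otherwise the predicate
    case-splits on the equality pattern of the parameters (set partitions),
    demanding the summed amount wherever parameters coincide.
    """
    if len(params) == 1:
        return f"{var}({params[0]}) >= 1"
    disjuncts = []
    for part in _set_partitions(params):
        eqs = []
        for block in part:
            for x, y in zip(block, block[1:]):
                eqs.append(f"{x} = {y}")
        reps = [b[0] for b in part]
        for i, x in enumerate(reps):
            for y in reps[i + 1:]:
                eqs.append(f"{x} /= {y}")
        demands = [f"{var}({b[0]}) >= {len(b)}" for b in part]
        disjuncts.append("(" + " & ".join(eqs + demands) + ")")
    return " or ".join(disjuncts)


def _set_partitions(items: List[str]):
    if not items:
        yield []
        return
    first, rest = items[0], items[1:]
    for part in _set_partitions(rest):
        for i in range(len(part)):
            yield part[:i] + [[first] + part[i]] + part[i + 1:]
        yield [[first]] + part


def _guard_text(g: Guard, ctx: EBContext, event: Event) -> str:
    if g.kind == "member":
        return f"{g.params[0]} : {g.set_name}"
    if g.kind == "avail_scalar":
        return f"{g.var} >= {g.amount}"
    if g.kind == "avail_func":
        return _eq_cases_text(g.var, list(g.params))
    if g.kind in ("linking", "ordering"):
        def term(p: str) -> str:
            param = next(pp for pp in event.params if pp.name == p)
            lf = next(f for f in ctx.label_funcs
                      if f.set_name == param.set_name and f.attr == g.attr)
            return f"{lf.name}({p})"
        lhs = " + ".join(term(p) for p in g.lhs_params) or "0"
        rhs = " + ".join(term(p) for p in g.rhs_params) or "0"
        op = "=" if g.kind == "linking" else "<="
        return f"{lhs} {op} {rhs}"
    raise ModelError(f"unknown guard kind {g.kind}")


def _action_text(act: Action) -> str:
    if act.kind == "scalar":
        op = "+" if act.delta >= 0 else "-"
        return f"{act.var} := {act.var} {op} {abs(act.delta)}"
    if len(act.updates) == 1:
        p, d = act.updates[0]
        op = "+" if d >= 0 else "-"
        return f"{act.var}({p}) := {act.var}({p}) {op} {abs(d)}"
    # accumulating override: deltas of coincident arguments add up
    ups = ", ".join(f"{p} |-> {d:+d}" for p, d in act.updates)
    return f"{act.var} := {act.var} <+delta {{{ups}}}"


def _invariant_text(inv: Invariant, machine: EBMachine) -> str:
    if inv.kind == "typing":
        v = machine.var_by_name(inv.var)
        if v.kind == "scalar":
            return f"{inv.var} : NAT"
        return f"{inv.var} : {v.set_name} --> NAT"
    if inv.kind == "conservation":
        terms = []
        for name, c in inv.coeffs.items():
            v = machine.var_by_name(name)
            total = name if v.kind == "scalar" else " + ".join(
                f"{name}({const})" for const in v.domain)
            if v.kind == "function":
                total = f"({total})"
            terms.append(total if c == 1 else f"{c} * {total}")
        return " + ".join(terms) + f" = {inv.constant}"
    if inv.kind == "gluing":
        v = machine.var_by_name(inv.var)
        rhs = " + ".join(f"{inv.var}({const})" for const in v.domain)
        return f"{inv.abstract_var} = {rhs}"
    raise ModelError(f"unknown invariant kind {inv.kind}")


def emit_text(model: Union[EBContext, EBMachine, EBModel],
              context: Optional[EBContext] = None) -> str:
    """Deterministic textual Event-B (Camille-like dialect).

    Byte-identical across runs for identical input.  The accumulating
    override ``<+delta`` updates a function at several (possibly coincident)
    arguments, summing the deltas of coincident ones.
    """
    if isinstance(model, EBModel):
        return emit_text(model.context) + "\n" + emit_text(model.machine, model.context)
    if isinstance(model, EBContext):
        lines = [f"context {model.name}"]
        if model.sets:
            lines.append("sets " + " ".join(s.name for s in model.sets))
        consts = [c for s in model.sets for c in s.constants] + \
                 [f.name for f in model.label_funcs]
        if consts:
            lines.append("constants " + " ".join(consts))
        ax = []
        for s in model.sets:
            ax.append(f"partition({s.name}, " + ", ".join(f"{{{c}}}" for c in s.constants) + ")")
        for f in model.label_funcs:
            pairs = ", ".join(f"{c} |-> {f.values[c]}" for c in
                              model.set_by_name(f.set_name).constants)
            ax.append(f"{f.name} = {{{pairs}}}")
        if ax:
            lines.append("axioms")
            for i, t in enumerate(ax, 1):
                lines.append(f"  @axm{i} {t}")
        lines.append("end")
        return "\n".join(lines) + "\n"

    machine = model
    lines = [f"machine {machine.name}"
             + (f" refines {machine.refines}" if machine.refines else "")
             + (" sees " + " ".join(machine.sees) if machine.sees else "")]
    if machine.variables:
        lines.append("variables " + " ".join(v.name for v in machine.variables))
    if machine.invariants:
        lines.append("invariants")
        for inv in machine.invariants:
            lines.append(f"  @{inv.label} {_invariant_text(inv, machine)}")
    lines.append("events")
    lines.append("  event INITIALISATION")
    lines.append("    then")
    k = 0
    for v in machine.variables:
        k += 1
        val = machine.init.get(v.name, 0)
        if v.kind == "scalar":
            lines.append(f"      @act{k} {v.name} := {val}")
        else:
            pairs = ", ".join(f"{c} |-> {val.get(c, 0)}" for c in v.domain)
            lines.append(f"      @act{k} {v.name} := {{{pairs}}}")
    lines.append("  end")
    for e in machine.events:
        lines.append(f"  event {e.name}")
        if e.params:
            lines.append("    any " + " ".join(p.name for p in e.params))
        if e.guards:
            lines.append("    where")
            for g in e.guards:
                lines.append(f"      @{g.label} {_guard_text(g, context or EBContext('_'), e)}")
        if e.actions:
            lines.append("    then")
            for act in e.actions:
                lines.append(f"      @{act.label} {_action_text(act)}")
        lines.append("  end")
    lines.append("end")
    return "\n".join(lines) + "\n"
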