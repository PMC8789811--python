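"""Consistency verification for generated Event-B machines.

Proof obligations (POs) are generated per (event, invariant) pair plus
initialisation, well-definedness, and — for a machine refining an abstract
one — guard-strengthening (GRD) and action-simulation (SIM) obligations per
event pair.  All atoms in the generated machines are linear (in)equalities
over naturals plus finite-domain parameter constraints, so a small sound
procedure discharges them:

* parameters range over variant sets, small by construction, and are
  handled by exhaustive case enumeration (most checks turn out to be
  case-independent and are decided once);
* equality-invariant preservation reduces to an exact integer identity
  ``coefficients . delta = 0``;
* non-negativity preservation reduces to guard sufficiency: the guard's
  lower bound must cover every subtraction, with coincidence-aware demands
  on function arguments;
* GRD follows from summing concrete availability bounds through the gluing
  equality with non-negativity of the remaining summands;
* SIM is the integer identity "glued concrete delta = abstract delta".

The procedure never reports ``discharged`` unsoundly; anything outside the
fragment comes back ``unknown`` with a reason.  A ``refuted`` result always
carries a concrete counterexample (parameter assignment + state satisfying
the hypotheses, found by bounded search from the initial state) that can be
re-checked by evaluation.

Bounded breadth-first exploration and seeded random trace-refinement
checking complement proving at desk scale.
"""

from __future__ import annotations

import itertools
import random
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple, Union

from .eventb import Action, EBMachine, EBModel, Event, Guard, Invariant, Parameter, Variable

__all__ = [
    "ProofObligation",
    "DischargeResult",
    "ExplorationReport",
    "TraceRefinementResult",
    "generate_pos",
    "discharge",
    "discharge_all",
    "explore",
    "reachable_states",
    "check_trace_refinement",
    "project_state",
    "spot_check_po",
    "initial_state",
    "enabled_moves",
    "apply_event",
    "guards_hold",
]

State = Dict[str, Union[int, Dict[str, int]]]
Case = Dict[str, str]


# ---------------------------------------------------------------------------
# Operational semantics
# ---------------------------------------------------------------------------

def initial_state(model: EBModel) -> State:
    st: State = {}
    for v in model.machine.variables:
        val = model.machine.init.get(v.name, 0)
        if v.kind == "scalar":
            st[v.name] = int(val)
        else:
            table = dict(val) if isinstance(val, dict) else {}
            st[v.name] = {c: int(table.get(c, 0)) for c in v.domain}
    return st


def state_key(machine: EBMachine, state: State) -> Tuple:
    key = []
    for v in machine.variables:
        if v.kind == "scalar":
            key.append(state[v.name])
        else:
            key.append(tuple(state[v.name][c] for c in v.domain))
    return tuple(key)


def _guard_holds(model: EBModel, event: Event, g: Guard, state: Optional[State],
                 case: Case) -> Optional[bool]:
    """Evaluate one guard; ``state=None`` evaluates only state-independent
    guards and returns None for state-dependent ones."""
    if g.kind == "member":
        p = next(pp for pp in event.params if pp.name == g.params[0])
        return case[g.params[0]] in p.domain
    if g.kind in ("linking", "ordering"):
        lhs = sum(model.context.label(case[p], g.attr) for p in g.lhs_params)
        rhs = sum(model.context.label(case[p], g.attr) for p in g.rhs_params)
        return lhs == rhs if g.kind == "linking" else lhs <= rhs
    if state is None:
        return None
    if g.kind == "avail_scalar":
        return state[g.var] >= g.amount
    if g.kind == "avail_func":
        demand: Dict[str, int] = {}
        for p in g.params:
            demand[case[p]] = demand.get(case[p], 0) + 1
        table = state[g.var]
        return all(table.get(c, 0) >= d for c, d in demand.items())
    raise ValueError(f"unknown guard kind {g.kind}")


def guards_hold(model: EBModel, event: Event, state: State, case: Case) -> bool:
    return all(_guard_holds(model, event, g, state, case) for g in event.guards)


def case_admissible(model: EBModel, event: Event, case: Case) -> bool:
    """State-independent guards only (membership, linking, ordering)."""
    for g in event.guards:
        r = _guard_holds(model, event, g, None, case)
        if r is False:
            return False
    return True


def apply_event(machine: EBMachine, event: Event, state: State, case: Case) -> State:
    new: State = {}
    for v in machine.variables:
        new[v.name] = state[v.name] if v.kind == "scalar" else dict(state[v.name])
    for act in event.actions:
        if act.kind == "scalar":
            new[act.var] = new[act.var] + act.delta
        else:
            table = new[act.var]
            for p, d in act.updates:
                c = case[p]
                table[c] = table.get(c, 0) + d
    return new


def enumerate_cases(model: EBModel, event: Event,
                    admissible_only: bool = True) -> Iterable[Case]:
    if not event.params:
        yield {}
        return
    names = [p.name for p in event.params]
    for combo in itertools.product(*(p.domain for p in event.params)):
        case = dict(zip(names, combo))
        if not admissible_only or case_admissible(model, event, case):
            yield case


def enabled_moves(model: EBModel, state: State) -> Iterable[Tuple[Event, Case]]:
    """All fireable (event, parameter case) pairs, in stable order."""
    for event in model.machine.events:
        for case in enumerate_cases(model, event):
            if guards_hold(model, event, state, case):
                yield event, case


def eval_invariant(model: EBModel, inv: Invariant, state: State,
                   abstract: Optional[EBModel] = None,
                   abstract_state: Optional[State] = None) -> bool:
    machine = model.machine
    if inv.kind == "typing":
        v = machine.var_by_name(inv.var)
        if v.kind == "scalar":
            return state[inv.var] >= 0
        return all(x >= 0 for x in state[inv.var].values())
    if inv.kind == "conservation":
        total = 0
        for name, c in inv.coeffs.items():
            v = machine.var_by_name(name)
            val = state[name] if v.kind == "scalar" else sum(state[name].values())
            total += c * val
        return total == inv.constant
    if inv.kind == "gluing":
        if abstract_state is None:
            return True  # relational; checked through SIM/projection
        return abstract_state[inv.abstract_var] == sum(state[inv.var].values())
    raise ValueError(f"unknown invariant kind {inv.kind}")


def project_state(model: EBModel, state: State) -> State:
    """Glue a concrete state onto the abstract state space.

    Function variables map through their gluing invariant's abstract
    variable (sum of values); scalar variables keep their name.
    """
    glue = {inv.var: inv.abstract_var for inv in model.machine.invariants
            if inv.kind == "gluing"}
    out: State = {}
    for v in model.machine.variables:
        if v.kind == "scalar":
            out[v.name] = state[v.name]
        else:
            abs_name = glue.get(v.name)
            if abs_name is None:
                raise ValueError(f"function variable {v.name} has no gluing invariant")
            out[abs_name] = sum(state[v.name].values())
    return out


# ---------------------------------------------------------------------------
# Proof obligations
# ---------------------------------------------------------------------------

@dataclass
class ProofObligation:
    id: str
    kind: str  # INV | INIT | WD | GRD | SIM
    event: Optional[str]
    invariant: Optional[str]
    model: EBModel = field(repr=False)
    abstract: Optional[EBModel] = field(default=None, repr=False)

    def describe(self) -> Dict:
        return {"id": self.id, "kind": self.kind, "event": self.event,
                "invariant": self.invariant, "machine": self.model.machine.name}


@dataclass
class DischargeResult:
    status: str  # "discharged" | "unknown" | "refuted"
    method: Optional[str] = None  # substitution | delta-check | case-enumeration | gluing-sum | frame
    witness: Optional[Dict] = None  # {"case": ..., "state": ...} for refuted
    reason: Optional[str] = None


def generate_pos(concrete: EBModel, abstract: Optional[EBModel] = None) -> List[ProofObligation]:
    """All consistency POs of ``concrete`` (and of its refinement of
    ``abstract`` when given): INV per (event, invariant), INIT per invariant,
    WD per function application, GRD and SIM per corresponding event pair.
    """
    machine = concrete.machine
    pos: List[ProofObligation] = []
    if abstract is not None and machine.refines:
        missing = []
        for v in machine.variables:
            if v.kind == "function":
                if not any(i.kind == "gluing" and i.var == v.name
                           for i in machine.invariants):
                    missing.append(v.name)
        if missing:
            raise ValueError(
                "missing gluing invariant for refined variable(s): " + ", ".join(missing))
    for inv in machine.invariants:
        pos.append(ProofObligation(f"INITIALISATION/{inv.label}/INIT", "INIT",
                                   None, inv.label, concrete, abstract))
    for event in machine.events:
        for inv in machine.invariants:
            pos.append(ProofObligation(f"{event.name}/{inv.label}/INV", "INV",
                                       event.name, inv.label, concrete, abstract))
        napp = _function_applications(event)
        for i in range(napp):
            pos.append(ProofObligation(f"{event.name}/app{i+1}/WD", "WD",
                                       event.name, None, concrete, abstract))
    if abstract is not None:
        for event in machine.events:
            try:
                abstract.machine.event_by_name(event.name)
            except KeyError:
                continue
            pos.append(ProofObligation(f"{event.name}/GRD", "GRD", event.name,
                                       None, concrete, abstract))
            pos.append(ProofObligation(f"{event.name}/SIM", "SIM", event.name,
                                       None, concrete, abstract))
    return pos


def _function_applications(event: Event) -> int:
    n = 0
    for g in event.guards:
        if g.kind == "avail_func":
            n += len(g.params)
        elif g.kind in ("linking", "ordering"):
            n += len(g.lhs_params) + len(g.rhs_params)
    for a in event.actions:
        if a.kind == "func":
            n += len(a.updates)
    return n


# -- discharge helpers ------------------------------------------------------

def _scalar_guard_bound(event: Event, var: str) -> int:
    return max((g.amount for g in event.guards
                if g.kind == "avail_scalar" and g.var == var), default=0)


def _scalar_delta(event: Event, var: str) -> int:
    return sum(a.delta for a in event.actions if a.kind == "scalar" and a.var == var)


def _func_updates(event: Event, var: str) -> List[Tuple[str, int]]:
    ups: List[Tuple[str, int]] = []
    for a in event.actions:
        if a.kind == "func" and a.var == var:
            ups.extend(a.updates)
    return ups


def _func_guard_params(event: Event, var: str) -> List[str]:
    ps: List[str] = []
    for g in event.guards:
        if g.kind == "avail_func" and g.var == var:
            ps.extend(g.params)
    return ps


def _event_touches(event: Event, var: str) -> bool:
    return any(a.var == var for a in event.actions)


def _abstract_delta(abs_model: EBModel, event_name: str, abs_var: str) -> int:
    ev = abs_model.machine.event_by_name(event_name)
    return _scalar_delta(ev, abs_var)


def _glued_delta(event: Event, var: Variable) -> int:
    """Net change of the glued sum; independent of the parameter case."""
    if var.kind == "scalar":
        return _scalar_delta(event, var.name)
    return sum(d for _, d in _func_updates(event, var.name))


def _witness_search(model: EBModel, event: Optional[Event],
                    fails_goal, max_states: int = 4000,
                    require_case: bool = True) -> Optional[Dict]:
    """Bounded BFS from init for a hypothesis-satisfying counterexample.

    A valid witness state satisfies every state-evaluable invariant; when an
    event is involved the event's guards must hold for some admissible case
    and ``fails_goal(state, case)`` must be true.
    """
    machine = model.machine
    seen = {state_key(machine, initial_state(model))}
    frontier = [initial_state(model)]
    cases = list(enumerate_cases(model, event)) if event is not None else [{}]
    checked = 0
    while frontier and checked < max_states:
        next_frontier = []
        for st in frontier:
            checked += 1
            inv_ok = all(eval_invariant(model, inv, st) for inv in machine.invariants
                         if inv.kind != "gluing")
            if inv_ok:
                for case in cases:
                    if event is not None and not guards_hold(model, event, st, case):
                        continue
                    if fails_goal(st, case):
                        return {"case": dict(case), "state": _state_dict(machine, st)}
            for ev, case in enabled_moves(model, st):
                nxt = apply_event(machine, ev, st, case)
                k = state_key(machine, nxt)
                if k not in seen and len(seen) < max_states:
                    seen.add(k)
                    next_frontier.append(nxt)
        frontier = next_frontier
    return None


def _state_dict(machine: EBMachine, state: State) -> Dict:
    out = {}
    for v in machine.variables:
        out[v.name] = state[v.name] if v.kind == "scalar" else dict(state[v.name])
    return out


# -- the discharger ---------------------------------------------------------

def discharge(po: ProofObligation) -> DischargeResult:
    """Sound automatic discharge within the linear fragment."""
    try:
        handler = {
            "INIT": _discharge_init,
            "INV": _discharge_inv,
            "WD": _discharge_wd,
            "GRD": _discharge_grd,
            "SIM": _discharge_sim,
        }[po.kind]
    except KeyError:
        return DischargeResult("unknown", reason=f"unknown PO kind {po.kind}")
    try:
        return handler(po)
    except ValueError as exc:
        return DischargeResult("unknown", reason=str(exc))


def _get_inv(po: ProofObligation) -> Invariant:
    for inv in po.model.machine.invariants:
        if inv.label == po.invariant:
            return inv
    raise ValueError(f"no invariant {po.invariant}")


def _discharge_init(po: ProofObligation) -> DischargeResult:
    inv = _get_inv(po)
    st = initial_state(po.model)
    if inv.kind == "gluing":
        if po.abstract is None:
            return DischargeResult("unknown", reason="gluing INIT needs the abstract machine")
        abs_st = initial_state(po.abstract)
        ok = eval_invariant(po.model, inv, st, po.abstract, abs_st)
    else:
        ok = eval_invariant(po.model, inv, st)
    if ok:
        return DischargeResult("discharged", method="substitution")
    return DischargeResult("refuted", method="substitution",
                           witness={"case": {}, "state": _state_dict(po.model.machine, st)})


def _discharge_inv(po: ProofObligation) -> DischargeResult:
    inv = _get_inv(po)
    machine = po.model.machine
    event = machine.event_by_name(po.event)
    if inv.kind == "typing":
        return _discharge_inv_typing(po, inv, event)
    if inv.kind == "conservation":
        return _discharge_inv_conservation(po, inv, event)
    if inv.kind == "gluing":
        return _discharge_inv_gluing(po, inv, event)
    raise ValueError(f"invariant kind {inv.kind} outside the fragment")


def _discharge_inv_typing(po: ProofObligation, inv: Invariant, event: Event) -> DischargeResult:
    machine = po.model.machine
    var = machine.var_by_name(inv.var)
    if not _event_touches(event, var.name):
        return DischargeResult("discharged", method="frame")
    if var.kind == "scalar":
        delta = _scalar_delta(event, var.name)
        if delta >= 0 or _scalar_guard_bound(event, var.name) + delta >= 0:
            return DischargeResult("discharged", method="substitution")
        w = _witness_search(po.model, event,
                            lambda st, case: st[var.name] + delta < 0)
        if w is not None:
            return DischargeResult("refuted", method="case-enumeration", witness=w)
        return DischargeResult(
            "unknown", reason=f"guard bound does not cover decrement of {var.name}; "
            "no reachable witness found")
    # function variable: guard demand must cover consumption at every
    # argument in every parameter case.  If the consuming parameters are a
    # sub-multiset of the availability-guard parameters this holds for every
    # case at once; otherwise enumerate cases.
    ups = _func_updates(event, var.name)
    consuming = sorted(p for p, d in ups for _ in range(-d) if d < 0)
    guard_ps = sorted(_func_guard_params(event, var.name))
    if _submultiset(consuming, guard_ps):
        return DischargeResult("discharged", method="substitution")
    for case in enumerate_cases(po.model, event):
        delta: Dict[str, int] = {}
        for p, d in ups:
            delta[case[p]] = delta.get(case[p], 0) + d
        demand: Dict[str, int] = {}
        for p in guard_ps:
            demand[case[p]] = demand.get(case[p], 0) + 1
        bad = [c for c, d in delta.items() if d < 0 and demand.get(c, 0) + d < 0]
        if bad:
            const = bad[0]
            w = _witness_search(
                po.model, event,
                lambda st, cs, _c=const, _ups=ups: _func_post(st, cs, var.name, _ups, _c) < 0)
            if w is not None:
                return DischargeResult("refuted", method="case-enumeration", witness=w)
            return DischargeResult(
                "unknown",
                reason=f"demand at {const} does not cover consumption; no witness found")
    return DischargeResult("discharged", method="case-enumeration")


def _func_post(state: State, case: Case, var: str, ups: List[Tuple[str, int]], const: str) -> int:
    val = state[var].get(const, 0)
    for p, d in ups:
        if case[p] == const:
            val += d
    return val


def _submultiset(a: List[str], b: List[str]) -> bool:
    from collections import Counter
    ca, cb = Counter(a), Counter(b)
    return all(cb[k] >= v for k, v in ca.items())


def _discharge_inv_conservation(po: ProofObligation, inv: Invariant, event: Event) -> DischargeResult:
    machine = po.model.machine
    total = 0
    for name, c in inv.coeffs.items():
        var = machine.var_by_name(name)
        total += c * _glued_delta(event, var)
    if total == 0:
        return DischargeResult("discharged", method="delta-check")
    w = _witness_search(po.model, event, lambda st, case: True)
    if w is not None:
        return DischargeResult("refuted", method="delta-check", witness=w)
    return DischargeResult("unknown",
                           reason=f"conserved total changes by {total}; no witness found")


def _discharge_inv_gluing(po: ProofObligation, inv: Invariant, event: Event) -> DischargeResult:
    if po.abstract is None:
        return DischargeResult("unknown", reason="gluing INV needs the abstract machine")
    machine = po.model.machine
    var = machine.var_by_name(inv.var)
    conc = _glued_delta(event, var)
    try:
        abs_delta = _abstract_delta(po.abstract, event.name, inv.abstract_var)
    except KeyError:
        return DischargeResult("unknown",
                               reason=f"no abstract event named {event.name}")
    if conc == abs_delta:
        return DischargeResult("discharged", method="delta-check")
    w = _witness_search(po.model, event, lambda st, case: True)
    if w is not None:
        return DischargeResult("refuted", method="delta-check", witness=w)
    return DischargeResult("unknown",
                           reason="glued delta differs from abstract delta; no witness found")


def _discharge_wd(po: ProofObligation) -> DischargeResult:
    """Function applications are well-defined when every applied parameter
    ranges over exactly the function's domain set (singleton-partitioned)."""
    machine = po.model.machine
    event = machine.event_by_name(po.event)
    pset = {p.name: p for p in event.params}
    for g in event.guards:
        if g.kind == "avail_func":
            var = machine.var_by_name(g.var)
            for p in g.params:
                if p not in pset or pset[p].set_name != var.set_name:
                    return DischargeResult(
                        "refuted", method="substitution",
                        witness={"case": {}, "state": {},
                                 "detail": f"parameter {p} outside domain of {g.var}"})
    for a in event.actions:
        if a.kind == "func":
            var = machine.var_by_name(a.var)
            for p, _ in a.updates:
                if p not in pset or pset[p].set_name != var.set_name:
                    return DischargeResult(
                        "refuted", method="substitution",
                        witness={"case": {}, "state": {},
                                 "detail": f"parameter {p} outside domain of {a.var}"})
    return DischargeResult("discharged", method="substitution")


def _discharge_grd(po: ProofObligation) -> DischargeResult:
    """Concrete guards + gluing + non-negativity entail the abstract guards."""
    machine = po.model.machine
    event = machine.event_by_name(po.event)
    abs_event = po.abstract.machine.event_by_name(po.event)
    glue = {inv.abstract_var: inv.var for inv in machine.invariants if inv.kind == "gluing"}
    for g in abs_event.guards:
        if g.kind != "avail_scalar":
            return DischargeResult("unknown",
                                   reason=f"abstract guard kind {g.kind} outside fragment")
        if g.var in glue:
            # A = sum rA(v) >= sum of per-argument demands = #consuming params
            demand = len(_func_guard_params(event, glue[g.var]))
            ok = demand >= g.amount
        else:
            ok = _scalar_guard_bound(event, g.var) >= g.amount
        if not ok:
            gv = g.var

            def fails(st: State, case: Case, _g=g) -> bool:
                proj = project_state(po.model, st)
                val = proj.get(_g.var)
                return val is None or val < _g.amount

            w = _witness_search(po.model, event, fails)
            if w is not None:
                return DischargeResult("refuted", method="gluing-sum", witness=w)
            return DischargeResult(
                "unknown", reason=f"cannot entail abstract guard on {gv}; no witness found")
    return DischargeResult("discharged", method="gluing-sum")


def _discharge_sim(po: ProofObligation) -> DischargeResult:
    """Glued effect of the concrete event equals the abstract action."""
    machine = po.model.machine
    event = machine.event_by_name(po.event)
    abs_machine = po.abstract.machine
    glue = {inv.var: inv.abstract_var for inv in machine.invariants if inv.kind == "gluing"}
    for av in abs_machine.variables:
        abs_delta = _scalar_delta(abs_machine.event_by_name(po.event), av.name)
        conc_var = None
        for v in machine.variables:
            if (v.kind == "scalar" and v.name == av.name) or glue.get(v.name) == av.name:
                conc_var = v
                break
        if conc_var is None:
            return DischargeResult("unknown",
                                   reason=f"abstract variable {av.name} has no concrete image")
        if _glued_delta(event, conc_var) != abs_delta:
            w = _witness_search(po.model, event, lambda st, case: True)
            if w is not None:
                return DischargeResult("refuted", method="delta-check", witness=w)
            return DischargeResult(
                "unknown",
                reason=f"glued delta of {av.name} differs from abstract; no witness found")
    return DischargeResult("discharged", method="delta-check")


def discharge_all(pos: Sequence[ProofObligation]) -> Dict:
    """Discharge every PO; summary with per-kind and per-status counts."""
    results = [(po, discharge(po)) for po in pos]
    summary = {
        "total": len(results),
        "discharged": sum(1 for _, r in results if r.status == "discharged"),
        "refuted": sum(1 for _, r in results if r.status == "refuted"),
        "unknown": sum(1 for _, r in results if r.status == "unknown"),
        "by_kind": {},
        "failures": [
            {**po.describe(), "status": r.status, "reason": r.reason,
             "witness": r.witness}
            for po, r in results if r.status != "discharged"
        ],
    }
    for po, r in results:
        k = summary["by_kind"].setdefault(po.kind, {"total": 0, "discharged": 0})
        k["total"] += 1
        if r.status == "discharged":
            k["discharged"] += 1
    return summary


# ---------------------------------------------------------------------------
# Exploration
# ---------------------------------------------------------------------------

@dataclass
class ExplorationReport:
    states: int
    transitions: int
    depth: int
    violations: List[Dict]
    truncated: bool = False


def reachable_states(model: EBModel, depth: int,
                     init: Optional[State] = None,
                     max_states: int = 100000) -> Tuple[List[State], bool]:
    """Breadth-first reachable states up to ``depth`` event firings."""
    machine = model.machine
    st0 = init if init is not None else initial_state(model)
    seen = {state_key(machine, st0)}
    states = [st0]
    frontier = [st0]
    truncated = False
    for _ in range(depth):
        nxt = []
        for st in frontier:
            for ev, case in enabled_moves(model, st):
                new = apply_event(machine, ev, st, case)
                k = state_key(machine, new)
                if k not in seen:
                    if len(seen) >= max_states:
                        truncated = True
                        continue
                    seen.add(k)
                    states.append(new)
                    nxt.append(new)
        frontier = nxt
        if not frontier:
            break
    return states, truncated


def explore(model: EBModel, depth: int, init: Optional[State] = None,
            max_states: int = 100000) -> ExplorationReport:
    """BFS reachability with invariant checking on every reached state."""
    if depth < 0:
        raise ValueError("depth must be >= 0")
    machine = model.machine
    st0 = init if init is not None else initial_state(model)
    seen = {state_key(machine, st0)}
    frontier = [st0]
    violations: List[Dict] = []
    transitions = 0
    truncated = False

    def check(st: State, trace: List[str]):
        for inv in machine.invariants:
            if inv.kind == "gluing":
                continue
            if not eval_invariant(model, inv, st):
                violations.append({"invariant": inv.label,
                                   "state": _state_dict(machine, st),
                                   "trace": list(trace)})

    check(st0, [])
    paths = {state_key(machine, st0): []}
    d = 0
    for d in range(1, depth + 1):
        nxt = []
        for st in frontier:
            trace = paths[state_key(machine, st)]
            for ev, case in enabled_moves(model, st):
                transitions += 1
                new = apply_event(machine, ev, st, case)
                k = state_key(machine, new)
                if k not in seen:
                    if len(seen) >= max_states:
                        truncated = True
                        continue
                    seen.add(k)
                    paths[k] = trace + [ev.name]
                    check(new, paths[k])
                    nxt.append(new)
        frontier = nxt
        if not frontier:
            break
    return ExplorationReport(states=len(seen), transitions=transitions,
                             depth=min(d, depth), violations=violations,
                             truncated=truncated)


# ---------------------------------------------------------------------------
# Trace refinement
# ---------------------------------------------------------------------------

@dataclass
class TraceRefinementResult:
    steps_run: int
    mismatches: List[Dict]

    @property
    def ok(self) -> bool:
        return not self.mismatches


def check_trace_refinement(concrete: EBModel, abstract: EBModel,
                           steps: int, seed: int) -> TraceRefinementResult:
    """Seeded random concrete traces, projected through the gluing sums.

    After every step the projected transition must be realized by the
    abstract event of the same name, and all abstract invariants must hold
    on the projection.
    """
    rng = random.Random(seed)
    machine = concrete.machine
    st = initial_state(concrete)
    mismatches: List[Dict] = []
    steps_run = 0
    for step in range(steps):
        moves = list(enabled_moves(concrete, st))
        if not moves:
            break
        ev, case = moves[rng.randrange(len(moves))]
        pre_proj = project_state(concrete, st)
        missing = [v.name for v in abstract.machine.variables if v.name not in pre_proj]
        if missing:
            mismatches.append({"step": step, "event": ev.name,
                               "error": "projection misses abstract variable(s)",
                               "variables": missing})
            break
        st2 = apply_event(machine, ev, st, case)
        post_proj = project_state(concrete, st2)
        steps_run += 1
        try:
            abs_ev = abstract.machine.event_by_name(ev.name)
        except KeyError:
            mismatches.append({"step": step, "event": ev.name,
                               "error": "no abstract event"})
            break
        if not guards_hold(abstract, abs_ev, pre_proj, {}):
            mismatches.append({"step": step, "event": ev.name,
                               "error": "abstract guard fails on projection",
                               "concrete": _state_dict(machine, st),
                               "projected": pre_proj})
            break
        expected = apply_event(abstract.machine, abs_ev, pre_proj, {})
        if state_key(abstract.machine, expected) != state_key(abstract.machine, post_proj):
            mismatches.append({"step": step, "event": ev.name,
                               "error": "projected transition not simulated",
                               "projected_post": post_proj,
                               "abstract_post": _state_dict(abstract.machine, expected)})
            break
        bad = [inv.label for inv in abstract.machine.invariants
               if not eval_invariant(abstract, inv, post_proj)]
        if bad:
            mismatches.append({"step": step, "event": ev.name,
                               "error": "abstract invariant fails on projection",
                               "invariants": bad})
            break
        st = st2
    return TraceRefinementResult(steps_run, mismatches)


# ---------------------------------------------------------------------------
# Stochastic spot check of discharged POs
# ---------------------------------------------------------------------------

def spot_check_po(po: ProofObligation, samples: int, seed: int,
                  walk_length: int = 12) -> int:
    """Randomized soundness check of a discharged PO.

    Samples hypothesis-satisfying states by seeded random walks from the
    initial state, picks random parameter cases, and evaluates the PO's goal
    concretely.  Returns the number of counterexamples found (0 expected for
    a soundly discharged PO).
    """
    rng = random.Random(seed)
    model = po.model
    machine = model.machine
    event = machine.event_by_name(po.event) if po.event else None
    cases = list(enumerate_cases(model, event)) if event is not None else [{}]
    found = 0
    for _ in range(samples):
        st = initial_state(model)
        for _ in range(rng.randrange(walk_length + 1)):
            moves = list(enabled_moves(model, st))
            if not moves:
                break
            ev, case = moves[rng.randrange(len(moves))]
            st = apply_event(machine, ev, st, case)
        if event is None:
            st = initial_state(model)
            case = {}
        else:
            case = cases[rng.randrange(len(cases))]
            if not guards_hold(model, event, st, case):
                continue
        if not _goal_holds(po, st, case):
            found += 1
    return found


def _goal_holds(po: ProofObligation, st: State, case: Case) -> bool:
    model = po.model
    machine = model.machine
    if po.kind == "INIT":
        inv = _get_inv(po)
        st0 = initial_state(model)
        if inv.kind == "gluing":
            return eval_invariant(model, inv, st0, po.abstract,
                                  initial_state(po.abstract))
        return eval_invariant(model, inv, st0)
    event = machine.event_by_name(po.event)
    post = apply_event(machine, event, st, case)
    if po.kind == "INV":
        inv = _get_inv(po)
        if inv.kind == "gluing":
            pre_proj = project_state(model, st)
            abs_ev = po.abstract.machine.event_by_name(event.name)
            abs_post = apply_event(po.abstract.machine, abs_ev, pre_proj, {})
            return eval_invariant(model, inv, post, po.abstract, abs_post)
        return eval_invariant(model, inv, post)
    if po.kind == "GRD":
        proj = project_state(model, st)
        abs_ev = po.abstract.machine.event_by_name(event.name)
        return guards_hold(po.abstract, abs_ev, proj, {})
    if po.kind == "SIM":
        pre_proj = project_state(model, st)
        abs_ev = po.abstract.machine.event_by_name(event.name)
        expected = apply_event(po.abstract.machine, abs_ev, pre_proj, {})
        post_proj = project_state(model, post)
        return state_key(po.abstract.machine, expected) == \
            state_key(po.abstract.machine, post_proj)
    if po.kind == "WD":
        return True
    return True
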