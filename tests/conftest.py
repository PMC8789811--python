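import copy
from dataclasses import dataclass
from typing import Dict, List, Optional

import pytest

from reactb.eventb import (EBModel, default_refined_init, gen_abstract_model,
                           gen_compact_model, gen_expanded_model)
from reactb.fixtures import load_fixture
from reactb.network import (conservation_basis, normalize_reversible,
                            stoichiometric_delta)
from reactb.refine import compact_plan, derive_variant_families, expand_network


@dataclass
class ModelBundle:
    """Everything derived from one network + refinement + init."""

    fixture: object
    norm: object
    delta: object
    laws: list
    rmap: object
    refined: object
    plan: object
    abstract: EBModel
    expanded: EBModel
    compact: EBModel
    init: Dict[str, int]
    refined_init: Dict[str, int]


def build_bundle(name: str, init: Optional[Dict[str, int]] = None) -> ModelBundle:
    fx = load_fixture(name)
    init = dict(init if init is not None else fx.init)
    norm = normalize_reversible(fx.network)
    delta = stoichiometric_delta(norm)
    laws = conservation_basis(delta, norm.species_ids)
    rmap = derive_variant_families(norm, fx.spec)
    refined = expand_network(norm, rmap)
    plan = compact_plan(norm, rmap)
    abstract = gen_abstract_model(norm, laws, init)
    rinit = default_refined_init(rmap, init)
    expanded = gen_expanded_model(refined, rinit)
    compact = gen_compact_model(plan, rmap, laws, rinit, abstract)
    return ModelBundle(fx, norm, delta, laws, rmap, refined, plan,
                       abstract, expanded, compact, init, rinit)


@pytest.fixture(scope="session")
def hsr() -> ModelBundle:
    return build_bundle("hsr")


@pytest.fixture(scope="session")
def hsr_small() -> ModelBundle:
    """HSR with a small initial state, for exhaustive exploration."""
    return build_bundle("hsr", init={"hsf": 3, "hse": 1, "prot": 2})


# -- machine mutation helpers (fault injection) -----------------------------

def weaken_guard(model: EBModel, event_name: str, var: str, amount: int) -> EBModel:
    m = copy.deepcopy(model)
    ev = m.machine.event_by_name(event_name)
    g = next(g for g in ev.guards if g.kind == "avail_scalar" and g.var == var)
    g.amount = amount
    return m


def perturb_action(model: EBModel, event_name: str, var: str, delta: int) -> EBModel:
    m = copy.deepcopy(model)
    ev = m.machine.event_by_name(event_name)
    a = next(a for a in ev.actions if a.var == var)
    a.delta = delta
    return m


def corrupt_gluing(model: EBModel, func_var: str, wrong_abstract: str) -> EBModel:
    m = copy.deepcopy(model)
    inv = next(i for i in m.machine.invariants
               if i.kind == "gluing" and i.var == func_var)
    inv.abstract_var = wrong_abstract
    return m
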