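"""End-to-end pipeline: parse -> normalize -> conserve -> refine -> emit -> verify.

``run_pipeline`` drives every stage on one network + refinement spec and
returns a JSON-ready report of all model statistics and verification
statuses.  Stage failures are re-raised as :class:`PipelineError` carrying
the stage label.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Mapping, Optional

from .eventb import (EBModel, default_refined_init, gen_abstract_model,
                     gen_compact_model, gen_expanded_model)
from .network import (ConservationLaw, ReactionNetwork, conservation_basis,
                      normalize_reversible, stoichiometric_delta)
from .refine import (CompactModelPlan, RefinedNetwork, RefinementMap,
                     RefinementSpec, compact_plan, derive_variant_families,
                     expand_network)
from .verify import (check_trace_refinement, discharge_all, explore,
                     generate_pos)

__all__ = ["PipelineError", "PipelineResult", "run_pipeline", "lift_laws"]


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        self.stage = stage
        self.cause = cause
        super().__init__(f"[{stage}] {cause}")


@dataclass
class PipelineResult:
    report: Dict
    abstract: Optional[EBModel] = None
    expanded: Optional[EBModel] = None
    compact: Optional[EBModel] = None
    refined: Optional[RefinedNetwork] = None

    @property
    def ok(self) -> bool:
        return self.report.get("all_discharged", True) and \
            not self.report.get("violations", 0)


def lift_laws(laws: List[ConservationLaw], rmap: RefinementMap) -> List[ConservationLaw]:
    """Abstract conservation laws restated over refined species, plus one
    label-moiety law per refined attribute (both hold on the refined
    stoichiometry by construction of the label-balanced expansion)."""
    out: List[ConservationLaw] = []
    for law in laws:
        coeffs = {v.id: c for s, c in law.coefficients.items()
                  for v in rmap.family(s).variants}
        out.append(ConservationLaw(coeffs, f"lifted {law.description}"))
    attrs = sorted({attr for fam in rmap.partition.values() for attr in fam.dims})
    for attr in attrs:
        coeffs = {v.id: v.label(attr) for fam in rmap.partition.values()
                  for v in fam.variants if v.label(attr) != 0}
        if coeffs:
            out.append(ConservationLaw(coeffs, f"label-moiety[{attr}]"))
    return out


def _stage(name: str):
    class _Ctx:
        def __enter__(self):
            return self

        def __exit__(self, exc_type, exc, tb):
            if exc is not None and not isinstance(exc, PipelineError):
                raise PipelineError(name, exc) from exc
            return False
    return _Ctx()


def run_pipeline(network: ReactionNetwork,
                 spec: Optional[RefinementSpec] = None,
                 init: Optional[Mapping[str, int]] = None,
                 *,
                 explore_depth: Optional[int] = None,
                 explore_init: Optional[Mapping[str, int]] = None,
                 trace_steps: int = 0,
                 seed: int = 0,
                 recompute_refined_laws: bool = False,
                 laws: Optional[List[ConservationLaw]] = None) -> PipelineResult:
    """Execute the full modeling + verification pipeline.

    With no refinement spec only the abstract model is built and verified.
    ``recompute_refined_laws`` switches the expanded model's conservation
    invariants from lifted abstract laws + label moieties to a full kernel
    recomputation on the refined stoichiometry (slower at scale).
    ``laws`` pins the conservation invariants instead of deriving them from
    the network's stoichiometry — useful for fault injection, where an
    edited network must be checked against the original moieties.
    """
    report: Dict = {"stages": []}
    init = dict(init or {})

    with _stage("normalize"):
        norm = normalize_reversible(network)
        report["species"] = len(norm.species)
        report["reactions"] = len(norm.reactions)
        report["stages"].append("normalize")

    with _stage("conservation"):
        if laws is None:
            delta = stoichiometric_delta(norm)
            laws = conservation_basis(delta, norm.species_ids)
        report["conservation_laws"] = [law.description for law in laws]
        report["stages"].append("conservation")

    with _stage("abstract-model"):
        abstract = gen_abstract_model(norm, laws, init)
        report["abstract"] = {
            "variables": len(abstract.machine.variables),
            "events": len(abstract.machine.events),
            "invariants": len(abstract.machine.invariants),
        }
        report["stages"].append("abstract-model")

    expanded = compact = refined = None
    if spec is not None:
        with _stage("refine"):
            rmap = derive_variant_families(norm, spec)
            refined = expand_network(norm, rmap)
            plan = compact_plan(norm, rmap)
            report["refined"] = {
                "species": len(refined.network.species),
                "reactions": len(refined.network.reactions),
                "families": {a: rmap.family(a).size for a in norm.species_ids},
                "empty_refinements": refined.empty_refinements,
            }
            report["stages"].append("refine")

        with _stage("expanded-model"):
            rinit = default_refined_init(rmap, init)
            rlaws = None if recompute_refined_laws else lift_laws(laws, rmap)
            expanded = gen_expanded_model(refined, rinit, laws=rlaws)
            report["expanded"] = {
                "variables": len(expanded.machine.variables),
                "events": len(expanded.machine.events),
                "invariants": len(expanded.machine.invariants),
            }
            report["stages"].append("expanded-model")

        with _stage("compact-model"):
            compact = gen_compact_model(plan, rmap, laws, rinit, abstract)
            report["compact"] = {
                "variables": len(compact.machine.variables),
                "events": len(compact.machine.events),
                "invariants": len(compact.machine.invariants),
            }
            report["stages"].append("compact-model")

    with _stage("verify"):
        verification = {}
        targets = [("abstract", abstract, None)]
        if expanded is not None:
            targets.append(("expanded", expanded, None))
        if compact is not None:
            targets.append(("compact", compact, abstract))
        all_ok = True
        for label, model, abs_model in targets:
            pos = generate_pos(model, abs_model)
            summary = discharge_all(pos)
            # witnesses can be bulky; keep only the headline in the report
            summary_slim = {k: v for k, v in summary.items() if k != "failures"}
            summary_slim["failures"] = [
                {k: f[k] for k in ("id", "kind", "status", "reason")}
                for f in summary["failures"]
            ]
            verification[label] = summary_slim
            all_ok = all_ok and summary["discharged"] == summary["total"]
        report["verification"] = verification
        report["all_discharged"] = all_ok
        report["stages"].append("verify")

    if explore_depth is not None:
        with _stage("explore"):
            target = compact if compact is not None else abstract
            ex_init = None
            if explore_init is not None:
                from .verify import initial_state
                base = gen_abstract_model(norm, laws, dict(explore_init))
                if target is compact:
                    r = default_refined_init(rmap, dict(explore_init))
                    target_tmp = gen_compact_model(plan, rmap, laws, r, base)
                    rep = explore(target_tmp, explore_depth)
                else:
                    rep = explore(base, explore_depth)
            else:
                rep = explore(target, explore_depth)
            report["exploration"] = {
                "states": rep.states, "transitions": rep.transitions,
                "violations": len(rep.violations), "truncated": rep.truncated,
            }
            report["violations"] = len(rep.violations)
            report["stages"].append("explore")

    if trace_steps and compact is not None:
        with _stage("trace-refinement"):
            res = check_trace_refinement(compact, abstract, trace_steps, seed)
            report["trace_refinement"] = {
                "steps": res.steps_run, "mismatches": len(res.mismatches),
            }
            report["stages"].append("trace-refinement")

    return PipelineResult(report, abstract, expanded, compact, refined)
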