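"""PO generation, linear-fragment discharge, exploration, trace refinement."""

import random

import pytest

from conftest import corrupt_gluing, perturb_action, weaken_guard
from reactb.eventb import gen_abstract_model
from reactb.network import conservation_basis, normalize_reversible, \
    parse_network, stoichiometric_delta
from reactb.verify import (apply_event, check_trace_refinement, discharge,
                           discharge_all, enabled_moves, explore,
                           generate_pos, initial_state, project_state,
                           reachable_states, spot_check_po, state_key)


def _simple_model(text="r1: A -> B", init=None):
    net = normalize_reversible(parse_network(text))
    laws = conservation_basis(stoichiometric_delta(net), net.species_ids)
    return gen_abstract_model(net, laws, init or {"A": 2})


class TestGeneratePos:
    def test_count_formula_hsr_abstract(self, hsr):
        """17 events x 13 invariants INV + 13 INIT, no WD (scalars only)."""
        pos = generate_pos(hsr.abstract)
        by_kind = {}
        for po in pos:
            by_kind[po.kind] = by_kind.get(po.kind, 0) + 1
        assert by_kind == {"INV": 17 * 13, "INIT": 13}
        # cross-check by explicit enumeration over pairs
        pairs = {(po.event, po.invariant) for po in pos if po.kind == "INV"}
        assert len(pairs) == 17 * 13

    def test_single_event_single_invariant(self):
        model = _simple_model()
        model.machine.invariants = model.machine.invariants[:1]
        pos = generate_pos(model)
        kinds = sorted(po.kind for po in pos)
        assert kinds == ["INIT", "INV"]

    def test_refinement_pos_for_all_event_pairs(self, hsr):
        pos = generate_pos(hsr.compact, hsr.abstract)
        grd = {po.event for po in pos if po.kind == "GRD"}
        sim = {po.event for po in pos if po.kind == "SIM"}
        assert len(grd) == len(sim) == 17

    def test_missing_gluing_invariant_rejected(self, hsr):
        import copy
        broken = copy.deepcopy(hsr.compact)
        broken.machine.invariants = [i for i in broken.machine.invariants
                                     if i.kind != "gluing"]
        with pytest.raises(ValueError, match="gluing"):
            generate_pos(broken, hsr.abstract)


class TestDischarge:
    def test_conservation_discharged_by_zero_delta(self):
        model = _simple_model()
        po = next(p for p in generate_pos(model)
                  if p.kind == "INV" and
                  model.machine.invariants[[i.label for i in model.machine.invariants]
                                           .index(p.invariant)].kind == "conservation")
        res = discharge(po)
        assert res.status == "discharged" and res.method == "delta-check"

    def test_all_hsr_machines_fully_discharged(self, hsr):
        """Every consistency PO of the abstract, expanded and compact HSR
        machines is discharged automatically."""
        for model, abstract in [(hsr.abstract, None), (hsr.expanded, None),
                                (hsr.compact, hsr.abstract)]:
            summary = discharge_all(generate_pos(model, abstract))
            assert summary["discharged"] == summary["total"], summary["failures"][:3]

    def test_gluing_sim_for_binding_event(self, hsr):
        # r5_f: hsp + hsf -> hsp:hsf (binding with two refined species)
        pos = generate_pos(hsr.compact, hsr.abstract)
        po = next(p for p in pos if p.kind == "SIM" and p.event == "r5_f")
        res = discharge(po)
        assert res.status == "discharged"

    def test_weakened_guard_refuted_with_checkable_witness(self, hsr):
        mutated = weaken_guard(hsr.abstract, "r1_f", "hsf", 1)
        summary = discharge_all(generate_pos(mutated))
        assert summary["refuted"] >= 1
        fail = next(f for f in summary["failures"] if f["status"] == "refuted")
        # re-check the counterexample by evaluation
        st = fail["witness"]["state"]
        ev = mutated.machine.event_by_name(fail["id"].split("/")[0])
        post = apply_event(mutated.machine, ev, st, fail["witness"]["case"])
        assert any(v < 0 for v in post.values() if isinstance(v, int))

    def test_perturbed_coefficient_refuted(self, hsr):
        mutated = perturb_action(hsr.abstract, "r10", "mfp", 2)
        summary = discharge_all(generate_pos(mutated))
        assert summary["refuted"] >= 1

    def test_broken_gluing_refuted(self, hsr):
        mutated = corrupt_gluing(hsr.compact, "rhsf", "hsf2")
        summary = discharge_all(generate_pos(mutated, hsr.abstract))
        assert summary["refuted"] >= 1

    def test_soundness_spot_check(self, hsr):
        """Discharged POs survive seeded random state/parameter sampling."""
        pos = generate_pos(hsr.compact, hsr.abstract)
        rng = random.Random(0)
        sample = rng.sample(pos, 40)
        total_samples = 0
        for po in sample:
            assert discharge(po).status == "discharged"
            total_samples += 250
            assert spot_check_po(po, 250, seed=rng.randrange(2 ** 30)) == 0
        assert total_samples == 10_000


class TestExplore:
    def test_depth_zero_is_initial_state_only(self, hsr_small):
        rep = explore(hsr_small.abstract, 0)
        assert rep.states == 1 and rep.transitions == 0

    def test_hsr_small_depth6_no_violations(self, hsr_small):
        rep = explore(hsr_small.abstract, 6)
        assert rep.violations == [] and rep.states > 1

    def test_explored_states_match_independent_simulation(self, hsr_small):
        """Oracle: direct multiset simulation from the reaction network,
        bypassing the Event-B machinery entirely."""
        norm = hsr_small.norm
        init = {s: hsr_small.init.get(s, 0) for s in norm.species_ids}

        def fire(state):
            for r in norm.reactions:
                if all(state[s] >= m for s, m in r.reactants.items()):
                    new = dict(state)
                    for s, m in r.reactants.items():
                        new[s] -= m
                    for s, m in r.products.items():
                        new[s] += m
                    yield new

        seen = {tuple(sorted(init.items()))}
        frontier = [init]
        for _ in range(5):
            nxt = []
            for stt in frontier:
                for new in fire(stt):
                    k = tuple(sorted(new.items()))
                    if k not in seen:
                        seen.add(k)
                        nxt.append(new)
            frontier = nxt
        states, _ = reachable_states(hsr_small.abstract, 5)
        machine = hsr_small.abstract.machine
        got = {state_key(machine, s) for s in states}
        oracle = {tuple(dict(k)[v.species] for v in machine.variables)
                  for k in seen}
        assert got == oracle

    def test_init_violating_conservation_flagged_at_depth_zero(self, hsr_small):
        st0 = initial_state(hsr_small.abstract)
        st0["hse"] += 5  # breaks the hse-moiety constant
        rep = explore(hsr_small.abstract, 0, init=st0)
        assert len(rep.violations) >= 1

    def test_state_cap_flags_truncation(self, hsr):
        rep = explore(hsr.abstract, 6, max_states=10)
        assert rep.truncated


class TestTraceRefinement:
    def test_compact_vs_abstract_thousand_steps(self, hsr):
        res = check_trace_refinement(hsr.compact, hsr.abstract, 1000, seed=7)
        assert res.mismatches == []
        assert res.steps_run == 1000

    def test_identity_projection_trivial(self, hsr):
        # a machine refining itself through identity gluing: projection is id
        res = check_trace_refinement(hsr.abstract, hsr.abstract, 50, seed=3)
        assert res.mismatches == []

    def test_corrupted_gluing_detected_within_bounded_steps(self, hsr):
        mutated = corrupt_gluing(hsr.compact, "rhsf", "hsf2")
        res = check_trace_refinement(mutated, hsr.abstract, 500, seed=1)
        assert len(res.mismatches) == 1

    def test_lockstep_oracle_expanded_machine(self, hsr_small):
        """The expanded machine executed in lockstep realizes every
        projected compact transition (independent oracle for gluing)."""
        rng = random.Random(11)
        comp = hsr_small.compact
        expd = hsr_small.expanded
        variant_of_const = {}
        for v in comp.machine.variables:
            for const, sid in zip(v.domain, v.domain_species):
                variant_of_const[(v.name, const)] = sid

        def expanded_equiv(state):
            # compact state -> expanded machine state (same refined counts)
            m = {}
            for v in comp.machine.variables:
                if v.kind == "scalar":
                    m[v.species] = state[v.name]
                else:
                    for const, sid in zip(v.domain, v.domain_species):
                        m[sid] = state[v.name][const]
            return {v.name: m[v.species] for v in expd.machine.variables}

        st = initial_state(comp)
        for _ in range(200):
            moves = list(enabled_moves(comp, st))
            if not moves:
                break
            ev, case = moves[rng.randrange(len(moves))]
            new = apply_event(comp.machine, ev, st, case)
            # some expanded event must produce the same refined state
            e_st = expanded_equiv(st)
            e_target = expanded_equiv(new)
            hits = [em for em, _ in enabled_moves(expd, e_st)
                    if state_key(expd.machine,
                                 apply_event(expd.machine, em, e_st, {}))
                    == state_key(expd.machine, e_target)]
            assert hits, ev.name
            st = new


class TestBisimulation:
    def test_projected_reachable_sets_equal(self, hsr_small):
        """Compact and expanded machines reach the same projected state
        sets at equal depth from matched small inits."""
        rmap = hsr_small.rmap
        comp, expd = hsr_small.compact, hsr_small.expanded
        abs_machine = hsr_small.abstract.machine
        sp_of_var = {v.name: v.species for v in abs_machine.variables}

        def proj_compact(stt):
            p = project_state(comp, stt)
            return tuple(sorted((sp_of_var[k], x) for k, x in p.items()))

        def proj_expanded(stt):
            out = {}
            for v in expd.machine.variables:
                a = rmap.abstract_of(v.species)
                out[a] = out.get(a, 0) + stt[v.name]
            return tuple(sorted(out.items()))

        for depth in (2, 4, 6):
            sc, tc = reachable_states(comp, depth)
            se, te = reachable_states(expd, depth)
            assert not tc and not te
            assert {proj_compact(s) for s in sc} == {proj_expanded(s) for s in se}
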