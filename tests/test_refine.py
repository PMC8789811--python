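"""Variant-family derivation, expansion, and compact-plan equivalence."""

import itertools
from collections import Counter

import pytest
from hypothesis import given, settings, strategies as st

from reactb.fixtures import load_fixture
from reactb.generator import GeneratorConfig, generate_random
from reactb.network import normalize_reversible, parse_network
from reactb.refine import (RefinementError, RefinementSpec, compact_plan,
                           derive_variant_families, expand_network)


def brute_force_refined(reaction, rmap):
    """Independent oracle: enumerate ordered variant tuples per occurrence
    unit, keep the label-balanced ones, canonicalize to side multisets."""
    occ_l = [sid for sid in sorted(reaction.reactants)
             for _ in range(reaction.reactants[sid])]
    occ_r = [sid for sid in sorted(reaction.products)
             for _ in range(reaction.products[sid])]
    out = set()
    for combo_l in itertools.product(*[rmap.family(s).variants for s in occ_l]):
        for combo_r in itertools.product(*[rmap.family(s).variants for s in occ_r]):
            attrs = {a for v in combo_l + combo_r for a, _ in v.labels}
            if any(sum(v.label(a) for v in combo_l) != sum(v.label(a) for v in combo_r)
                   for a in attrs):
                continue
            key = (tuple(sorted(Counter(v.id for v in combo_l).items())),
                   tuple(sorted(Counter(v.id for v in combo_r).items())))
            out.add(key)
    return out


class TestVariantFamilies:
    def test_hetero_complex_tuple_family(self):
        """A:B with A refined x2 and B refined x3 -> 6 tuple variants."""
        net = parse_network("r1: A + B -> C").with_compositions({"C": {"A": 1, "B": 1}})
        rmap = derive_variant_families(
            normalize_reversible(net),
            RefinementSpec({"A": ["0", "1"], "B": ["0", "1", "2"]}))
        fam = rmap.family("C")
        assert fam.size == 6 and fam.index_kind == "tuple"

    def test_dimer_aggregated_family(self):
        bundle = load_fixture("dimer_toy")
        rmap = derive_variant_families(normalize_reversible(bundle.network), bundle.spec)
        fam = rmap.family("C")
        assert fam.variant_ids() == ["C_A0", "C_A1", "C_A2"]
        assert fam.index_kind == "aggregate"

    def test_hsr_cascade_sizes(self, hsr):
        sizes = {a: hsr.rmap.family(a).size for a in hsr.norm.species_ids}
        assert sizes == {"hsf": 2, "hsp:hsf": 2, "hsf2": 3, "hsf3": 4,
                         "hsf3:hse": 4, "hse": 1, "hsp": 1, "prot": 1,
                         "mfp": 1, "hsp:mfp": 1}

    def test_ligand_receptor_two_by_four(self):
        net = parse_network("r1: EGF + EGFR -> EGF:EGFR").with_compositions(
            {"EGF:EGFR": {"EGF": 1, "EGFR": 1}})
        rmap = derive_variant_families(
            normalize_reversible(net),
            RefinementSpec({"EGF": ["EGF", "HRG"],
                            "EGFR": ["ErbB1", "ErbB2", "ErbB3", "ErbB4"]}))
        assert rmap.family("EGF:EGFR").size == 8

    def test_undeclared_refined_base_rejected(self):
        net = normalize_reversible(parse_network("r1: A -> B"))
        with pytest.raises(RefinementError):
            derive_variant_families(net, RefinementSpec({"Z": ["0", "1"]}))

    @given(k=st.integers(1, 5))
    @settings(deadline=None, derandomize=True)
    def test_family_size_law_two_variant_base(self, k):
        """A complex with k copies of a 2-variant base has k+1 variants,
        cross-checked by brute-force enumeration of subunit label multisets."""
        net = parse_network(f"r1: {k} A -> C").with_compositions({"C": {"A": k}})
        rmap = derive_variant_families(normalize_reversible(net),
                                       RefinementSpec({"A": ["0", "1"]}))
        assert rmap.family("C").size == k + 1
        # oracle: distinct aggregated sums of k subunit labels in {0,1}
        sums = {sum(c) for c in itertools.product((0, 1), repeat=k)}
        assert rmap.family("C").size == len(sums)


class TestExpansion:
    def test_binding_six_refined_reactions(self):
        bundle = load_fixture("binding_toy")
        norm = normalize_reversible(bundle.network)
        rmap = derive_variant_families(norm, bundle.spec)
        ref = expand_network(norm, rmap)
        assert len(ref.network.reactions) == 6

    def test_binding_one_side_refined(self):
        bundle = load_fixture("binding_toy")
        norm = normalize_reversible(bundle.network)
        rmap = derive_variant_families(norm, RefinementSpec({"A": ["0", "1"]}))
        ref = expand_network(norm, rmap)
        assert len(ref.network.reactions) == 2

    def test_dimerization_three_refined_reactions(self):
        bundle = load_fixture("dimer_toy")
        norm = normalize_reversible(bundle.network)
        rmap = derive_variant_families(norm, bundle.spec)
        ref = expand_network(norm, rmap)
        assert len(ref.network.reactions) == 3
        # multiset semantics: A_0 + A_1 -> C_1 appears exactly once
        mids = [tuple(sorted(r.reactants.items())) for r in ref.network.reactions]
        assert mids.count((("A_0", 1), ("A_1", 1))) == 1

    def test_identity_refinement_is_isomorphic(self, hsr):
        rmap = derive_variant_families(hsr.norm, RefinementSpec({}))
        ref = expand_network(hsr.norm, rmap)
        assert [s.id for s in ref.network.species] == hsr.norm.species_ids
        assert len(ref.network.reactions) == len(hsr.norm.reactions)
        for r, a in zip(ref.network.reactions, hsr.norm.reactions):
            assert r.reactants == a.reactants and r.products == a.products

    def test_hsr_refined_species_count(self, hsr):
        assert len(hsr.refined.network.species) == 20

    def test_hsr_refined_reactions_match_brute_force_oracle(self, hsr):
        total = 0
        for r in hsr.norm.reactions:
            oracle = brute_force_refined(r, hsr.rmap)
            got = {(tuple(sorted(rr.reactants.items())),
                    tuple(sorted(rr.products.items())))
                   for rr in hsr.refined.refined_reactions_of(r.id)}
            assert got == oracle, r.id
            total += len(oracle)
        assert len(hsr.refined.network.reactions) == total
        assert total == 55  # enumerated; the label-balanced cascade count

    def test_projection_roundtrip_and_label_conservation(self, hsr):
        by_id = {r.id: r for r in hsr.norm.reactions}
        variants = {v.id: v for fam in hsr.rmap.partition.values()
                    for v in fam.variants}
        for rr in hsr.refined.network.reactions:
            src = by_id[hsr.refined.source[rr.id]]
            assert hsr.rmap.project_counts(rr.reactants) == src.reactants
            assert hsr.rmap.project_counts(rr.products) == src.products
            lhs = sum(m * variants[v].label("hsf") for v, m in rr.reactants.items())
            rhs = sum(m * variants[v].label("hsf") for v, m in rr.products.items())
            assert lhs == rhs

    def test_label_constrained_synthesis_kept_to_level_zero(self):
        # catalytic synthesis of a refined species balances only at level 0
        net = parse_network("r1: X -> X + A")
        norm = normalize_reversible(net)
        rmap = derive_variant_families(norm, RefinementSpec({"A": ["0", "1"]}))
        ref = expand_network(norm, rmap)
        assert len(ref.refined_reactions_of("r1")) == 1
        assert ref.empty_refinements == []

    def test_unsatisfiable_balance_reported_not_dropped(self):
        from reactb.refine import RefinementMap, Variant, VariantFamily
        net = normalize_reversible(parse_network("r1: A -> B"))
        # hand-built degenerate map: A exists only at label 1, B unrefined,
        # so no refined version of r1 can balance the label total
        rmap = RefinementMap({
            "A": VariantFamily("A", [Variant("A_1", (("A", 1),))], "tuple",
                               {"A": (1, 1)}),
            "B": VariantFamily("B", [Variant("B", ())], "identity", {}),
        })
        ref = expand_network(net, rmap)
        assert ref.empty_refinements == ["r1"]
        assert len(ref.network.reactions) == 0


class TestCompactPlan:
    def test_binding_plan_shape(self):
        net = parse_network("r1: A + B -> C").with_compositions({"C": {"A": 1, "B": 1}})
        norm = normalize_reversible(net)
        rmap = derive_variant_families(norm, RefinementSpec({"A": ["0", "1"]}))
        plan = compact_plan(norm, rmap)
        entry = plan.entry("r1")
        assert len(entry.params) == 2  # one for A, one for C
        sides = {(p.abstract_id, p.side) for p in entry.params}
        assert sides == {("A", "lhs"), ("C", "rhs")}
        assert entry.scalar_reactants == {"B": 1}

    def test_dimer_plan_three_parameters(self):
        bundle = load_fixture("dimer_toy")
        norm = normalize_reversible(bundle.network)
        rmap = derive_variant_families(norm, bundle.spec)
        entry = compact_plan(norm, rmap).entry("r1")
        assert len(entry.params) == 3
        assert len(entry.consuming_params()) == 2

    def test_unrefined_reaction_degenerates(self, hsr):
        entry = hsr.plan.entry("r10")
        assert entry.params == [] and entry.attrs == []
        assert entry.scalar_reactants == {"prot": 1}

    def test_plan_expansion_equivalence_hsr(self, hsr):
        """Admissible parameter assignments reproduce exactly the expanded
        refined reactions, reaction by reaction."""
        for entry in hsr.plan.entries:
            plan_set = {entry.assignment_reaction(a)
                        for a in entry.admissible_assignments(hsr.rmap)}
            exp_set = {(tuple(sorted(r.reactants.items())),
                        tuple(sorted(r.products.items())))
                       for r in hsr.refined.refined_reactions_of(entry.reaction_id)}
            assert plan_set == exp_set, entry.reaction_id

    @given(seed=st.integers(0, 10_000))
    @settings(max_examples=15, deadline=None, derandomize=True)
    def test_plan_expansion_equivalence_random(self, seed):
        inst = generate_random(GeneratorConfig(seed=seed, n_species=8,
                                               n_reactions=8, n_refined_bases=2,
                                               variant_counts=(2, 3)))
        norm = normalize_reversible(inst.network)
        rmap = derive_variant_families(norm, inst.spec)
        ref = expand_network(norm, rmap)
        plan = compact_plan(norm, rmap)
        for entry in plan.entries:
            plan_set = {entry.assignment_reaction(a)
                        for a in entry.admissible_assignments(rmap)}
            exp_set = {(tuple(sorted(r.reactants.items())),
                        tuple(sorted(r.products.items())))
                       for r in ref.refined_reactions_of(entry.reaction_id)}
            assert plan_set == exp_set
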