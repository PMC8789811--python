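"""Seeded random reaction-network generator for scale and property testing.

Networks are assembled from moiety-conserving templates — complexation
``X + Y -> X:Y``, dissociation, and part exchange ``X:Y + Z -> X:Z + Y`` —
so every generated reaction conserves every base moiety by construction and
conservation analysis and refinement are always exercised.  The same seed
yields a byte-identical network and refinement spec.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

from .network import Reaction, ReactionNetwork, Species
from .refine import RefinementSpec

__all__ = ["GeneratorConfig", "GeneratedInstance", "generate_random"]


@dataclass
class GeneratorConfig:
    seed: int = 0
    n_species: int = 8
    n_reactions: int = 10
    p_reversible: float = 0.3
    max_subunits: int = 3  # cap on total subunit count of a complex
    n_refined_bases: int = 1
    variant_counts: Tuple[int, ...] = (2,)
    base_fraction: float = 0.4  # fraction of species that are bases
    max_init: int = 4  # initial copies per base species


@dataclass
class GeneratedInstance:
    network: ReactionNetwork
    spec: RefinementSpec
    init: Dict[str, int]


def _comp_key(comp: Dict[str, int]) -> Tuple[Tuple[str, int], ...]:
    return tuple(sorted(comp.items()))


def _comp_name(comp: Dict[str, int]) -> str:
    return "c" + "_".join(f"{b}x{k}" for b, k in sorted(comp.items()))


def generate_random(config: GeneratorConfig) -> GeneratedInstance:
    """Generate a well-formed, moiety-conserving random network + refinement."""
    if config.n_species <= 0 and config.n_reactions > 0:
        raise ValueError("infeasible config: reactions without species")
    if config.n_refined_bases > 0 and len(config.variant_counts) == 0:
        raise ValueError("infeasible config: refined bases without variant counts")
    rng = random.Random(config.seed)
    n_bases = max(2, int(round(config.n_species * config.base_fraction)))
    n_bases = min(n_bases, config.n_species)
    bases = [f"b{i+1}" for i in range(n_bases)]
    species: List[Species] = [Species(b) for b in bases]
    comps: Dict[Tuple[Tuple[str, int], ...], str] = {
        _comp_key({b: 1}): b for b in bases}

    # build complexes by combining existing species
    attempts = 0
    while len(species) < config.n_species and attempts < 50 * config.n_species:
        attempts += 1
        u = species[rng.randrange(len(species))]
        v = species[rng.randrange(len(species))]
        comp: Dict[str, int] = dict(u.composition_dict)
        for b, k in v.composition_dict.items():
            comp[b] = comp.get(b, 0) + k
        if sum(comp.values()) > config.max_subunits:
            continue
        key = _comp_key(comp)
        if key in comps:
            continue
        name = _comp_name(comp)
        comps[key] = name
        species.append(Species(name, key))
    if len(species) < config.n_species:
        raise ValueError(
            f"infeasible config: could not build {config.n_species} species "
            f"with max_subunits={config.max_subunits}")

    # candidate reactions (canonical form, deduplicated)
    sp_by_key = dict(comps)
    ids = [s.id for s in species]
    comp_of = {s.id: s.composition_dict for s in species}
    candidates: List[Tuple[Dict[str, int], Dict[str, int]]] = []
    seen_cand = set()

    def add(lhs: Dict[str, int], rhs: Dict[str, int]):
        key = (_comp_key(lhs), _comp_key(rhs))
        if key[0] == key[1] or key in seen_cand:
            return
        seen_cand.add(key)
        candidates.append((lhs, rhs))

    # complexation / dissociation: every species pair whose combined
    # composition is itself a declared species
    formations: Dict[str, List[Tuple[str, str]]] = {}
    for i, u in enumerate(ids):
        for v in ids[i:]:
            comp: Dict[str, int] = dict(comp_of[u])
            for b, k in comp_of[v].items():
                comp[b] = comp.get(b, 0) + k
            target = sp_by_key.get(_comp_key(comp))
            if target is None:
                continue
            lhs = {u: 2} if u == v else {u: 1, v: 1}
            add(lhs, {target: 1})
            add({target: 1}, lhs)
            formations.setdefault(target, []).append((u, v))
    # part exchange: X from (u, v) and Y from (u, w) gives X + w -> Y + v
    for target, pairs in sorted(formations.items()):
        for (u1, v1) in pairs:
            for other, pairs2 in sorted(formations.items()):
                if other == target:
                    continue
                for (u2, v2) in pairs2:
                    for shared, rest1 in ((u1, v1), (v1, u1)):
                        for s2, rest2 in ((u2, v2), (v2, u2)):
                            if shared == s2 and rest1 != rest2:
                                lhs: Dict[str, int] = {}
                                rhs: Dict[str, int] = {}
                                for d, sid in ((lhs, target), (lhs, rest2),
                                               (rhs, other), (rhs, rest1)):
                                    d[sid] = d.get(sid, 0) + 1
                                add(lhs, rhs)
        if len(candidates) > 20 * config.n_reactions:
            break

    if len(candidates) < config.n_reactions:
        raise ValueError(
            f"infeasible config: only {len(candidates)} candidate reactions "
            f"for {config.n_reactions} requested")
    chosen = rng.sample(range(len(candidates)), config.n_reactions)
    reactions = []
    for i, ci in enumerate(sorted(chosen)):
        lhs, rhs = candidates[ci]
        rev = rng.random() < config.p_reversible
        reactions.append(Reaction(f"r{i+1}", dict(lhs), dict(rhs), rev))

    net = ReactionNetwork(species, reactions)

    # refinement: prefer bases that occur inside at least one complex
    in_complex = sorted({b for s in species if not s.is_base
                         for b in s.composition_dict})
    pool = in_complex or bases
    n_ref = max(1, min(config.n_refined_bases, len(pool)))
    refined = rng.sample(pool, n_ref)
    spec = RefinementSpec({
        b: [str(j) for j in range(max(2, config.variant_counts[i % len(config.variant_counts)]))]
        for i, b in enumerate(sorted(refined))
    })

    init = {b: 1 + rng.randrange(config.max_init) for b in bases}
    return GeneratedInstance(net, spec, init)
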