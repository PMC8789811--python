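"""Attribute-based data refinement of reaction networks.

A refinement declares, for some base species, an ordered list of variant
labels (e.g. phosphorylation of one site: levels 0 and 1 per subunit).  The
refinement cascades through every complex containing a refined base:

* distinct refined subunit types contribute one index dimension each
  (a hetero-complex A:B with A refined x2 and B refined x3 gets 6
  tuple-indexed variants);
* identical copies of one refined base are indistinguishable, so k copies
  with per-subunit levels 0..L contribute a single aggregated-sum dimension
  with levels 0..k*L (a trimer of a 2-variant base gets 4 variants, not 8).

:func:`expand_network` materializes the refined network: each abstract
reaction is replaced by every variant assignment whose per-attribute label
totals balance across the reaction, with multiset deduplication for
identical reactants.  :func:`compact_plan` instead produces, per abstract
reaction, a parameterized event plan whose admissible parameter assignments
enumerate exactly the same refined reactions — the basis of the
size-preserving Event-B encoding.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Dict, FrozenSet, Iterable, List, Mapping, Optional, Sequence, Tuple

from .network import NetworkError, Reaction, ReactionNetwork, Species

__all__ = [
    "RefinementSpec",
    "Variant",
    "VariantFamily",
    "RefinementMap",
    "RefinedNetwork",
    "ParamSlot",
    "PlanEntry",
    "CompactModelPlan",
    "RefinementError",
    "derive_variant_families",
    "expand_network",
    "compact_plan",
]


class RefinementError(ValueError):
    pass


@dataclass
class RefinementSpec:
    """Base-species refinement request: base id -> ordered variant labels.

    The position of a label is its per-subunit attribute level (label list
    ``["u", "p"]`` means level 0 = unmodified, level 1 = modified).
    """

    refined_base: Dict[str, List[str]]

    def __post_init__(self):
        for base, labels in self.refined_base.items():
            labels = [str(l) for l in labels]
            if len(labels) < 2:
                raise RefinementError(f"{base}: need at least 2 variant labels")
            if len(set(labels)) != len(labels):
                raise RefinementError(f"{base}: variant labels must be distinct")
            self.refined_base[base] = labels


@dataclass(frozen=True)
class Variant:
    """One refined species: id plus its per-attribute aggregated label levels."""

    id: str
    labels: Tuple[Tuple[str, int], ...]  # (refined base id, aggregated level)

    def label(self, attr: str) -> int:
        return dict(self.labels).get(attr, 0)


@dataclass
class VariantFamily:
    """The variant set of one abstract species under a refinement."""

    abstract_id: str
    variants: List[Variant]
    index_kind: str  # "identity" | "tuple" | "aggregate" | "mixed"
    dims: Dict[str, Tuple[int, int]]  # attr -> (copies k, per-subunit max level L)

    @property
    def size(self) -> int:
        return len(self.variants)

    @property
    def is_identity(self) -> bool:
        return self.index_kind == "identity"

    def variant_ids(self) -> List[str]:
        return [v.id for v in self.variants]


@dataclass
class RefinementMap:
    """Partition of the refined species set, one family per abstract species."""

    partition: Dict[str, VariantFamily]
    spec: Optional[RefinementSpec] = None

    def __post_init__(self):
        seen: Dict[str, str] = {}
        for abs_id, fam in self.partition.items():
            if fam.abstract_id != abs_id:
                raise RefinementError(f"family for {abs_id} labelled {fam.abstract_id}")
            for v in fam.variants:
                if v.id in seen:
                    raise RefinementError(
                        f"variant {v.id} appears in families of {seen[v.id]} and {abs_id}"
                    )
                seen[v.id] = abs_id
        self._abstract_of = seen

    def family(self, abstract_id: str) -> VariantFamily:
        return self.partition[abstract_id]

    def abstract_of(self, variant_id: str) -> str:
        return self._abstract_of[variant_id]

    def refined_abstract_ids(self) -> List[str]:
        return [a for a, f in self.partition.items() if not f.is_identity]

    def project_counts(self, counts: Mapping[str, int]) -> Dict[str, int]:
        """Sum refined-species counts back to abstract species (gluing sums)."""
        out: Dict[str, int] = {}
        for vid, m in counts.items():
            a = self._abstract_of[vid]
            out[a] = out.get(a, 0) + m
        return {k: v for k, v in out.items() if v != 0}


def _variant_id(abs_id: str, spec: RefinementSpec, labels: Dict[str, int],
                fam_dims: Dict[str, Tuple[int, int]]) -> str:
    """Deterministic refined-species naming.

    A refined base keeps its own label text (``hsf -> hsf_0, hsf_1``); a
    complex is suffixed per refined subunit type with the aggregated level
    (``hsf3:hse -> hsf3:hse_hsf2`` for total phosphorylation level 2).
    """
    if abs_id in spec.refined_base and fam_dims.get(abs_id, (0, 0))[0] == 1 and len(labels) == 1:
        # the base species itself: use its declared label text
        lvl = labels[abs_id]
        return f"{abs_id}_{spec.refined_base[abs_id][lvl]}"
    parts = [f"{attr}{lvl}" for attr, lvl in sorted(labels.items())]
    return f"{abs_id}_" + "_".join(parts)


def derive_variant_families(net: ReactionNetwork, spec: RefinementSpec) -> RefinementMap:
    """Cascade base-species refinements through every complex of the network.

    Refining a species must refine every complex it is part of; the family of
    a complex is indexed by, per refined subunit type, the aggregated label
    level of its copies of that subunit.
    """
    declared = set(net.species_ids)
    for base in spec.refined_base:
        if base not in declared:
            raise RefinementError(f"refined base species {base} is not declared")
        if not net.get_species(base).is_base:
            raise RefinementError(f"refined species {base} is not a base species")
    partition: Dict[str, VariantFamily] = {}
    for sp in net.species:
        comp = sp.composition_dict
        for b in comp:
            if b not in declared:
                raise RefinementError(f"composition of {sp.id} references undeclared {b}")
        dims: Dict[str, Tuple[int, int]] = {}
        for base, labels in spec.refined_base.items():
            k = comp.get(base, 0)
            if k > 0:
                dims[base] = (k, len(labels) - 1)
        if not dims:
            partition[sp.id] = VariantFamily(sp.id, [Variant(sp.id, ())], "identity", {})
            continue
        attrs = sorted(dims)
        ranges = [range(dims[a][0] * dims[a][1] + 1) for a in attrs]
        variants = []
        for levels in itertools.product(*ranges):
            labels = dict(zip(attrs, levels))
            vid = _variant_id(sp.id, spec, labels, dims)
            variants.append(Variant(vid, tuple(sorted(labels.items()))))
        if len(dims) == 1 and next(iter(dims.values()))[0] > 1:
            kind = "aggregate"
        elif all(k == 1 for k, _ in dims.values()):
            kind = "tuple"
        else:
            kind = "mixed"
        partition[sp.id] = VariantFamily(sp.id, variants, kind, dims)
    return RefinementMap(partition, spec)


# ---------------------------------------------------------------------------
# Expanded refinement
# ---------------------------------------------------------------------------

SideKey = Tuple[Tuple[str, int], ...]  # sorted (variant id, multiplicity)


def _side_assignments(side: Mapping[str, int], rmap: RefinementMap) -> List[Tuple[SideKey, Dict[str, int]]]:
    """All variant multiset choices for one reaction side.

    For a species with multiplicity m, variants are chosen as an unordered
    multiset of size m (combinations with replacement — identical copies are
    indistinguishable).  Returns (canonical multiset key, per-attribute label
    total) pairs.
    """
    per_species: List[List[Tuple[Tuple[Variant, ...], Dict[str, int]]]] = []
    for sid in sorted(side):
        m = side[sid]
        fam = rmap.family(sid)
        opts = []
        for combo in itertools.combinations_with_replacement(fam.variants, m):
            labels: Dict[str, int] = {}
            for v in combo:
                for attr, lvl in v.labels:
                    labels[attr] = labels.get(attr, 0) + lvl
            opts.append((combo, labels))
        per_species.append(opts)
    out = []
    for choice in itertools.product(*per_species):
        counts: Dict[str, int] = {}
        labels: Dict[str, int] = {}
        for combo, lab in choice:
            for v in combo:
                counts[v.id] = counts.get(v.id, 0) + 1
            for attr, tot in lab.items():
                labels[attr] = labels.get(attr, 0) + tot
        key = tuple(sorted(counts.items()))
        out.append((key, labels))
    return out


@dataclass
class RefinedNetwork:
    """The expanded refined network plus its provenance."""

    network: ReactionNetwork
    source: Dict[str, str]  # refined reaction id -> abstract reaction id
    map: RefinementMap
    abstract: ReactionNetwork
    empty_refinements: List[str] = field(default_factory=list)

    def refined_reactions_of(self, abstract_rid: str) -> List[Reaction]:
        return [r for r in self.network.reactions if self.source[r.id] == abstract_rid]


def expand_network(net: ReactionNetwork, rmap: RefinementMap) -> RefinedNetwork:
    """Materialize every label-balanced refined version of every reaction.

    A refined reaction keeps, per attribute, the same label total on both
    sides (a reaction neither creates nor destroys the modified sites the
    attribute counts).  Reactions whose label balance is unsatisfiable are
    reported in ``empty_refinements`` rather than silently dropped.
    """
    if not net.is_normalized:
        raise NetworkError("network must be normalized before refinement")
    species: List[Species] = []
    for sp in net.species:
        fam = rmap.family(sp.id)
        for v in fam.variants:
            species.append(Species(v.id, sp.composition if fam.is_identity else sp.composition))
    reactions: List[Reaction] = []
    source: Dict[str, str] = {}
    empty: List[str] = []
    for r in net.reactions:
        lhs_opts = _side_assignments(r.reactants, rmap)
        rhs_opts = _side_assignments(r.products, rmap)
        seen: set = set()
        k = 0
        for (lkey, llab) in lhs_opts:
            for (rkey, rlab) in rhs_opts:
                attrs = set(llab) | set(rlab)
                if any(llab.get(a, 0) != rlab.get(a, 0) for a in attrs):
                    continue
                dedup = (lkey, rkey)
                if dedup in seen:
                    continue
                seen.add(dedup)
                rid = f"{r.id}__{k}"
                k += 1
                reactions.append(Reaction(rid, dict(lkey), dict(rkey), False))
                source[rid] = r.id
        if k == 0:
            empty.append(r.id)
    refined = ReactionNetwork(species, reactions)
    return RefinedNetwork(refined, source, rmap, net, empty)


# ---------------------------------------------------------------------------
# Compact (size-preserving) plan
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ParamSlot:
    """One event parameter: a refined-species occurrence in a reaction."""

    name: str
    abstract_id: str  # which abstract species' family it ranges over
    side: str  # "lhs" | "rhs"

    def __str__(self):
        return f"{self.name}:{self.abstract_id}[{self.side}]"


@dataclass
class PlanEntry:
    """Parameterized encoding of all refined versions of one reaction.

    ``params`` has one slot per unit of stoichiometry of each refined
    species occurrence; ``linking`` requires per-attribute label totals of
    LHS parameters to equal those of RHS parameters; scalar (unrefined)
    occurrences keep plain multiplicities.  Demand at a function argument is
    the number of consuming parameters assigned that argument — coincidence
    of parameters raises the demand, which matters for dimerization.
    """

    reaction_id: str
    params: List[ParamSlot]
    scalar_reactants: Dict[str, int]
    scalar_products: Dict[str, int]
    attrs: List[str]  # attributes with at least one refined occurrence

    def consuming_params(self) -> List[ParamSlot]:
        return [p for p in self.params if p.side == "lhs"]

    def producing_params(self) -> List[ParamSlot]:
        return [p for p in self.params if p.side == "rhs"]

    def admissible_assignments(self, rmap: RefinementMap) -> List[Dict[str, Variant]]:
        """Enumerate parameter assignments satisfying the linking constraints."""
        domains = [rmap.family(p.abstract_id).variants for p in self.params]
        out = []
        for combo in itertools.product(*domains):
            asg = dict(zip((p.name for p in self.params), combo))
            if self._balanced(asg):
                out.append(asg)
        return out

    def _balanced(self, asg: Mapping[str, Variant]) -> bool:
        for attr in self.attrs:
            lhs = sum(asg[p.name].label(attr) for p in self.params if p.side == "lhs")
            rhs = sum(asg[p.name].label(attr) for p in self.params if p.side == "rhs")
            if lhs != rhs:
                return False
        return True

    def assignment_reaction(self, asg: Mapping[str, Variant]) -> Tuple[SideKey, SideKey]:
        """The refined reaction (as canonical side multisets) an assignment denotes."""
        lhs: Dict[str, int] = dict(self.scalar_reactants)
        rhs: Dict[str, int] = dict(self.scalar_products)
        for p in self.params:
            side = lhs if p.side == "lhs" else rhs
            vid = asg[p.name].id
            side[vid] = side.get(vid, 0) + 1
        return (tuple(sorted(lhs.items())), tuple(sorted(rhs.items())))


@dataclass
class CompactModelPlan:
    entries: List[PlanEntry]
    map: RefinementMap
    abstract: ReactionNetwork

    def entry(self, reaction_id: str) -> PlanEntry:
        for e in self.entries:
            if e.reaction_id == reaction_id:
                return e
        raise KeyError(reaction_id)


def compact_plan(net: ReactionNetwork, rmap: RefinementMap) -> CompactModelPlan:
    """Build the size-preserving event plan: one entry per abstract reaction."""
    if not net.is_normalized:
        raise NetworkError("network must be normalized before planning")
    entries = []
    for r in net.reactions:
        params: List[ParamSlot] = []
        scalar_l: Dict[str, int] = {}
        scalar_r: Dict[str, int] = {}
        attrs: set = set()
        counter = 0
        for side_name, side, scal in (("lhs", r.reactants, scalar_l), ("rhs", r.products, scalar_r)):
            for sid in sorted(side):
                m = side[sid]
                fam = rmap.family(sid)
                if fam.is_identity:
                    scal[sid] = m
                else:
                    attrs.update(fam.dims)
                    for _ in range(m):
                        counter += 1
                        params.append(ParamSlot(f"p{counter}", sid, side_name))
        entries.append(PlanEntry(r.id, params, scalar_l, scalar_r, sorted(attrs)))
    return CompactModelPlan(entries, rmap, net)
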