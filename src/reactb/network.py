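"""Reaction networks: parsing, normalization and conservation analysis.

A network is a set of species and stoichiometric rewriting rules

    r:  m1 X1 + m2 X2 + ... -> m1' X1 + m2' X2 + ...

with non-negative integer multiplicities.  Reversible rules (``<->``) are
kept as a flag at parse time and split into a forward/backward pair by
:func:`normalize_reversible`; all downstream analysis (stoichiometric matrix,
conservation laws, Event-B generation) works on normalized networks.

Conservation laws are integer vectors ``c`` with ``c . delta = 0`` for the
species-by-reaction delta matrix; they express moieties whose total count is
invariant under every reaction (e.g. total heat-shock-element content).
"""

from __future__ import annotations

import itertools
import json
import re
from dataclasses import dataclass, field
from fractions import Fraction
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np

__all__ = [
    "Species",
    "Reaction",
    "ReactionNetwork",
    "ConservationLaw",
    "ReactionFormatError",
    "NetworkError",
    "parse_network",
    "normalize_reversible",
    "stoichiometric_delta",
    "conservation_basis",
    "integer_left_kernel",
    "network_stats",
]


class NetworkError(ValueError):
    """Ill-formed network (duplicate ids, undeclared species, ...)."""


class ReactionFormatError(NetworkError):
    """Syntax error in the plain-text reaction format."""

    def __init__(self, message: str, line: Optional[int] = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)


# Species identifiers: letters, then letters/digits/underscore/colon, so that
# complex names such as hsf3:hse and hsp:hsf are single tokens.
_IDENT = r"[A-Za-z][A-Za-z0-9_:]*"
_IDENT_RE = re.compile(rf"^{_IDENT}$")


@dataclass(frozen=True)
class Species:
    """A molecular species with a multiset composition over base species.

    A base species composes of itself once (``hsf -> {hsf: 1}``); a complex
    declares its subunit content (``hsf3:hse -> {hsf: 3, hse: 1}``).
    """

    id: str
    composition: Tuple[Tuple[str, int], ...] = ()

    def __post_init__(self):
        if not self.id or not _IDENT_RE.match(self.id):
            raise NetworkError(f"invalid species id {self.id!r}")
        comp = tuple(sorted(dict(self.composition).items()))
        if not comp:
            comp = ((self.id, 1),)
        for base, k in comp:
            if k <= 0:
                raise NetworkError(f"species {self.id}: non-positive subunit count for {base}")
        object.__setattr__(self, "composition", comp)

    @property
    def composition_dict(self) -> Dict[str, int]:
        return dict(self.composition)

    @property
    def is_base(self) -> bool:
        return self.composition == ((self.id, 1),)


@dataclass
class Reaction:
    """One rewriting rule; ``reversible`` survives only until normalization."""

    id: str
    reactants: Dict[str, int]
    products: Dict[str, int]
    reversible: bool = False

    def __post_init__(self):
        self.reactants = {s: int(m) for s, m in self.reactants.items() if int(m) != 0}
        self.products = {s: int(m) for s, m in self.products.items() if int(m) != 0}
        for side in (self.reactants, self.products):
            for s, m in side.items():
                if m < 0:
                    raise NetworkError(f"reaction {self.id}: negative coefficient for {s}")
        if not self.reactants and not self.products:
            raise NetworkError(f"reaction {self.id}: empty on both sides")

    def species_ids(self) -> set:
        return set(self.reactants) | set(self.products)


class ReactionNetwork:
    """A validated set of species and reactions."""

    def __init__(self, species: Sequence[Species], reactions: Sequence[Reaction]):
        self.species: List[Species] = list(species)
        self.reactions: List[Reaction] = list(reactions)
        ids = [s.id for s in self.species]
        if len(set(ids)) != len(ids):
            raise NetworkError("duplicate species ids")
        rids = [r.id for r in self.reactions]
        if len(set(rids)) != len(rids):
            dup = sorted({x for x in rids if rids.count(x) > 1})
            raise NetworkError(f"duplicate reaction id(s): {', '.join(dup)}")
        declared = set(ids)
        for r in self.reactions:
            missing = r.species_ids() - declared
            if missing:
                raise NetworkError(
                    f"reaction {r.id} references undeclared species: {', '.join(sorted(missing))}"
                )
        self._index = {s.id: i for i, s in enumerate(self.species)}
        self._by_id = {s.id: s for s in self.species}

    # -- accessors -------------------------------------------------------
    @property
    def species_ids(self) -> List[str]:
        return [s.id for s in self.species]

    def species_index(self, sid: str) -> int:
        return self._index[sid]

    def get_species(self, sid: str) -> Species:
        return self._by_id[sid]

    @property
    def is_normalized(self) -> bool:
        return not any(r.reversible for r in self.reactions)

    def with_compositions(self, compositions: Mapping[str, Mapping[str, int]]) -> "ReactionNetwork":
        """Return a copy with complex compositions attached.

        Species absent from ``compositions`` keep their base (self) composition.
        Composition entries must reference declared species.
        """
        declared = set(self._index)
        for sid, comp in compositions.items():
            if sid not in declared:
                raise NetworkError(f"composition given for undeclared species {sid}")
            for base in comp:
                if base not in declared:
                    raise NetworkError(
                        f"composition of {sid} references undeclared species {base}"
                    )
        new_species = [
            Species(s.id, tuple(compositions[s.id].items())) if s.id in compositions else s
            for s in self.species
        ]
        return ReactionNetwork(new_species, self.reactions)

    def __repr__(self):
        return f"ReactionNetwork({len(self.species)} species, {len(self.reactions)} reactions)"


# ---------------------------------------------------------------------------
# Parsing
# ---------------------------------------------------------------------------

_ARROW_RE = re.compile(r"(<->|->)")


def _parse_side(text: str, rid: str, lineno: int) -> Dict[str, int]:
    text = text.strip()
    if text == "0" or text == "":
        return {}
    side: Dict[str, int] = {}
    for term in text.split("+"):
        term = term.strip()
        if not term:
            raise ReactionFormatError(f"reaction {rid}: empty term", lineno)
        m = re.match(rf"^(?:(-?\d+)\s+)?({_IDENT})$", term)
        if not m:
            raise ReactionFormatError(f"reaction {rid}: cannot parse term {term!r}", lineno)
        coeff = int(m.group(1)) if m.group(1) else 1
        if coeff < 0:
            raise ReactionFormatError(f"reaction {rid}: negative coefficient in {term!r}", lineno)
        sid = m.group(2)
        side[sid] = side.get(sid, 0) + coeff
    return side


def parse_network(text: str) -> ReactionNetwork:
    """Parse the plain-text reaction format into a :class:`ReactionNetwork`.

    One rule per line: ``<id>: <terms> -> <terms>`` or ``<-> `` for a
    reversible rule; a term is ``[<int> ]<species>``; an empty side is
    written ``0``; ``#`` starts a comment.  Species are inferred from the
    rules in order of first appearance and get base compositions (attach
    complex compositions afterwards with
    :meth:`ReactionNetwork.with_compositions`).
    """
    reactions: List[Reaction] = []
    seen_ids: Dict[str, int] = {}
    species_order: List[str] = []
    seen_species: set = set()

    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if ":" not in line:
            raise ReactionFormatError("missing ':' after reaction id", lineno)
        rid, rest = line.split(":", 1)
        rid = rid.strip()
        if not _IDENT_RE.match(rid) and not re.match(r"^[A-Za-z0-9_]+$", rid):
            raise ReactionFormatError(f"invalid reaction id {rid!r}", lineno)
        if rid in seen_ids:
            raise ReactionFormatError(
                f"duplicate reaction id {rid!r} (first at line {seen_ids[rid]})", lineno
            )
        seen_ids[rid] = lineno
        arrows = _ARROW_RE.findall(rest)
        if len(arrows) != 1:
            raise ReactionFormatError("expected exactly one '->' or '<->'", lineno)
        lhs_txt, rhs_txt = _ARROW_RE.split(rest, maxsplit=1)[::2]
        reversible = arrows[0] == "<->"
        reactants = _parse_side(lhs_txt, rid, lineno)
        products = _parse_side(rhs_txt, rid, lineno)
        if not reactants and not products:
            raise ReactionFormatError(f"reaction {rid}: both sides empty", lineno)
        for sid in itertools.chain(reactants, products):
            if sid not in seen_species:
                seen_species.add(sid)
                species_order.append(sid)
        reactions.append(Reaction(rid, reactants, products, reversible))

    species = [Species(sid) for sid in species_order]
    return ReactionNetwork(species, reactions)


def format_network(net: ReactionNetwork) -> str:
    """Serialize back to the plain-text rule format (inverse of parsing)."""

    def side(d: Dict[str, int]) -> str:
        if not d:
            return "0"
        return " + ".join(
            (f"{m} {s}" if m != 1 else s) for s, m in sorted(d.items())
        )

    lines = []
    for r in net.reactions:
        arrow = "<->" if r.reversible else "->"
        lines.append(f"{r.id}: {side(r.reactants)} {arrow} {side(r.products)}")
    return "\n".join(lines) + ("\n" if lines else "")


# ---------------------------------------------------------------------------
# Normalization and stoichiometry
# ---------------------------------------------------------------------------

def normalize_reversible(net: ReactionNetwork) -> ReactionNetwork:
    """Split every reversible rule into forward (`_f`) and backward (`_b`) halves.

    Irreversible rules are kept as-is; the operation is idempotent and
    preserves the species set.
    """
    out: List[Reaction] = []
    for r in net.reactions:
        if r.reversible:
            out.append(Reaction(r.id + "_f", dict(r.reactants), dict(r.products), False))
            out.append(Reaction(r.id + "_b", dict(r.products), dict(r.reactants), False))
        else:
            out.append(Reaction(r.id, dict(r.reactants), dict(r.products), False))
    return ReactionNetwork(net.species, out)


def stoichiometric_delta(net: ReactionNetwork) -> np.ndarray:
    """Species-by-reaction integer delta matrix (products minus reactants)."""
    if not net.is_normalized:
        raise NetworkError("network must be normalized (no reversible reactions)")
    delta = np.zeros((len(net.species), len(net.reactions)), dtype=np.int64)
    for j, r in enumerate(net.reactions):
        for sid, m in r.reactants.items():
            delta[net.species_index(sid), j] -= m
        for sid, m in r.products.items():
            delta[net.species_index(sid), j] += m
    return delta


# ---------------------------------------------------------------------------
# Integer left kernel / conservation laws
# ---------------------------------------------------------------------------

@dataclass
class ConservationLaw:
    """An integer species combination invariant under every reaction."""

    coefficients: Dict[str, int]
    description: str = ""

    def __post_init__(self):
        self.coefficients = {s: int(c) for s, c in self.coefficients.items() if int(c) != 0}
        if not self.description:
            self.description = "moiety[" + " + ".join(
                (f"{c}*{s}" if c != 1 else s) for s, c in sorted(self.coefficients.items())
            ) + "]"

    def value(self, state: Mapping[str, int]) -> int:
        return sum(c * state.get(s, 0) for s, c in self.coefficients.items())

    def holds_for(self, net: ReactionNetwork) -> bool:
        """Check ``c . delta = 0`` for every reaction by direct arithmetic."""
        for r in net.reactions:
            total = 0
            for s, m in r.products.items():
                total += self.coefficients.get(s, 0) * m
            for s, m in r.reactants.items():
                total -= self.coefficients.get(s, 0) * m
            if total != 0:
                return False
        return True


def integer_left_kernel(delta: np.ndarray) -> List[List[int]]:
    """Primitive integer basis of ``{c : c . delta = 0}``.

    Fraction-free integer row elimination on ``[delta | I]``: unimodular row
    operations drive the delta block to row-echelon form; transform rows
    whose delta part vanished form a lattice basis of the left kernel.
    """
    m, n = delta.shape
    # rows of aug: [delta_row (n entries) | transform_row (m entries)]
    aug = [[int(x) for x in delta[i]] + [1 if j == i else 0 for j in range(m)] for i in range(m)]
    pivot_row = 0
    for col in range(n):
        if pivot_row >= m:
            break
        # gcd-style elimination in this column below pivot_row
        while True:
            nz = [i for i in range(pivot_row, m) if aug[i][col] != 0]
            if not nz:
                break
            i_min = min(nz, key=lambda i: abs(aug[i][col]))
            aug[pivot_row], aug[i_min] = aug[i_min], aug[pivot_row]
            p = aug[pivot_row][col]
            done = True
            for i in range(pivot_row + 1, m):
                if aug[i][col] != 0:
                    q = aug[i][col] // p
                    if q != 0:
                        aug[i] = [a - q * b for a, b in zip(aug[i], aug[pivot_row])]
                    if aug[i][col] != 0:
                        done = False
            if done:
                break
        if aug[pivot_row][col] != 0:
            pivot_row += 1
    kernel = []
    for i in range(m):
        if all(x == 0 for x in aug[i][:n]):
            vec = aug[i][n:]
            kernel.append(_primitive(vec))
    return kernel


def _primitive(vec: Sequence[int]) -> List[int]:
    g = 0
    for x in vec:
        g = np.gcd(g, abs(int(x)))
    g = int(g) or 1
    out = [int(x) // g for x in vec]
    for x in out:
        if x != 0:
            if x < 0:
                out = [-v for v in out]
            break
    return out


def _try_nonnegative_basis(basis: List[List[int]], bound: int = 3) -> Optional[List[List[int]]]:
    """Search small integer recombinations for an all-non-negative basis.

    Returns ``None`` when no such basis is found within the coefficient
    bound (or when the kernel dimension makes the search impractical).
    """
    k = len(basis)
    if k == 0:
        return []
    if all(all(x >= 0 for x in v) for v in basis):
        return [list(v) for v in basis]
    if k > 5:
        return None
    m = len(basis[0])
    candidates = []
    seen = set()
    for coeffs in itertools.product(range(-bound, bound + 1), repeat=k):
        if all(c == 0 for c in coeffs):
            continue
        vec = [sum(c * basis[i][j] for i, c in enumerate(coeffs)) for j in range(m)]
        if any(x < 0 for x in vec):
            continue
        vec = tuple(_primitive(vec))
        if any(x < 0 for x in vec) or vec in seen:
            continue
        seen.add(vec)
        candidates.append(list(vec))
    if len(candidates) < k:
        return None
    # prefer small support, then lexicographic order of the vector itself
    candidates.sort(key=lambda v: (sum(1 for x in v if x != 0), v))
    chosen: List[List[int]] = []
    rows: List[List[Fraction]] = []
    for cand in candidates:
        if _rank_with(rows, cand) > len(rows):
            chosen.append(cand)
            rows = _reduce_rows(rows, cand)
            if len(chosen) == k:
                break
    if len(chosen) < k:
        return None
    # ensure lattice (not just span) equality: each original vector must be
    # an integer combination of the chosen ones
    for v in basis:
        if not _is_integer_combination(chosen, v):
            return None
    return chosen


def _rank_with(reduced: List[List[Fraction]], vec: Sequence[int]) -> int:
    v = [Fraction(x) for x in vec]
    for row in reduced:
        lead = next(i for i, x in enumerate(row) if x != 0)
        if v[lead] != 0:
            f = v[lead] / row[lead]
            v = [a - f * b for a, b in zip(v, row)]
    if any(x != 0 for x in v):
        return len(reduced) + 1
    return len(reduced)


def _reduce_rows(reduced: List[List[Fraction]], vec: Sequence[int]) -> List[List[Fraction]]:
    v = [Fraction(x) for x in vec]
    for row in reduced:
        lead = next(i for i, x in enumerate(row) if x != 0)
        if v[lead] != 0:
            f = v[lead] / row[lead]
            v = [a - f * b for a, b in zip(v, row)]
    out = list(reduced)
    if any(x != 0 for x in v):
        out.append(v)
    return out


def _is_integer_combination(basis: List[List[int]], target: Sequence[int]) -> bool:
    import sympy

    if not basis:
        return all(x == 0 for x in target)
    A = sympy.Matrix([[b[j] for b in basis] for j in range(len(target))])
    b = sympy.Matrix([int(x) for x in target])
    try:
        sol, params = A.gauss_jordan_solve(b)
    except ValueError:
        return False
    if params.shape[0] > 0:
        sol = sol.subs({p: 0 for p in params})
    return all(x.is_integer for x in sol)


def conservation_basis(
    delta: np.ndarray, species: Optional[Sequence[str]] = None
) -> List[ConservationLaw]:
    """Canonical integer basis of the conservation laws of ``delta``.

    Each vector is primitive (gcd 1); when a non-negative basis exists within
    a bounded recombination search it is returned (physically meaningful
    moieties are non-negative), otherwise signed primitive vectors are kept.
    Laws are ordered by support (lexicographically on species indices).
    """
    if species is None:
        species = [f"S{i}" for i in range(delta.shape[0])]
    basis = integer_left_kernel(delta)
    nonneg = _try_nonnegative_basis(basis)
    if nonneg is not None:
        basis = nonneg
    basis.sort(key=lambda v: ([i for i, x in enumerate(v) if x != 0], v))
    laws = []
    for vec in basis:
        coeffs = {species[i]: int(x) for i, x in enumerate(vec) if x != 0}
        laws.append(ConservationLaw(coeffs))
    return laws


def network_stats(net: ReactionNetwork) -> Dict:
    """JSON-ready summary: species, reactions, conservation laws."""
    norm = normalize_reversible(net)
    delta = stoichiometric_delta(norm)
    laws = conservation_basis(delta, norm.species_ids)
    return {
        "species": len(net.species),
        "reactions": len(net.reactions),
        "reversible_reactions": sum(1 for r in net.reactions if r.reversible),
        "irreversible_reactions": len(norm.reactions),
        "conservation_laws": [
            {"coefficients": law.coefficients, "description": law.description} for law in laws
        ],
    }
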