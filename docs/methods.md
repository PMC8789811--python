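# Methods

## Model

A reaction network is a finite species set with stoichiometric rules
`Σ mi Xi → Σ mi' Xi` (natural coefficients). Reversible rules are split
into forward/backward halves (`_f`/`_b`) before any analysis; all
semantics below assume the normalized (irreversible) network. No kinetic
rates, inhibitor semantics or compartments are modeled: the state space is
discrete copy-number counting, and every enabled event may fire
nondeterministically. Catalysts are written explicitly on both sides of a
rule; there is no special syntax for them. Inhibitors are deliberately
unsupported — the rewriting-rule form has no inhibitor term and any
encoding would be a guess.

### Conservation laws

The delta matrix `Δ` (species × reactions, products minus reactants) is
analyzed for its integer left kernel `{c : c·Δ = 0}` by fraction-free
integer row elimination on `[Δ | I]` (Hermite-normal-form style; the
unimodular transform rows whose `Δ`-part vanishes form a lattice basis).
Each vector is reduced to primitive form (gcd 1). Because physically
meaningful moieties are non-negative, a bounded recombination search
(coefficients in `[-3, 3]`, kernel dimension ≤ 5) attempts an
all-non-negative basis with lattice equality verified; if none is found
the signed primitive vectors are returned unchanged. Laws are ordered by
support. The test suite cross-checks dimension and exactness against a
rational row-reduction oracle (sympy nullspace), kept independent of the
integer elimination path.

## Refinement semantics

A refinement declares ordered variant labels for some base species; label
position is the per-subunit attribute level (e.g. phosphorylation 0/1).
The cascade through complexes follows two indexing conventions, chosen to
match both worked binding/dimerization examples and the phosphorylation
cascade sizes of the bundled model:

* distinct refined subunit types contribute one tuple dimension each;
* `k` identical copies of a refined base with per-subunit levels `0..L`
  contribute a single aggregated-sum dimension `0..k·L` (identical
  subunits are indistinguishable — a trimer of a 2-variant base has 4
  variants, not 2³).

The expanded refined network contains, per abstract reaction, every
assignment of variants to reactant/product occurrences whose per-attribute
label totals balance across the reaction. Identical-reactant assignments
are deduplicated under multiset semantics (the canonical sorted form of
the reactant and product multisets is the identity of a refined reaction),
so a dimerization `2A → C` with a 2-variant `A` yields exactly three
refined reactions. Refinement refines species only; no new reactions
(e.g. phosphorylation interconversions) are synthesized. A reaction whose
label balance is unsatisfiable is reported in `empty_refinements`, never
silently dropped.

On the bundled heat shock response fixture this enumeration yields 20
refined species and 55 refined reactions. The published description of
the same refinement reports 22 variables / 57 reactions in its text and
20 species / 57 reactions in its statistics table; those counts are
internally inconsistent and the convention behind the 57 is not
recoverable (the earlier hand-built refined model it cites may contain
reactions beyond the pure cascade). We therefore report the enumerated
count, validated against an independent brute-force oracle in the tests,
and do not force agreement with 57.

## Event-B generation

Three encodings share one machine representation (variables, structured
invariants, guarded parameterized events with delta actions):

* **abstract** — variable per species, event per reaction, guards at the
  full reactant multiplicities (a catalyst must be present even when its
  net change is zero), invariants = typing per variable + one conservation
  equality per law with the constant fixed by the initial state;
* **expanded** — the same encoding over the expanded refined network;
* **compact** — refined species become functions on carrier sets
  partitioned into singleton variant constants (context axioms
  `partition(S_X, {X_0}, …)` plus label constant functions
  `lab_attr_X : S_X → ℕ`); each abstract reaction stays one event with
  one parameter per refined-species occurrence, membership guards,
  availability guards whose demand at an argument is the number of
  consuming parameters assigned to it (so two coincident dimer parameters
  demand 2), and one linking guard per attribute equating LHS and RHS
  label sums. Function actions are delta-accumulating overrides
  (coincident arguments sum). Gluing invariants `X = Σ_v rX(v)` are
  synthesized per refined species.

Invariant counting convention: typing per variable + conservation per
kernel-basis vector + gluing per refined species. For the bundled model
this gives 13 invariants for the abstract machine (10 + 3) and 18 for the
compact refined machine (10 + 3 + 5).

Initial values are not part of the network formalism, so `init` is a
required configuration; the bundled default places all mass in unmodified
pools (`hsf = 6, hse = 1, hsp = 3, prot = 5`, complexes empty; refined
inits put everything at attribute level 0). Inits are validated to be
non-negative, optionally against required conserved totals, and — for the
compact machine — to project onto the abstract init through the gluing
sums.

An optional symmetry-breaking guard (ordering the labels of
interchangeable identical-reactant parameters) is available but off by
default: it changes neither reachability nor the projected transition
relation, and merely mirrors unordered-reaction counting.

Emission is a pure function of the model: deterministic, stable-ordered
textual Event-B (Camille-like). The `<+delta` override notation in emitted
actions is this package's dialect for the accumulating function update;
Rodin project XML is out of scope. The JSON model round-trip
(`EBModel.to_dict`/`from_dict`) is the machine-readable interchange used
by the `verify`/`simulate` CLI; it is lossless for the structured guard
and action payloads the verifier needs.

## Verification

Proof obligations: INV per (event, invariant) pair, INIT per invariant,
WD per function application, and — for the compact machine against its
abstraction — GRD and SIM per corresponding event pair (events correspond
by name, one per abstract reaction). For the bundled abstract machine this
yields 17·13 INV + 13 INIT = 234 obligations.

All generated atoms are linear (in)equalities over naturals plus
finite-domain parameter constraints, so discharge is decidable without
external provers. Parameters are handled by exhaustive case enumeration
over the variant domains (small by construction); cases whose
state-independent guards (membership, linking) are unsatisfiable are
vacuous. Most checks are case-independent and decided once:

* conservation / gluing INV and SIM reduce to exact integer identities on
  (glued) action deltas;
* typing INV reduces to guard sufficiency — for scalars a bound
  comparison, for functions a sub-multiset check of consuming parameters
  against availability-guard parameters (which covers every coincidence
  pattern at once), falling back to per-case analysis;
* GRD follows by summing concrete availability demands through the gluing
  equality with non-negativity of the remaining summands.

The procedure never reports `discharged` unsoundly. When an identity
fails, a counterexample (parameter case + hypothesis-satisfying state) is
sought by bounded breadth-first search from the initial state; if found
the result is `refuted` with a re-checkable witness, otherwise `unknown`
with a reason. Anything outside the fragment is `unknown`, never guessed.

Bounded exploration fires all admissible (event, parameter) pairs in
stable lexicographic order, breadth-first, checking every invariant on
every reached state (with a state-count cap that flags truncation).
Trace-refinement checking runs seeded random concrete traces, projects
each state through the gluing sums, and verifies that the abstract event
of the same name realizes the projected transition and that all abstract
invariants hold on the projection.

## Synthetic network generator

The generator emulates the biochemical class the translation targets:
complex-forming networks with conserved moieties. It builds base species,
assembles complexes (subunit cap 3 by default), and draws reactions from
moiety-conserving templates only — complexation `X + Y → X:Y`,
dissociation, dimerization, and part exchange `X:Y + Z → X:Z + Y` — so
conservation analysis and refinement are always exercised and every
generated reaction conserves every base moiety by construction. The same
seed yields byte-identical output. Deliberately not emulated: kinetic
plausibility, synthesis/degradation (which destroy moieties), mass-action
structure, or realistic pathway topology. Passing tests on generated
networks therefore demonstrate structural correctness of the translation
and verification machinery, not biological fidelity of any particular
network.

Scale testing uses a 110-species / 242-reaction generated instance
(receptor-pathway scale); the full pipeline — including ~50k proof
obligations per machine — completes in seconds because almost all
discharges are case-independent integer checks. For the expanded machine
the pipeline uses lifted abstract laws plus one label-moiety law per
attribute as conservation invariants (both hold on the refined
stoichiometry by construction) instead of recomputing the full refined
kernel; `recompute_refined_laws=True` restores the full computation at
desk scale.

## Numerical and procedural choices

* All arithmetic is exact (Python integers / Fractions); no tolerances.
* Exploration and PO case enumeration iterate events in declaration order
  and parameter cases in domain product order; trace simulation picks
  uniformly among enabled pairs with a caller-supplied seed.
* Degenerate inputs: the empty network yields an empty (but valid)
  machine and report; empty reaction sides are written `0`; a base
  species' composition is itself once.
* Species ids admit `:` (complex names); Event-B identifiers are
  sanitized deterministically (`hsf3:hse → hsf3_hse`) with collision
  suffixes.

## Known limitations

* Multi-attribute refinements with interacting attributes, rate
  refinement, and model composition/union are out of scope.
* The discharger is specific to the generated linear fragment; it is not
  a general prover, and PO counts are this generator's own convention,
  not comparable to any external toolchain's prover statistics.
* Witness search for refutations is bounded; a genuinely violated
  obligation whose hypotheses are satisfiable only far from the initial
  state can come back `unknown`.
* SBML import is not implemented; the plain-text rule format and the JSON
  round-trip are the interchange formats.
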