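# reactb

Biochemical reaction networks as Event-B machines, with size-preserving
data refinement and automatic consistency verification.

## The problem

A reaction network is a set of stoichiometric rewriting rules

```
r:  m1 X1 + m2 X2 + ... + mn Xn  ->  m1' X1 + m2' X2 + ... + mn' Xn
```

over species `X1..Xn` with non-negative integer multiplicities. Such a
network translates naturally into an Event-B machine: one natural-number
variable per species, one guarded event per (irreversible) reaction —
the guard demands `Xi >= mi` for every reactant, the action applies
`Xi := Xi - mi + mi'` — plus typing invariants (`Xi ∈ ℕ`) and one
conservation invariant per moiety, i.e. per integer vector `c` in the left
null space of the stoichiometric matrix (`c·Δ = 0`).

Adding biological detail by **data refinement** — e.g. splitting the heat
shock factor `hsf` by the phosphorylation status of one site into
`hsf_0, hsf_1` — cascades through every complex the species is part of
(`hsf2` gets aggregated levels 0–2, the trimer `hsf3` levels 0–3, …) and
combinatorially multiplies the species and reactions of the expanded
refined network. The core idea implemented here avoids that blow-up in
the formal model: each refined species becomes a **single function
variable** `rX : {X_0,…,X_l} → ℕ` on a carrier set partitioned into
singleton variant constants, and each abstract reaction stays a **single
event** whose parameters pick the variants, constrained by partition
membership, coincidence-aware availability guards, and label-arithmetic
linking guards. Gluing invariants `X = rX(X_0) + … + rX(X_l)` tie the two
state spaces together, so the refined model keeps exactly the abstract
model's variable and event counts.

Consistency is checked automatically: the package generates the standard
Event-B proof obligations (invariant preservation, initialisation,
well-definedness, guard strengthening, action simulation) and discharges
them with a sound decision procedure for the linear fragment they live in,
complemented by bounded state exploration and seeded trace-refinement
checking. It is aimed at systems biologists and formal-methods users who
want machine-checked model refinement without hand proofs.

## Worked example

The bundled heat shock response (HSR) model has 12 rules (5 reversible)
over 10 species, refined by S230 phosphorylation of `hsf`:

```python
from reactb import (load_fixture, normalize_reversible, stoichiometric_delta,
                    conservation_basis, derive_variant_families, expand_network)

fx = load_fixture("hsr")
norm = normalize_reversible(fx.network)
print(len(norm.species), len(norm.reactions))
# 10 17

laws = conservation_basis(stoichiometric_delta(norm), norm.species_ids)
for law in laws:
    print(law.description)
# moiety[hsf + 2*hsf2 + 3*hsf3 + 3*hsf3:hse + hsp:hsf]
# moiety[hse + hsf3:hse]
# moiety[hsp:mfp + mfp + prot]

rmap = derive_variant_families(norm, fx.spec)
ref = expand_network(norm, rmap)
print(len(ref.network.species), len(ref.network.reactions))
# 20 55
```

The three printed moieties are the conserved quantities of the network
(total `hsf` content counting subunits, total `hse`, total protein); the
refinement cascade produces 20 refined species and 55 label-balanced
refined reactions. The full pipeline then builds and verifies all three
machines:

```
$ reactb pipeline hsr.rn hsr.yaml
...
"abstract": {"variables": 10, "events": 17, "invariants": 13},
"refined":  {"species": 20, "reactions": 55, ...},
"compact":  {"variables": 10, "events": 17, "invariants": 18},
"all_discharged": true
```

The compact refined machine has the same 10 variables and 17 events as
the abstract one — the size-preserving property — with 18 invariants
(10 typing + 3 conservation + 5 gluing), and every generated proof
obligation is discharged automatically.

The CLI (`reactb parse|stats|refine|emit|verify|simulate|pipeline`) writes
textual Event-B (`.ctx`/`.mch`) plus a lossless JSON model round-trip used
by `verify` and `simulate`.

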