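"""Bundled fixtures: the heat shock response network and two toy examples.

The heat shock response (HSR) is a conserved cellular stress mechanism:
under temperature stress proteins misfold (``prot -> mfp``) and heat shock
proteins (``hsp``) chaperone them back, while the heat shock factor
(``hsf``) trimerizes onto the heat shock element (``hse``) to drive ``hsp``
synthesis.  The bundled model has 12 rules, 5 of them reversible, over 10
species; the bundled refinement tracks the phosphorylation status of one
``hsf`` site (S230), splitting ``hsf`` into an unphosphorylated and a
phosphorylated variant and cascading through every ``hsf``-containing
complex.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Optional

import yaml

from .network import ReactionNetwork, parse_network
from .refine import RefinementSpec

__all__ = ["Fixture", "load_fixture", "FIXTURE_NAMES",
           "HSR_NETWORK_TEXT", "HSR_REFINEMENT_YAML", "load_refinement_yaml"]


HSR_NETWORK_TEXT = """\
# Eukaryotic heat shock response: 12 rules (5 reversible) over 10 species.
r1: 2 hsf <-> hsf2
r2: hsf + hsf2 <-> hsf3
r3: hsf3 + hse <-> hsf3:hse
r4: hsf3:hse -> hsf3:hse + hsp
r5: hsp + hsf <-> hsp:hsf
r6: hsp + hsf2 -> hsp:hsf + hsf
r7: hsp + hsf3 -> hsp:hsf + 2 hsf
r8: hsp + hsf3:hse -> hsp:hsf + 2 hsf + hse
r9: hsp -> 0
r10: prot -> mfp
r11: hsp + mfp <-> hsp:mfp
r12: hsp:mfp -> hsp + prot
"""

HSR_REFINEMENT_YAML = """\
# S230 phosphorylation refinement of hsf, with complex compositions.
refine:
  hsf: ["0", "1"]
composition:
  hsf2: {hsf: 2}
  hsf3: {hsf: 3}
  "hsf3:hse": {hsf: 3, hse: 1}
  "hsp:hsf": {hsp: 1, hsf: 1}
  "hsp:mfp": {hsp: 1, mfp: 1}
init:
  hsf: 6
  hse: 1
  hsp: 3
  prot: 5
"""

BINDING_TOY_TEXT = """\
# Binding toy: hetero-complex formation.
r1: A + B -> C
"""

BINDING_TOY_YAML = """\
refine:
  A: ["0", "1"]
  B: ["0", "1", "2"]
composition:
  C: {A: 1, B: 1}
init:
  A: 2
  B: 2
"""

DIMER_TOY_TEXT = """\
# Dimerization toy: homo-complex formation.
r1: 2 A -> C
"""

DIMER_TOY_YAML = """\
refine:
  A: ["0", "1"]
composition:
  C: {A: 2}
init:
  A: 4
"""

FIXTURE_NAMES = ("hsr", "binding_toy", "dimer_toy")

_TEXTS = {
    "hsr": (HSR_NETWORK_TEXT, HSR_REFINEMENT_YAML),
    "binding_toy": (BINDING_TOY_TEXT, BINDING_TOY_YAML),
    "dimer_toy": (DIMER_TOY_TEXT, DIMER_TOY_YAML),
}


@dataclass
class Fixture:
    name: str
    network: ReactionNetwork  # compositions attached, reversible flags kept
    spec: RefinementSpec
    init: Dict[str, int]


def load_refinement_yaml(text: str, network: ReactionNetwork):
    """Parse a refinement document: ``refine``, ``composition``, ``init``.

    Returns ``(network with compositions, RefinementSpec, init dict)``.
    """
    doc = yaml.safe_load(text) or {}
    comp = {sid: {b: int(k) for b, k in m.items()}
            for sid, m in (doc.get("composition") or {}).items()}
    net = network.with_compositions(comp) if comp else network
    spec = RefinementSpec({b: [str(x) for x in labels]
                           for b, labels in (doc.get("refine") or {}).items()})
    init = {s: int(v) for s, v in (doc.get("init") or {}).items()}
    return net, spec, init


def load_fixture(name: str) -> Fixture:
    """Return a parsed, validated bundled fixture (``hsr``, ``binding_toy``
    or ``dimer_toy``)."""
    try:
        net_text, ref_text = _TEXTS[name]
    except KeyError:
        raise ValueError(f"unknown fixture {name!r}; available: {', '.join(FIXTURE_NAMES)}")
    net = parse_network(net_text)
    net, spec, init = load_refinement_yaml(ref_text, net)
    return Fixture(name, net, spec, init)
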