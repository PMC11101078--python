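"""Metabolite and reaction universe for glycolysis + pentose phosphate pathway tracing.

The atlas declares every metabolite with its carbon count and every reaction
with an explicit substrate-carbon -> product-carbon mapping (an atom map).
Carbon numbering follows biochemical convention: C1 is the most oxidized end
(aldehyde, carboxyl or anomeric carbon).  Atom maps are bijections, so 13C
label is conserved exactly by construction; CO2 is treated as an ordinary
one-carbon product.

Key mechanistic conventions (textbook enzyme chemistry):

* transketolase transfers the C1-C2 glycolaldehyde unit of the ketose donor
  (Xu5P or F6P) onto the C1 end of the aldose acceptor;
* transaldolase transfers the C1-C3 dihydroxyacetone unit of the donor
  (S7P or F6P);
* the oxidative branch (G6P dehydrogenase + 6-phosphogluconate dehydrogenase,
  lumped) releases C1 of G6P as CO2 and yields Ru5P from C2-C6;
* the aldolase/triose-phosphate-isomerase lump splits F6P into one GAP made of
  C4-C6 in order and one GAP made of C1-C3 with the carbon order inverted
  (the DHAP half passes through TPI).

A plain-text serialization is provided so a network can be inspected, edited
and round-tripped, one reaction per line, e.g.::

    reaction TKT1 reversible: Xu5P[c1..c5] + R5P[c1..c5] -> S7P[Xu5P.c1..c2,R5P.c1..c5] + GAP[Xu5P.c3..c5]
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field


# --------------------------------------------------------------------------
# domain types
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class MetaboliteSpec:
    """A metabolite with a fixed carbon skeleton.

    ``aliases`` lists species the instrument cannot resolve from this one
    (e.g. ribose-5P reported together with ribulose-5P); they share the
    reported peak.
    """

    name: str
    n_carbons: int
    aliases: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.n_carbons < 1:
            raise ValueError(f"{self.name}: n_carbons must be >= 1")


# One atom-map entry: (substrate index, substrate carbon) -> (product index, product carbon).
# All indices 0-based internally; the text format prints 1-based carbons.
MapEntry = tuple[tuple[int, int], tuple[int, int]]


@dataclass(frozen=True)
class CarbonMap:
    """Bijective mapping of substrate carbons onto product carbons."""

    entries: tuple[MapEntry, ...]

    def forward(self) -> dict[tuple[int, int], tuple[int, int]]:
        return dict(self.entries)

    def backward(self) -> dict[tuple[int, int], tuple[int, int]]:
        return {dst: src for src, dst in self.entries}


@dataclass(frozen=True)
class ReactionSpec:
    name: str
    substrates: tuple[MetaboliteSpec, ...]
    products: tuple[MetaboliteSpec, ...]
    carbon_map: CarbonMap
    reversible: bool = False

    @property
    def n_substrate_carbons(self) -> int:
        return sum(m.n_carbons for m in self.substrates)

    @property
    def n_product_carbons(self) -> int:
        return sum(m.n_carbons for m in self.products)


@dataclass
class NetworkSpec:
    metabolites: dict[str, MetaboliteSpec] = field(default_factory=dict)
    reactions: dict[str, ReactionSpec] = field(default_factory=dict)

    def metabolite(self, name: str) -> MetaboliteSpec:
        return self.metabolites[name]

    def reaction(self, name: str) -> ReactionSpec:
        return self.reactions[name]

    def add_metabolite(self, met: MetaboliteSpec) -> MetaboliteSpec:
        if met.name in self.metabolites:
            raise ValueError(f"duplicate metabolite name {met.name!r}")
        self.metabolites[met.name] = met
        return met

    def add_reaction(self, rxn: ReactionSpec) -> ReactionSpec:
        if rxn.name in self.reactions:
            raise ValueError(f"duplicate reaction name {rxn.name!r}")
        self.reactions[rxn.name] = rxn
        return rxn


# --------------------------------------------------------------------------
# validation
# --------------------------------------------------------------------------

def validate_reaction(rxn: ReactionSpec) -> list[str]:
    """Check one reaction's atom map; return human-readable violations."""
    violations: list[str] = []
    if rxn.n_substrate_carbons != rxn.n_product_carbons:
        violations.append(
            f"{rxn.name}: carbon imbalance "
            f"({rxn.n_substrate_carbons} in, {rxn.n_product_carbons} out)"
        )

    sub_slots = {
        (i, c) for i, m in enumerate(rxn.substrates) for c in range(m.n_carbons)
    }
    prod_slots = {
        (i, c) for i, m in enumerate(rxn.products) for c in range(m.n_carbons)
    }

    seen_src: set[tuple[int, int]] = set()
    seen_dst: set[tuple[int, int]] = set()
    for src, dst in rxn.carbon_map.entries:
        if src not in sub_slots:
            violations.append(f"{rxn.name}: map source {src} is not a substrate carbon")
        if dst not in prod_slots:
            violations.append(f"{rxn.name}: map target {dst} is not a product carbon")
        if src in seen_src:
            violations.append(f"{rxn.name}: non-functional map, source {src} used twice")
        if dst in seen_dst:
            violations.append(f"{rxn.name}: non-injective map, target {dst} used twice")
        seen_src.add(src)
        seen_dst.add(dst)

    for slot in sorted(sub_slots - seen_src):
        violations.append(f"{rxn.name}: unmapped substrate carbon {slot}")
    for slot in sorted(prod_slots - seen_dst):
        violations.append(f"{rxn.name}: unmapped product carbon {slot}")
    return violations


def validate_network(net: NetworkSpec) -> list[str]:
    """Empty list iff every atom map is a carbon-balanced bijection over declared species."""
    violations: list[str] = []
    for rxn in net.reactions.values():
        for met in (*rxn.substrates, *rxn.products):
            if net.metabolites.get(met.name) is not met:
                violations.append(
                    f"{rxn.name}: references undeclared metabolite {met.name!r}"
                )
        violations.extend(validate_reaction(rxn))
    return violations


# --------------------------------------------------------------------------
# the shipped network
# --------------------------------------------------------------------------

def _identity_map(*pairs: tuple[int, int, int, int, int]) -> CarbonMap:
    """Build a map from (sub_idx, sub_start, prod_idx, prod_start, length) runs."""
    entries: list[MapEntry] = []
    for si, sc0, pi, pc0, n in pairs:
        entries.extend(((si, sc0 + k), (pi, pc0 + k)) for k in range(n))
    return CarbonMap(tuple(entries))


def default_network() -> NetworkSpec:
    """The trehalose / glycolysis / PPP network used throughout the package.

    Species that the HILIC-HRMS setup cannot resolve are flagged via aliases:
    the reported ribulose-5P peak pools Ru5P with R5P, and the fructose-6P
    peak pools F6P with glucose-1P.
    """
    net = NetworkSpec()

    tre = net.add_metabolite(MetaboliteSpec("trehalose", 12))
    glc = net.add_metabolite(MetaboliteSpec("glucose", 6))
    g6p = net.add_metabolite(MetaboliteSpec("G6P", 6))
    f6p = net.add_metabolite(MetaboliteSpec("F6P", 6, aliases=("G1P",)))
    ru5p = net.add_metabolite(MetaboliteSpec("Ru5P", 5, aliases=("R5P",)))
    r5p = net.add_metabolite(MetaboliteSpec("R5P", 5))
    xu5p = net.add_metabolite(MetaboliteSpec("Xu5P", 5))
    s7p = net.add_metabolite(MetaboliteSpec("S7P", 7))
    e4p = net.add_metabolite(MetaboliteSpec("E4P", 4))
    gap = net.add_metabolite(MetaboliteSpec("GAP", 3))
    pyr = net.add_metabolite(MetaboliteSpec("pyruvate", 3))
    lac = net.add_metabolite(MetaboliteSpec("lactate", 3))
    co2 = net.add_metabolite(MetaboliteSpec("CO2", 1))

    # trehalose -> 2 glucose: the two glucosyl units split with unit-wise identity
    net.add_reaction(ReactionSpec(
        "TRE", (tre,), (glc, glc),
        _identity_map((0, 0, 0, 0, 6), (0, 6, 1, 0, 6)),
    ))
    # hexokinase: glucose -> G6P, identity skeleton
    net.add_reaction(ReactionSpec(
        "HK", (glc,), (g6p,), _identity_map((0, 0, 0, 0, 6)),
    ))
    # phosphoglucose isomerase, reversible, identity skeleton
    net.add_reaction(ReactionSpec(
        "PGI", (g6p,), (f6p,), _identity_map((0, 0, 0, 0, 6)), reversible=True,
    ))
    # oxidative branch lump: G6P -> CO2 (from C1) + Ru5P (C2..C6 -> C1..C5)
    net.add_reaction(ReactionSpec(
        "OXPPP", (g6p,), (co2, ru5p),
        _identity_map((0, 0, 0, 0, 1), (0, 1, 1, 0, 5)),
    ))
    # pentose isomerase / epimerase: identity skeletons
    net.add_reaction(ReactionSpec(
        "RPI", (ru5p,), (r5p,), _identity_map((0, 0, 0, 0, 5)), reversible=True,
    ))
    net.add_reaction(ReactionSpec(
        "RPE", (ru5p,), (xu5p,), _identity_map((0, 0, 0, 0, 5)), reversible=True,
    ))
    # transketolase 1: Xu5P + R5P <-> S7P + GAP
    #   Xu5P C1-C2 -> S7P C1-C2; R5P C1-C5 -> S7P C3-C7; Xu5P C3-C5 -> GAP C1-C3
    net.add_reaction(ReactionSpec(
        "TKT1", (xu5p, r5p), (s7p, gap),
        _identity_map((0, 0, 0, 0, 2), (1, 0, 0, 2, 5), (0, 2, 1, 0, 3)),
        reversible=True,
    ))
    # transaldolase: S7P + GAP <-> E4P + F6P
    #   S7P C1-C3 -> F6P C1-C3; S7P C4-C7 -> E4P C1-C4; GAP C1-C3 -> F6P C4-C6
    net.add_reaction(ReactionSpec(
        "TAL", (s7p, gap), (e4p, f6p),
        _identity_map((0, 0, 1, 0, 3), (0, 3, 0, 0, 4), (1, 0, 1, 3, 3)),
        reversible=True,
    ))
    # transketolase 2: Xu5P + E4P <-> F6P + GAP
    #   Xu5P C1-C2 -> F6P C1-C2; E4P C1-C4 -> F6P C3-C6; Xu5P C3-C5 -> GAP C1-C3
    net.add_reaction(ReactionSpec(
        "TKT2", (xu5p, e4p), (f6p, gap),
        _identity_map((0, 0, 0, 0, 2), (1, 0, 0, 2, 4), (0, 2, 1, 0, 3)),
        reversible=True,
    ))
    # aldolase + TPI lump: F6P -> 2 GAP.  C4-C6 pass unchanged; C1-C3 arrive with
    # the carbon order inverted (DHAP half isomerized by TPI).
    net.add_reaction(ReactionSpec(
        "FBA", (f6p,), (gap, gap),
        CarbonMap((
            ((0, 3), (0, 0)), ((0, 4), (0, 1)), ((0, 5), (0, 2)),
            ((0, 0), (1, 2)), ((0, 1), (1, 1)), ((0, 2), (1, 0)),
        )),
    ))
    # lower glycolysis lump and lactate dehydrogenase: identity skeletons
    net.add_reaction(ReactionSpec(
        "GLY", (gap,), (pyr,), _identity_map((0, 0, 0, 0, 3)),
    ))
    net.add_reaction(ReactionSpec(
        "LDH", (pyr,), (lac,), _identity_map((0, 0, 0, 0, 3)),
    ))
    return net


# --------------------------------------------------------------------------
# plain-text serialization
# --------------------------------------------------------------------------

def _format_side_substrates(rxn: ReactionSpec) -> str:
    return " + ".join(
        f"{m.name}[c1..c{m.n_carbons}]" for m in rxn.substrates
    )


def _format_side_products(rxn: ReactionSpec) -> str:
    back = rxn.carbon_map.backward()
    parts = []
    for pi, m in enumerate(rxn.products):
        refs = []
        for pc in range(m.n_carbons):
            si, sc = back[(pi, pc)]
            refs.append(f"{rxn.substrates[si].name}.c{sc + 1}")
        # compress consecutive runs from the same substrate for readability
        parts.append(f"{m.name}[{_compress_refs(refs)}]")
    return " + ".join(parts)


def _compress_refs(refs: list[str]) -> str:
    out: list[str] = []
    i = 0
    while i < len(refs):
        met, c = refs[i].rsplit(".c", 1)
        j, c0 = i, int(c)
        while (
            j + 1 < len(refs)
            and refs[j + 1] == f"{met}.c{c0 + (j + 1 - i)}"
        ):
            j += 1
        if j > i:
            out.append(f"{met}.c{c0}..c{c0 + (j - i)}")
            i = j + 1
        else:
            out.append(refs[i])
            i += 1
    return ",".join(out)


def dumps_network(net: NetworkSpec) -> str:
    """Serialize a network to the declarative one-record-per-line text format."""
    lines = ["# pentrace network v1"]
    for met in net.metabolites.values():
        line = f"metabolite {met.name} {met.n_carbons}"
        if met.aliases:
            line += " aliases=" + ",".join(met.aliases)
        lines.append(line)
    for rxn in net.reactions.values():
        arrow = "<->" if rxn.reversible else "->"
        lines.append(
            f"reaction {rxn.name}: {_format_side_substrates(rxn)} "
            f"{arrow} {_format_side_products(rxn)}"
        )
    return "\n".join(lines) + "\n"


_SPECIES_RE = re.compile(r"^(?P<name>[\w-]+)\[(?P<body>[^\]]*)\]$")


def _expand_refs(body: str) -> list[str]:
    refs: list[str] = []
    for token in body.split(","):
        token = token.strip()
        m = re.match(r"^([\w-]+)\.c(\d+)\.\.c(\d+)$", token)
        if m:
            met, a, b = m.group(1), int(m.group(2)), int(m.group(3))
            refs.extend(f"{met}.c{k}" for k in range(a, b + 1))
        else:
            refs.append(token)
    return refs


def loads_network(text: str) -> NetworkSpec:
    """Parse the text format produced by :func:`dumps_network`."""
    net = NetworkSpec()
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        if line.startswith("metabolite "):
            parts = line.split()
            name, n = parts[1], int(parts[2])
            aliases: tuple[str, ...] = ()
            for extra in parts[3:]:
                if extra.startswith("aliases="):
                    aliases = tuple(extra[len("aliases="):].split(","))
            net.add_metabolite(MetaboliteSpec(name, n, aliases))
        elif line.startswith("reaction "):
            net.add_reaction(_parse_reaction(line, net, lineno))
        else:
            raise ValueError(f"line {lineno}: unrecognized record {line!r}")
    return net


def _parse_reaction(line: str, net: NetworkSpec, lineno: int) -> ReactionSpec:
    head, _, body = line[len("reaction "):].partition(":")
    name = head.strip()
    reversible = "<->" in body
    lhs, _, rhs = body.partition("<->" if reversible else "->")

    substrates: list[MetaboliteSpec] = []
    for term in lhs.split("+"):
        m = _SPECIES_RE.match(term.strip())
        if not m:
            raise ValueError(f"line {lineno}: bad substrate term {term.strip()!r}")
        substrates.append(net.metabolite(m.group("name")))

    # substrate names are unique within a reaction record, so "Met.cK" refs
    # resolve unambiguously; duplicated products are positional.
    sub_index = {met.name: i for i, met in enumerate(substrates)}
    products: list[MetaboliteSpec] = []
    entries: list[MapEntry] = []
    for pi, term in enumerate(rhs.split("+")):
        m = _SPECIES_RE.match(term.strip())
        if not m:
            raise ValueError(f"line {lineno}: bad product term {term.strip()!r}")
        met = net.metabolite(m.group("name"))
        products.append(met)
        refs = _expand_refs(m.group("body"))
        if len(refs) != met.n_carbons:
            raise ValueError(
                f"line {lineno}: {met.name} expects {met.n_carbons} carbon refs, "
                f"got {len(refs)}"
            )
        for pc, ref in enumerate(refs):
            src_met, c = ref.rsplit(".c", 1)
            entries.append(((sub_index[src_met], int(c) - 1), (pi, pc)))
    return ReactionSpec(
        name, tuple(substrates), tuple(products), CarbonMap(tuple(entries)),
        reversible=reversible,
    )
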