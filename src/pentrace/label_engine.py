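"""Exact propagation of 13C labeling states through the glycolysis/PPP network.

Two levels of machinery live here:

* **single-molecule states** (:class:`LabelState`) pushed through atom maps with
  :func:`apply_reaction` — used for the scheme-level worked examples: one
  transketolase/transaldolase recycling round (:func:`run_cyclic_round`) and the
  enumeration of first-round tracer placements (:func:`enumerate_first_round`);

* **pattern pools** (:class:`PatternPool`), exact probability distributions over
  all 2^n positional labeling patterns of a metabolite, convolved through
  reactions under a well-mixed-pool assumption (each reaction event draws its
  substrates independently from the current pool distributions).  Pools drive
  :func:`simulate_regime`, which produces the template mass-isotopologue
  distributions (MIDs) for the four labeling regimes used in pathway-mixture
  deconvolution:

  - ``direct_glycolysis``: tracer hexose runs straight down glycolysis;
  - ``oxppp_single_pass``: one oxidative decarboxylation, one
    transketolase/transaldolase recombination pass;
  - ``cyclic_ppp``: recombination hexoses re-enter further rounds; the
    transaldolase triose partner comes from the glycolytic GAP pool, so the
    early-phase "labeled GAP + unlabeled S7P" hexose (m+3, labeled at C4-C6)
    appears;
  - ``nonox_ppp``: pentoses formed from F6P + GAP by the reversed
    transketolase/transaldolase reactions.

Everything is enumerated exactly; there is no Monte Carlo anywhere.  The
largest species carries 12 carbons (trehalose), so the full state space is
at most 4096 patterns.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from functools import lru_cache
from math import comb

import numpy as np

from .carbon_atlas import (
    MetaboliteSpec,
    NetworkSpec,
    ReactionSpec,
    default_network,
)

REGIMES = ("direct_glycolysis", "oxppp_single_pass", "cyclic_ppp", "nonox_ppp")

#: metabolites whose MIDs the regime simulator reports (instrument-visible pools;
#: Ru5P is the combined ribulose-5P/ribose-5P peak, F6P the combined F6P/G1P peak)
REPORTED_METABOLITES = ("G6P", "F6P", "Ru5P", "S7P", "GAP", "lactate")

Pattern = tuple[int, ...]


# --------------------------------------------------------------------------
# single-molecule label states
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class LabelState:
    """Positional labeling of one molecule: pattern[i] == 1 iff carbon i+1 is 13C."""

    metabolite: MetaboliteSpec
    pattern: Pattern

    def __post_init__(self) -> None:
        if len(self.pattern) != self.metabolite.n_carbons:
            raise ValueError(
                f"{self.metabolite.name}: pattern length {len(self.pattern)} "
                f"!= {self.metabolite.n_carbons} carbons"
            )
        if any(f not in (0, 1) for f in self.pattern):
            raise ValueError("pattern flags must be 0 or 1")

    @property
    def mass_shift(self) -> int:
        return sum(self.pattern)


def fully_labeled(met: MetaboliteSpec) -> LabelState:
    return LabelState(met, (1,) * met.n_carbons)


def unlabeled(met: MetaboliteSpec) -> LabelState:
    return LabelState(met, (0,) * met.n_carbons)


def apply_reaction(
    rxn: ReactionSpec,
    substrate_states: list[LabelState] | tuple[LabelState, ...],
    direction: str = "forward",
) -> list[LabelState]:
    """Push labeled molecules through one reaction's atom map.

    ``direction="reverse"`` runs the reaction from products to substrates and
    is only legal for reversible reactions.  Label (the number of 13C carbons)
    is conserved exactly because the atom map is a bijection.
    """
    if direction not in ("forward", "reverse"):
        raise ValueError(f"direction must be forward|reverse, got {direction!r}")
    if direction == "reverse" and not rxn.reversible:
        raise ValueError(f"{rxn.name} is irreversible; cannot apply in reverse")

    inputs = rxn.substrates if direction == "forward" else rxn.products
    outputs = rxn.products if direction == "forward" else rxn.substrates
    mapping = (
        rxn.carbon_map.forward() if direction == "forward" else rxn.carbon_map.backward()
    )

    if len(substrate_states) != len(inputs):
        raise ValueError(
            f"{rxn.name}: expected {len(inputs)} input states, got {len(substrate_states)}"
        )
    for st, met in zip(substrate_states, inputs):
        if st.metabolite.name != met.name:
            raise ValueError(
                f"{rxn.name}: input state is {st.metabolite.name}, expected {met.name}"
            )

    out_patterns = [[0] * m.n_carbons for m in outputs]
    for (si, sc), (pi, pc) in mapping.items():
        out_patterns[pi][pc] = substrate_states[si].pattern[sc]
    return [
        LabelState(met, tuple(pat)) for met, pat in zip(outputs, out_patterns)
    ]


# --------------------------------------------------------------------------
# mass-isotopologue distributions
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class MID:
    """Fractional abundances over mass shifts m+0 ... m+n for an n-carbon species."""

    metabolite: MetaboliteSpec
    fractions: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.fractions) != self.metabolite.n_carbons + 1:
            raise ValueError(
                f"{self.metabolite.name}: MID needs {self.metabolite.n_carbons + 1} "
                f"fractions, got {len(self.fractions)}"
            )
        arr = np.asarray(self.fractions, dtype=float)
        if (arr < -1e-12).any() or (arr > 1 + 1e-12).any():
            raise ValueError("MID fractions must lie in [0, 1]")
        if abs(arr.sum() - 1.0) > 1e-9:
            raise ValueError(f"MID fractions must sum to 1, got {arr.sum()!r}")

    def as_array(self) -> np.ndarray:
        return np.asarray(self.fractions, dtype=float)

    def __getitem__(self, shift: int) -> float:
        return self.fractions[shift]


@dataclass(frozen=True)
class RegimeSpec:
    """One labeling regime: which pathway runs, for how many rounds, on which tracer.

    ``tracer`` maps entry species name ("glucose" and/or "trehalose") to its
    MID; ``enrichment`` is the fraction of the entry hexose pool that is
    tracer-derived (the rest is unlabeled endogenous influx).
    """

    regime: str
    tracer: dict[str, MID] = field(default_factory=dict)
    enrichment: float = 1.0
    rounds: int = 1

    def __post_init__(self) -> None:
        if self.regime not in REGIMES:
            raise ValueError(f"unknown regime {self.regime!r}; must be one of {REGIMES}")
        if not 0.0 <= self.enrichment <= 1.0:
            raise ValueError("enrichment must lie in [0, 1]")
        if self.rounds < 1:
            raise ValueError("rounds must be >= 1")


# --------------------------------------------------------------------------
# pattern pools (exact distributions over positional states)
# --------------------------------------------------------------------------

@dataclass
class PatternPool:
    """Exact probability distribution over the 2^n labeling patterns of a pool."""

    metabolite: MetaboliteSpec
    dist: dict[Pattern, float]

    def prune(self, tol: float = 1e-15) -> "PatternPool":
        d = {p: w for p, w in self.dist.items() if w > tol}
        total = sum(d.values())
        return PatternPool(self.metabolite, {p: w / total for p, w in d.items()})

    def mid(self) -> MID:
        n = self.metabolite.n_carbons
        frac = [0.0] * (n + 1)
        for pat, w in self.dist.items():
            frac[sum(pat)] += w
        total = sum(frac)
        return MID(self.metabolite, tuple(f / total for f in frac))


def pool_unlabeled_pattern(met: MetaboliteSpec) -> PatternPool:
    return PatternPool(met, {(0,) * met.n_carbons: 1.0})


def pool_from_mid(mid: MID) -> PatternPool:
    """Spread each mass-shift fraction uniformly over its positional patterns.

    Exchangeability across carbon positions holds exactly for the entry
    species this is used on (pure tracer, unlabeled pool, and i.i.d. per-carbon
    tracer impurity all give exchangeable patterns).
    """
    met = mid.metabolite
    n = met.n_carbons
    dist: dict[Pattern, float] = {}
    for shift, f in enumerate(mid.fractions):
        if f <= 0.0:
            continue
        per_pattern = f / comb(n, shift)
        for ones in itertools.combinations(range(n), shift):
            pat = tuple(1 if i in ones else 0 for i in range(n))
            dist[pat] = dist.get(pat, 0.0) + per_pattern
    return PatternPool(met, dist)


def mix_pools(pools: list[PatternPool], weights: list[float]) -> PatternPool:
    met = pools[0].metabolite
    if any(p.metabolite.name != met.name for p in pools):
        raise ValueError("cannot mix pools of different metabolites")
    total = sum(weights)
    dist: dict[Pattern, float] = {}
    for pool, w in zip(pools, weights):
        for pat, p in pool.dist.items():
            dist[pat] = dist.get(pat, 0.0) + (w / total) * p
    return PatternPool(met, dist).prune()


def react_pools(
    rxn: ReactionSpec,
    substrate_pools: list[PatternPool],
    direction: str = "forward",
) -> list[PatternPool]:
    """Convolve independent substrate pools through a reaction; return product pools.

    Each reaction event draws one molecule independently from every substrate
    pool (well-mixed assumption); the returned pools are the exact marginal
    distributions of the products.
    """
    inputs = rxn.substrates if direction == "forward" else rxn.products
    outputs = rxn.products if direction == "forward" else rxn.substrates
    out_dists: list[dict[Pattern, float]] = [{} for _ in outputs]

    for joint in itertools.product(*(p.dist.items() for p in substrate_pools)):
        states = [
            LabelState(met, pat) for met, (pat, _) in zip(inputs, joint)
        ]
        weight = 1.0
        for _, w in joint:
            weight *= w
        if weight <= 0.0:
            continue
        for k, prod in enumerate(apply_reaction(rxn, states, direction)):
            d = out_dists[k]
            d[prod.pattern] = d.get(prod.pattern, 0.0) + weight
    return [
        PatternPool(met, d).prune() for met, d in zip(outputs, out_dists)
    ]


# --------------------------------------------------------------------------
# the cyclic-PPP recycling round (single-molecule level)
# --------------------------------------------------------------------------

@dataclass
class CyclicRoundResult:
    """Products of one full recycling round on six pentose phosphates.

    Iterating yields ``(hexoses, trioses)`` — four regenerated hexose states
    and the two trioses handed to glycolysis.  Under the ``pool_unlabeled``
    transaldolase-partner policy the round additionally consumes two unlabeled
    trioses from the pool and emits the two transketolase-1 trioses into it;
    both are recorded so that the carbon balance can be audited.
    """

    hexoses: list[LabelState]
    trioses: list[LabelState]
    internal_trioses_emitted: list[LabelState]
    pool_trioses_consumed: list[LabelState]

    def __iter__(self):
        return iter((self.hexoses, self.trioses))

    def labeled_carbons_out(self) -> int:
        return sum(
            s.mass_shift
            for s in (*self.hexoses, *self.trioses, *self.internal_trioses_emitted)
        )


def _run_tkt_tal_set(
    net: NetworkSpec,
    xu_donor1: LabelState,
    r5p_acceptor: LabelState,
    xu_donor2: LabelState,
    tal_partner_policy: str,
) -> tuple[list[LabelState], list[LabelState], list[LabelState], list[LabelState]]:
    """One transketolase/transaldolase set: 3 pentoses -> 2 hexoses (+ trioses).

    Returns (hexoses, exported trioses, internal trioses emitted to the pool,
    pool trioses consumed); the latter two are empty under the ``internal``
    policy, where the transketolase-1 triose is consumed by transaldolase.
    """
    tkt1, tal, tkt2 = net.reaction("TKT1"), net.reaction("TAL"), net.reaction("TKT2")
    pgi = net.reaction("PGI")
    gap = net.metabolite("GAP")

    s7p, gap_internal = apply_reaction(tkt1, [xu_donor1, r5p_acceptor])
    if tal_partner_policy == "internal":
        partner = gap_internal
        emitted: list[LabelState] = []
        consumed: list[LabelState] = []
    elif tal_partner_policy == "pool_unlabeled":
        partner = unlabeled(gap)
        emitted = [gap_internal]
        consumed = [partner]
    else:
        raise ValueError(
            f"tal_partner_policy must be internal|pool_unlabeled, got {tal_partner_policy!r}"
        )
    e4p, f6p_tal = apply_reaction(tal, [s7p, partner])
    f6p_tkt2, gap_out = apply_reaction(tkt2, [xu_donor2, e4p])
    # hexoses reported as G6P via the (reversible) isomerase, identity skeleton
    hexoses = [
        apply_reaction(pgi, [f6p_tal], "reverse")[0],
        apply_reaction(pgi, [f6p_tkt2], "reverse")[0],
    ]
    return hexoses, [gap_out], emitted, consumed


def run_cyclic_round(
    pentose_states: list[LabelState],
    tal_partner_policy: str = "internal",
    net: NetworkSpec | None = None,
) -> CyclicRoundResult:
    """Recycle six pentose phosphates into four hexoses and two trioses.

    The six inputs are consumed as two transketolase/transaldolase sets, each
    ordered (Xu5P donor of TKT1, R5P acceptor, Xu5P donor of TKT2).
    """
    net = net or default_network()
    if len(pentose_states) != 6:
        raise ValueError(f"a cyclic round consumes exactly 6 pentoses, got {len(pentose_states)}")
    for st in pentose_states:
        if st.metabolite.n_carbons != 5:
            raise ValueError(f"{st.metabolite.name} is not a pentose")

    # coerce role metabolites (Ru5P/R5P/Xu5P share an identity skeleton)
    xu5p, r5p = net.metabolite("Xu5P"), net.metabolite("R5P")
    roles = [xu5p, r5p, xu5p, xu5p, r5p, xu5p]
    states = [
        LabelState(met, st.pattern) for met, st in zip(roles, pentose_states)
    ]

    hexoses: list[LabelState] = []
    trioses: list[LabelState] = []
    emitted: list[LabelState] = []
    consumed: list[LabelState] = []
    for k in (0, 3):
        h, t, e, c = _run_tkt_tal_set(
            net, states[k], states[k + 1], states[k + 2], tal_partner_policy
        )
        hexoses.extend(h)
        trioses.extend(t)
        emitted.extend(e)
        consumed.extend(c)
    return CyclicRoundResult(hexoses, trioses, emitted, consumed)


def enumerate_first_round(
    net: NetworkSpec | None = None,
) -> list[tuple[str, tuple[int, int]]]:
    """Enumerate first-round tracer placements on one transketolase/transaldolase set.

    Each of the three pentose inputs (TKT1 Xu5P donor, R5P acceptor, TKT2 Xu5P
    donor) is independently fully labeled (m+5) or unlabeled; the all-unlabeled
    assignment is excluded, leaving 2^3 - 1 = 7 combinations.  The transaldolase
    triose partner is drawn unlabeled from the pool.  Returns, per assignment,
    a label like ``"L-U-L"`` and the mass shifts of the two regenerated hexoses.
    """
    net = net or default_network()
    xu5p, r5p = net.metabolite("Xu5P"), net.metabolite("R5P")
    out: list[tuple[str, tuple[int, int]]] = []
    for flags in itertools.product((1, 0), repeat=3):
        if not any(flags):
            continue
        donor1 = fully_labeled(xu5p) if flags[0] else unlabeled(xu5p)
        acceptor = fully_labeled(r5p) if flags[1] else unlabeled(r5p)
        donor2 = fully_labeled(xu5p) if flags[2] else unlabeled(xu5p)
        hexoses, _, _, _ = _run_tkt_tal_set(
            net, donor1, acceptor, donor2, "pool_unlabeled"
        )
        label = "-".join("L" if f else "U" for f in flags)
        out.append((label, (hexoses[0].mass_shift, hexoses[1].mass_shift)))
    return out


# --------------------------------------------------------------------------
# regime simulation (pool level)
# --------------------------------------------------------------------------

def _entry_hexose_pool(net: NetworkSpec, spec: RegimeSpec) -> PatternPool:
    """Mix tracer-derived glucosyl units with unlabeled influx at the stated enrichment."""
    g6p = net.metabolite("G6P")
    tracer_pools: list[PatternPool] = []
    for name, mid in spec.tracer.items():
        if name == "trehalose" and mid.fractions[6] == 1.0:
            # hemolymph trehalose labeled at one glucosyl unit is block-labeled,
            # not exchangeable over its 12 carbons; either unit is equally likely
            pool = PatternPool(mid.metabolite, {
                (1,) * 6 + (0,) * 6: 0.5,
                (0,) * 6 + (1,) * 6: 0.5,
            })
        else:
            pool = pool_from_mid(mid)
        if name == "trehalose":
            glc1, glc2 = react_pools(net.reaction("TRE"), [pool])
            pool = mix_pools([glc1, glc2], [0.5, 0.5])
        elif name != "glucose":
            raise ValueError(f"unsupported tracer species {name!r}")
        g6p_pool = PatternPool(g6p, dict(pool.dist))  # HK/TRE keep the skeleton
        tracer_pools.append(g6p_pool)
    if not tracer_pools:
        raise ValueError("regime needs at least one tracer species")
    tracer_pool = mix_pools(tracer_pools, [1.0] * len(tracer_pools))
    return mix_pools(
        [tracer_pool, pool_unlabeled_pattern(g6p)],
        [spec.enrichment, 1.0 - spec.enrichment],
    )


def _retype(pool: PatternPool, met: MetaboliteSpec) -> PatternPool:
    """Relabel a pool as an isomeric metabolite with an identity carbon skeleton."""
    if met.n_carbons != pool.metabolite.n_carbons:
        raise ValueError(
            f"cannot retype {pool.metabolite.name} ({pool.metabolite.n_carbons}C) "
            f"as {met.name} ({met.n_carbons}C)"
        )
    return PatternPool(met, dict(pool.dist))


def _glycolytic_gap_pool(net: NetworkSpec, hexose: PatternPool) -> PatternPool:
    f6p = react_pools(net.reaction("PGI"), [hexose])[0]
    gap_a, gap_b = react_pools(net.reaction("FBA"), [f6p])
    return mix_pools([gap_a, gap_b], [0.5, 0.5])


def _recombination_pass(
    net: NetworkSpec, pentose: PatternPool, tal_partner: PatternPool
) -> tuple[PatternPool, PatternPool, list[PatternPool]]:
    """One TKT1/TAL/TKT2 pass on a pentose pool.

    Returns (hexose product pool, S7P pool, [triose pools emitted]).
    """
    xu5p, r5p = net.metabolite("Xu5P"), net.metabolite("R5P")
    xu_pool = PatternPool(xu5p, dict(pentose.dist))
    r5_pool = PatternPool(r5p, dict(pentose.dist))
    s7p, gap_i = react_pools(net.reaction("TKT1"), [xu_pool, r5_pool])
    e4p, f6p_tal = react_pools(net.reaction("TAL"), [s7p, tal_partner])
    f6p_tkt2, gap_o = react_pools(net.reaction("TKT2"), [xu_pool, e4p])
    hexose = mix_pools([f6p_tal, f6p_tkt2], [0.5, 0.5])
    return hexose, s7p, [gap_i, gap_o]


def simulate_regime(
    net: NetworkSpec, spec: RegimeSpec
) -> dict[str, MID]:
    """Exact template MIDs for one labeling regime.

    Returns MIDs for the instrument-visible pools: G6P, F6P (combined with
    G1P), Ru5P (combined with R5P), S7P, GAP and lactate.  Pools a regime does
    not label are reported as the unlabeled endogenous background (pure m+0).
    """
    g6p = net.metabolite("G6P")
    entry = _entry_hexose_pool(net, spec)
    gap_glyc = _glycolytic_gap_pool(net, entry)
    e = spec.enrichment

    def background(name: str) -> PatternPool:
        return pool_unlabeled_pattern(net.metabolite(name))

    if spec.regime == "direct_glycolysis":
        pools = {
            "G6P": entry,
            "F6P": entry,
            "Ru5P": background("Ru5P"),
            "S7P": background("S7P"),
            "GAP": gap_glyc,
            "lactate": gap_glyc,
        }

    elif spec.regime == "oxppp_single_pass":
        _, ru5p = react_pools(net.reaction("OXPPP"), [entry])
        # single pass: the TKT1 triose is consumed internally by transaldolase
        xu5p = PatternPool(net.metabolite("Xu5P"), dict(ru5p.dist))
        r5p = PatternPool(net.metabolite("R5P"), dict(ru5p.dist))
        s7p, gap_i = react_pools(net.reaction("TKT1"), [xu5p, r5p])
        e4p, f6p_tal = react_pools(net.reaction("TAL"), [s7p, gap_i])
        f6p_tkt2, gap_o = react_pools(net.reaction("TKT2"), [xu5p, e4p])
        hexose = mix_pools([f6p_tal, f6p_tkt2], [0.5, 0.5])
        pools = {
            "G6P": entry,
            "F6P": hexose,
            "Ru5P": ru5p,
            "S7P": s7p,
            "GAP": gap_o,
            "lactate": gap_o,
        }

    elif spec.regime == "cyclic_ppp":
        # Reported pentose/heptose pools are the first oxidative generation;
        # hexoses accumulate over rounds (recycled hexoses re-enter
        # recombination diluted by unlabeled influx at the enrichment scalar).
        _, ru5p_1 = react_pools(net.reaction("OXPPP"), [entry])
        hexose_pools = [entry]
        triose_pools = [gap_glyc]
        pentose = ru5p_1
        s7p_1: PatternPool | None = None
        for k in range(spec.rounds):
            hexose_k, s7p_k, gaps_k = _recombination_pass(net, pentose, gap_glyc)
            hexose_k = _retype(hexose_k, g6p)  # product F6P isomerized back to G6P
            if s7p_1 is None:
                s7p_1 = s7p_k
            hexose_pools.append(hexose_k)
            triose_pools.extend(gaps_k)
            if k + 1 < spec.rounds:
                recycled = mix_pools(
                    [hexose_k, pool_unlabeled_pattern(g6p)], [e, 1.0 - e]
                )
                pentose = react_pools(net.reaction("OXPPP"), [recycled])[1]
        hexose = mix_pools(hexose_pools, [1.0] * len(hexose_pools))
        gap = mix_pools(triose_pools, [1.0] * len(triose_pools))
        pools = {
            "G6P": hexose,
            "F6P": hexose,
            "Ru5P": ru5p_1,
            "S7P": s7p_1,
            "GAP": gap,
            "lactate": gap,
        }

    elif spec.regime == "nonox_ppp":
        f6p_pool = react_pools(net.reaction("PGI"), [entry])[0]
        # reversed TKT2: F6P + GAP -> Xu5P + E4P
        xu_2rev, e4p = react_pools(
            net.reaction("TKT2"), [f6p_pool, gap_glyc], "reverse"
        )
        # reversed TAL: E4P + F6P -> S7P + GAP
        s7p, _ = react_pools(net.reaction("TAL"), [e4p, f6p_pool], "reverse")
        # reversed TKT1: S7P + GAP -> Xu5P + R5P
        xu_1rev, r5_1rev = react_pools(
            net.reaction("TKT1"), [s7p, gap_glyc], "reverse"
        )
        ru5p_met = net.metabolite("Ru5P")
        pentose = mix_pools(
            [
                PatternPool(ru5p_met, dict(xu_2rev.dist)),
                PatternPool(ru5p_met, dict(xu_1rev.dist)),
                PatternPool(ru5p_met, dict(r5_1rev.dist)),
            ],
            [1.0, 1.0, 1.0],
        )
        pools = {
            "G6P": entry,
            "F6P": f6p_pool,
            "Ru5P": pentose,
            "S7P": s7p,
            "GAP": gap_glyc,
            "lactate": gap_glyc,
        }

    else:  # pragma: no cover - guarded by RegimeSpec
        raise ValueError(f"unknown regime {spec.regime!r}")

    # report every pool under its instrument-visible species (isomeric skeletons)
    return {
        name: _retype(pool, net.metabolite(name)).mid()
        for name, pool in pools.items()
    }


# --------------------------------------------------------------------------
# template packaging for mixture deconvolution
# --------------------------------------------------------------------------

@lru_cache(maxsize=64)
def _cached_templates(
    tracer_key: tuple[tuple[str, tuple[float, ...]], ...],
    enrichment: float,
    rounds: int,
) -> dict[str, dict[str, MID]]:
    net = default_network()
    tracer = {
        name: MID(net.metabolite(name), fr) for name, fr in tracer_key
    }
    out: dict[str, dict[str, MID]] = {}
    for regime in REGIMES:
        spec = RegimeSpec(regime, tracer=tracer, enrichment=enrichment, rounds=rounds)
        out[regime] = simulate_regime(net, spec)
    return out


def template_mids(
    net: NetworkSpec,
    tracer: dict[str, MID],
    enrichment: float,
    rounds: int = 2,
    regimes: tuple[str, ...] = REGIMES,
) -> "pd.DataFrame":
    """Template MIDs, one column per regime, rows indexed by (metabolite, mass_shift).

    Each regime column sums to 1 within every metabolite block.
    """
    import pandas as pd  # local import keeps the engine importable without pandas

    tracer_key = tuple(
        sorted((name, tuple(mid.fractions)) for name, mid in tracer.items())
    )
    all_mids = _cached_templates(tracer_key, float(enrichment), int(rounds))

    rows = []
    for met_name in REPORTED_METABOLITES:
        n = net.metabolite(met_name).n_carbons
        for shift in range(n + 1):
            rows.append((met_name, shift))
    index = pd.MultiIndex.from_tuples(rows, names=["metabolite", "mass_shift"])
    data = {
        regime: [
            all_mids[regime][met][shift] for met, shift in rows
        ]
        for regime in regimes
    }
    return pd.DataFrame(data, index=index)


def glucose_tracer(net: NetworkSpec, purity: float = 1.0) -> dict[str, MID]:
    """Fully labeled glucose tracer; impurity is i.i.d. per carbon (binomial MID)."""
    glc = net.metabolite("glucose")
    return {"glucose": _binomial_mid(glc, purity)}


def trehalose_tracer(
    net: NetworkSpec, purity: float = 1.0, half_labeled: bool = False
) -> dict[str, MID]:
    """Fully labeled trehalose (m+12), or the half-labeled m+6 hemolymph variant."""
    tre = net.metabolite("trehalose")
    if not half_labeled:
        return {"trehalose": _binomial_mid(tre, purity)}
    # one glucosyl unit labeled: uniform over the two positions is equivalent
    # to labeling the first unit, since the cleavage map is symmetric
    fractions = [0.0] * 13
    fractions[6] = 1.0
    return {"trehalose": MID(tre, tuple(fractions))}


def _binomial_mid(met: MetaboliteSpec, p: float) -> MID:
    n = met.n_carbons
    fr = tuple(comb(n, k) * p**k * (1 - p) ** (n - k) for k in range(n + 1))
    return MID(met, fr)
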