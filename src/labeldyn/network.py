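"""Metabolite pools, reactions and carbon atom-transition maps.

A :class:`NetworkScheme` is the topological object everything else runs on:
it lists the metabolite pools (with carbon counts and initial concentrations),
the reactions connecting them, and for every reaction an :class:`AtomMap`
stating where each substrate carbon ends up.  Two variants are shipped:

* variant ``A`` — one well-mixed cytosolic hexose-phosphate pool feeding both
  glycolysis and glycogen synthesis;
* variant ``B`` — an additional channeled hexose-phosphate pool (``hexP_chan``)
  with its own hexokinase, glucose-6-phosphatase, phosphofructokinase and
  fructose-bisphosphatase, from which glycogen synthase draws exclusively.

Carbon indexing is 1-based (glucose C1 = aldehyde carbon).  Isotopomers are
indexed by bitmask: bit ``i-1`` encodes carbon ``i`` (0 = 12C, 1 = 13C).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Literal

__all__ = [
    "Pool",
    "AtomMap",
    "Reaction",
    "NetworkScheme",
    "build_scheme",
    "load_scheme",
    "save_scheme",
    "validate_atom_maps",
    "reachable_labeling",
]

Location = Literal["medium", "cytosol", "channel", "mito"]

#: ((role, carbon), (role, carbon)) — roles disambiguate a pool used twice.
Entry = tuple[tuple[str, int], tuple[str, int]]


@dataclass(frozen=True)
class Pool:
    """A metabolite pool.

    ``conc0`` is the initial concentration in mM referred to medium volume
    (glycogen in mM glucosyl-unit equivalents).  Untracked pools (CO2) take
    part in total-concentration kinetics but carry no isotopomer vector and
    feed unlabeled carbon into any atom map that draws on them.
    """

    id: str
    n_carbons: int
    location: Location
    conc0: float
    is_tracked: bool = True

    def __post_init__(self) -> None:
        if self.n_carbons < 1:
            raise ValueError(f"pool {self.id}: n_carbons must be >= 1")
        if self.conc0 < 0:
            raise ValueError(f"pool {self.id}: conc0 must be >= 0")


@dataclass(frozen=True)
class AtomMapVariant:
    """One concrete carbon routing, applied with probability ``prob``."""

    prob: float
    entries: tuple[Entry, ...]
    released: tuple[tuple[str, int], ...] = ()


@dataclass(frozen=True)
class AtomMap:
    """Carbon atom-transition map of a reaction.

    ``variants`` holds one or more alternative routings (scramble variants for
    reactions passing through symmetric intermediates such as fumarate); their
    probabilities must sum to 1.  Every variant must route each substrate
    carbon to exactly one product carbon or release it, and fill each product
    carbon from exactly one source.
    """

    variants: tuple[AtomMapVariant, ...]

    @classmethod
    def single(
        cls,
        entries: Iterable[Entry],
        released: Iterable[tuple[str, int]] = (),
    ) -> "AtomMap":
        return cls((AtomMapVariant(1.0, tuple(entries), tuple(released)),))

    @classmethod
    def scrambled(
        cls,
        variants: Iterable[tuple[float, Iterable[Entry], Iterable[tuple[str, int]]]],
    ) -> "AtomMap":
        return cls(
            tuple(
                AtomMapVariant(p, tuple(e), tuple(r)) for p, e, r in variants
            )
        )


@dataclass(frozen=True)
class Reaction:
    """A reaction with carbon bookkeeping.

    ``substrates`` and ``products`` are (role, pool_id) pairs; roles are unique
    within the reaction and are what the atom map refers to, so a pool may
    legitimately appear twice (transketolase uses two pentose phosphates).
    ``kind`` is ``"net"`` for chemistry that moves mass and ``"exchange"`` for
    isotope-exchange-only fluxes that leave every total concentration unchanged.
    ``rate_law`` is a small dict understood by :mod:`labeldyn.kinetics`, e.g.
    ``{"law": "mass_action", "params": ["k_pk"]}`` or
    ``{"law": "enzyme", "enzyme": "ald", "component": "vf"}``.
    """

    id: str
    substrates: tuple[tuple[str, str], ...]
    products: tuple[tuple[str, str], ...]
    atom_map: AtomMap
    rate_law: dict
    kind: Literal["net", "exchange"] = "net"

    def substrate_pools(self) -> list[str]:
        return [p for _, p in self.substrates]

    def product_pools(self) -> list[str]:
        return [p for _, p in self.products]


@dataclass
class NetworkScheme:
    """A full scheme: pools + reactions + enzyme couplings.

    ``enzymes`` configures the three-step exchange-enzyme treatment (aldolase,
    transketolases, transaldolase): for each enzyme, the six elementary steps
    map to a rate-constant parameter and an optional concentration factor,
    e.g. ``{"v1": ["ald_k1", "fbp"], "v2": ["ald_k2", null], ...}``.
    """

    variant: str
    pools: dict[str, Pool]
    reactions: dict[str, Reaction]
    enzymes: dict[str, dict[str, tuple[str, str | None]]] = field(default_factory=dict)
    fast_equilibrium_groups: dict[str, list[str]] = field(default_factory=dict)

    def tracked_pools(self) -> list[Pool]:
        return [p for p in self.pools.values() if p.is_tracked]

    def parameter_names(self) -> list[str]:
        """All parameter names referenced by rate laws and enzyme couplings."""
        names: list[str] = []
        for rxn in self.reactions.values():
            names.extend(rxn.rate_law.get("params", []))
        for steps in self.enzymes.values():
            for pname, _conc in steps.values():
                names.append(pname)
        seen: set[str] = set()
        out = []
        for n in names:
            if n not in seen:
                seen.add(n)
                out.append(n)
        return out


# ---------------------------------------------------------------------------
# validation

def validate_atom_maps(scheme: NetworkScheme) -> list[str]:
    """Check carbon conservation and bijectivity of every atom map.

    Returns a list of human-readable violations (empty iff the scheme is
    sound) rather than raising, so callers can report all defects at once.
    """
    violations: list[str] = []
    for rxn in scheme.reactions.values():
        roles_sub: dict[str, str] = dict(rxn.substrates)
        roles_prod: dict[str, str] = dict(rxn.products)
        if len(roles_sub) != len(rxn.substrates) or len(roles_prod) != len(rxn.products):
            violations.append(f"({rxn.id}): duplicate role names")
            continue
        for role, pid in list(roles_sub.items()) + list(roles_prod.items()):
            if pid not in scheme.pools:
                violations.append(f"({rxn.id}): unknown pool {pid!r} for role {role!r}")
        if any(pid not in scheme.pools for pid in list(roles_sub.values()) + list(roles_prod.values())):
            continue
        total_prob = sum(v.prob for v in rxn.atom_map.variants)
        if abs(total_prob - 1.0) > 1e-9:
            violations.append(
                f"({rxn.id}): scramble variant probabilities ≠ 1 (sum={total_prob})"
            )
        n_sub = sum(scheme.pools[p].n_carbons for p in roles_sub.values())
        n_prod = sum(scheme.pools[p].n_carbons for p in roles_prod.values())
        for iv, var in enumerate(rxn.atom_map.variants):
            tag = f"({rxn.id}, variant {iv})" if len(rxn.atom_map.variants) > 1 else f"({rxn.id})"
            if len(var.entries) + len(var.released) != n_sub:
                violations.append(
                    f"{tag}: carbon count not conserved "
                    f"({len(var.entries)} mapped + {len(var.released)} released != {n_sub} substrate carbons)"
                )
            src_seen: set[tuple[str, int]] = set()
            dst_seen: set[tuple[str, int]] = set()
            for (srole, sc), (prole, pc) in var.entries:
                if srole not in roles_sub:
                    violations.append(f"{tag}: entry source role {srole!r} is not a substrate")
                    continue
                if prole not in roles_prod:
                    violations.append(f"{tag}: entry target role {prole!r} is not a product")
                    continue
                if not (1 <= sc <= scheme.pools[roles_sub[srole]].n_carbons):
                    violations.append(f"{tag}: carbon {srole} C{sc} out of range")
                if not (1 <= pc <= scheme.pools[roles_prod[prole]].n_carbons):
                    violations.append(f"{tag}: carbon {prole} C{pc} out of range")
                if (srole, sc) in src_seen:
                    violations.append(f"{tag}: substrate carbon ({srole}, C{sc}) mapped twice")
                src_seen.add((srole, sc))
                if (prole, pc) in dst_seen:
                    violations.append(f"{tag}: product carbon ({prole}, C{pc}) filled twice")
                dst_seen.add((prole, pc))
            for srole, sc in var.released:
                if (srole, sc) in src_seen:
                    violations.append(f"{tag}: substrate carbon ({srole}, C{sc}) both mapped and released")
                src_seen.add((srole, sc))
            # every substrate carbon accounted for, every product carbon filled
            for role, pid in roles_sub.items():
                for c in range(1, scheme.pools[pid].n_carbons + 1):
                    if (role, c) not in src_seen:
                        violations.append(f"{tag}: substrate carbon ({role}, C{c}) unaccounted")
            for role, pid in roles_prod.items():
                for c in range(1, scheme.pools[pid].n_carbons + 1):
                    if (role, c) not in dst_seen:
                        violations.append(f"{tag}: product carbon ({role}, C{c}) receives no source")
        if rxn.kind == "exchange":
            if sorted(roles_sub.values()) != sorted(roles_prod.values()):
                violations.append(
                    f"({rxn.id}): exchange-only reaction changes pool totals "
                    f"({sorted(roles_sub.values())} -> {sorted(roles_prod.values())})"
                )
    return violations


def reachable_labeling(scheme: NetworkScheme, tracer_pool: str) -> set[str]:
    """Pools a 13C label introduced in ``tracer_pool`` can reach.

    Transitive closure over atom-map entries; untracked pools are included
    when reached but not expanded (their isotopomers are not simulated, so
    label does not propagate through them).
    """
    if tracer_pool not in scheme.pools:
        raise KeyError(f"unknown pool {tracer_pool!r}")
    edges: dict[str, set[str]] = {p: set() for p in scheme.pools}
    for rxn in scheme.reactions.values():
        roles_sub = dict(rxn.substrates)
        roles_prod = dict(rxn.products)
        for var in rxn.atom_map.variants:
            for (srole, _sc), (prole, _pc) in var.entries:
                if srole in roles_sub and prole in roles_prod:
                    edges[roles_sub[srole]].add(roles_prod[prole])
    reached = {tracer_pool}
    frontier = [tracer_pool]
    while frontier:
        pool = frontier.pop()
        if not scheme.pools[pool].is_tracked:
            continue
        for nxt in edges[pool]:
            if nxt not in reached:
                reached.add(nxt)
                frontier.append(nxt)
    return reached


# ---------------------------------------------------------------------------
# JSON serialization — shipped schemes are data files

def _map_to_json(amap: AtomMap) -> list:
    return [
        {
            "prob": v.prob,
            "entries": [[list(src), list(dst)] for src, dst in v.entries],
            "released": [list(r) for r in v.released],
        }
        for v in amap.variants
    ]


def _map_from_json(obj: list) -> AtomMap:
    return AtomMap(
        tuple(
            AtomMapVariant(
                v["prob"],
                tuple(
                    ((e[0][0], e[0][1]), (e[1][0], e[1][1])) for e in v["entries"]
                ),
                tuple((r[0], r[1]) for r in v["released"]),
            )
            for v in obj
        )
    )


def scheme_to_dict(scheme: NetworkScheme) -> dict:
    return {
        "variant": scheme.variant,
        "pools": [
            {
                "id": p.id,
                "n_carbons": p.n_carbons,
                "location": p.location,
                "conc0": p.conc0,
                "is_tracked": p.is_tracked,
            }
            for p in scheme.pools.values()
        ],
        "reactions": [
            {
                "id": r.id,
                "substrates": [list(s) for s in r.substrates],
                "products": [list(s) for s in r.products],
                "atom_map": _map_to_json(r.atom_map),
                "rate_law": r.rate_law,
                "kind": r.kind,
            }
            for r in scheme.reactions.values()
        ],
        "enzymes": {
            eid: {step: list(spec) for step, spec in steps.items()}
            for eid, steps in scheme.enzymes.items()
        },
        "fast_equilibrium_groups": scheme.fast_equilibrium_groups,
    }


def scheme_from_dict(obj: dict) -> NetworkScheme:
    pools = {
        p["id"]: Pool(
            p["id"], p["n_carbons"], p["location"], p["conc0"], p.get("is_tracked", True)
        )
        for p in obj["pools"]
    }
    reactions = {}
    for r in obj["reactions"]:
        reactions[r["id"]] = Reaction(
            id=r["id"],
            substrates=tuple((s[0], s[1]) for s in r["substrates"]),
            products=tuple((s[0], s[1]) for s in r["products"]),
            atom_map=_map_from_json(r["atom_map"]),
            rate_law=r["rate_law"],
            kind=r.get("kind", "net"),
        )
    enzymes = {
        eid: {step: (spec[0], spec[1]) for step, spec in steps.items()}
        for eid, steps in obj.get("enzymes", {}).items()
    }
    return NetworkScheme(
        variant=obj["variant"],
        pools=pools,
        reactions=reactions,
        enzymes=enzymes,
        fast_equilibrium_groups=obj.get("fast_equilibrium_groups", {}),
    )


def save_scheme(scheme: NetworkScheme, path: str | Path) -> None:
    Path(path).write_text(json.dumps(scheme_to_dict(scheme), indent=1) + "\n")


def load_scheme(path: str | Path) -> NetworkScheme:
    return scheme_from_dict(json.loads(Path(path).read_text()))


def build_scheme(variant: str) -> NetworkScheme:
    """Load one of the two shipped scheme variants (``"A"`` or ``"B"``)."""
    if variant not in ("A", "B"):
        raise ValueError(f"variant must be 'A' or 'B', got {variant!r}")
    ref = resources.files("labeldyn.schemes").joinpath(f"scheme_{variant}.json")
    return scheme_from_dict(json.loads(ref.read_text()))
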