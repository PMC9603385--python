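"""Pathway knowledge base: reactions, routes, bypasses and final products.

The KB is the single source of truth for what "complete" means downstream.
A pathway is a set of alternative *routes* (ordered reaction lists) leading
to one or more final products; a *bypass* declares that a single enzyme can
substitute a contiguous segment of a route (e.g. a host alkaline phosphatase
standing in for a two-step dephosphorylation).  Bypasses are directional:
they may be restricted to one symbiotic partner via their ``side`` field,
which is what lets a host enzyme patch a symbiont route without the symbiont
(or the free-living reference genomes) being credited with it.

KB files are YAML; see ``docs/methods.md`` for the schema.
"""

from __future__ import annotations

import itertools
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import yaml

__all__ = [
    "KBError",
    "Reaction",
    "Bypass",
    "Product",
    "Pathway",
    "PathwayKB",
    "RouteVariant",
    "is_valid_ec",
    "load_kb",
    "enumerate_routes",
    "enumerate_route_variants",
]

#: Accepted EC identifier: four dot-separated fields, first three numeric,
#: last numeric or "-" (the 3-digit sub-subclass form).
_EC_RE = re.compile(r"^\d+\.\d+\.\d+\.(\d+|-)$")

SIDES = ("both", "host", "symbiont")


class KBError(ValueError):
    """Raised for schema violations or dangling references in a KB file."""


def is_valid_ec(ec: str) -> bool:
    """True for a 4-digit (``1.7.3.3``) or 3-digit (``3.1.3.-``) EC string."""
    return bool(_EC_RE.match(ec))


@dataclass(frozen=True)
class Reaction:
    """One enzymatic step, identified by EC number(s) and/or COG id(s).

    Multiple EC numbers on one reaction are *alternative* identifiers for
    the same step (e.g. SerB ``3.1.3.3`` and HisB ``3.1.3.-``): a genome
    possessing any one of them possesses the reaction.
    """

    reaction_id: str
    ec_numbers: frozenset[str] = frozenset()
    cog_ids: frozenset[str] = frozenset()
    reversible: bool = False
    name: str = ""

    def __post_init__(self) -> None:
        if not self.ec_numbers and not self.cog_ids:
            raise KBError(
                f"reaction {self.reaction_id!r}: needs at least one EC or COG id"
            )
        for ec in self.ec_numbers:
            if not is_valid_ec(ec):
                raise KBError(
                    f"reaction {self.reaction_id!r}: malformed EC number {ec!r}"
                )


@dataclass(frozen=True)
class Bypass:
    """One enzyme substituting a contiguous route segment.

    ``side`` restricts which partner's genomes may use the substituted
    variant when evaluated alone: ``"host"`` for host-only bypasses (the
    folate alkaline-phosphatase case), ``"symbiont"`` for the mirror case,
    ``"both"`` for unrestricted alternatives.  The union (collaborative)
    evaluation always considers every variant.
    """

    covered_reaction_ids: tuple[str, ...]
    bypass_reaction_id: str
    side: str = "both"

    def __post_init__(self) -> None:
        if not self.covered_reaction_ids:
            raise KBError("bypass must cover at least one reaction")
        if self.side not in SIDES:
            raise KBError(f"bypass side must be one of {SIDES}, got {self.side!r}")


@dataclass(frozen=True)
class Product:
    """A pathway end product with host-essentiality metadata."""

    name: str
    essential: bool = False
    product_class: str = "other"  # amino_acid | vitamin | cofactor | other


@dataclass(frozen=True)
class Pathway:
    pathway_id: str
    final_products: tuple[Product, ...]
    routes: tuple[tuple[str, ...], ...]
    bypasses: tuple[Bypass, ...] = ()
    name: str = ""

    def __post_init__(self) -> None:
        if not self.final_products:
            raise KBError(f"pathway {self.pathway_id!r}: no final products")
        if not self.routes or any(not r for r in self.routes):
            raise KBError(f"pathway {self.pathway_id!r}: routes must be non-empty")
        seen = set()
        for route in self.routes:
            key = frozenset(route)
            if key in seen:
                raise KBError(
                    f"pathway {self.pathway_id!r}: duplicate route {sorted(key)}"
                )
            seen.add(key)

    @property
    def product_names(self) -> tuple[str, ...]:
        return tuple(p.name for p in self.final_products)


@dataclass(frozen=True)
class RouteVariant:
    """A concrete reaction set sufficient for a pathway's products.

    ``bypass_sides`` maps each bypass reaction used in this variant to the
    side allowed to use it ("both"/"host"/"symbiont"); primary-route
    reactions are not listed.
    """

    reactions: frozenset[str]
    bypass_sides: Mapping[str, str] = field(default_factory=dict)

    def allowed_for(self, side: str) -> bool:
        """Whether a genome on ``side`` may complete the pathway via this variant."""
        return all(s in ("both", side) for s in self.bypass_sides.values())


@dataclass(frozen=True)
class PathwayKB:
    """Validated collection of pathways and reactions."""

    pathways: Mapping[str, Pathway]
    reactions: Mapping[str, Reaction]
    version: str = "unversioned"

    def __post_init__(self) -> None:
        for pw in self.pathways.values():
            referenced = set(itertools.chain.from_iterable(pw.routes))
            for bp in pw.bypasses:
                referenced.add(bp.bypass_reaction_id)
                referenced.update(bp.covered_reaction_ids)
                if not any(
                    set(bp.covered_reaction_ids) & set(route) for route in pw.routes
                ):
                    raise KBError(
                        f"pathway {pw.pathway_id!r}: bypass over "
                        f"{bp.covered_reaction_ids} covers no route reaction"
                    )
            missing = sorted(referenced - self.reactions.keys())
            if missing:
                raise KBError(
                    f"pathway {pw.pathway_id!r}: dangling reaction id(s) "
                    f"{', '.join(missing)}"
                )

    def pathway(self, pathway_id: str) -> Pathway:
        try:
            return self.pathways[pathway_id]
        except KeyError:
            raise KBError(f"unknown pathway id {pathway_id!r}") from None

    def reaction(self, reaction_id: str) -> Reaction:
        try:
            return self.reactions[reaction_id]
        except KeyError:
            raise KBError(f"unknown reaction id {reaction_id!r}") from None

    def pathways_for_product(self, product: str) -> list[Pathway]:
        return [
            pw for pw in self.pathways.values() if product in pw.product_names
        ]

    @property
    def all_products(self) -> list[Product]:
        out: dict[str, Product] = {}
        for pw in self.pathways.values():
            for prod in pw.final_products:
                out.setdefault(prod.name, prod)
        return list(out.values())


# ---------------------------------------------------------------------------
# Loading


def _parse_reaction(entry: Mapping, idx: int) -> Reaction:
    try:
        rid = entry["id"]
    except (KeyError, TypeError):
        raise KBError(f"reactions[{idx}]: missing required field 'id'") from None
    try:
        return Reaction(
            reaction_id=rid,
            ec_numbers=frozenset(entry.get("ec", []) or []),
            cog_ids=frozenset(entry.get("cog", []) or []),
            reversible=bool(entry.get("reversible", False)),
            name=entry.get("name", ""),
        )
    except KBError as exc:
        raise KBError(f"reactions[{idx}] ({rid!r}): {exc}") from None


def _parse_product(entry) -> Product:
    if isinstance(entry, str):
        return Product(name=entry)
    return Product(
        name=entry["name"],
        essential=bool(entry.get("essential", False)),
        product_class=entry.get("class", "other"),
    )


def _parse_pathway(entry: Mapping, idx: int) -> Pathway:
    try:
        pid = entry["id"]
        products = tuple(_parse_product(p) for p in entry["products"])
        routes = tuple(tuple(r) for r in entry["routes"])
    except (KeyError, TypeError) as exc:
        raise KBError(f"pathways[{idx}]: missing or malformed field: {exc}") from None
    bypasses = tuple(
        Bypass(
            covered_reaction_ids=tuple(bp["covers"]),
            bypass_reaction_id=bp["via"],
            side=bp.get("side", "both"),
        )
        for bp in entry.get("bypasses", []) or []
    )
    try:
        return Pathway(
            pathway_id=pid,
            final_products=products,
            routes=routes,
            bypasses=bypasses,
            name=entry.get("name", ""),
        )
    except KBError as exc:
        raise KBError(f"pathways[{idx}] ({pid!r}): {exc}") from None


def load_kb(path: str | Path) -> PathwayKB:
    """Load and validate a pathway KB from a YAML file.

    Raises :class:`KBError` naming the offending entry on schema violations
    and dangling reaction references.
    """
    path = Path(path)
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    if not isinstance(doc, Mapping):
        raise KBError(f"{path}: KB file must be a mapping")
    reactions = {}
    for i, entry in enumerate(doc.get("reactions", []) or []):
        rxn = _parse_reaction(entry, i)
        if rxn.reaction_id in reactions:
            raise KBError(f"{path}: duplicate reaction id {rxn.reaction_id!r}")
        reactions[rxn.reaction_id] = rxn
    pathways = {}
    for i, entry in enumerate(doc.get("pathways", []) or []):
        pw = _parse_pathway(entry, i)
        if pw.pathway_id in pathways:
            raise KBError(f"{path}: duplicate pathway id {pw.pathway_id!r}")
        pathways[pw.pathway_id] = pw
    try:
        return PathwayKB(
            pathways=pathways,
            reactions=reactions,
            version=str(doc.get("version", "unversioned")),
        )
    except KBError as exc:
        raise KBError(f"{path}: {exc}") from None


# ---------------------------------------------------------------------------
# Route enumeration


def _contiguous_spans(route: Sequence[str], segment: Sequence[str]) -> list[tuple[int, int]]:
    """Start/end indices where ``segment`` occurs contiguously in ``route``."""
    n, m = len(route), len(segment)
    return [
        (i, i + m)
        for i in range(n - m + 1)
        if tuple(route[i : i + m]) == tuple(segment)
    ]


def _expand_route(
    route: tuple[str, ...], bypasses: Sequence[Bypass]
) -> list[tuple[tuple[str, ...], dict[str, str]]]:
    """All bypass-substituted forms of one ordered route (including itself)."""
    variants: dict[tuple[str, ...], dict[str, str]] = {route: {}}
    frontier = [(route, {})]
    while frontier:
        current, sides = frontier.pop()
        for bp in bypasses:
            for start, end in _contiguous_spans(current, bp.covered_reaction_ids):
                new = current[:start] + (bp.bypass_reaction_id,) + current[end:]
                new_sides = dict(sides)
                new_sides[bp.bypass_reaction_id] = bp.side
                if new not in variants:
                    variants[new] = new_sides
                    frontier.append((new, new_sides))
    return list(variants.items())


def enumerate_route_variants(kb: PathwayKB, pathway_id: str) -> list[RouteVariant]:
    """Every route variant of a pathway after bypass substitution.

    Variants are minimal as *sets*: no returned reaction set is a strict
    superset of another.  Deterministically ordered by sorted reaction ids.
    """
    pw = kb.pathway(pathway_id)
    raw: dict[frozenset[str], dict[str, str]] = {}
    for route in pw.routes:
        for variant, sides in _expand_route(route, pw.bypasses):
            key = frozenset(variant)
            if key not in raw:
                raw[key] = sides
            else:
                # Keep the least-restricted side annotation for each bypass.
                for rid, side in sides.items():
                    if raw[key].get(rid) not in ("both", None):
                        if side == "both":
                            raw[key][rid] = side
                    raw[key].setdefault(rid, side)
    keys = list(raw)
    minimal = [
        k for k in keys if not any(other < k for other in keys if other != k)
    ]
    minimal.sort(key=lambda s: sorted(s))
    return [RouteVariant(reactions=k, bypass_sides=dict(raw[k])) for k in minimal]


def enumerate_routes(kb: PathwayKB, pathway_id: str) -> set[frozenset[str]]:
    """Minimal reaction-id sets each sufficient for the pathway's products."""
    return {v.reactions for v in enumerate_route_variants(kb, pathway_id)}
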