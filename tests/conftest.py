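"""Shared fixtures and the independent brute-force oracle.

The oracle deliberately avoids the library's route-enumeration and
decision code: it expands bypass substitutions by naive repeated string
rewriting over ordered routes and classifies by direct rule application,
so agreement with the package is a real cross-check.
"""

from __future__ import annotations

import itertools
import random

import pytest

from symbiopath import (
    GapThresholds,
    GenomeAnnotation,
    build_matrix,
    load_kb,
)
from symbiopath.pathway_kb import Bypass, Pathway, PathwayKB, Product, Reaction
from symbiopath.synthetic_data import blattodea_fixture


# ---------------------------------------------------------------------------
# KB construction helpers


def make_kb(pathways, reactions, version="test"):
    return PathwayKB(
        pathways={p.pathway_id: p for p in pathways},
        reactions={r.reaction_id: r for r in reactions},
        version=version,
    )


def simple_reactions(ids):
    """One reaction per id with a synthetic but well-formed EC number."""
    return [
        Reaction(reaction_id=rid, ec_numbers=frozenset({f"9.9.{i + 1}.{i + 1}"}))
        for i, rid in enumerate(sorted(ids))
    ]


@pytest.fixture(scope="session")
def fixture_bundle():
    return blattodea_fixture()


@pytest.fixture(scope="session")
def fixture_matrix(fixture_bundle):
    return build_matrix(list(fixture_bundle.annotations), fixture_bundle.kb)


@pytest.fixture
def toy_kb():
    """Three-reaction linear pathway plus a two-route pathway with a bypass."""
    reactions = [
        Reaction("r1", frozenset({"1.1.1.1"})),
        Reaction("r2", frozenset({"2.2.2.2"})),
        Reaction("r3", frozenset({"3.3.3.3"})),
        Reaction("a1", frozenset({"4.4.4.4"})),
        Reaction("a2", frozenset({"5.5.5.5"})),
        Reaction("byp", frozenset({"6.6.6.6"})),
    ]
    pathways = [
        Pathway(
            pathway_id="linear",
            final_products=(Product("P1"),),
            routes=(("r1", "r2", "r3"),),
        ),
        Pathway(
            pathway_id="branched",
            final_products=(Product("P2"),),
            routes=(("a1", "a2"), ("r1", "a2")),
            bypasses=(Bypass(("a1",), "byp"),),
        ),
    ]
    return make_kb(pathways, reactions)


def annotation_for(kb, reaction_ids, genome_id="G", role="focal-symbiont",
                   subset_labels=()):
    """Annotation carrying exactly the EC/COG identifiers of the reactions."""
    ecs, cogs = set(), set()
    for rid in reaction_ids:
        rxn = kb.reactions[rid]
        if rxn.ec_numbers:
            ecs.update(rxn.ec_numbers)
        else:
            cogs.update(rxn.cog_ids)
    return GenomeAnnotation(
        genome_id=genome_id, role=role,
        ec_set=frozenset(ecs), cog_set=frozenset(cogs),
        subset_labels=frozenset(subset_labels),
    )


# ---------------------------------------------------------------------------
# Brute-force oracle


def oracle_route_sets(pathway: Pathway) -> set[frozenset[str]]:
    """Bypass expansion by exhaustive rewriting; minimal sets only."""
    seen: set[tuple[str, ...]] = set()
    frontier = list(pathway.routes)
    while frontier:
        route = frontier.pop()
        if route in seen:
            continue
        seen.add(route)
        for bp in pathway.bypasses:
            seg = bp.covered_reaction_ids
            for i in range(len(route) - len(seg) + 1):
                if tuple(route[i : i + len(seg)]) == tuple(seg):
                    frontier.append(
                        route[:i] + (bp.bypass_reaction_id,) + route[i + len(seg):]
                    )
    sets = {frozenset(r) for r in seen}
    return {s for s in sets if not any(o < s for o in sets)}


def oracle_variant_sides(pathway: Pathway) -> dict[frozenset[str], dict[str, str]]:
    """Side annotation per variant: bypass reactions present in the variant."""
    out = {}
    bypass_side = {bp.bypass_reaction_id: bp.side for bp in pathway.bypasses}
    primary = {rid for route in pathway.routes for rid in route}
    for s in oracle_route_sets(pathway):
        out[s] = {
            rid: bypass_side[rid]
            for rid in s
            if rid in bypass_side and rid not in primary
        }
    return out


def oracle_state(pathway, present, side="symbiont", max_gaps=2):
    """(state, gap set) by exhaustive evaluation of usable variants."""
    best = None
    for variant, sides in sorted(
        oracle_variant_sides(pathway).items(), key=lambda kv: sorted(kv[0])
    ):
        if any(s not in ("both", side) for s in sides.values()):
            continue
        missing = frozenset(variant) - set(present)
        if not missing:
            state = "complete"
        elif len(missing) <= max_gaps and len(missing) < len(variant):
            state = "gapped"
        else:
            state = "absent"
        rank = {"complete": 2, "gapped": 1, "absent": 0}[state]
        key = (-rank, len(missing), tuple(sorted(missing)))
        if best is None or key < best[0]:
            best = (key, state, missing if state == "gapped" else frozenset())
    return best[1], best[2]


def oracle_relationship(
    pathway,
    sym_present: set[str],
    host_present: set[str],
    ref_absence: dict[str, float],
    thresholds: GapThresholds = GapThresholds(),
) -> str:
    """Five-category decision by direct rule application."""

    def category(rid):
        f = ref_absence.get(rid, 0.0)
        if f > thresholds.common_min_ref_absence:
            return "common"
        if f < thresholds.specific_max_ref_absence:
            return "specific"
        return "unclassified"

    def host_fills(rid):
        if rid in host_present:
            return True
        return any(
            rid in bp.covered_reaction_ids
            and bp.side in ("both", "host")
            and bp.bypass_reaction_id in host_present
            for bp in pathway.bypasses
        )

    sym_state, sym_gaps = oracle_state(pathway, sym_present, "symbiont",
                                       thresholds.max_gaps)
    host_state, _ = oracle_state(pathway, host_present, "host", thresholds.max_gaps)
    if sym_state == "complete":
        sym_ok = True
    elif sym_state == "absent":
        sym_ok = False
    else:
        sym_ok = not any(
            category(r) == "specific" and host_fills(r) for r in sym_gaps
        )
    host_ok = host_state == "complete"
    if sym_ok and host_ok:
        return "overlapping"
    if host_ok:
        return "host-dependent"
    if sym_ok:
        return "symbiont-dependent"
    assumed = {
        r for r in sym_gaps if category(r) in ("common", "unclassified")
    } - sym_present
    for variant, sides in sorted(
        oracle_variant_sides(pathway).items(), key=lambda kv: sorted(kv[0])
    ):
        sym_cov = {
            r for r in variant
            if r in sym_present and sides.get(r, "both") in ("both", "symbiont")
        }
        host_cov = {
            r for r in variant
            if r in host_present and sides.get(r, "both") in ("both", "host")
        }
        if set(variant) <= sym_cov | host_cov | assumed:
            if (sym_cov - host_cov - assumed) and (host_cov - sym_cov - assumed):
                return "collaborative"
    return "doubly-absent"


# ---------------------------------------------------------------------------
# Random small-KB generator for oracle-equivalence suites


def random_small_kb(rng: random.Random) -> PathwayKB:
    n_reactions = rng.randint(2, 10)
    rids = [f"x{i}" for i in range(n_reactions)]
    reactions = simple_reactions(rids)
    extra = Reaction("bypx", frozenset({"8.8.8.8"}))
    n_routes = rng.randint(1, 3)
    routes, seen = [], set()
    for _ in range(n_routes):
        k = rng.randint(1, n_reactions)
        route = tuple(rng.sample(rids, k))
        if frozenset(route) not in seen:
            seen.add(frozenset(route))
            routes.append(route)
    bypasses = []
    if rng.random() < 0.6:
        base = rng.choice(routes)
        seg_len = rng.randint(1, min(2, len(base)))
        start = rng.randint(0, len(base) - seg_len)
        bypasses.append(
            Bypass(
                covered_reaction_ids=tuple(base[start : start + seg_len]),
                bypass_reaction_id="bypx",
                side=rng.choice(["both", "host", "symbiont"]),
            )
        )
    pw = Pathway(
        pathway_id="pw",
        final_products=(Product("P"),),
        routes=tuple(routes),
        bypasses=tuple(bypasses),
    )
    return make_kb([pw], reactions + [extra])
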