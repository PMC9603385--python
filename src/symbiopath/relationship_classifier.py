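"""Five-category host-symbiont relationship calling per final product.

For each pathway end product and each (symbiont genome, host profile)
pairing the classifier decides, in order:

1. both partners effectively complete alone       -> **overlapping**  (O)
2. only the host effectively complete             -> **host-dependent** (H)
3. only the symbiont effectively complete         -> **symbiont-dependent** (B)
4. neither alone, but some route is covered by the
   union of the two enzyme sets, with each partner
   contributing at least one reaction beyond the
   symbiont's common gaps                         -> **collaborative** (C)
5. otherwise                                      -> **doubly-absent** (-)

"Effectively complete" encodes the biological assumptions: a symbiont
pathway whose gaps are all *common* is assumed completed by unknown
alternative enzymes shared across the clade; a symbiont pathway with
*specific* gaps that no host enzyme (directly or through a host-usable
bypass) can fill is assumed completed by a symbiont-specific alternative
enzyme and flagged ``assumed-alternative-enzyme``.  Only a specific gap
that the host *can* fill pushes the decision down to the collaborative
test.  Host pathways are effectively complete only with zero gaps: no
reference panel exists against which a host gap could be called common.
Unclassified (mid-frequency) gaps are treated like common gaps but flag
the resulting call ``unresolved-gap``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .function_annotation import GenomeAnnotation
from .gap_classifier import GapCall, GapThresholds, categorize_frequency
from .occurrence_matrix import (
    MatrixError,
    OccurrenceMatrix,
    evaluate_pathway,
    presence_set,
    reference_absence_frequency,
)
from .pathway_kb import PathwayKB, Pathway, RouteVariant, enumerate_route_variants

__all__ = [
    "CATEGORY_LETTERS",
    "HostProfile",
    "Pairing",
    "RelationshipCall",
    "RelationshipTable",
    "host_consensus",
    "standard_insect_profile",
    "effective_complete",
    "classify_relationship",
    "classify_all",
]

CATEGORY_LETTERS = {
    "overlapping": "O",
    "host-dependent": "H",
    "symbiont-dependent": "B",
    "collaborative": "C",
    "doubly-absent": "-",
}

#: Preference order when several pathways yield the same product: the call
#: reflecting the greatest joint biosynthetic capability wins.
_CATEGORY_PREFERENCE = [
    "overlapping",
    "symbiont-dependent",
    "host-dependent",
    "collaborative",
    "doubly-absent",
]


@dataclass(frozen=True)
class HostProfile:
    """A host enzyme repertoire: one genome, a consensus, or a curated set."""

    host_id: str
    ec_set: frozenset[str]
    cog_set: frozenset[str] = frozenset()
    consensus_rule: str = "single"  # single | all | majority | curated
    member_ids: tuple[str, ...] = ()
    #: identifier -> members lacking it, for identifiers not shared by all.
    member_absences: Mapping[str, tuple[str, ...]] = field(default_factory=dict)

    @property
    def identifiers(self) -> frozenset[str]:
        return self.ec_set | self.cog_set


def host_consensus(
    annotations: Sequence[GenomeAnnotation],
    rule: str = "majority",
    host_id: str = "host-consensus",
) -> HostProfile:
    """Consensus enzyme repertoire over several host genomes.

    ``rule="all"`` keeps identifiers present in every member;
    ``rule="majority"`` keeps those in strictly more than half.  Per-member
    differences (identifiers held by some but not all members) are reported
    alongside so that single-member deficits — e.g. the termite that lost
    part of the uricolytic pathway — stay visible.
    """
    if not annotations:
        raise MatrixError("host consensus needs at least one annotation")
    if rule not in ("all", "majority"):
        raise ValueError(f"unknown consensus rule {rule!r}")
    n = len(annotations)
    counts: dict[str, int] = {}
    kind: dict[str, str] = {}
    for ann in annotations:
        for ec in ann.ec_set:
            counts[ec] = counts.get(ec, 0) + 1
            kind[ec] = "ec"
        for cog in ann.cog_set:
            counts[cog] = counts.get(cog, 0) + 1
            kind[cog] = "cog"
    need = n if rule == "all" else n // 2 + 1
    kept = {ident for ident, c in counts.items() if c >= need}
    absences = {
        ident: tuple(
            a.genome_id for a in annotations if ident not in a.identifiers
        )
        for ident, c in sorted(counts.items())
        if c < n
    }
    return HostProfile(
        host_id=host_id,
        ec_set=frozenset(i for i in kept if kind[i] == "ec"),
        cog_set=frozenset(i for i in kept if kind[i] == "cog"),
        consensus_rule=rule,
        member_ids=tuple(a.genome_id for a in annotations),
        member_absences=absences,
    )


def standard_insect_profile(ec_set: Iterable[str], host_id: str = "standard-insect") -> HostProfile:
    """Curated 'standard insect gene set' profile (no member genomes)."""
    return HostProfile(
        host_id=host_id,
        ec_set=frozenset(ec_set),
        consensus_rule="curated",
        member_ids=(),
    )


@dataclass(frozen=True)
class Pairing:
    symbiont_id: str
    host_profile_id: str
    group_label: str = ""


@dataclass(frozen=True)
class RelationshipCall:
    product: str
    pathway_id: str
    symbiont_id: str
    host_profile_id: str
    category: str
    route_used: frozenset[str] = frozenset()
    symbiont_contributed: frozenset[str] = frozenset()
    host_contributed: frozenset[str] = frozenset()
    gap_calls: tuple[GapCall, ...] = ()
    flags: frozenset[str] = frozenset()  # unresolved-gap | assumed-alternative-enzyme

    @property
    def letter(self) -> str:
        return CATEGORY_LETTERS[self.category]


def _host_profile_annotation(profile: HostProfile) -> GenomeAnnotation:
    return GenomeAnnotation(
        genome_id=profile.host_id,
        role="host",
        ec_set=profile.ec_set,
        cog_set=profile.cog_set,
    )


def _host_fills(
    reaction_id: str,
    host_reactions: frozenset[str],
    pathway: Pathway,
) -> bool:
    """Whether the host can supply a reaction directly or via a host-usable bypass."""
    if reaction_id in host_reactions:
        return True
    for bp in pathway.bypasses:
        if (
            reaction_id in bp.covered_reaction_ids
            and bp.side in ("both", "host")
            and bp.bypass_reaction_id in host_reactions
        ):
            return True
    return False


def effective_complete(
    state,
    gap_calls: Sequence[GapCall],
    side: str,
    *,
    kb: PathwayKB | None = None,
    host_reactions: frozenset[str] = frozenset(),
) -> tuple[bool, frozenset[str]]:
    """Effective completeness of one partner's pathway, with flags.

    Symbiont side: complete, or gapped with every gap common (assumed
    alternative enzymes across the clade), or gapped with specific gaps
    that the host cannot fill (flagged ``assumed-alternative-enzyme``).
    Unclassified gaps count as common but flag ``unresolved-gap``.
    Host side: complete with zero gaps only.

    Raises :class:`MatrixError` when a gap reaction has no gap call.
    """
    if side == "host":
        return state.state == "complete", frozenset()
    if state.state == "complete":
        return True, frozenset()
    if state.state == "absent":
        return False, frozenset()
    by_reaction = {c.reaction_id: c for c in gap_calls}
    missing_calls = sorted(state.gap_reactions - by_reaction.keys())
    if missing_calls:
        raise MatrixError(
            f"pathway {state.pathway_id!r}: no gap call for reaction(s) "
            f"{', '.join(missing_calls)}"
        )
    flags: set[str] = set()
    fillable_specific = False
    has_specific = False
    for rid in sorted(state.gap_reactions):
        call = by_reaction[rid]
        if call.category == "unclassified":
            flags.add("unresolved-gap")
        elif call.category == "specific":
            has_specific = True
            if kb is not None and _host_fills(
                rid, host_reactions, kb.pathway(state.pathway_id)
            ):
                fillable_specific = True
    if fillable_specific:
        return False, frozenset(flags)
    if has_specific:
        flags.add("assumed-alternative-enzyme")
    return True, frozenset(flags)


def _union_collaborative(
    pathway: Pathway,
    variants: Sequence[RouteVariant],
    symbiont_reactions: frozenset[str],
    host_reactions: frozenset[str],
    assumed_common: frozenset[str],
) -> tuple[RouteVariant, frozenset[str], frozenset[str]] | None:
    """First route variant completed jointly with genuine mutual dependence.

    A reaction is covered by a partner only if that partner possesses it
    and the variant's bypass-side annotation permits that partner to use
    it.  ``assumed_common`` reactions (symbiont common gaps) count as
    covered without crediting either partner.  Returns the variant plus the
    exclusive contributions of each partner, or None.
    """
    for variant in variants:
        sym_cov, host_cov = set(), set()
        complete = True
        for rid in variant.reactions:
            side = variant.bypass_sides.get(rid, "both")
            s = rid in symbiont_reactions and side in ("both", "symbiont")
            h = rid in host_reactions and side in ("both", "host")
            if s:
                sym_cov.add(rid)
            if h:
                host_cov.add(rid)
            if not (s or h or rid in assumed_common):
                complete = False
                break
        if not complete:
            continue
        sym_only = frozenset(sym_cov - host_cov - assumed_common)
        host_only = frozenset(host_cov - sym_cov - assumed_common)
        if sym_only and host_only:
            return variant, sym_only, host_only
    return None


def classify_relationship(
    product: str,
    pathway_id: str,
    symbiont_state,
    symbiont_gap_calls: Sequence[GapCall],
    host_state,
    kb: PathwayKB,
    *,
    symbiont_reactions: frozenset[str],
    host_reactions: frozenset[str],
    host_profile_id: str = "host",
) -> RelationshipCall:
    """Apply the five-category decision order for one product and pairing."""
    pathway = kb.pathway(pathway_id)
    if product not in pathway.product_names:
        raise MatrixError(
            f"product {product!r} is not a final product of pathway {pathway_id!r}"
        )
    relevant_calls = tuple(
        c for c in symbiont_gap_calls if c.pathway_id == pathway_id
    )
    sym_ok, sym_flags = effective_complete(
        symbiont_state,
        relevant_calls,
        "symbiont",
        kb=kb,
        host_reactions=host_reactions,
    )
    host_ok, _ = effective_complete(host_state, (), "host")

    def call(category, route=frozenset(), sym_c=frozenset(), host_c=frozenset(),
             flags=frozenset()):
        return RelationshipCall(
            product=product,
            pathway_id=pathway_id,
            symbiont_id=symbiont_state.genome_id,
            host_profile_id=host_profile_id,
            category=category,
            route_used=frozenset(route),
            symbiont_contributed=frozenset(sym_c),
            host_contributed=frozenset(host_c),
            gap_calls=relevant_calls,
            flags=frozenset(flags),
        )

    if sym_ok and host_ok:
        return call("overlapping", route=host_state.route_used, flags=sym_flags)
    if host_ok:
        return call("host-dependent", route=host_state.route_used)
    if sym_ok:
        return call("symbiont-dependent", route=symbiont_state.route_used,
                    flags=sym_flags)

    # Neither partner suffices alone: look for a jointly-completed route.
    assumed_common = frozenset(
        c.reaction_id
        for c in relevant_calls
        if c.category in ("common", "unclassified")
        and c.reaction_id not in symbiont_reactions
    )
    joint_flags = frozenset(
        {"unresolved-gap"}
        if any(c.category == "unclassified" for c in relevant_calls)
        else ()
    )
    variants = enumerate_route_variants(kb, pathway_id)
    found = _union_collaborative(
        pathway, variants, symbiont_reactions, host_reactions, assumed_common
    )
    if found is not None:
        variant, sym_only, host_only = found
        return call(
            "collaborative",
            route=variant.reactions,
            sym_c=sym_only,
            host_c=host_only,
            flags=joint_flags,
        )
    return call("doubly-absent", flags=joint_flags)


@dataclass(frozen=True)
class RelationshipTable:
    """All calls for a run, with a products x pairings letter-code view."""

    calls: tuple[RelationshipCall, ...]

    def letters(self) -> pd.DataFrame:
        recs = {}
        for c in self.calls:
            recs.setdefault(c.product, {})[c.symbiont_id] = c.letter
        df = pd.DataFrame.from_dict(recs, orient="index").sort_index()
        return df[sorted(df.columns)]

    def to_tsv(self, path: str | Path) -> None:
        pd.DataFrame(
            [
                {
                    "product": c.product,
                    "pathway_id": c.pathway_id,
                    "symbiont_id": c.symbiont_id,
                    "host_profile_id": c.host_profile_id,
                    "category": c.category,
                    "letter": c.letter,
                    "symbiont_contributed": ",".join(sorted(c.symbiont_contributed)),
                    "host_contributed": ",".join(sorted(c.host_contributed)),
                    "flags": ",".join(sorted(c.flags)),
                }
                for c in self.calls
            ]
        ).to_csv(path, sep="\t", index=False)

    def collaborative_groups(
        self, group_of: Mapping[str, str] | None = None
    ) -> set[tuple[str, str]]:
        """Distinct (pathway, strain-group) combinations called collaborative."""
        group_of = group_of or {}
        return {
            (c.pathway_id, group_of.get(c.symbiont_id, c.symbiont_id))
            for c in self.calls
            if c.category == "collaborative"
        }


def classify_all(
    matrix: OccurrenceMatrix,
    kb: PathwayKB,
    thresholds: GapThresholds,
    pairings: Sequence[Pairing],
    host_profiles: Mapping[str, HostProfile],
    *,
    reference_roles: Iterable[str] = ("reference",),
) -> RelationshipTable:
    """One RelationshipCall per (final product, pairing). Deterministic.

    When several pathways yield the same product each is classified and the
    call highest in the capability preference order (overlapping first,
    doubly-absent last) is reported for the product.
    """
    from .gap_classifier import classify_gaps  # local to avoid cycle at import

    host_presence: dict[str, frozenset[str]] = {}
    for pid, profile in host_profiles.items():
        host_presence[pid] = presence_set(_host_profile_annotation(profile), kb)

    all_gap_calls = classify_gaps(
        matrix, kb, thresholds, reference_roles=reference_roles
    )
    calls: list[RelationshipCall] = []
    pref = {cat: i for i, cat in enumerate(_CATEGORY_PREFERENCE)}
    for pairing in pairings:
        if pairing.symbiont_id not in matrix.presence.index:
            raise MatrixError(f"pairing references unknown genome {pairing.symbiont_id!r}")
        if pairing.host_profile_id not in host_profiles:
            raise MatrixError(
                f"pairing references unknown host profile {pairing.host_profile_id!r}"
            )
        sym_reactions = matrix.present_reactions(pairing.symbiont_id)
        h_reactions = host_presence[pairing.host_profile_id]
        sym_calls = [c for c in all_gap_calls if c.genome_id == pairing.symbiont_id]
        for product in sorted(p.name for p in kb.all_products):
            candidates = []
            for pw in sorted(
                kb.pathways_for_product(product), key=lambda p: p.pathway_id
            ):
                sym_state = evaluate_pathway(
                    sym_reactions, kb, pw.pathway_id,
                    genome_id=pairing.symbiont_id,
                    max_gaps=thresholds.max_gaps, side="symbiont",
                )
                host_state = evaluate_pathway(
                    h_reactions, kb, pw.pathway_id,
                    genome_id=pairing.host_profile_id,
                    max_gaps=thresholds.max_gaps, side="host",
                )
                candidates.append(
                    classify_relationship(
                        product, pw.pathway_id, sym_state, sym_calls, host_state,
                        kb,
                        symbiont_reactions=sym_reactions,
                        host_reactions=h_reactions,
                        host_profile_id=pairing.host_profile_id,
                    )
                )
            calls.append(min(candidates, key=lambda c: pref[c.category]))
    return RelationshipTable(calls=tuple(calls))
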