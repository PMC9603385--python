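"""Genomes x reactions presence/absence matrix and per-pathway completeness.

A reaction is *present* in a genome when any of its KB-listed EC numbers is
in the genome's EC set (exact string match — a genome's ``3.1.3.-`` only
satisfies a reaction that explicitly lists the 3-digit form), or failing
that when any of its COG ids is in the genome's COG set.  Provenance (ec /
cog / none) is kept per cell so reports can distinguish the two evidence
classes.

Pathway completeness is evaluated against every route variant the genome's
side may use (host-only bypasses are invisible to symbiont and reference
genomes).  The variant minimising missing reactions is selected; a pathway
is ``complete`` with zero gaps, ``gapped`` with 1..max_gaps missing (default
2) provided at least one route reaction is present, and ``absent``
otherwise.  A route with every reaction missing is always ``absent``: gaps
are missing enzymes in pathways *otherwise* complete, and a wholly lost
two-step pathway is a loss, not a pair of gaps.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .function_annotation import GenomeAnnotation
from .pathway_kb import PathwayKB, Reaction, RouteVariant, enumerate_route_variants

__all__ = [
    "MatrixError",
    "OccurrenceMatrix",
    "PathwayState",
    "reaction_present",
    "build_matrix",
    "presence_set",
    "evaluate_pathway",
    "pathway_state",
    "reference_absence_frequency",
    "DEFAULT_MAX_GAPS",
]

DEFAULT_MAX_GAPS = 2

#: Ranking of states when choosing among route variants (higher is better).
_STATE_RANK = {"complete": 2, "gapped": 1, "absent": 0}

#: Which route-variant side a genome role evaluates under.
ROLE_SIDE = {
    "focal-symbiont": "symbiont",
    "reference": "symbiont",
    "outgroup": "symbiont",
    "host": "host",
}


class MatrixError(ValueError):
    pass


def reaction_present(
    annotation: GenomeAnnotation | "HostLike", reaction: Reaction
) -> str:
    """Presence with provenance: ``"ec"``, ``"cog"`` or ``"none"``.

    EC evidence takes precedence over COG evidence.
    """
    if reaction.ec_numbers & set(annotation.ec_set):
        return "ec"
    if reaction.cog_ids & set(getattr(annotation, "cog_set", frozenset())):
        return "cog"
    return "none"


@dataclass(frozen=True)
class OccurrenceMatrix:
    """Presence/absence with per-cell provenance and per-genome roles."""

    presence: pd.DataFrame  # bool, genomes x reactions
    provenance: pd.DataFrame  # str in {"ec","cog","none"}
    roles: Mapping[str, str]
    subset_labels: Mapping[str, frozenset[str]]

    @property
    def genome_ids(self) -> list[str]:
        return list(self.presence.index)

    @property
    def reaction_ids(self) -> list[str]:
        return list(self.presence.columns)

    def genomes_with_role(self, roles: Iterable[str]) -> list[str]:
        roles = set(roles)
        return [g for g in self.presence.index if self.roles[g] in roles]

    def is_present(self, genome_id: str, reaction_id: str) -> bool:
        return bool(self.presence.at[genome_id, reaction_id])

    def present_reactions(self, genome_id: str) -> frozenset[str]:
        row = self.presence.loc[genome_id]
        return frozenset(row.index[row])

    def to_tsv(self, path: str | Path, provenance_path: str | Path | None = None) -> None:
        out = self.presence.astype(int)
        out.insert(0, "role", [self.roles[g] for g in out.index])
        out.to_csv(path, sep="\t", index_label="genome_id")
        if provenance_path is not None:
            self.provenance.to_csv(provenance_path, sep="\t", index_label="genome_id")


@dataclass(frozen=True)
class PathwayState:
    genome_id: str
    pathway_id: str
    state: str  # complete | gapped | absent
    gap_reactions: frozenset[str]
    route_used: frozenset[str]

    def __post_init__(self) -> None:
        n = len(self.gap_reactions)
        if self.state == "complete" and n:
            raise MatrixError("complete state cannot carry gap reactions")
        if self.state == "gapped" and n == 0:
            raise MatrixError("gapped state needs at least one gap reaction")


def build_matrix(
    annotations: Sequence[GenomeAnnotation], kb: PathwayKB
) -> OccurrenceMatrix:
    """Project annotations onto every KB reaction. Deterministic."""
    ids = [a.genome_id for a in annotations]
    dupes = {g for g in ids if ids.count(g) > 1}
    if dupes:
        raise MatrixError(f"duplicate genome id(s): {sorted(dupes)}")
    reaction_ids = sorted(kb.reactions)
    prov_rows = {}
    for ann in annotations:
        prov_rows[ann.genome_id] = [
            reaction_present(ann, kb.reactions[rid]) for rid in reaction_ids
        ]
    provenance = pd.DataFrame.from_dict(
        prov_rows, orient="index", columns=reaction_ids
    )
    presence = provenance != "none"
    return OccurrenceMatrix(
        presence=presence,
        provenance=provenance,
        roles={a.genome_id: a.role for a in annotations},
        subset_labels={a.genome_id: a.subset_labels for a in annotations},
    )


def presence_set(annotation: GenomeAnnotation, kb: PathwayKB) -> frozenset[str]:
    """Reactions present for one annotation without building a full matrix."""
    return frozenset(
        rid
        for rid, rxn in kb.reactions.items()
        if reaction_present(annotation, rxn) != "none"
    )


def evaluate_pathway(
    present: frozenset[str],
    kb: PathwayKB,
    pathway_id: str,
    *,
    genome_id: str = "",
    max_gaps: int = DEFAULT_MAX_GAPS,
    side: str = "symbiont",
) -> PathwayState:
    """Classify one pathway given a genome's present-reaction set.

    Considers every route variant allowed for ``side``; picks the variant
    with the best state, then the fewest gaps, then the lexicographically
    smallest sorted gap-reaction tuple (a documented determinism tie-break).
    """
    variants = [
        v for v in enumerate_route_variants(kb, pathway_id) if v.allowed_for(side)
    ]
    if not variants:
        raise MatrixError(
            f"pathway {pathway_id!r}: no route variant usable by side {side!r}"
        )
    best: tuple | None = None
    for variant in variants:
        missing = tuple(sorted(variant.reactions - present))
        if not missing:
            state = "complete"
        elif len(missing) <= max_gaps and len(missing) < len(variant.reactions):
            state = "gapped"
        else:
            state = "absent"
        key = (-_STATE_RANK[state], len(missing), missing, tuple(sorted(variant.reactions)))
        if best is None or key < best[0]:
            best = (key, state, missing, variant)
    _, state, missing, variant = best
    return PathwayState(
        genome_id=genome_id,
        pathway_id=pathway_id,
        state=state,
        gap_reactions=frozenset(missing) if state == "gapped" else frozenset(),
        route_used=variant.reactions,
    )


def pathway_state(
    matrix: OccurrenceMatrix,
    genome_id: str,
    pathway_id: str,
    kb: PathwayKB,
    max_gaps: int = DEFAULT_MAX_GAPS,
) -> PathwayState:
    """Pathway completeness for one matrix row (side chosen from its role)."""
    if genome_id not in matrix.presence.index:
        raise MatrixError(f"unknown genome id {genome_id!r}")
    kb.pathway(pathway_id)  # raises on unknown id
    side = ROLE_SIDE[matrix.roles[genome_id]]
    return evaluate_pathway(
        matrix.present_reactions(genome_id),
        kb,
        pathway_id,
        genome_id=genome_id,
        max_gaps=max_gaps,
        side=side,
    )


def reference_absence_frequency(
    matrix: OccurrenceMatrix,
    reaction_id: str,
    reference_roles: Iterable[str] = ("reference",),
) -> float:
    """Fraction of reference-panel genomes lacking a reaction.

    Outgroup genomes are excluded unless their role is explicitly listed in
    ``reference_roles``.
    """
    panel = matrix.genomes_with_role(reference_roles)
    if not panel:
        raise MatrixError(
            f"empty reference panel for roles {sorted(set(reference_roles))}"
        )
    if reaction_id not in matrix.presence.columns:
        raise MatrixError(f"unknown reaction id {reaction_id!r}")
    col = matrix.presence.loc[panel, reaction_id]
    return float((~col).sum() / len(panel))
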