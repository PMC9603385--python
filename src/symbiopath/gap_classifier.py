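"""Gap taxonomy: common vs specific gaps by reference-panel frequency.

Each missing reaction of a gapped pathway in a focal (symbiont) genome is
classified by how often the free-living reference panel also lacks it:

* **common** — absent from strictly more than ``common_min_ref_absence``
  (default 70%) of references: interpreted as a step carried out by an
  unknown alternative enzyme across the whole clade, so not expected to be
  complemented by the host;
* **specific** — absent from strictly less than ``specific_max_ref_absence``
  (default 10%) of references: a genuine, symbiont-specific loss;
* **unclassified** — everything in between (the serine/SerB situation).
  Unclassified gaps propagate downstream as *unresolved* and force a
  flagged, not silent, relationship decision.

Both thresholds are strict inequalities ("over 70%", "less than 10%");
boundary frequencies are unclassified.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .occurrence_matrix import (
    DEFAULT_MAX_GAPS,
    MatrixError,
    OccurrenceMatrix,
    pathway_state,
    reference_absence_frequency,
)
from .pathway_kb import PathwayKB

__all__ = [
    "GapThresholds",
    "GapCall",
    "categorize_frequency",
    "classify_gaps",
    "subset_specific_gaps",
    "write_gap_table",
]


@dataclass(frozen=True)
class GapThresholds:
    common_min_ref_absence: float = 0.70
    specific_max_ref_absence: float = 0.10
    max_gaps: int = DEFAULT_MAX_GAPS

    def __post_init__(self) -> None:
        if not (0 <= self.specific_max_ref_absence < self.common_min_ref_absence <= 1):
            raise ValueError(
                "thresholds must satisfy 0 <= specific < common <= 1, got "
                f"specific={self.specific_max_ref_absence}, "
                f"common={self.common_min_ref_absence}"
            )


@dataclass(frozen=True)
class GapCall:
    genome_id: str
    pathway_id: str
    reaction_id: str
    category: str  # common | specific | unclassified
    ref_absence: float
    shared_by_all_focal: bool
    subset_labels: frozenset[str] = frozenset()


def categorize_frequency(ref_absence: float, thresholds: GapThresholds) -> str:
    if ref_absence > thresholds.common_min_ref_absence:
        return "common"
    if ref_absence < thresholds.specific_max_ref_absence:
        return "specific"
    return "unclassified"


def classify_gaps(
    matrix: OccurrenceMatrix,
    kb: PathwayKB,
    thresholds: GapThresholds = GapThresholds(),
    focal_role: str = "focal-symbiont",
    reference_roles: Iterable[str] = ("reference",),
) -> list[GapCall]:
    """One GapCall per (focal genome, gapped pathway, missing reaction).

    Pathways in state ``absent`` produce no calls (a lost pathway has no
    gaps, only losses); ``shared_by_all_focal`` marks reactions missing
    from every focal genome regardless of pathway state.
    """
    focal = matrix.genomes_with_role([focal_role])
    if not focal:
        raise MatrixError(f"no genomes with focal role {focal_role!r}")
    # raises MatrixError on an empty reference panel:
    panel_probe = matrix.genomes_with_role(reference_roles)
    if not panel_probe:
        raise MatrixError(f"no genomes with reference role(s) {tuple(reference_roles)}")

    calls: list[GapCall] = []
    for genome_id in focal:
        for pathway_id in sorted(kb.pathways):
            state = pathway_state(
                matrix, genome_id, pathway_id, kb, max_gaps=thresholds.max_gaps
            )
            if state.state != "gapped":
                continue
            for reaction_id in sorted(state.gap_reactions):
                freq = reference_absence_frequency(
                    matrix, reaction_id, reference_roles
                )
                calls.append(
                    GapCall(
                        genome_id=genome_id,
                        pathway_id=pathway_id,
                        reaction_id=reaction_id,
                        category=categorize_frequency(freq, thresholds),
                        ref_absence=freq,
                        shared_by_all_focal=all(
                            not matrix.is_present(g, reaction_id) for g in focal
                        ),
                        subset_labels=frozenset(matrix.subset_labels.get(genome_id, ())),
                    )
                )
    return calls


def subset_specific_gaps(
    matrix: OccurrenceMatrix,
    kb: PathwayKB,
    thresholds: GapThresholds = GapThresholds(),
    subset_labels: Iterable[str] = (),
    *,
    focal_role: str = "focal-symbiont",
    reference_roles: Iterable[str] = ("reference",),
) -> list[GapCall]:
    """Specific gaps at the level of a focal-strain subset.

    A reaction is a subset-specific gap when (i) it is missing from every
    member of the subset, (ii) its reference absence is below the specific
    threshold, and (iii) some pathway containing it retains at least one
    route reaction in every subset member.  Condition (iii) keeps
    wholly-lost pathways (losses, not gaps) out of the report while still
    catching subset losses inside pathways degraded beyond the per-genome
    gap budget (the PabA/TrpE situation).
    """
    labels = frozenset(subset_labels)
    focal = matrix.genomes_with_role([focal_role])
    if not focal:
        raise MatrixError(f"no genomes with focal role {focal_role!r}")
    if labels:
        members = [
            g for g in focal if labels <= matrix.subset_labels.get(g, frozenset())
        ]
    else:
        members = list(focal)
    if not members:
        raise MatrixError(f"no focal genome carries subset label(s) {sorted(labels)}")

    # pathways retaining >=1 route reaction in every subset member
    partially_retained: set[str] = set()
    for pathway_id, pw in kb.pathways.items():
        route_union = {rid for route in pw.routes for rid in route}
        if all(
            any(matrix.is_present(g, rid) for rid in route_union) for g in members
        ):
            partially_retained.add(pathway_id)

    reaction_pathways: dict[str, set[str]] = {}
    for pw in kb.pathways.values():
        for route in pw.routes:
            for rid in route:
                reaction_pathways.setdefault(rid, set()).add(pw.pathway_id)

    calls = []
    for reaction_id in sorted(matrix.reaction_ids):
        pathways = reaction_pathways.get(reaction_id, set())
        if not pathways & partially_retained:
            continue
        if any(matrix.is_present(g, reaction_id) for g in members):
            continue
        freq = reference_absence_frequency(matrix, reaction_id, reference_roles)
        if freq < thresholds.specific_max_ref_absence:
            calls.append(
                GapCall(
                    genome_id="+".join(sorted(members)),
                    pathway_id=min(pathways & partially_retained),
                    reaction_id=reaction_id,
                    category="specific",
                    ref_absence=freq,
                    shared_by_all_focal=all(
                        not matrix.is_present(g, reaction_id) for g in focal
                    ),
                    subset_labels=labels,
                )
            )
    return calls


def write_gap_table(calls: Sequence[GapCall], path: str | Path) -> None:
    pd.DataFrame(
        [
            {
                "genome_id": c.genome_id,
                "pathway_id": c.pathway_id,
                "reaction_id": c.reaction_id,
                "category": c.category,
                "ref_absence": round(c.ref_absence, 6),
                "shared_by_all_focal": int(c.shared_by_all_focal),
                "subset_labels": ",".join(sorted(c.subset_labels)),
            }
            for c in calls
        ],
        columns=[
            "genome_id",
            "pathway_id",
            "reaction_id",
            "category",
            "ref_absence",
            "shared_by_all_focal",
            "subset_labels",
        ],
    ).to_csv(path, sep="\t", index=False)
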