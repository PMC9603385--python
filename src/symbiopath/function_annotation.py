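"""Profile-hit filtering into per-genome EC/COG function assignments.

This module consumes *precomputed* domain-hit tables (gene id, domain id,
E-value) from profile scanners together with a domain-to-EC mapping table,
and applies the assignment rule: a gene receives an EC number iff it has at
least one hit with E-value strictly below the threshold (default 1e-10)
whose mapped EC carries 4 or 3 significant digits; coarser ECs (e.g.
``3.1.-.-``) are discarded to avoid ambiguous assignments.  Genes left
without any EC are then offered a COG fallback: the best remaining hit
assigns its COG if it passes the (separately configurable) threshold.
EC-assigned genes never gain a COG.

Running the scanners themselves is out of scope; direct EC/COG presence
lists are accepted everywhere downstream as an alternative input.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .pathway_kb import is_valid_ec

__all__ = [
    "AnnotationError",
    "DomainHit",
    "GenomeAnnotation",
    "ROLES",
    "assign_ec",
    "assign_cog",
    "build_genome_annotation",
    "read_hit_table",
    "read_mapping_table",
    "read_annotation_table",
    "write_annotation_table",
]

ROLES = ("focal-symbiont", "reference", "host", "outgroup")

DEFAULT_EVALUE_THRESHOLD = 1e-10


class AnnotationError(ValueError):
    pass


@dataclass(frozen=True)
class DomainHit:
    gene_id: str
    domain_id: str
    e_value: float

    def __post_init__(self) -> None:
        if not self.e_value > 0:
            raise AnnotationError(
                f"hit {self.gene_id}/{self.domain_id}: E-value must be positive, "
                f"got {self.e_value!r}"
            )


@dataclass(frozen=True)
class GenomeAnnotation:
    """One genome's assigned function identifiers plus role metadata."""

    genome_id: str
    role: str
    ec_set: frozenset[str] = frozenset()
    cog_set: frozenset[str] = frozenset()
    subset_labels: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if self.role not in ROLES:
            raise AnnotationError(
                f"genome {self.genome_id!r}: unknown role {self.role!r} "
                f"(expected one of {ROLES})"
            )
        for ec in self.ec_set:
            if not is_valid_ec(ec):
                raise AnnotationError(
                    f"genome {self.genome_id!r}: malformed EC number {ec!r}"
                )

    @property
    def identifiers(self) -> frozenset[str]:
        return self.ec_set | self.cog_set


def assign_ec(
    hits: Iterable[DomainHit],
    ec_map: Mapping[str, str | Sequence[str]],
    threshold: float = DEFAULT_EVALUE_THRESHOLD,
) -> dict[str, frozenset[str]]:
    """Per-gene EC assignments from domain hits.

    A gene is assigned every EC reached through a hit with
    ``e_value < threshold`` (strict) that maps to a 3- or 4-digit EC; a
    mapped EC with fewer significant digits is silently discarded.  Genes
    with no qualifying hit are omitted from the result.
    """
    out: dict[str, set[str]] = {}
    for hit in hits:
        if not hit.e_value > 0:  # defensive for untyped inputs
            raise AnnotationError(f"non-positive E-value for gene {hit.gene_id!r}")
        if hit.e_value >= threshold:
            continue
        mapped = ec_map.get(hit.domain_id)
        if mapped is None:
            continue
        ecs = [mapped] if isinstance(mapped, str) else list(mapped)
        for ec in ecs:
            if is_valid_ec(ec):
                out.setdefault(hit.gene_id, set()).add(ec)
    return {gene: frozenset(ecs) for gene, ecs in sorted(out.items())}


def assign_cog(
    hits: Iterable[DomainHit],
    cog_map: Mapping[str, str] | None = None,
    *,
    ec_assigned: Iterable[str] = (),
    threshold: float = DEFAULT_EVALUE_THRESHOLD,
) -> dict[str, str]:
    """COG fallback for genes that received no EC assignment.

    ``hits`` must only contain genes without an EC assignment; offering an
    EC-assigned gene is a precedence error.  Each gene is assigned the COG
    of its best (lowest-E-value) hit iff that hit passes the threshold;
    ties break to the lexicographically smallest COG id.
    """
    cog_map = cog_map or {}
    ec_assigned = set(ec_assigned)
    best: dict[str, DomainHit] = {}
    for hit in hits:
        if hit.gene_id in ec_assigned:
            raise AnnotationError(
                f"gene {hit.gene_id!r} already has an EC assignment; "
                "COG fallback only applies to EC-unassigned genes"
            )
        cur = best.get(hit.gene_id)
        if (
            cur is None
            or hit.e_value < cur.e_value
            or (
                hit.e_value == cur.e_value
                and cog_map.get(hit.domain_id, hit.domain_id)
                < cog_map.get(cur.domain_id, cur.domain_id)
            )
        ):
            best[hit.gene_id] = hit
    return {
        gene: cog_map.get(hit.domain_id, hit.domain_id)
        for gene, hit in sorted(best.items())
        if hit.e_value < threshold
    }


def build_genome_annotation(
    ec_assignments: Mapping[str, Iterable[str]],
    cog_assignments: Mapping[str, str],
    genome_id: str,
    role: str,
    subset_labels: Iterable[str] = (),
) -> GenomeAnnotation:
    """Collapse per-gene assignments into one genome-level identifier set."""
    ec_set = frozenset(
        ec for ecs in ec_assignments.values() for ec in ecs
    )
    cog_set = frozenset(cog_assignments.values())
    return GenomeAnnotation(
        genome_id=genome_id,
        role=role,
        ec_set=ec_set,
        cog_set=cog_set,
        subset_labels=frozenset(subset_labels),
    )


# ---------------------------------------------------------------------------
# TSV I/O (documented dialects; see docs/methods.md)


def read_hit_table(path: str | Path) -> list[DomainHit]:
    """Read a TSV with header ``gene_id, domain_id, e_value``."""
    df = pd.read_csv(path, sep="\t", dtype={"gene_id": str, "domain_id": str})
    required = {"gene_id", "domain_id", "e_value"}
    if not required <= set(df.columns):
        raise AnnotationError(
            f"{path}: hit table needs columns {sorted(required)}, "
            f"found {list(df.columns)}"
        )
    return [
        DomainHit(r.gene_id, r.domain_id, float(r.e_value))
        for r in df.itertuples(index=False)
    ]


def read_mapping_table(path: str | Path) -> dict[str, list[str]]:
    """Two-column TSV mapping domain ids to identifiers (EC2GO-style)."""
    df = pd.read_csv(path, sep="\t", header=None, names=["domain_id", "target"],
                     dtype=str, comment="#")
    out: dict[str, list[str]] = {}
    for r in df.itertuples(index=False):
        out.setdefault(r.domain_id, []).append(r.target)
    return out


def write_annotation_table(
    annotations: Iterable[GenomeAnnotation], path: str | Path
) -> None:
    """Write annotations as TSV: genome_id, role, subset_labels, identifier_type, identifier."""
    rows = []
    for ann in annotations:
        labels = ",".join(sorted(ann.subset_labels))
        for ec in sorted(ann.ec_set):
            rows.append((ann.genome_id, ann.role, labels, "EC", ec))
        for cog in sorted(ann.cog_set):
            rows.append((ann.genome_id, ann.role, labels, "COG", cog))
        if not ann.ec_set and not ann.cog_set:
            rows.append((ann.genome_id, ann.role, labels, "NONE", ""))
    pd.DataFrame(
        rows, columns=["genome_id", "role", "subset_labels", "identifier_type", "identifier"]
    ).to_csv(path, sep="\t", index=False)


def read_annotation_table(path: str | Path) -> list[GenomeAnnotation]:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False, comment="#")
    out = []
    for (genome_id, role, labels), grp in df.groupby(
        ["genome_id", "role", "subset_labels"], sort=True
    ):
        ecs = frozenset(grp.loc[grp.identifier_type == "EC", "identifier"])
        cogs = frozenset(grp.loc[grp.identifier_type == "COG", "identifier"])
        out.append(
            GenomeAnnotation(
                genome_id=genome_id,
                role=role,
                ec_set=ecs,
                cog_set=cogs,
                subset_labels=frozenset(l for l in labels.split(",") if l),
            )
        )
    return out
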