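"""Pipeline orchestration and report rendering.

``run_pipeline`` executes the stages annotation-table loading -> occurrence
matrix -> gap classification -> relationship calling -> reports, writing
every table as TSV (first line a ``# config_hash=...`` comment) plus a JSON
run manifest with per-stage counts.  Reruns with an identical configuration
are bit-identical for all TSV outputs; figures are derived artifacts and
are never treated as inputs or compared.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
from matplotlib.patches import Patch
import pandas as pd
import yaml

from .function_annotation import GenomeAnnotation, read_annotation_table
from .gap_classifier import GapCall, GapThresholds, classify_gaps, write_gap_table
from .occurrence_matrix import OccurrenceMatrix, build_matrix
from .pathway_kb import PathwayKB, load_kb
from .relationship_classifier import (
    HostProfile,
    Pairing,
    classify_all,
    host_consensus,
)

__all__ = ["PipelineError", "RunConfig", "run_pipeline", "render_matrix_report"]


class PipelineError(RuntimeError):
    """Stage failure; the message names the stage and offending record."""


@dataclass(frozen=True)
class RunConfig:
    kb_path: str
    annotations_path: str
    host_annotations_path: str
    manifest_path: str
    output_dir: str
    common_min_ref_absence: float = 0.70
    specific_max_ref_absence: float = 0.10
    max_gaps: int = 2
    consensus_rule: str = "majority"
    seed: int = 0
    verbosity: int = 1

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            doc = yaml.safe_load(fh) or {}
        return cls(**doc)

    @property
    def thresholds(self) -> GapThresholds:
        return GapThresholds(
            common_min_ref_absence=self.common_min_ref_absence,
            specific_max_ref_absence=self.specific_max_ref_absence,
            max_gaps=self.max_gaps,
        )

    def config_hash(self) -> str:
        """Hash of the analytic configuration (inputs and parameters).

        Destination and verbosity are excluded: rerunning the same analysis
        into a different directory must reproduce identical tables.
        """
        payload = asdict(self)
        payload.pop("output_dir")
        payload.pop("verbosity")
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True).encode()
        ).hexdigest()[:16]


def _load_manifest(
    path: str | Path, host_annotations: Sequence[GenomeAnnotation], rule: str
) -> tuple[dict[str, HostProfile], list[Pairing]]:
    with open(path) as fh:
        doc = yaml.safe_load(fh) or {}
    by_id = {a.genome_id: a for a in host_annotations}
    profiles: dict[str, HostProfile] = {}
    for pid, spec in (doc.get("host_profiles") or {}).items():
        members = spec.get("members", [])
        missing = [m for m in members if m not in by_id]
        if missing:
            raise PipelineError(
                f"stage=manifest: host profile {pid!r} references unknown host "
                f"genome(s) {missing}"
            )
        profiles[pid] = host_consensus(
            [by_id[m] for m in members], rule=spec.get("rule", rule), host_id=pid
        )
    pairings = [
        Pairing(
            symbiont_id=p["symbiont"],
            host_profile_id=p["host"],
            group_label=p.get("group", ""),
        )
        for p in doc.get("pairings") or []
    ]
    if not pairings:
        raise PipelineError("stage=manifest: no pairings defined")
    return profiles, pairings


def _write_with_hash(df: pd.DataFrame, path: Path, config_hash: str, **to_csv) -> None:
    with open(path, "w") as fh:
        fh.write(f"# config_hash={config_hash}\n")
        df.to_csv(fh, sep="\t", **to_csv)


def run_pipeline(config: RunConfig) -> dict[str, Path]:
    """Execute all stages; returns a mapping of artifact names to paths."""
    for name in ("kb_path", "annotations_path", "host_annotations_path", "manifest_path"):
        p = Path(getattr(config, name))
        if not p.exists():
            raise PipelineError(f"stage=config: {name} does not exist: {p}")
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    chash = config.config_hash()
    counts: dict[str, object] = {}

    try:
        kb = load_kb(config.kb_path)
    except Exception as exc:
        raise PipelineError(f"stage=kb: {exc}") from exc
    try:
        annotations = read_annotation_table(config.annotations_path)
        host_annotations = read_annotation_table(config.host_annotations_path)
    except Exception as exc:
        raise PipelineError(f"stage=annotation: {exc}") from exc
    profiles, pairings = _load_manifest(
        config.manifest_path, host_annotations, config.consensus_rule
    )
    counts["genomes"] = len(annotations)
    counts["host_genomes"] = len(host_annotations)
    counts["reactions"] = len(kb.reactions)
    counts["pathways"] = len(kb.pathways)

    try:
        matrix = build_matrix(annotations, kb)
    except Exception as exc:
        raise PipelineError(f"stage=matrix: {exc}") from exc
    matrix_df = matrix.presence.astype(int)
    matrix_df.insert(0, "role", [matrix.roles[g] for g in matrix_df.index])
    paths = {"matrix": outdir / "matrix.tsv", "provenance": outdir / "provenance.tsv"}
    _write_with_hash(matrix_df, paths["matrix"], chash, index_label="genome_id")
    _write_with_hash(matrix.provenance, paths["provenance"], chash,
                     index_label="genome_id")

    try:
        gap_calls = classify_gaps(matrix, kb, config.thresholds)
    except Exception as exc:
        raise PipelineError(f"stage=gaps: {exc}") from exc
    counts["gaps_by_category"] = {
        cat: sum(1 for c in gap_calls if c.category == cat)
        for cat in ("common", "specific", "unclassified")
    }
    paths["gaps"] = outdir / "gap_calls.tsv"
    gap_df = pd.DataFrame(
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
            for c in gap_calls
        ]
    )
    _write_with_hash(gap_df, paths["gaps"], chash, index=False)

    try:
        table = classify_all(matrix, kb, config.thresholds, pairings, profiles)
    except Exception as exc:
        raise PipelineError(f"stage=relationships: {exc}") from exc
    counts["relationships_by_category"] = {
        cat: sum(1 for c in table.calls if c.category == cat)
        for cat in ("overlapping", "host-dependent", "symbiont-dependent",
                    "collaborative", "doubly-absent")
    }
    paths["relationships"] = outdir / "relationships.tsv"
    rel_df = pd.DataFrame(
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
            for c in table.calls
        ]
    )
    _write_with_hash(rel_df, paths["relationships"], chash, index=False)
    paths["letters"] = outdir / "relationship_letters.tsv"
    _write_with_hash(table.letters(), paths["letters"], chash, index_label="product")

    try:
        fig = render_matrix_report(matrix, gap_calls, kb)
        paths["figure_svg"] = outdir / "matrix_report.svg"
        paths["figure_png"] = outdir / "matrix_report.png"
        fig.savefig(paths["figure_svg"], metadata={"Date": None})
        fig.savefig(paths["figure_png"], dpi=150)
        plt.close(fig)
    except Exception as exc:
        raise PipelineError(f"stage=report: {exc}") from exc

    paths["log"] = outdir / "run_manifest.json"
    with open(paths["log"], "w") as fh:
        json.dump(
            {"config_hash": chash, "config": asdict(config), "counts": counts},
            fh, indent=2, sort_keys=True,
        )
        fh.write("\n")
    return paths


_CELL_COLORS = {
    "ec": "#2166ac",        # EC-assigned evidence
    "cog": "#92c5de",       # COG-assigned evidence
    "none": "#ffffff",
    "common": "#ffd92f",    # gap shared with most references
    "specific": "#d62728",  # gap specific to the focal clade
    "unclassified": "#999999",
}


def render_matrix_report(
    matrix: OccurrenceMatrix,
    gap_calls: Sequence[GapCall],
    kb: PathwayKB,
) -> "plt.Figure":
    """Presence/absence heatmap with gaps colored by category.

    One cell per genome x reaction, columns grouped by pathway; presence is
    colored by evidence class (EC vs COG) and absences carrying a gap call
    are colored by gap category for the calling genome's row.
    """
    order: list[str] = []
    boundaries: list[tuple[str, int]] = []
    for pathway_id in sorted(kb.pathways):
        boundaries.append((pathway_id, len(order)))
        for route in kb.pathways[pathway_id].routes:
            for rid in route:
                if rid not in order:
                    order.append(rid)
    missing = [r for r in order if r not in matrix.presence.columns]
    if missing:
        raise PipelineError(f"stage=report: matrix lacks reaction(s) {missing}")
    genomes = matrix.genome_ids
    gap_lookup = {(c.genome_id, c.reaction_id): c.category for c in gap_calls}

    fig_w = max(6.0, 0.22 * len(order))
    fig_h = max(2.0, 0.22 * len(genomes) + 1.5)
    fig, ax = plt.subplots(figsize=(fig_w, fig_h))
    for yi, genome in enumerate(genomes):
        for xi, rid in enumerate(order):
            prov = matrix.provenance.at[genome, rid]
            color = _CELL_COLORS[prov]
            if prov == "none":
                cat = gap_lookup.get((genome, rid))
                if cat is not None:
                    color = _CELL_COLORS[cat]
            ax.add_patch(
                plt.Rectangle((xi, yi), 1, 1, facecolor=color,
                              edgecolor="#cccccc", linewidth=0.3)
            )
    for pathway_id, x in boundaries[1:]:
        ax.axvline(x, color="black", linewidth=0.8)
    ax.set_xlim(0, len(order))
    ax.set_ylim(len(genomes), 0)
    ax.set_xticks([x + 0.5 for x in range(len(order))])
    ax.set_xticklabels(order, rotation=90, fontsize=5)
    ax.set_yticks([y + 0.5 for y in range(len(genomes))])
    ax.set_yticklabels(genomes, fontsize=5)
    ax.set_title("Reaction presence/absence by genome")
    legend = [
        Patch(facecolor=_CELL_COLORS["ec"], label="present (EC evidence)"),
        Patch(facecolor=_CELL_COLORS["cog"], label="present (COG evidence)"),
        Patch(facecolor=_CELL_COLORS["common"], label="common gap"),
        Patch(facecolor=_CELL_COLORS["specific"], label="specific gap"),
        Patch(facecolor=_CELL_COLORS["unclassified"], label="unclassified gap"),
        Patch(facecolor="white", edgecolor="#cccccc", label="absent"),
    ]
    ax.legend(handles=legend, loc="upper left", bbox_to_anchor=(1.01, 1.0),
              fontsize=6, frameon=False)
    fig.tight_layout()
    return fig
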