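"""Synthetic gene-content data and the packaged Blattodea fixture.

Two generators live here:

* :func:`simulate_gene_content` — gene loss on a rooted phylogeny.  The
  root carries the full KB enzyme complement; along each branch every gene
  is lost independently with a branch-class-specific Bernoulli probability
  (classes: symbiont-stem, symbiont-crown, reference, host) and losses are
  inherited.  This emulates the regime the downstream analysis assumes —
  complete pathways ancestrally, massive loss on the symbiont stem, rare
  sporadic loss among free-living references — using only marginal
  presence/absence, which is all the classifiers consume.

* :func:`blattodea_fixture` — a deterministic cockroach/termite-symbiont
  data set encoding the presence/absence structure of the Blattodea -
  *Blattabacterium* system: 7 focal symbiont strains (5 generic plus the
  further-reduced CPUbr and MADAR), a 42-member free-living reference
  panel, a Bacteroidales-like outgroup, and 3 host gene sets whose majority
  consensus stands for the Blattodea host.  Which reference strains carry
  which rare absences is an arbitrary documented choice; every frequency
  class (>70% common, <10% specific, mid-frequency unclassified) is
  preserved exactly.

Scenario implantation (:func:`implant_scenario`) overwrites the cells a
ground-truth configuration needs *after* stochastic loss, so truth labels
are realizable by construction; all other cells are untouched.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import dendropy
import numpy as np

from .function_annotation import GenomeAnnotation
from .gap_classifier import GapThresholds
from .pathway_kb import PathwayKB, load_kb
from .relationship_classifier import HostProfile, Pairing, host_consensus

__all__ = [
    "LossModel",
    "ScenarioSpec",
    "ScenarioTruth",
    "SimulationResult",
    "simulate_gene_content",
    "implant_scenario",
    "default_symbiosis_tree",
    "blattodea_fixture",
    "expected_relationship_letters",
    "FixtureBundle",
    "packaged_kb_path",
]

BRANCH_CLASSES = ("symbiont-stem", "symbiont-crown", "reference", "host")


@dataclass(frozen=True)
class LossModel:
    """Per-branch-class gene-loss probabilities (per gene per branch)."""

    loss_probability: Mapping[str, float] = field(
        default_factory=lambda: {
            "symbiont-stem": 0.30,
            "symbiont-crown": 0.05,
            "reference": 0.02,
            "host": 0.05,
        }
    )
    retained: frozenset[str] = frozenset()  # reaction ids never lost
    seed: int = 0

    def __post_init__(self) -> None:
        for cls in BRANCH_CLASSES:
            p = self.loss_probability.get(cls)
            if p is None or not (0.0 <= p <= 1.0):
                raise ValueError(
                    f"loss probability for class {cls!r} must be in [0, 1], got {p!r}"
                )


@dataclass(frozen=True)
class ScenarioSpec:
    """One intended ground-truth configuration to implant.

    ``kind`` selects an archetype:

    * ``overlapping`` — both partners complete.
    * ``symbiont-dependent-complete`` — symbiont complete, host lost.
    * ``symbiont-dependent-common-gap`` — symbiont gapped at ``gap_reactions``,
      each absent from ~80% of references (assumed alternative enzymes).
    * ``symbiont-dependent-specific-unfilled`` — symbiont gapped at specific
      gap(s) the host cannot fill (assumed symbiont alternative enzyme).
    * ``host-dependent`` — host complete, symbiont lost.
    * ``collaborative-host-fills`` — symbiont specific gap(s) supplied by the
      host (folate/ArgH archetype).
    * ``collaborative-symbiont-fills`` — the mirror: host route gap supplied
      by the symbiont (ArgI archetype).
    * ``doubly-absent`` — both partners lost.
    * ``unresolved-gap`` — symbiont gap at mid reference frequency
      (serine archetype); called like a common gap but flagged.
    """

    pathway_id: str
    kind: str
    symbiont_id: str
    host_ids: tuple[str, ...]
    gap_reactions: tuple[str, ...] = ()

    #: category the classifier is expected to emit for the archetype
    KIND_CATEGORY = {
        "overlapping": "overlapping",
        "symbiont-dependent-complete": "symbiont-dependent",
        "symbiont-dependent-common-gap": "symbiont-dependent",
        "symbiont-dependent-specific-unfilled": "symbiont-dependent",
        "host-dependent": "host-dependent",
        "collaborative-host-fills": "collaborative",
        "collaborative-symbiont-fills": "collaborative",
        "doubly-absent": "doubly-absent",
        "unresolved-gap": "symbiont-dependent",
    }

    @property
    def intended_category(self) -> str:
        return self.KIND_CATEGORY[self.kind]


@dataclass(frozen=True)
class ScenarioTruth:
    """Implanted ground truth: intended category per (pathway, pairing)."""

    scenarios: tuple[ScenarioSpec, ...] = ()

    def intended(self) -> dict[tuple[str, str], str]:
        return {
            (s.pathway_id, s.symbiont_id): s.intended_category
            for s in self.scenarios
        }


@dataclass(frozen=True)
class SimulationResult:
    annotations: tuple[GenomeAnnotation, ...]
    truth: ScenarioTruth
    #: per-genome present reaction ids (the raw simulation state)
    states: Mapping[str, frozenset[str]]


# ---------------------------------------------------------------------------
# Tree handling


def default_symbiosis_tree(
    n_focal: int = 7, n_references: int = 42, n_hosts: int = 3
) -> tuple[str, dict[str, str]]:
    """A simple newick emulating the study design: a symbiont clade on a
    long stem nested among free-living references, plus a host clade.

    Returns (newick string, tip-role mapping).
    """
    focal = [f"SYM{i:02d}" for i in range(1, n_focal + 1)]
    refs = [f"REF{i:02d}" for i in range(1, n_references + 1)]
    hosts = [f"HOST{i}" for i in range(1, n_hosts + 1)]

    def ladder(tips: list[str]) -> str:
        clade = tips[0]
        for tip in tips[1:]:
            clade = f"({clade},{tip})"
        return clade

    newick = f"(({ladder(focal)},{ladder(refs)}),{ladder(hosts)});"
    roles = {t: "focal-symbiont" for t in focal}
    roles.update({t: "reference" for t in refs})
    roles.update({t: "host" for t in hosts})
    return newick, roles


def _branch_class(node, roles: Mapping[str, str]) -> str:
    """Branch class from the roles of the tips below a node."""
    tips = {leaf.taxon.label for leaf in node.leaf_iter()}
    tip_roles = {roles[t] for t in tips}
    if tip_roles == {"focal-symbiont"}:
        parent = node.parent_node
        if parent is None:
            return "symbiont-crown"
        parent_tips = {leaf.taxon.label for leaf in parent.leaf_iter()}
        parent_roles = {roles[t] for t in parent_tips}
        return "symbiont-crown" if parent_roles == {"focal-symbiont"} else "symbiont-stem"
    if tip_roles == {"host"}:
        return "host"
    return "reference"


def simulate_gene_content(
    tree: str | dendropy.Tree,
    kb: PathwayKB,
    model: LossModel = LossModel(),
    roles: Mapping[str, str] | None = None,
) -> SimulationResult:
    """Simulate lineage-specific gene loss on a rooted tree.

    ``tree`` is a newick string/path or a dendropy Tree; tip roles come
    from node annotations of the form ``label[&role=...]`` or from the
    ``roles`` mapping.  Every tip must have a role.  The root genome has
    the full KB reaction complement; each branch removes genes with its
    class probability.  Emitted annotations carry each present reaction's
    EC numbers (or COG ids for EC-less reactions).
    """
    if isinstance(tree, dendropy.Tree):
        t = tree
    else:
        text = str(tree)
        if Path(text).exists() if len(text) < 4096 and "\n" not in text and "(" not in text else False:
            t = dendropy.Tree.get(path=text, schema="newick")
        else:
            t = dendropy.Tree.get(data=text, schema="newick")
    roles = dict(roles or {})
    tips = [leaf.taxon.label for leaf in t.leaf_node_iter()]
    unlabeled = sorted(set(tips) - roles.keys())
    if unlabeled:
        raise ValueError(f"unlabeled tip(s): {', '.join(unlabeled)}")

    genes = sorted(kb.reactions)
    gene_index = {g: i for i, g in enumerate(genes)}
    retained_mask = np.zeros(len(genes), dtype=bool)
    for g in model.retained:
        retained_mask[gene_index[g]] = True

    rng = np.random.default_rng(model.seed)
    states: dict[str, frozenset[str]] = {}
    root = t.seed_node
    full = np.ones(len(genes), dtype=bool)

    def as_set(state: np.ndarray) -> frozenset[str]:
        return frozenset(genes[i] for i in np.flatnonzero(state))

    def recurse(node, state: np.ndarray) -> None:
        for child in node.child_nodes():
            cls = _branch_class(child, roles)
            p = model.loss_probability[cls]
            lost = rng.random(len(genes)) < p
            child_state = state & ~(lost & ~retained_mask)
            if child.is_leaf():
                states[child.taxon.label] = as_set(child_state)
            else:
                if child.label:  # labeled internal nodes are recorded too
                    states[child.label] = as_set(child_state)
                recurse(child, child_state)
        if node is root and node.is_leaf():  # degenerate single-tip tree
            states[node.taxon.label] = frozenset(genes)

    if root.label:
        states[root.label] = frozenset(genes)
    recurse(root, full)

    annotations = tuple(
        _annotation_from_state(tip, roles[tip], states[tip], kb)
        for tip in sorted(tips)
    )
    return SimulationResult(
        annotations=annotations, truth=ScenarioTruth(), states=states
    )


def _annotation_from_state(
    genome_id: str,
    role: str,
    present: frozenset[str],
    kb: PathwayKB,
    subset_labels: Iterable[str] = (),
) -> GenomeAnnotation:
    ecs, cogs = set(), set()
    for rid in present:
        rxn = kb.reactions[rid]
        if rxn.ec_numbers:
            ecs.update(rxn.ec_numbers)
        else:
            cogs.update(rxn.cog_ids)
    return GenomeAnnotation(
        genome_id=genome_id,
        role=role,
        ec_set=frozenset(ecs),
        cog_set=frozenset(cogs),
        subset_labels=frozenset(subset_labels),
    )


# ---------------------------------------------------------------------------
# Scenario implantation


def _set_reactions(
    states: dict[str, set[str]], genome: str, add: Iterable[str], remove: Iterable[str]
) -> None:
    states[genome] |= set(add)
    states[genome] -= set(remove)


def implant_scenario(
    result: SimulationResult,
    kb: PathwayKB,
    scenarios: Sequence[ScenarioSpec],
    thresholds: GapThresholds = GapThresholds(),
) -> SimulationResult:
    """Overwrite simulated states so each intended configuration holds exactly.

    Only the cells a scenario constrains are touched: the scenario pathway's
    reactions in the named symbiont and host genomes, and — for gap
    scenarios — the gap reactions' columns across the reference panel (set
    present everywhere for specific gaps, absent in 80% of references for
    common gaps, absent in 40% for unresolved gaps).
    """
    states: dict[str, set[str]] = {g: set(s) for g, s in result.states.items()}
    roles = {a.genome_id: a.role for a in result.annotations}
    refs = sorted(g for g, r in roles.items() if r == "reference")
    if not refs:
        raise ValueError("cannot implant scenarios without a reference panel")

    for sc in scenarios:
        pw = kb.pathway(sc.pathway_id)
        route = list(pw.routes[0])
        route_set = set(route)
        gaps = list(sc.gap_reactions)
        if any(g not in route_set for g in gaps):
            raise ValueError(
                f"scenario gap reactions {gaps} not all on the first route of "
                f"{sc.pathway_id!r}"
            )
        hosts = list(sc.host_ids)
        bypass_for = {
            rid: bp
            for bp in pw.bypasses
            for rid in bp.covered_reaction_ids
            if bp.side in ("both", "host")
        }

        def set_refs(reaction_id: str, absent_fraction: float) -> None:
            n_absent = round(absent_fraction * len(refs))
            for i, ref in enumerate(refs):
                if i < n_absent:
                    _set_reactions(states, ref, (), [reaction_id])
                else:
                    _set_reactions(states, ref, [reaction_id], ())

        kind = sc.kind
        if kind == "overlapping":
            _set_reactions(states, sc.symbiont_id, route_set, ())
            for h in hosts:
                _set_reactions(states, h, route_set, ())
        elif kind == "symbiont-dependent-complete":
            _set_reactions(states, sc.symbiont_id, route_set, ())
            for h in hosts:
                _set_reactions(states, h, (), route_set)
        elif kind in (
            "symbiont-dependent-common-gap",
            "symbiont-dependent-specific-unfilled",
            "unresolved-gap",
        ):
            if not gaps:
                raise ValueError(f"{kind} scenario needs gap_reactions")
            if len(gaps) >= len(route_set):
                raise ValueError("gap scenario would empty the route")
            _set_reactions(states, sc.symbiont_id, route_set - set(gaps), gaps)
            frac = {"symbiont-dependent-common-gap": 0.8,
                    "symbiont-dependent-specific-unfilled": 0.0,
                    "unresolved-gap": 0.4}[kind]
            for g in gaps:
                set_refs(g, frac)
            for h in hosts:  # host must not fill the gap nor complete alone
                bypass_rxns = {bp.bypass_reaction_id for bp in pw.bypasses}
                _set_reactions(states, h, (), route_set | set(gaps) | bypass_rxns)
        elif kind == "host-dependent":
            for h in hosts:
                _set_reactions(states, h, route_set, ())
            _set_reactions(states, sc.symbiont_id, (), route_set)
        elif kind == "collaborative-host-fills":
            if not gaps:
                raise ValueError("collaborative-host-fills needs gap_reactions")
            _set_reactions(states, sc.symbiont_id, route_set - set(gaps), gaps)
            for g in gaps:
                set_refs(g, 0.0)  # specific gaps: references retain the gene
            supply = {
                bypass_for[g].bypass_reaction_id if g in bypass_for else g
                for g in gaps
            }
            for h in hosts:
                _set_reactions(states, h, supply, route_set - set(gaps))
        elif kind == "collaborative-symbiont-fills":
            if not gaps:
                raise ValueError("collaborative-symbiont-fills needs gap_reactions")
            for h in hosts:
                _set_reactions(states, h, route_set - set(gaps), gaps)
            _set_reactions(states, sc.symbiont_id, gaps, route_set - set(gaps))
            for g in set(route_set) - set(gaps):
                set_refs(g, 0.0)
        elif kind == "doubly-absent":
            _set_reactions(states, sc.symbiont_id, (), route_set)
            for h in hosts:
                _set_reactions(states, h, (), route_set)
        else:
            raise ValueError(f"unknown scenario kind {sc.kind!r}")

    annotations = tuple(
        _annotation_from_state(
            a.genome_id, a.role, frozenset(states[a.genome_id]), kb, a.subset_labels
        )
        for a in result.annotations
    )
    return SimulationResult(
        annotations=annotations,
        truth=ScenarioTruth(scenarios=tuple(scenarios)),
        states={g: frozenset(s) for g, s in states.items()},
    )


# ---------------------------------------------------------------------------
# Packaged Blattodea fixture


def packaged_kb_path() -> Path:
    return Path(__file__).parent / "data" / "blattodea_kb.yaml"


def expected_relationship_letters():
    """Bundled expected letter-code table for the Blattodea fixture.

    Products x strains, letters in {B, H, O, -, C}; the regression tests
    require the pipeline to regenerate this table bit-identically.
    """
    import pandas as pd

    path = Path(__file__).parent / "data" / "blattodea_expected_relationships.tsv"
    return pd.read_csv(path, sep="\t", index_col="product", keep_default_na=False)


# Focal strains: five generic Blattabacterium-like strains plus the two
# further-reduced strains from the subsocial-roach / basal-termite hosts.
GENERIC_FOCAL = ("BPLAN", "BGIGA", "BGER", "BBOR", "BLAT")
REDUCED_FOCAL = ("CPUbr", "MADAR")
FOCAL_STRAINS = GENERIC_FOCAL + REDUCED_FOCAL

#: ECs absent from every focal strain (with the reference-panel absence
#: counts, out of 42, that place each in its frequency class).
_FOCAL_COMMON_LOSSES = {
    # EC -> number of references also lacking it (>29.4 -> common)
    "3.5.1.16": 32,   # arginine: acetylornithine deacetylase
    "2.3.1.31": 31,   # methionine: homoserine O-acetyltransferase
    "3.5.4.25": 33,   # riboflavin: GTP cyclohydrolase II
}
_FOCAL_SPECIFIC_LOSSES = {
    # EC -> number of references lacking it (<4.2 -> specific)
    "3.1.3.104": 2,   # riboflavin phosphatase step
    "3.6.1.67": 1,    # folate: dihydroneopterin triphosphate diphosphatase
    "3.6.1.-": 2,     # folate: second dephosphorylation step
    "1.4.3.5": 3,     # pyridoxine: pyridoxine 5'-phosphate oxidase step
    "6.2.1.26": 2,    # menaquinone: o-succinylbenzoate-CoA ligase
}
#: Additional losses only in the further-reduced strains (reference counts).
_REDUCED_EXTRA_LOSSES = {
    "4.3.2.1": 0,     # ArgH, argininosuccinate lyase
    "2.6.1.85": 1,    # PabA, aminodeoxychorismate synthase
    "4.1.3.38": 1,    # TrpE-like aminodeoxychorismate lyase
}
#: Whole pathways additionally lost by the reduced strains.
_REDUCED_LOST_PATHWAYS = ("trp", "thr", "met", "bcaa")

#: Pathways lost in every focal strain (host- or nobody-supplied products).
_FOCAL_LOST_PATHWAYS = (
    "gln", "asn", "gly", "pro", "protoheme", "uricolysis",
    "thiamine", "niacin", "pantothenate", "biotin", "cobalamin",
)

#: Bacterial-only enzyme repertoire: reactions never given to references
#: (host-route or host-bypass enzymes and the uricolytic pathway).
_NON_BACTERIAL_REACTIONS = (
    "pah", "cbs", "cgl", "alp", "uox", "uraD", "alnS", "alc",
)

#: Mid-frequency reference absence: SerB, absent from 17/42 references.
_SERB_REF_ABSENT = 17

#: Urease: present only in three pathogen-like reference strains.
_UREASE_REFS_WITH = ("WEEK01", "RIEM01", "CHRY01")


def _reference_names() -> list[str]:
    names = [f"FLAVO{i:02d}" for i in range(1, 40)]
    return names + list(_UREASE_REFS_WITH)


@dataclass(frozen=True)
class FixtureBundle:
    kb: PathwayKB
    annotations: tuple[GenomeAnnotation, ...]       # focal + references + outgroup
    host_annotations: tuple[GenomeAnnotation, ...]  # the three host gene sets
    host_profiles: dict[str, HostProfile]
    pairings: tuple[Pairing, ...]
    group_of: dict[str, str]
    thresholds: GapThresholds

    @property
    def all_annotations(self) -> tuple[GenomeAnnotation, ...]:
        return self.annotations


def _ec_complement(kb: PathwayKB, reaction_ids: Iterable[str]) -> tuple[set, set]:
    ecs, cogs = set(), set()
    for rid in reaction_ids:
        rxn = kb.reactions[rid]
        if rxn.ec_numbers:
            ecs.update(rxn.ec_numbers)
        else:
            cogs.update(rxn.cog_ids)
    return ecs, cogs


def blattodea_fixture() -> FixtureBundle:
    """The packaged cockroach/termite-symbiont fixture.

    Deterministic; encodes every presence/absence statement of the study
    system: urease in all symbiont strains but only pathogen-like
    references; essential-amino-acid pathway retention in the generic
    strains; the listed common and specific gap enzymes; ArgH/PabA/TrpE
    additionally lost in CPUbr and MADAR; host argininosuccinate lyase and
    alkaline phosphatase; and the termite host's three-enzyme uricolytic
    deficit.
    """
    kb = load_kb(packaged_kb_path())
    route_reactions: dict[str, set[str]] = {
        pid: {r for route in pw.routes for r in route}
        for pid, pw in kb.pathways.items()
    }
    bacterial_reactions = {
        rid for rid in kb.reactions if rid not in _NON_BACTERIAL_REACTIONS
    }

    def strain_ecs(strain: str) -> tuple[set, set]:
        lost_pathways = set(_FOCAL_LOST_PATHWAYS)
        lost_ecs = set(_FOCAL_COMMON_LOSSES) | set(_FOCAL_SPECIFIC_LOSSES)
        if strain in REDUCED_FOCAL:
            lost_pathways |= set(_REDUCED_LOST_PATHWAYS)
            lost_ecs |= set(_REDUCED_EXTRA_LOSSES)
        present = set(bacterial_reactions)
        for pid in lost_pathways:
            present -= route_reactions[pid]
        # keep reactions shared with retained pathways
        for pid, rxns in route_reactions.items():
            if pid not in lost_pathways:
                present |= rxns & bacterial_reactions
        for pid in lost_pathways:
            only_there = route_reactions[pid] - set().union(
                *(route_reactions[p] for p in route_reactions if p not in lost_pathways)
            )
            present -= only_there
        ecs, cogs = _ec_complement(kb, present)
        ecs -= lost_ecs
        # SerB itself is gone; the strains carry the HisB alternative, which
        # is an EC listed on the same reaction, so presence is unaffected.
        ecs.discard("3.1.3.3")
        return ecs, cogs

    annotations: list[GenomeAnnotation] = []
    for strain in FOCAL_STRAINS:
        ecs, cogs = strain_ecs(strain)
        if strain == "BGIGA":
            # one COG-evidence case: histidinol dehydrogenase via COG0141
            ecs.discard("1.1.1.23")
            cogs.add("COG0141")
        labels = frozenset({"CPUbr+MADAR"}) if strain in REDUCED_FOCAL else frozenset()
        annotations.append(
            GenomeAnnotation(
                genome_id=strain,
                role="focal-symbiont",
                ec_set=frozenset(ecs),
                cog_set=frozenset(cogs),
                subset_labels=labels,
            )
        )

    # Reference panel: full bacterial complement minus designed absences.
    ref_names = _reference_names()
    ref_absences: dict[str, set[str]] = {name: set() for name in ref_names}
    designed = dict(_FOCAL_COMMON_LOSSES)
    designed.update(_FOCAL_SPECIFIC_LOSSES)
    designed.update(_REDUCED_EXTRA_LOSSES)
    for ec, n_absent in sorted(designed.items()):
        for name in ref_names[:n_absent]:
            ref_absences[name].add(ec)
    for name in ref_names[:_SERB_REF_ABSENT]:
        ref_absences[name].add("3.1.3.3")
    for name in ref_names:
        if name not in _UREASE_REFS_WITH:
            ref_absences[name].add("3.5.1.5")

    base_ecs, base_cogs = _ec_complement(kb, bacterial_reactions)
    base_ecs.discard("3.1.3.-")  # HisB alternative is symbiont-specific here
    for name in ref_names:
        annotations.append(
            GenomeAnnotation(
                genome_id=name,
                role="reference",
                ec_set=frozenset(base_ecs - ref_absences[name]),
                cog_set=frozenset(base_cogs),
            )
        )
    annotations.append(
        GenomeAnnotation(
            genome_id="BACTOUT",
            role="outgroup",
            ec_set=frozenset(base_ecs - {"3.5.1.5"}),
            cog_set=frozenset(base_cogs),
        )
    )

    # Hosts: two cockroach gene sets and the Blattabacterium-free termite.
    host_core_reactions = {
        "gdh", "glnA", "aspC", "asnB", "serA", "serC", "serB", "glyA",
        "cbs", "cgl", "alaT", "pah", "proB", "proA", "proC",
        "hemA", "hemB", "hemH", "lipA", "lipB",
        "alp", "argH", "bcat",
    }
    uricolytic_reactions = ("uox", "uraD", "alnS", "alc")
    termite_missing = {"uox", "uraD", "alc"}  # three-enzyme uricolytic deficit

    def host_annotation(host_id: str, missing: set[str]) -> GenomeAnnotation:
        present = (host_core_reactions | set(uricolytic_reactions)) - missing
        ecs, cogs = _ec_complement(kb, present)
        return GenomeAnnotation(
            genome_id=host_id, role="host",
            ec_set=frozenset(ecs), cog_set=frozenset(cogs),
        )

    host_annotations = (
        host_annotation("PAME", set()),          # Periplaneta-like cockroach
        host_annotation("CPUN", set()),          # Cryptocercus-like cockroach
        host_annotation("ZNEV", termite_missing),  # Blattabacterium-free termite
    )
    profile = host_consensus(
        list(host_annotations), rule="majority", host_id="blattodea-consensus"
    )
    host_profiles = {profile.host_id: profile}

    pairings = tuple(
        Pairing(
            symbiont_id=strain,
            host_profile_id=profile.host_id,
            group_label="Cp&Md" if strain in REDUCED_FOCAL else "Others",
        )
        for strain in FOCAL_STRAINS
    )
    group_of = {p.symbiont_id: p.group_label for p in pairings}

    return FixtureBundle(
        kb=kb,
        annotations=tuple(annotations),
        host_annotations=host_annotations,
        host_profiles=host_profiles,
        pairings=pairings,
        group_of=group_of,
        thresholds=GapThresholds(),
    )
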