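# Methods

## Problem and model

The package infers host–symbiont metabolic relationships from gene content
alone. Its central difficulty is the interpretation of *gaps*: enzymes
missing from a pathway that is otherwise present. In clades without model
organisms, many reactions are carried out by uncharacterized alternative
enzymes, so a missing gene is not automatically a missing function. The
workflow resolves this by phylogenetic comparison: a gap shared with the
large majority of the symbiont's free-living relatives is evidence for an
unknown clade-wide alternative enzyme, whereas a gap nearly unique to the
symbiont is a genuine loss, possibly complemented by the host.

All inference operates on presence/absence; reaction directionality,
expression, and flux are outside the model (the `reversible` flag on
reactions is carried as metadata only).

## Pathway knowledge base

A KB file (YAML) defines reactions (EC numbers and/or COG ids), pathways
(ordered reaction routes per final product), and bypasses. Design points:

- **Alternative identifiers vs alternative routes.** Two enzymes catalysing
  the same step (SerB `3.1.3.3` and the HisB-type phosphatase `3.1.3.-`)
  are alternative EC strings on one reaction; genuinely different chemistry
  (bacterial vs metazoan cysteine synthesis) is modelled as separate
  routes. EC matching is exact-string: a genome's `3.1.3.-` satisfies only
  reactions that explicitly list the 3-digit form. This avoids wildcard
  matching silently conflating sub-subclasses.
- **Bypasses are directional.** A bypass (one enzyme substituting a
  contiguous route segment) carries a `side` ∈ {both, host, symbiont}.
  A host-only bypass — e.g. alkaline phosphatase replacing the folate
  two-step dephosphorylation — is invisible when evaluating symbiont or
  reference genomes alone, but available to the host and to the joint
  (union) evaluation. Without this, min-gap route selection would report
  the bypass variant's single gap for the symbiont and the canonical
  two-reaction specific gap would disappear from the gap table.
- The packaged KB (`data/blattodea_kb.yaml`) covers the 20 amino acids,
  the B-vitamins, menaquinone, protoheme, lipoate, uricolysis and urea
  hydrolysis, with deliberately compact routes: uncontested intermediate
  steps are collapsed, since only contested steps carry comparative
  signal. Which MetaCyc variant a curator would pick per product is an
  open choice; the file documents ours and is versioned data, not code.

## Function assignment

A gene gets an EC iff some hit has E-value strictly below 10⁻¹⁰ and maps
to a 4- or 3-digit EC; coarser ECs are discarded as ambiguous. Ties keep
all passing ECs (genes may be multifunctional; downstream logic only needs
set membership). Genes with no EC are offered a COG fallback (best hit,
same default threshold, separately configurable); EC-assigned genes never
gain a COG, and offering one is an error rather than a silent skip.
Assignment is monotone in the threshold and independent of input order.
Direct EC/COG presence lists can bypass this stage entirely.

## Pathway state

For a genome and pathway, every route variant usable by the genome's side
is scored by its missing-reaction count; the best variant is chosen by
(state, fewest gaps, lexicographically smallest gap set) — the last term
is a determinism tie-break. States:

- `complete`: nothing missing;
- `gapped`: 1..`max_gaps` (default 2) missing **and** at least one route
  reaction present;
- `absent`: otherwise.

The "something present" condition implements gaps as *missing enzymes in
pathways otherwise complete*: a wholly lost one- or two-step pathway is a
loss, not a bundle of gaps, and must not be promoted to "functional via
assumed alternative enzymes" downstream. Pathways with more than
`max_gaps` missing are considered absent rather than speculated upon.

## Gap classification

For each gap reaction of each gapped pathway in each focal genome, the
reference absence frequency is the fraction of reference-role genomes
lacking the reaction; the outgroup is excluded from denominators by
default (the thresholds are phrased against the symbiont's own order), and
the panel is configurable. Categories use strict inequalities — absence
> 0.70 → *common*, < 0.10 → *specific* — because the source phrasing is
"over" and "less than"; boundary frequencies fall to *unclassified*.
Unclassified gaps are never silently resolved: they propagate as
`unresolved-gap` flags.

Subset-level specific gaps (losses shared by a labelled strain subset,
e.g. the two further-reduced strains): a reaction qualifies when it is
absent throughout the subset, nearly universal among references, and some
pathway containing it retains at least one route reaction in every subset
member. The last condition admits losses inside pathways degraded beyond
the per-genome gap budget (the *p*-aminobenzoate branch case) while
excluding wholly lost pathways; with the subset equal to all focal strains
it reduces exactly to the `shared_by_all_focal` specific calls.

## Relationship categories

Per end product and (symbiont, host profile) pairing, decided in order:

1. both effectively complete → **overlapping**
2. host only → **host-dependent**
3. symbiont only → **symbiont-dependent**
4. neither alone, but some route variant is covered by the union of the
   two enzyme sets — crediting each reaction only to a partner whose side
   may use it, and counting the symbiont's common/unclassified gaps as
   covered without crediting anyone — with each partner contributing at
   least one exclusively-covered reaction → **collaborative**
5. otherwise → **doubly-absent**

*Effectively complete* encodes the biological assumptions. Symbiont side:
complete; or gapped with all gaps common (clade-wide alternative enzymes
assumed); or gapped with specific gaps that no host enzyme can fill
directly or via a host-usable bypass — then a symbiont-specific
alternative enzyme is assumed and the call is flagged
`assumed-alternative-enzyme`. Only a host-fillable specific gap pushes the
decision to the collaborative test, so collaboration is invoked exactly
when neither partner suffices and the host demonstrably supplies the
missing catalysis. Host side: complete with zero gaps only — hosts have no
reference panel against which a gap could be called common. Unclassified
gaps behave like common ones but flag the call `unresolved-gap` (this
keeps the serine-type ambiguity visible without changing the category).
Requiring *exclusive* contributions in step 4 makes collaborative calls
sound by construction: removing either partner's contributed reactions
breaks every completing route (asserted by re-evaluation in tests).

Host profiles are single genomes, consensus profiles (rule `all` or
`majority`, default majority — a capability present in two of three host
genomes is treated as ancestrally present, with per-member differences
reported alongside), or curated lists such as the bundled standard insect
gene set (`data/standard_insect_ec_set.tsv`). When several pathways yield
one product, each is classified and the call highest in the capability
preference order (overlapping, symbiont-dependent, host-dependent,
collaborative, doubly-absent) is reported.

## Synthetic data

`simulate_gene_content` performs independent Bernoulli gene loss per gene
per branch on a rooted newick tree, losses inherited; the root carries the
full KB complement. Branch classes (symbiont-stem, symbiont-crown,
reference, host) get separate rates; defaults are 0.30 / 0.05 / 0.02 /
0.05 per gene per branch — chosen for test power (a drastic stem-loss
regime over a sporadic background), since no quantitative loss-rate
estimates exist for these clades; they are not biological estimates. The
generator reproduces what the analysis assumes — marginal presence/absence
structured by lineage — and deliberately omits operon/linkage structure,
horizontal transfer, branch-length-dependent rates and annotation error;
passing recovery tests therefore validates the inference logic, not
robustness to correlated loss or mis-annotation in real genomes.

`implant_scenario` overwrites, after stochastic loss, exactly the cells a
ground-truth configuration constrains (the scenario pathway's reactions in
the named symbiont and host genomes, and the gap reactions' reference
columns: all-present for specific, 80% absent for common, 40% for
unresolved). Truth labels are thus realizable by construction, and
recovery is exact whenever the touched cells determine the category —
which the archetypes are designed to ensure.

The packaged Blattodea fixture is fully deterministic: 5 generic focal
strains plus CPUbr and MADAR, 42 references (urease confined to three
pathogen-like strains), one outgroup, and 3 host gene sets (two cockroach,
one termite lacking three uricolytic enzymes). It encodes every
presence/absence statement the analysis reproduces; where the underlying
description is silent (e.g. *which* references carry a rare absence), the
assignment is an arbitrary documented choice preserving every frequency
class. The expected relationship table ships as data and must be
regenerated bit-identically by the pipeline (regression-tested).

## Numerical and engineering choices

- All randomness flows through a single seeded numpy generator; fixed
  traversal and sorted gene order make simulations reproducible.
- Route enumeration returns minimal sets (no returned set strictly
  contains another) and is idempotent and order-independent.
- Pipeline TSVs carry a `# config_hash=` header derived from the analytic
  parameters (not the output location); reruns are bit-identical. Figures
  (SVG/PNG heatmap of the matrix with gap-category colouring) are derived
  artifacts only and never inputs.
- Degenerate inputs fail loudly: empty reference panels, duplicate genome
  ids, dangling KB references, non-positive E-values, EC-assigned genes
  offered to the COG fallback, and gap reactions without gap calls all
  raise typed errors naming the offender.
- Problem sizes used in the validation suites: 500 random small KBs
  (≤ 10 reactions, ≤ 3 routes, optional sided bypass) for brute-force
  equivalence, and 50 seeded simulations of the 52-tip study design for
  category recovery; both run in seconds on one core.

## Known limitations

- Completeness is binary per reaction; partial complexes, pseudogenes and
  expression are invisible.
- The host side has no frequency-based gap rescue; a single missing host
  enzyme renders a host pathway incomplete even if insect genomes
  generally encode an alternative (mitigated by consensus profiles).
- Collaborative detection requires the KB to state the bypass or shared
  route explicitly; it cannot discover novel complementation chemistry.
- The `max_gaps` budget (default 2) bounds speculation but also blinds
  the classifier to heavily degraded pathways that might still function.
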