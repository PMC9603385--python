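"""Five-category relationship calling and collaborative detection."""

import random

import pytest

from symbiopath import (
    GapThresholds,
    GenomeAnnotation,
    MatrixError,
    Pairing,
    build_matrix,
    classify_all,
    classify_gaps,
    classify_relationship,
    effective_complete,
    evaluate_pathway,
    host_consensus,
    standard_insect_profile,
)
from symbiopath.occurrence_matrix import presence_set
from symbiopath.pathway_kb import Bypass, Pathway, Product, Reaction
from symbiopath.relationship_classifier import HostProfile

from conftest import (
    annotation_for,
    make_kb,
    oracle_relationship,
    random_small_kb,
    simple_reactions,
)


def run_single(kb, pathway_id, product, sym_reactions, host_reactions,
               ref_panels, thresholds=GapThresholds(), n_refs=20):
    """Classify one product for a constructed symbiont/host/reference setup.

    ``ref_panels`` maps reaction ids to the number of references lacking
    them (out of ``n_refs``); unlisted reactions are present in all.
    """
    universe = sorted(
        {r for route in kb.pathway(pathway_id).routes for r in route}
        | {bp.bypass_reaction_id for bp in kb.pathway(pathway_id).bypasses}
    )
    anns = [annotation_for(kb, sym_reactions, "SYM")]
    for i in range(n_refs):
        present = [r for r in universe if i >= ref_panels.get(r, 0)]
        anns.append(annotation_for(kb, present, f"R{i:02d}", role="reference"))
    m = build_matrix(anns, kb)
    host_ann = annotation_for(kb, host_reactions, "HOSTX", role="host")
    profile = host_consensus([host_ann], rule="majority", host_id="H")
    table = classify_all(m, kb, thresholds, [Pairing("SYM", "H")], {"H": profile})
    return next(c for c in table.calls if c.product == product)


@pytest.fixture
def arg_like_kb():
    """Eight-step route ending in a lyase the host also encodes."""
    rids = [f"s{i}" for i in range(1, 8)] + ["lyase"]
    return make_kb(
        [Pathway("arg", (Product("Arg"),), (tuple(rids),))],
        simple_reactions(rids),
    )


class TestEffectiveComplete:
    def states(self, kb, present, pathway="arg"):
        return evaluate_pathway(frozenset(present), kb, pathway, genome_id="SYM")

    def test_all_common_gaps_effectively_complete(self, arg_like_kb, fixture_bundle):
        """A symbiont pathway whose only gaps are clade-wide common gaps is
        treated as functional (unknown alternative enzymes assumed)."""
        kb = fixture_bundle.kb
        anns = list(fixture_bundle.annotations)
        m = build_matrix(anns, kb)
        calls = [
            c for c in classify_gaps(m, kb, fixture_bundle.thresholds)
            if c.genome_id == "BPLAN" and c.pathway_id == "met"
        ]
        state = evaluate_pathway(
            m.present_reactions("BPLAN"), kb, "met", genome_id="BPLAN"
        )
        ok, flags = effective_complete(state, calls, "symbiont", kb=kb)
        assert ok and not flags
        assert all(c.category == "common" for c in calls)

    def test_unfilled_specific_gap_flags_assumed_alternative(
        self, fixture_bundle
    ):
        kb = fixture_bundle.kb
        m = build_matrix(list(fixture_bundle.annotations), kb)
        calls = [
            c for c in classify_gaps(m, kb, fixture_bundle.thresholds)
            if c.genome_id == "BPLAN" and c.pathway_id == "pyridoxine"
        ]
        state = evaluate_pathway(
            m.present_reactions("BPLAN"), kb, "pyridoxine", genome_id="BPLAN"
        )
        ok, flags = effective_complete(
            state, calls, "symbiont", kb=kb, host_reactions=frozenset()
        )
        assert ok and "assumed-alternative-enzyme" in flags

    def test_host_side_requires_zero_gaps(self, arg_like_kb):
        state = evaluate_pathway(
            frozenset({"s1"}), arg_like_kb, "arg", side="host", genome_id="H"
        )
        ok, _ = effective_complete(state, (), "host")
        assert not ok

    def test_missing_gap_call_is_an_error(self, arg_like_kb):
        state = self.states(arg_like_kb, [f"s{i}" for i in range(1, 8)])
        assert state.state == "gapped"
        with pytest.raises(MatrixError, match="no gap call"):
            effective_complete(state, (), "symbiont", kb=arg_like_kb)


class TestClassifyRelationship:
    def test_host_dependent_when_symbiont_lost(self, arg_like_kb):
        call = run_single(
            arg_like_kb, "arg", "Arg",
            sym_reactions=[],
            host_reactions=[f"s{i}" for i in range(1, 8)] + ["lyase"],
            ref_panels={},
        )
        assert call.category == "host-dependent"

    def test_collaborative_when_host_supplies_final_lyase(self, arg_like_kb):
        call = run_single(
            arg_like_kb, "arg", "Arg",
            sym_reactions=[f"s{i}" for i in range(1, 8)],
            host_reactions=["lyase"],
            ref_panels={},  # every reference retains everything: specific gap
        )
        assert call.category == "collaborative"
        assert call.host_contributed == frozenset({"lyase"})
        assert call.symbiont_contributed

    def test_doubly_absent_when_union_cannot_complete(self, arg_like_kb):
        call = run_single(
            arg_like_kb, "arg", "Arg",
            sym_reactions=["s1", "s2"], host_reactions=["lyase"], ref_panels={},
        )
        assert call.category == "doubly-absent"

    def test_overlapping_when_both_complete(self, arg_like_kb):
        full = [f"s{i}" for i in range(1, 8)] + ["lyase"]
        call = run_single(
            arg_like_kb, "arg", "Arg",
            sym_reactions=full, host_reactions=full, ref_panels={},
        )
        assert call.category == "overlapping"

    def test_unknown_product_for_pathway_raises(self, arg_like_kb):
        state = evaluate_pathway(frozenset(), arg_like_kb, "arg", genome_id="S")
        with pytest.raises(MatrixError, match="final product"):
            classify_relationship(
                "NotAProduct", "arg", state, (), state, arg_like_kb,
                symbiont_reactions=frozenset(), host_reactions=frozenset(),
            )

    def test_mirror_direction_symmetry(self):
        """Host-gap-filled-by-symbiont and symbiont-gap-filled-by-host are
        both collaborative (the two arginine archetypes)."""
        rids = ["u1", "u2", "otc", "d1"]
        kb = make_kb(
            [Pathway("urea_cycle", (Product("Arg"),), (tuple(rids),))],
            simple_reactions(rids),
        )
        host_fills = run_single(
            kb, "urea_cycle", "Arg",
            sym_reactions=["u1", "u2", "d1"], host_reactions=["otc"],
            ref_panels={},
        )
        symbiont_fills = run_single(
            kb, "urea_cycle", "Arg",
            sym_reactions=["otc"], host_reactions=["u1", "u2", "d1"],
            ref_panels={},
        )
        assert host_fills.category == symbiont_fills.category == "collaborative"
        assert host_fills.host_contributed == frozenset({"otc"})
        assert symbiont_fills.symbiont_contributed == frozenset({"otc"})

    def test_unresolved_gap_forces_flagged_common_like_call(self):
        """A mid-frequency (serine-style) gap yields the common-gap outcome
        but carries the unresolved-gap flag."""
        rids = ["q1", "q2", "q3"]
        kb = make_kb(
            [Pathway("ser", (Product("Ser"),), (tuple(rids),))],
            simple_reactions(rids),
        )
        call = run_single(
            kb, "ser", "Ser",
            sym_reactions=["q1", "q2"], host_reactions=[],
            ref_panels={"q3": 8},  # 8/20 = 40% reference absence
        )
        assert call.category == "symbiont-dependent"
        assert "unresolved-gap" in call.flags

    def test_collaborative_soundness_by_reevaluation(self, fixture_bundle,
                                                     fixture_matrix):
        """Removing either partner's contributed reactions breaks every
        completing route of each collaborative call."""
        b = fixture_bundle
        table = classify_all(
            fixture_matrix, b.kb, b.thresholds, list(b.pairings), b.host_profiles
        )
        collab = [c for c in table.calls if c.category == "collaborative"]
        assert collab
        for c in collab:
            sym = fixture_matrix.present_reactions(c.symbiont_id)
            profile = b.host_profiles[c.host_profile_id]
            host = presence_set(
                GenomeAnnotation(profile.host_id, "host", profile.ec_set,
                                 profile.cog_set),
                b.kb,
            )
            assumed = {
                gc.reaction_id for gc in c.gap_calls if gc.category == "common"
            }
            from symbiopath.pathway_kb import enumerate_route_variants

            for removed, kept_cov in (
                (c.symbiont_contributed, host | assumed),
                (c.host_contributed, sym | assumed),
            ):
                union = (sym | host | assumed) - removed
                assert not any(
                    v.reactions <= union
                    for v in enumerate_route_variants(b.kb, c.pathway_id)
                )

    def test_oracle_equivalence_on_random_kbs(self):
        rng = random.Random(20240915)
        agreements = 0
        for _ in range(300):
            kb = random_small_kb(rng)
            pw = kb.pathway("pw")
            universe = sorted(kb.reactions)
            sym = [r for r in universe if rng.random() < 0.6]
            host = [r for r in universe if rng.random() < 0.4]
            lacking = {
                r: rng.choice([0, 1, 3, 8, 15, 18, 20]) for r in universe
            }
            call = run_single(kb, "pw", "P", sym, host, lacking)
            expected = oracle_relationship(
                pw,
                set(presence_set(annotation_for(kb, sym), kb)),
                set(presence_set(annotation_for(kb, host), kb)),
                {r: n / 20 for r, n in lacking.items()},
            )
            assert call.category == expected
            agreements += 1
        assert agreements == 300


class TestClassifyAll:
    def test_partition_every_pair_exactly_one_category(self, fixture_bundle,
                                                       fixture_matrix):
        b = fixture_bundle
        table = classify_all(
            fixture_matrix, b.kb, b.thresholds, list(b.pairings), b.host_profiles
        )
        products = {p.name for p in b.kb.all_products}
        seen = {}
        for c in table.calls:
            key = (c.product, c.symbiont_id)
            assert key not in seen
            seen[key] = c.category
        assert len(seen) == len(products) * len(b.pairings)

    def test_unknown_pairing_ids_raise(self, fixture_bundle, fixture_matrix):
        b = fixture_bundle
        with pytest.raises(MatrixError, match="unknown"):
            classify_all(
                fixture_matrix, b.kb, b.thresholds,
                [Pairing("NOPE", "blattodea-consensus")], b.host_profiles,
            )


class TestHostConsensus:
    def anns(self, kb):
        a = annotation_for(kb, ["r1", "r2", "r3"], "H1", role="host")
        b = annotation_for(kb, ["r1", "r2", "r3"], "H2", role="host")
        c = annotation_for(kb, ["r1", "r2"], "H3", role="host")
        return [a, b, c]

    def test_identifier_in_all_members_kept_under_all(self, toy_kb):
        profile = host_consensus(self.anns(toy_kb), rule="all")
        ec_r1 = next(iter(toy_kb.reactions["r1"].ec_numbers))
        assert ec_r1 in profile.ec_set

    def test_two_of_three_dropped_under_all_kept_under_majority(self, toy_kb):
        ec_r3 = next(iter(toy_kb.reactions["r3"].ec_numbers))
        strict = host_consensus(self.anns(toy_kb), rule="all")
        majority = host_consensus(self.anns(toy_kb), rule="majority")
        assert ec_r3 not in strict.ec_set
        assert ec_r3 in majority.ec_set
        assert majority.member_absences[ec_r3] == ("H3",)

    def test_single_member_profile_is_identity(self, toy_kb):
        (a, *_rest) = self.anns(toy_kb)
        profile = host_consensus([a], rule="all", host_id="solo")
        assert profile.ec_set == a.ec_set and profile.member_ids == ("H1",)

    def test_empty_input_raises(self):
        with pytest.raises(MatrixError):
            host_consensus([], rule="all")

    def test_standard_insect_profile_has_no_members(self):
        profile = standard_insect_profile({"2.6.1.42", "4.3.2.1", "3.1.3.1"})
        assert profile.member_ids == () and "4.3.2.1" in profile.ec_set
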