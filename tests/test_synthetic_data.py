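"""Gene-loss simulation, scenario implantation and their invariants."""

import numpy as np
import pytest

from symbiopath import (
    GapThresholds,
    LossModel,
    Pairing,
    ScenarioSpec,
    build_matrix,
    classify_all,
    host_consensus,
    implant_scenario,
    load_kb,
    simulate_gene_content,
)
from symbiopath.pathway_kb import Pathway, Product
from symbiopath.synthetic_data import default_symbiosis_tree, packaged_kb_path

from conftest import make_kb, simple_reactions


NO_LOSS = {c: 0.0 for c in ("symbiont-stem", "symbiont-crown", "reference", "host")}


@pytest.fixture(scope="module")
def kb():
    return load_kb(packaged_kb_path())


def classify_sim(result, kb, symbiont_id, host_id, thresholds=GapThresholds()):
    matrix = build_matrix(list(result.annotations), kb)
    host_ann = [a for a in result.annotations if a.genome_id == host_id]
    profile = host_consensus(host_ann, rule="majority", host_id="H")
    return classify_all(
        matrix, kb, thresholds, [Pairing(symbiont_id, "H")], {"H": profile}
    )


class TestSimulation:
    def test_no_loss_limit_everything_overlapping(self, kb):
        newick, roles = default_symbiosis_tree(n_focal=3, n_references=6, n_hosts=2)
        result = simulate_gene_content(
            newick, kb, LossModel(loss_probability=NO_LOSS, seed=5), roles
        )
        assert all(
            len(result.states[a.genome_id]) == len(kb.reactions)
            for a in result.annotations
        )
        table = classify_sim(result, kb, "SYM01", "HOST1")
        assert {c.category for c in table.calls} == {"overlapping"}

    def test_same_seed_reproduces_annotations(self, kb):
        newick, roles = default_symbiosis_tree(n_focal=4, n_references=8)
        a = simulate_gene_content(newick, kb, LossModel(seed=99), roles)
        b = simulate_gene_content(newick, kb, LossModel(seed=99), roles)
        assert a.states == b.states and a.annotations == b.annotations
        c = simulate_gene_content(newick, kb, LossModel(seed=100), roles)
        assert c.states != a.states

    def test_reference_absence_matches_binomial_expectation(self):
        """On a 42-tip reference star tree the per-reaction absence
        frequency estimates the per-branch loss probability."""
        n_reactions, p, n_refs = 200, 0.05, 42
        rids = [f"g{i:03d}" for i in range(n_reactions)]
        big = make_kb(
            [
                Pathway(f"pw{i}", (Product(f"P{i}"),),
                        (tuple(rids[i * 5:(i + 1) * 5]),))
                for i in range(n_reactions // 5)
            ],
            simple_reactions(rids),
        )
        newick = "(" + ",".join(f"R{i:02d}" for i in range(n_refs)) + ");"
        roles = {f"R{i:02d}": "reference" for i in range(n_refs)}
        model = LossModel(
            loss_probability={**NO_LOSS, "reference": p}, seed=2024
        )
        result = simulate_gene_content(newick, big, model, roles)
        absences = np.mean(
            [
                1 - len(result.states[f"R{i:02d}"]) / n_reactions
                for i in range(n_refs)
            ]
        )
        se = np.sqrt(p * (1 - p) / (n_refs * n_reactions))
        assert abs(absences - p) < 3 * se

    def test_unlabeled_tip_rejected(self, kb):
        with pytest.raises(ValueError, match="unlabeled"):
            simulate_gene_content("(A,B);", kb, LossModel(), {"A": "reference"})

    def test_invalid_probability_rejected(self):
        with pytest.raises(ValueError, match=r"\[0, 1\]"):
            LossModel(loss_probability={**NO_LOSS, "reference": 1.5})

    def test_conservation_along_root_to_tip_paths(self, kb):
        """Present genes never reappear below a loss (labeled internal
        nodes expose the ancestral states)."""
        newick = "(((A,B)AB,C)ABC,(D,E)DE)ROOT;"
        roles = {t: r for t, r in zip(
            "ABCDE",
            ["focal-symbiont", "focal-symbiont", "reference", "host", "host"],
        )}
        model = LossModel(
            loss_probability={
                "symbiont-stem": 0.4, "symbiont-crown": 0.2,
                "reference": 0.1, "host": 0.15,
            },
            seed=7,
        )
        result = simulate_gene_content(newick, kb, model, roles)
        s = result.states
        assert s["A"] <= s["AB"] <= s["ABC"] <= s["ROOT"]
        assert s["B"] <= s["AB"] and s["C"] <= s["ABC"]
        assert s["D"] <= s["DE"] <= s["ROOT"]

    def test_retention_constraints_respected(self, kb):
        newick, roles = default_symbiosis_tree(n_focal=2, n_references=4)
        anchor = {"ure", "argH"}
        model = LossModel(
            loss_probability={
                "symbiont-stem": 1.0, "symbiont-crown": 1.0,
                "reference": 1.0, "host": 1.0,
            },
            retained=frozenset(anchor),
            seed=3,
        )
        result = simulate_gene_content(newick, kb, model, roles)
        for state in result.states.values():
            assert anchor <= state


class TestImplantation:
    @pytest.fixture()
    def base(self, kb):
        newick, roles = default_symbiosis_tree(n_focal=3, n_references=20,
                                               n_hosts=1)
        return simulate_gene_content(newick, kb, LossModel(seed=17), roles)

    def implant_and_classify(self, base, kb, spec):
        out = implant_scenario(base, kb, [spec])
        table = classify_sim(out, kb, spec.symbiont_id, spec.host_ids[0])
        call = next(
            c for c in table.calls if c.pathway_id == spec.pathway_id
        )
        return out, call

    def test_collaborative_host_fills_specific_gap(self, base, kb):
        spec = ScenarioSpec("lys", "collaborative-host-fills", "SYM01",
                            ("HOST1",), gap_reactions=("lysA",))
        _, call = self.implant_and_classify(base, kb, spec)
        assert call.category == spec.intended_category == "collaborative"

    def test_common_gap_implant_yields_common_call(self, base, kb):
        from symbiopath import classify_gaps

        spec = ScenarioSpec("arg", "symbiont-dependent-common-gap", "SYM01",
                            ("HOST1",), gap_reactions=("argE",))
        out, call = self.implant_and_classify(base, kb, spec)
        assert call.category == "symbiont-dependent"
        matrix = build_matrix(list(out.annotations), kb)
        gap = next(
            c for c in classify_gaps(matrix, kb)
            if c.genome_id == "SYM01" and c.reaction_id == "argE"
        )
        assert gap.category == "common" and gap.ref_absence == pytest.approx(0.8)

    def test_mid_frequency_implant_yields_unclassified(self, base, kb):
        from symbiopath import classify_gaps

        spec = ScenarioSpec("his", "unresolved-gap", "SYM01", ("HOST1",),
                            gap_reactions=("hisD",))
        out, call = self.implant_and_classify(base, kb, spec)
        assert call.category == "symbiont-dependent"
        assert "unresolved-gap" in call.flags
        matrix = build_matrix(list(out.annotations), kb)
        gap = next(
            c for c in classify_gaps(matrix, kb)
            if c.genome_id == "SYM01" and c.reaction_id == "hisD"
        )
        assert gap.category == "unclassified"

    def test_untouched_cells_preserved(self, base, kb):
        spec = ScenarioSpec("lys", "collaborative-host-fills", "SYM01",
                            ("HOST1",), gap_reactions=("lysA",))
        out = implant_scenario(base, kb, [spec])
        touched_reactions = {"dapA", "dapB", "lysA"}
        for genome, before in base.states.items():
            after = out.states[genome]
            assert before - touched_reactions == after - touched_reactions

    def test_gap_outside_route_rejected(self, base, kb):
        spec = ScenarioSpec("lys", "collaborative-host-fills", "SYM01",
                            ("HOST1",), gap_reactions=("ure",))
        with pytest.raises(ValueError, match="route"):
            implant_scenario(base, kb, [spec])
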