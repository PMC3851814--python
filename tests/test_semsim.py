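"""TCSS, IntelliGO and Wang protein similarities."""

import math
import random

import pytest

from ppipred.missing import is_missing
from ppipred.ontology import AnnotationSet, OntologyDAG, Term, compute_ic
from ppipred.semsim import (
    EvidenceWeightTable,
    intelligo_iaf,
    intelligo_protein_sim,
    tcss_ica,
    tcss_partition,
    tcss_protein_sim,
    wang_contributions,
    wang_protein_sim,
    wang_term_sim,
)
from toyfactories import random_annotations, random_dag, wang_bruteforce_sim


class TestTCSS:
    def test_ica_equals_propagated_ic(self, chain_dag, chain_annot):
        ica = tcss_ica(chain_dag, chain_annot, "BP")
        assert ica["r"] == pytest.approx(0.0, abs=1e-12)
        assert ica["a"] == pytest.approx(-math.log(2 / 3))
        assert ica["b"] == pytest.approx(-math.log(1 / 3))

    def test_degenerate_partition_single_subgraph(self, chain_dag, chain_annot):
        part = tcss_partition(chain_dag, chain_annot, "BP", ic_threshold=100.0)
        assert len(part.subgraphs) == 1
        root, terms = part.subgraphs[0]
        assert root == "r" and terms == frozenset("rab")
        assert part.ics[(0, "a")] == pytest.approx(
            math.log(3 / 2) / math.log(3)
        )
        assert part.ics[(0, "b")] == 1.0

    def test_two_branch_partition_and_duplication(
        self, two_branch_dag, two_branch_annot
    ):
        # ICA: r=0 < X=-ln(3/4) < Y=-ln(2/4); threshold splits r from both
        part = tcss_partition(
            two_branch_dag, two_branch_annot, "BP",
            ic_threshold=0.2, merge_tolerance=0.1,
        )
        assert len(part.subgraphs) == 2
        roots = {root for root, _ in part.subgraphs}
        assert roots == {"X", "Y"}
        assert part.membership["d"] == {0, 1}  # duplicated into both
        # within each subgraph, normalized IC attains 1
        for idx in range(2):
            assert max(
                v for (m, _), v in part.ics.items() if m == idx
            ) == pytest.approx(1.0)
        assert max(part.icm.values()) == pytest.approx(1.0)
        # subgraphs plus meta-graph cover every IC-bearing term
        covered = set().union(*(t for _, t in part.subgraphs)) | part.meta_terms
        assert covered == set(part.ica)

    def test_protein_sim_hand_values(self, chain_dag, chain_annot):
        part = tcss_partition(chain_dag, chain_annot, "BP", ic_threshold=100.0)
        val = tcss_protein_sim(part, chain_annot, "P1", "P2")
        assert val == pytest.approx(math.log(3 / 2) / math.log(3))
        assert tcss_protein_sim(part, chain_annot, "P3", "P1") == 0.0

    def test_self_similarity_at_max_term(self, chain_dag, chain_annot):
        part = tcss_partition(chain_dag, chain_annot, "BP", ic_threshold=100.0)
        # P1 is annotated with b, the unique max-ICA term of the subgraph
        assert tcss_protein_sim(part, chain_annot, "P1", "P1") == 1.0

    def test_cross_subgraph_uses_meta_graph(
        self, two_branch_dag, two_branch_annot
    ):
        part = tcss_partition(
            two_branch_dag, two_branch_annot, "BP",
            ic_threshold=0.2, merge_tolerance=0.1,
        )
        # A{x1} and D{y1} live in different subgraphs; their only common
        # ancestor on the meta-graph is the aspect root with ICM 0
        assert tcss_protein_sim(part, two_branch_annot, "A", "D") == 0.0

    def test_unannotated_protein_missing(self, chain_dag, chain_annot):
        part = tcss_partition(chain_dag, chain_annot, "BP", ic_threshold=100.0)
        assert is_missing(tcss_protein_sim(part, chain_annot, "P1", "PX"))

    def test_merge_tolerance_joins_equal_roots(self, two_branch_dag):
        # symmetric corpus: X and Y subtrees annotate 2 proteins each,
        # |ICA(X)-ICA(Y)| = 0 <= tolerance, so the subgraphs merge
        annot = AnnotationSet.from_direct(
            {
                "A": {("x1", "IDA")},
                "B": {("x2", "IDA")},
                "D": {("y1", "IDA")},
                "E": {("Y", "IDA")},
            },
            two_branch_dag,
        )
        part = tcss_partition(
            two_branch_dag, annot, "BP", ic_threshold=0.2, merge_tolerance=0.5
        )
        assert len(part.subgraphs) == 1

    def test_monotone_with_lca_depth(self, chain_dag, chain_annot):
        part = tcss_partition(chain_dag, chain_annot, "BP", ic_threshold=100.0)
        sims = [
            tcss_protein_sim(part, chain_annot, "P1", other)
            for other in ("P3", "P2", "P1")  # LCA depth r < a < b
        ]
        assert sims == sorted(sims)


class TestIntelliGO:
    def test_iaf_values(self, chain_dag, chain_annot):
        # 3-protein corpus, each term directly annotates one protein
        assert intelligo_iaf(chain_annot, "BP", "b") == pytest.approx(math.log(3))
        direct = {f"P{k}": {("a", "IDA")} for k in range(2)}
        direct.update({f"Q{k}": {("b", "IDA")} for k in range(2)})
        annot4 = AnnotationSet.from_direct(direct, chain_dag)
        assert intelligo_iaf(annot4, "BP", "a") == pytest.approx(math.log(2))

    def test_term_annotating_all_proteins_has_zero_iaf(self, chain_dag):
        annot = AnnotationSet.from_direct(
            {"P1": {("b", "IDA")}, "P2": {("b", "IEA")}}, chain_dag
        )
        assert intelligo_iaf(annot, "BP", "b") == 0.0

    def test_self_similarity_is_one(self, chain_dag, chain_annot):
        assert intelligo_protein_sim(
            chain_dag, chain_annot, None, "P1", "P1", "BP"
        ) == pytest.approx(1.0)

    def test_identical_single_term_any_evidence(self, chain_dag):
        annot = AnnotationSet.from_direct(
            {
                "P1": {("b", "IDA")},
                "P2": {("b", "IEA")},
                "P3": {("a", "IDA")},
            },
            chain_dag,
        )
        assert intelligo_protein_sim(
            chain_dag, annot, None, "P1", "P2", "BP"
        ) == pytest.approx(1.0)

    def test_root_lca_gives_zero(self, two_branch_dag, two_branch_annot):
        # x2 and y1 share only the root (depth 0): basis product 0
        assert intelligo_protein_sim(
            two_branch_dag, two_branch_annot, None, "B", "D", "BP"
        ) == 0.0

    def test_evidence_weight_scale_invariance(self, chain_dag, chain_annot):
        base = EvidenceWeightTable()
        scaled = EvidenceWeightTable(
            weights={k: 0.5 * v for k, v in base.weights.items()},
            default_weight=0.5 * base.default_weight,
        )
        for i, j in [("P1", "P2"), ("P1", "P3"), ("P2", "P3")]:
            assert intelligo_protein_sim(
                chain_dag, chain_annot, base, i, j, "BP"
            ) == pytest.approx(
                intelligo_protein_sim(chain_dag, chain_annot, scaled, i, j, "BP")
            )

    def test_unannotated_missing(self, chain_dag, chain_annot):
        assert is_missing(
            intelligo_protein_sim(chain_dag, chain_annot, None, "P1", "PX", "BP")
        )


class TestWang:
    def test_chain_contributions(self, chain_dag):
        table = wang_contributions(chain_dag, "b", w_is_a=0.8)
        assert table.s_values == pytest.approx({"b": 1.0, "a": 0.8, "r": 0.64})
        assert table.sv == pytest.approx(2.44)

    def test_root_anchor(self, chain_dag):
        table = wang_contributions(chain_dag, "r")
        assert table.s_values == {"r": 1.0}
        assert table.sv == 1.0

    def test_diamond_takes_max_path(self):
        # two routes to r: 0.8*0.8 = 0.64 beats the 0.6 part_of shortcut
        dag = OntologyDAG(
            {
                "r": Term("r", aspect="BP"),
                "a": Term("a", aspect="BP", parents=[("r", "is_a")]),
                "b": Term(
                    "b", aspect="BP",
                    parents=[("a", "is_a"), ("r", "part_of")],
                ),
            }
        )
        table = wang_contributions(dag, "b", w_is_a=0.8, w_part_of=0.6)
        assert table.s_values["r"] == pytest.approx(0.64)

    def test_term_sim_hand_values(self, chain_dag):
        assert wang_term_sim(chain_dag, "b", "b") == pytest.approx(1.0)
        assert wang_term_sim(chain_dag, "b", "a") == pytest.approx(3.24 / 4.24)
        assert wang_term_sim(chain_dag, "b", "r") == pytest.approx(1.64 / 3.44)

    def test_protein_sim(self, chain_dag, chain_annot):
        assert wang_protein_sim(
            chain_dag, chain_annot, "P1", "P2", "BP"
        ) == pytest.approx(3.24 / 4.24)
        assert wang_protein_sim(
            chain_dag, chain_annot, "P3", "P1", "BP"
        ) == pytest.approx(1.64 / 3.44)

    def test_shared_term_gives_one(self, chain_dag):
        annot = AnnotationSet.from_direct(
            {"P1": {("b", "IDA"), ("a", "IEA")}, "P2": {("b", "TAS")}},
            chain_dag,
        )
        assert wang_protein_sim(chain_dag, annot, "P1", "P2", "BP") == 1.0

    def test_matches_bruteforce_on_random_dags(self):
        rng = random.Random(17)
        for _ in range(40):
            dag = random_dag(rng, rng.randint(3, 15))
            ids = sorted(dag.terms)
            m, n = rng.choice(ids), rng.choice(ids)
            assert wang_term_sim(dag, m, n) == pytest.approx(
                wang_bruteforce_sim(dag, m, n), abs=1e-12
            )


class TestSharedProperties:
    def test_symmetry_and_range_on_random_corpora(self):
        rng = random.Random(23)
        for _ in range(10):
            dag = random_dag(rng, 20)
            annot = random_annotations(rng, dag, 12)
            part = tcss_partition(dag, annot, "BP")
            proteins = sorted(annot.direct)
            for _ in range(20):
                i, j = rng.choice(proteins), rng.choice(proteins)
                for value, mirrored in [
                    (
                        wang_protein_sim(dag, annot, i, j, "BP"),
                        wang_protein_sim(dag, annot, j, i, "BP"),
                    ),
                    (
                        intelligo_protein_sim(dag, annot, None, i, j, "BP"),
                        intelligo_protein_sim(dag, annot, None, j, i, "BP"),
                    ),
                    (
                        tcss_protein_sim(part, annot, i, j),
                        tcss_protein_sim(part, annot, j, i),
                    ),
                ]:
                    assert not is_missing(value)
                    assert value == pytest.approx(mirrored)
                    assert 0.0 <= value <= 1.0
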