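import pytest

from ppipred.ontology import AnnotationSet, OntologyDAG, Term
from ppipred.synthetic import make_cocomplex_benchmark
from ppipred.topology import PPINetwork


@pytest.fixture(scope="session")
def chain_dag() -> OntologyDAG:
    """Three-term BP chain r <- a <- b (all is_a)."""
    return OntologyDAG(
        {
            "r": Term("r", name="root", aspect="BP"),
            "a": Term("a", name="mid", aspect="BP", parents=[("r", "is_a")]),
            "b": Term("b", name="leaf", aspect="BP", parents=[("a", "is_a")]),
        }
    )


@pytest.fixture(scope="session")
def chain_annot(chain_dag) -> AnnotationSet:
    """P1 -> b, P2 -> a, P3 -> r; propagation gives p(r)=1, p(a)=2/3, p(b)=1/3."""
    return AnnotationSet.from_direct(
        {
            "P1": {("b", "IDA")},
            "P2": {("a", "IDA")},
            "P3": {("r", "IDA")},
        },
        chain_dag,
    )


@pytest.fixture(scope="session")
def two_branch_dag() -> OntologyDAG:
    """Root with branches X (children x1, x2) and Y (child y1); term d has
    parents in both branches (x1 and y1)."""
    return OntologyDAG(
        {
            "r": Term("r", aspect="BP"),
            "X": Term("X", aspect="BP", parents=[("r", "is_a")]),
            "Y": Term("Y", aspect="BP", parents=[("r", "is_a")]),
            "x1": Term("x1", aspect="BP", parents=[("X", "is_a")]),
            "x2": Term("x2", aspect="BP", parents=[("X", "is_a")]),
            "y1": Term("y1", aspect="BP", parents=[("Y", "is_a")]),
            "d": Term("d", aspect="BP", parents=[("x1", "is_a"), ("y1", "part_of")]),
        }
    )


@pytest.fixture(scope="session")
def two_branch_annot(two_branch_dag) -> AnnotationSet:
    """Corpus of 4: ICA(r)=0, ICA(X)=-ln(3/4), ICA(Y)=-ln(2/4)."""
    return AnnotationSet.from_direct(
        {
            "A": {("x1", "IDA")},
            "B": {("x2", "IDA")},
            "C": {("d", "IDA")},
            "D": {("y1", "IDA")},
        },
        two_branch_dag,
    )


@pytest.fixture(scope="session")
def k4_net() -> PPINetwork:
    nodes = ["a", "b", "c", "d"]
    return PPINetwork(
        [(u, v) for i, u in enumerate(nodes) for v in nodes[i + 1 :]]
    )


@pytest.fixture(scope="session")
def star5_net() -> PPINetwork:
    return PPINetwork([("c", f"l{i}") for i in range(1, 6)])


@pytest.fixture(scope="session")
def cocomplex_bench():
    """The co-complex study benchmark: 30 complexes, sizes 5-10, coherent
    CC annotation and pathways, degree-preserving negatives."""
    return make_cocomplex_benchmark(
        n_complexes=30, size_range=(5, 10), annotation_coherence=0.9, seed=42
    )
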