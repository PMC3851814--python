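"""Protein-level GO semantic similarity: TCSS, IntelliGO and Wang.

Three measures, each computable per GO aspect:

* **TCSS** (topological clustering semantic similarity) partitions an
  aspect DAG into subgraphs by thresholding the information content of
  annotation (ICA), normalizes IC within each subgraph (ICS) and across
  the meta-graph of subgraph roots (ICM), and scores a protein pair by the
  best normalized IC of a common ancestor over all annotation term pairs.
* **IntelliGO** represents each protein as a vector over its directly
  annotated terms, with coefficients ``alpha_t = w(EC) * IAF(t)`` (evidence
  code weight times inverse annotation frequency), and scores pairs by a
  generalized cosine whose basis-term products depend on the depth of the
  max-IC common ancestor and the shortest path between the terms.
* **Wang** propagates semantic contributions down each term's ancestor
  DAG with typed edge weights (is_a / part_of) and scores term pairs by
  the contribution mass of shared ancestors; protein similarity is the max
  over annotation term pairs.

All three return a value in [0, 1] and the :data:`~ppipred.missing.MISSING`
sentinel for proteins without usable annotation in the aspect.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import networkx as nx

from .errors import DifferentAspectsError, EmptyCorpusError, UnknownTermError
from .missing import MISSING
from .ontology import (
    AnnotationSet,
    ICTable,
    OntologyDAG,
    compute_ic,
    max_ic_common_ancestor,
)

# Fraction of the aspect's maximum ICA used for the default TCSS subgraph
# threshold and root-merge tolerance (the method defines neither).
DEFAULT_TCSS_THRESHOLD_FRACTION = 0.35
DEFAULT_TCSS_MERGE_FRACTION = 0.05

DEFAULT_WANG_WEIGHTS = {"is_a": 0.8, "part_of": 0.6}


# --------------------------------------------------------------------------
# TCSS
# --------------------------------------------------------------------------


def tcss_ica(
    dag: OntologyDAG,
    annot: AnnotationSet,
    aspect: str,
    literal_children: bool = False,
) -> dict[str, float]:
    """Information content of annotation for every term of one aspect.

    ``ICA(t) = -ln(|proteins annotated to t or any descendant| / corpus)``.
    By default the descendant union is realized through the propagated
    closure (all descendants); ``literal_children=True`` restricts the
    union to direct annotations of ``t`` and its immediate children.
    """
    n_corpus = len(annot.corpus.get(aspect, ()))
    if n_corpus < 1:
        raise EmptyCorpusError(f"no proteins annotated in aspect {aspect}")
    if not literal_children:
        return dict(compute_ic(dag, annot, aspect, count="propagated").ic)
    ica = {}
    for tid in dag.aspect_terms(aspect):
        proteins = set(annot.term_proteins_direct.get(tid, ()))
        for cid in dag.children_index[tid]:
            proteins |= annot.term_proteins_direct.get(cid, set())
        if proteins:
            ica[tid] = -math.log(len(proteins) / n_corpus)
    return ica


@dataclass
class SubgraphPartition:
    """TCSS decomposition of one aspect: subgraphs, meta-graph and the
    ICA/ICS/ICM tables used by :func:`tcss_protein_sim`."""

    aspect: str
    dag: OntologyDAG
    subgraphs: list[tuple[str, frozenset[str]]]  # (root id, term set)
    membership: dict[str, set[int]]  # term -> subgraph indices (duplication)
    meta_terms: frozenset[str]
    ica: dict[str, float]
    ics: dict[tuple[int, str], float]
    icm: dict[str, float]
    ic_threshold: float
    merge_tolerance: float
    _pair_cache: dict[tuple[str, str], float] = field(
        default_factory=dict, repr=False
    )


def tcss_partition(
    dag: OntologyDAG,
    annot: AnnotationSet,
    aspect: str,
    ic_threshold: float | None = None,
    merge_tolerance: float | None = None,
    literal_children: bool = False,
) -> SubgraphPartition:
    """Partition one aspect into ICA-thresholded subgraphs plus a meta-graph.

    Subgraph roots are the maximal terms whose ICA reaches the threshold
    (no proper ancestor also reaches it); each root's subgraph is the root
    plus all its IC-bearing descendants, and a term reachable from several
    roots is duplicated into each subgraph.  Roots with ICA within
    ``merge_tolerance`` of each other (chained on the sorted ICA values)
    are merged into one subgraph.  The meta-graph consists of the subgraph
    roots together with every term above the threshold.  If no term
    reaches the threshold, a single subgraph rooted at the aspect root
    covers the whole aspect.
    """
    ica = tcss_ica(dag, annot, aspect, literal_children=literal_children)
    max_ica = max(ica.values())
    if ic_threshold is None:
        ic_threshold = DEFAULT_TCSS_THRESHOLD_FRACTION * max_ica
    if merge_tolerance is None:
        merge_tolerance = DEFAULT_TCSS_MERGE_FRACTION * max_ica
    if ic_threshold < 0:
        raise ValueError("ic_threshold must be >= 0")

    qualifying = {t for t, v in ica.items() if v >= ic_threshold}
    roots = sorted(
        t
        for t in qualifying
        if not (dag.ancestors(t, include_self=False) & qualifying)
    )
    if not roots or max_ica == 0.0:
        roots = [dag.aspect_roots[aspect]]
        groups = [roots]
    else:
        # chain-merge roots whose ICA values are within tolerance
        ordered = sorted(roots, key=lambda t: (ica[t], t))
        groups = [[ordered[0]]]
        for r in ordered[1:]:
            if ica[r] - ica[groups[-1][-1]] <= merge_tolerance:
                groups[-1].append(r)
            else:
                groups.append([r])

    subgraphs: list[tuple[str, frozenset[str]]] = []
    membership: dict[str, set[int]] = {}
    for group in groups:
        terms: set[str] = set()
        for r in group:
            terms |= {t for t in dag.descendants(r) if t in ica}
        rep = min(group, key=lambda t: (ica.get(t, 0.0), t))
        idx = len(subgraphs)
        subgraphs.append((rep, frozenset(terms)))
        for t in terms:
            membership.setdefault(t, set()).add(idx)

    ics: dict[tuple[int, str], float] = {}
    for idx, (_root, terms) in enumerate(subgraphs):
        sub_max = max(ica[t] for t in terms)
        for t in terms:
            ics[(idx, t)] = ica[t] / sub_max if sub_max > 0 else 0.0

    meta_terms = frozenset(
        {t for t, v in ica.items() if v < ic_threshold}
        | {r for group in groups for r in group}
    )
    meta_max = max(ica[t] for t in meta_terms)
    icm = {t: (ica[t] / meta_max if meta_max > 0 else 0.0) for t in meta_terms}

    return SubgraphPartition(
        aspect=aspect,
        dag=dag,
        subgraphs=subgraphs,
        membership=membership,
        meta_terms=meta_terms,
        ica=ica,
        ics=ics,
        icm=icm,
        ic_threshold=ic_threshold,
        merge_tolerance=merge_tolerance,
    )


def _tcss_term_pair(partition: SubgraphPartition, s: str, t: str) -> float:
    key = (s, t) if s <= t else (t, s)
    cached = partition._pair_cache.get(key)
    if cached is not None:
        return cached
    dag, ica = partition.dag, partition.ica
    common_all = dag.ancestors(s) & dag.ancestors(t)
    shared = partition.membership.get(s, set()) & partition.membership.get(t, set())
    score = 0.0
    if shared:
        for idx in shared:
            common = common_all & partition.subgraphs[idx][1]
            if common:
                lca = min(common, key=lambda x: (-ica[x], x))
                score = max(score, partition.ics[(idx, lca)])
    else:
        common = common_all & partition.meta_terms
        if common:
            lca = min(common, key=lambda x: (-ica[x], x))
            score = partition.icm[lca]
    partition._pair_cache[key] = score
    return score


def tcss_protein_sim(
    partition: SubgraphPartition, annot: AnnotationSet, i: str, j: str
) -> float:
    """TCSS similarity between proteins ``i`` and ``j``: the maximum over
    all annotation term pairs of the normalized IC (ICS within a shared
    subgraph, ICM on the meta-graph otherwise) of the max-IC common
    ancestor.  Returns MISSING if either protein has no usable annotation
    in the aspect."""
    dag = partition.dag
    terms_i = {
        t
        for t in annot.direct_terms(i, dag, partition.aspect)
        if t in partition.ica
    }
    terms_j = {
        t
        for t in annot.direct_terms(j, dag, partition.aspect)
        if t in partition.ica
    }
    if not terms_i or not terms_j:
        return MISSING
    best = max(
        _tcss_term_pair(partition, s, t) for s in terms_i for t in terms_j
    )
    return min(max(best, 0.0), 1.0)


# --------------------------------------------------------------------------
# IntelliGO
# --------------------------------------------------------------------------

# Evidence-code weights: experimental codes weigh full, curated and
# computational evidence 0.8, electronic (IEA) and anything unknown 0.6.
DEFAULT_EC_WEIGHTS: dict[str, float] = {
    **{ec: 1.0 for ec in ("EXP", "IDA", "IPI", "IMP", "IGI", "IEP")},
    **{
        ec: 0.8
        for ec in (
            "TAS", "IC", "ISS", "ISO", "ISA", "ISM", "IGC",
            "IBA", "IBD", "IKR", "IRD", "RCA", "NAS",
        )
    },
    "IEA": 0.6,
}
DEFAULT_EC_DEFAULT_WEIGHT = 0.6


@dataclass
class EvidenceWeightTable:
    """Evidence-code -> weight in (0, 1]; unknown codes fall back to
    ``default_weight``."""

    weights: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_EC_WEIGHTS)
    )
    default_weight: float = DEFAULT_EC_DEFAULT_WEIGHT

    def __post_init__(self):
        if self.default_weight <= 0 or any(w <= 0 for w in self.weights.values()):
            raise ValueError("evidence-code weights must be positive")

    def __getitem__(self, ec: str) -> float:
        return self.weights.get(ec, self.default_weight)


def intelligo_iaf(annot: AnnotationSet, aspect: str, t: str) -> float:
    """Inverse annotation frequency of a term:
    ``ln(corpus size / number of proteins directly annotated with t)``."""
    n_corpus = len(annot.corpus.get(aspect, ()))
    if n_corpus < 1:
        raise EmptyCorpusError(f"no proteins annotated in aspect {aspect}")
    n_t = len(annot.term_proteins_direct.get(t, ()))
    if n_t == 0:
        raise UnknownTermError(f"term {t} directly annotates no protein")
    return math.log(n_corpus / n_t)


def _intelligo_ic(dag: OntologyDAG, annot: AnnotationSet, aspect: str) -> ICTable:
    cache = getattr(annot, "_intelligo_ic_cache", None)
    if cache is None:
        cache = {}
        object.__setattr__(annot, "_intelligo_ic_cache", cache)
    if aspect not in cache:
        cache[aspect] = compute_ic(dag, annot, aspect, count="propagated")
    return cache[aspect]


def _basis_product(dag: OntologyDAG, ic: ICTable, s: str, t: str) -> float:
    """Basis-term inner product: 2*depth(maxLCA) / (minSPL + 2*depth(maxLCA)),
    with depth counted from the aspect root and minSPL the shortest
    s -> LCA -> t path length.  Identical terms give 1; terms whose only
    common ancestor is the root (depth 0) give 0."""
    if s == t:
        return 1.0
    cache = getattr(dag, "_basis_cache", None)
    if cache is None:
        cache = {}
        object.__setattr__(dag, "_basis_cache", cache)
    key = (s, t) if s <= t else (t, s)
    if key not in cache:
        lca = max_ic_common_ancestor(dag, ic, s, t)
        depth = dag.depth(lca)
        if depth == 0:
            value = 0.0
        else:
            spl = dag.upward_distance(s, lca) + dag.upward_distance(t, lca)
            value = 2.0 * depth / (spl + 2.0 * depth)
        cache[key] = value
    return cache[key]


def _intelligo_coords(
    dag: OntologyDAG,
    annot: AnnotationSet,
    ec_weights: EvidenceWeightTable,
    protein: str,
    aspect: str,
) -> dict[str, float]:
    best_ec: dict[str, float] = {}
    for tid, ec in annot.direct_pairs(protein, dag, aspect):
        w = ec_weights[ec]
        if w > best_ec.get(tid, 0.0):
            best_ec[tid] = w
    coords = {}
    for tid, w in best_ec.items():
        alpha = w * intelligo_iaf(annot, aspect, tid)
        if alpha > 0:
            coords[tid] = alpha
    return coords


def intelligo_protein_sim(
    dag: OntologyDAG,
    annot: AnnotationSet,
    ec_weights: EvidenceWeightTable | None,
    i: str,
    j: str,
    aspect: str,
) -> float:
    """IntelliGO similarity: generalized cosine between the annotation
    vectors of ``i`` and ``j``.  A protein annotated with the same term
    under several evidence codes uses the maximum code weight.  Returns
    MISSING when either protein lacks a positive-IAF direct annotation in
    the aspect."""
    if ec_weights is None:
        ec_weights = EvidenceWeightTable()
    ic = _intelligo_ic(dag, annot, aspect)
    ci = _intelligo_coords(dag, annot, ec_weights, i, aspect)
    cj = _intelligo_coords(dag, annot, ec_weights, j, aspect)
    if not ci or not cj:
        return MISSING

    def inner(a: dict[str, float], b: dict[str, float]) -> float:
        return sum(
            wa * wb * _basis_product(dag, ic, s, t)
            for s, wa in a.items()
            for t, wb in b.items()
        )

    denom = math.sqrt(inner(ci, ci) * inner(cj, cj))
    if denom == 0:
        return MISSING
    # the basis-product matrix is not guaranteed PSD; clamp the cosine
    return min(max(inner(ci, cj) / denom, 0.0), 1.0)


# --------------------------------------------------------------------------
# Wang
# --------------------------------------------------------------------------


@dataclass
class WangContributionTable:
    """Semantic contributions of every ancestor to an anchor term:
    ``s_values[n] = S_anchor(n)`` with S(anchor) = 1, and ``sv`` their sum."""

    anchor: str
    s_values: dict[str, float]
    sv: float


def wang_contributions(
    dag: OntologyDAG,
    t: str,
    w_is_a: float = DEFAULT_WANG_WEIGHTS["is_a"],
    w_part_of: float = DEFAULT_WANG_WEIGHTS["part_of"],
) -> WangContributionTable:
    """Semantic contribution table over the ancestor DAG of ``t``.

    ``S_t(t) = 1``; for an ancestor ``n``, ``S_t(n)`` is the max over
    children ``n'`` of ``n`` inside the ancestor DAG of
    ``w_edge(n' -> n) * S_t(n')``.
    """
    if not (0 < w_is_a <= 1 and 0 < w_part_of <= 1):
        raise ValueError("edge weights must lie in (0, 1]")
    t = dag.resolve(t)
    weight = {"is_a": w_is_a, "part_of": w_part_of}
    anc = dag.ancestors(t)
    g = nx.DiGraph()  # child -> parent, restricted to DAG_t
    g.add_nodes_from(anc)
    for node in anc:
        for pid, rel in dag.terms[node].parents:
            if pid in anc:
                w = weight[rel]
                if g.has_edge(node, pid):
                    w = max(w, g[node][pid]["w"])
                g.add_edge(node, pid, w=w)
    s_values = {t: 1.0}
    for node in nx.topological_sort(g):  # children before parents
        if node == t:
            continue
        s_values[node] = max(
            g[child][node]["w"] * s_values[child]
            for child, _ in g.in_edges(node)
        )
    return WangContributionTable(anchor=t, s_values=s_values, sv=sum(s_values.values()))


def _wang_table_cached(
    dag: OntologyDAG, t: str, w_is_a: float, w_part_of: float
) -> WangContributionTable:
    cache = getattr(dag, "_wang_cache", None)
    if cache is None:
        cache = {}
        object.__setattr__(dag, "_wang_cache", cache)
    key = (t, w_is_a, w_part_of)
    if key not in cache:
        cache[key] = wang_contributions(dag, t, w_is_a, w_part_of)
    return cache[key]


def wang_term_sim(
    dag: OntologyDAG,
    m: str,
    n: str,
    w_is_a: float = DEFAULT_WANG_WEIGHTS["is_a"],
    w_part_of: float = DEFAULT_WANG_WEIGHTS["part_of"],
) -> float:
    """Wang similarity between two terms of the same aspect:
    ``sum_{t in T_m ∩ T_n} (S_m(t) + S_n(t)) / (SV(m) + SV(n))``."""
    m, n = dag.resolve(m), dag.resolve(n)
    if dag.aspect_of(m) != dag.aspect_of(n):
        raise DifferentAspectsError(
            f"terms {m} and {n} belong to different aspects"
        )
    tm = _wang_table_cached(dag, m, w_is_a, w_part_of)
    tn = _wang_table_cached(dag, n, w_is_a, w_part_of)
    shared = tm.s_values.keys() & tn.s_values.keys()
    num = sum(tm.s_values[t] + tn.s_values[t] for t in shared)
    return min(num / (tm.sv + tn.sv), 1.0)  # guard the m == n ulp overshoot


def wang_protein_sim(
    dag: OntologyDAG,
    annot: AnnotationSet,
    i: str,
    j: str,
    aspect: str,
    w_is_a: float = DEFAULT_WANG_WEIGHTS["is_a"],
    w_part_of: float = DEFAULT_WANG_WEIGHTS["part_of"],
) -> float:
    """Wang similarity between proteins: the maximum term-level similarity
    over the cross product of their direct annotation sets in the aspect.
    Returns MISSING for unannotated proteins."""
    terms_i = annot.direct_terms(i, dag, aspect)
    terms_j = annot.direct_terms(j, dag, aspect)
    if not terms_i or not terms_j:
        return MISSING
    return max(
        wang_term_sim(dag, s, t, w_is_a, w_part_of)
        for s in terms_i
        for t in terms_j
    )
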