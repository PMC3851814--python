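"""Gene Ontology style DAGs, annotation sets and information content.

The three GO aspects — biological process (BP), molecular function (MF) and
cellular component (CC) — are each a rooted DAG whose edges are typed
``is_a`` or ``part_of``.  Proteins carry *direct* annotations (term +
evidence code); the true-path rule propagates each direct annotation to
every ancestor of the term.  The information content of a term is
``IC(t) = -ln p(t)`` where ``p(t)`` is the fraction of the aspect's
annotated proteins that carry ``t``.

This module provides the parsers (OBO via :mod:`obonet`, GAF 2.x), the
propagation closure, IC tables, max-IC common ancestors and transitive
reduction that the semantic-similarity measures are built on.
"""

from __future__ import annotations

import logging
import math
from collections.abc import Iterable
from dataclasses import dataclass, field

import networkx as nx
import obonet

from .errors import (
    DifferentAspectsError,
    EmptyAnnotationError,
    EmptyCorpusError,
    GafParseError,
    OboParseError,
    OntologyValidationError,
    UnknownTermError,
)

logger = logging.getLogger(__name__)

ASPECTS = ("BP", "MF", "CC")
RECOGNIZED_RELATIONS = ("is_a", "part_of")

_NAMESPACE_TO_ASPECT = {
    "biological_process": "BP",
    "molecular_function": "MF",
    "cellular_component": "CC",
}
_ASPECT_TO_GAF_CODE = {"BP": "P", "MF": "F", "CC": "C"}
_GAF_CODE_TO_ASPECT = {v: k for k, v in _ASPECT_TO_GAF_CODE.items()}


@dataclass
class Term:
    """A single ontology term.

    ``parents`` is a list of ``(parent_id, edge_type)`` with edge_type in
    ``{"is_a", "part_of"}``; other relation types are dropped at parse time.
    """

    id: str
    name: str = ""
    aspect: str = "BP"
    parents: list[tuple[str, str]] = field(default_factory=list)
    obsolete: bool = False


class OntologyDAG:
    """Typed is_a/part_of DAG spanning the three GO aspects.

    Parameters
    ----------
    terms
        Mapping term-id -> :class:`Term`.  Edges must stay within one
        aspect and must be acyclic; each aspect must have exactly one root
        (a non-obsolete term without parents).
    alt_ids
        Optional mapping of alternative (merged) ids to primary ids.
    """

    def __init__(self, terms: dict[str, Term], alt_ids: dict[str, str] | None = None):
        self.terms = terms
        self.alt_ids = dict(alt_ids or {})
        self.children_index: dict[str, set[str]] = {tid: set() for tid in terms}
        for term in terms.values():
            for pid, rel in term.parents:
                if pid not in terms:
                    raise OntologyValidationError(
                        f"term {term.id} references unknown parent {pid}"
                    )
                if terms[pid].aspect != term.aspect:
                    raise OntologyValidationError(
                        f"edge {term.id} -> {pid} crosses aspects "
                        f"({term.aspect} -> {terms[pid].aspect})"
                    )
                if rel not in RECOGNIZED_RELATIONS:
                    raise OntologyValidationError(f"unrecognized relation {rel!r}")
                self.children_index[pid].add(term.id)

        self.aspect_roots: dict[str, str] = {}
        for tid, term in terms.items():
            if term.obsolete or term.parents:
                continue
            if term.aspect in self.aspect_roots:
                raise OntologyValidationError(
                    f"aspect {term.aspect} has multiple roots: "
                    f"{self.aspect_roots[term.aspect]}, {tid}"
                )
            self.aspect_roots[term.aspect] = tid

        self._check_acyclic()
        self._ancestor_cache: dict[str, frozenset[str]] = {}
        self._depth_cache: dict[str, dict[str, int]] = {}

    # -- structure ---------------------------------------------------------

    def _check_acyclic(self) -> None:
        g = nx.DiGraph()
        g.add_nodes_from(self.terms)
        for term in self.terms.values():
            for pid, _ in term.parents:
                g.add_edge(term.id, pid)
        if not nx.is_directed_acyclic_graph(g):
            cycle = nx.find_cycle(g)
            raise OntologyValidationError(f"ontology contains a cycle: {cycle}")

    def __contains__(self, tid: str) -> bool:
        return tid in self.terms or tid in self.alt_ids

    def resolve(self, tid: str) -> str:
        """Map an id (possibly an alt_id) to its primary term id."""
        if tid in self.terms:
            return tid
        if tid in self.alt_ids:
            return self.alt_ids[tid]
        raise UnknownTermError(f"unknown term id {tid!r}")

    def aspect_of(self, tid: str) -> str:
        return self.terms[self.resolve(tid)].aspect

    def parents_of(self, tid: str) -> list[tuple[str, str]]:
        return self.terms[self.resolve(tid)].parents

    def aspect_terms(self, aspect: str) -> set[str]:
        return {tid for tid, t in self.terms.items() if t.aspect == aspect}

    def ancestors(self, tid: str, include_self: bool = True) -> frozenset[str]:
        """All terms reachable from ``tid`` by is_a/part_of edges (true-path
        closure).  The term itself is included by default."""
        tid = self.resolve(tid)
        if tid not in self._ancestor_cache:
            closure = {tid}
            stack = [tid]
            while stack:
                for pid, _ in self.terms[stack.pop()].parents:
                    if pid not in closure:
                        closure.add(pid)
                        stack.append(pid)
            self._ancestor_cache[tid] = frozenset(closure)
        anc = self._ancestor_cache[tid]
        return anc if include_self else anc - {tid}

    def descendants(self, tid: str, include_self: bool = True) -> set[str]:
        tid = self.resolve(tid)
        closure = {tid}
        stack = [tid]
        while stack:
            for cid in self.children_index[stack.pop()]:
                if cid not in closure:
                    closure.add(cid)
                    stack.append(cid)
        return closure if include_self else closure - {tid}

    def depth(self, tid: str) -> int:
        """Shortest edge count from the aspect root down to ``tid``."""
        tid = self.resolve(tid)
        aspect = self.terms[tid].aspect
        if aspect not in self._depth_cache:
            root = self.aspect_roots[aspect]
            depths = {root: 0}
            frontier = [root]
            while frontier:
                nxt = []
                for node in frontier:
                    for cid in self.children_index[node]:
                        if cid not in depths:
                            depths[cid] = depths[node] + 1
                            nxt.append(cid)
                frontier = nxt
            self._depth_cache[aspect] = depths
        try:
            return self._depth_cache[aspect][tid]
        except KeyError:
            raise UnknownTermError(
                f"term {tid} is not reachable from the {aspect} root"
            ) from None

    def upward_distance(self, tid: str, ancestor: str) -> int:
        """Shortest number of is_a/part_of edges from ``tid`` up to
        ``ancestor``; raises if ``ancestor`` is not an ancestor of ``tid``."""
        tid, ancestor = self.resolve(tid), self.resolve(ancestor)
        if ancestor == tid:
            return 0
        dist = {tid: 0}
        frontier = [tid]
        while frontier:
            nxt = []
            for node in frontier:
                for pid, _ in self.terms[node].parents:
                    if pid not in dist:
                        dist[pid] = dist[node] + 1
                        if pid == ancestor:
                            return dist[pid]
                        nxt.append(pid)
            frontier = nxt
        raise UnknownTermError(f"{ancestor} is not an ancestor of {tid}")


def parse_obo(path) -> OntologyDAG:
    """Parse an OBO 1.2/1.4 flat file into an :class:`OntologyDAG`.

    Obsolete terms are retained but flagged; ``alt_id`` lines populate the
    alt-id map; relationship types other than is_a/part_of are dropped with
    a logged warning.
    """
    try:
        graph = obonet.read_obo(path, ignore_obsolete=False)
    except Exception as exc:  # obonet raises bare ValueError on bad stanzas
        raise OboParseError(f"failed to parse OBO file {path}: {exc}") from exc

    terms: dict[str, Term] = {}
    alt_ids: dict[str, str] = {}
    dropped = 0
    for tid, data in graph.nodes(data=True):
        namespace = data.get("namespace", "biological_process")
        aspect = _NAMESPACE_TO_ASPECT.get(namespace)
        if aspect is None:
            raise OboParseError(f"term {tid}: unknown namespace {namespace!r}")
        parents = []
        for _, pid, rel in graph.out_edges(tid, keys=True):
            if rel in RECOGNIZED_RELATIONS:
                parents.append((pid, rel))
            else:
                dropped += 1
        term = Term(
            id=tid,
            name=data.get("name", ""),
            aspect=aspect,
            parents=sorted(parents),
            obsolete=data.get("is_obsolete", "false") == "true",
        )
        terms[tid] = term
        for alt in data.get("alt_id", []):
            alt_ids[alt] = tid
    if dropped:
        logger.warning(
            "dropped %d edge(s) with relations outside %s",
            dropped,
            RECOGNIZED_RELATIONS,
        )
    return OntologyDAG(terms, alt_ids)


@dataclass
class AnnotationSet:
    """Direct and propagated protein annotations.

    ``direct`` maps protein id -> set of ``(term_id, evidence_code)``;
    ``propagated`` maps protein id -> set of term ids closed under the
    true-path rule.  Evidence codes are kept on direct annotations only.
    """

    direct: dict[str, set[tuple[str, str]]]
    propagated: dict[str, set[str]]
    corpus: dict[str, set[str]]  # aspect -> proteins annotated in aspect
    term_proteins_propagated: dict[str, set[str]]  # term -> proteins (closure)
    term_proteins_direct: dict[str, set[str]]  # term -> directly annotated

    @classmethod
    def from_direct(
        cls, direct: dict[str, set[tuple[str, str]]], dag: OntologyDAG
    ) -> "AnnotationSet":
        propagated: dict[str, set[str]] = {}
        corpus: dict[str, set[str]] = {a: set() for a in ASPECTS}
        tp_prop: dict[str, set[str]] = {}
        tp_dir: dict[str, set[str]] = {}
        for protein, pairs in direct.items():
            closure: set[str] = set()
            for tid, _ec in pairs:
                closure |= dag.ancestors(tid)
                tp_dir.setdefault(tid, set()).add(protein)
                corpus[dag.aspect_of(tid)].add(protein)
            propagated[protein] = closure
            for tid in closure:
                tp_prop.setdefault(tid, set()).add(protein)
        return cls(direct, propagated, corpus, tp_prop, tp_dir)

    @property
    def corpus_size(self) -> dict[str, int]:
        return {a: len(p) for a, p in self.corpus.items()}

    def direct_terms(self, protein: str, dag: OntologyDAG, aspect: str) -> set[str]:
        return {
            tid
            for tid, _ec in self.direct.get(protein, ())
            if dag.aspect_of(tid) == aspect
        }

    def direct_pairs(
        self, protein: str, dag: OntologyDAG, aspect: str
    ) -> set[tuple[str, str]]:
        return {
            (tid, ec)
            for tid, ec in self.direct.get(protein, ())
            if dag.aspect_of(tid) == aspect
        }

    def propagated_terms(
        self, protein: str, dag: OntologyDAG, aspect: str
    ) -> set[str]:
        return {
            tid
            for tid in self.propagated.get(protein, ())
            if dag.aspect_of(tid) == aspect
        }


def parse_gaf(path, dag: OntologyDAG) -> AnnotationSet:
    """Parse a GAF 2.x file against an ontology.

    NOT-qualified rows are skipped, unknown or obsolete term ids are skipped
    with a warning, alt_ids are resolved to primary ids, and duplicate rows
    collapse (set semantics).  Raises :class:`EmptyAnnotationError` when no
    usable row remains.
    """
    direct: dict[str, set[tuple[str, str]]] = {}
    skipped_unknown = 0
    skipped_not = 0
    try:
        with open(path, encoding="utf-8") as handle:
            for lineno, raw in enumerate(handle, start=1):
                line = raw.rstrip("\r\n")
                if not line or line.startswith("!"):
                    continue
                fields = line.split("\t")
                if len(fields) < 7:
                    raise GafParseError(
                        f"{path}:{lineno}: expected >=7 tab-separated fields, "
                        f"got {len(fields)}"
                    )
                protein, qualifier, term_id, evidence = (
                    fields[1],
                    fields[3],
                    fields[4],
                    fields[6],
                )
                if "NOT" in qualifier.split("|"):
                    skipped_not += 1
                    continue
                try:
                    tid = dag.resolve(term_id)
                except UnknownTermError:
                    skipped_unknown += 1
                    continue
                if dag.terms[tid].obsolete:
                    skipped_unknown += 1
                    continue
                direct.setdefault(protein, set()).add((tid, evidence))
    except OSError as exc:
        raise GafParseError(f"cannot read GAF file {path}: {exc}") from exc
    if skipped_unknown:
        logger.warning("skipped %d row(s) with unknown/obsolete terms", skipped_unknown)
    if skipped_not:
        logger.debug("skipped %d NOT-qualified row(s)", skipped_not)
    if not direct:
        raise EmptyAnnotationError(f"no usable annotation rows in {path}")
    return AnnotationSet.from_direct(direct, dag)


@dataclass
class ICTable:
    """Per-aspect information content, ``ic(t) = -ln p(t)`` in nats.

    Terms annotating zero proteins are omitted (rather than carrying
    infinite IC); similarity code treats them as unannotated.
    """

    aspect: str
    ic: dict[str, float]

    def __contains__(self, tid: str) -> bool:
        return tid in self.ic

    def __getitem__(self, tid: str) -> float:
        return self.ic[tid]


def compute_ic(
    dag: OntologyDAG,
    annot: AnnotationSet,
    aspect: str,
    count: str = "propagated",
) -> ICTable:
    """Information content of every annotated term of one aspect.

    ``p(t)`` is the number of proteins carrying ``t`` divided by the number
    of proteins with any annotation in the aspect.  ``count`` selects
    whether term occurrence uses the propagated closure (default, the field
    standard) or direct annotations only.
    """
    if count not in ("propagated", "direct"):
        raise ValueError(f"count must be 'propagated' or 'direct', got {count!r}")
    n_corpus = len(annot.corpus.get(aspect, ()))
    if n_corpus < 1:
        raise EmptyCorpusError(f"no proteins annotated in aspect {aspect}")
    index = (
        annot.term_proteins_propagated
        if count == "propagated"
        else annot.term_proteins_direct
    )
    ic = {}
    for tid, proteins in index.items():
        if dag.aspect_of(tid) != aspect or not proteins:
            continue
        ic[tid] = -math.log(len(proteins) / n_corpus)
    return ICTable(aspect, ic)


def max_ic_common_ancestor(
    dag: OntologyDAG, ic: ICTable, t1: str, t2: str
) -> str:
    """The common ancestor of ``t1`` and ``t2`` with the highest IC.

    Each term counts as its own ancestor.  Ties break toward the
    lexicographically smallest id, making the choice deterministic.
    """
    t1, t2 = dag.resolve(t1), dag.resolve(t2)
    if dag.aspect_of(t1) != dag.aspect_of(t2):
        raise DifferentAspectsError(
            f"{t1} ({dag.aspect_of(t1)}) and {t2} ({dag.aspect_of(t2)}) "
            "share no common ancestor"
        )
    common = [t for t in dag.ancestors(t1) & dag.ancestors(t2) if t in ic]
    if not common:
        raise UnknownTermError(
            f"no IC-bearing common ancestor of {t1} and {t2} in aspect "
            f"{ic.aspect}"
        )
    return min(common, key=lambda t: (-ic[t], t))


def transitive_reduction(
    dag: OntologyDAG, term_set: Iterable[str] | None = None
) -> nx.DiGraph:
    """Transitive reduction of the DAG restricted to ``term_set``.

    Returns the smallest graph (child -> parent edges, with ``relation``
    attributes copied from the original) whose transitive closure equals
    that of the input slice.
    """
    nodes = set(term_set) if term_set is not None else set(dag.terms)
    g = nx.DiGraph()
    g.add_nodes_from(nodes)
    rel = {}
    for tid in nodes:
        for pid, edge_type in dag.terms[dag.resolve(tid)].parents:
            if pid in nodes:
                g.add_edge(tid, pid)
                rel[(tid, pid)] = edge_type
    if not nx.is_directed_acyclic_graph(g):
        raise OntologyValidationError("slice is not acyclic")
    reduced = nx.transitive_reduction(g)
    nx.set_edge_attributes(
        reduced, {e: rel[e] for e in reduced.edges}, name="relation"
    )
    return reduced
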