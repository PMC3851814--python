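"""Seeded generators for toy ontologies, annotations, pathway tables and
gold-standard PPI networks.

Two benchmark flavors mirror the statistical structure of the usual yeast
gold standards:

* **binary**: a sparse network of pairwise-measured interactions (default
  scale 1078 proteins / 1263 interactions, mean degree ~2.3) in which
  interacting pairs preferentially share deep biological-process terms —
  the aspect mechanistically tied to interaction.
* **co-complex**: disjoint protein complexes expanded to cliques (matrix
  model), where all within-complex pairs are positives, complex members
  share deep cellular-component terms and pathways, and any cross-complex
  pair has no common network neighbor at all.

Every generated object round-trips losslessly through the package's own
OBO/GAF/TSV parsers, and regeneration with the same seed and parameters
is byte-identical.
"""

from __future__ import annotations

import json
import math
import random
from dataclasses import dataclass
from pathlib import Path

from .ontology import AnnotationSet, OntologyDAG, Term, _ASPECT_TO_GAF_CODE
from .pathway import PathwayMembership
from .prediction import LabeledPairSet, canonical_pair, sample_negatives
from .topology import PPINetwork

ASPECTS = ("BP", "MF", "CC")
_ASPECT_NAMESPACE = {
    "BP": "biological_process",
    "MF": "molecular_function",
    "CC": "cellular_component",
}
_EVIDENCE_CODES = ("IDA", "IMP", "IPI", "IGI", "ISS", "TAS", "IEA")


# --------------------------------------------------------------------------
# ontology generation and serialization
# --------------------------------------------------------------------------


def make_toy_ontology(
    branching: int = 3,
    depth: int = 4,
    diamond_fraction: float = 0.1,
    part_of_fraction: float = 0.2,
    seed: int = 0,
    n_terms_per_aspect: int | None = None,
) -> OntologyDAG:
    """Three independent aspect DAGs: full ``branching``-ary trees of the
    given depth, with a ``diamond_fraction`` of terms at depth >= 2 given a
    second parent and a ``part_of_fraction`` of edges typed part_of.

    ``n_terms_per_aspect`` optionally truncates each aspect to its first
    terms in breadth-first order.
    """
    if branching < 1 or depth < 1:
        raise ValueError("branching and depth must be positive")
    rng = random.Random(seed)
    terms: dict[str, Term] = {}
    for a_idx, aspect in enumerate(ASPECTS, start=1):
        ids_by_level: list[list[str]] = []
        counter = 0

        def new_id() -> str:
            nonlocal counter
            counter += 1
            return f"GO:{a_idx}{counter:06d}"

        root = new_id()
        terms[root] = Term(root, name=f"{aspect} root", aspect=aspect)
        ids_by_level.append([root])
        total = 1
        cap = n_terms_per_aspect or math.inf
        for level in range(1, depth + 1):
            current: list[str] = []
            for parent in ids_by_level[level - 1]:
                for _ in range(branching):
                    if total >= cap:
                        break
                    tid = new_id()
                    rel = (
                        "part_of"
                        if rng.random() < part_of_fraction
                        else "is_a"
                    )
                    parents = [(parent, rel)]
                    if level >= 2 and rng.random() < diamond_fraction:
                        alt = rng.choice(ids_by_level[level - 1])
                        if alt != parent:
                            rel2 = (
                                "part_of"
                                if rng.random() < part_of_fraction
                                else "is_a"
                            )
                            parents.append((alt, rel2))
                    terms[tid] = Term(
                        tid,
                        name=f"{aspect} term {counter}",
                        aspect=aspect,
                        parents=sorted(parents),
                    )
                    current.append(tid)
                    total += 1
            ids_by_level.append(current)
    return OntologyDAG(terms)


def ontology_to_obo(dag: OntologyDAG) -> str:
    """Serialize an :class:`OntologyDAG` to OBO 1.2 text."""
    lines = ["format-version: 1.2", "ontology: synthetic-go", ""]
    for tid in sorted(dag.terms):
        term = dag.terms[tid]
        lines.append("[Term]")
        lines.append(f"id: {tid}")
        lines.append(f"name: {term.name}")
        lines.append(f"namespace: {_ASPECT_NAMESPACE[term.aspect]}")
        for pid, rel in sorted(term.parents):
            if rel == "is_a":
                lines.append(f"is_a: {pid}")
            else:
                lines.append(f"relationship: {rel} {pid}")
        if term.obsolete:
            lines.append("is_obsolete: true")
        lines.append("")
    return "\n".join(lines)


def annotations_to_gaf(annot: AnnotationSet, dag: OntologyDAG) -> str:
    """Serialize direct annotations to GAF 2.2 text (17 columns)."""
    lines = ["!gaf-version: 2.2"]
    for protein in sorted(annot.direct):
        for tid, ec in sorted(annot.direct[protein]):
            aspect_code = _ASPECT_TO_GAF_CODE[dag.aspect_of(tid)]
            fields = [
                "SYNTH", protein, protein, "", tid, "SYNTH:0000001", ec, "",
                aspect_code, "", "", "protein", "taxon:0", "20130101",
                "SYNTH", "", "",
            ]
            lines.append("\t".join(fields))
    lines.append("")
    return "\n".join(lines)


def pathways_to_tsv(pm: PathwayMembership) -> str:
    lines = []
    for protein in sorted(pm.pathways):
        for pathway in sorted(pm.pathways[protein]):
            lines.append(f"{protein}\t{pathway}")
    lines.append("")
    return "\n".join(lines)


def network_to_tsv(net: PPINetwork) -> str:
    lines = [f"{u}\t{v}" for u, v in sorted(map(sorted, net.graph.edges))]
    lines.append("")
    return "\n".join(lines)


def pairs_to_tsv(pairs) -> str:
    lines = [f"{u}\t{v}" for u, v in sorted(map(tuple, map(sorted, pairs)))]
    lines.append("")
    return "\n".join(lines)


# --------------------------------------------------------------------------
# benchmarks
# --------------------------------------------------------------------------


@dataclass
class SyntheticBenchmark:
    """A complete synthetic study: ontology, annotations, pathways, PPI
    network and labeled gold standard, reproducible from seed + params."""

    dag: OntologyDAG
    annot: AnnotationSet
    pm: PathwayMembership
    net: PPINetwork
    gold: LabeledPairSet
    seed: int
    params: dict

    def write(self, outdir) -> dict[str, Path]:
        """Write all artifacts as plain-text files; returns the path map."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        files = {
            "ontology": outdir / "ontology.obo",
            "annotations": outdir / "annotations.gaf",
            "pathways": outdir / "pathways.tsv",
            "network": outdir / "network.tsv",
            "gold_positives": outdir / "gold_positives.tsv",
            "gold_negatives": outdir / "gold_negatives.tsv",
            "params": outdir / "params.json",
        }
        files["ontology"].write_text(ontology_to_obo(self.dag))
        files["annotations"].write_text(annotations_to_gaf(self.annot, self.dag))
        files["pathways"].write_text(pathways_to_tsv(self.pm))
        files["network"].write_text(network_to_tsv(self.net))
        files["gold_positives"].write_text(pairs_to_tsv(self.gold.positives))
        files["gold_negatives"].write_text(pairs_to_tsv(self.gold.negatives))
        files["params"].write_text(
            json.dumps({"seed": self.seed, **self.params}, indent=2, sort_keys=True)
            + "\n"
        )
        return files


def _flip_labels(
    gold: LabeledPairSet, rng: random.Random, fraction: float
) -> LabeledPairSet:
    """Label-noise model: flip the sign of a random fraction of gold labels."""
    if fraction <= 0:
        return gold
    labels = gold.labels.copy()
    n_flip = int(round(fraction * len(labels)))
    for idx in rng.sample(range(len(labels)), n_flip):
        labels[idx] = -labels[idx]
    return LabeledPairSet(list(gold.pairs), labels)


def _deep_terms(dag: OntologyDAG, aspect: str) -> list[str]:
    """Terms in the deepest third of the aspect (high prospective IC)."""
    terms = sorted(dag.aspect_terms(aspect))
    max_depth = max(dag.depth(t) for t in terms)
    cutoff = math.ceil(2 * max_depth / 3)
    return [t for t in terms if dag.depth(t) >= cutoff]


def _nonroot_terms(dag: OntologyDAG, aspect: str) -> list[str]:
    root = dag.aspect_roots[aspect]
    return sorted(dag.aspect_terms(aspect) - {root})


def make_cocomplex_benchmark(
    n_complexes: int = 30,
    size_range: tuple[int, int] = (5, 10),
    annotation_coherence: float = 0.9,
    seed: int = 0,
    branching: int = 3,
    depth: int = 4,
    flip_fraction: float = 0.0,
) -> SyntheticBenchmark:
    """Co-complex gold standard: disjoint complexes rendered as cliques.

    Positives are all within-complex pairs (matrix model); negatives come
    from degree-preserving sampling and are necessarily cross-complex,
    hence share no network neighbor.  Members of one complex share a deep
    CC term and a pathway with probability ``annotation_coherence``; every
    protein additionally carries one random term per aspect.
    """
    if n_complexes < 2:
        raise ValueError("need at least 2 complexes")
    rng = random.Random(seed)
    dag = make_toy_ontology(branching=branching, depth=depth, seed=seed)
    deep_cc = _deep_terms(dag, "CC")
    noise = {a: _nonroot_terms(dag, a) for a in ASPECTS}

    complexes: list[list[str]] = []
    counter = 0
    for _ in range(n_complexes):
        size = rng.randint(*size_range)
        members = [f"P{counter + k:04d}" for k in range(size)]
        counter += size
        complexes.append(members)

    edges: list[tuple[str, str]] = []
    positives: list[tuple[str, str]] = []
    direct: dict[str, set[tuple[str, str]]] = {}
    pathways: dict[str, set[str]] = {}
    for c_idx, members in enumerate(complexes):
        for a in range(len(members)):
            for b in range(a + 1, len(members)):
                pair = canonical_pair(members[a], members[b])
                edges.append(pair)
                positives.append(pair)
        signature = rng.choice(deep_cc)
        pathway = f"path:{c_idx:03d}"
        for protein in members:
            annotations = direct.setdefault(protein, set())
            if rng.random() < annotation_coherence:
                annotations.add((signature, rng.choice(_EVIDENCE_CODES)))
            for aspect in ASPECTS:
                annotations.add(
                    (rng.choice(noise[aspect]), rng.choice(_EVIDENCE_CODES))
                )
            if rng.random() < annotation_coherence:
                pathways.setdefault(protein, set()).add(pathway)
            if rng.random() < 0.2:
                pathways.setdefault(protein, set()).add(
                    f"path:x{rng.randrange(10):02d}"
                )

    negatives = sample_negatives(positives, seed=seed + 1)
    gold = _flip_labels(
        LabeledPairSet.from_pos_neg(positives, negatives), rng, flip_fraction
    )
    params = {
        "mode": "cocomplex",
        "n_complexes": n_complexes,
        "size_range": list(size_range),
        "annotation_coherence": annotation_coherence,
        "branching": branching,
        "depth": depth,
        "flip_fraction": flip_fraction,
    }
    return SyntheticBenchmark(
        dag=dag,
        annot=AnnotationSet.from_direct(direct, dag),
        pm=PathwayMembership(pathways),
        net=PPINetwork(edges),
        gold=gold,
        seed=seed,
        params=params,
    )


def make_binary_benchmark(
    n_proteins: int = 1078,
    n_interactions: int = 1263,
    annotation_coherence: float = 0.8,
    seed: int = 0,
    branching: int = 3,
    depth: int = 4,
    flip_fraction: float = 0.0,
) -> SyntheticBenchmark:
    """Binary-interaction gold standard at the scale of the usual yeast
    two-hybrid set (1078 proteins, 1263 interactions, mean degree ~2.3).

    The network is a random spanning tree plus triangle-closing extra
    edges so that neighborhoods overlap.  Interacting pairs share a deep
    BP term with probability ``annotation_coherence`` and deep MF/CC terms
    with probability ``0.3 * annotation_coherence`` (interaction is a
    biological-process phenomenon, so BP carries most of the signal);
    pathway co-membership is enriched on edges.
    """
    max_edges = n_proteins * (n_proteins - 1) // 2
    if n_interactions > max_edges:
        raise ValueError(
            f"cannot place {n_interactions} edges among {n_proteins} proteins"
        )
    rng = random.Random(seed)
    dag = make_toy_ontology(branching=branching, depth=depth, seed=seed)
    deep = {a: _deep_terms(dag, a) for a in ASPECTS}
    noise = {a: _nonroot_terms(dag, a) for a in ASPECTS}
    proteins = [f"P{k:04d}" for k in range(n_proteins)]

    # random spanning tree (random attachment), then close triangles
    edge_set: set[tuple[str, str]] = set()
    adjacency: dict[str, set[str]] = {p: set() for p in proteins}

    def add_edge(u: str, v: str) -> None:
        edge_set.add(canonical_pair(u, v))
        adjacency[u].add(v)
        adjacency[v].add(u)

    n_tree = min(n_proteins, n_interactions + 1)
    for idx in range(1, n_tree):
        add_edge(proteins[idx], proteins[rng.randrange(idx)])
    attempts = 0
    while len(edge_set) < n_interactions and attempts < 50 * n_interactions:
        attempts += 1
        w = rng.choice(proteins)
        if len(adjacency[w]) < 2:
            continue
        u, v = rng.sample(sorted(adjacency[w]), 2)
        if canonical_pair(u, v) not in edge_set:
            add_edge(u, v)
    while len(edge_set) < n_interactions:
        u, v = rng.sample(proteins, 2)
        if canonical_pair(u, v) not in edge_set:
            add_edge(u, v)

    positives = sorted(edge_set)
    direct: dict[str, set[tuple[str, str]]] = {p: set() for p in proteins}
    pathways: dict[str, set[str]] = {}
    n_pathways = max(4, n_proteins // 25)
    for u, v in positives:
        if rng.random() < annotation_coherence:
            shared = rng.choice(deep["BP"])
            direct[u].add((shared, rng.choice(_EVIDENCE_CODES)))
            direct[v].add((shared, rng.choice(_EVIDENCE_CODES)))
        for aspect in ("MF", "CC"):
            if rng.random() < 0.3 * annotation_coherence:
                shared = rng.choice(deep[aspect])
                direct[u].add((shared, rng.choice(_EVIDENCE_CODES)))
                direct[v].add((shared, rng.choice(_EVIDENCE_CODES)))
        if rng.random() < 0.5 * annotation_coherence:
            pathway = f"path:{rng.randrange(n_pathways):03d}"
            pathways.setdefault(u, set()).add(pathway)
            pathways.setdefault(v, set()).add(pathway)
    for protein in proteins:
        for aspect in ASPECTS:
            direct[protein].add(
                (rng.choice(noise[aspect]), rng.choice(_EVIDENCE_CODES))
            )
        if rng.random() < 0.3:
            pathways.setdefault(protein, set()).add(
                f"path:{rng.randrange(n_pathways):03d}"
            )

    negatives = sample_negatives(positives, seed=seed + 1)
    gold = _flip_labels(
        LabeledPairSet.from_pos_neg(positives, negatives), rng, flip_fraction
    )
    params = {
        "mode": "binary",
        "n_proteins": n_proteins,
        "n_interactions": n_interactions,
        "annotation_coherence": annotation_coherence,
        "branching": branching,
        "depth": depth,
        "flip_fraction": flip_fraction,
    }
    return SyntheticBenchmark(
        dag=dag,
        annot=AnnotationSet.from_direct(direct, dag),
        pm=PathwayMembership(pathways),
        net=PPINetwork(positives, nodes=proteins),
        gold=gold,
        seed=seed,
        params=params,
    )
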