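"""Seeded factories and brute-force oracles shared by the test modules.

The oracles here are deliberately naive (path enumeration, DFS
reachability, pairwise counting) so they stay independent of the
implementations they check.
"""

from __future__ import annotations

import random

from ppipred.ontology import AnnotationSet, OntologyDAG, Term


def random_dag(rng: random.Random, n_terms: int, aspect: str = "BP") -> OntologyDAG:
    """Random single-aspect DAG: term k picks 1-2 parents among terms < k."""
    terms = {"T000": Term("T000", aspect=aspect)}
    ids = ["T000"]
    for k in range(1, n_terms):
        tid = f"T{k:03d}"
        n_parents = 2 if (rng.random() < 0.3 and len(ids) > 1) else 1
        parents = sorted(
            (p, rng.choice(("is_a", "part_of")))
            for p in rng.sample(ids, n_parents)
        )
        terms[tid] = Term(tid, aspect=aspect, parents=parents)
        ids.append(tid)
    return OntologyDAG(terms)


def random_annotations(
    rng: random.Random, dag: OntologyDAG, n_proteins: int, max_terms: int = 3
) -> AnnotationSet:
    evidence = ("IDA", "IMP", "ISS", "IEA", "TAS")
    ids = sorted(dag.terms)
    direct = {}
    for k in range(n_proteins):
        n = rng.randint(1, max_terms)
        direct[f"P{k:03d}"] = {
            (rng.choice(ids), rng.choice(evidence)) for _ in range(n)
        }
    return AnnotationSet.from_direct(direct, dag)


def ancestors_by_dfs(dag: OntologyDAG, tid: str) -> set[str]:
    """Reachability oracle: plain DFS over parent edges."""
    seen = set()
    stack = [tid]
    while stack:
        node = stack.pop()
        if node in seen:
            continue
        seen.add(node)
        stack.extend(pid for pid, _ in dag.terms[node].parents)
    return seen


def wang_bruteforce_svalues(
    dag: OntologyDAG, anchor: str, w_is_a: float, w_part_of: float
) -> dict[str, float]:
    """Semantic-contribution oracle: max path-weight product over every
    directed path from the anchor up to each ancestor."""
    weight = {"is_a": w_is_a, "part_of": w_part_of}
    best = {anchor: 1.0}

    def walk(node: str, product: float) -> None:
        for pid, rel in dag.terms[node].parents:
            p = product * weight[rel]
            if p > best.get(pid, 0.0):
                best[pid] = p
            walk(pid, p)

    walk(anchor, 1.0)
    return best


def wang_bruteforce_sim(
    dag: OntologyDAG, m: str, n: str, w_is_a: float = 0.8, w_part_of: float = 0.6
) -> float:
    sm = wang_bruteforce_svalues(dag, m, w_is_a, w_part_of)
    sn = wang_bruteforce_svalues(dag, n, w_is_a, w_part_of)
    shared = sm.keys() & sn.keys()
    return sum(sm[t] + sn[t] for t in shared) / (
        sum(sm.values()) + sum(sn.values())
    )


def auc_bruteforce(scores, labels) -> float:
    """Mann-Whitney oracle: count concordant pairs, half credit for ties."""
    pos = [s for s, y in zip(scores, labels) if y == 1]
    neg = [s for s, y in zip(scores, labels) if y == -1]
    total = sum(
        1.0 if p > n else (0.5 if p == n else 0.0) for p in pos for n in neg
    )
    return total / (len(pos) * len(neg))
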