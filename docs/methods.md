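# Methods

This note records the models implemented in `ppipred`, the conventions
and defaults chosen where the underlying methods leave room, and what the
synthetic benchmarks do and do not demonstrate.

## Information content and annotation propagation

A protein directly annotated to a GO term is implicitly annotated to all
of the term's ancestors (true-path rule); `AnnotationSet.from_direct`
materializes this closure over is_a and part_of edges. The probability of
a term, p(t), is the number of proteins carrying t in the propagated
closure divided by the number of proteins with at least one annotation in
the aspect — a per-protein, per-aspect denominator, not a per-annotation
one. IC(t) = −ln p(t), in nats; natural logarithms are used uniformly
across the package (the base cancels in every normalized ratio, and it
makes Adamic–Adar comparable with the standard literature definition).
`compute_ic(..., count="direct")` switches to direct-annotation counts
for users who prefer that convention; the propagated count is the default
because it is the field standard and makes IC monotone non-decreasing
from parent to child.

Terms annotating zero proteins are omitted from the IC table rather than
being assigned infinite IC; similarity code treats proteins annotated
only with such terms as unannotated (missing), which keeps every stored
value finite.

Evidence codes are retained on direct annotations only. Propagation
discards them: the only consumer of evidence codes is the IntelliGO
vector model, which is defined on direct annotations.

## TCSS

The aspect DAG is partitioned by a threshold on the information content
of annotation, ICA (identical to IC under the propagated-count
convention; a literal variant that counts only a term and its immediate
children is available as `literal_children=True`, kept because the
coarser count is sometimes seen in descriptions of the method but
under-counts deep descendants).

Subgraph roots are the *maximal* terms at or above the threshold — terms
whose ICA reaches the threshold while no proper ancestor's does; each
root's subgraph is the root plus all its IC-bearing descendants. The
description "roots are the terms below the threshold" is read
topologically (just below the cut in the DAG), which is the only reading
under which a root-plus-two-branches ontology with the threshold between
them yields two subgraphs. Roots whose ICA values lie within a merge
tolerance are grouped by chaining on the sorted ICA sequence (a
deterministic, order-independent rule). A term reachable from several
roots is duplicated into each subgraph (its `membership` set has several
indices). If no term reaches the threshold, the partition degenerates to
a single subgraph rooted at the aspect root; every pair is then
same-subgraph and the meta-graph is never consulted (its normalizer is 0
in that case and ICM is defined as identically 0).

Within a subgraph, ICS(t) = ICA(t) / max ICA over the subgraph; over the
meta-graph — the subgraph roots together with all above-threshold terms —
ICM(t) = ICA(t) / max ICA over the meta-graph. The pair score for terms
(s, t) is ICS at their max-ICA common ancestor if they share a subgraph
(max over shared subgraphs), else ICM at their max-ICA common ancestor
restricted to the meta-graph; protein similarity is the max over the two
proteins' direct annotation term pairs. Transitive reduction is exposed
as its own operation (and oracle-tested against brute-force
reachability), but the scores are computed on the original DAG restricted
to subgraph term sets: reduction preserves the transitive closure by
definition, so ancestor sets — and hence every ICS/ICM lookup — are
unchanged by it.

Defaults: the IC threshold is 0.35 × the aspect's maximum ICA and the
merge tolerance 0.05 × the maximum ICA. The method itself names no
values; these fractions put the cut well below the leaves on corpora of
the sizes we simulate while keeping a non-trivial meta-graph, and both
are arguments everywhere they appear (API and CLI config).

Ties in "common ancestor with the highest IC" break toward the
lexicographically smallest term id, making every score deterministic.

## IntelliGO

Coefficients α_t = w(EC) · IAF(t), with IAF(t) = ln(corpus size /
proteins *directly* annotated with t). When a protein carries the same
term under several evidence codes, the maximum code weight is used. The
default weight table: experimental codes (EXP, IDA, IPI, IMP, IGI, IEP)
1.0; curated/computational codes (TAS, IC, ISS, ISO, ISA, ISM, IGC, IBA,
IBD, IKR, IRD, RCA, NAS) 0.8; IEA and unknown codes 0.6. The table is
fully user-overridable; only the ratios matter, since the cosine
normalization makes the similarity invariant to a global rescaling of
the weights (property-tested).

The basis-term inner product e_s·e_t = 2·depth(LCA) / (minSPL(s,t) +
2·depth(LCA)) — depth counted in edges from the aspect root, minSPL the
shortest s→LCA→t path, LCA the max-IC common ancestor — is adopted from
the vector-space formulation of the measure's original authors; it is an
externally sourced convention, isolated in one function
(`semsim._basis_product`) so it can be swapped. Direct annotations are
used throughout (evidence codes exist only there). The resulting Gram
matrix is not guaranteed positive semidefinite, so the cosine can
overshoot 1 by a numerical epsilon on adversarial DAGs; values are
clamped to [0, 1].

## Wang

S_t(t) = 1 and S_t(n) = max over children n′ of n inside t's ancestor
DAG of w_edge(n′→n) · S_t(n′), evaluated in reverse topological order;
equivalently the best path-weight product from t up to n, which is the
brute-force oracle the tests compare against. Edge weights default to
0.8 (is_a) and 0.6 (part_of), the values conventional for this measure.
Term similarity is the shared-ancestor contribution mass normalized by
SV(m) + SV(n); protein similarity is the max over direct annotation term
pairs.

## Pathway and topology features

Pathway similarity is the Jaccard index of pathway-membership sets. A
pair in which *neither* protein has any pathway is missing (the measure
cannot work), while exactly one empty side scores 0 — being annotated to
disjoint pathway sets is evidence, being absent from the resource is
not. The same missing-versus-zero distinction applies to proteins absent
from the PPI network for the three topology features.

Adamic–Adar uses the natural log (configurable base); common neighbors
necessarily have degree ≥ 2, so the sum is always finite. When a
gold-standard pair is itself a network edge, the edge is *not* removed
before computing neighborhoods; a `mask_edge` option provides the
leave-one-out variant for users who consider self-influence a leak. The
network used is exactly the one supplied by the caller — no implicit
union of gold-standard and query edges.

## Negative sampling

Negatives are drawn over the positive-set proteins so that each
protein's incidence count among negatives equals its degree among
positives: the positive edge list is cut into stubs, shuffled, and
greedily re-paired, rejecting self-pairs, duplicates, and positive
pairs, with up to 100 restarts. Some degree sequences are unrealizable
under these constraints (a triangle is the minimal example); the sampler
then returns the largest valid set found, with a warning and a reported
shortfall, rather than silently relaxing the constraints.

## Classifier and evaluation

The SVM uses the RBF kernel with cost 1 and gamma = 1/n_features — the
library defaults of the classical implementations — behind per-column
training-median imputation and standardization; no hyperparameter search
is performed. Zero-variance columns are dropped with a warning;
all-missing columns are an error. Cross-validation is stratified (plain
k-fold can produce single-class folds on small sets), seeded, and scored
by pooling the held-out decision values of all folds into one ROC curve;
per-fold AUCs are available as an option. AUC follows the Mann–Whitney
convention with half credit for ties — stated explicitly because
heavily tied topology features (many exact zeros) make the tie rule
visible in the result. Query pairs are labeled by the sign of the
decision value at a configurable threshold (default 0); −1 on a supplied
interaction flags a likely false positive, +1 on a candidate non-edge a
potential false negative.

## Synthetic benchmarks

The generators exist so every stage of the pipeline can be exercised,
end to end, with no external database, at the statistical scale of the
usual yeast gold standards.

* The **binary** benchmark defaults to 1078 proteins and 1263
  interactions (mean degree ≈ 2.34), the scale of the classical
  high-quality yeast two-hybrid set. The network is a random spanning
  tree plus triangle-closing extra edges, so neighborhoods overlap
  modestly. Interacting pairs share a deep BP term with probability
  `annotation_coherence` (default 0.8) and deep MF/CC terms with
  probability 0.3 × coherence — encoding that interaction is primarily a
  biological-process phenomenon; every protein also carries one uniform
  noise term per aspect, and pathway co-membership is enriched on edges.
* The **co-complex** benchmark renders complexes as full cliques (the
  matrix model of complex expansion: all within-complex pairs count as
  interactions; defaults 30 complexes, sizes 5–10). Positives are all
  within-complex pairs; negatives come from the same degree-preserving
  sampler as the pipeline and are necessarily cross-complex. Complex
  members share a deep CC term and a complex-specific pathway with
  probability `annotation_coherence` (default 0.9). Coherent terms are
  drawn from the deepest third of the DAG so they carry high IC.

Toy ontologies are three independent full b-ary trees (default branching
3, depth 4, 121 terms per aspect) with a configurable fraction of
two-parent "diamond" terms and part_of edges.

The co-complex construction realizes exactly the structural mechanism
that makes topology features dominate on co-complex data: the network is
a disjoint union of cliques, so any cross-complex pair has no common
neighbor and all three topology features are identically zero, while
every within-complex pair in a clique of size s has Jaccard
(s−2)/s ≥ 0.6. Topology-only cross-validated AUC is therefore exactly
1.0, and the full 13-feature matrix stays at ≥ 0.999. This is a
mechanism reproduction, not evidence about real interactomes: the
generators model neither scale-free degree structure, nor inter-complex
edges, nor annotation bias or label noise (a label-flip option exists
but defaults to 0), so passing benchmarks show the pipeline is correct
and well-calibrated on data with known structure, not that it will reach
the same AUCs on experimental data.

Problem sizes in the test suite (e.g. 200-protein binary benchmarks for
the BP-versus-MF comparison, 30-complex co-complex studies) were chosen
to make the full suite run in a few seconds while leaving every
qualitative effect intact; the generator defaults remain at the scales
above.

## Known limitations

* Only is_a and part_of relations are honored; other GO relations are
  dropped with a warning, and OWL inputs are out of scope.
* The TCSS threshold/merge defaults are corpus-relative heuristics; on
  real GO releases users should expect to tune them.
* The IntelliGO basis product is one published convention among several;
  results are sensitive to it on shallow ontologies.
* The negative sampler guarantees degree preservation only when the
  constraint set is realizable; otherwise it reports a shortfall.
* No probability calibration, kernel search, or classifiers beyond the
  SVM; no best-match-average aggregation variants for the GO measures.
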