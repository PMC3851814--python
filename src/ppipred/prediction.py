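"""Gold-standard assembly, SVM training, cross-validation and scoring.

The prediction pipeline: degree-preserving negative sampling over the
positive gold standard, per-pair assembly of up to 13 heterogeneous
feature columns (three GO semantic similarity measures x three aspects,
KEGG co-pathway similarity, three network-topology similarities), an
RBF-kernel SVM with median imputation and standardization, stratified
k-fold cross-validation with pooled ROC/AUC, and scoring of query pairs
to flag likely false positives / recover false negatives.
"""

from __future__ import annotations

import logging
import random
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.impute import SimpleImputer
from sklearn.metrics import roc_auc_score, roc_curve
from sklearn.model_selection import StratifiedKFold
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from . import semsim, topology
from .errors import FeatureConfigError, PpipredError, SingleClassError
from .missing import MISSING
from .pathway import PathwayMembership, kegg_sim

logger = logging.getLogger(__name__)

ASPECTS = ("BP", "MF", "CC")
GO_MEASURES = ("wang", "intelligo", "tcss")
GO_FEATURES = tuple(f"{m}_{a}" for m in GO_MEASURES for a in ASPECTS)
TOPOLOGY_FEATURES = ("jaccard", "aa", "ra")
ALL_FEATURES = GO_FEATURES + ("kegg",) + TOPOLOGY_FEATURES

#: SVM defaults: RBF kernel, cost 1, gamma = 1 / n_features.
DEFAULT_SVM_PARAMS = {"kernel": "rbf", "C": 1.0, "gamma": "auto"}


def canonical_pair(i: str, j: str) -> tuple[str, str]:
    return (i, j) if i <= j else (j, i)


@dataclass
class LabeledPairSet:
    """Unordered protein pairs with +1 / -1 labels.

    Invariants: no duplicate unordered pairs; the positive and negative
    sets are disjoint.
    """

    pairs: list[tuple[str, str]]
    labels: np.ndarray

    def __post_init__(self):
        self.pairs = [canonical_pair(*p) for p in self.pairs]
        self.labels = np.asarray(self.labels, dtype=int)
        if len(self.pairs) != len(self.labels):
            raise ValueError("pairs and labels must be parallel")
        if not set(np.unique(self.labels)) <= {-1, 1}:
            raise ValueError("labels must be +1 or -1")
        if len(set(self.pairs)) != len(self.pairs):
            raise ValueError("duplicate unordered pairs in labeled set")

    @classmethod
    def from_pos_neg(cls, positives, negatives) -> "LabeledPairSet":
        pos = [canonical_pair(*p) for p in positives]
        neg = [canonical_pair(*p) for p in negatives]
        if set(pos) & set(neg):
            raise ValueError("positive and negative sets overlap")
        return cls(pos + neg, np.array([1] * len(pos) + [-1] * len(neg)))

    @property
    def positives(self) -> list[tuple[str, str]]:
        return [p for p, y in zip(self.pairs, self.labels) if y == 1]

    @property
    def negatives(self) -> list[tuple[str, str]]:
        return [p for p, y in zip(self.pairs, self.labels) if y == -1]

    def __len__(self) -> int:
        return len(self.pairs)


def sample_negatives(
    positives: list[tuple[str, str]],
    seed: int,
    max_restarts: int = 100,
) -> list[tuple[str, str]]:
    """Degree-preserving random negative pairs over the positive-set
    proteins.

    Each protein appears in the negative set exactly as often as its
    degree among the positives (edge-stub shuffling), and self-pairs,
    duplicates and positive pairs are rejected.  Deterministic given
    ``seed``.  If the constraint set is unrealizable within
    ``max_restarts`` attempts, the largest valid set found is returned
    with a warning.
    """
    if not positives:
        raise ValueError("positive set is empty")
    pos_set = {canonical_pair(*p) for p in positives}
    stubs_master: list[str] = []
    for u, v in sorted(pos_set):
        stubs_master.extend((u, v))
    rng = random.Random(seed)
    n_target = len(pos_set)
    best: list[tuple[str, str]] = []
    for _attempt in range(max_restarts):
        pool = list(stubs_master)
        rng.shuffle(pool)
        chosen: list[tuple[str, str]] = []
        chosen_set: set[tuple[str, str]] = set()
        while pool:
            u = pool.pop()
            partner_idx = None
            for idx in range(len(pool) - 1, -1, -1):
                v = pool[idx]
                if v == u:
                    continue
                key = canonical_pair(u, v)
                if key in pos_set or key in chosen_set:
                    continue
                partner_idx = idx
                break
            if partner_idx is None:
                continue  # stub u left unmatched this attempt
            key = canonical_pair(u, pool.pop(partner_idx))
            chosen.append(key)
            chosen_set.add(key)
        if len(chosen) == n_target:
            return chosen
        if len(chosen) > len(best):
            best = chosen
    warnings.warn(
        f"degree-preserving negative sampling realized only {len(best)} of "
        f"{n_target} pairs after {max_restarts} restarts; returning the "
        "best-effort set",
        stacklevel=2,
    )
    return best


@dataclass
class FeatureMatrix:
    """Per-pair feature values with an explicit missing mask (NaN)."""

    pairs: list[tuple[str, str]]
    X: pd.DataFrame

    def __post_init__(self):
        if len(self.pairs) != len(self.X):
            raise ValueError("pairs and feature rows must be parallel")

    @property
    def columns(self) -> list[str]:
        return list(self.X.columns)

    @property
    def missing_mask(self) -> pd.DataFrame:
        return self.X.isna()

    def __len__(self) -> int:
        return len(self.pairs)

    def subset(self, indices) -> "FeatureMatrix":
        return FeatureMatrix(
            [self.pairs[i] for i in indices], self.X.iloc[indices].reset_index(drop=True)
        )


def build_features(
    pairs,
    config,
    dag=None,
    annot=None,
    pm: PathwayMembership | None = None,
    net: topology.PPINetwork | None = None,
    *,
    tcss_threshold: float | None = None,
    tcss_merge_tolerance: float | None = None,
    wang_weights: dict[str, float] | None = None,
    ec_weights: semsim.EvidenceWeightTable | None = None,
    mask_edge: bool = False,
) -> FeatureMatrix:
    """Assemble the feature matrix for a pair list.

    ``config`` is an iterable of feature names drawn from
    :data:`ALL_FEATURES` (e.g. ``["wang_BP", "kegg", "jaccard"]``).  Every
    resource required by an active column must be supplied; similarities
    that cannot work for a pair are left missing (NaN).
    """
    config = list(config)
    unknown = [c for c in config if c not in ALL_FEATURES]
    if unknown:
        raise FeatureConfigError(
            f"unknown feature name(s) {unknown}; valid names: {list(ALL_FEATURES)}"
        )
    if not config:
        raise FeatureConfigError("empty feature configuration")
    pairs = [tuple(p) for p in pairs]
    wang_weights = wang_weights or dict(semsim.DEFAULT_WANG_WEIGHTS)

    go_cols = [c for c in config if c in GO_FEATURES]
    if go_cols and (dag is None or annot is None):
        raise FeatureConfigError("GO features require an ontology and annotations")
    if "kegg" in config and pm is None:
        raise FeatureConfigError("kegg feature requires a pathway membership table")
    if any(c in TOPOLOGY_FEATURES for c in config) and net is None:
        raise FeatureConfigError("topology features require a PPI network")

    partitions: dict[str, semsim.SubgraphPartition] = {}
    for col in go_cols:
        measure, aspect = col.rsplit("_", 1)
        if measure == "tcss" and aspect not in partitions:
            partitions[aspect] = semsim.tcss_partition(
                dag, annot, aspect, tcss_threshold, tcss_merge_tolerance
            )

    data: dict[str, list[float]] = {c: [] for c in config}
    topo_rows = None
    if any(c in TOPOLOGY_FEATURES for c in config):
        topo_rows = topology.topology_features(net, pairs, mask_edge=mask_edge)
    for idx, (i, j) in enumerate(pairs):
        for col in config:
            if col in GO_FEATURES:
                measure, aspect = col.rsplit("_", 1)
                if measure == "wang":
                    value = semsim.wang_protein_sim(
                        dag, annot, i, j, aspect, **{
                            "w_is_a": wang_weights["is_a"],
                            "w_part_of": wang_weights["part_of"],
                        }
                    )
                elif measure == "intelligo":
                    value = semsim.intelligo_protein_sim(
                        dag, annot, ec_weights, i, j, aspect
                    )
                else:
                    value = semsim.tcss_protein_sim(partitions[aspect], annot, i, j)
            elif col == "kegg":
                value = kegg_sim(pm, i, j)
            else:
                value = topo_rows[idx][TOPOLOGY_FEATURES.index(col)]
            data[col].append(value)
    X = pd.DataFrame(data, columns=config, dtype=float)
    return FeatureMatrix(pairs, X)


@dataclass
class TrainedClassifier:
    """Fitted SVM plus the preprocessing state needed to score new pairs.

    Imputation (per-column training medians) and standardization are part
    of the fitted pipeline, so query pairs are always filled with
    training-set statistics.
    """

    pipeline: Pipeline
    feature_names: list[str]
    used_features: list[str]
    dropped_features: list[str] = field(default_factory=list)

    @property
    def imputation_stats(self) -> dict[str, float]:
        imputer = self.pipeline.named_steps["impute"]
        return dict(zip(self.used_features, imputer.statistics_))

    @property
    def scaling_stats(self) -> dict[str, tuple[float, float]]:
        scaler = self.pipeline.named_steps["scale"]
        return {
            c: (m, s)
            for c, m, s in zip(self.used_features, scaler.mean_, scaler.scale_)
        }

    def _validate(self, X: pd.DataFrame) -> pd.DataFrame:
        if list(X.columns) != self.feature_names:
            raise PpipredError(
                f"feature columns {list(X.columns)} do not match training "
                f"columns {self.feature_names}"
            )
        return X[self.used_features]

    def decision_function(self, features: FeatureMatrix | pd.DataFrame) -> np.ndarray:
        X = features.X if isinstance(features, FeatureMatrix) else features
        if len(X) == 0:
            return np.empty(0)
        return self.pipeline.decision_function(self._validate(X).to_numpy())


def train(
    features: FeatureMatrix | pd.DataFrame,
    labels,
    svm_params: dict | None = None,
    seed: int = 0,
) -> TrainedClassifier:
    """Fit the preprocessing + RBF-SVM pipeline on labeled pairs.

    Missing values are imputed with per-column training medians, columns
    are standardized, and zero-variance columns are dropped with a
    warning.  An all-missing column or single-class labels raise.
    """
    X = features.X if isinstance(features, FeatureMatrix) else features
    y = np.asarray(labels, dtype=int)
    if len(np.unique(y)) < 2:
        raise SingleClassError("training data contains a single class")
    counts = pd.Series(y).value_counts()
    if counts.min() < 2:
        raise SingleClassError("need at least 2 samples per class")
    all_missing = [c for c in X.columns if X[c].isna().all()]
    if all_missing:
        raise PpipredError(f"column(s) entirely missing: {all_missing}")
    constant = [c for c in X.columns if X[c].dropna().nunique() <= 1]
    used = [c for c in X.columns if c not in constant]
    if constant:
        warnings.warn(
            f"dropping zero-variance column(s): {constant}", stacklevel=2
        )
    if not used:
        raise PpipredError("no informative feature column remains")
    params = dict(DEFAULT_SVM_PARAMS)
    params.update(svm_params or {})
    pipeline = Pipeline(
        [
            ("impute", SimpleImputer(strategy="median")),
            ("scale", StandardScaler()),
            ("svm", SVC(random_state=seed, **params)),
        ]
    )
    pipeline.fit(X[used].to_numpy(), y)
    return TrainedClassifier(
        pipeline=pipeline,
        feature_names=list(X.columns),
        used_features=used,
        dropped_features=constant,
    )


@dataclass
class EvaluationResult:
    """Pooled scores, ROC curve and AUC (plus CV fold bookkeeping)."""

    scores: np.ndarray
    labels: np.ndarray
    roc: list[tuple[float, float]]
    auc: float
    pairs: list[tuple[str, str]] | None = None
    fold_assignments: dict[tuple[str, str], int] | None = None
    fold_aucs: list[float] | None = None


def roc_auc(scores, labels) -> EvaluationResult:
    """ROC curve and AUC for ±1 labels.

    AUC is the Mann-Whitney probability that a random positive outscores a
    random negative, with half credit for ties; it equals the trapezoidal
    area under the threshold-swept ROC curve.
    """
    scores = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=int)
    if len(np.unique(y)) < 2:
        raise SingleClassError("ROC analysis requires both classes")
    fpr, tpr, _ = roc_curve(y == 1, scores, drop_intermediate=False)
    auc = float(roc_auc_score(y == 1, scores))
    return EvaluationResult(
        scores=scores, labels=y, roc=list(zip(fpr.tolist(), tpr.tolist())), auc=auc
    )


def cross_validate(
    features: FeatureMatrix,
    labels,
    k: int = 10,
    seed: int = 0,
    svm_params: dict | None = None,
    per_fold: bool = False,
) -> EvaluationResult:
    """Stratified seeded k-fold cross-validation with pooled ROC/AUC.

    Every pair is scored exactly once by a model not trained on it; the
    pooled decision values across folds feed one ROC curve.  With
    ``per_fold=True`` the per-fold AUCs are reported as well.
    """
    y = np.asarray(labels, dtype=int)
    n = len(features)
    if n < k:
        raise ValueError(f"need at least k={k} samples, got {n}")
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    scores = np.empty(n)
    fold_assignments: dict[tuple[str, str], int] = {}
    fold_aucs: list[float] = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)
        for fold, (tr, te) in enumerate(skf.split(np.zeros(n), y)):
            model = train(features.subset(tr), y[tr], svm_params, seed)
            scores[te] = model.decision_function(features.subset(te))
            for idx in te:
                fold_assignments[features.pairs[idx]] = fold
            if per_fold:
                fold_aucs.append(roc_auc(scores[te], y[te]).auc)
    result = roc_auc(scores, y)
    result.pairs = list(features.pairs)
    result.fold_assignments = fold_assignments
    result.fold_aucs = fold_aucs if per_fold else None
    return result


def predict_query(
    model: TrainedClassifier,
    query_features: FeatureMatrix,
    threshold: float = 0.0,
) -> dict[tuple[str, str], tuple[float, int]]:
    """Score query pairs: decision value plus ±1 label at ``threshold``.

    Query pairs labeled -1 are flagged as likely false positives; scoring
    candidate non-edges and keeping the +1 ones recovers candidate false
    negatives.  Missing features are imputed with training medians, never
    with query statistics.
    """
    if len(query_features) == 0:
        return {}
    scores = model.decision_function(query_features)
    return {
        pair: (float(s), 1 if s > threshold else -1)
        for pair, s in zip(query_features.pairs, scores)
    }
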