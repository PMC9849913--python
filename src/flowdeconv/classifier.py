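"""Stages 2-3: cluster-to-species classification.

A random forest (default 1,000 trees) learns what each species' clusters
look like from monocultures, where every cluster's label is known because
the culture was seeded with a single species. The trained forest then
assigns a species (with a class probability) to every cluster found in
co-cultures and sterile backgrounds. Features default to the
cluster's five channel means (the cluster description the classifier is
meant to learn); the mixture weight and per-channel SDs can be appended for
audit, but weight is off by default because monoculture training weights are
stereotyped by subcluster structure while co-culture weights reflect
community composition — an out-of-distribution shift that degrades exactly
the predictions the tool exists to make.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import joblib
import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier

from .clustering import Cluster, ClusterSet
from .events import CHANNELS, SPECIES

def feature_names(include_weight: bool = False, include_sd: bool = False) -> tuple[str, ...]:
    names = tuple(f"{ch} mean" for ch in CHANNELS)
    if include_weight:
        names += ("weight",)
    if include_sd:
        names += tuple(f"{ch} sd" for ch in CHANNELS)
    return names


def featurize(cluster: Cluster, include_weight: bool = False,
              include_sd: bool = False) -> np.ndarray:
    """Deterministic cluster -> feature vector mapping."""
    feats = cluster.mean.astype(float)
    if include_weight:
        feats = np.concatenate([feats, [cluster.weight]])
    if include_sd:
        feats = np.concatenate([feats, np.sqrt(np.diag(cluster.cov))])
    return feats


@dataclass(frozen=True)
class ClusterPrediction:
    sample_id: str
    cluster_index: int
    species: str
    probability: float
    weight: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.probability <= 1.0:
            raise ValueError("probability outside [0, 1]")


@dataclass
class ClusterClassifier:
    model: RandomForestClassifier
    class_labels: tuple[str, ...]
    feature_names: tuple[str, ...]
    include_weight: bool = False
    include_sd: bool = False
    training_report: dict = field(default_factory=dict)

    def save(self, path) -> None:
        joblib.dump(self, path)

    @staticmethod
    def load(path) -> "ClusterClassifier":
        return joblib.load(path)


def _feature_matrix(clustersets, include_weight: bool, include_sd: bool):
    rows, labels, meta = [], [], []
    for cs, label in clustersets:
        for i, c in enumerate(cs.clusters):
            rows.append(featurize(c, include_weight, include_sd))
            labels.append(label)
            meta.append((cs.sample_id, i, c.weight, cs.n_events_used))
    return np.asarray(rows), np.asarray(labels), meta


def train(labeled_clustersets, n_trees: int = 1000, seed: int = 0,
          include_weight: bool = False, include_sd: bool = False) -> ClusterClassifier:
    """Train the forest on labeled monoculture clusters.

    ``labeled_clustersets``: iterable of (ClusterSet, species_label). All
    clusters are used regardless of weight or cell count. Requires at least
    two classes. The training report carries out-of-bag error (when
    estimable) and impurity-based feature importances.
    """
    if n_trees < 1:
        raise ValueError("need at least one tree")
    x, y, _ = _feature_matrix(labeled_clustersets, include_weight, include_sd)
    if x.size == 0:
        raise ValueError("no clusters to train on")
    classes = sorted(set(y))
    if len(classes) < 2:
        raise ValueError(f"training requires >= 2 species, got {classes}")

    rf = RandomForestClassifier(n_estimators=n_trees, random_state=seed,
                                oob_score=len(x) >= 10, n_jobs=1)
    rf.fit(x, y)
    names = feature_names(include_weight, include_sd)
    report = {
        "n_training_clusters": int(len(x)),
        "classes": classes,
        "oob_error": float(1.0 - rf.oob_score_) if rf.oob_score else None,
        "feature_importances": dict(zip(names, rf.feature_importances_.tolist())),
    }
    return ClusterClassifier(model=rf, class_labels=tuple(rf.classes_),
                             feature_names=names, include_weight=include_weight,
                             include_sd=include_sd, training_report=report)


def predict(clf: ClusterClassifier, clusterset: ClusterSet) -> list[ClusterPrediction]:
    """One species call + probability per cluster; nothing left unassigned."""
    if not clusterset.clusters:
        return []
    x = np.asarray([featurize(c, clf.include_weight, clf.include_sd)
                    for c in clusterset.clusters])
    if x.shape[1] != len(clf.feature_names):
        raise ValueError(
            f"feature schema mismatch: model expects {len(clf.feature_names)} "
            f"features, clusters yield {x.shape[1]}"
        )
    proba = clf.model.predict_proba(x)
    best = np.argmax(proba, axis=1)
    return [
        ClusterPrediction(sample_id=clusterset.sample_id, cluster_index=i,
                          species=str(clf.class_labels[j]),
                          probability=float(proba[i, j]),
                          weight=clusterset.clusters[i].weight)
        for i, j in enumerate(best)
    ]


def class_probabilities(clf: ClusterClassifier, clusterset: ClusterSet) -> np.ndarray:
    """Full (k, n_classes) posterior matrix for a sample's clusters."""
    if not clusterset.clusters:
        return np.zeros((0, len(clf.class_labels)))
    x = np.asarray([featurize(c, clf.include_weight, clf.include_sd)
                    for c in clusterset.clusters])
    return clf.model.predict_proba(x)


@dataclass
class EvaluationReport:
    overall_error: float
    weighted_error: float
    per_species_error: dict[str, float]
    table: pd.DataFrame  # per-cluster diagnostics


def evaluate(clf: ClusterClassifier, labeled_clustersets) -> EvaluationReport:
    """Score the classifier on held-out labeled clusters.

    Reports the unweighted cluster misclassification fraction (each cluster
    counts once), a weight-weighted variant, per-species errors, and a
    per-cluster table (weight, estimated cell count, probability,
    correctness) supporting diagnostics of which clusters fail.
    """
    rows = []
    for cs, label in labeled_clustersets:
        for pred, c in zip(predict(clf, cs), cs.clusters):
            rows.append({
                "sample_id": cs.sample_id,
                "cluster_index": pred.cluster_index,
                "true_species": label,
                "predicted_species": pred.species,
                "probability": pred.probability,
                "weight": c.weight,
                "est_cell_count": c.weight * cs.n_events_used,
                "correct": pred.species == label,
            })
    if not rows:
        raise ValueError("no held-out clusters to evaluate")
    table = pd.DataFrame(rows)
    overall = float(1.0 - table["correct"].mean())
    weighted = float(
        1.0 - (table["correct"] * table["weight"]).sum() / table["weight"].sum()
    )
    per_species = {
        sp: float(1.0 - grp["correct"].mean())
        for sp, grp in table.groupby("true_species")
    }
    return EvaluationReport(overall_error=overall, weighted_error=weighted,
                            per_species_error=per_species, table=table)
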