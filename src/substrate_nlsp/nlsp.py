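"""Network-based label-space partition (NLSP) multi-label classifier.

The label space is partitioned by community detection on the label
co-occurrence graph of the training set: labels are nodes, and an edge
connects two labels whenever some training compound carries both (edge
weight = number of such compounds).  One label-powerset (LP) classifier is
fitted per community — each distinct combination of the community's labels
observed in training becomes one multiclass class — and prediction is the
union of the labelsets decoded from every community's classifier.

The RAkELd baseline (random disjoint k-labelsets) reuses the same
machinery with a random disjoint partition in place of detected
communities.

Base learners follow the scikit-learn estimator contract (``fit`` /
``predict``, optionally ``predict_proba`` for label scores); any such
classifier plugs in via the learner factory.
"""

from __future__ import annotations

import logging
import pickle
from collections import Counter
from dataclasses import dataclass, field
from typing import Callable

import networkx as nx
import numpy as np
import pandas as pd
from sklearn.ensemble import (
    ExtraTreesClassifier,
    RandomForestClassifier,
)
from sklearn.neighbors import KNeighborsClassifier
from sklearn.svm import SVC

logger = logging.getLogger(__name__)

SERIALIZATION_VERSION = 1

COMMUNITY_METHODS = ("greedy_modularity", "async_label_propagation")


def build_label_graph(Y: pd.DataFrame, weighted: bool = True) -> nx.Graph:
    """Label co-occurrence graph of a binary label matrix.

    Every label is a node (isolated labels stay as nodes); an edge joins
    labels i and j iff some row carries both, with weight the number of
    such rows (weight 1 when ``weighted`` is off).
    """
    labels = list(Y.columns)
    g = nx.Graph()
    g.add_nodes_from(labels)
    arr = Y.astype(bool).to_numpy().astype(np.int64)
    co = arr.T @ arr
    for i in range(len(labels)):
        for j in range(i + 1, len(labels)):
            w = int(co[i, j])
            if w > 0:
                g.add_edge(labels[i], labels[j], weight=w if weighted else 1)
    return g


@dataclass
class CommunityPartition:
    """A covering set of label communities (possibly intersecting)."""

    communities: list[frozenset[str]]
    method: str
    seed: int | None = None

    def __post_init__(self) -> None:
        if any(len(c) == 0 for c in self.communities):
            raise ValueError("empty community in partition")
        self.communities = [frozenset(c) for c in self.communities]

    @property
    def labels(self) -> frozenset[str]:
        out: set[str] = set()
        for c in self.communities:
            out |= c
        return frozenset(out)

    def covers(self, labels) -> bool:
        return set(labels) <= self.labels


def _canonical(communities) -> tuple[tuple[str, ...], ...]:
    return tuple(sorted(tuple(sorted(c)) for c in communities))


def detect_communities(
    g: nx.Graph, method: str = "greedy_modularity", seed: int = 0, restarts: int = 5
) -> CommunityPartition:
    """Detect label communities on a co-occurrence graph.

    ``greedy_modularity`` is the agglomerative modularity-maximisation
    search (deterministic); ``async_label_propagation`` runs ``restarts``
    seeded asynchronous label-propagation passes and keeps the partition
    occurring most often (ties broken by canonical order).  Isolated
    labels become singleton communities in either case.
    """
    if method not in COMMUNITY_METHODS:
        raise ValueError(
            f"unknown community method {method!r}; expected one of {COMMUNITY_METHODS}"
        )
    if g.number_of_nodes() == 0:
        raise ValueError("label graph has no nodes")
    isolated = [n for n in g.nodes if g.degree(n) == 0]
    core = g.subgraph([n for n in g.nodes if g.degree(n) > 0])
    comms: list[frozenset[str]] = [frozenset([n]) for n in sorted(isolated)]
    if core.number_of_nodes() > 0:
        if method == "greedy_modularity":
            found = nx.community.greedy_modularity_communities(core, weight="weight")
            comms.extend(frozenset(c) for c in found)
        else:
            runs = Counter()
            for r in range(restarts):
                found = nx.community.asyn_lpa_communities(
                    core, weight="weight", seed=seed + r
                )
                runs[_canonical(found)] += 1
            best = min(runs, key=lambda part: (-runs[part], part))
            comms.extend(frozenset(c) for c in best)
    comms = sorted(comms, key=lambda c: tuple(sorted(c)))
    return CommunityPartition(communities=comms, method=method, seed=seed)


def rakeld_partition(labels, k: int, seed: int = 0) -> CommunityPartition:
    """Random disjoint partition of the label space into k subsets.

    Subset sizes differ by at most one.  This is the RAkELd label-space
    split; feeding it to :func:`fit_nlsp` yields the RAkELd ensemble.
    """
    labels = list(labels)
    if not 1 <= k <= len(labels):
        raise ValueError(f"k={k} out of range for {len(labels)} labels")
    rng = np.random.default_rng(seed)
    order = list(rng.permutation(labels))
    comms = [frozenset(order[i::k]) for i in range(k)]
    return CommunityPartition(communities=sorted(comms, key=lambda c: tuple(sorted(c))),
                              method="rakeld", seed=seed)


def make_learner(name: str = "rf", seed: int = 0, **params) -> object:
    """Factory for the pluggable base learners.

    ``rf`` (random forest, the default engine), ``ert`` (extremely
    randomized trees), ``svm`` (RBF SVC with probability estimates) and
    ``knn1`` (1-nearest-neighbour, a memorizing learner useful in tests).
    """
    if name == "rf":
        return RandomForestClassifier(
            n_estimators=params.pop("n_estimators", 200),
            random_state=seed,
            n_jobs=1,
            **params,
        )
    if name == "ert":
        return ExtraTreesClassifier(
            n_estimators=params.pop("n_estimators", 200),
            random_state=seed,
            n_jobs=1,
            **params,
        )
    if name == "svm":
        return SVC(probability=True, random_state=seed, **params)
    if name == "knn1":
        return KNeighborsClassifier(n_neighbors=1, **params)
    raise ValueError(f"unknown learner {name!r}")


@dataclass
class LabelPowersetUnit:
    """One fitted LP classifier over a subset of labels.

    The codebook maps multiclass class ids to labelset tuples (restricted
    to this unit's labels).  The empty labelset is a legitimate class: a
    compound negative for every label of the community must be
    representable.
    """

    labels: tuple[str, ...]
    learner: object
    codebook: dict[int, tuple[str, ...]]

    def decode(self, class_id: int) -> frozenset[str]:
        return frozenset(self.codebook[int(class_id)])


def fit_label_powerset(
    X: np.ndarray, Ysub: pd.DataFrame, learner: object
) -> LabelPowersetUnit:
    """Fit one label-powerset unit on features X and a label sub-matrix."""
    if Ysub.shape[1] < 1 or len(Ysub) < 1:
        raise ValueError("label powerset needs at least one label and one sample")
    labels = tuple(Ysub.columns)
    B = Ysub.astype(bool).to_numpy()
    keys = [tuple(lab for lab, v in zip(labels, row) if v) for row in B]
    classes = sorted(set(keys))
    if len(classes) == 1:
        logger.warning(
            "single distinct labelset %r in training; unit predicts it constantly",
            classes[0],
        )
    class_of = {ls: i for i, ls in enumerate(classes)}
    y = np.array([class_of[k] for k in keys])
    learner.fit(np.asarray(X), y)
    return LabelPowersetUnit(
        labels=labels,
        learner=learner,
        codebook={i: ls for ls, i in class_of.items()},
    )


@dataclass
class NLSPModel:
    """Fitted NLSP ensemble: one LP unit per label community."""

    partition: CommunityPartition
    units: list[LabelPowersetUnit]
    label_order: tuple[str, ...]
    feature_names: tuple[str, ...] | None = None
    version: int = SERIALIZATION_VERSION
    meta: dict = field(default_factory=dict)

    @property
    def n_features(self) -> int | None:
        return len(self.feature_names) if self.feature_names is not None else None

    def save(self, path) -> None:
        with open(path, "wb") as fh:
            pickle.dump({"format": "nlsp-model", "version": self.version,
                         "model": self}, fh)

    @classmethod
    def load(cls, path) -> "NLSPModel":
        with open(path, "rb") as fh:
            payload = pickle.load(fh)
        if not isinstance(payload, dict) or payload.get("format") != "nlsp-model":
            raise ValueError(f"{path} is not an NLSP model archive")
        if payload.get("version") != SERIALIZATION_VERSION:
            raise ValueError(
                f"model archive version {payload.get('version')} not supported"
            )
        return payload["model"]


def fit_nlsp(
    X: np.ndarray,
    Y: pd.DataFrame,
    partition: CommunityPartition,
    learner_factory: Callable[[int], object],
    seed: int = 0,
    feature_names=None,
) -> NLSPModel:
    """Fit one label-powerset unit per community of the partition.

    Every unit sees the full feature matrix with the label matrix
    restricted to its community's columns.  Each unit's learner comes from
    ``learner_factory(unit_seed)`` with a seed derived deterministically
    from ``seed`` so that identical seeds give identical models.
    """
    if not partition.covers(Y.columns):
        missing = set(Y.columns) - set(partition.labels)
        raise ValueError(f"partition does not cover labels: {sorted(missing)}")
    unknown = set(partition.labels) - set(Y.columns)
    if unknown:
        raise ValueError(f"partition references unknown labels: {sorted(unknown)}")
    X = np.asarray(X)
    if X.shape[0] != len(Y):
        raise ValueError("feature matrix and label matrix are not row-aligned")
    units = []
    for i, comm in enumerate(partition.communities):
        cols = [lab for lab in Y.columns if lab in comm]
        learner = learner_factory((seed + 1000003 * (i + 1)) % (2**31 - 1))
        units.append(fit_label_powerset(X, Y[cols], learner))
    return NLSPModel(
        partition=partition,
        units=units,
        label_order=tuple(Y.columns),
        feature_names=tuple(feature_names) if feature_names is not None else None,
    )


def _check_features(model: NLSPModel, X: np.ndarray) -> np.ndarray:
    X = np.asarray(X)
    if model.n_features is not None and X.shape[1] != model.n_features:
        raise ValueError(
            f"feature width {X.shape[1]} does not match model "
            f"feature spec ({model.n_features} columns)"
        )
    return X


def predict_nlsp(model: NLSPModel, X: np.ndarray) -> pd.DataFrame:
    """Predicted label matrix: per row, the union of the labelsets decoded
    from every community's LP classifier.  Rows may be all-zero."""
    X = _check_features(model, X)
    out = np.zeros((X.shape[0], len(model.label_order)), dtype=np.int64)
    col = {lab: i for i, lab in enumerate(model.label_order)}
    for unit in model.units:
        pred = unit.learner.predict(X)
        for r, cid in enumerate(pred):
            for lab in unit.decode(cid):
                out[r, col[lab]] = 1
    return pd.DataFrame(out, columns=list(model.label_order))


def predict_label_scores(model: NLSPModel, X: np.ndarray) -> pd.DataFrame:
    """Per-label scores in [0, 1] for ranking/AUROC.

    The score of label ℓ is the maximum, over communities containing ℓ, of
    the summed class probabilities of the LP classes whose decoded
    labelset contains ℓ.  Requires base learners with ``predict_proba``.
    """
    X = _check_features(model, X)
    scores = np.zeros((X.shape[0], len(model.label_order)))
    col = {lab: i for i, lab in enumerate(model.label_order)}
    for unit in model.units:
        if not hasattr(unit.learner, "predict_proba"):
            raise AttributeError(
                f"base learner {type(unit.learner).__name__} does not expose "
                "predict_proba; label scores unavailable"
            )
        proba = unit.learner.predict_proba(X)
        fitted_classes = getattr(unit.learner, "classes_", range(proba.shape[1]))
        comm_scores = np.zeros((X.shape[0], len(model.label_order)))
        for k, cid in enumerate(fitted_classes):
            for lab in unit.decode(cid):
                comm_scores[:, col[lab]] += proba[:, k]
        scores = np.maximum(scores, comm_scores)
    return pd.DataFrame(np.clip(scores, 0.0, 1.0), columns=list(model.label_order))
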