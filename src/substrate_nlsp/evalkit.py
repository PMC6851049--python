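"""Evaluation toolkit: multi-label metrics, label-wise binary metrics,
AUROC, iterative-stratification k-fold CV, and jackknife protocols.

Multi-label performance follows Chou's five-metric convention.  With
𝕃ₖ the true labelset of sample k and 𝕃ₖ* the predicted one:

    Aiming        = mean |𝕃ₖ ∩ 𝕃ₖ*| / |𝕃ₖ*|       (precision-like)
    Coverage      = mean |𝕃ₖ ∩ 𝕃ₖ*| / |𝕃ₖ|        (recall-like)
    Accuracy      = mean |𝕃ₖ ∩ 𝕃ₖ*| / |𝕃ₖ ∪ 𝕃ₖ*|  (Jaccard)
    Absolute True = mean 1[𝕃ₖ = 𝕃ₖ*]               (exact match)
    Hamming loss  = mean |𝕃ₖ ⊝ 𝕃ₖ*| / M            (per-label error rate)

An empty predicted set contributes 0 to the aiming and accuracy terms
(the 0/0 convention).  Hamming loss divides the symmetric difference by
the number of labels M by default; ``raw=True`` leaves the per-sample
symmetric-difference count unnormalised.

Fold assignment for multi-label data uses iterative stratification:
labels are processed rarest-first and each of their remaining samples is
greedily placed into the fold that still wants most samples of that
label, keeping even rare labels represented in every fold.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Callable, Protocol, runtime_checkable

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score

logger = logging.getLogger(__name__)

BINARY_METRIC_COLUMNS = (
    "accuracy", "specificity", "sensitivity", "ccr", "f1", "auroc",
)


@dataclass
class MultiLabelMetrics:
    """Chou-style multi-label scores; all in [0, 1] except raw Hamming."""

    aiming: float
    coverage: float
    accuracy: float
    absolute_true: float
    hamming_loss: float
    n_samples: int = 0

    def as_dict(self) -> dict[str, float]:
        return {
            "aiming": self.aiming,
            "coverage": self.coverage,
            "accuracy": self.accuracy,
            "absolute_true": self.absolute_true,
            "hamming_loss": self.hamming_loss,
        }


def multilabel_metrics(
    Ytrue: pd.DataFrame, Ypred: pd.DataFrame, hamming_raw: bool = False
) -> MultiLabelMetrics:
    """Evaluate predicted against true label matrices (same shape/columns)."""
    if Ytrue.shape != Ypred.shape or list(Ytrue.columns) != list(Ypred.columns):
        raise ValueError("true and predicted label matrices must share shape and columns")
    T = Ytrue.astype(bool).to_numpy()
    P = Ypred.astype(bool).to_numpy()
    if not T.any(axis=1).all():
        raise ValueError("every true labelset must be non-empty")
    n, m = T.shape
    inter = (T & P).sum(axis=1)
    union = (T | P).sum(axis=1)
    pred_sz = P.sum(axis=1)
    true_sz = T.sum(axis=1)
    aiming = np.where(pred_sz > 0, inter / np.maximum(pred_sz, 1), 0.0)
    coverage = inter / true_sz
    accuracy = np.where(union > 0, inter / np.maximum(union, 1), 0.0)
    absolute_true = (T == P).all(axis=1).astype(float)
    symdiff = (T ^ P).sum(axis=1)
    hamming = symdiff if hamming_raw else symdiff / m
    return MultiLabelMetrics(
        aiming=float(aiming.mean()),
        coverage=float(coverage.mean()),
        accuracy=float(accuracy.mean()),
        absolute_true=float(absolute_true.mean()),
        hamming_loss=float(hamming.mean()),
        n_samples=n,
    )


@dataclass
class BinaryMetrics:
    """Confusion-count metrics for one label; CCR is balanced accuracy."""

    tp: int
    tn: int
    fp: int
    fn: int
    accuracy: float
    specificity: float
    sensitivity: float
    ccr: float
    f1: float
    auroc: float = math.nan

    def as_dict(self) -> dict[str, float]:
        return {
            "accuracy": self.accuracy,
            "specificity": self.specificity,
            "sensitivity": self.sensitivity,
            "ccr": self.ccr,
            "f1": self.f1,
            "auroc": self.auroc,
        }


def binary_metrics(ytrue, ypred) -> BinaryMetrics:
    """Standard confusion-count metrics; zero denominators give 0 with a warning."""
    t = np.asarray(ytrue).astype(bool)
    p = np.asarray(ypred).astype(bool)
    if t.shape != p.shape:
        raise ValueError("truth and prediction vectors must have equal length")
    tp = int((t & p).sum())
    tn = int((~t & ~p).sum())
    fp = int((~t & p).sum())
    fn = int((t & ~p).sum())

    def safe(num: float, den: float, name: str) -> float:
        if den == 0:
            logger.warning("zero denominator for %s; metric set to 0", name)
            return 0.0
        return num / den

    sens = safe(tp, tp + fn, "sensitivity")
    spec = safe(tn, tn + fp, "specificity")
    prec = safe(tp, tp + fp, "precision")
    f1 = safe(2 * prec * sens, prec + sens, "f1") if (prec + sens) > 0 else 0.0
    return BinaryMetrics(
        tp=tp, tn=tn, fp=fp, fn=fn,
        accuracy=(tp + tn) / max(tp + tn + fp + fn, 1),
        specificity=spec,
        sensitivity=sens,
        ccr=(sens + spec) / 2.0,
        f1=f1,
    )


def auroc(ytrue, scores) -> float:
    """Area under the ROC curve by the trapezoidal rule.

    Equals P(score⁺ > score⁻) + ½·P(score⁺ = score⁻) over all
    positive/negative pairs.  Undefined for single-class truth: returns
    NaN with a warning.
    """
    t = np.asarray(ytrue).astype(bool)
    s = np.asarray(scores, dtype=float)
    if t.shape != s.shape:
        raise ValueError("truth and score vectors must have equal length")
    if t.all() or not t.any():
        logger.warning("AUROC undefined for single-class truth; returning NaN")
        return math.nan
    return float(roc_auc_score(t.astype(int), s))


@dataclass
class FoldAssignment:
    """k disjoint sample-id folds covering the dataset."""

    folds: list[set[str]]
    seed: int
    proportions: tuple[float, ...]

    @property
    def k(self) -> int:
        return len(self.folds)

    def fold_of(self) -> dict[str, int]:
        return {sid: j for j, fold in enumerate(self.folds) for sid in fold}

    def to_frame(self) -> pd.DataFrame:
        rows = sorted(self.fold_of().items())
        return pd.DataFrame(rows, columns=["compound_id", "fold"])

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, seed: int = -1) -> "FoldAssignment":
        """Rebuild an assignment from a ``compound_id, fold`` table."""
        k = int(frame["fold"].max()) + 1
        folds: list[set[str]] = [set() for _ in range(k)]
        for row in frame.itertuples(index=False):
            folds[int(row.fold)].add(str(row.compound_id))
        return cls(folds=folds, seed=seed, proportions=tuple([1.0 / k] * k))


def iterative_stratification(
    Y: pd.DataFrame,
    k: int,
    proportions=None,
    seed: int = 0,
) -> FoldAssignment:
    """Greedy rarest-label-first multi-label fold assignment.

    Desired per-fold sizes are cⱼ = n·rⱼ and desired per-label counts
    cⱼⁱ = nᵢ·rⱼ.  While samples remain, the label with the fewest (but at
    least one) remaining samples is selected (ties broken randomly); each
    of its remaining samples goes to the fold with the largest remaining
    cⱼⁱ, ties broken by the largest remaining cⱼ and then randomly, after
    which the chosen fold's desired counts are decremented.  Samples
    without any label are placed at the end into the folds with the
    largest remaining cⱼ.
    """
    n = len(Y)
    if k < 2:
        raise ValueError("need at least k=2 folds")
    if k > n:
        raise ValueError(f"k={k} folds exceed the {n} available samples")
    if proportions is None:
        proportions = tuple([1.0 / k] * k)
    else:
        proportions = tuple(float(r) for r in proportions)
        if len(proportions) != k or not math.isclose(sum(proportions), 1.0, abs_tol=1e-9):
            raise ValueError("proportions must have length k and sum to 1")
    rng = np.random.default_rng(seed)
    labels = list(Y.columns)
    B = Y.astype(bool)
    ids = list(Y.index)

    c_fold = np.array([n * r for r in proportions], dtype=float)
    c_label = {
        lab: np.array([int(B[lab].sum()) * r for r in proportions], dtype=float)
        for lab in labels
    }
    remaining: set[str] = set(ids)
    labels_of = {sid: [lab for lab in labels if B.at[sid, lab]] for sid in ids}
    folds: list[set[str]] = [set() for _ in range(k)]

    def assign(sid: str, j: int) -> None:
        folds[j].add(sid)
        remaining.discard(sid)
        for lab in labels_of[sid]:
            c_label[lab][j] -= 1
        c_fold[j] -= 1

    while True:
        # remaining sample count per label, considering unassigned samples only
        counts = {
            lab: sum(1 for sid in remaining if B.at[sid, lab]) for lab in labels
        }
        candidates = [lab for lab in labels if counts[lab] > 0]
        if not candidates:
            break
        fewest = min(counts[lab] for lab in candidates)
        tied = [lab for lab in candidates if counts[lab] == fewest]
        lab = tied[rng.integers(len(tied))] if len(tied) > 1 else tied[0]
        members = sorted(sid for sid in remaining if B.at[sid, lab])
        for sid in members:
            want = c_label[lab]
            best = want.max()
            M = np.flatnonzero(want == best)
            if len(M) > 1:
                sizes = c_fold[M]
                M = M[np.flatnonzero(sizes == sizes.max())]
            j = int(M[rng.integers(len(M))]) if len(M) > 1 else int(M[0])
            assign(sid, j)

    # label-free samples: fold with largest remaining desired size
    for sid in sorted(remaining):
        j = int(np.argmax(c_fold + rng.random(k) * 1e-9))
        assign(sid, j)

    return FoldAssignment(folds=folds, seed=seed, proportions=proportions)


def random_folds(Y: pd.DataFrame, k: int, seed: int = 0) -> FoldAssignment:
    """Naive unstratified random folds of near-equal size (baseline)."""
    rng = np.random.default_rng(seed)
    ids = list(Y.index)
    order = rng.permutation(len(ids))
    folds: list[set[str]] = [set() for _ in range(k)]
    for pos, idx in enumerate(order):
        folds[pos % k].add(ids[idx])
    return FoldAssignment(folds=folds, seed=seed, proportions=tuple([1.0 / k] * k))


def fold_label_deviation(Y: pd.DataFrame, assignment: FoldAssignment) -> float:
    """Mean absolute deviation of per-label fold proportions from target.

    For each label i and fold j, compares the fraction of label-i samples
    landing in fold j with the desired proportion rⱼ; averages the
    absolute deviation over all labels with at least one sample.
    """
    B = Y.astype(bool)
    devs = []
    fold_sets = assignment.folds
    for lab in Y.columns:
        n_lab = int(B[lab].sum())
        if n_lab == 0:
            continue
        pos = set(B.index[B[lab]])
        for j, fold in enumerate(fold_sets):
            frac = len(pos & fold) / n_lab
            devs.append(abs(frac - assignment.proportions[j]))
    return float(np.mean(devs))


@runtime_checkable
class TrainablePipeline(Protocol):
    """Protocol for objects the evaluation protocols can train and query.

    ``fit`` receives the training compound ids; ``predict`` returns a
    binary label DataFrame indexed like the requested ids.  An optional
    ``predict_scores`` returning per-label real scores enables AUROC.
    """

    def fit(self, train_ids: list[str]) -> None: ...

    def predict(self, ids: list[str]) -> pd.DataFrame: ...


def _per_label_metrics(
    Ytrue: pd.DataFrame,
    Ypred: pd.DataFrame,
    scores: pd.DataFrame | None,
) -> pd.DataFrame:
    rows = {}
    for lab in Ytrue.columns:
        bm = binary_metrics(Ytrue[lab], Ypred[lab])
        if scores is not None and Ytrue[lab].astype(bool).nunique() > 1:
            bm.auroc = auroc(Ytrue[lab], scores[lab])
        rows[lab] = bm.as_dict()
    return pd.DataFrame(rows).T[list(BINARY_METRIC_COLUMNS)]


@dataclass
class EvaluationResult:
    """Pooled multi-label metrics plus the per-label binary-metric table."""

    multilabel: MultiLabelMetrics
    per_label: pd.DataFrame
    predictions: pd.DataFrame | None = None
    details: dict = field(default_factory=dict)


def jackknife(
    make_pipeline: Callable[[], TrainablePipeline],
    Y: pd.DataFrame,
) -> EvaluationResult:
    """Leave-one-out evaluation: each compound is held out once.

    Every round trains a fresh pipeline on the other n−1 compounds (the
    pipeline is responsible for re-encoding features without the held-out
    compound) and predicts the held-out one; pooled predictions are
    scored once at the end.
    """
    ids = list(Y.index)
    if len(ids) < 2:
        raise ValueError("jackknife needs at least 2 samples")
    preds = []
    scores = []
    have_scores = True
    for round_idx, held in enumerate(ids):
        train = [sid for sid in ids if sid != held]
        try:
            pipe = make_pipeline()
            pipe.fit(train)
            preds.append(pipe.predict([held]))
            if have_scores and hasattr(pipe, "predict_scores"):
                scores.append(pipe.predict_scores([held]))
            else:
                have_scores = False
        except Exception as exc:
            raise RuntimeError(
                f"jackknife round {round_idx} (held-out {held!r}) failed: {exc}"
            ) from exc
    Ypred = pd.concat(preds).loc[ids]
    Sc = pd.concat(scores).loc[ids] if have_scores and scores else None
    ml = multilabel_metrics(Y, Ypred)
    return EvaluationResult(
        multilabel=ml,
        per_label=_per_label_metrics(Y, Ypred, Sc),
        predictions=Ypred,
        details={"protocol": "jackknife", "rounds": len(ids)},
    )


def repeated_stratified_cv(
    make_pipeline: Callable[[], TrainablePipeline],
    Y: pd.DataFrame,
    k: int = 10,
    repeats: int = 10,
    seed: int = 0,
) -> EvaluationResult:
    """Repeated k-fold iterative-stratification cross-validation.

    Per repeat, folds come from :func:`iterative_stratification` with a
    derived seed; each fold is predicted by a pipeline trained on the
    remaining folds (features re-encoded on the training split only).
    Per-label metrics are averaged over all folds and repeats; the pooled
    multi-label metrics are averaged over repeats.  AUROC for a label is
    skipped (with a warning) in folds where its truth is single-class.
    """
    ids = list(Y.index)
    per_fold_tables = []
    ml_per_repeat = []
    fold_assignments = []
    for rep in range(repeats):
        rep_seed = (seed + 7919 * rep) % (2**31 - 1)
        assignment = iterative_stratification(Y, k=k, seed=rep_seed)
        fold_assignments.append(assignment)
        rep_preds = []
        rep_scores = []
        have_scores = True
        for fold in assignment.folds:
            test = sorted(fold)
            if not test:
                continue
            train = [sid for sid in ids if sid not in fold]
            pipe = make_pipeline()
            pipe.fit(train)
            pred = pipe.predict(test)
            rep_preds.append(pred)
            sc = None
            if have_scores and hasattr(pipe, "predict_scores"):
                sc = pipe.predict_scores(test)
                rep_scores.append(sc)
            else:
                have_scores = False
            per_fold_tables.append(
                _per_label_metrics(Y.loc[test], pred, sc)
            )
        Ypred = pd.concat(rep_preds).loc[ids]
        ml_per_repeat.append(multilabel_metrics(Y, Ypred))
    per_label = (
        pd.concat(per_fold_tables)
        .groupby(level=0)
        .mean()  # NaN AUROC folds are skipped by the mean
        .loc[list(Y.columns), list(BINARY_METRIC_COLUMNS)]
    )
    ml_mean = MultiLabelMetrics(
        aiming=float(np.mean([m.aiming for m in ml_per_repeat])),
        coverage=float(np.mean([m.coverage for m in ml_per_repeat])),
        accuracy=float(np.mean([m.accuracy for m in ml_per_repeat])),
        absolute_true=float(np.mean([m.absolute_true for m in ml_per_repeat])),
        hamming_loss=float(np.mean([m.hamming_loss for m in ml_per_repeat])),
        n_samples=len(ids),
    )
    return EvaluationResult(
        multilabel=ml_mean,
        per_label=per_label,
        details={
            "protocol": f"{repeats}x{k}-fold stratified CV",
            "fold_assignments": fold_assignments,
            "multilabel_per_repeat": ml_per_repeat,
        },
    )
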