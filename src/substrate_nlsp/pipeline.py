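"""End-to-end pipeline: featurize substrates, fit NLSP, predict labels.

The feature vector of a compound has 2·M columns for M transporter
classes: a structural block (per-class maximum average-Tanimoto
similarity to the class's training substrates) followed by a semantic
block (per-class maximum Lin similarity between ontology annotations).
All encoding state — class subsets, the information-content table — is
derived from the training split only, so held-out compounds never leak
into their own features.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .chemstruct import encode_structural_many
from .dataset import SubstrateDataset
from .nlsp import (
    CommunityPartition,
    NLSPModel,
    build_label_graph,
    detect_communities,
    fit_nlsp,
    make_learner,
    predict_label_scores,
    predict_nlsp,
    rakeld_partition,
)
from .ontosem import ICTable, compute_ic, encode_semantic_many

logger = logging.getLogger(__name__)


def feature_names(labels) -> list[str]:
    """Column layout of the 2·M feature matrix: str_<label> then sem_<label>."""
    return [f"str_{lab}" for lab in labels] + [f"sem_{lab}" for lab in labels]


@dataclass
class NLSPPipeline:
    """Trainable predictor satisfying the evaluation protocols.

    Parameters mirror the method's tunables: the fingerprint types
    averaged in the structural block, the community-detection method and
    whether the co-occurrence graph is weighted, and the pluggable base
    learner (random forest by default).  ``partition`` may be supplied
    explicitly (e.g. from :func:`~substrate_nlsp.nlsp.rakeld_partition`)
    to bypass community detection.
    """

    dataset: SubstrateDataset
    fp_types: tuple[str, ...] | None = None
    community_method: str = "greedy_modularity"
    weighted_graph: bool = True
    learner: str = "rf"
    learner_params: dict = field(default_factory=dict)
    partition: CommunityPartition | None = None
    rakeld_k: int | None = None
    ic_table: ICTable | None = None
    exclude_self: bool = True
    seed: int = 0

    model: NLSPModel | None = None

    def __post_init__(self) -> None:
        if self.fp_types is None:
            self.fp_types = tuple(self.dataset.fp_types)

    # -- featurization -------------------------------------------------

    def _encode(self, ids, subsets, ic: ICTable | None) -> np.ndarray:
        records = self.dataset.records(ids)
        X_str = encode_structural_many(
            records,
            subsets,
            self.dataset.compounds,
            self.fp_types,
            exclude_self=self.exclude_self,
        )
        if self.dataset.dag is not None and ic is not None:
            X_sem = encode_semantic_many(
                records,
                subsets,
                self.dataset.compounds,
                self.dataset.dag,
                ic,
                exclude_self=self.exclude_self,
            )
        else:
            X_sem = np.zeros_like(X_str)
        return np.hstack([X_str, X_sem])

    def featurize(self, ids, train_ids=None) -> pd.DataFrame:
        """2·M-column feature frame for ``ids`` against training subsets.

        ``train_ids`` defaults to the whole dataset; pass the training
        split during cross-validation so encodings never see held-out
        compounds.
        """
        subsets = self.dataset.subsets(train_ids)
        ic = self._fit_ic(train_ids)
        X = self._encode(list(ids), subsets, ic)
        return pd.DataFrame(
            X, index=list(ids), columns=feature_names(self.dataset.label_names)
        )

    def _fit_ic(self, train_ids) -> ICTable | None:
        if self.dataset.dag is None:
            return None
        if self.ic_table is not None:
            return self.ic_table
        ann = self.dataset.annotations(train_ids)
        if not ann:
            logger.warning("no ontology annotations; semantic block will be zero")
            return None
        return compute_ic(self.dataset.dag, ann)

    # -- training / prediction -----------------------------------------

    def fit(self, train_ids) -> "NLSPPipeline":
        train_ids = list(train_ids)
        Y = self.dataset.labels.loc[train_ids]
        self._subsets = self.dataset.subsets(train_ids)
        self._ic = self._fit_ic(train_ids)
        X = self._encode(train_ids, self._subsets, self._ic)
        if self.partition is not None:
            partition = self.partition
        elif self.rakeld_k is not None:
            partition = rakeld_partition(Y.columns, self.rakeld_k, seed=self.seed)
        else:
            g = build_label_graph(Y, weighted=self.weighted_graph)
            partition = detect_communities(
                g, method=self.community_method, seed=self.seed
            )
        factory = lambda s: make_learner(  # noqa: E731
            self.learner, seed=s, **dict(self.learner_params)
        )
        self.model = fit_nlsp(
            X,
            Y,
            partition,
            factory,
            seed=self.seed,
            feature_names=feature_names(self.dataset.label_names),
        )
        return self

    def _require_model(self) -> NLSPModel:
        if self.model is None:
            raise RuntimeError("pipeline is not fitted; call fit() first")
        return self.model

    def predict(self, ids) -> pd.DataFrame:
        model = self._require_model()
        X = self._encode(list(ids), self._subsets, self._ic)
        pred = predict_nlsp(model, X)
        pred.index = list(ids)
        return pred

    def predict_scores(self, ids) -> pd.DataFrame:
        model = self._require_model()
        X = self._encode(list(ids), self._subsets, self._ic)
        scores = predict_label_scores(model, X)
        scores.index = list(ids)
        return scores
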