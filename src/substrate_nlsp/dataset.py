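"""In-memory container binding compounds, labels and ontology together."""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .chemstruct import CANONICAL_FP_TYPES, ClassSubsets, CompoundRecord
from .ontosem import OntologyDAG


@dataclass
class SubstrateDataset:
    """Compounds with fingerprints, a binary label matrix and an optional
    ontology.

    ``labels`` is indexed by compound id with one 0/1 column per
    transporter class; every label-matrix row must reference a known
    compound.
    """

    compounds: dict[str, CompoundRecord]
    labels: pd.DataFrame
    dag: OntologyDAG | None = None
    fp_types: tuple[str, ...] = CANONICAL_FP_TYPES
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        unknown = [i for i in self.labels.index if i not in self.compounds]
        if unknown:
            raise ValueError(
                f"label matrix references unknown compound ids: {unknown[:5]}"
                + ("..." if len(unknown) > 5 else "")
            )
        if self.labels.index.has_duplicates:
            raise ValueError("duplicate compound ids in label matrix")

    @property
    def n_compounds(self) -> int:
        return len(self.labels)

    @property
    def label_names(self) -> list[str]:
        return list(self.labels.columns)

    def subsets(self, ids=None) -> ClassSubsets:
        """Transporter class subsets, optionally restricted to a split."""
        Y = self.labels if ids is None else self.labels.loc[list(ids)]
        return ClassSubsets.from_label_frame(Y)

    def annotations(self, ids=None) -> dict[str, str]:
        """compound id → ontology term, for annotated compounds only."""
        universe = self.labels.index if ids is None else ids
        out = {}
        for cid in universe:
            term = self.compounds[cid].ontology_term
            if term is not None:
                out[cid] = term
        return out

    def records(self, ids) -> list[CompoundRecord]:
        return [self.compounds[cid] for cid in ids]
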