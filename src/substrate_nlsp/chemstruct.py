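"""Fingerprint-based structural similarity and per-class feature encoding.

Substrate structures are represented by binary substructure fingerprints
(canonically MACCS, FP2, FP3 and FP4 as produced by Open Babel).  Pairwise
similarity is the Tanimoto coefficient averaged over the available
fingerprint types, and each compound is featurized against a set of
transporter substrate classes by its *maximum* average similarity to the
members of each class.

Fingerprint bit-vectors are opaque to this module: generating them is the
job of an external tool (or the synthetic generator); here they are only
compared.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Fingerprint types used by default when a dataset carries all four.
CANONICAL_FP_TYPES = ("MACCS", "FP2", "FP3", "FP4")


@dataclass(frozen=True)
class Fingerprint:
    """A named binary substructure fingerprint.

    Parameters
    ----------
    fp_type : str
        Fingerprint family name.  The set is open; ``MACCS``, ``FP2``,
        ``FP3`` and ``FP4`` are the canonical members.
    bits : numpy.ndarray
        Boolean vector of fixed length (> 0).  Length must be constant
        across a dataset for a given ``fp_type``.
    """

    fp_type: str
    bits: np.ndarray

    def __post_init__(self) -> None:
        arr = np.asarray(self.bits, dtype=bool)
        if arr.ndim != 1 or arr.size == 0:
            raise ValueError("fingerprint bits must be a non-empty 1-D vector")
        object.__setattr__(self, "bits", arr)

    def __len__(self) -> int:
        return int(self.bits.size)

    @classmethod
    def from_hex(cls, fp_type: str, hex_bits: str, n_bits: int) -> "Fingerprint":
        """Decode a big-endian, left-padded hex string into a fingerprint."""
        n_hex = (n_bits + 3) // 4
        s = hex_bits.strip().lower().removeprefix("0x").zfill(n_hex)
        if len(s) > n_hex:
            raise ValueError(
                f"hex string of {len(s)} digits cannot encode {n_bits} bits"
            )
        value = int(s, 16)
        bits = np.zeros(n_bits, dtype=bool)
        for i in range(n_bits):
            # bit 0 is the most significant bit of the padded hex string
            bits[i] = (value >> (n_bits - 1 - i)) & 1
        return cls(fp_type, bits)

    def to_hex(self) -> str:
        value = 0
        for b in self.bits:
            value = (value << 1) | int(b)
        n_hex = (len(self) + 3) // 4
        return format(value, f"0{n_hex}x")


@dataclass
class CompoundRecord:
    """One substrate compound.

    ``smiles`` may be empty when precomputed fingerprints are supplied;
    ``ontology_term`` is the optional ChEBI-style annotation used by the
    semantic-similarity features.
    """

    id: str
    smiles: str = ""
    fingerprints: dict[str, Fingerprint] = field(default_factory=dict)
    ontology_term: str | None = None

    def fingerprint(self, fp_type: str) -> Fingerprint:
        try:
            return self.fingerprints[fp_type]
        except KeyError:
            raise KeyError(
                f"compound {self.id!r} lacks fingerprint type {fp_type!r}"
            ) from None


@dataclass
class ClassSubsets:
    """Ordered transporter classes and their member compound ids.

    A compound may appear in several subsets (the task is multi-label).
    """

    labels: list[str]
    members: dict[str, set[str]]

    def __post_init__(self) -> None:
        if len(self.labels) < 1:
            raise ValueError("need at least one class label")
        for lab in self.labels:
            self.members.setdefault(lab, set())

    @classmethod
    def from_label_frame(cls, Y: pd.DataFrame) -> "ClassSubsets":
        """Build subsets from a binary label matrix (rows = compound ids)."""
        labels = list(Y.columns)
        members = {
            lab: set(Y.index[Y[lab].astype(bool)]) for lab in labels
        }
        return cls(labels=labels, members=members)

    def restrict_to(self, ids: set[str]) -> "ClassSubsets":
        """Subsets intersected with a compound-id universe (e.g. a training split)."""
        return ClassSubsets(
            labels=list(self.labels),
            members={lab: self.members[lab] & ids for lab in self.labels},
        )


def tanimoto(fp_a: Fingerprint, fp_b: Fingerprint) -> float:
    """Tanimoto coefficient c / (a + b - c) between two fingerprints.

    ``a`` and ``b`` are the set-bit counts of each fingerprint and ``c``
    the number of shared set bits.  Two all-zero fingerprints share no
    substructure evidence; that 0/0 case is defined as 0 (with a warning).
    """
    if fp_a.fp_type != fp_b.fp_type:
        raise ValueError(
            f"fingerprint type mismatch: {fp_a.fp_type!r} vs {fp_b.fp_type!r}"
        )
    if len(fp_a) != len(fp_b):
        raise ValueError(
            f"fingerprint length mismatch for {fp_a.fp_type!r}: "
            f"{len(fp_a)} vs {len(fp_b)}"
        )
    a = int(fp_a.bits.sum())
    b = int(fp_b.bits.sum())
    c = int((fp_a.bits & fp_b.bits).sum())
    if a == 0 and b == 0:
        logger.warning(
            "Tanimoto of two all-zero %s fingerprints; returning 0", fp_a.fp_type
        )
        return 0.0
    return c / (a + b - c)


def average_similarity(
    c_a: CompoundRecord, c_b: CompoundRecord, fp_types: list[str] | tuple[str, ...]
) -> float:
    """Arithmetic mean of Tanimoto coefficients over the requested types."""
    if not fp_types:
        raise ValueError("fp_types must not be empty")
    return float(
        np.mean(
            [tanimoto(c_a.fingerprint(t), c_b.fingerprint(t)) for t in fp_types]
        )
    )


def _bit_matrix(
    compounds: list[CompoundRecord], fp_type: str
) -> np.ndarray:
    """Stack one fingerprint type into an (n_compounds, n_bits) bool matrix."""
    rows = [c.fingerprint(fp_type).bits for c in compounds]
    lengths = {r.size for r in rows}
    if len(lengths) > 1:
        raise ValueError(
            f"inconsistent {fp_type!r} fingerprint lengths in dataset: {sorted(lengths)}"
        )
    return np.stack(rows)


def bulk_average_similarity(
    queries: list[CompoundRecord],
    targets: list[CompoundRecord],
    fp_types: list[str] | tuple[str, ...],
) -> np.ndarray:
    """Average-Tanimoto matrix between two compound lists, vectorised.

    Returns an array of shape ``(len(queries), len(targets))``.  Equivalent
    to calling :func:`average_similarity` for every pair but computed with
    matrix products over the packed bit matrices.
    """
    if not fp_types:
        raise ValueError("fp_types must not be empty")
    out = np.zeros((len(queries), len(targets)))
    for t in fp_types:
        Q = _bit_matrix(queries, t).astype(np.float64)
        T = _bit_matrix(targets, t).astype(np.float64)
        if Q.shape[1] != T.shape[1]:
            raise ValueError(f"fingerprint length mismatch for {t!r}")
        shared = Q @ T.T
        a = Q.sum(axis=1)[:, None]
        b = T.sum(axis=1)[None, :]
        denom = a + b - shared
        with np.errstate(invalid="ignore", divide="ignore"):
            tc = np.where(denom > 0, shared / denom, 0.0)
        if np.any(denom == 0):
            logger.warning(
                "all-zero %s fingerprint pair(s) encountered; similarity set to 0", t
            )
        out += tc
    return out / len(fp_types)


def encode_structural(
    query: CompoundRecord,
    subsets: ClassSubsets,
    dataset: dict[str, CompoundRecord],
    fp_types: list[str] | tuple[str, ...] = CANONICAL_FP_TYPES,
    exclude_self: bool = True,
) -> np.ndarray:
    """Per-class maximum structural similarity feature vector.

    Component *i* is the maximum average fingerprint similarity between the
    query and the member substrates of class *i*.  With ``exclude_self``
    (the default, appropriate when featurizing training compounds) the
    query's own id is removed from each class first, so that membership
    does not leak a trivial 1.0.
    """
    return encode_structural_many(
        [query], subsets, dataset, fp_types, exclude_self=exclude_self
    )[0]


def encode_structural_many(
    queries: list[CompoundRecord],
    subsets: ClassSubsets,
    dataset: dict[str, CompoundRecord],
    fp_types: list[str] | tuple[str, ...] = CANONICAL_FP_TYPES,
    exclude_self: bool = True,
) -> np.ndarray:
    """Vectorised :func:`encode_structural` for many queries (rows)."""
    member_ids = sorted(set().union(*subsets.members.values())) if subsets.members else []
    for mid in member_ids:
        if mid not in dataset:
            raise KeyError(f"class member {mid!r} not found in dataset")
    targets = [dataset[m] for m in member_ids]
    col_of = {m: j for j, m in enumerate(member_ids)}
    if targets:
        sim = bulk_average_similarity(queries, targets, fp_types)
    else:
        sim = np.zeros((len(queries), 0))
    out = np.zeros((len(queries), len(subsets.labels)))
    for i, lab in enumerate(subsets.labels):
        for qi, q in enumerate(queries):
            ids = subsets.members[lab]
            if exclude_self:
                ids = ids - {q.id}
            if not ids:
                logger.warning(
                    "class %r empty%s for query %r; structural feature set to 0",
                    lab,
                    " after self-exclusion" if exclude_self else "",
                    q.id,
                )
                continue
            cols = [col_of[m] for m in ids]
            out[qi, i] = sim[qi, cols].max()
    return out


def pairwise_similarity_summary(
    dataset: dict[str, CompoundRecord] | list[CompoundRecord],
    fp_types: list[str] | tuple[str, ...] = CANONICAL_FP_TYPES,
) -> dict[str, float]:
    """Mean pairwise Tanimoto per fingerprint type over all unordered pairs.

    Returns a mapping ``fp_type -> mean similarity`` plus an ``"average"``
    entry: the mean over pairs of the per-pair type-averaged score (equal
    to the mean of the per-type means).
    """
    compounds = list(dataset.values()) if isinstance(dataset, dict) else list(dataset)
    n = len(compounds)
    if n < 2:
        raise ValueError("pairwise similarity needs at least 2 compounds")
    iu = np.triu_indices(n, k=1)
    summary: dict[str, float] = {}
    avg_accum = np.zeros(iu[0].size)
    for t in fp_types:
        B = _bit_matrix(compounds, t).astype(np.float64)
        shared = B @ B.T
        a = B.sum(axis=1)
        denom = a[:, None] + a[None, :] - shared
        with np.errstate(invalid="ignore", divide="ignore"):
            tc = np.where(denom > 0, shared / denom, 0.0)
        vals = tc[iu]
        summary[t] = float(vals.mean())
        avg_accum += vals
    summary["average"] = float((avg_accum / len(fp_types)).mean())
    return summary
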