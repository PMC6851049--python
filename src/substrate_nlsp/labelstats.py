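"""Label-correlation analytics for multi-label substrate data.

Association between two transporter labels is measured by the
bias-corrected Cramér's V (Bergsma's correction), computed from the 2×2
contingency table of label co-membership.  Labelset intersection tallies
(the data behind UpSet-style plots) are also provided.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import chi2_contingency

logger = logging.getLogger(__name__)


@dataclass
class ContingencyTable:
    """An r×c table of non-negative integer counts."""

    counts: np.ndarray

    def __post_init__(self) -> None:
        arr = np.asarray(self.counts)
        if arr.ndim != 2:
            raise ValueError("contingency table must be 2-D")
        if np.any(arr < 0):
            raise ValueError("contingency table counts must be non-negative")
        self.counts = arr.astype(np.int64)

    @property
    def n(self) -> int:
        return int(self.counts.sum())

    def drop_empty_margins(self) -> "ContingencyTable":
        """Drop all-zero rows/columns (with a warning); they carry no data."""
        arr = self.counts
        row_ok = arr.sum(axis=1) > 0
        col_ok = arr.sum(axis=0) > 0
        if not row_ok.all() or not col_ok.all():
            logger.warning(
                "dropping %d empty row(s) and %d empty column(s) from table",
                int((~row_ok).sum()),
                int((~col_ok).sum()),
            )
            arr = arr[np.ix_(row_ok, col_ok)]
        return ContingencyTable(arr)


def chi_square(table: ContingencyTable) -> float:
    """Pearson chi-square statistic without continuity correction."""
    t = table.drop_empty_margins()
    if t.n == 0 or t.counts.shape[0] < 2 or t.counts.shape[1] < 2:
        raise ValueError(
            "chi-square needs a table with at least 2 non-empty rows and columns"
        )
    stat, _, _, _ = chi2_contingency(t.counts, correction=False)
    return float(stat)


def cramers_v_corrected(table: ContingencyTable) -> float:
    """Bias-corrected Cramér's V in [0, 1].

    With n the total count, r×c the table shape and χ² the uncorrected
    Pearson statistic:

        φ²  = χ²/n
        φ̃²  = max(0, φ² − (r−1)(c−1)/(n−1))
        r̃   = r − (r−1)²/(n−1),   c̃ = c − (c−1)²/(n−1)
        Ṽ   = sqrt(φ̃² / min(r̃−1, c̃−1))

    The correction removes the upward small-sample bias of the plain V.
    """
    t = table.drop_empty_margins()
    r, c = t.counts.shape
    n = t.n
    chi2 = chi_square(t)
    phi2 = chi2 / n
    phi2_tilde = max(0.0, phi2 - (r - 1) * (c - 1) / (n - 1))
    r_tilde = r - (r - 1) ** 2 / (n - 1)
    c_tilde = c - (c - 1) ** 2 / (n - 1)
    m_tilde = min(r_tilde - 1, c_tilde - 1)
    if m_tilde <= 0:
        logger.warning("degenerate corrected table dimension (m̃ ≤ 0); V set to 0")
        return 0.0
    return float(np.sqrt(phi2_tilde / m_tilde))


def cramers_v(table: ContingencyTable) -> float:
    """Uncorrected sample Cramér's V, sqrt(φ²/min(r−1, c−1))."""
    t = table.drop_empty_margins()
    r, c = t.counts.shape
    chi2 = chi_square(t)
    return float(np.sqrt(chi2 / t.n / min(r - 1, c - 1)))


def label_pair_table(Y: pd.DataFrame, i: str | int, j: str | int) -> ContingencyTable:
    """2×2 co-membership table for a pair of labels.

    Rows index absence/presence of label ``i``; columns of label ``j``.
    ``counts[1, 1]`` is the number of compounds carrying both labels.
    """
    cols = list(Y.columns)
    li = cols[i] if isinstance(i, int) else i
    lj = cols[j] if isinstance(j, int) else j
    if li == lj:
        raise ValueError("label pair must be two distinct labels")
    a = Y[li].astype(bool).to_numpy()
    b = Y[lj].astype(bool).to_numpy()
    counts = np.array(
        [
            [int((~a & ~b).sum()), int((~a & b).sum())],
            [int((a & ~b).sum()), int((a & b).sum())],
        ]
    )
    return ContingencyTable(counts)


def correlation_matrix(Y: pd.DataFrame, corrected: bool = True) -> pd.DataFrame:
    """Pairwise label-association matrix of (bias-corrected) Cramér's V.

    Diagonal is 1 by convention.  Constant labels (never or always
    present) have undefined association; their entries are 0 with a
    warning so downstream heatmaps stay finite.
    """
    labels = list(Y.columns)
    if len(labels) < 2:
        raise ValueError("need at least 2 labels for a correlation matrix")
    stat = cramers_v_corrected if corrected else cramers_v
    M = np.eye(len(labels))
    for i in range(len(labels)):
        for j in range(i + 1, len(labels)):
            col_i = Y[labels[i]].astype(bool)
            col_j = Y[labels[j]].astype(bool)
            if col_i.nunique() < 2 or col_j.nunique() < 2:
                logger.warning(
                    "constant label in pair (%s, %s); association set to 0",
                    labels[i],
                    labels[j],
                )
                v = 0.0
            else:
                v = stat(label_pair_table(Y, labels[i], labels[j]))
            M[i, j] = M[j, i] = v
    return pd.DataFrame(M, index=labels, columns=labels)


def intersection_tallies(
    Y: pd.DataFrame,
) -> tuple[dict[frozenset[str], int], pd.DataFrame]:
    """Exact labelset tallies plus pairwise co-membership counts.

    Returns ``(tallies, co_counts)`` where ``tallies`` maps each distinct
    observed labelset (as a frozenset of label names) to the number of
    compounds carrying exactly that set, and ``co_counts`` is the M×M
    matrix of compounds carrying both labels of each pair (diagonal =
    label totals).  Tallies sum to the number of compounds.
    """
    labels = list(Y.columns)
    B = Y.astype(bool)
    tallies: dict[frozenset[str], int] = {}
    for _, row in B.iterrows():
        key = frozenset(lab for lab in labels if row[lab])
        tallies[key] = tallies.get(key, 0) + 1
    arr = B.to_numpy().astype(np.int64)
    co = arr.T @ arr
    return tallies, pd.DataFrame(co, index=labels, columns=labels)


def tallies_to_frame(tallies: dict[frozenset[str], int]) -> pd.DataFrame:
    """Flatten tallies for export: columns ``labelset`` ('|'-joined) and ``count``."""
    rows = sorted(
        ((("|".join(sorted(k)) if k else "<none>"), v) for k, v in tallies.items()),
        key=lambda kv: (-kv[1], kv[0]),
    )
    return pd.DataFrame(rows, columns=["labelset", "count"])
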