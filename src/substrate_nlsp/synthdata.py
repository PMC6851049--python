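"""Deterministic synthetic benchmark generator.

Every module of the package is exercisable without downloads: this module
generates compounds with four named fingerprint types, a random rooted
ontology DAG with compound annotations, and an imbalanced, correlated
multi-label matrix over the 13 transporter classes.

The default shape mirrors the real benchmark's statistical structure:
13 labels named after the transporters (ABCG2, MDR1, MRP1–4, NTCP2,
S15A1, S22A1, SO1A2, SO1B1, SO1B3, SO2B1) with marginal prevalences
proportional to the published class sizes (MDR1 the heavy majority down
to SO2B1 at ~2%), one strongly associated label pair (SO1B1/SO1B3, the
pair with the highest reported association in the real data), and
class-conditioned fingerprint bit blocks so that within-class structural
similarity exceeds between-class similarity.  SMILES strings are
placeholders — the generator emulates the statistics of the inputs, not
real chemistry.

All randomness flows from ``SynthConfig.seed`` through spawned
child generators, so identical configs give identical datasets.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .chemstruct import CompoundRecord, Fingerprint
from .dataset import SubstrateDataset
from .ontosem import OntologyDAG

#: Transporter class names, majority first as in the benchmark anatomy.
DEFAULT_LABELS = (
    "ABCG2", "MDR1", "MRP1", "MRP2", "MRP3", "MRP4", "NTCP2",
    "S15A1", "S22A1", "SO1A2", "SO1B1", "SO1B3", "SO2B1",
)

#: Class sizes of the published benchmark (out of 1,846 unique substrates);
#: the default prevalences are class size / 1,846, i.e. the fraction of
#: unique compounds carrying each label (MDR1 ≈ 0.49 down to SO2B1 ≈ 0.02).
_BENCHMARK_CLASS_SIZES = (
    344, 910, 138, 136, 63, 47, 53, 230, 144, 54, 87, 48, 39,
)
_BENCHMARK_N_UNIQUE = 1846

DEFAULT_FP_BITS = {"MACCS": 166, "FP2": 1024, "FP3": 64, "FP4": 512}
DEFAULT_FP_DENSITY = {"MACCS": 0.25, "FP2": 0.08, "FP3": 0.15, "FP4": 0.12}


@dataclass
class SynthConfig:
    """Knobs of the synthetic benchmark.

    ``label_prevalences`` are marginal Bernoulli rates per label;
    ``pairwise_label_odds`` maps label pairs to an odds ratio > 0
    inducing co-occurrence (1 = independent).  ``effect_size`` controls
    how strongly a compound's classes elevate bits in the class's
    signature block of each fingerprint, i.e. the classification signal.
    """

    n_compounds: int = 200
    labels: tuple[str, ...] = DEFAULT_LABELS
    label_prevalences: tuple[float, ...] = tuple(
        s / _BENCHMARK_N_UNIQUE for s in _BENCHMARK_CLASS_SIZES
    )
    pairwise_label_odds: dict[tuple[str, str], float] = field(
        default_factory=lambda: {("ABCG2", "MDR1"): 10.0}
    )
    fingerprint_bits: dict[str, int] = field(
        default_factory=lambda: dict(DEFAULT_FP_BITS)
    )
    fingerprint_density: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_FP_DENSITY)
    )
    effect_size: float = 0.3
    ontology_size: int = 60
    annotation_noise: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.label_prevalences) != len(self.labels):
            raise ValueError("one prevalence per label required")
        if not all(0.0 < p < 1.0 for p in self.label_prevalences):
            raise ValueError("prevalences must lie in (0, 1)")
        if any(o <= 0 for o in self.pairwise_label_odds.values()):
            raise ValueError("odds ratios must be positive")
        seen: set[str] = set()
        for i, j in self.pairwise_label_odds:
            if i not in self.labels or j not in self.labels or i == j:
                raise ValueError(f"bad correlated pair ({i}, {j})")
            if i in seen or j in seen:
                raise ValueError("correlated pairs must be disjoint")
            seen |= {i, j}

    def prevalence_of(self, label: str) -> float:
        return self.label_prevalences[self.labels.index(label)]


def _rngs(cfg: SynthConfig, n: int) -> list[np.random.Generator]:
    return [np.random.default_rng(s) for s in np.random.SeedSequence(cfg.seed).spawn(n)]


def _joint_p11(pi: float, pj: float, odds: float) -> float:
    """P(both labels) of a 2×2 table with given margins and odds ratio."""
    if math.isclose(odds, 1.0):
        return pi * pj
    # (θ−1)x² − [θ(pi+pj) + 1 − pi − pj]x + θ·pi·pj = 0
    a = odds - 1.0
    b = -(odds * (pi + pj) + 1.0 - pi - pj)
    c = odds * pi * pj
    disc = b * b - 4 * a * c
    if disc < 0:
        raise ValueError("infeasible odds/prevalence combination")
    lo, hi = max(0.0, pi + pj - 1.0), min(pi, pj)
    for root in ((-b - math.sqrt(disc)) / (2 * a), (-b + math.sqrt(disc)) / (2 * a)):
        if lo - 1e-12 <= root <= hi + 1e-12:
            return min(max(root, lo), hi)
    raise ValueError("infeasible odds/prevalence combination")


def gen_labels(cfg: SynthConfig) -> pd.DataFrame:
    """Imbalanced correlated multi-label matrix; every row has ≥1 label.

    Labels outside the configured pairs are independent Bernoulli draws;
    each configured pair is drawn jointly from the 2×2 table with the
    requested odds ratio and the configured margins.  A row that comes
    out all-zero is rescued with a single label drawn from the unpaired
    labels in proportion to their prevalence, and the unpaired base
    rates are shrunk by a fixed point so the *observed* marginals still
    match the configured prevalences.  Because rescue never touches the
    paired labels, their observed 2×2 tables — margins and odds ratio —
    are exactly the configured ones.

    The empty-row rescue concentrates its mass on singleton labelsets,
    which induces a mild negative association among the unpaired labels
    (an exclusivity that real substrate data shares: most compounds are
    substrates of exactly one transporter).  An infeasible configuration
    (prevalences summing to ≤ 1, or a rare label unable to absorb its
    rescue share) raises a config error.
    """
    rng = _rngs(cfg, 4)[0]
    paired = {lab for pair in cfg.pairwise_label_odds for lab in pair}
    unpaired = [lab for lab in cfg.labels if lab not in paired]
    targets = dict(zip(cfg.labels, cfg.label_prevalences))
    if sum(targets.values()) <= 1.0:
        # rows carry ≥1 label, so observed marginals must sum to at least 1
        raise ValueError(
            "prevalences sum to ≤ 1; cannot match marginals while every "
            "compound carries at least one label"
        )
    if not unpaired:
        raise ValueError(
            "at least one label must stay outside the correlated pairs "
            "(the empty-row rescue draws from the unpaired labels)"
        )
    joint = {
        (li, lj): _joint_p11(targets[li], targets[lj], odds)
        for (li, lj), odds in cfg.pairwise_label_odds.items()
    }
    w_total = sum(targets[lab] for lab in unpaired)
    rescue_w = {lab: targets[lab] / w_total for lab in unpaired}

    # fixed point for the unpaired base rates: b = t − e·w with e = P(all
    # labels absent under b and the pair joints)
    base = {lab: targets[lab] for lab in unpaired}
    e = 0.0
    for _ in range(500):
        e = 1.0
        for lab in unpaired:
            e *= 1.0 - base[lab]
        for (li, lj), p11 in joint.items():
            e *= 1.0 - targets[li] - targets[lj] + p11
        new = {lab: targets[lab] - e * rescue_w[lab] for lab in unpaired}
        if min(new.values()) <= 0:
            raise ValueError(
                "infeasible prevalence/odds configuration: a rare label "
                "cannot absorb its share of the empty-row rescue mass"
            )
        delta = max(abs(new[lab] - base[lab]) for lab in unpaired)
        base = new
        if delta < 1e-13:
            break

    n = cfg.n_compounds
    col = {lab: k for k, lab in enumerate(cfg.labels)}
    Y = np.zeros((n, len(cfg.labels)), dtype=np.int64)
    b_vec = np.array([base[lab] for lab in unpaired])
    unpaired_cols = np.array([col[lab] for lab in unpaired])
    rescue_p = np.array([rescue_w[lab] for lab in unpaired])
    for r in range(n):
        Y[r, unpaired_cols] = rng.random(len(unpaired)) < b_vec
        for (li, lj), p11 in joint.items():
            pi, pj = targets[li], targets[lj]
            u = rng.random()
            if u < p11:
                Y[r, col[li]], Y[r, col[lj]] = 1, 1
            elif u < pi:
                Y[r, col[li]], Y[r, col[lj]] = 1, 0
            elif u < pi + (pj - p11):
                Y[r, col[li]], Y[r, col[lj]] = 0, 1
        if Y[r].sum() == 0:
            Y[r, unpaired_cols[rng.choice(len(unpaired), p=rescue_p)]] = 1
    ids = [f"C{i:04d}" for i in range(n)]
    return pd.DataFrame(Y, index=pd.Index(ids, name="id"), columns=list(cfg.labels))


def gen_fingerprints(
    cfg: SynthConfig, Y: pd.DataFrame | None = None
) -> dict[str, CompoundRecord]:
    """Compounds with four class-conditioned fingerprint bit-vectors.

    Each fingerprint type reserves one block of bits per label; compounds
    carrying a label draw that block at elevated density
    d + effect·(1−d), all other bits at the background density d.  This
    makes within-label mean Tanimoto exceed between-label similarity —
    the structural signal the classifier learns.
    """
    if Y is None:
        Y = gen_labels(cfg)
    rng = _rngs(cfg, 4)[1]
    n = len(Y)
    m = len(cfg.labels)
    compounds = {
        cid: CompoundRecord(id=cid, smiles=f"SYN-{cid}") for cid in Y.index
    }
    B = Y.astype(bool).to_numpy()
    for fp_type, n_bits in cfg.fingerprint_bits.items():
        d = cfg.fingerprint_density[fp_type]
        hot = min(1.0, d + cfg.effect_size * (1.0 - d))
        block = n_bits // m
        prob = np.full((n, n_bits), d)
        for j in range(m):
            lo, hi = j * block, (j + 1) * block
            prob[B[:, j], lo:hi] = hot
        bits = rng.random((n, n_bits)) < prob
        for r, cid in enumerate(Y.index):
            compounds[cid].fingerprints[fp_type] = Fingerprint(fp_type, bits[r])
    return compounds


def gen_ontology(
    cfg: SynthConfig, Y: pd.DataFrame | None = None
) -> tuple[OntologyDAG, dict[str, str]]:
    """Random rooted DAG plus label-correlated compound annotations.

    Term 0 is the sole root; every later term attaches to 1–2 parents
    among the earlier terms (acyclic by construction).  Each label owns a
    distinct "home" term in the deeper half of the DAG; a compound is
    annotated to the home term of one of its labels with probability
    1 − annotation_noise, otherwise to a uniformly random term.
    """
    if cfg.ontology_size < 3:
        raise ValueError("ontology_size must be at least 3")
    if Y is None:
        Y = gen_labels(cfg)
    rng = _rngs(cfg, 4)[2]
    terms = [f"SYN:{i:07d}" for i in range(cfg.ontology_size)]
    parents: dict[str, set[str]] = {terms[0]: set()}
    for i in range(1, cfg.ontology_size):
        k = 1 if (i == 1 or rng.random() < 0.7) else 2
        idx = rng.choice(i, size=min(k, i), replace=False)
        parents[terms[i]] = {terms[j] for j in np.atleast_1d(idx)}
    dag = OntologyDAG(terms=set(terms), parents=parents)

    deep = terms[cfg.ontology_size // 2:]
    if len(deep) < len(cfg.labels):
        raise ValueError("ontology too small for one home term per label")
    home_idx = rng.choice(len(deep), size=len(cfg.labels), replace=False)
    home = {lab: deep[j] for lab, j in zip(cfg.labels, home_idx)}

    annotations: dict[str, str] = {}
    B = Y.astype(bool)
    for cid in Y.index:
        own = [lab for lab in cfg.labels if B.at[cid, lab]]
        if own and rng.random() >= cfg.annotation_noise:
            lab = own[rng.integers(len(own))]
            annotations[cid] = home[lab]
        else:
            annotations[cid] = terms[rng.integers(cfg.ontology_size)]
    return dag, annotations


def gen_dataset(cfg: SynthConfig) -> SubstrateDataset:
    """Full synthetic benchmark: labels, fingerprints, ontology, annotations."""
    Y = gen_labels(cfg)
    compounds = gen_fingerprints(cfg, Y)
    dag, annotations = gen_ontology(cfg, Y)
    for cid, term in annotations.items():
        compounds[cid].ontology_term = term
    return SubstrateDataset(
        compounds=compounds,
        labels=Y,
        dag=dag,
        fp_types=tuple(cfg.fingerprint_bits),
        meta={"generator": "synthdata", "seed": cfg.seed},
    )
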