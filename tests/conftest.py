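"""Shared fixtures: tiny hand-built compounds, a chain ontology with a
hand-countable IC corpus, and small synthetic datasets."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from substrate_nlsp.chemstruct import ClassSubsets, CompoundRecord, Fingerprint
from substrate_nlsp.ontosem import compute_ic, parse_obo
from substrate_nlsp.synthdata import SynthConfig, gen_dataset


def fp(bits: str, fp_type: str = "FPX") -> Fingerprint:
    """Fingerprint from a literal bit string like '1010'."""
    return Fingerprint(fp_type, np.array([c == "1" for c in bits]))


def make_compound(cid: str, bit_strings: dict[str, str], term: str | None = None):
    return CompoundRecord(
        id=cid,
        smiles=f"SMILES-{cid}",
        fingerprints={t: fp(b, t) for t, b in bit_strings.items()},
        ontology_term=term,
    )


@pytest.fixture
def two_type_compounds():
    """Four compounds carrying two fingerprint types with known bit patterns."""
    compounds = {
        "c1": make_compound("c1", {"A": "11110000", "B": "1100"}),
        "c2": make_compound("c2", {"A": "11000000", "B": "0110"}),
        "c3": make_compound("c3", {"A": "00001111", "B": "0011"}),
        "c4": make_compound("c4", {"A": "10101010", "B": "1111"}),
    }
    return compounds


CHAIN_OBO = """\
format-version: 1.2

[Term]
id: T:ROOT
name: root

[Term]
id: T:B
name: mid
is_a: T:ROOT

[Term]
id: T:A
name: leaf-a
is_a: T:B

[Term]
id: T:A2
name: leaf-a2
is_a: T:B
"""


@pytest.fixture
def chain_dag():
    """root <- B <- {A, A2}."""
    return parse_obo(CHAIN_OBO)


@pytest.fixture
def chain_ic(chain_dag):
    """Corpus of 4 compounds: A and A2 once each, two at the root.

    Propagated counts: A=1, A2=1, B=2, root=4, hence IC(A)=IC(A2)=ln 4,
    IC(B)=ln 2, IC(root)=0.
    """
    annotations = {"c1": "T:A", "c2": "T:A2", "c3": "T:ROOT", "c4": "T:ROOT"}
    return compute_ic(chain_dag, annotations)


@pytest.fixture
def small_dataset():
    """Compact synthetic benchmark for pipeline-level tests."""
    return gen_dataset(SynthConfig(n_compounds=60, seed=11))


@pytest.fixture
def tiny_label_matrix():
    """Rows {A,B}, {A}, {B,C}, {C} over labels A,B,C."""
    return pd.DataFrame(
        [[1, 1, 0], [1, 0, 0], [0, 1, 1], [0, 0, 1]],
        index=["s1", "s2", "s3", "s4"],
        columns=["A", "B", "C"],
    )


def subsets_of(Y: pd.DataFrame) -> ClassSubsets:
    return ClassSubsets.from_label_frame(Y)
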