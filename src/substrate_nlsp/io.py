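"""Delimited-text readers and writers for the on-disk interchange formats.

Formats
-------
compound table : CSV with header ``id, smiles[, ontology_term]``
fingerprints   : CSV with header ``compound_id, fp_type, hex_bits, n_bits``
                 (hex big-endian bit order, left-padded)
label matrix   : CSV, first column compound id, remaining columns one 0/1
                 column per transporter label
IC override    : CSV with header ``term_id, ic_value``
"""

from __future__ import annotations

import pandas as pd

from .chemstruct import CompoundRecord, Fingerprint
from .ontosem import ICTable


def read_compound_table(path) -> dict[str, CompoundRecord]:
    df = pd.read_csv(path, dtype=str).fillna("")
    required = {"id", "smiles"}
    if not required <= set(df.columns):
        raise ValueError(
            f"compound table needs columns {sorted(required)}, got {list(df.columns)}"
        )
    if df["id"].duplicated().any():
        dupes = df.loc[df["id"].duplicated(), "id"].tolist()
        raise ValueError(f"duplicate compound ids in table: {dupes[:5]}")
    has_term = "ontology_term" in df.columns
    out: dict[str, CompoundRecord] = {}
    for row in df.itertuples(index=False):
        term = getattr(row, "ontology_term", "") if has_term else ""
        out[row.id] = CompoundRecord(
            id=row.id, smiles=row.smiles, ontology_term=term or None
        )
    return out


def write_compound_table(compounds: dict[str, CompoundRecord], path) -> None:
    rows = [
        {
            "id": c.id,
            "smiles": c.smiles,
            "ontology_term": c.ontology_term or "",
        }
        for c in compounds.values()
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


def read_fingerprints(path, compounds: dict[str, CompoundRecord]) -> None:
    """Attach fingerprints from a fingerprint file to existing compounds."""
    df = pd.read_csv(path, dtype={"compound_id": str, "fp_type": str,
                                  "hex_bits": str, "n_bits": int})
    required = {"compound_id", "fp_type", "hex_bits", "n_bits"}
    if not required <= set(df.columns):
        raise ValueError(
            f"fingerprint file needs columns {sorted(required)}, got {list(df.columns)}"
        )
    for row in df.itertuples(index=False):
        if row.compound_id not in compounds:
            raise KeyError(
                f"fingerprint file references unknown compound {row.compound_id!r}"
            )
        fp = Fingerprint.from_hex(row.fp_type, row.hex_bits, int(row.n_bits))
        compounds[row.compound_id].fingerprints[row.fp_type] = fp


def write_fingerprints(compounds: dict[str, CompoundRecord], path) -> None:
    rows = []
    for c in compounds.values():
        for fp_type, fp in sorted(c.fingerprints.items()):
            rows.append(
                {
                    "compound_id": c.id,
                    "fp_type": fp_type,
                    "hex_bits": fp.to_hex(),
                    "n_bits": len(fp),
                }
            )
    pd.DataFrame(rows).to_csv(path, index=False)


def read_label_matrix(path) -> pd.DataFrame:
    df = pd.read_csv(path, index_col=0, dtype=str)
    df.index = df.index.astype(str)
    Y = df.astype(int)
    bad = set(Y.to_numpy().ravel()) - {0, 1}
    if bad:
        raise ValueError(f"label matrix cells must be 0/1; found {sorted(bad)}")
    return Y


def write_label_matrix(Y: pd.DataFrame, path) -> None:
    Y.astype(int).rename_axis("id").to_csv(path)


def read_ic_table(path, corpus_size: int = 0) -> ICTable:
    df = pd.read_csv(path, dtype={"term_id": str, "ic_value": float})
    required = {"term_id", "ic_value"}
    if not required <= set(df.columns):
        raise ValueError(
            f"IC table needs columns {sorted(required)}, got {list(df.columns)}"
        )
    if (df["ic_value"] < 0).any():
        raise ValueError("IC values must be non-negative")
    return ICTable(
        ic=dict(zip(df["term_id"], df["ic_value"])), corpus_size=corpus_size
    )


def write_ic_table(ic: ICTable, path) -> None:
    pd.DataFrame(
        sorted(ic.ic.items()), columns=["term_id", "ic_value"]
    ).to_csv(path, index=False)
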