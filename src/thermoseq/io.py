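"""Reading and writing the formats the tool touches.

The canonical record type is :class:`ProteinRecord`: a sequence over the 20
standard one-letter amino-acid codes, optionally annotated with a
thermophilic/mesophilic label and the optimal growth temperature (OGT, in
degrees Celsius) of the source organism.  Records containing non-standard
residues (B, J, O, U, X, Z, ...) are routed to a reject list rather than
silently altered, because every downstream descriptor assumes the 20-letter
alphabet.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

STANDARD_AA = "ACDEFGHIKLMNPQRSTVWY"
_STANDARD_SET = frozenset(STANDARD_AA)

LABEL_THERMOPHILIC = "thermophilic"
LABEL_MESOPHILIC = "mesophilic"
_VALID_LABELS = (LABEL_THERMOPHILIC, LABEL_MESOPHILIC)


@dataclass
class ProteinRecord:
    """One protein sequence with optional class label and OGT annotation."""

    id: str
    sequence: str
    label: str | None = None
    ogt: float | None = None
    description: str = ""

    def __post_init__(self) -> None:
        self.sequence = self.sequence.upper()
        if self.label is not None and self.label not in _VALID_LABELS:
            raise ValueError(
                f"unknown label {self.label!r}; expected one of {_VALID_LABELS}"
            )

    def __len__(self) -> int:
        return len(self.sequence)

    def invalid_residues(self) -> set[str]:
        return set(self.sequence) - _STANDARD_SET


@dataclass
class RejectedRecord:
    """A record that failed validation, with the reason it was rejected."""

    id: str
    sequence: str
    reason: str


def read_fasta(path: str | Path) -> tuple[list[ProteinRecord], list[RejectedRecord]]:
    """Parse a FASTA file into accepted and rejected protein records.

    The header token before the first whitespace becomes the record id;
    sequences are uppercased.  Records that are empty or contain characters
    outside ``ACDEFGHIKLMNPQRSTVWY`` go to the reject list with the offending
    characters named.  Every input entry appears in exactly one of the two
    lists.

    Raises
    ------
    FileNotFoundError
        If *path* does not exist.
    ValueError
        If the file contains no entries, or two entries share an id.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"FASTA file not found: {path}")
    accepted: list[ProteinRecord] = []
    rejected: list[RejectedRecord] = []
    seen: set[str] = set()
    n_entries = 0
    for entry in SeqIO.parse(str(path), "fasta"):
        n_entries += 1
        rec_id = entry.id
        if rec_id in seen:
            raise ValueError(f"duplicate record id in {path}: {rec_id!r}")
        seen.add(rec_id)
        seq = str(entry.seq).upper()
        desc = entry.description[len(entry.id):].strip()
        if not seq:
            rejected.append(RejectedRecord(rec_id, seq, "empty sequence"))
            continue
        bad = sorted(set(seq) - _STANDARD_SET)
        if bad:
            rejected.append(
                RejectedRecord(
                    rec_id, seq, f"non-standard residues: {','.join(bad)}"
                )
            )
            continue
        accepted.append(ProteinRecord(rec_id, seq, description=desc))
    if n_entries == 0:
        raise ValueError(f"no FASTA entries found in {path}")
    return accepted, rejected


def write_fasta(records: Iterable[ProteinRecord], path: str | Path) -> None:
    """Write records to FASTA (60-column wrapped)."""
    seq_records = [
        SeqRecord(Seq(r.sequence), id=r.id, description=r.description)
        for r in records
    ]
    SeqIO.write(seq_records, str(path), "fasta")


def read_labels(path: str | Path) -> dict[str, tuple[str | None, float | None]]:
    """Read a delimited sidecar table mapping id -> (label, ogt).

    The table must have an ``id`` column and at least one of ``label`` /
    ``ogt``.  Labels are parsed case-insensitively; OGT is decimal degrees
    Celsius.  Rows carrying neither a label nor an OGT are dropped.

    Raises
    ------
    ValueError
        On an unrecognised label string or a non-numeric OGT.
    """
    path = Path(path)
    df = pd.read_csv(path, dtype=str).rename(columns=str.lower)
    if "id" not in df.columns:
        raise ValueError(f"label table {path} has no 'id' column")
    if "label" not in df.columns and "ogt" not in df.columns:
        raise ValueError(f"label table {path} needs a 'label' or 'ogt' column")
    out: dict[str, tuple[str | None, float | None]] = {}
    for _, row in df.iterrows():
        rec_id = str(row["id"])
        label_raw = row.get("label")
        ogt_raw = row.get("ogt")
        label: str | None = None
        if isinstance(label_raw, str) and label_raw.strip():
            label = label_raw.strip().lower()
            if label not in _VALID_LABELS:
                raise ValueError(
                    f"unknown label {label_raw.strip()!r} for id {rec_id!r}"
                )
        ogt: float | None = None
        if isinstance(ogt_raw, str) and ogt_raw.strip():
            try:
                ogt = float(ogt_raw)
            except ValueError:
                raise ValueError(
                    f"non-numeric ogt {ogt_raw!r} for id {rec_id!r}"
                ) from None
            if not math.isfinite(ogt):
                raise ValueError(f"non-finite ogt for id {rec_id!r}")
        if label is None and ogt is None:
            continue
        out[rec_id] = (label, ogt)
    return out


def write_labels(records: Iterable[ProteinRecord], path: str | Path) -> None:
    """Write the id/label/ogt sidecar table for *records*."""
    rows = [
        {"id": r.id, "label": r.label or "", "ogt": "" if r.ogt is None else r.ogt}
        for r in records
    ]
    pd.DataFrame(rows, columns=["id", "label", "ogt"]).to_csv(path, index=False)


def write_feature_table(vectors: Iterable, path: str | Path) -> None:
    """Write feature vectors as CSV: first column id, one column per feature.

    All vectors must share the same feature-name ordering.  Values are
    written with the shortest round-trip representation, so the table reads
    back through :func:`read_feature_table` bit-identically.
    """
    vectors = list(vectors)
    if not vectors:
        Path(path).write_text("id\n")
        return
    names = list(vectors[0].names)
    for v in vectors[1:]:
        if list(v.names) != names:
            raise ValueError(
                f"inconsistent feature names: record {v.id!r} does not "
                f"match record {vectors[0].id!r}"
            )
    df = pd.DataFrame(
        [list(v.values) for v in vectors],
        columns=names,
        index=pd.Index([v.id for v in vectors], name="id"),
    )
    df.to_csv(path)


def read_feature_table(path: str | Path) -> pd.DataFrame:
    """Read a feature table written by :func:`write_feature_table`."""
    return pd.read_csv(path, index_col="id", float_precision="round_trip")
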