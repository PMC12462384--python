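"""Peptide and feature-matrix I/O.

Sequences travel as standard FASTA; binary labels live in a sidecar TSV
(``id<TAB>label``) keyed by record id, which keeps the FASTA itself
standard-conformant.  Every sequence is validated on the way in: the toolkit
works exclusively on the 20 proteinogenic canonical amino acids, and
anything else (ambiguity codes B/J/O/U/X/Z included) is a hard error rather
than a silent drop.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from ._tables import ALPHABET
from .errors import (
    ColumnMismatchError,
    DuplicateIdError,
    MissingLabelError,
    NonCanonicalResidueError,
    SequenceError,
    TooShortError,
    UnknownHeaderError,
)
from .matrix import FeatureMatrix

_CANONICAL = frozenset(ALPHABET)
MIN_LENGTH = 3


@dataclass(frozen=True)
class Peptide:
    """A validated peptide: id, uppercase canonical sequence, optional label.

    ``label`` is 1 for the positive class (CPP, or high uptake efficiency in
    stage 2) and 0 for the negative class.
    """

    id: str
    sequence: str
    label: int | None = None

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass
class LabeledDataset:
    """An ordered peptide collection with unique ids.

    Labels are all-or-nothing: either every peptide carries one or none does.
    """

    peptides: list[Peptide]

    def __post_init__(self) -> None:
        ids = [p.id for p in self.peptides]
        seen: set[str] = set()
        for i in ids:
            if i in seen:
                raise DuplicateIdError(f"duplicate peptide id {i!r}")
            seen.add(i)
        labelled = [p.label is not None for p in self.peptides]
        if any(labelled) and not all(labelled):
            missing = [p.id for p in self.peptides if p.label is None]
            raise MissingLabelError(f"peptides without labels: {missing[:5]}")

    def __len__(self) -> int:
        return len(self.peptides)

    def __iter__(self):
        return iter(self.peptides)

    @property
    def has_labels(self) -> bool:
        return bool(self.peptides) and self.peptides[0].label is not None

    @property
    def ids(self) -> list[str]:
        return [p.id for p in self.peptides]

    @property
    def sequences(self) -> list[str]:
        return [p.sequence for p in self.peptides]

    @property
    def labels(self) -> np.ndarray | None:
        if not self.has_labels:
            return None
        return np.array([p.label for p in self.peptides], dtype=int)

    @property
    def class_counts(self) -> tuple[int, int] | None:
        """(negatives, positives), or None when the dataset is unlabeled."""
        y = self.labels
        if y is None:
            return None
        return int(np.sum(y == 0)), int(np.sum(y == 1))


def validate_sequence(raw: str) -> str:
    """Canonicalize a raw sequence string.

    Whitespace is stripped, case is folded to upper, and the result is
    accepted iff it contains only the 20 canonical residues and has length
    at least 3 (so the tripeptide block has at least one window).
    """
    seq = "".join(raw.split()).upper()
    if not seq:
        raise TooShortError(seq)
    offending = [(i + 1, c) for i, c in enumerate(seq) if c not in _CANONICAL]
    if offending:
        raise NonCanonicalResidueError(seq, offending)
    if len(seq) < MIN_LENGTH:
        raise TooShortError(seq)
    return seq


def read_labels(path: str | Path) -> dict[str, int]:
    """Read an ``id<TAB>label`` sidecar TSV (header row optional)."""
    labels: dict[str, int] = {}
    with open(path, newline="") as fh:
        reader = csv.reader(fh, delimiter="\t")
        for row_no, row in enumerate(reader, start=1):
            if not row or (len(row) == 1 and not row[0].strip()):
                continue
            if len(row) < 2:
                raise UnknownHeaderError(
                    f"{path}: line {row_no} has {len(row)} column(s), expected 2"
                )
            key, value = row[0].strip(), row[1].strip()
            if row_no == 1 and value.lower() in {"label", "class", "y"}:
                continue  # header row
            if value not in {"0", "1"}:
                raise UnknownHeaderError(
                    f"{path}: line {row_no}: label must be 0 or 1, got {value!r}"
                )
            if key in labels:
                raise DuplicateIdError(f"{path}: duplicate id {key!r} in label sidecar")
            labels[key] = int(value)
    return labels


def read_fasta(path: str | Path, labels: str | Path | None = None) -> LabeledDataset:
    """Read a FASTA file (optionally joining a label sidecar) into a dataset.

    The FASTA id is the first whitespace-delimited token of the header.
    Validation errors are re-raised with the offending record id attached.
    """
    label_map = read_labels(labels) if labels is not None else None
    peptides: list[Peptide] = []
    seen: set[str] = set()
    for record in SeqIO.parse(str(path), "fasta"):
        if record.id in seen:
            raise DuplicateIdError(f"{path}: duplicate FASTA id {record.id!r}")
        seen.add(record.id)
        try:
            seq = validate_sequence(str(record.seq))
        except SequenceError as exc:
            exc.args = (f"record {record.id!r}: {exc}",)
            raise
        label = None
        if label_map is not None:
            if record.id not in label_map:
                raise MissingLabelError(
                    f"id {record.id!r} present in FASTA but absent from label sidecar"
                )
            label = label_map[record.id]
        peptides.append(Peptide(id=record.id, sequence=seq, label=label))
    return LabeledDataset(peptides)


def write_fasta(ds: LabeledDataset, path: str | Path, labels: str | Path | None = None) -> None:
    """Write a dataset as FASTA, optionally emitting the label sidecar too."""
    records = [SeqRecord(Seq(p.sequence), id=p.id, description="") for p in ds]
    SeqIO.write(records, str(path), "fasta")
    if labels is not None:
        if not ds.has_labels:
            raise MissingLabelError("dataset carries no labels to write")
        with open(labels, "w", newline="") as fh:
            writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
            writer.writerow(["id", "label"])
            for p in ds:
                writer.writerow([p.id, p.label])


def write_feature_matrix(matrix: FeatureMatrix, path: str | Path) -> None:
    """Write a feature matrix as TSV ('.' decimal separator, 12 significant
    digits, header row ``id, <features...>[, label]``)."""
    matrix.to_frame().to_csv(path, sep="\t", index=False, float_format="%.12g")


def read_feature_matrix(path: str | Path) -> FeatureMatrix:
    """Read a TSV feature matrix written by :func:`write_feature_matrix`."""
    try:
        frame = pd.read_csv(path, sep="\t", header=0, dtype={0: str})
    except pd.errors.ParserError as exc:
        raise ColumnMismatchError(f"{path}: ragged rows ({exc})") from exc
    if frame.columns.empty or frame.columns[0] != "id":
        raise UnknownHeaderError(f"{path}: first column must be 'id'")
    # Ragged short rows surface as trailing NaNs after pandas' permissive parse.
    if frame.isna().any().any():
        raise ColumnMismatchError(f"{path}: missing values (ragged row?)")
    names = [c for c in frame.columns[1:] if c != "label"]
    labels = None
    if "label" in frame.columns:
        if list(frame.columns).index("label") != len(frame.columns) - 1:
            raise UnknownHeaderError(f"{path}: 'label' must be the last column")
        labels = frame["label"].to_numpy(dtype=int)
    values = frame[names].to_numpy(dtype=float)
    return FeatureMatrix(
        ids=frame["id"].astype(str).tolist(), names=names, values=values, labels=labels
    )
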