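"""Record-level identification-error classification and the classification matrix.

The decision tree applied to each morphologically reviewed record:

1. records determined by a blocked reviewer are excluded up front
   (circularity filter);
2. no parseable original identification at species rank -> ``not_identified``;
3. the (original, revised) pair is looked up in the concept rule book ->
   the rule's category;
4. otherwise, rank-free name equality with the revised species -> ``correct``;
5. otherwise ``unresolvable`` (reported, excluded from denominators).
"""

from __future__ import annotations

import csv
import logging
import unicodedata
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .errors import DataValidationError
from .nomenclature import (
    CAT_CORRECT,
    ConceptRuleBook,
    TaxonName,
    names_match_rank_free,
    parse_name,
)
from .occ_model import OccurrenceRecord

logger = logging.getLogger(__name__)

CAT_NOT_IDENTIFIED = "not_identified"
CAT_EXCLUDED = "excluded_circularity"
CAT_UNRESOLVABLE = "unresolvable"

#: categories counted as incorrect identifications
INCORRECT_CATEGORIES = frozenset(
    {"misidentification", "soft_change", "hard_change", CAT_NOT_IDENTIFIED}
)

#: row label of the unidentified-record row in the classification matrix
NOT_IDENTIFIED_LABEL = "Not identified"

#: reviewers whose determinations define the reference taxonomy
DEFAULT_BLOCKED_IDENTIFIERS = ("Valcárcel", "McAllister", "Vargas", "Rutherford")


@dataclass(frozen=True)
class ErrorClassification:
    record_id: str
    category: str


def _fold(text: str) -> str:
    """Lowercase and strip diacritics for surname comparison."""
    decomposed = unicodedata.normalize("NFKD", text)
    return "".join(ch for ch in decomposed if not unicodedata.combining(ch)).lower()


def filter_circularity(
    records: Sequence[OccurrenceRecord],
    blocked_identifiers: Sequence[str] = DEFAULT_BLOCKED_IDENTIFIERS,
) -> tuple[list[OccurrenceRecord], list[OccurrenceRecord]]:
    """Partition records into (kept, excluded), preserving order.

    A record is excluded iff any blocked surname occurs (case- and
    accent-insensitively) inside a token of its ``identified_by`` field, so
    that label formats like ``"det. Valcárcel, V."`` still match.
    """
    blocked = [_fold(b) for b in blocked_identifiers]
    kept: list[OccurrenceRecord] = []
    excluded: list[OccurrenceRecord] = []
    for rec in records:
        tokens = [_fold(t) for t in _tokenize(rec.identified_by)]
        if any(b in t for t in tokens for b in blocked):
            excluded.append(rec)
        else:
            kept.append(rec)
    return kept, excluded


def _tokenize(text: str) -> list[str]:
    out, cur = [], []
    for ch in text:
        if ch.isalpha():
            cur.append(ch)
        elif cur:
            out.append("".join(cur))
            cur = []
    if cur:
        out.append("".join(cur))
    return out


def classify_record(record: OccurrenceRecord, kb: ConceptRuleBook) -> ErrorClassification:
    """Classify one post-filter record against the rule book."""
    if record.revised_species is None:
        raise DataValidationError(
            f"record {record.record_id!r} has no revised identification; "
            "the audit requires a reviewed determination"
        )
    name = parse_name(record.original_name_verbatim)
    if name is None:
        return ErrorClassification(record.record_id, CAT_NOT_IDENTIFIED)
    rule = kb.lookup(name, record.revised_species)
    if rule is not None:
        return ErrorClassification(record.record_id, rule.category)
    if names_match_rank_free(name, record.revised_species):
        return ErrorClassification(record.record_id, CAT_CORRECT)
    logger.warning(
        "unresolvable pair: %r -> %r (record %s)",
        record.original_name_verbatim,
        record.revised_species,
        record.record_id,
    )
    return ErrorClassification(record.record_id, CAT_UNRESOLVABLE)


def classify_records(
    records: Sequence[OccurrenceRecord], kb: ConceptRuleBook
) -> list[tuple[OccurrenceRecord, ErrorClassification]]:
    return [(rec, classify_record(rec, kb)) for rec in records]


def _row_sort_key(label: str) -> tuple:
    name = parse_name(label)
    if name is None:  # defensive; labels come from matrix_label()
        return (1, label, 1, "")
    return (0, f"{name.genus} {name.specific_epithet}",
            0 if name.infraspecific_epithet is None else 1,
            name.infraspecific_epithet or "")


@dataclass
class ClassificationMatrix:
    """Counts of records per (original-name row, revised-species column)."""

    row_labels: list[str]
    col_labels: list[str]
    counts: np.ndarray  # shape (rows, cols), non-negative ints

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.shape != (len(self.row_labels), len(self.col_labels)):
            raise ValueError("counts shape does not match labels")
        if (self.counts < 0).any():
            raise ValueError("matrix cells must be non-negative")

    def total(self) -> int:
        return int(self.counts.sum())

    def cell(self, row: str, col: str) -> int:
        return int(self.counts[self.row_labels.index(row), self.col_labels.index(col)])

    def column_total(self, col: str) -> int:
        return int(self.counts[:, self.col_labels.index(col)].sum())

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ClassificationMatrix):
            return NotImplemented
        return (
            self.row_labels == other.row_labels
            and self.col_labels == other.col_labels
            and np.array_equal(self.counts, other.counts)
        )

    def write_csv(self, path: str | Path, delimiter: str = ",") -> None:
        with Path(path).open("w", newline="", encoding="utf-8") as fh:
            writer = csv.writer(fh, delimiter=delimiter)
            writer.writerow(["original_name", *self.col_labels])
            for label, row in zip(self.row_labels, self.counts):
                writer.writerow([label, *row.tolist()])

    @classmethod
    def read_csv(cls, path: str | Path, delimiter: str = ",") -> "ClassificationMatrix":
        with Path(path).open(newline="", encoding="utf-8") as fh:
            reader = csv.reader(fh, delimiter=delimiter)
            header = next(reader)
            col_labels = header[1:]
            row_labels, rows = [], []
            for row in reader:
                if not row:
                    continue
                row_labels.append(row[0])
                rows.append([int(c) for c in row[1:]])
        return cls(row_labels, col_labels, np.array(rows, dtype=np.int64))


def build_matrix(
    classified: Iterable[tuple[OccurrenceRecord, ErrorClassification]],
) -> ClassificationMatrix:
    """Cross-tabulate classified records; excluded/unresolvable are skipped.

    Rows are ordered species-rank-first alphabetically with infraspecifics
    grouped under their species; the unidentified row comes last.  Columns
    (revised species) are alphabetical.
    """
    cells: dict[tuple[str, str], int] = {}
    for rec, cls_ in classified:
        if cls_.category in (CAT_EXCLUDED, CAT_UNRESOLVABLE):
            logger.warning("record %s (%s) skipped in matrix", rec.record_id, cls_.category)
            continue
        if cls_.category == CAT_NOT_IDENTIFIED:
            row = NOT_IDENTIFIED_LABEL
        else:
            name = parse_name(rec.original_name_verbatim)
            assert name is not None  # guaranteed by classification
            row = name.matrix_label()
        revised = parse_name(rec.revised_species or "")
        col = revised.binomial if revised is not None else (rec.revised_species or "")
        cells[(row, col)] = cells.get((row, col), 0) + 1

    name_rows = sorted({r for r, _ in cells if r != NOT_IDENTIFIED_LABEL}, key=_row_sort_key)
    row_labels = name_rows + ([NOT_IDENTIFIED_LABEL] if any(
        r == NOT_IDENTIFIED_LABEL for r, _ in cells) else [])
    col_labels = sorted({c for _, c in cells})
    counts = np.zeros((len(row_labels), len(col_labels)), dtype=np.int64)
    for (row, col), n in cells.items():
        counts[row_labels.index(row), col_labels.index(col)] = n
    return ClassificationMatrix(row_labels, col_labels, counts)


def expand_matrix(matrix: ClassificationMatrix, seed: int = 0) -> list[OccurrenceRecord]:
    """Turn a classification matrix into a record-level fixture.

    Emits exactly ``cell`` records per (row, column); the unidentified row
    yields records with an empty verbatim identification.  Record order is a
    seeded permutation of row-major order, and record ids are assigned after
    permutation, so the output is deterministic given the seed.
    """
    entries: list[tuple[str, str]] = []
    for i, row in enumerate(matrix.row_labels):
        verbatim = "" if row == NOT_IDENTIFIED_LABEL else row
        for j, col in enumerate(matrix.col_labels):
            entries.extend([(verbatim, col)] * int(matrix.counts[i, j]))
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(entries))
    records = []
    for k, idx in enumerate(order):
        verbatim, revised = entries[idx]
        records.append(
            OccurrenceRecord(
                record_id=f"fx-{k:06d}",
                original_name_verbatim=verbatim,
                revised_species=revised,
            )
        )
    return records


def write_classifications(
    classified: Sequence[tuple[OccurrenceRecord, ErrorClassification]],
    path: str | Path,
) -> int:
    with Path(path).open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(["occurrenceID", "verbatimIdentification", "scientificName", "category"])
        for rec, cls_ in classified:
            writer.writerow(
                [rec.record_id, rec.original_name_verbatim, rec.revised_species, cls_.category]
            )
    return len(classified)
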