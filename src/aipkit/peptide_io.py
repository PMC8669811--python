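"""Reading, validating and writing labelled peptide sequence sets.

Sequences are restricted to the 20 standard amino-acid one-letter codes.
Ambiguity/non-standard codes (B, J, O, U, X, Z) are rejected or dropped
depending on the validation policy; lowercase input is folded to uppercase
before validation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "ALPHABET",
    "PeptideRecord",
    "PeptideSet",
    "PeptideIOError",
    "ValidationError",
    "read_fasta",
    "write_fasta",
    "read_labels",
    "write_labels",
]

logger = logging.getLogger(__name__)

#: The 20 standard amino acids, alphabetical by one-letter code.
ALPHABET = "ACDEFGHIKLMNPQRSTVWY"
_ALPHABET_SET = frozenset(ALPHABET)

#: Minimum peptide length in the reference datasets for this problem class.
DEFAULT_MIN_LENGTH = 5

_POLICIES = ("reject", "skip", "sanitize")


class PeptideIOError(ValueError):
    """File-level problem: unreadable, empty, or malformed input."""


class ValidationError(ValueError):
    """A record violates the sequence alphabet or length constraints."""


@dataclass(frozen=True)
class PeptideRecord:
    """One validated peptide: identifier, sequence, optional binary label."""

    id: str
    sequence: str
    label: int | None = None

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass
class PeptideSet:
    """Ordered collection of peptide records with unique identifiers.

    Record order is preserved from input and defines the row order of every
    feature matrix derived from the set.
    """

    records: list[PeptideRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for rec in self.records:
            if rec.id in seen:
                raise ValidationError(f"duplicate record id {rec.id!r}")
            seen.add(rec.id)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[PeptideRecord]:
        return iter(self.records)

    def __getitem__(self, i: int) -> PeptideRecord:
        return self.records[i]

    @property
    def ids(self) -> list[str]:
        return [r.id for r in self.records]

    @property
    def sequences(self) -> list[str]:
        return [r.sequence for r in self.records]

    def labels(self) -> np.ndarray:
        """Binary label vector; raises if any record is unlabelled."""
        if any(r.label is None for r in self.records):
            missing = next(r.id for r in self.records if r.label is None)
            raise ValidationError(f"record {missing!r} has no label")
        return np.asarray([r.label for r in self.records], dtype=int)

    def label_counts(self) -> dict[int | None, int]:
        counts: dict[int | None, int] = {}
        for r in self.records:
            counts[r.label] = counts.get(r.label, 0) + 1
        return counts

    def with_labels(self, labels: dict[str, int]) -> "PeptideSet":
        """Return a copy with labels assigned from an id -> {0,1} mapping."""
        out = []
        for r in self.records:
            if r.id not in labels:
                raise ValidationError(f"no label provided for record {r.id!r}")
            out.append(PeptideRecord(r.id, r.sequence, int(labels[r.id])))
        return PeptideSet(out)

    def concat(self, other: "PeptideSet") -> "PeptideSet":
        return PeptideSet(self.records + other.records)


def _validate_record(
    rid: str, seq: str, min_length: int, policy: str
) -> PeptideRecord | None:
    """Validate one raw record; return None when policy drops it."""
    seq = seq.strip().upper()
    if policy == "sanitize":
        seq = seq.replace("*", "").replace("-", "").replace(" ", "")
    bad = set(seq) - _ALPHABET_SET
    if bad:
        if policy == "reject":
            raise ValidationError(
                f"record {rid!r} contains non-standard residue(s) "
                f"{''.join(sorted(bad))!r}"
            )
        logger.warning("dropping record %r: non-standard residue(s) %s",
                       rid, "".join(sorted(bad)))
        return None
    if len(seq) < min_length:
        if policy == "reject":
            raise ValidationError(
                f"record {rid!r} has length {len(seq)} < minimum {min_length}"
            )
        logger.warning("dropping record %r: length %d < %d",
                       rid, len(seq), min_length)
        return None
    return PeptideRecord(rid, seq)


def read_fasta(
    path: str | Path,
    label: int | None = None,
    min_length: int = DEFAULT_MIN_LENGTH,
    policy: str = "reject",
) -> PeptideSet:
    """Read a FASTA file into a validated :class:`PeptideSet`.

    Parameters
    ----------
    path
        FASTA file (multi-record; wrapped or single-line sequences).
    label
        Optional binary class assigned to every record in the file
        (1 = positive/anti-inflammatory, 0 = negative).
    min_length
        Minimum accepted sequence length.
    policy
        ``"reject"`` raises on the first invalid record, ``"skip"`` drops
        invalid records with a logged warning, ``"sanitize"`` additionally
        strips gap/stop characters before validating.
    """
    if policy not in _POLICIES:
        raise ValueError(f"policy must be one of {_POLICIES}, got {policy!r}")
    path = Path(path)
    if not path.exists():
        raise PeptideIOError(f"no such file: {path}")
    records: list[PeptideRecord] = []
    n_dropped = 0
    for raw in SeqIO.parse(str(path), "fasta"):
        rec = _validate_record(raw.id, str(raw.seq), min_length, policy)
        if rec is None:
            n_dropped += 1
            continue
        if label is not None:
            rec = PeptideRecord(rec.id, rec.sequence, int(label))
        records.append(rec)
    if not records and n_dropped == 0:
        raise PeptideIOError(f"no FASTA records found in {path}")
    if n_dropped:
        logger.warning("%s: dropped %d invalid record(s)", path, n_dropped)
    return PeptideSet(records)


def write_fasta(peptides: PeptideSet, path: str | Path) -> Path:
    """Write a peptide set as single-line-sequence FASTA.

    Round-trips exactly with :func:`read_fasta` on (id, sequence) pairs.
    """
    if len(peptides) == 0:
        raise PeptideIOError("refusing to write an empty peptide set")
    path = Path(path)
    seq_records = [
        SeqRecord(Seq(r.sequence), id=r.id, description="") for r in peptides
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=None)
        writer.write_file(seq_records)
    return path


def read_labels(path: str | Path) -> dict[str, int]:
    """Read a two-column (id, label) TSV into a mapping."""
    path = Path(path)
    labels: dict[str, int] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise PeptideIOError(
                    f"{path}:{lineno}: expected 2 tab-separated columns"
                )
            rid, lab = parts
            if lab not in ("0", "1"):
                raise PeptideIOError(
                    f"{path}:{lineno}: label must be 0 or 1, got {lab!r}"
                )
            labels[rid] = int(lab)
    if not labels:
        raise PeptideIOError(f"no labels found in {path}")
    return labels


def write_labels(peptides: PeptideSet, path: str | Path) -> Path:
    """Write (id, label) TSV for a labelled set."""
    labels = peptides.labels()
    path = Path(path)
    with open(path, "w") as fh:
        for rec, lab in zip(peptides, labels):
            fh.write(f"{rec.id}\t{lab}\n")
    return path


def as_sequences(X: "PeptideSet | Iterable[str | PeptideRecord]") -> list[str]:
    """Coerce estimator input to a list of sequence strings."""
    if isinstance(X, PeptideSet):
        return X.sequences
    out = []
    for item in X:
        if isinstance(item, PeptideRecord):
            out.append(item.sequence)
        elif isinstance(item, str):
            out.append(item)
        else:
            raise TypeError(
                f"expected str or PeptideRecord, got {type(item).__name__}"
            )
    return out
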