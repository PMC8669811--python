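"""Peptide sequence descriptors: AAC, DDE and g-gap dipeptide composition.

Three complementary channels of compositional information:

* **AAC** (amino-acid composition): the 20 per-residue frequencies
  ``AAC(j) = N(j) / L``.
* **DDE** (dipeptide deviation from expected mean): for each of the 400
  ordered residue pairs, the standardised deviation of the observed
  adjacent-dipeptide frequency ``DC(j) = n_j / (L - 1)`` from a
  codon-usage-derived expectation ``TM(j) = (C_j1/CN)(C_j2/CN)`` with
  theoretical variance ``TV(j) = TM(j)(1 - TM(j)) / (L - 1)``:
  ``DDE(j) = (DC(j) - TM(j)) / sqrt(TV(j))``.
* **GDC** (g-gap dipeptide composition): frequencies of ordered residue
  pairs at positions ``(i, i + g)``; each sequence of length L contributes
  ``L - g`` pairs and the 400 counts are normalised to sum to one.

Encoders are scikit-learn transformers: they accept a ``PeptideSet``, a
list of sequence strings or of ``PeptideRecord``; ``transform`` returns an
``(n_samples, n_features)`` float array and ``get_feature_names_out`` the
prefixed column names (``AAC:A``, ``DDE:AA``, ``GDC1:AA`` ...). Thin
module-level functions wrap them into labelled :class:`FeatureMatrix`
objects.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .peptide_io import ALPHABET, PeptideSet, as_sequences

__all__ = [
    "DIPEPTIDES",
    "CodonTable",
    "DEFAULT_CODON_TABLE",
    "FeatureMatrix",
    "AACEncoder",
    "DDEEncoder",
    "GGapDipeptideEncoder",
    "encode_aac",
    "encode_dde",
    "encode_gdc",
    "encode_features",
    "combine",
    "register_encoder",
    "ENCODER_REGISTRY",
]

#: Ordered dipeptides, row-major over the alphabet (AA, AC, ..., AY, CA, ...).
DIPEPTIDES = [a + b for a in ALPHABET for b in ALPHABET]

_RESIDUE_INDEX = {aa: i for i, aa in enumerate(ALPHABET)}


@dataclass(frozen=True)
class CodonTable:
    """Sense-codon counts per amino acid for the DDE expectation.

    The default is the standard genetic code with the three stop codons
    excluded: 61 sense codons in total.
    """

    codon_counts: dict[str, int]

    def __post_init__(self) -> None:
        missing = set(ALPHABET) - set(self.codon_counts)
        if missing:
            raise ValueError(f"codon table missing residues {sorted(missing)}")
        if any(c < 1 for c in self.codon_counts.values()):
            raise ValueError("codon counts must be positive integers")

    @property
    def cn(self) -> int:
        """Total number of sense codons (CN)."""
        return sum(self.codon_counts.values())

    def theoretical_means(self) -> np.ndarray:
        """TM vector over the 400 ordered dipeptides."""
        cn = self.cn
        frac = np.array([self.codon_counts[a] / cn for a in ALPHABET])
        return np.outer(frac, frac).ravel()


DEFAULT_CODON_TABLE = CodonTable(
    {
        "A": 4, "C": 2, "D": 2, "E": 2, "F": 2, "G": 4, "H": 2, "I": 3,
        "K": 2, "L": 6, "M": 1, "N": 2, "P": 4, "Q": 2, "R": 6, "S": 6,
        "T": 4, "V": 4, "W": 1, "Y": 2,
    }
)
assert DEFAULT_CODON_TABLE.cn == 61


@dataclass
class FeatureMatrix:
    """Numeric sample-by-feature matrix with names, ids and optional labels."""

    values: np.ndarray
    feature_names: list[str]
    sample_ids: list[str]
    labels: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D array")
        n, d = self.values.shape
        if len(self.feature_names) != d:
            raise ValueError(
                f"{len(self.feature_names)} feature names for {d} columns"
            )
        if len(set(self.feature_names)) != d:
            raise ValueError("feature names must be unique")
        if len(self.sample_ids) != n:
            raise ValueError(f"{len(self.sample_ids)} sample ids for {n} rows")
        if self.labels is not None:
            self.labels = np.asarray(self.labels, dtype=int)
            if self.labels.shape != (n,):
                raise ValueError("labels length must match row count")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    def select(self, columns: Sequence[int] | Sequence[str]) -> "FeatureMatrix":
        """Column subset by index or by feature name, order preserved."""
        cols = list(columns)
        if cols and isinstance(cols[0], str):
            index = {name: i for i, name in enumerate(self.feature_names)}
            try:
                cols = [index[c] for c in cols]
            except KeyError as e:
                raise KeyError(f"unknown feature name {e.args[0]!r}") from None
        cols = np.asarray(cols, dtype=int)
        return FeatureMatrix(
            self.values[:, cols],
            [self.feature_names[i] for i in cols],
            list(self.sample_ids),
            None if self.labels is None else self.labels.copy(),
        )

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            self.values, columns=self.feature_names,
            index=pd.Index(self.sample_ids, name="sample_id"),
        )
        if self.labels is not None:
            df["label"] = self.labels
        return df

    def to_tsv(self, path: str | Path) -> Path:
        path = Path(path)
        # %.17g round-trips float64 exactly
        self.to_frame().to_csv(path, sep="\t", float_format="%.17g")
        return path

    @classmethod
    def from_tsv(cls, path: str | Path) -> "FeatureMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0,
                         float_precision="round_trip")
        labels = None
        if "label" in df.columns:
            labels = df.pop("label").to_numpy(dtype=int)
        return cls(
            df.to_numpy(dtype=float),
            [str(c) for c in df.columns],
            [str(i) for i in df.index],
            labels,
        )


def _sequence_lengths(seqs: list[str], minimum: int, who: str,
                      ids: list[str] | None = None) -> None:
    for k, s in enumerate(seqs):
        if len(s) < minimum:
            rid = ids[k] if ids else f"#{k}"
            raise ValueError(
                f"{who} requires length >= {minimum}; "
                f"record {rid} has length {len(s)}"
            )


def _residue_indices(seq: str) -> np.ndarray:
    try:
        return np.fromiter(
            (_RESIDUE_INDEX[c] for c in seq), dtype=np.intp, count=len(seq)
        )
    except KeyError as e:
        raise ValueError(
            f"invalid residue {e.args[0]!r}; sequences must be validated "
            "through peptide_io first"
        ) from None


def _seqs_and_ids(X) -> tuple[list[str], list[str] | None]:
    ids = X.ids if isinstance(X, PeptideSet) else None
    return as_sequences(X), ids


class _SequenceEncoder(TransformerMixin, BaseEstimator):
    """Shared plumbing: stateless fit, sequence coercion."""

    _min_length = 1

    def fit(self, X, y=None):
        seqs, ids = _seqs_and_ids(X)
        if not seqs:
            raise ValueError("empty peptide set")
        _sequence_lengths(seqs, self._min_length, type(self).__name__, ids)
        self.n_features_in_ = 1  # one "column": the raw sequence
        return self

    def fit_transform(self, X, y=None, **fit_params):
        return self.fit(X, y).transform(X)

    def _encode_one(self, idx: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def transform(self, X) -> np.ndarray:
        seqs, ids = _seqs_and_ids(X)
        if not seqs:
            raise ValueError("empty peptide set")
        _sequence_lengths(seqs, self._min_length, type(self).__name__, ids)
        return np.vstack([self._encode_one(_residue_indices(s)) for s in seqs])


class AACEncoder(_SequenceEncoder):
    """Amino-acid composition: 20 per-residue frequencies summing to 1."""

    _min_length = 1

    def _encode_one(self, idx: np.ndarray) -> np.ndarray:
        counts = np.bincount(idx, minlength=20).astype(float)
        return counts / idx.size

    def get_feature_names_out(self, input_features=None) -> np.ndarray:
        return np.asarray([f"AAC:{a}" for a in ALPHABET], dtype=object)


class GGapDipeptideEncoder(_SequenceEncoder):
    """g-gap dipeptide composition over ordered pairs at positions (i, i+g).

    A sequence of length L yields ``L - g`` pairs, so L must exceed g; the
    400 pair counts are normalised per sequence to sum to 1.
    """

    def __init__(self, g: int = 1):
        self.g = g

    def _check_g(self) -> int:
        g = self.g
        if not (isinstance(g, (int, np.integer)) and 1 <= g <= 4):
            raise ValueError(f"g must be an integer in 1..4, got {g!r}")
        return int(g)

    @property
    def _min_length(self) -> int:  # type: ignore[override]
        return self._check_g() + 1

    def _encode_one(self, idx: np.ndarray) -> np.ndarray:
        g = self._check_g()
        pair_idx = idx[:-g] * 20 + idx[g:]
        counts = np.bincount(pair_idx, minlength=400).astype(float)
        return counts / counts.sum()

    def get_feature_names_out(self, input_features=None) -> np.ndarray:
        g = self._check_g()
        return np.asarray([f"GDC{g}:{d}" for d in DIPEPTIDES], dtype=object)


class DDEEncoder(_SequenceEncoder):
    """Dipeptide deviation from expected mean over the 400 adjacent pairs.

    The expectation TM and variance TV derive from sense-codon multiplicity
    (how many codons encode each residue of the pair), so DDE depends on the
    sequence only through its adjacent-dipeptide counts and its length.
    """

    _min_length = 2

    def __init__(self, codon_table: CodonTable | None = None):
        self.codon_table = codon_table

    def _table(self) -> CodonTable:
        return self.codon_table if self.codon_table is not None else DEFAULT_CODON_TABLE

    def _encode_one(self, idx: np.ndarray) -> np.ndarray:
        tm = self._table().theoretical_means()
        n_pairs = idx.size - 1
        pair_idx = idx[:-1] * 20 + idx[1:]
        dc = np.bincount(pair_idx, minlength=400).astype(float) / n_pairs
        tv = tm * (1.0 - tm) / n_pairs
        return (dc - tm) / np.sqrt(tv)

    def get_feature_names_out(self, input_features=None) -> np.ndarray:
        return np.asarray([f"DDE:{d}" for d in DIPEPTIDES], dtype=object)


#: Registry mapping encoder names to zero-argument factories; third-party
#: descriptors can be plugged in via :func:`register_encoder`.
ENCODER_REGISTRY: dict[str, type | object] = {}


def register_encoder(name: str, factory) -> None:
    """Register a transformer factory under an encoder name."""
    ENCODER_REGISTRY[name.lower()] = factory


register_encoder("aac", AACEncoder)
register_encoder("dde", DDEEncoder)
for _g in (1, 2, 3, 4):
    register_encoder(f"gdc{_g}", lambda g=_g: GGapDipeptideEncoder(g=g))


def _matrix_from(encoder, peptides: PeptideSet) -> FeatureMatrix:
    values = encoder.fit_transform(peptides)
    labels = None
    counts = peptides.label_counts()
    if None not in counts:
        labels = peptides.labels()
    return FeatureMatrix(
        values,
        list(encoder.get_feature_names_out()),
        peptides.ids,
        labels,
    )


def encode_aac(peptides: PeptideSet) -> FeatureMatrix:
    """AAC feature matrix (20 columns, alphabetical A..Y)."""
    return _matrix_from(AACEncoder(), peptides)


def encode_dde(peptides: PeptideSet,
               codons: CodonTable | None = None) -> FeatureMatrix:
    """DDE feature matrix (400 columns in fixed dipeptide order)."""
    return _matrix_from(DDEEncoder(codon_table=codons), peptides)


def encode_gdc(peptides: PeptideSet, g: int) -> FeatureMatrix:
    """g-gap dipeptide composition matrix (400 columns) for g in 1..4."""
    return _matrix_from(GGapDipeptideEncoder(g=g), peptides)


def combine(features: Iterable[FeatureMatrix]) -> FeatureMatrix:
    """Column-wise concatenation of feature blocks over identical samples."""
    blocks = list(features)
    if not blocks:
        raise ValueError("no feature matrices to combine")
    first = blocks[0]
    for b in blocks[1:]:
        if b.sample_ids != first.sample_ids:
            raise ValueError(
                "feature matrices have mismatched sample ids/order"
            )
        if first.labels is not None and b.labels is not None and not np.array_equal(
            b.labels, first.labels
        ):
            raise ValueError("feature matrices have conflicting labels")
    names: list[str] = []
    for b in blocks:
        names.extend(b.feature_names)
    return FeatureMatrix(
        np.hstack([b.values for b in blocks]),
        names,
        list(first.sample_ids),
        None if first.labels is None else first.labels.copy(),
    )


def encode_features(
    peptides: PeptideSet,
    encoders: Sequence[str] = ("aac", "dde", "gdc1"),
    codon_table: CodonTable | None = None,
) -> FeatureMatrix:
    """Encode with a named subset of {aac, dde, gdc1..gdc4} and concatenate."""
    blocks = []
    for name in encoders:
        key = name.lower().strip()
        if key not in ENCODER_REGISTRY:
            raise ValueError(
                f"unknown encoder {name!r}; available: "
                f"{sorted(ENCODER_REGISTRY)}"
            )
        factory = ENCODER_REGISTRY[key]
        enc = factory() if callable(factory) else factory
        if key == "dde" and codon_table is not None:
            enc = DDEEncoder(codon_table=codon_table)
        blocks.append(_matrix_from(enc, peptides))
    return combine(blocks)
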