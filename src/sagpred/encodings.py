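"""Fixed-length protein sequence descriptors: k-mer, PC-PseAAC, ACC.

Three descriptor families turn a variable-length protein sequence into a
fixed-length real vector:

* **Kmer** — normalized frequencies of all overlapping length-``k``
  substrings over the 20-letter alphabet (``k=2`` gives the classic
  400-dimensional dipeptide composition).

* **PC-PseAAC** — type-1 (parallel-correlation) pseudo amino acid
  composition: the 20 residue-composition fractions plus ``lambda``
  sequence-order correlation factors

  .. math::

     \\theta_j = \\frac{1}{L-j} \\sum_{i=1}^{L-j} \\Theta(R_i, R_{i+j}),
     \\qquad
     \\Theta(R_i, R_j) = \\frac{1}{P} \\sum_{p} (H_p(R_j) - H_p(R_i))^2

  over ``P`` standardized physicochemical scales, the whole vector weighted
  by ``w`` and jointly normalized to sum 1 (20 + lambda components).

* **ACC** — auto-cross covariance: the sequence is translated into ``P``
  numeric property tracks; lagged auto-covariances (same property) and
  cross-covariances (ordered property pairs) for lags 1..``LAG`` give
  ``P*LAG + P*(P-1)*LAG`` components (27 with the default three properties
  and LAG = 3). Track means are per-sequence, so every descriptor is a pure
  function of the single sequence.

Fusions concatenate descriptor blocks column-wise in the declared encoder
order; with defaults the seven possible combinations have widths
400, 22, 27, 422, 427, 49 and 449.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Sequence

import numpy as np

from .sequence_io import ProteinRecord

#: Canonical residue order for all descriptor components.
ALPHABET = "ACDEFGHIKLMNPQRSTVWY"
_RESIDUE_INDEX = {aa: i for i, aa in enumerate(ALPHABET)}

KMER = "kmer"
PC_PSEAAC = "pseaac"
ACC = "acc"
ENCODER_NAMES = (KMER, PC_PSEAAC, ACC)


class EncodingError(ValueError):
    """A sequence violates an encoder precondition (length or residues)."""


def _residue_indices(seq: str, record_id: str = "<sequence>") -> np.ndarray:
    """Map a sequence to alphabet indices; non-standard residues are an error."""
    bad = set(seq) - set(ALPHABET)
    if bad:
        raise EncodingError(
            f"record {record_id!r}: non-standard residues {sorted(bad)!r}; "
            "run the ambiguity filter first"
        )
    if not seq:
        raise EncodingError(f"record {record_id!r}: empty sequence")
    return np.array([_RESIDUE_INDEX[aa] for aa in seq], dtype=np.int64)


class PropertyTable:
    """Per-residue physicochemical scales feeding PC-PseAAC and ACC.

    Each scale is standardized to mean 0 and population standard deviation 1
    (denominator 20) over the 20 standard residues, the convention under
    which pseudo-amino-acid correlation factors are defined.
    """

    def __init__(
        self,
        names: Sequence[str],
        values: dict[str, dict[str, float]],
        normalize: bool = True,
    ) -> None:
        self.names = list(names)
        matrix = np.array(
            [[float(values[name][aa]) for aa in ALPHABET] for name in self.names],
            dtype=np.float64,
        )
        if normalize:
            mean = matrix.mean(axis=1, keepdims=True)
            sd = matrix.std(axis=1, ddof=0, keepdims=True)
            if np.any(sd == 0):
                flat = [n for n, s in zip(self.names, sd.ravel()) if s == 0]
                raise ValueError(f"constant property scales cannot be used: {flat}")
            matrix = (matrix - mean) / sd
        self.matrix = matrix  # shape (P, 20)
        self.normalized = bool(normalize)

    @property
    def n_properties(self) -> int:
        return len(self.names)

    def tracks(self, indices: np.ndarray) -> np.ndarray:
        """Translate residue indices into the (P, L) numeric track matrix."""
        return self.matrix[:, indices]

    @classmethod
    def default(cls) -> "PropertyTable":
        """The shipped hydrophobicity / hydrophilicity / side-chain-mass table."""
        raw = json.loads(
            resources.files("sagpred.data").joinpath("properties.json").read_text()
        )
        return cls(raw["names"], raw["values"], normalize=True)


_DEFAULT_TABLE: PropertyTable | None = None


def default_property_table() -> PropertyTable:
    global _DEFAULT_TABLE
    if _DEFAULT_TABLE is None:
        _DEFAULT_TABLE = PropertyTable.default()
    return _DEFAULT_TABLE


@dataclass(frozen=True, eq=False)
class EncodingSpec:
    """Which descriptors to compute, with which parameters.

    The spec fixes the feature dimensionality and the minimum sequence
    length an input must have to be encodable.
    """

    encoders: tuple[str, ...] = (KMER, PC_PSEAAC)
    k: int = 2
    lam: int = 2
    w: float = 0.05
    lag: int = 3
    property_table: PropertyTable = field(default_factory=default_property_table)

    def __post_init__(self) -> None:
        if not self.encoders:
            raise ValueError("at least one encoder is required")
        unknown = set(self.encoders) - set(ENCODER_NAMES)
        if unknown:
            raise ValueError(f"unknown encoders {sorted(unknown)}; choose from {ENCODER_NAMES}")
        if self.k < 1:
            raise ValueError(f"k must be >= 1, got {self.k}")
        if self.lam < 0:
            raise ValueError(f"lambda must be >= 0, got {self.lam}")
        if not 0 < self.w < 1:
            raise ValueError(f"w must be in (0, 1), got {self.w}")
        if self.lag < 1:
            raise ValueError(f"LAG must be >= 1, got {self.lag}")

    @property
    def min_sequence_length(self) -> int:
        """Shortest sequence length every requested encoder accepts."""
        need = 1
        if KMER in self.encoders:
            need = max(need, self.k)
        if PC_PSEAAC in self.encoders:
            need = max(need, self.lam + 1)
        if ACC in self.encoders:
            need = max(need, self.lag + 1)
        return need


def dimensionality(spec: EncodingSpec) -> int:
    """Total feature count of the fused descriptor defined by ``spec``."""
    p = spec.property_table.n_properties
    widths = {
        KMER: 20**spec.k,
        PC_PSEAAC: 20 + spec.lam,
        ACC: p * spec.lag + p * (p - 1) * spec.lag,
    }
    return sum(widths[e] for e in spec.encoders)


def encode_kmer(seq: str, k: int = 2, record_id: str = "<sequence>") -> np.ndarray:
    """Overlapping k-mer composition: counts / (L - k + 1), length 20**k.

    Components are ordered lexicographically over ``ALPHABET``; the vector
    sums to 1.
    """
    idx = _residue_indices(seq, record_id)
    L = idx.size
    if L < k:
        raise EncodingError(
            f"record {record_id!r}: length {L} < k = {k}; cannot extract k-mers"
        )
    n_windows = L - k + 1
    codes = np.zeros(n_windows, dtype=np.int64)
    for j in range(k):
        codes = codes * 20 + idx[j : j + n_windows]
    counts = np.bincount(codes, minlength=20**k).astype(np.float64)
    return counts / n_windows


def encode_pc_pseaac(
    seq: str,
    lam: int = 2,
    w: float = 0.05,
    props: PropertyTable | None = None,
    record_id: str = "<sequence>",
) -> np.ndarray:
    """Type-1 pseudo amino acid composition, length 20 + lam; sums to 1."""
    props = props or default_property_table()
    idx = _residue_indices(seq, record_id)
    L = idx.size
    if L <= lam:
        raise EncodingError(
            f"record {record_id!r}: length {L} <= lambda = {lam}; "
            "sequence-order factors undefined"
        )
    tracks = props.tracks(idx)  # (P, L)
    f = np.bincount(idx, minlength=20).astype(np.float64) / L
    thetas = np.empty(lam, dtype=np.float64)
    for j in range(1, lam + 1):
        diff = tracks[:, j:] - tracks[:, :-j]  # (P, L-j)
        thetas[j - 1] = np.mean((diff**2).mean(axis=0))
    denom = 1.0 + w * thetas.sum()
    return np.concatenate([f, w * thetas]) / denom


def encode_acc(
    seq: str,
    lag: int = 3,
    props: PropertyTable | None = None,
    record_id: str = "<sequence>",
) -> np.ndarray:
    """Auto-cross covariance over per-sequence-centered property tracks.

    Output order: all auto-covariance blocks (property-major, lag-minor),
    then all cross-covariance blocks (ordered-pair-major, lag-minor); with
    P properties the length is ``P*lag + P*(P-1)*lag``.
    """
    props = props or default_property_table()
    idx = _residue_indices(seq, record_id)
    L = idx.size
    if L <= lag:
        raise EncodingError(
            f"record {record_id!r}: length {L} <= LAG = {lag}; "
            "lagged covariances undefined"
        )
    tracks = props.tracks(idx)
    centered = tracks - tracks.mean(axis=1, keepdims=True)
    p = props.n_properties
    out: list[float] = []
    for a in range(p):
        for g in range(1, lag + 1):
            out.append(float(centered[a, :-g] @ centered[a, g:]) / (L - g))
    for a in range(p):
        for b in range(p):
            if a == b:
                continue
            for g in range(1, lag + 1):
                out.append(float(centered[a, :-g] @ centered[b, g:]) / (L - g))
    return np.array(out, dtype=np.float64)


def _kmer_labels(k: int) -> list[str]:
    return ["kmer:" + "".join(t) for t in itertools.product(ALPHABET, repeat=k)]


def _pseaac_labels(lam: int) -> list[str]:
    return [f"pseaac:{aa}" for aa in ALPHABET] + [
        f"pseaac:theta{j}" for j in range(1, lam + 1)
    ]


def _acc_labels(lag: int, props: PropertyTable) -> list[str]:
    labels = [
        f"acc:AC({name},{g})" for name in props.names for g in range(1, lag + 1)
    ]
    for a in props.names:
        for b in props.names:
            if a == b:
                continue
            labels.extend(f"acc:CC({a},{b},{g})" for g in range(1, lag + 1))
    return labels


def feature_labels(spec: EncodingSpec) -> list[str]:
    """Column names of the fused descriptor, in output order."""
    labels: list[str] = []
    for enc in spec.encoders:
        if enc == KMER:
            labels.extend(_kmer_labels(spec.k))
        elif enc == PC_PSEAAC:
            labels.extend(_pseaac_labels(spec.lam))
        else:
            labels.extend(_acc_labels(spec.lag, spec.property_table))
    return labels


@dataclass
class FeatureMatrix:
    """A (records x features) real matrix with named rows and columns."""

    row_ids: list[str]
    col_names: list[str]
    values: np.ndarray
    spec: EncodingSpec | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2:
            raise ValueError("feature matrix must be 2-D")
        if self.values.shape != (len(self.row_ids), len(self.col_names)):
            raise ValueError(
                f"shape {self.values.shape} does not match "
                f"{len(self.row_ids)} row ids x {len(self.col_names)} columns"
            )

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(self.values, index=self.row_ids, columns=self.col_names)


def encode_sequence(seq: str, spec: EncodingSpec, record_id: str = "<sequence>") -> np.ndarray:
    """Fused descriptor vector for one sequence, in the spec's encoder order."""
    parts = []
    for enc in spec.encoders:
        if enc == KMER:
            parts.append(encode_kmer(seq, spec.k, record_id))
        elif enc == PC_PSEAAC:
            parts.append(
                encode_pc_pseaac(seq, spec.lam, spec.w, spec.property_table, record_id)
            )
        else:
            parts.append(encode_acc(seq, spec.lag, spec.property_table, record_id))
    return np.concatenate(parts)


def encode_matrix(records: Iterable[ProteinRecord], spec: EncodingSpec) -> FeatureMatrix:
    """Encode a batch of records into a :class:`FeatureMatrix`.

    All records are validated against every encoder's length precondition
    first; any offender aborts the whole batch with an error listing the ids
    (no partial matrix is returned).
    """
    records = list(records)
    min_len = spec.min_sequence_length
    too_short = [r.id for r in records if len(r) < min_len]
    if too_short:
        raise EncodingError(
            f"{len(too_short)} record(s) shorter than the minimum encodable "
            f"length {min_len}: {too_short[:10]}"
        )
    n_cols = dimensionality(spec)
    values = np.empty((len(records), n_cols), dtype=np.float64)
    for i, rec in enumerate(records):
        values[i] = encode_sequence(rec.sequence, spec, rec.id)
    return FeatureMatrix(
        row_ids=[r.id for r in records],
        col_names=feature_labels(spec),
        values=values,
        spec=spec,
    )
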