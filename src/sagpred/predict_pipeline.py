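"""Proteome-wide prediction workflow: clean, encode, score, extract ids.

Prediction-mode cleaning applies only the ambiguity filter and the encoder
length preconditions — redundancy clustering is a training-set concern and
is never applied here. Records that cannot be scored are reported with a
reason instead of being silently dropped, so the output id multiset always
equals the input id multiset.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

from .classifiers import ModelBundle, predict_scores
from .encodings import EncodingSpec, encode_matrix
from .preprocess import CleaningConfig, _is_ambiguous
from .sequence_io import ProteinRecord

SAG = "SAG"
NON_SAG = "non-SAG"

AMBIGUOUS = "ambiguous_residues"
TOO_SHORT = "too_short"


class PredictionError(ValueError):
    pass


@dataclass(frozen=True)
class PredictionRecord:
    """Outcome for one input sequence: a score+label, or a skip reason."""

    id: str
    score: float | None = None
    label: str | None = None
    skipped_reason: str | None = None

    def __post_init__(self) -> None:
        scored = self.score is not None and self.label is not None
        skipped = self.skipped_reason is not None
        if scored == skipped:
            raise ValueError(
                f"record {self.id!r}: exactly one of (score+label) or "
                "skipped_reason must be present"
            )


def clean_new(
    records: Sequence[ProteinRecord],
    spec: EncodingSpec,
    min_length: int = 50,
    forbidden_residues: frozenset[str] = CleaningConfig.forbidden_residues,
) -> tuple[list[ProteinRecord], list[PredictionRecord]]:
    """Prediction-mode cleaning: ambiguity filter + length preconditions.

    A record is skipped if it contains non-standard residues, or if it is
    shorter than ``min_length`` or too short for any encoder in ``spec``.
    Returns (encodable records, skipped records with reasons).
    """
    min_ok = max(min_length, spec.min_sequence_length)
    kept: list[ProteinRecord] = []
    skipped: list[PredictionRecord] = []
    for rec in records:
        if _is_ambiguous(rec, forbidden_residues):
            skipped.append(PredictionRecord(id=rec.id, skipped_reason=AMBIGUOUS))
        elif len(rec) < min_ok:
            skipped.append(PredictionRecord(id=rec.id, skipped_reason=TOO_SHORT))
        else:
            kept.append(rec)
    return kept, skipped


def predict_sags(
    records: Sequence[ProteinRecord],
    bundle: ModelBundle,
    min_length: int = 50,
    chunk_size: int = 2000,
) -> list[PredictionRecord]:
    """Score every record with the bundle's pipeline; skip unencodable ones.

    Encoding is streamed in chunks so whole proteomes fit in bounded memory;
    the chunk size never changes the output. Results are returned in input
    order, one entry per input id.
    """
    if bundle.spec is None:
        raise PredictionError(
            "bundle carries no encoding spec; cannot encode raw sequences"
        )
    spec = bundle.spec
    encodable, skipped = clean_new(records, spec, min_length=min_length)
    by_id: dict[str, PredictionRecord] = {p.id: p for p in skipped}
    for start in range(0, len(encodable), chunk_size):
        chunk = encodable[start : start + chunk_size]
        feats = encode_matrix(chunk, spec)
        scores = predict_scores(bundle, feats)
        for rec, score in zip(chunk, scores):
            label = SAG if score >= bundle.decision_threshold else NON_SAG
            by_id[rec.id] = PredictionRecord(id=rec.id, score=float(score), label=label)
    return [by_id[rec.id] for rec in records]


def extract_ids(
    predictions: Iterable[PredictionRecord], which: str = SAG
) -> list[str]:
    """Ids of predictions carrying the requested label, input order preserved."""
    return [p.id for p in predictions if p.label == which]


def summarize_proteome(predictions: Sequence[PredictionRecord]) -> dict:
    """Proteome-level summary: counts and the percentage of predicted SAGs.

    Skipped records are excluded from the percentage denominator and
    reported separately.
    """
    n_total = len(predictions)
    scored = [p for p in predictions if p.skipped_reason is None]
    n_skipped = n_total - len(scored)
    if not scored:
        raise PredictionError("no scored records; cannot summarize")
    n_sag = sum(1 for p in scored if p.label == SAG)
    return {
        "n_total": n_total,
        "n_scored": len(scored),
        "n_skipped": n_skipped,
        "n_sag": n_sag,
        "sag_percentage": 100.0 * n_sag / len(scored),
    }
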