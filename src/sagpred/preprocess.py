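"""Training-set cleaning: ambiguity filter, length filter, redundancy removal.

Three rules are applied in order:

1. drop records containing ambiguous residues (B, J, O, U, X, Z by default)
   or any character outside the 20 standard amino-acid letters;
2. drop records shorter than a minimum length (default 50 residues);
3. collapse redundant sequences with greedy longest-first clustering at a
   fractional identity threshold (default 0.7), keeping one representative
   (the longest member) per cluster.

Identity between two sequences is the number of identical aligned residues
in a best-scoring global alignment divided by the length of the shorter
sequence — the convention of the classic greedy clustering tools. With match
score 1 and zero mismatch/gap penalties the optimal global alignment score
equals the length of the longest common subsequence, which makes the measure
deterministic and alignment-path independent.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from Bio import Align

from .sequence_io import STANDARD_RESIDUES, ProteinRecord


@dataclass(frozen=True)
class CleaningConfig:
    """Parameters of the three cleaning rules."""

    forbidden_residues: frozenset[str] = frozenset("BJOUXZ")
    min_length: int = 50
    redundancy_threshold: float = 0.7
    redundancy_enabled: bool = True

    def __post_init__(self) -> None:
        if not 0 < self.redundancy_threshold <= 1:
            raise ValueError(
                f"redundancy_threshold must be in (0, 1], got "
                f"{self.redundancy_threshold}"
            )
        if self.min_length < 1:
            raise ValueError(f"min_length must be >= 1, got {self.min_length}")


@dataclass
class CleaningReport:
    """Audit trail of one cleaning run; counts always reconcile."""

    n_input: int = 0
    n_removed_ambiguous: int = 0
    n_removed_short: int = 0
    n_removed_redundant: int = 0
    n_kept: int = 0
    removed_ids: dict[str, list[str]] = field(
        default_factory=lambda: {"ambiguous": [], "short": [], "redundant": []}
    )

    def __post_init__(self) -> None:
        total = (
            self.n_kept
            + self.n_removed_ambiguous
            + self.n_removed_short
            + self.n_removed_redundant
        )
        if self.n_input != total:
            raise ValueError(
                f"cleaning report does not reconcile: n_input={self.n_input} "
                f"but removed+kept={total}"
            )


def _is_ambiguous(record: ProteinRecord, forbidden: frozenset[str]) -> bool:
    chars = set(record.sequence)
    return bool(chars & forbidden) or bool(chars - STANDARD_RESIDUES)


def filter_ambiguous(
    records: list[ProteinRecord], config: CleaningConfig | None = None
) -> tuple[list[ProteinRecord], list[ProteinRecord]]:
    """Split records into (kept, removed) by the ambiguous-residue rule.

    A record is removed iff it contains a forbidden residue or any character
    outside the 20 standard amino-acid letters (internal stops included).
    Order of kept records is preserved.
    """
    config = config or CleaningConfig()
    kept, removed = [], []
    for rec in records:
        (removed if _is_ambiguous(rec, config.forbidden_residues) else kept).append(rec)
    return kept, removed


def filter_length(
    records: list[ProteinRecord], config: CleaningConfig | None = None
) -> tuple[list[ProteinRecord], list[ProteinRecord]]:
    """Split records into (kept, removed): removed iff shorter than min_length."""
    config = config or CleaningConfig()
    kept, removed = [], []
    for rec in records:
        (kept if len(rec) >= config.min_length else removed).append(rec)
    return kept, removed


def _make_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 1
    aligner.mismatch_score = 0
    aligner.open_gap_score = 0
    aligner.extend_gap_score = 0
    return aligner


_ALIGNER = _make_aligner()


def pairwise_identity(a: str, b: str) -> float:
    """Fraction of identical aligned residues over the shorter sequence.

    Best-scoring global alignment with match=1, mismatch=0, gap=0; the score
    is then the maximum number of matched residues (the LCS length).
    """
    if not a or not b:
        return 0.0
    matches = _ALIGNER.score(a, b)
    return matches / min(len(a), len(b))


def remove_redundancy(
    records: list[ProteinRecord], config: CleaningConfig | None = None
) -> tuple[list[ProteinRecord], dict[str, list[str]]]:
    """Greedy longest-first clustering at the configured identity threshold.

    Records are visited by decreasing length (ties by id); each joins the
    first existing cluster whose representative it matches at identity >=
    threshold, else founds a new cluster. The founder, being the longest
    member, is the representative. Returns representatives in the original
    input order and a mapping representative-id -> member ids (representative
    first, then joiners in visit order).
    """
    config = config or CleaningConfig()
    ordered = sorted(records, key=lambda r: (-len(r), r.id))
    reps: list[ProteinRecord] = []
    clusters: dict[str, list[str]] = {}
    for rec in ordered:
        for rep in reps:
            if pairwise_identity(rec.sequence, rep.sequence) >= config.redundancy_threshold:
                clusters[rep.id].append(rec.id)
                break
        else:
            reps.append(rec)
            clusters[rec.id] = [rec.id]
    rep_ids = set(clusters)
    representatives = [r for r in records if r.id in rep_ids]
    return representatives, clusters


def clean(
    records: list[ProteinRecord], config: CleaningConfig | None = None
) -> tuple[list[ProteinRecord], CleaningReport]:
    """Apply all cleaning rules in order and return (kept, report).

    A record failing several rules is attributed to the first rule that
    removes it, so the report counts partition the input.
    """
    config = config or CleaningConfig()
    after_amb, removed_amb = filter_ambiguous(records, config)
    after_len, removed_len = filter_length(after_amb, config)
    if config.redundancy_enabled:
        kept, clusters = remove_redundancy(after_len, config)
        kept_ids = {r.id for r in kept}
        removed_red = [r.id for r in after_len if r.id not in kept_ids]
    else:
        kept = after_len
        removed_red = []
    report = CleaningReport(
        n_input=len(records),
        n_removed_ambiguous=len(removed_amb),
        n_removed_short=len(removed_len),
        n_removed_redundant=len(removed_red),
        n_kept=len(kept),
        removed_ids={
            "ambiguous": [r.id for r in removed_amb],
            "short": [r.id for r in removed_len],
            "redundant": removed_red,
        },
    )
    return kept, report
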