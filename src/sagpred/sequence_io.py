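"""Protein FASTA input/output.

The toolkit's record model is deliberately strict: identifiers are the first
whitespace-delimited header token, must be unique within a file, and sequences
are case-folded to uppercase on read. A single trailing ``*`` (translation
stop) is stripped and logged; internal ``*`` characters are kept so that the
downstream ambiguity filter can reject the record with a proper audit trail.
Alignment gap characters (``-``, ``.``) are rejected outright.
"""

from __future__ import annotations

import logging
import string
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

logger = logging.getLogger("sagpred.sequence_io")

#: The 20 standard amino-acid one-letter codes, in alphabetical order.
STANDARD_RESIDUES = frozenset("ACDEFGHIKLMNPQRSTVWY")

_ALLOWED_CHARS = frozenset(string.ascii_uppercase) | {"*"}


class FastaParseError(ValueError):
    """Malformed FASTA input (reported with the offending line number)."""


class DuplicateIdError(ValueError):
    """Two records in one file share an identifier."""


@dataclass(frozen=True)
class ProteinRecord:
    """One FASTA entry: identifier, free-text description, residue string."""

    id: str
    description: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("record id must be non-empty")
        bad = set(self.sequence) - _ALLOWED_CHARS
        if bad:
            raise ValueError(
                f"record {self.id!r}: invalid sequence characters "
                f"{sorted(bad)!r} (gaps and lowercase are not allowed)"
            )

    def __len__(self) -> int:
        return len(self.sequence)


def _finish_record(header: str, chunks: list[str], lineno: int) -> ProteinRecord:
    parts = header.split(None, 1)
    if not parts:
        raise FastaParseError(f"line {lineno}: empty FASTA header")
    rec_id = parts[0]
    description = parts[1].strip() if len(parts) > 1 else ""
    seq = "".join(chunks).upper()
    if "-" in seq or "." in seq:
        raise FastaParseError(
            f"record {rec_id!r}: alignment gap characters ('-'/'.') are not "
            "accepted; supply ungapped protein sequences"
        )
    if seq.endswith("*"):
        seq = seq[:-1]
        logger.info("record %s: stripped one trailing stop character '*'", rec_id)
    return ProteinRecord(id=rec_id, description=description, sequence=seq)


def read_fasta(path: str | Path) -> list[ProteinRecord]:
    """Parse a protein FASTA file into a list of :class:`ProteinRecord`.

    Multi-line sequence bodies are concatenated and case-folded to uppercase;
    one trailing ``*`` per record is removed. Records are returned in file
    order. Raises :class:`FastaParseError` if sequence data precedes the
    first ``>`` header (with the line number) and :class:`DuplicateIdError`
    if an identifier occurs twice.
    """
    records: list[ProteinRecord] = []
    header: str | None = None
    header_line = 0
    chunks: list[str] = []
    with open(path, "r", encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith(">"):
                if header is not None:
                    records.append(_finish_record(header, chunks, header_line))
                header = line[1:].strip()
                header_line = lineno
                chunks = []
            else:
                if header is None:
                    raise FastaParseError(
                        f"line {lineno}: sequence data encountered before any "
                        "'>' header"
                    )
                chunks.append(line)
    if header is not None:
        records.append(_finish_record(header, chunks, header_line))

    seen: set[str] = set()
    dupes: set[str] = set()
    for rec in records:
        if rec.id in seen:
            dupes.add(rec.id)
        seen.add(rec.id)
    if dupes:
        raise DuplicateIdError(f"duplicate record ids in {path}: {sorted(dupes)}")
    return records


def write_fasta(
    records: Iterable[ProteinRecord], path: str | Path, wrap: int = 60
) -> int:
    """Write records as multi-line FASTA; returns the number written.

    ``wrap`` is the sequence line width (must be positive). Reading the file
    back reproduces id, description and sequence exactly.
    """
    if wrap < 1:
        raise ValueError(f"wrap must be a positive integer, got {wrap}")
    n = 0
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        for rec in records:
            header = f">{rec.id} {rec.description}".rstrip()
            fh.write(header + "\n")
            for start in range(0, len(rec.sequence), wrap):
                fh.write(rec.sequence[start : start + wrap] + "\n")
            n += 1
    return n


def write_table(frame, path: str | Path) -> None:
    """Write a DataFrame as the toolkit's standard TSV (header, UTF-8, LF)."""
    frame.to_csv(path, sep="\t", index=False, encoding="utf-8", lineterminator="\n")
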