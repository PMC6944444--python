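"""Sequence records and FASTA input/output.

A repertoire is a list of :class:`SequenceRecord`.  FASTA headers carry two
optional key=value tags, ``species`` and ``annotation`` (``NLR``,
``non-NLR`` or ``unknown``), either bare (``species=tomato``) or bracketed
(``[species=tomato]``).  Residues are stored upper-case; ``X`` marks an
unknown or masked residue.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional

from Bio import SeqIO

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
VALID_RESIDUES = frozenset(AMINO_ACIDS + "X")

ANNOTATIONS = ("NLR", "non-NLR", "unknown")

_TAG_RE = re.compile(r"\[?(\w+)=([^\s\]]+)\]?")


@dataclass
class SequenceRecord:
    """One protein sequence with its provenance tags."""

    id: str
    residues: str
    species: str = "unknown"
    annotation: str = "unknown"

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("record id must be non-empty")
        self.residues = self.residues.upper()
        if not self.residues:
            raise ValueError(f"record {self.id!r}: empty sequence")
        if "-" in self.residues:
            raise ValueError(f"record {self.id!r}: gap characters not allowed")
        bad = set(self.residues) - VALID_RESIDUES
        if bad:
            raise ValueError(
                f"record {self.id!r}: invalid residue symbols {sorted(bad)}"
            )
        if self.annotation not in ANNOTATIONS:
            raise ValueError(
                f"record {self.id!r}: annotation must be one of {ANNOTATIONS}"
            )

    def __len__(self) -> int:
        return len(self.residues)


@dataclass
class DomainAnnotation:
    """NB-ARC anchor and derived N-terminal domain interval (1-based)."""

    record_id: str
    ploop_start: Optional[int] = None
    nbarc_start: Optional[int] = None
    nterm_interval: Optional[tuple[int, int]] = field(default=None)
    nterm_length: int = 0

    def __post_init__(self) -> None:
        if self.nbarc_start is not None:
            if self.nterm_length != self.nbarc_start - 1:
                raise ValueError(
                    "nterm_length must equal nbarc_start - 1 "
                    f"({self.nterm_length} != {self.nbarc_start - 1})"
                )
            if self.nterm_interval is not None and self.nterm_interval[1] >= self.nbarc_start:
                raise ValueError("nterm_interval must end before nbarc_start")


def _parse_header(header: str) -> tuple[str, str, str]:
    parts = header.split(None, 1)
    rec_id = parts[0]
    species = "unknown"
    annotation = "unknown"
    if len(parts) > 1:
        for key, value in _TAG_RE.findall(parts[1]):
            if key == "species":
                species = value
            elif key == "annotation":
                annotation = value
    return rec_id, species, annotation


def read_fasta(path: str | Path) -> list[SequenceRecord]:
    """Read a protein FASTA file into a list of records.

    Order is preserved; wrapped sequence lines are concatenated; residues
    are upper-cased.  Duplicate ids and empty files are errors.
    """
    path = Path(path)
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    for seq_rec in SeqIO.parse(str(path), "fasta"):
        rec_id, species, annotation = _parse_header(seq_rec.description or seq_rec.id)
        if rec_id in seen:
            raise ValueError(f"duplicate record id {rec_id!r} in {path}")
        seen.add(rec_id)
        records.append(
            SequenceRecord(
                id=rec_id,
                residues=str(seq_rec.seq),
                species=species,
                annotation=annotation,
            )
        )
    if not records:
        raise ValueError(f"no FASTA records found in {path}")
    return records


def write_fasta(records: Iterable[SequenceRecord], path: str | Path, width: int = 60) -> None:
    """Write records as FASTA, wrapped at ``width`` columns.

    ``species``/``annotation`` tags are emitted only when informative, so
    write∘read round-trips exactly.
    """
    path = Path(path)
    with open(path, "w") as fh:
        for rec in records:
            header = rec.id
            if rec.species != "unknown":
                header += f" species={rec.species}"
            if rec.annotation != "unknown":
                header += f" annotation={rec.annotation}"
            fh.write(f">{header}\n")
            for i in range(0, len(rec.residues), width):
                fh.write(rec.residues[i : i + width] + "\n")
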