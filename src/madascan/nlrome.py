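"""NLRome compilation: p-loop detection, NB-ARC anchoring, N-terminal
domain extraction and the database filters.

Candidate NLRs are kept only if they contain a Walker-A p-loop, have an
N-terminal region strictly longer than ``min_nterm`` residues before the
NB-ARC anchor, and are not flagged as TIR-clade members.  All coordinates
are 1-based inclusive.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Optional, Sequence

from .records import DomainAnnotation, SequenceRecord

#: Walker-A nucleotide-binding motif G-x(4)-G-K-[S/T]; configurable because
#: upstream NLR annotation tools do not publish a single canonical regex.
DEFAULT_PLOOP_PATTERN = r"G.{4}GK[ST]"


@dataclass
class DroppedRecord:
    record: SequenceRecord
    reason: str  # no_ploop | short_nterm | tir_clade


def detect_ploop(record: SequenceRecord, pattern: str = DEFAULT_PLOOP_PATTERN) -> Optional[int]:
    """1-based start of the first Walker-A match, or ``None`` if absent."""
    m = re.search(pattern, record.residues)
    return m.start() + 1 if m else None


def annotate_domains(record: SequenceRecord, offset_to_nbarc: int = 0,
                     pattern: str = DEFAULT_PLOOP_PATTERN) -> DomainAnnotation:
    """Anchor the NB-ARC at ``ploop_start - offset_to_nbarc`` (floored at 1)
    and derive the N-terminal domain interval ``[1, nbarc_start - 1]``."""
    ploop = detect_ploop(record, pattern)
    if ploop is None:
        raise ValueError(
            f"record {record.id!r} has no p-loop; filter such records before annotating"
        )
    nbarc_start = max(1, ploop - offset_to_nbarc)
    nterm_length = nbarc_start - 1
    interval = (1, nterm_length) if nterm_length >= 1 else None
    return DomainAnnotation(
        record_id=record.id,
        ploop_start=ploop,
        nbarc_start=nbarc_start,
        nterm_interval=interval,
        nterm_length=nterm_length,
    )


def nterm_sequence(record: SequenceRecord, annotation: DomainAnnotation) -> str:
    if annotation.nterm_interval is None:
        return ""
    lo, hi = annotation.nterm_interval
    return record.residues[lo - 1 : hi]


def nbarc_sequence(record: SequenceRecord, annotation: DomainAnnotation,
                   length: Optional[int] = None) -> str:
    """NB-ARC region from the anchor, optionally truncated to ``length``."""
    start = annotation.nbarc_start - 1
    seq = record.residues[start:]
    return seq[:length] if length is not None else seq


def compile_cc_nlr_db(
    records: Sequence[SequenceRecord],
    min_nterm: int = 30,
    offset_to_nbarc: int = 0,
    tir_ids: Iterable[str] = (),
    pattern: str = DEFAULT_PLOOP_PATTERN,
) -> tuple[list[tuple[SequenceRecord, DomainAnnotation]], list[DroppedRecord]]:
    """Apply the database filters.

    Drops records lacking a p-loop (``no_ploop``), records whose
    N-terminal domain is not strictly longer than ``min_nterm`` residues
    (``short_nterm``), and records listed in ``tir_ids`` — typically the
    output of :func:`madascan.phylo.flag_clade` on the NB-ARC tree
    (``tir_clade``).  Returns ``(kept, dropped)``; kept entries carry
    their :class:`DomainAnnotation`.
    """
    tir_ids = set(tir_ids)
    kept: list[tuple[SequenceRecord, DomainAnnotation]] = []
    dropped: list[DroppedRecord] = []
    for rec in records:
        if rec.id in tir_ids:
            dropped.append(DroppedRecord(rec, "tir_clade"))
            continue
        ploop = detect_ploop(rec, pattern)
        if ploop is None:
            dropped.append(DroppedRecord(rec, "no_ploop"))
            continue
        ann = annotate_domains(rec, offset_to_nbarc, pattern)
        if ann.nterm_length <= min_nterm:
            dropped.append(DroppedRecord(rec, "short_nterm"))
            continue
        kept.append((rec, ann))
    return kept, dropped


def write_dropped_report(dropped: Sequence[DroppedRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("record_id\treason\n")
        for d in dropped:
            fh.write(f"{d.record.id}\t{d.reason}\n")
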