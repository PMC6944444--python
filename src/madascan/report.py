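"""Positional classification of motif hits and summary tables.

Percentages are always ``round(100 * a / b, 1)`` and recompute exactly
from the emitted counts.  A motif occurrence is "very N-terminal" when
the extension before it (start - 1 residues) is at most 15 residues;
longer extensions are "extended".
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .hmm import HmmHit
from .records import SequenceRecord

VERY_N_TERMINAL = "very_n_terminal"
EXTENDED = "extended"

#: N-terminal regions at least this long (before the predicted CC start)
#: are reported as NTD-bearing; a declared heuristic for the ~600-residue
#: sensor extension domains.
NTD_MIN_LENGTH = 450


def pct(a: float, b: float) -> float:
    return round(100.0 * a / b, 1) if b else 0.0


def position_class(hit: HmmHit, extension_max: int = 15) -> str:
    """Classify a hit by the length of sequence before the motif."""
    if hit.start < 1:
        raise ValueError("hit has no start position")
    extension = hit.start - 1
    return EXTENDED if extension > extension_max else VERY_N_TERMINAL


def precision_vs_annotation(hits: Sequence[HmmHit],
                            records: Sequence[SequenceRecord],
                            cutoff: float = 10.0,
                            bin_width: float = 5.0):
    """Fraction of above-cutoff hits that land on annotated NLRs.

    Returns ``(per_species, overall, histogram)``: per-species and
    overall ``(nlr_hits, total_hits, precision_pct)`` over hits scoring
    >= cutoff, plus a score histogram (NLR vs non-NLR counts per bin of
    ``bin_width`` bits) over all reported hits.
    """
    by_id = {r.id: r for r in records}
    known = [r for r in by_id.values() if r.annotation != "unknown"]
    if not known:
        raise ValueError("no records carry an NLR/non-NLR annotation")
    rows = []
    for h in hits:
        rec = by_id.get(h.record_id)
        if rec is None:
            raise KeyError(f"hit on unknown record {h.record_id!r}")
        rows.append({
            "record_id": h.record_id,
            "species": rec.species,
            "score": h.score,
            "is_nlr": rec.annotation == "NLR",
        })
    df = pd.DataFrame(rows)
    over = df[df["score"] >= cutoff] if len(df) else df
    per_species = {}
    if len(over):
        for species, grp in over.groupby("species"):
            nlr = int(grp["is_nlr"].sum())
            per_species[species] = (nlr, len(grp), pct(nlr, len(grp)))
    nlr_total = int(over["is_nlr"].sum()) if len(over) else 0
    overall = (nlr_total, len(over), pct(nlr_total, len(over)))

    if len(df):
        bins = np.floor(df["score"] / bin_width) * bin_width
        hist = (df.assign(bin=bins)
                  .groupby("bin")["is_nlr"]
                  .agg(nlr="sum", total="count")
                  .assign(non_nlr=lambda t: t["total"] - t["nlr"])
                  .drop(columns="total")
                  .astype(int))
    else:
        hist = pd.DataFrame(columns=["nlr", "non_nlr"])
    return per_species, overall, hist


@dataclass
class SummaryReport:
    species_table: pd.DataFrame
    tribe_table: pd.DataFrame
    positional: dict
    clade_table: pd.DataFrame
    precision: Optional[dict] = None

    def to_dict(self) -> dict:
        out = {
            "species": self.species_table.reset_index().to_dict(orient="records"),
            "tribes": self.tribe_table.reset_index().to_dict(orient="records"),
            "positional": self.positional,
            "clades": self.clade_table.reset_index().to_dict(orient="records"),
        }
        if self.precision is not None:
            out["precision"] = self.precision
        return out

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2, sort_keys=True, default=str)

    def write(self, outdir: str | Path, stem: str = "summary") -> None:
        outdir = Path(outdir)
        (outdir / f"{stem}.json").write_text(self.to_json() + "\n")
        self.species_table.to_csv(outdir / f"{stem}_species.tsv", sep="\t")
        self.tribe_table.to_csv(outdir / f"{stem}_tribes.tsv", sep="\t")
        self.clade_table.to_csv(outdir / f"{stem}_clades.tsv", sep="\t")


def summarize(db, tribes, hits: Sequence[HmmHit],
              clade_labels: Optional[dict[str, str]] = None,
              extension_max: int = 15) -> SummaryReport:
    """Assemble the summary tables.

    ``db`` is the compiled database: a sequence of
    ``(SequenceRecord, DomainAnnotation)`` pairs.  ``hits`` must already
    carry class labels (see :func:`madascan.hmm.classify`).  ``tribes``
    may be ``None``; ``clade_labels`` maps record ids to clade names.
    """
    recs = {rec.id: (rec, ann) for rec, ann in db}
    orphans = [h.record_id for h in hits if h.record_id not in recs]
    if tribes is not None:
        orphans += [i for i in tribes.tribe_of if i not in recs]
    if orphans:
        raise ValueError(f"ids not in the database: {sorted(set(orphans))}")

    label_of = {h.record_id: (h.label or "none") for h in hits}
    hit_of = {h.record_id: h for h in hits}

    sp_rows: dict[str, dict] = {}
    for rec_id, (rec, _ann) in recs.items():
        row = sp_rows.setdefault(rec.species,
                                 {"total": 0, "mada": 0, "madal": 0})
        row["total"] += 1
        label = label_of.get(rec_id, "none")
        if label == "MADA":
            row["mada"] += 1
        elif label == "MADAL":
            row["madal"] += 1
    species_table = pd.DataFrame.from_dict(sp_rows, orient="index")
    species_table.index.name = "species"
    species_table = species_table.sort_index()
    species_table["pct_mada_madal"] = [
        pct(r.mada + r.madal, r.total) for r in species_table.itertuples()]

    if tribes is not None:
        tr_rows = []
        for tid in sorted(tribes.tribes):
            members = tribes.tribes[tid]
            mada = sum(1 for m in members if label_of.get(m) == "MADA")
            madal = sum(1 for m in members if label_of.get(m) == "MADAL")
            tr_rows.append({"tribe_id": tid, "size": len(members),
                            "mada": mada, "madal": madal})
        tribe_table = pd.DataFrame(tr_rows).set_index("tribe_id")
    else:
        tribe_table = pd.DataFrame(columns=["size", "mada", "madal"])
        tribe_table.index.name = "tribe_id"

    positive = [h for h in hits if h.label in ("MADA", "MADAL")]
    starts = sorted(h.start for h in positive)
    n_very = sum(1 for h in positive
                 if position_class(h, extension_max) == VERY_N_TERMINAL)
    total_db = len(recs)
    positional = {
        "n_mada": sum(1 for h in positive if h.label == "MADA"),
        "n_madal": sum(1 for h in positive if h.label == "MADAL"),
        "n_db": total_db,
        "pct_mada_madal_of_db": pct(len(positive), total_db),
        "n_very_n_terminal": n_very,
        "n_extended": len(positive) - n_very,
        "pct_very_n_terminal": pct(n_very, len(positive)),
        "start_histogram": {str(s): starts.count(s) for s in sorted(set(starts))},
    }

    clade_rows = []
    if clade_labels:
        for clade in sorted(set(clade_labels.values())):
            members = [i for i, c in clade_labels.items() if c == clade and i in recs]
            mada = sum(1 for m in members if label_of.get(m) == "MADA")
            madal = sum(1 for m in members if label_of.get(m) == "MADAL")
            ntd = sum(1 for m in members
                      if recs[m][1].nterm_length >= NTD_MIN_LENGTH)
            clade_rows.append({
                "clade": clade, "examined": len(members),
                "mada_predicted": mada, "madal": madal,
                "ntd_bearing": ntd,
                "pct_mada": pct(mada, len(members)),
            })
    clade_table = (pd.DataFrame(clade_rows).set_index("clade")
                   if clade_rows else
                   pd.DataFrame(columns=["examined", "mada_predicted", "madal",
                                         "ntd_bearing", "pct_mada"]))
    return SummaryReport(species_table=species_table, tribe_table=tribe_table,
                         positional=positional, clade_table=clade_table)
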