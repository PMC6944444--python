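"""Loaders and counting helpers for published score/tribe/clade tables.

These functions recompute headline counts (MADA / MADA-like totals,
overall percentages, positional fractions, per-proteome precision and
helper/sensor clade tallies) directly from tabular exports of the kind
that accompany an NLRome HMM scan: one row per protein with a bit
score, motif start/end, tribe assignment, clade label and annotation.
Tables are read as TSV/CSV; column names are matched case-insensitively
with common variants (including the ``MADA_strat`` spelling that
appears in published tables).
"""

from __future__ import annotations

from pathlib import Path
from typing import Optional

import pandas as pd

_COLUMN_ALIASES = {
    "id": {"id", "record_id", "protein", "protein_id", "name", "seqid"},
    "score": {"score", "hmm_score", "hmm score", "bits", "bit_score"},
    "start": {"start", "mada_start", "mada_strat", "motif_start"},
    "end": {"end", "mada_end", "motif_end"},
    "tribe": {"tribe", "tribe_id", "tribe-mcl", "tribe_mcl"},
    "clade": {"clade", "nrc", "nrc_clade", "nrc clade"},
    "annotation": {"annotation", "annot", "class", "category"},
    "species": {"species", "organism"},
}


def _standardize(df: pd.DataFrame) -> pd.DataFrame:
    rename = {}
    for col in df.columns:
        key = str(col).strip().lower()
        for standard, aliases in _COLUMN_ALIASES.items():
            if key in aliases:
                rename[col] = standard
                break
    return df.rename(columns=rename)


def load_table(path: str | Path) -> pd.DataFrame:
    """Read a TSV/CSV table and standardize its column names."""
    path = Path(path)
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    return _standardize(pd.read_csv(path, sep=sep))


def count_mada_madal(df: pd.DataFrame, cutoff: float = 10.0,
                     madal_floor: float = 0.0) -> tuple[int, int]:
    """(n_mada, n_madal): rows scoring >= cutoff, and rows with
    madal_floor < score < cutoff."""
    scores = pd.to_numeric(df["score"], errors="coerce").dropna()
    n_mada = int((scores >= cutoff).sum())
    n_madal = int(((scores > madal_floor) & (scores < cutoff)).sum())
    return n_mada, n_madal


def pct_of_db(df: pd.DataFrame, n_db: int, cutoff: float = 10.0,
              madal_floor: float = 0.0) -> float:
    n_mada, n_madal = count_mada_madal(df, cutoff, madal_floor)
    return round(100.0 * (n_mada + n_madal) / n_db, 1)


def positional_fraction(df: pd.DataFrame, extension_max: int = 15,
                        cutoff: float = 10.0, madal_floor: float = 0.0) -> tuple[int, int, float]:
    """(n_very_n_terminal, n_total, pct) among MADA+MADAL rows."""
    scores = pd.to_numeric(df["score"], errors="coerce")
    starts = pd.to_numeric(df["start"], errors="coerce")
    positive = df[(scores > madal_floor) & starts.notna()]
    starts = starts[positive.index]
    very = int((starts - 1 <= extension_max).sum())
    total = len(positive)
    return very, total, round(100.0 * very / total, 1) if total else 0.0


def annotation_precision(df: pd.DataFrame, cutoff: float = 10.0,
                         nlr_label: str = "NLR") -> tuple[int, int, float]:
    """(n_nlr, n_total, pct) among rows scoring over the cutoff."""
    scores = pd.to_numeric(df["score"], errors="coerce")
    over = df[scores > cutoff]
    n_nlr = int((over["annotation"].astype(str).str.upper()
                 .str.contains(nlr_label.upper())).sum())
    total = len(over)
    return n_nlr, total, round(100.0 * n_nlr / total, 1) if total else 0.0


def clade_counts(df: pd.DataFrame, cutoff: float = 10.0) -> dict[str, tuple[int, int]]:
    """Per clade label: (examined, n scoring >= cutoff)."""
    out: dict[str, tuple[int, int]] = {}
    scores = pd.to_numeric(df["score"], errors="coerce").fillna(float("-inf"))
    for clade, grp in df.assign(_score=scores).groupby("clade"):
        out[str(clade)] = (len(grp), int((grp["_score"] >= cutoff).sum()))
    return out


def tribe_sizes(df: pd.DataFrame) -> pd.Series:
    """Tribe sizes, descending (singletons included)."""
    return df.groupby("tribe").size().sort_values(ascending=False)


def count_tribes(df: pd.DataFrame) -> tuple[int, int]:
    """(n tribes of >= 2 members, n singletons)."""
    sizes = tribe_sizes(df)
    return int((sizes >= 2).sum()), int((sizes == 1).sum())
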