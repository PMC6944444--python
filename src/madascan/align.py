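"""Pairwise and progressive multiple protein alignment.

The pairwise aligner is a full affine-gap dynamic program (global
Needleman–Wunsch with terminal gaps penalized, or local Smith–Waterman)
over BLOSUM62 by default.  A gap of length k costs
``gap_open + (k - 1) * gap_extend``; traceback ties break
diagonal > up > left so outputs are deterministic.

The multiple aligner is progressive: a neighbour-joining guide tree on
pairwise identity distances, then profile–profile merges with the same
scoring scheme.  Bulk pairwise distance computation is delegated to
Biopython's C pairwise aligner, which implements the identical scoring
scheme; the in-package dynamic program is the reference implementation
and the two are cross-checked in the test suite.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
from Bio import Align as _BioAlign
from Bio.Align import substitution_matrices

from .records import AMINO_ACIDS, SequenceRecord
from . import phylo

GAP = "-"
NEG_INF = float("-inf")

_AA_INDEX = {aa: i for i, aa in enumerate(AMINO_ACIDS)}


def load_matrix(name: str = "BLOSUM62") -> np.ndarray:
    """Substitution matrix as a 20x20 array in AMINO_ACIDS order."""
    m = substitution_matrices.load(name)
    out = np.zeros((20, 20))
    for i, a in enumerate(AMINO_ACIDS):
        for j, b in enumerate(AMINO_ACIDS):
            out[i, j] = m[a][b]
    return out


@dataclass
class Alignment:
    ids: list[str]
    rows: list[str]
    matrix_name: str = "BLOSUM62"
    gap_open: float = 11.0
    gap_extend: float = 1.0

    def __post_init__(self) -> None:
        if len(self.ids) != len(self.rows):
            raise ValueError("ids and rows must have the same length")
        if self.rows and len({len(r) for r in self.rows}) > 1:
            raise ValueError("all alignment rows must have equal length")

    @property
    def n_columns(self) -> int:
        return len(self.rows[0]) if self.rows else 0

    def ungapped(self, i: int) -> str:
        return self.rows[i].replace(GAP, "")


def _encode(seq: str) -> np.ndarray:
    try:
        return np.array([_AA_INDEX[c] for c in seq], dtype=np.int64)
    except KeyError as exc:
        raise ValueError(f"unknown residue symbol {exc.args[0]!r}") from None


def alignment_score(row_a: str, row_b: str, matrix: Optional[np.ndarray] = None,
                    gap_open: float = 11.0, gap_extend: float = 1.0) -> float:
    """Column-by-column score of an aligned pair (affine gap costs)."""
    if matrix is None:
        matrix = load_matrix()
    score = 0.0
    in_gap_a = in_gap_b = False
    for ca, cb in zip(row_a, row_b):
        if ca == GAP and cb == GAP:
            continue
        if ca == GAP:
            score -= gap_extend if in_gap_a else gap_open
            in_gap_a, in_gap_b = True, False
        elif cb == GAP:
            score -= gap_extend if in_gap_b else gap_open
            in_gap_b, in_gap_a = True, False
        else:
            score += matrix[_AA_INDEX[ca], _AA_INDEX[cb]]
            in_gap_a = in_gap_b = False
    return score


def pairwise_align(a: str, b: str, mode: str = "global",
                   matrix: Optional[np.ndarray] = None,
                   matrix_name: str = "BLOSUM62",
                   gap_open: float = 11.0, gap_extend: float = 1.0,
                   ids: tuple[str, str] = ("a", "b")) -> tuple[Alignment, float]:
    """Optimal affine-gap pairwise alignment.

    Returns the alignment and its score.  In local mode, if no pair of
    residues scores positively the empty alignment with score 0 is
    returned.
    """
    if mode not in ("global", "local"):
        raise ValueError(f"mode must be 'global' or 'local', got {mode!r}")
    if not a or not b:
        raise ValueError("sequences must be non-empty")
    if matrix is None:
        matrix = load_matrix(matrix_name)
    xa, xb = _encode(a), _encode(b)
    n, m = len(a), len(b)
    local = mode == "local"

    # M: match/mismatch, U: gap in b (consume a, "up"), L: gap in a ("left")
    M = np.full((n + 1, m + 1), NEG_INF)
    U = np.full((n + 1, m + 1), NEG_INF)
    L = np.full((n + 1, m + 1), NEG_INF)
    # pointers: 0 diag(M), 1 up(U), 2 left(L), 3 local-start
    ptrM = np.zeros((n + 1, m + 1), dtype=np.int8)
    ptrU = np.zeros((n + 1, m + 1), dtype=np.int8)
    ptrL = np.zeros((n + 1, m + 1), dtype=np.int8)

    M[0, 0] = 0.0
    if not local:
        for i in range(1, n + 1):
            U[i, 0] = -gap_open - (i - 1) * gap_extend
            ptrU[i, 0] = 1 if i > 1 else 0
        for j in range(1, m + 1):
            L[0, j] = -gap_open - (j - 1) * gap_extend
            ptrL[0, j] = 2 if j > 1 else 0
    else:
        M[:, 0] = 0.0
        M[0, :] = 0.0
        ptrM[:, 0] = 3
        ptrM[0, :] = 3
        ptrM[0, 0] = 3

    for i in range(1, n + 1):
        si = matrix[xa[i - 1]]
        for j in range(1, m + 1):
            s = si[xb[j - 1]]
            # tie-break: diagonal > up > left
            best, ptr = M[i - 1, j - 1], 0
            if U[i - 1, j - 1] > best:
                best, ptr = U[i - 1, j - 1], 1
            if L[i - 1, j - 1] > best:
                best, ptr = L[i - 1, j - 1], 2
            val = best + s
            if local and val < 0:
                val, ptr = 0.0, 3
            M[i, j], ptrM[i, j] = val, ptr

            open_u = M[i - 1, j] - gap_open
            ext_u = U[i - 1, j] - gap_extend
            if open_u >= ext_u:
                U[i, j], ptrU[i, j] = open_u, 0
            else:
                U[i, j], ptrU[i, j] = ext_u, 1

            open_l = M[i, j - 1] - gap_open
            ext_l = L[i, j - 1] - gap_extend
            if open_l >= ext_l:
                L[i, j], ptrL[i, j] = open_l, 0
            else:
                L[i, j], ptrL[i, j] = ext_l, 2

    if local:
        stacked = M  # local optimum always ends in a match state
        end = np.unravel_index(int(np.argmax(stacked)), stacked.shape)
        score = float(stacked[end])
        if score <= 0:
            return Alignment(ids=list(ids), rows=["", ""],
                             matrix_name=matrix_name,
                             gap_open=gap_open, gap_extend=gap_extend), 0.0
        i, j = end
        state = 0
    else:
        candidates = [(M[n, m], 0), (U[n, m], 1), (L[n, m], 2)]
        score, state = max(candidates, key=lambda t: (t[0], -t[1]))
        i, j = n, m

    ra, rb = [], []
    if local:
        while True:
            if state == 0:
                if ptrM[i, j] == 3 and M[i, j] == 0.0:
                    break  # fresh-start sentinel cell: nothing to emit
                ptr = ptrM[i, j]
                ra.append(a[i - 1])
                rb.append(b[j - 1])
                i, j = i - 1, j - 1
                if ptr == 3:
                    break  # the alignment begins at this residue pair
                state = ptr
            elif state == 1:
                ptr = ptrU[i, j]
                ra.append(a[i - 1])
                rb.append(GAP)
                i -= 1
                state = ptr
            else:
                ptr = ptrL[i, j]
                ra.append(GAP)
                rb.append(b[j - 1])
                j -= 1
                state = ptr
    else:
        while i > 0 or j > 0:
            if state == 0:
                ptr = ptrM[i, j]
                ra.append(a[i - 1])
                rb.append(b[j - 1])
                i, j = i - 1, j - 1
                state = ptr
            elif state == 1:
                ptr = ptrU[i, j]
                ra.append(a[i - 1])
                rb.append(GAP)
                i -= 1
                state = ptr
            else:
                ptr = ptrL[i, j]
                ra.append(GAP)
                rb.append(b[j - 1])
                j -= 1
                state = ptr
    aln = Alignment(ids=list(ids), rows=["".join(reversed(ra)), "".join(reversed(rb))],
                    matrix_name=matrix_name, gap_open=gap_open, gap_extend=gap_extend)
    return aln, float(score)


# --- fast pairwise identity distances (Biopython engine) ------------------

def make_bio_aligner(mode: str = "global", matrix_name: str = "BLOSUM62",
                     gap_open: float = 11.0, gap_extend: float = 1.0) -> _BioAlign.PairwiseAligner:
    aligner = _BioAlign.PairwiseAligner()
    aligner.mode = mode
    aligner.substitution_matrix = substitution_matrices.load(matrix_name)
    aligner.open_gap_score = -gap_open
    aligner.extend_gap_score = -gap_extend
    return aligner


def identity_distance(a: str, b: str, aligner: Optional[_BioAlign.PairwiseAligner] = None) -> float:
    """1 - identities / aligned non-gap columns from a global alignment."""
    if aligner is None:
        aligner = make_bio_aligner()
    aln = next(iter(aligner.align(a, b)))
    ident = comparable = 0
    for (sa, ea), (sb, eb) in zip(*aln.aligned):
        comparable += ea - sa
        ident += sum(1 for x, y in zip(a[sa:ea], b[sb:eb]) if x == y)
    if comparable == 0:
        return 1.0
    return 1.0 - ident / comparable


# --- progressive MSA ------------------------------------------------------

def _profile(rows: list[str]) -> np.ndarray:
    """(L x 21) column counts; index 20 is the gap character."""
    L = len(rows[0])
    prof = np.zeros((L, 21))
    for row in rows:
        for i, c in enumerate(row):
            prof[i, _AA_INDEX.get(c, 20) if c != GAP else 20] += 1
    return prof


def _profile_align(rows_a: list[str], rows_b: list[str], matrix: np.ndarray,
                   gap_open: float, gap_extend: float) -> tuple[list[str], list[str]]:
    """Global affine profile-profile alignment; returns gapped row groups."""
    pa, pb = _profile(rows_a), _profile(rows_b)
    fa = pa[:, :20] / np.maximum(pa[:, :20].sum(axis=1, keepdims=True), 1e-12)
    fb = pb[:, :20] / np.maximum(pb[:, :20].sum(axis=1, keepdims=True), 1e-12)
    S = fa @ matrix @ fb.T  # expected substitution score per column pair
    n, m = S.shape
    M = np.full((n + 1, m + 1), NEG_INF)
    U = np.full((n + 1, m + 1), NEG_INF)
    L = np.full((n + 1, m + 1), NEG_INF)
    ptrM = np.zeros((n + 1, m + 1), dtype=np.int8)
    ptrU = np.zeros((n + 1, m + 1), dtype=np.int8)
    ptrL = np.zeros((n + 1, m + 1), dtype=np.int8)
    M[0, 0] = 0.0
    for i in range(1, n + 1):
        U[i, 0] = -gap_open - (i - 1) * gap_extend
        ptrU[i, 0] = 1 if i > 1 else 0
    for j in range(1, m + 1):
        L[0, j] = -gap_open - (j - 1) * gap_extend
        ptrL[0, j] = 2 if j > 1 else 0
    for i in range(1, n + 1):
        prevM, prevU, prevL = M[i - 1], U[i - 1], L[i - 1]
        diag = np.maximum(np.maximum(prevM[:-1], prevU[:-1]), prevL[:-1])
        ptr_d = np.where(prevM[:-1] >= diag, 0,
                         np.where(prevU[:-1] >= diag, 1, 2)).astype(np.int8)
        M[i, 1:] = diag + S[i - 1]
        ptrM[i, 1:] = ptr_d
        open_u = prevM[1:] - gap_open
        ext_u = prevU[1:] - gap_extend
        U[i, 1:] = np.maximum(open_u, ext_u)
        ptrU[i, 1:] = np.where(open_u >= ext_u, 0, 1)
        U[i, 0] = -gap_open - (i - 1) * gap_extend
        # L needs a sequential scan along j
        rowM, rowL = M[i], L[i]
        for j in range(1, m + 1):
            open_l = rowM[j - 1] - gap_open
            ext_l = rowL[j - 1] - gap_extend
            if open_l >= ext_l:
                rowL[j], ptrL[i, j] = open_l, 0
            else:
                rowL[j], ptrL[i, j] = ext_l, 2

    candidates = [(M[n, m], 0), (U[n, m], 1), (L[n, m], 2)]
    _, state = max(candidates, key=lambda t: (t[0], -t[1]))
    i, j = n, m
    ops = []  # 0 both, 1 col from a only, 2 col from b only
    while i > 0 or j > 0:
        if state == 0:
            ops.append(0)
            state = ptrM[i, j]
            i, j = i - 1, j - 1
        elif state == 1:
            ops.append(1)
            state = ptrU[i, j]
            i -= 1
        else:
            ops.append(2)
            state = ptrL[i, j]
            j -= 1
    ops.reverse()
    out_a = [[] for _ in rows_a]
    out_b = [[] for _ in rows_b]
    ia = ib = 0
    for op in ops:
        if op in (0, 1):
            for k, row in enumerate(rows_a):
                out_a[k].append(row[ia])
            ia += 1
        else:
            for k in range(len(rows_a)):
                out_a[k].append(GAP)
        if op in (0, 2):
            for k, row in enumerate(rows_b):
                out_b[k].append(row[ib])
            ib += 1
        else:
            for k in range(len(rows_b)):
                out_b[k].append(GAP)
    return ["".join(r) for r in out_a], ["".join(r) for r in out_b]


def progressive_msa(records: Sequence[SequenceRecord], matrix_name: str = "BLOSUM62",
                    gap_open: float = 11.0, gap_extend: float = 1.0) -> Alignment:
    """Progressive multiple alignment.

    Guide tree: neighbour joining on pairwise identity distances
    (1 - identities / aligned non-gap columns); merges proceed in guide
    tree post-order via profile–profile alignment.  Deterministic for a
    fixed input order.
    """
    if len(records) < 2:
        raise ValueError("progressive MSA needs at least 2 records")
    matrix = load_matrix(matrix_name)
    ids = [r.id for r in records]
    seqs = {r.id: r.residues for r in records}
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate record ids")
    if len(records) == 2:
        aln, _ = pairwise_align(records[0].residues, records[1].residues,
                                matrix=matrix, matrix_name=matrix_name,
                                gap_open=gap_open, gap_extend=gap_extend,
                                ids=(ids[0], ids[1]))
        return aln

    aligner = make_bio_aligner("global", matrix_name, gap_open, gap_extend)
    n = len(records)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = identity_distance(
                records[i].residues, records[j].residues, aligner)
    tree = phylo.nj_tree(phylo.DistanceMatrix(ids=ids, matrix=d))

    def merge(node) -> tuple[list[str], list[str]]:
        if node.is_leaf():
            return [node.name], [seqs[node.name]]
        groups = [merge(c) for c in node.children]
        acc_ids, acc_rows = groups[0]
        for gids, grows in groups[1:]:
            left, right = _profile_align(acc_rows, grows, matrix, gap_open, gap_extend)
            acc_ids, acc_rows = acc_ids + gids, left + right
        return acc_ids, acc_rows

    out_ids, out_rows = merge(tree.root)
    order = {rid: k for k, rid in enumerate(ids)}
    paired = sorted(zip(out_ids, out_rows), key=lambda t: order[t[0]])
    return Alignment(ids=[p[0] for p in paired], rows=[p[1] for p in paired],
                     matrix_name=matrix_name, gap_open=gap_open, gap_extend=gap_extend)


def strip_gap_columns(msa: Alignment, max_gap_fraction: float = 0.0) -> Alignment:
    """Remove columns whose gap fraction exceeds ``max_gap_fraction``
    (default: any column containing a gap)."""
    nrow = len(msa.rows)
    keep = []
    for c in range(msa.n_columns):
        gaps = sum(1 for row in msa.rows if row[c] == GAP)
        if gaps / nrow <= max_gap_fraction:
            keep.append(c)
    if not keep:
        raise ValueError(
            "stripping removed every column; raise max_gap_fraction")
    rows = ["".join(row[c] for c in keep) for row in msa.rows]
    return Alignment(ids=list(msa.ids), rows=rows, matrix_name=msa.matrix_name,
                     gap_open=msa.gap_open, gap_extend=msa.gap_extend)


def nterm_identity(a: str, b: str, first_n: int = 17) -> int:
    """Count of identical residues at positions 1..first_n (ungapped)."""
    if len(a) < first_n or len(b) < first_n:
        raise ValueError(f"both sequences must be at least {first_n} residues")
    return sum(1 for x, y in zip(a[:first_n], b[:first_n]) if x == y)


# --- I/O -----------------------------------------------------------------

def write_aligned_fasta(msa: Alignment, path: str | Path) -> None:
    with open(path, "w") as fh:
        for rid, row in zip(msa.ids, msa.rows):
            fh.write(f">{rid}\n")
            for i in range(0, len(row), 60):
                fh.write(row[i : i + 60] + "\n")


def read_aligned_fasta(path: str | Path) -> Alignment:
    from Bio import SeqIO

    ids, rows = [], []
    for rec in SeqIO.parse(str(path), "fasta"):
        ids.append(rec.id)
        rows.append(str(rec.seq).upper())
    if not ids:
        raise ValueError(f"no records in {path}")
    return Alignment(ids=ids, rows=rows)


def write_stockholm(msa: Alignment, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("# STOCKHOLM 1.0\n")
        width = max(len(i) for i in msa.ids) + 2
        for rid, row in zip(msa.ids, msa.rows):
            fh.write(f"{rid:<{width}}{row}\n")
        fh.write("//\n")


def read_stockholm(path: str | Path) -> Alignment:
    from Bio import AlignIO

    aln = AlignIO.read(str(path), "stockholm")
    return Alignment(ids=[r.id for r in aln], rows=[str(r.seq).upper() for r in aln])
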