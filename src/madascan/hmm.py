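"""Profile HMM construction, HMMER2 ASCII save-format I/O, bit-score
scanning and MADA / MADA-like classification.

Model topology (local-in-sequence, global-in-model): flanking states N
and C emit background residues on their self-loop transitions, so the
motif may sit anywhere in the target; match states M1..MM carry the
motif, with insert and delete states available between them (unused by
models built from ungapped site alignments).  The per-sequence flank
self-loop probability is set to L/(L+1), matching the null model's
length distribution, so flank emissions cancel exactly and the bit
score is

    S = log2 P(seq | model) - log2 P(seq | null)

with the null a 0-order background with geometric length.  The forward
score sums over all admissible paths and is therefore always >= the
Viterbi (best-path) score.  Only the best-scoring domain per sequence
is reported.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
from scipy import stats
from sklearn.base import BaseEstimator, ClassifierMixin

from .records import AMINO_ACIDS, SequenceRecord

_AA_INDEX = {aa: i for i, aa in enumerate(AMINO_ACIDS)}
LOG2_ZERO = -1e30  # stand-in for log2(0) that survives arithmetic


@dataclass
class ProfileHMM:
    name: str
    match_emissions: np.ndarray  # (M, 20)
    insert_emissions: np.ndarray  # (M, 20)
    background: np.ndarray  # (20,)
    # per-node transition probabilities; index k is node k+1
    t_mm: np.ndarray
    t_mi: np.ndarray
    t_md: np.ndarray
    t_im: np.ndarray
    t_ii: np.ndarray
    t_dm: np.ndarray
    t_dd: np.ndarray
    b_m: np.ndarray  # entry B -> M_k
    m_e: np.ndarray  # exit M_k -> E
    n_seq: int = 0
    evd_mu: Optional[float] = None
    evd_lambda: Optional[float] = None

    def __post_init__(self) -> None:
        self.match_emissions = np.asarray(self.match_emissions, dtype=float)
        self.insert_emissions = np.asarray(self.insert_emissions, dtype=float)
        self.background = np.asarray(self.background, dtype=float)
        M = self.match_emissions.shape[0]
        if M < 1 or self.match_emissions.shape != (M, 20):
            raise ValueError("match_emissions must be (M, 20) with M >= 1")
        # integer-precision file round-trips make sums exact only to ~1e-3
        if not np.allclose(self.match_emissions.sum(axis=1), 1.0, atol=5e-3):
            raise ValueError("match emission rows must sum to 1")
        if not np.isclose(self.background.sum(), 1.0, atol=5e-3):
            raise ValueError("background must sum to 1")
        out = self.t_mm + self.t_mi + self.t_md + self.m_e
        if not np.allclose(out, 1.0, atol=5e-3):
            raise ValueError("transitions out of each match state must sum to 1")

    @property
    def n_states(self) -> int:
        return self.match_emissions.shape[0]

    @property
    def uses_deletes(self) -> bool:
        return bool(np.any(self.t_md > 0) or np.any(self.t_dd > 0))

    def consensus(self) -> str:
        return "".join(AMINO_ACIDS[int(i)]
                       for i in np.argmax(self.match_emissions, axis=1))


@dataclass
class HmmHit:
    record_id: str
    score: float
    start: int  # 1-based inclusive
    end: int
    reported: bool = False
    label: Optional[str] = None


@dataclass
class ClassLabel:
    label: str  # MADA | MADAL | none
    cutoff: float


def build_hmm(sites, name: str = "motif", background: Optional[np.ndarray] = None,
              pseudocount: float = 1.0) -> ProfileHMM:
    """Build a profile HMM from an (ungapped) motif site alignment.

    ``sites`` is an alignment object (``rows`` attribute) or a list of
    equal-length strings.  Every column becomes a match state; match
    emissions are Laplace-smoothed counts,
    ``(c + pseudocount) / (n + 20 * pseudocount)`` (gap/X characters in a
    column are simply not counted).  The default background is uniform.
    """
    rows = list(getattr(sites, "rows", sites))
    if not rows:
        raise ValueError("empty site alignment")
    if len({len(r) for r in rows}) != 1:
        raise ValueError("site rows must have equal length")
    M = len(rows[0])
    if background is None:
        background = np.full(20, 1.0 / 20)
    counts = np.full((M, 20), pseudocount)
    for row in rows:
        for i, c in enumerate(row.upper()):
            if c in _AA_INDEX:
                counts[i, _AA_INDEX[c]] += 1
    match = counts / counts.sum(axis=1, keepdims=True)
    insert = np.tile(background, (M, 1))
    ones, zeros = np.ones(M), np.zeros(M)
    t_mm = ones.copy()
    t_mm[-1] = 0.0  # last match exits to E
    m_e = zeros.copy()
    m_e[-1] = 1.0
    b_m = zeros.copy()
    b_m[0] = 1.0
    hmm = ProfileHMM(
        name=name, match_emissions=match, insert_emissions=insert,
        background=np.asarray(background, dtype=float),
        t_mm=t_mm, t_mi=zeros.copy(), t_md=zeros.copy(),
        t_im=ones.copy(), t_ii=zeros.copy(), t_dm=ones.copy(), t_dd=zeros.copy(),
        b_m=b_m, m_e=m_e, n_seq=len(rows),
    )
    assert np.allclose(hmm.match_emissions.sum(axis=1), 1.0, atol=1e-9)
    return hmm


def _encode(seq: str) -> np.ndarray:
    return np.array([_AA_INDEX.get(c, -1) for c in seq], dtype=np.int64)


def _log2_safe(p: np.ndarray) -> np.ndarray:
    out = np.full_like(p, LOG2_ZERO, dtype=float)
    pos = p > 0
    out[pos] = np.log2(p[pos])
    return out


class _ScoringTables:
    """Log2-odds emission and transition tables for the DP."""

    def __init__(self, hmm: ProfileHMM):
        bg = hmm.background
        # column 20 handles unknown residues: odds ratio 1 (background)
        self.lo_match = np.hstack([
            _log2_safe(hmm.match_emissions) - _log2_safe(bg)[None, :],
            np.zeros((hmm.n_states, 1)),
        ])
        self.lo_ins = np.hstack([
            _log2_safe(hmm.insert_emissions) - _log2_safe(bg)[None, :],
            np.zeros((hmm.n_states, 1)),
        ])
        for name in ("t_mm", "t_mi", "t_md", "t_im", "t_ii", "t_dm", "t_dd",
                     "b_m", "m_e"):
            setattr(self, name, _log2_safe(getattr(hmm, name)))


def _dp_viterbi(hmm: ProfileHMM, x: np.ndarray) -> tuple[float, int, int]:
    """Viterbi bit score and 1-based (start, end) of the best domain."""
    T = _ScoringTables(hmm)
    L, M = len(x), hmm.n_states
    r = L / (L + 1.0)
    entry = T.b_m + math.log2(1.0 - r)
    emit_cost = -math.log2(r)  # null charges log2(r) per model-emitted residue

    neg = np.full(M, LOG2_ZERO)
    vm, vi, vd = neg.copy(), neg.copy(), neg.copy()
    zero_idx = np.zeros(M, dtype=np.int64)
    sm, si, sd = zero_idx.copy(), zero_idx.copy(), zero_idx.copy()
    best, best_end, best_start = LOG2_ZERO, -1, -1
    idx = np.arange(M)

    def shift(v, fill=LOG2_ZERO):
        out = np.empty_like(v)
        out[0] = fill
        out[1:] = v[:-1]
        return out

    for i in range(L):
        e_m = T.lo_match[:, x[i]] + emit_cost
        e_i = T.lo_ins[:, x[i]] + emit_cost

        opts = np.stack([
            entry,
            shift(vm) + shift(T.t_mm),
            shift(vi) + shift(T.t_im),
            shift(vd) + shift(T.t_dm),
        ])
        starts = np.stack([
            np.full(M, i, dtype=np.int64),
            shift(sm, 0), shift(si, 0), shift(sd, 0),
        ])
        choice = np.argmax(opts, axis=0)
        new_m = opts[choice, idx] + e_m
        new_sm = starts[choice, idx]

        from_m = vm + T.t_mi
        from_i = vi + T.t_ii
        new_i = e_i + np.maximum(from_m, from_i)
        new_si = np.where(from_m >= from_i, sm, si)

        new_d, new_sd = neg.copy(), zero_idx.copy()
        if hmm.uses_deletes:
            for k in range(1, M):
                a = new_m[k - 1] + T.t_md[k - 1]
                b = new_d[k - 1] + T.t_dd[k - 1]
                if a >= b:
                    new_d[k], new_sd[k] = a, new_sm[k - 1]
                else:
                    new_d[k], new_sd[k] = b, new_sd[k - 1]

        vm, vi, vd = new_m, new_i, new_d
        sm, si, sd = new_sm, new_si, new_sd

        ends = vm + T.m_e
        k_top = int(np.argmax(ends))
        if ends[k_top] > best:
            best, best_end, best_start = float(ends[k_top]), i, int(sm[k_top])

    if best_end < 0:
        return float(LOG2_ZERO), 0, 0
    return best, best_start + 1, best_end + 1


def _forward_score(hmm: ProfileHMM, x: np.ndarray) -> float:
    """Forward bit score: log2 of the summed odds over all paths."""
    T = _ScoringTables(hmm)
    L, M = len(x), hmm.n_states
    r = L / (L + 1.0)
    entry = T.b_m + math.log2(1.0 - r)
    emit_cost = -math.log2(r)
    neg = np.full(M, LOG2_ZERO)
    fm, fi, fd = neg.copy(), neg.copy(), neg.copy()
    total = LOG2_ZERO

    def shift(v):
        out = np.empty_like(v)
        out[0] = LOG2_ZERO
        out[1:] = v[:-1]
        return out

    for i in range(L):
        e_m = T.lo_match[:, x[i]] + emit_cost
        e_i = T.lo_ins[:, x[i]] + emit_cost
        pe = np.logaddexp2(
            np.logaddexp2(shift(fm) + shift(T.t_mm), shift(fi) + shift(T.t_im)),
            shift(fd) + shift(T.t_dm))
        new_fm = np.logaddexp2(entry, pe) + e_m
        new_fi = e_i + np.logaddexp2(fm + T.t_mi, fi + T.t_ii)
        new_fd = neg.copy()
        if hmm.uses_deletes:
            for k in range(1, M):
                new_fd[k] = np.logaddexp2(new_fm[k - 1] + T.t_md[k - 1],
                                          new_fd[k - 1] + T.t_dd[k - 1])
        fm, fi, fd = new_fm, new_fi, new_fd
        total = np.logaddexp2(total, np.logaddexp2.reduce(fm + T.m_e))
    return float(total)


def score_sequence(hmm: ProfileHMM, seq, algorithm: str = "viterbi") -> HmmHit:
    """Score one sequence; only the best domain is reported.

    ``seq`` may be a string or a :class:`SequenceRecord`.  Unknown
    residues are scored as background (a warning is emitted).  The
    ``reported`` flag marks hits with a positive bit score.
    """
    if algorithm not in ("viterbi", "forward"):
        raise ValueError("algorithm must be 'viterbi' or 'forward'")
    if isinstance(seq, SequenceRecord):
        rec_id, residues = seq.id, seq.residues
    else:
        rec_id, residues = "seq", str(seq).upper()
    if not residues:
        raise ValueError("sequence must be non-empty")
    x = _encode(residues)
    n_unknown = int(np.sum(x < 0)) - residues.count("X")
    if n_unknown > 0:
        warnings.warn(f"{rec_id}: {n_unknown} unknown residue(s) scored as background")
    score, start, end = _dp_viterbi(hmm, x)
    if algorithm == "forward":
        score = _forward_score(hmm, x)
    return HmmHit(record_id=rec_id, score=round(score, 6), start=start, end=end,
                  reported=score > 0.0)


def score_records(hmm: ProfileHMM, records: Sequence[SequenceRecord],
                  algorithm: str = "viterbi") -> list[HmmHit]:
    return [score_sequence(hmm, rec, algorithm) for rec in records]


def classify(hit: HmmHit, cutoff: float = 10.0, madal_floor: float = 0.0) -> ClassLabel:
    """MADA if score >= cutoff; MADA-like if reported with
    madal_floor < score < cutoff; otherwise none."""
    if hit.score >= cutoff:
        label = "MADA"
    elif hit.reported and madal_floor < hit.score < cutoff:
        label = "MADAL"
    else:
        label = "none"
    hit.label = label
    return ClassLabel(label=label, cutoff=cutoff)


def calibrate(hmm: ProfileHMM, n_random: int = 5000, len_dist: int = 350,
              seed: int = 0) -> ProfileHMM:
    """Fit an extreme-value null by scoring random background sequences.

    Viterbi scores of ``n_random`` i.i.d. background sequences of length
    ``len_dist`` are fitted with a Gumbel by maximum likelihood
    (scipy); ``mu`` is the location (bits) and ``lambda = 1/scale`` the
    natural-log rate, giving E(S) = n_db * exp(-lambda * (S - mu)).
    """
    if n_random < 100:
        raise ValueError("n_random must be >= 100 for a stable fit")
    rng = np.random.default_rng(seed)
    X = rng.choice(20, size=(n_random, len_dist), p=hmm.background)
    scores = _viterbi_scores_batch(hmm, X)
    mu, scale = stats.gumbel_r.fit(scores)
    out = ProfileHMM(**{f: getattr(hmm, f) for f in (
        "name", "match_emissions", "insert_emissions", "background",
        "t_mm", "t_mi", "t_md", "t_im", "t_ii", "t_dm", "t_dd", "b_m", "m_e",
        "n_seq")})
    out.evd_mu = float(mu)
    out.evd_lambda = float(1.0 / scale)
    return out


def evalue(hmm: ProfileHMM, score: float, n_db: int) -> float:
    if hmm.evd_mu is None or hmm.evd_lambda is None:
        raise ValueError("model is not calibrated")
    return n_db * math.exp(-hmm.evd_lambda * (score - hmm.evd_mu))


def _viterbi_scores_batch(hmm: ProfileHMM, X: np.ndarray) -> np.ndarray:
    """Viterbi bit scores for equal-length encoded sequences (n, L).
    Delete states are ignored (models built from ungapped alignments)."""
    T = _ScoringTables(hmm)
    n, L = X.shape
    M = hmm.n_states
    r = L / (L + 1.0)
    entry = T.b_m + math.log2(1.0 - r)
    emit_cost = -math.log2(r)
    vm = np.full((n, M), LOG2_ZERO)
    vi = np.full((n, M), LOG2_ZERO)
    best = np.full(n, LOG2_ZERO)
    for i in range(L):
        e_m = T.lo_match[:, X[:, i]].T + emit_cost  # (n, M)
        e_i = T.lo_ins[:, X[:, i]].T + emit_cost
        cand = np.full((n, M), LOG2_ZERO)
        cand[:, 0] = entry[0]
        cand[:, 1:] = np.maximum(
            np.maximum(vm[:, :-1] + T.t_mm[:-1], vi[:, :-1] + T.t_im[:-1]),
            entry[1:])
        new_m = cand + e_m
        new_i = e_i + np.maximum(vm + T.t_mi, vi + T.t_ii)
        vm, vi = new_m, new_i
        best = np.maximum(best, np.max(vm + T.m_e, axis=1))
    return best


# --- sklearn-style front end ---------------------------------------------


class ProfileHmmClassifier(ClassifierMixin, BaseEstimator):
    """Profile-HMM motif classifier (scikit-learn style).

    ``fit(X)`` takes the motif site alignment (list of equal-length
    strings); ``decision_function`` returns bit scores and ``predict``
    the class labels (``MADA`` / ``MADAL`` / ``none``) at the configured
    cutoff.
    """

    def __init__(self, cutoff: float = 10.0, madal_floor: float = 0.0,
                 algorithm: str = "viterbi", name: str = "motif"):
        self.cutoff = cutoff
        self.madal_floor = madal_floor
        self.algorithm = algorithm
        self.name = name

    def fit(self, X: Sequence[str], y=None):
        self.hmm_ = build_hmm(list(X), name=self.name)
        return self

    def decision_function(self, X: Sequence[str]) -> np.ndarray:
        return np.array([
            score_sequence(self.hmm_, s, self.algorithm).score for s in X
        ])

    def predict(self, X: Sequence[str]) -> np.ndarray:
        labels = []
        for s in X:
            hit = score_sequence(self.hmm_, s, self.algorithm)
            labels.append(classify(hit, self.cutoff, self.madal_floor).label)
        return np.array(labels)


# --- HMMER2 ASCII save format --------------------------------------------

_HMM_ALPHA_LINE = ("HMM        " + "      ".join(AMINO_ACIDS))
_HMM_TRANS_LINE = ("         m->m   m->i   m->d   i->m   i->i   d->m   d->d   "
                   "b->m   m->e")


def _encode_score(p: float, null: float = 1.0) -> str:
    """Integer 1/1000-bit log-odds; '*' encodes probability zero."""
    if p <= 0.0:
        return "*"
    return str(int(round(1000.0 * math.log2(p / null))))


def _decode_score(tok: str, null: float = 1.0) -> float:
    if tok == "*":
        return 0.0
    return null * 2.0 ** (int(tok) / 1000.0)


def write_hmm(hmm: ProfileHMM, path: str | Path) -> None:
    """Write the model in HMMER2 ASCII save format (integer 1/1000-bit
    scores; emissions are stored relative to the null residue
    frequencies, transitions relative to 1)."""
    M = hmm.n_states
    bg = hmm.background
    with open(path, "w") as fh:
        fh.write("HMMER2.0  [madascan]\n")
        fh.write(f"NAME  {hmm.name}\n")
        fh.write(f"LENG  {M}\n")
        fh.write("ALPH  Amino\n")
        fh.write(f"NSEQ  {hmm.n_seq}\n")
        fh.write("XT      -8455     -4  -1000  -1000  -8455     -4  -8455     -4\n")
        fh.write("NULT      -4  -8455\n")
        nule = " ".join(f"{_encode_score(p, 1.0 / 20):>6}" for p in bg)
        fh.write(f"NULE  {nule}\n")
        if hmm.evd_mu is not None and hmm.evd_lambda is not None:
            fh.write(f"EVD   {hmm.evd_mu:.6f}   {hmm.evd_lambda:.6f}\n")
        fh.write(_HMM_ALPHA_LINE + "\n")
        fh.write(_HMM_TRANS_LINE + "\n")
        for k in range(M):
            match = " ".join(_encode_score(p, bg[j]) .rjust(6)
                             for j, p in enumerate(hmm.match_emissions[k]))
            fh.write(f"{k + 1:>6} {match}\n")
            ins = " ".join(_encode_score(p, bg[j]).rjust(6)
                           for j, p in enumerate(hmm.insert_emissions[k]))
            fh.write(f"{'-':>6} {ins}\n")
            trans = [
                hmm.t_mm[k], hmm.t_mi[k], hmm.t_md[k],
                hmm.t_im[k], hmm.t_ii[k], hmm.t_dm[k], hmm.t_dd[k],
                hmm.b_m[k], hmm.m_e[k],
            ]
            fh.write(f"{'-':>6} " + " ".join(_encode_score(t).rjust(6)
                                             for t in trans) + "\n")
        fh.write("//\n")


class Hmmer2ParseError(ValueError):
    pass


def read_hmm(path: str | Path) -> ProfileHMM:
    """Read a HMMER2 ASCII save file.

    Probabilities are decoded as ``2**(score/1000) * null`` (null = the
    NULE residue frequency for emissions, 1 for transitions); ``*``
    decodes to probability zero.  Malformed or truncated files raise
    :class:`Hmmer2ParseError` with the offending line number.
    """
    path = Path(path)
    lines = path.read_text().splitlines()
    if not lines or not lines[0].startswith("HMMER2.0"):
        raise Hmmer2ParseError(f"{path}:1: not a HMMER2.0 save file")
    name, leng, n_seq = "model", None, 0
    background = np.full(20, 1.0 / 20)
    evd_mu = evd_lambda = None
    i = 1
    while i < len(lines) and not lines[i].startswith("HMM "):
        tokens = lines[i].split()
        if not tokens:
            i += 1
            continue
        key = tokens[0]
        try:
            if key == "NAME":
                name = tokens[1]
            elif key == "LENG":
                leng = int(tokens[1])
            elif key == "NSEQ":
                n_seq = int(tokens[1])
            elif key == "NULE":
                if len(tokens) != 21:
                    raise Hmmer2ParseError(
                        f"{path}:{i + 1}: NULE needs 20 scores, got {len(tokens) - 1}")
                background = np.array([
                    _decode_score(t, 1.0 / 20) for t in tokens[1:]])
            elif key == "EVD":
                evd_mu, evd_lambda = float(tokens[1]), float(tokens[2])
        except (IndexError, ValueError) as exc:
            if isinstance(exc, Hmmer2ParseError):
                raise
            raise Hmmer2ParseError(f"{path}:{i + 1}: bad {key} line: {exc}") from None
        i += 1
    if i >= len(lines):
        raise Hmmer2ParseError(f"{path}: missing HMM section")
    if leng is None:
        raise Hmmer2ParseError(f"{path}: missing LENG header")
    i += 2  # skip the alphabet and transition-name lines
    M = leng
    match = np.zeros((M, 20))
    insert = np.zeros((M, 20))
    trans = np.zeros((M, 9))
    for k in range(M):
        base = i + 3 * k
        if base + 2 >= len(lines):
            raise Hmmer2ParseError(f"{path}: truncated at node {k + 1}")
        mt = lines[base].split()
        it = lines[base + 1].split()
        tt = lines[base + 2].split()
        if len(mt) < 21 or mt[0] != str(k + 1):
            raise Hmmer2ParseError(
                f"{path}:{base + 1}: expected match line for node {k + 1}")
        if len(it) < 21 or len(tt) < 10:
            raise Hmmer2ParseError(f"{path}:{base + 2}: malformed node {k + 1}")
        match[k] = [_decode_score(t, background[j])
                    for j, t in enumerate(mt[1:21])]
        insert[k] = [_decode_score(t, background[j])
                     for j, t in enumerate(it[1:21])]
        trans[k] = [_decode_score(t) for t in tt[1:10]]
    tail = i + 3 * M
    if tail >= len(lines) or lines[tail].strip() != "//":
        raise Hmmer2ParseError(
            f"{path}:{min(tail + 1, len(lines))}: missing terminating '//'")
    return ProfileHMM(
        name=name, match_emissions=match, insert_emissions=insert,
        background=background,
        t_mm=trans[:, 0], t_mi=trans[:, 1], t_md=trans[:, 2],
        t_im=trans[:, 3], t_ii=trans[:, 4], t_dm=trans[:, 5], t_dd=trans[:, 6],
        b_m=trans[:, 7], m_e=trans[:, 8],
        n_seq=n_seq, evd_mu=evd_mu, evd_lambda=evd_lambda,
    )


def write_hits(hits: Sequence[HmmHit], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("record_id\tscore\tstart\tend\tclass\n")
        for h in hits:
            fh.write(f"{h.record_id}\t{h.score:.2f}\t{h.start}\t{h.end}\t"
                     f"{h.label or 'none'}\n")
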