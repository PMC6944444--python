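"""Clustering of N-terminal domains into tribes.

An all-vs-all local-alignment similarity graph is thresholded on
Karlin–Altschul E-values (gapped BLOSUM62 constants lambda = 0.267,
K = 0.041, effective lengths = raw lengths; exact agreement with BLASTP
is not claimed), then partitioned by Markov clustering (MCL): iterate
expansion (matrix squaring) and inflation (entrywise power with column
renormalization) on a column-stochastic transition matrix with
self-loops until the matrix stops changing, and read clusters off the
attractor structure of the limit matrix.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import networkx as nx
import numpy as np
from sklearn.base import BaseEstimator, ClusterMixin

from .align import make_bio_aligner

#: Gapped BLOSUM62 Karlin-Altschul constants (open 11 / extend 1).
KA_LAMBDA = 0.267
KA_K = 0.041

WEIGHT_CAP = 200.0


@dataclass
class SimilarityGraph:
    graph: nx.Graph
    evalue_max: float

    @property
    def node_ids(self) -> list[str]:
        return list(self.graph.nodes)


@dataclass
class TribeAssignment:
    """Partition of records into tribes.

    Tribe ids are dense from 1, ordered by descending size then by the
    lexicographically smallest member.
    """

    tribe_of: dict[str, int]
    tribes: dict[int, list[str]] = field(default_factory=dict)
    converged: bool = True

    def __post_init__(self) -> None:
        if not self.tribes:
            grouped: dict[int, list[str]] = {}
            for rec_id, tid in self.tribe_of.items():
                grouped.setdefault(tid, []).append(rec_id)
            self.tribes = {t: sorted(m) for t, m in grouped.items()}

    def is_singleton(self, record_id: str) -> bool:
        return len(self.tribes[self.tribe_of[record_id]]) == 1

    @property
    def n_tribes_multi(self) -> int:
        return sum(1 for m in self.tribes.values() if len(m) > 1)

    @property
    def n_singletons(self) -> int:
        return sum(1 for m in self.tribes.values() if len(m) == 1)


def karlin_altschul_evalue(score: float, m: int, n: int,
                           lam: float = KA_LAMBDA, k: float = KA_K) -> float:
    """E = K * m * n * exp(-lambda * S)."""
    return k * m * n * math.exp(-lam * score)


def all_vs_all_graph(nterm_seqs: dict[str, str], evalue_max: float = 1e-8,
                     min_length: int = 10) -> SimilarityGraph:
    """Local-alignment similarity graph over N-terminal domain sequences.

    Smith–Waterman score per pair (the symmetric score serves both
    directed comparisons; the directed E-values coincide because the
    search-space term m*n is symmetric).  An edge is kept when
    E < ``evalue_max``; its weight is -log10(E) capped at 200.
    Sequences shorter than ``min_length`` are skipped with a warning.
    """
    if len(nterm_seqs) < 2:
        raise ValueError("need at least 2 sequences")
    usable: dict[str, str] = {}
    g = nx.Graph()
    for rec_id, seq in nterm_seqs.items():
        if len(seq) < min_length:
            warnings.warn(f"sequence {rec_id!r} shorter than {min_length}; skipped")
            continue
        usable[rec_id] = seq
        g.add_node(rec_id)
    aligner = make_bio_aligner("local")
    ids = list(usable)
    for i, a in enumerate(ids):
        for b in ids[i + 1 :]:
            score = aligner.score(usable[a], usable[b])
            e = karlin_altschul_evalue(score, len(usable[a]), len(usable[b]))
            if e < evalue_max:
                weight = min(-math.log10(max(e, 1e-300)), WEIGHT_CAP)
                g.add_edge(a, b, weight=weight)
    return SimilarityGraph(graph=g, evalue_max=evalue_max)


class MarkovClustering(ClusterMixin, BaseEstimator):
    """Markov clustering of a weighted similarity graph.

    scikit-learn style: ``fit`` accepts a square non-negative affinity
    matrix (or a :class:`SimilarityGraph` / networkx graph) and exposes
    ``labels_``; labels are dense tribe ids starting at 1 ordered by
    descending cluster size then lexicographic smallest member.

    Parameters
    ----------
    inflation : entrywise power applied after each expansion; larger
        values give finer clusters.  2.0 is the canonical Tribe-MCL
        default.
    max_iter : iteration cap; non-convergence sets ``converged_ = False``
        and emits a warning rather than failing.
    prune_eps : entries below this are zeroed (then columns renormalized)
        to keep the matrix sparse-ish.
    tol : convergence threshold on the max absolute change per iteration.
    """

    def __init__(self, inflation: float = 2.0, max_iter: int = 200,
                 prune_eps: float = 1e-6, tol: float = 1e-8):
        self.inflation = inflation
        self.max_iter = max_iter
        self.prune_eps = prune_eps
        self.tol = tol

    @staticmethod
    def _as_matrix(X) -> tuple[np.ndarray, list[str]]:
        if isinstance(X, SimilarityGraph):
            X = X.graph
        if isinstance(X, nx.Graph):
            ids = sorted(X.nodes)
            mat = nx.to_numpy_array(X, nodelist=ids, weight="weight")
            return mat, ids
        mat = np.asarray(X, dtype=float)
        if mat.ndim != 2 or mat.shape[0] != mat.shape[1]:
            raise ValueError("affinity matrix must be square")
        if np.any(mat < 0):
            raise ValueError("affinities must be non-negative")
        return mat, [str(i) for i in range(mat.shape[0])]

    def fit(self, X, y=None):
        mat, ids = self._as_matrix(X)
        n = mat.shape[0]
        if n == 0:
            raise ValueError("empty graph")
        mat = mat.copy()
        # self-loops: per-node max incident weight (1 for isolated nodes)
        loops = np.maximum(mat.max(axis=0), 1e-12)
        loops[loops <= 1e-12] = 1.0
        np.fill_diagonal(mat, loops)
        M = mat / mat.sum(axis=0, keepdims=True)

        converged = False
        for _ in range(self.max_iter):
            prev = M
            M = M @ M  # expansion
            M = np.power(M, self.inflation)  # inflation
            M[M < self.prune_eps] = 0.0
            colsum = M.sum(axis=0, keepdims=True)
            zero = colsum == 0
            if np.any(zero):  # restore pruned-to-zero columns as self-loops
                idx = np.nonzero(zero[0])[0]
                M[idx, idx] = 1.0
                colsum = M.sum(axis=0, keepdims=True)
            M = M / colsum
            if prev.shape == M.shape and np.max(np.abs(M - prev)) < self.tol:
                converged = True
                break
        if not converged:
            warnings.warn("MCL did not converge within max_iter; "
                          "returning the current clustering")

        # attractor-overlap components: connect i-j when M[i, j] > 0
        support = nx.Graph()
        support.add_nodes_from(range(n))
        rows, cols = np.nonzero(M > self.prune_eps)
        support.add_edges_from(zip(rows.tolist(), cols.tolist()))
        components = [sorted(c) for c in nx.connected_components(support)]
        components.sort(key=lambda c: (-len(c), ids[c[0]]))

        labels = np.empty(n, dtype=int)
        for tid, comp in enumerate(components, start=1):
            for k in comp:
                labels[k] = tid
        self.labels_ = labels
        self.node_ids_ = ids
        self.converged_ = converged
        self.n_iter_matrix_ = M
        return self

    def fit_predict(self, X, y=None):
        return self.fit(X).labels_


def mcl_cluster(graph: SimilarityGraph, inflation: float = 2.0,
                max_iter: int = 200, prune_eps: float = 1e-6) -> TribeAssignment:
    """Cluster a similarity graph into tribes (wrapper over
    :class:`MarkovClustering`)."""
    est = MarkovClustering(inflation=inflation, max_iter=max_iter,
                           prune_eps=prune_eps)
    labels = est.fit_predict(graph)
    return TribeAssignment(
        tribe_of={rid: int(t) for rid, t in zip(est.node_ids_, labels)},
        converged=est.converged_,
    )


MONOCOT_SPECIES = {"rice", "barley", "oryza", "hordeum", "wheat", "maize",
                   "brachypodium"}


def tribe_summary(assignment: TribeAssignment, species_of: dict[str, str],
                  monocots: Optional[set] = None):
    """Per-tribe size table with monocot/dicot composition.

    Returns a pandas DataFrame indexed by tribe id with columns
    ``size``, ``monocot``, ``dicot``, ``singleton``.
    """
    import pandas as pd

    if monocots is None:
        monocots = MONOCOT_SPECIES
    rows = []
    for tid in sorted(assignment.tribes):
        members = assignment.tribes[tid]
        mono = sum(1 for m in members
                   if species_of.get(m, "unknown").lower() in monocots)
        rows.append({
            "tribe_id": tid,
            "size": len(members),
            "monocot": mono,
            "dicot": len(members) - mono,
            "singleton": len(members) == 1,
        })
    return pd.DataFrame(rows).set_index("tribe_id")


# --- I/O -----------------------------------------------------------------

def write_abc(graph: SimilarityGraph, path: str | Path) -> None:
    """ABC edge list: ``node1 node2 weight`` per line."""
    with open(path, "w") as fh:
        for a, b, data in sorted(graph.graph.edges(data=True)):
            fh.write(f"{a}\t{b}\t{data['weight']:.4f}\n")


def read_abc(path: str | Path, evalue_max: float = float("nan")) -> SimilarityGraph:
    g = nx.Graph()
    with open(path) as fh:
        for line in fh:
            parts = line.split()
            if not parts:
                continue
            a, b, w = parts[0], parts[1], float(parts[2])
            g.add_edge(a, b, weight=w)
    return SimilarityGraph(graph=g, evalue_max=evalue_max)


def write_assignment(assignment: TribeAssignment, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("record_id\ttribe_id\tis_singleton\n")
        for rec_id in sorted(assignment.tribe_of):
            tid = assignment.tribe_of[rec_id]
            fh.write(f"{rec_id}\t{tid}\t{int(assignment.is_singleton(rec_id))}\n")


def read_assignment(path: str | Path) -> TribeAssignment:
    tribe_of: dict[str, int] = {}
    with open(path) as fh:
        header = fh.readline()
        for line in fh:
            rec_id, tid, _single = line.rstrip("\n").split("\t")
            tribe_of[rec_id] = int(tid)
    return TribeAssignment(tribe_of=tribe_of)
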