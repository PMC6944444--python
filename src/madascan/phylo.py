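"""Neighbour-joining phylogenies from NB-ARC alignments.

Distances are p-distances over mutually non-gap columns (optionally
Poisson-corrected, ``-ln(1 - p)``).  Trees are built by the Saitou–Nei
agglomeration with deterministic tie-breaking (lowest index pair) and
negative branch lengths clamped to zero with the deficit transferred to
the sibling branch.  Bootstrap support is the fraction of
column-resampled replicate trees containing each bipartition of the
point-estimate tree.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np


@dataclass
class DistanceMatrix:
    ids: list[str]
    matrix: np.ndarray
    model: str = "p-distance"

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        n = len(self.ids)
        if self.matrix.shape != (n, n):
            raise ValueError("matrix shape must match number of ids")
        if not np.allclose(self.matrix, self.matrix.T):
            raise ValueError("distance matrix must be symmetric")
        if not np.allclose(np.diag(self.matrix), 0.0):
            raise ValueError("distance matrix must have zero diagonal")
        if not np.all(np.isfinite(self.matrix)) or np.any(self.matrix < 0):
            raise ValueError("distances must be finite and non-negative")


class Node:
    """Tree node; the root of an unrooted tree is a trifurcation."""

    __slots__ = ("name", "children", "length", "support")

    def __init__(self, name: Optional[str] = None,
                 children: Optional[list["Node"]] = None,
                 length: float = 0.0, support: Optional[float] = None):
        self.name = name
        self.children = children or []
        self.length = length
        self.support = support

    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> list["Node"]:
        if self.is_leaf():
            return [self]
        out = []
        for c in self.children:
            out.extend(c.leaves())
        return out

    def leaf_names(self) -> list[str]:
        return [l.name for l in self.leaves()]


@dataclass
class PhyloTree:
    root: Node
    has_support: bool = False

    def leaf_names(self) -> list[str]:
        return self.root.leaf_names()

    def bipartitions(self) -> dict[frozenset, Optional[float]]:
        """Non-trivial bipartitions as canonical leaf sets -> stem support.

        Each internal edge splits the leaves in two; the set is
        canonicalized as the side *not* containing the first leaf.
        """
        all_leaves = frozenset(self.leaf_names())
        ref = min(all_leaves)
        out: dict[frozenset, Optional[float]] = {}

        def visit(node: Node) -> None:
            for child in node.children:
                clade = frozenset(child.leaf_names())
                if 1 < len(clade) < len(all_leaves) - 1:
                    side = clade if ref not in clade else all_leaves - clade
                    out[side] = child.support
                visit(child)

        visit(self.root)
        return out

    def clades(self) -> list[tuple[frozenset, Optional[float]]]:
        """All directed clades (leaf set below each edge, both orientations)
        with the stem support of that edge.  Leaf clades get support 1.0."""
        all_leaves = frozenset(self.leaf_names())
        out: list[tuple[frozenset, Optional[float]]] = []

        def visit(node: Node) -> None:
            for child in node.children:
                clade = frozenset(child.leaf_names())
                support = 1.0 if len(clade) == 1 else child.support
                out.append((clade, support))
                comp = all_leaves - clade
                comp_support = 1.0 if len(comp) == 1 else child.support
                out.append((comp, comp_support))
                visit(child)

        visit(self.root)
        return out

    def to_newick(self, include_support: bool = True) -> str:
        def fmt(node: Node) -> str:
            if node.is_leaf():
                return f"{node.name}:{node.length:.6g}"
            inner = ",".join(fmt(c) for c in node.children)
            label = ""
            if include_support and node.support is not None:
                label = f"{node.support:.3g}"
            return f"({inner}){label}:{node.length:.6g}"

        inner = ",".join(fmt(c) for c in self.root.children)
        return f"({inner});"

    def path_length(self, a: str, b: str) -> float:
        """Sum of branch lengths on the leaf-to-leaf path."""
        def path_to(node: Node, target: str) -> Optional[list[Node]]:
            if node.is_leaf():
                return [node] if node.name == target else None
            for c in node.children:
                sub = path_to(c, target)
                if sub is not None:
                    return [node] + sub
            return None

        pa = path_to(self.root, a)
        pb = path_to(self.root, b)
        if pa is None or pb is None:
            raise KeyError(f"leaf not found: {a if pa is None else b}")
        common = 0
        for x, y in zip(pa, pb):
            if x is y:
                common += 1
            else:
                break
        return sum(n.length for n in pa[common:]) + sum(n.length for n in pb[common:])


def _encode_alignment(rows: Sequence[str]) -> np.ndarray:
    """Rows to int codes; gaps ('-', '.') and X map to -1 (excluded)."""
    lookup = np.full(128, -1, dtype=np.int8)
    for i, aa in enumerate("ACDEFGHIKLMNPQRSTVWY"):
        lookup[ord(aa)] = i
    arr = np.frombuffer("".join(rows).encode(), dtype=np.uint8)
    return lookup[arr].reshape(len(rows), -1)


def compute_distances(msa, model: str = "p-distance") -> DistanceMatrix:
    """Pairwise distances from an alignment (any object with ``ids`` and
    equal-length ``rows``).

    p-distance = fraction of differing residues over mutually non-gap
    columns; ``poisson`` applies ``-ln(1 - p)``.  A pair with zero
    comparable columns is an error.
    """
    if model not in ("p-distance", "poisson"):
        raise ValueError(f"unknown distance model {model!r}")
    X = _encode_alignment(msa.rows)
    n = X.shape[0]
    if n < 2 or X.shape[1] < 1:
        raise ValueError("alignment must have >= 2 rows and >= 1 column")
    valid = X >= 0
    d = np.zeros((n, n))
    for i in range(n):
        both = valid[i] & valid[i + 1 :]
        comp = both.sum(axis=1)
        if np.any(comp == 0):
            j = i + 1 + int(np.argmax(comp == 0))
            raise ValueError(
                f"no mutually non-gap columns between {msa.ids[i]!r} and {msa.ids[j]!r}"
            )
        diff = ((X[i] != X[i + 1 :]) & both).sum(axis=1)
        d[i, i + 1 :] = diff / comp
    d = d + d.T
    if model == "poisson":
        p = np.clip(d, 0.0, 0.999999)
        d = -np.log1p(-p)
        np.fill_diagonal(d, 0.0)
    return DistanceMatrix(ids=list(msa.ids), matrix=d, model=model)


def nj_tree(dm: DistanceMatrix) -> PhyloTree:
    """Saitou–Nei neighbour joining.

    On an additive matrix the generating topology and branch lengths are
    recovered exactly.  Ties in the Q matrix break to the lowest (i, j)
    index pair; negative branch lengths are clamped to 0 with the deficit
    moved to the sibling branch.
    """
    n = len(dm.ids)
    if n < 3:
        raise ValueError("neighbour joining needs at least 3 taxa")
    nodes: list[Node] = [Node(name=i) for i in dm.ids]
    d = dm.matrix.astype(float).copy()

    while len(nodes) > 3:
        r = len(nodes)
        R = d.sum(axis=0)
        Q = (r - 2) * d - R[:, None] - R[None, :]
        np.fill_diagonal(Q, np.inf)
        flat = int(np.argmin(Q))  # row-major argmin -> lowest (i, j) on ties
        i, j = divmod(flat, r)
        if i > j:
            i, j = j, i
        li = 0.5 * d[i, j] + (R[i] - R[j]) / (2 * (r - 2))
        lj = d[i, j] - li
        if li < 0:
            lj += li
            li = 0.0
        if lj < 0:
            li += lj
            lj = 0.0
        li, lj = max(li, 0.0), max(lj, 0.0)
        nodes[i].length, nodes[j].length = li, lj
        parent = Node(children=[nodes[i], nodes[j]])
        dnew = 0.5 * (d[i] + d[j] - d[i, j])
        keep = [k for k in range(r) if k not in (i, j)]
        d = np.vstack([d[keep][:, keep], dnew[keep][None, :]])
        d = np.hstack([d, np.append(dnew[keep], 0.0)[:, None]])
        nodes = [nodes[k] for k in keep] + [parent]

    a, b, c = nodes
    dab, dac, dbc = d[0, 1], d[0, 2], d[1, 2]
    a.length = max(0.0, 0.5 * (dab + dac - dbc))
    b.length = max(0.0, 0.5 * (dab + dbc - dac))
    c.length = max(0.0, 0.5 * (dac + dbc - dab))
    return PhyloTree(root=Node(children=[a, b, c]))


def bootstrap_support(msa, n_replicates: int = 100, seed: int = 0,
                      model: str = "p-distance") -> PhyloTree:
    """NJ tree with bootstrap supports from column resampling.

    With ``n_replicates == 0`` the point tree is returned with all
    supports absent.
    """
    point = nj_tree(compute_distances(msa, model))
    if n_replicates == 0:
        return point
    if len(msa.ids) < 4:
        raise ValueError("bootstrap support needs >= 4 taxa")
    rng = np.random.default_rng(seed)
    ncol = len(msa.rows[0])
    counts: dict[frozenset, int] = {bp: 0 for bp in point.bipartitions()}
    for _ in range(n_replicates):
        cols = rng.integers(0, ncol, size=ncol)
        rows = ["".join(row[c] for c in cols) for row in msa.rows]
        rep = nj_tree(compute_distances(
            _SimpleMsa(list(msa.ids), rows), model))
        rep_bps = set(rep.bipartitions())
        for bp in counts:
            if bp in rep_bps:
                counts[bp] += 1

    all_leaves = frozenset(point.leaf_names())
    ref = min(all_leaves)

    def annotate(node: Node) -> None:
        for child in node.children:
            clade = frozenset(child.leaf_names())
            if 1 < len(clade) < len(all_leaves) - 1:
                side = clade if ref not in clade else all_leaves - clade
                child.support = counts[side] / n_replicates
            annotate(child)

    annotate(point.root)
    point.has_support = True
    return point


@dataclass
class _SimpleMsa:
    ids: list[str]
    rows: list[str]


def flag_clade(tree: PhyloTree, anchor_ids: Sequence[str], support_min: float = 0.7) -> set[str]:
    """Leaves of the smallest well-supported clade containing all anchors.

    A clade qualifies if its stem support is >= ``support_min`` (single
    leaves qualify trivially).  If no qualifying clade contains every
    anchor, the whole leaf set is returned.
    """
    leaves = set(tree.leaf_names())
    anchors = set(anchor_ids)
    unknown = anchors - leaves
    if unknown:
        raise KeyError(f"unknown anchor ids: {sorted(unknown)}")
    best: Optional[frozenset] = None
    for clade, support in tree.clades():
        if not anchors <= clade:
            continue
        if len(clade) > 1 and (support is None or support < support_min):
            continue
        if best is None or len(clade) < len(best):
            best = clade
    return set(best) if best is not None else leaves


# --- I/O -----------------------------------------------------------------

def write_phylip(dm: DistanceMatrix, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(f"{len(dm.ids)}\n")
        for name, row in zip(dm.ids, dm.matrix):
            fh.write(name + "  " + "  ".join(f"{x:.6f}" for x in row) + "\n")


def read_phylip(path: str | Path) -> DistanceMatrix:
    with open(path) as fh:
        n = int(fh.readline().split()[0])
        ids, rows = [], []
        for _ in range(n):
            parts = fh.readline().split()
            ids.append(parts[0])
            rows.append([float(x) for x in parts[1 : n + 1]])
    return DistanceMatrix(ids=ids, matrix=np.array(rows))


def write_newick(tree: PhyloTree, path: str | Path) -> None:
    Path(path).write_text(tree.to_newick() + "\n")


def read_newick(path: str | Path) -> PhyloTree:
    """Parse a newick file (internal-node labels read as supports)."""
    text = Path(path).read_text().strip()
    pos = 0

    def parse() -> Node:
        nonlocal pos
        node = Node()
        if text[pos] == "(":
            pos += 1
            while True:
                node.children.append(parse())
                if text[pos] == ",":
                    pos += 1
                else:
                    break
            if text[pos] != ")":
                raise ValueError(f"newick parse error at offset {pos}")
            pos += 1
        # label
        start = pos
        while pos < len(text) and text[pos] not in ":,();":
            pos += 1
        label = text[start:pos]
        if label:
            if node.is_leaf():
                node.name = label
            else:
                node.support = float(label)
        if pos < len(text) and text[pos] == ":":
            pos += 1
            start = pos
            while pos < len(text) and text[pos] not in ",();":
                pos += 1
            node.length = float(text[start:pos])
        return node

    root = parse()
    tree = PhyloTree(root=root)
    tree.has_support = any(s is not None for _, s in tree.bipartitions().items())
    return tree
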