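"""Genetic and expression distance matrices and BIONJ tree construction.

The genetic distance between strains is the Tamura-Nei (TN93) nucleotide
distance, which separates the two transition classes (A<->G, C<->T) from
transversions and allows unequal base frequencies.  The expression distance
is the Euclidean distance between replicate-averaged TPM profiles scaled by
1/1000.  Trees are built with BIONJ, the variance-weighted variant of
neighbor joining: at each agglomeration the reduction weight lambda is
chosen to minimise the variance of the reduced distance matrix.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .stats import spearman

_BASE_CODE = {"A": 0, "C": 1, "G": 2, "T": 3}


@dataclass
class Node:
    """Tree node; ``length`` is the branch to the parent (0 at the root)."""

    name: str | None = None
    length: float = 0.0
    children: list["Node"] = field(default_factory=list)

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> list["Node"]:
        if self.is_leaf:
            return [self]
        out: list[Node] = []
        for c in self.children:
            out.extend(c.leaves())
        return out


@dataclass
class DistanceMatrix:
    labels: list[str]
    d: np.ndarray

    def __post_init__(self) -> None:
        self.d = np.asarray(self.d, dtype=float)
        n = len(self.labels)
        if self.d.shape != (n, n):
            raise ValueError("DistanceMatrix: shape does not match labels")
        if not np.allclose(self.d, self.d.T):
            raise ValueError("DistanceMatrix: not symmetric")
        if not np.allclose(np.diag(self.d), 0.0):
            raise ValueError("DistanceMatrix: nonzero diagonal")
        if not np.all(np.isfinite(self.d)):
            raise ValueError("DistanceMatrix: non-finite entries")
        if np.any(self.d < -1e-12):
            raise ValueError("DistanceMatrix: negative distances")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.d, index=self.labels, columns=self.labels)


def _encode(seq: str) -> np.ndarray:
    arr = np.frombuffer(seq.upper().encode("ascii"), dtype=np.uint8)
    out = np.full(arr.size, -1, dtype=np.int8)
    for base, code in _BASE_CODE.items():
        out[arr == ord(base)] = code
    return out


def tn93_pair(a: np.ndarray, b: np.ndarray) -> float:
    """TN93 distance between two encoded sequences with pairwise deletion.

    Sites where either sequence has a gap or ambiguous base are dropped for
    this pair only.  Base frequencies are averaged over the two sequences at
    the retained sites.  Saturation (a non-positive logarithm argument)
    raises rather than returning infinity.
    """
    mask = (a >= 0) & (b >= 0)
    n = int(mask.sum())
    if n == 0:
        raise ValueError("tn93: no comparable sites after pairwise deletion")
    x, y = a[mask], b[mask]
    counts = np.bincount(x, minlength=4) + np.bincount(y, minlength=4)
    pi = counts / (2.0 * n)
    pa, pc, pg, pt = pi
    pr, py_ = pa + pg, pc + pt
    diff = x != y
    ag = np.sum(diff & (((x == 0) & (y == 2)) | ((x == 2) & (y == 0))))
    ct = np.sum(diff & (((x == 1) & (y == 3)) | ((x == 3) & (y == 1))))
    p1 = float(ag) / n
    p2 = float(ct) / n
    q = float(diff.sum() - ag - ct) / n
    if p1 == 0.0 and p2 == 0.0 and q == 0.0:
        return 0.0
    if pr <= 0 or py_ <= 0:
        raise ValueError("tn93: a purine/pyrimidine class is absent")
    k1 = 2.0 * pa * pg / pr
    k2 = 2.0 * pc * pt / py_
    k3 = 2.0 * (pr * py_ - pa * pg * py_ / pr - pc * pt * pr / py_)
    w1 = 1.0 - (p1 / k1 if k1 > 0 else 0.0) - q / (2.0 * pr)
    w2 = 1.0 - (p2 / k2 if k2 > 0 else 0.0) - q / (2.0 * py_)
    w3 = 1.0 - q / (2.0 * pr * py_)
    if w1 <= 0 or w2 <= 0 or w3 <= 0:
        raise ValueError("tn93: distance saturated (log argument <= 0)")
    d = 0.0
    if k1 > 0:
        d -= k1 * math.log(w1)
    if k2 > 0:
        d -= k2 * math.log(w2)
    d -= k3 * math.log(w3)
    return d


def tn93_distance(aln: dict[str, str]) -> DistanceMatrix:
    """Pairwise TN93 distances for an alignment of equal-length sequences."""
    labels = list(aln)
    if len(labels) < 2:
        raise ValueError("tn93_distance: need at least 2 taxa")
    lengths = {len(s) for s in aln.values()}
    if len(lengths) != 1:
        raise ValueError("tn93_distance: sequences must have equal length")
    enc = {k: _encode(v) for k, v in aln.items()}
    n = len(labels)
    d = np.zeros((n, n))
    for i, j in itertools.combinations(range(n), 2):
        try:
            d[i, j] = d[j, i] = tn93_pair(enc[labels[i]], enc[labels[j]])
        except ValueError as e:
            raise ValueError(f"tn93 failed for pair ({labels[i]}, {labels[j]}): {e}") from e
    return DistanceMatrix(labels, d)


def expression_distance(tpm: pd.DataFrame, samples: pd.DataFrame,
                        condition: str, scale: float = 1000.0) -> DistanceMatrix:
    """Euclidean distance between strains on replicate-mean TPM / ``scale``.

    ``tpm`` is genes x samples; ``samples`` carries strain/condition columns
    indexed by sample id.
    """
    strains = sorted(samples["strain"].unique())
    profiles = []
    for s in strains:
        ids = samples.index[(samples["strain"] == s) & (samples["condition"] == condition)]
        if len(ids) == 0:
            raise ValueError(f"expression_distance: strain {s} has no {condition} samples")
        profiles.append(tpm[list(ids)].mean(axis=1).to_numpy() / scale)
    mat = np.stack(profiles)
    diff = mat[:, None, :] - mat[None, :, :]
    d = np.sqrt((diff ** 2).sum(axis=2))
    np.fill_diagonal(d, 0.0)
    d = (d + d.T) / 2.0
    return DistanceMatrix(strains, d)


def bionj(dm: DistanceMatrix) -> Node:
    """BIONJ agglomeration (Gascuel's variance-weighted neighbor joining).

    Variances are initialised to the distances.  The reduction weight is
    lambda = 1/2 + sum_k(V(j,k) - V(i,k)) / (2 (r-2) V(i,j)), clamped to
    [0, 1].  Negative branch lengths are clamped to zero with the deficit
    moved to the sibling branch so leaf-to-leaf path lengths are preserved.
    Returns an unrooted tree as a trifurcating root.
    """
    labels = dm.labels
    if len(labels) < 3:
        raise ValueError("bionj: need at least 3 taxa")
    cap = 2 * len(labels)
    d = np.zeros((cap, cap))
    v = np.zeros((cap, cap))
    n0 = len(labels)
    d[:n0, :n0] = dm.d
    v[:n0, :n0] = dm.d
    nodes: dict[int, Node] = {i: Node(name=labels[i]) for i in range(n0)}
    active = list(range(n0))
    nxt = n0

    def _clamp(bi: float, bj: float) -> tuple[float, float]:
        if bi < 0:
            bj += bi
            bi = 0.0
        if bj < 0:
            bi += bj
            bj = 0.0
        return max(bi, 0.0), max(bj, 0.0)

    while len(active) > 3:
        r = len(active)
        idx = np.array(active)
        sub = d[np.ix_(idx, idx)]
        s = sub.sum(axis=1)
        q = (r - 2) * sub - s[:, None] - s[None, :]
        np.fill_diagonal(q, np.inf)
        ai, aj = divmod(int(np.argmin(q)), r)
        if ai > aj:
            ai, aj = aj, ai
        i, j = active[ai], active[aj]
        dij = d[i, j]
        bi = 0.5 * dij + (s[ai] - s[aj]) / (2.0 * (r - 2))
        bj = dij - bi
        bi, bj = _clamp(bi, bj)
        others = [k for k in active if k not in (i, j)]
        vij = v[i, j]
        if vij > 0:
            lam = 0.5 + sum(v[j, k] - v[i, k] for k in others) / (2.0 * (r - 2) * vij)
            lam = min(1.0, max(0.0, lam))
        else:
            lam = 0.5
        u = nxt
        nxt += 1
        nodes[u] = Node(children=[nodes[i], nodes[j]])
        nodes[i].length, nodes[j].length = bi, bj
        for k in others:
            d[u, k] = d[k, u] = lam * (d[i, k] - bi) + (1 - lam) * (d[j, k] - bj)
            v[u, k] = v[k, u] = lam * v[i, k] + (1 - lam) * v[j, k] - lam * (1 - lam) * vij
        active = [k for k in active if k not in (i, j)] + [u]

    a, b, c = active
    ba = 0.5 * (d[a, b] + d[a, c] - d[b, c])
    bb = 0.5 * (d[a, b] + d[b, c] - d[a, c])
    bc = 0.5 * (d[a, c] + d[b, c] - d[a, b])
    for node, ln in ((nodes[a], ba), (nodes[b], bb), (nodes[c], bc)):
        node.length = max(ln, 0.0)
    return Node(children=[nodes[a], nodes[b], nodes[c]])


def cophenetic(tree: Node) -> DistanceMatrix:
    """Leaf-to-leaf path-length matrix of a tree (sorted leaf labels)."""
    paths: dict[str, dict[str, float]] = {}

    def _walk(node: Node, depth: float, acc: dict[str, float]) -> None:
        if node.is_leaf:
            if node.name is None:
                raise ValueError("cophenetic: unnamed leaf")
            acc[node.name] = depth
            return
        for c in node.children:
            _walk(c, depth + c.length, acc)

    def _collect(node: Node) -> dict[str, float]:
        acc: dict[str, float] = {}
        _walk(node, 0.0, acc)
        return acc

    # distance(leaf x, leaf y) = depth(x) + depth(y) - 2 depth(lca);
    # computed by recursing: for each internal node, pairs split across
    # children meet exactly there.
    labels = sorted(l.name for l in tree.leaves())
    index = {name: k for k, name in enumerate(labels)}
    d = np.zeros((len(labels), len(labels)))

    def _rec(node: Node) -> dict[str, float]:
        if node.is_leaf:
            return {node.name: 0.0}
        child_maps = []
        for c in node.children:
            m = _rec(c)
            child_maps.append({k: dist + c.length for k, dist in m.items()})
        for m1, m2 in itertools.combinations(child_maps, 2):
            for x, dx in m1.items():
                for y, dy in m2.items():
                    d[index[x], index[y]] = d[index[y], index[x]] = dx + dy
        merged: dict[str, float] = {}
        for m in child_maps:
            merged.update(m)
        return merged

    _rec(tree)
    return DistanceMatrix(labels, d)


def splits(tree: Node) -> set[frozenset[str]]:
    """Non-trivial bipartitions of an unrooted tree, as leaf-name sets."""
    all_leaves = frozenset(l.name for l in tree.leaves())
    out: set[frozenset[str]] = set()

    def _rec(node: Node) -> frozenset[str]:
        if node.is_leaf:
            return frozenset([node.name])
        below = frozenset().union(*(_rec(c) for c in node.children))
        if 1 < len(below) < len(all_leaves) - 1:
            out.add(min(below, all_leaves - below, key=sorted))
        return below

    for c in tree.children:
        _rec(c)
    return out


def compare_matrices(d1: DistanceMatrix, d2: DistanceMatrix) -> float:
    """Spearman correlation of the strictly-lower-triangle entries, paired by label."""
    if set(d1.labels) != set(d2.labels):
        raise ValueError("compare_matrices: label sets differ")
    order = sorted(d1.labels)
    a = d1.to_frame().loc[order, order].to_numpy()
    b = d2.to_frame().loc[order, order].to_numpy()
    tri = np.tril_indices(len(order), k=-1)
    return spearman(a[tri], b[tri])
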