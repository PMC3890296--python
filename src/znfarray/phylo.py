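"""Distance-based tree inference with VAF and quartet-based edge confidence.

Trees are inferred from the allele distance matrix by neighbor joining,
optionally followed by nearest-neighbor-interchange (NNI) hill climbing under
the balanced minimum-evolution criterion (Pauplin tree length). Branch
lengths are refit by ordinary least squares against the input matrix, with
negative estimates clamped to zero. Confidence is quantified without
bootstrapping (the prevalence of unit indels rules out a site-wise multiple
alignment): the whole-tree VAF (variance accounted for by patristic
distances) and, per internal edge, Re — the fraction of cross-split quartets
whose four-point condition agrees with the split.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
from skbio import DistanceMatrix as SkbioDM
from skbio.tree import nj as skbio_nj

from .msalign import AlleleDistanceMatrix

DEFAULT_MAX_QUARTETS = 100_000


class InvalidMatrixError(ValueError):
    pass


class InvalidEdgeError(ValueError):
    pass


@dataclass
class PhyloTree:
    """Unrooted binary tree over allele leaves.

    ``adj`` maps each node to its neighbors; leaves are label strings,
    internal nodes integers. ``lengths`` maps each edge (frozenset of its two
    endpoints) to a non-negative branch length. ``re`` maps internal-edge
    splits (frozenset of the labels on one side) to quartet confidences.
    """

    labels: list[str]
    adj: dict
    lengths: dict = field(default_factory=dict)
    re: dict = field(default_factory=dict)
    vaf: float | None = None

    # -- structure ---------------------------------------------------------

    def edges(self) -> list[frozenset]:
        out = set()
        for u, nbrs in self.adj.items():
            for v in nbrs:
                out.add(frozenset((u, v)))
        return sorted(out, key=lambda e: sorted(map(str, e)))

    def internal_edges(self) -> list[frozenset]:
        return [e for e in self.edges() if all(isinstance(n, int) for n in e)]

    def split_of_edge(self, edge: frozenset) -> frozenset:
        """Leaf labels on one (deterministic) side of ``edge``."""
        u, v = sorted(edge, key=str)
        side = self._leaves_beyond(u, v)
        other = frozenset(self.labels) - side
        return min(side, other, key=lambda s: (len(s), sorted(s)))

    def _leaves_beyond(self, start, blocked) -> frozenset:
        """Leaves reachable from ``start`` without crossing edge (start, blocked)."""
        seen = {blocked, start}
        stack = [start]
        leaves = set()
        while stack:
            node = stack.pop()
            if isinstance(node, str):
                leaves.add(node)
            for nb in self.adj[node]:
                if nb not in seen:
                    seen.add(nb)
                    stack.append(nb)
        return frozenset(leaves)

    def splits(self) -> set[frozenset]:
        """Non-trivial splits (one per internal edge), canonical side."""
        return {self.split_of_edge(e) for e in self.internal_edges()}

    # -- metrics -----------------------------------------------------------

    def _paths_from(self, leaf, weight) -> dict:
        dist = {leaf: 0.0}
        stack = [leaf]
        while stack:
            node = stack.pop()
            for nb in self.adj[node]:
                if nb not in dist:
                    dist[nb] = dist[node] + weight(frozenset((node, nb)))
                    stack.append(nb)
        return dist

    def patristic_matrix(self) -> np.ndarray:
        n = len(self.labels)
        t = np.zeros((n, n))
        for i, a in enumerate(self.labels):
            dist = self._paths_from(a, lambda e: self.lengths.get(e, 0.0))
            for j, b in enumerate(self.labels):
                t[i, j] = dist[b]
        return t

    def topological_distances(self) -> np.ndarray:
        n = len(self.labels)
        p = np.zeros((n, n), dtype=int)
        for i, a in enumerate(self.labels):
            dist = self._paths_from(a, lambda e: 1)
            for j, b in enumerate(self.labels):
                p[i, j] = dist[b]
        return p

    # -- serialization -----------------------------------------------------

    def to_newick(self, re_labels: bool = True) -> str:
        root = next(n for n in self.adj if isinstance(n, int))

        def fmt(node, parent) -> str:
            length = self.lengths.get(frozenset((node, parent)), 0.0)
            if isinstance(node, str):
                return f"{node}:{length:.6g}"
            kids = [fmt(nb, node) for nb in self.adj[node] if nb != parent]
            label = ""
            if re_labels and self.re:
                split = self.split_of_edge(frozenset((node, parent)))
                if split in self.re:
                    label = f"{self.re[split]:.4f}"
            return f"({','.join(kids)}){label}:{length:.6g}"

        kids = [fmt(nb, root) for nb in self.adj[root]]
        return f"({','.join(kids)});"


# ---------------------------------------------------------------------------
# Tree construction
# ---------------------------------------------------------------------------

def _validate(labels, D) -> np.ndarray:
    D = np.asarray(D, dtype=float)
    if D.shape != (len(labels), len(labels)):
        raise InvalidMatrixError("matrix shape does not match label count")
    if not np.allclose(D, D.T):
        raise InvalidMatrixError("matrix is not symmetric")
    if np.any(np.diag(D) != 0):
        raise InvalidMatrixError("diagonal must be zero")
    off = D[~np.eye(len(labels), dtype=bool)]
    if np.any(off < 0):
        raise InvalidMatrixError("negative off-diagonal entry")
    return (D + D.T) / 2.0  # remove rounding-level asymmetry


def _skbio_to_adj(tree, labels) -> dict:
    adj: dict = {}
    counter = [0]

    def node_id(node):
        if node.is_tip():
            return node.name
        if not hasattr(node, "_zid"):
            node._zid = counter[0]
            counter[0] += 1
        return node._zid

    for node in tree.traverse(include_self=True):
        nid = node_id(node)
        adj.setdefault(nid, [])
        for child in node.children:
            cid = node_id(child)
            adj[nid].append(cid)
            adj.setdefault(cid, []).append(nid)
    # suppress degree-2 nodes (a rooted representation of an unrooted tree)
    for nid in [n for n, nb in adj.items() if isinstance(n, int) and len(nb) == 2]:
        a, b = adj.pop(nid)
        adj[a] = [x for x in adj[a] if x != nid] + [b]
        adj[b] = [x for x in adj[b] if x != nid] + [a]
    return adj


def _bme_length(tree: PhyloTree, D: np.ndarray) -> float:
    """Balanced minimum-evolution tree length (Pauplin's formula)."""
    p = tree.topological_distances()
    n = len(tree.labels)
    iu = np.triu_indices(n, 1)
    return float(np.sum(D[iu] * np.exp2(1.0 - p[iu])))


def _nni_candidates(tree: PhyloTree):
    for edge in tree.internal_edges():
        u, v = sorted(edge, key=str)
        au = [x for x in tree.adj[u] if x != v]
        av = [x for x in tree.adj[v] if x != u]
        if len(au) != 2 or len(av) != 2:
            continue  # non-binary vertex; no standard NNI
        b = au[1]
        for c in av:
            yield u, v, b, c


def _apply_nni(adj: dict, u, v, b, c) -> None:
    adj[u] = [x if x != b else c for x in adj[u]]
    adj[v] = [x if x != c else b for x in adj[v]]
    adj[b] = [x if x != u else v for x in adj[b]]
    adj[c] = [x if x != v else u for x in adj[c]]


def _ols_branch_lengths(tree: PhyloTree, labels, D) -> None:
    """Least-squares branch lengths against D, negatives clamped to zero."""
    edges = tree.edges()
    eidx = {e: k for k, e in enumerate(edges)}
    # edge sets on the path from an arbitrary internal root to every node
    root = next(n for n in tree.adj if isinstance(n, int))
    path: dict = {root: frozenset()}
    stack = [root]
    while stack:
        node = stack.pop()
        for nb in tree.adj[node]:
            if nb not in path:
                path[nb] = path[node] | {frozenset((node, nb))}
                stack.append(nb)
    pairs = list(combinations(range(len(labels)), 2))
    X = np.zeros((len(pairs), len(edges)))
    y = np.zeros(len(pairs))
    for r, (i, j) in enumerate(pairs):
        for e in path[labels[i]] ^ path[labels[j]]:
            X[r, eidx[e]] = 1.0
        y[r] = D[i, j]
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    beta = np.clip(beta, 0.0, None)
    tree.lengths = {e: float(beta[k]) for e, k in eidx.items()}


def build_tree(dm: AlleleDistanceMatrix, method: str = "me_nni") -> PhyloTree:
    """Infer an unrooted tree from a distance matrix.

    ``nj``: canonical neighbor joining, then OLS branch lengths with negative
    estimates clamped to zero. ``me_nni``: NJ starting tree followed by NNI
    hill climbing under the balanced minimum-evolution criterion until no
    swap improves the Pauplin tree length.
    """
    labels = list(dm.allele_ids)
    if len(labels) < 4:
        raise InvalidMatrixError("need at least 4 labels")
    D = _validate(labels, dm.D_align)
    # NJ needs distinct rows; skbio tolerates ties deterministically
    sk = skbio_nj(SkbioDM(D, ids=labels))
    tree = PhyloTree(labels=labels, adj=_skbio_to_adj(sk, labels))
    if method == "me_nni":
        improved = True
        while improved:
            improved = False
            best = _bme_length(tree, D)
            best_move = None
            for u, v, b, c in _nni_candidates(tree):
                _apply_nni(tree.adj, u, v, b, c)
                cand = _bme_length(tree, D)
                _apply_nni(tree.adj, u, v, c, b)  # undo
                if cand < best - 1e-12:
                    best = cand
                    best_move = (u, v, b, c)
            if best_move is not None:
                _apply_nni(tree.adj, *best_move)
                improved = True
    elif method != "nj":
        raise ValueError(f"unknown method {method!r}")
    _ols_branch_lengths(tree, labels, D)
    return tree


# ---------------------------------------------------------------------------
# Confidence measures
# ---------------------------------------------------------------------------

def vaf(dm: AlleleDistanceMatrix, tree: PhyloTree) -> float:
    """Variance accounted for: concordance of matrix and patristic distances.

    VAF = 1 - sum (d_ij - t_ij)^2 / sum (d_ij - mean d)^2 over i<j.
    """
    labels = list(dm.allele_ids)
    if set(labels) != set(tree.labels) or len(labels) < 2:
        raise ValueError("tree leaves must equal matrix labels (>= 2)")
    D = np.asarray(dm.D_align, dtype=float)
    order = [labels.index(l) for l in tree.labels]
    D = D[np.ix_(order, order)]
    T = tree.patristic_matrix()
    iu = np.triu_indices(len(labels), 1)
    d, t = D[iu], T[iu]
    denom = np.sum((d - d.mean()) ** 2)
    if denom == 0:
        return 1.0 if np.allclose(d, t) else -np.inf
    value = 1.0 - np.sum((d - t) ** 2) / denom
    tree.vaf = float(value)
    return float(value)


def edge_re(
    dm: AlleleDistanceMatrix,
    tree: PhyloTree,
    edge: frozenset,
    max_quartets: int = DEFAULT_MAX_QUARTETS,
    seed: int | None = None,
) -> float:
    """Fraction of cross-split quartets supporting an internal edge.

    A quartet {a,a'} from one side and {b,b'} from the other is well designed
    when d(a,a') + d(b,b') < min(d(a,b)+d(a',b'), d(a,b')+d(a',b)) — the
    strict four-point condition; ties do not count. All quartets are
    enumerated up to ``max_quartets``, beyond which a seeded uniform sample
    of ``max_quartets`` quartets is scored.
    """
    if edge not in set(tree.internal_edges()):
        raise InvalidEdgeError("edge is not an internal edge of the tree")
    labels = list(dm.allele_ids)
    idx = {l: i for i, l in enumerate(labels)}
    D = np.asarray(dm.D_align, dtype=float)
    u, v = sorted(edge, key=str)
    s1 = sorted(tree._leaves_beyond(u, v))
    s2 = sorted(set(labels) - set(s1))
    if len(s1) < 2 or len(s2) < 2:
        raise InvalidEdgeError("both sides of the split need >= 2 leaves")

    def well_designed(a, a2, b, b2) -> bool:
        ia, ia2, ib, ib2 = idx[a], idx[a2], idx[b], idx[b2]
        same = D[ia, ia2] + D[ib, ib2]
        cross = min(D[ia, ib] + D[ia2, ib2], D[ia, ib2] + D[ia2, ib])
        return same < cross

    n1 = len(s1) * (len(s1) - 1) // 2
    n2 = len(s2) * (len(s2) - 1) // 2
    total = n1 * n2
    if total <= max_quartets:
        good = sum(
            well_designed(a, a2, b, b2)
            for a, a2 in combinations(s1, 2)
            for b, b2 in combinations(s2, 2)
        )
        value = good / total
    else:
        rng = random.Random(seed)
        good = 0
        for _ in range(max_quartets):
            a, a2 = rng.sample(s1, 2)
            b, b2 = rng.sample(s2, 2)
            good += well_designed(a, a2, b, b2)
        value = good / max_quartets
    tree.re[tree.split_of_edge(edge)] = value
    return value


def average_re(
    dm: AlleleDistanceMatrix,
    tree: PhyloTree,
    max_quartets: int = DEFAULT_MAX_QUARTETS,
    seed: int | None = None,
) -> float:
    """Mean Re over all internal edges with >= 2 leaves on each side."""
    values = []
    for edge in tree.internal_edges():
        try:
            values.append(edge_re(dm, tree, edge, max_quartets, seed))
        except InvalidEdgeError:
            continue
    if not values:
        raise ValueError("tree has no internal edge eligible for Re")
    return float(np.mean(values))


def robinson_foulds(t1: PhyloTree, t2: PhyloTree) -> int:
    """Symmetric-difference distance between the trees' non-trivial splits."""
    if set(t1.labels) != set(t2.labels):
        raise ValueError("trees must share a leaf set")

    def canon(tree):
        full = frozenset(tree.labels)
        out = set()
        for s in tree.splits():
            if 1 < len(s) < len(tree.labels) - 1:
                out.add(min(s, full - s, key=lambda x: (len(x), sorted(x))))
        return out

    return len(canon(t1) ^ canon(t2))
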