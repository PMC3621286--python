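"""Tree building under the K2P (K80) model: NJ, ML with NNI, bootstrap.

Trees are stored unrooted as an adjacency map with branch lengths in
substitutions/site and per-split bootstrap support.  The likelihood engine
is Felsenstein pruning with the K80 rate matrix (equal base frequencies,
transition rate ``kappa`` times the transversion rate, uniform rates among
sites); ambiguity codes contribute partial likelihoods over their compatible
bases and gaps/N are uninformative.

The ML search hill-climbs over nearest-neighbor-interchange neighborhoods
with per-branch Brent re-optimization, accepting only strict log-likelihood
improvements, so the result is a deterministic local optimum.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable

import numpy as np
from scipy.optimize import minimize_scalar

from .seq_io import AMBIGUITY, Alignment, Sequence
from .distances import distance_matrix, unique_sequences

BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(BASES)}
#: transition partner of each base (A<->G, C<->T)
_TS_PARTNER = np.array([2, 3, 0, 1])

_CHARS = sorted(AMBIGUITY) + ["-"]
_CHAR_CODE = {c: i for i, c in enumerate(_CHARS)}
_CHAR_VEC = np.zeros((len(_CHARS), 4))
for _c, _i in _CHAR_CODE.items():
    if _c == "-":
        _CHAR_VEC[_i] = 1.0
    else:
        for _b in AMBIGUITY[_c]:
            _CHAR_VEC[_i, _BASE_INDEX[_b]] = 1.0

_MIN_BRANCH = 1e-9
_MAX_BRANCH = 5.0


class Tree:
    """Unrooted tree: adjacency with branch lengths, tip labels, support."""

    def __init__(self) -> None:
        self.adj: dict[int, dict[int, float]] = {}
        self.labels: dict[int, str] = {}
        #: canonical split (frozenset of tip labels) -> bootstrap percentage
        self.support: dict[frozenset[str], float] = {}
        self._next_id = 0

    # -- construction -------------------------------------------------
    def new_node(self, label: str | None = None) -> int:
        nid = self._next_id
        self._next_id += 1
        self.adj[nid] = {}
        if label is not None:
            self.labels[nid] = label
        return nid

    def add_edge(self, u: int, v: int, length: float) -> None:
        self.adj[u][v] = length
        self.adj[v][u] = length

    def remove_edge(self, u: int, v: int) -> None:
        del self.adj[u][v]
        del self.adj[v][u]

    def set_length(self, u: int, v: int, length: float) -> None:
        self.adj[u][v] = length
        self.adj[v][u] = length

    def copy(self) -> "Tree":
        t = Tree()
        t.adj = {u: dict(nb) for u, nb in self.adj.items()}
        t.labels = dict(self.labels)
        t.support = dict(self.support)
        t._next_id = self._next_id
        return t

    # -- queries ------------------------------------------------------
    def tips(self) -> dict[str, int]:
        return {lab: nid for nid, lab in self.labels.items()}

    def tip_labels(self) -> set[str]:
        return set(self.labels.values())

    def degree(self, u: int) -> int:
        return len(self.adj[u])

    def edges(self) -> list[tuple[int, int]]:
        return sorted(
            (u, v) for u in self.adj for v in self.adj[u] if u < v
        )

    def internal_edges(self) -> list[tuple[int, int]]:
        return [
            (u, v) for u, v in self.edges()
            if self.degree(u) > 1 and self.degree(v) > 1
        ]

    def _side_tips(self, u: int, v: int) -> frozenset[str]:
        """Tip labels in the component containing v after cutting (u, v)."""
        out, stack, seen = [], [v], {u, v}
        while stack:
            x = stack.pop()
            if x in self.labels:
                out.append(self.labels[x])
            for y in self.adj[x]:
                if y not in seen:
                    seen.add(y)
                    stack.append(y)
        return frozenset(out)

    def canonical_split(self, side: frozenset[str]) -> frozenset[str]:
        """The side of a bipartition not containing the smallest tip label."""
        ref = min(self.tip_labels())
        return frozenset(self.tip_labels() - side) if ref in side else side

    def splits(self) -> set[frozenset[str]]:
        """Canonical nontrivial splits of the unrooted tree."""
        all_tips = self.tip_labels()
        out = set()
        for u, v in self.internal_edges():
            side = self._side_tips(u, v)
            if 1 < len(side) < len(all_tips) - 1:
                out.add(self.canonical_split(side))
        return out

    def total_length(self) -> float:
        return sum(self.adj[u][v] for u, v in self.edges())


# ---------------------------------------------------------------------------
# Neighbor joining


def nj(ids: list[str], mat: np.ndarray) -> Tree:
    """Saitou-Nei neighbor joining.

    Negative branch lengths are clamped to zero; tied Q-criterion minima are
    broken by the lexicographic pair of cluster names (a cluster is named by
    its smallest member tip).
    """
    n = len(ids)
    if n < 3:
        raise ValueError("neighbor joining requires at least 3 taxa")
    if mat.shape != (n, n):
        raise ValueError("matrix shape does not match taxa")
    if not np.allclose(mat, mat.T):
        raise ValueError("distance matrix must be symmetric")
    if not np.all(np.isfinite(mat)):
        raise ValueError("distance matrix must be finite")

    tree = Tree()
    nodes = [tree.new_node(label=name) for name in ids]
    active = list(range(n))  # indices into D bookkeeping
    D = {i: {j: float(mat[i, j]) for j in range(n) if j != i} for i in range(n)}
    node_of = {i: nodes[i] for i in range(n)}
    name_of = {i: ids[i] for i in range(n)}
    next_key = n

    while len(active) > 3:
        m = len(active)
        r = {i: sum(D[i][j] for j in active if j != i) for i in active}
        best = None
        for ai in range(len(active)):
            for aj in range(ai + 1, len(active)):
                i, j = active[ai], active[aj]
                q = (m - 2) * D[i][j] - r[i] - r[j]
                namepair = tuple(sorted((name_of[i], name_of[j])))
                key = (q, namepair)
                if best is None or key < best[0]:
                    best = (key, i, j)
        _, i, j = best
        li = 0.5 * D[i][j] + (r[i] - r[j]) / (2 * (m - 2))
        lj = D[i][j] - li
        li, lj = max(li, 0.0), max(lj, 0.0)
        u = tree.new_node()
        tree.add_edge(node_of[i], u, li)
        tree.add_edge(node_of[j], u, lj)
        key = next_key
        next_key += 1
        D[key] = {}
        for k in active:
            if k in (i, j):
                continue
            duk = 0.5 * (D[i][k] + D[j][k] - D[i][j])
            D[key][k] = duk
            D[k][key] = duk
        node_of[key] = u
        name_of[key] = min(name_of[i], name_of[j])
        active = [k for k in active if k not in (i, j)] + [key]

    a, b, c = sorted(active, key=lambda k: name_of[k])
    la = 0.5 * (D[a][b] + D[a][c] - D[b][c])
    lb = 0.5 * (D[a][b] + D[b][c] - D[a][c])
    lc = 0.5 * (D[a][c] + D[b][c] - D[a][b])
    center = tree.new_node()
    tree.add_edge(node_of[a], center, max(la, 0.0))
    tree.add_edge(node_of[b], center, max(lb, 0.0))
    tree.add_edge(node_of[c], center, max(lc, 0.0))
    return tree


def nj_from_alignment(alignment: Alignment, collapse: bool = False) -> Tree:
    """NJ tree from pairwise-deletion K2P distances of an alignment."""
    seqs = unique_sequences(list(alignment)) if collapse else list(alignment)
    ids, mat = distance_matrix(seqs)
    return nj(ids, mat)


# ---------------------------------------------------------------------------
# K80 likelihood


@dataclass
class MLConfig:
    """Likelihood-search settings.

    ``kappa=None`` estimates the transition/transversion rate ratio by a
    coarse grid over [1, 20] (step 0.5) followed by bounded refinement.
    ``collapse_below`` is the consensus-writer collapse threshold and
    ``support_high`` the bootstrap percentage treated as high support for
    monophyly claims.
    """

    kappa: float | None = None
    B: int = 1000
    collapse_below: float = 50.0
    support_high: float = 70.0

    def __post_init__(self) -> None:
        if self.kappa is not None and self.kappa <= 0:
            raise ValueError("kappa must be positive")
        if not 0 < self.collapse_below <= 100:
            raise ValueError("collapse_below must be in (0, 100]")


def k80_transition_matrix(t: float, kappa: float) -> np.ndarray:
    """P(t) under K80 with branch length t in expected substitutions/site."""
    beta = 1.0 / (kappa + 2.0)
    alpha = kappa * beta
    e1 = math.exp(-4.0 * beta * t)
    e2 = math.exp(-2.0 * (alpha + beta) * t)
    p_same = 0.25 + 0.25 * e1 + 0.5 * e2
    p_ts = 0.25 + 0.25 * e1 - 0.5 * e2
    p_tv = 0.25 - 0.25 * e1
    P = np.full((4, 4), p_tv)
    np.fill_diagonal(P, p_same)
    for i in range(4):
        P[i, _TS_PARTNER[i]] = p_ts
    return P


class _PatternData:
    """Site-pattern-compressed alignment restricted to a set of tips."""

    def __init__(self, alignment: Alignment, tip_labels: list[str]) -> None:
        if alignment.length == 0:
            raise ValueError("zero-length alignment")
        by_id = {s.id: s for s in alignment}
        rows = []
        for lab in tip_labels:
            if lab not in by_id:
                raise KeyError(f"tree tip {lab!r} not in alignment")
            rows.append([_CHAR_CODE[c] for c in by_id[lab].residues])
        arr = np.asarray(rows, dtype=np.uint8)  # (ntips, nsites)
        patterns, counts = np.unique(arr, axis=1, return_counts=True)
        self.tip_labels = tip_labels
        self.tip_vecs = {
            lab: _CHAR_VEC[patterns[i]] for i, lab in enumerate(tip_labels)
        }  # (npat, 4) each
        self.counts = counts.astype(float)
        self.n_sites = arr.shape[1]


def _pattern_data(tree: Tree, alignment: Alignment) -> _PatternData:
    return _PatternData(alignment, sorted(tree.tip_labels()))


def _loglik_patterns(tree: Tree, data: _PatternData, kappa: float) -> float:
    """Pruning likelihood, rooting at the smallest-labeled tip."""
    root = tree.tips()[min(tree.tip_labels())]
    # iterative postorder
    order: list[tuple[int, int]] = []  # (node, parent)
    stack = [(root, -1)]
    while stack:
        node, parent = stack.pop()
        order.append((node, parent))
        for nb in sorted(tree.adj[node]):
            if nb != parent:
                stack.append((nb, node))
    partial: dict[int, np.ndarray] = {}
    for node, parent in reversed(order):
        if node in tree.labels:
            L = data.tip_vecs[tree.labels[node]].copy()
        else:
            L = np.ones((len(data.counts), 4))
        for nb in sorted(tree.adj[node]):
            if nb == parent:
                continue
            P = k80_transition_matrix(tree.adj[node][nb], kappa)
            L = L * (partial.pop(nb) @ P.T)
        partial[node] = L
    site_lik = 0.25 * partial[root].sum(axis=1)
    if np.any(site_lik <= 0):
        return -math.inf
    return float(np.log(site_lik) @ data.counts)


def loglik(tree: Tree, alignment: Alignment, kappa: float = 4.0) -> float:
    """Log-likelihood of an alignment on a tree under K80.

    Equal base frequencies 1/4; ambiguity codes are partial likelihoods over
    their compatible bases; gaps and N are all-ones (uninformative).
    """
    return _loglik_patterns(tree, _pattern_data(tree, alignment), kappa)


def optimize_branch_lengths(
    tree: Tree,
    alignment: Alignment,
    kappa: float = 4.0,
    rounds: int = 3,
    tol: float = 1e-6,
) -> float:
    """Brent-optimize each branch in turn (in place); returns final logL."""
    data = _pattern_data(tree, alignment)
    return _optimize_branches(tree, data, kappa, rounds, tol)


def _optimize_branches(
    tree: Tree,
    data: _PatternData,
    kappa: float,
    rounds: int = 3,
    tol: float = 1e-6,
) -> float:
    current = _loglik_patterns(tree, data, kappa)
    for _ in range(rounds):
        improved = False
        for u, v in tree.edges():
            old = tree.adj[u][v]

            def neg(t: float) -> float:
                tree.set_length(u, v, t)
                return -_loglik_patterns(tree, data, kappa)

            res = minimize_scalar(
                neg, bounds=(_MIN_BRANCH, _MAX_BRANCH), method="bounded",
                options={"xatol": tol},
            )
            if -res.fun > current + 1e-12:
                tree.set_length(u, v, float(res.x))
                current = -res.fun
                improved = True
            else:
                tree.set_length(u, v, old)
        if not improved:
            break
    return current


def estimate_kappa(tree: Tree, alignment: Alignment) -> float:
    """Grid search over [1, 20] at 0.5 steps, then bounded refinement."""
    data = _pattern_data(tree, alignment)
    grid = np.arange(1.0, 20.0 + 1e-9, 0.5)
    scores = [_loglik_patterns(tree, data, k) for k in grid]
    best = int(np.argmax(scores))
    lo = grid[max(best - 1, 0)]
    hi = grid[min(best + 1, len(grid) - 1)]
    if lo == hi:
        return float(grid[best])
    res = minimize_scalar(
        lambda k: -_loglik_patterns(tree, data, k),
        bounds=(lo, hi), method="bounded", options={"xatol": 1e-3},
    )
    return float(res.x)


# ---------------------------------------------------------------------------
# NNI search


def nni_neighbors(tree: Tree) -> list[Tree]:
    """The two NNI rearrangements of every internal edge, in a fixed order."""
    out = []
    for u, v in tree.internal_edges():
        if tree.degree(u) < 3 or tree.degree(v) < 3:
            continue
        a = min(x for x in tree.adj[u] if x != v)
        for c in sorted(x for x in tree.adj[v] if x != u):
            t = tree.copy()
            la, lc = t.adj[u][a], t.adj[v][c]
            t.remove_edge(u, a)
            t.remove_edge(v, c)
            t.add_edge(u, c, lc)
            t.add_edge(v, a, la)
            out.append(t)
    return out


def nni_search(
    start: Tree,
    alignment: Alignment,
    cfg: MLConfig | None = None,
    kappa: float | None = None,
) -> tuple[Tree, float]:
    """Hill-climb over NNI neighborhoods with branch re-optimization.

    Accepts only improvements above 1e-8 in logL; neighbor ordering is
    deterministic, so the local optimum reached is reproducible.
    """
    cfg = cfg or MLConfig()
    if kappa is None:
        kappa = cfg.kappa if cfg.kappa is not None else estimate_kappa(
            start, alignment
        )
    data = _pattern_data(start, alignment)
    current = start.copy()
    cur_ll = _optimize_branches(current, data, kappa)
    while True:
        best_tree, best_ll = None, cur_ll
        for nb in nni_neighbors(current):
            ll = _optimize_branches(nb, data, kappa)
            if ll > best_ll + 1e-8:
                best_tree, best_ll = nb, ll
        if best_tree is None:
            return current, cur_ll
        current, cur_ll = best_tree, best_ll


def ml_tree(
    alignment: Alignment, cfg: MLConfig | None = None
) -> tuple[Tree, float, float]:
    """NJ start, kappa estimation, NNI hill-climb.

    Returns ``(tree, logL, kappa)``.
    """
    cfg = cfg or MLConfig()
    start = nj_from_alignment(alignment)
    kappa = cfg.kappa if cfg.kappa is not None else estimate_kappa(
        start, alignment
    )
    tree, ll = nni_search(start, alignment, cfg, kappa=kappa)
    return tree, ll, kappa


# ---------------------------------------------------------------------------
# Bootstrap and monophyly


def _resampled(alignment: Alignment, cols: np.ndarray) -> Alignment:
    return Alignment([
        Sequence(
            id=s.id,
            residues="".join(s.residues[c] for c in cols),
            species=s.species,
            marker=s.marker,
        )
        for s in alignment
    ])


def bootstrap(
    alignment: Alignment,
    builder: Callable[[Alignment], Tree],
    B: int = 1000,
    seed: int = 1,
) -> Tree:
    """Column-resampling bootstrap; annotates the full-data tree's splits.

    ``builder`` maps an alignment to a tree (NJ or the ML pipeline).  Splits
    of the full-data tree receive the percentage of replicates in which they
    reappear.
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    full = builder(alignment)
    counts: dict[frozenset[str], int] = {s: 0 for s in full.splits()}
    rng = np.random.default_rng(seed)
    length = alignment.length
    for _ in range(B):
        cols = rng.integers(0, length, size=length)
        rep = builder(_resampled(alignment, cols))
        for s in rep.splits():
            if s in counts:
                counts[s] += 1
    full.support = {s: 100.0 * c / B for s, c in counts.items()}
    return full


def monophyly(
    tree: Tree, tip_set: set[str]
) -> tuple[bool, float | None]:
    """Is ``tip_set`` one side of a split?  Returns its bootstrap support.

    Singletons and the full tip set are trivially monophyletic with support
    ``None``.
    """
    tips = tree.tip_labels()
    unknown = set(tip_set) - tips
    if unknown:
        raise KeyError(f"unknown tips: {sorted(unknown)}")
    if not tip_set:
        raise ValueError("tip_set must be non-empty")
    if len(tip_set) == 1 or set(tip_set) == tips:
        return True, None
    canon = tree.canonical_split(frozenset(tip_set))
    if canon in tree.splits():
        return True, tree.support.get(canon)
    return False, None


def collapse_low_support(tree: Tree, threshold: float) -> Tree:
    """Contract internal edges whose support is below ``threshold`` percent.

    Splits without recorded support are kept.  The result may be
    multifurcating (a consensus-style topology).
    """
    t = tree.copy()
    changed = True
    while changed:
        changed = False
        for u, v in t.internal_edges():
            side = t._side_tips(u, v)
            if not (1 < len(side) < len(t.tip_labels()) - 1):
                continue
            sup = t.support.get(t.canonical_split(side))
            if sup is not None and sup < threshold:
                # merge v into u
                for w, lw in list(t.adj[v].items()):
                    if w != u:
                        t.remove_edge(v, w)
                        t.add_edge(u, w, lw)
                t.remove_edge(u, v)
                del t.adj[v]
                t.support.pop(t.canonical_split(side), None)
                changed = True
                break
    return t


# ---------------------------------------------------------------------------
# Newick I/O


def to_newick(tree: Tree, with_support: bool = True) -> str:
    """Newick string; bootstrap supports appear as internal-node labels."""
    root_tip = tree.tips()[min(tree.tip_labels())]
    root = next(iter(tree.adj[root_tip]))
    all_tips = tree.tip_labels()

    def fmt_support(node: int, parent: int) -> str:
        side = tree._side_tips(parent, node)
        if not (1 < len(side) < len(all_tips) - 1):
            return ""
        sup = tree.support.get(tree.canonical_split(side))
        return "" if sup is None else f"{sup:g}"

    def rec(node: int, parent: int) -> str:
        if node in tree.labels:
            return f"{tree.labels[node]}:{tree.adj[node][parent]:.6f}"
        parts = [rec(nb, node) for nb in sorted(tree.adj[node]) if nb != parent]
        label = fmt_support(node, parent) if with_support else ""
        return f"({','.join(parts)}){label}:{tree.adj[node][parent]:.6f}"

    parts = [rec(nb, root) for nb in sorted(tree.adj[root]) if nb != root_tip]
    parts.insert(0, f"{tree.labels[root_tip]}:{tree.adj[root_tip][root]:.6f}")
    return f"({','.join(parts)});"


def from_newick(text: str) -> Tree:
    """Parse a newick string (via dendropy); internal labels become support."""
    import dendropy

    dt = dendropy.Tree.get(data=text, schema="newick")
    tree = Tree()
    node_map: dict = {}

    def conv(dnode) -> int:
        label = dnode.taxon.label if dnode.taxon is not None else None
        nid = tree.new_node(label=label)
        node_map[dnode] = nid
        return nid

    for dnode in dt.preorder_node_iter():
        nid = conv(dnode)
        if dnode.parent_node is not None:
            pid = node_map[dnode.parent_node]
            length = dnode.edge.length if dnode.edge.length is not None else 0.0
            tree.add_edge(pid, nid, float(length))
    # suppress a degree-2 artificial root
    for nid in list(tree.adj):
        if tree.degree(nid) == 2 and nid not in tree.labels:
            (a, la), (b, lb) = list(tree.adj[nid].items())
            tree.remove_edge(nid, a)
            tree.remove_edge(nid, b)
            del tree.adj[nid]
            tree.add_edge(a, b, la + lb)
    # internal-node labels -> support, keyed by canonical split
    n_tips = len(tree.labels)
    for dnode in dt.preorder_node_iter():
        if dnode.taxon is None and dnode.label is not None:
            side = frozenset(
                lf.taxon.label for lf in dnode.leaf_iter()
            )
            if not 1 < len(side) < n_tips - 1:
                continue
            try:
                tree.support[tree.canonical_split(side)] = float(dnode.label)
            except ValueError:
                pass
    return tree
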