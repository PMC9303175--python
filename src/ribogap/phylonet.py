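"""Distance-based trees and reticulation diagnostics.

Barcode repeat pools that evolved tree-like sit on a neighbour-joining
tree; pools shaped by reticulation (hybridization, repeat exchange) do
not.  This module provides both sides of that diagnosis:

* :func:`nj` — Saitou–Nei neighbour joining with a deterministic
  lexicographic tie-break and branch lengths clamped at zero;
* :func:`neighbour_net` — the two-stage neighbour-net agglomeration
  producing a circular taxon ordering, with split weights fitted by
  non-negative least squares over all splits compatible with the
  ordering; an additive (tree) metric comes back as exactly the tree
  splits, while conflicting signal shows up as incompatible splits
  rendering as parallel-edge boxes;
* :func:`delta_score` — per-quartet departure from the four-point
  condition (0 on tree metrics, 1 on a maximally conflicting "box"
  quartet) plus a Q-residual, quantifying how non-tree-like a distance
  matrix is.

All algorithms are deterministic for a fixed input ordering; outputs are
invariant to taxon permutation up to relabelling.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import scipy.optimize

from .distance import DistanceMatrix

_log = logging.getLogger(__name__)

__all__ = [
    "Tree",
    "Split",
    "SplitSystem",
    "TreelikenessStats",
    "nj",
    "neighbour_net",
    "circular_ordering",
    "all_circular_splits",
    "estimate_split_weights",
    "delta_score",
    "write_nexus_splits",
]


# ---------------------------------------------------------------------------
# trees


@dataclass
class Tree:
    """Unrooted tree: adjacency map with branch lengths, leaves labelled."""

    adjacency: dict[int, list[tuple[int, float]]]
    leaf_labels: dict[int, str]

    @property
    def labels(self) -> list[str]:
        return [self.leaf_labels[i] for i in sorted(self.leaf_labels)]

    def leaf_distances(self) -> DistanceMatrix:
        """Path-length metric between leaves (the additive metric of the tree)."""
        leaves = sorted(self.leaf_labels)
        n = len(leaves)
        mat = np.zeros((n, n))
        for a_idx, a in enumerate(leaves):
            # BFS/DFS accumulating path lengths
            dist = {a: 0.0}
            stack = [a]
            while stack:
                u = stack.pop()
                for v, w in self.adjacency[u]:
                    if v not in dist:
                        dist[v] = dist[u] + w
                        stack.append(v)
            for b_idx, b in enumerate(leaves):
                mat[a_idx, b_idx] = dist[b]
        labels = [self.leaf_labels[i] for i in leaves]
        return DistanceMatrix.from_square(labels, mat)

    def splits(self) -> list[tuple[frozenset[str], float]]:
        """Every edge's leaf bipartition (side not containing the first leaf)
        with its branch length."""
        first_leaf = min(self.leaf_labels)
        out = []
        seen_edges = set()
        for u, nbrs in self.adjacency.items():
            for v, w in nbrs:
                edge = (min(u, v), max(u, v))
                if edge in seen_edges:
                    continue
                seen_edges.add(edge)
                # leaves reachable from v without crossing u
                side: set[str] = set()
                stack = [(v, u)]
                contains_first = False
                while stack:
                    node, parent = stack.pop()
                    if node in self.leaf_labels:
                        side.add(self.leaf_labels[node])
                        if node == first_leaf:
                            contains_first = True
                    for nxt, _ in self.adjacency[node]:
                        if nxt != parent:
                            stack.append((nxt, node))
                if contains_first:
                    side = {
                        lab for lab in self.leaf_labels.values() if lab not in side
                    }
                out.append((frozenset(side), w))
        return out

    def newick(self) -> str:
        # root at an internal node (highest id = last join) if any
        internal = [n for n in self.adjacency if n not in self.leaf_labels]
        root = max(internal) if internal else next(iter(self.adjacency))

        def fmt_label(label: str) -> str:
            if any(c in label for c in " (),:;'[]"):
                return "'" + label.replace("'", "''") + "'"
            return label

        def rec(node: int, parent: int | None) -> str:
            children = [
                (v, w) for v, w in self.adjacency[node] if v != parent
            ]
            if not children and node in self.leaf_labels:
                return fmt_label(self.leaf_labels[node])
            parts = [f"{rec(v, node)}:{w:.10g}" for v, w in children]
            name = fmt_label(self.leaf_labels[node]) if node in self.leaf_labels else ""
            return f"({','.join(parts)}){name}"

        return rec(root, None) + ";"


def nj(dm: DistanceMatrix) -> Tree:
    """Saitou–Nei neighbour joining.

    Deterministic: among equal Q-criterion minima the smallest (row, col)
    lexicographic pair is joined.  Negative branch lengths are clamped to 0
    (logged).
    """
    n = dm.n
    if n < 3:
        raise ValueError("neighbour joining needs at least 3 taxa")
    D = dm.percent.astype(float).copy()
    active = list(range(n))            # node ids of current rows
    adjacency: dict[int, list[tuple[int, float]]] = {i: [] for i in range(n)}
    leaf_labels = {i: lab for i, lab in enumerate(dm.labels)}
    next_id = n
    clamped = 0

    def add_edge(u: int, v: int, w: float):
        nonlocal clamped
        if w < 0:
            clamped += 1
            w = 0.0
        adjacency.setdefault(u, []).append((v, w))
        adjacency.setdefault(v, []).append((u, w))

    while len(active) > 3:
        m = len(active)
        r = D.sum(axis=1)
        Q = (m - 2) * D - r[:, None] - r[None, :]
        np.fill_diagonal(Q, np.inf)
        flat = int(np.argmin(Q))        # row-major argmin = lexicographic tie-break
        i, j = divmod(flat, m)
        if i > j:
            i, j = j, i
        dij = D[i, j]
        li = 0.5 * dij + (r[i] - r[j]) / (2 * (m - 2))
        lj = dij - li
        new = next_id
        next_id += 1
        add_edge(active[i], new, li)
        add_edge(active[j], new, lj)
        d_new = 0.5 * (D[i, :] + D[j, :] - dij)
        # replace row i by the new node, drop row j
        D[i, :] = d_new
        D[:, i] = d_new
        D[i, i] = 0.0
        keep = [k for k in range(m) if k != j]
        D = D[np.ix_(keep, keep)]
        active[i] = new
        del active[j]

    # final three-way join
    (a, b, c) = active
    dab, dac, dbc = D[0, 1], D[0, 2], D[1, 2]
    center = next_id
    add_edge(a, center, 0.5 * (dab + dac - dbc))
    add_edge(b, center, 0.5 * (dab + dbc - dac))
    add_edge(c, center, 0.5 * (dac + dbc - dab))
    if clamped:
        _log.warning("clamped %d negative branch lengths to 0", clamped)
    return Tree(adjacency, leaf_labels)


# ---------------------------------------------------------------------------
# neighbour-net


@dataclass(frozen=True)
class Split:
    """Taxon bipartition, stored as the side not containing the anchor taxon."""

    side: frozenset[str]
    all_taxa: frozenset[str]

    @property
    def other_side(self) -> frozenset[str]:
        return self.all_taxa - self.side

    def separates(self, a: str, b: str) -> bool:
        return (a in self.side) != (b in self.side)

    @property
    def trivial(self) -> bool:
        return min(len(self.side), len(self.all_taxa) - len(self.side)) == 1

    @staticmethod
    def make(side: Sequence[str], all_taxa: Sequence[str]) -> "Split":
        taxa = frozenset(all_taxa)
        s = frozenset(side)
        anchor = min(taxa)
        if anchor in s:
            s = taxa - s
        if not s or s == taxa:
            raise ValueError("split sides must both be non-empty")
        return Split(s, taxa)


@dataclass
class SplitSystem:
    """Weighted splits compatible with one circular taxon ordering."""

    taxa: list[str]
    ordering: list[str]                    # circular ordering of taxa
    splits: list[Split]
    weights: np.ndarray
    residual_norm: float
    metadata: dict = field(default_factory=dict)

    def nontrivial(self) -> list[tuple[Split, float]]:
        return [
            (s, float(w))
            for s, w in zip(self.splits, self.weights)
            if not s.trivial
        ]

    def weight_of(self, side: Sequence[str]) -> float:
        target = Split.make(side, self.taxa)
        for s, w in zip(self.splits, self.weights):
            if s == target:
                return float(w)
        return 0.0

    def to_rows(self) -> list[dict]:
        return [
            {
                "split": "|".join(sorted(s.side)),
                "size": min(len(s.side), len(s.all_taxa) - len(s.side)),
                "weight": float(w),
            }
            for s, w in zip(self.splits, self.weights)
        ]


def _reduc(d: np.ndarray, x: int, y: int, z: int) -> None:
    """Collapse the chain x–y–z into two nodes kept in slots x and z.

    The new endpoints average the chain with weights 2/3 (outer node) and
    1/3 (collapsed middle node); their mutual distance is the mean of the
    three chain distances.
    """
    u = (2.0 / 3.0) * d[x, :] + d[y, :] / 3.0
    v = (2.0 / 3.0) * d[z, :] + d[y, :] / 3.0
    uv = (d[x, y] + d[x, z] + d[y, z]) / 3.0
    d[x, :] = u
    d[:, x] = u
    d[z, :] = v
    d[:, z] = v
    d[y, :] = 0.0
    d[:, y] = 0.0
    d[x, z] = d[z, x] = uv
    d[x, x] = d[z, z] = 0.0


def _cluster_matrix(d: np.ndarray, CL: list[list[int]]) -> np.ndarray:
    m = len(CL)
    DM = np.zeros((m, m))
    for i in range(m):
        for j in range(i + 1, m):
            DM[i, j] = DM[j, i] = d[np.ix_(CL[i], CL[j])].mean()
    return DM


def _rx(d: np.ndarray, nodes: list[int], others: list[list[int]]) -> np.ndarray:
    """Row sums treating each of *nodes* as a singleton cluster and averaging
    over the remaining clusters."""
    res = np.zeros(len(nodes))
    for i, xi in enumerate(nodes):
        tmp = 0.0
        for j, xj in enumerate(nodes):
            if j != i:
                tmp += d[xi, xj]
        for cl in others:
            tmp += d[xi, cl].mean()
        res[i] = tmp
    return res


def circular_ordering(dm: DistanceMatrix) -> list[str]:
    """Neighbour-net circular ordering of the taxa.

    Two-stage agglomeration: cluster pairs are selected with the NJ-style
    criterion on cluster-averaged distances; within the selected pair the
    node pair (cluster endpoints) minimizing the same criterion over the
    expanded cluster list is linked, and any 3-chain is immediately reduced
    to its two endpoints (2/3–1/3 reduction).  The orderings accumulated per
    cluster concatenate into a circular ordering of all taxa.
    """
    n = dm.n
    if n < 3:
        raise ValueError("circular ordering needs at least 3 taxa")
    d = dm.percent.astype(float).copy()
    CL: list[list[int]] = [[i] for i in range(n)]      # active endpoint nodes
    order: list[list[int]] = [[i] for i in range(n)]   # full taxon orderings
    new_ord: list[int] = list(range(n))

    def cluster_key(e: int) -> str:
        return min(dm.labels[i] for i in order[e])

    while len(CL) > 1:
        m = len(CL)
        DM = _cluster_matrix(d, CL)
        if m > 2:
            r = DM.sum(axis=1) / (m - 2)
            Q = DM - r[:, None] - r[None, :]
            np.fill_diagonal(Q, np.inf)
            # at 4 clusters complementary pairs tie exactly (an identity of
            # the selection criterion), so ties are broken canonically by
            # taxon label to keep the result input-order invariant
            qmin = float(Q.min())
            tol = 1e-9 * (1.0 + abs(qmin))
            candidates = [
                (i, j)
                for i in range(m)
                for j in range(i + 1, m)
                if Q[i, j] <= qmin + tol
            ]
            e1, e2 = min(
                candidates,
                key=lambda p: tuple(sorted((cluster_key(p[0]), cluster_key(p[1])))),
            )
        else:
            e1, e2 = 0, 1
        n1, n2 = len(CL[e1]), len(CL[e2])
        if n1 == 1 and n2 == 1:
            new_cl = CL[e1] + CL[e2]
            new_ord = order[e1] + order[e2]
        else:
            nodes2 = CL[e1] + CL[e2]
            others = [CL[k] for k in range(m) if k not in (e1, e2)]
            ltmp = len(nodes2) + len(others)
            r2 = _rx(d, nodes2, others)
            if ltmp > 2:
                r2 = r2 / (ltmp - 2)
            DM3 = d[np.ix_(nodes2, nodes2)] - (r2[:, None] + r2[None, :])
            TMP2 = DM3[:n1, n1:n1 + n2]
            # first minimum in column-major order
            flat = int(np.argmin(TMP2.T))
            jj, ii = divmod(flat, n1)
            x = CL[e1]
            y = CL[e2]
            if n1 == 2 and n2 == 1:
                if (ii, jj) == (1, 0):        # link x[1] -- y[0]
                    new_cl = [x[0], y[0]]
                    new_ord = order[e1] + order[e2]
                    _reduc(d, x[0], x[1], y[0])
                else:                          # link x[0] -- y[0]
                    new_cl = [y[0], x[1]]
                    new_ord = order[e2] + order[e1]
                    _reduc(d, y[0], x[0], x[1])
            elif n1 == 1 and n2 == 2:
                if (ii, jj) == (0, 0):        # link x[0] -- y[0]
                    new_cl = [x[0], y[1]]
                    new_ord = order[e1] + order[e2]
                    _reduc(d, x[0], y[0], y[1])
                else:                          # link x[0] -- y[1]
                    new_cl = [y[0], x[0]]
                    new_ord = order[e2] + order[e1]
                    _reduc(d, y[0], y[1], x[0])
            else:  # n1 == 2 and n2 == 2
                if (ii, jj) == (0, 0):        # link x[0] -- y[0]
                    new_cl = [x[1], y[1]]
                    new_ord = list(reversed(order[e1])) + order[e2]
                    _reduc(d, x[1], x[0], y[0])
                    _reduc(d, x[1], y[0], y[1])
                elif (ii, jj) == (1, 0):      # link x[1] -- y[0]
                    new_cl = [x[0], y[1]]
                    new_ord = order[e1] + order[e2]
                    _reduc(d, x[0], x[1], y[0])
                    _reduc(d, x[0], y[0], y[1])
                elif (ii, jj) == (0, 1):      # link x[0] -- y[1]
                    new_cl = [x[1], y[0]]
                    new_ord = list(reversed(order[e1])) + list(reversed(order[e2]))
                    _reduc(d, x[1], x[0], y[1])
                    _reduc(d, x[1], y[1], y[0])
                else:                          # link x[1] -- y[1]
                    new_cl = [x[0], y[0]]
                    new_ord = order[e1] + list(reversed(order[e2]))
                    _reduc(d, x[0], x[1], y[1])
                    _reduc(d, x[0], y[1], y[0])
        order[e1] = new_ord
        CL[e1] = new_cl
        del order[e2]
        del CL[e2]
    return [dm.labels[i] for i in new_ord]


def all_circular_splits(ordering: Sequence[str]) -> list[Split]:
    """The n(n-1)/2 splits compatible with a circular ordering: every
    contiguous arc not containing the first taxon."""
    n = len(ordering)
    taxa = list(ordering)
    splits = []
    for p in range(1, n):
        for q in range(p, n):
            splits.append(Split.make(taxa[p:q + 1], taxa))
    return splits


def estimate_split_weights(
    dm: DistanceMatrix, splits: Sequence[Split]
) -> tuple[np.ndarray, float]:
    """Non-negative least-squares fit of split metrics to the distances.

    Rejects duplicate splits (singular design).  Returns (weights,
    residual norm).
    """
    if len(set(splits)) != len(splits):
        raise ValueError("duplicate splits in design")
    labels = dm.labels
    pairs = list(itertools.combinations(range(len(labels)), 2))
    A = np.zeros((len(pairs), len(splits)))
    for col, s in enumerate(splits):
        for row, (i, j) in enumerate(pairs):
            if s.separates(labels[i], labels[j]):
                A[row, col] = 1.0
    b = np.array([dm.percent[i, j] for i, j in pairs])
    weights, rnorm = scipy.optimize.nnls(A, b)
    return weights, float(rnorm)


def neighbour_net(
    dm: DistanceMatrix, *, min_weight: float = 1e-9
) -> SplitSystem:
    """Neighbour-net circular split system of a distance matrix.

    Splits compatible with the circular ordering are weighted by NNLS;
    splits below ``min_weight`` are dropped.  On an additive matrix the
    surviving splits are exactly the tree's splits with the branch lengths
    as weights.
    """
    if dm.n < 4:
        # too few taxa to express conflicting splits; the NJ tree carries
        # the full structure
        tree = nj(dm)
        ordering = list(dm.labels)
        taxa = list(dm.labels)
        splits, weights = [], []
        for side, w in tree.splits():
            sp = Split.make(side, taxa)
            if sp in splits:
                weights[splits.index(sp)] += w
            else:
                splits.append(sp)
                weights.append(w)
        return SplitSystem(
            taxa, ordering, splits, np.array(weights), 0.0,
            metadata={"method": "nj-fallback"},
        )
    ordering = circular_ordering(dm)
    candidates = all_circular_splits(ordering)
    weights, rnorm = estimate_split_weights(dm, candidates)
    keep = [k for k, w in enumerate(weights) if w >= min_weight]
    return SplitSystem(
        taxa=list(dm.labels),
        ordering=ordering,
        splits=[candidates[k] for k in keep],
        weights=weights[keep],
        residual_norm=rnorm,
        metadata={"min_weight": min_weight, "reduction": "2/3-1/3"},
    )


# ---------------------------------------------------------------------------
# treelikeness


@dataclass
class TreelikenessStats:
    mean_delta: float
    per_taxon_delta: dict[str, float]
    q_residual: float
    n_quartets: int


def delta_score(dm: DistanceMatrix) -> TreelikenessStats:
    """Quartet delta scores and Q-residuals of a distance matrix.

    For each quartet the three pairwise sums are ordered s1 >= s2 >= s3 and
    delta = (s1 - s2) / (s1 - s3) (0 when all equal).  An additive metric
    satisfies the four-point condition (s1 == s2), giving delta 0; a
    maximally conflicting quartet (box with equal sides) gives 1.  The
    Q-residual is mean(((s1 - s2) / scale)^2) with scale = mean off-diagonal
    distance.
    """
    n = dm.n
    if n < 4:
        raise ValueError("delta score needs at least 4 taxa")
    D = dm.percent
    scale = D[np.triu_indices(n, k=1)].mean()
    total = 0.0
    qres = 0.0
    per_taxon_sum = np.zeros(n)
    per_taxon_cnt = np.zeros(n, dtype=int)
    count = 0
    for i, j, k, l in itertools.combinations(range(n), 4):
        s = sorted(
            (D[i, j] + D[k, l], D[i, k] + D[j, l], D[i, l] + D[j, k]),
            reverse=True,
        )
        s1, s2, s3 = s
        delta = 0.0 if s1 - s3 <= 0 else (s1 - s2) / (s1 - s3)
        total += delta
        if scale > 0:
            qres += ((s1 - s2) / scale) ** 2
        for t in (i, j, k, l):
            per_taxon_sum[t] += delta
            per_taxon_cnt[t] += 1
        count += 1
    per_taxon = {
        dm.labels[t]: float(per_taxon_sum[t] / per_taxon_cnt[t])
        for t in range(n)
    }
    return TreelikenessStats(
        mean_delta=total / count,
        per_taxon_delta=per_taxon,
        q_residual=qres / count,
        n_quartets=count,
    )


# ---------------------------------------------------------------------------
# export


def write_nexus_splits(ss: SplitSystem, path: str | Path) -> None:
    """NEXUS splits block readable by standard split-network viewers."""
    taxa = ss.taxa
    index = {t: i + 1 for i, t in enumerate(taxa)}
    cycle = " ".join(str(index[t]) for t in ss.ordering)
    lines = [
        "#NEXUS",
        "",
        "BEGIN Taxa;",
        f"DIMENSIONS ntax={len(taxa)};",
        "TAXLABELS",
    ]
    lines += [f"  [{i + 1}] '{t}'" for i, t in enumerate(taxa)]
    lines += [
        ";",
        "END;",
        "",
        "BEGIN Splits;",
        f"DIMENSIONS ntax={len(taxa)} nsplits={len(ss.splits)};",
        "FORMAT labels=no weights=yes confidences=no intervals=no;",
        f"CYCLE {cycle};",
        "MATRIX",
    ]
    for s, w in zip(ss.splits, ss.weights):
        members = " ".join(str(index[t]) for t in sorted(s.side, key=index.get))
        lines.append(f"  [{float(w):.10g}] {float(w):.10g} \t {members},")
    lines += [";", "END;", ""]
    Path(path).write_text("\n".join(lines))
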