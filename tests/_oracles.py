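"""Independent reference implementations used only to check results.

These deliberately avoid the code paths they verify: identity comes
from a hand-written Gotoh dynamic program, and tree topologies from an
exhaustive least-squares search over all unrooted shapes.
"""

from __future__ import annotations

import io
import itertools

import numpy as np
from Bio.Align import substitution_matrices

_BLOSUM62 = substitution_matrices.load("BLOSUM62")


def gotoh_identity(a: str, b: str, gap_open: float = 11.0, gap_extend: float = 1.0) -> float:
    """Percent identity of one optimal global affine-gap alignment
    (BLOSUM62), computed by an explicit O(nm) dynamic program."""
    n, m = len(a), len(b)
    neg = -1e9
    # score layers and traceback: M diagonal, X gap in b (deletion), Y gap in a
    M = np.full((n + 1, m + 1), neg)
    X = np.full((n + 1, m + 1), neg)
    Y = np.full((n + 1, m + 1), neg)
    M[0, 0] = 0.0
    for i in range(1, n + 1):
        X[i, 0] = -gap_open - gap_extend * (i - 1)
    for j in range(1, m + 1):
        Y[0, j] = -gap_open - gap_extend * (j - 1)
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            s = _BLOSUM62[a[i - 1], b[j - 1]]
            M[i, j] = max(M[i - 1, j - 1], X[i - 1, j - 1], Y[i - 1, j - 1]) + s
            X[i, j] = max(M[i - 1, j] - gap_open, X[i - 1, j] - gap_extend)
            Y[i, j] = max(M[i, j - 1] - gap_open, Y[i, j - 1] - gap_extend)
    # traceback (ties: M > X > Y, matching the maxima above)
    i, j = n, m
    layer = int(np.argmax([M[i, j], X[i, j], Y[i, j]]))
    matches = columns = 0
    while i > 0 or j > 0:
        columns += 1
        if layer == 0:
            s = _BLOSUM62[a[i - 1], b[j - 1]]
            if a[i - 1] == b[j - 1]:
                matches += 1
            prev = [M[i - 1, j - 1], X[i - 1, j - 1], Y[i - 1, j - 1]]
            layer = int(np.argmax(prev))
            i, j = i - 1, j - 1
        elif layer == 1:
            if i == 1 and j == 0:
                layer = 0
            elif abs(X[i, j] - (M[i - 1, j] - gap_open)) < 1e-9:
                layer = 0
            i -= 1
        else:
            if j == 1 and i == 0:
                layer = 0
            elif abs(Y[i, j] - (M[i, j - 1] - gap_open)) < 1e-9:
                layer = 0
            j -= 1
    return 100.0 * matches / columns


# ---------------------------------------------------------------------------
# Exhaustive least-squares tree topology search
# ---------------------------------------------------------------------------


def enumerate_topologies(labels):
    """All unrooted binary topologies over labels, as edge lists.

    Leaves are label strings; internal nodes are negative ints.
    3 labels -> 1 topology, 4 -> 3, 5 -> 15.
    """
    trees = [[(-1, labels[0]), (-1, labels[1]), (-1, labels[2])]]
    next_internal = -2
    for leaf in labels[3:]:
        grown = []
        for t in trees:
            for idx in range(len(t)):
                u, v = t[idx]
                w = next_internal
                t2 = [e for k, e in enumerate(t) if k != idx]
                t2 += [(u, w), (w, v), (w, leaf)]
                grown.append(t2)
        trees = grown
        next_internal -= 1
    return trees


def _leaf_paths(edges, labels):
    """Map each unordered leaf pair to the set of edge indices on its path."""
    adj: dict = {}
    for k, (u, v) in enumerate(edges):
        adj.setdefault(u, []).append((v, k))
        adj.setdefault(v, []).append((u, k))
    paths = {}
    for a in labels:
        # BFS from a
        seen = {a: []}
        queue = [a]
        while queue:
            x = queue.pop(0)
            for y, k in adj[x]:
                if y not in seen:
                    seen[y] = seen[x] + [k]
                    queue.append(y)
        for b in labels:
            if b > a:
                paths[(a, b)] = seen[b]
    return paths


def topology_splits(edges, labels):
    """Canonical non-trivial splits: for each edge, the leaf side not
    containing labels[0], kept when both sides have >= 2 leaves."""
    adj: dict = {}
    for u, v in edges:
        adj.setdefault(u, []).append(v)
        adj.setdefault(v, []).append(u)
    splits = set()
    for u, v in edges:
        # leaves reachable from v without crossing u
        seen = {u, v}
        stack = [v]
        side = set()
        while stack:
            x = stack.pop()
            if isinstance(x, str):
                side.add(x)
            for y in adj[x]:
                if y not in seen:
                    seen.add(y)
                    stack.append(y)
        if 2 <= len(side) <= len(labels) - 2:
            if labels[0] in side:
                side = set(labels) - side
            splits.add(frozenset(side))
    return splits


def least_squares_topology(dist: np.ndarray, labels):
    """Best-fitting unrooted topology by ordinary least squares over all
    shapes; returns its canonical split set."""
    best_ssr, best_splits = None, None
    pairs = list(itertools.combinations(sorted(labels), 2))
    d = {}
    order = {lab: i for i, lab in enumerate(labels)}
    for a, b in pairs:
        d[(a, b)] = dist[order[a], order[b]]
    y = np.array([d[p] for p in pairs])
    for edges in enumerate_topologies(sorted(labels)):
        paths = _leaf_paths(edges, sorted(labels))
        A = np.zeros((len(pairs), len(edges)))
        for r, p in enumerate(pairs):
            for k in paths[p]:
                A[r, k] = 1.0
        sol, residuals, rank, _ = np.linalg.lstsq(A, y, rcond=None)
        ssr = float(np.sum((A @ sol - y) ** 2))
        if best_ssr is None or ssr < best_ssr - 1e-12:
            best_ssr, best_splits = ssr, topology_splits(edges, sorted(labels))
    return best_splits


def newick_splits(newick: str, labels):
    """Canonical split set of a Newick tree (via skbio parsing)."""
    from skbio import TreeNode

    tree = TreeNode.read(io.StringIO(newick))
    labels = sorted(labels)
    all_tips = set(labels)
    splits = set()
    for node in tree.traverse(include_self=False):
        if node.is_tip():
            continue
        side = {t.name for t in node.tips()}
        if 2 <= len(side) <= len(all_tips) - 2:
            if labels[0] in side:
                side = all_tips - side
            splits.add(frozenset(side))
    return splits


def random_additive_matrix(labels, rng):
    """A random topology with U(0.05, 0.3) branch lengths and its exact
    path-length (additive) distance matrix.  Returns (matrix, splits)."""
    labels = sorted(labels)
    topologies = enumerate_topologies(labels)
    edges = topologies[rng.integers(len(topologies))]
    lengths = rng.uniform(0.05, 0.3, size=len(edges))
    paths = _leaf_paths(edges, labels)
    n = len(labels)
    order = {lab: i for i, lab in enumerate(labels)}
    dist = np.zeros((n, n))
    for (a, b), path in paths.items():
        val = float(sum(lengths[k] for k in path))
        dist[order[a], order[b]] = dist[order[b], order[a]] = val
    return dist, topology_splits(edges, labels)
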