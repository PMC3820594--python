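"""Independent brute-force oracles used to cross-check the implementation.

Everything here is deliberately naive (per-position scans, exhaustive
enumeration, unconstrained least squares) and shares no code with the
package's own scanners and tree builder.
"""

from __future__ import annotations

import itertools

import numpy as np

S_SET = set("GASTDNPE")


def naive_motif_starts(seq: str) -> list[int]:
    """Every start of a [YC]x[GASTDNPE][QH] match, checked per position."""
    out = []
    for i in range(len(seq) - 3):
        if seq[i] in "YC" and seq[i + 2] in S_SET and seq[i + 3] in "QH":
            out.append(i)
    return out


def greedy_fingers(seq: str, cys_gaps=(2, 5), inner=12, his=3, terminal="HC"):
    """Greedy left-to-right finger matching by explicit position checks.

    ``cys_gaps`` is (min, max+1).  Returns (c1, c2, h1, h2) tuples.
    """
    fingers = []
    i = 0
    n = len(seq)
    while i < n:
        match = None
        if seq[i] == "C":
            for g in range(*cys_gaps):
                c2 = i + g + 1
                h1 = c2 + inner + 1
                h2 = h1 + his + 1
                if h2 < n and seq[c2] == "C" and seq[h1] == "H" and seq[h2] in terminal:
                    match = (i, c2, h1, h2)
                    break
        if match:
            fingers.append(match)
            i = match[3] + 1
        else:
            i += 1
    return fingers


def chain_runs(starts: list[int], lo: int, hi: int) -> list[tuple[int, ...]]:
    """Maximal chains of indices whose successive start differences lie in [lo, hi]."""
    runs = []
    i = 0
    while i < len(starts):
        j = i
        while j + 1 < len(starts) and lo <= starts[j + 1] - starts[j] <= hi:
            j += 1
        if j > i:
            runs.append(tuple(range(i, j + 1)))
        i = j + 1
    return runs


# ------------------------------------------------------------ tree oracles


def enumerate_unrooted_topologies(taxa: list[str]):
    """All unrooted binary topologies as edge lists over node labels.

    Leaves are the taxon names; internal nodes are integers.  Built by
    attaching each new taxon to every edge of every partial topology
    (3, 15, 105 ... topologies for 4, 5, 6 taxa; the initial 3-taxon star
    is unique).
    """
    assert len(taxa) >= 3
    star_center = 0
    base = [(star_center, taxa[0]), (star_center, taxa[1]), (star_center, taxa[2])]
    topologies = [(base, 1)]  # (edges, next internal node id)
    for leaf in taxa[3:]:
        new_topologies = []
        for edges, nxt in topologies:
            for k, (u, v) in enumerate(edges):
                w = nxt
                new_edges = edges[:k] + edges[k + 1 :]
                new_edges = new_edges + [(u, w), (w, v), (w, leaf)]
                new_topologies.append((new_edges, nxt + 1))
        topologies = new_topologies
    return [edges for edges, _ in topologies]


def topology_splits(edges, taxa: list[str]) -> set[frozenset[str]]:
    """Canonical nontrivial bipartitions of an edge-list topology."""
    adj: dict = {}
    for u, v in edges:
        adj.setdefault(u, []).append(v)
        adj.setdefault(v, []).append(u)
    taxa_set = frozenset(taxa)
    ref = min(taxa)
    splits = set()
    for u, v in edges:
        # leaves on v's side when edge (u,v) is cut
        stack, seen = [v], {u, v}
        side = set()
        while stack:
            x = stack.pop()
            if isinstance(x, str):
                side.add(x)
            for y in adj[x]:
                if y not in seen:
                    seen.add(y)
                    stack.append(y)
        side = frozenset(side)
        if ref in side:
            side = taxa_set - side
        if 1 < len(side) < len(taxa) - 1:
            splits.add(side)
    return splits


def least_squares_fit(edges, taxa: list[str], dm: dict[tuple[str, str], float]) -> float:
    """Residual of the unconstrained least-squares branch-length fit."""
    adj: dict = {}
    for k, (u, v) in enumerate(edges):
        adj.setdefault(u, []).append((v, k))
        adj.setdefault(v, []).append((u, k))

    def path_edges(a: str, b: str):
        stack = [(a, None, [])]
        seen = {a}
        while stack:
            node, _, path = stack.pop()
            if node == b:
                return path
            for nxt, edge_k in adj[node]:
                if nxt not in seen:
                    seen.add(nxt)
                    stack.append((nxt, node, path + [edge_k]))
        raise AssertionError("disconnected topology")

    pairs = list(itertools.combinations(taxa, 2))
    a_mat = np.zeros((len(pairs), len(edges)))
    y = np.zeros(len(pairs))
    for row, (p, q) in enumerate(pairs):
        for k in path_edges(p, q):
            a_mat[row, k] = 1.0
        y[row] = dm[(p, q)]
    sol, residuals, *_ = np.linalg.lstsq(a_mat, y, rcond=None)
    pred = a_mat @ sol
    return float(((pred - y) ** 2).sum())


def best_topology_splits(taxa: list[str], dm: dict[tuple[str, str], float]) -> set[frozenset[str]]:
    """Splits of the exhaustive least-squares-optimal topology."""
    best = None
    for edges in enumerate_unrooted_topologies(taxa):
        res = least_squares_fit(edges, taxa, dm)
        if best is None or res < best[0]:
            best = (res, edges)
    return topology_splits(best[1], taxa)


def random_additive_tree(taxa: list[str], rng: np.random.Generator):
    """A random topology with positive lengths and its additive distances."""
    topologies = enumerate_unrooted_topologies(taxa)
    edges = topologies[rng.integers(0, len(topologies))]
    lengths = {k: float(rng.uniform(0.05, 1.0)) for k in range(len(edges))}
    adj: dict = {}
    for k, (u, v) in enumerate(edges):
        adj.setdefault(u, []).append((v, k))
        adj.setdefault(v, []).append((u, k))

    def dist(a, b):
        stack = [(a, 0.0)]
        seen = {a}
        while stack:
            node, acc = stack.pop()
            if node == b:
                return acc
            for nxt, k in adj[node]:
                if nxt not in seen:
                    seen.add(nxt)
                    stack.append((nxt, acc + lengths[k]))
        raise AssertionError

    dm = {}
    for p, q in itertools.combinations(taxa, 2):
        dm[(p, q)] = dm[(q, p)] = dist(p, q)
    return edges, dm
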