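"""Phylogenetics of zinc-finger regions and duplication-history inference.

The zinc-finger regions of SP/KLF proteins are rigidly structured: twelve
zinc-binding anchors (four per finger) in fixed relative order.  That
structure drives an anchor-based alignment (anchors mapped to shared
columns, inter-anchor spans gap-padded), a p-distance (optionally
Poisson-corrected), neighbor-joining tree building with deterministic tie
breaking, and a monophyly test under explicit outgroup rooting.  NJ is used
as a deterministic, dependency-light stand-in for likelihood methods; the
scientific claims carried here are clade-recovery properties, not branch
support values.

Family expansion histories are inferred from extant members: each member's
parent is its nearest homolog by zinc-finger-region identity, and the copy
mechanism is read from gene structure and location — an intronless copy of
an intron-containing parent arose by retrotransposition (RT) of spliced
mRNA; a copy within the locality threshold of its parent on the same
chromosome arose by local gene duplication (LGD); a distal intronless copy
of an intronless parent is likewise an RT product.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np

from .errors import MalformedInputError, NotApplicableError
from .synteny import GeneFeature
from .zf_grammar import ZincFinger, extract_zf_region

logger = logging.getLogger(__name__)

__all__ = [
    "AnchoredAlignment",
    "DistanceMatrix",
    "Tree",
    "TreeNode",
    "EventMember",
    "EventCall",
    "EventHistory",
    "anchor_align",
    "p_distance",
    "nj_tree",
    "is_monophyletic",
    "classify_events",
]


# ---------------------------------------------------------------- alignment


@dataclass(frozen=True)
class AnchoredAlignment:
    """Zinc-finger regions aligned by mapping anchors to shared columns."""

    ids: tuple[str, ...]
    rows: tuple[str, ...]
    anchor_columns: tuple[int, ...]

    def __post_init__(self):
        if len(self.ids) != len(self.rows):
            raise MalformedInputError("ids and rows differ in length")
        if len({len(r) for r in self.rows}) > 1:
            raise MalformedInputError("aligned rows have unequal lengths")

    @property
    def n_columns(self) -> int:
        return len(self.rows[0]) if self.rows else 0

    def degapped(self, i: int) -> str:
        return self.rows[i].replace("-", "")


def anchor_align(
    regions: list[tuple[str, list[ZincFinger], str]]
) -> AnchoredAlignment:
    """Align zinc-finger regions by their C/H anchors.

    Each entry is (id, parsed fingers, full protein sequence).  All entries
    must have the same finger count.  The anchors of each sequence are mapped
    to shared anchor columns; each inter-anchor span is padded with gaps to
    the maximal span width, residues right-aligned against the downstream
    anchor (deletions between cysteines therefore show as gaps immediately
    after the upstream anchor).  Deterministic; degapping any row recovers
    its zinc-finger region.
    """
    if not regions:
        raise MalformedInputError("no regions to align")
    counts = {len(fingers) for _, fingers, _ in regions}
    if len(counts) != 1:
        raise MalformedInputError(f"finger-count mismatch across regions: {sorted(counts)}")
    if counts == {0}:
        raise MalformedInputError("regions have no fingers")

    ids, anchor_lists, span_lists = [], [], []
    for rid, fingers, seq in regions:
        fingers = sorted(fingers)
        region = extract_zf_region(seq, fingers)
        base = fingers[0].c1
        anchors = [p - base for f in fingers for p in (f.c1, f.c2, f.h1, f.h2)]
        spans = [region[a + 1 : b] for a, b in zip(anchors, anchors[1:])]
        ids.append(rid)
        anchor_lists.append([region[a] for a in anchors])
        span_lists.append(spans)

    n_anchors = len(anchor_lists[0])
    widths = [max(len(s[j]) for s in span_lists) for j in range(n_anchors - 1)]

    rows, anchor_cols = [], []
    for row_i, (anchors, spans) in enumerate(zip(anchor_lists, span_lists)):
        parts = []
        col = 0
        for j, a in enumerate(anchors):
            parts.append(a)
            if row_i == 0:
                anchor_cols.append(col)
            col += 1
            if j < n_anchors - 1:
                pad = widths[j] - len(spans[j])
                parts.append("-" * pad + spans[j])
                col += widths[j]
        rows.append("".join(parts))
    return AnchoredAlignment(tuple(ids), tuple(rows), tuple(anchor_cols))


# ---------------------------------------------------------------- distances


@dataclass(frozen=True)
class DistanceMatrix:
    ids: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        if v.shape != (len(self.ids), len(self.ids)):
            raise MalformedInputError("distance matrix shape does not match ids")
        if not np.allclose(v, v.T):
            raise MalformedInputError("distance matrix must be symmetric")
        if (v < 0).any():
            raise MalformedInputError("distances must be non-negative")
        if not np.allclose(np.diag(v), 0):
            raise MalformedInputError("diagonal must be zero")
        object.__setattr__(self, "values", v)

    def __getitem__(self, pair) -> float:
        a, b = pair
        return float(self.values[self.ids.index(a), self.ids.index(b)])

    def to_tsv(self, path) -> None:
        import pandas as pd

        pd.DataFrame(self.values, index=self.ids, columns=self.ids).to_csv(
            path, sep="\t", index_label="id"
        )


def p_distance(alignment: AnchoredAlignment, poisson: bool = False) -> DistanceMatrix:
    """Pairwise mismatch fraction over columns where both rows are ungapped.

    With ``poisson=True`` the Poisson correction -ln(1 - p) is applied;
    p >= 0.75 then raises (correction diverges).
    """
    n = len(alignment.ids)
    if n < 2:
        raise NotApplicableError("need at least two rows")
    rows = alignment.rows
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            shared = mismatch = 0
            for a, b in zip(rows[i], rows[j]):
                if a != "-" and b != "-":
                    shared += 1
                    mismatch += a != b
            if shared == 0:
                raise NotApplicableError(
                    f"no shared ungapped columns between {alignment.ids[i]} and {alignment.ids[j]}"
                )
            p = mismatch / shared
            if poisson:
                if p >= 0.75:
                    raise NotApplicableError(
                        f"p-distance {p:.3f} >= 0.75: Poisson correction undefined"
                    )
                p = -math.log(1.0 - p)
            d[i, j] = d[j, i] = p
    return DistanceMatrix(tuple(alignment.ids), d)


# ---------------------------------------------------------------- trees


@dataclass
class TreeNode:
    """A node of an (unrooted-as-rooted) tree; leaves carry names."""

    name: str | None = None
    children: list[tuple["TreeNode", float]] = field(default_factory=list)

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def leaf_names(self) -> list[str]:
        if self.is_leaf:
            return [self.name]
        out = []
        for child, _ in self.children:
            out.extend(child.leaf_names())
        return out


@dataclass
class Tree:
    """Unrooted tree stored rooted at an internal node; Newick-serializable."""

    root: TreeNode

    def leaf_names(self) -> list[str]:
        return self.root.leaf_names()

    def newick(self) -> str:
        def render(node: TreeNode) -> str:
            if node.is_leaf:
                return node.name
            inner = ",".join(
                f"{render(child)}:{length:.6g}" for child, length in node.children
            )
            return f"({inner})"

        return render(self.root) + ";"

    def splits(self) -> set[frozenset[str]]:
        """Leaf set on the child side of every edge (including leaf edges)."""
        out: set[frozenset[str]] = set()

        def walk(node: TreeNode):
            for child, _ in node.children:
                out.add(frozenset(child.leaf_names()))
                walk(child)

        walk(self.root)
        return out

    def nontrivial_splits(self) -> set[frozenset[str]]:
        """Canonical internal bipartitions (side not containing the first leaf)."""
        leaves = frozenset(self.leaf_names())
        ref = min(leaves)
        out = set()
        for side in self.splits():
            side = leaves - side if ref in side else side
            if 1 < len(side) < len(leaves) - 1:
                out.add(side)
        return out


def nj_tree(dm: DistanceMatrix) -> Tree:
    """Neighbor joining (Saitou-Nei) with deterministic tie breaking.

    Pair selection minimizes the Q criterion; ties are broken by the
    lexicographic pair of subtree representative ids (the smallest leaf id
    under each node).  Negative branch lengths are clamped to zero.
    """
    n = len(dm.ids)
    if n < 3:
        raise NotApplicableError("neighbor joining needs at least 3 taxa")

    nodes: dict[int, TreeNode] = {i: TreeNode(name=name) for i, name in enumerate(dm.ids)}
    reps: dict[int, str] = {i: name for i, name in enumerate(dm.ids)}
    dist: dict[tuple[int, int], float] = {}
    for i in range(n):
        for j in range(i + 1, n):
            dist[(i, j)] = float(dm.values[i, j])

    def d(i, j):
        return 0.0 if i == j else dist[(min(i, j), max(i, j))]

    active = list(range(n))
    next_id = n
    while len(active) > 3:
        m = len(active)
        r = {i: sum(d(i, k) for k in active) for i in active}
        best = None
        for ai in range(m):
            for aj in range(ai + 1, m):
                i, j = active[ai], active[aj]
                q = (m - 2) * d(i, j) - r[i] - r[j]
                tie = tuple(sorted((reps[i], reps[j])))
                key = (q, tie)
                if best is None or key < best[0]:
                    best = (key, i, j)
        _, i, j = best
        li = d(i, j) / 2 + (r[i] - r[j]) / (2 * (m - 2))
        lj = d(i, j) - li
        li, lj = max(li, 0.0), max(lj, 0.0)
        new = TreeNode(children=[(nodes[i], li), (nodes[j], lj)])
        u = next_id
        next_id += 1
        nodes[u] = new
        reps[u] = min(reps[i], reps[j])
        for k in active:
            if k in (i, j):
                continue
            dist[(min(u, k), max(u, k))] = (d(i, k) + d(j, k) - d(i, j)) / 2
        active = [k for k in active if k not in (i, j)] + [u]

    a, b, c = active
    la = max((d(a, b) + d(a, c) - d(b, c)) / 2, 0.0)
    lb = max((d(a, b) + d(b, c) - d(a, c)) / 2, 0.0)
    lc = max((d(a, c) + d(b, c) - d(a, b)) / 2, 0.0)
    root = TreeNode(children=[(nodes[a], la), (nodes[b], lb), (nodes[c], lc)])
    return Tree(root)


def is_monophyletic(tree: Tree, outgroup_id: str, taxa: set[str]) -> bool:
    """Whether ``taxa`` form a complete clade when rooted at ``outgroup_id``.

    A singleton taxon set is monophyletic by convention; the outgroup may not
    be part of the tested set.
    """
    leaves = set(tree.leaf_names())
    if outgroup_id not in leaves:
        raise MalformedInputError(f"outgroup {outgroup_id!r} is not a leaf")
    taxa = set(taxa)
    if outgroup_id in taxa:
        raise MalformedInputError("taxa set must not contain the outgroup")
    if not taxa <= leaves:
        raise MalformedInputError("taxa must be a subset of the leaves")
    if len(taxa) == 1:
        return True
    all_leaves = frozenset(leaves)
    for side in tree.splits():
        ingroup_side = side if outgroup_id not in side else all_leaves - side
        if ingroup_side == taxa:
            return True
    return False


# ---------------------------------------------------------------- events


@dataclass(frozen=True)
class EventMember:
    """One extant family member entering event-history inference."""

    id: str
    feature: GeneFeature
    intron_structure: str  # intron_containing | intronless | unknown
    zf_sequence: str


@dataclass(frozen=True)
class EventCall:
    child: str
    parent: str
    mechanism: str  # LGD | RT | distal_unknown | root
    identity: float
    distance_bp: float  # inf when on different chromosomes


@dataclass(frozen=True)
class EventHistory:
    root_id: str
    events: tuple[EventCall, ...]

    @property
    def mechanisms(self) -> tuple[str, ...]:
        return tuple(e.mechanism for e in self.events)

    def parent_of(self) -> dict[str, str]:
        return {e.child: e.parent for e in self.events}


def _identity(a: str, b: str) -> float:
    """Fraction of identical residues; NW-aligned when lengths differ."""
    if len(a) == len(b):
        if not a:
            return 0.0
        return sum(x == y for x, y in zip(a, b)) / len(a)
    from Bio import Align

    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 1.0
    aligner.mismatch_score = 0.0
    aligner.open_gap_score = -0.01
    aligner.extend_gap_score = -0.001
    return max(aligner.score(a, b), 0.0) / max(len(a), len(b))


def _distance_bp(a: GeneFeature, b: GeneFeature) -> float:
    if a.chrom != b.chrom:
        return math.inf
    return float(abs(a.start - b.start))


def classify_events(
    members: list[EventMember],
    locality_bp: int = 250_000,
    root_id: str | None = None,
) -> EventHistory:
    """Infer the LGD/RT expansion history of a gene family.

    Each non-root member's parent is its nearest homolog by zinc-finger
    identity (ties broken by chromosomal proximity, then id).  Cycles in the
    resulting parent graph (mutual nearest neighbors) are broken by
    re-attaching the lexicographically smallest cycle member to its best
    non-descendant homolog, with a warning.  Events are emitted parent-first
    (depth-first from the root, children in id order).
    """
    if len(members) < 2:
        raise NotApplicableError("need at least two members")
    by_id = {m.id: m for m in members}
    if len(by_id) != len(members):
        raise MalformedInputError("duplicate member ids")
    root = root_id if root_id is not None else members[0].id
    if root not in by_id:
        raise MalformedInputError(f"root member {root!r} not among members")

    ident: dict[tuple[str, str], float] = {}
    ids = sorted(by_id)
    for i, a in enumerate(ids):
        for b in ids[i + 1 :]:
            v = _identity(by_id[a].zf_sequence, by_id[b].zf_sequence)
            ident[(a, b)] = ident[(b, a)] = v

    def ranked_candidates(child: str, exclude: set[str]) -> list[str]:
        cands = [x for x in ids if x != child and x not in exclude]
        # Introns are lost to retrotransposition, never regained: an
        # intron-containing member cannot descend from an intronless one.
        if by_id[child].intron_structure == "intron_containing":
            filtered = [
                x for x in cands if by_id[x].intron_structure != "intronless"
            ]
            if filtered:
                cands = filtered
        return sorted(
            cands,
            key=lambda x: (
                -ident[(child, x)],
                _distance_bp(by_id[child].feature, by_id[x].feature),
                x,
            ),
        )

    parent: dict[str, str] = {}
    for m in ids:
        if m == root:
            continue
        parent[m] = ranked_candidates(m, set())[0]

    def descendants(node: str) -> set[str]:
        out = set()
        for m in parent:
            cur = m
            seen = set()
            while cur in parent and cur not in seen:
                seen.add(cur)
                cur = parent[cur]
                if cur == node:
                    out.add(m)
                    break
        return out

    def find_cycle() -> list[str] | None:
        for start in parent:
            cur, chain = start, []
            seen = set()
            while cur in parent and cur not in seen:
                seen.add(cur)
                chain.append(cur)
                cur = parent[cur]
            if cur in seen:
                k = chain.index(cur)
                return chain[k:]
        return None

    while (cycle := find_cycle()) is not None:
        m = min(cycle)
        excluded = descendants(m) | {m}
        choice = ranked_candidates(m, excluded)[0]
        logger.warning(
            "cyclic parent assignment among %s; re-attaching %s to %s", cycle, m, choice
        )
        parent[m] = choice

    def mechanism(child: EventMember, par: EventMember) -> str:
        if (
            child.intron_structure == "intronless"
            and par.intron_structure == "intron_containing"
        ):
            return "RT"
        if _distance_bp(child.feature, par.feature) <= locality_bp:
            return "LGD"
        if child.intron_structure == "intronless":
            return "RT"
        return "distal_unknown"

    children: dict[str, list[str]] = {i: [] for i in ids}
    for child, par in parent.items():
        children[par].append(child)

    events: list[EventCall] = []

    def visit(node: str):
        for child in sorted(children[node]):
            c, p = by_id[child], by_id[node]
            events.append(
                EventCall(
                    child=child,
                    parent=node,
                    mechanism=mechanism(c, p),
                    identity=ident[(child, node)],
                    distance_bp=_distance_bp(c.feature, p.feature),
                )
            )
            visit(child)

    visit(root)
    if len(events) != len(members) - 1:
        raise MalformedInputError("parent graph is not a tree rooted at the root member")
    return EventHistory(root, tuple(events))
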