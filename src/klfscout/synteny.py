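"""Synteny-anchored locus finding and cross-genome presence matrices.

A candidate locus is located not by sequence similarity but by its conserved
gene neighborhood: a set of upstream anchor genes (default B4GALT2, CCDC24,
SLC6A9) and downstream anchor genes (default DMAP1, ERI3, RNF220) that flank
the KLF17/KLF18 locus in the same order across placental mammal genomes.
The interval between the innermost found anchors is the search window handed
to the translated locus scanner.  Per-genome results are collected into a
presence/copy-number matrix with status coding | pseudogene | partial |
absent.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import pandas as pd

from .errors import MalformedInputError

logger = logging.getLogger(__name__)

__all__ = [
    "GeneFeature",
    "GeneTable",
    "SyntenyLocus",
    "GenomeLocusResult",
    "DEFAULT_UPSTREAM_ANCHORS",
    "DEFAULT_DOWNSTREAM_ANCHORS",
    "find_anchored_interval",
    "orientation_relation",
    "count_copies_in_interval",
    "combine_status",
    "build_presence_matrix",
]

DEFAULT_UPSTREAM_ANCHORS = ("B4GALT2", "CCDC24", "SLC6A9")
DEFAULT_DOWNSTREAM_ANCHORS = ("DMAP1", "ERI3", "RNF220")

STATUSES = ("coding", "pseudogene", "partial", "absent")


@dataclass(frozen=True, order=True)
class GeneFeature:
    """One annotated gene: 0-based half-open genomic interval plus strand."""

    chrom: str
    start: int
    end: int
    gene_id: str
    strand: str = "+"

    def __post_init__(self):
        if self.start >= self.end:
            raise MalformedInputError(
                f"{self.gene_id}: start must be < end ({self.start} >= {self.end})"
            )
        if self.strand not in ("+", "-"):
            raise MalformedInputError(f"{self.gene_id}: strand must be + or -")


@dataclass
class GeneTable:
    """All gene features of one genome, indexed by chromosome."""

    genome_id: str
    features: list[GeneFeature] = field(default_factory=list)

    def __post_init__(self):
        seen = set()
        for f in self.features:
            if f.gene_id in seen:
                raise MalformedInputError(
                    f"duplicate gene_id {f.gene_id!r} in genome {self.genome_id}"
                )
            seen.add(f.gene_id)
        self.features = sorted(self.features, key=lambda f: (f.chrom, f.start, f.gene_id))

    def by_chrom(self) -> dict[str, list[GeneFeature]]:
        out: dict[str, list[GeneFeature]] = {}
        for f in self.features:
            out.setdefault(f.chrom, []).append(f)
        return out

    def get(self, gene_id: str) -> GeneFeature | None:
        for f in self.features:
            if f.gene_id == gene_id:
                return f
        return None


@dataclass(frozen=True)
class SyntenyLocus:
    """The interval between the innermost upstream and downstream anchors.

    ``orientation`` is "+" when the upstream anchors precede the downstream
    anchors in genomic coordinates and "-" for the mirror-image arrangement
    (whole-locus inversion); the interval itself is always given in genomic
    coordinates (start <= end).  Anchor lists are ordered innermost-first.
    """

    genome_id: str
    chrom: str
    start: int
    end: int
    upstream_anchors_found: tuple[str, ...]
    downstream_anchors_found: tuple[str, ...]
    orientation: str = "+"

    def __post_init__(self):
        if self.start > self.end:
            raise MalformedInputError("locus interval start must be <= end")


def _try_orientation(
    ups: list[GeneFeature], downs: list[GeneFeature]
) -> tuple[int, int, list[GeneFeature], list[GeneFeature]] | None:
    """Interval for the arrangement 'all ups strictly before all downs'."""
    inner_up = max(ups, key=lambda f: f.end)
    inner_down = min(downs, key=lambda f: f.start)
    if inner_up.end > inner_down.start:
        return None
    ups_sorted = sorted(ups, key=lambda f: -f.end)  # innermost first
    downs_sorted = sorted(downs, key=lambda f: f.start)
    return inner_up.end, inner_down.start, ups_sorted, downs_sorted


def find_anchored_interval(
    table: GeneTable,
    upstream: tuple[str, ...] = DEFAULT_UPSTREAM_ANCHORS,
    downstream: tuple[str, ...] = DEFAULT_DOWNSTREAM_ANCHORS,
    max_span: int = 1_000_000,
) -> SyntenyLocus | None:
    """Locate the interval sandwiched by upstream and downstream anchors.

    One found anchor per side suffices; more raise confidence and are all
    reported.  Both the forward arrangement and its mirror image (inverted
    locus) are recognized.  Returns ``None`` when no chromosome carries both
    sides consistently, with a diagnostic logged.
    """
    if not upstream or not downstream:
        raise MalformedInputError("anchor lists must be non-empty")
    up_set, down_set = set(upstream), set(downstream)
    candidates = []
    for chrom, feats in sorted(table.by_chrom().items()):
        ups = [f for f in feats if f.gene_id in up_set]
        downs = [f for f in feats if f.gene_id in down_set]
        if not ups or not downs:
            continue
        fwd = _try_orientation(ups, downs)
        if fwd is not None:
            start, end, u, d = fwd
            orientation = "+"
        else:
            rev = _try_orientation(downs, ups)
            if rev is None:
                logger.warning(
                    "%s/%s: anchors found on both sides but inconsistently ordered",
                    table.genome_id,
                    chrom,
                )
                continue
            start, end, d, u = rev
            orientation = "-"
        if end - start > max_span:
            logger.warning(
                "%s/%s: anchored interval span %d exceeds max_span %d; rejected",
                table.genome_id,
                chrom,
                end - start,
                max_span,
            )
            continue
        candidates.append(
            SyntenyLocus(
                table.genome_id,
                chrom,
                start,
                end,
                tuple(f.gene_id for f in u),
                tuple(f.gene_id for f in d),
                orientation,
            )
        )
    if not candidates:
        logger.info("%s: no anchored interval found", table.genome_id)
        return None
    # Most anchor support wins; ties broken by chromosome name.
    return max(
        candidates,
        key=lambda l: (
            len(l.upstream_anchors_found) + len(l.downstream_anchors_found),
            l.chrom,
        ),
    )


def orientation_relation(a: GeneFeature, b: GeneFeature) -> str:
    """Relation of two ordered neighbors: tail_to_tail, head_to_head or co_oriented.

    ``a`` must precede ``b`` on the same chromosome.  Two genes transcribed
    toward each other (a on +, b on -) are tail-to-tail; transcribed away
    from each other, head-to-head; same strand, co-oriented.
    """
    if a.chrom != b.chrom:
        raise MalformedInputError("features must lie on the same chromosome")
    if a.end > b.start:
        raise MalformedInputError(
            f"features overlap or are unordered: {a.gene_id} vs {b.gene_id}"
        )
    if a.strand == "+" and b.strand == "-":
        return "tail_to_tail"
    if a.strand == "-" and b.strand == "+":
        return "head_to_head"
    return "co_oriented"


def count_copies_in_interval(locus: SyntenyLocus, candidate_hits: list[GeneFeature]) -> int:
    """Number of candidate features fully contained in the locus interval."""
    return sum(
        1
        for h in candidate_hits
        if h.chrom == locus.chrom and h.start >= locus.start and h.end <= locus.end
    )


def combine_status(copy_statuses: list[str], repeat_region_found: bool = False) -> str:
    """Genome-level status from per-copy status calls.

    Any clean coding copy makes the genome coding; otherwise any pseudogene
    copy makes it a pseudogene; otherwise a detected repeat-region similarity
    without zinc fingers (e.g. an N-masked finger region) is partial; else
    absent.
    """
    if "coding" in copy_statuses:
        return "coding"
    if "pseudogene" in copy_statuses:
        return "pseudogene"
    if repeat_region_found:
        return "partial"
    return "absent"


@dataclass(frozen=True)
class GenomeLocusResult:
    """One genome's row of the presence matrix."""

    genome_id: str
    locus_found: bool
    n_copies: int
    status: str

    def __post_init__(self):
        if self.status not in STATUSES:
            raise MalformedInputError(f"unknown status {self.status!r}")
        if self.status == "absent" and self.n_copies != 0:
            raise MalformedInputError("status absent requires n_copies == 0")
        if self.n_copies < 0:
            raise MalformedInputError("n_copies must be >= 0")


def build_presence_matrix(results: list[GenomeLocusResult]) -> pd.DataFrame:
    """Deterministic genomes x (locus_found, n_copies, status) matrix."""
    rows = [
        {
            "genome_id": r.genome_id,
            "locus_found": r.locus_found,
            "n_copies": r.n_copies,
            "status": r.status,
        }
        for r in results
    ]
    frame = pd.DataFrame(rows, columns=["genome_id", "locus_found", "n_copies", "status"])
    return frame.set_index("genome_id")
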