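"""Six-frame translated search of genomic DNA for zinc-finger signatures.

Stands in for translated alignment searches: the DNA of a candidate locus is
translated in all six frames (standard genetic code; stop codons render as
``*`` and codons containing N as ``X``) and each translation is scanned with
the spacing grammar.  Because only the four zinc-binding anchors are
constrained by the grammar, a finger whose spacer carries an in-frame stop
codon is still detected — which is precisely how premature stops inside
finger-coding regions are located for pseudogene calling.  Detected finger
fragments are assembled into a gene model: a single fragment covering all
three fingers is intronless; a finger-1 fragment and a fingers-2/3 fragment
separated by a GT...AG gap on the coding strand form an intron-containing
model (the family's conserved intron between the first finger and the last
two); anything else is left unknown.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

from Bio.Data.CodonTable import standard_dna_table

from .errors import MalformedInputError
from .records import normalize_dna_sequence
from .repeat_motif import DEFAULT_MOTIF, MotifPattern, scan_motif
from .zf_grammar import GrammarParams, ZincFinger, find_c2h2_domains

logger = logging.getLogger(__name__)

__all__ = [
    "FrameHit",
    "LocusModel",
    "translate",
    "reverse_complement",
    "six_frame_scan",
    "assemble_gene_model",
    "scan_locus_copies",
    "call_status",
    "has_repeat_similarity",
]

_CODON_TABLE = dict(standard_dna_table.forward_table)
for _stop in standard_dna_table.stop_codons:
    _CODON_TABLE[_stop] = "*"

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def translate(dna: str) -> str:
    """Translate a DNA string with the standard code.

    Stops become ``*``; codons containing N (or any non-ACGT letter) become
    ``X``; a trailing partial codon is ignored.
    """
    return "".join(
        _CODON_TABLE.get(dna[i : i + 3], "X") for i in range(0, len(dna) - 2, 3)
    )


def reverse_complement(dna: str) -> str:
    return dna.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class FrameHit:
    """A finger-coding fragment found in one reading frame.

    ``start``/``end`` are 0-based half-open genomic coordinates of the
    finger-coding DNA (first cysteine codon through last histidine codon).
    ``pep_start`` is the fragment's first residue index within the full
    frame translation; ``fingers`` are finger coordinates relative to
    ``peptide``.
    """

    chrom: str
    strand: str
    frame: int
    start: int
    end: int
    peptide: str
    fingers: tuple[ZincFinger, ...]
    pep_start: int

    def __post_init__(self):
        if (self.end - self.start) % 3 != 0:
            raise MalformedInputError("FrameHit interval length must be divisible by 3")
        if (self.end - self.start) // 3 != len(self.peptide):
            raise MalformedInputError("FrameHit peptide does not match interval length")

    @property
    def n_fingers(self) -> int:
        return len(self.fingers)


def _fragment_fingers(
    fingers: list[ZincFinger], linker: int
) -> list[list[ZincFinger]]:
    """Group consecutive fingers joined by exactly the canonical linker."""
    groups: list[list[ZincFinger]] = []
    for f in fingers:
        if groups and f.c1 - groups[-1][-1].h2 - 1 == linker:
            groups[-1].append(f)
        else:
            groups.append([f])
    return groups


def six_frame_scan(
    dna: str,
    params: GrammarParams = GrammarParams(),
    chrom: str = "",
    offset: int = 0,
) -> list[FrameHit]:
    """Scan all six reading frames for finger-coding fragments.

    Single- and multi-finger fragments are both reported; peptide coordinates
    are mapped back to genomic coordinates exactly (``offset`` shifts all
    genomic coordinates, for scanning sub-intervals of a chromosome).
    """
    dna = normalize_dna_sequence(dna)
    length = len(dna)
    hits: list[FrameHit] = []
    for strand in "+-":
        template = dna if strand == "+" else reverse_complement(dna)
        for frame in range(3):
            pep = translate(template[frame:])
            for group in _fragment_fingers(find_c2h2_domains(pep, params), params.linker_length):
                a, b = group[0].c1, group[-1].h2  # fragment span in frame peptide
                if strand == "+":
                    gstart = offset + frame + 3 * a
                    gend = offset + frame + 3 * (b + 1)
                else:
                    gstart = offset + length - (frame + 3 * (b + 1))
                    gend = offset + length - (frame + 3 * a)
                rel = tuple(
                    ZincFinger(f.c1 - a, f.c2 - a, f.h1 - a, f.h2 - a) for f in group
                )
                hits.append(
                    FrameHit(
                        chrom=chrom,
                        strand=strand,
                        frame=frame,
                        start=gstart,
                        end=gend,
                        peptide=pep[a : b + 1],
                        fingers=rel,
                        pep_start=a,
                    )
                )
    hits.sort(key=lambda h: (h.start, h.strand, h.frame))
    return hits


@dataclass(frozen=True)
class LocusModel:
    """Assembled gene model for one candidate locus."""

    chrom: str
    strand: str
    segments: tuple[FrameHit, ...]
    intron: tuple[int, int] | None
    intron_structure: str  # intron_containing | intronless | unknown
    premature_stops: tuple[int, ...]
    degraded_fingers: int = 0

    @property
    def n_fingers(self) -> int:
        return sum(s.n_fingers for s in self.segments)


def _stop_positions(hit: FrameHit) -> list[int]:
    """Genomic codon-start positions of in-frame stops inside a segment."""
    out = []
    for j, aa in enumerate(hit.peptide):
        if aa != "*":
            continue
        if hit.strand == "+":
            out.append(hit.start + 3 * j)
        else:
            out.append(hit.end - 3 * (j + 1))
    return out


def _find_intron(gap_dna: str, linker_length: int) -> tuple[int, int] | None:
    """Locate a canonical GT...AG intron inside an inter-fragment gap.

    The gap between a finger-1 fragment and a fingers-2/3 fragment carries
    the split linker codons on either side of the intron.  The intron is
    accepted when, for some split k + m = linker_length, removing k leading
    and m trailing linker codons leaves a GT...AG interval (the spliced exons
    then reconstitute the canonical linker).  A gap that is purely intron
    (no linker codons, k = m = 0) is also accepted.  Returns (k, m) codon
    counts, smallest k first, or None.
    """
    candidates = [(k, linker_length - k) for k in range(linker_length + 1)]
    candidates.append((0, 0))
    for k, m in candidates:
        lo, hi = 3 * k, len(gap_dna) - 3 * m
        if hi - lo < 4:
            continue
        inner = gap_dna[lo:hi]
        if inner.startswith("GT") and inner.endswith("AG"):
            return k, m
    return None


def _count_degraded(
    dna: str, hits: list[FrameHit], params: GrammarParams, offset: int
) -> int:
    """Look for deteriorated fingers adjacent to detected fragments.

    Only the positions where a missing neighbor finger would sit (one
    canonical linker away, same frame) are examined; a candidate with exactly
    one zinc-binding anchor replaced by a standard residue (not X, not a
    stop) counts as degraded.  This keeps the check precise: free-running
    one-mismatch scans over whole translations would hit random DNA.
    """
    degraded = 0
    length = len(dna)
    translations: dict[tuple[str, int], str] = {}

    def frame_pep(strand: str, frame: int) -> str:
        key = (strand, frame)
        if key not in translations:
            template = dna if strand == "+" else reverse_complement(dna)
            translations[key] = translate(template[frame:])
        return translations[key]

    terminal_ok = "HC" if params.allow_terminal_cys_for_his else "H"
    for hit in hits:
        pep = frame_pep(hit.strand, hit.frame)
        frag_end = hit.pep_start + len(hit.peptide)  # exclusive
        for side in ("after", "before"):
            for g in range(params.cys_gap_min, params.cys_gap_max + 1):
                span = g + params.inner_gap + params.his_gap + 4
                if side == "after":
                    s = frag_end + params.linker_length
                else:
                    s = hit.pep_start - params.linker_length - span
                if s < 0 or s + span > len(pep):
                    continue
                anchors = [
                    (pep[s], "C"),
                    (pep[s + g + 1], "C"),
                    (pep[s + g + 1 + params.inner_gap + 1], "H"),
                    (pep[s + span - 1], terminal_ok),
                ]
                misses = [(obs, exp) for obs, exp in anchors if obs not in exp]
                if len(misses) == 1 and misses[0][0] not in ("X", "*"):
                    degraded += 1
                    break
            else:
                continue
            break
    return degraded


def assemble_gene_model(
    hits: list[FrameHit],
    dna: str,
    params: GrammarParams = GrammarParams(),
    max_pair_gap: int = 20_000,
    detect_degraded: bool = True,
    offset: int = 0,
) -> LocusModel:
    """Assemble finger fragments into a gene model for one locus window.

    ``dna`` is the locus DNA the hits were scanned from (with the same
    ``offset``).  If hits lie on both strands the strand carrying the most
    fingers is kept (ties favor +).  A fragment covering all three fingers
    yields an intronless model; a finger-1 fragment paired with a
    fingers-2/3 fragment across a GT...AG gap yields an intron-containing
    model; otherwise the intron structure is unknown.
    """
    dna = normalize_dna_sequence(dna)
    if not hits:
        return LocusModel("", "+", (), None, "unknown", ())

    by_strand = {"+": [], "-": []}
    for h in hits:
        by_strand[h.strand].append(h)
    n_plus = sum(h.n_fingers for h in by_strand["+"])
    n_minus = sum(h.n_fingers for h in by_strand["-"])
    strand = "+" if n_plus >= n_minus else "-"
    chosen = sorted(by_strand[strand], key=lambda h: h.start)
    if n_plus and n_minus:
        logger.info("hits on both strands; keeping %s (fingers %d vs %d)", strand, n_plus, n_minus)

    for a, b in zip(chosen, chosen[1:]):
        if a.end > b.start:
            raise MalformedInputError(
                "conflicting overlapping hits: "
                + "; ".join(f"{h.strand}{h.frame}@[{h.start},{h.end})" for h in (a, b))
            )

    chrom = chosen[0].chrom

    def finish(segments, intron, structure):
        stops = []
        for seg in segments:
            stops.extend(_stop_positions(seg))
        degraded = 0
        if detect_degraded and sum(s.n_fingers for s in segments) < 3:
            degraded = _count_degraded(dna, list(segments), params, offset)
        return LocusModel(
            chrom, strand, tuple(segments), intron, structure, tuple(sorted(stops)), degraded
        )

    full = [h for h in chosen if h.n_fingers >= 3]
    if full:
        return finish((full[0],), None, "intronless")

    # transcript order: genomic order on +, reversed on -
    transcript = chosen if strand == "+" else list(reversed(chosen))
    singles = [h for h in transcript if h.n_fingers == 1]
    doubles = [h for h in transcript if h.n_fingers == 2]
    for a in singles:
        for b in doubles:
            pair = _try_splice_pair(a, b, dna, offset, params, max_pair_gap)
            if pair is not None:
                return finish((a, b), pair, "intron_containing")

    return finish(tuple(transcript), None, "unknown")


def _try_splice_pair(
    a: FrameHit,
    b: FrameHit,
    dna: str,
    offset: int,
    params: GrammarParams,
    max_pair_gap: int,
) -> tuple[int, int] | None:
    """Genomic intron interval if fragments a (exon 1) and b (exons 2-3) splice."""
    if a.strand != b.strand:
        return None
    strand = a.strand
    if strand == "+":
        if a.end > b.start or b.start - a.end > max_pair_gap:
            return None
        gap = dna[a.end - offset : b.start - offset]
    else:
        if b.end > a.start or a.start - b.end > max_pair_gap:
            return None
        gap = reverse_complement(dna[b.end - offset : a.start - offset])
    found = _find_intron(gap, params.linker_length)
    if found is None:
        return None
    k, m = found
    if strand == "+":
        return (a.end + 3 * k, b.start - 3 * m)
    return (b.end + 3 * m, a.start - 3 * k)


def call_status(model: LocusModel) -> str:
    """Coding / pseudogene / absent call for an assembled locus model.

    A gene call requires the full three-finger family signature: isolated
    chance C2H2 matches in six-frame translations of non-coding or
    repeat-coding DNA are not family loci.  Pseudogene: a three-finger model
    with at least one in-frame stop codon inside its finger-coding segments,
    or a deteriorated finger (a zinc-binding anchor mutated to a standard
    residue next to a detected fragment).  Coding: three fingers, clean.
    Absent: anything less.
    """
    if not model.segments or model.n_fingers == 0:
        return "absent"
    if model.degraded_fingers > 0:
        return "pseudogene"
    if model.n_fingers >= 3:
        return "pseudogene" if model.premature_stops else "coding"
    return "absent"


def scan_locus_copies(
    dna: str,
    params: GrammarParams = GrammarParams(),
    chrom: str = "",
    offset: int = 0,
    max_pair_gap: int = 20_000,
    detect_degraded: bool = True,
) -> list[LocusModel]:
    """Assemble every gene-copy model in a window that may hold tandem copies.

    Each strand's fragments are walked in transcript order: a fragment
    covering three fingers closes an intronless copy; a one-finger fragment
    followed by a two-finger fragment across a spliceable gap closes an
    intron-containing copy; remaining finger-bearing fragments are collected
    into one unknown-structure model per strand (masked or deteriorated
    loci).  Models are returned sorted by genomic start.
    """
    dna = normalize_dna_sequence(dna)
    hits = six_frame_scan(dna, params, chrom, offset)
    models: list[LocusModel] = []
    for strand in "+-":
        frags = sorted(
            (h for h in hits if h.strand == strand),
            key=lambda h: h.start,
            reverse=(strand == "-"),
        )
        used = [False] * len(frags)
        for i, f in enumerate(frags):
            if f.n_fingers >= 3 and not used[i]:
                used[i] = True
                models.append(_model_from(chrom, strand, (f,), None, "intronless", dna, params, detect_degraded))
        # Candidate spliced pairs: any finger-1 fragment with any downstream
        # fingers-2/3 fragment whose gap splices.  Chance fragments (in the
        # intron, or upstream in another frame) can also splice by accident,
        # so assignment is greedy by parsimony: a stop-free exon 1 beats a
        # stop-carrying one, then the smaller intron wins.
        candidates = []
        for i, f in enumerate(frags):
            if f.n_fingers != 1:
                continue
            for j in range(i + 1, len(frags)):
                if frags[j].n_fingers != 2:
                    continue
                intron = _try_splice_pair(f, frags[j], dna, offset, params, max_pair_gap)
                if intron is not None:
                    gap = abs(intron[1] - intron[0])
                    candidates.append((("*" in f.peptide), gap, i, j, intron))
        for has_stop, gap, i, j, intron in sorted(candidates):
            if used[i] or used[j]:
                continue
            used[i] = used[j] = True
            models.append(
                _model_from(
                    chrom, strand, (frags[i], frags[j]), intron, "intron_containing", dna, params, detect_degraded
                )
            )
        leftovers = [f for i, f in enumerate(frags) if not used[i]]
        if leftovers and sum(h.n_fingers for h in leftovers) > 0:
            models.append(
                _model_from(chrom, strand, tuple(sorted(leftovers, key=lambda h: h.start)), None, "unknown", dna, params, detect_degraded)
            )
    # A reading of the opposite strand, another frame, or intron DNA already
    # explained by a structured model occasionally matches a stray finger;
    # drop unknown models that overlap a structured model's span.
    structured = [m for m in models if m.intron_structure != "unknown"]
    spans = [
        (sm.chrom, min(s.start for s in sm.segments), max(s.end for s in sm.segments))
        for sm in structured
    ]

    def _overlaps_structured(m: LocusModel) -> bool:
        for seg in m.segments:
            for chrom_s, lo, hi in spans:
                if seg.chrom == chrom_s and seg.start < hi and seg.end > lo:
                    return True
        return False

    models = [
        m
        for m in models
        if m.intron_structure != "unknown" or not _overlaps_structured(m)
    ]
    models.sort(key=lambda m: min((s.start for s in m.segments), default=0))
    return models


def _model_from(chrom, strand, segments, intron, structure, dna, params, detect_degraded) -> LocusModel:
    stops = []
    for seg in segments:
        stops.extend(_stop_positions(seg))
    degraded = 0
    if detect_degraded and sum(s.n_fingers for s in segments) < 3:
        degraded = _count_degraded(dna, list(segments), params, 0)
    return LocusModel(chrom, strand, tuple(segments), intron, structure, tuple(sorted(stops)), degraded)


def has_repeat_similarity(
    dna: str,
    pattern: MotifPattern = DEFAULT_MOTIF,
    min_hits: int = 5,
) -> bool:
    """Whether any translation frame of ``dna`` carries a repeat-motif cluster.

    Used to flag loci whose finger-coding region is missing or masked but
    whose N-terminal repeat region is still recognizable (reported as a
    partial locus).
    """
    dna = normalize_dna_sequence(dna)
    for strand in "+-":
        template = dna if strand == "+" else reverse_complement(dna)
        for frame in range(3):
            if len(scan_motif(translate(template[frame:]), pattern)) >= min_hits:
                return True
    return False
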