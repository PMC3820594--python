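"""C2H2 zinc-finger detection by spacing grammar and SP/KLF classification.

The SP/KLF transcription-factor family carries three C2H2 zinc fingers with a
rigid residue-spacing signature: the two zinc-binding cysteines of the three
fingers are separated by 4, 4 and 2 residues respectively, the inner spacer
between the second cysteine and the first histidine is 12 residues, the two
histidines are 3 residues apart, and successive fingers are joined by
7-residue linkers (CX4CX12HX3HX7CX4CX12HX3HX7CX2CX12HX3H).  Related C2H2
proteins differ only in these spacings: EGR-type fingers show cysteine
separations (4,2,2) and the Wilms' tumor protein carries a fourth finger with
a 4-residue cysteine separation.  This module detects fingers matching a
configurable grammar, summarizes a protein's finger signature, assigns a
family label, and reports conservation of the DNA-contacting arginines and
their acidic partners.

Coordinates are 0-based residue indices; "gap" always means the number of
residues strictly between two anchors (so X4 means gap 4).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from enum import Enum

from .errors import MalformedInputError, NotApplicableError
from .records import ProteinRecord

__all__ = [
    "GrammarParams",
    "ZincFinger",
    "FamilyLabel",
    "FamilySignature",
    "ContactSite",
    "ContactSpec",
    "ContactCheck",
    "ConservationReport",
    "DEFAULT_CONTACT_SPEC",
    "find_c2h2_domains",
    "signature_of",
    "contact_report",
    "extract_zf_region",
]


@dataclass(frozen=True)
class GrammarParams:
    """Spacing grammar for C2H2 finger detection.

    Defaults encode the SP/KLF consensus: cysteine gaps 2-4 (the family shows
    4 and 2; 3 is admitted for configurability), inner spacer 12, histidine
    gap 3, inter-finger linker 7.  ``allow_terminal_cys_for_his`` accepts a
    cysteine in the final zinc-binding position (seen in the mouse
    three-finger protein mCG120027, and generally tolerated by C2H2 domains).
    """

    cys_gap_min: int = 2
    cys_gap_max: int = 4
    inner_gap: int = 12
    his_gap: int = 3
    linker_length: int = 7
    allow_terminal_cys_for_his: bool = True

    def __post_init__(self):
        if self.cys_gap_min < 0 or self.inner_gap < 0 or self.his_gap < 0:
            raise MalformedInputError("grammar gaps must be non-negative")
        if self.cys_gap_min > self.cys_gap_max:
            raise MalformedInputError("cys_gap_min must be <= cys_gap_max")
        if self.linker_length < 0:
            raise MalformedInputError("linker_length must be non-negative")

    @property
    def finger_span(self) -> int:
        """Residue span c1..h2 (inclusive) of a finger with the *maximal* cys gap."""
        return self.cys_gap_max + self.inner_gap + self.his_gap + 4

    def regex(self) -> re.Pattern:
        """Compiled finger pattern.

        The cysteine-gap quantifier is lazy, so at a given start position the
        smallest admissible gap is preferred; ``re.finditer`` then yields
        exactly the greedy left-to-right non-overlapping matching.  Anchors
        are literal C/H (X never matches an anchor); spacer positions are
        unconstrained.
        """
        terminal = "[HC]" if self.allow_terminal_cys_for_his else "H"
        return re.compile(
            f"C.{{{self.cys_gap_min},{self.cys_gap_max}}}?"
            f"C.{{{self.inner_gap}}}H.{{{self.his_gap}}}{terminal}"
        )


@dataclass(frozen=True, order=True)
class ZincFinger:
    """One detected C2H2 finger: indices of the four zinc-binding anchors."""

    c1: int
    c2: int
    h1: int
    h2: int

    def __post_init__(self):
        if not (self.c1 < self.c2 < self.h1 < self.h2):
            raise MalformedInputError(f"anchor order violated: {self}")

    @property
    def cys_gap(self) -> int:
        return self.c2 - self.c1 - 1

    @property
    def inner_gap(self) -> int:
        return self.h1 - self.c2 - 1

    @property
    def his_gap(self) -> int:
        return self.h2 - self.h1 - 1

    @property
    def span(self) -> int:
        """Residue count c1..h2 inclusive."""
        return self.h2 - self.c1 + 1


class FamilyLabel(str, Enum):
    SPKLF_STRICT = "SPKLF_STRICT"
    SPKLF_RELAXED = "SPKLF_RELAXED"
    EGR_LIKE = "EGR_LIKE"
    WT1_LIKE = "WT1_LIKE"
    OTHER_C2H2 = "OTHER_C2H2"
    NO_C2H2 = "NO_C2H2"


@dataclass(frozen=True)
class FamilySignature:
    """Per-protein finger summary driving family classification."""

    finger_count: int
    cys_gaps: tuple[int, ...]
    linker_lengths: tuple[int, ...]
    label: FamilyLabel

    def __post_init__(self):
        if len(self.cys_gaps) != self.finger_count:
            raise MalformedInputError("cys_gaps length must equal finger_count")
        expected_linkers = max(self.finger_count - 1, 0)
        if len(self.linker_lengths) != expected_linkers:
            raise MalformedInputError("linker_lengths length must be finger_count - 1")


@dataclass(frozen=True)
class ContactSite:
    """One expected DNA-contact residue: finger index + offset in the inner spacer."""

    finger: int  # 0-based index into the (three) fingers
    offset: int  # 0-based offset within the 12-residue inner spacer


@dataclass(frozen=True)
class ContactSpec:
    """Expected positions of the three invariant arginines and their acidic partners.

    Offsets are measured within the inner spacer (the residues strictly
    between the second cysteine and the first histidine), so the residue
    checked is ``sequence[finger.c2 + 1 + offset]``.  The defaults follow the
    KLF recognition-helix architecture: the base-reading arginines sit at
    spacer offsets 5 and 11 of finger 2 and offset 5 of finger 3 (two in the
    second finger, one in the third), and the aspartate/glutamate residues
    that orient their guanidinium groups at offsets 7 and 8 of finger 2 and 7
    of finger 3.  These are configuration, not fixed constants.
    """

    arginine_sites: tuple[ContactSite, ...] = (
        ContactSite(1, 5),
        ContactSite(1, 11),
        ContactSite(2, 5),
    )
    acidic_sites: tuple[ContactSite, ...] = (
        ContactSite(1, 7),
        ContactSite(1, 8),
        ContactSite(2, 7),
    )

    def validate(self, params: GrammarParams) -> None:
        for site in self.arginine_sites + self.acidic_sites:
            if not (0 <= site.offset < params.inner_gap):
                raise MalformedInputError(
                    f"contact offset {site.offset} outside inner spacer [0,{params.inner_gap})"
                )


DEFAULT_CONTACT_SPEC = ContactSpec()


@dataclass(frozen=True)
class ContactCheck:
    """Outcome for one expected contact residue."""

    finger: int
    offset: int
    expected_class: str  # "R" or "DE"
    observed: str
    passed: bool


@dataclass(frozen=True)
class ConservationReport:
    """Conservation of DNA-contact residues across the three fingers."""

    protein_id: str
    checks: tuple[ContactCheck, ...]

    @property
    def n_checked(self) -> int:
        return len(self.checks)

    @property
    def n_pass(self) -> int:
        return sum(c.passed for c in self.checks)

    @property
    def pass_fraction(self) -> float:
        return self.n_pass / self.n_checked if self.checks else 0.0


def _sequence_of(protein) -> str:
    return protein.sequence if isinstance(protein, ProteinRecord) else str(protein)


def find_c2h2_domains(
    protein: ProteinRecord | str, params: GrammarParams = GrammarParams()
) -> list[ZincFinger]:
    """Detect all non-overlapping C2H2 fingers, greedy left-to-right.

    Within one start position the smallest cysteine gap in range is
    preferred; a matched finger consumes its residues.  Returns fingers
    sorted by first cysteine; an empty list when nothing matches.
    """
    seq = _sequence_of(protein)
    fingers = []
    for m in params.regex().finditer(seq):
        c1 = m.start()
        h2 = m.end() - 1
        cys_gap = (m.end() - m.start()) - params.inner_gap - params.his_gap - 4
        c2 = c1 + cys_gap + 1
        h1 = c2 + params.inner_gap + 1
        fingers.append(ZincFinger(c1, c2, h1, h2))
    return fingers


def _check_sorted_nonoverlapping(fingers: list[ZincFinger]) -> None:
    for prev, cur in zip(fingers, fingers[1:]):
        if cur.c1 <= prev.h2:
            raise MalformedInputError(
                f"overlapping fingers: [{prev.c1},{prev.h2}] and [{cur.c1},{cur.h2}]"
            )


def signature_of(
    fingers: list[ZincFinger],
    protein_length: int,
    params: GrammarParams = GrammarParams(),
) -> FamilySignature:
    """Summarize fingers into a family signature and assign a label.

    Canonical values (inner spacer, histidine gap, linker length) are taken
    from ``params``; labels follow the spacing taxonomy: SP/KLF strict is
    three fingers with cysteine gaps (4,4,2); SP/KLF relaxed admits other
    gaps from {2,4} (e.g. the rat-type (2,2,2) produced by two-residue
    deletions); EGR-like is (4,2,2); WT1-like is four fingers, the first
    three (4,4,2) and the fourth with gap 4.
    """
    fingers = sorted(fingers)
    _check_sorted_nonoverlapping(fingers)
    n = len(fingers)
    cys_gaps = tuple(f.cys_gap for f in fingers)
    linkers = tuple(b.c1 - a.h2 - 1 for a, b in zip(fingers, fingers[1:]))

    canonical_frame = all(
        f.inner_gap == params.inner_gap and f.his_gap == params.his_gap for f in fingers
    )
    canonical_linkers = all(l == params.linker_length for l in linkers)

    if n == 0:
        label = FamilyLabel.NO_C2H2
    elif n == 3 and canonical_frame and canonical_linkers and cys_gaps == (4, 4, 2):
        label = FamilyLabel.SPKLF_STRICT
    elif n == 3 and cys_gaps == (4, 2, 2):
        # Checked before the relaxed SP/KLF rule: (4,2,2) is the EGR spacing
        # even though its gaps also lie in {2,4}.
        label = FamilyLabel.EGR_LIKE
    elif (
        n == 3
        and canonical_frame
        and canonical_linkers
        and all(g in (2, 4) for g in cys_gaps)
    ):
        label = FamilyLabel.SPKLF_RELAXED
    elif n == 4 and cys_gaps[:3] == (4, 4, 2) and cys_gaps[3] == 4:
        label = FamilyLabel.WT1_LIKE
    else:
        label = FamilyLabel.OTHER_C2H2

    return FamilySignature(n, cys_gaps, linkers, label)


def contact_report(
    protein: ProteinRecord | str,
    fingers: list[ZincFinger],
    spec: ContactSpec = DEFAULT_CONTACT_SPEC,
    params: GrammarParams = GrammarParams(),
) -> ConservationReport:
    """Check the DNA-contact residues of a three-finger protein.

    For every site in ``spec`` the residue at ``finger.c2 + 1 + offset`` is
    read and flagged against its expected class (arginine, or aspartate/
    glutamate).
    """
    if len(fingers) != 3:
        raise NotApplicableError(
            f"contact report requires exactly 3 fingers, got {len(fingers)}"
        )
    spec.validate(params)
    seq = _sequence_of(protein)
    fingers = sorted(fingers)
    checks = []
    for site, expected in [(s, "R") for s in spec.arginine_sites] + [
        (s, "DE") for s in spec.acidic_sites
    ]:
        pos = fingers[site.finger].c2 + 1 + site.offset
        observed = seq[pos]
        checks.append(
            ContactCheck(site.finger, site.offset, expected, observed, observed in expected)
        )
    pid = protein.id if isinstance(protein, ProteinRecord) else ""
    return ConservationReport(pid, tuple(checks))


def extract_zf_region(protein: ProteinRecord | str, fingers: list[ZincFinger]) -> str:
    """Substring from the first finger's c1 to the last finger's h2, inclusive."""
    if not fingers:
        raise NotApplicableError("no fingers: zinc-finger region undefined")
    fingers = sorted(fingers)
    seq = _sequence_of(protein)
    return seq[fingers[0].c1 : fingers[-1].h2 + 1]
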