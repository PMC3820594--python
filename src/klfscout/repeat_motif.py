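"""N-terminal repeat-motif analytics.

KLF18-type proteins carry, upstream of their zinc fingers, tandem repeats of
a four-residue motif [YC]x[GASTDNPE][QH]: tyrosine (occasionally cysteine),
any residue, a small residue or glutamate/aspartate-like small set, then
glutamine or histidine.  This module scans proteins for the motif, computes
motif density (matches per residue of protein length), extracts the
14-residue windows around each match (5 flanking residues on each side),
builds the position-frequency matrix behind a sequence logo, detects tandem
runs with ~14-residue periodicity, and ranks a proteome by motif density.
The fraction of matches starting with Y separates the Y-rich KLF18-type
repeat from the cysteine-started matches typical of keratins.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import MalformedInputError
from .records import AA20, ProteinRecord

__all__ = [
    "MotifPattern",
    "MotifHit",
    "RepeatRun",
    "PositionFrequencyMatrix",
    "RepeatProfile",
    "DEFAULT_MOTIF",
    "scan_motif",
    "motif_density",
    "extend_segments",
    "build_pfm",
    "find_tandem_runs",
    "repeat_profile",
    "rank_proteome",
]

_BRACKET = re.compile(r"\[([A-Z]+)\]|([A-Zx.])")


@dataclass(frozen=True)
class MotifPattern:
    """Per-position allowed residue sets; ``None`` means any residue."""

    positions: tuple[frozenset[str] | None, ...]

    def __post_init__(self):
        if not self.positions:
            raise MalformedInputError("motif pattern is empty")
        for p in self.positions:
            if p is not None and not p:
                raise MalformedInputError("motif position set is empty")

    def __len__(self) -> int:
        return len(self.positions)

    def matches(self, fragment: str) -> bool:
        if len(fragment) != len(self.positions):
            return False
        return all(p is None or c in p for p, c in zip(self.positions, fragment))

    @classmethod
    def from_string(cls, text: str) -> "MotifPattern":
        """Parse a bracket expression such as ``[YC]x[GASTDNPE][QH]``.

        ``x`` or ``.`` denotes any residue; a bare letter denotes itself.
        """
        positions: list[frozenset | None] = []
        pos = 0
        for m in _BRACKET.finditer(text):
            if m.start() != pos:
                raise MalformedInputError(f"cannot parse motif pattern at {pos!r}: {text}")
            if m.group(1) is not None:
                positions.append(frozenset(m.group(1)))
            elif m.group(2) in ("x", "."):
                positions.append(None)
            else:
                positions.append(frozenset(m.group(2)))
            pos = m.end()
        if pos != len(text):
            raise MalformedInputError(f"cannot parse motif pattern: {text}")
        return cls(tuple(positions))

    def to_string(self) -> str:
        parts = []
        for p in self.positions:
            if p is None:
                parts.append("x")
            elif len(p) == 1:
                parts.append(next(iter(p)))
            else:
                parts.append("[" + "".join(sorted(p)) + "]")
        return "".join(parts)


#: The KLF18-type N-terminal repeat motif.
DEFAULT_MOTIF = MotifPattern.from_string("[YC]x[GASTDNPE][QH]")


@dataclass(frozen=True)
class MotifHit:
    protein_id: str
    start: int
    matched_text: str


@dataclass(frozen=True)
class RepeatRun:
    """A maximal chain of hits with near-14-residue periodicity."""

    hit_indices: tuple[int, ...]
    periods: tuple[int, ...]

    def __post_init__(self):
        if len(self.hit_indices) < 2:
            raise MalformedInputError("a repeat run needs at least two hits")

    def __len__(self) -> int:
        return len(self.hit_indices)


def scan_motif(
    protein: ProteinRecord | str, pattern: MotifPattern = DEFAULT_MOTIF
) -> list[MotifHit]:
    """All motif match positions, ascending.

    Every start position is tested (for the default pattern, overlapping
    matches are impossible anyway: the position-1 and position-3/4 residue
    sets are disjoint, so any two matches are at least 4 residues apart).
    """
    seq = protein.sequence if isinstance(protein, ProteinRecord) else str(protein)
    pid = protein.id if isinstance(protein, ProteinRecord) else ""
    k = len(pattern)
    return [
        MotifHit(pid, i, seq[i : i + k])
        for i in range(len(seq) - k + 1)
        if pattern.matches(seq[i : i + k])
    ]


def motif_density(hits: list[MotifHit], protein_length: int) -> float:
    """Number of motif matches divided by protein length."""
    if protein_length <= 0:
        raise MalformedInputError("protein_length must be positive")
    return len(hits) / protein_length


def extend_segments(
    hits: list[MotifHit], protein: ProteinRecord | str, flank: int = 5
) -> list[str]:
    """Extend each hit by ``flank`` residues on both sides.

    Hits without a full flank on either side are dropped (not padded), so
    every returned segment has the same length (14 for the default motif and
    flank 5).
    """
    if flank < 0:
        raise MalformedInputError("flank must be non-negative")
    seq = protein.sequence if isinstance(protein, ProteinRecord) else str(protein)
    segments = []
    for hit in hits:
        lo = hit.start - flank
        hi = hit.start + len(hit.matched_text) + flank
        if lo >= 0 and hi <= len(seq):
            segments.append(seq[lo:hi])
    return segments


@dataclass(frozen=True)
class PositionFrequencyMatrix:
    """Residue counts per column over equal-length segments, plus logo numbers.

    ``counts`` is a (length x 20) DataFrame indexed by 1-based position.
    Unknown residues (X) are excluded from counts, so a column sum equals the
    number of counted (non-X) residues in that column.  ``information`` is
    the per-column information content in bits: log2(20) minus the Shannon
    entropy of the column's relative frequencies.
    """

    counts: pd.DataFrame
    n_segments: int

    @property
    def frequencies(self) -> pd.DataFrame:
        totals = self.counts.sum(axis=1)
        return self.counts.div(totals.replace(0, np.nan), axis=0).fillna(0.0)

    @property
    def information(self) -> pd.Series:
        freqs = self.frequencies.to_numpy()
        logs = np.zeros_like(freqs)
        np.log2(freqs, out=logs, where=freqs > 0)
        entropy = -(freqs * logs).sum(axis=1)
        return pd.Series(math.log2(20) - entropy, index=self.counts.index, name="bits")

    def to_tsv(self, path) -> None:
        out = self.counts.copy()
        out["information_bits"] = self.information
        out.to_csv(path, sep="\t", index_label="position")


def build_pfm(segments: list[str]) -> PositionFrequencyMatrix:
    """Count residues per column over equal-length segments (X excluded)."""
    if not segments:
        raise MalformedInputError("no segments to build a PFM from")
    length = len(segments[0])
    if any(len(s) != length for s in segments):
        raise MalformedInputError("segments have mixed lengths")
    counts = np.zeros((length, 20), dtype=int)
    col = {aa: j for j, aa in enumerate(AA20)}
    for seg in segments:
        for i, c in enumerate(seg):
            if c in col:
                counts[i, col[c]] += 1
    frame = pd.DataFrame(counts, index=range(1, length + 1), columns=list(AA20))
    return PositionFrequencyMatrix(frame, len(segments))


def find_tandem_runs(
    hits: list[MotifHit], period_target: int = 14, tolerance: int = 4
) -> list[RepeatRun]:
    """Maximal chains of hits whose successive start differences are ~period_target.

    A chain extends while the next start difference lies within
    [period_target - tolerance, period_target + tolerance].
    """
    lo, hi = period_target - tolerance, period_target + tolerance
    runs: list[RepeatRun] = []
    i = 0
    while i < len(hits):
        j = i
        while j + 1 < len(hits) and lo <= hits[j + 1].start - hits[j].start <= hi:
            j += 1
        if j > i:
            runs.append(
                RepeatRun(
                    tuple(range(i, j + 1)),
                    tuple(hits[k + 1].start - hits[k].start for k in range(i, j)),
                )
            )
        i = j + 1
    return runs


def _y_fraction(hits: list[MotifHit]) -> float:
    if not hits:
        return 0.0
    return sum(h.matched_text[0] == "Y" for h in hits) / len(hits)


@dataclass(frozen=True)
class RepeatProfile:
    """Full repeat-motif summary for one protein."""

    protein_id: str
    n_hits: int
    density: float
    y_fraction: float
    segments: tuple[str, ...]
    pfm: PositionFrequencyMatrix | None
    runs: tuple[RepeatRun, ...]


def repeat_profile(
    protein: ProteinRecord,
    pattern: MotifPattern = DEFAULT_MOTIF,
    flank: int = 5,
    period_target: int = 14,
    tolerance: int = 4,
) -> RepeatProfile:
    """Scan one protein and derive all repeat analytics in one pass."""
    hits = scan_motif(protein, pattern)
    segments = extend_segments(hits, protein, flank)
    return RepeatProfile(
        protein_id=protein.id,
        n_hits=len(hits),
        density=motif_density(hits, len(protein)),
        y_fraction=_y_fraction(hits),
        segments=tuple(segments),
        pfm=build_pfm(segments) if segments else None,
        runs=tuple(find_tandem_runs(hits, period_target, tolerance)),
    )


def rank_proteome(
    proteins: list[ProteinRecord], pattern: MotifPattern = DEFAULT_MOTIF
) -> pd.DataFrame:
    """Rank a proteome by motif density (descending; ties broken by id)."""
    if not proteins:
        raise MalformedInputError("proteome is empty")
    rows = []
    for p in proteins:
        hits = scan_motif(p, pattern)
        rows.append(
            {
                "id": p.id,
                "length": len(p),
                "n_hits": len(hits),
                "density": motif_density(hits, len(p)),
                "y_fraction": _y_fraction(hits),
            }
        )
    frame = pd.DataFrame(rows)
    frame = frame.sort_values(
        ["density", "id"], ascending=[False, True], kind="mergesort"
    ).reset_index(drop=True)
    return frame
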