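"""Named sequence records used throughout the pipeline.

Protein sequences are normalized to upper case over the 20 standard amino
acids; any other letter becomes ``X`` (unknown).  Genomic sequences are
upper-case over ``ACGTN``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .errors import MalformedInputError

#: The 20 standard amino-acid one-letter codes.
AA20 = "ACDEFGHIKLMNPQRSTVWY"
AA20_SET = frozenset(AA20)

#: DNA alphabet accepted by the genomic scanners.
DNA_ALPHABET = frozenset("ACGTN")

_AA_VALID = AA20_SET | {"X"}


def normalize_protein_sequence(sequence: str) -> str:
    """Upper-case a protein sequence and map non-standard letters to X.

    Whitespace is removed; an empty result raises ``MalformedInputError``.
    """
    seq = "".join(sequence.split()).upper()
    if not seq:
        raise MalformedInputError("protein sequence is empty")
    return "".join(c if c in _AA_VALID else "X" for c in seq)


def normalize_dna_sequence(sequence: str) -> str:
    """Upper-case a DNA sequence; letters outside ACGT become N."""
    seq = "".join(sequence.split()).upper()
    if not seq:
        raise MalformedInputError("DNA sequence is empty")
    return "".join(c if c in DNA_ALPHABET else "N" for c in seq)


@dataclass(frozen=True)
class ProteinRecord:
    """A named amino-acid sequence with a provenance label.

    The sequence is normalized on construction: upper case, no whitespace,
    unknown letters mapped to ``X``.
    """

    id: str
    sequence: str
    source_tag: str = ""

    def __post_init__(self):
        object.__setattr__(self, "sequence", normalize_protein_sequence(self.sequence))

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class GenomeRecord:
    """A genome: named chromosome/scaffold sequences plus a provenance label."""

    id: str
    chromosomes: dict[str, str] = field(default_factory=dict)
    source_tag: str = ""

    def __post_init__(self):
        object.__setattr__(
            self,
            "chromosomes",
            {name: normalize_dna_sequence(seq) for name, seq in self.chromosomes.items()},
        )

    def __len__(self) -> int:
        return sum(len(s) for s in self.chromosomes.values())
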