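"""Synthetic genomes, proteomes and gene tables with planted truth.

The generator emulates the study conditions of a placental-mammal KLF18
survey: genomes carrying a three-finger SP/KLF-signature gene whose single
coding intron splits finger 1 from fingers 2-3, tandem duplicates,
intronless retrocopies on other chromosomes, stop-codon pseudogenes,
conserved flanking anchor genes, N-terminal regions with 10-50 copies of the
[YC]x[GASTDNPE][QH] repeat motif, and decoy C2H2 proteins with EGR-like and
WT1-like spacings.  Every planted element is recorded with exact coordinates
so each pipeline stage can be scored against truth.

Determinism: every operation takes a seed (or numpy Generator) and is fully
reproducible.  Filler choices are deliberately conservative so that planted
features are the only detectable ones at mutation rate zero: protein filler
near fingers excludes C/H (no accidental grammar anchors) and Y/C in repeat
flanks (no accidental motif starts); DNA filler is resampled in the rare
case a random stretch happens to translate into a spurious finger.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from Bio.Data.CodonTable import standard_dna_table

from .errors import MalformedInputError
from .records import AA20, GenomeRecord, ProteinRecord
from .synteny import (
    DEFAULT_DOWNSTREAM_ANCHORS,
    DEFAULT_UPSTREAM_ANCHORS,
    GeneFeature,
    GeneTable,
)
from .zf_grammar import (
    DEFAULT_CONTACT_SPEC,
    ContactSpec,
    GrammarParams,
    ZincFinger,
    find_c2h2_domains,
)

__all__ = [
    "CopyPlan",
    "FamilySpec",
    "PlantedLocus",
    "TruthSet",
    "make_zf_protein",
    "make_repeat_decoy",
    "make_decoy_protein",
    "make_background_protein",
    "make_locus",
    "make_genome",
    "make_panel",
    "murine_spec",
    "mutate",
    "mutate_protein",
    "anchor_positions",
    "random_dna",
    "simulate_klf_family",
    "simulate_murine_members",
]

#: Repeat-flank filler: no C or Y, so planted motifs are the only matches.
BACKGROUND_NTERM = "".join(sorted(set(AA20) - set("CY")))
#: Finger-region filler: additionally no H (anchors) and no Q (motif ends).
BACKGROUND_FINGER = "".join(sorted(set(AA20) - set("CHYQ")))
#: Small-residue set of the motif's third position.
S_SET = "GASTDNPE"

_CODONS_FOR: dict[str, list[str]] = {}
for _codon, _aa in standard_dna_table.forward_table.items():
    _CODONS_FOR.setdefault(_aa, []).append(_codon)
for _aa in _CODONS_FOR:
    _CODONS_FOR[_aa].sort()

_DNA = "ACGT"


def _rng(seed) -> np.random.Generator:
    return seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)


def _choice_str(rng: np.random.Generator, alphabet: str, n: int) -> str:
    return "".join(alphabet[i] for i in rng.integers(0, len(alphabet), size=n))


def random_dna(rng, n: int, clean: bool = True, params: GrammarParams = GrammarParams()) -> str:
    """Random uniform ACGT filler.

    With ``clean=True`` the stretch is resampled (up to 50 times) if any of
    its six translation frames happens to contain a grammar-matching finger,
    so filler never fakes a planted feature.
    """
    from .locus_scan import six_frame_scan  # local import: avoid cycle

    rng = _rng(rng)
    for _ in range(50):
        dna = _choice_str(rng, _DNA, n)
        if not clean or n < 60 or not six_frame_scan(dna, params):
            return dna
    raise MalformedInputError("could not generate clean filler DNA")


# ---------------------------------------------------------------- proteins


def _repeat_region(rng: np.random.Generator, n_repeats: int, y_prob: float, q_prob: float) -> str:
    """``n_repeats`` 14-residue units: 5 flank + [YC]x[s]Q/H + 5 flank.

    The three positions immediately before the motif favor Q, T, L, matching
    the observed flank preferences of the repeat.
    """
    units = []
    for _ in range(n_repeats):
        flank5 = list(_choice_str(rng, BACKGROUND_NTERM, 5))
        for k, fav in zip((2, 3, 4), "QTL"):
            if rng.random() < 0.8:
                flank5[k] = fav
        first = "Y" if rng.random() < y_prob else "C"
        x = BACKGROUND_NTERM[rng.integers(0, len(BACKGROUND_NTERM))]
        s = S_SET[rng.integers(0, len(S_SET))]
        last = "Q" if rng.random() < q_prob else "H"
        after = _choice_str(rng, BACKGROUND_NTERM, 5)
        units.append("".join(flank5) + first + x + s + last + after)
    return "".join(units)


def _finger_region(
    rng: np.random.Generator,
    cys_gaps: tuple[int, ...],
    params: GrammarParams,
    contacts: ContactSpec | None,
    terminal_his: bool,
) -> str:
    """Finger region matching the spacing spec, contact residues planted."""
    arg_sites = {(s.finger, s.offset) for s in contacts.arginine_sites} if contacts else set()
    acid_sites = (
        {(s.finger, s.offset): aa for s, aa in zip(contacts.acidic_sites, "DED")}
        if contacts
        else {}
    )
    parts = []
    for i, gap in enumerate(cys_gaps):
        inner = list(_choice_str(rng, BACKGROUND_FINGER, params.inner_gap))
        for off in range(params.inner_gap):
            if (i, off) in arg_sites:
                inner[off] = "R"
            elif (i, off) in acid_sites:
                inner[off] = acid_sites[(i, off)]
        last = "H"
        if i == len(cys_gaps) - 1 and not terminal_his:
            last = "C"
        parts.append(
            "C"
            + _choice_str(rng, BACKGROUND_FINGER, gap)
            + "C"
            + "".join(inner)
            + "H"
            + _choice_str(rng, BACKGROUND_FINGER, params.his_gap)
            + last
        )
        if i < len(cys_gaps) - 1:
            parts.append(_choice_str(rng, BACKGROUND_FINGER, params.linker_length))
    return "".join(parts)


def make_zf_protein(
    protein_id: str,
    n_repeats: int,
    seed,
    cys_gaps: tuple[int, ...] = (4, 4, 2),
    terminal_his: bool = True,
    y_prob: float = 0.9,
    q_prob: float = 0.9,
    params: GrammarParams = GrammarParams(),
    contacts: ContactSpec | None = DEFAULT_CONTACT_SPEC,
    source_tag: str = "synthetic",
) -> ProteinRecord:
    """A synthetic KLF-like protein: repeat region, then spacing-spec fingers.

    The N-terminal region carries exactly ``n_repeats`` motif matches (the
    filler alphabets guarantee no accidental ones); the finger region matches
    ``cys_gaps`` with canonical inner/histidine gaps and linkers, contact
    arginines and acidic partners planted per ``contacts``.
    """
    if n_repeats < 0:
        raise MalformedInputError("n_repeats must be >= 0")
    if not cys_gaps:
        raise MalformedInputError("need at least one finger")
    for g in cys_gaps:
        if not (params.cys_gap_min <= g <= params.cys_gap_max):
            raise MalformedInputError(f"cys gap {g} outside grammar range")
    rng = _rng(seed)
    nterm = _repeat_region(rng, n_repeats, y_prob, q_prob)
    spacer = _choice_str(rng, BACKGROUND_FINGER, 10)
    fingers = _finger_region(rng, tuple(cys_gaps), params, contacts, terminal_his)
    tail = _choice_str(rng, BACKGROUND_FINGER, 8)
    return ProteinRecord(protein_id, nterm + spacer + fingers + tail, source_tag)


def make_repeat_decoy(protein_id: str, n_repeats: int, seed, first_residue: str = "C") -> ProteinRecord:
    """A keratin-like decoy: repeat-dense but with C (not Y) starting each motif."""
    rng = _rng(seed)
    y_prob = 1.0 if first_residue == "Y" else 0.0
    seq = _repeat_region(rng, n_repeats, y_prob, 0.9) + _choice_str(rng, BACKGROUND_NTERM, 20)
    return ProteinRecord(protein_id, seq, "synthetic")


def make_decoy_protein(kind: str, protein_id: str, seed) -> ProteinRecord:
    """An EGR-like ((4,2,2) spacing) or WT1-like (four-finger) decoy."""
    gaps = {"EGR": (4, 2, 2), "WT1": (4, 4, 2, 4)}.get(kind)
    if gaps is None:
        raise MalformedInputError(f"unknown decoy kind {kind!r}")
    rng = _rng(seed)
    nterm = _choice_str(rng, BACKGROUND_NTERM, 40)
    fingers = _finger_region(rng, gaps, GrammarParams(), None, True)
    return ProteinRecord(protein_id, nterm + fingers + _choice_str(rng, BACKGROUND_FINGER, 8), "synthetic")


def make_background_protein(protein_id: str, length: int, seed) -> ProteinRecord:
    """A motif-free, finger-free filler protein."""
    return ProteinRecord(protein_id, _choice_str(_rng(seed), BACKGROUND_NTERM, length), "synthetic")


# ---------------------------------------------------------------- mutation


def mutate(seq: str, rate: float, seed, alphabet: str | None = None, protected=()) -> str:
    """Per-site substitution at the given rate (deterministic per seed).

    Each unprotected site mutates independently with probability ``rate`` to
    a different letter drawn uniformly from ``alphabet`` (default: DNA for
    ACGTN sequences, otherwise the 20 amino acids).
    """
    if not (0 <= rate < 1):
        raise MalformedInputError("rate must be in [0,1)")
    rng = _rng(seed)
    if alphabet is None:
        alphabet = _DNA if set(seq) <= set("ACGTN") else AA20
    protected = set(protected)
    out = list(seq)
    draws = rng.random(len(seq))
    for i, (c, u) in enumerate(zip(seq, draws)):
        if u < rate and i not in protected:
            choices = [a for a in alphabet if a != c]
            out[i] = choices[rng.integers(0, len(choices))]
    return "".join(out)


def anchor_positions(seq: str, params: GrammarParams = GrammarParams()) -> set[int]:
    """Zinc-binding anchor indices of every detected finger in ``seq``."""
    return {
        p for f in find_c2h2_domains(seq, params) for p in (f.c1, f.c2, f.h1, f.h2)
    }


def mutate_protein(seq: str, rate: float, seed, params: GrammarParams = GrammarParams()) -> str:
    """Substitution model for family simulations.

    Zinc-binding anchors are protected and substitution targets exclude
    C/H/Y/Q — purifying selection against spurious anchors or motif starts,
    so the planted grammar/motif structure stays parseable while all other
    positions drift.
    """
    return mutate(seq, rate, seed, alphabet=BACKGROUND_FINGER, protected=anchor_positions(seq, params))


# ---------------------------------------------------------------- loci


@dataclass(frozen=True)
class PlantedLocus:
    """Truth record for one planted gene copy (absolute genomic coordinates)."""

    copy_id: str
    gene: GeneFeature
    status: str  # coding | pseudogene | masked
    intron_structure: str  # intron_containing | intronless
    n_repeats: int
    parent_id: str | None
    mechanism: str | None  # LGD | RT | None for the root
    stop_positions: tuple[int, ...]
    zf_interval: tuple[int, int]  # genomic interval of finger-coding DNA incl. intron
    protein: ProteinRecord


@dataclass(frozen=True)
class TruthSet:
    genome_id: str
    loci: tuple[PlantedLocus, ...]
    expected_status: str  # genome-level presence status
    expected_copies_in_locus: int


@dataclass(frozen=True)
class _LocusBuild:
    dna: str
    cds_interval: tuple[int, int]
    intron: tuple[int, int] | None
    stop_positions: tuple[int, ...]
    zf_interval: tuple[int, int]


def make_locus(
    protein: ProteinRecord,
    intron_plan: str = "none",
    pseudogenize: int | None = None,
    seed=0,
    flank_bp: int = 200,
    intron_len: int = 150,
    params: GrammarParams = GrammarParams(),
) -> _LocusBuild:
    """Back-translate a protein into a genomic locus fragment.

    ``intron_plan`` is ``none`` (intronless) or ``GT_AG_between_f1_f2`` (a
    canonical GT...AG intron inserted in the linker between finger 1 and
    finger 2).  ``pseudogenize`` plants a TAA stop at the given protein
    residue position, which must lie inside a finger span.  Codon choice is
    uniform and seeded.  All coordinates in the returned record are relative
    to the fragment.
    """
    rng = _rng(seed)
    fingers = find_c2h2_domains(protein, params)
    if intron_plan not in ("none", "GT_AG_between_f1_f2"):
        raise MalformedInputError(f"unknown intron plan {intron_plan!r}")
    if intron_plan != "none" and len(fingers) < 2:
        raise MalformedInputError("intron plan requires at least two fingers")

    codons = []
    for aa in protein.sequence:
        opts = _CODONS_FOR.get(aa, _CODONS_FOR["G"])  # X falls back arbitrarily
        codons.append(opts[rng.integers(0, len(opts))])
    if pseudogenize is not None:
        if not any(f.c1 <= pseudogenize <= f.h2 for f in fingers):
            raise MalformedInputError(
                f"stop position {pseudogenize} lies outside every finger span"
            )
        codons[pseudogenize] = "TAA"

    intron = None
    if intron_plan == "GT_AG_between_f1_f2":
        split_res = fingers[1].c1 - 3  # mid-linker, strictly between fingers 1 and 2
        intron_dna = "GT" + _choice_str(rng, _DNA, intron_len - 4) + "AG"
        cds5, cds3 = codons[:split_res], codons[split_res:]
        left = random_dna(rng, flank_bp)
        body = "".join(cds5) + intron_dna + "".join(cds3)
        intron = (flank_bp + 3 * split_res, flank_bp + 3 * split_res + intron_len)
        shift = intron_len
    else:
        left = random_dna(rng, flank_bp)
        body = "".join(codons)
        shift = 0
        split_res = None
    right = random_dna(rng, flank_bp)
    dna = left + body + right

    def genomic(res: int) -> int:
        g = flank_bp + 3 * res
        if split_res is not None and res >= split_res:
            g += shift
        return g

    stops = tuple([genomic(pseudogenize)] if pseudogenize is not None else [])
    zf_start = genomic(fingers[0].c1)
    zf_end = genomic(fingers[-1].h2) + 3
    return _LocusBuild(
        dna=dna,
        cds_interval=(flank_bp, flank_bp + len(body)),
        intron=intron,
        stop_positions=stops,
        zf_interval=(zf_start, zf_end),
    )


# ---------------------------------------------------------------- genomes


@dataclass(frozen=True)
class CopyPlan:
    """One planted family-member copy.

    ``placement``: ``locus`` (inside the anchored interval, in plan order),
    ``distal`` (its own chromosome), or ``near:<copy_id>`` (immediately after
    a previously placed copy, e.g. a tandem duplicate of a retrocopy).
    """

    copy_id: str
    placement: str = "locus"
    strand: str = "+"
    intron_plan: str = "GT_AG_between_f1_f2"
    stop_in_finger: int | None = None  # plant a stop in this finger's inner spacer
    mask_fingers: bool = False
    parent_id: str | None = None
    mechanism: str | None = None  # planted truth: LGD | RT | None (root)
    mutation_rate: float = 0.0
    n_repeats: int | None = None
    cys_gaps: tuple[int, ...] = (4, 4, 2)
    terminal_his: bool = True


@dataclass(frozen=True)
class FamilySpec:
    """Per-genome plan: anchors, planted copies, repeat range."""

    genome_id: str
    copies: tuple[CopyPlan, ...] = ()
    upstream_anchors: tuple[str, ...] = DEFAULT_UPSTREAM_ANCHORS
    downstream_anchors: tuple[str, ...] = DEFAULT_DOWNSTREAM_ANCHORS
    n_repeats_range: tuple[int, int] = (10, 50)
    anchor_gene_bp: int = 600
    spacer_bp: int = 200

    def __post_init__(self):
        if self.n_repeats_range[0] < 0 or self.n_repeats_range[0] > self.n_repeats_range[1]:
            raise MalformedInputError("invalid n_repeats_range")


def _mirror(interval: tuple[int, int], length: int) -> tuple[int, int]:
    s, e = interval
    return length - e, length - s


_RC = str.maketrans("ACGTN", "TGCAN")


def make_genome(spec: FamilySpec, seed) -> tuple[GenomeRecord, GeneTable, TruthSet]:
    """Assemble a genome with anchors, planted copies and truth labels.

    Chromosome 1 carries the upstream anchors, the locus copies in plan
    order, and the downstream anchors; distal copies get their own
    chromosomes; ``near:`` copies are appended right after their target.
    Returns the genome, its gene table, and the planted truth.
    """
    rng = _rng(seed)
    params = GrammarParams()

    # 1. proteins along the planted lineage
    proteins: dict[str, ProteinRecord] = {}
    for plan in spec.copies:
        n_rep = (
            plan.n_repeats
            if plan.n_repeats is not None
            else int(rng.integers(spec.n_repeats_range[0], spec.n_repeats_range[1] + 1))
        )
        if plan.parent_id is None:
            prot = make_zf_protein(
                plan.copy_id,
                n_rep,
                rng,
                cys_gaps=plan.cys_gaps,
                terminal_his=plan.terminal_his,
                params=params,
            )
        else:
            if plan.parent_id not in proteins:
                raise MalformedInputError(
                    f"{plan.copy_id}: parent {plan.parent_id!r} not planted before child"
                )
            seq = mutate_protein(proteins[plan.parent_id].sequence, plan.mutation_rate, rng, params)
            prot = ProteinRecord(plan.copy_id, seq, "synthetic")
        proteins[plan.copy_id] = prot

    # 2. locus fragments
    builds: dict[str, _LocusBuild] = {}
    repeat_counts: dict[str, int] = {}
    for plan in spec.copies:
        prot = proteins[plan.copy_id]
        from .repeat_motif import DEFAULT_MOTIF, scan_motif

        repeat_counts[plan.copy_id] = len(scan_motif(prot, DEFAULT_MOTIF))
        stop_pos = None
        if plan.stop_in_finger is not None:
            fingers = find_c2h2_domains(prot, params)
            f = fingers[plan.stop_in_finger]
            stop_pos = f.c2 + 1 + 2  # inner-spacer offset 2: not a planted contact site
        build = make_locus(prot, plan.intron_plan, stop_pos, rng, params=params)
        if plan.mask_fingers:
            s, e = build.zf_interval
            dna = build.dna[:s] + "N" * (e - s) + build.dna[e:]
            build = replace(build, dna=dna)
        builds[plan.copy_id] = build

    # 3. chromosome assembly
    chrom_seqs: dict[str, list[str]] = {"chr1": []}
    chrom_len: dict[str, int] = {"chr1": 0}
    features: list[GeneFeature] = []
    placed: dict[str, tuple[str, int, int, str]] = {}  # copy -> chrom,start,end,strand

    def append(chrom: str, dna: str) -> int:
        start = chrom_len[chrom]
        chrom_seqs[chrom].append(dna)
        chrom_len[chrom] += len(dna)
        return start

    def place_copy(plan: CopyPlan, chrom: str):
        build = builds[plan.copy_id]
        frag = build.dna
        if plan.strand == "-":
            frag = frag.translate(_RC)[::-1]
        off = append(chrom, frag)
        append(chrom, random_dna(rng, spec.spacer_bp))
        L = len(build.dna)

        def abs_iv(iv):
            s, e = iv if plan.strand == "+" else _mirror(iv, L)
            return s + off, e + off

        gs, ge = abs_iv(build.cds_interval)
        feature = GeneFeature(chrom, gs, ge, plan.copy_id, plan.strand)
        features.append(feature)
        placed[plan.copy_id] = (chrom, gs, ge, plan.strand)

        stops = tuple(
            sorted(
                (s + off if plan.strand == "+" else off + L - (s + 3))
                for s in build.stop_positions
            )
        )
        zf_iv = abs_iv(build.zf_interval)
        status = (
            "masked"
            if plan.mask_fingers
            else ("pseudogene" if plan.stop_in_finger is not None else "coding")
        )
        structure = (
            "intron_containing" if plan.intron_plan != "none" else "intronless"
        )
        truth_loci.append(
            PlantedLocus(
                copy_id=plan.copy_id,
                gene=feature,
                status=status,
                intron_structure=structure,
                n_repeats=repeat_counts[plan.copy_id],
                parent_id=plan.parent_id,
                mechanism=plan.mechanism,
                stop_positions=stops,
                zf_interval=zf_iv,
                protein=proteins[plan.copy_id],
            )
        )

    truth_loci: list[PlantedLocus] = []
    append("chr1", random_dna(rng, 500))
    for anchor in spec.upstream_anchors:
        start = append("chr1", random_dna(rng, spec.anchor_gene_bp))
        features.append(GeneFeature("chr1", start, start + spec.anchor_gene_bp, anchor, "+"))
        append("chr1", random_dna(rng, spec.spacer_bp))

    locus_plans = [p for p in spec.copies if p.placement == "locus"]
    for plan in locus_plans:
        place_copy(plan, "chr1")

    for anchor in spec.downstream_anchors:
        start = append("chr1", random_dna(rng, spec.anchor_gene_bp))
        features.append(GeneFeature("chr1", start, start + spec.anchor_gene_bp, anchor, "+"))
        append("chr1", random_dna(rng, spec.spacer_bp))
    append("chr1", random_dna(rng, 300))

    next_chrom = 2
    for plan in spec.copies:
        if plan.placement == "locus":
            continue
        if plan.placement == "distal":
            chrom = f"chr{next_chrom}"
            next_chrom += 1
            chrom_seqs[chrom] = []
            chrom_len[chrom] = 0
            append(chrom, random_dna(rng, 400))
            place_copy(plan, chrom)
            append(chrom, random_dna(rng, 300))
        elif plan.placement.startswith("near:"):
            target = plan.placement.split(":", 1)[1]
            if target not in placed:
                raise MalformedInputError(
                    f"{plan.copy_id}: near-target {target!r} not placed yet"
                )
            place_copy(plan, placed[target][0])
        else:
            raise MalformedInputError(f"unknown placement {plan.placement!r}")

    genome = GenomeRecord(
        spec.genome_id, {c: "".join(parts) for c, parts in chrom_seqs.items()}, "synthetic"
    )
    table = GeneTable(spec.genome_id, features)

    copy_statuses = [l.status for l in truth_loci]
    if "coding" in copy_statuses:
        expected = "coding"
    elif "pseudogene" in copy_statuses:
        expected = "pseudogene"
    elif "masked" in copy_statuses:
        expected = "partial"
    else:
        expected = "absent"
    n_in_locus = sum(1 for p in locus_plans)
    truth = TruthSet(spec.genome_id, tuple(truth_loci), expected, n_in_locus)
    return genome, table, truth


def make_panel(
    n_genomes: int,
    seed,
    statuses: tuple[str, ...] = ("coding", "pseudogene", "absent"),
) -> list[tuple[GenomeRecord, GeneTable, TruthSet]]:
    """A panel of single-copy genomes cycling through planted statuses.

    ``coding`` plants a clean intron-containing copy; ``pseudogene`` plants a
    stop codon inside finger 2; ``partial`` masks the finger-coding DNA with
    N; ``absent`` plants anchors only.
    """
    rng = _rng(seed)
    out = []
    for i in range(n_genomes):
        status = statuses[i % len(statuses)]
        copies: tuple[CopyPlan, ...]
        if status == "coding":
            copies = (CopyPlan("KLF18", strand="-"),)
        elif status == "pseudogene":
            copies = (CopyPlan("KLF18", strand="-", stop_in_finger=1),)
        elif status == "partial":
            copies = (CopyPlan("KLF18", strand="-", mask_fingers=True),)
        elif status == "absent":
            copies = ()
        else:
            raise MalformedInputError(f"unknown planned status {status!r}")
        spec = FamilySpec(genome_id=f"genome{i:03d}", copies=copies)
        out.append(make_genome(spec, rng.integers(0, 2**31 - 1)))
    return out


def murine_spec(genome_id: str = "murine_like", rate: float = 0.0) -> FamilySpec:
    """The murine expansion scenario: LGD, RT, LGD, RT.

    KLF17 duplicates locally into KLF18 (tandem, tail-to-tail, both with the
    family intron); a spliced KLF18 mRNA retrotransposes to another
    chromosome (Zfp352, intronless); that retrocopy duplicates locally
    (Zfp352l, tail-to-tail); and Zfp352's mRNA retrotransposes again to a
    third chromosome (Zfp353).
    """
    return FamilySpec(
        genome_id=genome_id,
        copies=(
            CopyPlan("KLF17", n_repeats=14),
            CopyPlan(
                "KLF18", strand="-", parent_id="KLF17", mechanism="LGD", mutation_rate=rate
            ),
            CopyPlan(
                "Zfp352",
                placement="distal",
                intron_plan="none",
                parent_id="KLF18",
                mechanism="RT",
                mutation_rate=rate,
            ),
            CopyPlan(
                "Zfp352l",
                placement="near:Zfp352",
                strand="-",
                intron_plan="none",
                parent_id="Zfp352",
                mechanism="LGD",
                mutation_rate=rate,
            ),
            CopyPlan(
                "Zfp353",
                placement="distal",
                intron_plan="none",
                parent_id="Zfp352",
                mechanism="RT",
                mutation_rate=rate,
            ),
        ),
    )


# ---------------------------------------------------------------- family sims


def simulate_klf_family(
    seed,
    base_rate: float = 0.05,
    fast_multiplier: float = 3.0,
) -> tuple[list[tuple[str, list[ZincFinger], str]], set[str], str]:
    """Zinc-finger regions evolved along a fixed family genealogy.

    The KLF17/KLF18-like pair evolves at ``fast_multiplier`` times the base
    substitution rate (including their shared stem), emulating the elevated
    evolutionary rate of that clade; a WT1-like long-branch sequence serves
    as the outgroup.  Anchors are protected (purifying selection), so every
    leaf region parses into exactly three fingers.

    Returns (regions for anchor_align, the fast-clade id set, outgroup id).
    """
    rng = _rng(seed)
    params = GrammarParams()
    root = make_zf_protein("ancestor", 0, rng, params=params)
    fingers0 = find_c2h2_domains(root, params)
    region0 = root.sequence[fingers0[0].c1 : fingers0[-1].h2 + 1]

    def evolve(seq: str, rate: float) -> str:
        return mutate_protein(seq, rate, rng, params)

    fast = base_rate * fast_multiplier
    wt1 = evolve(region0, 2 * base_rate)
    a = evolve(region0, base_rate)
    a1 = evolve(a, base_rate)
    leaves = {
        "WT1": wt1,
        "KLF1": evolve(evolve(a1, base_rate), base_rate),
        "KLF2": evolve(evolve(a1, base_rate), base_rate),
        "KLF4": evolve(a1, base_rate),
    }
    stem = evolve(a1, fast)
    leaves["KLF17"] = evolve(stem, fast)
    leaves["KLF18"] = evolve(stem, fast)
    b = evolve(a, base_rate)
    leaves["KLF3"] = evolve(b, base_rate)
    leaves["KLF5"] = evolve(b, base_rate)
    leaves["KLF6"] = evolve(a, base_rate)

    regions = [
        (name, find_c2h2_domains(seq, params), seq) for name, seq in sorted(leaves.items())
    ]
    return regions, {"KLF17", "KLF18"}, "WT1"


def simulate_murine_members(seed, rate: float = 0.05):
    """Extant murine family members with planted mechanisms, for event inference.

    Sequences accumulate substitutions along the planted genealogy
    (KLF17 -> KLF18 -> Zfp352 -> {Zfp352l, Zfp353}); gene locations and intron
    structures follow the murine layout.  Returns (members, truth mechanisms).
    """
    from .evolution import EventMember

    rng = _rng(seed)
    params = GrammarParams()
    root = make_zf_protein("KLF17", 0, rng, params=params)
    f0 = find_c2h2_domains(root, params)
    k17 = root.sequence[f0[0].c1 : f0[-1].h2 + 1]
    k18 = mutate_protein(k17, rate, rng, params)
    z352 = mutate_protein(k18, rate, rng, params)
    z352l = mutate_protein(z352, rate, rng, params)
    z353 = mutate_protein(z352, rate, rng, params)

    members = [
        EventMember("KLF17", GeneFeature("chr1", 10_000, 10_900, "KLF17", "+"), "intron_containing", k17),
        EventMember("KLF18", GeneFeature("chr1", 11_100, 12_000, "KLF18", "-"), "intron_containing", k18),
        EventMember("Zfp352", GeneFeature("chr5", 50_000, 50_900, "Zfp352", "+"), "intronless", z352),
        EventMember("Zfp352l", GeneFeature("chr5", 51_100, 52_000, "Zfp352l", "-"), "intronless", z352l),
        EventMember("Zfp353", GeneFeature("chr9", 70_000, 70_900, "Zfp353", "+"), "intronless", z353),
    ]
    truth = {"KLF18": "LGD", "Zfp352": "RT", "Zfp352l": "LGD", "Zfp353": "RT"}
    return members, truth
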