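"""Six-frame translated scanning, gene-model assembly, pseudogene calling."""

import numpy as np
import pytest
from Bio.Seq import Seq

from oracles import greedy_fingers

from klfscout.locus_scan import (
    assemble_gene_model,
    call_status,
    has_repeat_similarity,
    reverse_complement,
    scan_locus_copies,
    six_frame_scan,
    translate,
)
from klfscout.synthetic_data import (
    CopyPlan,
    FamilySpec,
    make_genome,
    make_locus,
    make_zf_protein,
)
from klfscout.zf_grammar import GrammarParams, find_c2h2_domains


def back_translate_simple(protein: str) -> str:
    """Deterministic back-translation using one fixed codon per residue."""
    table = {
        "A": "GCT", "C": "TGT", "D": "GAT", "E": "GAA", "F": "TTT", "G": "GGT",
        "H": "CAT", "I": "ATT", "K": "AAA", "L": "CTT", "M": "ATG", "N": "AAT",
        "P": "CCT", "Q": "CAA", "R": "CGT", "S": "TCT", "T": "ACT", "V": "GTT",
        "W": "TGG", "Y": "TAT",
    }
    return "".join(table[c] for c in protein)


class TestTranslation:
    def test_matches_biopython_on_clean_dna(self):
        rng = np.random.default_rng(5)
        dna = "".join("ACGT"[i] for i in rng.integers(0, 4, size=300))
        assert translate(dna) == str(Seq(dna).translate())

    def test_n_codons_become_x_and_stops_star(self):
        assert translate("ATGNNATAA") == "MX*"


class TestSixFrameScan:
    def test_forward_frame0_consensus(self, consensus_seq, params):
        dna = back_translate_simple(consensus_seq)
        hits = [h for h in six_frame_scan(dna, params) if h.strand == "+"]
        assert len(hits) == 1
        h = hits[0]
        assert (h.frame, h.n_fingers) == (0, 3)
        # peptide round-trip: translating the genomic interval reproduces it
        assert translate(dna[h.start : h.end]) == h.peptide

    def test_strand_symmetry(self, consensus_seq, params):
        dna = back_translate_simple(consensus_seq)
        fwd = six_frame_scan(dna, params)
        rev = six_frame_scan(reverse_complement(dna), params)
        length = len(dna)
        mirrored = sorted(
            (length - h.end, length - h.start, "-" if h.strand == "+" else "+", h.peptide)
            for h in fwd
        )
        got = sorted((h.start, h.end, h.strand, h.peptide) for h in rev)
        assert got == mirrored

    def test_random_dna_matches_per_frame_oracle(self, params):
        rng = np.random.default_rng(8)
        dna = "".join("ACGT"[i] for i in rng.integers(0, 4, size=10_000))
        hits = six_frame_scan(dna, params)
        # oracle: enumerate finger fragments per frame translation naively
        expected = set()
        for strand in "+-":
            template = dna if strand == "+" else reverse_complement(dna)
            for frame in range(3):
                pep = translate(template[frame:])
                fingers = greedy_fingers(pep)
                groups = []
                for f in fingers:
                    if groups and f[0] - groups[-1][-1][3] - 1 == 7:
                        groups[-1].append(f)
                    else:
                        groups.append([f])
                for g in groups:
                    expected.add((strand, frame, g[0][0], len(g)))
        got = {(h.strand, h.frame, h.pep_start, h.n_fingers) for h in hits}
        assert got == expected
        # coordinate round-trip on both strands
        for h in hits:
            segment = dna[h.start : h.end]
            if h.strand == "-":
                segment = reverse_complement(segment)
            assert translate(segment) == h.peptide


class TestAssembly:
    def test_planted_intron_detected(self):
        prot = make_zf_protein("p", 3, 2)
        build = make_locus(prot, "GT_AG_between_f1_f2", seed=3)
        model = assemble_gene_model(six_frame_scan(build.dna), build.dna)
        assert model.intron_structure == "intron_containing"
        assert model.intron == build.intron
        assert call_status(model) == "coding"

    def test_contiguous_dna_is_intronless(self):
        prot = make_zf_protein("p", 3, 2)
        build = make_locus(prot, "none", seed=4)
        model = assemble_gene_model(six_frame_scan(build.dna), build.dna)
        assert model.intron_structure == "intronless"
        assert len(model.segments) == 1 and model.n_fingers == 3

    def test_noncanonical_splice_sites_rejected(self):
        prot = make_zf_protein("p", 3, 2)
        build = make_locus(prot, "GT_AG_between_f1_f2", seed=5)
        s, e = build.intron
        dna = list(build.dna)
        dna[s : s + 2] = "CT"
        dna[e - 2 : e] = "AC"
        dna = "".join(dna)
        model = assemble_gene_model(six_frame_scan(dna), dna)
        assert model.intron_structure == "unknown"

    def test_empty_hits_absent(self):
        model = assemble_gene_model([], "ACGT" * 100)
        assert call_status(model) == "absent"


class TestStatusCalls:
    def test_planted_stop_reported_at_exact_position(self, params):
        prot = make_zf_protein("p", 3, 6)
        fingers = find_c2h2_domains(prot, params)
        stop_res = fingers[1].c2 + 3  # inside finger 2's inner spacer
        build = make_locus(prot, "none", pseudogenize=stop_res, seed=7)
        model = assemble_gene_model(six_frame_scan(build.dna), build.dna)
        assert call_status(model) == "pseudogene"
        assert model.premature_stops == build.stop_positions

    def test_degraded_anchor_called_pseudogene(self, params):
        """A zinc-binding cysteine mutated to arginine deteriorates the finger."""
        prot = make_zf_protein("p", 3, 8)
        fingers = find_c2h2_domains(prot, params)
        build = make_locus(prot, "none", seed=9)
        c1_codon = build.zf_interval[0] + 3 * (fingers[1].c1 - fingers[0].c1)
        dna = build.dna[:c1_codon] + "CGT" + build.dna[c1_codon + 3 :]  # C -> R
        model = assemble_gene_model(six_frame_scan(dna), dna)
        assert model.n_fingers < 3
        assert model.degraded_fingers > 0
        assert call_status(model) == "pseudogene"

    def test_stop_panel_recall_and_precision(self, params):
        """Planted stop codons are recovered perfectly on a seeded locus panel."""
        rng = np.random.default_rng(33)
        tp = fp = fn = 0
        for i in range(12):
            prot = make_zf_protein(f"p{i}", 2, rng)
            fingers = find_c2h2_domains(prot, params)
            pseudo = i % 2 == 0
            stop_res = None
            if pseudo:
                f = fingers[int(rng.integers(0, 3))]
                stop_res = f.c2 + 1 + int(rng.integers(0, 5))
            build = make_locus(prot, "none", pseudogenize=stop_res, seed=rng)
            model = assemble_gene_model(six_frame_scan(build.dna), build.dna)
            called = call_status(model) == "pseudogene"
            tp += called and pseudo
            fp += called and not pseudo
            fn += pseudo and not called
        assert (tp, fp, fn) == (6, 0, 0)


class TestMultiCopyScan:
    def test_tandem_copies_each_modelled(self):
        copies = tuple(
            [CopyPlan("KLF17")]
            + [
                CopyPlan(
                    f"KLF18_{i}",
                    strand="-",
                    parent_id="KLF17" if i == 1 else f"KLF18_{i - 1}",
                    mechanism="LGD",
                )
                for i in range(1, 4)
            ]
        )
        genome, table, truth = make_genome(FamilySpec("g", copies), 13)
        dna = genome.chromosomes["chr1"]
        models = scan_locus_copies(dna, chrom="chr1")
        full = [m for m in models if m.n_fingers >= 3]
        assert len(full) == 4
        assert sorted(m.strand for m in full) == ["+", "-", "-", "-"]
        assert all(m.intron_structure == "intron_containing" for m in full)


class TestRepeatSimilarity:
    def test_masked_fingers_but_repeats_found(self):
        spec = FamilySpec("g", (CopyPlan("KLF18", mask_fingers=True),))
        genome, table, truth = make_genome(spec, 21)
        dna = genome.chromosomes["chr1"]
        assert not six_frame_scan(dna) or all(
            h.n_fingers < 3 for h in six_frame_scan(dna)
        )
        assert has_repeat_similarity(dna)

    def test_plain_dna_has_no_repeat_similarity(self):
        rng = np.random.default_rng(2)
        dna = "".join("ACGT"[i] for i in rng.integers(0, 4, size=3000))
        assert not has_repeat_similarity(dna)
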