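"""Spacing-grammar detection, family classification, contact conservation."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import build_finger_string
from oracles import greedy_fingers

from klfscout.errors import MalformedInputError, NotApplicableError
from klfscout.records import ProteinRecord
from klfscout.synthetic_data import make_decoy_protein, make_zf_protein
from klfscout.zf_grammar import (
    FamilyLabel,
    GrammarParams,
    ZincFinger,
    contact_report,
    extract_zf_region,
    find_c2h2_domains,
    signature_of,
)


class TestFindDomains:
    def test_consensus_single_finger(self, params):
        seq = "A" * 10 + "C" + "A" * 4 + "C" + "A" * 12 + "H" + "A" * 3 + "H"
        fingers = find_c2h2_domains(seq, params)
        assert len(fingers) == 1
        f = fingers[0]
        assert (f.c1, f.cys_gap, f.inner_gap, f.his_gap) == (10, 4, 12, 3)

    def test_no_cysteines_no_fingers(self, params):
        assert find_c2h2_domains("A" * 120, params) == []

    def test_planted_finger_in_random_background(self, params):
        rng = np.random.default_rng(42)
        background = "ADEFGIKLMNPQRSTVWY"  # no C/H: the plant is the only match
        seq = list("".join(background[i] for i in rng.integers(0, 18, size=500)))
        finger = "C" + "G" * 4 + "C" + "G" * 12 + "H" + "G" * 3 + "H"
        start = 231
        seq[start : start + len(finger)] = finger
        seq = "".join(seq)
        fingers = find_c2h2_domains(seq, params)
        assert [(f.c1, f.c2, f.h1, f.h2) for f in fingers] == [
            t for t in greedy_fingers(seq)
        ]
        assert len(fingers) == 1 and fingers[0].c1 == start

    def test_smallest_cys_gap_preferred(self, params):
        # C at 0 can close with the C at 3 (gap 2) or at 5 (gap 4);
        # H anchors are planted so that both alternatives complete
        seq = list("A" * 30)
        for pos, ch in [(0, "C"), (3, "C"), (5, "C"), (16, "H"), (18, "H"), (20, "H"), (22, "H")]:
            seq[pos] = ch
        fingers = find_c2h2_domains("".join(seq), params)
        assert fingers and fingers[0].cys_gap == 2

    def test_x_never_matches_anchor(self, params):
        seq = "X" + "A" * 4 + "C" + "A" * 12 + "H" + "A" * 3 + "H"
        assert find_c2h2_domains(seq, params) == []

    @settings(derandomize=True, max_examples=150)
    @given(st.text(alphabet="CHAX*GR", min_size=0, max_size=160))
    def test_greedy_matches_bruteforce_oracle(self, seq):
        params = GrammarParams()
        ours = [(f.c1, f.c2, f.h1, f.h2) for f in find_c2h2_domains(seq, params)]
        assert ours == greedy_fingers(seq)
        for f in find_c2h2_domains(seq, params):
            assert seq[f.c1] == "C" and seq[f.c2] == "C"
            assert seq[f.h1] == "H" and seq[f.h2] in "HC"

    def test_terminal_cys_tolerance(self):
        seq = build_finger_string()
        swapped = seq[: len(seq) - 6] + "C" + seq[len(seq) - 5 :]
        assert seq[-6] == "H" and swapped[-6] == "C"
        tolerant = GrammarParams(allow_terminal_cys_for_his=True)
        strict = GrammarParams(allow_terminal_cys_for_his=False)
        base = find_c2h2_domains(seq, tolerant)
        assert find_c2h2_domains(swapped, tolerant) == base
        assert len(find_c2h2_domains(swapped, strict)) == len(base) - 1


class TestSignature:
    @pytest.mark.parametrize(
        "gaps,label",
        [
            ((4, 4, 2), FamilyLabel.SPKLF_STRICT),
            ((4, 2, 2), FamilyLabel.EGR_LIKE),
            ((2, 2, 2), FamilyLabel.SPKLF_RELAXED),
            ((2, 4, 2), FamilyLabel.SPKLF_RELAXED),
            ((4, 4, 2, 4), FamilyLabel.WT1_LIKE),
            ((4, 4), FamilyLabel.OTHER_C2H2),
            ((3, 4, 2), FamilyLabel.OTHER_C2H2),
        ],
    )
    def test_labels_from_spacings(self, gaps, label, params):
        seq = build_finger_string(gaps)
        fingers = find_c2h2_domains(seq, params)
        sig = signature_of(fingers, len(seq), params)
        assert sig.finger_count == len(gaps)
        assert sig.cys_gaps == gaps
        assert sig.label == label

    def test_no_fingers(self, params):
        assert signature_of([], 100, params).label == FamilyLabel.NO_C2H2

    def test_linker_lengths(self, params, consensus_seq):
        sig = signature_of(find_c2h2_domains(consensus_seq, params), len(consensus_seq), params)
        assert sig.linker_lengths == (7, 7)

    def test_overlapping_fingers_rejected(self, params):
        a = ZincFinger(0, 5, 18, 22)
        b = ZincFinger(10, 15, 28, 32)
        with pytest.raises(MalformedInputError):
            signature_of([a, b], 100, params)

    def test_classification_separation_on_decoy_panel(self, params):
        """Generated SP/KLF, EGR and WT1 panels classify with full accuracy."""
        rng = np.random.default_rng(7)
        n = 100
        panel = []
        for i in range(n):
            panel.append((make_zf_protein(f"klf{i}", 0, rng), FamilyLabel.SPKLF_STRICT))
            panel.append((make_decoy_protein("EGR", f"egr{i}", rng), FamilyLabel.EGR_LIKE))
            panel.append((make_decoy_protein("WT1", f"wt1{i}", rng), FamilyLabel.WT1_LIKE))
        for protein, expected in panel:
            fingers = find_c2h2_domains(protein, params)
            assert signature_of(fingers, len(protein), params).label == expected


class TestContactReport:
    def test_planted_contacts_all_pass(self, params):
        prot = make_zf_protein("p", 5, 11)
        fingers = find_c2h2_domains(prot, params)
        rep = contact_report(prot, fingers, params=params)
        assert (rep.n_pass, rep.n_checked) == (6, 6)
        assert rep.pass_fraction == 1.0

    def test_mutated_arginine_identified(self, params):
        prot = make_zf_protein("p", 5, 11)
        fingers = find_c2h2_domains(prot, params)
        pos = fingers[1].c2 + 1 + 5  # first contact arginine of finger 2
        seq = prot.sequence[:pos] + "K" + prot.sequence[pos + 1 :]
        rep = contact_report(ProteinRecord("p", seq), fingers, params=params)
        assert rep.n_pass == 5
        failing = [c for c in rep.checks if not c.passed]
        assert len(failing) == 1
        assert (failing[0].finger, failing[0].offset, failing[0].observed) == (1, 5, "K")

    def test_requires_three_fingers(self, params, consensus_seq):
        fingers = find_c2h2_domains(consensus_seq, params)
        with pytest.raises(NotApplicableError):
            contact_report(consensus_seq, fingers[:2], params=params)


class TestExtractRegion:
    def test_single_finger_span(self, params):
        seq = "A" * 10 + "C" + "A" * 4 + "C" + "A" * 12 + "H" + "A" * 3 + "H" + "A" * 5
        fingers = find_c2h2_domains(seq, params)
        region = extract_zf_region(seq, fingers)
        assert len(region) == fingers[0].h2 - fingers[0].c1 + 1 == 23

    def test_three_finger_length_identity(self, params, consensus_seq):
        fingers = find_c2h2_domains(consensus_seq, params)
        region = extract_zf_region(consensus_seq, fingers)
        # spans 23 + 23 + 21 plus two 7-residue linkers
        assert len(region) == fingers[-1].h2 - fingers[0].c1 + 1 == 81
        # reconstruction: region is exactly the substring between the anchors
        assert region == consensus_seq[fingers[0].c1 : fingers[-1].h2 + 1]

    def test_empty_fingers_error(self, consensus_seq):
        with pytest.raises(NotApplicableError):
            extract_zf_region(consensus_seq, [])
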