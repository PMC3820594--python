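import pytest

from klfscout.zf_grammar import GrammarParams


@pytest.fixture
def params():
    return GrammarParams()


def build_finger_string(cys_gaps=(4, 4, 2), leader=10, linker=7, tail=5, filler="A"):
    """A deterministic protein string with consensus-spaced fingers."""
    parts = [filler * leader]
    for i, g in enumerate(cys_gaps):
        parts.append("C" + filler * g + "C" + filler * 12 + "H" + filler * 3 + "H")
        if i < len(cys_gaps) - 1:
            parts.append(filler * linker)
    parts.append(filler * tail)
    return "".join(parts)


@pytest.fixture
def consensus_seq():
    return build_finger_string()
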