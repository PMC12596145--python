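import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

from phylogeoscan import Alignment, ScoringScheme, SequenceRecord


@pytest.fixture
def linear_scheme():
    """Linear gap penalty (open == extend), the regime the enumeration oracles
    cover."""
    return ScoringScheme(match=1.0, mismatch=-1.0, gap_open=-1.0, gap_extend=-1.0)


@pytest.fixture
def toy_alignment():
    return Alignment([
        SequenceRecord("A", "ACGTACGT"),
        SequenceRecord("B", "ACGAACGT"),
        SequenceRecord("C", "TCGAACGA"),
        SequenceRecord("D", "TCGAACGA"),
    ])


@pytest.fixture
def write_fasta_file(tmp_path):
    def _write(text, name="input.fasta"):
        p = tmp_path / name
        p.write_text(text)
        return p

    return _write
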