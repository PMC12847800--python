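import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

from rbfclust.io_sequences import SequenceRecord, SequenceSet


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def toy_fasta(tmp_path):
    """Three-record FASTA with multi-line bodies and a blank line."""
    path = tmp_path / "toy.fasta"
    path.write_text(
        ">APC|NM_000038 adenomatous polyposis coli\n"
        "ACGTACGT\nACGT\n"
        "\n"
        ">SMAD4|NM_005359\nGGGGCCCC\n"
        ">TP53\nACGT\nACGT\nACGT\n"
    )
    return path


@pytest.fixture
def small_set():
    return SequenceSet(
        records=[
            SequenceRecord("APC", "NM_000038", "ACGT" * 300),
            SequenceRecord("SMAD4", "NM_005359", "GGCC" * 250),
            SequenceRecord("TP53", "", "AACC" * 260),
        ],
        provenance="test",
    )
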