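import pytest

from apofrag.formats_io import ProteinRecord, RunConfig


@pytest.fixture
def config():
    return RunConfig()


@pytest.fixture
def protein_100():
    # deterministic 100-residue protein with aspartates at known positions
    seq = ("MKTAYIAKQRQISFVKSHFSRQLEERLGLIEVQAPILSRVGDGTQDNLSGAEKAVQVKVK"
           "ALPDAQFEVVHSLAKWKRQTLGQHDFSAGEGLYTHMKA")
    assert len(seq) == 98
    return ProteinRecord("P00001", "TESTG", seq + "DD")
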