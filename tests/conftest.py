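import pytest

from aarepeat.repeat_detection import DetectorParams
from aarepeat.sequence_io import CodingRecord, PairedRecord, ProteinRecord, pair_cds


@pytest.fixture
def params():
    return DetectorParams()


def make_paired(protein_id, sequence, codons, species="test"):
    """PairedRecord from an explicit codon list (bypasses FASTA plumbing)."""
    protein = ProteinRecord(protein_id, protein_id, species, sequence)
    cds = CodingRecord(protein_id, "".join(codons))
    return pair_cds(protein, cds)


@pytest.fixture
def paired_factory():
    return make_paired
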