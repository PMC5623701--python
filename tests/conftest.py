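import pytest

from groupcons.alignment import Alignment, GroupPartition
from groupcons.synthetic import SyntheticConfig, generate_alignment

MSF_TEXT = """PileUp

 MSF: 6  Type: P  Check: 1234 ..

 Name: seq1 Len: 6  Check: 111  Weight: 1.0
 Name: seq2 Len: 6  Check: 222  Weight: 1.0

//

seq1  AC.DEF
seq2  ACGD~F
"""


@pytest.fixture
def msf_file(tmp_path):
    path = tmp_path / "toy.msf"
    path.write_text(MSF_TEXT)
    return path


@pytest.fixture
def toy_alignment():
    return Alignment(("a", "b", "c", "d"),
                     ("ACDE-", "ACD-F", "AC-EF", "GCDEF"))


@pytest.fixture
def two_group_alignment():
    """10 vs 10: group g1 all-A, group g2 all-C at column 1."""
    ids = tuple(f"s{i:02d}" for i in range(20))
    rows = tuple(["AW"] * 10 + ["CW"] * 10)
    aln = Alignment(ids, rows)
    part = GroupPartition({sid: ("g1" if i < 10 else "g2")
                           for i, sid in enumerate(ids)})
    return aln, part


@pytest.fixture(scope="session")
def benchmark():
    """The default synthetic benchmark: 4 groups x 50 seqs, 500 columns."""
    config = SyntheticConfig(seed=1)
    alignment, partition, truth = generate_alignment(config)
    return config, alignment, partition, truth
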