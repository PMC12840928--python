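import pytest

from helpers import make_alignment


@pytest.fixture
def toy_alignment():
    """Three short sequences: pair diffs (1, 2, 1), k = 4/3, two haplotype pairs."""
    return make_alignment(["AAA", "AAT", "ATT"])


@pytest.fixture(scope="session")
def study_dataset():
    """A fixed-seed study-shaped simulated dataset (n=76, L=648, theta=2.7)."""
    from mtdemog.coalsim import emulate_study
    return emulate_study("study648", seed=20260917)


@pytest.fixture
def fasta_file(tmp_path):
    def _write(seqs, ids=None, name="test.fasta"):
        aln = make_alignment(seqs, ids)
        path = tmp_path / name
        from mtdemog.alignment import write_fasta
        write_fasta(aln, path)
        return path
    return _write
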