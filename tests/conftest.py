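import pytest

from cidkit.alignment import from_sequences


@pytest.fixture
def small_alignment():
    """3 ungapped sequences of length 10."""
    return from_sequences(
        [
            ("seq1", "ACDEFGHIKL"),
            ("seq2", "ACDEFGHIKM"),
            ("seq3", "ACDEYGHIKN"),
        ]
    )


@pytest.fixture
def gapped_alignment():
    return from_sequences(
        [
            ("a", "Y-RAC"),
            ("b", "YARAC"),
            ("c", "Y-R-C"),
        ]
    )


@pytest.fixture
def fasta_file(tmp_path, small_alignment):
    from cidkit.alignment import write_alignment

    path = tmp_path / "aln.fasta"
    write_alignment(small_alignment, path)
    return path
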