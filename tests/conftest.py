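import pytest

from seqdbkit.synthetic import (annotation_table, random_protein_entries,
                                random_transcripts)


@pytest.fixture(scope="session")
def entries20():
    return random_protein_entries(20, seed=7)


@pytest.fixture(scope="session")
def entries200():
    return random_protein_entries(200, seed=11)


@pytest.fixture()
def sqpd20(tmp_path, entries20):
    from seqdbkit.core import DatabaseMeta
    from seqdbkit.sqpd import create_sqpd
    h = create_sqpd(tmp_path / "toy.sqpd",
                    DatabaseMeta(db_name="toydb", db_version="1",
                                 db_source="uniprot"))
    h.add_entries(entries20)
    yield h
    h.close()


@pytest.fixture(scope="session")
def transcripts50():
    return random_transcripts(50, seed=3, min_len=30, max_len=600)


@pytest.fixture()
def uniprot_fixture(tmp_path, entries20):
    """FASTA + UniProt-style annotation table on disk for the toy proteome."""
    from seqdbkit.textio import write_fasta
    fasta = tmp_path / "up.fasta"
    table = tmp_path / "up.tsv"
    write_fasta(entries20, fasta, dialect="uniprot")
    table.write_text(annotation_table(entries20), encoding="utf-8")
    return fasta, table
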