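"""FASTA/PEFF I/O, the PEFF tag grammar, and format detection."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from seqdbkit.errors import (EmptyRecord, MalformedTag, NotFasta, NotPeff)
from seqdbkit.textio import (PeffTag, detect_format, format_peff_tags,
                             parse_peff_tags, read_fasta, read_peff,
                             read_peptide_list, write_fasta, write_peff,
                             features_to_tags, tags_to_features)
from seqdbkit.core import DatabaseMeta, Feature


class TestFasta:
    def test_multiline_sequence_joined(self, tmp_path):
        p = tmp_path / "a.fasta"
        p.write_text(">a\nACD\nEFG\n")
        (e,) = read_fasta(p)
        assert e.sequence == "ACDEFG"

    def test_crlf_and_blank_lines_tolerated(self, tmp_path):
        p = tmp_path / "a.fasta"
        p.write_bytes(b"\r\n>a desc\r\nACD \r\n\r\nEFG\r\n")
        (e,) = read_fasta(p)
        assert e.sequence == "ACDEFG" and e.description == "desc"

    def test_roundtrip_many_entries(self, tmp_path, entries200):
        p = tmp_path / "r.fasta"
        write_fasta(entries200, p, wrap=60)
        back = list(read_fasta(p))
        assert [(e.accession, e.sequence) for e in back] == \
            [(e.accession, e.sequence) for e in entries200]
        assert [e.description for e in back] == \
            [e.description for e in entries200]

    def test_wrap_zero_single_line(self, tmp_path, entries20):
        p = tmp_path / "w.fasta"
        write_fasta(entries20[:1], p, wrap=0)
        assert len(p.read_text().strip().splitlines()) == 2

    def test_header_without_sequence_is_empty_record(self, tmp_path):
        p = tmp_path / "bad.fasta"
        p.write_text(">a\n>b\nAC\n")
        with pytest.raises(EmptyRecord):
            list(read_fasta(p))

    def test_non_fasta_rejected(self, tmp_path):
        p = tmp_path / "x.txt"
        p.write_text("hello world\n")
        with pytest.raises(NotFasta):
            list(read_fasta(p))


class TestPeffTags:
    def test_scalar_and_positional_tags(self):
        tags = parse_peff_tags(
            "\\PName=Test protein \\Length=10 \\VariantSimple=(3|A)(5|T)")
        assert [t.key for t in tags] == ["PName", "Length", "VariantSimple"]
        assert tags[0].values == [["Test protein"]]
        assert tags[1].values == [["10"]]
        assert tags[2].values == [["3", "A"], ["5", "T"]]

    def test_processed_tuple(self):
        (tag,) = parse_peff_tags("\\Processed=(1|22|signal peptide)")
        assert tag.values == [["1", "22", "signal peptide"]]

    def test_empty_remainder(self):
        assert parse_peff_tags("") == []

    @pytest.mark.parametrize("bad", [
        "\\Variant=(3|A", "\\=x", "\\Key", "no backslash"])
    def test_malformed(self, bad):
        with pytest.raises(MalformedTag):
            parse_peff_tags(bad)

    def test_format_is_inverse_of_parse(self):
        s = "\\PName=Toy one \\Length=9 \\Processed=(1|3|signal peptide)(4|9|mature protein) \\VariantSimple=(5|W)"
        assert format_peff_tags(parse_peff_tags(s)) == s

    @given(st.lists(
        st.tuples(st.integers(1, 50), st.integers(0, 30),
                  st.sampled_from("ACDEFGHIKLMNPQRSTVWY")),
        min_size=0, max_size=5))
    @settings(max_examples=50, derandomize=True)
    def test_feature_codec_roundtrip(self, raw):
        feats = []
        for start, extent, res in raw:
            feats.append(Feature("VARIANT", start, start, res))
            feats.append(Feature("MOD_RES", start, start + extent, "Phospho"))
            feats.append(Feature("CHAIN", start, start + extent))
        back, passthrough = tags_to_features(features_to_tags(feats))
        assert passthrough == []
        assert sorted(f.triple() for f in back) == \
            sorted(f.triple() for f in feats)


class TestPeffFiles:
    MINIMAL = "# PEFF 1.0\n# DbName=toy\n# //\n>gen:A \\Length=3\nACD\n"

    def test_minimal_file(self, tmp_path):
        p = tmp_path / "m.peff"
        p.write_text(self.MINIMAL)
        meta, entries = read_peff(p)
        assert meta.extra["DbName"] == "toy" and meta.db_name == "toy"
        assert len(entries) == 1 and len(entries[0].sequence) == 3

    def test_fasta_rejected(self, tmp_path):
        p = tmp_path / "f.fasta"
        p.write_text(">a\nACD\n")
        with pytest.raises(NotPeff):
            read_peff(p)

    def test_roundtrip_with_features(self, tmp_path, entries20):
        p = tmp_path / "rt.peff"
        meta = DatabaseMeta(db_name="toydb", db_version="2")
        write_peff(meta, entries20, p)
        meta2, back = read_peff(p)
        assert meta2.db_name == "toydb" and meta2.db_version == "2"
        assert [(e.accession, e.sequence) for e in back] == \
            [(e.accession, e.sequence) for e in entries20]
        for orig, rt in zip(entries20, back):
            assert sorted(f.triple() for f in rt.features) == \
                sorted(f.triple() for f in orig.features)

    def test_write_read_write_is_stable(self, tmp_path, entries20):
        a, b = tmp_path / "a.peff", tmp_path / "b.peff"
        meta = DatabaseMeta(db_name="t", db_version="1", created="2024-01-01T00:00:00Z")
        write_peff(meta, entries20, a)
        m2, e2 = read_peff(a)
        write_peff(m2, e2, b)
        assert a.read_text() == b.read_text()


class TestDetectFormat:
    def test_fasta(self, tmp_path):
        p = tmp_path / "x"
        p.write_text(">x\nACDE\n")
        assert detect_format(p) == ("fasta", [])

    def test_peptide_list(self, tmp_path):
        p = tmp_path / "x"
        p.write_text("PEPTIDE\nSEQ\n")
        assert detect_format(p)[0] == "peptide_list"
        assert read_peptide_list(p) == ["PEPTIDE", "SEQ"]

    def test_duplicate_accession_reported_not_fatal(self, tmp_path):
        p = tmp_path / "x"
        p.write_text(">x\nAC\n>x\nDE\n")
        fmt, issues = detect_format(p)
        assert fmt == "fasta" and any("duplicate accession x" in i for i in issues)

    def test_set_and_unknown_json(self, tmp_path):
        s = tmp_path / "s.set"
        s.write_text('{"format": "SET", "entries": []}')
        assert detect_format(s)[0] == "set"
        u = tmp_path / "u.json"
        u.write_text('{"hello": 1}')
        assert detect_format(u)[0] == "unknown"

    def test_sqpd_by_magic(self, tmp_path):
        from seqdbkit.synthetic import toy_sqpd
        h = toy_sqpd(tmp_path / "t.sqpd", n=3, seed=0)
        h.close()
        assert detect_format(tmp_path / "t.sqpd")[0] == "sqpd"

    def test_peff_magic(self, tmp_path):
        p = tmp_path / "p"
        p.write_text(TestPeffFiles.MINIMAL)
        assert detect_format(p)[0] == "peff"

    def test_prose_is_unknown(self, tmp_path):
        p = tmp_path / "x"
        p.write_text("once upon a time 123\n")
        assert detect_format(p)[0] == "unknown"
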