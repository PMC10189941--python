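"""SQPD creation, population, querying, and the UniProt feature mapping."""

import pytest

from seqdbkit.core import DatabaseMeta, Feature, ProteinEntry
from seqdbkit.errors import (AccessionNotFound, DuplicateAccession,
                             InvalidMeta, MalformedFeatureCell, PathExists)
from seqdbkit.sqpd import (create_sqpd, map_uniprot_features, open_sqpd)
from seqdbkit.textio import features_to_tags


def _meta(**kw):
    return DatabaseMeta(db_name=kw.pop("db_name", "t"), **kw)


class TestLifecycle:
    def test_meta_roundtrip(self, tmp_path):
        h = create_sqpd(tmp_path / "a.sqpd",
                        _meta(db_version="3", db_source="uniprot"))
        h.close()
        with open_sqpd(tmp_path / "a.sqpd") as h2:
            m = h2.meta
            assert (m.db_name, m.db_version, m.db_source) == ("t", "3", "uniprot")
            assert m.n_entries == 0

    def test_empty_db_name_rejected(self, tmp_path):
        with pytest.raises(InvalidMeta):
            create_sqpd(tmp_path / "b.sqpd", DatabaseMeta(db_name=""))

    def test_existing_path_protected(self, tmp_path):
        create_sqpd(tmp_path / "c.sqpd", _meta()).close()
        with pytest.raises(PathExists):
            create_sqpd(tmp_path / "c.sqpd", _meta())
        create_sqpd(tmp_path / "c.sqpd", _meta(), overwrite=True).close()

    def test_file_has_sqlite_magic(self, tmp_path):
        create_sqpd(tmp_path / "d.sqpd", _meta()).close()
        assert (tmp_path / "d.sqpd").open("rb").read(16) == b"SQLite format 3\x00"


class TestAddAndGet:
    def test_count_and_n_entries(self, sqpd20, entries20):
        assert len(sqpd20) == 20 and sqpd20.meta.n_entries == 20

    def test_get_returns_identical_entry(self, sqpd20, entries20):
        for orig in entries20[:5]:
            got = sqpd20.get_entry(orig.accession)
            assert got.sequence == orig.sequence
            assert [f.triple() for f in got.features] == \
                [f.triple() for f in orig.features]
            assert got.description == orig.description

    def test_unknown_accession(self, sqpd20):
        with pytest.raises(AccessionNotFound):
            sqpd20.get_entry("NOPE")

    def test_duplicate_error_policy_is_atomic(self, sqpd20, entries20):
        fresh = ProteinEntry(accession="FRESH1", sequence="MKTAYIAK")
        with pytest.raises(DuplicateAccession):
            sqpd20.add_entries([fresh, entries20[0]])
        # whole batch rolled back: FRESH1 absent, count unchanged
        assert len(sqpd20) == 20
        with pytest.raises(AccessionNotFound):
            sqpd20.get_entry("FRESH1")

    def test_duplicate_skip_and_suffix(self, sqpd20, entries20):
        assert sqpd20.add_entries([entries20[0]], on_duplicate="skip") == 0
        assert sqpd20.add_entries([entries20[0]], on_duplicate="suffix") == 1
        assert sqpd20.get_entry(entries20[0].accession + "_2").sequence == \
            entries20[0].sequence

    def test_glycine_average_mass(self, tmp_path):
        # Gly residue 57.0519 + water 18.0153
        h = create_sqpd(tmp_path / "g.sqpd", _meta())
        h.add_entries([ProteinEntry(accession="G1", sequence="G")])
        mass = h._con.execute(
            "SELECT mass FROM entries WHERE accession='G1'").fetchone()[0]
        h.close()
        assert mass == pytest.approx(75.07, abs=0.01)


class TestQueries:
    def brute(self, entries, lo, hi):
        return sorted(e.accession for e in entries if lo <= len(e.sequence) <= hi)

    def test_length_range_matches_bruteforce(self, sqpd20, entries20):
        for lo, hi in [(30, 60), (50, 200), (0, 1000), (100, 100)]:
            assert sqpd20.query_entries(length=(lo, hi)) == \
                self.brute(entries20, lo, hi)

    def test_feature_key_query(self, sqpd20, entries20):
        want = sorted(e.accession for e in entries20
                      if any(f.kind == "SIGNAL" for f in e.features))
        assert sqpd20.query_entries(feature_key="SIGNAL") == want

    def test_accession_list_and_conjunction(self, sqpd20, entries20):
        accs = [e.accession for e in entries20[:6]]
        got = sqpd20.query_entries(length=(0, 150), accessions=accs)
        want = sorted(a for a in accs
                      if len(next(e for e in entries20
                                  if e.accession == a).sequence) <= 150)
        assert got == want

    def test_random_access_does_not_scan_all_rows(self, sqpd20):
        sqpd20.rows_read = 0
        sqpd20.get_entry("P00003")
        sqpd20.get_entry("P00007")
        assert sqpd20.rows_read == 2
        plan = sqpd20._con.execute(
            "EXPLAIN QUERY PLAN SELECT * FROM entries WHERE accession=?",
            ("P00003",)).fetchall()
        assert any("USING INDEX" in row[-1].upper() or
                   "USING COVERING INDEX" in row[-1].upper() for row in plan)


class TestUniProtFeatureMapping:
    def test_signal_range(self):
        row = {"Signal peptide": 'SIGNAL 1..22; /evidence="ECO:0000255"'}
        (f,) = map_uniprot_features(row)
        assert f.triple() == ("SIGNAL", 1, 22, "")

    def test_simple_variant_replacement(self):
        row = {"Natural variant": 'VARIANT 54; /note="A -> T"'}
        (f,) = map_uniprot_features(row)
        assert f.triple() == ("VARIANT", 54, 54, "T")

    def test_modified_residue_note(self):
        row = {"Modified residue": 'MOD_RES 10; /note="Phosphoserine"'}
        (f,) = map_uniprot_features(row)
        assert f.triple() == ("MOD_RES", 10, 10, "Phosphoserine")

    def test_multi_interval_cell_split(self):
        row = {"Chain": 'CHAIN 1..10; /note="Chain A"; CHAIN 11..30; /note="Chain B"'}
        feats = map_uniprot_features(row)
        assert [f.triple() for f in feats] == \
            [("CHAIN", 1, 10, "Chain A"), ("CHAIN", 11, 30, "Chain B")]

    def test_empty_cell(self):
        assert map_uniprot_features({"Chain": ""}) == []

    def test_uncertain_bounds_skipped(self):
        row = {"Signal peptide": "SIGNAL <1..?22"}
        assert map_uniprot_features(row) == []

    def test_unparseable_cell_raises(self):
        with pytest.raises(MalformedFeatureCell):
            map_uniprot_features({"Chain": "not a feature"})


class TestPeffMapping:
    def test_signal_to_processed(self):
        (tag,) = features_to_tags([Feature("SIGNAL", 1, 22)])
        assert tag.key == "Processed"
        assert tag.values == [["1", "22", "signal peptide"]]

    def test_simple_variant_to_variantsimple(self):
        (tag,) = features_to_tags([Feature("VARIANT", 54, 54, "T")])
        assert tag.key == "VariantSimple" and tag.values == [["54", "T"]]

    def test_empty(self):
        assert features_to_tags([]) == []
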