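"""Decoys, translation, mature forms, and the sORF finders (oracle-checked)."""

import random

import pytest
from Bio.Seq import Seq

from seqdbkit.core import Feature, ProteinEntry
from seqdbkit.errors import (LengthNotMultipleOfThree, TagCollision, UsageError)
from seqdbkit.generation import (SorfNamer, extract_mature_forms,
                                 find_sorfs_circular, find_sorfs_linear,
                                 make_decoys, reverse_complement, sorf_name,
                                 translate)

STOPS = {"TAA", "TAG", "TGA"}


def oracle_linear(seq, starts, min_pep, max_pep, strands="forward"):
    """Brute force: test every position for a start codon, scan forward in
    codon steps for the first stop, translate with Biopython."""
    out = set()
    strand_seqs = [seq] if strands == "forward" else [seq, reverse_complement(seq)]
    for si, s in enumerate(strand_seqs):
        L = len(s)
        for i in range(L - 2):
            if s[i:i + 3] not in starts:
                continue
            stop = None
            j = i
            while j + 3 <= L:
                if s[j:j + 3] in STOPS:
                    stop = j
                    break
                j += 3
            if stop is None:
                continue
            pep = str(Seq(s[i:stop]).translate())
            if min_pep <= len(pep) <= max_pep:
                out.add((si, i + 1, stop + 3, pep))
    return out


class TestDecoys:
    def test_full_reversal(self):
        e = ProteinEntry(accession="T1", sequence="ABCDEF")
        (d,) = make_decoys([e], tag="rev_")
        assert d.sequence == "FEDCBA" and d.accession == "rev_T1"
        assert d.features == []

    def test_involution_preserves_sequence_and_multiset(self, entries20):
        once = list(make_decoys(entries20, tag="r1_"))
        twice = list(make_decoys(once, tag="r2_"))
        for orig, back in zip(entries20, twice):
            assert back.sequence == orig.sequence
            assert sorted(back.sequence) == sorted(orig.sequence)

    def test_concat_mode_targets_first(self, entries20):
        out = list(make_decoys(entries20, tag="rev_", mode="concat"))
        assert len(out) == 40
        assert [e.accession for e in out[:20]] == \
            [e.accession for e in entries20]

    def test_tag_collision(self):
        e = ProteinEntry(accession="rev_T1", sequence="MK")
        with pytest.raises(TagCollision):
            list(make_decoys([e], tag="rev_"))


class TestTranslate:
    @pytest.mark.parametrize("na,aa", [
        ("ATGAAATAG", "MK*"),
        ("ATGNNN", "MX"),
        ("augaaa", "MK"),  # RNA input normalized
    ])
    def test_examples(self, na, aa):
        assert translate(na) == aa

    def test_length_must_be_multiple_of_three(self):
        with pytest.raises(LengthNotMultipleOfThree):
            translate("ATGA")

    def test_agrees_with_biopython_on_random_sequences(self):
        rng = random.Random(5)
        for _ in range(20):
            seq = "".join(rng.choice("ACGT") for _ in range(3 * rng.randint(5, 60)))
            expected = str(Seq(seq).translate())
            assert translate(seq) == expected


class TestMatureForms:
    def test_signal_and_chain_slices(self):
        e = ProteinEntry(accession="P1", sequence="MKKKAAAACCCC",
                         features=[Feature("SIGNAL", 1, 4),
                                   Feature("CHAIN", 5, 12)])
        forms = extract_mature_forms(e, min_len=1)
        assert [(m.name, m.sequence) for m in forms] == [
            ("P1|SIGNAL|1-4", "MKKK"), ("P1|CHAIN|5-12", "AAAACCCC")]

    def test_init_met_removed(self):
        e = ProteinEntry(accession="P2", sequence="MABC",
                         features=[Feature("INIT_MET", 1, 1)])
        (m,) = extract_mature_forms(e, min_len=1)
        assert (m.form_kind, m.start, m.end, m.sequence) == \
            ("INIT_MET_REMOVED", 2, 4, "ABC")

    def test_no_features_no_forms(self):
        e = ProteinEntry(accession="P3", sequence="MKT")
        assert extract_mature_forms(e) == []

    def test_min_len_drops_short_forms(self):
        e = ProteinEntry(accession="P4", sequence="MKKKAAAACCCC",
                         features=[Feature("SIGNAL", 1, 4),
                                   Feature("CHAIN", 5, 12)])
        forms = extract_mature_forms(e, min_len=5)
        assert [m.form_kind for m in forms] == ["CHAIN"]

    def test_every_form_is_exact_substring_at_range(self, entries20):
        for e in entries20:
            for m in extract_mature_forms(e, min_len=1):
                assert m.sequence == e.sequence[m.start - 1:m.end]


class TestLinearSorfs:
    def test_simple_orf(self):
        (r,) = find_sorfs_linear("tx1", "ATGAAATAG", {"ATG"}, min_pep=1)
        assert (r.frame, r.peptide, r.orf_start, r.orf_end_linearized,
                r.terminated) == (1, "MK", 1, 9, True)
        assert r.junction_crossings == 0

    def test_frame_shift(self):
        (r,) = find_sorfs_linear("tx1", "CATGAAATAGC", {"ATG"}, min_pep=1)
        assert (r.frame, r.peptide, r.orf_start, r.orf_end_linearized) == \
            (2, "MK", 2, 10)

    def test_orf_length_arithmetic(self, transcripts50):
        for tid, seq in transcripts50:
            for r in find_sorfs_linear(tid, seq, {"ATG"}, 1, None,
                                       strands="both"):
                if r.terminated:
                    assert 3 * len(r.peptide) + 3 == \
                        r.orf_end_linearized - r.orf_start + 1

    @pytest.mark.parametrize("starts", [
        {"ATG"}, {"ATG", "CTG", "GTG", "TTG", "ACG"}])
    @pytest.mark.parametrize("strands", ["forward", "both"])
    def test_matches_bruteforce_oracle(self, transcripts50, starts, strands):
        for tid, seq in transcripts50:
            got = {(0 if r.frame <= 3 else 1, r.orf_start,
                    r.orf_end_linearized, r.peptide)
                   for r in find_sorfs_linear(tid, seq, starts, 1, 10**9,
                                              strands=strands)}
            assert got == oracle_linear(seq, starts, 1, 10**9, strands)

    def test_longest_only_keeps_5prime_most(self):
        # two ATGs sharing one stop
        seq = "ATGATGAAATAG"
        rs = find_sorfs_linear("t", seq, {"ATG"}, 1)
        assert len(rs) == 2
        (r,) = find_sorfs_linear("t", seq, {"ATG"}, 1, longest_only=True)
        assert r.orf_start == 1

    def test_runoff_orfs_only_without_require_stop(self):
        seq = "ATGAAAAAA"  # no stop
        assert find_sorfs_linear("t", seq, {"ATG"}, 1) == []
        (r,) = find_sorfs_linear("t", seq, {"ATG"}, 1, require_stop=False)
        assert r.peptide == "MKK" and not r.terminated


class TestCircularSorfs:
    def test_rolling_circle_example(self):
        """L=10 circle: stop reached on the third pass, two junction
        crossings; cross-checked against the unrolled 3-copy sequence."""
        seq = "ATGAAAAAAA"
        (r,) = find_sorfs_circular("tx2", seq, {"ATG"}, min_pep=1, max_pep=None)
        assert r.peptide == "MKKNEKK" and r.junction_crossings == 2
        assert r.terminated and r.orf_end_linearized == 24
        unrolled = seq * 3
        assert unrolled[21:24] in STOPS
        assert str(Seq(unrolled[0:21]).translate()) == r.peptide

    def test_no_wrap_when_length_divisible_by_three(self):
        (r,) = find_sorfs_circular("t", "ATGTAA", {"ATG"}, min_pep=1)
        assert r.peptide == "M" and r.junction_crossings == 0

    def test_no_stop_translates_three_wraps(self):
        # L=10 (not divisible by 3); the only T sits inside ATG and the codon
        # it starts (TGC) is not a stop, so no frame ever terminates
        seq = "ATGCCCCCCC"
        rs = find_sorfs_circular("t", seq, {"ATG"}, min_pep=1, max_pep=None)
        (r,) = [x for x in rs if r_start(x) == 1]
        assert not r.terminated and len(r.peptide) == len(seq)

    def test_rotation_invariance_of_peptide_multiset(self):
        rng = random.Random(9)
        for _ in range(20):
            L = rng.randint(20, 90)
            seq = "".join(rng.choice("ACGT") for _ in range(L))
            k = rng.randrange(1, L)
            rot = seq[k:] + seq[:k]
            peps = lambda s: sorted(r.peptide for r in find_sorfs_circular(
                "t", s, {"ATG"}, min_pep=1, max_pep=None))
            assert peps(seq) == peps(rot)

    def test_junction_crossings_at_most_one_when_divisible_no_stop(self):
        rng = random.Random(13)
        for _ in range(30):
            L = rng.choice([21, 30, 45])
            seq = "".join(rng.choice("AC") for _ in range(L))  # no stop possible
            for r in find_sorfs_circular("t", "ATG" + seq[3:], {"ATG"},
                                         min_pep=1, max_pep=None):
                if not r.terminated:
                    assert r.junction_crossings <= 1


def r_start(r):
    return r.orf_start


class TestNaming:
    def test_linear_name(self):
        (r,) = find_sorfs_linear("tx1", "ATGAAATAG", {"ATG"}, min_pep=1)
        assert sorf_name(r) == "tx1|F1|ATG|lin|1-9"

    def test_circular_name_with_junctions(self):
        (r,) = find_sorfs_circular("tx2", "ATGAAAAAAA", {"ATG"}, min_pep=1,
                                   max_pep=None)
        assert sorf_name(r) == "tx2|F1|ATG|cir|1-24|J2"

    def test_collision_suffix(self):
        (r,) = find_sorfs_linear("tx1", "ATGAAATAG", {"ATG"}, min_pep=1)
        namer = SorfNamer()
        assert namer(r) == "tx1|F1|ATG|lin|1-9"
        assert namer(r) == "tx1|F1|ATG|lin|1-9_2"
        assert namer(r) == "tx1|F1|ATG|lin|1-9_3"
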