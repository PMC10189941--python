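"""FASTA-generating computation: decoys, mature proteoforms, sORF prediction.

* Reversed decoy databases for FDR estimation (full character reversal,
  tagged accessions, optional target+decoy concatenation).
* Mature-form extraction from proteoform features: annotated chains, signal /
  transit / propeptides, and the initiator-methionine-removed form, each with
  a composed name ``<accession>|<KIND>|<start>-<end>``.
* Small-ORF / SEP prediction on linear and circular transcripts.  On a circle
  translation proceeds with the nucleotide index modulo L; the reading frame
  returns to its starting phase after one traversal when 3 | L and after
  three traversals otherwise, which bounds the scan.  Each ORF records how
  often the read crossed the back-splice junction (the L -> 1 boundary),
  a quantity proteomics pipelines use to recognize rolling-circle products.

Translation uses the NCBI genetic-code tables (table 1 by default); codons
containing N translate to 'X'.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Iterator

from Bio.Data import CodonTable

from .core import Feature, ProteinEntry, validate_sequence
from .errors import (FeatureOutOfRange, LengthNotMultipleOfThree,
                     TagCollision, UsageError)

log = logging.getLogger(__name__)

START_CODON_PRESETS = {
    "canonical": {"ATG"},
    "near-cognate": {"ATG", "CTG", "GTG", "TTG", "ACG"},
}

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(na_seq: str) -> str:
    return na_seq.translate(_COMPLEMENT)[::-1]


# --- decoys ------------------------------------------------------------------

def make_decoys(entries: Iterable[ProteinEntry], tag: str = "rev_",
                mode: str = "decoy_only") -> Iterator[ProteinEntry]:
    """Reversed-sequence decoys for false-discovery-rate estimation.

    Each decoy is the full character reversal of its target with accession
    ``tag + original``; no features are carried over.  ``concat`` mode yields
    the unchanged targets first, then their decoys.
    """
    if not tag:
        raise UsageError("decoy tag must be non-empty")
    if mode not in ("decoy_only", "concat"):
        raise UsageError(f"bad decoy mode {mode!r}")
    entries = list(entries)
    for e in entries:
        if e.accession.startswith(tag):
            raise TagCollision(
                f"target accession {e.accession} already starts with {tag!r}")
    if mode == "concat":
        yield from entries
    for e in entries:
        yield ProteinEntry(
            accession=tag + e.accession,
            sequence=e.sequence[::-1],
            prefix=e.prefix,
            description=f"decoy of {e.accession}",
        )


# --- translation -------------------------------------------------------------

def _code_table(table_id: int) -> tuple[dict[str, str], set[str]]:
    t = CodonTable.unambiguous_dna_by_id[table_id]
    return t.forward_table, set(t.stop_codons)


def translate(na_seq: str, table_id: int = 1) -> str:
    """Translate a DNA sequence (length divisible by 3): stop codons become
    '*', codons containing N become 'X'."""
    seq = validate_sequence(na_seq, "NA")
    if len(seq) % 3:
        raise LengthNotMultipleOfThree(f"length {len(seq)}")
    forward, stops = _code_table(table_id)
    out = []
    for i in range(0, len(seq), 3):
        codon = seq[i:i + 3]
        if codon in stops:
            out.append("*")
        elif "N" in codon:
            out.append("X")
        else:
            out.append(forward[codon])
    return "".join(out)


# --- mature forms ------------------------------------------------------------

FORM_KINDS = ("SIGNAL", "CHAIN", "PROPEP", "TRANSIT", "INIT_MET_REMOVED")


@dataclass
class MatureForm:
    """One post-processing proteoform slice of a precursor."""

    source_accession: str
    form_kind: str
    start: int   # 1-based inclusive
    end: int
    sequence: str

    @property
    def name(self) -> str:
        """Composed identifier: source id | polypeptide kind | range."""
        return f"{self.source_accession}|{self.form_kind}|{self.start}-{self.end}"

    def to_entry(self) -> ProteinEntry:
        return ProteinEntry(accession=self.name, sequence=self.sequence,
                            description=f"mature form of {self.source_accession}")


def extract_mature_forms(entry: ProteinEntry,
                         kinds: Iterable[str] | None = None,
                         min_len: int = 1) -> list[MatureForm]:
    """Slice one mature form per matching feature.

    SIGNAL/CHAIN/PROPEP/TRANSIT features yield their annotated range;
    INIT_MET features yield the sequence with the leading methionine removed
    (range 2..L, kind INIT_MET_REMOVED).  Forms shorter than ``min_len``
    residues are dropped.
    """
    wanted = set(kinds) if kinds is not None else set(FORM_KINDS)
    bad = wanted - set(FORM_KINDS)
    if bad:
        raise UsageError(f"unknown mature-form kinds: {sorted(bad)}")
    L = len(entry.sequence)
    forms: list[MatureForm] = []
    for f in entry.features:
        if f.end > L:
            raise FeatureOutOfRange(
                f"{entry.accession}: {f.kind} {f.start}..{f.end} beyond length {L}")
        if f.kind in ("SIGNAL", "CHAIN", "PROPEP", "TRANSIT") and f.kind in wanted:
            forms.append(MatureForm(entry.accession, f.kind, f.start, f.end,
                                    entry.sequence[f.start - 1:f.end]))
        elif f.kind == "INIT_MET" and "INIT_MET_REMOVED" in wanted and L >= 2:
            forms.append(MatureForm(entry.accession, "INIT_MET_REMOVED", 2, L,
                                    entry.sequence[1:]))
    return [m for m in forms if len(m.sequence) >= min_len]


# --- sORF / SEP prediction ---------------------------------------------------

@dataclass
class SorfRecord:
    """One predicted small ORF.

    ``orf_start`` is 1-based on the given strand; ``orf_end_linearized`` is
    the 1-based coordinate on the unrolled sequence (it exceeds the transcript
    length when a circular ORF wraps).  ``frame`` is 1..3 forward, 4..6
    reverse.  ``junction_crossings`` counts passes of the circular L -> 1
    boundary from start codon through stop codon inclusive (0 for linear).
    """

    transcript_id: str
    frame: int
    start_codon: str
    topology: str            # linear | circular
    orf_start: int
    orf_end_linearized: int
    peptide: str
    junction_crossings: int = 0
    terminated: bool = True


def find_sorfs_linear(transcript_id: str, na_seq: str,
                      start_codons: Iterable[str] = ("ATG",),
                      min_pep: int = 7, max_pep: int | None = 100,
                      strands: str = "forward",
                      require_stop: bool = True,
                      longest_only: bool = False,
                      table_id: int = 1) -> list[SorfRecord]:
    """Scan a linear transcript for small ORFs.

    Every in-frame occurrence of a start codon is extended codon-by-codon to
    the first stop; nested starts sharing a stop are each reported unless
    ``longest_only`` collapses them to the 5'-most.  With
    ``require_stop=False`` run-off ORFs at the sequence end are also emitted
    (``terminated=False``).
    """
    seq = validate_sequence(na_seq, "NA")
    if len(seq) < 3:
        raise UsageError("transcript shorter than one codon")
    if strands not in ("forward", "both"):
        raise UsageError(f"bad strands {strands!r}")
    starts = {validate_sequence(c, "NA") for c in start_codons}
    forward, stops = _code_table(table_id)
    records: list[SorfRecord] = []
    strand_seqs = [(seq, 0)]
    if strands == "both":
        strand_seqs.append((reverse_complement(seq), 3))

    for sseq, frame_offset in strand_seqs:
        L = len(sseq)
        for pos in range(L - 2):  # 0-based start of candidate codon
            if sseq[pos:pos + 3] not in starts:
                continue
            pep, terminated = [], False
            i = pos
            while i + 3 <= L:
                codon = sseq[i:i + 3]
                if codon in stops:
                    terminated = True
                    break
                pep.append("X" if "N" in codon else forward.get(codon, "X"))
                i += 3
            if not terminated and require_stop:
                continue
            n = len(pep)
            if n < min_pep or (max_pep is not None and n > max_pep) or n == 0:
                continue
            end = pos + 3 * n + (3 if terminated else 0)
            records.append(SorfRecord(
                transcript_id=transcript_id,
                frame=frame_offset + (pos % 3) + 1,
                start_codon=sseq[pos:pos + 3],
                topology="linear",
                orf_start=pos + 1,
                orf_end_linearized=end,
                peptide="".join(pep),
                terminated=terminated,
            ))
    if longest_only:
        records = _collapse_nested(records)
    return records


def _collapse_nested(records: list[SorfRecord]) -> list[SorfRecord]:
    """Keep the 5'-most start per (frame, stop position)."""
    best: dict[tuple, SorfRecord] = {}
    for r in records:
        key = (r.frame, r.orf_end_linearized, r.topology)
        if key not in best or r.orf_start < best[key].orf_start:
            best[key] = r
    return sorted(best.values(), key=lambda r: (r.frame, r.orf_start))


def find_sorfs_circular(transcript_id: str, na_seq: str,
                        start_codons: Iterable[str] = ("ATG",),
                        min_pep: int = 7, max_pep: int | None = 100,
                        table_id: int = 1) -> list[SorfRecord]:
    """Scan a circular transcript (forward strand) for small ORFs.

    Candidate starts sit at every position 1..L; translation reads codons
    with the nucleotide index modulo L and stops at the first stop codon or
    when the read head returns to the start position in the same phase —
    after L/3 codons when 3 | L, after L codons (three traversals) otherwise.
    Non-terminating ORFs are reported with ``terminated=False`` and the
    peptide truncated at cycle closure.
    """
    seq = validate_sequence(na_seq, "NA")
    L = len(seq)
    if L < 3:
        raise UsageError("transcript shorter than one codon")
    starts = {validate_sequence(c, "NA") for c in start_codons}
    forward, stops = _code_table(table_id)
    max_codons = L // 3 if L % 3 == 0 else L

    def codon_at(p0: int) -> str:  # p0 is 0-based
        return seq[p0 % L] + seq[(p0 + 1) % L] + seq[(p0 + 2) % L]

    records: list[SorfRecord] = []
    for pos in range(L):
        if codon_at(pos) not in starts:
            continue
        pep, terminated = [], False
        k = 0
        while k < max_codons:
            codon = codon_at(pos + 3 * k)
            if codon in stops:
                terminated = True
                break
            pep.append("X" if "N" in codon else forward.get(codon, "X"))
            k += 1
        n = len(pep)
        if n < min_pep or (max_pep is not None and n > max_pep) or n == 0:
            continue
        end = pos + 3 * n + (3 if terminated else 0)  # 1-based linearized end
        records.append(SorfRecord(
            transcript_id=transcript_id,
            frame=(pos % 3) + 1,
            start_codon=codon_at(pos),
            topology="circular",
            orf_start=pos + 1,
            orf_end_linearized=end,
            peptide="".join(pep),
            junction_crossings=(end - 1) // L,
            terminated=terminated,
        ))
    return records


class SorfNamer:
    """Compose unique sORF names; identical names get _2, _3 ... suffixes."""

    def __init__(self) -> None:
        self._seen: dict[str, int] = {}

    def __call__(self, r: SorfRecord) -> str:
        base = (f"{r.transcript_id}|F{r.frame}|{r.start_codon}|"
                f"{'cir' if r.topology == 'circular' else 'lin'}|"
                f"{r.orf_start}-{r.orf_end_linearized}")
        if r.topology == "circular":
            base += f"|J{r.junction_crossings}"
        count = self._seen.get(base, 0) + 1
        self._seen[base] = count
        return base if count == 1 else f"{base}_{count}"


def sorf_name(r: SorfRecord) -> str:
    """Name one record in isolation (no collision bookkeeping)."""
    return SorfNamer()(r)


def sorfs_to_entries(records: Iterable[SorfRecord]) -> list[ProteinEntry]:
    namer = SorfNamer()
    out = []
    for r in records:
        desc = f"SEP from {r.topology} transcript {r.transcript_id}"
        if not r.terminated:
            desc += " (no stop codon)"
        out.append(ProteinEntry(accession=namer(r), sequence=r.peptide,
                                description=desc))
    return out
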