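# seqdbkit

A proteoform-aware protein sequence database toolkit for shotgun proteomics.

Search databases built from plain FASTA carry only full-length reference
sequences, while real samples contain *proteoforms*: chains with the signal
or transit peptide cleaved off, the initiator methionine removed, point
variants, and modified residues. The PSI extended FASTA format (PEFF)
annotates all of this as backslash key-value pairs in the header line, but a
text file still has to be parsed front to back for every lookup. `seqdbkit`
stores the same information in two derived formats built for random access
and minimal footprint:

* **SQPD** — a single SQLite file holding a `meta` table (database identity),
  an `entries` table (accession, description, sequence, with length and
  average molecular mass precomputed and indexed) and a `features` table
  (one row per proteoform annotation, 1-based inclusive coordinates,
  PEFF-compatible controlled terms). Fetching one of 10,000 entries touches
  one indexed row instead of reparsing the whole text file.
* **SET** — a JSON manifest `{"format": "SET", "db_name", "db_version",
  "entries": [...]}` naming an ordered, duplicate-free subset of a parent
  database. It contains no sequence text, so its size is independent of
  sequence lengths; it resolves back to sequences through the parent SQPD.

Around the formats sits a library plus 18 command-line tools in five
categories:

| category   | tools |
|------------|-------|
| retrieval  | UpSpecies, UpRetrieval, NCBISpecies, NCBIRetrieval, EnsemblSpecies, EnsemblRetrieval, DbManage |
| generation | SeqDecoy (reversed decoys for FDR), MatureSeq (mature proteoforms), SepFinder (sORF/SEP prediction on linear and circular RNA) |
| conversion | CheckSeq, UpConvert, SeqConvert |
| filter     | SeqFilter, TabFilter (both emit SET files) |
| analysis   | SeqAnnotate (ten physicochemical properties), MotifCount, SeqWindow |

Highlights of the science inside:

* **sORF prediction on circles.** For a circular transcript of length *L*
  the ribosome-like scan reads codons with the nucleotide index modulo *L*;
  the frame returns to its start after one traversal when 3 | *L* and after
  three otherwise. Each predicted ORF reports how often the read crossed the
  back-splice junction. Example: the 10-nt circle `ATGAAAAAAA` yields the
  7-residue peptide `MKKNEKK`, terminating at a TGA assembled on the third
  pass, with 2 junction crossings — named `tx2|F1|ATG|cir|1-24|J2`.
* **Physicochemical annotation.** pI and net charge from the
  Henderson–Hasselbalch model with the EMBOSS pKa set (bisection on the
  strictly decreasing charge curve), Pace extinction coefficients,
  Kyte–Doolittle GRAVY, Guruprasad instability, grouped residue composition.

## Worked example

```sh
# circRNA transcripts -> SEP database -> target+decoy FASTA
cat > circ.fasta <<EOF
>tx2 circ test
ATGAAAAAAA
EOF
seqdbkit SepFinder --in circ.fasta --out seps.fasta --tsv seps.tsv \
    --min-pep 1 --max-pep 0
seqdbkit SeqDecoy --in seps.fasta --out sep_td.fasta --mode concat
cat seps.fasta
```

prints

```
>tx2|F1|ATG|cir|1-24|J2 SEP (circular)
MKKNEKK
```

i.e. one sORF on transcript `tx2`, frame 1, ATG start, circular topology,
nucleotides 1–24 on the unrolled circle, crossing the junction twice; the
decoy file then holds `MKKNEKK` followed by its reversal `KKENKKM` under the
accession `rev_tx2|F1|ATG|cir|1-24|J2`. The Python API mirrors every tool
(`seqdbkit.find_sorfs_circular`, `seqdbkit.make_decoys`, ...), and
`seqdbkit --list-tools --json` dumps the full machine-readable registry.

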