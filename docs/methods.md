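# Methods

## Data model

A database is a set of `ProteinEntry` records: unique accession, source
prefix (`sp`/`tr`/`ncbi`/`ensembl`/`generic`), free-text description, an
uppercase residue sequence over the 20 standard amino acids plus the
ambiguity/rare letters B, Z, X, U, O, J, a header key-value map (OS, OX, GN,
PE, SV, entry name), and an ordered list of `Feature`s. A feature is one
proteoform annotation: a controlled kind (SIGNAL, CHAIN, PROPEP, TRANSIT,
INIT_MET, VARIANT, MOD_RES, CONFLICT), a 1-based inclusive range bounded by
the sequence length (the UniProt/PEFF convention; slicing converts to
0-based at the call site), and a payload (variant replacement residue,
modification name). Nucleotide sequences use A, C, G, T, N with U normalized
to T on input.

## Formats

**FASTA** headers are parsed by dialect grammars tried in the fixed order
uniprot → ncbi → ensembl → generic (first match wins). Writing wraps
sequences at 60 columns by default; `parse(compose(entry))` preserves
accession, prefix and meta for every dialect.

**PEFF 1.0** files open with a `#`-prefixed header block terminated by
`# //`; each entry line is `>prefix:accession` followed by backslash tags.
Values run verbatim to the next backslash; a literal backslash inside a
value is unsupported and raises an error. Positional tags map to features:
`Processed=(start|end|term)` with the terms *signal peptide*, *mature
protein*, *propeptide*, *transit peptide*, *initiator methionine*;
`VariantSimple=(pos|residue)`; `ModRes=(start|end|name)`. Two extensions
keep the feature codec invertible: non-single-residue variants are written
as `VariantComplex=(start|end|replacement)` and sequence conflicts as a
`Conflict=(start|end|payload)` tag; both are read back into the
corresponding feature kinds. All other tags (PName, SV, custom keys) pass
through the entry meta map untouched, so write∘read is the identity on
modeled fields. One file carries exactly one header block.

**SQPD** is a single SQLite 3 file with tables `meta(key, value)`,
`entries(id, prefix, accession UNIQUE, description, sequence, length, mass)`,
`features(id, entry_id, key, start, end, payload)` and an auxiliary
`entry_meta(entry_id, key, value)` for header key-values, with indices on
accession, length, mass, feature key and the foreign keys. The schema names
are this package's own design, frozen under the meta row
`schema_version=sqpd-1` so later migrations are detectable. The `mass`
column stores the average molecular mass at insert time so mass filters need
no recomputation. Batch inserts are transactional: any failure (including a
duplicate accession under the default `error` policy) rolls the whole batch
back; `skip` and `suffix` policies are available. Queries over length, mass,
feature presence and accession lists are pushed into SQL; only motif clauses
evaluate in Python, over the SQL-narrowed candidate set.

**SET** is a UTF-8 JSON object with the frozen keys `format` (the literal
`"SET"`, also the detection signature), `set_name`, `db_name`, `db_version`,
`created`, `description`, `entries`. Order is preserved (a list, not a set)
so downstream FASTA exports are deterministic; duplicates are rejected on
read. Resolution yields entries in SET order; a parent name/version mismatch
warns by default and errors under `strict_db`.

**Format detection** is a pure function of content: SQLite magic bytes →
sqpd (with a schema check reported as an issue, not a failure), `# PEFF` →
peff, leading `>` → fasta, a JSON object with the SET signature → set, all
amino-acid lines → peptide list. Recoverable problems (duplicate accessions,
illegal residues) are reported alongside the verdict.

## UniProt feature tables

UniProt TSV feature cells follow the grammar
`TOKEN start..end; /qualifier="value"; ... TOKEN ...` with single positions
as `TOKEN pos`. The mapping onto the controlled kinds (Signal peptide →
SIGNAL, Chain → CHAIN, Propeptide → PROPEP, Transit peptide → TRANSIT,
Initiator methionine → INIT_MET, Natural variant → VARIANT, Modified
residue → MOD_RES, Sequence conflict → CONFLICT) follows public PEFF 1.0
naming; it is this package's rendering, not guaranteed byte-identical to any
other tool's. Variant replacements come from `/note="X -> Y"` (payload Y).
Multi-interval cells split into separate features. Uncertain bounds
(`<`, `>`, `?`) and unknown tokens are skipped with a logged warning;
databases from sources without a table ingest featureless by default.

## sORF / SEP prediction

Linear scan: every position whose codon is in the start set (default {ATG};
preset `near-cognate` = {ATG, CTG, GTG, TTG, ACG}, common sORF practice)
extends codon-by-codon to the first stop. Nested starts sharing a stop are
each reported; `longest_only` keeps the 5′-most. `require_stop=False` also
emits run-off ORFs. Reverse-strand frames 4–6 are coordinates on the
reverse complement. Defaults min_pep 7 (shortest routinely identifiable
tryptic-scale peptide) and max_pep 100 (the usual "small" ORF bound), both
exposed.

Circular scan (forward strand by default — deposited circRNA sequences are
the mature circle): candidate starts at every position 1..L, codons read
modulo L. The read head returns to its starting phase after L/3 codons when
3 | L and after L codons (three traversals) otherwise, which bounds the
scan; non-terminating ORFs are reported with `terminated=False` and the
peptide truncated at cycle closure rather than dropped. Junction crossings
count passes of the L → 1 boundary over the nucleotide span from start
through stop codon inclusive, computed as ⌊(end_linearized − 1)/L⌋.
Consequences used as test invariants: rotation of the circle leaves the
peptide multiset unchanged, and a stop-free circle with 3 | L crosses the
junction at most once.

Names are frozen as
`<transcript>|F<frame>|<start codon>|<lin|cir>|<start>-<end_linearized>`
plus `|J<crossings>` for circles, with `_2`, `_3` suffixes on collisions.
Translation uses the NCBI genetic-code tables (table 1 default, flag for
others); codons containing N give X.

## Mature forms and decoys

Mature forms slice the annotated range per feature
(`<accession>|<KIND>|<start>-<end>`); INIT_MET additionally emits the
Met-trimmed sequence as kind INIT_MET_REMOVED over 2..L. Decoys are full
character reversals (an involution preserving length and residue multiset)
with a tag prefix on the accession, no features carried over, and an
optional target+decoy concatenation.

## Physicochemical properties

* Mass: sum of average residue masses plus one water (18.0153 Da);
  monoisotopic by flag. Residue masses come from the standard IUPAC tables.
* Charge/pI: Henderson–Hasselbalch per ionizable group. Default pKa set is
  EMBOSS (N-term 8.6, C-term 3.6, K 10.8, R 12.5, H 6.5, D 3.9, E 4.1,
  C 8.5, Y 10.1); a Bjellqvist-style set is selectable. Net charge is
  strictly decreasing in pH, so pI is found by sign bisection on [0, 14] to
  a 1e-8 pH interval, leaving |charge| < 1e-4 even on the flat mid-range
  plateau. Physiological charge is evaluated at pH 7.4 (flag).
* Extinction at 280 nm: Pace coefficients 5500·nW + 1490·nY, plus 125 per
  cystine pair (⌊nC/2⌋) for the oxidized value.
* Instability: (10/L)·Σ Guruprasad DIWV over the L−1 dipeptides; GRAVY:
  mean Kyte–Doolittle hydropathy. The hydropathy, DIWV and genetic-code
  tables are taken from Biopython's published data.
* Nonstandard residues (B, Z, X, U, O, J) are excluded from mass, charge,
  GRAVY and the instability dipeptides with a logged warning; plain
  composition still counts them, and the grouped composition places them in
  an `other` bin. Groups are aliphatic AVLIMG, aromatic FWY, polar STCNQ,
  positive KRH, negative DE, special P — a documented choice among several
  conventional groupings.

Motif patterns use amino-acid letters, `x` as wildcard and bracket classes
(`Nx[ST]`); counting is overlapping (every start position tested). Windows
around sites or peptides are always 2·flank+1 long, `-`-padded beyond the
termini; peptide queries report every occurrence, centered on the first
residue, and unlocatable peptides yield an empty window plus a warning.

## Retrieval

All network logic is deterministic given an injectable transport
`(request) -> (status, bytes)`; the default is stdlib urllib, and canned
transports replay recorded payloads for offline use (the CLI exposes
`--payload-*` flags). Endpoints are configuration with defaults, overridable
by a JSON or key=value file. Zero hits on a successful response raise
`EmptyResult`, distinct from `TransportError`. The local registry keeps
`seqdbs/<db>/<version>/{classic,next}` (text formats vs SQPD/SET);
registration stages into a temporary directory and renames atomically, so a
failed register leaves no partial version.

## Synthetic data

The fixture generator emulates the shapes of real inputs: UniProt-dialect
FASTA with OS/OX/GN/PE/SV tags, a UniProt-style TSV feature table whose
cells follow the grammar above, and random transcripts. Defaults: proteins
of 30–240 residues with uniform residue usage, ~70 % of entries carrying a
consistent mix of SIGNAL/CHAIN/PROPEP/INIT_MET/VARIANT/MOD_RES/CONFLICT
features; transcripts of 30–600 nt with uniform base usage. Real proteomes
are longer, biased in composition and richer in annotation, so passing
tests demonstrate format and algorithm correctness, not biological realism.
All generators are seeded and deterministic.

## Verification sizes and numerical choices

The shipped checks use a 200-entry featured proteome for the
FASTA→SQPD→PEFF→SQPD round-trip, 50 transcripts × 2 start sets for the
linear ORF oracle, 20 random circles for rotation invariance, 100 random
filter specifications against a brute-force evaluator, and a 10,000-entry
database (30–80 residue sequences) for the indexed-lookup vs text-reparse
ordering — sizes at which every check completes in seconds while exercising
all code paths. Closed-form anchors: pI(GG) = (3.6+8.6)/2 = 6.1,
ext(WY) = 6990 M⁻¹cm⁻¹, GRAVY(AG) = 0.7, aromaticity(FWYA) = 0.75,
instability(GG) = 5·DIWV(G,G) = 66.7.

## Limitations

Multi-residue variant semantics beyond (start, end, replacement) are not
modeled (no insertion/deletion algebra); PEFF CRC64 tags pass through
unverified; gzip inputs are not transparently decompressed; filters combine
by conjunction only; live endpoint correctness is not asserted (interfaces
are exercised against canned payloads); the circular scanner does not score
start-codon context (no Kozak model) or integrate ribosome profiling
evidence.
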