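"""Domain types and FASTA header grammars.

The foundation layer shared by every other module: the :class:`ProteinEntry`
record (one database entry), :class:`Feature` (one proteoform annotation with
1-based inclusive coordinates, the UniProt/PEFF convention), and
:class:`DatabaseMeta` (database identity), plus parsing and composition of the
FASTA header dialects of UniProt, NCBI, Ensembl and generic files.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from datetime import datetime, timezone

from .errors import EmptySequence, IllegalCharacter, MalformedHeader

# 20 standard residues plus ambiguity/rare letters B, Z, X, U, O, J
AA_STANDARD = set("ACDEFGHIKLMNPQRSTVWY")
AA_EXTENDED = AA_STANDARD | set("BZXUOJ")
NA_ALPHABET = set("ACGTN")

FEATURE_KINDS = (
    "SIGNAL", "CHAIN", "PROPEP", "TRANSIT",
    "INIT_MET", "VARIANT", "MOD_RES", "CONFLICT",
)


@dataclass
class Feature:
    """One proteoform annotation: kind + 1-based inclusive range + payload.

    ``payload`` carries the variant replacement residue(s) or the modification
    name; ``source_key`` remembers the key in the source annotation (UniProt
    column or PEFF tag) the feature was decoded from.
    """

    kind: str
    start: int
    end: int
    payload: str = ""
    source_key: str = ""

    def __post_init__(self) -> None:
        if self.kind not in FEATURE_KINDS:
            raise ValueError(f"unknown feature kind {self.kind!r}")
        if not (1 <= self.start <= self.end):
            raise ValueError(f"bad feature range {self.start}..{self.end}")

    def triple(self) -> tuple:
        """(kind, start, end, payload) — the identity used by round-trip checks."""
        return (self.kind, self.start, self.end, self.payload)


@dataclass
class ProteinEntry:
    """One database record: accession, header metadata, sequence, features."""

    accession: str
    sequence: str
    prefix: str = "generic"
    description: str = ""
    features: list[Feature] = field(default_factory=list)
    meta: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.accession:
            raise ValueError("accession must be non-empty")
        if not self.sequence or not re.fullmatch(r"[A-Z]+", self.sequence):
            raise ValueError("sequence must match [A-Z]+")
        for f in self.features:
            if f.end > len(self.sequence):
                raise ValueError(
                    f"feature {f.kind} {f.start}..{f.end} exceeds sequence "
                    f"length {len(self.sequence)} for {self.accession}"
                )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class DatabaseMeta:
    """Database identity: name, version, source, sequence type, entry count."""

    db_name: str
    db_version: str = "1"
    db_source: str = "custom"       # uniprot | ncbi | ensembl | custom
    sequence_type: str = "AA"       # AA | NA
    n_entries: int = 0
    created: str = ""
    extra: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.created:
            self.created = datetime.now(timezone.utc).strftime("%Y-%m-%dT%H:%M:%SZ")


def validate_sequence(seq: str, alphabet: str = "AA") -> str:
    """Normalize and validate a residue string.

    Uppercases, strips all whitespace, and checks every character against the
    chosen alphabet: amino acids (20 standard + B,Z,X,U,O,J) or nucleotides
    (A,C,G,T,N with U normalized to T). Idempotent. Raises
    :class:`EmptySequence` or :class:`IllegalCharacter` (with the 1-based
    position of the first offender).
    """
    s = "".join(seq.split()).upper()
    if not s:
        raise EmptySequence("sequence is empty")
    if alphabet == "NA":
        s = s.replace("U", "T")
        allowed = NA_ALPHABET
    elif alphabet == "AA":
        allowed = AA_EXTENDED
    else:
        raise ValueError(f"unknown alphabet {alphabet!r}")
    for i, c in enumerate(s, start=1):
        if c not in allowed:
            raise IllegalCharacter(c, i)
    return s


# --- header grammars ---------------------------------------------------------

_UNIPROT_RE = re.compile(r"^>(sp|tr)\|([^|\s]+)\|(\S+)(?:\s+(.*))?$")
_NCBI_RE = re.compile(r"^>(\S+\.\d+)(?:\s+(.*))?$")
_ENSEMBL_RE = re.compile(r"^>(ENS[A-Z]*[PGT]\d+(?:\.\d+)?)(?:\s+(.*))?$")
# UniProt description tags, e.g. "OS=Mus musculus OX=10090 GN=Tst PE=1 SV=2"
_TAG_RE = re.compile(r"\s*([A-Z]{2})=(.*?)(?=\s+[A-Z]{2}=|$)")
_UNIPROT_META_KEYS = ("OS", "OX", "GN", "PE", "SV")


def _split_uniprot_description(text: str) -> tuple[str, dict[str, str]]:
    m = re.search(r"\s*[A-Z]{2}=", text)
    if not m:
        return text.strip(), {}
    desc = text[: m.start()].strip()
    meta = {k: v.strip() for k, v in _TAG_RE.findall(text[m.start():])
            if k in _UNIPROT_META_KEYS}
    return desc, meta


def parse_header(line: str, dialect: str = "auto") -> tuple[str, str, str, dict[str, str]]:
    """Parse a FASTA header line into (prefix, accession, description, meta).

    Dialects: ``uniprot`` (``>sp|ACC|NAME desc OS=... GN=...``), ``ncbi``
    (``>ACC.V desc``), ``ensembl`` (``>ENSP... desc``), ``generic`` (first
    whitespace-delimited token is the accession), or ``auto`` which tries them
    in that order and takes the first grammar that matches.
    """
    if not line.startswith(">"):
        raise MalformedHeader("header must start with '>'")
    if line.strip() == ">":
        raise MalformedHeader("empty header line")
    line = line.rstrip()

    if dialect == "auto":
        for d in ("uniprot", "ncbi", "ensembl"):
            try:
                return parse_header(line, d)
            except MalformedHeader:
                continue
        return parse_header(line, "generic")

    if dialect == "uniprot":
        m = _UNIPROT_RE.match(line)
        if not m:
            raise MalformedHeader(f"not a UniProt header: {line[:60]!r}")
        prefix, acc, entry_name, rest = m.group(1), m.group(2), m.group(3), m.group(4) or ""
        desc, meta = _split_uniprot_description(rest)
        meta["entry_name"] = entry_name
        return prefix, acc, desc, meta
    if dialect == "ncbi":
        m = _NCBI_RE.match(line)
        if not m or "|" in m.group(1):
            raise MalformedHeader(f"not an NCBI header: {line[:60]!r}")
        return "ncbi", m.group(1), (m.group(2) or "").strip(), {}
    if dialect == "ensembl":
        m = _ENSEMBL_RE.match(line)
        if not m:
            raise MalformedHeader(f"not an Ensembl header: {line[:60]!r}")
        return "ensembl", m.group(1), (m.group(2) or "").strip(), {}
    if dialect == "generic":
        body = line[1:].strip()
        if not body:
            raise MalformedHeader("empty header line")
        parts = body.split(None, 1)
        return "generic", parts[0], parts[1].strip() if len(parts) > 1 else "", {}
    raise ValueError(f"unknown dialect {dialect!r}")


def compose_header(entry: ProteinEntry, dialect: str = "generic") -> str:
    """Compose a FASTA header such that :func:`parse_header` round-trips the
    accession, prefix and meta fields."""
    if dialect == "uniprot":
        prefix = entry.prefix if entry.prefix in ("sp", "tr") else "sp"
        name = entry.meta.get("entry_name", f"{entry.accession}_UNK")
        parts = [f">{prefix}|{entry.accession}|{name}"]
        if entry.description:
            parts.append(entry.description)
        for key in _UNIPROT_META_KEYS:
            if key in entry.meta:
                parts.append(f"{key}={entry.meta[key]}")
        return " ".join(parts)
    if dialect == "generic":
        return f">{entry.accession} {entry.description}".rstrip()
    raise ValueError(f"unsupported compose dialect {dialect!r}")


def entry_from_header(line: str, sequence: str, dialect: str = "auto") -> ProteinEntry:
    """Build a ProteinEntry from a raw header line and sequence."""
    prefix, acc, desc, meta = parse_header(line, dialect)
    return ProteinEntry(accession=acc, sequence=sequence, prefix=prefix,
                        description=desc, meta=meta)
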