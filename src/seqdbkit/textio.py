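"""FASTA and PEFF 1.0 readers/writers, PEFF tag grammar, format detection.

PEFF is FASTA extended with structured header annotations: after the
``>prefix:accession`` token, a header carries backslash key-value tags such as
``\\PName=Thy protein`` (scalar) or ``\\VariantSimple=(3|A)(5|T)`` (positional
tuples).  A PEFF file opens with a ``#``-prefixed header block terminated by
``# //`` whose ``# Key=Value`` lines describe the sequence database.

Format detection (the CheckSeq core) is a pure function of file content:
SQLite magic bytes -> sqpd, ``# PEFF`` magic -> peff, leading ``>`` -> fasta,
a JSON object carrying the SET signature -> set, all-amino-acid lines ->
peptide_list.
"""

from __future__ import annotations

import json
import re
import sqlite3
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator

from .core import (AA_EXTENDED, DatabaseMeta, Feature, ProteinEntry,
                   entry_from_header)
from .errors import (EmptyRecord, EmptySequence, FileUnreadable, MalformedTag,
                     NotFasta, NotPeff)

# PEFF tags that encode Features; everything else passes through entry.meta
PROCESSED_TERMS = {
    "SIGNAL": "signal peptide",
    "CHAIN": "mature protein",
    "PROPEP": "propeptide",
    "TRANSIT": "transit peptide",
    "INIT_MET": "initiator methionine",
}
TERM_TO_KIND = {v: k for k, v in PROCESSED_TERMS.items()}


# --- FASTA -------------------------------------------------------------------

def read_fasta(path, dialect: str = "auto") -> Iterator[ProteinEntry]:
    """Stream ProteinEntry records from a FASTA file.

    Tolerates CRLF line endings, blank lines and trailing whitespace. Raises
    :class:`NotFasta` if the first non-blank character is not ``>`` and
    :class:`EmptyRecord` for a header with no sequence lines.
    """
    header = None
    chunks: list[str] = []
    seen_any = False
    with open(path, encoding="utf-8") as fh:
        for raw in fh:
            line = raw.rstrip("\r\n").rstrip()
            if not line:
                continue
            if line.startswith(">"):
                if not seen_any:
                    seen_any = True
                if header is not None:
                    yield _finish_record(header, chunks, dialect)
                header, chunks = line, []
            else:
                if not seen_any:
                    raise NotFasta(f"{path}: first non-blank character is not '>'")
                chunks.append("".join(line.split()))
    if header is not None:
        yield _finish_record(header, chunks, dialect)
    elif not seen_any:
        raise NotFasta(f"{path}: no records found")


def _finish_record(header: str, chunks: list[str], dialect: str) -> ProteinEntry:
    seq = "".join(chunks).upper()
    if not seq:
        raise EmptyRecord(f"header {header[:40]!r} has no sequence")
    return entry_from_header(header, seq, dialect)


def write_fasta(entries: Iterable[ProteinEntry], path, wrap: int = 60,
                dialect: str | None = None) -> int:
    """Write entries as FASTA, wrapping sequences at ``wrap`` columns
    (0 = single line). Headers are composed per-entry: UniProt-style for
    sp/tr-prefixed entries, generic otherwise (or force via ``dialect``)."""
    from .core import compose_header
    n = 0
    with open(path, "w", encoding="utf-8") as fh:
        for e in entries:
            d = dialect or ("uniprot" if e.prefix in ("sp", "tr") else "generic")
            fh.write(compose_header(e, d) + "\n")
            fh.write(_wrap_seq(e.sequence, wrap))
            n += 1
    return n


def _wrap_seq(seq: str, wrap: int) -> str:
    if wrap <= 0:
        return seq + "\n"
    return "\n".join(seq[i:i + wrap] for i in range(0, len(seq), wrap)) + "\n"


# --- PEFF tag grammar --------------------------------------------------------

@dataclass
class PeffTag:
    """One backslash key-value tag. ``values`` is a list of tuples; scalar
    tags hold exactly one single-element tuple, positional tags one tuple per
    parenthesized group with the pipe-separated elements split out."""

    key: str
    values: list[list[str]]


_GROUP_RE = re.compile(r"\(([^()]*)\)")


def parse_peff_tags(remainder: str) -> list[PeffTag]:
    """Parse everything after ``>prefix:accession`` into PeffTags.

    Values run verbatim up to the next unescaped ``\\`` (literal backslashes
    inside values are not supported and raise :class:`MalformedTag`).
    """
    remainder = remainder.strip()
    if not remainder:
        return []
    if not remainder.startswith("\\"):
        raise MalformedTag(f"tags must start with '\\': {remainder[:40]!r}")
    tags: list[PeffTag] = []
    for segment in remainder.split("\\"):
        segment = segment.strip()
        if not segment:
            continue
        key, eq, value = segment.partition("=")
        key = key.strip()
        if not eq or not key:
            raise MalformedTag(f"missing key or '=' in segment {segment[:40]!r}")
        value = value.strip()
        if value.startswith("("):
            if value.count("(") != value.count(")") or not value.endswith(")"):
                raise MalformedTag(f"unbalanced parenthesis in {segment[:60]!r}")
            groups = _GROUP_RE.findall(value)
            leftover = _GROUP_RE.sub("", value).strip()
            if leftover:
                raise MalformedTag(f"stray text {leftover!r} in {segment[:60]!r}")
            tags.append(PeffTag(key, [g.split("|") for g in groups]))
        else:
            tags.append(PeffTag(key, [[value]]))
    return tags


def format_peff_tags(tags: Iterable[PeffTag]) -> str:
    """Inverse of :func:`parse_peff_tags` (canonical single-space form)."""
    parts = []
    for t in tags:
        if len(t.values) == 1 and len(t.values[0]) == 1 and not _needs_tuple(t):
            parts.append(f"\\{t.key}={t.values[0][0]}")
        else:
            body = "".join("(" + "|".join(tup) + ")" for tup in t.values)
            parts.append(f"\\{t.key}={body}")
    return " ".join(parts)


_TUPLE_KEYS = {"VariantSimple", "VariantComplex", "ModRes", "ModResPsi",
               "Processed", "Conflict"}


def _needs_tuple(tag: PeffTag) -> bool:
    return tag.key in _TUPLE_KEYS


# --- Feature <-> PEFF tag codec ----------------------------------------------

def features_to_tags(features: Iterable[Feature]) -> list[PeffTag]:
    """Encode Features as PEFF positional tags.

    Processing features become ``Processed`` tuples (start|end|term); simple
    single-residue variants become ``VariantSimple`` (pos|residue); modified
    residues become ``ModRes`` (pos|pos|name). Non-simple variants are written
    as ``VariantComplex`` (start|end|replacement) and sequence conflicts as a
    ``Conflict`` extension tag so that the inverse recovers every feature.
    """
    processed, vsimple, vcomplex, modres, conflict = [], [], [], [], []
    for f in features:
        if f.kind in PROCESSED_TERMS:
            processed.append([str(f.start), str(f.end), PROCESSED_TERMS[f.kind]])
        elif f.kind == "VARIANT":
            if f.start == f.end and len(f.payload) == 1:
                vsimple.append([str(f.start), f.payload])
            else:
                vcomplex.append([str(f.start), str(f.end), f.payload])
        elif f.kind == "MOD_RES":
            modres.append([str(f.start), str(f.end), f.payload])
        elif f.kind == "CONFLICT":
            conflict.append([str(f.start), str(f.end), f.payload])
    out = []
    if processed:
        out.append(PeffTag("Processed", processed))
    if vsimple:
        out.append(PeffTag("VariantSimple", vsimple))
    if vcomplex:
        out.append(PeffTag("VariantComplex", vcomplex))
    if modres:
        out.append(PeffTag("ModRes", modres))
    if conflict:
        out.append(PeffTag("Conflict", conflict))
    return out


def tags_to_features(tags: Iterable[PeffTag]) -> tuple[list[Feature], list[PeffTag]]:
    """Decode Feature-bearing tags; returns (features, passthrough tags)."""
    feats: list[Feature] = []
    passthrough: list[PeffTag] = []
    for t in tags:
        if t.key == "Processed":
            for tup in t.values:
                if len(tup) != 3:
                    raise MalformedTag(f"Processed tuple needs 3 fields: {tup}")
                kind = TERM_TO_KIND.get(tup[2])
                if kind is None:
                    passthrough.append(PeffTag("Processed", [tup]))
                    continue
                feats.append(Feature(kind, int(tup[0]), int(tup[1]), source_key=t.key))
        elif t.key == "VariantSimple":
            for tup in t.values:
                if len(tup) != 2:
                    raise MalformedTag(f"VariantSimple tuple needs 2 fields: {tup}")
                pos = int(tup[0])
                feats.append(Feature("VARIANT", pos, pos, tup[1], source_key=t.key))
        elif t.key == "VariantComplex":
            for tup in t.values:
                feats.append(Feature("VARIANT", int(tup[0]), int(tup[1]),
                                     tup[2] if len(tup) > 2 else "", source_key=t.key))
        elif t.key == "ModRes":
            for tup in t.values:
                if len(tup) != 3:
                    raise MalformedTag(f"ModRes tuple needs 3 fields: {tup}")
                feats.append(Feature("MOD_RES", int(tup[0]), int(tup[1]), tup[2],
                                     source_key=t.key))
        elif t.key == "Conflict":
            for tup in t.values:
                feats.append(Feature("CONFLICT", int(tup[0]), int(tup[1]),
                                     tup[2] if len(tup) > 2 else "", source_key=t.key))
        else:
            passthrough.append(t)
    return feats, passthrough


# --- PEFF files --------------------------------------------------------------

def read_peff(path) -> tuple[DatabaseMeta, list[ProteinEntry]]:
    """Read a PEFF 1.0 file into (DatabaseMeta, entries).

    The ``# Key=Value`` header lines populate ``meta.extra`` (DbName/DbVersion/
    DbSource map onto the corresponding DatabaseMeta fields); entry header tags
    are decoded into Features where positional, kept in ``entry.meta`` under
    ``peff:<Key>`` otherwise.
    """
    lines = Path(path).read_text(encoding="utf-8").splitlines()
    if not lines or not lines[0].lstrip().startswith("# PEFF"):
        raise NotPeff(f"{path}: missing '# PEFF' magic")
    extra: dict[str, str] = {}
    i = 1
    while i < len(lines):
        line = lines[i].rstrip()
        if line.startswith("# //"):
            i += 1
            break
        if line.startswith("#"):
            body = line[1:].strip()
            if "=" in body:
                k, _, v = body.partition("=")
                extra[k.strip()] = v.strip()
            i += 1
        else:
            break
    meta = DatabaseMeta(
        db_name=extra.get("DbName", Path(path).stem),
        db_version=extra.get("DbVersion", "1"),
        db_source=extra.get("DbSource", "custom").lower()
        if extra.get("DbSource", "custom").lower() in ("uniprot", "ncbi", "ensembl", "custom")
        else "custom",
        extra=extra,
    )

    entries: list[ProteinEntry] = []
    header: tuple[str, str, str] | None = None  # (prefix, accession, tag text)
    chunks: list[str] = []
    for lineno in range(i, len(lines)):
        line = lines[lineno].rstrip()
        if not line:
            continue
        if line.startswith(">"):
            if header is not None:
                entries.append(_finish_peff_record(header, chunks))
            m = re.match(r"^>(\w+):(\S+)\s*(.*)$", line)
            if not m:
                raise NotPeff(f"line {lineno + 1}: entry header must be "
                              f"'>prefix:accession': {line[:60]!r}")
            header, chunks = (m.group(1), m.group(2), m.group(3)), []
        else:
            if header is None:
                raise NotPeff(f"line {lineno + 1}: sequence before any entry header")
            chunks.append("".join(line.split()))
    if header is not None:
        entries.append(_finish_peff_record(header, chunks))
    meta.n_entries = len(entries)
    return meta, entries


def _finish_peff_record(header: tuple[str, str, str], chunks: list[str]) -> ProteinEntry:
    prefix, acc, tagtext = header
    seq = "".join(chunks).upper()
    if not seq:
        raise EmptyRecord(f"PEFF entry {acc!r} has no sequence")
    tags = parse_peff_tags(tagtext)
    feats, passthrough = tags_to_features(tags)
    meta: dict[str, str] = {}
    desc = ""
    for t in passthrough:
        if t.key == "PName":
            desc = t.values[0][0]
        elif t.key == "Length":
            continue  # recomputed from the sequence
        else:
            meta["peff:" + t.key] = format_peff_tags([t])[len(t.key) + 2:]
    return ProteinEntry(accession=acc, sequence=seq, prefix=prefix,
                        description=desc, features=feats, meta=meta)


def write_peff(meta: DatabaseMeta, entries: Iterable[ProteinEntry], path,
               wrap: int = 0) -> int:
    """Write a PEFF 1.0 file: one header block, then one record per entry.

    Sequences are unwrapped by default (``wrap=0``).  Round-trips all modeled
    fields: description (PName), Length, Features, and any ``peff:*`` meta
    tags carried by the entries.
    """
    n = 0
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("# PEFF 1.0\n")
        header_keys = dict(meta.extra)
        header_keys.setdefault("DbName", meta.db_name)
        header_keys.setdefault("DbVersion", meta.db_version)
        header_keys.setdefault("DbSource", meta.db_source)
        for k, v in header_keys.items():
            fh.write(f"# {k}={v}\n")
        fh.write("# //\n")
        for e in entries:
            tags: list[PeffTag] = []
            if e.description:
                tags.append(PeffTag("PName", [[e.description]]))
            tags.append(PeffTag("Length", [[str(len(e.sequence))]]))
            tags.extend(features_to_tags(e.features))
            for k, v in e.meta.items():
                if k.startswith("peff:"):
                    tags.extend(parse_peff_tags(f"\\{k[5:]}={v}"))
            prefix = e.prefix if re.fullmatch(r"\w+", e.prefix or "") else "gen"
            fh.write(f">{prefix}:{e.accession} {format_peff_tags(tags)}\n")
            fh.write(_wrap_seq(e.sequence, wrap))
            n += 1
    return n


# --- peptide lists -----------------------------------------------------------

def read_peptide_list(path) -> list[str]:
    """Read a plain-text peptide list: one sequence per line, '#' comments and
    blank lines ignored."""
    peptides = []
    for lineno, raw in enumerate(open(path, encoding="utf-8"), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        if not set(line.upper()) <= AA_EXTENDED:
            raise EmptySequence(f"line {lineno}: not an amino-acid sequence: {line[:30]!r}")
        peptides.append(line.upper())
    return peptides


# --- format detection --------------------------------------------------------

SQLITE_MAGIC = b"SQLite format 3\x00"


def detect_format(path) -> tuple[str, list[str]]:
    """Classify a file as fasta / peff / sqpd / set / peptide_list / unknown.

    Pure function of file content (no extension sniffing).  The second return
    value lists recoverable issues (duplicate accessions, illegal residues,
    incomplete SQPD schema) without failing detection.
    """
    p = Path(path)
    try:
        head = p.open("rb").read(64)
    except OSError as exc:
        raise FileUnreadable(str(exc)) from exc
    if not head:
        raise FileUnreadable(f"{path}: empty file")
    issues: list[str] = []

    if head.startswith(SQLITE_MAGIC):
        try:
            con = sqlite3.connect(f"file:{p}?mode=ro", uri=True)
            names = {r[0] for r in con.execute(
                "SELECT name FROM sqlite_master WHERE type='table'")}
            con.close()
        except sqlite3.Error as exc:
            raise FileUnreadable(f"{path}: {exc}") from exc
        missing = {"meta", "entries", "features"} - names
        if missing:
            issues.append("missing SQPD tables: " + ", ".join(sorted(missing)))
        return "sqpd", issues

    try:
        text = p.read_text(encoding="utf-8")
    except UnicodeDecodeError:
        return "unknown", ["binary content without a known magic"]
    stripped = text.lstrip()
    if not stripped:
        raise FileUnreadable(f"{path}: only whitespace")

    if stripped.startswith("# PEFF"):
        return "peff", _text_issues(text, peff=True)
    if stripped.startswith(">"):
        return "fasta", _text_issues(text, peff=False)
    if stripped.startswith("{"):
        try:
            obj = json.loads(text)
        except json.JSONDecodeError:
            return "unknown", ["starts with '{' but is not valid JSON"]
        if isinstance(obj, dict) and obj.get("format") == "SET":
            return "set", []
        return "unknown", ["JSON object without the SET signature key"]
    lines = [l.strip() for l in text.splitlines() if l.strip() and not l.startswith("#")]
    if lines and all(set(l.upper()) <= AA_EXTENDED for l in lines):
        return "peptide_list", []
    return "unknown", []


def _text_issues(text: str, peff: bool) -> list[str]:
    issues: list[str] = []
    seen: set[str] = set()
    acc = None
    for line in text.splitlines():
        line = line.strip()
        if not line or (peff and line.startswith("#")):
            continue
        if line.startswith(">"):
            token = line[1:].split()[0] if line[1:].split() else ""
            acc = token.rpartition(":")[2] if peff else token.split("|")[1] if token.count("|") >= 2 else token
            if acc in seen:
                issues.append(f"duplicate accession {acc}")
            seen.add(acc)
        else:
            bad = set(line.upper()) - AA_EXTENDED - {"*", "-"}
            if bad:
                issues.append(f"illegal residue(s) {''.join(sorted(bad))} in entry {acc}")
    return issues
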