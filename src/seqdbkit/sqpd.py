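"""The SQPD format: a proteoform-aware protein database in a single SQLite file.

SQPD keeps PEFF semantics in relational tables so that sequences and features
can be fetched or filtered by index instead of reparsing text:

* ``meta(key, value)`` — database identity (name, version, source, type,
  entry count, creation time, schema version) plus passthrough header keys;
* ``entries(id, prefix, accession, description, sequence, length, mass)`` —
  one row per protein, with length and average molecular mass precomputed
  and indexed for filtering;
* ``features(id, entry_id, key, start, end, payload)`` — one row per
  proteoform annotation (1-based inclusive coordinates).

The schema name set is frozen under the ``schema_version`` meta row
("sqpd-1") so later migrations are detectable.

Also here: the UniProt tab-separated feature-table grammar and its mapping
onto the controlled feature kinds (Signal peptide -> SIGNAL, Natural variant
-> VARIANT with the replacement residue as payload, ...), and the
Feature <-> PEFF tag codec re-exported from :mod:`seqdbkit.textio`.
"""

from __future__ import annotations

import logging
import re
import sqlite3
from pathlib import Path
from typing import Iterable, Iterator

from .analysis import average_mass
from .core import DatabaseMeta, Feature, ProteinEntry
from .errors import (AccessionNotFound, DuplicateAccession, InvalidMeta,
                     MalformedFeatureCell, NotSqpd, PathExists)
from .textio import features_to_tags, tags_to_features  # noqa: F401  (public codec surface)

log = logging.getLogger(__name__)

SCHEMA_VERSION = "sqpd-1"

_SCHEMA = """
CREATE TABLE meta (key TEXT PRIMARY KEY, value TEXT);
CREATE TABLE entries (
    id INTEGER PRIMARY KEY,
    prefix TEXT,
    accession TEXT UNIQUE NOT NULL,
    description TEXT,
    sequence TEXT NOT NULL,
    length INTEGER NOT NULL,
    mass REAL
);
CREATE TABLE features (
    id INTEGER PRIMARY KEY,
    entry_id INTEGER NOT NULL REFERENCES entries(id) ON DELETE CASCADE,
    key TEXT NOT NULL,
    start INTEGER,
    end INTEGER,
    payload TEXT
);
CREATE INDEX idx_entries_accession ON entries(accession);
CREATE INDEX idx_entries_length ON entries(length);
CREATE INDEX idx_entries_mass ON entries(mass);
CREATE INDEX idx_features_entry ON features(entry_id);
CREATE INDEX idx_features_key ON features(key);
CREATE TABLE entry_meta (
    entry_id INTEGER NOT NULL REFERENCES entries(id) ON DELETE CASCADE,
    key TEXT NOT NULL,
    value TEXT
);
CREATE INDEX idx_entry_meta_entry ON entry_meta(entry_id);
"""


class SqpdHandle:
    """An open SQPD database: metadata plus a query surface over entries and
    features.  Usable as a context manager."""

    def __init__(self, path, con: sqlite3.Connection):
        self.path = Path(path)
        self._con = con
        self.rows_read = 0  # sequence rows materialized; supports access-pattern checks

    # -- lifecycle ------------------------------------------------------------

    def close(self) -> None:
        self._con.close()

    def __enter__(self) -> "SqpdHandle":
        return self

    def __exit__(self, *exc) -> None:
        self.close()

    # -- metadata -------------------------------------------------------------

    @property
    def meta(self) -> DatabaseMeta:
        rows = dict(self._con.execute("SELECT key, value FROM meta"))
        known = {"db_name", "db_version", "db_source", "sequence_type",
                 "n_entries", "created", "schema_version"}
        return DatabaseMeta(
            db_name=rows.get("db_name", ""),
            db_version=rows.get("db_version", "1"),
            db_source=rows.get("db_source", "custom"),
            sequence_type=rows.get("sequence_type", "AA"),
            n_entries=int(rows.get("n_entries", 0)),
            created=rows.get("created", ""),
            extra={k: v for k, v in rows.items() if k not in known},
        )

    def __len__(self) -> int:
        return int(self._con.execute(
            "SELECT value FROM meta WHERE key='n_entries'").fetchone()[0])

    # -- writes ---------------------------------------------------------------

    def add_entries(self, entries: Iterable[ProteinEntry],
                    on_duplicate: str = "error",
                    monoisotopic: bool = False) -> int:
        """Insert a batch of entries atomically (all-or-nothing).

        ``on_duplicate``: ``error`` aborts and rolls the whole batch back,
        ``skip`` drops the colliding entry, ``suffix`` stores it under
        ``accession_2``, ``_3``, ...
        """
        if on_duplicate not in ("error", "skip", "suffix"):
            raise ValueError(f"bad duplicate policy {on_duplicate!r}")
        cur = self._con.cursor()
        added = 0
        try:
            cur.execute("BEGIN")
            for e in entries:
                acc = e.accession
                exists = cur.execute(
                    "SELECT 1 FROM entries WHERE accession=?", (acc,)).fetchone()
                if exists:
                    if on_duplicate == "error":
                        raise DuplicateAccession(acc)
                    if on_duplicate == "skip":
                        log.warning("skipping duplicate accession %s", acc)
                        continue
                    k = 2
                    while cur.execute("SELECT 1 FROM entries WHERE accession=?",
                                      (f"{acc}_{k}",)).fetchone():
                        k += 1
                    acc = f"{acc}_{k}"
                    log.warning("duplicate accession stored as %s", acc)
                cur.execute(
                    "INSERT INTO entries (prefix, accession, description, "
                    "sequence, length, mass) VALUES (?,?,?,?,?,?)",
                    (e.prefix, acc, e.description, e.sequence, len(e.sequence),
                     average_mass(e.sequence, monoisotopic)))
                eid = cur.lastrowid
                cur.executemany(
                    "INSERT INTO features (entry_id, key, start, end, payload) "
                    "VALUES (?,?,?,?,?)",
                    [(eid, f.kind, f.start, f.end, f.payload) for f in e.features])
                if e.meta:
                    cur.executemany(
                        "INSERT INTO entry_meta (entry_id, key, value) VALUES (?,?,?)",
                        [(eid, k, v) for k, v in e.meta.items()])
                added += 1
            n = cur.execute("SELECT COUNT(*) FROM entries").fetchone()[0]
            cur.execute("UPDATE meta SET value=? WHERE key='n_entries'", (str(n),))
            self._con.commit()
        except BaseException:
            self._con.rollback()
            raise
        return added

    # -- reads ----------------------------------------------------------------

    def _row_to_entry(self, row, cur) -> ProteinEntry:
        eid, prefix, acc, desc, seq = row
        feats = [Feature(k, s, e, p or "") for k, s, e, p in cur.execute(
            "SELECT key, start, end, payload FROM features "
            "WHERE entry_id=? ORDER BY id", (eid,))]
        meta = dict(cur.execute(
            "SELECT key, value FROM entry_meta WHERE entry_id=?", (eid,)))
        self.rows_read += 1
        return ProteinEntry(accession=acc, sequence=seq, prefix=prefix or "generic",
                            description=desc or "", features=feats, meta=meta)

    def get_entry(self, accession: str) -> ProteinEntry:
        """Fetch one entry (with features) by accession via the index."""
        cur = self._con.cursor()
        row = cur.execute(
            "SELECT id, prefix, accession, description, sequence "
            "FROM entries WHERE accession=?", (accession,)).fetchone()
        if row is None:
            raise AccessionNotFound(accession)
        return self._row_to_entry(row, self._con.cursor())

    def iter_entries(self) -> Iterator[ProteinEntry]:
        cur = self._con.cursor()
        for row in cur.execute(
                "SELECT id, prefix, accession, description, sequence "
                "FROM entries ORDER BY accession"):
            yield self._row_to_entry(row, self._con.cursor())

    def query_entries(self, length: tuple | None = None,
                      mass: tuple | None = None,
                      feature_key: str | None = None,
                      accessions: list[str] | None = None) -> list[str]:
        """Accessions matching the conjunction of predicates, pushed into SQL
        (no full scan in application code).  Ranges are inclusive; ``None``
        bounds are open.  Result is sorted ascending."""
        where, params = [], []
        for col, rng in (("length", length), ("mass", mass)):
            if rng is not None:
                lo, hi = rng
                if lo is not None:
                    where.append(f"{col} >= ?")
                    params.append(lo)
                if hi is not None:
                    where.append(f"{col} <= ?")
                    params.append(hi)
        if feature_key is not None:
            where.append("id IN (SELECT entry_id FROM features WHERE key=?)")
            params.append(feature_key)
        if accessions is not None:
            marks = ",".join("?" * len(accessions))
            where.append(f"accession IN ({marks})")
            params.extend(accessions)
        sql = "SELECT accession FROM entries"
        if where:
            sql += " WHERE " + " AND ".join(where)
        sql += " ORDER BY accession"
        return [r[0] for r in self._con.execute(sql, params)]

    def accessions(self) -> list[str]:
        return [r[0] for r in
                self._con.execute("SELECT accession FROM entries ORDER BY accession")]


def create_sqpd(path, meta: DatabaseMeta, overwrite: bool = False) -> SqpdHandle:
    """Create a new SQPD file with the full schema and meta rows."""
    p = Path(path)
    if not meta.db_name or not meta.db_version:
        raise InvalidMeta("db_name and db_version must be non-empty")
    if p.exists():
        if not overwrite:
            raise PathExists(str(p))
        p.unlink()
    con = sqlite3.connect(p)
    con.isolation_level = None
    con.executescript(_SCHEMA)
    rows = [("db_name", meta.db_name), ("db_version", meta.db_version),
            ("db_source", meta.db_source), ("sequence_type", meta.sequence_type),
            ("n_entries", "0"), ("created", meta.created),
            ("schema_version", SCHEMA_VERSION)]
    rows += [(k, v) for k, v in meta.extra.items()]
    con.executemany("INSERT OR REPLACE INTO meta (key, value) VALUES (?,?)", rows)
    con.commit()
    return SqpdHandle(p, con)


def open_sqpd(path, readonly: bool = False) -> SqpdHandle:
    """Open an existing SQPD file, verifying the schema."""
    p = Path(path)
    if not p.exists():
        raise NotSqpd(f"{p}: no such file")
    uri = f"file:{p}?mode=ro" if readonly else str(p)
    con = sqlite3.connect(uri, uri=readonly)
    con.isolation_level = None
    names = {r[0] for r in con.execute(
        "SELECT name FROM sqlite_master WHERE type='table'")}
    if not {"meta", "entries", "features"} <= names:
        con.close()
        raise NotSqpd(f"{p}: missing SQPD tables")
    return SqpdHandle(p, con)


# --- UniProt feature-table parsing -------------------------------------------

# column header -> (cell token, feature kind)
UNIPROT_FEATURE_COLUMNS = {
    "Signal peptide": ("SIGNAL", "SIGNAL"),
    "Chain": ("CHAIN", "CHAIN"),
    "Propeptide": ("PROPEP", "PROPEP"),
    "Transit peptide": ("TRANSIT", "TRANSIT"),
    "Initiator methionine": ("INIT_MET", "INIT_MET"),
    "Natural variant": ("VARIANT", "VARIANT"),
    "Modified residue": ("MOD_RES", "MOD_RES"),
    "Sequence conflict": ("CONFLICT", "CONFLICT"),
}
_TOKEN_TO_KIND = {tok: kind for tok, kind in UNIPROT_FEATURE_COLUMNS.values()}

_FEAT_RE = re.compile(
    r"(?P<token>[A-Z][A-Z_]+)\s+(?P<start>[<>?]?\??\d+|\?)"
    r"(?:\.\.(?P<end>[<>?]?\??\d+|\?))?")
_NOTE_RE = re.compile(r'/note="([^"]*)"')
_ARROW_RE = re.compile(r"^\s*([A-Z]+)\s*->\s*([A-Z]+)")


def _parse_bound(text: str) -> int | None:
    """None for uncertain ('<', '>', '?') bounds."""
    if any(c in text for c in "<>?"):
        return None
    return int(text)


def map_uniprot_features(row: dict[str, str]) -> list[Feature]:
    """Decode the feature cells of one UniProt TSV row into Features.

    Cell grammar: ``TOKEN start..end; /qualifier="v"; ... TOKEN start..end``;
    single positions appear as ``TOKEN pos``. Variant replacement residues are
    parsed from ``/note="X -> Y"``.  Unknown tokens and uncertain ('<', '>',
    '?') bounds are skipped with a warning; a non-empty cell yielding no
    parseable token raises :class:`MalformedFeatureCell`.
    """
    features: list[Feature] = []
    for column, cell in row.items():
        if column not in UNIPROT_FEATURE_COLUMNS:
            continue
        cell = (cell or "").strip()
        if not cell:
            continue
        matches = list(_FEAT_RE.finditer(cell))
        if not matches:
            raise MalformedFeatureCell(
                f"column {column!r}: cannot parse cell {cell[:60]!r}")
        for i, m in enumerate(matches):
            token = m.group("token")
            seg_end = matches[i + 1].start() if i + 1 < len(matches) else len(cell)
            segment = cell[m.start():seg_end]
            kind = _TOKEN_TO_KIND.get(token)
            if kind is None:
                log.warning("unknown feature token %r skipped", token)
                continue
            start = _parse_bound(m.group("start"))
            end = _parse_bound(m.group("end")) if m.group("end") else start
            if start is None or end is None:
                log.warning("uncertain bounds in %r skipped", segment.strip()[:40])
                continue
            payload = ""
            note = _NOTE_RE.search(segment)
            if note:
                payload = note.group(1)
                if kind == "VARIANT":
                    arrow = _ARROW_RE.match(payload)
                    payload = arrow.group(2) if arrow else payload
            features.append(Feature(kind, start, end, payload, source_key=column))
    return features
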