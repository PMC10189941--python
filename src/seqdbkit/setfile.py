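"""The SET format: a JSON manifest naming a subset of a parent database.

A SET file carries no sequence text — only the parent database identity and
an ordered list of unique accessions — so its size is independent of sequence
lengths and it can be resolved against the parent SQPD on demand.

Frozen JSON keys::

    {"format": "SET", "set_name": ..., "db_name": ..., "db_version": ...,
     "created": ..., "description": ..., "entries": [...]}
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path
from typing import Iterator

from .core import ProteinEntry
from .errors import DuplicateEntryInSet, MissingAccession, NotSet, UsageError

log = logging.getLogger(__name__)

FORMAT_TAG = "SET"


@dataclass
class EntrySet:
    """An ordered, duplicate-free list of accessions tied to a parent
    database name/version."""

    set_name: str
    db_name: str
    db_version: str
    entries: list[str]
    description: str = ""
    created: str = ""

    def __post_init__(self) -> None:
        if self.created == "":
            self.created = datetime.now(timezone.utc).strftime("%Y-%m-%dT%H:%M:%SZ")
        seen = set()
        for acc in self.entries:
            if not acc or not isinstance(acc, str):
                raise ValueError("entries must be non-empty strings")
            if acc in seen:
                raise DuplicateEntryInSet(acc)
            seen.add(acc)

    def __len__(self) -> int:
        return len(self.entries)


def write_set(s: EntrySet, path) -> None:
    obj = {
        "format": FORMAT_TAG,
        "set_name": s.set_name,
        "db_name": s.db_name,
        "db_version": s.db_version,
        "created": s.created,
        "description": s.description,
        "entries": list(s.entries),
    }
    Path(path).write_text(json.dumps(obj, indent=1) + "\n", encoding="utf-8")


def read_set(path) -> EntrySet:
    try:
        obj = json.loads(Path(path).read_text(encoding="utf-8"))
    except json.JSONDecodeError as exc:
        raise NotSet(f"{path}: not valid JSON ({exc})") from exc
    if not isinstance(obj, dict) or obj.get("format") != FORMAT_TAG:
        raise NotSet(f"{path}: missing SET signature key")
    return EntrySet(
        set_name=obj.get("set_name", ""),
        db_name=obj.get("db_name", ""),
        db_version=obj.get("db_version", ""),
        created=obj.get("created", ""),
        description=obj.get("description", ""),
        entries=list(obj.get("entries", [])),
    )


def resolve_set(s: EntrySet, handle, on_missing: str = "report",
                strict_db: bool = False) -> Iterator[ProteinEntry]:
    """Yield the SET's entries from an open SQPD handle, in SET order.

    ``on_missing``: ``error`` raises :class:`MissingAccession`, ``skip`` drops
    silently, ``report`` (default) drops with a warning.  A db_name/db_version
    mismatch between SET and SQPD meta warns, or raises when ``strict_db``.
    """
    if on_missing not in ("error", "skip", "report"):
        raise UsageError(f"bad on_missing policy {on_missing!r}")
    meta = handle.meta
    if (s.db_name, s.db_version) != (meta.db_name, meta.db_version):
        msg = (f"SET references {s.db_name}/{s.db_version} but database is "
               f"{meta.db_name}/{meta.db_version}")
        if strict_db:
            raise UsageError(msg)
        log.warning(msg)
    from .errors import AccessionNotFound
    for acc in s.entries:
        try:
            yield handle.get_entry(acc)
        except AccessionNotFound:
            if on_missing == "error":
                raise MissingAccession(acc) from None
            if on_missing == "report":
                log.warning("accession %s not in database; skipped", acc)
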