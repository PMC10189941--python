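"""Subset selection: SQPD content filters and annotation-table filters.

Both filters produce :class:`~seqdbkit.setfile.EntrySet` manifests — never
sequence files — so a selection stays tiny and resolvable against its parent
database.  A :class:`FilterSpec` is a conjunction of clauses; disjunction is
achieved by running twice and merging SET files.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable

import pandas as pd

from .analysis import compile_motif
from .core import ProteinEntry
from .errors import MissingColumn, NonNumericColumn, UnknownField, UsageError
from .setfile import EntrySet

log = logging.getLogger(__name__)

SEQ_FIELDS = ("length", "mass", "feature_key", "motif", "accession_in")
OPS = ("ge", "le", "between", "has", "matches", "in")


@dataclass(frozen=True)
class Clause:
    field: str   # length | mass | feature_key | motif | accession_in | column:<name>
    op: str      # ge | le | between | has | matches | in
    value: object

    def __post_init__(self) -> None:
        if self.op not in OPS:
            raise UsageError(f"unknown op {self.op!r}")
        if self.op == "between":
            lo, hi = self.value  # type: ignore[misc]
            if lo is not None and hi is not None and lo > hi:
                raise UsageError(f"empty between range {lo}..{hi}")


@dataclass
class FilterSpec:
    """A conjunction of clauses (at least one)."""

    clauses: list[Clause]

    def __post_init__(self) -> None:
        if not self.clauses:
            raise UsageError("a filter needs at least one clause")
        for c in self.clauses:
            if c.op in ("ge", "le", "between") and not (
                    c.field in ("length", "mass") or c.field.startswith("column:")):
                raise UsageError(f"numeric op {c.op} on non-numeric field {c.field}")


def _numeric_range(clause: Clause) -> tuple:
    if clause.op == "ge":
        return (clause.value, None)
    if clause.op == "le":
        return (None, clause.value)
    return tuple(clause.value)  # between


def seq_filter(handle, spec: FilterSpec, set_name: str = "filtered") -> EntrySet:
    """Filter an open SQPD by length, mass, proteoform feature, motif or an
    accession list; returns an EntrySet (ascending accession order) stamped
    with the database's name/version.  An empty result is a valid SET."""
    length = mass = feature_key = accessions = None
    motifs: list[str] = []
    for c in spec.clauses:
        if c.field == "length" and c.op in ("ge", "le", "between"):
            length = _merge_range(length, _numeric_range(c))
        elif c.field == "mass" and c.op in ("ge", "le", "between"):
            mass = _merge_range(mass, _numeric_range(c))
        elif c.field == "feature_key" and c.op == "has":
            if feature_key is not None and feature_key != c.value:
                # two different feature keys: intersect via accession list
                accs = set(handle.query_entries(feature_key=str(c.value)))
                accessions = sorted(accs if accessions is None
                                    else accs & set(accessions))
            else:
                feature_key = str(c.value)
        elif c.field == "motif" and c.op == "matches":
            motifs.append(str(c.value))
        elif c.field == "accession_in" and c.op == "in":
            accs = set(c.value)  # type: ignore[arg-type]
            accessions = sorted(accs if accessions is None
                                else accs & set(accessions))
        else:
            raise UnknownField(f"{c.field}/{c.op} is not filterable on SQPD")

    result = handle.query_entries(length=length, mass=mass,
                                  feature_key=feature_key,
                                  accessions=accessions)
    if motifs:
        patterns = [compile_motif(m) for m in motifs]
        kept = []
        for acc in result:
            seq = handle.get_entry(acc).sequence
            if all(any(rx.match(seq, i) for i in range(len(seq)))
                   for rx in patterns):
                kept.append(acc)
        result = kept
    meta = handle.meta
    return EntrySet(set_name=set_name, db_name=meta.db_name,
                    db_version=meta.db_version, entries=sorted(result),
                    description=f"seq_filter: {len(spec.clauses)} clause(s)")


def _merge_range(old: tuple | None, new: tuple) -> tuple:
    if old is None:
        return new
    lo = max((v for v in (old[0], new[0]) if v is not None), default=None)
    hi = min((v for v in (old[1], new[1]) if v is not None), default=None)
    return (lo, hi)


def brute_force_filter(entries: Iterable[ProteinEntry], spec: FilterSpec,
                       masses: dict[str, float] | None = None) -> list[str]:
    """Reference evaluation of a FilterSpec over in-memory entries — the
    oracle the SQL path is checked against.  ``masses`` supplies precomputed
    average masses (recomputed if absent)."""
    from .analysis import average_mass
    out = []
    for e in entries:
        ok = True
        for c in spec.clauses:
            if c.field == "length":
                ok = _num_ok(len(e.sequence), c)
            elif c.field == "mass":
                m = masses[e.accession] if masses else average_mass(e.sequence)
                ok = _num_ok(m, c)
            elif c.field == "feature_key":
                ok = any(f.kind == c.value for f in e.features)
            elif c.field == "motif":
                rx = compile_motif(str(c.value))
                ok = any(rx.match(e.sequence, i) for i in range(len(e.sequence)))
            elif c.field == "accession_in":
                ok = e.accession in set(c.value)  # type: ignore[arg-type]
            else:
                raise UnknownField(c.field)
            if not ok:
                break
        if ok:
            out.append(e.accession)
    return sorted(out)


def _num_ok(x, clause: Clause) -> bool:
    lo, hi = _numeric_range(clause)
    return (lo is None or x >= lo) and (hi is None or x <= hi)


def tab_filter(table_path, spec: FilterSpec, id_column: str = "accession",
               set_name: str = "tab_filtered",
               db_name: str = "", db_version: str = "") -> EntrySet:
    """Filter a TSV annotation table on its columns; returns the unique ids
    passing all clauses.

    Numeric columns parse leniently: blank or non-numeric cells are excluded
    from numeric clauses with a warning; a column with no numeric cells at
    all raises :class:`NonNumericColumn`.
    """
    df = pd.read_csv(table_path, sep="\t", dtype=str)
    if id_column not in df.columns:
        raise MissingColumn(id_column)
    if df[id_column].duplicated().any():
        log.warning("duplicate ids in %s deduplicated", table_path)
        df = df.drop_duplicates(subset=id_column, keep="first")

    mask = pd.Series(True, index=df.index)
    for c in spec.clauses:
        if not c.field.startswith("column:"):
            raise UnknownField(f"{c.field}: table filters use column:<name>")
        col = c.field.split(":", 1)[1]
        if col not in df.columns:
            raise MissingColumn(col)
        if c.op in ("ge", "le", "between"):
            vals = pd.to_numeric(df[col], errors="coerce")
            if vals.notna().sum() == 0:
                raise NonNumericColumn(col)
            n_bad = int(vals.isna().sum())
            if n_bad:
                log.warning("column %s: %d non-numeric cell(s) excluded", col, n_bad)
            lo, hi = _numeric_range(c)
            ok = vals.notna()
            if lo is not None:
                ok &= vals >= lo
            if hi is not None:
                ok &= vals <= hi
            mask &= ok
        elif c.op == "matches":
            rx = compile_motif(str(c.value))
            mask &= df[col].fillna("").map(
                lambda s: any(rx.match(s.upper(), i) for i in range(len(s))))
        elif c.op == "in":
            mask &= df[col].isin(set(c.value))  # type: ignore[arg-type]
        else:
            raise UnknownField(f"{c.field}/{c.op} not supported on tables")

    ids = list(dict.fromkeys(df.loc[mask, id_column].tolist()))
    return EntrySet(set_name=set_name, db_name=db_name, db_version=db_version,
                    entries=ids, description=f"tab_filter on {id_column}")
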