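"""Species lookup and proteome download with an injectable transport.

A *transport* is any callable ``transport(request: HttpRequest) -> (status,
bytes)``.  The default transport uses stdlib urllib; tests and offline use
inject canned payloads, so every parsing and bookkeeping path here is
deterministic given the transport output.

Endpoint URLs and query parameters are configuration (:data:`DEFAULT_ENDPOINTS`
overridable via a key=value or JSON config file), not code constants, so API
drift needs no code change.

``db_manage`` maintains the on-disk database layout::

    seqdbs/<db_name>/<version>/classic/   # FASTA / PEFF / annotation tables
    seqdbs/<db_name>/<version>/next/      # SQPD / SET

Registration stages into a temporary directory and renames atomically, so a
failure never leaves a half-registered version behind.
"""

from __future__ import annotations

import json
import logging
import shutil
import tempfile
import urllib.parse
import urllib.request
from dataclasses import dataclass, field
from pathlib import Path

from .core import DatabaseMeta
from .errors import (EmptyResult, TransportError, UnknownDb, UsageError,
                     VersionExists)

log = logging.getLogger(__name__)

SOURCES = ("uniprot", "ncbi", "ensembl")

DEFAULT_ENDPOINTS = {
    "uniprot.taxonomy": "https://rest.uniprot.org/taxonomy/search",
    "uniprot.proteome": "https://rest.uniprot.org/uniprotkb/stream",
    "ncbi.taxonomy": "https://eutils.ncbi.nlm.nih.gov/entrez/eutils/esummary.fcgi",
    "ncbi.proteome": "https://eutils.ncbi.nlm.nih.gov/entrez/eutils/efetch.fcgi",
    "ensembl.taxonomy": "https://rest.ensembl.org/taxonomy/name",
    "ensembl.proteome": "https://rest.ensembl.org/sequence/id",
}

# UniProt TSV fields needed for basic + proteoform annotation of an SQPD
UNIPROT_TABLE_FIELDS = (
    "accession,gene_names,protein_name,organism_name,organism_id,"
    "ft_signal,ft_chain,ft_propep,ft_transit,ft_init_met,"
    "ft_variant,ft_mod_res,ft_conflict"
)


def load_endpoints(config_path=None) -> dict[str, str]:
    """Merge DEFAULT_ENDPOINTS with a JSON or key=value config file."""
    endpoints = dict(DEFAULT_ENDPOINTS)
    if config_path:
        text = Path(config_path).read_text(encoding="utf-8")
        try:
            endpoints.update(json.loads(text))
        except json.JSONDecodeError:
            for line in text.splitlines():
                line = line.strip()
                if line and not line.startswith("#") and "=" in line:
                    k, _, v = line.partition("=")
                    endpoints[k.strip()] = v.strip()
    return endpoints


@dataclass
class HttpRequest:
    url: str
    params: dict[str, str] = field(default_factory=dict)

    @property
    def full_url(self) -> str:
        if not self.params:
            return self.url
        return self.url + "?" + urllib.parse.urlencode(self.params)


def urllib_transport(request: HttpRequest, timeout: float = 60.0) -> tuple[int, bytes]:
    """Default live transport (stdlib urllib)."""
    try:
        with urllib.request.urlopen(request.full_url, timeout=timeout) as resp:
            return resp.status, resp.read()
    except urllib.error.HTTPError as exc:
        return exc.code, exc.read()
    except OSError as exc:
        raise TransportError(str(exc)) from exc


def canned_transport(payloads: dict[str, bytes] | list[bytes]):
    """Build a transport that replays canned payloads; for offline use the
    CLI feeds response files through this."""
    if isinstance(payloads, dict):
        def transport(req: HttpRequest):
            for key, body in payloads.items():
                if key in req.url:
                    return 200, body
            return 404, b""
    else:
        queue = list(payloads)

        def transport(req: HttpRequest):
            if not queue:
                return 404, b""
            return 200, queue.pop(0)
    return transport


@dataclass
class SpeciesHit:
    taxon_id: int
    scientific_name: str
    common_name: str
    source: str

    def __post_init__(self) -> None:
        if self.taxon_id <= 0:
            raise ValueError("taxon_id must be positive")


def _check(status: int, body: bytes, what: str) -> bytes:
    if status != 200:
        raise TransportError(f"{what}: HTTP status {status}")
    return body


def search_species(query: str, source: str, transport=urllib_transport,
                   endpoints: dict[str, str] | None = None) -> list[SpeciesHit]:
    """Search a taxonomy service for species matching ``query``.

    Raises :class:`EmptyResult` for a well-formed response with zero hits —
    distinct from :class:`TransportError` for network/HTTP failures.
    """
    if not query:
        raise UsageError("species query must be non-empty")
    if source not in SOURCES:
        raise UsageError(f"unknown source {source!r}")
    endpoints = endpoints or DEFAULT_ENDPOINTS
    req = _species_request(query, source, endpoints)
    status, body = transport(req)
    hits = _parse_species(_check(status, body, f"{source} taxonomy"), source)
    if not hits:
        raise EmptyResult(f"no {source} taxonomy hits for {query!r}")
    return hits


def _species_request(query: str, source: str, endpoints) -> HttpRequest:
    if source == "uniprot":
        return HttpRequest(endpoints["uniprot.taxonomy"],
                           {"query": query, "format": "json"})
    if source == "ncbi":
        return HttpRequest(endpoints["ncbi.taxonomy"],
                           {"db": "taxonomy", "term": query, "retmode": "json"})
    return HttpRequest(endpoints["ensembl.taxonomy"].rstrip("/") + "/" + query,
                       {"content-type": "application/json"})


def _parse_species(body: bytes, source: str) -> list[SpeciesHit]:
    try:
        obj = json.loads(body.decode("utf-8"))
    except (UnicodeDecodeError, json.JSONDecodeError) as exc:
        raise TransportError(f"unparseable {source} taxonomy payload: {exc}") from exc
    hits: list[SpeciesHit] = []
    if source == "uniprot":
        for rec in obj.get("results", []):
            hits.append(SpeciesHit(int(rec["taxonId"]),
                                   rec.get("scientificName", ""),
                                   rec.get("commonName", ""), "uniprot"))
    elif source == "ncbi":
        result = obj.get("result", {})
        for uid in result.get("uids", []):
            rec = result.get(str(uid), {})
            hits.append(SpeciesHit(int(uid), rec.get("scientificname", ""),
                                   rec.get("commonname", ""), "ncbi"))
    else:
        for rec in obj if isinstance(obj, list) else []:
            hits.append(SpeciesHit(int(rec["id"]), rec.get("scientific_name", ""),
                                   rec.get("display_name", rec.get("name", "")),
                                   "ensembl"))
    return hits


def fetch_proteome(taxon_id: int, source: str, options: dict | None = None,
                   transport=urllib_transport,
                   endpoints: dict[str, str] | None = None
                   ) -> tuple[bytes, bytes | None]:
    """Download the species proteome: (FASTA bytes, annotation-table bytes).

    For UniProt the second component is the TSV annotation table carrying the
    feature columns the SQPD builder maps; for NCBI/Ensembl it is ``None``
    (no automatic proteoform annotation — such databases convert to SQPD
    without features by default).  Payloads are returned unmodified.
    """
    if taxon_id <= 0:
        raise UsageError("taxon_id must be positive")
    if source not in SOURCES:
        raise UsageError(f"unknown source {source!r}")
    options = options or {}
    endpoints = endpoints or DEFAULT_ENDPOINTS

    if source == "uniprot":
        q = f"organism_id:{taxon_id}"
        if options.get("reviewed"):
            q += " AND reviewed:true"
        fasta_params = {"query": q, "format": "fasta"}
        if options.get("isoforms"):
            fasta_params["includeIsoform"] = "true"
        status, fasta = transport(HttpRequest(endpoints["uniprot.proteome"], fasta_params))
        _check(status, fasta, "uniprot fasta")
        status, table = transport(HttpRequest(
            endpoints["uniprot.proteome"],
            {"query": q, "format": "tsv", "fields": UNIPROT_TABLE_FIELDS}))
        _check(status, table, "uniprot table")
        if not fasta.strip():
            raise EmptyResult(f"empty proteome for taxon {taxon_id}")
        return fasta, table

    key = f"{source}.proteome"
    params = ({"db": "protein", "id": str(taxon_id), "rettype": "fasta"}
              if source == "ncbi" else {"type": "protein", "taxon": str(taxon_id)})
    status, fasta = transport(HttpRequest(endpoints[key], params))
    _check(status, fasta, f"{source} fasta")
    if not fasta.strip():
        raise EmptyResult(f"empty proteome for taxon {taxon_id}")
    return fasta, None


# --- local database registry -------------------------------------------------

def db_manage(seqdbs_root, action: str, db_name: str | None = None,
              version: str | None = None,
              fasta_path=None, table_path=None, force: bool = False):
    """Maintain the seqdbs/ directory registry.

    Actions: ``register`` (stage FASTA [+ annotation table] into classic/ and
    build the SQPD in next/), ``update`` (re-register, implies force),
    ``list`` (all (db_name, version) pairs), ``delete``.
    """
    root = Path(seqdbs_root)
    root.mkdir(parents=True, exist_ok=True)

    if action == "list":
        pairs = []
        for db_dir in sorted(p for p in root.iterdir() if p.is_dir()):
            for ver_dir in sorted(p for p in db_dir.iterdir() if p.is_dir()):
                pairs.append((db_dir.name, ver_dir.name))
        return pairs

    if not db_name or not version:
        raise UsageError(f"action {action!r} needs db_name and version")
    target = root / db_name / version

    if action == "delete":
        if not target.exists():
            raise UnknownDb(f"{db_name}/{version}")
        shutil.rmtree(target)
        if not any((root / db_name).iterdir()):
            (root / db_name).rmdir()
        return db_manage(root, "list")

    if action in ("register", "update"):
        if action == "update":
            if not target.exists():
                raise UnknownDb(f"{db_name}/{version}")
            force = True
        if target.exists() and not force:
            raise VersionExists(f"{db_name}/{version}")
        if fasta_path is None:
            raise UsageError("register needs a FASTA payload")
        from .sqpd import create_sqpd, map_uniprot_features
        from .textio import read_fasta
        import csv

        staging = Path(tempfile.mkdtemp(prefix=f".{version}-", dir=root / db_name
                       if (root / db_name).exists() else root))
        try:
            classic = staging / "classic"
            nxt = staging / "next"
            classic.mkdir(parents=True)
            nxt.mkdir()
            shutil.copy(fasta_path, classic / f"{db_name}.fasta")
            feature_rows: dict[str, dict] = {}
            if table_path is not None:
                shutil.copy(table_path, classic / f"{db_name}.tsv")
                with open(table_path, encoding="utf-8") as fh:
                    for row in csv.DictReader(fh, delimiter="\t"):
                        acc = row.get("Entry") or row.get("accession") or ""
                        if acc:
                            feature_rows[acc] = row
            meta = DatabaseMeta(db_name=db_name, db_version=version,
                                db_source="uniprot" if table_path else "custom")
            entries = []
            for e in read_fasta(classic / f"{db_name}.fasta"):
                if e.accession in feature_rows:
                    e.features = map_uniprot_features(feature_rows[e.accession])
                entries.append(e)
            with create_sqpd(nxt / f"{db_name}.sqpd", meta) as h:
                h.add_entries(entries)
            (root / db_name).mkdir(exist_ok=True)
            if target.exists():
                shutil.rmtree(target)
            staging.rename(target)
        except BaseException:
            shutil.rmtree(staging, ignore_errors=True)
            raise
        return db_manage(root, "list")

    raise UsageError(f"unknown action {action!r}")
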