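"""Deterministic synthetic fixtures: toy proteomes, annotation tables,
transcripts.

Everything a test or demonstration needs is generated here from a seed — no
bundled data files.  The generators emulate the *shapes* of real inputs (a
UniProt-dialect FASTA with OS/OX/GN/PE/SV tags, a UniProt TSV feature table
with SIGNAL/CHAIN/VARIANT/MOD_RES cells, linear and circular transcripts
with planted ORFs) at sizes a laptop handles in seconds.  Residue usage is
uniform over the 20 standard amino acids; real proteomes are biased and far
longer, so these fixtures exercise format and algorithm correctness, not
biological realism.
"""

from __future__ import annotations

import random
from typing import Iterable

from .core import DatabaseMeta, Feature, ProteinEntry

AA20 = "ACDEFGHIKLMNPQRSTVWY"
NT4 = "ACGT"

SPECIES = [
    ("Mus musculus", "10090", "Mm"),
    ("Homo sapiens", "9606", "Hs"),
    ("Escherichia coli", "83333", "Ec"),
]


def random_protein_entries(n: int = 50, seed: int = 0,
                           min_len: int = 30, max_len: int = 240,
                           feature_fraction: float = 0.7) -> list[ProteinEntry]:
    """A toy proteome with UniProt-style accessions and metadata.

    About ``feature_fraction`` of the entries carry a random consistent mix
    of SIGNAL / CHAIN / PROPEP / TRANSIT / INIT_MET / VARIANT / MOD_RES /
    CONFLICT features, all within sequence bounds.
    """
    rng = random.Random(seed)
    entries = []
    for i in range(n):
        L = rng.randint(min_len, max_len)
        seq = "M" + "".join(rng.choice(AA20) for _ in range(L - 1))
        acc = f"P{i:05d}"
        os_name, ox, tag = rng.choice(SPECIES)
        features: list[Feature] = []
        if rng.random() < feature_fraction:
            features = _random_features(seq, rng)
        entries.append(ProteinEntry(
            accession=acc, sequence=seq, prefix="sp",
            description=f"Synthetic protein {i}",
            features=features,
            meta={"entry_name": f"SYN{i:03d}_{tag.upper()}", "OS": os_name,
                  "OX": ox, "GN": f"Syn{i}", "PE": str(rng.randint(1, 5)),
                  "SV": str(rng.randint(1, 3))},
        ))
    return entries


def _random_features(seq: str, rng: random.Random) -> list[Feature]:
    L = len(seq)
    feats: list[Feature] = []
    if rng.random() < 0.5 and L > 40:
        cut = rng.randint(15, 30)
        feats.append(Feature("SIGNAL", 1, cut))
        feats.append(Feature("CHAIN", cut + 1, L))
    else:
        if rng.random() < 0.4:
            feats.append(Feature("INIT_MET", 1, 1))
            feats.append(Feature("CHAIN", 2, L))
        else:
            feats.append(Feature("CHAIN", 1, L))
    if rng.random() < 0.3 and L > 60:
        a = rng.randint(L // 2, L - 10)
        feats.append(Feature("PROPEP", a, min(L, a + rng.randint(5, 15))))
    for _ in range(rng.randint(0, 3)):
        pos = rng.randint(2, L)
        feats.append(Feature("VARIANT", pos, pos, rng.choice(AA20)))
    for _ in range(rng.randint(0, 2)):
        pos = rng.randint(1, L)
        feats.append(Feature("MOD_RES", pos, pos,
                             rng.choice(["Phosphoserine", "N6-acetyllysine",
                                         "Phosphothreonine"])))
    if rng.random() < 0.2:
        pos = rng.randint(1, L)
        feats.append(Feature("CONFLICT", pos, pos, rng.choice(AA20)))
    return feats


def annotation_table(entries: Iterable[ProteinEntry]) -> str:
    """Render entries as a UniProt-style TSV feature table (the format the
    SQPD builder's feature mapper consumes)."""
    cols = ["Entry", "Gene Names", "Protein names", "Organism", "Organism (ID)",
            "Signal peptide", "Chain", "Propeptide", "Transit peptide",
            "Initiator methionine", "Natural variant", "Modified residue",
            "Sequence conflict"]
    kind_to_col = {"SIGNAL": ("Signal peptide", "SIGNAL"),
                   "CHAIN": ("Chain", "CHAIN"),
                   "PROPEP": ("Propeptide", "PROPEP"),
                   "TRANSIT": ("Transit peptide", "TRANSIT"),
                   "INIT_MET": ("Initiator methionine", "INIT_MET"),
                   "VARIANT": ("Natural variant", "VARIANT"),
                   "MOD_RES": ("Modified residue", "MOD_RES"),
                   "CONFLICT": ("Sequence conflict", "CONFLICT")}
    lines = ["\t".join(cols)]
    for e in entries:
        cells = {c: "" for c in cols}
        cells["Entry"] = e.accession
        cells["Gene Names"] = e.meta.get("GN", "")
        cells["Protein names"] = e.description
        cells["Organism"] = e.meta.get("OS", "")
        cells["Organism (ID)"] = e.meta.get("OX", "")
        for f in e.features:
            col, token = kind_to_col[f.kind]
            rng_txt = f"{f.start}" if f.start == f.end else f"{f.start}..{f.end}"
            part = f"{token} {rng_txt}"
            if f.kind == "VARIANT" and f.payload:
                orig = e.sequence[f.start - 1]
                part += f'; /note="{orig} -> {f.payload}"'
            elif f.payload:
                part += f'; /note="{f.payload}"'
            part += '; /evidence="ECO:0000255"; '
            cells[col] += part
        lines.append("\t".join(cells[c].rstrip("; ") if c not in
                               ("Entry", "Gene Names", "Protein names",
                                "Organism", "Organism (ID)")
                               else cells[c] for c in cols))
    return "\n".join(lines) + "\n"


def random_transcripts(n: int = 20, seed: int = 0, min_len: int = 30,
                       max_len: int = 600) -> list[tuple[str, str]]:
    """Random nucleotide transcripts as (id, sequence) pairs."""
    rng = random.Random(seed)
    return [(f"tx{i}", "".join(rng.choice(NT4)
                               for _ in range(rng.randint(min_len, max_len))))
            for i in range(n)]


def toy_sqpd(path, n: int = 50, seed: int = 0, db_name: str = "toydb",
             db_version: str = "1", **kwargs):
    """Create an SQPD file populated with a random toy proteome; returns an
    open handle."""
    from .sqpd import create_sqpd
    entries = random_protein_entries(n, seed, **kwargs)
    meta = DatabaseMeta(db_name=db_name, db_version=db_version,
                        db_source="uniprot")
    h = create_sqpd(path, meta, overwrite=True)
    h.add_entries(entries)
    return h
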