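"""Epitope-bearing protein (EProt) database construction.

Scans a proteome FASTA for sequences containing at least one complete native
epitope and keeps only those, mirroring how the search database for gluten
peptidomics is restricted to proteins that can yield epitope-bearing
peptides. Matching is exact, case-normalized substring containment;
ambiguous residues (B, J, Z, X, U, O) never match.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord
import pandas as pd

__all__ = [
    "ProteinRecord",
    "EProtDatabase",
    "find_occurrences",
    "scan_proteome",
    "epitope_protein_counts",
    "write_eprot_fasta",
    "read_fasta",
]

_AMBIGUOUS = set("BJZXUO")


@dataclass(frozen=True)
class ProteinRecord:
    accession: str
    description: str
    sequence: str
    taxon: str | None = None


@dataclass
class EProtDatabase:
    """Retained proteins plus an epitope -> accessions index and the exact
    match positions (1-based start) per (accession, epitope)."""

    proteins: list[ProteinRecord] = field(default_factory=list)
    epitope_index: dict[str, set[str]] = field(default_factory=dict)
    occurrences: dict[tuple[str, str], tuple[int, ...]] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.proteins)

    def accessions(self) -> set[str]:
        return {p.accession for p in self.proteins}

    def sequences(self) -> dict[str, str]:
        return {p.accession: p.sequence for p in self.proteins}


def find_occurrences(sequence: str, motif: str) -> tuple[int, ...]:
    """All 1-based start positions of ``motif`` in ``sequence``, overlaps
    allowed; windows containing ambiguous residues never match."""
    hits = []
    start = sequence.find(motif)
    while start != -1:
        if not _AMBIGUOUS & set(sequence[start : start + len(motif)]):
            hits.append(start + 1)
        start = sequence.find(motif, start + 1)
    return tuple(hits)


def read_fasta(path: str | Path) -> list[ProteinRecord]:
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        desc = rec.description
        if desc.startswith(rec.id):
            desc = desc[len(rec.id) :].strip()
        records.append(ProteinRecord(rec.id, desc, str(rec.seq).upper()))
    return records


def scan_proteome(
    proteome: str | Path | Iterable[ProteinRecord],
    registry,
    collapse_il: bool = False,
) -> EProtDatabase:
    """Retain every protein whose sequence contains >= 1 complete native
    epitope from the registry's active set; input order is preserved.

    ``collapse_il`` treats isoleucine and leucine as equivalent during
    matching (off by default; the epitope catalogue gives no I/L classes).
    """
    if isinstance(proteome, (str, Path)):
        proteome = read_fasta(proteome)
    actives = registry.active_records()
    if not actives:
        raise ValueError("registry active set is empty")

    def norm(s: str) -> str:
        s = s.upper()
        return s.replace("I", "L") if collapse_il else s

    db = EProtDatabase(epitope_index={r.name: set() for r in actives})
    n_input = 0
    for prot in proteome:
        n_input += 1
        seq = prot.sequence.upper()
        hit = False
        for rec in actives:
            occ = find_occurrences(norm(seq), norm(rec.native_seq))
            if occ:
                hit = True
                db.epitope_index[rec.name].add(prot.accession)
                db.occurrences[(prot.accession, rec.name)] = occ
        if hit:
            if "amylase" in prot.description.lower():
                warnings.warn(
                    f"{prot.accession} is annotated as an alpha-amylase-inhibitor "
                    "entry but contains a celiac-active epitope; retained "
                    "(such entries have historically been re-annotated as gluten)"
                )
            db.proteins.append(
                ProteinRecord(prot.accession, prot.description, seq, prot.taxon)
            )
    if n_input == 0:
        warnings.warn("empty proteome: EProt database is empty")
    return db


def epitope_protein_counts(db: EProtDatabase) -> pd.DataFrame:
    """One row per active epitope with the number of proteins containing it
    (zero-count epitopes included)."""
    return pd.DataFrame(
        {"epitope": list(db.epitope_index), "n_proteins": [len(v) for v in db.epitope_index.values()]}
    )


def write_eprot_fasta(db: EProtDatabase, path: str | Path) -> None:
    """Write the database as wrapped FASTA (60 columns); empty databases
    produce an empty file with a warning."""
    if not db.proteins:
        warnings.warn("writing an empty EProt database")
    records = [
        SeqRecord(Seq(p.sequence), id=p.accession, description=p.description)
        for p in db.proteins
    ]
    with open(path, "w") as fh:
        SeqIO.write(records, fh, "fasta")
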