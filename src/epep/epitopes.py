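"""Registry of celiac-disease-active T-cell epitopes.

The published epitope catalogue lists 9-mer core sequences in their
deamidated form (glutamate produced by tissue transglutaminase). Wheat
proteins encode the native, glutamine-containing sequence, so matching
against a proteome requires reverting deamidation (E -> Q). Several
published epitopes collapse onto the same native 9-mer after reversion;
the registry deduplicates them, annotates internal protease cleavage
sites, derives the cleavage-shortened suffix forms used to recover
cleaved epitopes, and records the epitope groups used for sliced
analyses of gliadin peptides.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping

from .digest import SHORTFORM_ENZYMES, find_cleavage_sites

__all__ = [
    "EpitopeRecord",
    "EpitopeRegistry",
    "EPITOPE_GROUPS",
    "NON_TRITICUM",
    "revert_deamidation",
    "derive_short_forms",
    "read_epitope_table",
    "build_registry",
    "assign_groups",
    "default_registry",
]

#: Epitope names absent from all *Triticum* protein sequences (barley/oat
#: assigned); excluded from the active set by default.
NON_TRITICUM = frozenset({"PI", "PYF", "PYP", "PYI"})

#: Gliadin epitope groups defined by overlapping sequences co-occurring in
#: single peptides. Groups 1-3 are alpha-gliadin, 4 gamma-gliadin,
#: 5 gamma/omega-gliadin; IQ and ungrouped epitopes stay singletons.
EPITOPE_GROUPS: dict[int, frozenset[str]] = {
    1: frozenset({"QYI", "FR"}),
    2: frozenset({"QGS", "QGV"}),
    3: frozenset({"PYY", "PFY", "PLQ"}),
    4: frozenset({"PSQ", "SQ", "PQQ"}),
    5: frozenset({"QPY", "QPP", "QFP", "PFF", "LQ", "PQW"}),
}

_VALID_AA = set("ACDEFGHIKLMNPQRSTVWY")


def revert_deamidation(deamidated_seq: str, positions: Iterable[int] | None = None) -> str:
    """Revert transglutaminase deamidation, substituting Q for E.

    With ``positions`` (1-based) only those residues are reverted and each
    must actually be an E; otherwise every E is reverted. Non-E residues are
    never altered.
    """
    seq = deamidated_seq
    bad = set(seq) - _VALID_AA
    if bad:
        raise ValueError(f"invalid residue(s) {sorted(bad)} in {seq!r}")
    if positions is None:
        return seq.replace("E", "Q")
    chars = list(seq)
    for pos in positions:
        if not 1 <= pos <= len(seq):
            raise ValueError(f"position {pos} out of range for {seq!r}")
        if chars[pos - 1] != "E":
            raise ValueError(f"residue at position {pos} of {seq!r} is not E")
        chars[pos - 1] = "Q"
    return "".join(chars)


@dataclass(frozen=True)
class EpitopeRecord:
    """One nonredundant celiac-active epitope in native (reverted) form."""

    name: str
    full_name: str
    deamidated_seq: str
    native_seq: str
    hla_restriction: str
    protein_type: str
    in_triticum: bool
    internal_cleavage_sites: tuple[int, ...] = ()
    short_forms: tuple[str, ...] = ()
    merged_names: tuple[str, ...] = ()  # full designations collapsed into this record

    def __post_init__(self) -> None:
        if len(self.native_seq) != len(self.deamidated_seq):
            raise ValueError("native and deamidated sequences differ in length")
        for a, b in zip(self.deamidated_seq, self.native_seq):
            if a != b and not (a == "E" and b == "Q"):
                raise ValueError(
                    f"{self.name}: native sequence must differ from the deamidated "
                    f"one only by E->Q ({a!r} vs {b!r})"
                )


def derive_short_forms(
    record: EpitopeRecord,
    enzyme_rules=SHORTFORM_ENZYMES,
    min_length: int = 4,
) -> list[str]:
    """Suffixes of the native epitope remaining after cleavage at an internal
    site permitted by ``enzyme_rules`` (proline blocking applies), discarding
    suffixes shorter than ``min_length``."""
    seq = record.native_seq
    sites = find_cleavage_sites(seq, enzyme_rules)
    return [seq[i:] for i in sites if len(seq) - i >= min_length]


@dataclass
class EpitopeRegistry:
    """Nonredundant epitope records keyed by short name, with group
    assignments and the excluded (non-*Triticum*) name set."""

    records: dict[str, EpitopeRecord] = field(default_factory=dict)
    groups: dict[int, frozenset[str]] = field(default_factory=dict)
    excluded: frozenset[str] = frozenset()

    @property
    def n_nonredundant(self) -> int:
        return len(self.records)

    def active_names(self) -> list[str]:
        return [n for n in self.records if n not in self.excluded]

    def active_records(self) -> list[EpitopeRecord]:
        return [self.records[n] for n in self.active_names()]

    def group_of(self, name: str) -> int | None:
        for gid, members in self.groups.items():
            if name in members:
                return gid
        return None

    def to_json(self, path: str | Path | None = None) -> str:
        doc = {
            "records": {
                n: {
                    "full_name": r.full_name,
                    "deamidated_seq": r.deamidated_seq,
                    "native_seq": r.native_seq,
                    "hla_restriction": r.hla_restriction,
                    "protein_type": r.protein_type,
                    "in_triticum": r.in_triticum,
                    "internal_cleavage_sites": list(r.internal_cleavage_sites),
                    "short_forms": list(r.short_forms),
                    "merged_names": list(r.merged_names),
                }
                for n, r in self.records.items()
            },
            "groups": {str(g): sorted(m) for g, m in self.groups.items()},
            "excluded": sorted(self.excluded),
        }
        text = json.dumps(doc, indent=1)
        if path is not None:
            Path(path).write_text(text)
        return text


def read_epitope_table(path: str | Path) -> list[dict]:
    """Read the epitope table TSV (``#`` comment lines ignored)."""
    with open(path, encoding="utf-8") as fh:
        lines = [ln for ln in fh if not ln.startswith("#")]
    rows = list(csv.DictReader(lines, delimiter="\t"))
    required = {"name", "full_name", "deamidated_seq", "restriction", "protein_type"}
    if rows and (missing := required - set(rows[0])):
        raise ValueError(f"epitope table missing column(s): {sorted(missing)}")
    return rows


def build_registry(
    rows: Iterable[Mapping[str, str]],
    exclude_non_triticum: bool = True,
    short_form_min_length: int = 4,
) -> EpitopeRegistry:
    """Build the registry from table rows: revert deamidation, collapse rows
    sharing a native sequence (first-seen name wins, all designations kept in
    ``merged_names``), annotate cleavage sites and short forms, and assign
    epitope groups."""
    by_native: dict[str, EpitopeRecord] = {}
    name_to_native: dict[str, str] = {}
    for row in rows:
        deam = row["deamidated_seq"].strip().upper()
        native = row.get("native_seq", "").strip().upper() or revert_deamidation(deam)
        name = row["name"].strip()
        in_trit = str(row.get("in_triticum", "yes")).strip().lower() in {"yes", "true", "1"}
        if name in name_to_native and name_to_native[name] != native:
            raise ValueError(f"duplicate epitope name {name!r} with conflicting sequences")
        name_to_native[name] = native
        if native in by_native:
            prev = by_native[native]
            by_native[native] = replace(
                prev,
                in_triticum=prev.in_triticum or in_trit,
                merged_names=prev.merged_names + (row["full_name"].strip(),),
            )
            continue
        rec = EpitopeRecord(
            name=name,
            full_name=row["full_name"].strip(),
            deamidated_seq=deam,
            native_seq=native,
            hla_restriction=row["restriction"].strip(),
            protein_type=row["protein_type"].strip(),
            in_triticum=in_trit,
            merged_names=(row["full_name"].strip(),),
        )
        sites = tuple(
            i for i in find_cleavage_sites(native, SHORTFORM_ENZYMES) if i <= len(native) - 1
        )
        forms = tuple(derive_short_forms(replace(rec, internal_cleavage_sites=sites),
                                         min_length=short_form_min_length))
        by_native[native] = replace(rec, internal_cleavage_sites=sites, short_forms=forms)

    records = {rec.name: rec for rec in by_native.values()}
    excluded = frozenset(n for n, r in records.items() if not r.in_triticum) if exclude_non_triticum else frozenset()
    registry = EpitopeRegistry(records=records, excluded=excluded)
    return assign_groups(registry)


def assign_groups(
    registry: EpitopeRegistry,
    groups: Mapping[int, frozenset[str]] | None = None,
) -> EpitopeRegistry:
    """Attach gliadin epitope-group definitions.

    The built-in definitions are restricted to names present in the registry
    (partial tables are valid); explicitly supplied ``groups`` must not
    reference unknown epitopes.
    """
    strict = groups is not None
    source = groups if groups is not None else EPITOPE_GROUPS
    out: dict[int, frozenset[str]] = {}
    for gid, members in source.items():
        unknown = set(members) - set(registry.records)
        if strict and unknown:
            raise ValueError(f"group {gid} references unknown epitope(s) {sorted(unknown)}")
        present = frozenset(members) & set(registry.records)
        if present:
            out[gid] = frozenset(present)
    registry.groups = out
    return registry


def default_registry(exclude_non_triticum: bool = True) -> EpitopeRegistry:
    """Registry built from the packaged epitope table."""
    with resources.as_file(resources.files("epep.data") / "epitope_table.tsv") as p:
        return build_registry(read_epitope_table(p), exclude_non_triticum)
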