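"""MaxQuant-style peptide-table ingest, filtering and EPep matrix assembly.

Consumes a post-search peptide quantitation table (one row per peptide with
an identification score, reverse/contaminant flags and one label-free
intensity column per run) together with a sample design (species x cultivar
x technical replicates). Applies the identification filter chain: drop
reverse and contaminant rows, require score >= 40, treat zero intensity as
"not identified", require identification in at least two of three technical
replicates, and average LFQ intensities over the identified replicates.
Surviving peptides are matched against the epitope registry - complete
containment anywhere in the peptide, or an enabled cleavage-shortened form
(FR/FS by default) at the peptide N-terminus confirmed by a mapped protein
carrying the complete epitope - and assembled into an EPep x sample matrix
of mean LFQ intensities with explicit missingness.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "SampleDesign",
    "EPepMatch",
    "LFQMatrix",
    "read_peptide_table",
    "apply_filters",
    "replicate_consensus",
    "match_epitopes",
    "build_lfq_matrix",
    "run_pipeline",
]

#: Display names for gluten protein types as used in the field.
PROTEIN_TYPE_LABELS = {
    "glut-L": "LMW-GS",
    "glut-H": "HMW-GS",
    "glia-alpha": "alpha-gliadin",
    "glia-gamma": "gamma-gliadin",
    "glia-omega": "omega-gliadin",
}


@dataclass
class SampleDesign:
    """Samples (species x cultivar) and their ordered technical-replicate
    run identifiers."""

    samples: list[tuple[str, str, str]]  # (sample_id, species, cultivar)
    replicates: dict[str, list[str]]
    species_order: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        runs = [r for reps in self.replicates.values() for r in reps]
        if len(runs) != len(set(runs)):
            raise ValueError("run identifiers must be unique across samples")
        if not self.species_order:
            seen = dict.fromkeys(sp for _, sp, _ in self.samples)
            self.species_order = list(seen)

    @property
    def sample_ids(self) -> list[str]:
        return [s for s, _, _ in self.samples]

    @property
    def run_ids(self) -> list[str]:
        return [r for s in self.sample_ids for r in self.replicates[s]]

    def species_of(self, sample_id: str) -> str:
        for s, sp, _ in self.samples:
            if s == sample_id:
                return sp
        raise KeyError(sample_id)

    def samples_of_species(self, species: str) -> list[str]:
        return [s for s, sp, _ in self.samples if sp == species]

    @classmethod
    def from_table(cls, table: pd.DataFrame | str | Path) -> "SampleDesign":
        """Build from a long-format design table with columns sample_id,
        species, cultivar, run_id (one row per run)."""
        if isinstance(table, (str, Path)):
            table = pd.read_csv(table, sep="\t")
        samples, replicates = [], {}
        for (sid, sp, cv), grp in table.groupby(
            ["sample_id", "species", "cultivar"], sort=False
        ):
            samples.append((sid, sp, cv))
            replicates[sid] = list(grp["run_id"])
        return cls(samples=samples, replicates=replicates)

    def to_table(self) -> pd.DataFrame:
        rows = [
            {"sample_id": s, "species": sp, "cultivar": cv, "run_id": r}
            for s, sp, cv in self.samples
            for r in self.replicates[s]
        ]
        return pd.DataFrame(rows)


@dataclass(frozen=True)
class EPepMatch:
    peptide_sequence: str
    epitope_name: str
    position: int  # 1-based start within the peptide
    match_kind: str  # "complete" | "short_form"
    specificity_confirmed: bool | None = None  # short_form only


_MANDATORY = ["Sequence", "Proteins", "Score", "Reverse", "Potential contaminant"]


def read_peptide_table(
    table: pd.DataFrame | str | Path, design: SampleDesign
) -> pd.DataFrame:
    """Parse a MaxQuant-style peptide table into typed rows.

    Returns a DataFrame with columns ``sequence``, ``proteins`` (tuple of
    accessions), ``score``, ``is_reverse``, ``is_contaminant``, one intensity
    column per run id, and (when the table provides per-run scores) one
    ``score:<run>`` column per run. "+" markers are parsed as booleans and
    absent intensity cells as 0.
    """
    if isinstance(table, (str, Path)):
        table = pd.read_csv(table, sep="\t", dtype=str, keep_default_na=False)
    table = table.copy()
    for col in _MANDATORY:
        if col not in table.columns:
            raise ValueError(f"peptide table is missing mandatory column {col!r}")
    run_cols = {}
    for run in design.run_ids:
        col = f"Intensity {run}"
        if col not in table.columns:
            raise ValueError(f"peptide table lacks intensity column for run {run!r}")
        run_cols[run] = col
    extra = [
        c for c in table.columns
        if c.startswith("Intensity ") and c[len("Intensity "):] not in design.run_ids
    ]
    if extra:
        raise ValueError(f"intensity column(s) {extra} do not match the sample design")

    out = pd.DataFrame(
        {
            "sequence": table["Sequence"].astype(str).str.strip().str.upper(),
            "proteins": table["Proteins"]
            .astype(str)
            .map(lambda s: tuple(p for p in s.split(";") if p)),
            "score": pd.to_numeric(table["Score"], errors="coerce").fillna(0.0),
            "is_reverse": table["Reverse"].astype(str).str.strip().eq("+"),
            "is_contaminant": table["Potential contaminant"].astype(str).str.strip().eq("+"),
        }
    )
    blocks = [out]
    intens = {
        run: pd.to_numeric(table[col], errors="coerce").fillna(0.0).clip(lower=0)
        for run, col in run_cols.items()
    }
    blocks.append(pd.DataFrame(intens))
    ev_scores = {
        f"score:{run}": pd.to_numeric(table[f"Score {run}"], errors="coerce").fillna(0.0)
        for run in run_cols
        if f"Score {run}" in table.columns
    }
    if ev_scores:
        blocks.append(pd.DataFrame(ev_scores))
    return pd.concat(blocks, axis=1)


def apply_filters(
    rows: pd.DataFrame, design: SampleDesign, score_min: float = 40.0
) -> pd.DataFrame:
    """Apply the identification filter chain.

    Reverse/contaminant rows are dropped regardless of score. With row-level
    scores, rows scoring below ``score_min`` are dropped; with per-run scores
    (``score:<run>`` columns) the failing run's intensity is zeroed instead.
    Zero intensity already means "not identified in that run".
    """
    rows = rows.loc[~rows["is_reverse"] & ~rows["is_contaminant"]].copy()
    evidence_cols = [c for c in rows.columns if c.startswith("score:")]
    if evidence_cols:
        for c in evidence_cols:
            run = c[len("score:"):]
            rows.loc[rows[c] < score_min, run] = 0.0
    else:
        rows = rows.loc[rows["score"] >= score_min].copy()
    return rows


def replicate_consensus(
    rows: pd.DataFrame, design: SampleDesign, min_replicates: int = 2
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-(peptide, sample) presence and mean LFQ over identified runs.

    A peptide is present in a sample iff it was identified (nonzero,
    score-passing intensity) in at least ``min_replicates`` of its runs; for
    samples with a replicate count n != 3 the requirement scales as
    ceil(2/3 * n). The mean is computed over identified runs only.

    Returns ``(presence, mean_lfq)`` DataFrames indexed by peptide sequence
    with one column per sample id.
    """
    if rows["sequence"].duplicated().any():
        warnings.warn("duplicate peptide sequences in table; intensities summed per run")
        agg = {run: "sum" for run in design.run_ids}
        agg.update({"proteins": "first", "score": "max",
                    "is_reverse": "any", "is_contaminant": "any"})
        rows = rows.groupby("sequence", as_index=False, sort=False).agg(agg)
    seqs = rows["sequence"]
    presence = pd.DataFrame(index=seqs, dtype=bool)
    mean_lfq = pd.DataFrame(index=seqs, dtype=float)
    for sid in design.sample_ids:
        runs = design.replicates[sid]
        need = min_replicates
        if len(runs) != 3:
            warnings.warn(
                f"sample {sid} has {len(runs)} replicates; presence rule scales "
                f"to ceil(2/3*n)"
            )
            need = math.ceil(2 * len(runs) / 3)
        block = rows[runs].to_numpy(dtype=float)
        identified = block > 0
        n_id = identified.sum(axis=1)
        present = n_id >= need
        with np.errstate(invalid="ignore"):
            means = np.where(
                present, block.sum(axis=1) / np.maximum(n_id, 1), np.nan
            )
        presence[sid] = present
        mean_lfq[sid] = means
    return presence, mean_lfq


def match_epitopes(
    sequence: str,
    registry,
    protein_seqs: Mapping[str, str] | None = None,
    accessions: Iterable[str] = (),
    enabled_short_forms: frozenset[str] = frozenset({"FR", "FS"}),
) -> list[EPepMatch]:
    """All epitope matches within a peptide.

    Complete matches report every occurrence (overlaps allowed). A peptide
    whose N-terminus equals an enabled short form additionally yields a
    short-form match; its specificity is confirmed iff at least one mapped
    protein contains the complete native epitope. Unconfirmed short-form
    matches are reported flagged False and do not confer EPep status.
    """
    from .eprot import find_occurrences

    sequence = sequence.upper()
    matches: list[EPepMatch] = []
    accessions = tuple(accessions)
    for rec in registry.active_records():
        for pos in find_occurrences(sequence, rec.native_seq):
            matches.append(EPepMatch(sequence, rec.name, pos, "complete"))
        if rec.name in enabled_short_forms:
            for sf in rec.short_forms:
                if sequence.startswith(sf):
                    if protein_seqs is None:
                        raise ValueError(
                            "protein sequences required to confirm short-form specificity"
                        )
                    missing = [a for a in accessions if a not in protein_seqs]
                    if missing:
                        raise KeyError(
                            f"accession(s) {missing} missing from protein_seqs; "
                            "short-form specificity cannot be evaluated"
                        )
                    confirmed = any(
                        rec.native_seq in protein_seqs[a] for a in accessions
                    )
                    matches.append(
                        EPepMatch(sequence, rec.name, 1, "short_form", confirmed)
                    )
    return matches


def _qualifying(matches: Iterable[EPepMatch]) -> list[EPepMatch]:
    return [
        m
        for m in matches
        if m.match_kind == "complete"
        or (m.match_kind == "short_form" and m.specificity_confirmed)
    ]


@dataclass
class LFQMatrix:
    """EPeps x samples mean LFQ intensities (NaN = not present) with
    per-row epitope annotations."""

    values: pd.DataFrame
    row_annotations: pd.DataFrame  # epitopes, match_kinds, groups, protein_types
    design: SampleDesign

    @property
    def presence(self) -> pd.DataFrame:
        return self.values.notna()

    def sample_counts(self) -> pd.Series:
        """Number of distinct EPeps present per sample."""
        return self.presence.sum(axis=0)

    def species_sets(self) -> dict[str, set[str]]:
        """EPep set per species, union over its cultivars."""
        out: dict[str, set[str]] = {}
        for sp in self.design.species_order:
            cols = self.design.samples_of_species(sp)
            mask = self.presence[cols].any(axis=1)
            out[sp] = set(self.values.index[mask])
        return out

    def to_long(self) -> pd.DataFrame:
        long = (
            self.values.rename_axis("sequence")
            .reset_index()
            .melt(id_vars="sequence", var_name="sample_id", value_name="mean_lfq")
            .dropna(subset=["mean_lfq"])
        )
        return long

    def to_table(self) -> pd.DataFrame:
        return pd.concat([self.row_annotations, self.values], axis=1)


def build_lfq_matrix(
    rows: pd.DataFrame,
    presence: pd.DataFrame,
    mean_lfq: pd.DataFrame,
    registry,
    protein_seqs: Mapping[str, str],
    design: SampleDesign,
    enabled_short_forms: frozenset[str] = frozenset({"FR", "FS"}),
) -> LFQMatrix:
    """Restrict the consensus matrix to EPeps and attach row annotations
    (epitope names, match kinds, epitope groups, gluten protein types)."""
    prot_by_seq = dict(zip(rows["sequence"], rows["proteins"]))
    keep, annots = [], []
    for seq in mean_lfq.index:
        if not presence.loc[seq].any():
            continue
        matches = _qualifying(
            match_epitopes(
                seq, registry, protein_seqs, prot_by_seq.get(seq, ()), enabled_short_forms
            )
        )
        if not matches:
            continue
        names = sorted({m.epitope_name for m in matches})
        kinds = sorted({m.match_kind for m in matches})
        groups = sorted({g for n in names if (g := registry.group_of(n)) is not None})
        types = sorted({registry.records[n].protein_type for n in names})
        keep.append(seq)
        annots.append(
            {
                "epitopes": ";".join(names),
                "match_kinds": ";".join(kinds),
                "groups": ";".join(map(str, groups)),
                "protein_types": ";".join(types),
            }
        )
    values = mean_lfq.loc[keep].where(presence.loc[keep])
    return LFQMatrix(
        values=values,
        row_annotations=pd.DataFrame(annots, index=pd.Index(keep, name="sequence")),
        design=design,
    )


def run_pipeline(
    table: pd.DataFrame | str | Path,
    design: SampleDesign,
    registry,
    protein_seqs: Mapping[str, str],
    score_min: float = 40.0,
    min_replicates: int = 2,
    enabled_short_forms: frozenset[str] = frozenset({"FR", "FS"}),
) -> LFQMatrix:
    """Full ingest: parse, filter, replicate consensus, epitope matching,
    EPep LFQ matrix."""
    rows = read_peptide_table(table, design)
    rows = apply_filters(rows, design, score_min)
    presence, mean_lfq = replicate_consensus(rows, design, min_replicates)
    return build_lfq_matrix(
        rows, presence, mean_lfq, registry, protein_seqs, design, enabled_short_forms
    )
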