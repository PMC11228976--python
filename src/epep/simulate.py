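"""Synthetic gluten-peptidomics studies with planted ground truth.

Generates a fully self-contained study - gluten-like proteome FASTA,
MaxQuant-style peptide quantitation table and sample design - whose
statistical structure emulates a multi-species wheat comparison: five
species of three ploidy levels (diploid einkorn, tetraploid emmer and durum
wheat, hexaploid common wheat and spelt) x eight cultivars x three technical
replicates. Epitope availability is restricted by simulated subgenomes (A,
B, D) so hexaploid species draw from a superset of epitope pools; protein
backgrounds are glutamine/proline-rich to stress overlapping-epitope
matching; intensities are log-normal so the pipeline's ln-transformation
yields Gaussian structure; replicate dropout, contaminant rows, reversed
decoy rows and an identification-score distribution exercise the filter
chain. Every artifact is reproducible from the seed, and the generator
records its own truth - planted epitope positions and the expected post-
filter EPep presence matrix - against which pipeline recovery is scored.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .digest import DEFAULT_ENZYMES, DigestParams, digest
from .eprot import ProteinRecord, find_occurrences
from .quant import SampleDesign

__all__ = [
    "StudyDesignSpec",
    "SpeciesProfile",
    "SimParams",
    "SimTruth",
    "SimulatedStudy",
    "reference_scenario",
    "generate_proteome",
    "simulate_peptide_table",
    "generate_study",
    "recovery_report",
    "write_study",
]

PLOIDY_SUBGENOMES = {"diploid": ("A",), "tetraploid": ("A", "B"),
                     "hexaploid": ("A", "B", "D")}

#: Which epitopes may occur on which simulated subgenome. Hexaploid species
#: (A+B+D) therefore carry a superset of the diploid (A) pool; epitopes
#: restricted to B or D (e.g. PFV, SQ, PQQ, QPY) never occur in einkorn.
DEFAULT_SUBGENOME_POOLS = {
    "A": ("FS", "QGS", "QGV", "FR", "QYI", "IQ", "QFP", "LQ"),
    "B": ("PFV", "SQ", "PQQ", "QGY", "PFF", "PQW", "QPP"),
    "D": ("PYY", "PFY", "PLQ", "QPY", "PSQ", "PQC", "PFP"),
}


@dataclass(frozen=True)
class StudyDesignSpec:
    """Study layout: species with ploidy, cultivars per species, technical
    replicates, and the seed that makes generation reproducible."""

    species: tuple[tuple[str, str], ...] = (
        ("common_wheat", "hexaploid"),
        ("spelt", "hexaploid"),
        ("durum", "tetraploid"),
        ("emmer", "tetraploid"),
        ("einkorn", "diploid"),
    )
    cultivars_per_species: int = 8
    replicates: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.cultivars_per_species < 1 or self.replicates < 1 or not self.species:
            raise ValueError("all design counts must be >= 1")

    def sample_design(self) -> SampleDesign:
        samples, reps = [], {}
        for sp, _ in self.species:
            for j in range(self.cultivars_per_species):
                cv = f"cv{j + 1:02d}"
                sid = f"{sp}_{cv}"
                samples.append((sid, sp, cv))
                reps[sid] = [f"{sid}_r{k + 1}" for k in range(self.replicates)]
        return SampleDesign(samples=samples, replicates=reps,
                            species_order=[sp for sp, _ in self.species])


@dataclass(frozen=True)
class SpeciesProfile:
    """How a species samples the shared subgenome proteins: the fraction of
    each available subgenome pool it keeps, how many private proteins it
    carries, and multiplicative intensity boosts for peptides bearing
    particular epitopes."""

    keep_fraction: float = 1.0
    n_private: int = 2
    intensity_boost: dict[str, float] = field(default_factory=dict)


@dataclass(frozen=True)
class SimParams:
    """Generator parameters; defaults define the reference scenario."""

    subgenome_pools: dict[str, tuple[str, ...]] = field(
        default_factory=lambda: dict(DEFAULT_SUBGENOME_POOLS)
    )
    proteins_per_subgenome: int = 6
    species_profiles: dict[str, SpeciesProfile] = field(
        default_factory=lambda: {
            "common_wheat": SpeciesProfile(keep_fraction=0.90, n_private=2),
            "spelt": SpeciesProfile(keep_fraction=1.0, n_private=3),
            "durum": SpeciesProfile(keep_fraction=0.78, n_private=2),
            "emmer": SpeciesProfile(keep_fraction=0.85, n_private=3),
            # narrow pool, but elevated intensities for FS/QGS peptides
            "einkorn": SpeciesProfile(
                keep_fraction=0.55, n_private=2,
                intensity_boost={"FS": 3.0, "QGS": 3.0},
            ),
        }
    )
    protein_length: int = 70
    epitopes_per_protein: tuple[int, int] = (1, 2)
    qp_fraction: float = 0.6  # gluten-like Q/P-rich background
    intensity_location: float = 16.0  # ln-intensity mean (LFQ ~ 9e6)
    intensity_scale: float = 1.2
    cultivar_effect_scale: float = 0.3
    replicate_noise_scale: float = 0.25
    dropout: float = 0.1
    cultivar_protein_dropout: float = 0.08
    n_contaminants: int = 10
    n_reverse: int = 10
    score_loc: float = 120.0
    score_scale: float = 40.0
    score_floor: float = 0.0
    score_ceiling: float = 300.0
    digest_params: DigestParams = DigestParams()

    def __post_init__(self) -> None:
        for p in (self.dropout, self.cultivar_protein_dropout, self.qp_fraction):
            if not 0 <= p <= 1:
                raise ValueError("probabilities must lie in [0, 1]")
        for s in (self.intensity_scale, self.replicate_noise_scale, self.score_scale):
            if s <= 0:
                raise ValueError("scales must be positive")


def reference_scenario(seed: int = 0, dropout: float = 0.1) -> tuple[StudyDesignSpec, SimParams]:
    """The preset study: 5 species x 8 cultivars x 3 replicates, epitope
    pools widening with ploidy, einkorn with a narrow pool but boosted
    FS/QGS intensities."""
    return StudyDesignSpec(seed=seed), replace(SimParams(), dropout=dropout)


@dataclass
class SimTruth:
    """Planted ground truth, recomputable from seed and parameters."""

    epitope_positions: dict[str, dict[str, tuple[int, ...]]] = field(default_factory=dict)
    species_proteins: dict[str, set[str]] = field(default_factory=dict)
    cultivar_proteins: dict[str, set[str]] = field(default_factory=dict)
    expected_presence: pd.DataFrame | None = None  # EPep seq x sample, bool
    expected_means: pd.DataFrame | None = None  # EPep seq x sample, NaN if absent

    def expected_species_counts(self, design: SampleDesign) -> pd.DataFrame:
        pres = self.expected_presence
        rows = []
        for sid in design.sample_ids:
            rows.append({"sample_id": sid, "species": design.species_of(sid),
                         "n_epeps": int(pres[sid].sum())})
        return pd.DataFrame(rows)

    def expected_species_sets(self, design: SampleDesign) -> dict[str, set[str]]:
        out = {}
        for sp in design.species_order:
            cols = design.samples_of_species(sp)
            mask = self.expected_presence[cols].any(axis=1)
            out[sp] = set(self.expected_presence.index[mask])
        return out


@dataclass
class SimulatedStudy:
    proteome: list[ProteinRecord]
    peptide_table: pd.DataFrame
    sample_design: SampleDesign
    truth: SimTruth
    design_spec: StudyDesignSpec
    params: SimParams


_AA = np.array(list("ACDEFGHIKLMNRSTVWY"))  # background alphabet sans Q/P


def _background(rng: np.random.Generator, length: int, qp_fraction: float) -> np.ndarray:
    """Q/P-rich random residues mimicking gluten repetitive domains."""
    u = rng.random(length)
    out = np.empty(length, dtype="<U1")
    q_cut = qp_fraction * 0.58  # Q somewhat more frequent than P, as in gluten
    out[u < q_cut] = "Q"
    out[(u >= q_cut) & (u < qp_fraction)] = "P"
    n_rest = int((u >= qp_fraction).sum())
    out[u >= qp_fraction] = rng.choice(_AA, size=n_rest)
    return out


def _make_protein(rng, accession, description, pool, registry, params) -> ProteinRecord:
    seq = _background(rng, params.protein_length, params.qp_fraction)
    lo, hi = params.epitopes_per_protein
    n_epi = int(rng.integers(lo, hi + 1))
    chosen = rng.choice(len(pool), size=n_epi, replace=True)
    occupied: list[tuple[int, int]] = []
    for ci in chosen:
        native = registry.records[pool[ci]].native_seq
        for _ in range(20):  # find a non-overlapping slot
            start = int(rng.integers(0, params.protein_length - len(native) + 1))
            if all(start + len(native) <= a or start >= b for a, b in occupied):
                seq[start : start + len(native)] = list(native)
                occupied.append((start, start + len(native)))
                break
    return ProteinRecord(accession, description, "".join(seq))


def generate_proteome(
    design: StudyDesignSpec, registry, params: SimParams, seed: int | None = None
) -> tuple[list[ProteinRecord], SimTruth]:
    """Shared subgenome proteins plus species-private proteins, with planted
    epitopes; truth records per-protein epitope positions (verified by
    substring scan of the emitted sequences) and per-species/cultivar
    repertoires."""
    rng = np.random.default_rng(design.seed if seed is None else seed)
    active = set(registry.active_names())
    pools = {g: tuple(e for e in members if e in active)
             for g, members in params.subgenome_pools.items()}
    unknown = {e for members in params.subgenome_pools.values() for e in members} - set(
        registry.records
    )
    if unknown:
        raise ValueError(f"epitope pool references unknown epitope(s) {sorted(unknown)}")

    shared: dict[str, list[ProteinRecord]] = {}
    proteome: list[ProteinRecord] = []
    for g in sorted(pools):
        shared[g] = []
        for k in range(params.proteins_per_subgenome):
            prot = _make_protein(
                rng, f"SYN{g}{k + 1:02d}",
                f"synthetic gluten-like protein, subgenome {g}", pools[g],
                registry, params,
            )
            shared[g].append(prot)
            proteome.append(prot)

    truth = SimTruth()
    for sp, ploidy in design.species:
        profile = params.species_profiles.get(sp, SpeciesProfile())
        repertoire: set[str] = set()
        for g in PLOIDY_SUBGENOMES[ploidy]:
            cand = shared.get(g, [])
            n_keep = int(round(profile.keep_fraction * len(cand)))
            kept = rng.choice(len(cand), size=n_keep, replace=False)
            repertoire.update(cand[i].accession for i in sorted(kept))
        species_pool = tuple(
            e for g in PLOIDY_SUBGENOMES[ploidy] for e in pools.get(g, ())
        )
        for k in range(profile.n_private):
            prot = _make_protein(
                rng, f"SYN{sp.upper()[:3]}{k + 1:02d}",
                f"synthetic gluten-like protein, private to {sp}",
                species_pool or tuple(active), registry, params,
            )
            proteome.append(prot)
            repertoire.add(prot.accession)
        truth.species_proteins[sp] = repertoire

    # per-cultivar repertoires: species repertoire minus random losses
    sdesign = design.sample_design()
    for sid, sp, _ in sdesign.samples:
        lost = {a for a in sorted(truth.species_proteins[sp])
                if rng.random() < params.cultivar_protein_dropout}
        truth.cultivar_proteins[sid] = truth.species_proteins[sp] - lost

    for prot in proteome:
        hits = {}
        for name in sorted(active):
            occ = find_occurrences(prot.sequence, registry.records[name].native_seq)
            if occ:
                hits[name] = occ
        truth.epitope_positions[prot.accession] = hits
    return proteome, truth


def _is_epep(seq: str, parents, registry, truth, enabled_short_forms) -> bool:
    """Generator-side EPep rule: complete epitope contained, or an enabled
    short form at the N-terminus with a parent protein carrying the
    complete epitope."""
    for name in registry.active_names():
        rec = registry.records[name]
        if rec.native_seq in seq:
            return True
        if name in enabled_short_forms and any(seq.startswith(sf) for sf in rec.short_forms):
            if any(name in truth.epitope_positions.get(a, {}) for a in parents):
                return True
    return False


def simulate_peptide_table(
    proteome: list[ProteinRecord],
    truth: SimTruth,
    design: StudyDesignSpec,
    params: SimParams,
    registry,
    seed: int | None = None,
    enabled_short_forms: frozenset[str] = frozenset({"FR", "FS"}),
) -> tuple[pd.DataFrame, SimTruth]:
    """In-silico digest of the planted proteome with per-run log-normal
    intensities, replicate dropout, identification scores and flagged
    contaminant/decoy rows; updates truth with the expected post-filter
    EPep presence/mean matrices."""
    rng = np.random.default_rng((design.seed if seed is None else seed) + 1)
    sdesign = design.sample_design()

    parents: dict[str, set[str]] = {}
    for prot in proteome:
        for pep in digest(prot.sequence, DEFAULT_ENZYMES, params.digest_params,
                          accession=prot.accession):
            parents.setdefault(pep.sequence, set()).add(prot.accession)
    seqs = sorted(parents)
    n = len(seqs)
    samples = sdesign.sample_ids
    n_s, n_r = len(samples), design.replicates

    # peptide expressed in a cultivar iff any parent protein is in its repertoire
    expressed = np.zeros((n, n_s), dtype=bool)
    for j, sid in enumerate(samples):
        rep = truth.cultivar_proteins[sid]
        expressed[:, j] = [bool(parents[s] & rep) for s in seqs]

    base = rng.normal(params.intensity_location, params.intensity_scale, size=n)
    cult = rng.normal(0.0, params.cultivar_effect_scale, size=(n, n_s))
    noise = rng.normal(0.0, params.replicate_noise_scale, size=(n, n_s, n_r))
    drop = rng.random((n, n_s, n_r)) < params.dropout
    scores = np.clip(
        rng.normal(params.score_loc, params.score_scale, size=n),
        params.score_floor, params.score_ceiling,
    )

    boost = np.zeros((n, n_s))
    for j, sid in enumerate(samples):
        sp = sdesign.species_of(sid)
        boosts = params.species_profiles.get(sp, SpeciesProfile()).intensity_boost
        if not boosts:
            continue
        factors = np.array([
            max(
                [b for e, b in boosts.items()
                 if registry.records[e].native_seq in s],
                default=1.0,
            )
            for s in seqs
        ])
        boost[:, j] = np.log(factors)

    ln_int = base[:, None, None] + cult[:, :, None] + boost[:, :, None] + noise
    intensity = np.where(expressed[:, :, None] & ~drop, np.exp(ln_int), 0.0)

    run_cols = [r for sid in samples for r in sdesign.replicates[sid]]
    flat = intensity.reshape(n, n_s * n_r)
    meta = pd.DataFrame({
        "Sequence": seqs,
        "Proteins": [";".join(sorted(parents[s])) for s in seqs],
        "Score": np.round(scores, 3),
        "Reverse": "",
        "Potential contaminant": "",
    })
    intens = pd.DataFrame(np.round(flat, 3),
                          columns=[f"Intensity {c}" for c in run_cols])
    table = pd.concat([meta, intens], axis=1)

    # flagged rows: planted sequences, scrambled (and decoys reversed) so that
    # only the flag - not the sequence - drives their exclusion
    peptide_set = set(seqs)
    extra = []
    epep_seqs = [s for s in seqs if _is_epep(s, parents[s], registry, truth,
                                             enabled_short_forms)]
    for kind, count in (("contaminant", params.n_contaminants),
                        ("reverse", params.n_reverse)):
        for _ in range(count):
            src = epep_seqs[int(rng.integers(len(epep_seqs)))] if epep_seqs else "QPQLPYPQPQ"
            if kind == "reverse":
                cand = src[::-1]
                if cand in peptide_set:
                    cand = (src + "K")[::-1]
            else:
                for _ in range(10):
                    perm = rng.permutation(len(src))
                    cand = "".join(src[i] for i in perm)
                    if cand not in peptide_set:
                        break
            peptide_set.add(cand)
            row = {
                "Sequence": cand,
                "Proteins": "CON__SYN" if kind == "contaminant" else "REV__SYN",
                "Score": float(np.round(np.clip(
                    rng.normal(params.score_loc, params.score_scale),
                    params.score_floor, params.score_ceiling), 3)),
                "Reverse": "+" if kind == "reverse" else "",
                "Potential contaminant": "+" if kind == "contaminant" else "",
            }
            vals = np.round(np.exp(rng.normal(
                params.intensity_location, params.intensity_scale,
                size=len(run_cols))), 3)
            row.update({f"Intensity {c}": v for c, v in zip(run_cols, vals)})
            extra.append(row)
    if extra:
        table = pd.concat([table, pd.DataFrame(extra)], ignore_index=True)

    # expected post-filter EPep matrix from the generator's own draws
    is_epep = np.array([s in set(epep_seqs) for s in seqs])
    identified = intensity > 0
    n_id = identified.sum(axis=2)
    present = (n_id >= 2) & (scores >= 40.0)[:, None] & is_epep[:, None]
    with np.errstate(invalid="ignore"):
        means = np.where(present,
                         np.round(flat, 3).reshape(n, n_s, n_r).sum(axis=2)
                         / np.maximum(n_id, 1), np.nan)
    truth.expected_presence = pd.DataFrame(
        present[is_epep], index=pd.Index(np.array(seqs)[is_epep], name="sequence"),
        columns=samples,
    )
    truth.expected_means = pd.DataFrame(
        means[is_epep], index=truth.expected_presence.index, columns=samples
    )
    return table, truth


def generate_study(
    design: StudyDesignSpec | None = None,
    params: SimParams | None = None,
    registry=None,
    seed: int | None = None,
) -> SimulatedStudy:
    """Generate a complete study (proteome, peptide table, design, truth)."""
    from .epitopes import default_registry

    design = design or StudyDesignSpec()
    if seed is not None:
        design = replace(design, seed=seed)
    params = params or SimParams()
    registry = registry or default_registry()
    proteome, truth = generate_proteome(design, registry, params)
    table, truth = simulate_peptide_table(proteome, truth, design, params, registry)
    return SimulatedStudy(proteome, table, design.sample_design(), truth, design, params)


def recovery_report(matrix, truth: SimTruth) -> dict:
    """Score pipeline output against planted truth.

    sensitivity = recovered planted (EPep, sample) presences / truth
    presences; specificity = 1 - spurious presences / possible negatives
    over the union of truth and recovered EPep rows; per-species count
    deltas accompany them.
    """
    pres = matrix.presence
    tpres = truth.expected_presence
    if list(pres.columns) != list(tpres.columns):
        raise ValueError("pipeline output and truth use different sample designs")
    all_seqs = sorted(set(pres.index) | set(tpres.index))
    P = pres.reindex(all_seqs, fill_value=False).to_numpy()
    T = tpres.reindex(all_seqs, fill_value=False).to_numpy()
    tp = int((P & T).sum())
    fp = int((P & ~T).sum())
    fn = int((~P & T).sum())
    tn = int((~P & ~T).sum())
    design = matrix.design
    deltas = {}
    for sid in design.sample_ids:
        deltas[sid] = int(pres.reindex(all_seqs, fill_value=False)[sid].sum()
                          - tpres.reindex(all_seqs, fill_value=False)[sid].sum())
    return {
        "sensitivity": tp / (tp + fn) if tp + fn else 1.0,
        "specificity": tn / (tn + fp) if tn + fp else 1.0,
        "true_positives": tp, "false_positives": fp,
        "false_negatives": fn, "true_negatives": tn,
        "per_sample_count_delta": deltas,
    }


def write_study(study: SimulatedStudy, outdir) -> dict[str, str]:
    """Write FASTA, peptide table, design table and truth JSON; byte-stable
    for a fixed seed."""
    import json
    from pathlib import Path

    from .eprot import write_eprot_fasta, EProtDatabase

    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    fasta = out / "proteome.fasta"
    db = EProtDatabase(proteins=study.proteome)
    write_eprot_fasta(db, fasta)
    table = out / "peptides.tsv"
    study.peptide_table.to_csv(table, sep="\t", index=False, float_format="%.3f")
    design = out / "design.tsv"
    study.sample_design.to_table().to_csv(design, sep="\t", index=False)
    truth = out / "truth.json"
    doc = {
        "epitope_positions": {a: {e: list(p) for e, p in h.items()}
                              for a, h in study.truth.epitope_positions.items()},
        "species_proteins": {s: sorted(v) for s, v in study.truth.species_proteins.items()},
        "cultivar_proteins": {s: sorted(v) for s, v in study.truth.cultivar_proteins.items()},
        "expected_presence": {
            seq: [int(v) for v in row]
            for seq, row in study.truth.expected_presence.iterrows()
        },
        "samples": list(study.truth.expected_presence.columns),
    }
    truth.write_text(json.dumps(doc, indent=1, sort_keys=True))
    return {"fasta": str(fasta), "peptides": str(table),
            "design": str(design), "truth": str(truth)}
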