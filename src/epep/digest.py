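"""In-silico tryptic/chymotryptic digestion.

Emulates the sample-preparation proteolysis and the search-engine digestion
settings used for gluten peptidomics: cleavage-site prediction for trypsin and
chymotrypsin, exhaustive fragment generation with missed cleavages, and the
length/mass filters applied during peptide identification (minimum seven
residues, at most 5000 Da with carbamidomethylated cysteines).

Two chymotrypsin presets are provided because search configuration and enzyme
biology differ on one point: the search-engine setting ("chymotrypsin+") cuts
after F, L, M, W, Y unconditionally, while the biological rule suppresses
cleavage when proline follows. Digestion defaults to the search-engine preset;
epitope short-form derivation uses the proline-blocked preset.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

from pyteomics import mass as _pmass

__all__ = [
    "EnzymeRule",
    "DigestParams",
    "TheoreticalPeptide",
    "TRYPSIN",
    "CHYMOTRYPSIN_PLUS",
    "CHYMOTRYPSIN_BLOCKED",
    "DEFAULT_ENZYMES",
    "SHORTFORM_ENZYMES",
    "find_cleavage_sites",
    "digest",
    "peptide_mono_mass",
    "theoretical_epeps",
    "eprot_coverage",
]

STANDARD_AA = set("ACDEFGHIKLMNPQRSTVWY")

#: Monoisotopic mass of water (peptide termini), Da.
WATER_MONO = _pmass.calculate_mass(formula="H2O")

#: Carbamidomethylation of cysteine (fixed modification), Da.
CARBAMIDOMETHYL = 57.02146


@dataclass(frozen=True)
class EnzymeRule:
    """A protease cleavage specificity: cut C-terminally of ``cut_after``
    residues unless the next residue is in ``blocked_before``."""

    name: str
    cut_after: frozenset[str]
    blocked_before: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if not self.cut_after:
            raise ValueError("cut_after must be non-empty")


TRYPSIN = EnzymeRule("trypsin", frozenset("KR"), frozenset("P"))
CHYMOTRYPSIN_PLUS = EnzymeRule("chymotrypsin+", frozenset("FLMWY"))
CHYMOTRYPSIN_BLOCKED = EnzymeRule("chymotrypsin", frozenset("FLMWY"), frozenset("P"))

#: Search-engine configuration: trypsin + unblocked chymotrypsin.
DEFAULT_ENZYMES = (TRYPSIN, CHYMOTRYPSIN_PLUS)
#: Biological rule set used when deriving cleaved epitope short forms.
SHORTFORM_ENZYMES = (TRYPSIN, CHYMOTRYPSIN_BLOCKED)


@dataclass(frozen=True)
class DigestParams:
    """Digestion and identification filters.

    Defaults mirror the peptide-identification settings: up to ten missed
    cleavage sites, minimum length seven, maximum (modified) monoisotopic
    mass 5000 Da, cysteines carbamidomethylated.
    """

    max_missed_cleavages: int = 10
    min_length: int = 7
    max_mass: float = 5000.0
    fixed_mod_mass_per_C: float = CARBAMIDOMETHYL

    def __post_init__(self) -> None:
        if self.max_missed_cleavages < 0 or self.max_mass < 0:
            raise ValueError("digestion parameters must be non-negative")
        if self.min_length < 1:
            raise ValueError("min_length must be >= 1")


@dataclass(frozen=True)
class TheoreticalPeptide:
    sequence: str
    parent_accession: str
    start: int  # 1-based inclusive
    end: int  # 1-based inclusive
    missed_cleavages: int
    mono_mass: float
    epitopes: tuple[str, ...] = field(default=())


def find_cleavage_sites(sequence: str, rules) -> list[int]:
    """Positions (1-based) after which any of ``rules`` may cut.

    The sequence terminus is never a site. A position qualifies when its
    residue is in an enzyme's ``cut_after`` set and the following residue is
    not in that enzyme's ``blocked_before`` set.
    """
    if isinstance(rules, EnzymeRule):
        rules = (rules,)
    sites = []
    for i in range(len(sequence) - 1):
        res, nxt = sequence[i], sequence[i + 1]
        if any(res in r.cut_after and nxt not in r.blocked_before for r in rules):
            sites.append(i + 1)
    return sites


def peptide_mono_mass(sequence: str, fixed_mod_mass_per_C: float = CARBAMIDOMETHYL) -> float:
    """Monoisotopic peptide mass in Da, cysteines carrying the fixed
    carbamidomethyl modification."""
    bad = set(sequence) - STANDARD_AA
    if bad:
        raise ValueError(f"non-standard residue(s) {sorted(bad)} in {sequence!r}")
    base = sum(_pmass.std_aa_mass[a] for a in sequence) + WATER_MONO
    return base + fixed_mod_mass_per_C * sequence.count("C")


def digest(
    sequence: str,
    rules=DEFAULT_ENZYMES,
    params: DigestParams = DigestParams(),
    accession: str = "",
) -> list[TheoreticalPeptide]:
    """All site-delimited fragments of ``sequence`` with at most
    ``params.max_missed_cleavages`` internal sites spanned, then filtered by
    minimum length and maximum modified mass.

    Fragments are returned in (start, end) order; coordinates are 1-based
    inclusive in the parent.
    """
    sequence = sequence.upper()
    sites = find_cleavage_sites(sequence, rules)
    bounds = [0] + sites + [len(sequence)]
    out = []
    for i, j in itertools.combinations(range(len(bounds)), 2):
        missed = j - i - 1
        if missed > params.max_missed_cleavages:
            continue
        frag = sequence[bounds[i] : bounds[j]]
        if len(frag) < params.min_length:
            continue
        try:
            m = peptide_mono_mass(frag, params.fixed_mod_mass_per_C)
        except ValueError:
            continue  # ambiguous residues in parent: fragment not searchable
        if m > params.max_mass:
            continue
        out.append(
            TheoreticalPeptide(
                sequence=frag,
                parent_accession=accession,
                start=bounds[i] + 1,
                end=bounds[j],
                missed_cleavages=missed,
                mono_mass=m,
            )
        )
    return out


def theoretical_epeps(
    db,
    registry,
    rules=DEFAULT_ENZYMES,
    params: DigestParams = DigestParams(),
    enabled_short_forms: frozenset[str] = frozenset({"FR", "FS"}),
) -> list[TheoreticalPeptide]:
    """Theoretical digestion peptides of every database protein that carry at
    least one complete native epitope, or start with an enabled short form
    whose parent protein contains the complete epitope."""
    out = []
    for prot in db.proteins:
        for pep in digest(prot.sequence, rules, params, accession=prot.accession):
            hits = []
            for rec in registry.active_records():
                if rec.native_seq in pep.sequence:
                    hits.append(rec.name)
                elif (
                    rec.name in enabled_short_forms
                    and any(pep.sequence.startswith(sf) for sf in rec.short_forms)
                    and rec.native_seq in prot.sequence
                ):
                    hits.append(rec.name)
            if hits:
                out.append(
                    TheoreticalPeptide(
                        **{**pep.__dict__, "epitopes": tuple(sorted(set(hits)))}
                    )
                )
    return out


def eprot_coverage(
    db,
    registry,
    rules=DEFAULT_ENZYMES,
    params: DigestParams = DigestParams(),
    enabled_short_forms: frozenset[str] = frozenset({"FR", "FS"}),
) -> float:
    """Fraction of database proteins that yield at least one theoretical
    epitope-bearing peptide under the digestion constraints."""
    if not db.proteins:
        raise ValueError("coverage undefined for an empty database")
    covered = {p.parent_accession for p in theoretical_epeps(db, registry, rules, params, enabled_short_forms)}
    return len(covered) / len(db.proteins)
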