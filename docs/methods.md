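# Methods

This note documents the models, rules and numerical choices behind `epep`,
and what the synthetic studies do and do not establish about real data.

## Epitope registry

CD-active T-cell epitopes are published as deamidated 9-mer cores. Because
tissue transglutaminase deamidation converts glutamine to glutamate,
matching plant-encoded sequences requires the reverse substitution. The
default reversal replaces **every** E with Q; a per-record list of 1-based
positions can restrict the substitution when only specific residues were
deamidated. Reversal is idempotent and length-preserving, and rejects
positions that do not hold an E.

Several published epitopes collapse onto one native 9-mer after reversal
(the same core is catalogued under multiple HLA restrictions, or shared by
wheat gliadins and their barley/rye homologues hordein and secalin). The
registry deduplicates by native sequence; the first-seen short name becomes
the record key and all collapsed designations are retained in
`merged_names`. The shipped table reconstructs the published catalogue's
structure — 38 entries, 27 nonredundant native sequences, 23 of them found
in *Triticum* — with the four barley/oat-assigned epitopes (PI, PYF, PYP,
PYI) excluded from the active set by default. The reconstruction is
labelled as such in the data file: the original figure is not
redistributable, so sequences not quoted verbatim in the study text were
taken from the standard epitope nomenclature where known and otherwise
chosen as plausible 9-mers consistent with every documented count and
grouping. Analyses that depend only on table *structure* (counts,
deduplication, grouping, short-form logic) are unaffected by this choice;
analyses of specific real proteomes would require the authoritative table.

**Short forms.** A protease cut inside an epitope leaves a suffix that can
still appear at a peptide's N-terminus. Short forms are derived with the
biological enzyme rules (trypsin K/R and chymotrypsin F/L/M/W/Y, both
blocked before proline), keeping suffixes of ≥ 4 residues (configurable);
shorter suffixes are too unspecific to be useful surrogates. Only the FR
and FS short forms participate in EPep selection by default — they are the
two for which specific matches were observed — but the set is
configurable.

**Groups.** Overlapping gliadin epitopes that co-occur in single peptides
are analysed as groups: 1 = {QYI, FR}, 2 = {QGS, QGV}, 3 = {PYY, PFY,
PLQ} (α-gliadins), 4 = {PSQ, SQ, PQQ} (γ-gliadins), 5 = {QPY, QPP, QFP,
PFF, LQ, PQW} (γ/ω-gliadins). IQ and the glutenin epitopes stay
singletons. An epitope belongs to at most one group.

## EProt database

A protein qualifies as an EProt iff its sequence contains ≥ 1 complete
native epitope as a contiguous substring. Matching is case-normalized and
exact; isoleucine/leucine are **not** collapsed (no I/L equivalence is
documented for these epitopes; a `collapse_il` flag exists for sensitivity
analyses). Ambiguous residues (B, J, Z, X, U, O) never match. All
occurrence positions are recorded, overlaps allowed. Entries annotated as
alpha-amylase-inhibitor proteins are retained with a warning when they
contain an epitope — such UniProtKB entries have historically turned out
to be misannotated gluten sequences.

## In-silico digestion

Cleavage sites are the union over enzyme rules; a site exists after
position *i* iff residue *i* is in the enzyme's cut set and residue *i*+1
is not blocked. Two chymotrypsin presets are kept because search
configuration and enzyme biology differ on the proline block: the
search-engine preset ("chymotrypsin+", F/L/M/W/Y unconditionally) is the
digestion default, while short-form derivation uses the proline-blocked
biological rule. The discrepancy is deliberate configuration, not hidden
harmonization. Trypsin uses the strict K/R-not-before-P rule; rare
documented exceptions are ignored as unspecified.

Fragments are all intervals between cleavage boundaries (including the
termini) spanning ≤ `max_missed_cleavages` internal sites (default 10),
filtered to length ≥ 7 and monoisotopic mass ≤ 5000 Da. With *s* internal
sites and no filters the fragment count is (s+1)(s+2)/2. Masses are
monoisotopic residue sums plus water, with +57.02146 Da per cysteine
(carbamidomethylation as a fixed modification); the 5000 Da bound applies
to the modified mass. Semi-specific peptides are not generated — observed
cleaved epitopes are handled by the short-form rule at matching time.
Coverage of an EProt database is the fraction of proteins yielding ≥ 1
theoretical epitope-bearing peptide.

## LFQ ingest and the filter chain

The ingest consumes a MaxQuant-style peptide table (one row per peptide:
`Sequence`, `Proteins`, `Score`, `Reverse`, `Potential contaminant`, one
`Intensity <run>` column per run) and a sample design (species × cultivar
× 3 technical replicates). Filters, in order:

1. reverse and contaminant rows are dropped regardless of score;
2. identifications with score < 40 are removed — at row level when the
   table carries one score per peptide (the `peptides.txt` convention,
   default), or per run when `Score <run>` columns are present;
3. zero intensity means "not identified in that run";
4. a peptide is present in a sample iff identified in ≥ 2 of 3 replicates
   (scaled as ⌈2n/3⌉ with a warning for other replicate counts);
5. the sample's LFQ value is the mean over the identified replicates only
   — zeros are non-identifications, not measurements, so they do not
   drag the mean.

Epitope matching reports every complete occurrence. A peptide whose
N-terminus equals an enabled short form additionally qualifies iff ≥ 1
protein mapped to that peptide contains the complete epitope; an
unconfirmed short-form match is reported but never confers EPep status.
Internal truncated epitopes never qualify. The EPep × sample matrix keeps
explicit missingness (NaN where the replicate rule failed) and annotates
rows with epitopes, match kinds, groups, and gluten protein types taken
from the registry (glut-L → LMW-GS etc.), not from free-text protein
names. All coordinates are 1-based inclusive; the pipeline is
deterministic.

## Comparative statistics

- **Counts**: nonmissing cells per sample column; species mean ± SD over
  cultivars with the n−1 denominator.
- **ANOVA/Tukey**: scipy one-way ANOVA, statsmodels Tukey HSD, and a
  hand-written insert–absorb compact-letter display (no installed package
  provides one). Letters are assigned alphabetically in group order;
  adjusted p exactly equal to α counts as not significant. Pairwise
  *t*-tests use Bonferroni: p_adj = min(1, p·m).
- **Overlaps**: exact counts for all 2^k − 1 regions (k ≤ 6) by direct
  membership classification; region counts sum to the union size.
- **PCA**: samples as observations over ln-transformed, imputed
  intensities, column-centered, full SVD (scikit-learn).
- **Clustering**: ward linkage on Euclidean distances of the ln-scaled
  matrix — the R `hclust` "ward.D2" convention, which scipy's `ward`
  reproduces when given Euclidean (not squared) distances; verified in the
  tests against an independent Lance–Williams implementation to 1e-8.
- **Prevalence/scaling**: rows present in strictly more than 30 of 40
  samples are retained and z-scored over their nonmissing ln-values
  (mean 0, SD 1, n−1); constant rows become all-zero with a warning.

**Missing values.** The LFQ literature treats missingness as
left-censoring at the detection limit, so PCA and clustering impute
missing ln-values as ln(half the global minimum observed intensity) by
default; `zero` and `rowmean` policies are available. Row scaling, by
contrast, uses only observed cells — imputing before z-scoring would
manufacture variance.

## Synthetic studies

The generator's defaults define the study conditions: 5 species
(hexaploid common wheat and spelt, tetraploid durum and emmer, diploid
einkorn) × 8 cultivars × 3 technical replicates. Epitope pools are
attached to simulated subgenomes (A/B/D) so that hexaploid species sample
a superset of pools and einkorn can never carry B/D-restricted epitopes
(PFV, SQ, PQQ, QPY among them). Each species keeps a fraction of the
shared subgenome proteins (spelt 1.0, common wheat 0.90, emmer 0.85,
durum 0.78, einkorn 0.55) plus 2–3 private proteins; cultivars lose each
protein with probability 0.08. These fractions were chosen so that the
per-species EPep counts land in the magnitude range reported for real
wheat collections (means of roughly 60–200 per sample) with the ordering
spelt > common wheat > {emmer, durum} > einkorn; einkorn additionally
receives a 3× intensity boost for FS- and QGS-bearing peptides,
mirroring its elevated amounts of those peptides despite a narrow
repertoire.

Proteins are 70-residue Q/P-rich backgrounds (60 % Q/P, as in gluten
repetitive domains — deliberately stressing overlapping-epitope matching)
with 1–2 planted epitopes each. The peptide table contains every
theoretical digest product of the proteome under the default constraints,
with ln-intensities `N(16, 1.2)` plus cultivar effects `N(0, 0.3)` and
replicate noise `N(0, 0.25)` (log-normal intensities, so the pipeline's
ln step recovers Gaussian structure), per-run dropout (default 0.1;
presets use 0 or 0.2), per-row scores `N(120, 40)` clipped to [0, 300],
and 10 contaminant plus 10 reversed-decoy rows built from scrambled or
reversed planted sequences so the flag, not the sequence, drives their
exclusion. Everything is driven by one seeded RNG; artifacts are
byte-stable under a fixed seed.

The generator records its own truth — planted epitope positions (verified
by substring scan), per-cultivar repertoires, and the expected
post-filter EPep presence/mean matrices computed directly from its draws
by the stated rules. Recovery is scored as sensitivity (recovered
presences / planted presences) and specificity (1 − spurious / possible
negatives). On noiseless data recovery is exact by construction; with
dropout it remains exact *against the truth* because the truth accounts
for the draws.

**What passing does not show.** The simulation has no chromatography,
charge states, co-elution, match-between-runs transfers, deamidated
variants, shared-peptide inference ambiguity, or database-dependent
identification bias. Exact recovery therefore validates the pipeline's
logic (filters, matching, bookkeeping), not the analytical performance of
LC–MS/MS on real flours; the per-species magnitudes show the statistics
behave sensibly at realistic scale, not that real species differ.

## Problem sizes and determinism

Default analyses use ~30 proteins and ~1300 peptide rows per study —
small enough that the full suite and the acceptance script run in
seconds, large enough that every code path (overlapping epitopes, short
forms, dropout, decoys) is exercised. Multi-seed checks use 20 seeds.
Ties in clustering break by input order; all randomness flows from
`numpy.random.default_rng(seed)`.

## Known limitations

- The shipped epitope table is a structural reconstruction (see above).
- Quantitative comparability across runs relies on upstream LFQ
  normalization; the pipeline consumes, never recomputes, it.
- FDR control, match-between-runs and search scoring are upstream
  concerns; the score-40 filter is a pass-through convention.
- Epitopes longer or shorter than 9 residues, HLA-binding prediction and
  epitope discovery are out of scope.
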