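# epep — celiac-disease epitope peptidomics for wheat species

`epep` is a Python toolkit for comparative gluten peptidomics: it identifies
and compares peptides carrying celiac-disease (CD)-active T-cell epitopes
(**EPeps**) across wheat species from label-free quantitation (LFQ) data.
It is aimed at food chemists and proteomics researchers who work with
MaxQuant-style peptide tables of tryptic/chymotryptic gluten digests and
want a reproducible, tested path from an epitope catalogue and a proteome
FASTA to per-species statistics.

## What it computes

CD-active epitopes are 9-mer cores recognized by HLA-DQ2/DQ8-restricted
T cells. They are catalogued in deamidated form (tissue transglutaminase
converts selected Q → E), so matching against plant-encoded proteins first
requires **deamidation reversal** (E → Q). The pipeline then:

1. **Epitope registry** — loads the published epitope table, reverts
   deamidation, collapses records that share a native 9-mer, excludes
   epitopes absent from *Triticum*, annotates internal protease cleavage
   sites, and derives cleavage-shortened **short forms** (suffixes left
   after a tryptic/chymotryptic cut inside the epitope).
2. **EProt database** — filters a proteome FASTA to proteins containing at
   least one complete native epitope (exact substring containment,
   overlaps allowed), with a per-epitope protein index.
3. **In-silico digestion** — trypsin (cuts after K/R, not before P) and
   chymotrypsin (cuts after F/L/M/W/Y; with and without the proline block)
   with up to 10 missed cleavages, minimum length 7, maximum monoisotopic
   mass 5000 Da (cysteines carbamidomethylated, +57.02146 Da); reports the
   fraction of EProts that can yield an epitope-bearing peptide.
4. **LFQ ingest** — MaxQuant-style peptide tables are filtered (no
   reverse/contaminant rows, Andromeda score ≥ 40, intensity 0 = not
   identified, identified in ≥ 2 of 3 technical replicates), replicate
   intensities averaged, and peptides matched to epitopes. A peptide
   starting with an enabled short form (FR, FS by default) counts only if
   a mapped protein carries the complete epitope (**specificity rule**).
5. **Comparative statistics** — per-sample EPep counts with one-way ANOVA,
   Tukey HSD and a compact-letter display; Bonferroni pairwise *t*-tests;
   exact k-set overlap (Venn region) counts; PCA and ward.D2 hierarchical
   clustering of ln-transformed mean LFQ intensities; epitope-group /
   protein-type slices; and a prevalence filter (> 30 of 40 samples) with
   per-row z-scaling for quantitative comparison.
6. **Synthetic studies** — a seeded generator plants epitopes into
   Q/P-rich gluten-like proteins across 5 species × 8 cultivars × 3
   replicates, with ploidy-restricted epitope pools (diploid A; tetraploid
   A+B; hexaploid A+B+D), log-normal intensities, replicate dropout, decoy
   and contaminant rows — and records the ground truth the pipeline must
   recover.

The shipped epitope table (`src/epep/data/epitope_table.tsv`) is a
labelled reconstruction of the published catalogue: 38 epitope entries
collapsing to 27 nonredundant native sequences, 23 of them present in
*Triticum* proteins.

## Worked example

The numbered scripts under `analysis/` run the whole pipeline on the
reference synthetic study (seed 1, 20 % replicate dropout):

```bash
python analysis/01_simulate_study.py   # proteome + peptide table + truth
python analysis/02_build_eprot.py      # EProt database and epitope counts
python analysis/03_digest_coverage.py  # coverage by enzyme preset
python analysis/04_quantify_epeps.py   # filter chain + species statistics
python analysis/05_compare_species.py  # overlaps, PCA, clustering, scaling
```

`04_quantify_epeps.py` prints:

```
373 EPeps across 40 samples
     species    mean        sd letter
common_wheat 171.250  9.924717      a
       spelt 201.875 13.767846      b
       durum 123.000 12.467100      c
       emmer 130.500 14.372593      c
     einkorn  62.250 11.585089      d
one-way ANOVA: F = 142.9, p = 3.67e-21
recovery vs planted truth: sensitivity 1.000, specificity 1.000
```

Reading: 373 distinct EPeps survived the filter chain; spelt cultivars
carry the most distinct EPeps and einkorn the fewest; species sharing a
Tukey letter (durum and emmer, "c") do not differ significantly at
α = 0.05; and every planted presence/absence was recovered exactly.
`05_compare_species.py` then reports 35 EPeps common to all five species,
the PCA variance split (PC1 32.5 %, PC2 15.3 %, PC3 12.5 %), and that the
top-level ward.D2 split separates the hexaploid from the tetra-/diploid
samples.

A thin CLI wraps the same functions: `epep simulate`, `epep build-eprot`,
`epep run` (see `epep --help`).

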