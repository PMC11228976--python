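"""Build the epitope-bearing protein (EProt) database from the simulated
proteome and tabulate how many proteins carry each epitope.

Reads scratch/study/proteome.fasta (written by 01_simulate_study.py),
retains every protein containing >= 1 complete native epitope, and writes
per-epitope protein counts to results/eprot_counts.tsv.
"""

from pathlib import Path

from epep import default_registry, epitope_protein_counts, scan_proteome
from epep.eprot import write_eprot_fasta

ROOT = Path(__file__).resolve().parent.parent
FASTA = ROOT / "scratch" / "study" / "proteome.fasta"
if not FASTA.exists():
    raise SystemExit("run analysis/01_simulate_study.py first")

registry = default_registry()
db = scan_proteome(FASTA, registry)
write_eprot_fasta(db, ROOT / "scratch" / "study" / "eprot.fasta")
counts = epitope_protein_counts(db).sort_values("n_proteins", ascending=False)
counts.to_csv(ROOT / "results" / "eprot_counts.tsv", sep="\t", index=False)

print(f"EProt database: {len(db)} of the input proteins carry >= 1 epitope")
print(counts.to_string(index=False))
zero = counts.loc[counts["n_proteins"] == 0, "epitope"].tolist()
print(f"epitopes absent from this proteome: {zero or 'none'}")
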