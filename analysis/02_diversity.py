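"""Per-accession diversity statistics (Table-1 analogue).

Reads results/data/genotypes.csv, writes results/diversity.csv and
prints the collection-level averages.
"""

from pathlib import Path

from beandiv.diversity import diversity_summary
from beandiv.io import read_genotype_table

if __name__ == "__main__":
    geno = read_genotype_table("results/data/genotypes.csv", "wide")
    table = diversity_summary(geno)
    Path("results").mkdir(exist_ok=True)
    table.to_csv("results/diversity.csv")
    m = table.mean(numeric_only=True)
    print(f"{len(table)} accessions, rarefaction g = "
          f"{int(table['g'].iloc[0])} gene copies")
    print(f"mean N_a = {m['N_a']:.3f}  N_ar = {m['N_ar']:.3f}  "
          f"N_e = {m['N_e']:.3f}")
    print(f"mean H_O = {m['H_O']:.3f}  H_E = {m['H_E']:.3f} "
          "(selfing collection: H_O << H_E)")
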