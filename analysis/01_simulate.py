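"""Generate the synthetic bean collection used by all downstream steps.

Writes genotype (wide CSV + STRUCTURE), trait, phaseolin and coordinate
tables plus the generator ground truth under results/data/.
"""

from pathlib import Path

from beandiv.simulate import SimulationConfig, simulate_collection, \
    write_collection

OUT = Path("results/data")
SEED = 2024

if __name__ == "__main__":
    cfg = SimulationConfig(seed=SEED)
    sim = simulate_collection(cfg, SEED)
    write_collection(sim, OUT)
    n_adm = sum(1 for k in sim.truth.accession_kind.values()
                if k == "admixed")
    print(f"collection: {len(sim.geno.accessions)} accessions x "
          f"{cfg.individuals_per_accession} plants, {sim.geno.n_loci} SSR "
          f"loci; {n_adm} accessions admixed by construction")
    print(f"files in {OUT}/ (genotypes.csv, traits.csv, phaseolin.csv, "
          "coords.csv, truth.json)")
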