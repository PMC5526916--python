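import numpy as np
import pytest

from beandiv.io import GenotypeMatrix
from beandiv.simulate import SimulationConfig, simulate_collection


def make_geno(rows, loci=None, accession_of=None):
    """Build a GenotypeMatrix from {individual: [(a, b), ...]} rows."""
    individuals = list(rows)
    n_loci = len(next(iter(rows.values())))
    loci = loci or [f"L{i+1}" for i in range(n_loci)]
    if accession_of is None:
        accession_of = {ind: ind.rsplit("_", 1)[0] for ind in individuals}
    alleles = np.array([[list(pair) for pair in rows[ind]]
                        for ind in individuals], dtype=np.int64)
    return GenotypeMatrix(individuals, loci, accession_of, alleles)


@pytest.fixture(scope="session")
def small_sim():
    """One 30-accession simulated collection shared across tests."""
    cfg = SimulationConfig(n_accessions=30, seed=11)
    return simulate_collection(cfg, 11)


@pytest.fixture
def toy_geno():
    """Three 2-individual accessions, 2 loci, with one missing call."""
    return make_geno({
        "A_1": [(100, 100), (200, 202)],
        "A_2": [(100, 102), (200, 200)],
        "B_1": [(104, 104), (202, 202)],
        "B_2": [(104, 104), (202, 204)],
        "C_1": [(100, 104), (-1, -1)],
        "C_2": [(102, 102), (204, 204)],
    })
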