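import numpy as np
import pytest

from opgblup import SimulationConfig, simulate_dataset
from opgblup.kernels import (
    PedigreeTable,
    build_additive_kernel,
    build_numerator_relationship,
    compute_allele_frequencies,
)


@pytest.fixture(scope="session")
def clean_sim():
    """Small uncontaminated OP-family dataset (pure maternal half-sibs)."""
    cfg = SimulationConfig(
        n_parents=40,
        n_families=40,
        offspring_per_family=6,
        n_loci=600,
        pollen_pool_size=6,
        selfing_rate=0.0,
        repeated_sire_rate=0.0,
        n_dominance_loci=60,
        n_epistatic_pairs=200,
        seed=11,
    )
    return simulate_dataset(cfg)


@pytest.fixture(scope="session")
def clean_kernels(clean_sim):
    freqs, _ = compute_allele_frequencies(clean_sim.genotypes)
    g_add = build_additive_kernel(clean_sim.genotypes, freqs)
    ped = PedigreeTable.from_frame(clean_sim.assumed_pedigree)
    return {"A": build_numerator_relationship(ped), "G_add": g_add}


def random_pedigree(rng: np.random.Generator, n: int = 12):
    """Random acyclic pedigree: founders first, then offspring of earlier ids."""
    rows = []
    n_founders = max(3, n // 3)
    for i in range(n):
        name = f"p{i}"
        if i < n_founders:
            rows.append((name, None, None))
            continue
        candidates = [f"p{j}" for j in range(i)]
        dam = rng.choice(candidates) if rng.random() < 0.9 else None
        sire_pool = [c for c in candidates if c != dam]
        sire = rng.choice(sire_pool) if sire_pool and rng.random() < 0.8 else None
        rows.append((name, dam, sire))
    return rows
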