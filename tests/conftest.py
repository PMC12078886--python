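import numpy as np
import pandas as pd
import pytest

from walnutgp import (
    GenotypeMatrix,
    SimulationConfig,
    TraitArchitecture,
    simulate_genotypes,
    simulate_phenotypes,
)


@pytest.fixture(scope="session")
def small_panel():
    """Desk-scale panel for unit tests: 170 accessions x 1000 SNPs."""
    return simulate_genotypes(SimulationConfig(n_snps=1000, seed=101))


@pytest.fixture(scope="session")
def small_polygenic(small_panel):
    """Adjusted phenotype + truth for a polygenic h2=0.8 trait."""
    from walnutgp import adjust_trait

    arch = TraitArchitecture("poly", n_qtl=30, h2_broad=0.8)
    pheno, truth = simulate_phenotypes(small_panel, arch, seed=7)
    return adjust_trait(pheno, "poly"), truth


@pytest.fixture()
def toy_genotypes():
    """Hand-built 5-accession x 8-SNP matrix with integral dosages."""
    rng = np.random.default_rng(3)
    dosage = rng.integers(0, 3, size=(5, 8)).astype(float)
    snps = pd.DataFrame(
        dict(
            snp_id=[f"s{j}" for j in range(8)],
            chromosome=["1"] * 4 + ["2"] * 4,
            position=[10, 20, 30, 40] * 2,
            allele_ref=["A"] * 8,
            allele_alt=["G"] * 8,
            call_rate=[1.0] * 8,
            maf=[0.0] * 8,
        )
    )
    return GenotypeMatrix([f"a{i}" for i in range(5)], snps, dosage)
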