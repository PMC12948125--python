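import numpy as np
import pandas as pd
import pytest

import snpsom
from snpsom.genotype_io import MISSING, GenotypeMatrix


def make_geno(rows, sample_ids=None, snp_ids=None) -> GenotypeMatrix:
    """Build a GenotypeMatrix from a list of dosage rows (None = missing)."""
    arr = np.array(
        [[MISSING if v is None else v for v in row] for row in rows], dtype=np.int8
    )
    g, s = arr.shape
    snp_ids = snp_ids or [f"snp{i}" for i in range(g)]
    sample_ids = sample_ids or [f"s{j}" for j in range(s)]
    return GenotypeMatrix(
        values=arr,
        snps=pd.DataFrame(
            {
                "id": snp_ids,
                "chrom": "1",
                "pos": np.arange(1, g + 1),
                "allele_a": "A",
                "allele_b": "B",
            }
        ),
        samples=pd.DataFrame({"id": sample_ids}),
    )


@pytest.fixture(scope="session")
def small_sim():
    """A small planted-module simulation shared across unit tests."""
    geno, truth = snpsom.simulate_admixed(
        K=3, G=400, S=120, n_module_snps_per_component=40, seed=42
    )
    return snpsom.polarize_to_minor(geno), truth


@pytest.fixture(scope="session")
def small_model(small_sim):
    """A small trained map over the small simulation."""
    geno, _ = small_sim
    scores = snpsom.compute_snp_score(geno)
    return snpsom.train_som(scores, width=10, height=10, epochs=8, seed=7)


@pytest.fixture(scope="session")
def recovery_sim():
    """The standard parameter-recovery simulation (polarized)."""
    geno, truth = snpsom.simulate_admixed(**snpsom.desk_profile("recovery"), seed=1)
    return snpsom.polarize_to_minor(geno), truth


@pytest.fixture(scope="session")
def recovery_fit(recovery_sim):
    """Full-precision admixture fit at the true K on the recovery data."""
    geno, _ = recovery_sim
    return snpsom.fit_admixture(geno, 3, seed=1)


@pytest.fixture(scope="session")
def recovery_model(recovery_sim):
    """A 30x30 map trained on the recovery simulation's scores."""
    geno, _ = recovery_sim
    scores = snpsom.compute_snp_score(geno)
    return snpsom.train_som(scores, width=30, height=30, epochs=10, seed=1)
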