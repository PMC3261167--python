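import numpy as np
import pandas as pd
import pytest

from longsig.simulate import StudyConfig, generate_study
from longsig.study import GenotypeStudy


@pytest.fixture(scope="session")
def null_study():
    """Structure-free null study: no planted effects, no missingness."""
    return generate_study(
        StudyConfig(n_cases=150, n_controls=160, n_snps=1200, seed=42)
    )


@pytest.fixture(scope="session")
def lav_study():
    """Study with strong planted dominant variants (carrier 0.45 vs 0.20)."""
    return generate_study(
        StudyConfig(
            n_cases=150, n_controls=160, n_snps=600, n_lavs=20,
            lav_models=("dominant",), lav_effect=((0.45, 0.20),), seed=7,
        )
    )


def make_study(genotypes, phenotypes, **subject_cols) -> GenotypeStudy:
    """Hand-build a tiny study from a genotype matrix and phenotype labels."""
    genotypes = np.asarray(genotypes, dtype=np.int8)
    n, m = genotypes.shape
    subject_meta = pd.DataFrame(
        {
            "id": [f"S{i}" for i in range(n)],
            "phenotype": list(phenotypes),
            "age_years": subject_cols.get("age_years", [100.0] * n),
            "sex": subject_cols.get("sex", ["F"] * n),
            "batch": subject_cols.get("batch", [0] * n),
            "subpop": [0] * n,
            "latent_group": [0] * n,
            "event_flag": [1] * n,
        }
    )
    snp_meta = pd.DataFrame(
        {
            "id": [f"snp{j}" for j in range(m)],
            "chrom": [1] * m,
            "pos": list(range(1, m + 1)),
            "allele_M": ["A"] * m,
            "allele_m": ["G"] * m,
            "is_lav": [False] * m,
        }
    )
    return GenotypeStudy(genotypes, snp_meta, subject_meta)
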