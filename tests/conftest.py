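import numpy as np
import pandas as pd
import pytest

from shapeqt.genotypes import genotype_matrix_from_counts
from shapeqt.synthetic_data import CohortSpec, make_template_femur, simulate_cohort


@pytest.fixture(scope="session")
def template():
    return make_template_femur()


@pytest.fixture(scope="session")
def small_cohort(template):
    """150 subjects, 1 additive effect + 10 null SNPs; shared across tests."""
    spec = CohortSpec(
        n_subjects=150,
        seed=42,
        null_snps=10,
        effects=(
            __import__("shapeqt").GeneticEffectSpec(
                "rs_eff", 0.4, "additive", 3, -0.01
            ),
        ),
    )
    return simulate_cohort(spec, template)


def make_gm(calls_by_snp: dict[str, np.ndarray]) -> "object":
    """GenotypeMatrix from a dict snp -> minor-allele counts."""
    ids = list(calls_by_snp)
    calls = np.column_stack([calls_by_snp[s] for s in ids]).astype(np.int8)
    n = calls.shape[0]
    snps = pd.DataFrame(
        {"snp": ids, "chrom": ["1"] * len(ids), "pos": range(1, len(ids) + 1)}
    )
    subj = [f"x{i}" for i in range(n)]
    return genotype_matrix_from_counts(subj, subj, snps, calls)
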