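import numpy as np
import pandas as pd
import pytest

from polaris.io_formats import (
    CovariateTable,
    GenotypeMatrix,
    SummaryStats,
    VariantRecord,
)


def make_variants(n, chrom="1", start=1000, spacing=1000, alleles=("A", "G")):
    return [
        VariantRecord(f"rs{j + 1}", chrom, start + j * spacing, *alleles)
        for j in range(n)
    ]


def make_genotypes(calls, chrom="1", samples=None, variants=None):
    calls = np.asarray(calls, dtype=np.int8)
    n, m = calls.shape
    samples = samples or [f"S{i + 1}" for i in range(n)]
    variants = variants or make_variants(m, chrom=chrom)
    return GenotypeMatrix(samples, variants, calls)


def make_sumstats(rows):
    """rows: list of (id, chrom, pos, ea, oa, beta, se, p)."""
    df = pd.DataFrame(
        rows, columns=["id", "chrom", "pos", "effect_allele", "other_allele",
                       "beta", "se", "p"]
    )
    return SummaryStats(df)


def make_covariates(phenotype, seed=0, n_pcs=3):
    rng = np.random.default_rng(seed)
    phenotype = np.asarray(phenotype)
    n = len(phenotype)
    table = pd.DataFrame({
        "sample_id": [f"S{i + 1}" for i in range(n)],
        "phenotype": phenotype,
        "age": rng.normal(75, 8, n).round(1),
        "sex": rng.integers(0, 2, n),
    })
    for k in range(n_pcs):
        table[f"PC{k + 1}"] = rng.standard_normal(n)
    return CovariateTable(table)


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)
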