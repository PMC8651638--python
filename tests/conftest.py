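import warnings

import numpy as np
import pandas as pd
import pytest

from endopheno import (
    CohortSpec,
    Partition,
    arcsinh_transform,
    filter_low_expression,
    generate_cohort,
    generate_validation_cohort,
    rank_genes_by_variability,
    remove_sex_genes,
)

warnings.filterwarnings("ignore", category=FutureWarning)
warnings.filterwarnings("ignore", category=UserWarning)


@pytest.fixture(scope="session")
def cohort():
    """One default synthetic discovery cohort (seed 11), shared read-only."""
    spec = CohortSpec(seed=11)
    expr, clin, surv, geno, truth, ann = generate_cohort(spec)
    return {
        "spec": spec,
        "expr": expr,
        "clinical": clin,
        "survival": surv,
        "genotype": geno,
        "truth": truth,
        "annotation": ann,
    }


@pytest.fixture(scope="session")
def transformed(cohort):
    """Preprocessed (filtered, sex-removed, arcsinh) matrix for the cohort."""
    m = filter_low_expression(cohort["expr"])
    m = remove_sex_genes(m, cohort["annotation"])
    return arcsinh_transform(m)


@pytest.fixture(scope="session")
def top300(transformed):
    _, (genes,) = rank_genes_by_variability(transformed, sizes=[300])
    return transformed.subset_genes(genes)


@pytest.fixture(scope="session")
def truth_partition(cohort):
    return Partition(labels=cohort["truth"].labels, k=3)


@pytest.fixture(scope="session")
def validation(cohort):
    clin, surv, truth = generate_validation_cohort(cohort["spec"], cohort["truth"])
    return {"clinical": clin, "survival": surv, "truth": truth}


def two_blob_matrix(n_per=30, dim=5, sep=10.0, sd=0.1, seed=0):
    """Well-separated Gaussian blobs as an ExpressionMatrix-like substrate."""
    from endopheno.preprocess import ExpressionMatrix

    rng = np.random.default_rng(seed)
    a = rng.normal(-sep / 2, sd, size=(n_per, dim))
    b = rng.normal(sep / 2, sd, size=(n_per, dim))
    x = np.vstack([a, b]).T + sep  # genes x samples, keep non-negative
    cols = [f"s{i}" for i in range(2 * n_per)]
    df = pd.DataFrame(x, index=[f"g{i}" for i in range(dim)], columns=cols)
    labels = np.array([1] * n_per + [2] * n_per)
    return ExpressionMatrix(df, "arcsinh"), labels
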