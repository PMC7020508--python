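import numpy as np
import pandas as pd
import pytest

from exprqc.io import (
    CountMatrix,
    GeneAnnotation,
    PhenotypeSheet,
    assemble,
)


def make_counts(values, genes=None, samples=None, is_raw=None):
    arr = np.asarray(values, dtype=float)
    genes = genes or [f"g{i}" for i in range(arr.shape[0])]
    samples = samples or [f"s{j}" for j in range(arr.shape[1])]
    return CountMatrix(pd.DataFrame(arr, index=genes, columns=samples), is_raw=is_raw)


def make_pheno(samples, groups, **covariates):
    df = pd.DataFrame({"group": groups}, index=pd.Index(samples, name="sample"))
    for name, values in covariates.items():
        df[name] = values
    return PhenotypeSheet(df)


def make_annotation(genes, lengths, gc):
    return GeneAnnotation(
        pd.DataFrame(
            {"length_bp": lengths, "gc_fraction": gc},
            index=pd.Index(genes, name="gene_id"),
        )
    )


def make_dataset(values, groups=None, annotation=None, organism="human", **covariates):
    counts = make_counts(values)
    n = counts.values.shape[1]
    groups = groups or ["a"] * (n // 2) + ["b"] * (n - n // 2)
    pheno = make_pheno(counts.sample_ids, groups, **covariates)
    return assemble(pheno, counts, annotation, organism=organism)


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def random_dataset(rng):
    """20 genes x 6 samples of NB-ish counts with matching annotation."""
    vals = rng.poisson(rng.lognormal(3, 1, size=(20, 1)), size=(20, 6)).astype(float)
    counts = make_counts(vals)
    anno = make_annotation(
        counts.gene_ids,
        rng.integers(200, 5000, 20),
        rng.beta(5, 5, 20),
    )
    pheno = make_pheno(counts.sample_ids, ["a", "a", "a", "b", "b", "b"])
    return assemble(pheno, counts, anno, organism="human")
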