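"""Expression-matrix transforms used throughout the QC surface.

Four transforms cover every downstream metric:

* :func:`tpm` — transcripts per million for human/mouse data with a gene
  annotation: ``TPM(g, s) = (c(g,s)/l(g)) / sum_g'(c(g',s)/l(g')) * 1e6``
  where ``c`` is the read count and ``l`` the gene length. Every column
  sums to one million by construction.
* :func:`vst_like` — a variance-stabilizing fallback for organisms without
  a bundled annotation: median-of-ratios size factors (the standard
  count-depth estimator) followed by ``log2(count/size_factor + 1)``.
* :func:`zscore_rows` — per-gene standardization to mean 0, variance 1
  across samples (population standard deviation), feeding normalized PCA.
* :func:`log2p1` — the shared ``log2(x + 1)`` transform behind box plots,
  clustering and correlations.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any, Union

import numpy as np
import pandas as pd

from .errors import ValidationError
from .io import CountMatrix, GeneAnnotation

MatrixLike = Union[pd.DataFrame, CountMatrix, "NormalizedMatrix"]


@dataclass
class NormalizedMatrix:
    """A transformed gene-by-sample matrix plus the parameters that made it."""

    values: pd.DataFrame
    method: str  # tpm | vst_like | log2p1 | zscore | none
    provenance: dict[str, Any] = field(default_factory=dict)


def matrix_values(matrix: MatrixLike) -> pd.DataFrame:
    """Extract the gene-by-sample DataFrame from any accepted container."""
    if isinstance(matrix, pd.DataFrame):
        return matrix
    return matrix.values


def tpm(counts: CountMatrix, annotation: GeneAnnotation) -> NormalizedMatrix:
    """Transcripts-per-million normalization over the annotated genes.

    Genes lacking an annotation entry are excluded before the per-sample
    rate sums are formed (and listed in the provenance); the remaining
    columns therefore each sum to exactly 1e6.
    """
    if not counts.is_raw:
        raise ValidationError("TPM requires raw (integral) counts")
    shared = counts.values.index.intersection(annotation.data.index)
    dropped = counts.values.index.difference(annotation.data.index)
    if len(shared) == 0:
        raise ValidationError("no gene in the count matrix has an annotation entry")
    sub = counts.values.loc[shared]
    lengths = annotation.data.loc[shared, "length_bp"].to_numpy(dtype=float)
    rates = sub.to_numpy() / lengths[:, None]
    denom = rates.sum(axis=0)
    zero = np.flatnonzero(denom == 0)
    if zero.size:
        raise ValidationError(
            f"sample '{sub.columns[zero[0]]}' has zero counts over annotated genes"
        )
    out = pd.DataFrame(rates / denom * 1e6, index=shared, columns=sub.columns)
    return NormalizedMatrix(
        out,
        method="tpm",
        provenance={"genes_without_annotation": list(map(str, dropped))},
    )


def vst_like(counts: CountMatrix) -> NormalizedMatrix:
    """Depth-normalize by median-of-ratios size factors, then log2(x+1).

    The size factor of sample *s* is the median, over genes whose geometric
    mean across samples is positive, of ``count(g,s) / geomean_g``. This is
    the classic RNA-seq depth estimator; the subsequent log transform gives
    approximate variance stabilization for cross-sample comparison.
    """
    if not counts.is_raw:
        raise ValidationError("size-factor normalization requires raw counts")
    arr = counts.values.to_numpy(dtype=float)
    positive = (arr > 0).all(axis=1)
    if not positive.any():
        raise ValidationError(
            "no gene has positive counts in every sample; size factors undefined"
        )
    log_gm = np.log(arr[positive]).mean(axis=1)
    size_factors = np.exp(
        np.median(np.log(arr[positive]) - log_gm[:, None], axis=0)
    )
    out = pd.DataFrame(
        np.log2(arr / size_factors + 1.0),
        index=counts.values.index,
        columns=counts.values.columns,
    )
    return NormalizedMatrix(
        out,
        method="vst_like",
        provenance={
            "size_factors": dict(zip(counts.values.columns, size_factors.tolist()))
        },
    )


def zscore_rows(matrix: MatrixLike) -> NormalizedMatrix:
    """Standardize each gene row to mean 0, variance 1 across samples.

    Uses the population standard deviation so a non-constant row has unit
    variance exactly. Zero-spread rows become all-zero (keeping the matrix
    shape stable for PCA) and are counted in the provenance.
    """
    vals = matrix_values(matrix)
    if vals.shape[1] < 2:
        raise ValidationError("z-scoring requires at least 2 samples")
    arr = vals.to_numpy(dtype=float)
    mu = arr.mean(axis=1, keepdims=True)
    sd = arr.std(axis=1, ddof=0, keepdims=True)
    constant = sd[:, 0] == 0
    sd[constant] = 1.0
    z = (arr - mu) / sd
    z[constant] = 0.0
    out = pd.DataFrame(z, index=vals.index, columns=vals.columns)
    return NormalizedMatrix(
        out, method="zscore", provenance={"constant_rows": int(constant.sum())}
    )


def log2p1(matrix: MatrixLike) -> NormalizedMatrix:
    """Elementwise ``log2(x + 1)``; rejects negative input."""
    vals = matrix_values(matrix)
    arr = vals.to_numpy(dtype=float)
    if (arr < 0).any():
        raise ValidationError("log2(x+1) requires non-negative values")
    return NormalizedMatrix(
        pd.DataFrame(np.log2(arr + 1.0), index=vals.index, columns=vals.columns),
        method="log2p1",
    )
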