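"""Dimensionality reduction and sample-relationship structure.

Four views of the sample space:

* **PCA** with samples as observations and genes as (centered) variables,
  run twice — on the row z-scored matrix, where biology should dominate,
  and on the raw counts, where library-size differences deliberately
  dominate PC1 so a depth-collapsed sample stands apart;
* **multiple factor analysis (MFA)** — a weighted global PCA over variable
  groups (the expression block plus one indicator-expanded block per
  categorical covariate), each group scaled by the inverse of its own
  first eigenvalue so no single group dominates; the per-group share of
  each global component attributes sample variance to covariates such as
  library protocol or flow cell;
* **agglomerative hierarchical clustering** of samples on Euclidean
  distance over the log2(count+1) matrix;
* **Pearson and Spearman correlation matrices** with a Ward-linkage leaf
  order for heatmap display.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Union

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist, squareform
from sklearn.decomposition import PCA

from .errors import ValidationError
from .io import QCDataset
from .normalize import MatrixLike, NormalizedMatrix, matrix_values

logger = logging.getLogger(__name__)


@dataclass
class PCAResult:
    scores: pd.DataFrame  # samples x components
    variance_explained: np.ndarray  # fraction per component
    loadings: pd.DataFrame  # genes x components
    mode: str  # "zscored" | "unnormalized"


@dataclass
class MFAResult:
    scores: pd.DataFrame  # samples x components
    variance_explained: np.ndarray
    group_weights: dict[str, float]  # 1 / first eigenvalue of each group
    group_contributions: pd.DataFrame  # groups x components, columns sum to 1
    dropped_groups: list[str] = field(default_factory=list)


@dataclass
class MFASkipped:
    """Marker returned when the dataset carries no usable covariate."""

    reason: str


@dataclass
class Dendrogram:
    linkage_matrix: np.ndarray  # scipy (n-1) x 4 merge table
    sample_ids: list[str]
    method: str

    @property
    def merges(self) -> list[tuple[int, int]]:
        return [(int(a), int(b)) for a, b in self.linkage_matrix[:, :2]]

    @property
    def heights(self) -> np.ndarray:
        return self.linkage_matrix[:, 2]

    @property
    def leaf_order(self) -> list[str]:
        return [self.sample_ids[i] for i in hierarchy.leaves_list(self.linkage_matrix)]


@dataclass
class CorrelationResult:
    matrix: pd.DataFrame  # samples x samples
    method: str  # "pearson" | "spearman"
    leaf_order: list[str]
    undefined_samples: list[str] = field(default_factory=list)


def _fix_signs(scores: np.ndarray, loadings: np.ndarray) -> None:
    """Make each component's largest-magnitude loading positive, in place."""
    for k in range(loadings.shape[1]):
        j = np.argmax(np.abs(loadings[:, k]))
        if loadings[j, k] < 0:
            loadings[:, k] *= -1
            scores[:, k] *= -1


def pca_samples(matrix: MatrixLike, mode: str = "zscored") -> PCAResult:
    """PCA of samples over gene variables.

    ``mode='zscored'`` expects a row-standardized matrix; ``mode='unnormalized'``
    takes raw counts as-is. In both cases gene variables are centered (and
    only centered) before the decomposition, so the un-normalized run keeps
    depth differences in play. Component signs follow the
    largest-|loading|-positive convention for run-to-run reproducibility.
    """
    if mode not in ("zscored", "unnormalized"):
        raise ValidationError(f"unknown PCA mode '{mode}'")
    vals = matrix_values(matrix)
    n_samples = vals.shape[1]
    if n_samples < 2:
        raise ValidationError("PCA requires at least 2 samples")
    X = vals.to_numpy(dtype=float).T  # samples x genes
    n_comp = min(n_samples - 1, X.shape[1])
    model = PCA(n_components=n_comp)
    scores = model.fit_transform(X)
    loadings = model.components_.T.copy()
    _fix_signs(scores, loadings)
    comp_names = [f"PC{i + 1}" for i in range(n_comp)]
    return PCAResult(
        scores=pd.DataFrame(scores, index=vals.columns, columns=comp_names),
        variance_explained=model.explained_variance_ratio_.copy(),
        loadings=pd.DataFrame(loadings, index=vals.index, columns=comp_names),
        mode=mode,
    )


def _indicator_block(labels: pd.Series) -> pd.DataFrame:
    """Centered one-hot indicators scaled by 1/sqrt(level frequency) (MCA-style)."""
    dummies = pd.get_dummies(labels.astype(str))
    freq = dummies.mean(axis=0)
    block = (dummies - freq) / np.sqrt(freq)
    block.columns = [f"{labels.name}={lvl}" for lvl in dummies.columns]
    return block.astype(float)


def mfa(
    dataset: QCDataset,
    zscored_expression: NormalizedMatrix,
    include_expression: bool = True,
) -> Union[MFAResult, MFASkipped]:
    """Multiple factor analysis of expression and covariate blocks.

    Each block is standardized in its own terms (z-scored genes; centered,
    frequency-scaled covariate indicators), its first eigenvalue found by a
    separate decomposition, and its variables divided by the square root of
    that eigenvalue — the inverse-first-eigenvalue weighting that stops any
    one block from dominating. A global PCA of the concatenated weighted
    blocks yields sample scores; squared component loadings summed within
    each block give the per-group contribution shares.

    Datasets without covariates return :class:`MFASkipped` — the analysis
    has nothing to attribute, which the report records rather than erroring.
    """
    covariates = dataset.pheno.covariates
    if not covariates:
        return MFASkipped("no covariate column in the phenotype sheet")

    blocks: dict[str, pd.DataFrame] = {}
    if include_expression:
        expr = matrix_values(zscored_expression).T  # samples x genes
        blocks["expression"] = expr
    dropped: list[str] = []
    for cov in covariates:
        labels = dataset.pheno.data[cov]
        if labels.nunique() < 2:
            logger.warning("covariate '%s' is constant; dropped from MFA", cov)
            dropped.append(cov)
            continue
        blocks[cov] = _indicator_block(labels)
    if not any(g in covariates for g in blocks):
        return MFASkipped("all covariate columns are constant across samples")

    weighted: list[np.ndarray] = []
    group_of: list[str] = []
    weights: dict[str, float] = {}
    for name, block in blocks.items():
        X = block.to_numpy(dtype=float)
        Xc = X - X.mean(axis=0)
        lam1 = PCA(n_components=1).fit(Xc).explained_variance_[0]
        if lam1 <= 0:
            logger.warning("group '%s' has zero variance; dropped from MFA", name)
            dropped.append(name)
            continue
        weights[name] = 1.0 / lam1
        weighted.append(Xc / np.sqrt(lam1))
        group_of.extend([name] * X.shape[1])

    Z = np.hstack(weighted)
    n_comp = min(Z.shape[0] - 1, Z.shape[1])
    model = PCA(n_components=n_comp)
    scores = model.fit_transform(Z)
    loadings = model.components_.T.copy()
    _fix_signs(scores, loadings)
    comp_names = [f"PC{i + 1}" for i in range(n_comp)]
    group_idx = pd.Index(group_of, name="group")
    contrib = (
        pd.DataFrame(loadings**2, index=group_idx, columns=comp_names)
        .groupby(level=0)
        .sum()
        .loc[list(weights)]
    )
    return MFAResult(
        scores=pd.DataFrame(scores, index=dataset.sample_ids, columns=comp_names),
        variance_explained=model.explained_variance_ratio_.copy(),
        group_weights=weights,
        group_contributions=contrib,
        dropped_groups=dropped,
    )


def hcluster_samples(matrix: MatrixLike, method: str = "complete") -> Dendrogram:
    """Agglomerative clustering of samples on Euclidean distance over genes."""
    vals = matrix_values(matrix)
    if vals.shape[1] < 2:
        raise ValidationError("clustering requires at least 2 samples")
    X = vals.to_numpy(dtype=float).T
    Z = hierarchy.linkage(pdist(X, metric="euclidean"), method=method)
    return Dendrogram(
        linkage_matrix=Z, sample_ids=list(vals.columns), method=method
    )


def correlate_samples(matrix: MatrixLike, method: str = "pearson") -> CorrelationResult:
    """All pairwise sample correlations plus a Ward-ordered heatmap layout.

    A zero-variance sample's coefficients are undefined; its row/column is
    set to NaN (diagonal kept at 1) and the sample is listed in
    ``undefined_samples``. Spearman uses average ranks for ties.
    """
    if method not in ("pearson", "spearman"):
        raise ValidationError(f"unknown correlation method '{method}'")
    vals = matrix_values(matrix)
    if vals.shape[1] < 2:
        raise ValidationError("correlation requires at least 2 samples")
    samples = list(vals.columns)
    arr = vals.to_numpy(dtype=float)
    undefined = [s for s, sd in zip(samples, arr.std(axis=0)) if sd == 0]
    corr = vals.corr(method=method)
    corr = (corr + corr.T) / 2.0  # enforce exact symmetry
    np.fill_diagonal(corr.values, 1.0)

    # Ward linkage on d = 1 - r supplies the heatmap leaf order; undefined
    # samples cannot be placed and are appended at the end.
    defined = [s for s in samples if s not in undefined]
    if len(defined) >= 2:
        sub = corr.loc[defined, defined].to_numpy()
        d = np.clip(1.0 - sub, 0.0, None)
        np.fill_diagonal(d, 0.0)
        Z = hierarchy.linkage(squareform(d, checks=False), method="ward")
        order = [defined[i] for i in hierarchy.leaves_list(Z)]
    else:
        order = defined
    return CorrelationResult(
        matrix=corr,
        method=method,
        leaf_order=order + undefined,
        undefined_samples=undefined,
    )
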