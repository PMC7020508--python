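"""Sample-level bias diagnostics.

* **Mapped-read density** — a Gaussian kernel density of the normalized,
  log-transformed expression values of each sample on a shared grid; a
  sample with little usable signal shows a distorted, zero-heavy curve.
* **GC-bias curves** — per sample, a LOWESS fit of log2(count+1) against
  gene GC fraction. A curve sitting below the rest, especially on the
  high-GC side, points at a library-preparation artifact.
* **Gene profiles** — log2-scale expression of a chosen gene across
  samples, and the housekeeping shortcut for GAPDH/ACTB (human) or
  Gapdh/Actb (mouse). Housekeeping genes are stably and highly expressed,
  so a sample where both sit lowest is suspect regardless of phenotype.

Gene profiles (housekeeping included) default to the raw-count log2 scale:
they exist to expose depth problems, which within-sample normalization
such as TPM would cancel.
"""

from __future__ import annotations

import difflib
import logging
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy.stats import gaussian_kde
from statsmodels.nonparametric.smoothers_lowess import lowess as _sm_lowess

from .errors import ValidationError
from .io import QCDataset, strip_gene_version
from .normalize import MatrixLike, NormalizedMatrix, log2p1, matrix_values, tpm, vst_like

logger = logging.getLogger(__name__)

#: symbol and Ensembl-id aliases for the two housekeeping genes, per organism
HOUSEKEEPING_ALIASES: dict[str, dict[str, tuple[str, ...]]] = {
    "human": {
        "GAPDH": ("GAPDH", "ENSG00000111640"),
        "ACTB": ("ACTB", "ENSG00000075624"),
    },
    "mouse": {
        "Gapdh": ("GAPDH", "ENSMUSG00000057666"),
        "Actb": ("ACTB", "ENSMUSG00000029580"),
    },
}


@dataclass
class DensityCurve:
    sample_id: str
    grid: np.ndarray
    density: np.ndarray
    flat: bool = False  # zero-variance sample: placeholder uniform curve


@dataclass
class GCCurve:
    sample_id: str
    gc: np.ndarray  # sorted GC-fraction abscissae
    fitted: np.ndarray  # LOWESS-smoothed log2(count+1)


@dataclass
class GeneProfile:
    gene: str
    values: pd.Series  # log2-scale expression per sample
    source: str  # tag of the matrix the profile was read from


@dataclass
class HousekeepingSkipped:
    reason: str


def density_input(dataset: QCDataset) -> NormalizedMatrix:
    """Pick the normalization feeding the density plot.

    Human/mouse data with an annotation use TPM; other raw data fall back
    to the size-factor transform; pre-normalized input is used as-is.
    """
    if not dataset.counts.is_raw:
        return NormalizedMatrix(dataset.counts.values, method="none")
    if dataset.organism in ("human", "mouse") and dataset.annotation is not None:
        return tpm(dataset.counts, dataset.annotation)
    return vst_like(dataset.counts)


def mapped_density(
    dataset: QCDataset,
    normalized: Optional[NormalizedMatrix] = None,
    grid_points: int = 512,
) -> list[DensityCurve]:
    """Gaussian KDE of log2(value+1) per sample on a shared evaluation grid.

    Bandwidths follow Silverman's rule per sample; the grid spans the
    global transformed range padded by three times the widest bandwidth so
    each curve integrates to ~1. An all-constant sample gets a flagged
    flat placeholder instead of a failing KDE.
    """
    if normalized is None:
        normalized = density_input(dataset)
    if normalized.method in ("tpm", "none"):
        logged = np.log2(normalized.values.to_numpy(dtype=float) + 1.0)
    else:  # vst_like output is already on a log scale
        logged = normalized.values.to_numpy(dtype=float)
    samples = list(normalized.values.columns)

    kdes: dict[str, gaussian_kde] = {}
    bandwidths = []
    for j, s in enumerate(samples):
        col = logged[:, j]
        if np.ptp(col) == 0:
            continue
        kde = gaussian_kde(col, bw_method="silverman")
        kdes[s] = kde
        bandwidths.append(np.sqrt(kde.covariance[0, 0]))
    pad = 3.0 * max(bandwidths, default=1.0)
    lo, hi = logged.min() - pad, logged.max() + pad
    grid = np.linspace(lo, hi, grid_points)

    curves = []
    for j, s in enumerate(samples):
        if s in kdes:
            curves.append(DensityCurve(s, grid, kdes[s](grid), flat=False))
        else:
            logger.warning("sample '%s' has constant expression; flat density", s)
            flat = np.full_like(grid, 1.0 / (hi - lo))
            curves.append(DensityCurve(s, grid, flat, flat=True))
    return curves


def lowess_fit(
    x: np.ndarray,
    y: np.ndarray,
    frac: float = 2.0 / 3.0,
    robust_iters: int = 3,
    delta: Optional[float] = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Tricube-weighted local linear regression evaluated at the observed x.

    Classic scatterplot smoothing: each fitted value comes from a weighted
    linear fit over the ``int(frac * n)`` nearest neighbours, with
    ``robust_iters`` bisquare re-weighting passes to shrug off outliers.
    ``delta`` is the usual speed/exactness dial: points closer than delta
    reuse a linear interpolation of the previous local fit. The default
    fits every point exactly up to n=200 and switches to 1% of the x-range
    beyond that. Returns (sorted x, fitted y).
    """
    if delta is None:
        delta = 0.0 if len(x) <= 200 else 0.01 * np.ptp(x)
    out = _sm_lowess(y, x, frac=frac, it=robust_iters, delta=delta, return_sorted=True)
    return out[:, 0], out[:, 1]


def gc_bias(
    dataset: QCDataset,
    frac: float = 2.0 / 3.0,
    robust_iters: int = 3,
    min_genes: int = 20,
) -> list[GCCurve]:
    """Per-sample LOWESS of log2(count+1) against gene GC fraction.

    Computed over the genes shared between the count matrix and the
    annotation; requires the annotation and at least ``min_genes`` shared
    genes.
    """
    if dataset.annotation is None:
        raise ValidationError("GC-bias curves require a gene annotation")
    shared = dataset.counts.values.index.intersection(dataset.annotation.data.index)
    if len(shared) < min_genes:
        raise ValidationError(
            f"only {len(shared)} genes shared with the annotation; "
            f"need at least {min_genes} for a stable fit"
        )
    gc = dataset.annotation.data.loc[shared, "gc_fraction"].to_numpy()
    logged = np.log2(dataset.counts.values.loc[shared].to_numpy(dtype=float) + 1.0)
    curves = []
    for j, s in enumerate(dataset.sample_ids):
        xs, fitted = lowess_fit(gc, logged[:, j], frac=frac, robust_iters=robust_iters)
        curves.append(GCCurve(s, xs, fitted))
    return curves


def _resolve_gene(index: pd.Index, gene: str) -> Optional[str]:
    if gene in index:
        return gene
    stripped = strip_gene_version(gene)
    matches = index[[strip_gene_version(g) == stripped for g in index]]
    if len(matches):
        return matches[0]
    lowered = {g.lower(): g for g in index}
    return lowered.get(gene.lower())


def gene_profile(
    dataset: QCDataset, gene: str, matrix: Optional[MatrixLike] = None
) -> GeneProfile:
    """log2-scale expression of one gene across the retained samples.

    Defaults to log2(count+1) of the raw counts, which keeps library-depth
    differences visible; pass ``matrix`` to profile any other transform.
    Lookup strips Ensembl version suffixes and falls back to a
    case-insensitive match; an absent gene raises with near-miss
    suggestions.
    """
    if matrix is None:
        matrix = log2p1(dataset.counts)
        source = "log2_counts"
        vals = matrix.values
    else:
        vals = matrix_values(matrix)
        source = matrix.method if isinstance(matrix, NormalizedMatrix) else "custom"
        vals = np.log2(vals + 1.0) if source in ("tpm", "none", "custom") else vals
    resolved = _resolve_gene(vals.index, gene)
    if resolved is None:
        near = difflib.get_close_matches(gene, list(map(str, vals.index)), n=3)
        hint = f"; similar ids: {', '.join(near)}" if near else ""
        raise ValidationError(f"gene '{gene}' not found in the matrix{hint}")
    return GeneProfile(gene=resolved, values=vals.loc[resolved].copy(), source=source)


def housekeeping(
    dataset: QCDataset, matrix: Optional[MatrixLike] = None
) -> tuple[GeneProfile, GeneProfile] | HousekeepingSkipped:
    """GAPDH and ACTB profiles for human/mouse data.

    Resolution tries the bundled symbol and Ensembl-id aliases (case
    insensitive for symbols). When either gene cannot be found — e.g. a
    non-Ensembl id scheme — the metric is skipped with a note pointing the
    user at the manual gene-profile lookup instead.
    """
    if dataset.organism not in HOUSEKEEPING_ALIASES:
        return HousekeepingSkipped(
            f"housekeeping profiles are defined for human/mouse, not "
            f"'{dataset.organism}'"
        )
    profiles = []
    for canonical, aliases in HOUSEKEEPING_ALIASES[dataset.organism].items():
        hit = None
        for alias in (canonical,) + aliases:
            hit = _resolve_gene(dataset.counts.values.index, alias)
            if hit is not None:
                break
        if hit is None:
            return HousekeepingSkipped(
                f"could not resolve housekeeping gene {canonical} in the count "
                f"matrix; use the expression plot (gene_profile) with your own id"
            )
        profiles.append(gene_profile(dataset, hit, matrix=matrix))
    return profiles[0], profiles[1]
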