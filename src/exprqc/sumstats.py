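"""Per-sample descriptive statistics and count-distribution box summaries.

The summary table is the first thing a user reads: one row per sample with
the number of gene rows, moments of the raw count column, library size and
the number of expressed genes (count > 0). A sample whose mean, maximum
and expressed-gene count all sit well below its group is the classic
low-expression outlier signature.

Conventions (several descriptive-statistics estimators exist; these are
fixed and documented rather than guessed per call):

* mean/median/min/max/range on the raw count scale;
* standard deviation with ddof=1 (sample SD);
* skewness = Fisher–Pearson ``g1 = m3 / m2**1.5`` and excess kurtosis
  ``g2 = m4 / m2**2 - 3``, both population (no bias correction) and both
  defined as 0 for a zero-spread column;
* box statistics on ``log2(count + 1)`` with linear-interpolation
  quartiles.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats

from .io import QCDataset
from .normalize import log2p1

SUMMARY_COLUMNS = [
    "detected_genes",
    "mean",
    "sd",
    "median",
    "min",
    "max",
    "range",
    "skewness",
    "kurtosis",
    "library_size",
    "expressed_genes",
]


def sample_summary(dataset: QCDataset) -> pd.DataFrame:
    """One row of descriptive statistics per sample, on the raw count scale."""
    vals = dataset.counts.values
    arr = vals.to_numpy(dtype=float)
    n_genes = arr.shape[0]

    spread = arr.std(axis=0, ddof=0)
    with warnings.catch_warnings():
        # constant columns trip scipy's precision warning; the zero-spread
        # policy below overrides those entries anyway
        warnings.simplefilter("ignore", RuntimeWarning)
        skew = stats.skew(arr, axis=0, bias=True)
        kurt = stats.kurtosis(arr, axis=0, fisher=True, bias=True)
    zero_spread = spread == 0
    skew = np.where(zero_spread, 0.0, skew)
    kurt = np.where(zero_spread, 0.0, kurt)

    out = pd.DataFrame(
        {
            "detected_genes": n_genes,
            "mean": arr.mean(axis=0),
            "sd": arr.std(axis=0, ddof=1),
            "median": np.median(arr, axis=0),
            "min": arr.min(axis=0),
            "max": arr.max(axis=0),
            "range": arr.max(axis=0) - arr.min(axis=0),
            "skewness": skew,
            "kurtosis": kurt,
            "library_size": arr.sum(axis=0),
            "expressed_genes": (arr > 0).sum(axis=0),
        },
        index=vals.columns,
    )
    out.index.name = "sample"
    if dataset.counts.is_raw:
        for col in ("library_size", "min", "max", "range"):
            out[col] = out[col].astype(int)
    return out[SUMMARY_COLUMNS]


def count_distribution(dataset: QCDataset) -> pd.DataFrame:
    """Five-number summary per sample on the log2(count+1) scale."""
    logged = log2p1(dataset.counts).values
    arr = logged.to_numpy()
    q = np.percentile(arr, [0, 25, 50, 75, 100], axis=0)
    out = pd.DataFrame(
        {"min": q[0], "q1": q[1], "median": q[2], "q3": q[3], "max": q[4]},
        index=logged.columns,
    )
    out.index.name = "sample"
    return out
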