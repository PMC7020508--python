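"""Readers, writers and validation for the three tab-delimited inputs.

The tool consumes

* a **phenotype sheet** — one row per sample with a ``sample`` and a
  ``group`` column (header match is case-insensitive); every additional
  column is treated as a categorical covariate (batch, flow cell,
  library protocol, ...);
* a **count matrix** — genes in rows (first column holds the identifier
  or symbol), samples in columns, raw or pre-normalized values as written
  by RSEM, HTSeq, featureCounts, Kallisto, Salmon and friends;
* an optional **gene annotation** — per-gene length in base pairs and GC
  fraction, used for TPM normalization and the GC-bias curves.

Sample selection is driven entirely by the phenotype sheet: columns of the
count matrix that are absent from the sheet are dropped with a warning, so
removing a suspect sample from an analysis is a one-line edit of the sheet,
never a code change.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .errors import SchemaError, ValidationError

logger = logging.getLogger(__name__)

_VERSION_SUFFIX = re.compile(r"\.\d+$")

ORGANISMS = ("human", "mouse", "other")


def strip_gene_version(gene_id: str) -> str:
    """Drop a trailing Ensembl-style version suffix (``ENSG....5`` -> ``ENSG...``)."""
    return _VERSION_SUFFIX.sub("", gene_id)


@dataclass
class PhenotypeSheet:
    """Per-sample metadata: group label plus optional categorical covariates."""

    data: pd.DataFrame  # index: sample_id; columns: 'group' + covariates

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def groups(self) -> pd.Series:
        return self.data["group"]

    @property
    def covariates(self) -> list[str]:
        return [c for c in self.data.columns if c != "group"]

    def __post_init__(self) -> None:
        idx = self.data.index
        if idx.duplicated().any():
            dups = sorted(set(idx[idx.duplicated()]))
            raise ValidationError(f"duplicate sample ids: {', '.join(dups)}")
        if len(idx) < 2:
            raise ValidationError("phenotype sheet must describe at least 2 samples")
        if any(s == "" for s in idx):
            raise ValidationError("empty sample id in phenotype sheet")
        if "group" not in self.data.columns:
            raise SchemaError("phenotype sheet lacks the required 'group' column")
        bad = self.data.columns[self.data.isna().any() | (self.data == "").any()]
        if len(bad):
            raise ValidationError(
                f"empty cells in phenotype column(s): {', '.join(bad)}"
            )


@dataclass
class CountMatrix:
    """Gene-by-sample expression table; ``is_raw`` marks all-integral values."""

    values: pd.DataFrame  # index: gene_id; columns: samples; dtype float
    is_raw: bool = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        v = self.values
        if v.shape[0] < 2 or v.shape[1] < 2:
            raise ValidationError(
                f"count matrix must have >=2 genes and >=2 samples, got {v.shape}"
            )
        if v.index.duplicated().any():
            dups = sorted(set(v.index[v.index.duplicated()]))
            raise ValidationError(f"duplicate gene ids: {', '.join(map(str, dups))}")
        arr = v.to_numpy()
        if (arr < 0).any():
            g, s = np.argwhere(arr < 0)[0]
            raise ValidationError(
                f"negative value at gene '{v.index[g]}', sample '{v.columns[s]}'"
            )
        if self.is_raw is None:
            self.is_raw = bool(np.allclose(arr, np.round(arr), atol=0.0))

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)


@dataclass
class GeneAnnotation:
    """Per-gene length (bp) and GC fraction."""

    data: pd.DataFrame  # index: gene_id; columns: length_bp, gc_fraction

    def __post_init__(self) -> None:
        d = self.data
        if d.index.duplicated().any():
            dups = sorted(set(d.index[d.index.duplicated()]))
            raise ValidationError(f"duplicate gene ids in annotation: {', '.join(dups)}")
        if (d["length_bp"] < 1).any():
            bad = d.index[d["length_bp"] < 1][0]
            raise ValidationError(f"length_bp < 1 for gene '{bad}'")
        gc = d["gc_fraction"]
        if ((gc < 0) | (gc > 1)).any():
            bad = d.index[(gc < 0) | (gc > 1)][0]
            raise ValidationError(f"gc_fraction outside [0, 1] for gene '{bad}'")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.data.index)


@dataclass
class QCDataset:
    """Counts restricted and ordered to the phenotype sheet's samples."""

    counts: CountMatrix
    pheno: PhenotypeSheet
    annotation: Optional[GeneAnnotation] = None
    organism: str = "human"

    def __post_init__(self) -> None:
        if self.organism not in ORGANISMS:
            raise ValidationError(
                f"organism must be one of {ORGANISMS}, got '{self.organism}'"
            )
        if list(self.counts.values.columns) != list(self.pheno.data.index):
            raise ValidationError("counts columns and phenotype rows are not aligned")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.pheno.data.index)

    @property
    def n_samples(self) -> int:
        return len(self.pheno.data)


def _find_column(columns: Sequence[str], name: str) -> Optional[str]:
    for c in columns:
        if c.strip().lower() == name:
            return c
    return None


def read_phenotype(path: str | Path) -> PhenotypeSheet:
    """Read and validate a tab-delimited phenotype sheet.

    Requires ``sample`` and ``group`` columns (case-insensitive header
    match); every other column is kept, in file order, as a covariate.
    """
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    sample_col = _find_column(df.columns, "sample")
    group_col = _find_column(df.columns, "group")
    if sample_col is None:
        raise SchemaError("phenotype sheet is missing the required 'sample' column")
    if group_col is None:
        raise SchemaError("phenotype sheet is missing the required 'group' column")
    df = df.rename(columns={sample_col: "sample", group_col: "group"})
    df["sample"] = df["sample"].str.strip()
    order = ["group"] + [c for c in df.columns if c not in ("sample", "group")]
    return PhenotypeSheet(df.set_index("sample")[order])


def read_counts(path: str | Path, strip_versions: bool = True) -> CountMatrix:
    """Read a tab-delimited gene-by-sample count matrix.

    The first column holds gene identifiers or symbols (its header cell may
    be empty or any label); remaining columns must be numeric and
    non-negative. ``is_raw`` is set when every value is integral. With
    ``strip_versions`` (default), Ensembl ``.N`` version suffixes are
    removed from gene ids before duplicate checking.
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    for col in df.columns:
        if not pd.api.types.is_numeric_dtype(df[col]):
            coerced = pd.to_numeric(df[col], errors="coerce")
            bad = df.index[coerced.isna() & df[col].notna()]
            loc = f"gene '{bad[0]}', sample '{col}'" if len(bad) else f"column '{col}'"
            raise ValidationError(f"non-numeric value at {loc}")
    if strip_versions:
        df.index = [strip_gene_version(g) for g in df.index]
    return CountMatrix(df.astype(float))


def read_annotation(path: str | Path, strip_versions: bool = True) -> GeneAnnotation:
    """Read a three-column gene annotation table (gene_id, length_bp, gc_fraction)."""
    df = pd.read_csv(path, sep="\t")
    cols = {c.strip().lower(): c for c in df.columns}
    missing = [c for c in ("gene_id", "length_bp", "gc_fraction") if c not in cols]
    if missing:
        raise SchemaError(
            f"annotation is missing required column(s): {', '.join(missing)}"
        )
    df = df.rename(columns={cols[k]: k for k in ("gene_id", "length_bp", "gc_fraction")})
    df["gene_id"] = df["gene_id"].astype(str)
    if strip_versions:
        df["gene_id"] = df["gene_id"].map(strip_gene_version)
    df = df.set_index("gene_id")[["length_bp", "gc_fraction"]]
    return GeneAnnotation(df.astype({"length_bp": int, "gc_fraction": float}))


def assemble(
    pheno: PhenotypeSheet,
    counts: CountMatrix,
    annotation: Optional[GeneAnnotation] = None,
    organism: str = "human",
) -> QCDataset:
    """Match phenotype samples to count-matrix columns and build a dataset.

    Count-matrix columns not named in the phenotype sheet are dropped with
    a logged warning — this is the sample-exclusion mechanism: remove a
    sample from the sheet and the whole QC run recomputes without it. A
    phenotype sample missing from the counts is an error.
    """
    missing = [s for s in pheno.sample_ids if s not in counts.values.columns]
    if missing:
        raise ValidationError(
            f"phenotype sample(s) not found in count matrix: {', '.join(missing)}"
        )
    dropped = [s for s in counts.values.columns if s not in set(pheno.sample_ids)]
    if dropped:
        logger.warning(
            "dropping %d count-matrix sample(s) absent from the phenotype sheet: %s",
            len(dropped),
            ", ".join(dropped),
        )
    sub = CountMatrix(counts.values[pheno.sample_ids].copy(), is_raw=counts.is_raw)
    return QCDataset(counts=sub, pheno=pheno, annotation=annotation, organism=organism)


def write_phenotype(sheet: PhenotypeSheet, path: str | Path) -> None:
    sheet.data.rename_axis("sample").reset_index().to_csv(path, sep="\t", index=False)


def write_counts(counts: CountMatrix, path: str | Path) -> None:
    out = counts.values
    if counts.is_raw:
        out = out.astype(int)
    out.rename_axis("gene_id").to_csv(path, sep="\t", float_format="%.10g")


def write_annotation(annotation: GeneAnnotation, path: str | Path) -> None:
    annotation.data.rename_axis("gene_id").to_csv(
        path, sep="\t", float_format="%.10g"
    )
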