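"""Orchestration: run every QC metric, write the tables, flag suspects.

:func:`run_qc` executes the full pipeline — input validation, the
normalization ladder, summary statistics, both PCAs, MFA (or its skip
note), clustering, the two correlation matrices, density, housekeeping and
GC-bias curves — and serializes each result as a TSV next to the rendered
figures, plus a single ``report.json`` manifest.

:func:`flag_outliers` codifies the ensemble reading a human applies to
those metrics. Each rule computes a robust z-score (median/MAD) of one
per-sample statistic — library size, housekeeping level, un-normalized PC1
position, GC-curve height — and triggers past ±2.5. Individual rule hits
are advisory; a sample is *called* an outlier only when at least two
independent rules agree, mirroring the principle that no single metric
justifies excluding a sample. Nothing is ever removed automatically: the
user drops a sample by editing the phenotype sheet and re-running.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Any, Optional, Union

import numpy as np
import pandas as pd

from .version import __version__
from .bias import (
    DensityCurve,
    GCCurve,
    GeneProfile,
    HousekeepingSkipped,
    density_input,
    gc_bias,
    gene_profile,
    housekeeping,
    mapped_density,
)
from .errors import ExprQCError, StageError, ValidationError
from .io import (
    QCDataset,
    assemble,
    read_annotation,
    read_counts,
    read_phenotype,
)
from .multivariate import (
    CorrelationResult,
    Dendrogram,
    MFAResult,
    MFASkipped,
    PCAResult,
    correlate_samples,
    hcluster_samples,
    mfa,
    pca_samples,
)
from .normalize import NormalizedMatrix, log2p1, matrix_values, tpm, zscore_rows
from .sumstats import count_distribution, sample_summary

logger = logging.getLogger(__name__)

METRICS = (
    "summary",
    "distribution",
    "density",
    "housekeeping",
    "pca",
    "mfa",
    "hclust",
    "correlation",
    "gc",
    "gene",
)

ROBUST_Z_THRESHOLD = 2.5
MIN_SAMPLES_FOR_FLAGS = 4
MIN_RULES_FOR_CALL = 2


@dataclass
class QCConfig:
    """Everything a QC run needs; file paths plus tunables."""

    counts: str
    pheno: str
    outdir: str
    annotation: Optional[str] = None
    organism: str = "human"
    gene: Optional[str] = None
    linkage: str = "complete"
    lowess_fraction: float = 2.0 / 3.0
    correlation_input: str = "log"  # raw | log | tpm
    plot_format: str = "png"
    seed: int = 0
    skip: tuple[str, ...] = ()
    make_plots: bool = True

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


@dataclass
class OutlierFlag:
    sample_id: str
    rule: str
    statistic: float
    threshold: float


@dataclass
class QCReport:
    dataset: QCDataset
    summary: Optional[pd.DataFrame] = None
    distribution: Optional[pd.DataFrame] = None
    density: Optional[list[DensityCurve]] = None
    housekeeping: Union[tuple[GeneProfile, GeneProfile], HousekeepingSkipped, None] = None
    pca_zscored: Optional[PCAResult] = None
    pca_unnormalized: Optional[PCAResult] = None
    mfa: Union[MFAResult, MFASkipped, None] = None
    dendrogram: Optional[Dendrogram] = None
    pearson: Optional[CorrelationResult] = None
    spearman: Optional[CorrelationResult] = None
    gc_curves: Optional[list[GCCurve]] = None
    gene: Optional[GeneProfile] = None
    flags: list[OutlierFlag] = field(default_factory=list)
    flagged_samples: list[str] = field(default_factory=list)
    skip_reasons: dict[str, str] = field(default_factory=dict)
    outputs: list[str] = field(default_factory=list)


def robust_z(x: np.ndarray) -> np.ndarray:
    """Median/MAD z-scores; falls back to the scaled mean absolute
    deviation when the MAD degenerates, and to zeros when both do."""
    x = np.asarray(x, dtype=float)
    med = np.median(x)
    mad = np.median(np.abs(x - med))
    scale = 1.4826 * mad
    if scale == 0:
        scale = 1.2533 * np.mean(np.abs(x - med))
    if scale == 0:
        return np.zeros_like(x)
    return (x - med) / scale


def flag_outliers(
    summary: Optional[pd.DataFrame],
    pca_unnormalized: Optional[PCAResult],
    hk: Union[tuple[GeneProfile, GeneProfile], HousekeepingSkipped, None],
    gc_curves: Optional[list[GCCurve]] = None,
    threshold: float = ROBUST_Z_THRESHOLD,
) -> list[OutlierFlag]:
    """Evaluate the advisory outlier rules; returns one flag per rule hit.

    Rules (each independent, each on a robust z-score of a per-sample
    statistic): ``low_library_size`` and ``low_housekeeping`` trigger below
    -threshold; ``extreme_pc1`` triggers beyond |threshold| on the
    un-normalized PC1 scores; ``depressed_gc_curve`` triggers below
    -threshold on the mean fitted GC-curve height. With fewer than
    4 samples the MAD is meaningless and no rule is evaluated.
    """
    statistics: dict[str, pd.Series] = {}
    if summary is not None:
        statistics["low_library_size"] = summary["library_size"].astype(float)
    if isinstance(hk, tuple):
        statistics["low_housekeeping"] = (hk[0].values + hk[1].values) / 2.0
    if pca_unnormalized is not None:
        statistics["extreme_pc1"] = pca_unnormalized.scores["PC1"]
    if gc_curves:
        statistics["depressed_gc_curve"] = pd.Series(
            {c.sample_id: float(np.mean(c.fitted)) for c in gc_curves}
        )

    flags: list[OutlierFlag] = []
    for rule, series in statistics.items():
        if len(series) < MIN_SAMPLES_FOR_FLAGS:
            logger.warning("fewer than %d samples; outlier rules skipped", MIN_SAMPLES_FOR_FLAGS)
            return []
        z = robust_z(series.to_numpy())
        for sample, zi in zip(series.index, z):
            hit = abs(zi) > threshold if rule == "extreme_pc1" else zi < -threshold
            if hit:
                flags.append(OutlierFlag(str(sample), rule, float(zi), threshold))
    return flags


def call_outliers(flags: list[OutlierFlag], min_rules: int = MIN_RULES_FOR_CALL) -> list[str]:
    """Samples flagged by at least ``min_rules`` distinct rules."""
    per_sample: dict[str, set[str]] = {}
    for f in flags:
        per_sample.setdefault(f.sample_id, set()).add(f.rule)
    return sorted(s for s, rules in per_sample.items() if len(rules) >= min_rules)


def _write_tsv(df: pd.DataFrame, path: Path, outputs: list[str]) -> None:
    df.to_csv(path, sep="\t", float_format="%.10g")
    outputs.append(path.name)


def _curves_frame(curves: list, xname: str) -> pd.DataFrame:
    rows = []
    for c in curves:
        x = c.grid if hasattr(c, "grid") else c.gc
        y = c.density if hasattr(c, "density") else c.fitted
        rows.append(pd.DataFrame({"sample": c.sample_id, xname: x, "y": y}))
    return pd.concat(rows, ignore_index=True).set_index("sample")


def load_dataset(config: QCConfig) -> QCDataset:
    pheno = read_phenotype(config.pheno)
    counts = read_counts(config.counts)
    annotation = read_annotation(config.annotation) if config.annotation else None
    return assemble(pheno, counts, annotation, organism=config.organism)


def run_qc(config: QCConfig) -> QCReport:
    """Execute the full QC pipeline and write all outputs under ``outdir``."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    skip = set(config.skip)
    unknown = skip - set(METRICS)
    if unknown:
        raise ValidationError(f"unknown metric(s) in skip list: {', '.join(sorted(unknown))}")

    def stage(name: str, fn, *args, **kwargs):
        try:
            return fn(*args, **kwargs)
        except ExprQCError:
            raise
        except Exception as exc:  # pragma: no cover - defensive
            raise StageError(name, exc) from exc

    report_dataset = stage("core_io", load_dataset, config)
    report = QCReport(dataset=report_dataset)
    ds = report_dataset
    outputs = report.outputs

    logged = stage("normalize", log2p1, ds.counts)
    zscored = stage("normalize", zscore_rows, logged)
    density_matrix: Optional[NormalizedMatrix] = None

    if "summary" not in skip:
        report.summary = stage("sumstats", sample_summary, ds)
        _write_tsv(report.summary, outdir / "summary_statistics.tsv", outputs)
    if "distribution" not in skip:
        report.distribution = stage("sumstats", count_distribution, ds)
        _write_tsv(report.distribution, outdir / "count_distribution.tsv", outputs)
    if "density" not in skip:
        density_matrix = stage("normalize", density_input, ds)
        report.density = stage("bias_metrics", mapped_density, ds, density_matrix)
        _write_tsv(
            _curves_frame(report.density, "x"), outdir / "mapped_density.tsv", outputs
        )
    if "housekeeping" not in skip:
        report.housekeeping = stage("bias_metrics", housekeeping, ds)
        if isinstance(report.housekeeping, HousekeepingSkipped):
            report.skip_reasons["housekeeping"] = report.housekeeping.reason
        else:
            hk_df = pd.DataFrame(
                {p.gene: p.values for p in report.housekeeping}
            ).rename_axis("sample")
            _write_tsv(hk_df, outdir / "housekeeping.tsv", outputs)
    if "pca" not in skip:
        report.pca_zscored = stage("multivariate", pca_samples, zscored, "zscored")
        report.pca_unnormalized = stage(
            "multivariate", pca_samples, ds.counts, "unnormalized"
        )
        for res, tag in (
            (report.pca_zscored, "zscored"),
            (report.pca_unnormalized, "unnormalized"),
        ):
            scores = res.scores.copy()
            scores.loc["variance_explained"] = res.variance_explained
            _write_tsv(
                scores.rename_axis("sample"), outdir / f"pca_{tag}.tsv", outputs
            )
    if "mfa" not in skip:
        report.mfa = stage("multivariate", mfa, ds, zscored)
        if isinstance(report.mfa, MFASkipped):
            report.skip_reasons["mfa"] = report.mfa.reason
        else:
            _write_tsv(
                report.mfa.group_contributions.rename_axis("group"),
                outdir / "mfa_contributions.tsv",
                outputs,
            )
            _write_tsv(
                report.mfa.scores.rename_axis("sample"), outdir / "mfa_scores.tsv", outputs
            )
    if "hclust" not in skip:
        report.dendrogram = stage(
            "multivariate", hcluster_samples, logged, config.linkage
        )
        merge_df = pd.DataFrame(
            report.dendrogram.linkage_matrix,
            columns=["left", "right", "height", "size"],
        ).rename_axis("merge")
        _write_tsv(merge_df, outdir / "dendrogram_merges.tsv", outputs)
    if "correlation" not in skip:
        corr_matrix = {
            "raw": ds.counts.values,
            "log": logged.values,
            "tpm": None,
        }.get(config.correlation_input)
        if corr_matrix is None:
            if config.correlation_input != "tpm":
                raise ValidationError(
                    f"unknown correlation input '{config.correlation_input}'"
                )
            if ds.annotation is None:
                raise ValidationError("correlation on TPM requires an annotation")
            corr_matrix = tpm(ds.counts, ds.annotation).values
        for method in ("pearson", "spearman"):
            res = stage("multivariate", correlate_samples, corr_matrix, method)
            setattr(report, method, res)
            _write_tsv(
                res.matrix.rename_axis("sample"),
                outdir / f"correlation_{method}.tsv",
                outputs,
            )
    if "gc" not in skip:
        if ds.annotation is None:
            report.skip_reasons["gc"] = (
                "no gene annotation supplied; GC-bias curves need gene GC content"
            )
        else:
            report.gc_curves = stage(
                "bias_metrics", gc_bias, ds, config.lowess_fraction
            )
            _write_tsv(
                _curves_frame(report.gc_curves, "gc"), outdir / "gc_bias.tsv", outputs
            )
    if "gene" not in skip and config.gene:
        report.gene = stage("bias_metrics", gene_profile, ds, config.gene)
        _write_tsv(
            report.gene.values.to_frame(report.gene.gene).rename_axis("sample"),
            outdir / f"gene_{report.gene.gene}.tsv",
            outputs,
        )

    if len(ds.sample_ids) < MIN_SAMPLES_FOR_FLAGS:
        report.skip_reasons["outlier_flags"] = (
            "fewer than 4 samples: median/MAD rules are unstable"
        )
    else:
        report.flags = flag_outliers(
            report.summary, report.pca_unnormalized, report.housekeeping, report.gc_curves
        )
        report.flagged_samples = call_outliers(report.flags)
    if report.flags:
        flag_df = pd.DataFrame(
            [asdict(f) for f in report.flags]
        ).set_index("sample_id")
        _write_tsv(flag_df, outdir / "outlier_flags.tsv", outputs)

    if config.make_plots:
        from . import plots

        stage("report_cli", plots.render_all, report, config, outdir)

    manifest = {
        "exprqc_version": __version__,
        "config": asdict(config),
        "config_hash": config.config_hash(),
        "n_samples": len(ds.sample_ids),
        "n_genes": len(ds.counts.gene_ids),
        "skip_reasons": report.skip_reasons,
        "flags": [asdict(f) for f in report.flags],
        "flagged_samples": report.flagged_samples,
        "outputs": sorted(outputs),
    }
    (outdir / "report.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return report
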