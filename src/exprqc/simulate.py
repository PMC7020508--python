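"""Negative-binomial RNA-seq count simulator with planted technical artifacts.

Every downstream metric is testable against matrices produced here: counts
follow ``NB(mean = L_s * mu_g * exp(group + covariate + gc term), dispersion)``
with

* per-gene baselines ``mu_g`` drawn from a lognormal (a handful of highly
  expressed genes over a long low tail, as in real bulk RNA-seq);
* per-sample library scales ``L_s`` (a collapsed library, e.g. 5%, is the
  classic depth outlier);
* group effects on a random subset of genes (ordinary biology);
* covariate effects (library protocol, flow cell, extraction method) —
  per-level lognormal shifts on a gene subset, modelling technical batch
  structure;
* a per-sample GC slope acting multiplicatively through
  ``exp(slope * (gc_g - 0.5))``, so a negative slope depresses high-GC
  genes the way a library-preparation artifact does;
* optional per-sample "biological variability" — sample-specific
  expression shifts (symmetric in log space) on a random subset of genes,
  mimicking a sample whose biology genuinely differs from its group
  without any technical defect: its profile widens but its depth and its
  log-scale level statistics stay centred. The shifts are planted outside
  the top percentile of baseline expression, because the most highly
  expressed genes are constitutive machinery that is stable between
  individuals — a variable-but-healthy sample scatters on equal-weight
  views of the data, not on depth-dominated ones.

Two housekeeping genes (GAPDH, ACTB for the default human organism) are
planted with high, stable baselines untouched by group, covariate or
jitter effects; they still feel library scale and the GC term, which is
exactly why their profile exposes depth problems.

Gene lengths are discretized lognormals (>= 200 bp) and GC fractions are
Beta(5, 5), centered near 0.5 like real transcriptomes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .errors import ValidationError
from .io import CountMatrix, GeneAnnotation, PhenotypeSheet

HOUSEKEEPING_BY_ORGANISM = {
    "human": ("GAPDH", "ACTB"),
    "mouse": ("Gapdh", "Actb"),
}


@dataclass
class CovariateEffect:
    """A categorical technical covariate and its planted expression effect."""

    name: str
    levels: list[str]  # one label per sample, phenotype-sheet order
    effect_sd: float  # SD of the per-level log-normal gene shifts
    gene_frac: float = 0.3  # fraction of genes the covariate touches


@dataclass
class SimScenario:
    """Parameters of one simulated experiment."""

    n_genes: int = 2000
    groups: dict[str, int] = field(
        default_factory=lambda: {"control": 4, "diseased": 4}
    )
    log_mu_mean: float = 5.0  # lognormal baseline: ln-mean ...
    log_mu_sd: float = 1.5  # ... and ln-sd of per-gene means
    # NB dispersion follows the canonical decreasing trend in the mean,
    # alpha(mu) = dispersion + dispersion_mean_scale / mu, so highly
    # expressed genes are tight across replicates while low ones stay
    # noisy; set dispersion_mean_scale=0 for a constant dispersion.
    dispersion: float = 0.05
    dispersion_mean_scale: float = 5.0
    group_effect_sd: float = 0.5
    group_gene_frac: float = 0.1
    library_scale: dict[str, float] = field(default_factory=dict)
    gc_slope: dict[str, float] = field(default_factory=dict)
    bio_noise: dict[str, float] = field(default_factory=dict)
    bio_gene_frac: float = 0.15  # genes touched by per-sample biological shifts
    covariates: list[CovariateEffect] = field(default_factory=list)
    organism: str = "human"
    seed: int = 0

    def validate(self) -> None:
        if self.n_genes < 10:
            raise ValidationError("need at least 10 genes")
        if self.dispersion <= 0:
            raise ValidationError("dispersion must be positive")
        if self.dispersion_mean_scale < 0:
            raise ValidationError("dispersion_mean_scale must be non-negative")
        if any(v <= 0 for v in self.library_scale.values()):
            raise ValidationError("library scales must be positive")
        if any(sd < 0 for sd in self.bio_noise.values()):
            raise ValidationError("bio-noise SDs must be non-negative")
        n = self.n_samples
        for cov in self.covariates:
            if len(cov.levels) != n:
                raise ValidationError(
                    f"covariate '{cov.name}' has {len(cov.levels)} labels "
                    f"for {n} samples"
                )

    @property
    def n_samples(self) -> int:
        return sum(self.groups.values())

    @property
    def sample_ids(self) -> list[str]:
        return [
            f"{g}{i + 1}" for g, k in self.groups.items() for i in range(k)
        ]


def _nb_draw(
    rng: np.random.Generator, mean: np.ndarray, dispersion: np.ndarray
) -> np.ndarray:
    """NB with mean ``mean`` and variance ``mean + dispersion * mean**2``."""
    out = np.zeros_like(mean, dtype=np.int64)
    pos = mean > 0
    size = 1.0 / np.asarray(dispersion)[pos]
    out[pos] = rng.negative_binomial(size, size / (size + mean[pos]))
    return out


def simulate(
    scenario: SimScenario, seed: Optional[int] = None
) -> tuple[CountMatrix, PhenotypeSheet, GeneAnnotation]:
    """Draw one (counts, phenotype, annotation) triple from a scenario."""
    scenario.validate()
    rng = np.random.default_rng(scenario.seed if seed is None else seed)
    n_g, n_s = scenario.n_genes, scenario.n_samples
    samples = scenario.sample_ids
    group_of = [g for g, k in scenario.groups.items() for _ in range(k)]

    hk = HOUSEKEEPING_BY_ORGANISM.get(scenario.organism, ())
    gene_ids = list(hk) + [f"G{i:05d}" for i in range(1, n_g - len(hk) + 1)]
    stable = np.zeros(n_g, dtype=bool)
    stable[: len(hk)] = True  # housekeeping rows: no group/cov/jitter effects

    mu = rng.lognormal(scenario.log_mu_mean, scenario.log_mu_sd, n_g)
    mu[stable] = rng.lognormal(scenario.log_mu_mean + 3.0, 0.1, stable.sum())

    # annotation
    lengths = np.maximum(200, np.round(rng.lognormal(7.5, 0.6, n_g))).astype(int)
    gc = rng.beta(5.0, 5.0, n_g)

    # per-gene, per-sample log effects
    log_effect = np.zeros((n_g, n_s))
    ref_group = next(iter(scenario.groups))
    for g_name in scenario.groups:
        if g_name == ref_group:
            continue
        de = (rng.random(n_g) < scenario.group_gene_frac) & ~stable
        delta = np.where(de, rng.normal(0.0, scenario.group_effect_sd, n_g), 0.0)
        cols = [j for j, gg in enumerate(group_of) if gg == g_name]
        log_effect[:, cols] += delta[:, None]
    for cov in scenario.covariates:
        affected = (rng.random(n_g) < cov.gene_frac) & ~stable
        for level in dict.fromkeys(cov.levels):
            shift = np.where(affected, rng.normal(0.0, cov.effect_sd, n_g), 0.0)
            cols = [j for j, lv in enumerate(cov.levels) if lv == level]
            log_effect[:, cols] += shift[:, None]

    lib = np.array([scenario.library_scale.get(s, 1.0) for s in samples])
    slope = np.array([scenario.gc_slope.get(s, 0.0) for s in samples])
    mean = lib[None, :] * mu[:, None] * np.exp(
        log_effect + slope[None, :] * (gc[:, None] - 0.5)
    )
    # constitutive top-expressors stay stable between individuals
    variable_pool = ~stable & (mu < np.quantile(mu, 0.99))
    for j, s in enumerate(samples):
        sd = scenario.bio_noise.get(s, 0.0)
        if sd > 0:
            touched = (rng.random(n_g) < scenario.bio_gene_frac) & variable_pool
            shift = np.where(touched, rng.normal(0.0, sd, n_g), 0.0)
            mean[:, j] *= np.exp(shift)

    disp = scenario.dispersion + np.divide(
        scenario.dispersion_mean_scale,
        mean,
        out=np.zeros_like(mean),
        where=mean > 0,
    )
    counts = pd.DataFrame(
        _nb_draw(rng, mean, disp), index=gene_ids, columns=samples
    )
    pheno = pd.DataFrame({"group": group_of}, index=pd.Index(samples, name="sample"))
    for cov in scenario.covariates:
        pheno[cov.name] = cov.levels
    anno = pd.DataFrame(
        {"length_bp": lengths, "gc_fraction": gc},
        index=pd.Index(gene_ids, name="gene_id"),
    )
    return (
        CountMatrix(counts.astype(float), is_raw=True),
        PhenotypeSheet(pheno),
        GeneAnnotation(anno),
    )


def scenario_presets() -> dict[str, SimScenario]:
    """Named scenarios covering the canonical QC failure modes.

    * **A** — clean two-group design, no artifacts (false-positive control);
    * **B** — one library-collapsed, GC-depressed outlier (control4) plus
      one biologically variable but healthy sample (diseased3);
    * **C** — library protocol and flow cell dominating the variance;
    * **D** — RNA-extraction protocol confounded with cell type, with the
      technical effect stronger than the biological one.
    """
    presets: dict[str, SimScenario] = {}
    presets["A"] = SimScenario()
    presets["B"] = SimScenario(
        library_scale={"control4": 0.05},
        gc_slope={"control4": -2.0},
        bio_noise={"diseased3": 0.8},
    )
    presets["C"] = SimScenario(
        groups={"YPD": 4, "Delft": 4, "YPGly": 4},
        group_effect_sd=0.3,
        covariates=[
            CovariateEffect(
                "protocol",
                ["P1", "P2"] * 6,
                effect_sd=1.0,
                gene_frac=0.3,
            ),
            CovariateEffect(
                "flow_cell",
                ["F1", "F2", "F3"] * 4,
                effect_sd=0.4,
                gene_frac=0.2,
            ),
        ],
    )
    presets["D"] = SimScenario(
        groups={"CD20": 4, "CD14": 4},
        group_effect_sd=0.5,
        group_gene_frac=0.1,
        covariates=[
            CovariateEffect(
                "extraction",
                ["Pap", "Pap", "Pam", "Pam"] * 2,
                effect_sd=1.2,
                gene_frac=0.4,
            ),
        ],
    )
    return presets
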