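"""Synthetic RNA-Seq cohorts with planted co-expression modules.

The generator emulates the statistical structure a module-discovery
pipeline assumes in peripheral-blood bulk RNA-Seq of a depression cohort:

* negative-binomially distributed gene counts over ~150 samples x ~6000
  genes, with log-normal library sizes (CV ~ 0.3);
* block-correlated gene modules induced by a Gaussian latent factor per
  module (a one-parameter copula: gene-level log-signal is
  ``sqrt(rho) * factor + sqrt(1 - rho) * noise``);
* a small number of modules whose latent factors are linearly coupled to
  a MADRS-like severity trait, and to a diagnosis (MDD/HC) obtained by
  thresholding the same liability at its median so trait and diagnosis
  are correlated;
* per-batch, per-gene log-scale offsets; covariates (sex, age, BMI,
  smoking, self-reported ancestry) with small trait effects;
* a fraction of genes with log-means low enough to fail a read-count
  filter, a fraction with inflated per-sample variance (high COV), and a
  few samples shifted in many genes (geometric outliers).

Everything is deterministic given ``SimulationConfig.seed``; all
sub-generators derive child streams from one ``numpy`` seed sequence.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .io import write_counts_tsv, write_gmt, write_json, write_phenotypes_csv

__all__ = [
    "SimulationConfig",
    "SyntheticCohort",
    "Truth",
    "generate_cohort",
    "generate_replication_cohort",
]


class ConfigurationError(ValueError):
    """A simulation configuration violates one of its invariants."""


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of a planted-module cohort.

    Parameters
    ----------
    n_samples, n_genes : int
        Cohort dimensions.
    module_sizes : sequence of int
        Sizes of the planted modules; remaining genes are uncorrelated
        background.
    rho : float in (0, 1)
        Within-module latent-signal correlation (the copula parameter).
    n_trait_modules : int
        How many leading modules have their factor coupled to the trait.
    trait_effect : float
        Trait-score units added per standard deviation of each
        trait-module factor.
    n_batches, batch_sd : int, float
        Number of batches and the SD of the per-batch per-gene
        natural-log offsets.
    nb_dispersion : float > 0
        Negative-binomial dispersion; variance = mu + dispersion * mu^2.
    frac_low_count : float in [0, 1)
        Fraction of genes (drawn from the background) with log-means low
        enough to fail a ">= 2-7 reads in >= 15 samples" filter.
    frac_high_cov : float in [0, 1)
        Fraction of genes (background) with inflated per-sample variance
        so that their CPM coefficient of variation exceeds ~0.8.
    n_outliers, outlier_shift : int, float
        Number of geometric outlier samples, and the shift applied to
        half of their genes in multiples of the per-gene log SD.
    library_size_mean, library_size_cv : float
        Log-normal library-size distribution (reads).
    seed : int
        Master seed; the cohort is reproducible byte for byte.
    """

    n_samples: int = 160
    n_genes: int = 6000
    module_sizes: tuple[int, ...] = (200, 180, 150, 120, 100)
    rho: float = 0.6
    n_trait_modules: int = 2
    trait_effect: float = 6.0
    n_batches: int = 2
    batch_sd: float = 0.1
    nb_dispersion: float = 0.1
    frac_low_count: float = 0.25
    frac_high_cov: float = 0.08
    n_outliers: int = 2
    outlier_shift: float = 5.0
    library_size_mean: float = 3.0e6
    library_size_cv: float = 0.3
    seed: int = 0

    def __post_init__(self):
        object.__setattr__(self, "module_sizes", tuple(int(s) for s in self.module_sizes))
        self.validate()

    def validate(self) -> None:
        if self.n_samples <= 0:
            raise ConfigurationError("n_samples must be positive")
        if self.n_genes <= 0:
            raise ConfigurationError("n_genes must be positive")
        if any(s <= 0 for s in self.module_sizes):
            raise ConfigurationError("module_sizes must all be positive")
        if sum(self.module_sizes) > self.n_genes:
            raise ConfigurationError("sum(module_sizes) exceeds n_genes")
        if not 0.0 < self.rho < 1.0:
            raise ConfigurationError("rho must lie strictly in (0, 1)")
        if not 0 <= self.n_trait_modules <= len(self.module_sizes):
            raise ConfigurationError(
                "n_trait_modules must not exceed the number of modules"
            )
        for name in ("frac_low_count", "frac_high_cov"):
            value = getattr(self, name)
            if not 0.0 <= value < 1.0:
                raise ConfigurationError(f"{name} must lie in [0, 1)")
        if self.nb_dispersion <= 0:
            raise ConfigurationError("nb_dispersion must be positive")
        if self.n_batches <= 0:
            raise ConfigurationError("n_batches must be positive")
        if not 0 <= self.n_outliers < self.n_samples:
            raise ConfigurationError("n_outliers must be fewer than n_samples")
        n_special = int(round((self.frac_low_count + self.frac_high_cov) * self.n_genes))
        if sum(self.module_sizes) + n_special > self.n_genes:
            raise ConfigurationError(
                "low-count and high-COV fractions leave too few background genes"
            )

    def replace(self, **kwargs) -> "SimulationConfig":
        return dataclasses.replace(self, **kwargs)


@dataclass
class Truth:
    """Ground truth of a simulated cohort."""

    module_labels: pd.Series  # per gene, 0 = background
    trait_modules: list[int]
    outliers: list[str]
    low_count_genes: list[str] = field(default_factory=list)
    high_cov_genes: list[str] = field(default_factory=list)

    def gene_sets(self) -> dict[str, list[str]]:
        sets: dict[str, list[str]] = {}
        for label in sorted(set(self.module_labels) - {0}):
            genes = self.module_labels.index[self.module_labels == label]
            sets[f"M{label}"] = list(genes)
        return sets


@dataclass
class SyntheticCohort:
    counts: pd.DataFrame  # genes x samples, non-negative integers
    phenotypes: pd.DataFrame  # indexed by sample id
    truth: Truth
    config: SimulationConfig

    def write(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_counts_tsv(self.counts, out / "counts.tsv")
        write_phenotypes_csv(self.phenotypes, out / "phenotypes.csv")
        write_gmt(self.truth.gene_sets(), out / "truth_modules.gmt")
        write_json(
            {
                "trait_modules": [f"M{m}" for m in self.truth.trait_modules],
                "outliers": self.truth.outliers,
                "low_count_genes": self.truth.low_count_genes,
                "high_cov_genes": self.truth.high_cov_genes,
            },
            out / "truth.json",
        )


# per-gene biological log-signal SD range (natural log). The range is a
# compromise: large enough that within-module logCPM correlations stay
# near 0.7 * rho after count-noise attenuation, small enough that a
# typical gene's CPM coefficient of variation stays below the 0.8
# filter (only low-abundance genes and the designated high-COV genes
# exceed it, as in real cohorts)
_SCALE_RANGE = (0.35, 0.6)
_BASELINE_LOG_CPM_MEAN = np.log(30.0)
_BASELINE_LOG_CPM_SD = 1.2
_LOW_COUNT_LOG_CPM = np.log(0.05)
_HIGH_COV_EXTRA_SD = 1.1
_TRAIT_INTERCEPT = 12.0
_TRAIT_NOISE_SD = 6.0
_SRA_LEVELS = ("Caucasian", "African-American", "Native American", "Asian American", "Other")
_SRA_PROBS = (0.76, 0.08, 0.03, 0.03, 0.10)


def _nb_counts(rng: np.random.Generator, mean: np.ndarray, dispersion: float) -> np.ndarray:
    """Gamma-Poisson draw with var = mu + dispersion * mu^2."""
    shape = 1.0 / dispersion
    lam = rng.gamma(shape, mean * dispersion)
    return rng.poisson(lam)


def _assemble(
    config: SimulationConfig,
    rng_children: list[np.random.Generator],
    diagnosis_from_factors: bool = False,
) -> SyntheticCohort:
    (
        rng_structure,
        rng_factors,
        rng_noise,
        rng_pheno,
        rng_counts,
    ) = rng_children
    n, g = config.n_samples, config.n_genes
    sizes = config.module_sizes
    n_mod = len(sizes)

    gene_ids = np.array([f"G{i:05d}" for i in range(g)])
    sample_ids = [f"S{i:03d}" for i in range(n)]

    # --- planted structure: module membership, low-count / high-COV genes
    perm = rng_structure.permutation(g)
    labels = np.zeros(g, dtype=int)
    pos = 0
    for m, size in enumerate(sizes, start=1):
        labels[perm[pos : pos + size]] = m
        pos += size
    background = perm[pos:]
    n_low = int(round(config.frac_low_count * g))
    n_hcv = int(round(config.frac_high_cov * g))
    low_idx = background[:n_low]
    hcv_idx = background[n_low : n_low + n_hcv]

    baseline = rng_structure.normal(_BASELINE_LOG_CPM_MEAN, _BASELINE_LOG_CPM_SD, g)
    baseline[low_idx] = _LOW_COUNT_LOG_CPM
    scale = rng_structure.uniform(*_SCALE_RANGE, g)
    batch_offsets = rng_structure.normal(0.0, config.batch_sd, (config.n_batches, g))

    # --- latent factors and gene-level log signal
    factors = rng_factors.standard_normal((n, n_mod))
    z = rng_noise.standard_normal((n, g))
    for m in range(1, n_mod + 1):
        in_m = labels == m
        z[:, in_m] = np.sqrt(config.rho) * factors[:, [m - 1]] + np.sqrt(
            1.0 - config.rho
        ) * z[:, in_m]
    z[:, hcv_idx] += rng_noise.normal(0.0, _HIGH_COV_EXTRA_SD, (n, n_hcv))

    # --- phenotypes
    sex = np.where(rng_pheno.random(n) < 0.55, "F", "M")
    age = np.clip(np.round(rng_pheno.normal(32, 10, n)), 18, 55).astype(int)
    bmi = np.round(np.clip(rng_pheno.normal(28, 6, n), 16, 50), 1)
    smoking = np.where(rng_pheno.random(n) < 0.09, "yes", "no")
    sra = rng_pheno.choice(_SRA_LEVELS, size=n, p=_SRA_PROBS)
    batch = np.array([f"B{i % config.n_batches + 1}" for i in range(n)])

    trait_sum = factors[:, : config.n_trait_modules].sum(axis=1)
    covariate_term = (
        1.0 * (sex == "F") + 0.05 * (age - age.mean()) + 0.10 * (bmi - bmi.mean())
    )
    liability = (
        config.trait_effect * trait_sum
        + covariate_term
        + rng_pheno.normal(0.0, _TRAIT_NOISE_SD, n)
    )
    madrs = np.maximum(0, np.round(_TRAIT_INTERCEPT + liability)).astype(int)
    if diagnosis_from_factors and config.n_trait_modules > 0:
        diag_liability = config.trait_effect * trait_sum + rng_pheno.normal(
            0.0, _TRAIT_NOISE_SD, n
        )
    else:
        diag_liability = liability
    diagnosis = np.where(diag_liability >= np.median(diag_liability), "MDD", "HC")

    # --- outliers: shift half of the genes by outlier_shift gene-SDs
    outlier_samples = rng_pheno.choice(n, size=config.n_outliers, replace=False)
    shifted_genes = rng_pheno.permutation(g)[: g // 2]
    for s in outlier_samples:
        z[s, shifted_genes] += config.outlier_shift

    # --- counts
    library = config.library_size_mean * rng_counts.lognormal(
        -0.5 * np.log1p(config.library_size_cv**2),
        np.sqrt(np.log1p(config.library_size_cv**2)),
        n,
    )
    batch_index = np.arange(n) % config.n_batches
    log_cpm = baseline[None, :] + scale[None, :] * z + batch_offsets[batch_index, :]
    mean_counts = np.exp(log_cpm) * (library[:, None] / 1.0e6)
    counts = _nb_counts(rng_counts, mean_counts, config.nb_dispersion)  # samples x genes

    counts_df = pd.DataFrame(counts.T, index=gene_ids, columns=sample_ids)
    counts_df.index.name = "gene"
    pheno = pd.DataFrame(
        {
            "diagnosis": diagnosis,
            "madrs": madrs,
            "sex": sex,
            "age": age,
            "bmi": bmi,
            "batch": batch,
            "smoking": smoking,
            "sra": sra,
        },
        index=pd.Index(sample_ids, name="sample"),
    )
    truth = Truth(
        module_labels=pd.Series(labels, index=gene_ids, name="module"),
        trait_modules=list(range(1, config.n_trait_modules + 1)),
        outliers=[sample_ids[s] for s in sorted(outlier_samples)],
        low_count_genes=list(gene_ids[np.sort(low_idx)]),
        high_cov_genes=list(gene_ids[np.sort(hcv_idx)]),
    )
    return SyntheticCohort(counts=counts_df, phenotypes=pheno, truth=truth, config=config)


_STREAMS = {"discovery": 0, "replication": 2}


def _child_rngs(seed: int, label: str) -> list[np.random.Generator]:
    root = np.random.SeedSequence(seed, spawn_key=(_STREAMS[label],))
    return [np.random.default_rng(s) for s in root.spawn(5)]


def generate_cohort(config: SimulationConfig) -> SyntheticCohort:
    """Simulate a discovery cohort with planted modules and a coupled trait."""
    config.validate()
    return _assemble(config, _child_rngs(config.seed, "discovery"))


def generate_replication_cohort(
    config: SimulationConfig,
    modules: Mapping[str, Sequence[str]] | pd.Series,
    overlap_fraction: float,
) -> SyntheticCohort:
    """Simulate an independent cohort covering only part of each module.

    Each discovery module keeps ``round(overlap_fraction * size)`` of its
    genes (the rest vanish from the replication gene universe, mimicking a
    different low-abundance filter); kept genes retain their discovery ids
    so gene-set overlap can be computed downstream. Diagnosis is coupled to
    the trait-module factors; module order follows the input mapping.
    """
    if isinstance(modules, pd.Series):
        sets = {
            f"M{label}": list(modules.index[modules == label])
            for label in sorted(set(modules) - {0})
        }
    else:
        sets = {name: list(genes) for name, genes in modules.items()}
    if not sets or all(len(g) == 0 for g in sets.values()):
        raise ValueError("modules must be non-empty")
    if not 0.0 < overlap_fraction <= 1.0:
        raise ValueError("overlap_fraction must lie in (0, 1]")

    rng = np.random.default_rng(np.random.SeedSequence(config.seed, spawn_key=(1,)))
    kept: dict[str, list[str]] = {}
    for name, genes in sets.items():
        k = int(np.rint(overlap_fraction * len(genes)))
        k = max(k, 1)
        chosen = sorted(rng.choice(len(genes), size=k, replace=False))
        kept[name] = [genes[i] for i in chosen]

    kept_sizes = tuple(len(g) for g in kept.values())
    n_background = max(config.n_genes - sum(len(g) for g in sets.values()), 0)
    sub = config.replace(
        n_genes=sum(kept_sizes) + n_background,
        module_sizes=kept_sizes,
        n_trait_modules=min(config.n_trait_modules, len(kept_sizes)),
        frac_low_count=0.0,
        frac_high_cov=0.0,
        n_outliers=0,
    )
    cohort = _assemble(sub, _child_rngs(config.seed, "replication"), diagnosis_from_factors=True)

    # rename: module genes keep their discovery ids, background genes get R-prefixed ids
    labels = cohort.truth.module_labels
    new_ids = np.array([f"R{i:05d}" for i in range(len(labels))], dtype=object)
    for m, (name, genes) in enumerate(kept.items(), start=1):
        new_ids[np.flatnonzero(labels.to_numpy() == m)] = genes
    cohort.counts.index = pd.Index(new_ids, name="gene")
    cohort.truth.module_labels = pd.Series(
        labels.to_numpy(), index=cohort.counts.index, name="module"
    )
    cohort.phenotypes.index = pd.Index(
        [f"E{i:03d}" for i in range(len(cohort.phenotypes))], name="sample"
    )
    cohort.counts.columns = cohort.phenotypes.index
    return cohort
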