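"""End-to-end orchestration: counts -> modules -> scores -> associations.

``run_pipeline`` executes preprocessing, network module detection,
ssGSEA scoring, trait association (with smoking and ancestry-subset
sensitivity analyses), centrality analysis, and optionally replication
on a second cohort. Inputs come either from files (counts TSV +
phenotype CSV) or from a simulation block; every intermediate artifact
and a run manifest are written to the output directory.
"""

from __future__ import annotations

import traceback
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .association import ModuleTraitRegression, subset_sensitivity, build_covariates, scale_trait
from .centrality import centrality_report
from .cohort_stats import table_one
from .io import (
    read_counts_tsv,
    read_phenotypes_csv,
    write_expression_tsv,
    write_gmt,
    write_json,
)
from .network import CoexpressionModuleDetector
from .preprocess import RNASeqPreprocessor
from .replicate import replication_analysis
from .scores import SSGSEAScorer
from .simulate import SimulationConfig, generate_cohort, generate_replication_cohort

__all__ = ["run_pipeline", "default_config", "PipelineError"]


class PipelineError(RuntimeError):
    """A pipeline stage failed; carries the stage name and provenance so far."""

    def __init__(self, stage: str, cause: BaseException, provenance: dict):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage
        self.provenance = provenance


def default_config(seed: int = 0) -> dict:
    """The demo configuration: a simulated cohort at study scale."""
    return {
        "seed": seed,
        "simulate": {},
        "preprocess": {
            "min_samples": 15,
            "min_reads_range": [2, 7],
            "abof_threshold": 0.001,
            "cov_threshold": 0.8,
        },
        "network": {
            "tau_grid": [0.1, 0.15, 0.2, 0.25, 0.3],
            "target_mean_size": 200,
            "min_module_size": 30,
        },
        "scores": {"alpha": 0.25, "normalize": True},
        "association": {
            "covariates": ["sex", "age", "bmi", "batch"],
            "fdr": 0.05,
            "smoking_sensitivity": True,
            "subset_column": "sra",
            "subset_value": "Caucasian",
        },
        "centrality": {"top_k": 100},
        "replication": {"overlap_fraction": 0.8, "n_samples": 300},
    }


def _load_config(config: str | Path | Mapping[str, Any]) -> dict:
    if isinstance(config, (str, Path)):
        with open(config) as handle:
            return yaml.safe_load(handle)
    return dict(config)


def run_pipeline(config: str | Path | Mapping[str, Any], out_dir: str | Path) -> dict:
    """Run the full workflow; returns the manifest dict.

    The config needs either an ``inputs`` block (``counts`` TSV path and
    ``phenotypes`` CSV path) or a ``simulate`` block (SimulationConfig
    fields; empty dict for defaults). Artifacts are written under
    ``out_dir``.
    """
    cfg = _load_config(config)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seed = int(cfg.get("seed", 0))
    manifest: dict[str, Any] = {
        "seed": seed,
        "version": __version__,
        "config": {k: v for k, v in cfg.items()},
        "stages": {},
    }

    stage = "inputs"
    try:
        truth = None
        if "simulate" in cfg and cfg["simulate"] is not None:
            sim_kwargs = dict(cfg["simulate"] or {})
            sim_kwargs.setdefault("seed", seed)
            sim_config = SimulationConfig(**sim_kwargs)
            cohort = generate_cohort(sim_config)
            cohort.write(out / "simulated")
            counts, phenotypes = cohort.counts, cohort.phenotypes
            truth = cohort.truth
            manifest["stages"]["simulate"] = {
                "n_samples": sim_config.n_samples,
                "n_genes": sim_config.n_genes,
                "module_sizes": list(sim_config.module_sizes),
                "trait_modules": truth.trait_modules,
            }
        elif "inputs" in cfg:
            counts = read_counts_tsv(cfg["inputs"]["counts"])
            phenotypes = read_phenotypes_csv(cfg["inputs"]["phenotypes"])
        else:
            raise ValueError("config needs an 'inputs' or a 'simulate' block")

        stage = "cohort_stats"
        try:
            stats = table_one(phenotypes)
            stats.to_csv(out / "table_one.tsv", sep="\t")
        except ValueError:
            stats = None  # e.g. single-group phenotype table

        stage = "preprocess"
        pre = RNASeqPreprocessor(**_coerce_pre(cfg.get("preprocess", {})))
        expr = pre.fit_transform(counts, phenotypes)
        write_expression_tsv(expr, out / "expression.tsv")
        write_json(pre.provenance_, out / "provenance.json")
        prov = pre.provenance_
        manifest["stages"]["preprocess"] = {
            "n_genes_in": prov["n_genes_in"],
            "n_low_count": prov["low_count"]["n_removed"],
            "n_normalized": prov["normalized_genes"],
            "n_high_cov": prov["high_cov"]["n_removed"],
            "n_genes_out": prov["n_genes_out"],
            "n_samples_in": prov["n_samples_in"],
            "outliers_removed": prov["outliers"]["removed"],
            "n_samples_out": prov["n_samples_out"],
        }
        phenotypes = phenotypes.loc[expr.index]

        stage = "network"
        net_cfg = dict(cfg.get("network", {}))
        detector = CoexpressionModuleDetector(**net_cfg)
        detector.fit(expr)
        labels = pd.Series(detector.labels_, index=expr.columns, name="module")
        labels.to_csv(out / "module_labels.tsv", sep="\t")
        write_gmt(detector.gene_sets_, out / "modules.gmt")
        if hasattr(detector, "tuning_report_"):
            detector.tuning_report_.to_csv(out / "tau_report.tsv", sep="\t", index=False)
        manifest["stages"]["network"] = {
            "tau": detector.tau_,
            "n_modules": len(detector.modules_),
            "module_sizes": detector.module_sizes_,
            "n_unassigned": int(np.sum(detector.labels_ == 0)),
        }

        stage = "scores"
        scorer = SSGSEAScorer(gene_sets=detector.gene_sets_, **dict(cfg.get("scores", {})))
        scores = scorer.fit().transform(expr)
        write_expression_tsv(scores, out / "module_scores.tsv")

        stage = "association"
        assoc_cfg = dict(cfg.get("association", {}))
        model = ModuleTraitRegression(
            covariates=assoc_cfg.get("covariates", ("sex", "age", "bmi", "batch")),
            add_smoking=assoc_cfg.get("smoking_sensitivity", False),
            fdr=assoc_cfg.get("fdr", 0.05),
        )
        model.fit(scores, phenotypes["madrs"], phenotypes)
        model.results_.to_csv(out / "association.tsv", sep="\t")
        manifest["stages"]["association"] = {
            "significant_modules": list(map(str, model.significant_modules_)),
            "covariates": model.results_.attrs.get("covariates", []),
        }
        if hasattr(model, "smoking_results_"):
            model.smoking_results_.to_csv(out / "association_smoking.tsv", sep="\t")
            choice = model.smoking_bic_choice_
            manifest["stages"]["association"]["smoking_bic"] = {
                "without": choice.bic[0],
                "with": choice.bic[1],
                "chosen": "with_smoking" if choice.chosen == 1 else "base",
            }
        subset_col = assoc_cfg.get("subset_column")
        if subset_col and subset_col in phenotypes.columns:
            mask = (phenotypes[subset_col] == assoc_cfg.get("subset_value")).to_numpy()
            if mask.sum() > scores.shape[1] + 6:
                cov = build_covariates(
                    phenotypes, model.covariates
                )
                subset = subset_sensitivity(
                    scores, scale_trait(phenotypes["madrs"]), cov, mask
                )
                subset.to_csv(out / "association_subset.tsv", sep="\t")
                manifest["stages"]["association"]["subset_n"] = int(mask.sum())

        stage = "centrality"
        per_gene, per_module = centrality_report(
            detector.adjacency_,
            detector.gene_ids_,
            expr,
            phenotypes["diagnosis"],
            labels,
            top_k=int(dict(cfg.get("centrality", {})).get("top_k", 100)),
        )
        per_gene.to_csv(out / "centrality_genes.tsv", sep="\t")
        per_module.to_csv(out / "centrality_modules.tsv", sep="\t")
        manifest["stages"]["centrality"] = {
            "n_components_note": "largest connected component used",
        }

        stage = "replication"
        rep_cfg = cfg.get("replication")
        if rep_cfg is not None and "simulate" in cfg:
            sim_kwargs = dict(cfg["simulate"] or {})
            sim_kwargs.setdefault("seed", seed)
            rep_sim = SimulationConfig(**sim_kwargs).replace(
                n_samples=int(rep_cfg.get("n_samples", 300))
            )
            target_sets = {
                name: detector.gene_sets_[name]
                for name in map(str, manifest["stages"]["association"]["significant_modules"])
                if name in detector.gene_sets_
            } or detector.gene_sets_
            external = generate_replication_cohort(
                rep_sim, target_sets, float(rep_cfg.get("overlap_fraction", 0.8))
            )
            ext_pre = RNASeqPreprocessor(**_coerce_pre(cfg.get("preprocess", {})))
            ext_expr = ext_pre.fit_transform(external.counts, external.phenotypes)
            rep = replication_analysis(
                ext_expr,
                target_sets,
                external.phenotypes.loc[ext_expr.index],
            )
            rep.to_csv(out / "replication.tsv", sep="\t")
            manifest["stages"]["replication"] = {
                "n_external_samples": int(ext_expr.shape[0]),
                "modules_tested": list(rep.index.astype(str)),
            }

        # manifest arithmetic: in - low_count - high_cov = network input
        pre_stage = manifest["stages"]["preprocess"]
        assert (
            pre_stage["n_genes_in"]
            - pre_stage["n_low_count"]
            - pre_stage["n_high_cov"]
            == pre_stage["n_genes_out"]
        )
        write_json(manifest, out / "manifest.json")
        return manifest
    except PipelineError:
        raise
    except Exception as exc:  # noqa: BLE001 - re-raised with stage context
        manifest["failed_stage"] = stage
        manifest["error"] = "".join(traceback.format_exception_only(exc)).strip()
        write_json(manifest, out / "manifest.json")
        raise PipelineError(stage, exc, manifest) from exc


def _coerce_pre(block: Mapping[str, Any]) -> dict:
    block = dict(block)
    if "min_reads_range" in block:
        block["min_reads_range"] = tuple(block["min_reads_range"])
    return block


def write_default_config(path: str | Path, seed: int = 0) -> None:
    with open(path, "w") as handle:
        yaml.safe_dump(default_config(seed), handle, sort_keys=False)
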