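"""End-to-end orchestration: ingest, reduce, partition, scan, project.

``run_gea`` executes the full analysis from a configuration mapping (usually
loaded from YAML): ingest -> MAF filter -> kNN imputations -> correlation
pruning -> standardization -> neutral-structure PCs -> diversity/Fst
summaries -> variance partitioning -> GEA outlier scan -> adaptively
enriched refit -> adaptive index -> genomic offset per future scenario.
Every intermediate artifact is written to the output directory along with a
machine-readable manifest (parameters, seeds, versions).  ``run_simulate``
wraps the synthetic-data generator with the same config/logging conventions.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd

from . import __version__
from . import io as gio
from .datatypes import EnvTable, GenotypeMatrix, SiteTable
from .landscape import adaptive_index, fit_aerda, genomic_offset
from .ordination import fit_rda
from .outliers import classify_outliers, mahalanobis_scan, neutral_structure
from .partition import partition, subsample_categories
from .popgen import pairwise_fst, per_pop_diversity
from .preprocess import (
    knn_impute_env,
    knn_impute_genotypes,
    maf_filter,
    prune_correlated,
    standardize,
    standardize_like,
)
from .simulate import EnvVarSpec, ScenarioBundle, SimConfig, make_scenario

log = logging.getLogger(__name__)

__all__ = ["run_gea", "run_simulate", "gea_scan", "DEFAULTS", "gea_from_bundle"]

DEFAULTS: dict[str, Any] = {
    "maf_threshold": 0.01,
    "impute_genotypes_k": 5,
    "impute_genotypes_m": 30,
    "impute_env_k": 10,
    "r_threshold": 0.7,
    "keep_list": [],
    "neutral_fdr": 0.40,
    "k_scan": 2,
    "n_pcs": 2,
    "k_axes": 2,
    "gea_alpha": 0.01,
    "threshold_type": "bonferroni",
    "condition_on_longitude": False,
    "n_perm": 99,
    "subsample_n_vars": 4,
    "subsample_n_iter": 100,
    "run_subsampling": False,
    "seed": 0,
}


def _merged(config: dict[str, Any]) -> dict[str, Any]:
    out = dict(DEFAULTS)
    out.update(config)
    return out


def _load_inputs(cfg: dict[str, Any]) -> tuple[GenotypeMatrix, SiteTable, EnvTable, list[EnvTable]]:
    site_table = gio.read_site_table(cfg["sites"])
    site_of = gio.read_individual_map(cfg["individuals"])
    geno_path = str(cfg["genotypes"])
    if geno_path.endswith((".vcf", ".vcf.gz")):
        G = gio.read_vcf(geno_path, site_of=site_of)
    else:
        G = gio.read_dosage_tsv(geno_path)
        G = GenotypeMatrix(G.dosages, G.locus_ids, G.individual_ids, site_of)
    site_table.validate_against(G)
    env = gio.read_env_table(cfg["env"], cfg["env_meta"], scenario_tag="current")
    futures = []
    for entry in cfg.get("future_env", []):
        futures.append(
            gio.read_env_table(entry["path"], cfg["env_meta"], scenario_tag=entry.get("tag", "future"))
        )
    return G, site_table, env, futures


def run_gea(config: dict[str, Any], out_dir: str | Path) -> dict[str, Any]:
    """Run the full genotype-environment analysis; returns a results dict.

    ``config`` names the input files (``genotypes``, ``individuals``,
    ``sites``, ``env``, ``env_meta``, optional ``future_env`` list of
    ``{path, tag}``) and may override any threshold in ``DEFAULTS``.
    Partial outputs are retained if a stage fails; the failing stage is
    named in the raised error.
    """
    cfg = _merged(config)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    results: dict[str, Any] = {}
    stage = "ingest"
    try:
        G, site_table, env_raw, futures = _load_inputs(cfg)

        stage = "maf_filter"
        G = maf_filter(G, cfg["maf_threshold"])

        stage = "impute_genotypes"
        G = knn_impute_genotypes(G, k=cfg["impute_genotypes_k"], m_ld_loci=cfg["impute_genotypes_m"])

        stage = "impute_env"
        env = knn_impute_env(env_raw, k=cfg["impute_env_k"])

        stage = "prune_correlated"
        env, dropped = prune_correlated(env, cfg["r_threshold"], cfg["keep_list"])
        dropped.to_csv(out / "dropped_variables.csv", index=False)

        stage = "standardize"
        env = standardize(env)

        stage = "neutral_structure"
        neutral_mask, pc_scores, neutral_report = neutral_structure(
            G.dosages, G.locus_ids, fdr=cfg["neutral_fdr"],
            k_scan=cfg["k_scan"], n_pcs=cfg["n_pcs"],
        )
        neutral_report.to_csv(out / "neutral_scan.csv")

        stage = "popgen_stats"
        waterway = site_table.waterway_of()
        diversity = per_pop_diversity(G, waterway)
        fst = pairwise_fst(G, waterway)
        diversity.to_csv(out / "diversity.csv")
        fst.to_csv(out / "fst.csv")

        stage = "variance_partitioning"
        Y = G.dosages - G.dosages.mean(axis=0)
        X_env = env.per_individual(G)
        predictors = X_env.copy()
        categories = {cat: list(cols) for cat, cols in env.categories().items()}
        for a in range(cfg["n_pcs"]):
            predictors[f"PC{a + 1}"] = pc_scores[:, a]
        categories["neutral_structure"] = [f"PC{a + 1}" for a in range(cfg["n_pcs"])]
        lon = site_table.table.set_index("site_id")["longitude"]
        predictors["longitude"] = lon.loc[G.sites].to_numpy()
        categories["geography"] = ["longitude"]
        part = partition(Y, predictors, categories, seed=cfg["seed"], n_perm=cfg["n_perm"])
        part.to_csv(out / "partition.csv")
        results["partition"] = part
        if cfg["run_subsampling"]:
            sub = subsample_categories(
                Y, predictors, categories,
                n_vars=cfg["subsample_n_vars"], n_iter=cfg["subsample_n_iter"],
                seed=cfg["seed"],
            )
            sub.to_csv(out / "subsampled_adj_r2.csv", index=False)
            results["subsampling"] = sub

        stage = "gea_scan"
        cond_cols = [f"PC{a + 1}" for a in range(cfg["n_pcs"])]
        if cfg["condition_on_longitude"]:
            cond_cols.append("longitude")
        Z = predictors[cond_cols]
        gea_fit = fit_rda(Y, X_env, Z, locus_ids=G.locus_ids)
        gea_fit.to_dir(out / "rda")
        report = mahalanobis_scan(
            gea_fit.locus_loadings[:, : cfg["k_axes"]], locus_ids=G.locus_ids
        )
        report = classify_outliers(report, cfg["gea_alpha"], cfg["threshold_type"])
        report.to_csv(out / "outliers.csv")
        report.manhattan_frame().to_csv(out / "manhattan.csv", index=False)
        results["gea_fit"] = gea_fit
        results["outliers"] = report

        stage = "aerda"
        ae_fit = fit_aerda(Y, report.flags, X_env, Z, locus_ids=G.locus_ids)
        ae_fit.to_dir(out / "aerda")
        results["aerda_fit"] = ae_fit

        stage = "adaptive_index"
        axes = tuple(range(1, cfg["k_axes"] + 1))
        ai = adaptive_index(ae_fit, env, axes=axes)
        ai.to_csv(out / "adaptive_index.csv")
        results["adaptive_index"] = ai

        stage = "genomic_offset"
        if futures:
            for fut in futures:
                fut_model = knn_impute_env(fut, k=cfg["impute_env_k"]).select(env.variables)
                fut_std = standardize_like(fut_model, env)
                grid = genomic_offset(ae_fit, env, fut_std, axes=axes)
                grid.to_csv(out / f"offset_{fut.scenario_tag}.csv")
                results[f"offset_{fut.scenario_tag}"] = grid
        else:
            log.info("no future scenarios configured; offset stage skipped")

        stage = "manifest"
        manifest = {
            "adaptscape_version": __version__,
            "numpy_version": np.__version__,
            "pandas_version": pd.__version__,
            "parameters": {k: v for k, v in cfg.items() if not isinstance(v, (pd.DataFrame,))},
            "n_individuals": G.n_individuals,
            "n_loci": G.n_loci,
            "n_outliers": int(report.flags.sum()),
            "inflation_factor": report.inflation_factor,
        }
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    except Exception as exc:
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc
    results["diversity"] = diversity
    results["fst"] = fst
    results["neutral_mask"] = neutral_mask
    return results


def gea_scan(
    G: GenotypeMatrix,
    env_raw: EnvTable,
    keep_list: list[str] | tuple[str, ...] = (),
    k_axes: int = 2,
    alpha: float = 0.01,
    threshold_type: str = "bonferroni",
    n_pcs: int = 2,
    neutral_fdr: float = 0.40,
    maf_threshold: float = 0.01,
) -> dict[str, Any]:
    """In-memory GEA core: reduce, condition on neutral PCs, scan for outliers.

    A programmatic shortcut through the pipeline's central stages (no files
    written): MAF filter, genotype/environment kNN imputation, correlation
    pruning, standardization, neutral-structure PCs, partial RDA conditioned
    on those PCs, Mahalanobis scan and outlier classification.  Returns the
    intermediate objects keyed by stage.
    """
    G = maf_filter(G, maf_threshold)
    G = knn_impute_genotypes(G)
    env = knn_impute_env(env_raw)
    env, dropped = prune_correlated(env, keep_list=list(keep_list))
    env = standardize(env)
    _, pcs, _ = neutral_structure(G.dosages, G.locus_ids, fdr=neutral_fdr, n_pcs=n_pcs)
    Y = G.dosages - G.dosages.mean(axis=0)
    X = env.per_individual(G)
    Z = pd.DataFrame({f"PC{a + 1}": pcs[:, a] for a in range(n_pcs)}, index=X.index)
    fit = fit_rda(Y, X, Z, locus_ids=G.locus_ids)
    report = mahalanobis_scan(fit.locus_loadings[:, :k_axes], locus_ids=G.locus_ids)
    report = classify_outliers(report, alpha, threshold_type)
    return {
        "genotypes": G, "env": env, "dropped": dropped, "pc_scores": pcs,
        "Y": Y, "X": X, "Z": Z, "fit": fit, "report": report,
    }


def _sim_config_from_dict(config: dict[str, Any]) -> SimConfig:
    cfg = dict(config)
    env_spec = cfg.pop("env", None)
    fields = {f.name for f in dataclasses.fields(SimConfig)}
    unknown = [k for k in cfg if k not in fields]
    if unknown:
        raise ValueError(f"unknown simulation config keys: {unknown}")
    if env_spec is not None:
        cfg["env"] = [EnvVarSpec(**spec) for spec in env_spec]
    return SimConfig(**cfg)


def run_simulate(
    config: dict[str, Any], out_dir: str | Path, genotype_format: str = "tsv"
):
    """Generate a synthetic scenario directory from a config mapping."""
    sim_cfg = _sim_config_from_dict(config)
    bundle = make_scenario(sim_cfg, out_dir=out_dir, genotype_format=genotype_format)
    log.info("wrote scenario (%d individuals x %d loci) to %s",
             bundle.genotypes.n_individuals, bundle.genotypes.n_loci, out_dir)
    return bundle


def gea_from_bundle(bundle: ScenarioBundle, out_dir: str | Path, **overrides) -> dict[str, Any]:
    """Convenience: run the GEA pipeline directly on an in-memory scenario."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    make_dir = out / "inputs"
    make_scenario(bundle.config, out_dir=make_dir)  # deterministic re-write
    config = {
        "genotypes": str(make_dir / "genotypes.tsv"),
        "individuals": str(make_dir / "individuals.csv"),
        "sites": str(make_dir / "sites.csv"),
        "env": str(make_dir / "env_current.csv"),
        "env_meta": str(make_dir / "env_meta.csv"),
        "future_env": [{"path": str(make_dir / "env_future.csv"), "tag": bundle.config.future_tag}],
        "seed": bundle.config.seed,
    }
    config.update(overrides)
    return run_gea(config, out)
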