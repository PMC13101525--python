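"""Pipeline orchestration: run every analysis stage from one config.

A :class:`PipelineConfig` either points at input files (abundance table,
optional function table, metadata, optional tree) or carries synthetic-
generator parameters; exactly one of the two. Stages run in dependency
order, each stage derives its own seed deterministically from the global
seed and the stage name (inserting a stage never perturbs another stage's
randomness), and results are collected into a JSON-serializable report plus
per-stage TSVs.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy.stats import wilcoxon

from . import diversity as div
from . import multivariate as mv
from . import ncm as ncm_mod
from . import network as net_mod
from . import partition as part_mod
from . import synthetic as syn
from .io import (
    AbundanceTable,
    read_abundance_table,
    read_metadata,
    read_newick,
    to_relative,
    write_abundance_table,
    write_edge_list,
    write_json,
)

logger = logging.getLogger(__name__)

ALL_STAGES = (
    "diversity", "ordination", "compare", "decoupling",
    "network", "ncm", "partition",
)


@dataclass
class PipelineConfig:
    """Everything a run needs; exactly one of input paths / synthetic."""

    # inputs
    abundance_path: str | None = None
    function_path: str | None = None
    metadata_path: str | None = None
    tree_path: str | None = None
    synthetic: dict | None = None
    # analysis options
    stages: tuple[str, ...] = ALL_STAGES
    group_column: str = "group"
    normalization: str = "relative"          # relative | none
    distance_metrics: tuple[str, ...] = ("bray_curtis", "jaccard")
    n_permutations: int = 9999
    network_r_threshold: float = 0.75
    network_p_threshold: float = 0.01
    network_min_prevalence: float = 0.0
    network_per_group: bool = True
    high_weight_threshold: float = 0.9
    robustness_fraction: float = 0.5
    robustness_reps: int = 100
    ncm_N: float | None = None
    ncm_d: float | None = None
    ncm_n_boot: int = 1000
    ncm_per_group: bool = False              # pooled fit by default
    partition_min_samples: int = 1
    seed: int = 0
    outdir: str | None = None

    def __post_init__(self) -> None:
        has_paths = self.abundance_path is not None
        has_syn = self.synthetic is not None
        if has_paths == has_syn:
            raise ValueError(
                "config must provide exactly one of abundance_path / synthetic"
            )
        unknown = set(self.stages) - set(ALL_STAGES)
        if unknown:
            raise ValueError(f"unknown stages: {sorted(unknown)}")
        if "decoupling" in self.stages and not (has_syn or self.function_path):
            raise ValueError(
                "decoupling stage enabled but no function table available"
            )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        if "stages" in raw:
            raw["stages"] = tuple(raw["stages"])
        if "distance_metrics" in raw:
            raw["distance_metrics"] = tuple(raw["distance_metrics"])
        return cls(**raw)


def stage_seed(global_seed: int, stage: str) -> int:
    """Deterministic per-stage seed: global seed XOR stage-name hash."""
    h = int.from_bytes(hashlib.sha256(stage.encode()).digest()[:4], "big")
    return (int(global_seed) ^ h) % (2**31 - 1)


def decoupling_analysis(
    taxon_table: AbundanceTable,
    function_table: AbundanceTable,
    groups,
    n_perm: int = 9999,
    seed: int | None = 0,
) -> dict:
    """Contrast taxonomic vs functional community structure.

    Computes Bray-Curtis matrices on both tables, compares the matched
    off-diagonal distance distributions by Wilcoxon signed rank, runs a
    Mantel test between the matrices, and ANOSIM/PERMANOVA on both.
    """
    if taxon_table.sample_ids != function_table.sample_ids:
        raise ValueError("taxon and function tables have mismatched samples")
    bc_taxa = div.beta_diversity(to_relative(taxon_table), "bray_curtis")
    bc_func = div.beta_diversity(to_relative(function_table), "bray_curtis")
    n = len(bc_taxa.ids)
    iu = np.triu_indices(n, k=1)
    dt = np.asarray(bc_taxa.data)[iu]
    df_ = np.asarray(bc_func.data)[iu]
    if np.allclose(dt, df_):
        wilcoxon_p = 1.0
    else:
        wilcoxon_p = float(wilcoxon(dt, df_).pvalue)
    out = {
        "median_bc_taxa": float(np.median(dt)),
        "median_bc_function": float(np.median(df_)),
        "mean_bc_taxa": float(np.mean(dt)),
        "mean_bc_function": float(np.mean(df_)),
        "wilcoxon_p": wilcoxon_p,
        "mantel": mv.mantel(bc_taxa, bc_func, "spearman", n_perm, seed).to_dict(),
        "anosim_taxa": mv.anosim(bc_taxa, groups, n_perm, seed).to_dict(),
        "anosim_function": mv.anosim(bc_func, groups, n_perm, seed).to_dict(),
        "permanova_taxa": mv.permanova(bc_taxa, groups, n_perm, seed).to_dict(),
        "permanova_function": mv.permanova(bc_func, groups, n_perm, seed).to_dict(),
    }
    return out


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the configured stages and return the analysis report.

    When ``config.outdir`` is set, the report (JSON) and per-stage TSVs are
    written there. Any stage failure aborts the run with the stage named.
    """
    report: dict = {"config": _config_echo(config), "stages": {}}
    outdir = Path(config.outdir) if config.outdir else None
    if outdir:
        outdir.mkdir(parents=True, exist_ok=True)

    # --- inputs -----------------------------------------------------------
    if config.synthetic is not None:
        params = dict(config.synthetic)
        params.setdefault("seed", stage_seed(config.seed, "synthetic"))
        ds = syn.generate_redundant_strains(**params)
        table, func_table, metadata = ds.abundance, ds.function_table, ds.metadata
        report["stages"]["synthetic"] = {
            k: v for k, v in ds.truth.items() if k not in ("guild_map", "guild_weights")
        }
        if outdir:
            ds.write(outdir / "synthetic")
    else:
        table = read_abundance_table(config.abundance_path)
        func_table = (
            read_abundance_table(config.function_path)
            if config.function_path else None
        )
        metadata = read_metadata(config.metadata_path) if config.metadata_path else None
    tree = read_newick(config.tree_path) if config.tree_path else None
    groups = (
        metadata[config.group_column].to_dict() if metadata is not None else None
    )
    logger.info(
        "inputs: %d samples x %d taxa; normalization=%s",
        table.n_samples, table.n_taxa, config.normalization,
    )
    norm = to_relative(table) if config.normalization == "relative" else table

    def _run(stage, fn):
        try:
            return fn()
        except Exception as exc:
            raise RuntimeError(f"stage {stage!r} failed: {exc}") from exc

    # --- stages -----------------------------------------------------------
    if "diversity" in config.stages:
        def _diversity():
            alpha = div.alpha_diversity(norm, tree)
            if outdir:
                alpha.to_csv(outdir / "alpha_diversity.tsv", sep="\t")
            return {"alpha_mean": alpha.mean().to_dict()}
        report["stages"]["diversity"] = _run("diversity", _diversity)

    dms = {}
    if {"ordination", "compare"} & set(config.stages):
        for metric in config.distance_metrics:
            dms[metric] = div.beta_diversity(norm, metric)

    if "ordination" in config.stages:
        def _ordination():
            out = {}
            for metric, dm in dms.items():
                ord_ = div.pcoa(dm)
                out[metric] = {
                    "proportion_explained": ord_.proportion_explained[:3].tolist(),
                    "n_negative_eigenvalues": int(len(ord_.negative_eigenvalues)),
                }
                if outdir:
                    ord_.coordinates.to_csv(
                        outdir / f"pcoa_{metric}.tsv", sep="\t")
            return out
        report["stages"]["ordination"] = _run("ordination", _ordination)

    if "compare" in config.stages:
        def _compare():
            if groups is None:
                raise ValueError("group comparisons need sample metadata")
            sd = stage_seed(config.seed, "compare")
            out = {}
            for metric, dm in dms.items():
                out[metric] = {
                    "anosim": mv.anosim(dm, groups, config.n_permutations, sd).to_dict(),
                    "permanova": mv.permanova(dm, groups, config.n_permutations, sd).to_dict(),
                }
            return out
        report["stages"]["compare"] = _run("compare", _compare)

    if "decoupling" in config.stages:
        def _decoupling():
            if func_table is None or groups is None:
                raise ValueError("decoupling needs a function table and metadata")
            return decoupling_analysis(
                table, func_table, groups, config.n_permutations,
                stage_seed(config.seed, "decoupling"),
            )
        report["stages"]["decoupling"] = _run("decoupling", _decoupling)

    if "network" in config.stages:
        def _network():
            sd = stage_seed(config.seed, "network")
            subsets: dict[str, AbundanceTable] = {}
            if config.network_per_group and groups is not None:
                for g in sorted(set(groups.values())):
                    rows = [s for s in table.sample_ids if groups[s] == g]
                    subsets[g] = AbundanceTable(
                        table.data.loc[rows], taxonomy=table.taxonomy)
            else:
                subsets["all"] = table
            out = {}
            for name, sub in subsets.items():
                net = net_mod.correlation_network(
                    sub, config.network_r_threshold,
                    config.network_p_threshold, config.network_min_prevalence)
                metrics = (
                    net_mod.network_metrics(net) if net.n_nodes >= 2
                    else {"n_nodes": net.n_nodes, "n_edges": 0}
                )
                entry = dict(metrics)
                entry["positive_edge_fraction"] = net.positive_edge_fraction()
                if net.n_nodes >= 3 and net.n_edges > 0:
                    entry["robustness"] = net_mod.robustness(
                        net, config.robustness_fraction,
                        config.robustness_reps, sd)
                    vul = net_mod.vulnerability(net)
                    entry["global_efficiency"] = vul["global_efficiency"]
                    entry["vulnerability"] = vul["vulnerability"]
                hw, hw_counts = net_mod.high_weight_edges(
                    net, config.high_weight_threshold)
                entry["n_high_weight_edges"] = int(len(hw))
                if outdir:
                    write_edge_list(net, outdir / f"network_{name}_edges.tsv")
                    hw_counts.to_csv(
                        outdir / f"network_{name}_high_weight_family_pairs.tsv",
                        sep="\t", index=False)
                out[name] = entry
            return out
        report["stages"]["network"] = _run("network", _network)

    if "ncm" in config.stages:
        def _ncm():
            sd = stage_seed(config.seed, "ncm")
            fits = {}
            jobs = {"pooled": table}
            if config.ncm_per_group and groups is not None:
                for g in sorted(set(groups.values())):
                    rows = [s for s in table.sample_ids if groups[s] == g]
                    jobs[g] = AbundanceTable(table.data.loc[rows])
            for name, sub in jobs.items():
                fit = ncm_mod.bootstrap_ncm(
                    sub, config.ncm_n_boot, sd,
                    N=config.ncm_N, d=config.ncm_d)
                classified = ncm_mod.classify_partitions(fit)
                summary = fit.to_dict()
                summary["class_counts"] = (
                    classified["class"].value_counts().to_dict())
                fits[name] = summary
                if outdir:
                    classified.to_csv(outdir / f"ncm_{name}_per_taxon.tsv",
                                      sep="\t", index_label="taxon")
            return fits
        report["stages"]["ncm"] = _run("ncm", _ncm)

    if "partition" in config.stages:
        def _partition():
            if groups is None:
                raise ValueError("partitioning needs sample metadata")
            part = part_mod.partition_taxa(
                table, groups, config.partition_min_samples)
            if outdir:
                part.to_frame().to_csv(outdir / "taxon_partition.tsv",
                                       sep="\t", index=False)
                part_mod.intersection_frame(part.intersection_counts).to_csv(
                    outdir / "intersection_counts.tsv", sep="\t", index=False)
            return {
                "n_core": len(part.core),
                "n_accessory": len(part.accessory),
                "n_specific": {g: len(s) for g, s in part.specific.items()},
                "abundance_share": part.abundance_share,
            }
        report["stages"]["partition"] = _run("partition", _partition)

    if outdir:
        write_json(report, outdir / "report.json")
        write_abundance_table(table, outdir / "abundance_used.tsv")
    return report


def _config_echo(config: PipelineConfig) -> dict:
    echo = {k: v for k, v in vars(config).items()}
    echo["stages"] = list(config.stages)
    echo["distance_metrics"] = list(config.distance_metrics)
    return echo
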