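"""End-to-end survey and microcosm pipelines.

Each run executes: rarefaction -> prevalence filter -> diversity
(richness trends, NMDS, ANOSIM, distance decay) -> bipartite networks
(Spearman + RMT threshold + per-site metrics) -> NST -> moving-window
partitioning -> Procrustes congruence -> best-subset OLS -> Mantel and
variation partitioning, writing plain TSV/JSON artifacts plus a
manifest.  Every stochastic stage draws from a child seed derived from
the master seed and the stage name.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, asdict
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from trophograd import (congruence, diversity, gradient_partitioning,
                        synthetic_data, trend_models, trophic_networks)
from trophograd.assembly_stochasticity import NullModelConfig, nst
from trophograd.core_data import (
    AsvTable, harmonize, metadata_frame, prevalence_filter, rarefy,
    read_asv_table, read_metadata,
)

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Configuration for one pipeline run (survey or microcosm)."""

    bacteria_path: str | None = None
    protist_path: str | None = None
    virus_path: str | None = None
    metadata_path: str | None = None
    simulation: synthetic_data.SimulationConfig | None = None
    gradient_variable: str = "latitude"        # latitude | temperature | SWC
    split_point: float = 32.0
    prevalence_threshold: float = 0.3
    rarefaction_depth: int | str = "min"
    rmt_min_eigenvalues: int = 50
    rmt_alpha: float = 0.05
    n_null: int = 100
    window_size: int | None = None
    n_perm: int = 999
    n_perm_protest: int = 1000
    positive_only: bool = False
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "simulation" in raw and raw["simulation"] is not None:
            sim = raw["simulation"]
            if "richness_shapes" in sim:
                sim["richness_shapes"] = {
                    k: synthetic_data.RichnessShape(**v)
                    for k, v in sim["richness_shapes"].items()}
            if "covariate_model" in sim:
                sim["covariate_model"] = synthetic_data.CovariateModel(
                    **sim["covariate_model"])
            raw["simulation"] = synthetic_data.SimulationConfig(**sim)
        return cls(**raw)

    def child_seed(self, stage: str) -> int:
        digest = int.from_bytes(stage.encode(), "big") % (2**31)
        return int(np.random.SeedSequence([self.seed, digest])
                   .generate_state(1)[0] % (2**31))


def _load_inputs(config: PipelineConfig):
    if config.simulation is not None:
        sim = config.simulation
        metadata, tables, registries = synthetic_data.simulate_survey(sim)
        return metadata, tables
    tables = {}
    for kingdom, path in (("bacteria", config.bacteria_path),
                          ("protist", config.protist_path),
                          ("virus", config.virus_path)):
        if path is not None:
            tables[kingdom] = read_asv_table(path, kingdom)
    if "bacteria" not in tables:
        raise ValueError("a bacteria table is required")
    if config.metadata_path is None:
        raise ValueError("metadata is required")
    metadata = read_metadata(config.metadata_path)
    return metadata, tables


def _json_default(o: Any):
    if isinstance(o, (np.floating, np.integer)):
        return o.item()
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(type(o).__name__)


def _write_json(obj: Any, path: Path) -> None:
    path.write_text(json.dumps(obj, indent=2, default=_json_default) + "\n")


def run_survey(config: PipelineConfig, outdir: str | Path) -> dict[str, Any]:
    """Run the full survey analysis; returns a result bundle and writes
    all stage artifacts under ``outdir``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, Any] = {"stages": [], "config": _config_summary(config)}
    bundle: dict[str, Any] = {}

    metadata, tables = _load_inputs(config)

    # --- rarefaction & harmonization -----------------------------------
    rare: dict[str, AsvTable] = {}
    for kingdom, table in tables.items():
        rare[kingdom] = rarefy(table, config.rarefaction_depth,
                               seed=config.child_seed(f"rarefy:{kingdom}"))
    table_list, metadata = harmonize(list(rare.values()), metadata)
    rare = {t.kingdom: t for t in table_list}
    meta_df = metadata_frame(metadata)
    gradient = _gradient_values(meta_df, config.gradient_variable)
    groups_split = np.where(gradient < config.split_point, "low", "high")
    manifest["stages"].append("rarefy")

    # --- diversity ------------------------------------------------------
    richness_trends = {}
    ordinations = {}
    for kingdom, table in rare.items():
        fit = trend_models.fit_gradient_trend(table.richness(), gradient)
        richness_trends[kingdom] = _trend_summary(fit)
        d_bc = diversity.community_distance(table, "bray_curtis", "hellinger")
        ordinations[kingdom] = diversity.nmds(
            d_bc, k=2, seed=config.child_seed(f"nmds:{kingdom}"))
        ordinations[kingdom].frame().to_csv(
            outdir / f"nmds_{kingdom}.tsv", sep="\t", index_label="site_id")
        if kingdom == "bacteria":
            bundle["bacteria_bray_curtis"] = d_bc
    _write_json(richness_trends, outdir / "richness_trends.json")

    anosim_res = {}
    if len(np.unique(groups_split)) == 2 and min(
            np.bincount((groups_split == "low").astype(int))) >= 2:
        for kingdom, table in rare.items():
            d_bc = diversity.community_distance(table, "bray_curtis", "hellinger")
            anosim_res[kingdom] = diversity.anosim(
                d_bc, groups_split, n_perm=config.n_perm,
                seed=config.child_seed(f"anosim:{kingdom}"))
    _write_json(anosim_res, outdir / "anosim.json")

    ddr = None
    if config.gradient_variable == "latitude":
        geo = diversity.geographic_distance(metadata)
        ddr = diversity.distance_decay(
            bundle["bacteria_bray_curtis"], geo, groups=groups_split)
        _write_json(ddr, outdir / "distance_decay.json")
    manifest["stages"].append("diversity")

    # --- networks -------------------------------------------------------
    site_metrics = []
    networks = {}
    for kingdom, label in (("protist", "PB"), ("virus", "VB")):
        if kingdom not in rare:
            logger.warning("no %s table; skipping %s network stages",
                           kingdom, label)
            continue
        try:
            prey_f = prevalence_filter(rare["bacteria"], config.prevalence_threshold)
            pred_f = prevalence_filter(rare[kingdom], config.prevalence_threshold)
            block = trophic_networks.spearman_block(prey_f, pred_f)
            scan = trophic_networks.rmt_threshold(
                block, alpha=config.rmt_alpha,
                min_eigenvalues=config.rmt_min_eigenvalues)
            meta_net = trophic_networks.build_meta_network(
                block, scan.chosen_threshold, config.positive_only)
            per_site = trophic_networks.site_subnetworks(
                meta_net, prey_f, pred_f, pair_label=label)
        except (RuntimeError, ValueError) as err:
            logger.warning("%s network stage failed: %s", label, err)
            continue
        networks[label] = {"threshold": scan.chosen_threshold,
                           "E": meta_net.edge_count, "N": meta_net.node_count,
                           "C": meta_net.connectance}
        meta_net.edge_list().to_csv(outdir / f"network_{label}_edges.tsv",
                                    sep="\t", index=False)
        scan.table().to_csv(outdir / f"rmt_scan_{label}.tsv", sep="\t",
                            index=False)
        site_metrics.append(per_site)
    _write_json(networks, outdir / "meta_networks.json")
    if site_metrics:
        pd.concat(site_metrics, ignore_index=True).to_csv(
            outdir / "site_network_metrics.tsv", sep="\t", index=False)
    manifest["stages"].append("networks")

    # --- predictors -----------------------------------------------------
    X = _predictor_table(meta_df, site_metrics, rare["bacteria"].sample_ids)
    groups = {name: [c for c in cols if c in X.columns]
              for name, cols in gradient_partitioning.DEFAULT_GROUPS.items()}
    groups = {k: v for k, v in groups.items() if v}

    # --- NST + moving window -------------------------------------------
    presence = rare["bacteria"].presence()
    null_cfg = NullModelConfig(n_null=config.n_null,
                               seed=config.child_seed("nst"))
    nst_all = nst(presence, null_cfg)
    _write_json({"ST": nst_all.ST, "NST": nst_all.NST,
                 "determinism": nst_all.determinism,
                 "n_null": config.n_null}, outdir / "nst.json")

    d_bac = bundle["bacteria_bray_curtis"]
    windows = None
    n_pred = sum(len(v) for v in groups.values())
    w = config.window_size or int((gradient < config.split_point).sum())
    if w >= n_pred + 5 and w <= len(gradient):
        windows = gradient_partitioning.moving_window(
            d_bac, X, groups, gradient, presence=presence, window_size=w,
            null_config=null_cfg, split_point=config.split_point)
        gradient_partitioning.window_table(windows).to_csv(
            outdir / "moving_window.tsv", sep="\t", index=False)
    else:
        logger.warning("window size %d not viable; skipping moving window", w)
    manifest["stages"].append("nst+moving_window")

    # --- Procrustes -----------------------------------------------------
    procrustes_out = {}
    for kingdom, label in (("protist", "PB"), ("virus", "VB")):
        if kingdom not in ordinations:
            continue
        res = congruence.protest(
            ordinations["bacteria"].coordinates,
            ordinations[kingdom].coordinates,
            n_perm=config.n_perm_protest,
            seed=config.child_seed(f"protest:{label}"))
        trend = congruence.residual_gradient(res, gradient)
        procrustes_out[label] = {
            "m2": res.m2, "R2": res.R2, "p": res.p, "n_perm": res.n_perm,
            "residual_trend": _trend_summary(trend)}
        pd.DataFrame({"site_id": rare["bacteria"].sample_ids,
                      "residual": res.residuals}).to_csv(
            outdir / f"procrustes_residuals_{label}.tsv", sep="\t", index=False)
    _write_json(procrustes_out, outdir / "procrustes.json")
    manifest["stages"].append("procrustes")

    # --- OLS, Mantel, VPA ----------------------------------------------
    ols_fit = None
    if X.shape[1] and len(X) > X.shape[1] + 2:
        X_pruned, removed = gradient_partitioning.vif_prune(X)
        ols_fit = trend_models.ols_best_subset(
            rare["bacteria"].richness(), X_pruned, response="bacteria_richness")
        _write_json({"terms": ols_fit.terms, "beta": ols_fit.beta.to_dict(),
                     "R2": ols_fit.R2, "AIC": ols_fit.AIC,
                     "pvalues": ols_fit.pvalues.to_dict(),
                     "vif_removed": removed}, outdir / "ols_richness.json")

    mantel_out = {}
    for kingdom, label in (("protist", "PB"), ("virus", "VB")):
        if kingdom not in rare:
            continue
        d_pred = diversity.community_distance(rare[kingdom], "bray_curtis",
                                              "hellinger")
        mantel_out[label] = diversity.mantel(
            d_bac, d_pred, n_perm=config.n_perm,
            seed=config.child_seed(f"mantel:{label}"))
    _write_json(mantel_out, outdir / "mantel.json")

    vpa = None
    biotic_cols = [c for c in X.columns if c.startswith(("PB_", "VB_"))]
    vpa_groups = {"climatic": groups.get("climatic", []),
                  "edaphic": groups.get("edaphic", []),
                  "biotic": biotic_cols}
    if all(vpa_groups.values()):
        vpa = gradient_partitioning.variation_partition(d_bac, X, vpa_groups)
        _write_json(vpa, outdir / "variation_partition.json")
    manifest["stages"].append("ols+mantel+vpa")

    _write_json(manifest, outdir / "manifest.json")
    bundle.update({
        "metadata": metadata, "tables": rare, "gradient": gradient,
        "richness_trends": richness_trends, "anosim": anosim_res, "ddr": ddr,
        "networks": networks, "site_metrics": site_metrics, "nst": nst_all,
        "windows": windows, "procrustes": procrustes_out, "ols": ols_fit,
        "mantel": mantel_out, "vpa": vpa, "manifest": manifest,
    })
    return bundle


def run_microcosm(config: PipelineConfig, outdir: str | Path,
                  arm: str = "temperature") -> dict[str, Any]:
    """Microcosm arm: the gradient covariate is temperature or SWC; with
    five or fewer levels the moving window is replaced by per-level
    summaries and trend fits against the gradient."""
    if config.gradient_variable not in ("temperature", "SWC"):
        raise ValueError("microcosm gradient must be temperature or SWC")
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    sim = config.simulation or synthetic_data.SimulationConfig(seed=config.seed)
    design, tables, registries = synthetic_data.simulate_microcosm(sim, arm=arm)
    gradient_col = "temperature" if arm == "temperature" else "SWC"
    gradient = design[gradient_col].to_numpy(dtype=float)
    levels = np.unique(gradient)
    if len(levels) < 3:
        raise ValueError("need at least 3 gradient levels")

    rare = {k: rarefy(t, "min", seed=config.child_seed(f"rarefy:{k}"))
            for k, t in tables.items()}
    table_list, _ = harmonize(list(rare.values()),
                              [synthetic_data.SiteMetadata(u, 0.0, 0.0)
                               for u in design["unit_id"]])
    rare = {t.kingdom: t for t in table_list}
    keep = [design["unit_id"].tolist().index(s)
            for s in rare["bacteria"].sample_ids]
    gradient = gradient[keep]
    design = design.iloc[keep].reset_index(drop=True)
    design.to_csv(outdir / "design.tsv", sep="\t", index=False)

    out: dict[str, Any] = {"design": design, "n_units": len(design)}
    results = {}
    for kingdom, label in (("protist", "PB"), ("virus", "VB")):
        if kingdom not in rare:
            continue
        try:
            prey_f = prevalence_filter(rare["bacteria"], config.prevalence_threshold)
            pred_f = prevalence_filter(rare[kingdom], config.prevalence_threshold)
            block = trophic_networks.spearman_block(prey_f, pred_f)
            scan = trophic_networks.rmt_threshold(
                block, alpha=config.rmt_alpha,
                min_eigenvalues=config.rmt_min_eigenvalues)
            meta_net = trophic_networks.build_meta_network(
                block, scan.chosen_threshold, config.positive_only)
            per_site = trophic_networks.site_subnetworks(
                meta_net, prey_f, pred_f, pair_label=label)
        except (RuntimeError, ValueError) as err:
            logger.warning("%s microcosm network failed: %s", label, err)
            continue
        trends = {}
        for metric in ("E", "C"):
            y = per_site[metric].to_numpy(dtype=float)
            if np.ptp(y) > 0:
                trends[metric] = _trend_summary(
                    trend_models.fit_gradient_trend(y, gradient))
        level_summary = per_site.assign(level=gradient).groupby("level")[
            ["E", "N", "C"]].mean().reset_index()
        level_summary.to_csv(outdir / f"levels_{label}.tsv", sep="\t",
                             index=False)
        results[label] = {"threshold": scan.chosen_threshold,
                          "metric_trends": trends}

        ord_b = diversity.nmds(
            diversity.community_distance(rare["bacteria"], "bray_curtis",
                                         "hellinger"),
            seed=config.child_seed("nmds:bacteria"))
        ord_p = diversity.nmds(
            diversity.community_distance(rare[kingdom], "bray_curtis",
                                         "hellinger"),
            seed=config.child_seed(f"nmds:{kingdom}"))
        res = congruence.protest(ord_b.coordinates, ord_p.coordinates,
                                 n_perm=config.n_perm_protest,
                                 seed=config.child_seed(f"protest:{label}"))
        results[label]["procrustes"] = {
            "m2": res.m2, "R2": res.R2, "p": res.p,
            "residual_trend": _trend_summary(
                congruence.residual_gradient(res, gradient))}
    _write_json(results, outdir / "microcosm_results.json")
    out["results"] = results
    return out


# ---------------------------------------------------------------------------
# helpers
# ---------------------------------------------------------------------------

def _gradient_values(meta_df: pd.DataFrame, variable: str) -> np.ndarray:
    if variable == "latitude":
        return meta_df["latitude"].to_numpy(dtype=float)
    if variable == "temperature":
        return meta_df["MAT"].to_numpy(dtype=float)
    if variable in meta_df.columns:
        return meta_df[variable].to_numpy(dtype=float)
    raise ValueError(f"unknown gradient variable {variable!r}")


def _predictor_table(meta_df: pd.DataFrame, site_metrics: list[pd.DataFrame],
                     sample_ids: list[str]) -> pd.DataFrame:
    X = pd.DataFrame(index=sample_ids)
    for col in ("MAT", "MAP", "MTCM", "PSCV", "pH", "SWC", "C_N"):
        if col in meta_df.columns:
            X[col] = meta_df.loc[sample_ids, col].to_numpy(dtype=float)
    for per_site in site_metrics:
        label = per_site["pair"].iloc[0]
        indexed = per_site.set_index("site_id").loc[sample_ids]
        X[f"{label}_edges"] = indexed["E"].to_numpy(dtype=float)
        X[f"{label}_connectance"] = indexed["C"].to_numpy(dtype=float)
    # drop constant columns: they carry no variance to partition
    keep = [c for c in X.columns if np.ptp(X[c].to_numpy()) > 0]
    return X[keep]


def _trend_summary(fit) -> dict[str, Any]:
    return {"model": fit.model, "coefficients": list(fit.coefficients),
            "R2": fit.R2, "AIC": fit.AIC, "p": fit.p_overall,
            "significant": fit.significant, "vertex": fit.vertex}


def _config_summary(config: PipelineConfig) -> dict[str, Any]:
    out = asdict(config)
    if config.simulation is not None:
        out["simulation"] = asdict(config.simulation)
    return out
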