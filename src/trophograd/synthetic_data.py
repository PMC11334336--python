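"""Synthetic survey and microcosm datasets with planted ground truth.

Communities are generated from a latent model: each ASV has a log-normal
baseline abundance and a Gaussian niche on the gradient; per-site
occupancy probabilities are scaled so the expected richness follows a
configured shape (linear, quadratic or flat in the gradient), and counts
are drawn by multinomial sampling at a fixed sequencing depth.
Predator-prey links are planted on the latent (pre-multinomial) scale
through a Gaussian copula, so sampling noise attenuates but does not
erase them.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import pandas as pd
import yaml
from scipy import stats

from trophograd.core_data import (
    AsvTable, SiteMetadata, write_asv_table, write_metadata,
)

__all__ = [
    "CovariateModel", "RichnessShape", "SimulationConfig",
    "simulate_metadata", "simulate_communities", "plant_trophic_links",
    "simulate_survey", "microcosm_design", "simulate_microcosm",
    "write_dataset",
]


@dataclass
class CovariateModel:
    """Affine-in-gradient covariate generators: value = a + b*gradient + noise."""

    mat_intercept: float = 36.0
    mat_slope: float = -0.70          # degrees C per degree latitude
    mat_sd: float = 1.5
    map_intercept: float = 2600.0
    map_slope: float = -50.0
    map_sd: float = 150.0
    mtcm_intercept: float = 12.0
    mtcm_slope: float = -1.0
    mtcm_sd: float = 2.0
    pscv_intercept: float = 60.0
    pscv_slope: float = 0.6
    pscv_sd: float = 8.0
    swc_intercept: float = 5.0
    swc_map_slope: float = 0.01       # SWC tracks MAP (target r ~ 0.66)
    swc_sd: float = 4.9
    ph_intercept: float = 5.8
    ph_slope: float = 0.02
    ph_sd: float = 0.6
    cn_intercept: float = 9.5
    cn_slope: float = 0.05
    cn_sd: float = 1.5

    def scale_noise(self, factor: float) -> "CovariateModel":
        kw = asdict(self)
        for k in kw:
            if k.endswith("_sd"):
                kw[k] *= factor
        return CovariateModel(**kw)


@dataclass
class RichnessShape:
    """Expected-richness curve over the gradient.

    ``kind='linear'``: richness = level + slope * (g - g_min).
    ``kind='quadratic'``: richness = level - curvature * (g - peak)^2.
    ``kind='flat'``: richness = level + slope * (g - g_min) (small slope).
    """

    kind: Literal["linear", "quadratic", "flat"]
    level: float
    slope: float = 0.0
    peak: float = 32.0
    curvature: float = 0.0

    def expected(self, gradient: np.ndarray, g_min: float) -> np.ndarray:
        g = np.asarray(gradient, dtype=float)
        if self.kind == "quadratic":
            r = self.level - self.curvature * (g - self.peak) ** 2
        else:
            r = self.level + self.slope * (g - g_min)
        return np.clip(r, 2.0, None)


def _default_shapes() -> dict[str, RichnessShape]:
    return {
        "bacteria": RichnessShape("linear", level=180.0, slope=-3.2),
        "protist": RichnessShape("quadratic", level=90.0, peak=32.0, curvature=0.25),
        "virus": RichnessShape("flat", level=30.0, slope=0.5),
    }


def _default_pools() -> dict[str, int]:
    return {"bacteria": 300, "protist": 150, "virus": 80}


def _default_links() -> dict[str, int]:
    return {"protist": 15, "virus": 10}


@dataclass
class SimulationConfig:
    """Knobs for the survey and microcosm generators."""

    n_sites: int = 73
    latitude_range: tuple[float, float] = (19.27, 47.41)
    richness_shapes: dict[str, RichnessShape] = field(default_factory=_default_shapes)
    n_asv_pool: dict[str, int] = field(default_factory=_default_pools)
    n_true_links: dict[str, int] = field(default_factory=_default_links)
    link_strength: float = 0.9
    covariate_model: CovariateModel = field(default_factory=CovariateModel)
    depth: int = 10_000
    filter_strength: float = 1.0      # 0 = neutral occupancy, larger = stronger niches
    niche_width: float = 0.6          # Gaussian niche SD on the scaled gradient
    abundance_sigma: float = 1.2      # log-normal baseline spread
    abundance_noise: float = 0.4      # per-cell log-scale noise
    seed: int = 0
    # microcosm design
    temperature_levels: tuple[float, ...] = (5.0, 10.0, 15.0, 20.0, 25.0)
    moisture_levels: tuple[float, ...] = (10.0, 15.0, 20.0, 25.0)
    n_replicates: int = 8
    temperature_arm_swc: float = 13.7
    moisture_arm_temperature: float = 20.0

    def __post_init__(self) -> None:
        if self.n_sites <= 0 or self.depth < 0:
            raise ValueError("n_sites must be positive and depth non-negative")
        if not 0.0 <= self.link_strength <= 1.0:
            raise ValueError("link_strength must be in [0, 1]")
        for k, v in self.n_asv_pool.items():
            if v <= 0:
                raise ValueError(f"ASV pool for {k} must be positive")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimulationConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "richness_shapes" in raw:
            raw["richness_shapes"] = {
                k: RichnessShape(**v) for k, v in raw["richness_shapes"].items()}
        if "covariate_model" in raw:
            raw["covariate_model"] = CovariateModel(**raw["covariate_model"])
        for key in ("latitude_range", "temperature_levels", "moisture_levels"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)

    def child_rng(self, stage: str) -> np.random.Generator:
        """Deterministic per-stage generator derived from the master seed."""
        digest = int.from_bytes(stage.encode(), "big") % (2**31)
        return np.random.default_rng(np.random.SeedSequence([self.seed, digest]))


# ---------------------------------------------------------------------------
# Metadata
# ---------------------------------------------------------------------------

def simulate_metadata(config: SimulationConfig) -> list[SiteMetadata]:
    """Draw site coordinates and covariates tied to latitude.

    MAT decreases with latitude, MAP decreases with latitude, SWC tracks
    MAP, pH and C:N carry weak latitude signals; remaining edaphic
    variables are latitude-free log-normal draws.
    """
    rng = config.child_rng("metadata")
    cm = config.covariate_model
    lo, hi = config.latitude_range
    lat = np.sort(rng.uniform(lo, hi, config.n_sites))
    lon = 108.0 + 0.55 * (lat - lo) + rng.normal(0, 3.0, config.n_sites)
    elev = rng.uniform(5.0, 500.0, config.n_sites)

    mat = cm.mat_intercept + cm.mat_slope * lat + rng.normal(0, cm.mat_sd, config.n_sites)
    map_ = cm.map_intercept + cm.map_slope * lat + rng.normal(0, cm.map_sd, config.n_sites)
    map_ = np.clip(map_, 50.0, None)
    mtcm = cm.mtcm_intercept + cm.mtcm_slope * lat + rng.normal(0, cm.mtcm_sd, config.n_sites)
    pscv = cm.pscv_intercept + cm.pscv_slope * lat + rng.normal(0, cm.pscv_sd, config.n_sites)
    swc = cm.swc_intercept + cm.swc_map_slope * map_ + rng.normal(0, cm.swc_sd, config.n_sites)
    swc = np.clip(swc, 0.5, 100.0)
    ph = np.clip(cm.ph_intercept + cm.ph_slope * lat + rng.normal(0, cm.ph_sd, config.n_sites),
                 3.0, 9.5)
    cn = np.clip(cm.cn_intercept + cm.cn_slope * lat + rng.normal(0, cm.cn_sd, config.n_sites),
                 2.0, None)

    som = rng.lognormal(1.2, 0.4, config.n_sites)
    tn = rng.lognormal(0.3, 0.3, config.n_sites)
    tc = tn * cn * (1.0 + rng.normal(0, 0.02, config.n_sites))
    no3 = rng.lognormal(2.0, 0.5, config.n_sites)
    nh4 = rng.lognormal(2.2, 0.5, config.n_sites)
    ap = rng.lognormal(2.5, 0.4, config.n_sites)

    width = len(str(config.n_sites))
    records = []
    for i in range(config.n_sites):
        records.append(SiteMetadata(
            site_id=f"S{i + 1:0{width}d}",
            latitude=round(float(lat[i]), 6),
            longitude=round(float(lon[i]), 6),
            elevation=round(float(elev[i]), 2),
            climatic={"MAT": round(float(mat[i]), 4),
                      "MAP": round(float(map_[i]), 4),
                      "MTCM": round(float(mtcm[i]), 4),
                      "PSCV": round(float(pscv[i]), 4)},
            edaphic={"pH": round(float(ph[i]), 4),
                     "SWC": round(float(swc[i]), 4),
                     "SOM": round(float(som[i]), 4),
                     "TN": round(float(tn[i]), 4),
                     "TC": round(float(tc[i]), 4),
                     "NO3": round(float(no3[i]), 4),
                     "NH4": round(float(nh4[i]), 4),
                     "AP": round(float(ap[i]), 4),
                     "C_N": round(float(cn[i]), 4)},
        ))
    return records


# ---------------------------------------------------------------------------
# Communities
# ---------------------------------------------------------------------------

def _latent_community(gradient: np.ndarray, g_range: tuple[float, float],
                      shape: RichnessShape, pool: int,
                      config: SimulationConfig,
                      rng: np.random.Generator) -> np.ndarray:
    """Latent per-site, per-ASV expected abundance (zeros encode absence)."""
    lo, hi = g_range
    span = (hi - lo) or 1.0
    z = (np.asarray(gradient, dtype=float) - lo) / span  # scaled to [0, 1]

    optima = rng.uniform(-0.1, 1.1, pool)
    widths = config.niche_width * rng.uniform(0.6, 1.6, pool)
    baseline = rng.normal(0.0, config.abundance_sigma, pool)

    # occupancy: niche weights renormalized so the expected richness per
    # site matches the configured shape
    w = np.exp(-config.filter_strength
               * ((z[:, None] - optima[None, :]) / widths[None, :]) ** 2)
    r_target = shape.expected(gradient, lo)
    p = w * (r_target[:, None] / w.sum(axis=1)[:, None])
    p = np.clip(p, 0.0, 0.995)
    present = rng.random(p.shape) < p
    # no empty sites: force the best-matching ASV in
    empty = ~present.any(axis=1)
    if empty.any():
        present[empty, np.argmax(w[empty], axis=1)] = True

    noise = rng.normal(0.0, config.abundance_noise, p.shape)
    latent = present * np.exp(baseline[None, :] + np.sqrt(w) + noise)
    return latent


def _multinomial_counts(latent: np.ndarray, depth: int,
                        rng: np.random.Generator) -> np.ndarray:
    if depth <= 0:
        raise ValueError("sequencing depth must be positive")
    counts = np.empty(latent.shape, dtype=np.int64)
    probs = latent / latent.sum(axis=1, keepdims=True)
    for i in range(latent.shape[0]):
        counts[i] = rng.multinomial(depth, probs[i])
    return counts


def simulate_communities(metadata: Sequence[SiteMetadata],
                         config: SimulationConfig,
                         gradient: np.ndarray | None = None,
                         ) -> dict[str, AsvTable]:
    """Generate one count table per kingdom from the latent niche model.

    ``gradient`` defaults to site latitude; the microcosm arm passes
    temperature or soil water content instead.  Each returned table
    carries its latent matrix as a ``.latent`` attribute for link
    planting.
    """
    if not metadata:
        raise ValueError("metadata must be non-empty")
    if gradient is None:
        gradient = np.array([m.latitude for m in metadata], dtype=float)
    gradient = np.asarray(gradient, dtype=float)
    g_range = (float(gradient.min()), float(gradient.max()))
    sample_ids = [m.site_id for m in metadata]

    tables: dict[str, AsvTable] = {}
    for kingdom, shape in config.richness_shapes.items():
        pool = config.n_asv_pool[kingdom]
        rng = config.child_rng(f"community:{kingdom}")
        latent = _latent_community(gradient, g_range, shape, pool, config, rng)
        counts = _multinomial_counts(latent, config.depth, rng)
        prefix = {"bacteria": "B", "protist": "P", "virus": "V"}.get(kingdom, "X")
        asv_ids = [f"{prefix}{j + 1:04d}" for j in range(pool)]
        table = AsvTable(sample_ids, asv_ids, counts, kingdom)
        table.latent = latent  # type: ignore[attr-defined]
        tables[kingdom] = table
    return tables


# ---------------------------------------------------------------------------
# Trophic links
# ---------------------------------------------------------------------------

def _normal_scores(x: np.ndarray) -> np.ndarray:
    """Rank-based inverse-normal transform (average ranks for ties)."""
    n = len(x)
    ranks = stats.rankdata(x, method="average")
    return stats.norm.ppf(ranks / (n + 1.0))


def plant_trophic_links(prey_table: AsvTable, predator_table: AsvTable,
                        config: SimulationConfig,
                        n_links: int | None = None,
                        ) -> tuple[AsvTable, pd.DataFrame]:
    """Rewire selected predator ASVs to track selected prey ASVs.

    For each planted pair the predator's latent abundance profile is a
    Gaussian-copula mix of the prey's profile (weight ``link_strength``)
    and independent noise; counts are re-drawn by multinomial sampling.
    Returns the modified predator table and a registry of true pairs.
    """
    if prey_table.sample_ids != predator_table.sample_ids:
        raise ValueError("prey and predator tables must share sample ids")
    if n_links is None:
        n_links = config.n_true_links.get(predator_table.kingdom, 0)
    if n_links > min(prey_table.n_asvs, predator_table.n_asvs):
        raise ValueError("more links requested than available ASV pairs")

    rng = config.child_rng(f"links:{predator_table.kingdom}")
    prey_latent = np.asarray(
        getattr(prey_table, "latent", prey_table.counts), dtype=float)
    pred_latent = np.asarray(
        getattr(predator_table, "latent", predator_table.counts), dtype=float).copy()

    # prefer prevalent prey so the link is observable across sites
    prey_prev = (prey_table.counts > 0).mean(axis=0)
    eligible = np.flatnonzero(prey_prev >= np.quantile(prey_prev, 0.5))
    if len(eligible) < n_links:
        eligible = np.arange(prey_table.n_asvs)
    prey_idx = rng.choice(eligible, size=n_links, replace=False)
    pred_idx = rng.choice(predator_table.n_asvs, size=n_links, replace=False)

    rho = config.link_strength
    n = prey_table.n_samples
    sigma = np.log(10.0)  # planted predator profiles span ~2 orders of magnitude
    for pi, bi in zip(pred_idx, prey_idx):
        z_prey = _normal_scores(prey_latent[:, bi])
        if rho >= 1.0:
            z_pred = z_prey
        else:
            # mix with the predator's own (env-structured) profile so that
            # rho = 0 leaves planted pairs exchangeable with background
            z_own = _normal_scores(pred_latent[:, pi]
                                   + 1e-9 * rng.standard_normal(n))
            z_pred = rho * z_prey + np.sqrt(1.0 - rho**2) * z_own
        scale = np.median(pred_latent[:, pi][pred_latent[:, pi] > 0]) if \
            (pred_latent[:, pi] > 0).any() else 1.0
        pred_latent[:, pi] = scale * np.exp(sigma * z_pred)

    counts = _multinomial_counts(pred_latent, config.depth, rng)
    out = AsvTable(list(predator_table.sample_ids), list(predator_table.asv_ids),
                   counts, predator_table.kingdom)
    out.latent = pred_latent  # type: ignore[attr-defined]
    registry = pd.DataFrame({
        "predator_asv": [predator_table.asv_ids[i] for i in pred_idx],
        "prey_asv": [prey_table.asv_ids[i] for i in prey_idx],
    })
    return out, registry


# ---------------------------------------------------------------------------
# Full datasets
# ---------------------------------------------------------------------------

def simulate_survey(config: SimulationConfig,
                    ) -> tuple[list[SiteMetadata], dict[str, AsvTable],
                               dict[str, pd.DataFrame]]:
    """Metadata + three kingdom tables + planted-link registries."""
    metadata = simulate_metadata(config)
    tables = simulate_communities(metadata, config)
    registries: dict[str, pd.DataFrame] = {}
    for kingdom in ("protist", "virus"):
        if kingdom in tables and config.n_true_links.get(kingdom, 0) > 0:
            tables[kingdom], registries[kingdom] = plant_trophic_links(
                tables["bacteria"], tables[kingdom], config)
    return metadata, tables, registries


def microcosm_design(config: SimulationConfig) -> pd.DataFrame:
    """Two-arm incubation design: temperature levels and moisture levels,
    each with a fixed replicate count, as one row per experimental unit."""
    rows = []
    for t in config.temperature_levels:
        for r in range(1, config.n_replicates + 1):
            rows.append({"unit_id": f"T{t:04.1f}_r{r}", "arm": "temperature",
                         "temperature": t, "SWC": config.temperature_arm_swc,
                         "replicate": r})
    for w in config.moisture_levels:
        for r in range(1, config.n_replicates + 1):
            rows.append({"unit_id": f"W{w:04.1f}_r{r}", "arm": "moisture",
                         "temperature": config.moisture_arm_temperature,
                         "SWC": w, "replicate": r})
    return pd.DataFrame(rows)


def simulate_microcosm(config: SimulationConfig, arm: str = "temperature",
                       ) -> tuple[pd.DataFrame, dict[str, AsvTable],
                                  dict[str, pd.DataFrame]]:
    """Generate communities for one microcosm arm along its gradient."""
    design = microcosm_design(config)
    sub = design[design["arm"] == arm].reset_index(drop=True)
    if sub.empty:
        raise ValueError(f"unknown microcosm arm: {arm!r}")
    gradient_col = "temperature" if arm == "temperature" else "SWC"
    gradient = sub[gradient_col].to_numpy(dtype=float)
    metadata = [
        SiteMetadata(site_id=row.unit_id, latitude=0.0, longitude=0.0,
                     climatic={"MAT": float(row.temperature)},
                     edaphic={"SWC": float(row.SWC)})
        for row in sub.itertuples()
    ]
    tables = simulate_communities(metadata, config, gradient=gradient)
    registries: dict[str, pd.DataFrame] = {}
    for kingdom in ("protist", "virus"):
        if kingdom in tables and config.n_true_links.get(kingdom, 0) > 0:
            tables[kingdom], registries[kingdom] = plant_trophic_links(
                tables["bacteria"], tables[kingdom], config)
    return sub, tables, registries


def write_dataset(outdir: str | Path, metadata: Sequence[SiteMetadata],
                  tables: dict[str, AsvTable],
                  registries: dict[str, pd.DataFrame] | None = None) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_metadata(metadata, outdir / "metadata.tsv")
    for kingdom, table in tables.items():
        write_asv_table(table, outdir / f"asv_{kingdom}.tsv")
    if registries:
        frames = []
        for kingdom, reg in registries.items():
            reg = reg.copy()
            reg.insert(0, "predator_kingdom", kingdom)
            frames.append(reg)
        pd.concat(frames, ignore_index=True).to_csv(
            outdir / "true_links.tsv", sep="\t", index=False)
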