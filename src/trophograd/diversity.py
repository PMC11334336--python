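"""Alpha/beta diversity, ordination and distance-based permutation tests."""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from scipy.spatial.distance import pdist, squareform
from sklearn.manifold import smacof

from trophograd.core_data import AsvTable, DistanceMatrix, relative_abundance

EARTH_RADIUS_KM = 6371.0


@dataclass
class OrdinationResult:
    """Non-metric MDS configuration with Kruskal stress-1."""

    coordinates: np.ndarray
    stress: float
    converged: bool
    n_starts_used: int
    ids: list[str]

    def frame(self) -> pd.DataFrame:
        cols = [f"NMDS{i + 1}" for i in range(self.coordinates.shape[1])]
        return pd.DataFrame(self.coordinates, index=self.ids, columns=cols)


def hellinger(profiles: np.ndarray) -> np.ndarray:
    """Square root of row-normalized abundances; rows get unit sum of squares."""
    profiles = np.asarray(profiles, dtype=float)
    sums = profiles.sum(axis=1, keepdims=True)
    if (sums == 0).any():
        raise ValueError("all-zero row; Hellinger transform undefined")
    return np.sqrt(profiles / sums)


def community_distance(table: AsvTable, metric: str = "bray_curtis",
                       transform: str = "none") -> DistanceMatrix:
    """Pairwise Bray-Curtis (on abundances) or Jaccard (on presence/absence).

    ``transform='hellinger'`` applies the Hellinger transform before
    Bray-Curtis; it is ignored for Jaccard, which is defined on
    presence/absence.
    """
    if table.n_samples < 2:
        raise ValueError("need at least 2 samples")
    if (table.sample_sums() == 0).sum() >= 1:
        raise ValueError("all-zero sample; distances undefined")
    if metric == "bray_curtis":
        profiles = relative_abundance(table).to_numpy()
        if transform == "hellinger":
            profiles = hellinger(profiles)
        elif transform != "none":
            raise ValueError(f"unknown transform {transform!r}")
        condensed = pdist(profiles, metric="braycurtis")
    elif metric == "jaccard":
        condensed = pdist(table.presence().astype(bool), metric="jaccard")
    else:
        raise ValueError(f"unknown metric {metric!r}")
    return DistanceMatrix(list(table.sample_ids), squareform(condensed), metric)


# ---------------------------------------------------------------------------
# NMDS
# ---------------------------------------------------------------------------

def _pcoa_coordinates(d: np.ndarray, k: int) -> np.ndarray:
    """Classical-scaling start configuration (top-k positive axes)."""
    n = d.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ (d**2) @ j
    vals, vecs = np.linalg.eigh(b)
    order = np.argsort(vals)[::-1][:k]
    vals_k = np.clip(vals[order], 0.0, None)
    return vecs[:, order] * np.sqrt(vals_k)


def nmds(d: DistanceMatrix, k: int = 2, n_starts: int = 20,
         seed: int = 0, max_iter: int = 300, eps: float = 1e-7) -> OrdinationResult:
    """Kruskal non-metric MDS: best of ``n_starts`` random starts plus one
    classical-scaling start; stress is Kruskal stress-1."""
    if k < 1:
        raise ValueError("k must be >= 1")
    dm = d.values
    best_coords, best_stress = None, np.inf
    used = 0
    if n_starts > 0:
        coords, stress = smacof(
            dm, metric=False, n_components=k, n_init=n_starts,
            max_iter=max_iter, eps=eps, random_state=seed,
            normalized_stress=True)
        best_coords, best_stress = coords, stress
        used += n_starts
    init = _pcoa_coordinates(dm, k)
    coords, stress = smacof(
        dm, metric=False, n_components=k, init=init, n_init=1,
        max_iter=max_iter, eps=eps, random_state=seed,
        normalized_stress=True)
    used += 1
    if stress < best_stress:
        best_coords, best_stress = coords, stress
    best_coords = best_coords - best_coords.mean(axis=0, keepdims=True)
    return OrdinationResult(best_coords, float(best_stress),
                            converged=np.isfinite(best_stress),
                            n_starts_used=used, ids=list(d.ids))


# ---------------------------------------------------------------------------
# Permutation tests
# ---------------------------------------------------------------------------

def _check_groups(groups: np.ndarray) -> None:
    labels, counts = np.unique(groups, return_counts=True)
    if len(labels) < 2:
        raise ValueError("need at least 2 groups")
    if (counts < 2).any():
        raise ValueError("every group needs at least 2 members")


def _anosim_r(ranks: np.ndarray, within: np.ndarray, m: int) -> float:
    return (ranks[~within].mean() - ranks[within].mean()) / (m / 2.0)


def anosim(d: DistanceMatrix, groups, n_perm: int = 999,
           seed: int = 0, exhaustive: bool = False) -> dict:
    """Analysis of similarities on ranked distances.

    R = (mean between-group rank - mean within-group rank) / (M/2) with
    M = n(n-1)/2; the p-value is one-sided upper with add-one correction.
    ``exhaustive=True`` enumerates all distinct label permutations
    (small n only).
    """
    groups = np.asarray(groups)
    _check_groups(groups)
    n = d.n
    if len(groups) != n:
        raise ValueError("groups length must match matrix size")
    ranks = stats.rankdata(d.condensed())
    m = n * (n - 1) // 2
    iu, ju = np.triu_indices(n, k=1)

    def r_for(labels: np.ndarray) -> float:
        within = labels[iu] == labels[ju]
        return _anosim_r(ranks, within, m)

    r_obs = r_for(groups)
    if exhaustive:
        from itertools import permutations
        perms = {tuple(p) for p in permutations(groups)}
        r_perm = np.array([r_for(np.array(p)) for p in perms])
        p = float((r_perm >= r_obs - 1e-12).sum() / len(r_perm))
        return {"R": float(r_obs), "p": p, "n_perm": len(r_perm)}
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        if r_for(rng.permutation(groups)) >= r_obs - 1e-12:
            count += 1
    p = (count + 1) / (n_perm + 1)
    return {"R": float(r_obs), "p": float(p), "n_perm": n_perm}


def mantel(d1: DistanceMatrix, d2: DistanceMatrix, n_perm: int = 999,
           seed: int = 0, exhaustive: bool = False) -> dict:
    """Mantel correlation of two distance matrices with a one-sided upper
    permutation p-value (row/column permutation of the second matrix)."""
    if d1.ids != d2.ids:
        raise ValueError("distance matrices must share ids in the same order")
    x = d1.condensed()
    v2 = d2.values
    y = d2.condensed()
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero variance in a distance matrix")
    r_obs = float(np.corrcoef(x, y)[0, 1])
    n = d1.n
    iu = np.triu_indices(n, k=1)

    def r_for(perm: np.ndarray) -> float:
        return float(np.corrcoef(x, v2[np.ix_(perm, perm)][iu])[0, 1])

    if exhaustive:
        from itertools import permutations
        r_perm = np.array([r_for(np.array(p)) for p in permutations(range(n))])
        p = float((r_perm >= r_obs - 1e-12).sum() / len(r_perm))
        return {"r": r_obs, "p": p, "n_perm": len(r_perm)}
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        if r_for(rng.permutation(n)) >= r_obs - 1e-12:
            count += 1
    return {"r": r_obs, "p": float((count + 1) / (n_perm + 1)), "n_perm": n_perm}


# ---------------------------------------------------------------------------
# Geography
# ---------------------------------------------------------------------------

def geographic_distance(metadata) -> DistanceMatrix:
    """Great-circle (haversine) distances in km, Earth radius 6371 km."""
    lat = np.radians([m.latitude for m in metadata])
    lon = np.radians([m.longitude for m in metadata])
    if np.isnan(lat).any() or np.isnan(lon).any():
        raise ValueError("missing coordinates")
    dlat = lat[:, None] - lat[None, :]
    dlon = lon[:, None] - lon[None, :]
    a = (np.sin(dlat / 2.0) ** 2
         + np.cos(lat)[:, None] * np.cos(lat)[None, :] * np.sin(dlon / 2.0) ** 2)
    dist = 2.0 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(a, 0.0, 1.0)))
    np.fill_diagonal(dist, 0.0)
    return DistanceMatrix([m.site_id for m in metadata], dist, "haversine_km")


def distance_decay(community_d: DistanceMatrix, geo_d: DistanceMatrix,
                   groups=None, n_perm: int = 0, seed: int = 0) -> dict:
    """Distance-decay: OLS of community similarity (1 - distance) on
    geographic distance, using within-group site pairs only.

    With exactly two groups, the slope difference is tested through the
    interaction term of a pooled OLS; ``n_perm > 0`` switches to a
    permutation p-value obtained by reshuffling site group labels.
    """
    if community_d.ids != geo_d.ids:
        raise ValueError("distance matrices must share ids in the same order")
    n = community_d.n
    iu, ju = np.triu_indices(n, k=1)
    sim = 1.0 - community_d.condensed()
    dist = geo_d.condensed()

    if groups is None:
        slope, intercept, r, p, _ = stats.linregress(dist, sim)
        return {"slopes": {"all": float(slope)}, "intercepts": {"all": float(intercept)},
                "r2": {"all": float(r**2)}, "p": {"all": float(p)},
                "slope_difference_p": None}
    groups = np.asarray(groups)
    pair_same = groups[iu] == groups[ju]
    pair_group = np.where(pair_same, groups[iu], "__cross__")

    slopes, intercepts, r2s, ps = {}, {}, {}, {}
    labels = [g for g in np.unique(groups)]
    for g in labels:
        mask = pair_group == str(g)
        if mask.sum() < 3:
            raise ValueError(f"group {g!r} has fewer than 3 within-group pairs")
        slope, intercept, r, p, _ = stats.linregress(dist[mask], sim[mask])
        slopes[str(g)] = float(slope)
        intercepts[str(g)] = float(intercept)
        r2s[str(g)] = float(r**2)
        ps[str(g)] = float(p)

    slope_diff_p = None
    if len(labels) == 2:
        def interaction_t(site_groups: np.ndarray) -> float | None:
            same = site_groups[iu] == site_groups[ju]
            keep = same
            if keep.sum() < 6:
                return None
            ind = (site_groups[iu][keep] == labels[1]).astype(float)
            x = np.column_stack([
                np.ones(keep.sum()), dist[keep], ind, dist[keep] * ind])
            fit = sm.OLS(sim[keep], x).fit()
            return float(fit.tvalues[3])

        t_obs = interaction_t(groups)
        if n_perm > 0:
            rng = np.random.default_rng(seed)
            count = 0
            valid = 0
            for _ in range(n_perm):
                t_p = interaction_t(rng.permutation(groups))
                if t_p is None:
                    continue
                valid += 1
                if abs(t_p) >= abs(t_obs) - 1e-12:
                    count += 1
            slope_diff_p = (count + 1) / (valid + 1)
        else:
            same = groups[iu] == groups[ju]
            ind = (groups[iu][same] == labels[1]).astype(float)
            x = np.column_stack([
                np.ones(same.sum()), dist[same], ind, dist[same] * ind])
            fit = sm.OLS(sim[same], x).fit()
            slope_diff_p = float(fit.pvalues[3])
    return {"slopes": slopes, "intercepts": intercepts, "r2": r2s, "p": ps,
            "slope_difference_p": slope_diff_p}
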