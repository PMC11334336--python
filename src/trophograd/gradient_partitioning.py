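"""Distance-based redundancy analysis, hierarchical and variation
partitioning over predictor groups, and the moving-window gradient scan.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from trophograd.assembly_stochasticity import NullModelConfig, nst
from trophograd.core_data import DistanceMatrix

logger = logging.getLogger(__name__)

#: Default predictor grouping used by the pipeline (Fig.-2-style groups).
DEFAULT_GROUPS = {
    "climatic": ["MAT", "MAP", "MTCM", "PSCV"],
    "edaphic": ["pH", "SWC", "C_N"],
    "PB": ["PB_edges", "PB_connectance"],
    "VB": ["VB_edges", "VB_connectance"],
}


@dataclass
class DbrdaResult:
    R2: float
    adj_R2: float
    F: float
    p: float | None
    n_perm: int
    dropped_inertia: float


@dataclass
class WindowPartition:
    window_index: int
    member_sites: list[str]
    center: float
    determinism: float | None
    independent_effects: dict[str, float]
    total_adj_R2: float


# ---------------------------------------------------------------------------
# VIF
# ---------------------------------------------------------------------------

def _vif(x: np.ndarray, j: int) -> float:
    others = np.delete(x, j, axis=1)
    design = np.column_stack([np.ones(len(x)), others])
    beta, *_ = np.linalg.lstsq(design, x[:, j], rcond=None)
    resid = x[:, j] - design @ beta
    tss = ((x[:, j] - x[:, j].mean()) ** 2).sum()
    if tss == 0:
        return np.inf
    r2 = 1.0 - (resid**2).sum() / tss
    return np.inf if r2 >= 1.0 - 1e-12 else 1.0 / (1.0 - r2)


def vif_prune(X: pd.DataFrame, limit: float = 10.0) -> tuple[pd.DataFrame, list[str]]:
    """Iteratively drop the predictor with the largest variance inflation
    factor until all VIFs are below ``limit``; returns the pruned frame
    and the removal log."""
    if X.shape[0] <= X.shape[1] + 1:
        raise ValueError("need n_sites > n_predictors + 1")
    cols = list(X.columns)
    removed: list[str] = []
    while len(cols) > 1:
        x = X[cols].to_numpy(dtype=float)
        vifs = np.array([_vif(x, j) for j in range(len(cols))])
        if (vifs < limit).all():
            break
        worst = int(np.argmax(vifs))
        removed.append(cols[worst])
        logger.info("vif_prune: removing %s (VIF=%.2f)", cols[worst], vifs[worst])
        cols.pop(worst)
    if len(cols) == 0:
        raise ValueError("all predictors removed; unresolvable collinearity")
    return X[cols], removed


# ---------------------------------------------------------------------------
# dbRDA
# ---------------------------------------------------------------------------

def pcoa_coordinates(d: DistanceMatrix, tol: float = 1e-10,
                     ) -> tuple[np.ndarray, float]:
    """Principal coordinates of a distance matrix, keeping positive
    eigenvalues only; returns (coordinates, dropped inertia fraction)."""
    dm = d.values
    n = dm.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ (dm**2) @ j
    vals, vecs = np.linalg.eigh(b)
    order = np.argsort(vals)[::-1]
    vals, vecs = vals[order], vecs[:, order]
    pos = vals > tol * max(vals.max(), 1.0)
    dropped = float(np.abs(vals[~pos]).sum())
    total = float(vals[pos].sum() + dropped)
    if not pos.any():
        raise ValueError("no positive eigenvalues in PCoA")
    if dropped > 0:
        logger.info("pcoa: dropping %.3f%% of inertia (negative/zero axes)",
                    100.0 * dropped / total)
    coords = vecs[:, pos] * np.sqrt(vals[pos])
    return coords, dropped / total if total else 0.0


def _r2_on_coords(y: np.ndarray, x: np.ndarray) -> float:
    """Constrained / total inertia of centered coordinates y given
    predictors x (intercept added)."""
    design = np.column_stack([np.ones(len(x)), x])
    q, _ = np.linalg.qr(design)
    fitted = q @ (q.T @ y)
    total = (y**2).sum()
    return float((fitted**2).sum() / total)


def adjusted_r2(r2: float, n: int, p: int) -> float:
    """Ezekiel adjustment 1 - (1 - R^2)(n - 1)/(n - p - 1)."""
    if n - p - 1 <= 0:
        raise ValueError("saturated model: need n > p + 1")
    return 1.0 - (1.0 - r2) * (n - 1) / (n - p - 1)


def dbrda(d: DistanceMatrix, X: pd.DataFrame, n_perm: int = 999,
          seed: int = 0) -> DbrdaResult:
    """Distance-based RDA: regress principal coordinates on predictors.

    The p-value comes from unrestricted row permutations of the
    predictor matrix; ``n_perm=0`` skips the test.
    """
    x = np.asarray(X, dtype=float)
    n, p = x.shape
    if n != d.n:
        raise ValueError("predictor rows must match distance matrix ids")
    if p >= n - 1:
        raise ValueError("saturated model: too many predictors")
    y, dropped = pcoa_coordinates(d)
    y = y - y.mean(axis=0, keepdims=True)
    r2 = _r2_on_coords(y, x)
    adj = adjusted_r2(r2, n, p)
    f = (r2 / p) / ((1.0 - r2) / (n - p - 1))
    p_val = None
    if n_perm > 0:
        rng = np.random.default_rng(seed)
        count = 0
        for _ in range(n_perm):
            r2_perm = _r2_on_coords(y, x[rng.permutation(n)])
            if r2_perm >= r2 - 1e-12:
                count += 1
        p_val = (count + 1) / (n_perm + 1)
    return DbrdaResult(r2, adj, f, p_val, n_perm, dropped)


# ---------------------------------------------------------------------------
# Partitioning
# ---------------------------------------------------------------------------

def _group_matrices(X: pd.DataFrame, groups: Mapping[str, Sequence[str]],
                    ) -> dict[str, np.ndarray]:
    out = {}
    seen: set[str] = set()
    for name, cols in groups.items():
        cols = list(cols)
        missing = [c for c in cols if c not in X.columns]
        if missing:
            raise ValueError(f"group {name!r} references missing columns {missing}")
        overlap = seen & set(cols)
        if overlap:
            raise ValueError(f"groups must be disjoint; {sorted(overlap)} repeated")
        seen |= set(cols)
        out[name] = X[cols].to_numpy(dtype=float)
    return out


def _subset_adj_r2(d: DistanceMatrix, mats: dict[str, np.ndarray],
                   ) -> dict[frozenset, float]:
    """Adjusted R^2 of every non-empty group subset (empty set -> 0)."""
    y, _ = pcoa_coordinates(d)
    y = y - y.mean(axis=0, keepdims=True)
    n = y.shape[0]
    names = list(mats)
    table: dict[frozenset, float] = {frozenset(): 0.0}
    for k in range(1, len(names) + 1):
        for subset in combinations(names, k):
            x = np.column_stack([mats[g] for g in subset])
            if x.shape[1] >= n - 1:
                raise ValueError(f"saturated subset model {subset}")
            table[frozenset(subset)] = adjusted_r2(
                _r2_on_coords(y, x), n, x.shape[1])
    return table


def hierarchical_partition(d: DistanceMatrix, X: pd.DataFrame,
                           groups: Mapping[str, Sequence[str]],
                           ) -> tuple[dict[str, float], float]:
    """All-subsets hierarchical partitioning of dbRDA adjusted R^2.

    The independent effect of a group is its incremental adjusted R^2
    averaged first over same-size subsets and then over hierarchy
    levels; effects sum exactly to the full-model adjusted R^2.
    """
    mats = _group_matrices(X, groups)
    names = list(mats)
    k = len(names)
    if k > 8:
        raise ValueError("at most 8 groups (2^k - 1 subset models)")
    table = _subset_adj_r2(d, mats)
    effects: dict[str, float] = {}
    for g in names:
        others = [x for x in names if x != g]
        level_means = []
        for h in range(k):  # size of the base subset
            incs = [table[frozenset(s) | {g}] - table[frozenset(s)]
                    for s in combinations(others, h)]
            level_means.append(float(np.mean(incs)))
        effects[g] = float(np.mean(level_means))
    total = table[frozenset(names)]
    return effects, float(total)


def variation_partition(d: DistanceMatrix, X: pd.DataFrame,
                        groups: Mapping[str, Sequence[str]],
                        ) -> dict[str, float]:
    """Three-group variation partitioning by inclusion-exclusion on
    adjusted R^2; fractions may be slightly negative and are reported
    as-is.  Keys: unique_<g>, shared_<g1>_<g2>, shared_all, total."""
    if len(groups) != 3:
        raise ValueError("variation_partition requires exactly 3 groups")
    mats = _group_matrices(X, groups)
    a, b, c = list(mats)
    t = _subset_adj_r2(d, mats)
    s = lambda *gs: t[frozenset(gs)]
    abc = s(a, b, c)
    unique = {a: abc - s(b, c), b: abc - s(a, c), c: abc - s(a, b)}
    shared_all = (s(a) + s(b) + s(c)) - (s(a, b) + s(a, c) + s(b, c)) + abc
    out = {f"unique_{g}": unique[g] for g in (a, b, c)}
    # pairwise shared via inclusion-exclusion: shared(ab) = a + b - ab - shared_all
    out[f"shared_{a}_{b}"] = s(a) + s(b) - s(a, b) - shared_all
    out[f"shared_{a}_{c}"] = s(a) + s(c) - s(a, c) - shared_all
    out[f"shared_{b}_{c}"] = s(b) + s(c) - s(b, c) - shared_all
    out["shared_all"] = shared_all
    out["total"] = abc
    return out


# ---------------------------------------------------------------------------
# Moving window
# ---------------------------------------------------------------------------

def moving_window(d: DistanceMatrix, X: pd.DataFrame,
                  groups: Mapping[str, Sequence[str]],
                  gradient: Sequence[float],
                  presence: np.ndarray | None = None,
                  window_size: int | None = None,
                  null_config: NullModelConfig | None = None,
                  split_point: float = 32.0,
                  ) -> list[WindowPartition]:
    """Slide a fixed-size window along the gradient-sorted sites and run
    hierarchical partitioning (plus NST when a presence matrix is given)
    inside each window.

    ``window_size`` defaults to the size of the low-gradient group
    defined by ``split_point``.  Windows are contiguous runs of sorted
    sites, step 1, so there are n - w + 1 of them.
    """
    gradient = np.asarray(gradient, dtype=float)
    n = d.n
    if len(gradient) != n or len(X) != n:
        raise ValueError("gradient and predictors must match distance ids")
    order = np.argsort(gradient, kind="stable")
    if window_size is None:
        window_size = int((gradient < split_point).sum())
    w = int(window_size)
    if w > n:
        raise ValueError("window size exceeds number of sites")
    n_pred = sum(len(c) for c in groups.values())
    if w < n_pred + 5:
        raise ValueError(f"window size {w} below minimum viable {n_pred + 5}")

    ids_sorted = [d.ids[i] for i in order]
    results = []
    for start in range(n - w + 1):
        idx = order[start:start + w]
        member_ids = ids_sorted[start:start + w]
        d_win = DistanceMatrix(member_ids,
                               d.values[np.ix_(idx, idx)], d.metric)
        x_win = X.iloc[idx]
        determinism = None
        if presence is not None:
            cfg = null_config or NullModelConfig(n_null=100)
            cfg = NullModelConfig(cfg.algorithm, cfg.n_null,
                                  seed=cfg.seed + start)
            pres_win = presence[idx][:, np.asarray(presence[idx]).sum(axis=0) > 0]
            res = nst(pres_win, cfg, group_id=f"window_{start}")
            determinism = res.determinism
        effects, total = hierarchical_partition(d_win, x_win, groups)
        results.append(WindowPartition(
            window_index=start, member_sites=member_ids,
            center=float(np.median(gradient[idx])),
            determinism=determinism, independent_effects=effects,
            total_adj_R2=total))
    return results


def window_table(windows: Sequence[WindowPartition]) -> pd.DataFrame:
    rows = []
    for wp in windows:
        row = {"window_index": wp.window_index, "center_gradient": wp.center,
               "n_sites": len(wp.member_sites), "determinism": wp.determinism}
        row.update({f"effect_{g}": v for g, v in wp.independent_effects.items()})
        row["total_adj_R2"] = wp.total_adj_R2
        rows.append(row)
    return pd.DataFrame(rows)
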