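"""Bipartite predator-prey correlation networks with random-matrix
threshold selection, and per-site induced-subnetwork metrics.

The threshold scan zeroes correlations below each candidate cutoff,
embeds the rectangular predator x prey block as the off-diagonal blocks
of a symmetric matrix (whose nonzero eigenvalues are the +/- singular
values of the block), unfolds the positive spectrum with a smoothing
spline on the cumulative spectral density, and tests the
nearest-neighbor spacing distribution (NNSD) against the Poisson law
e^(-u).  The chosen cutoff is the smallest one whose NNSD is
Poisson-consistent: at that point the surviving network behaves like
uncorrelated signal rather than a correlated noise bulk (which follows
the Wigner-Dyson law (pi*u/2) e^(-pi*u^2/4)).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import networkx as nx
from scipy import interpolate, stats

from trophograd.core_data import AsvTable, relative_abundance

__all__ = [
    "CorrelationBlock", "RmtScan", "BipartiteNetwork",
    "spearman_block", "rmt_threshold", "build_meta_network",
    "site_subnetworks", "threshold_sensitivity",
    "wigner_surmise", "poisson_spacing",
]


def poisson_spacing(u: np.ndarray) -> np.ndarray:
    """Poisson NNSD density e^(-u) (uncorrelated eigenvalues)."""
    return np.exp(-np.asarray(u, dtype=float))


def wigner_surmise(u: np.ndarray) -> np.ndarray:
    """GOE Wigner surmise density (pi*u/2) exp(-pi*u^2/4)."""
    u = np.asarray(u, dtype=float)
    return (np.pi * u / 2.0) * np.exp(-np.pi * u**2 / 4.0)


@dataclass
class CorrelationBlock:
    predator_ids: list[str]
    prey_ids: list[str]
    rho: np.ndarray          # predators x prey

    def __post_init__(self) -> None:
        rho = np.asarray(self.rho, dtype=float)
        if rho.shape != (len(self.predator_ids), len(self.prey_ids)):
            raise ValueError("rho shape does not match id lists")
        if np.nanmax(np.abs(rho), initial=0.0) > 1.0 + 1e-9:
            raise ValueError("correlations must lie in [-1, 1]")
        self.rho = rho


@dataclass
class RmtScan:
    thresholds: np.ndarray
    poisson_pvalues: np.ndarray       # NaN where not evaluable
    wigner_pvalues: np.ndarray
    n_eigenvalues: np.ndarray
    chosen_threshold: float
    alpha: float

    def table(self) -> pd.DataFrame:
        return pd.DataFrame({
            "threshold": self.thresholds,
            "n_eigenvalues": self.n_eigenvalues,
            "poisson_p": self.poisson_pvalues,
            "wigner_p": self.wigner_pvalues,
        })


@dataclass
class BipartiteNetwork:
    predator_ids: list[str]
    prey_ids: list[str]
    adjacency: np.ndarray    # binary predators x prey
    rho: np.ndarray          # signed correlations retained for export
    threshold: float
    node_count: int = field(init=False)
    edge_count: int = field(init=False)
    connectance: float = field(init=False)

    def __post_init__(self) -> None:
        adj = np.asarray(self.adjacency)
        if not np.isin(adj, (0, 1)).all():
            raise ValueError("adjacency must be binary")
        self.adjacency = adj.astype(np.int8)
        self.edge_count = int(self.adjacency.sum())
        pred_deg = self.adjacency.sum(axis=1)
        prey_deg = self.adjacency.sum(axis=0)
        self.node_count = int((pred_deg > 0).sum() + (prey_deg > 0).sum())
        self.connectance = (self.edge_count / self.node_count**2
                            if self.node_count else 0.0)

    def edge_list(self) -> pd.DataFrame:
        pi, bi = np.nonzero(self.adjacency)
        rho = self.rho[pi, bi]
        return pd.DataFrame({
            "predator_id": [self.predator_ids[i] for i in pi],
            "prey_id": [self.prey_ids[i] for i in bi],
            "rho": rho,
            "sign": np.where(rho >= 0, "+", "-"),
        })

    def to_graph(self) -> nx.Graph:
        g = nx.Graph()
        for _, row in self.edge_list().iterrows():
            g.add_node(row["predator_id"], guild="predator")
            g.add_node(row["prey_id"], guild="prey")
            g.add_edge(row["predator_id"], row["prey_id"],
                       rho=float(row["rho"]), sign=row["sign"])
        return g


# ---------------------------------------------------------------------------
# Correlations
# ---------------------------------------------------------------------------

def spearman_block(prey: AsvTable, predator: AsvTable) -> CorrelationBlock:
    """Spearman correlations (average ranks for ties) between every
    predator and prey ASV across sites, on relative abundances.
    Constant ASVs get rho = 0 with a warning."""
    if prey.sample_ids != predator.sample_ids:
        raise ValueError("prey and predator tables must share sample order")
    ra_prey = relative_abundance(prey).to_numpy()
    ra_pred = relative_abundance(predator).to_numpy()

    def ranked(m: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        r = np.apply_along_axis(stats.rankdata, 0, m)
        r = r - r.mean(axis=0, keepdims=True)
        sd = np.sqrt((r**2).sum(axis=0))
        return r, sd

    rp, sd_prey = ranked(ra_prey)
    rq, sd_pred = ranked(ra_pred)
    n_const = int((sd_prey == 0).sum() + (sd_pred == 0).sum())
    if n_const:
        warnings.warn(f"{n_const} constant ASV vector(s); their correlations "
                      "are recorded as 0", stacklevel=2)
    denom = np.outer(np.where(sd_pred == 0, 1.0, sd_pred),
                     np.where(sd_prey == 0, 1.0, sd_prey))
    rho = (rq.T @ rp) / denom
    rho[np.outer(sd_pred == 0, np.ones(len(sd_prey), dtype=bool))] = 0.0
    rho[np.outer(np.ones(len(sd_pred), dtype=bool), sd_prey == 0)] = 0.0
    rho = np.clip(rho, -1.0, 1.0)
    return CorrelationBlock(list(predator.asv_ids), list(prey.asv_ids), rho)


# ---------------------------------------------------------------------------
# RMT threshold
# ---------------------------------------------------------------------------

def _unfolded_spacings(eigenvalues: np.ndarray, n_knots: int = 10) -> np.ndarray:
    """Unfold a 1-D spectrum via a cubic smoothing spline fitted to the
    empirical cumulative spectral density; return nearest-neighbor
    spacings (mean ~ 1)."""
    lam = np.sort(np.asarray(eigenvalues, dtype=float))
    n = len(lam)
    # collapse exact degeneracies: ties carry no spacing information
    uniq, counts = np.unique(lam, return_counts=True)
    cum = np.cumsum(counts) - counts / 2.0  # mid-rank cumulative count
    if len(uniq) < 5:
        raise ValueError("too few distinct eigenvalues to unfold")
    k = min(n_knots, max(2, len(uniq) // 5))
    knots = np.quantile(uniq, np.linspace(0, 1, k + 2)[1:-1])
    knots = np.unique(np.clip(knots, uniq[0] + 1e-12, uniq[-1] - 1e-12))
    try:
        spline = interpolate.LSQUnivariateSpline(uniq, cum, knots, k=3)
        unfolded = spline(uniq)
    except Exception:
        unfolded = np.interp(uniq, uniq, cum)
    spacings = np.diff(np.sort(unfolded))
    spacings = spacings[np.isfinite(spacings)]
    spacings = np.clip(spacings, 0.0, None)
    mean = spacings.mean()
    if mean <= 0:
        raise ValueError("degenerate spectrum; spacings all zero")
    return spacings / mean


def _nnsd_pvalue(spacings: np.ndarray, density, n_bins: int = 40,
                 support: float = 3.0) -> float:
    """Chi-square goodness of fit of unit-mean spacings to a reference
    NNSD density over fixed bins on [0, support] plus an overflow bin.
    Adjacent bins are pooled until every expected count is >= 5."""
    edges = np.linspace(0.0, support, n_bins + 1)
    obs = np.histogram(spacings, bins=edges)[0].astype(float)
    obs = np.append(obs, (spacings >= support).sum())
    grid = np.linspace(0.0, support, 4001)
    dens = density(grid)
    cdf = np.concatenate([[0.0], np.cumsum((dens[1:] + dens[:-1]) / 2.0
                                           * np.diff(grid))])
    cdf_at = np.interp(edges, grid, cdf)
    probs = np.append(np.diff(cdf_at), max(1.0 - cdf_at[-1], 0.0))
    probs = probs / probs.sum()
    expected = probs * len(spacings)

    # pool low-expectation bins left to right
    pooled_obs, pooled_exp = [], []
    acc_o = acc_e = 0.0
    for o, e in zip(obs, expected):
        acc_o += o
        acc_e += e
        if acc_e >= 5.0:
            pooled_obs.append(acc_o)
            pooled_exp.append(acc_e)
            acc_o = acc_e = 0.0
    if acc_e > 0 and pooled_exp:
        pooled_obs[-1] += acc_o
        pooled_exp[-1] += acc_e
    if len(pooled_exp) < 2:
        return np.nan
    pooled_obs = np.asarray(pooled_obs)
    pooled_exp = np.asarray(pooled_exp)
    pooled_exp *= pooled_obs.sum() / pooled_exp.sum()
    chi2 = ((pooled_obs - pooled_exp) ** 2 / pooled_exp).sum()
    return float(stats.chi2.sf(chi2, len(pooled_exp) - 1))


def _surviving_singular_values(rho: np.ndarray, threshold: float,
                               tol: float = 1e-10) -> np.ndarray:
    b = np.where(np.abs(rho) >= threshold, rho, 0.0)
    if not b.any():
        return np.array([])
    sv = np.linalg.svd(b, compute_uv=False)
    return sv[sv > tol]


def rmt_threshold(block: CorrelationBlock,
                  scan: np.ndarray | None = None,
                  alpha: float = 0.05,
                  min_eigenvalues: int = 50,
                  n_bins: int = 40) -> RmtScan:
    """Scan correlation cutoffs and pick the smallest whose surviving
    spectrum has a Poisson-consistent NNSD (chi-square p > ``alpha``).

    Thresholds where fewer than ``min_eigenvalues`` nonzero eigenvalues
    survive are not evaluable; the scan stops there.  If no evaluable
    threshold is Poisson-consistent, the last evaluable threshold is
    taken when its Poisson fit beats the Wigner-Dyson fit, otherwise an
    error carrying the scan table is raised.
    """
    if scan is None:
        scan = np.round(np.arange(0.30, 0.981, 0.01), 4)
    scan = np.asarray(scan, dtype=float)
    poisson_p = np.full(len(scan), np.nan)
    wigner_p = np.full(len(scan), np.nan)
    n_eig = np.zeros(len(scan), dtype=int)

    chosen = None
    last_evaluable = None
    for i, s in enumerate(scan):
        sv = _surviving_singular_values(block.rho, s)
        n_eig[i] = len(sv)
        if len(sv) < min_eigenvalues:
            break
        try:
            spacings = _unfolded_spacings(sv)
        except ValueError:
            continue
        poisson_p[i] = _nnsd_pvalue(spacings, poisson_spacing, n_bins=n_bins)
        wigner_p[i] = _nnsd_pvalue(spacings, wigner_surmise, n_bins=n_bins)
        last_evaluable = i
        if np.isfinite(poisson_p[i]) and poisson_p[i] > alpha:
            chosen = float(s)
            break

    if chosen is None and last_evaluable is not None:
        i = last_evaluable
        if np.isfinite(poisson_p[i]) and (
                not np.isfinite(wigner_p[i]) or poisson_p[i] > wigner_p[i]):
            chosen = float(scan[i])
            warnings.warn(
                "no threshold reached Poisson consistency; taking the last "
                f"evaluable threshold {chosen} where Poisson fits better than "
                "Wigner-Dyson", stacklevel=2)
    if chosen is None:
        table = pd.DataFrame({"threshold": scan, "n_eigenvalues": n_eig,
                              "poisson_p": poisson_p, "wigner_p": wigner_p})
        raise RuntimeError(
            "RMT scan found no Poisson-consistent threshold; scan table:\n"
            + table.to_string(index=False))
    return RmtScan(scan, poisson_p, wigner_p, n_eig, chosen, alpha)


# ---------------------------------------------------------------------------
# Networks
# ---------------------------------------------------------------------------

def build_meta_network(block: CorrelationBlock, threshold: float,
                       positive_only: bool = False) -> BipartiteNetwork:
    """Binary bipartite meta-network: edge iff |rho| >= threshold (or
    rho >= threshold with ``positive_only``); C = E/N^2 over non-isolated
    nodes."""
    if not 0.0 <= threshold <= 1.0:
        raise ValueError("threshold must be in [0, 1]")
    rho = block.rho
    adj = (rho >= threshold) if positive_only else (np.abs(rho) >= threshold)
    return BipartiteNetwork(list(block.predator_ids), list(block.prey_ids),
                            adj.astype(np.int8), rho, threshold)


def site_subnetworks(meta: BipartiteNetwork, prey: AsvTable,
                     predator: AsvTable, pair_label: str = "") -> pd.DataFrame:
    """Induce the meta-network on the ASVs present (count > 0) at each
    site; report per-site E, N (degree >= 1 nodes) and C = E/N^2."""
    if prey.sample_ids != predator.sample_ids:
        raise ValueError("prey and predator tables must share sample order")
    pred_col = {a: i for i, a in enumerate(predator.asv_ids)}
    prey_col = {a: i for i, a in enumerate(prey.asv_ids)}
    missing = [a for a in meta.predator_ids if a not in pred_col] + \
              [a for a in meta.prey_ids if a not in prey_col]
    if missing:
        raise ValueError(f"meta-network ASVs absent from tables: {missing[:5]}")
    pred_present = predator.counts[:, [pred_col[a] for a in meta.predator_ids]] > 0
    prey_present = prey.counts[:, [prey_col[a] for a in meta.prey_ids]] > 0

    rows = []
    adj = meta.adjacency.astype(bool)
    for s in range(len(prey.sample_ids)):
        sub = adj & np.outer(pred_present[s], prey_present[s])
        e = int(sub.sum())
        n = int((sub.any(axis=1)).sum() + (sub.any(axis=0)).sum())
        rows.append({"site_id": prey.sample_ids[s], "pair": pair_label,
                     "E": e, "N": n, "C": e / n**2 if n else 0.0})
    return pd.DataFrame(rows)


def threshold_sensitivity(prey: AsvTable, predator: AsvTable,
                          prevalence_levels=(0.2, 0.3, 0.4),
                          threshold: float | None = None,
                          pair_label: str = "") -> pd.DataFrame:
    """Cross-prevalence-level Spearman correlation of per-site network
    metrics (E and C).  ``threshold=None`` re-runs the RMT scan per level."""
    from trophograd.core_data import prevalence_filter

    levels = list(prevalence_levels)
    if len(levels) < 2:
        raise ValueError("need at least 2 prevalence levels")
    per_level: dict[float, pd.DataFrame] = {}
    for lev in levels:
        p_f = prevalence_filter(prey, lev)
        q_f = prevalence_filter(predator, lev)
        block = spearman_block(p_f, q_f)
        thr = threshold if threshold is not None else \
            rmt_threshold(block).chosen_threshold
        meta = build_meta_network(block, thr)
        per_level[lev] = site_subnetworks(meta, p_f, q_f, pair_label)

    rows = []
    for i, a in enumerate(levels):
        for b in levels[i + 1:]:
            for metric in ("E", "C"):
                x = per_level[a][metric].to_numpy(dtype=float)
                y = per_level[b][metric].to_numpy(dtype=float)
                if np.ptp(x) == 0 or np.ptp(y) == 0:
                    r = np.nan
                else:
                    r = stats.spearmanr(x, y).statistic
                rows.append({"pair": pair_label, "metric": metric,
                             "level_a": a, "level_b": b, "spearman_r": r})
    return pd.DataFrame(rows)
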