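"""Normalized stochasticity ratio (NST) on Jaccard distances.

One explicit, documented definition is used throughout.  For each sample
pair, D is the observed Jaccard dissimilarity and E the mean Jaccard
over null communities that preserve per-sample richness and draw taxa
with probability proportional to observed occupancy:

    ST  pair = E/D if D >= E else D/E           (both 0 -> 1)
    NST pair = (1-D)/(1-E) if D >= E else D/E   (max dissimilarity 1)

ST and NST are pairwise means, determinism = 1 - NST.  Values near 1
mean the observation looks like the null (stochastic); values near 0
mean strong deterministic convergence or divergence.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import pdist


@dataclass
class NullModelConfig:
    algorithm: str = "proportional_fixed"
    n_null: int = 1000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.algorithm != "proportional_fixed":
            raise ValueError(f"unknown null model {self.algorithm!r}")
        if self.n_null < 2:
            raise ValueError("n_null must be >= 2")


@dataclass
class AssemblyResult:
    group_id: str
    ST: float
    NST: float
    determinism: float
    pairwise_D: np.ndarray = field(repr=False)
    pairwise_E: np.ndarray = field(repr=False)
    n_null: int = 0


def null_randomize(presence: np.ndarray, config: NullModelConfig) -> np.ndarray:
    """Null presence/absence matrices preserving per-sample richness with
    occupancy-proportional taxon selection.

    Returns an array of shape (n_null, n_samples, n_taxa).
    """
    presence = np.asarray(presence) > 0
    n_samples, n_taxa = presence.shape
    richness = presence.sum(axis=1)
    if (richness == 0).any():
        raise ValueError("empty sample row in presence matrix")
    occupancy = presence.sum(axis=0).astype(float)
    pool = np.flatnonzero(occupancy > 0)
    if (richness > len(pool)).any():
        raise ValueError("sample richness exceeds the occupied taxon pool")
    weights = occupancy[pool] / occupancy[pool].sum()
    rng = np.random.default_rng(config.seed)
    nulls = np.zeros((config.n_null, n_samples, n_taxa), dtype=np.int8)
    for b in range(config.n_null):
        for i in range(n_samples):
            chosen = rng.choice(pool, size=int(richness[i]), replace=False,
                                p=weights)
            nulls[b, i, chosen] = 1
    return nulls


def _jaccard(presence: np.ndarray) -> np.ndarray:
    return pdist(presence.astype(bool), metric="jaccard")


def nst(presence: np.ndarray, config: NullModelConfig,
        group_id: str = "all") -> AssemblyResult:
    """Normalized stochasticity ratio of one sample group (see module doc)."""
    presence = np.asarray(presence) > 0
    if presence.shape[0] < 3:
        raise ValueError("need at least 3 samples")
    d_obs = _jaccard(presence)
    nulls = null_randomize(presence, config)
    e_null = np.mean([_jaccard(nulls[b]) for b in range(config.n_null)], axis=0)

    st = np.empty_like(d_obs)
    nst_pair = np.empty_like(d_obs)
    for k, (d, e) in enumerate(zip(d_obs, e_null)):
        if d == 0.0 and e == 0.0:
            st[k] = 1.0
            nst_pair[k] = 1.0
        elif d >= e:
            st[k] = e / d
            nst_pair[k] = min((1.0 - d) / (1.0 - e), 1.0) if e < 1.0 else 1.0
        else:
            st[k] = d / e
            nst_pair[k] = d / e
    if np.all(d_obs == 0.0) and np.all(e_null == 0.0):
        warnings.warn("all samples identical and nulls degenerate; ST = 0",
                      stacklevel=2)
        return AssemblyResult(group_id, 0.0, 0.0, 1.0, d_obs, e_null,
                              config.n_null)
    nst_val = float(np.clip(nst_pair.mean(), 0.0, 1.0))
    return AssemblyResult(group_id, float(st.mean()), nst_val,
                          1.0 - nst_val, d_obs, e_null, config.n_null)
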