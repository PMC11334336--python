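"""Symmetric Procrustes superimposition of two ordinations, PROTEST
permutation significance, and residual-versus-gradient trends."""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from trophograd.trend_models import TrendFit, fit_gradient_trend


@dataclass
class ProcrustesResult:
    m2: float                       # badness of fit, in [0, 1]
    R2: float                       # 1 - m2, squared Procrustes correlation
    residuals: np.ndarray = field(repr=False)
    p: float | None = None
    n_perm: int = 0


def _standardize_configuration(x: np.ndarray) -> np.ndarray:
    """Center and scale to unit sum of squares."""
    x = np.asarray(x, dtype=float)
    x = x - x.mean(axis=0, keepdims=True)
    norm = np.sqrt((x**2).sum())
    if norm == 0:
        raise ValueError("zero-variance configuration")
    return x / norm


def procrustes_fit(a: np.ndarray, b: np.ndarray) -> ProcrustesResult:
    """Symmetric Procrustes: both configurations centered and unit-scaled,
    optimal orthogonal rotation (reflections allowed) from the SVD of the
    cross-product; m^2 = 1 - (sum of singular values)^2, residuals are
    per-row distances after superimposition."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("configurations must have identical shape")
    if a.shape[0] < 3:
        raise ValueError("need at least 3 sites")
    a_std = _standardize_configuration(a)
    b_std = _standardize_configuration(b)
    u, s, vt = np.linalg.svd(a_std.T @ b_std)
    trace = s.sum()
    rotation = vt.T @ u.T
    scale = trace  # optimal symmetric scaling of b onto a
    b_fit = scale * b_std @ rotation
    m2 = max(1.0 - trace**2, 0.0)
    residuals = np.sqrt(((a_std - b_fit) ** 2).sum(axis=1))
    return ProcrustesResult(m2=float(m2), R2=float(1.0 - m2),
                            residuals=residuals)


def protest(a: np.ndarray, b: np.ndarray, n_perm: int = 1000,
            seed: int = 0, exhaustive: bool = False) -> ProcrustesResult:
    """PROTEST: permute the row order of the second configuration; the
    one-sided p-value is the add-one-corrected fraction of permutations
    with m^2 at most the observed."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    obs = procrustes_fit(a, b)
    n = a.shape[0]
    if n < 5:
        warnings.warn("fewer than 5 sites: permutation test is weak",
                      stacklevel=2)
    a_std = _standardize_configuration(a)
    b_std = _standardize_configuration(b)

    def m2_for(perm: np.ndarray) -> float:
        s = np.linalg.svd(a_std.T @ b_std[perm], compute_uv=False)
        return max(1.0 - s.sum() ** 2, 0.0)

    if exhaustive:
        from itertools import permutations
        m2_perm = np.array([m2_for(np.array(p))
                            for p in permutations(range(n))])
        p = float((m2_perm <= obs.m2 + 1e-12).sum() / len(m2_perm))
        return ProcrustesResult(obs.m2, obs.R2, obs.residuals, p, len(m2_perm))
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        if m2_for(rng.permutation(n)) <= obs.m2 + 1e-12:
            count += 1
    p = (count + 1) / (n_perm + 1)
    return ProcrustesResult(obs.m2, obs.R2, obs.residuals, float(p), n_perm)


def residual_gradient(result: ProcrustesResult, gradient) -> TrendFit:
    """AIC-selected linear/quadratic trend of Procrustes residuals on the
    gradient; a constant-residual input yields a flat fit with warning."""
    gradient = np.asarray(gradient, dtype=float)
    if len(gradient) != len(result.residuals):
        raise ValueError("gradient length must match residuals")
    if np.ptp(result.residuals) == 0:
        warnings.warn("constant residuals; returning flat fit", stacklevel=2)
    return fit_gradient_trend(result.residuals, gradient)
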