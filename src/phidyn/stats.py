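"""Statistical procedures: dominance analysis with a permutation test,
spatial correlation against autocorrelation-preserving nulls, cross-species
gene ranking, sigmoid normalization and FDR plumbing."""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .io import RegionalMap
from .synthetic import msr_surrogate_maps

__all__ = [
    "DominanceResult",
    "SpatialCorrResult",
    "dominance_analysis",
    "permutation_r2_test",
    "spatial_corr_msr",
    "cross_species_gene_rank",
    "sigmoid_normalize",
    "fdr_bh",
]


def _r2(x: np.ndarray, y: np.ndarray) -> float:
    """Coefficient of determination of an OLS fit with intercept."""
    design = np.column_stack([np.ones(len(y)), x]) if x.size else \
        np.ones((len(y), 1))
    beta, *_ = np.linalg.lstsq(design, y, rcond=None)
    resid = y - design @ beta
    tss = float(np.sum((y - y.mean()) ** 2))
    if tss == 0:
        return 0.0
    return 1.0 - float(np.sum(resid**2)) / tss


@dataclass
class DominanceResult:
    """General-dominance decomposition of regression variance."""

    per_predictor_importance: np.ndarray
    total_r2: float
    adjusted_r2: float
    percent_importance: np.ndarray
    permutation_p: float | None = None
    predictor_names: list[str] | None = None


@dataclass
class SpatialCorrResult:
    rho: float
    p_null: float
    null_distribution: np.ndarray


def _all_subset_r2(x: np.ndarray, y: np.ndarray) -> dict:
    p = x.shape[1]
    cache = {(): 0.0 if np.var(y) == 0 else _r2(np.empty((len(y), 0)), y)}
    for size in range(1, p + 1):
        for subset in combinations(range(p), size):
            cache[subset] = _r2(x[:, list(subset)], y)
    return cache


def dominance_analysis(predictors: np.ndarray, target: np.ndarray,
                       names: list[str] | None = None) -> DominanceResult:
    """General dominance: each predictor's importance is its incremental R²
    averaged over subset sizes and, within each size, over all subsets of
    the remaining predictors.  Importances sum exactly to the full-model R².

    Exhaustive enumeration; refuses more than 15 predictors.
    """
    x = np.asarray(predictors, dtype=float)
    y = np.asarray(target, dtype=float).ravel()
    if x.ndim != 2:
        raise ValueError("predictors must be an n x p matrix")
    n, p = x.shape
    if p < 2:
        raise ValueError("need at least two predictors")
    if p > 15:
        raise ValueError("exhaustive dominance limited to p <= 15 predictors")
    if n <= p:
        raise ValueError("need more observations than predictors")
    if y.size != n:
        raise ValueError("target length does not match predictors")
    design = np.column_stack([np.ones(n), x])
    if np.linalg.cond(design.T @ design) > 1e10:
        raise ValueError("predictors are (near-)collinear; dominance "
                         "increments are not identified")
    cache = _all_subset_r2(x, y)
    importance = np.zeros(p)
    for j in range(p):
        others = [k for k in range(p) if k != j]
        by_size = []
        for size in range(p):
            incs = [cache[tuple(sorted(s + (j,)))] - cache[s]
                    for s in combinations(others, size)]
            by_size.append(np.mean(incs))
        importance[j] = np.mean(by_size)
    total = cache[tuple(range(p))]
    adj = 1.0 - (1.0 - total) * (n - 1) / (n - p - 1)
    pct = 100.0 * importance / total if total > 0 else np.full(p, np.nan)
    return DominanceResult(importance, float(total), float(adj), pct,
                           predictor_names=names)


def permutation_r2_test(predictors: np.ndarray, target: np.ndarray,
                        n_perm: int = 999, seed: int = 0) -> float:
    """One-sided permutation p for the multiple-regression R²: the target is
    reshuffled, the predictors stay fixed; p = (1 + #{R²_perm >= R²_emp}) /
    (n_perm + 1)."""
    if n_perm < 99:
        raise ValueError("n_perm must be >= 99")
    x = np.asarray(predictors, dtype=float)
    y = np.asarray(target, dtype=float).ravel()
    r2_emp = _r2(x, y)
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        if _r2(x, rng.permutation(y)) >= r2_emp:
            count += 1
    return (1 + count) / (n_perm + 1)


def spatial_corr_msr(map_a: RegionalMap, map_b: RegionalMap,
                     weights: np.ndarray, n_surr: int = 999,
                     seed: int = 0) -> SpatialCorrResult:
    """Spearman correlation of two regional maps, tested against Moran
    spectral randomization surrogates of ``map_a`` (two-sided, by absolute
    value)."""
    if map_a.n != map_b.n:
        raise ValueError("maps must have the same length")
    if n_surr < 99:
        raise ValueError("n_surr must be >= 99")
    if np.ptp(map_a.values) == 0 or np.ptp(map_b.values) == 0:
        raise ValueError("rank correlation undefined for a constant map")
    rho = float(sps.spearmanr(map_a.values, map_b.values).statistic)
    nulls = np.array([
        sps.spearmanr(s.values, map_b.values).statistic
        for s in msr_surrogate_maps(map_a, weights, n_surr, seed=seed)])
    p = (1 + int(np.sum(np.abs(nulls) >= abs(rho)))) / (n_surr + 1)
    return SpatialCorrResult(rho, p, nulls)


def cross_species_gene_rank(per_species: pd.DataFrame,
                            zscore_before_average: bool = False
                            ) -> pd.Series:
    """Aggregate per-species gene-map correlations into a consensus ranking.

    Within each species (row), genes are ranked from most negative to most
    positive correlation; ranks are averaged across species, the averaged
    ranks are z-scored, and the final score is the z-score's magnitude, so
    genes extreme in either direction score high.  Returns scores sorted
    descending.  ``zscore_before_average`` switches to z-scoring each
    species' ranks before averaging (an alternative reading of the same
    recipe; the default applies the z-score after averaging).
    """
    if per_species.isna().any().any():
        raise ValueError("missing entries; filter to the common gene set first")
    ranks = per_species.rank(axis=1, method="average")
    if zscore_before_average:
        ranks = ranks.apply(
            lambda r: (r - r.mean()) / (r.std() if r.std() > 0 else 1.0),
            axis=1)
    avg = ranks.mean(axis=0)
    sd = avg.std()
    z = (avg - avg.mean()) / (sd if sd > 0 else 1.0)
    return z.abs().sort_values(ascending=False)


def sigmoid_normalize(m: RegionalMap) -> RegionalMap:
    """Squash a regional map into (0, 1): z-score then logistic.

    Rank order is preserved; the median of a symmetric map lands near 0.5.
    """
    v = m.values
    if np.ptp(v) == 0:
        raise ValueError("cannot sigmoid-normalize a constant map")
    z = (v - v.mean()) / v.std()
    return RegionalMap(1.0 / (1.0 + np.exp(-z)), list(m.labels),
                       normalized=True)


def fdr_bh(p_values) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values."""
    p = np.asarray(p_values, dtype=float).ravel()
    if p.size == 0:
        return p
    if np.any(p < 0) or np.any(p > 1) or not np.all(np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]
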