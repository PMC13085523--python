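"""Rank correlation of production rates against material/microbial variables.

Spearman's rank correlation (average ranks, tie-corrected) screens for
monotone associations between a response — typically the ethene production
rate — and material properties, biomarker abundances and other rates.
Significance is reported in the tiers p < 0.01, p < 0.05 and ns, using the
t approximation for n >= 8 complete pairs and exact permutation enumeration
below that (batch experiments rarely offer more than a handful of bottles,
where the t approximation is unreliable). Variables significantly
correlated with the response can then be passed to a standardized PCA
(eigendecomposition of their correlation matrix) to visualize
co-correlation structure.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import permutations

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "SpearmanResult",
    "PCAResult",
    "spearman_pair",
    "spearman_matrix",
    "pca_significant",
    "EXACT_P_MAX_N",
]

#: Below this many complete pairs the permutation null is enumerated exactly.
EXACT_P_MAX_N = 8

TIER_STRONG = "p<0.01"
TIER_WEAK = "p<0.05"
TIER_NS = "ns"
TIER_UNDEFINED = "undefined"

MIN_PAIRS = 4


def _rho_of_ranks(rx: np.ndarray, ry: np.ndarray) -> float:
    """Pearson correlation of two rank vectors (tie-corrected Spearman rho)."""
    rx = rx - rx.mean()
    ry = ry - ry.mean()
    denom = np.sqrt((rx**2).sum() * (ry**2).sum())
    if denom == 0:
        return float("nan")
    return float((rx * ry).sum() / denom)


def _exact_permutation_p(x: np.ndarray, y: np.ndarray, rho_obs: float) -> float:
    """Two-sided exact permutation p over all n! orderings of one variable."""
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    n = len(rx)
    hits = 0
    total = 0
    threshold = abs(rho_obs) - 1e-12
    for perm in permutations(range(n)):
        rho = _rho_of_ranks(rx, ry[list(perm)])
        total += 1
        if abs(rho) >= threshold:
            hits += 1
    return hits / total


@dataclass(frozen=True)
class SpearmanResult:
    rho: float
    p_value: float
    n: int
    tier: str


def spearman_pair(x, y) -> SpearmanResult:
    """Spearman rho and p for one pair of variables, NaNs dropped pairwise."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    mask = ~(np.isnan(x) | np.isnan(y))
    x, y = x[mask], y[mask]
    n = len(x)
    if n < MIN_PAIRS:
        raise ValueError(f"need >= {MIN_PAIRS} complete pairs, got {n}")
    if np.all(x == x[0]) or np.all(y == y[0]):
        return SpearmanResult(float("nan"), float("nan"), n, TIER_UNDEFINED)
    rho = float(stats.spearmanr(x, y).statistic)
    if n < EXACT_P_MAX_N:
        p = _exact_permutation_p(x, y, rho)
    else:
        # t approximation; |rho| = 1 degenerates to p = 0
        if abs(rho) >= 1.0:
            p = 0.0
        else:
            t = rho * np.sqrt((n - 2) / (1.0 - rho**2))
            p = float(2.0 * stats.t.sf(abs(t), n - 2))
    if p < 0.01:
        tier = TIER_STRONG
    elif p < 0.05:
        tier = TIER_WEAK
    else:
        tier = TIER_NS
    return SpearmanResult(rho, p, n, tier)


def spearman_matrix(
    table: pd.DataFrame,
    response: str | None = None,
    bh_correct: bool = False,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Full Spearman correlation matrix with p-values and significance tiers.

    ``table`` holds one observation per row (treatment × replicate or
    treatment means) and one numeric variable per column; missing values are
    dropped pairwise. Returns (rho, p, tier) DataFrames indexed by variable.
    ``response``, if given, must name a column (it is not treated specially
    beyond validation — slice the returned row for a response-vs-rest view).
    ``bh_correct=True`` applies Benjamini–Hochberg across the strict upper
    triangle before tiering (off by default; raw tiers are the convention).
    """
    cols = list(table.columns)
    if len(cols) != len(set(cols)):
        raise ValueError("column names must be unique")
    if response is not None and response not in cols:
        raise KeyError(f"response column {response!r} not in table")
    num = table.apply(pd.to_numeric, errors="raise")
    k = len(cols)
    rho = pd.DataFrame(np.eye(k), index=cols, columns=cols)
    pmat = pd.DataFrame(np.zeros((k, k)), index=cols, columns=cols)
    tier = pd.DataFrame("", index=cols, columns=cols)
    for i, a in enumerate(cols):
        tier.loc[a, a] = TIER_STRONG
        for b in cols[i + 1:]:
            res = spearman_pair(num[a].to_numpy(), num[b].to_numpy())
            rho.loc[a, b] = rho.loc[b, a] = res.rho
            pmat.loc[a, b] = pmat.loc[b, a] = res.p_value
            tier.loc[a, b] = tier.loc[b, a] = res.tier
    if bh_correct:
        iu = np.triu_indices(k, 1)
        raw = pmat.to_numpy()[iu]
        order = np.argsort(raw)
        m = len(raw)
        adj = np.empty(m)
        prev = 1.0
        for rank_idx in range(m - 1, -1, -1):
            idx = order[rank_idx]
            prev = min(prev, raw[idx] * m / (rank_idx + 1))
            adj[idx] = prev
        arr = pmat.to_numpy()
        arr[iu] = adj
        arr[(iu[1], iu[0])] = adj
        pmat = pd.DataFrame(arr, index=cols, columns=cols)
        for i, a in enumerate(cols):
            for b in cols[i + 1:]:
                if tier.loc[a, b] == TIER_UNDEFINED:
                    continue
                p = pmat.loc[a, b]
                t = TIER_STRONG if p < 0.01 else TIER_WEAK if p < 0.05 else TIER_NS
                tier.loc[a, b] = tier.loc[b, a] = t
    return rho, pmat, tier


@dataclass(frozen=True)
class PCAResult:
    """Standardized PCA restricted to response-significant variables."""

    variables: tuple[str, ...]
    scores: pd.DataFrame  # observations × components
    loadings: pd.DataFrame  # variables × components
    variance_explained: np.ndarray  # fractions, sum to 1

    @property
    def empty(self) -> bool:
        return len(self.variables) == 0


def pca_significant(
    table: pd.DataFrame, response: str, alpha: float = 0.05
) -> PCAResult:
    """PCA of the variables significantly Spearman-correlated with ``response``.

    Each selected variable is standardized to zero mean and unit variance;
    the eigendecomposition of their correlation matrix gives components
    ordered by decreasing variance explained. Sign convention: within each
    component the largest-magnitude loading is positive, making repeated
    runs bit-identical. Fewer than two significant variables yields an
    explicit empty result. Rows with missing values in the selected
    variables are dropped.
    """
    if response not in table.columns:
        raise KeyError(f"response column {response!r} not in table")
    significant = []
    for col in table.columns:
        if col == response:
            continue
        res = spearman_pair(table[response].to_numpy(dtype=float),
                            table[col].to_numpy(dtype=float))
        if res.tier in (TIER_STRONG, TIER_WEAK) and res.p_value < alpha:
            significant.append(col)
    if len(significant) < 2:
        return PCAResult(
            variables=(),
            scores=pd.DataFrame(),
            loadings=pd.DataFrame(),
            variance_explained=np.array([]),
        )
    sub = table[significant].astype(float).dropna()
    x = sub.to_numpy()
    std = x.std(axis=0, ddof=1)
    if np.any(std == 0):
        flat = [c for c, s in zip(significant, std) if s == 0]
        raise ValueError(f"constant variables cannot be standardized: {flat}")
    z = (x - x.mean(axis=0)) / std
    corr = np.corrcoef(z, rowvar=False)
    eigvals, eigvecs = np.linalg.eigh(corr)
    order = np.argsort(eigvals)[::-1]
    eigvals = np.clip(eigvals[order], 0.0, None)
    eigvecs = eigvecs[:, order]
    for j in range(eigvecs.shape[1]):
        lead = np.argmax(np.abs(eigvecs[:, j]))
        if eigvecs[lead, j] < 0:
            eigvecs[:, j] = -eigvecs[:, j]
    comp_names = [f"PC{i + 1}" for i in range(len(eigvals))]
    scores = pd.DataFrame(z @ eigvecs, index=sub.index, columns=comp_names)
    loadings = pd.DataFrame(eigvecs, index=significant, columns=comp_names)
    return PCAResult(
        variables=tuple(significant),
        scores=scores,
        loadings=loadings,
        variance_explained=eigvals / eigvals.sum(),
    )
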