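"""Group inference: covariate-adjusted permutation tests, paired tests,
BH-FDR, one-sample rich-club presence tests, NBS component inference and
partial correlations with Bonferroni families.

Covariate adjustment follows the Freedman-Lane scheme: the outcome is
regressed on the nuisance covariates, the residuals are permuted, refitted
and the group statistic recomputed, so the permutation distribution respects
the nuisance structure.  With no covariates this reduces exactly to the
classical two-sample permutation test (and is enumerated exhaustively when
the number of distinct group assignments does not exceed the requested
permutation count).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "PermTestResult",
    "NBSResult",
    "CorrelationResult",
    "perm_test_group",
    "paired_compare",
    "fdr_bh",
    "rich_club_presence",
    "nbs",
    "partial_correlation",
    "bonferroni_threshold",
]


@dataclass
class PermTestResult:
    stat: float
    p: float
    n_perm: int
    seed: int | None
    method: str
    covariates: list[str] = field(default_factory=list)
    exhaustive: bool = False
    warning: str | None = None


@dataclass
class NBSResult:
    primary_p: float
    edge_stats: np.ndarray
    edge_pvals: np.ndarray
    components: list[list[tuple[int, int]]]  # edge lists, largest first
    component_sizes: list[int]
    fwe_pvals: list[float]
    n_perm: int
    seed: int | None


@dataclass
class CorrelationResult:
    r: float
    p: float
    n: int
    covariates: list[str]
    family_size: int
    alpha_bonferroni: float

    @property
    def significant(self) -> bool:
        return self.p < self.alpha_bonferroni


def bonferroni_threshold(alpha: float, family_size: int) -> float:
    """Per-test threshold alpha / m (e.g. 0.05/27 = 0.00185, 0.05/4 = 0.0125)."""
    if family_size < 1:
        raise ValueError("family_size must be >= 1")
    return alpha / family_size


def _design(covariates: np.ndarray | None, n: int) -> np.ndarray:
    if covariates is None or (hasattr(covariates, "size") and covariates.size == 0):
        return np.ones((n, 1))
    z = np.atleast_2d(np.asarray(covariates, dtype=float))
    if z.shape[0] != n:
        z = z.T
    if z.shape[0] != n:
        raise ValueError("covariates must have one row per subject")
    z = np.column_stack([np.ones(n), z])
    if np.linalg.matrix_rank(z) < z.shape[1]:
        raise ValueError("rank-deficient covariate design")
    return z


def _residualize(y: np.ndarray, z: np.ndarray) -> np.ndarray:
    beta, *_ = np.linalg.lstsq(z, y, rcond=None)
    return y - z @ beta


def perm_test_group(
    values: np.ndarray,
    groups: np.ndarray,
    covariates: np.ndarray | None = None,
    n_perm: int = 10_000,
    seed: int = 0,
    stat: str = "mean_diff",
    covariate_names: list[str] | None = None,
) -> PermTestResult:
    """Two-group permutation test with optional covariate adjustment.

    ``groups`` is any two-level labeling; the statistic is the difference of
    covariate-adjusted group means (group 1 minus group 0 in sorted label
    order), or a two-sample t statistic when ``stat='t'``.  Two-tailed
    p-value with the (1+b)/(1+m) Monte-Carlo convention.
    """
    y = np.asarray(values, dtype=float)
    labels = np.asarray(groups)
    lev = np.unique(labels)
    if lev.size != 2:
        raise ValueError("exactly two groups required")
    g1 = labels == lev[1]
    n = y.size
    if g1.sum() < 2 or (~g1).sum() < 2:
        raise ValueError("each group needs >= 2 subjects")
    z = _design(covariates, n)
    # the group indicator must not be explainable by the covariates
    if np.linalg.norm(_residualize(g1.astype(float), z)) < 1e-10 * np.sqrt(n):
        raise ValueError("group indicator is collinear with the covariates")

    names = covariate_names or ([] if z.shape[1] == 1 else [f"cov{i}" for i in range(z.shape[1] - 1)])
    if np.ptp(y) == 0:
        return PermTestResult(0.0, 1.0, 0, seed, f"freedman_lane_{stat}", names,
                              warning="constant values")

    resid = _residualize(y, z)

    def stat_of(rows: np.ndarray) -> np.ndarray:
        """Statistic for each row of residualized data (rows x n)."""
        r1 = rows[:, g1]
        r0 = rows[:, ~g1]
        diff = r1.mean(axis=1) - r0.mean(axis=1)
        if stat == "mean_diff":
            return diff
        v = r1.var(axis=1, ddof=1) / r1.shape[1] + r0.var(axis=1, ddof=1) / r0.shape[1]
        return diff / np.sqrt(v)

    obs = float(stat_of(resid[None, :])[0])
    hat = z @ np.linalg.pinv(z)

    n1 = int(g1.sum())
    from math import comb

    exhaustive = z.shape[1] == 1 and comb(n, n1) <= n_perm
    if exhaustive:
        stats_perm = []
        centered = y - y.mean()
        for pick in combinations(range(n), n1):
            mask = np.zeros(n, bool)
            mask[list(pick)] = True
            d = centered[mask].mean() - centered[~mask].mean()
            if stat == "mean_diff":
                stats_perm.append(d)
            else:
                v = centered[mask].var(ddof=1) / n1 + centered[~mask].var(ddof=1) / (n - n1)
                stats_perm.append(d / np.sqrt(v))
        stats_perm = np.asarray(stats_perm)
        p = float(np.mean(np.abs(stats_perm) >= np.abs(obs) - 1e-12))
        return PermTestResult(obs, p, stats_perm.size, seed, f"exhaustive_{stat}", names, True)

    rng = np.random.default_rng(seed)
    # Freedman-Lane: permute reduced-model residuals, re-residualize, recompute
    chunk = max(1, min(n_perm, int(5e6 // max(n, 1))))
    count = 0
    done = 0
    while done < n_perm:
        m = min(chunk, n_perm - done)
        perms = np.argsort(rng.random((m, n)), axis=1)
        e = resid[perms]
        r = e - e @ hat.T
        count += int(np.sum(np.abs(stat_of(r)) >= np.abs(obs) - 1e-12))
        done += m
    p = (1 + count) / (1 + n_perm)
    return PermTestResult(obs, float(p), n_perm, seed, f"freedman_lane_{stat}", names)


def paired_compare(off: np.ndarray, on: np.ndarray, alpha_normal: float = 0.05) -> PermTestResult:
    """Paired OFF vs ON comparison with a normality gate.

    A one-sample Kolmogorov-Smirnov test (against a normal fitted to the
    paired differences) selects a paired t test when normality is not
    rejected at ``alpha_normal``, and a Wilcoxon signed-rank test otherwise.
    The statistic reported is the mean OFF-ON difference.
    """
    off = np.asarray(off, dtype=float)
    on = np.asarray(on, dtype=float)
    if off.shape != on.shape or off.size < 3:
        raise ValueError("need equal-length paired vectors with n >= 3")
    d = off - on
    if np.allclose(d, 0):
        return PermTestResult(0.0, 1.0, 0, None, "paired_degenerate", warning="all differences zero")
    sd = d.std(ddof=1)
    if sd == 0:
        # constant nonzero shift: ranks are all ties of one sign
        res = stats.wilcoxon(off, on)
        return PermTestResult(float(d.mean()), float(res.pvalue), 0, None, "wilcoxon_signed_rank")
    ks_p = stats.kstest((d - d.mean()) / sd, "norm").pvalue
    if ks_p > alpha_normal:
        res = stats.ttest_rel(off, on)
        return PermTestResult(float(d.mean()), float(res.pvalue), 0, None, "paired_t")
    res = stats.wilcoxon(off, on)
    return PermTestResult(float(d.mean()), float(res.pvalue), 0, None, "wilcoxon_signed_rank")


def fdr_bh(pvals: np.ndarray, q: float = 0.05) -> tuple[np.ndarray, float]:
    """Benjamini-Hochberg step-up; returns (rejection mask, p threshold)."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return np.zeros(0, dtype=bool), 0.0
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    reject, *_ = multipletests(p, alpha=q, method="fdr_bh")
    threshold = float(p[reject].max()) if reject.any() else 0.0
    return reject, threshold


def rich_club_presence(
    curves: np.ndarray, k_levels: np.ndarray, q: float = 0.05
) -> dict[str, np.ndarray]:
    """Per-k one-sided one-sample t test of phi_norm > 1 with FDR across k.

    ``curves`` is subjects x k levels, NaN marking undefined entries; levels
    with fewer than 3 finite values or zero variance are skipped.
    """
    curves = np.asarray(curves, dtype=float)
    n_k = curves.shape[1]
    tstat = np.full(n_k, np.nan)
    pval = np.full(n_k, np.nan)
    for j in range(n_k):
        col = curves[:, j]
        col = col[np.isfinite(col)]
        if col.size < 3 or col.std(ddof=1) == 0:
            continue
        res = stats.ttest_1samp(col, 1.0, alternative="greater")
        tstat[j], pval[j] = res.statistic, res.pvalue
    tested = np.isfinite(pval)
    reject = np.zeros(n_k, dtype=bool)
    if tested.any():
        reject[tested], _ = fdr_bh(pval[tested], q)
    return {"k": np.asarray(k_levels), "t": tstat, "p": pval, "reject_fdr": reject}


def _glm_group_t(y: np.ndarray, x: np.ndarray, g_col: int,
                 pinv: np.ndarray | None = None, var_g: float | None = None) -> np.ndarray:
    """t statistic of the group column of X for each column of Y."""
    n, p = x.shape
    if pinv is None:
        pinv = np.linalg.pinv(x)
    if var_g is None:
        var_g = np.linalg.inv(x.T @ x)[g_col, g_col]
    beta = pinv @ y
    resid = y - x @ beta
    dof = n - p
    sigma2 = np.sum(resid**2, axis=0) / dof
    with np.errstate(invalid="ignore", divide="ignore"):
        t = beta[g_col] / np.sqrt(sigma2 * var_g)
    return np.nan_to_num(t)


def _component_sizes(edges: list[tuple[int, int]]) -> tuple[dict[int, list[tuple[int, int]]], list[int]]:
    """Union-find over edge endpoints; returns components (by root) and edge counts."""
    parent: dict[int, int] = {}

    def find(v: int) -> int:
        while parent.setdefault(v, v) != v:
            parent[v] = parent[parent[v]]
            v = parent[v]
        return v

    for a, b in edges:
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[ra] = rb
    by_root: dict[int, list[tuple[int, int]]] = {}
    for e in edges:
        by_root.setdefault(find(e[0]), []).append(e)
    return by_root, [len(v) for v in by_root.values()]


def nbs(
    edge_values: np.ndarray,
    groups: np.ndarray,
    edge_index: list[tuple[int, int]],
    covariates: np.ndarray | None = None,
    primary_p: float = 0.05,
    n_perm: int = 5000,
    seed: int = 0,
) -> NBSResult:
    """Network-based statistic over a fixed edge set.

    Each edge is tested with a two-tailed GLM t test for the group effect
    (covariates adjusted); edges with p below ``primary_p`` form a graph
    whose connected components are scored by edge count against the
    permutation null distribution of the maximum component size
    (Freedman-Lane permutation of covariate residuals).
    """
    y = np.asarray(edge_values, dtype=float)
    labels = np.asarray(groups)
    lev = np.unique(labels)
    if lev.size != 2:
        raise ValueError("exactly two groups required")
    g = (labels == lev[1]).astype(float)
    n, m = y.shape
    if m != len(edge_index):
        raise ValueError("edge_index length must match edge_values columns")
    z = _design(covariates, n)
    x = np.column_stack([z, g])
    g_col = x.shape[1] - 1
    dof = n - x.shape[1]
    if dof < 1:
        raise ValueError("not enough subjects for the design")
    pinv_x = np.linalg.pinv(x)
    var_g = float(np.linalg.inv(x.T @ x)[g_col, g_col])
    # |t| cutoff equivalent to the two-tailed primary p threshold
    t_crit = np.inf if primary_p <= 0 else stats.t.isf(primary_p / 2, dof)

    def supra_components(tvals: np.ndarray) -> tuple[list[list[tuple[int, int]]], list[int]]:
        keep = np.flatnonzero(np.abs(tvals) > t_crit)
        if keep.size == 0:
            return [], []
        by_root, sizes = _component_sizes([edge_index[e] for e in keep])
        comps = sorted(by_root.values(), key=len, reverse=True)
        return comps, [len(c) for c in comps]

    t_obs = _glm_group_t(y, x, g_col, pinv_x, var_g)
    components, sizes = supra_components(t_obs)
    edge_p = 2 * stats.t.sf(np.abs(t_obs), dof)

    fwe = []
    if components:
        rng = np.random.default_rng(seed)
        beta0, *_ = np.linalg.lstsq(z, y, rcond=None)
        fitted0 = z @ beta0
        resid0 = y - fitted0
        max_sizes = np.zeros(n_perm, dtype=int)
        for b in range(n_perm):
            perm = rng.permutation(n)
            y_star = fitted0 + resid0[perm]
            t_star = _glm_group_t(y_star, x, g_col, pinv_x, var_g)
            _, s = supra_components(t_star)
            max_sizes[b] = max(s) if s else 0
        for size in sizes:
            fwe.append(float((1 + np.sum(max_sizes >= size)) / (1 + n_perm)))
    return NBSResult(primary_p, t_obs, edge_p, components, sizes, fwe, n_perm, seed)


def partial_correlation(
    x: np.ndarray,
    y: np.ndarray,
    covariates: np.ndarray | None = None,
    family_size: int = 1,
    alpha: float = 0.05,
    covariate_names: list[str] | None = None,
) -> CorrelationResult:
    """Partial Pearson correlation of x and y given covariates.

    Both variables are residualized on the covariates (with intercept); the
    p-value uses a t reference with n - 2 - c degrees of freedom.  The
    Bonferroni-adjusted per-test threshold ``alpha / family_size`` is
    attached to the result.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = x.size
    z = _design(covariates, n)
    c = z.shape[1] - 1
    dof = n - 2 - c
    if dof < 1:
        raise ValueError("insufficient degrees of freedom")
    rx = _residualize(x, z)
    ry = _residualize(y, z)
    denom = np.sqrt(np.sum(rx**2) * np.sum(ry**2))
    if denom == 0:
        warnings.warn("zero variance after residualization; r undefined, set to 0")
        return CorrelationResult(0.0, 1.0, n, covariate_names or [], family_size,
                                 bonferroni_threshold(alpha, family_size))
    r = float(np.clip(np.sum(rx * ry) / denom, -1.0, 1.0))
    if abs(r) == 1.0:
        p = 0.0
    else:
        t = r * np.sqrt(dof / (1 - r**2))
        p = float(2 * stats.t.sf(abs(t), dof))
    return CorrelationResult(r, p, n, covariate_names or [], family_size,
                             bonferroni_threshold(alpha, family_size))
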