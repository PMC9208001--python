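"""Independent brute-force oracles used across the test suite.

Everything here is written directly from first principles (explicit loops,
exhaustive enumeration) and never calls into hierconn, so each oracle is an
independent route to the quantity it checks.
"""

from __future__ import annotations

from itertools import combinations

import numpy as np


def pearson_matrix(ts: np.ndarray) -> np.ndarray:
    """Pairwise Pearson correlations by the textbook formula."""
    n = ts.shape[0]
    out = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            x, y = ts[i] - ts[i].mean(), ts[j] - ts[j].mean()
            out[i, j] = np.sum(x * y) / np.sqrt(np.sum(x**2) * np.sum(y**2))
    return out


def top_edges(weights: np.ndarray, n_keep: int) -> set[tuple[int, int]]:
    """The n_keep strongest positive upper-triangle edges via full sort."""
    n = weights.shape[0]
    ranked = sorted(
        ((i, j) for i in range(n) for j in range(i + 1, n) if weights[i, j] > 0),
        key=lambda e: (-weights[e], e[0], e[1]),
    )
    return set(ranked[:n_keep])


def degree_strength_tally(weights: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Edge-list tally of binary degree and strength."""
    n = weights.shape[0]
    deg = np.zeros(n, int)
    stren = np.zeros(n)
    for i in range(n):
        for j in range(n):
            if i != j and weights[i, j] > 0:
                deg[i] += 1
                stren[i] += weights[i, j]
    return deg, stren


def rich_club_curve(weights: np.ndarray) -> dict[int, float]:
    """phi_w(k) by exhaustive enumeration of the club and the top weights."""
    deg, _ = degree_strength_tally(weights)
    all_w = sorted(
        (weights[i, j] for i in range(len(weights)) for j in range(i + 1, len(weights))
         if weights[i, j] > 0),
        reverse=True,
    )
    out = {}
    for k in range(1, int(deg.max()) + 1):
        club = [i for i in range(len(weights)) if deg[i] > k]
        edges = [(i, j) for a, i in enumerate(club) for j in club[a + 1:] if weights[i, j] > 0]
        if len(club) < 2 or not edges:
            continue
        w_club = sum(weights[e] for e in edges)
        out[k] = w_club / sum(all_w[: len(edges)])
    return out


def participation(weights: np.ndarray, membership: np.ndarray) -> np.ndarray:
    """P_i by direct summation over communities (binary edge counts)."""
    n = weights.shape[0]
    out = np.zeros(n)
    for i in range(n):
        k = sum(1 for j in range(n) if j != i and weights[i, j] > 0)
        if k == 0:
            continue
        acc = 0.0
        for s in np.unique(membership):
            kis = sum(
                1 for j in range(n)
                if j != i and weights[i, j] > 0 and membership[j] == s
            )
            acc += (kis / k) ** 2
        out[i] = 1 - acc
    return out


def floyd_warshall_efficiency(weights: np.ndarray) -> float:
    """Global efficiency via Floyd-Warshall on lengths 1/w."""
    n = weights.shape[0]
    d = np.full((n, n), np.inf)
    np.fill_diagonal(d, 0.0)
    for i in range(n):
        for j in range(n):
            if i != j and weights[i, j] > 0:
                d[i, j] = 1.0 / weights[i, j]
    for m in range(n):
        for i in range(n):
            for j in range(n):
                if d[i, m] + d[m, j] < d[i, j]:
                    d[i, j] = d[i, m] + d[m, j]
    total = sum(
        1.0 / d[i, j]
        for i in range(n) for j in range(n)
        if i != j and np.isfinite(d[i, j])
    )
    return total / (n * (n - 1))


def modularity(weights: np.ndarray, membership: np.ndarray, resolution: float = 1.0) -> float:
    """Weighted Newman modularity by direct double sum."""
    two_m = weights.sum()
    if two_m == 0:
        return 0.0
    k = weights.sum(axis=1)
    q = 0.0
    n = weights.shape[0]
    for i in range(n):
        for j in range(n):
            if membership[i] == membership[j]:
                q += weights[i, j] - resolution * k[i] * k[j] / two_m
    return q / two_m


def best_partition_exhaustive(weights: np.ndarray) -> tuple[np.ndarray, float]:
    """Maximum-modularity partition by enumerating all set partitions (n <= 8)."""
    n = weights.shape[0]

    def partitions(elements):
        if not elements:
            yield []
            return
        first, rest = elements[0], elements[1:]
        for smaller in partitions(rest):
            for i, block in enumerate(smaller):
                yield smaller[:i] + [block + [first]] + smaller[i + 1:]
            yield [[first]] + smaller

    best_q, best_m = -np.inf, None
    for part in partitions(list(range(n))):
        membership = np.empty(n, int)
        for cid, block in enumerate(part):
            membership[block] = cid
        q = modularity(weights, membership)
        if q > best_q:
            best_q, best_m = q, membership
    return best_m, best_q


def subnetwork_tally(weights: np.ndarray, classes: np.ndarray) -> dict[str, float]:
    """Strengths, interactions and degree sums by edge-list tally."""
    n = weights.shape[0]
    out = {
        "strength_rich": 0.0, "strength_feeder": 0.0, "strength_peripheral": 0.0,
        "interaction_RF": 0.0, "interaction_FP": 0.0, "rich_peripheral": 0.0,
        "degsum_rich": 0.0, "degsum_feeder": 0.0, "degsum_peripheral": 0.0,
    }
    for i in range(n):
        for j in range(i + 1, n):
            w = weights[i, j]
            if w <= 0:
                continue
            pair = frozenset((classes[i], classes[j]))
            if pair == {"rich"}:
                out["strength_rich"] += w
            elif pair == {"feeder"}:
                out["strength_feeder"] += w
            elif pair == {"peripheral"}:
                out["strength_peripheral"] += w
            elif pair == {"rich", "feeder"}:
                out["interaction_RF"] += w
            elif pair == {"feeder", "peripheral"}:
                out["interaction_FP"] += w
            else:
                out["rich_peripheral"] += w
    deg = np.count_nonzero(weights, axis=1)
    for c in ("rich", "feeder", "peripheral"):
        out[f"degsum_{c}"] = float(deg[classes == c].sum())
    return out


def bh_stepup(pvals: np.ndarray, q: float) -> np.ndarray:
    """Benjamini-Hochberg by the literal step-up definition."""
    p = np.asarray(pvals, float)
    m = p.size
    order = np.argsort(p, kind="stable")
    k_star = 0
    for rank, idx in enumerate(order, start=1):
        if p[idx] <= rank * q / m:
            k_star = rank
    reject = np.zeros(m, bool)
    reject[order[:k_star]] = True
    return reject


def exhaustive_two_sample_p(values: np.ndarray, n1: int, observed_first_n1: bool = True) -> float:
    """Exhaustive two-sample permutation p for the mean-difference statistic.

    The observed grouping is the first n1 values vs the rest.
    """
    values = np.asarray(values, float)
    n = values.size
    obs = values[:n1].mean() - values[n1:].mean()
    stats_all = []
    for pick in combinations(range(n), n1):
        mask = np.zeros(n, bool)
        mask[list(pick)] = True
        stats_all.append(values[mask].mean() - values[~mask].mean())
    stats_all = np.asarray(stats_all)
    return float(np.mean(np.abs(stats_all) >= abs(obs) - 1e-12))


def wilcoxon_exact_p(d: np.ndarray) -> float:
    """Exact two-sided signed-rank p by enumerating all sign assignments."""
    d = np.asarray(d, float)
    assert np.all(d != 0)
    ranks = np.argsort(np.argsort(np.abs(d))) + 1.0
    w_obs = min(ranks[d > 0].sum(), ranks[d < 0].sum())
    n = d.size
    count = 0
    for signs in range(2**n):
        pos = np.array([(signs >> i) & 1 for i in range(n)], bool)
        w = min(ranks[pos].sum(), ranks[~pos].sum())
        if w <= w_obs + 1e-12:
            count += 1
    return count / 2**n


def partial_corr_two_stage(x: np.ndarray, y: np.ndarray, z: np.ndarray) -> float:
    """Partial correlation via two explicit OLS residualizations."""
    design = np.column_stack([np.ones(len(x)), z])
    bx, *_ = np.linalg.lstsq(design, x, rcond=None)
    by, *_ = np.linalg.lstsq(design, y, rcond=None)
    rx, ry = x - design @ bx, y - design @ by
    return float(np.sum(rx * ry) / np.sqrt(np.sum(rx**2) * np.sum(ry**2)))
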