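"""Independent brute-force oracles used only by the tests.

Each oracle recomputes a quantity by the most transparent method
available (triple-loop Floyd-Warshall, exhaustive triangle enumeration,
exhaustive partition search, exact label enumeration, normal equations)
and stays independent of the implementation paths it checks.
"""

from __future__ import annotations

from itertools import combinations

import numpy as np


def floyd_warshall(w: np.ndarray) -> np.ndarray:
    """All-pairs shortest paths with edge length 1/weight, by the
    classic k-relaxation."""
    n = w.shape[0]
    d = np.full((n, n), np.inf)
    np.fill_diagonal(d, 0.0)
    for i in range(n):
        for j in range(n):
            if i != j and w[i, j] > 0:
                d[i, j] = 1.0 / w[i, j]
    for k in range(n):
        for i in range(n):
            for j in range(n):
                if d[i, k] + d[k, j] < d[i, j]:
                    d[i, j] = d[i, k] + d[k, j]
    return d


def path_summaries(d: np.ndarray) -> dict[str, float]:
    """Path-length summaries recomputed from a distance matrix."""
    n = d.shape[0]
    pl, ecc = [], []
    inv_sum = 0.0
    for i in range(n):
        finite = [d[i, j] for j in range(n) if j != i and np.isfinite(d[i, j])]
        if finite:
            pl.append(sum(finite) / len(finite))
            ecc.append(max(finite))
        for j in range(n):
            if j != i and np.isfinite(d[i, j]):
                inv_sum += 1.0 / d[i, j]
    return {
        "characteristic_path_length": float(np.mean(pl)),
        "eccentricity": float(np.mean(ecc)),
        "radius": float(min(ecc)),
        "diameter": float(max(ecc)),
        "global_efficiency": inv_sum / (n * (n - 1)),
    }


def onnela_clustering(w: np.ndarray) -> tuple[float, float]:
    """Weighted clustering and transitivity by explicit triangle
    enumeration."""
    n = w.shape[0]
    wmax = w.max()
    if wmax == 0:
        return 0.0, 0.0
    what = (w / wmax) ** (1.0 / 3.0)
    ci = np.zeros(n)
    tri = np.zeros(n)
    k = (w > 0).sum(axis=1)
    for i in range(n):
        for j in range(n):
            for h in range(n):
                if i != j and i != h and j != h:
                    tri[i] += what[i, j] * what[i, h] * what[j, h]
        if k[i] >= 2:
            ci[i] = tri[i] / (k[i] * (k[i] - 1))
    denom = (k * (k - 1)).sum()
    transitivity = tri.sum() / denom if denom > 0 else 0.0
    return float(ci.mean()), float(transitivity)


def assortativity_longhand(w: np.ndarray) -> float:
    """Weighted degree assortativity as an explicit weighted Pearson
    correlation over the edge list, each edge listed in both
    orientations with its weight as frequency."""
    n = w.shape[0]
    deg = (w > 0).sum(axis=1).astype(float)
    xs, ys, ws = [], [], []
    for i in range(n):
        for j in range(i + 1, n):
            if w[i, j] > 0:
                xs += [deg[i], deg[j]]
                ys += [deg[j], deg[i]]
                ws += [w[i, j], w[i, j]]
    x, y, wt = np.array(xs), np.array(ys), np.array(ws)
    if len(x) < 4:
        return float("nan")
    mx = np.average(x, weights=wt)
    my = np.average(y, weights=wt)
    cov = np.average((x - mx) * (y - my), weights=wt)
    vx = np.average((x - mx) ** 2, weights=wt)
    vy = np.average((y - my) ** 2, weights=wt)
    if vx <= 1e-15 or vy <= 1e-15:
        return float("nan")
    return float(cov / np.sqrt(vx * vy))


def newman_q(w: np.ndarray, assignment: np.ndarray) -> float:
    """Weighted Newman modularity of one partition."""
    two_m = w.sum()
    k = w.sum(axis=1)
    b = w - np.outer(k, k) / two_m
    same = assignment[:, None] == assignment[None, :]
    return float((b * same).sum() / two_m)


def max_modularity_exhaustive(w: np.ndarray, max_blocks: int = 3) -> float:
    """Maximum Q over all assignments of nodes to at most ``max_blocks``
    labeled blocks (exhaustive; feasible to n ~ 12)."""
    n = w.shape[0]
    two_m = w.sum()
    k = w.sum(axis=1)
    b = w - np.outer(k, k) / two_m
    grids = np.indices((max_blocks,) * n).reshape(n, -1).T  # all assignments
    q = np.zeros(len(grids))
    for i in range(n):
        q += np.diag(b)[i]
        for j in range(i + 1, n):
            q += 2 * b[i, j] * (grids[:, i] == grids[:, j])
    return float(q.max() / two_m)


def mannwhitney_exact_p(x: np.ndarray, y: np.ndarray) -> float:
    """Two-sided Mann-Whitney p by exhaustive enumeration of all label
    assignments (no ties assumed): the fraction of assignments whose U
    is at least as far from n1*n2/2 as the observed U."""
    pooled = np.concatenate([x, y])
    n1, n2 = len(x), len(y)
    center = n1 * n2 / 2.0

    def u_stat(idx):
        xs = pooled[list(idx)]
        ys = np.delete(pooled, list(idx))
        return sum((xi > yi) + 0.5 * (xi == yi) for xi in xs for yi in ys)

    u_obs = u_stat(range(n1))
    count = total = 0
    for idx in combinations(range(n1 + n2), n1):
        total += 1
        if abs(u_stat(idx) - center) >= abs(u_obs - center) - 1e-12:
            count += 1
    return count / total


def partial_corr_recursion(x, y, z) -> float:
    """First-order partial correlation by the recursion formula
    r_xy.z = (r_xy - r_xz r_yz) / sqrt((1-r_xz^2)(1-r_yz^2))."""
    rxy = np.corrcoef(x, y)[0, 1]
    rxz = np.corrcoef(x, z)[0, 1]
    ryz = np.corrcoef(y, z)[0, 1]
    return float((rxy - rxz * ryz) / np.sqrt((1 - rxz**2) * (1 - ryz**2)))


def normal_equation_residuals(X: np.ndarray, C: np.ndarray) -> np.ndarray:
    """OLS residuals via explicitly solved normal equations."""
    n = X.shape[0]
    design = np.column_stack([np.ones(n), C])
    beta = np.linalg.solve(design.T @ design, design.T @ X)
    return X - design @ beta


def t_from_summary(m1, s1, n1, m2, s2, n2) -> float:
    """Pooled-variance two-sample t statistic from summary statistics."""
    sp2 = ((n1 - 1) * s1**2 + (n2 - 1) * s2**2) / (n1 + n2 - 2)
    return (m1 - m2) / np.sqrt(sp2 * (1.0 / n1 + 1.0 / n2))
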