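"""Independent brute-force oracles used to validate the implementation.

Everything here is deliberately naive — breadth-first search, explicit
neighbourhood scans, literal refits — and shares no code path with the
package.
"""

from __future__ import annotations

import itertools
from collections import deque

import numpy as np


def neighbour_offsets(connectivity: int) -> list[tuple[int, int, int]]:
    offs = []
    for d in itertools.product((-1, 0, 1), repeat=3):
        if d == (0, 0, 0):
            continue
        order = sum(abs(v) for v in d)
        if connectivity == 6 and order > 1:
            continue
        if connectivity == 18 and order > 2:
            continue
        offs.append(d)
    return offs


def bfs_components(mask: np.ndarray, connectivity: int) -> list[frozenset]:
    """Connected components of a 3D boolean mask via literal BFS flood fill."""
    offs = neighbour_offsets(connectivity)
    shape = mask.shape
    seen = np.zeros(shape, dtype=bool)
    comps = []
    for start in zip(*np.nonzero(mask)):
        if seen[start]:
            continue
        comp = set()
        queue = deque([start])
        seen[start] = True
        while queue:
            v = queue.popleft()
            comp.add(v)
            for d in offs:
                w = (v[0] + d[0], v[1] + d[1], v[2] + d[2])
                if all(0 <= w[i] < shape[i] for i in range(3)) and mask[w] and not seen[w]:
                    seen[w] = True
                    queue.append(w)
        comps.append(frozenset(comp))
    return comps


def partition_of_labels(labels: np.ndarray) -> set[frozenset]:
    out = set()
    for k in range(1, int(labels.max(initial=0)) + 1):
        voxels = frozenset(zip(*np.nonzero(labels == k)))
        if voxels:
            out.add(voxels)
    return out


def brute_force_opening(mask: np.ndarray, radius: int) -> np.ndarray:
    """Erosion then dilation with a discrete ball, by explicit scanning."""
    offs = [
        d
        for d in itertools.product(range(-radius, radius + 1), repeat=3)
        if sum(v * v for v in d) <= radius * radius
    ]
    shape = mask.shape

    def shift_ok(v, d):
        return all(0 <= v[i] + d[i] < shape[i] for i in range(3))

    eroded = np.zeros(shape, dtype=bool)
    for v in zip(*np.nonzero(mask)):
        if all(shift_ok(v, d) and mask[v[0] + d[0], v[1] + d[1], v[2] + d[2]] for d in offs):
            eroded[v] = True
    dilated = np.zeros(shape, dtype=bool)
    for v in zip(*np.nonzero(eroded)):
        for d in offs:
            if shift_ok(v, d):
                dilated[v[0] + d[0], v[1] + d[1], v[2] + d[2]] = True
    return dilated


def mwu_enumeration(a, b) -> tuple[float, float]:
    """Exhaustive-permutation Mann–Whitney: U by direct pair counting,
    two-sided p as the fraction of group assignments at least as extreme."""
    a = list(map(float, a))
    b = list(map(float, b))
    n1, n2 = len(a), len(b)
    pooled = a + b

    def u_stat(group_a):
        group_b = list(pooled)
        for v in group_a:
            group_b.remove(v)
        u = 0.0
        for x in group_a:
            for y in group_b:
                if x > y:
                    u += 1.0
                elif x == y:
                    u += 0.5
        return u

    mu = n1 * n2 / 2.0
    dev_obs = abs(u_stat(a) - mu)
    extreme = total = 0
    for combo in itertools.combinations(range(n1 + n2), n1):
        ga = [pooled[i] for i in combo]
        total += 1
        if abs(u_stat(ga) - mu) >= dev_obs - 1e-12:
            extreme += 1
    return u_stat(a), extreme / total


def bh_stepup_by_hand(p_values):
    """BH q-values computed from the literal step-up definition."""
    p = list(map(float, p_values))
    m = len(p)
    order = sorted(range(m), key=lambda i: p[i])
    q = [0.0] * m
    running = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, p[i] * m / rank)
        q[i] = running
    return q


def loo_refit_diagnostics(X: np.ndarray, y: np.ndarray):
    """Literal leave-one-out Cook's D, leverage and standardized DFBETAS."""
    n, p = X.shape
    beta_full, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta_full
    mse = float(resid @ resid) / (n - p)
    xtx_inv = np.linalg.inv(X.T @ X)
    hat = np.einsum("ij,jk,ik->i", X, xtx_inv, X)
    cooks = np.zeros(n)
    dfbetas = np.zeros((n, p))
    for i in range(n):
        keep = np.ones(n, dtype=bool)
        keep[i] = False
        beta_i, *_ = np.linalg.lstsq(X[keep], y[keep], rcond=None)
        diff = beta_full - beta_i
        cooks[i] = float(diff @ (X.T @ X) @ diff) / (p * mse)
        resid_i = y[keep] - X[keep] @ beta_i
        s2_i = float(resid_i @ resid_i) / (n - 1 - p)
        dfbetas[i] = diff / np.sqrt(s2_i * np.diag(xtx_inv))
    return cooks, hat, dfbetas


def partial_from_precision(table: np.ndarray, i: int, j: int) -> float:
    """Partial correlation of columns i, j given all others, from the
    inverse of the Spearman (rank) correlation matrix."""
    from scipy.stats import rankdata

    ranks = np.column_stack([rankdata(table[:, k]) for k in range(table.shape[1])])
    corr = np.corrcoef(ranks, rowvar=False)
    prec = np.linalg.inv(corr)
    return float(-prec[i, j] / np.sqrt(prec[i, i] * prec[j, j]))
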